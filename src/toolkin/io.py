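"""File formats, pipeline orchestration, configuration and provenance.

All interchange formats are plain delimited text so that inputs and outputs
stay transparent and diff-able:

- ``trajectories`` — long table ``trial_id, t, x, y, z`` (seconds, meters);
  blank/NaN coordinates mark missing (occluded) frames; a ``frame`` column
  may replace ``t`` and is converted as ``frame / sample_rate``;
- ``events`` — one row per trial with the six annotated event times;
- ``meta`` — one row per trial: participant, site, stimulation type, pulse
  onset, run/order labels and (optionally) the two performance scores;
- ``outcomes`` — one row per trial of boolean outcome flags, from which the
  scores are recomputed when provided;
- ``features`` — output table: trial keys plus the 22 kinematic parameters.

Units are fixed (meters, seconds, Hz; no unit auto-detection — millimeter
exports must be converted with ``position_scale``). Every analysis parameter
defaults to the published constant (0.42 s smoothing, 0.05 m/s activity and
prominence thresholds, VIF cap 5, selection alpha 0.10). Trials that cannot
be preprocessed are excluded with a logged reason, never silently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .kinematics import (
    ACTIVITY_THRESHOLD,
    FEATURE_NAMES,
    PEAK_PROMINENCE,
    extract_features,
)
from .phases import EventError, TrialEvents, segment
from .preprocess import (
    DEFAULT_MAX_GAP_S,
    DEFAULT_SMOOTHING_WINDOW_S,
    PreprocessError,
    Trajectory,
    preprocess_trajectory,
)
from .scoring import TrialOutcome, score_anova, score_production, score_selection
from .stimclassify import (
    SELECTION_ALPHA,
    VIF_CAP,
    ModelInputError,
    binarize_timepoint,
    classify_stim_type,
    site_discrimination_check,
)

logger = logging.getLogger("toolkin")

EVENT_COLUMNS = (
    "t_signal", "t_move", "t_toolcontact", "t_grasped", "t_cylcontact", "t_lift"
)
OUTCOME_COLUMNS = (
    "correct_tool_selected", "self_corrections", "goal_achieved",
    "tool_grasped", "tool_moved_to_cylinder", "tool_attached",
)
META_COLUMNS = (
    "trial_id", "participant", "site", "stim_type", "pulse_onset",
    "run", "order_group", "selection", "production",
)


@dataclass
class RunConfig:
    """Paths and analysis parameters for a full pipeline run."""

    trajectories: str = "trajectories.csv"
    events: str = "events.csv"
    meta: str = "meta.csv"
    outcomes: str = None  # optional; scores recomputed from it when present
    output_dir: str = "toolkin_out"
    sample_rate: float = 100.0
    position_scale: float = 1.0  # multiply coordinates (e.g. 0.001 for mm files)
    smoothing_window: float = DEFAULT_SMOOTHING_WINDOW_S
    max_gap: float = DEFAULT_MAX_GAP_S
    activity_threshold: float = ACTIVITY_THRESHOLD
    prominence: float = PEAK_PROMINENCE
    vif_cap: float = VIF_CAP
    alpha: float = SELECTION_ALPHA
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            logger.warning("ignoring unknown config keys: %s", sorted(unknown))
        return cls(**{k: v for k, v in raw.items() if k in known})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# --- readers / writers -----------------------------------------------------

def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def read_trajectories(
    path, sample_rate: float = 100.0, position_scale: float = 1.0
) -> dict[str, Trajectory]:
    """Load per-trial trajectories from a delimited long table.

    Requires columns ``trial_id``, ``x``, ``y``, ``z`` and either ``t``
    (seconds) or ``frame`` (converted as frame / sample_rate). Rows with any
    blank coordinate become missing frames. Timestamp uniformity at the
    stated rate is validated per trial.
    """
    df = _read_table(path)
    cols = set(df.columns)
    if "trial_id" not in cols or not {"x", "y", "z"} <= cols:
        raise ValueError(f"{path}: need columns trial_id, x, y, z (+ t or frame)")
    if "t" not in cols:
        if "frame" not in cols:
            raise ValueError(f"{path}: need a 't' or 'frame' column")
        df = df.assign(t=df["frame"].astype(float) / sample_rate)
    extra = cols - {"trial_id", "t", "frame", "x", "y", "z"}
    if extra:
        logger.warning("%s: ignoring unknown columns %s", path, sorted(extra))
    out: dict[str, Trajectory] = {}
    for tid, g in df.groupby("trial_id", sort=False):
        g = g.sort_values("t")
        p = g[["x", "y", "z"]].to_numpy(dtype=float) * position_scale
        out[str(tid)] = Trajectory(
            t=g["t"].to_numpy(dtype=float),
            p=p,
            sample_rate=sample_rate,
            trial_id=str(tid),
        )
    return out


def write_trajectories(path, trajectories: dict[str, Trajectory]) -> None:
    frames = []
    for tid, traj in trajectories.items():
        p = traj.p.copy()
        p[traj.missing] = np.nan
        frames.append(
            pd.DataFrame({"trial_id": tid, "t": traj.t, "x": p[:, 0], "y": p[:, 1], "z": p[:, 2]})
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_events(path) -> dict[str, TrialEvents]:
    df = _read_table(path)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: events table lacks columns {sorted(missing)}")
    return {
        str(r["trial_id"]): TrialEvents(**{c: float(r[c]) for c in EVENT_COLUMNS})
        for _, r in df.iterrows()
    }


def write_events(path, events: dict[str, TrialEvents]) -> None:
    rows = [
        {"trial_id": tid, **{c: getattr(ev, c) for c in EVENT_COLUMNS}}
        for tid, ev in events.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_outcomes(path) -> dict[str, TrialOutcome]:
    df = _read_table(path)
    missing = set(OUTCOME_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: outcomes table lacks columns {sorted(missing)}")
    out = {}
    for _, r in df.iterrows():
        kwargs = {c: bool(r[c]) for c in OUTCOME_COLUMNS if c != "self_corrections"}
        kwargs["self_corrections"] = int(r["self_corrections"])
        out[str(r["trial_id"])] = TrialOutcome(**kwargs)
    return out


def write_outcomes(path, outcomes: dict[str, TrialOutcome]) -> None:
    rows = [
        {"trial_id": tid, **{c: getattr(o, c) for c in OUTCOME_COLUMNS}}
        for tid, o in outcomes.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_meta(path) -> pd.DataFrame:
    df = _read_table(path)
    need = {"trial_id", "participant", "site", "stim_type", "pulse_onset"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"{path}: meta table lacks columns {sorted(missing)}")
    df["trial_id"] = df["trial_id"].astype(str)
    return df.set_index("trial_id", drop=False)


# --- in-memory pipeline stages ---------------------------------------------

def compute_features_table(
    trajectories: dict[str, Trajectory],
    events: dict[str, TrialEvents],
    smoothing_window: float = DEFAULT_SMOOTHING_WINDOW_S,
    max_gap: float = DEFAULT_MAX_GAP_S,
    activity_threshold: float = ACTIVITY_THRESHOLD,
    prominence: float = PEAK_PROMINENCE,
) -> tuple[pd.DataFrame, list[dict]]:
    """Run preprocessing, segmentation and feature extraction per trial.

    Returns the feature table (rows indexed by trial id, columns the 22
    parameters) and the exclusion list: trials whose trajectory or events
    could not be used, each with a reason.
    """
    rows = {}
    exclusions: list[dict] = []
    for tid, traj in trajectories.items():
        ev = events.get(tid)
        if ev is None:
            exclusions.append({"trial_id": tid, "reason": "no events annotated"})
            continue
        try:
            filled, profile = preprocess_trajectory(
                traj, window=smoothing_window, max_gap=max_gap
            )
            windows = segment(filled, ev)
            rows[tid] = extract_features(
                filled, profile, windows,
                activity_threshold=activity_threshold, prominence=prominence,
            )
        except (PreprocessError, EventError, ValueError) as exc:
            exclusions.append({"trial_id": tid, "reason": str(exc)})
    for exc in exclusions:
        logger.warning("excluded trial %s: %s", exc["trial_id"], exc["reason"])
    feats = pd.DataFrame(rows).T
    if not feats.empty:
        feats = feats[list(FEATURE_NAMES)]
    feats.index.name = "trial_id"
    return feats, exclusions


def simulated_to_tables(trials) -> tuple[dict, dict, pd.DataFrame, dict]:
    """Unpack a simulated dataset into the pipeline's input structures."""
    trajs = {tr.meta.trial_id: tr.trajectory for tr in trials}
    events = {tr.meta.trial_id: tr.events for tr in trials}
    outcomes = {tr.meta.trial_id: tr.meta.outcome for tr in trials}
    meta = pd.DataFrame(
        [
            {
                "trial_id": tr.meta.trial_id,
                "participant": tr.meta.participant,
                "site": tr.meta.site,
                "stim_type": tr.meta.stim_type,
                "timepoint": tr.meta.timepoint,
                "pulse_onset": tr.meta.pulse_onset,
                "run": tr.meta.run,
                "order_group": tr.meta.order_group,
                "selection": tr.meta.selection,
                "production": tr.meta.production,
            }
            for tr in trials
        ]
    ).set_index("trial_id", drop=False)
    return trajs, events, meta, outcomes


def analyze_study(
    features: pd.DataFrame,
    meta: pd.DataFrame,
    vif_cap: float = VIF_CAP,
    alpha: float = SELECTION_ALPHA,
    run_anova: bool = True,
) -> dict:
    """The study-level statistical analysis on a completed feature table.

    Binarizes the stimulation timepoint with one global median split, runs
    the sham-only site-discrimination model, then — per its verdict — either
    one pooled or two per-site verum/sham classification models, plus the two
    score ANOVAs. Returns a dict of reports.
    """
    meta = meta.loc[features.index].copy()
    tp, cutoff = binarize_timepoint(meta["pulse_onset"].to_numpy())
    meta["timepoint"] = tp
    results: dict = {"timepoint_cutoff": cutoff}

    site_report, per_site = site_discrimination_check(
        features, meta, vif_cap=vif_cap, alpha=alpha, timepoint=tp
    )
    results["site_check"] = site_report
    results["per_site_required"] = per_site

    models = {}
    if per_site:
        for site in np.unique(meta["site"]):
            m = meta["site"].to_numpy() == site
            models[str(site)] = classify_stim_type(
                features.loc[m], meta.loc[m], vif_cap=vif_cap, alpha=alpha,
                timepoint=tp[m],
            )
    else:
        models["pooled"] = classify_stim_type(
            features, meta, vif_cap=vif_cap, alpha=alpha, timepoint=tp
        )
    results["type_models"] = models

    if run_anova and {"selection", "production"} <= set(meta.columns):
        anovas = {}
        for score in ("selection", "production"):
            try:
                anovas[score] = score_anova(
                    meta.rename(columns={score: "score"}), value="score"
                )
            except ValueError as exc:
                logger.warning("score ANOVA (%s) skipped: %s", score, exc)
        results["score_anovas"] = anovas
    return results


# --- full disk pipeline ----------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """End-to-end run from input files to artifacts on disk.

    Writes the feature table, score tables, ANOVA reports, the sham-only
    site-check report, the classification model report(s), ROC polylines and
    a provenance log (config hash, counts and reasons of excluded trials).
    Returns the in-memory results dict.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    trajs = read_trajectories(
        config.trajectories, sample_rate=config.sample_rate,
        position_scale=config.position_scale,
    )
    events = read_events(config.events)
    meta = read_meta(config.meta)

    if config.outcomes:
        outcomes = read_outcomes(config.outcomes)
        meta["selection"] = [
            score_selection(outcomes[t]) if t in outcomes else np.nan for t in meta.index
        ]
        meta["production"] = [
            score_production(outcomes[t]) if t in outcomes else np.nan for t in meta.index
        ]
    if not {"selection", "production"} <= set(meta.columns):
        raise ValueError("scores missing: provide them in meta or via an outcomes file")

    feats, exclusions = compute_features_table(
        trajs, events,
        smoothing_window=config.smoothing_window, max_gap=config.max_gap,
        activity_threshold=config.activity_threshold, prominence=config.prominence,
    )
    known = feats.index.intersection(meta.index)
    for tid in feats.index.difference(meta.index):
        exclusions.append({"trial_id": tid, "reason": "no metadata row"})
    feats = feats.loc[known]

    feat_out = meta.loc[known, ["participant", "site", "stim_type"]].join(feats)
    feat_out.to_csv(outdir / "features.csv")

    results = analyze_study(feats, meta.loc[known], vif_cap=config.vif_cap, alpha=config.alpha)

    reports = {
        "site_check": results["site_check"].to_dict(),
        "per_site_required": results["per_site_required"],
        "timepoint_cutoff": results["timepoint_cutoff"],
        "type_models": {k: v.to_dict() for k, v in results["type_models"].items()},
    }
    (outdir / "model_reports.json").write_text(json.dumps(reports, indent=2))
    results["site_check"].roc.to_csv(outdir / "roc_site_check.csv", index=False)
    for name, model in results["type_models"].items():
        model.roc.to_csv(outdir / f"roc_type_{name}.csv", index=False)
    if results.get("score_anovas"):
        anova_json = {k: v.to_dict("records") for k, v in results["score_anovas"].items()}
        (outdir / "score_anova.json").write_text(json.dumps(anova_json, indent=2))

    cfg = config.to_dict()
    provenance = {
        "package_version": _pkg_version,
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "n_trials_read": len(trajs),
        "n_trials_analyzed": int(len(feats)),
        "n_excluded": len(exclusions),
        "exclusions": exclusions,
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    results["exclusions"] = exclusions
    results["features"] = feats
    return results
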