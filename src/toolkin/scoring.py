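"""Performance scoring, inter-rater agreement and the score ANOVAs.

Each trial's outcome is annotated with a small set of boolean flags (which
tool was taken, how far execution got, whether the cylinder was lifted). Two
scores summarise a trial:

- **selection** (0/1): 1 point for picking the proper tool (at most one
  self-correction), or — even with the wrong tool — for achieving the final
  goal of lifting the cylinder out of its socket;
- **production** (0-3): 3 for complete task execution, 2 for grasping the
  tool and moving it to the cylinder without attaching it, 1 for grasping
  without moving it there, 0 for doing nothing.

Scores are averaged per participant and condition cell and analysed with a
mixed ANOVA (stimulation site between participants; stimulation type and
binarized stimulation timepoint within). Inter-rater agreement between two
independent video raters is quantified with unweighted Cohen's kappa.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("toolkin")


@dataclass(frozen=True)
class TrialOutcome:
    """Annotated outcome flags of one trial.

    The execution flags are monotone: achieving the goal implies attaching
    the tool, which implies moving it to the cylinder, which implies grasping.
    """

    correct_tool_selected: bool
    self_corrections: int
    goal_achieved: bool
    tool_grasped: bool
    tool_moved_to_cylinder: bool
    tool_attached: bool

    def __post_init__(self) -> None:
        if self.self_corrections < 0:
            raise ValueError("self_corrections must be >= 0")
        chain = (
            self.goal_achieved,
            self.tool_attached,
            self.tool_moved_to_cylinder,
            self.tool_grasped,
        )
        for earlier, later in zip(chain, chain[1:]):
            if earlier and not later:
                raise ValueError(f"inconsistent outcome flags: {self}")


@dataclass(frozen=True)
class ScorePair:
    selection: int
    production: int

    def __post_init__(self) -> None:
        if self.selection not in (0, 1):
            raise ValueError("selection score must be 0 or 1")
        if self.production not in (0, 1, 2, 3):
            raise ValueError("production score must be in 0..3")


def score_selection(outcome: TrialOutcome) -> int:
    """0/1 tool-selection score (one self-correction tolerated; goal rescues)."""
    if outcome.correct_tool_selected and outcome.self_corrections <= 1:
        return 1
    if outcome.goal_achieved:
        return 1
    return 0


def score_production(outcome: TrialOutcome) -> int:
    """0-3 production score, resolved top-down (3 before 2 before 1)."""
    if outcome.goal_achieved:
        return 3
    if outcome.tool_moved_to_cylinder:
        return 2
    if outcome.tool_grasped:
        return 1
    return 0


def score_trial(outcome: TrialOutcome) -> ScorePair:
    return ScorePair(score_selection(outcome), score_production(outcome))


def cohens_kappa(ratings_a, ratings_b, conf_level: float = 0.95):
    """Unweighted Cohen's kappa with a large-sample confidence interval.

    Returns ``(kappa, (lo, hi))``. The standard error is the simple
    large-sample form ``sqrt(po (1 - po) / (n (1 - pe)^2))``.
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.size == 0 or a.shape != b.shape:
        raise ValueError("ratings must be equal-length non-empty vectors")
    cats = np.union1d(a, b)
    n = a.size
    po = float(np.mean(a == b))
    pa = np.array([np.mean(a == c) for c in cats])
    pb = np.array([np.mean(b == c) for c in cats])
    pe = float(pa @ pb)
    if pe >= 1.0:  # both raters constant and identical
        return 1.0, (1.0, 1.0)
    kappa = (po - pe) / (1.0 - pe)
    se = math.sqrt(po * (1.0 - po) / (n * (1.0 - pe) ** 2))
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    return kappa, (kappa - z * se, kappa + z * se)


# --- mixed ANOVA on participant-averaged scores ---------------------------

_CELLS = (("sham", "early"), ("sham", "late"), ("verum", "early"), ("verum", "late"))


def _cell_means(scores: pd.DataFrame, value: str) -> pd.DataFrame:
    """Average a trial-level score per participant x (type, timepoint) cell.

    Participants missing any of the four cells are dropped with a warning
    (listwise exclusion). Returns one row per participant with the four cell
    means plus the participant's site.
    """
    req = {"participant", "site", "stim_type", "timepoint", value}
    missing = req - set(scores.columns)
    if missing:
        raise ValueError(f"score table lacks columns: {sorted(missing)}")
    g = (
        scores.groupby(["participant", "site", "stim_type", "timepoint"], observed=True)[value]
        .mean()
        .unstack(["stim_type", "timepoint"])
    )
    want = pd.MultiIndex.from_tuples(_CELLS)
    g = g.reindex(columns=want)
    bad = g.index[g.isna().any(axis=1)]
    if len(bad):
        logger.warning(
            "score ANOVA: excluding %d participant(s) missing a condition cell: %s",
            len(bad), [b[0] for b in bad],
        )
        g = g.drop(index=bad)
    g = g.reset_index()
    g.columns = ["participant", "site"] + [f"{t}_{tp}" for t, tp in _CELLS]
    return g


def _f_from_contrast(y: np.ndarray, site_code: np.ndarray):
    """Type-III F tests of the intercept and site slope in y ~ 1 + site.

    ``site_code`` is effect-coded (+0.5 / -0.5) so the intercept is the
    unweighted mean of the two site-group means. Returns two
    (F, df1, df2, p, partial eta^2) tuples: the within-effect test (intercept)
    and its interaction with site (slope).
    """
    n = y.size
    X = np.column_stack([np.ones(n), site_code])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sse = float(resid @ resid)
    df2 = n - 2
    xtx_inv = np.linalg.inv(X.T @ X)
    mse = sse / df2 if df2 > 0 else np.nan
    # zero-variance data: every F is 0 by convention (flagged via p = 1)
    degenerate = sse <= 1e-18 * max(1.0, float(y @ y))
    out = []
    for j in (0, 1):
        if degenerate or df2 <= 0:
            out.append((0.0 if degenerate else np.nan, 1, df2, 1.0, 0.0))
            continue
        ss_eff = beta[j] ** 2 / xtx_inv[j, j]
        F = ss_eff / mse
        p = float(stats.f.sf(F, 1, df2))
        eta = ss_eff / (ss_eff + sse)
        out.append((float(F), 1, df2, p, float(eta)))
    return out


def score_anova(scores: pd.DataFrame, value: str = "score") -> pd.DataFrame:
    """Mixed ANOVA of a score: site between; type and timepoint within.

    ``scores`` is trial-level (or cell-level) with columns ``participant``,
    ``site``, ``stim_type`` (sham/verum), ``timepoint`` (early/late) and the
    score column. All three factors have two levels, so every effect is
    tested as a participant-level contrast regressed on the (effect-coded)
    site factor, giving the classical F(1, n_participants - 2) tests.

    Returns a table with F, df, p and partial eta squared for the seven
    effects (three mains, three two-way interactions, one three-way).
    """
    cells = _cell_means(scores, value)
    if len(cells) < 3:
        raise ValueError("need at least 3 complete participants for the ANOVA")
    sites = np.sort(cells["site"].unique())
    if sites.size != 2:
        raise ValueError(f"expected exactly 2 sites, got {list(sites)}")
    code = np.where(cells["site"].to_numpy() == sites[0], 0.5, -0.5)
    c = {f"{t}_{tp}": cells[f"{t}_{tp}"].to_numpy(dtype=float) for t, tp in _CELLS}

    # participant-level contrast scores (2-level factors)
    y_mean = sum(c.values()) / 4.0
    y_type = (c["verum_early"] + c["verum_late"] - c["sham_early"] - c["sham_late"]) / 2.0
    y_tp = (c["sham_late"] + c["verum_late"] - c["sham_early"] - c["verum_early"]) / 2.0
    y_int = c["verum_late"] - c["verum_early"] - c["sham_late"] + c["sham_early"]

    rows = []
    # between-participants factor: one-way test on participant means
    _, site_test = _f_from_contrast(y_mean, code)
    rows.append(("site",) + site_test)
    for name, y in (("stim_type", y_type), ("timepoint", y_tp), ("stim_type:timepoint", y_int)):
        within, inter = _f_from_contrast(y, code)
        rows.append((name,) + within)
        rows.append((f"{name}:site",) + inter)
    table = pd.DataFrame(
        rows, columns=["effect", "F", "df1", "df2", "p", "partial_eta_sq"]
    )
    order = [
        "site", "stim_type", "timepoint", "stim_type:site", "timepoint:site",
        "stim_type:timepoint", "stim_type:timepoint:site",
    ]
    return table.set_index("effect").loc[order].reset_index()
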