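"""Interaction logistic models classifying stimulation type and site.

The analysis asks whether a trial's kinematic fingerprint carries information
about the stimulation it received. Pulse-onset latency is binarized at its
empirical median into early/late; every kinematic parameter is z-scored and
enters the candidate set three ways: as a main column and as two
*per-timepoint slope* columns (feature x early, feature x late). This coding
deliberately departs from classical main-effect + interaction coding because
the scientific question is whether a feature predicts stimulation *within*
early-stimulated and *within* late-stimulated trials, possibly with opposite
signs — both slopes must be estimable in the same final model.

Model reduction is a deterministic two-phase backward selection:

1. **collinearity phase** — while any variance inflation factor (VIF) is at
   or above the cap (default 5), drop the column with the highest VIF (the
   per-timepoint coding makes each main column the exact sum of its two
   slope columns, so this phase always removes one member of each such
   dependent triple);
2. **significance phase** — refit the logistic model and drop the
   highest-p term while any Wald p-value is at or above alpha (default 0.10).

The final model is reported with coefficients, odds ratios (reference
categories: sham for stimulation type, early for timepoint), VIFs, an
in-sample ROC/AUC with a DeLong 95% CI, and a likelihood-ratio test against
the intercept-only null. A sham-only model discriminating the two
stimulation sites decides whether type classification must branch per site.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .kinematics import FEATURE_NAMES

logger = logging.getLogger("toolkin")

VIF_CAP = 5.0
SELECTION_ALPHA = 0.10

#: Labels used throughout: reference category first.
STIM_TYPES = ("sham", "verum")
TIMEPOINTS = ("early", "late")
SITES = ("aSMG", "vPreCG")


class ModelInputError(ValueError):
    """Raised for degenerate modeling inputs (one class, one site, ...)."""


@dataclass
class ModelReport:
    """Fitted classification model summary.

    ``terms`` has one row per retained predictor with beta, SE, p, OR and the
    final-design VIF. ``trace`` records every column dropped during backward
    selection (step, column, reason, value). ``roc`` is the ROC polyline with
    the Youden-optimal threshold flagged.
    """

    outcome: str
    terms: pd.DataFrame
    auc: float
    auc_ci: tuple[float, float]
    lrt_chi2: float
    lrt_df: int
    lrt_p: float
    n_trials: int
    trace: pd.DataFrame
    roc: pd.DataFrame
    fitted_prob: np.ndarray = field(repr=False, default=None)
    intercept: float = np.nan

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "n_trials": int(self.n_trials),
            "intercept": float(self.intercept),
            "terms": self.terms.reset_index().rename(columns={"index": "term"}).to_dict("records"),
            "auc": float(self.auc),
            "auc_ci": [float(self.auc_ci[0]), float(self.auc_ci[1])],
            "lrt": {"chi2": float(self.lrt_chi2), "df": int(self.lrt_df), "p": float(self.lrt_p)},
            "selection_trace": self.trace.to_dict("records"),
        }


# --- timepoint binarization ------------------------------------------------

def binarize_timepoint(pulse_onsets) -> tuple[np.ndarray, float]:
    """Median-split pulse-onset latencies into early/late labels.

    The cutoff is the empirical median of the analysis set (recomputed from
    the data at hand, never a hard-coded constant); onsets strictly below the
    cutoff are "early", the rest "late". Raises on a degenerate split (all
    onsets identical).
    """
    x = np.asarray(pulse_onsets, dtype=float)
    if x.size < 2:
        raise ModelInputError("need at least 2 trials for a median split")
    cutoff = float(np.median(x))
    if np.all(x == x[0]):
        raise ModelInputError("all pulse onsets identical — median split degenerate")
    labels = np.where(x < cutoff, "early", "late")
    return labels, cutoff


# --- design matrix ---------------------------------------------------------

def build_design(
    features: pd.DataFrame,
    timepoint: np.ndarray,
    selection: np.ndarray = None,
    production: np.ndarray = None,
) -> pd.DataFrame:
    """Candidate predictor matrix: scaled features, scores, timepoint, slopes.

    ``features`` holds the 22 kinematic parameters (rows = trials). Every
    continuous predictor is z-scored within the analysis set. Columns:

    - one z-scored main column per kinematic parameter,
    - ``selection`` and ``production`` scores (z-scored),
    - ``timepoint_late`` indicator (early = reference),
    - per-timepoint slopes ``<feature>:early`` and ``<feature>:late``.

    Zero-variance predictors are dropped with a warning before modeling.
    """
    n = len(features)
    tp = np.asarray(timepoint)
    late = (tp == "late").astype(float)
    early = 1.0 - late
    cols: dict[str, np.ndarray] = {}
    dropped: list[str] = []

    def add_scaled(name: str, x: np.ndarray) -> np.ndarray | None:
        x = np.asarray(x, dtype=float)
        sd = x.std(ddof=0)
        if sd == 0 or not np.isfinite(sd):
            dropped.append(name)
            return None
        z = (x - x.mean()) / sd
        cols[name] = z
        return z

    zs = {}
    for name in features.columns:
        z = add_scaled(name, features[name].to_numpy())
        if z is not None:
            zs[name] = z
    if selection is not None:
        add_scaled("selection", selection)
    if production is not None:
        add_scaled("production", production)
    cols["timepoint_late"] = late
    for name, z in zs.items():
        cols[f"{name}:early"] = z * early
        cols[f"{name}:late"] = z * late
    if dropped:
        logger.warning("zero-variance predictors dropped: %s", dropped)
    X = pd.DataFrame(cols, index=features.index)
    # interaction columns can be constant if one timepoint class is (almost) absent
    const = [c for c in X.columns if X[c].std(ddof=0) == 0]
    if const:
        logger.warning("constant design columns dropped: %s", const)
        X = X.drop(columns=const)
    return X


# --- VIF -------------------------------------------------------------------

def compute_vifs(X: np.ndarray) -> np.ndarray:
    """Variance inflation factors via the inverse correlation matrix.

    Equivalent to the classical per-column OLS auxiliary regressions
    (VIF_j = 1 / (1 - R^2_j)) but computed in one shot. Columns involved in
    an exact linear dependency receive ``inf``.
    """
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    sd[sd == 0] = 1.0
    Z = Xc / sd
    R = (Z.T @ Z) / len(Z)
    p = R.shape[0]
    if p == 1:
        return np.ones(1)
    eigvals, eigvecs = np.linalg.eigh(R)
    vifs = np.full(p, np.inf)
    if eigvals[0] > 1e-10:
        vifs = np.diag(np.linalg.inv(R)).copy()
    else:
        # exact dependency: flag the columns loading on the null space
        null_load = np.abs(eigvecs[:, eigvals < 1e-10]).max(axis=1)
        ok = null_load < 1e-8
        if ok.any():
            sub = np.ix_(ok, ok)
            Rok = R[sub]
            if np.linalg.eigvalsh(Rok)[0] > 1e-10:
                vifs[ok] = np.diag(np.linalg.inv(Rok))
    return vifs


def _null_space_drop(X: np.ndarray, involved: np.ndarray) -> int:
    """Among exactly dependent columns, pick the one loading most on the
    null space of the correlation matrix (e.g. a total that equals the sum
    of its parts, or a main effect equal to the sum of its slope terms)."""
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    sd[sd == 0] = 1.0
    Z = Xc / sd
    R = (Z.T @ Z) / len(Z)
    eigvals, eigvecs = np.linalg.eigh(R)
    null = eigvecs[:, eigvals < 1e-10]
    if null.size == 0:  # numerical borderline; fall back to first involved
        return int(np.flatnonzero(involved)[0])
    load = np.abs(null).max(axis=1)
    load[~involved] = -1.0
    return int(np.argmax(load))


def _vif_phase(X: pd.DataFrame, cap: float, trace: list[dict]) -> pd.DataFrame:
    step = len(trace)
    while X.shape[1] > 1:
        vifs = compute_vifs(X.to_numpy())
        if np.isinf(vifs).any():
            worst = _null_space_drop(X.to_numpy(), np.isinf(vifs))
        else:
            worst = int(np.argmax(vifs))
        if vifs[worst] < cap:
            break
        col = X.columns[worst]
        trace.append(
            {"step": step, "column": col, "reason": "vif",
             "value": float(vifs[worst]) if np.isfinite(vifs[worst]) else float("inf")}
        )
        X = X.drop(columns=[col])
        step += 1
    return X


# --- logistic fitting ------------------------------------------------------

def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    """Fit a logistic model with intercept; returns the statsmodels result.

    Returns None if the fit fails to converge (quasi-separation etc.).
    """
    Xc = sm.add_constant(X.to_numpy(), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(method="newton", maxiter=50, disp=0)
        except Exception:
            try:
                res = sm.Logit(y, Xc).fit(method="bfgs", maxiter=200, disp=0)
            except Exception:
                return None
    if not np.all(np.isfinite(res.params)) or not np.all(np.isfinite(res.bse)):
        return None
    return res


def _null_llf(y: np.ndarray) -> float:
    p = y.mean()
    if p in (0.0, 1.0):
        return 0.0
    n1 = y.sum()
    n0 = y.size - n1
    return float(n1 * np.log(p) + n0 * np.log(1 - p))


def backward_select(
    X: pd.DataFrame,
    y: np.ndarray,
    outcome_name: str = "outcome",
    vif_cap: float = VIF_CAP,
    alpha: float = SELECTION_ALPHA,
) -> ModelReport:
    """Two-phase backward selection (VIF first, then Wald p) on a logistic model.

    Deterministic: ties resolve to the earliest column. Non-converging fits
    (separation) drop the column with the largest \\|coefficient\\| and are
    logged in the trace. If nothing survives, an intercept-only report is
    returned with a warning.
    """
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ModelInputError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ModelInputError("outcome has a single class")
    trace: list[dict] = []
    X = _vif_phase(X.copy(), vif_cap, trace)

    res = None
    while X.shape[1] > 0:
        res = _fit_logit(y, X)
        if res is None:
            coefs = _ridge_coef_magnitude(y, X)
            worst = int(np.argmax(coefs))
            trace.append(
                {"step": len(trace), "column": X.columns[worst],
                 "reason": "separation", "value": float(coefs[worst])}
            )
            X = X.drop(columns=[X.columns[worst]])
            continue
        pvals = res.pvalues[1:]  # skip intercept
        worst = int(np.argmax(pvals))
        if pvals[worst] < alpha:
            break
        trace.append(
            {"step": len(trace), "column": X.columns[worst],
             "reason": "p", "value": float(pvals[worst])}
        )
        X = X.drop(columns=[X.columns[worst]])
        res = None

    trace_df = pd.DataFrame(trace, columns=["step", "column", "reason", "value"])
    ll0 = _null_llf(y)
    if X.shape[1] == 0 or res is None:
        logger.warning("backward selection retained no predictors; intercept-only model")
        p0 = np.full(y.size, y.mean())
        roc = pd.DataFrame({"fpr": [0.0, 1.0], "tpr": [0.0, 1.0], "threshold": [np.inf, -np.inf],
                            "youden": [False, False]})
        return ModelReport(
            outcome=outcome_name,
            terms=pd.DataFrame(columns=["beta", "se", "p", "OR", "vif"]),
            auc=0.5, auc_ci=(0.5, 0.5),
            lrt_chi2=0.0, lrt_df=0, lrt_p=1.0,
            n_trials=y.size, trace=trace_df, roc=roc,
            fitted_prob=p0, intercept=float(np.log(y.mean() / (1 - y.mean()))),
        )

    beta = res.params[1:]
    terms = pd.DataFrame(
        {
            "beta": beta,
            "se": res.bse[1:],
            "p": res.pvalues[1:],
            "OR": np.exp(beta),
            "vif": compute_vifs(X.to_numpy()),
        },
        index=list(X.columns),
    )
    prob = res.predict()
    auc, ci = delong_auc_ci(prob, y)
    roc = roc_polyline(prob, y)
    chi2 = max(0.0, 2.0 * (res.llf - ll0))
    df = X.shape[1]
    return ModelReport(
        outcome=outcome_name,
        terms=terms,
        auc=auc, auc_ci=ci,
        lrt_chi2=chi2, lrt_df=df, lrt_p=float(stats.chi2.sf(chi2, df)) if df else 1.0,
        n_trials=int(y.size), trace=trace_df, roc=roc,
        fitted_prob=prob, intercept=float(res.params[0]),
    )


def _ridge_coef_magnitude(y: np.ndarray, X: pd.DataFrame) -> np.ndarray:
    """|coefficients| of a lightly ridge-regularized logistic fit.

    Used only to pick which column to blame when the unpenalized fit
    separates; the ridge keeps the coefficients finite.
    """
    Xc = sm.add_constant(X.to_numpy(), has_constant="add")
    beta = np.zeros(Xc.shape[1])
    lam = 1e-2
    for _ in range(25):
        eta = Xc @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        Wd = mu * (1 - mu) + 1e-12
        H = (Xc * Wd[:, None]).T @ Xc + lam * np.eye(Xc.shape[1])
        g = Xc.T @ (y - mu) - lam * beta
        try:
            beta = beta + np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
    return np.abs(beta[1:])


# --- ROC / AUC -------------------------------------------------------------

def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """Empirical AUC via the Mann-Whitney identity (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ModelInputError("AUC needs both classes present")
    ranks = stats.rankdata(scores)  # midranks
    r_pos = ranks[labels == 1].sum()
    n1, n0 = pos.size, neg.size
    return float((r_pos - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def delong_auc_ci(
    scores: np.ndarray, labels: np.ndarray, conf_level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """AUC with the DeLong asymptotic confidence interval.

    Uses the structural-components estimator of the AUC variance for a
    single correlated ROC curve; the CI is normal-theory, clipped to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ModelInputError("AUC needs both classes present")
    m, n = pos.size, neg.size
    # midrank structural components
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n  # per-positive components
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m  # per-negative components
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return auc, (max(0.0, auc - half), min(1.0, auc + half))


def roc_polyline(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Empirical ROC polyline with the Youden-optimal point flagged."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(labels, scores)
    youden = np.zeros(fpr.size, dtype=bool)
    youden[int(np.argmax(tpr - fpr))] = True
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr, "youden": youden})


def lrt_vs_null(llf_model: float, llf_null: float, df: int) -> tuple[float, int, float]:
    """Likelihood-ratio test of a fitted model against the intercept-only null."""
    chi2 = 2.0 * (llf_model - llf_null)
    if chi2 < -1e-8:
        raise ValueError("model log-likelihood below the null — models not nested?")
    chi2 = max(0.0, chi2)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return chi2, df, p


# --- top-level analyses ----------------------------------------------------

def classify_stim_type(
    features: pd.DataFrame,
    meta: pd.DataFrame,
    vif_cap: float = VIF_CAP,
    alpha: float = SELECTION_ALPHA,
    timepoint: np.ndarray = None,
) -> ModelReport:
    """Verum-vs-sham model on one analysis set (typically one site's trials).

    ``meta`` rows align with ``features`` and carry ``stim_type``,
    ``pulse_onset``, ``selection``, ``production``. Predictor scaling is
    within this analysis set; the early/late labels default to a median
    split of this set's pulse onsets but can be supplied (e.g. one global
    split shared by all models, as in the study).
    """
    if timepoint is None:
        tp, _ = binarize_timepoint(meta["pulse_onset"].to_numpy())
    else:
        tp = np.asarray(timepoint)
    X = build_design(
        features,
        tp,
        selection=meta["selection"].to_numpy(),
        production=meta["production"].to_numpy(),
    )
    y = (meta["stim_type"].to_numpy() == "verum").astype(float)
    return backward_select(X, y, outcome_name="stim_type", vif_cap=vif_cap, alpha=alpha)


def site_discrimination_check(
    features: pd.DataFrame,
    meta: pd.DataFrame,
    vif_cap: float = VIF_CAP,
    alpha: float = SELECTION_ALPHA,
    timepoint: np.ndarray = None,
) -> tuple[ModelReport, bool]:
    """Sham-only model discriminating the two stimulation sites.

    Runs the same selection machinery with site as the outcome, restricted to
    sham trials. Returns the report and a flag: when the AUC confidence
    interval excludes 0.5 the kinematics are site-dependent and downstream
    type classification must be run per site.
    """
    sham = meta["stim_type"].to_numpy() == "sham"
    msub = meta.loc[sham]
    fsub = features.loc[sham]
    counts = msub["site"].value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ModelInputError(
            f"need >= 2 sham trials per site for the discrimination check; got {counts.to_dict()}"
        )
    if timepoint is None:
        tp, _ = binarize_timepoint(msub["pulse_onset"].to_numpy())
    else:
        tp = np.asarray(timepoint)[sham]
    X = build_design(
        fsub,
        tp,
        selection=msub["selection"].to_numpy(),
        production=msub["production"].to_numpy(),
    )
    y = (msub["site"].to_numpy() == SITES[1]).astype(float)  # aSMG = reference
    report = backward_select(X, y, outcome_name="site", vif_cap=vif_cap, alpha=alpha)
    lo, hi = report.auc_ci
    per_site_required = bool(lo > 0.5 or hi < 0.5)
    return report, per_site_required
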