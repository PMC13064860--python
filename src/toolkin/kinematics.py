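"""The 22 phase-wise kinematic parameters of one reach-to-grasp-and-use trial.

Six parameter families, computed per phase on the smoothed speed profile
(raw positions for pathlength):

- **PD** phase duration (s) — GoCue, Reaching, Preparing, Using, Total;
- **MV** maximum velocity (m/s) — Reaching, Preparing, Using;
- **TVP** timepoint of the velocity peak as % of phase duration — same phases;
- **PL** 3D pathlength (m) — same phases;
- **NP** velocity peaks per meter (prominence >= 0.05 m/s) — the three
  movement phases and the total trial;
- **RA** relative activity, % of samples with speed > 0.05 m/s — the three
  movement phases and the total trial.

Higher PL and NP indicate less efficient / less smooth movement; RA indexes
how continuously the hand is in motion; TVP > 50% means a late speed peak
(short deceleration), TVP < 50% an early peak (long deceleration).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .phases import PhaseWindows
from .preprocess import SpeedProfile, Trajectory

logger = logging.getLogger("toolkin")

#: Speed above which the hand counts as "active" (m/s).
ACTIVITY_THRESHOLD = 0.05
#: Minimum topographic prominence for a velocity peak (m/s).
PEAK_PROMINENCE = 0.05

#: Canonical order of the 22 features in every output table.
FEATURE_NAMES = (
    "PD_GoCue", "PD_Reach", "PD_Prep", "PD_Use", "PD_Total",
    "MV_Reach", "MV_Prep", "MV_Use",
    "TVP_Reach", "TVP_Prep", "TVP_Use",
    "PL_Reach", "PL_Prep", "PL_Use",
    "NP_Reach", "NP_Prep", "NP_Use", "NP_Total",
    "RA_Reach", "RA_Prep", "RA_Use", "RA_Total",
)

_PHASE_KEY = {"Reaching": "Reach", "Preparing": "Prep", "Using": "Use"}


def phase_duration(window: tuple[int, int], sample_rate: float) -> float:
    """Duration of a half-open sample window in seconds (n_samples / rate)."""
    lo, hi = window
    if hi - lo < 1:
        raise ValueError("empty phase window")
    return (hi - lo) / sample_rate


def relative_activity(
    v_smooth: np.ndarray,
    window: tuple[int, int],
    threshold: float = ACTIVITY_THRESHOLD,
) -> float:
    """Percent of in-window samples with smoothed speed strictly above threshold."""
    lo, hi = window
    if hi - lo < 1:
        raise ValueError("empty phase window")
    v = v_smooth[lo:hi]
    return 100.0 * float(np.count_nonzero(v > threshold)) / v.size


def pathlength(p: np.ndarray, window: tuple[int, int]) -> float:
    """Sum of Euclidean distances between consecutive in-window positions (m)."""
    lo, hi = window
    if hi - lo < 1:
        raise ValueError("empty phase window")
    seg = p[lo:hi]
    if seg.shape[0] < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(seg, axis=0), axis=1).sum())


def count_velocity_peaks(
    v_smooth: np.ndarray,
    window: tuple[int, int],
    prominence: float = PEAK_PROMINENCE,
) -> int:
    """Local maxima of the smoothed speed with prominence >= ``prominence``.

    Prominence is evaluated within the window only, so peaks near the phase
    boundaries use the window edges as bases.
    """
    lo, hi = window
    v = v_smooth[lo:hi]
    if v.size < 3:
        return 0
    peaks, _ = find_peaks(v, prominence=prominence)
    return int(peaks.size)


def peaks_per_meter(
    v_smooth: np.ndarray,
    window: tuple[int, int],
    pl: float,
    prominence: float = PEAK_PROMINENCE,
) -> float:
    """Velocity-peak count divided by the phase pathlength (peaks/m).

    A zero pathlength yields 0 with a warning (nothing was traversed, so a
    per-meter rate is undefined).
    """
    n = count_velocity_peaks(v_smooth, window, prominence)
    if pl <= 0.0:
        if n:
            logger.warning("velocity peaks found but pathlength is 0; NP set to 0")
        return 0.0
    return n / pl


def max_velocity(
    v_smooth: np.ndarray, window: tuple[int, int], sample_rate: float
) -> tuple[float, float]:
    """Maximum smoothed speed in the window and its timing.

    Returns ``(MV, TVP)`` where TVP is the offset of the (earliest) argmax
    from the window start as a percentage of the phase duration.
    """
    lo, hi = window
    if hi - lo < 1:
        raise ValueError("empty phase window")
    v = v_smooth[lo:hi]
    i = int(np.argmax(v))  # earliest index on ties
    mv = float(v[i])
    tvp = 100.0 * i / v.size  # i/rate over (n/rate)
    return mv, tvp


def extract_features(
    traj: Trajectory,
    profile: SpeedProfile,
    windows: PhaseWindows,
    activity_threshold: float = ACTIVITY_THRESHOLD,
    prominence: float = PEAK_PROMINENCE,
) -> pd.Series:
    """Compute the full 22-parameter feature vector for one trial.

    ``traj`` must be gap-free (interpolated) and ``profile`` smoothed; all
    three inputs must describe the same trial. Returns a Series indexed by
    :data:`FEATURE_NAMES`.
    """
    if profile.v_smooth is None:
        raise ValueError("speed profile must be smoothed before feature extraction")
    if traj.missing.any():
        raise ValueError("trajectory still has missing samples")
    if traj.n_samples != profile.v_raw.size:
        raise ValueError("trajectory and speed profile length mismatch")
    rate = traj.sample_rate
    v = profile.v_smooth
    out: dict[str, float] = {}
    out["PD_GoCue"] = phase_duration(windows.gocue, rate)
    for phase in ("Reaching", "Preparing", "Using"):
        key = _PHASE_KEY[phase]
        win = windows[phase]
        out[f"PD_{key}"] = phase_duration(win, rate)
        mv, tvp = max_velocity(v, win, rate)
        out[f"MV_{key}"] = mv
        out[f"TVP_{key}"] = tvp
        pl = pathlength(traj.p, win)
        out[f"PL_{key}"] = pl
        out[f"NP_{key}"] = peaks_per_meter(v, win, pl, prominence)
        out[f"RA_{key}"] = relative_activity(v, win, activity_threshold)
    total = windows.total
    out["PD_Total"] = phase_duration(total, rate)
    pl_total = pathlength(traj.p, total)
    out["NP_Total"] = peaks_per_meter(v, total, pl_total, prominence)
    out["RA_Total"] = relative_activity(v, total, activity_threshold)
    return pd.Series([out[k] for k in FEATURE_NAMES], index=list(FEATURE_NAMES), name=traj.trial_id)
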