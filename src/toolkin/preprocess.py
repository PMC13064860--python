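"""Turn raw, possibly gappy 3D marker positions into a smoothed speed profile.

The processing chain mirrors standard optical motion-capture practice for a
single hand marker sampled at a fixed rate (100 Hz by default):

1. short dropouts (occluded frames) are filled per coordinate with a local
   cubic polynomial fitted to the valid samples flanking each gap;
2. the scalar speed profile is the Euclidean distance between consecutive
   positions times the sample rate (forward difference);
3. the speed series is smoothed with a 0.42-s loess filter (local quadratic
   regression with tricube weights).

Pathlength-type metrics are computed downstream from the *unsmoothed*
positions, so the identity  sum(v_raw) * dt == raw pathlength  holds exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger("toolkin")

#: Default loess span in seconds (full window width).
DEFAULT_SMOOTHING_WINDOW_S = 0.42
#: Longest dropout run that interpolation will attempt to bridge, in seconds.
DEFAULT_MAX_GAP_S = 0.5
#: Valid samples used on each side of a gap for the cubic fit.
GAP_FIT_SUPPORT = 4


class PreprocessError(ValueError):
    """Raised for unusable trajectories (leading/trailing or oversized gaps)."""


@dataclass
class Trajectory:
    """Uniformly sampled 3D position series for one trial.

    Attributes
    ----------
    t : (n,) float array, seconds, strictly increasing with constant step.
    p : (n, 3) float array, meters. Finite wherever ``missing`` is False.
    missing : (n,) bool array marking dropped (occluded) frames.
    sample_rate : sampling frequency in Hz.
    trial_id : identifier used in error messages and output tables.
    """

    t: np.ndarray
    p: np.ndarray
    missing: np.ndarray = None
    sample_rate: float = 100.0
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.missing is None:
            self.missing = ~np.isfinite(self.p).all(axis=1)
        self.missing = np.asarray(self.missing, dtype=bool)
        n = self.t.size
        if self.p.shape != (n, 3):
            raise ValueError(f"p must be (n, 3); got {self.p.shape} for n={n}")
        if self.missing.shape != (n,):
            raise ValueError("missing mask length mismatch")
        if n >= 2:
            dt = np.diff(self.t)
            if not np.allclose(dt, 1.0 / self.sample_rate, rtol=0, atol=1e-6 / self.sample_rate):
                raise ValueError("time stamps are not uniform at the stated sample rate")
        if n and (self.missing[0] or self.missing[-1]):
            raise PreprocessError(
                f"trial {self.trial_id!r}: first/last sample missing — cannot anchor interpolation"
            )
        if not np.isfinite(self.p[~self.missing]).all():
            raise ValueError("non-missing positions must be finite")

    @property
    def n_samples(self) -> int:
        return self.t.size


@dataclass
class SpeedProfile:
    """Raw and smoothed scalar speed for one trial (same grid as the source)."""

    t: np.ndarray
    v_raw: np.ndarray
    v_smooth: np.ndarray = None
    sample_rate: float = 100.0
    smoothing_window: float = 0.0  # seconds; 0 until smooth_speed is applied
    trial_id: str = ""


def _missing_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous runs of True in ``mask`` as half-open (start, stop) pairs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(int)))
    return list(zip(idx[0::2], idx[1::2]))


def interpolate_gaps(
    traj: Trajectory,
    max_gap: float = DEFAULT_MAX_GAP_S,
    support: int = GAP_FIT_SUPPORT,
) -> Trajectory:
    """Fill dropout runs with local cubic polynomials.

    Each gap is bridged per coordinate by a cubic fitted (least squares) to the
    ``support`` nearest valid samples on each side. Non-missing samples are
    returned unchanged. Gaps longer than ``max_gap`` seconds, or touching the
    first/last sample, raise :class:`PreprocessError` naming the trial.
    """
    if not traj.missing.any():
        return traj
    p = traj.p.copy()
    t = traj.t
    valid = np.flatnonzero(~traj.missing)
    for start, stop in _missing_runs(traj.missing):
        gap_s = (stop - start) / traj.sample_rate
        if gap_s > max_gap:
            raise PreprocessError(
                f"trial {traj.trial_id!r}: gap of {gap_s:.3f} s "
                f"(samples {start}-{stop - 1}) exceeds the {max_gap} s cap"
            )
        left = valid[valid < start][-support:]
        right = valid[valid >= stop][:support]
        sup = np.concatenate([left, right])
        # center/scale time for conditioning
        t0 = t[start]
        ts = (t[sup] - t0) * traj.sample_rate
        tg = (t[start:stop] - t0) * traj.sample_rate
        deg = min(3, sup.size - 1)
        V = np.vander(ts, deg + 1, increasing=True)
        coef, *_ = np.linalg.lstsq(V, p[sup], rcond=None)  # all 3 coords at once
        p[start:stop] = np.vander(tg, deg + 1, increasing=True) @ coef
    out = replace(traj, p=p, missing=np.zeros_like(traj.missing))
    return out


def compute_speed(traj: Trajectory) -> SpeedProfile:
    """Euclidean forward-difference speed, assigned to the leading sample.

    ``v_raw[i] = ||p[i+1] - p[i]|| * sample_rate`` for ``i < n-1``; the last
    value is replicated so the profile keeps the trajectory's length and
    ``sum(v_raw[:-1]) / sample_rate`` equals the raw pathlength exactly.
    """
    if traj.missing.any():
        raise PreprocessError(f"trial {traj.trial_id!r}: interpolate gaps before computing speed")
    if traj.n_samples < 2:
        raise PreprocessError(f"trial {traj.trial_id!r}: need at least 2 samples for a speed profile")
    step = np.linalg.norm(np.diff(traj.p, axis=0), axis=1)
    v = np.empty(traj.n_samples)
    v[:-1] = step * traj.sample_rate
    v[-1] = v[-2]
    return SpeedProfile(
        t=traj.t, v_raw=v, sample_rate=traj.sample_rate, trial_id=traj.trial_id
    )


def _loess_quadratic(t: np.ndarray, y: np.ndarray, window: int) -> np.ndarray:
    """Degree-2 loess with tricube weights over the ``window`` nearest samples.

    On a uniform grid the nearest-k neighbourhood of sample ``i`` is the
    contiguous window of length ``window`` containing ``i``, clamped at the
    series ends. All local weighted quadratic fits are solved in one batched
    3x3 normal-equation solve.
    """
    n = y.size
    half = (window - 1) // 2
    starts = np.clip(np.arange(n) - half, 0, n - window)
    cols = starts[:, None] + np.arange(window)[None, :]  # (n, w) neighbour indices
    u = t[cols] - t[:, None]  # local abscissa, centred on the fit point
    d = np.abs(u)
    dmax = d.max(axis=1, keepdims=True)
    w = (1.0 - (d / dmax) ** 3) ** 3  # tricube
    # weighted quadratic fit via the normal equations, assembled from the
    # weighted moments sum(w u^k) and sum(w u^k y), k = 0..4
    wu = w * u
    wu2 = wu * u
    yw = y[cols]
    s0 = w.sum(axis=1)
    s1 = wu.sum(axis=1)
    s2 = wu2.sum(axis=1)
    s3 = (wu2 * u).sum(axis=1)
    s4 = (wu2 * u * u).sum(axis=1)
    t0 = (w * yw).sum(axis=1)
    t1 = (wu * yw).sum(axis=1)
    t2 = (wu2 * yw).sum(axis=1)
    ata = np.empty((n, 3, 3))
    ata[:, 0, 0] = s0
    ata[:, 0, 1] = ata[:, 1, 0] = s1
    ata[:, 0, 2] = ata[:, 2, 0] = ata[:, 1, 1] = s2
    ata[:, 1, 2] = ata[:, 2, 1] = s3
    ata[:, 2, 2] = s4
    atb = np.stack([t0, t1, t2], axis=1)
    beta = np.linalg.solve(ata, atb[:, :, None])[:, :, 0]
    return beta[:, 0]  # fitted value at u = 0


def smooth_speed(
    profile: SpeedProfile, window: float = DEFAULT_SMOOTHING_WINDOW_S
) -> SpeedProfile:
    """Smooth ``v_raw`` with a loess filter of ``window`` seconds (full width).

    Local quadratic regression with tricube weights over the
    ``round(window * sample_rate)`` nearest samples; fitted values below zero
    are clipped to zero (speed is nonnegative by definition).
    """
    w = int(round(window * profile.sample_rate))
    if w < 4:
        raise PreprocessError(
            f"smoothing window of {window} s spans only {w} samples at "
            f"{profile.sample_rate} Hz; need >= 4 for a local quadratic fit"
        )
    w = min(w, profile.v_raw.size)
    if w < 4:
        raise PreprocessError("profile too short for quadratic smoothing")
    v_smooth = _loess_quadratic(profile.t, profile.v_raw, w)
    np.clip(v_smooth, 0.0, None, out=v_smooth)
    return SpeedProfile(
        t=profile.t,
        v_raw=profile.v_raw,
        v_smooth=v_smooth,
        sample_rate=profile.sample_rate,
        smoothing_window=window,
        trial_id=profile.trial_id,
    )


def preprocess_trajectory(
    traj: Trajectory,
    window: float = DEFAULT_SMOOTHING_WINDOW_S,
    max_gap: float = DEFAULT_MAX_GAP_S,
) -> tuple[Trajectory, SpeedProfile]:
    """Convenience chain: interpolate gaps, compute speed, smooth."""
    filled = interpolate_gaps(traj, max_gap=max_gap)
    return filled, smooth_speed(compute_speed(filled), window=window)
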