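"""Synthetic reach-to-grasp-and-use trials with injectable stimulation effects.

Real trials consist of a stationary Go-Cue dwell (button pressed, planning),
a reach to the chosen tool, a transport/preparation segment bringing the tool
to the cylinder, and a use segment attaching the tool and lifting the
cylinder. No raw motion data are deposited for the study this package
re-implements, so this module generates trials with the statistical structure
the downstream analysis assumes:

- one marker (base of the left index finger) sampled at 100 Hz;
- each movement segment is a minimum-jerk point-to-point profile (the
  standard model for reaches), optionally time-warped;
- dwell phases carry low-amplitude sinusoidal jitter below the 0.05 m/s
  activity threshold;
- TMS pulse-onset latency is uniform on a configured interval
  (0.100-0.300 s after the start of planning);
- Gaussian positional noise and random frame dropouts emulate optical
  motion-capture artifacts;
- optional corrective submovements add secondary velocity peaks.

Natural between-trial shape variance comes from three independent time
warps that preserve each segment's endpoints, duration and travelled
distance: a power-law warp (peak earlier/later), a symmetric
sharpening/flattening warp, and an interior peak-speed boost confined to
the high-speed mid-profile (without it, maximum velocity would be an exact
function of amplitude and duration and the feature set would be singular).

Condition effects ("verum" stimulation shifting a kinematic parameter in a
subset of trials) are injected by warping the *generating* parameters, never
by editing computed features, so the full pipeline is exercised end to end.
Each supported feature has an orthogonalized mechanism: durations shift
phase duration, amplitudes shift pathlength, a plateau-translation warp
slides the velocity-peak time, and the interior boost scales maximum
velocity; peak-time and peak-speed targets are solved against the smoothed,
in-context profile so the injected shift survives the 0.42-s measurement
filter.

Segment realism presets (speeds, durations, dispersions) follow the marginal
condition means reported for this task: reaching pathlength ~0.40 +/- 0.06 m,
preparing maximum velocity ~0.75 +/- 0.15 m/s, Go-Cue duration
~0.55 +/- 0.22 s, preparing/using velocity-peak times ~51%/~33% of phase
duration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .phases import TrialEvents
from .preprocess import Trajectory, _loess_quadratic
from .scoring import TrialOutcome, score_production, score_selection

logger = logging.getLogger("toolkin")

SITES = ("aSMG", "vPreCG")
STIM_TYPES = ("sham", "verum")
TIMEPOINTS = ("early", "late")

#: Between-trial SDs of the generated features under the default presets
#: (measured once at large n), used to convert "shift in SD units" into
#: feature-unit targets so that a 1-SD injection moves the measured feature
#: by about one pooled SD.
NOMINAL_EFFECT_SD = {
    "PD_GoCue": 0.21, "PD_Reach": 0.08, "PD_Prep": 0.085, "PD_Use": 0.10,
    "PL_Reach": 0.055, "PL_Prep": 0.03, "PL_Use": 0.035,
    "MV_Reach": 0.26, "MV_Prep": 0.16, "MV_Use": 0.135,
    "TVP_Reach": 9.0, "TVP_Prep": 8.5, "TVP_Use": 13.5,
}
INJECTABLE_FEATURES = tuple(NOMINAL_EFFECT_SD)


class SimConfigError(ValueError):
    """Raised for invalid simulation configurations (unknown features etc.)."""


@dataclass(frozen=True)
class SimConfig:
    """Study-shaped simulation configuration.

    Defaults reproduce the study conditions: 37 participants split between
    the two stimulation sites, 14 tool-cylinder combinations performed once
    under verum and once under sham stimulation, 100 Hz sampling, pulse
    onsets uniform on 100-300 ms.

    ``effect_spec`` maps a feature name to a list of
    ``(condition_selector, shift_in_SD_units)`` pairs; the selector is a dict
    over ``site`` / ``stim_type`` / ``timepoint`` (missing keys match any
    level). ``seed`` fully determines every generated trial.
    """

    n_participants: int = 37
    trials_per_condition: int = 14
    sample_rate: float = 100.0
    pulse_onset_range: tuple[float, float] = (0.100, 0.300)
    effect_spec: dict = field(default_factory=dict)
    noise_sd: float = 0.00015  # meters, per coordinate
    dropout_prob: float = 0.005  # per interior frame
    dwell_jitter_speed: float = 0.02  # m/s, below the activity threshold
    submovement_prob: float = 0.2  # per movement segment
    submovement_amp: float = 0.035  # meters
    margin: float = 0.12  # stationary padding before signal / after lift, s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise SimConfigError("sample_rate must be positive")
        lo, hi = self.pulse_onset_range
        if not (0 < lo < hi):
            raise SimConfigError("pulse_onset_range must be ordered and positive")
        if not (0 <= self.dropout_prob < 1):
            raise SimConfigError("dropout_prob must be a probability")
        if self.n_participants < 1 or self.trials_per_condition < 1:
            raise SimConfigError("counts must be positive")
        for feat, entries in self.effect_spec.items():
            if feat not in INJECTABLE_FEATURES:
                raise SimConfigError(
                    f"effect_spec names unknown/unsupported feature {feat!r}; "
                    f"injectable: {INJECTABLE_FEATURES}"
                )
            for sel, _shift in _as_entries(entries):
                bad = set(sel) - {"site", "stim_type", "timepoint"}
                if bad:
                    raise SimConfigError(f"unknown selector keys {bad} for {feat}")


def _as_entries(entries):
    if isinstance(entries, tuple) and len(entries) == 2 and isinstance(entries[0], dict):
        return [entries]
    return list(entries)


# --- analytic trial geometry ----------------------------------------------

def _minjerk(s: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile on normalized time (10t^3 - 15t^4 + 6t^5)."""
    return s**3 * (10.0 - 15.0 * s + 6.0 * s * s)


def _warp(tau: np.ndarray, gamma: float, lam: float) -> np.ndarray:
    """Composed time warp: asymmetric power law, then symmetric sharpening.

    ``gamma`` moves the velocity peak (>1 later, <1 earlier); ``lam`` in
    (-2, 1) sharpens (>0) or flattens (<0) the peak while keeping the
    endpoints, duration and travelled distance fixed.
    """
    g = tau**gamma if gamma != 1.0 else tau
    if lam != 0.0:
        g = (1.0 - lam) * g + lam * (3.0 * g * g - 2.0 * g**3)
    return g


def _boost(tau: np.ndarray, kappa: float, center: float, width: float) -> np.ndarray:
    """Interior speed-boost time warp, confined to the high-speed mid-profile.

    Inside a window of ``width`` (normalized time) around ``center`` the local
    time rate is scaled by ``1 - kappa*cos(2*pi*u)`` (so the rate at the
    window center is ``1 + kappa``), integrating back to the identity at the
    window edges. Peak speed scales by about ``1 + kappa`` while duration,
    pathlength, peak time and the low-speed tails stay fixed — this is the
    shape variance that makes maximum velocity a parameter of its own rather
    than a function of amplitude and duration. Monotone for |kappa| < 1.
    """
    a = max(0.02, center - width / 2.0)
    b = min(0.98, center + width / 2.0)
    u = (tau - a) / (b - a)
    inside = (u > 0) & (u < 1)
    out = tau.copy()
    out[inside] = tau[inside] - kappa * (b - a) * np.sin(2 * np.pi * u[inside]) / (2 * np.pi)
    return out


def _interior_shift(tau: np.ndarray, delta: float, center: float, width: float) -> np.ndarray:
    """Peak-translating time warp confined to the mid-profile.

    Adds ``delta`` times a plateau function: smoothstep ramps over the outer
    30% of a window around ``center`` and a flat top across the middle. On
    the plateau the warp is a pure time translation (unit rate), so the
    velocity peak slides earlier (delta > 0) or later (delta < 0) by
    ``delta`` of normalized time *without scaling its height*; the
    compensating compression sits in the low-speed flanks. Window edges —
    and with them the sub-threshold tails, duration and pathlength — are
    untouched. Monotone for ``|delta| < 0.2 * width``.
    """
    a = max(0.03, center - width / 2.0)
    b = min(0.97, center + width / 2.0)
    u = np.clip((tau - a) / (b - a), 0.0, 1.0)
    r = 0.30  # ramp fraction at each window end
    up = np.clip(u / r, 0.0, 1.0)
    down = np.clip((1.0 - u) / r, 0.0, 1.0)
    plateau = (up * up * (3 - 2 * up)) * (down * down * (3 - 2 * down))
    return tau + delta * plateau


@dataclass(frozen=True)
class MoveSegment:
    """One point-to-point movement: start, displacement, duration and warps."""

    duration: float
    start: np.ndarray
    displacement: np.ndarray
    gamma: float = 1.0
    lam: float = 0.0
    kappa: float = 0.0  # interior peak-speed boost
    boost_center: float = 0.5  # normalized time of the (unboosted) peak
    boost_width: float = 0.65
    shift: float = 0.0  # interior peak-time shift (normalized time)
    shift_center: float = 0.5
    shift_width: float = 0.9
    bump_amp: float = 0.0
    bump_dir: np.ndarray = None
    bump_start: float = 0.55  # normalized time
    bump_frac: float = 0.35

    def position(self, t_local: np.ndarray) -> np.ndarray:
        tau = np.clip(t_local / self.duration, 0.0, 1.0)
        if self.shift != 0.0:
            tau = _interior_shift(tau, self.shift, self.shift_center, self.shift_width)
        if self.kappa != 0.0:
            tau = _boost(tau, self.kappa, self.boost_center, self.boost_width)
        s = _minjerk(_warp(tau, self.gamma, self.lam))
        p = self.start[None, :] + s[:, None] * self.displacement[None, :]
        if self.bump_amp != 0.0:
            u = np.clip((tau - self.bump_start) / self.bump_frac, 0.0, 1.0)
            p = p + (self.bump_amp * np.sin(np.pi * u) ** 2)[:, None] * self.bump_dir[None, :]
        return p

    @property
    def end(self) -> np.ndarray:
        return self.start + self.displacement


@dataclass(frozen=True)
class DwellSegment:
    """Stationary hold with tapered sinusoidal jitter (below activity threshold)."""

    duration: float
    point: np.ndarray
    jitter_amp: np.ndarray = None  # (3,) amplitudes; None = perfectly still
    jitter_freq: np.ndarray = None
    jitter_phase: np.ndarray = None

    def position(self, t_local: np.ndarray) -> np.ndarray:
        p = np.broadcast_to(self.point, (t_local.size, 3)).copy()
        if self.jitter_amp is not None:
            env = np.sin(np.pi * np.clip(t_local / self.duration, 0, 1)) ** 2
            osc = np.sin(
                2.0 * np.pi * self.jitter_freq[None, :] * t_local[:, None]
                + self.jitter_phase[None, :]
            )
            p = p + env[:, None] * self.jitter_amp[None, :] * osc
        return p

    @property
    def end(self) -> np.ndarray:
        return self.point


def _segment_speed(seg: MoveSegment, n_dense: int = 201) -> tuple[np.ndarray, np.ndarray]:
    """Dense speed profile of a movement segment (numerical derivative)."""
    t = np.linspace(0.0, seg.duration, n_dense)
    p = seg.position(t)
    v = np.linalg.norm(np.gradient(p, t, axis=0), axis=1)
    return t, v


def _peak_speed(seg: MoveSegment) -> float:
    return float(_segment_speed(seg)[1].max())


def _raw_peak_count(seg: MoveSegment, prominence: float = 0.05) -> int:
    t, v = _segment_speed(seg)
    return _brute_prominent_peaks(v, prominence)


def _tvp_percent(seg: MoveSegment) -> float:
    t, v = _segment_speed(seg)
    return 100.0 * t[int(np.argmax(v))] / seg.duration


def _measured_profile(
    seg: MoveSegment,
    prev: MoveSegment = None,
    nxt: MoveSegment = None,
    window_s: float = 0.42,
    pad: float = 0.30,
    dt: float = 0.015,
) -> tuple[float, float]:
    """(peak time %, peak speed) as the pipeline measures them: smoothed.

    The loess window attenuates sharp peaks, drags asymmetric ones toward
    mid-phase and mixes in the flanking movement, so warp targets for
    peak-time and peak-speed injections are solved on the smoothed profile.
    The pad region holds the stationary endpoints unless the actual
    neighbouring segments are supplied.
    """
    t = np.arange(-pad, seg.duration + pad + dt, dt)
    p = seg.position(t)  # clamps to the endpoints outside [0, duration]
    before = t < 0
    after = t > seg.duration
    if prev is not None and before.any():
        p[before] = prev.position(t[before] + prev.duration)
    if nxt is not None and after.any():
        p[after] = nxt.position(t[after] - seg.duration)
    v = np.linalg.norm(np.gradient(p, t, axis=0), axis=1)
    vs = _loess_quadratic(t, v, max(4, int(round(window_s / dt))))
    m = (t >= 0) & (t <= seg.duration)
    i = int(np.argmax(vs[m]))
    return 100.0 * t[m][i] / seg.duration, float(vs[m][i])


def _measured_tvp(seg: MoveSegment, prev=None, nxt=None) -> float:
    return _measured_profile(seg, prev, nxt)[0]


def _secant(f, x0: float, x1: float, lo: float, hi: float, ftol: float,
            max_iter: int = 8) -> float:
    """Bounded secant root search; returns the best iterate on max-iter."""
    x0 = float(np.clip(x0, lo, hi))
    x1 = float(np.clip(x1, lo, hi))
    f0, f1 = f(x0), f(x1)
    best_x, best_f = (x0, f0) if abs(f0) < abs(f1) else (x1, f1)
    for _ in range(max_iter):
        if abs(best_f) < ftol:
            return best_x
        if f1 == f0 or x1 == x0:
            break
        x2 = float(np.clip(x1 - f1 * (x1 - x0) / (f1 - f0), lo, hi))
        x0, f0 = x1, f1
        x1, f1 = x2, f(x2)
        if abs(f1) < abs(best_f):
            best_x, best_f = x1, f1
    return best_x


def _with_center(seg: MoveSegment) -> MoveSegment:
    """Recenter the interior boost window on the unboosted peak position."""
    t, v = _segment_speed(replace(seg, kappa=0.0), n_dense=151)
    return replace(seg, boost_center=float(t[int(np.argmax(v))] / seg.duration))


def _solve_kappa_for_peak(
    seg: MoveSegment, target: float, prev=None, nxt=None
) -> MoveSegment:
    """Solve the interior boost so the *measured* peak speed hits target.

    Measured peak speed is nearly linear in kappa (multiplier ~ 1 + kappa),
    so a bounded secant from the linear guess converges in a couple of
    steps; unreachable targets clip at the physical bounds.
    """
    p0 = _measured_profile(seg, prev, nxt)[1]
    if target < 0.92 * p0:
        # strong reductions need a wider window, spreading the compensating
        # speed-up into low-speed regions instead of raising shoulder humps
        seg = replace(seg, boost_width=max(seg.boost_width, 0.85))
        p0 = _measured_profile(seg, prev, nxt)[1]
    base = p0 / (1.0 + seg.kappa)
    guess = target / base - 1.0
    kappa = _secant(
        lambda k: _measured_profile(replace(seg, kappa=k), prev, nxt)[1] - target,
        seg.kappa, guess, -0.55, 0.6, ftol=0.004, max_iter=5,
    )
    seg = replace(seg, kappa=kappa)
    if kappa < -0.05:
        # a reduction that splits the speed profile into extra humps is a
        # kernel artifact, not movement physics: back the boost off until
        # no new prominent peak appears, and deliver the rest otherwise
        base_peaks = _raw_peak_count(replace(seg, kappa=0.0))
        if _raw_peak_count(seg) > base_peaks:
            lo, hi = kappa, 0.0
            for _ in range(6):
                mid = 0.5 * (lo + hi)
                if _raw_peak_count(replace(seg, kappa=mid)) > base_peaks:
                    lo = mid
                else:
                    hi = mid
            seg = replace(seg, kappa=hi)
    achieved = _measured_profile(seg, prev, nxt)[1]
    if achieved - target > 0.008 and target > 0:
        # the interior boost saturates on already-flat profiles (the
        # compensating speed-up raises the shoulders to the reduced peak);
        # deliver the remainder by stretching the segment slightly (peak
        # speed scales as ~1/duration at fixed shape and distance), capped
        # so the phase-duration side effect stays well below its natural SD
        seg = replace(
            seg, duration=float(seg.duration * min(achieved / target, 1.10))
        )
        achieved = _measured_profile(seg, prev, nxt)[1]
        if achieved - target > 0.008:
            # final fallback: flatten the whole profile
            lam = _secant(
                lambda l: _measured_profile(replace(seg, lam=l), prev, nxt)[1] - target,
                seg.lam, seg.lam - 0.25, -0.45, seg.lam, ftol=0.004, max_iter=6,
            )
            seg = replace(seg, lam=lam)
    return seg


def _solve_shift_for_tvp(
    seg: MoveSegment, target_pct: float, prev=None, nxt=None
) -> MoveSegment:
    """Solve the interior peak-time shift so the *measured* (smoothed)
    velocity peak lands at the target percentage of phase duration.

    The shift window is centered on the segment's current raw peak, so the
    low-speed tails (hence relative activity and the phase boundaries) stay
    untouched; residual peak-speed scaling is compensated afterwards by the
    interior boost. Targets beyond the monotone warp range clip.
    """
    target_pct = float(np.clip(target_pct, 10.0, 90.0))
    t, v = _segment_speed(replace(seg, shift=0.0), n_dense=151)
    center = float(t[int(np.argmax(v))] / seg.duration)
    seg = replace(seg, shift_center=center)
    # translations beyond the flat-top halfwidth would compress the flanks
    # into the peak (scaling speeds); cap there and accept the attenuation
    a = max(0.03, center - seg.shift_width / 2.0)
    b = min(0.97, center + seg.shift_width / 2.0)
    bound = min(0.165, 0.95 * (0.5 - 0.30) * (b - a))
    f = lambda d: _measured_tvp(replace(seg, shift=d), prev, nxt) - target_pct
    tvp0 = _measured_tvp(seg, prev, nxt)
    guess = seg.shift + (tvp0 - target_pct) / 100.0
    delta = _secant(f, seg.shift, guess, -bound, bound, ftol=0.5)
    if abs(f(delta)) > 3.0:
        # multi-peaked profiles give a discontinuous response; fall back to a
        # coarse scan for the best reachable point
        grid = np.linspace(-bound, bound, 9)
        vals = np.array([abs(f(d)) for d in grid])
        delta = float(grid[int(np.argmin(vals))])
    return replace(seg, shift=delta)


# --- ground truth ----------------------------------------------------------

@dataclass
class GroundTruth:
    """Per-trial generation ledger for parameter-recovery tests.

    ``segments`` is the ordered list of analytic segments (dwells and moves),
    ``boundaries`` the true phase-boundary times (signal at 0), ``labels`` the
    condition labels, and ``injected`` the applied shifts in SD units.
    """

    segments: list
    boundaries: dict
    labels: dict
    injected: dict
    pulse_onset: float

    def position(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the noise-free analytic trajectory at arbitrary times.

        ``t`` is in trial time (signal at 0); times before the first or after
        the last segment hold the end positions.
        """
        t = np.asarray(t, dtype=float)
        out = np.empty((t.size, 3))
        # segment start times: the first dwell begins margin seconds pre-signal
        starts = [self._start_time()]
        for seg in self.segments[:-1]:
            starts.append(starts[-1] + seg.duration)
        for k, seg in enumerate(self.segments):
            s0 = starts[k]
            s1 = s0 + seg.duration
            if k == 0:
                m = t < s1
            elif k == len(self.segments) - 1:
                m = t >= s0
            else:
                m = (t >= s0) & (t < s1)
            out[m] = seg.position(np.clip(t[m] - s0, 0.0, seg.duration))
        return out

    def _start_time(self) -> float:
        # first segment is the pre-signal + Go-Cue dwell ending at t_move
        return self.boundaries["t_move"] - self.segments[0].duration


@dataclass
class TrialMeta:
    trial_id: str
    participant: str
    site: str
    stim_type: str
    timepoint: str
    pulse_onset: float
    run: int
    order_group: str
    selection: int
    production: int
    outcome: TrialOutcome = None


@dataclass
class SimulatedTrial:
    trajectory: Trajectory
    events: TrialEvents
    meta: TrialMeta
    ground_truth: GroundTruth


# --- trial synthesis -------------------------------------------------------

def _tnorm(rng, mean, sd, lo, hi) -> float:
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _draw_outcome(rng) -> TrialOutcome:
    """Performance annotation with study-like score marginals.

    Tuned so mean selection ~0.88 and mean production ~2.6: wrong-tool trials
    rarely achieve the goal, correct-tool trials usually do.
    """
    correct = rng.random() < 0.87
    self_corr = int(rng.choice(3, p=[0.90, 0.08, 0.02]))
    probs = [0.01, 0.05, 0.14, 0.80] if correct else [0.05, 0.25, 0.60, 0.10]
    level = int(rng.choice(4, p=probs))
    return TrialOutcome(
        correct_tool_selected=correct,
        self_corrections=self_corr,
        goal_achieved=level == 3,
        tool_grasped=level >= 1,
        tool_moved_to_cylinder=level >= 2,
        tool_attached=level >= 3,
    )


def _collect_shifts(config: SimConfig, labels: dict) -> dict[str, float]:
    """Total injected shift (SD units) per feature for this trial's labels."""
    shifts: dict[str, float] = {}
    for feat, entries in config.effect_spec.items():
        for sel, shift in _as_entries(entries):
            if all(labels.get(k) == v for k, v in sel.items()):
                shifts[feat] = shifts.get(feat, 0.0) + float(shift)
    return shifts


def simulate_trial(
    config: SimConfig,
    condition: dict,
    trial_key: int = 0,
    meta_fields: dict = None,
) -> SimulatedTrial:
    """Generate one trial for a (site, stim_type) condition.

    ``trial_key`` decorrelates trials generated under the same config seed;
    the pair (config.seed, trial_key) fully determines the output.
    """
    site = condition.get("site", SITES[0])
    stim_type = condition.get("stim_type", STIM_TYPES[0])
    if site not in SITES or stim_type not in STIM_TYPES:
        raise SimConfigError(f"unknown condition labels: {condition}")
    rng = np.random.default_rng(np.random.SeedSequence((int(config.seed), int(trial_key))))

    lo, hi = config.pulse_onset_range
    pulse_onset = float(rng.uniform(lo, hi))
    timepoint = "early" if pulse_onset < 0.5 * (lo + hi) else "late"
    labels = {"site": site, "stim_type": stim_type, "timepoint": timepoint}
    shifts = _collect_shifts(config, labels)

    # natural generating parameters; the peak-sharpness warp (lam) varies
    # between trials so that maximum velocity carries shape variance of its
    # own instead of being determined by amplitude and duration
    d_gc = _tnorm(rng, 0.55, 0.22, 0.18, 1.6)
    params = {
        "reach": {"A": _tnorm(rng, 0.40, 0.055, 0.18, 0.70),
                  "T": _tnorm(rng, 0.75, 0.08, 0.45, 1.1),
                  "gamma": _tnorm(rng, 1.00, 0.14, 0.60, 1.6),
                  "lam": _tnorm(rng, 0.0, 0.15, -0.35, 0.45),
                  "kappa": _tnorm(rng, 0.0, 0.22, -0.38, 0.60)},
        "prep": {"A": _tnorm(rng, 0.32, 0.030, 0.14, 0.55),
                 "T": _tnorm(rng, 0.80, 0.085, 0.45, 1.2),
                 "gamma": _tnorm(rng, 1.03, 0.14, 0.60, 1.6),
                 "lam": _tnorm(rng, 0.0, 0.15, -0.35, 0.45),
                 "kappa": _tnorm(rng, 0.0, 0.22, -0.38, 0.60)},
        "use": {"A": _tnorm(rng, 0.18, 0.030, 0.08, 0.35),
                "T": _tnorm(rng, 0.70, 0.10, 0.40, 1.1),
                "gamma": _tnorm(rng, 0.78, 0.15, 0.45, 1.25),
                "lam": _tnorm(rng, 0.0, 0.15, -0.35, 0.45),
                "kappa": _tnorm(rng, 0.0, 0.22, -0.38, 0.60)},
    }
    if "PD_GoCue" in shifts:
        d_gc = float(np.clip(d_gc + shifts["PD_GoCue"] * NOMINAL_EFFECT_SD["PD_GoCue"], 0.12, 2.5))

    # movement directions: reach and transport roughly horizontal, lift upward
    az1, az2 = rng.uniform(0, 2 * np.pi, 2)
    dirs = {
        "reach": _unit(np.array([np.cos(az1), np.sin(az1), rng.uniform(-0.15, 0.15)])),
        "prep": _unit(np.array([np.cos(az2), np.sin(az2), rng.uniform(-0.1, 0.1)])),
        "use": _unit(np.array([rng.uniform(-0.25, 0.25), rng.uniform(-0.25, 0.25), 1.0])),
    }

    # corrective submovements near target acquisition, drawn independently
    # for the reach (tool approach) and use (cylinder approach) segments
    bumps: dict[str, dict] = {}
    for name in ("reach", "use"):
        if rng.random() < config.submovement_prob:
            bumps[name] = {
                "bump_amp": config.submovement_amp * rng.uniform(0.6, 1.4),
                "bump_dir": _unit(rng.normal(size=3)),
                "bump_start": rng.uniform(0.45, 0.60),
                "bump_frac": rng.uniform(0.28, 0.38),
            }

    # pass 1: natural segments, with duration/amplitude (PD/PL) shifts applied
    names = ("reach", "prep", "use")
    phase_key = {"reach": "Reach", "prep": "Prep", "use": "Use"}
    segs: dict[str, MoveSegment] = {}
    seg0s: dict[str, MoveSegment] = {}
    touched: dict[str, bool] = {}
    start = np.zeros(3)
    for name in names:
        key = phase_key[name]
        prm = params[name]
        A, T = prm["A"], prm["T"]
        seg0 = _with_center(
            MoveSegment(duration=T, start=start, displacement=A * dirs[name],
                        gamma=prm["gamma"], lam=prm["lam"], kappa=prm["kappa"],
                        **bumps.get(name, {}))
        )
        seg = seg0
        if f"PD_{key}" in shifts:
            T = float(np.clip(T + shifts[f"PD_{key}"] * NOMINAL_EFFECT_SD[f"PD_{key}"], 0.3, 2.0))
        if f"PL_{key}" in shifts:
            A = float(np.clip(A + shifts[f"PL_{key}"] * NOMINAL_EFFECT_SD[f"PL_{key}"], 0.05, 1.0))
        if seg0.duration != T or not np.array_equal(seg0.displacement, A * dirs[name]):
            seg = _with_center(replace(seg0, duration=T, displacement=A * dirs[name]))
        segs[name] = seg
        seg0s[name] = seg0
        touched[name] = any(f"{fam}_{key}" in shifts for fam in ("PD", "PL", "TVP", "MV"))
        start = seg.end

    # pass 2: peak-time and peak-speed warps solved against the *in-context*
    # natural reference (the neighbouring segments sit inside the smoothing
    # window, so isolated-segment targets would be biased); a second sweep
    # refines against the updated neighbours so that adjacent injections do
    # not dilute each other
    if any(touched.values()):
        neighbours = {"reach": (None, "prep"), "prep": ("reach", "use"), "use": ("prep", None)}

        def _ctx(name):
            prv, nx = neighbours[name]
            return segs.get(prv), segs.get(nx)

        refs = {
            name: _measured_profile(seg0s[name], *_ctx(name))
            for name in names
            if touched[name]
        }
        for _sweep in range(2):
            for name in names:
                if not touched[name]:
                    continue
                key = phase_key[name]
                if _sweep and f"TVP_{key}" not in shifts:
                    continue  # only peak-time warps are neighbour-sensitive
                if _sweep:
                    # re-solve only if the first sweep drifted in final context
                    tvp_t = refs[name][0] + shifts[f"TVP_{key}"] * NOMINAL_EFFECT_SD[f"TVP_{key}"]
                    cur = _measured_tvp(segs[name], *_ctx(name))
                    if abs(cur - float(np.clip(tvp_t, 10.0, 90.0))) < 1.5:
                        continue
                tvp_ref, mv_ref = refs[name]
                prv, nx = _ctx(name)
                seg = segs[name]
                tvp_target = None
                if f"TVP_{key}" in shifts:
                    tvp_target = tvp_ref + shifts[f"TVP_{key}"] * NOMINAL_EFFECT_SD[f"TVP_{key}"]
                    # recenter the boost window first: the solve calibrates
                    # against the profile it is given, so nothing may move
                    # the boost afterwards
                    seg = _solve_shift_for_tvp(_with_center(seg), tvp_target, prv, nx)
                mv_target = mv_ref + shifts.get(f"MV_{key}", 0.0) * NOMINAL_EFFECT_SD[f"MV_{key}"]
                cand = _solve_kappa_for_peak(seg, max(0.05, mv_target), prv, nx)
                if tvp_target is not None and cand.kappa != seg.kappa:
                    # on multi-peaked profiles the speed restore can flip the
                    # smoothed argmax; the peak-time target takes precedence
                    if abs(_measured_tvp(cand, prv, nx) - np.clip(tvp_target, 10, 90)) > 4.0:
                        cand = seg
                segs[name] = cand

    # dwell jitter (tapered sinusoids, bounded below the activity threshold)
    def _dwell(duration: float, point: np.ndarray) -> DwellSegment:
        if config.dwell_jitter_speed <= 0:
            return DwellSegment(duration=duration, point=point)
        freq = rng.uniform(0.6, 1.8, size=3)
        phase = rng.uniform(0, 2 * np.pi, size=3)
        cap = config.dwell_jitter_speed / np.sqrt(3.0)
        amp = cap / (2 * np.pi * freq + np.pi / duration)
        return DwellSegment(duration, point, amp, freq, phase)

    t_move = d_gc
    t_grasped = t_move + segs["reach"].duration
    t_cyl = t_grasped + segs["prep"].duration
    t_lift = t_cyl + segs["use"].duration
    boundaries = {
        "t_signal": 0.0, "t_move": t_move, "t_toolcontact": t_grasped,
        "t_grasped": t_grasped, "t_cylcontact": t_cyl, "t_lift": t_lift,
    }
    segments = [
        _dwell(config.margin + d_gc, np.zeros(3)),
        segs["reach"], segs["prep"], segs["use"],
        _dwell(config.margin, segs["use"].end),
    ]
    gt = GroundTruth(
        segments=segments,
        boundaries=boundaries,
        labels=labels,
        injected=shifts,
        pulse_onset=pulse_onset,
    )

    # sample, add measurement noise, mask dropouts
    rate = config.sample_rate
    total = config.margin + t_lift + config.margin
    n = int(np.floor(total * rate)) + 1
    t = np.arange(n) / rate - config.margin
    p = gt.position(t)
    if config.noise_sd > 0:
        p = p + rng.normal(0.0, config.noise_sd, size=p.shape)
    missing = np.zeros(n, dtype=bool)
    if config.dropout_prob > 0 and n > 2:
        missing[1:-1] = rng.random(n - 2) < config.dropout_prob
    p = p.copy()
    p[missing] = np.nan

    outcome = _draw_outcome(rng)
    mf = meta_fields or {}
    meta = TrialMeta(
        trial_id=mf.get("trial_id", f"T{trial_key:05d}"),
        participant=mf.get("participant", "P000"),
        site=site,
        stim_type=stim_type,
        timepoint=timepoint,
        pulse_onset=pulse_onset,
        run=mf.get("run", 1),
        order_group=mf.get("order_group", "A"),
        selection=score_selection(outcome),
        production=score_production(outcome),
        outcome=outcome,
    )
    traj = Trajectory(t=t, p=p, missing=missing, sample_rate=rate,
                      trial_id=meta.trial_id)
    events = TrialEvents(**boundaries)
    return SimulatedTrial(trajectory=traj, events=events, meta=meta, ground_truth=gt)


def simulate_dataset(config: SimConfig) -> list[SimulatedTrial]:
    """Balanced study-shaped dataset.

    Participants alternate between the two stimulation sites; each performs
    ``trials_per_condition`` trials under verum and the same number under
    sham stimulation, split over two runs mirroring the counterbalanced
    coil-order groups (A: verum first in run 1; B: sham first).
    """
    trials: list[SimulatedTrial] = []
    key = 0
    tpc = config.trials_per_condition
    for pidx in range(config.n_participants):
        site = SITES[pidx % 2]
        group = "A" if (pidx // 2) % 2 == 0 else "B"
        for cidx in range(2 * tpc):
            run = 1 if cidx < tpc else 2
            half = (cidx % tpc) >= (tpc + 1) // 2
            first_verum = (group == "A") == (run == 1)
            stim = "verum" if (half != first_verum) else "sham"
            trial = simulate_trial(
                config,
                {"site": site, "stim_type": stim},
                trial_key=key,
                meta_fields={
                    "trial_id": f"P{pidx:03d}_R{run}_{cidx % tpc:02d}",
                    "participant": f"P{pidx:03d}",
                    "run": run,
                    "order_group": group,
                },
            )
            trials.append(trial)
            key += 1
    return trials


# --- independent dense reference for recovery tests ------------------------

def _dense_loess(t: np.ndarray, v: np.ndarray, window_s: float) -> np.ndarray:
    """Plain (slow) degree-2 tricube loess used as an independent reference."""
    out = np.empty_like(v)
    dt = t[1] - t[0]
    w = max(4, int(round(window_s / dt)))
    n = v.size
    half = (w - 1) // 2
    P = np.polynomial.polynomial
    for i in range(n):
        s = min(max(i - half, 0), n - w)
        tt = t[s:s + w] - t[i]
        d = np.abs(tt)
        wt = (1 - (d / d.max()) ** 3) ** 3
        coef = P.polyfit(tt, v[s:s + w], 2, w=np.sqrt(wt))
        out[i] = coef[0]
    return np.clip(out, 0.0, None)


def _brute_prominent_peaks(v: np.ndarray, prominence: float) -> int:
    """O(n^2) textbook prominence count (independent of scipy)."""
    count = 0
    n = v.size
    for i in range(1, n - 1):
        if not (v[i] > v[i - 1] and v[i] >= v[i + 1]):
            continue
        if v[i] == v[i + 1]:  # plateau: count only the left edge of the plateau
            j = i + 1
            while j < n and v[j] == v[i]:
                j += 1
            if j < n and v[j] > v[i]:
                continue
        bases = []
        for step in (-1, 1):
            j = i + step
            lowest = v[i]
            while 0 <= j < n and v[j] <= v[i]:
                lowest = min(lowest, v[j])
                j += step
            bases.append(lowest)
        if v[i] - max(bases) >= prominence:
            count += 1
    return count


def reference_features(
    gt: GroundTruth,
    config: SimConfig,
    oversample: int = 8,
    smoothing_window: float = 0.42,
    activity_threshold: float = 0.05,
    prominence: float = 0.05,
) -> tuple[dict, dict]:
    """Expected feature values from dense evaluation of the analytic trial.

    Evaluates the noise-free trajectory on an ``oversample``-times finer grid,
    applies the defining smoothing (independent implementation) and computes
    every feature directly, together with per-feature one-sample
    discretization tolerances:

    - PD: one sample interval (half a sample per snapped boundary); the
      closed Using/Total windows include one extra sample, accounted exactly;
    - MV: ``dt * max|dv/dt|`` within the phase;
    - TVP: 1.5 samples as a percentage of phase duration;
    - PL: boundary-sample speed times dt, plus a 0.1% chord-vs-arc allowance;
    - RA: 1.5 samples per threshold crossing, as a percentage;
    - NP: the count must agree; the tolerance propagates the PL tolerance.

    Returns ``(values, tolerances)`` keyed like the pipeline's feature names.
    """
    rate = config.sample_rate
    dt = 1.0 / rate
    fine = rate * oversample
    b = gt.boundaries
    t = np.arange(int(np.floor((config.margin + b["t_lift"] + config.margin) * fine)) + 1) / fine
    t -= config.margin
    p = gt.position(t)
    v = np.linalg.norm(np.gradient(p, t, axis=0), axis=1)
    vs = _dense_loess(t, v, smoothing_window)

    def win(lo_t, hi_t, closed=False):
        lo = int(np.searchsorted(t, lo_t - 1e-9))
        hi = int(np.searchsorted(t, hi_t - 1e-9))
        return lo, (hi + oversample if closed else hi)

    windows = {
        "GoCue": win(b["t_signal"], b["t_move"]),
        "Reach": win(b["t_move"], b["t_grasped"]),
        "Prep": win(b["t_grasped"], b["t_cylcontact"]),
        "Use": win(b["t_cylcontact"], b["t_lift"], closed=True),
        "Total": win(b["t_signal"], b["t_lift"], closed=True),
    }
    durations = {
        "GoCue": b["t_move"] - b["t_signal"],
        "Reach": b["t_grasped"] - b["t_move"],
        "Prep": b["t_cylcontact"] - b["t_grasped"],
        "Use": b["t_lift"] - b["t_cylcontact"] + dt,
        "Total": b["t_lift"] - b["t_signal"] + dt,
    }
    vals: dict[str, float] = {}
    tols: dict[str, float] = {}
    for key in ("GoCue", "Reach", "Prep", "Use", "Total"):
        vals[f"PD_{key}"] = durations[key]
        tols[f"PD_{key}"] = dt + 1e-9
    for key in ("Reach", "Prep", "Use", "Total"):
        lo, hi = windows[key]
        vv = vs[lo:hi]
        dur = durations[key]
        # pathlength of the dense polyline
        pl = float(np.linalg.norm(np.diff(p[lo:hi], axis=0), axis=1).sum())
        edge = max(v[max(lo - oversample, 0):lo + oversample + 1].max(initial=0.0),
                   v[max(hi - oversample, 0):min(hi + oversample, v.size)].max(initial=0.0))
        pl_tol = 2.0 * dt * edge + 1e-3 * pl + 1e-6
        npk = _brute_prominent_peaks(vv, prominence)
        ra = 100.0 * float(np.mean(vv > activity_threshold))
        crossings = int(np.count_nonzero(np.diff(vv > activity_threshold)))
        if key != "Total":
            imax = int(np.argmax(vv))
            vdot = np.max(np.abs(np.gradient(vv, t[lo:hi])))
            vals[f"MV_{key}"] = float(vv[imax])
            tols[f"MV_{key}"] = dt * float(vdot) + 2e-3
            vals[f"TVP_{key}"] = 100.0 * (t[lo + imax] - t[lo]) / dur
            tols[f"TVP_{key}"] = 100.0 * 1.5 * dt / dur
            vals[f"PL_{key}"] = pl
            tols[f"PL_{key}"] = pl_tol
        if pl > 0:
            vals[f"NP_{key}"] = npk / pl
            tols[f"NP_{key}"] = npk * pl_tol / pl**2 + 1e-9
        else:
            vals[f"NP_{key}"] = 0.0
            tols[f"NP_{key}"] = 1e-9
        vals[f"RA_{key}"] = ra
        tols[f"RA_{key}"] = 100.0 * 1.5 * dt * max(crossings, 1) / dur
    return vals, tols
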