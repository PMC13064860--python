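"""Partition a trial into the four task phases from annotated event times.

A trial runs from the start signal (button still pressed) to the moment the
cylinder is lifted out of its socket, and every frame belongs to exactly one
phase:

- **Go Cue** — signal onset until one frame before the hand starts moving;
- **Reaching** — first frame of hand movement until the tool is securely
  grasped (the brief finger-contact-to-grasp interval is kept in Reaching so
  that coverage is total; the contact time is retained for provenance);
- **Preparing** — grasped tool until the tool touches the cylinder
  (transport included);
- **Using** — tool-cylinder contact until the cylinder is lifted.

Event times come from frame-by-frame video annotation (or from the simulator's
ground truth); boundaries are snapped to the nearest sample, ties toward the
earlier sample, and phases are half-open index intervals with the final phase
closed at the lift frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import SpeedProfile, Trajectory

PHASE_NAMES = ("GoCue", "Reaching", "Preparing", "Using")

#: Sentinel returned by detect_movement_onset when speed never crosses threshold.
NO_ONSET = None


class EventError(ValueError):
    """Raised for inconsistent or out-of-range trial events."""


@dataclass(frozen=True)
class TrialEvents:
    """The six annotated timestamps of one trial, in seconds.

    ``t_signal < t_move <= t_toolcontact <= t_grasped <= t_cylcontact < t_lift``.
    ``t_toolcontact`` (first finger contact with the tool handle) is not a
    phase boundary but is kept for provenance.
    """

    t_signal: float
    t_move: float
    t_toolcontact: float
    t_grasped: float
    t_cylcontact: float
    t_lift: float

    def __post_init__(self) -> None:
        e = self.as_tuple()
        if not all(np.isfinite(e)):
            raise EventError("all event times must be finite")
        ok = (
            self.t_signal < self.t_move
            and self.t_move <= self.t_toolcontact <= self.t_grasped
            and self.t_grasped <= self.t_cylcontact < self.t_lift
        )
        if not ok:
            raise EventError(f"event times out of order: {e}")

    def as_tuple(self) -> tuple[float, ...]:
        return (
            self.t_signal,
            self.t_move,
            self.t_toolcontact,
            self.t_grasped,
            self.t_cylcontact,
            self.t_lift,
        )


@dataclass(frozen=True)
class PhaseWindows:
    """Half-open sample-index intervals per phase, contiguous and disjoint.

    ``total`` spans the whole trial (signal to lift, inclusive of the lift
    frame), i.e. the union of the four phase windows.
    """

    gocue: tuple[int, int]
    reaching: tuple[int, int]
    preparing: tuple[int, int]
    using: tuple[int, int]

    def __getitem__(self, phase: str) -> tuple[int, int]:
        return {
            "GoCue": self.gocue,
            "Reaching": self.reaching,
            "Preparing": self.preparing,
            "Using": self.using,
        }[phase]

    @property
    def total(self) -> tuple[int, int]:
        return (self.gocue[0], self.using[1])


def _snap(t_event: float, t0: float, rate: float) -> int:
    """Nearest sample index for an event time; ties go to the earlier sample."""
    x = (t_event - t0) * rate
    return int(np.ceil(x - 0.5))


def segment(traj: Trajectory, events: TrialEvents) -> PhaseWindows:
    """Map event times onto sample-index phase windows for this trajectory.

    GoCue = [signal, move), Reaching = [move, grasped),
    Preparing = [grasped, cylcontact), Using = [cylcontact, lift].
    Raises :class:`EventError` if any event lies outside the sampled range or
    any phase would be empty after snapping.
    """
    t0 = traj.t[0]
    rate = traj.sample_rate
    n = traj.n_samples
    for name, te in zip(
        ("t_signal", "t_move", "t_toolcontact", "t_grasped", "t_cylcontact", "t_lift"),
        events.as_tuple(),
    ):
        if te < traj.t[0] - 0.5 / rate or te > traj.t[-1] + 0.5 / rate:
            raise EventError(
                f"trial {traj.trial_id!r}: event {name}={te:.3f} s outside "
                f"trajectory range [{traj.t[0]:.3f}, {traj.t[-1]:.3f}]"
            )
    i_signal = _snap(events.t_signal, t0, rate)
    i_move = _snap(events.t_move, t0, rate)
    i_grasp = _snap(events.t_grasped, t0, rate)
    i_cyl = _snap(events.t_cylcontact, t0, rate)
    i_lift = _snap(events.t_lift, t0, rate)
    i_signal = max(i_signal, 0)
    i_lift = min(i_lift, n - 1)
    windows = PhaseWindows(
        gocue=(i_signal, i_move),
        reaching=(i_move, i_grasp),
        preparing=(i_grasp, i_cyl),
        using=(i_cyl, i_lift + 1),  # closed at the lift frame
    )
    for phase in PHASE_NAMES:
        lo, hi = windows[phase]
        if hi - lo < 1:
            raise EventError(
                f"trial {traj.trial_id!r}: phase {phase} is empty after snapping "
                f"events to the {rate:g} Hz grid"
            )
    return windows


def detect_movement_onset(
    profile: SpeedProfile,
    after: float,
    threshold: float = 0.05,
    min_samples: int = 3,
) -> float | None:
    """First time >= ``after`` where smoothed speed exceeds ``threshold`` for
    at least ``min_samples`` consecutive samples.

    An auto-annotation aid for synthetic or pilot data — real event times come
    from video. Returns :data:`NO_ONSET` (``None``) if the threshold is never
    sustained. A non-positive threshold is trivially exceeded everywhere and
    returns ``after`` itself.
    """
    if profile.v_smooth is None:
        raise ValueError("profile must be smoothed before onset detection")
    v = profile.v_smooth
    t = profile.t
    if after < t[0] or after > t[-1]:
        raise EventError(f"'after'={after} s outside profile range")
    if threshold <= 0:
        return float(after)
    start = int(np.searchsorted(t, after - 1e-12))
    above = v[start:] > threshold
    if min_samples <= 1:
        hits = np.flatnonzero(above)
    else:
        kernel = np.ones(min_samples, dtype=int)
        runs = np.convolve(above.astype(int), kernel, mode="valid") == min_samples
        hits = np.flatnonzero(runs)
    if hits.size == 0:
        return NO_ONSET
    return float(t[start + hits[0]])
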