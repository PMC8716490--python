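"""Open-field trajectory analytics.

The arena is a square (default 100 cm x 100 cm, origin at a corner, y
upward) with a concentric central zone (default 60 cm x 60 cm); everything
else is the peripheral zone. The zone boundary is *closed*: a point exactly
on the central-zone edge counts as central.

An exploration trial is a peripheral-to-central entry with at least 4 s of
continuous peripheral residence immediately before the entry; the entry
moment is the reference point (RP). A trial is *valid* when the animal then
dwells in the central zone for at least 4 s and the full [-4, +4] s window
fits inside the recording; entries with shorter dwell are kept but flagged
invalid, entries whose window falls outside the recording are dropped.
Tracking jitter at the boundary is handled by debouncing: zone runs shorter
than 0.2 s are merged into their neighbours before entries are detected
(raw, undebounced transitions are still what the entry *count* in
:func:`behavior_summary` reports).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import DataError, ParameterError, TimeSeries

__all__ = [
    "ArenaSpec",
    "Trajectory",
    "ExplorationTrial",
    "BehaviorSummary",
    "TrialSegments",
    "classify_zone",
    "is_central",
    "extract_trials",
    "behavior_summary",
    "speed_series",
    "align_lfp_to_trials",
]

#: tolerance (cm) for points marginally outside the arena (tracking noise)
ARENA_TOLERANCE_CM = 0.1
#: zone flickers shorter than this are treated as tracking jitter
DEBOUNCE_S = 0.2


@dataclass(frozen=True)
class ArenaSpec:
    """Square arena with a concentric square central zone (cm)."""

    side: float = 100.0
    centre_side: float = 60.0

    def __post_init__(self) -> None:
        if not (0 < self.centre_side < self.side):
            raise ParameterError(
                f"need 0 < centre_side < side, got centre {self.centre_side} "
                f"in arena {self.side}"
            )

    @property
    def centre_lo(self) -> float:
        return (self.side - self.centre_side) / 2

    @property
    def centre_hi(self) -> float:
        return (self.side + self.centre_side) / 2


@dataclass
class Trajectory:
    """Tracked position over time: t (s, strictly increasing), x and y (cm)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.size == self.x.size == self.y.size):
            raise DataError("t, x, y must have equal lengths")
        if self.t.size < 2:
            raise DataError("a trajectory needs at least 2 samples")
        if not np.all(np.diff(self.t) > 0):
            raise DataError("timestamps must be strictly increasing")
        if not (
            np.all(np.isfinite(self.t))
            and np.all(np.isfinite(self.x))
            and np.all(np.isfinite(self.y))
        ):
            raise DataError("trajectory contains non-finite values")

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class ExplorationTrial:
    """A central-zone entry with its RP, dwell and validity flag."""

    rp_time: float
    dwell: float
    valid: bool

    @property
    def window(self) -> tuple[float, float]:
        return (self.rp_time - 4.0, self.rp_time + 4.0)

    def to_dict(self) -> dict:
        return {"rp_time": self.rp_time, "dwell": self.dwell, "valid": self.valid}


@dataclass
class BehaviorSummary:
    """The open-field metrics: distance, entries, centre time, mean speed."""

    total_distance: float
    entries: int
    time_in_centre: float
    mean_speed: float
    rearing: int | None = None

    def to_dict(self) -> dict:
        d = {
            "total_distance_cm": self.total_distance,
            "entries": self.entries,
            "time_in_centre_s": self.time_in_centre,
            "mean_speed_cm_s": self.mean_speed,
        }
        if self.rearing is not None:
            d["rearing"] = self.rearing
        return d


def _check_in_arena(x: np.ndarray, y: np.ndarray, arena: ArenaSpec) -> None:
    lo, hi = -ARENA_TOLERANCE_CM, arena.side + ARENA_TOLERANCE_CM
    bad = (x < lo) | (x > hi) | (y < lo) | (y > hi)
    if np.any(bad):
        i = int(np.argmax(bad))
        raise DataError(
            f"point ({np.asarray(x).flat[i]:.2f}, {np.asarray(y).flat[i]:.2f}) cm "
            f"is outside the {arena.side} cm arena beyond the "
            f"{ARENA_TOLERANCE_CM} cm tolerance (index {i})"
        )


def is_central(x, y, arena: ArenaSpec = ArenaSpec()) -> np.ndarray:
    """Vectorised central-zone membership (closed boundary)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_in_arena(x, y, arena)
    lo, hi = arena.centre_lo, arena.centre_hi
    return (x >= lo) & (x <= hi) & (y >= lo) & (y <= hi)


def classify_zone(x: float, y: float, arena: ArenaSpec = ArenaSpec()) -> str:
    """'central' or 'peripheral' for a single point."""
    return "central" if bool(is_central(x, y, arena)) else "peripheral"


def _runs(labels: np.ndarray) -> list[tuple[int, int, bool]]:
    """Run-length encode a boolean sequence as (start, stop, value)."""
    changes = np.flatnonzero(np.diff(labels.astype(np.int8))) + 1
    starts = np.concatenate(([0], changes))
    stops = np.concatenate((changes, [labels.size]))
    return [(int(s), int(e), bool(labels[s])) for s, e in zip(starts, stops)]


def _debounce(central: np.ndarray, t: np.ndarray, min_s: float) -> np.ndarray:
    """Merge zone runs shorter than ``min_s`` into their neighbours."""
    out = central.copy()
    changed = True
    while changed:
        changed = False
        runs = _runs(out)
        if len(runs) <= 1:
            break
        for k, (s, e, val) in enumerate(runs):
            if k == 0:  # the initial state is taken at face value
                continue
            dur = t[min(e, t.size - 1)] - t[s] if e < t.size else t[-1] - t[s]
            if dur < min_s:
                out[s:e] = not val
                changed = True
                break
    return out


def extract_trials(
    traj: Trajectory,
    arena: ArenaSpec = ArenaSpec(),
    min_peripheral_s: float = 4.0,
    min_dwell_s: float = 4.0,
    window_half_s: float = 4.0,
    debounce_s: float = DEBOUNCE_S,
) -> list[ExplorationTrial]:
    """Detect exploration trials: peripheral-to-central entries.

    An entry requires at least ``min_peripheral_s`` of continuous peripheral
    residence immediately before the crossing. The dwell is the continuous
    central residence from the RP. Trials whose [-4, +4] s window exceeds
    the recording are dropped; trials with dwell < ``min_dwell_s`` are kept
    with ``valid=False``. An empty list is a legal result.
    """
    if traj.duration < 2 * window_half_s:
        raise DataError(
            f"trajectory covers {traj.duration:.1f} s; need at least "
            f"{2 * window_half_s:.0f} s"
        )
    central = is_central(traj.x, traj.y, arena)
    central = _debounce(central, traj.t, debounce_s)
    runs = _runs(central)
    trials: list[ExplorationTrial] = []
    for k in range(1, len(runs)):
        s, e, val = runs[k]
        if not val:
            continue  # not a central run
        ps, pe, pval = runs[k - 1]
        # preceding run is peripheral by construction of run-length encoding
        rp = float(traj.t[s])
        peripheral_s = rp - float(traj.t[ps])
        if peripheral_s < min_peripheral_s:
            continue
        if e < len(traj):
            dwell = float(traj.t[e]) - rp
        else:
            dt = float(np.median(np.diff(traj.t)))
            dwell = float(traj.t[-1]) + dt - rp
        if rp - window_half_s < traj.t[0] or rp + window_half_s > traj.t[-1]:
            continue  # window exceeds the recording: dropped
        trials.append(ExplorationTrial(rp, dwell, dwell >= min_dwell_s))
    return trials


def behavior_summary(
    traj: Trajectory,
    arena: ArenaSpec = ArenaSpec(),
    rearing: int | None = None,
) -> BehaviorSummary:
    """The open-field metrics the assay reports.

    Entries are *raw* peripheral-to-central transitions (no dwell filter, no
    debouncing), matching an entry counter; time in the centre integrates
    the sample intervals whose midpoint lies in the central zone. Rearing
    counts cannot be derived from a trajectory and pass through unchanged.
    """
    dx = np.diff(traj.x)
    dy = np.diff(traj.y)
    dt = np.diff(traj.t)
    total_distance = float(np.hypot(dx, dy).sum())
    central = is_central(traj.x, traj.y, arena)
    entries = int(np.sum(~central[:-1] & central[1:]))
    mid_central = is_central(
        (traj.x[:-1] + traj.x[1:]) / 2, (traj.y[:-1] + traj.y[1:]) / 2, arena
    )
    time_in_centre = float(dt[mid_central].sum())
    mean_speed = total_distance / traj.duration if traj.duration > 0 else 0.0
    return BehaviorSummary(total_distance, entries, time_in_centre, mean_speed, rearing)


def speed_series(traj: Trajectory, smooth_win: float = 0.5) -> TimeSeries:
    """Instantaneous speed (cm/s), boxcar-smoothed over ``smooth_win`` s.

    Finite differences via central differencing; the output has the same
    length as the trajectory (edges replicated by the smoothing pad).
    """
    vx = np.gradient(traj.x, traj.t)
    vy = np.gradient(traj.y, traj.t)
    speed = np.hypot(vx, vy)
    dt = float(np.median(np.diff(traj.t)))
    k = max(1, int(round(smooth_win / dt)))
    if k > 1:
        pad = k // 2
        padded = np.pad(speed, pad, mode="edge")
        kernel = np.ones(k) / k
        smoothed = np.convolve(padded, kernel, mode="same")[pad:pad + speed.size]
    else:
        smoothed = speed
    return TimeSeries(smoothed, fs=1.0 / dt, t0=float(traj.t[0]), region="other")


@dataclass
class TrialSegments:
    """LFP segments for one trial, time-referenced to the RP (t0 < 0)."""

    trial: ExplorationTrial
    phase_seg: TimeSeries
    amp_seg: TimeSeries


def align_lfp_to_trials(
    phase_lfp: TimeSeries,
    amp_lfp: TimeSeries,
    trials: list[ExplorationTrial],
    pad_s: float = 0.0,
    window_half_s: float = 4.0,
) -> list[TrialSegments]:
    """Cut per-trial LFP segments around each valid trial's RP.

    Each segment covers [-window_half - pad, +window_half + pad] s relative
    to the RP, cut at sample precision (alignment error <= half a sample
    period). ``pad_s`` should cover the filter edge margin (about 1 s) when
    the segments feed windowed MI estimators. Trials whose padded window
    falls outside the LFP support are dropped with a warning.
    """
    if phase_lfp.fs != amp_lfp.fs:
        raise DataError("phase and amplitude LFPs must share a sampling rate")
    fs = phase_lfp.fs
    half = window_half_s + pad_s
    n_seg = int(round(2 * half * fs))
    out: list[TrialSegments] = []
    for trial in trials:
        if not trial.valid:
            continue
        ok = True
        segs = []
        for lfp in (phase_lfp, amp_lfp):
            i0 = int(round((trial.rp_time - half - lfp.t0) * fs))
            if i0 < 0 or i0 + n_seg > len(lfp):
                ok = False
                break
            seg = lfp.with_samples(
                lfp.samples[i0:i0 + n_seg].copy(), t0=-half, edge_margin_s=0.0
            )
            segs.append(seg)
        if not ok:
            warnings.warn(
                f"trial at RP={trial.rp_time:.2f} s: window outside the LFP "
                "support; dropped",
                stacklevel=2,
            )
            continue
        out.append(TrialSegments(trial, segs[0], segs[1]))
    return out
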