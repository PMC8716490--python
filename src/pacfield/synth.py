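"""Synthetic two-region LFP sessions with known ground-truth coupling.

The generator makes every downstream stage testable without recordings. The
signal model is the standard cross-frequency-coupling test construction:

* the *phase region* (mPFC-like driver) carries a slow sinusoid,
  ``a_p * sin(2*pi*f_p*t) + noise``;
* the *amplitude region* (BLA-like) carries a fast sinusoid whose envelope
  is multiplicatively modulated by the driver's rhythm,
  ``a_A * [(1 - chi) + chi * (sin(2*pi*f_p*t) + 1) / 2] * sin(2*pi*f_A*t)
  + noise``.

The coupling depth ``chi`` in [0, 1] is the ground-truth analogue of the
Modulation Index: chi = 0 leaves the fast envelope constant (MI ~ 0), chi =
1 drives the envelope between 0 and a_A once per slow cycle (strong MI).
chi may also be a per-sample array, which produces non-stationary coupling
(used e.g. to test peri-event MI time courses). Noise is additive white
Gaussian by default; 1/f-coloured noise is available but off by default, to
keep closed-form examples exact.

Open-field trajectories are smoothed random walks (Ornstein-Uhlenbeck-style
velocity) confined to the arena, with scripted excursions into the central
zone so the number of exploration trials is known by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .behavior import ArenaSpec, Trajectory
from .core import ConfigError, TimeSeries

__all__ = [
    "SynthConfig",
    "SynthSession",
    "gen_coupled_lfp",
    "gen_trajectory",
    "gen_group_dataset",
    "subject_seeds",
]

#: per-visit time budget (s): >= 4 s peripheral approach plus slack
_MIN_APPROACH_S = 5.0
#: tail after the last dwell so the +4 s window fits
_MIN_TAIL_S = 5.0


@dataclass
class SynthConfig:
    """Parameters of one synthetic coupled-LFP pair.

    Defaults match the recording conditions the pipeline targets: a theta
    driver at 8 Hz, a high-gamma carrier at 80 Hz, sampling at 2 kHz.
    Amplitudes are in microvolts; ``noise_sd`` is the SD of the additive
    white noise on each channel.
    """

    f_p: float = 8.0
    f_A: float = 80.0
    chi: float | np.ndarray = 1.0
    a_p: float = 100.0
    a_A: float = 30.0
    noise_sd: float = 10.0
    fs: float = 2000.0
    duration: float = 8.0
    seed: int = 0
    colored_noise: bool = False

    def __post_init__(self) -> None:
        chi = np.asarray(self.chi, dtype=float)
        if np.any(chi < 0) or np.any(chi > 1):
            raise ConfigError(f"coupling depth chi must lie in [0, 1], got {self.chi}")
        if not (0 < self.f_p < self.f_A < self.fs / 2):
            raise ConfigError(
                f"need 0 < f_p < f_A < fs/2, got f_p={self.f_p}, "
                f"f_A={self.f_A}, fs={self.fs}"
            )
        if self.duration <= 0:
            raise ConfigError(f"duration must be positive, got {self.duration}")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if chi.ndim == 1 and chi.size != int(round(self.fs * self.duration)):
            raise ConfigError(
                f"per-sample chi has {chi.size} samples but the session has "
                f"{int(round(self.fs * self.duration))}"
            )

    def to_dict(self) -> dict:
        chi = self.chi
        return {
            "f_p": self.f_p,
            "f_A": self.f_A,
            "chi": float(chi) if np.isscalar(chi) else "per-sample",
            "a_p": self.a_p,
            "a_A": self.a_A,
            "noise_sd": self.noise_sd,
            "fs": self.fs,
            "duration": self.duration,
            "seed": self.seed,
            "colored_noise": self.colored_noise,
        }


@dataclass
class SynthSession:
    """A coupled LFP pair plus trajectory and the parameters that made them."""

    lfp_phase_region: TimeSeries
    lfp_amp_region: TimeSeries
    trajectory: Trajectory
    config: SynthConfig
    group_label: str = "control"
    subject_id: str = "s0"
    traj_seed: int = 0


def _noise(rng: np.random.Generator, n: int, sd: float, colored: bool, fs: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    if not colored:
        return sd * white
    # 1/f shaping in the frequency domain, renormalised to the requested SD
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1 / fs)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(f)
    shaped = np.fft.irfft(spec, n)
    return sd * shaped / shaped.std()


def gen_coupled_lfp(config: SynthConfig) -> tuple[TimeSeries, TimeSeries]:
    """Generate the (driver, modulated-carrier) LFP pair.

    Deterministic under a fixed ``config.seed``: the same config yields
    bit-identical traces.
    """
    n = int(round(config.fs * config.duration))
    t = np.arange(n) / config.fs
    rng = np.random.default_rng(config.seed)
    slow = np.sin(2 * np.pi * config.f_p * t)
    chi = np.asarray(config.chi, dtype=float)
    envelope = (1.0 - chi) + chi * (slow + 1.0) / 2.0
    ch1 = config.a_p * slow + _noise(
        rng, n, config.noise_sd, config.colored_noise, config.fs
    )
    ch2 = config.a_A * envelope * np.sin(2 * np.pi * config.f_A * t) + _noise(
        rng, n, config.noise_sd, config.colored_noise, config.fs
    )
    fs = config.fs
    return (
        TimeSeries(ch1, fs, region="mPFC"),
        TimeSeries(ch2, fs, region="BLA"),
    )


def _ou_walk(
    rng: np.random.Generator,
    n: int,
    dt: float,
    arena: ArenaSpec,
    start: np.ndarray,
    scheduled_central: np.ndarray,
    entry_targets: dict[int, np.ndarray],
    speed_sd: float = 12.0,
    tau: float = 1.0,
    margin: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed random walk clamped, sample by sample, to the scheduled zone.

    ``scheduled_central[i]`` says whether sample i must lie in the central
    zone. ``entry_targets`` maps a sample index to a point the walk is
    steered toward over the preceding ~2 s, so zone changes are approached
    smoothly rather than by teleporting.
    """
    lo_c, hi_c = arena.centre_lo, arena.centre_hi
    pos = np.empty((n, 2))
    pos[0] = start
    vel = np.zeros(2)
    steer_horizon = int(round(2.0 / dt))
    next_target_idx = sorted(entry_targets)
    ti = 0
    for i in range(1, n):
        # advance past consumed targets
        while ti < len(next_target_idx) and next_target_idx[ti] < i:
            ti += 1
        drift = np.zeros(2)
        if ti < len(next_target_idx) and next_target_idx[ti] - i <= steer_horizon:
            target = entry_targets[next_target_idx[ti]]
            remaining = max(next_target_idx[ti] - i, 1) * dt
            drift = (target - pos[i - 1]) / remaining
        vel += (-vel / tau + drift / tau) * dt
        vel += speed_sd * math.sqrt(dt) * rng.standard_normal(2)
        p = pos[i - 1] + vel * dt
        # arena walls (reflecting)
        for d in range(2):
            if p[d] < margin:
                p[d] = 2 * margin - p[d]
                vel[d] = -vel[d]
            elif p[d] > arena.side - margin:
                p[d] = 2 * (arena.side - margin) - p[d]
                vel[d] = -vel[d]
        # zone schedule (projecting)
        if scheduled_central[i]:
            p = np.clip(p, lo_c + margin, hi_c - margin)
        else:
            inside = (lo_c - margin < p[0] < hi_c + margin) and (
                lo_c - margin < p[1] < hi_c + margin
            )
            if inside:
                # push out through the nearest face of the central square
                dists = [
                    p[0] - (lo_c - margin),
                    (hi_c + margin) - p[0],
                    p[1] - (lo_c - margin),
                    (hi_c + margin) - p[1],
                ]
                face = int(np.argmin(dists))
                if face == 0:
                    p[0] = lo_c - margin
                elif face == 1:
                    p[0] = hi_c + margin
                elif face == 2:
                    p[1] = lo_c - margin
                else:
                    p[1] = hi_c + margin
        p = np.clip(p, 0.0, arena.side)
        pos[i] = p
    return pos[:, 0], pos[:, 1]


def gen_trajectory(
    arena: ArenaSpec,
    duration: float,
    n_center_visits: int,
    dwell_range: tuple[float, float],
    seed: int,
    fs_traj: float = 25.0,
) -> Trajectory:
    """Random open-field path with exactly ``n_center_visits`` centre entries.

    Each excursion is preceded by at least 4 s of peripheral residence and
    dwells in the central zone for a time drawn uniformly from
    ``dwell_range``. Timestamps are uniform at ``fs_traj`` Hz.
    """
    if n_center_visits < 0:
        raise ConfigError("n_center_visits must be >= 0")
    d_lo, d_hi = float(dwell_range[0]), float(dwell_range[1])
    if n_center_visits > 0 and not (0 < d_lo <= d_hi < duration):
        raise ConfigError(f"dwell_range {dwell_range} must lie within (0, {duration})")
    min_needed = (
        _MIN_APPROACH_S
        + n_center_visits * (d_lo + _MIN_TAIL_S)
    )
    if duration < min_needed:
        raise ConfigError(
            f"{n_center_visits} centre visits with dwell >= {d_lo} s do not "
            f"fit in {duration} s (need >= {min_needed:.1f} s)"
        )
    rng = np.random.default_rng(seed)
    dt = 1.0 / fs_traj
    n = int(round(duration * fs_traj))
    # schedule: alternating peripheral / central segments, slack spread evenly
    dwells = rng.uniform(d_lo, d_hi, size=n_center_visits)
    dwells = np.minimum(dwells, d_hi)
    slack = duration - (_MIN_APPROACH_S + dwells.sum()
                        + n_center_visits * _MIN_TAIL_S)
    extra = (
        rng.dirichlet(np.ones(n_center_visits + 1)) * max(slack, 0.0)
        if n_center_visits > 0
        else np.array([max(slack, 0.0)])
    )
    scheduled_central = np.zeros(n, dtype=bool)
    entry_targets: dict[int, np.ndarray] = {}
    cursor = _MIN_APPROACH_S + extra[0]
    lo_c, hi_c, m = arena.centre_lo, arena.centre_hi, 2.0
    for k in range(n_center_visits):
        i_in = int(round(cursor * fs_traj))
        i_out = int(round((cursor + dwells[k]) * fs_traj))
        i_out = min(i_out, n)
        scheduled_central[i_in:i_out] = True
        # entry point just inside a random face of the central square
        face = rng.integers(4)
        along = rng.uniform(lo_c + 2 * m, hi_c - 2 * m)
        pts = {
            0: (lo_c + m, along),
            1: (hi_c - m, along),
            2: (along, lo_c + m),
            3: (along, hi_c - m),
        }
        entry_targets[i_in] = np.asarray(pts[int(face)])
        # exit point just outside the same face
        pts_out = {
            0: (lo_c - m, along),
            1: (hi_c + m, along),
            2: (along, lo_c - m),
            3: (along, hi_c + m),
        }
        if i_out < n:
            entry_targets[i_out] = np.asarray(pts_out[int(face)])
        cursor += dwells[k] + _MIN_TAIL_S + extra[k + 1]
    start = np.array([arena.centre_lo / 2, arena.centre_lo / 2])
    x, y = _ou_walk(rng, n, dt, arena, start, scheduled_central, entry_targets)
    t = np.arange(n) * dt
    return Trajectory(t, x, y)


def subject_seeds(master_seed: int, n: int) -> list[tuple[int, int]]:
    """Deterministic (lfp_seed, traj_seed) pairs derived from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    out = []
    for child in ss.spawn(n):
        s = child.generate_state(2, np.uint32)
        out.append((int(s[0]) & 0x7FFFFFFF, int(s[1]) & 0x7FFFFFFF))
    return out


def gen_group_dataset(
    n_subjects: int,
    trials_per_subject: int,
    chi_control: float,
    chi_cums: float,
    seed: int,
    dwell_range: tuple[float, float] = (5.0, 6.0),
    arena: ArenaSpec = ArenaSpec(),
    **config_overrides,
) -> list[SynthSession]:
    """Two labelled groups whose only systematic difference is coupling depth.

    Per-subject seeds derive deterministically from ``seed``, so any subject
    re-runs identically in isolation. Group labels are ``control`` (coupling
    chi_control) and ``cums`` (chi_cums <= chi_control), mirroring a
    stressed group with weakened prefrontal-amygdala coupling.
    """
    if not (0 <= chi_cums <= chi_control <= 1):
        raise ConfigError(
            f"need 0 <= chi_cums <= chi_control <= 1, got "
            f"{chi_cums}, {chi_control}"
        )
    per_visit = dwell_range[1] + _MIN_TAIL_S + 2.0
    duration = math.ceil(
        max(12.0, _MIN_APPROACH_S + 3.0 + trials_per_subject * per_visit)
    )
    seeds = subject_seeds(seed, 2 * n_subjects)
    sessions: list[SynthSession] = []
    for g, (label, chi) in enumerate(
        [("control", chi_control), ("cums", chi_cums)]
    ):
        for s in range(n_subjects):
            lfp_seed, traj_seed = seeds[g * n_subjects + s]
            cfg = SynthConfig(
                chi=chi, duration=float(duration), seed=lfp_seed, **config_overrides
            )
            ch1, ch2 = gen_coupled_lfp(cfg)
            traj = gen_trajectory(
                arena, float(duration), trials_per_subject, dwell_range, traj_seed
            )
            sessions.append(
                SynthSession(ch1, ch2, traj, cfg, label, f"{label}_{s}", traj_seed)
            )
    return sessions
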