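"""Entropy-based phase-amplitude coupling (PAC).

The estimator quantifies how strongly the instantaneous amplitude of a fast
oscillation depends on the instantaneous phase of a slow oscillation. Both
are read off the Hilbert analytic signal of band-limited traces. The phase
axis is divided into N bins (default N = 18, i.e. 20 deg per bin), the mean
amplitude per bin is normalised into a distribution

    P(i) = <A>_i / sum_k <A>_k,

and the Modulation Index is the normalised Shannon-entropy deficit

    MI = (log N - H(P)) / log N,     H(P) = -sum_i P(i) log P(i),

so MI = 0 for a uniform distribution (no coupling) and MI = 1 for a
Dirac-like distribution (all amplitude concentrated at one phase). MI is
invariant to the logarithm base, to amplitude rescaling and to permutations
of the bins.

Bins are left-closed, right-open, starting at -pi; phases are reduced to
[-pi, pi). Natural logarithms are used internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import hilbert

from .core import (
    BandSpec,
    CANONICAL_BANDS,
    DataError,
    DegenerateDataError,
    EmptyBinError,
    InsufficientDataError,
    ParameterError,
    TimeSeries,
)
from .preprocess import bandpass, edge_margin_for_band

__all__ = [
    "PhaseSeries",
    "AmplitudeEnvelope",
    "BinnedAmplitude",
    "PhaseAmplitudeDistribution",
    "MIResult",
    "Comodulogram",
    "MITimeCourse",
    "analytic_decompose",
    "bin_amplitude_by_phase",
    "normalize_distribution",
    "modulation_index",
    "mi_from_phase_amp",
    "compute_mi",
    "comodulogram",
    "mi_timecourse",
    "zone_mi",
    "default_phase_grid",
    "default_amp_grid",
    "THETA",
    "HIGH_GAMMA",
]

THETA = CANONICAL_BANDS["theta"]
HIGH_GAMMA = CANONICAL_BANDS["high_gamma"]

DEFAULT_N_BINS = 18


def _resolve_band(band: str | BandSpec) -> BandSpec:
    if isinstance(band, str):
        try:
            return CANONICAL_BANDS[band]
        except KeyError:
            raise ParameterError(
                f"unknown band {band!r}; valid names: "
                + ", ".join(sorted(CANONICAL_BANDS))
            ) from None
    return band


@dataclass
class PhaseSeries:
    """Instantaneous phase in radians, wrapped to [-pi, pi)."""

    values: np.ndarray
    fs: float
    source_band: BandSpec | None = None
    t0: float = 0.0
    edge_margin_s: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return self.values.size


@dataclass
class AmplitudeEnvelope:
    """Instantaneous amplitude (modulus of the analytic signal), in uV."""

    values: np.ndarray
    fs: float
    source_band: BandSpec | None = None
    t0: float = 0.0
    edge_margin_s: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return self.values.size


@dataclass
class BinnedAmplitude:
    """Mean amplitude per phase bin, before normalisation.

    Empty bins carry mean NaN and count 0; they are flagged, never
    interpolated, because silent fill-in biases the entropy.
    """

    mean_amp: np.ndarray
    counts: np.ndarray
    bin_edges: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.mean_amp.size

    @property
    def has_empty_bins(self) -> bool:
        return bool(np.any(self.counts == 0))

    @property
    def bin_centres(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class PhaseAmplitudeDistribution:
    """Normalised mean-amplitude-per-phase-bin distribution P(i)."""

    P: np.ndarray
    N: int = 0

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if self.N == 0:
            self.N = self.P.size
        if self.N != self.P.size or self.N < 2:
            raise DataError(f"need N = len(P) >= 2 bins, got N={self.N}")
        if np.any(self.P < 0):
            raise DataError("P(i) must be non-negative")
        s = self.P.sum()
        if not math.isclose(s, 1.0, rel_tol=0, abs_tol=1e-9):
            raise DataError(f"P must sum to 1, got {s!r}")
        self.P = self.P / s  # exact renormalisation to machine precision


@dataclass
class MIResult:
    """Modulation Index with the entropy and band pair that produced it."""

    mi: float
    entropy: float
    n_bins: int
    phase_band: BandSpec | None = None
    amp_band: BandSpec | None = None
    n_samples: int = 0

    def to_dict(self) -> dict:
        return {
            "mi": self.mi,
            "entropy": self.entropy,
            "n_bins": self.n_bins,
            "phase_band": None
            if self.phase_band is None
            else [self.phase_band.f_low, self.phase_band.f_high],
            "amp_band": None
            if self.amp_band is None
            else [self.amp_band.f_low, self.amp_band.f_high],
            "n_samples": self.n_samples,
        }


@dataclass
class Comodulogram:
    """MI over a grid of (phase band, amplitude band) pairs.

    Cells whose band pair is infeasible for the sampling rate, or whose
    estimate failed, hold NaN (missing), never zero.
    """

    phase_centres: np.ndarray
    amp_centres: np.ndarray
    mi_grid: np.ndarray
    phase_bw: float
    amp_bw: float | None  # None means adaptive: max(10, 2 * phase centre)

    def argmax(self) -> tuple[float, float]:
        """(phase centre, amplitude centre) of the strongest coupling."""
        grid = np.where(np.isnan(self.mi_grid), -np.inf, self.mi_grid)
        i, j = np.unravel_index(np.argmax(grid), grid.shape)
        return float(self.phase_centres[i]), float(self.amp_centres[j])

    def max_mi(self) -> float:
        return float(np.nanmax(self.mi_grid))


@dataclass
class MITimeCourse:
    """Trial-averaged MI in sliding windows around the reference point."""

    rel_times: np.ndarray
    mi_mean: np.ndarray
    mi_sem: np.ndarray
    window_len: float
    step: float
    mi_trials: np.ndarray | None = None  # (n_trials, n_windows)

    @property
    def peak_time(self) -> float:
        return float(self.rel_times[int(np.argmax(self.mi_mean))])


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Reduce angles to [-pi, pi)."""
    return np.mod(np.asarray(phi, dtype=float) + np.pi, 2 * np.pi) - np.pi


def analytic_decompose(
    ts: TimeSeries, source_band: BandSpec | None = None
) -> tuple[PhaseSeries, AmplitudeEnvelope]:
    """Instantaneous phase and amplitude via the Hilbert analytic signal.

    The input must already be band-limited (the caller's responsibility);
    phase and amplitude of a broadband trace are not interpretable.
    """
    if not np.all(np.isfinite(ts.samples)):
        raise DataError("cannot decompose a series with non-finite samples")
    z = hilbert(ts.samples)
    phase = wrap_phase(np.angle(z))
    amp = np.abs(z)
    margin = max(ts.edge_margin_s, 0.0)
    ph = PhaseSeries(phase, ts.fs, source_band, ts.t0, margin)
    env = AmplitudeEnvelope(amp, ts.fs, source_band, ts.t0, margin)
    return ph, env


def bin_amplitude_by_phase(
    phase: PhaseSeries | np.ndarray,
    amp: AmplitudeEnvelope | np.ndarray,
    n_bins: int = DEFAULT_N_BINS,
    mask: np.ndarray | None = None,
) -> BinnedAmplitude:
    """Mean amplitude in each of ``n_bins`` equal phase bins over [-pi, pi).

    Bin i covers [-pi + i*2pi/N, -pi + (i+1)*2pi/N), left-closed. A boolean
    ``mask`` (True = analyse) lets the caller exclude filter edge margins.
    """
    if n_bins < 2:
        raise ParameterError(f"need at least 2 phase bins, got {n_bins}")
    phi = phase.values if isinstance(phase, PhaseSeries) else np.asarray(phase, float)
    a = amp.values if isinstance(amp, AmplitudeEnvelope) else np.asarray(amp, float)
    if phi.size != a.size:
        raise DataError(
            f"phase ({phi.size}) and amplitude ({a.size}) lengths differ"
        )
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.size != phi.size:
            raise DataError("mask length does not match the series")
        phi, a = phi[mask], a[mask]
    if phi.size == 0:
        raise InsufficientDataError("no samples left to bin after masking")
    phi = wrap_phase(phi)
    width = 2 * np.pi / n_bins
    idx = np.floor((phi + np.pi) / width).astype(np.intp)
    np.clip(idx, 0, n_bins - 1, out=idx)  # guards phi == pi after rounding
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=a, minlength=n_bins)
    mean_amp = np.full(n_bins, np.nan)
    nonzero = counts > 0
    mean_amp[nonzero] = sums[nonzero] / counts[nonzero]
    edges = -np.pi + width * np.arange(n_bins + 1)
    return BinnedAmplitude(mean_amp, counts, edges)


def normalize_distribution(binned: BinnedAmplitude) -> PhaseAmplitudeDistribution:
    """P(i) = mean amplitude in bin i divided by the sum over bins (Eq. P)."""
    if binned.has_empty_bins:
        empty = np.flatnonzero(binned.counts == 0)
        raise EmptyBinError(
            f"phase bins {empty.tolist()} received no samples; the segment is "
            "too short or the phase coverage too narrow for an unbiased MI"
        )
    total = binned.mean_amp.sum()
    if not total > 0:
        raise DegenerateDataError("all mean amplitudes are zero; MI undefined")
    return PhaseAmplitudeDistribution(binned.mean_amp / total, binned.n_bins)


def modulation_index(
    P: PhaseAmplitudeDistribution | Sequence[float],
    phase_band: BandSpec | None = None,
    amp_band: BandSpec | None = None,
    n_samples: int = 0,
) -> MIResult:
    """Shannon entropy H(P) and the Modulation Index (log N - H) / log N.

    The 0*log(0) := 0 convention applies, so a Dirac-like distribution has
    H = 0 and MI = 1; the uniform distribution has H = log N and MI = 0.
    """
    if not isinstance(P, PhaseAmplitudeDistribution):
        P = PhaseAmplitudeDistribution(np.asarray(P, dtype=float))
    p = P.P
    nz = p > 0
    entropy = float(-np.sum(p[nz] * np.log(p[nz])))
    log_n = math.log(P.N)
    mi = (log_n - entropy) / log_n
    # clip floating-point dust just outside [0, 1]
    mi = min(1.0, max(0.0, mi))
    entropy = min(log_n, max(0.0, entropy))
    return MIResult(mi, entropy, P.N, phase_band, amp_band, n_samples)


def mi_from_phase_amp(
    phase: np.ndarray | PhaseSeries,
    amp: np.ndarray | AmplitudeEnvelope,
    n_bins: int = DEFAULT_N_BINS,
    mask: np.ndarray | None = None,
    phase_band: BandSpec | None = None,
    amp_band: BandSpec | None = None,
) -> MIResult:
    """MI straight from already-decomposed phase and amplitude series."""
    binned = bin_amplitude_by_phase(phase, amp, n_bins, mask)
    dist = normalize_distribution(binned)
    return modulation_index(
        dist, phase_band, amp_band, n_samples=int(binned.counts.sum())
    )


def _overlap_slice(a: TimeSeries, b: TimeSeries) -> tuple[TimeSeries, TimeSeries]:
    if a.fs != b.fs:
        raise DataError(f"sampling rates differ: {a.fs} vs {b.fs}")
    t_start = max(a.t0, b.t0)
    t_end = min(a.t0 + a.duration, b.t0 + b.duration)
    if t_end - t_start <= 0:
        raise DataError("the two series do not overlap in time")
    if a.t0 == b.t0 and len(a) == len(b):
        return a, b
    return a.slice_time(t_start, t_end), b.slice_time(t_start, t_end)


class _DecompCache:
    """Per-call cache of band extraction + Hilbert decomposition."""

    def __init__(self) -> None:
        self._store: dict[tuple[int, float, float], tuple] = {}

    def get(self, ts: TimeSeries, band: BandSpec):
        key = (id(ts), band.f_low, band.f_high)
        if key not in self._store:
            filtered = bandpass(ts, band)
            self._store[key] = analytic_decompose(filtered, band)
        return self._store[key]


def _mi_for_bands(
    phase_src: TimeSeries,
    amp_src: TimeSeries,
    phase_band: BandSpec,
    amp_band: BandSpec,
    n_bins: int,
    cache: _DecompCache | None = None,
    return_intermediates: bool = False,
):
    cache = cache or _DecompCache()
    phase, _ = cache.get(phase_src, phase_band)
    _, amp = cache.get(amp_src, amp_band)
    margin = max(phase.edge_margin_s, amp.edge_margin_s)
    n = len(phase)
    k = int(round(margin * phase.fs))
    mask = np.ones(n, dtype=bool)
    if k > 0:
        mask[:k] = False
        mask[n - k:] = False
    analysed_s = mask.sum() / phase.fs
    min_s = 3.0 / phase_band.f_low
    if analysed_s < min_s:
        raise InsufficientDataError(
            f"only {analysed_s:.2f} s of data remain after excluding "
            f"{margin:.2f} s edge margins; need >= 3 cycles of "
            f"{phase_band.f_low} Hz ({min_s:.2f} s)"
        )
    binned = bin_amplitude_by_phase(phase, amp, n_bins, mask)
    dist = normalize_distribution(binned)
    result = modulation_index(
        dist, phase_band, amp_band, n_samples=int(binned.counts.sum())
    )
    if return_intermediates:
        return result, binned, dist
    return result


def compute_mi(
    phase_src: TimeSeries,
    amp_src: TimeSeries,
    phase_band: str | BandSpec = THETA,
    amp_band: str | BandSpec = HIGH_GAMMA,
    n_bins: int = DEFAULT_N_BINS,
) -> MIResult:
    """Full MI chain on raw traces.

    Band-limits the phase source at ``phase_band`` and the amplitude source
    at ``amp_band`` (zero-phase Butterworth), extracts phase and envelope by
    Hilbert transform, excludes the filter edge margins, bins amplitude by
    phase and returns the Modulation Index. Raises
    :class:`InsufficientDataError` if fewer than 3 cycles of the phase
    band's lower edge survive the margin exclusion.
    """
    phase_band = _resolve_band(phase_band)
    amp_band = _resolve_band(amp_band)
    a, b = _overlap_slice(phase_src, amp_src)
    return _mi_for_bands(a, b, phase_band, amp_band, n_bins)


def default_phase_grid() -> np.ndarray:
    """Phase-band centres 2..20 Hz in 1 Hz steps."""
    return np.arange(2.0, 20.0 + 0.5, 1.0)


def default_amp_grid() -> np.ndarray:
    """Amplitude-band centres 20..120 Hz in 5 Hz steps."""
    return np.arange(20.0, 120.0 + 2.5, 5.0)


def adaptive_amp_bw(phase_centre: float) -> float:
    """Amplitude bandwidth wide enough to include modulation side peaks."""
    return max(10.0, 2.0 * phase_centre)


def comodulogram(
    phase_src: TimeSeries,
    amp_src: TimeSeries,
    phase_centres: Iterable[float] | None = None,
    amp_centres: Iterable[float] | None = None,
    phase_bw: float = 2.0,
    amp_bw: float | None = None,
    n_bins: int = DEFAULT_N_BINS,
) -> Comodulogram:
    """MI over a grid of (phase, amplitude) band pairs.

    The phase bands are kept narrow (default 2 Hz) so the instantaneous
    phase is well defined; the amplitude bands are widened with the phase
    frequency (default max(10, 2 * phase centre) Hz) so the modulation side
    peaks at f_A +/- f_p fall inside the band. Cells whose band would reach
    DC or the Nyquist frequency, and cells whose estimate fails, are NaN.
    """
    phase_centres = (
        default_phase_grid() if phase_centres is None else np.asarray(
            list(phase_centres), dtype=float)
    )
    amp_centres = (
        default_amp_grid() if amp_centres is None else np.asarray(
            list(amp_centres), dtype=float)
    )
    a, b = _overlap_slice(phase_src, amp_src)
    nyq = a.fs / 2
    cache = _DecompCache()
    grid = np.full((phase_centres.size, amp_centres.size), np.nan)
    for i, pc in enumerate(phase_centres):
        p_lo, p_hi = pc - phase_bw / 2, pc + phase_bw / 2
        if p_lo <= 0 or p_hi >= nyq:
            continue
        pband = BandSpec(f"phase_{pc:g}Hz", p_lo, p_hi)
        bw = adaptive_amp_bw(pc) if amp_bw is None else amp_bw
        for j, ac in enumerate(amp_centres):
            a_lo, a_hi = ac - bw / 2, ac + bw / 2
            if a_lo <= 0 or a_hi >= nyq:
                continue
            aband = BandSpec(f"amp_{ac:g}Hz", a_lo, a_hi)
            try:
                grid[i, j] = _mi_for_bands(a, b, pband, aband, n_bins, cache).mi
            except (InsufficientDataError, EmptyBinError, DegenerateDataError):
                pass  # recorded as missing
    return Comodulogram(phase_centres, amp_centres, grid, phase_bw, amp_bw)


def _window_centres(
    span: tuple[float, float], window_len: float, step: float
) -> np.ndarray:
    lo = span[0] + window_len / 2
    hi = span[1] - window_len / 2
    n = int(math.floor((hi - lo) / step + 1e-9)) + 1
    return lo + step * np.arange(n)


def _decompose_trial(
    phase_seg: TimeSeries,
    amp_seg: TimeSeries,
    phase_band: BandSpec,
    amp_band: BandSpec,
) -> tuple[PhaseSeries, AmplitudeEnvelope]:
    ph, _ = analytic_decompose(bandpass(phase_seg, phase_band), phase_band)
    _, env = analytic_decompose(bandpass(amp_seg, amp_band), amp_band)
    return ph, env


def _usable_interval(
    ph: PhaseSeries, env: AmplitudeEnvelope
) -> tuple[float, float]:
    margin = max(ph.edge_margin_s, env.edge_margin_s)
    t0 = ph.t0 + margin
    t1 = ph.t0 + len(ph) / ph.fs - margin
    return t0, t1


def mi_timecourse(
    trial_pairs: Sequence[tuple[TimeSeries, TimeSeries]],
    phase_band: str | BandSpec = THETA,
    amp_band: str | BandSpec = HIGH_GAMMA,
    window_len: float = 1.0,
    step: float = 0.1,
    span: tuple[float, float] = (-4.0, 4.0),
    n_bins: int = DEFAULT_N_BINS,
) -> MITimeCourse:
    """Trial-aligned MI time course around the reference point (RP).

    ``trial_pairs`` are (phase-region, amplitude-region) LFP segments whose
    ``t0`` is expressed relative to the RP (RP = 0 s). MI is computed per
    trial in sliding windows (centre reported in ``rel_times``), then
    averaged across trials; the SEM is across trials. Segments must extend
    beyond ``span`` by the filter edge margin (about 1 s); use
    ``align_lfp_to_trials(..., pad_s=...)`` to cut padded segments.
    """
    if len(trial_pairs) == 0:
        raise InsufficientDataError("no trials supplied")
    phase_band = _resolve_band(phase_band)
    amp_band = _resolve_band(amp_band)
    centres = _window_centres(span, window_len, step)
    mi_trials = np.empty((len(trial_pairs), centres.size))
    for k, (pseg, aseg) in enumerate(trial_pairs):
        ph, env = _decompose_trial(pseg, aseg, phase_band, amp_band)
        lo, hi = _usable_interval(ph, env)
        if lo > span[0] + 1e-9 or hi < span[1] - 1e-9:
            raise InsufficientDataError(
                f"trial {k}: usable interval [{lo:.2f}, {hi:.2f}] s does not "
                f"cover the requested span {span}; supply padded segments"
            )
        t = ph.t0 + np.arange(len(ph)) / ph.fs
        for w, c in enumerate(centres):
            sel = (t >= c - window_len / 2) & (t < c + window_len / 2)
            mi_trials[k, w] = mi_from_phase_amp(
                ph.values[sel], env.values[sel], n_bins
            ).mi
    mean = mi_trials.mean(axis=0)
    if mi_trials.shape[0] > 1:
        sem = mi_trials.std(axis=0, ddof=1) / math.sqrt(mi_trials.shape[0])
    else:
        sem = np.zeros_like(mean)
    return MITimeCourse(centres, mean, sem, window_len, step, mi_trials)


def zone_mi(
    trial_pairs: Sequence[tuple[TimeSeries, TimeSeries]],
    phase_band: str | BandSpec = THETA,
    amp_band: str | BandSpec = HIGH_GAMMA,
    n_bins: int = DEFAULT_N_BINS,
    method: str = "segment",
    window_len: float = 1.0,
    step: float = 0.1,
) -> "np.ndarray":
    """Per-trial MI in the peripheral ([-4, 0) s) and central ([0, 4) s) zones.

    ``method='segment'`` (default) computes one MI per 4 s zone segment —
    longer segments stabilise the entropy estimate. ``method='windowed'``
    averages sliding-window MI within each zone instead.

    Returns an array of shape (n_trials, 2): columns (peripheral, central).
    """
    if len(trial_pairs) == 0:
        raise InsufficientDataError("no trials supplied")
    if method not in ("segment", "windowed"):
        raise ParameterError(f"method must be 'segment' or 'windowed', got {method!r}")
    phase_band = _resolve_band(phase_band)
    amp_band = _resolve_band(amp_band)
    out = np.empty((len(trial_pairs), 2))
    zones = ((-4.0, 0.0), (0.0, 4.0))
    for k, (pseg, aseg) in enumerate(trial_pairs):
        ph, env = _decompose_trial(pseg, aseg, phase_band, amp_band)
        lo, hi = _usable_interval(ph, env)
        if lo > -4.0 + 1e-9 or hi < 4.0 - 1e-9:
            raise InsufficientDataError(
                f"trial {k}: usable interval [{lo:.2f}, {hi:.2f}] s does not "
                "cover [-4, 4] s; supply padded segments"
            )
        t = ph.t0 + np.arange(len(ph)) / ph.fs
        for z, (z0, z1) in enumerate(zones):
            if method == "segment":
                sel = (t >= z0) & (t < z1)
                out[k, z] = mi_from_phase_amp(
                    ph.values[sel], env.values[sel], n_bins
                ).mi
            else:
                centres = _window_centres((z0, z1), window_len, step)
                vals = []
                for c in centres:
                    sel = (t >= c - window_len / 2) & (t < c + window_len / 2)
                    vals.append(
                        mi_from_phase_amp(ph.values[sel], env.values[sel], n_bins).mi
                    )
                out[k, z] = float(np.mean(vals))
    return out
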