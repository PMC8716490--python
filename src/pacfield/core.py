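"""Core containers for band-limited voltage traces and frequency bands.

The package analyses local field potentials (LFPs): extracellular voltage
traces sampled uniformly in time, in microvolts. A :class:`TimeSeries`
carries the samples together with the sampling rate, start time, a region
label (e.g. ``mPFC`` or ``BLA``) and an *edge margin* — the span at each end
of the trace that zero-phase IIR filtering and Hilbert transforms may have
distorted. Downstream coupling estimators exclude the margins rather than
trimming samples silently.

A :class:`BandSpec` names a frequency band. The canonical rodent LFP bands
(delta 1–4 Hz, theta 4–12 Hz, beta 12–30 Hz, low gamma 30–70 Hz, high gamma
70–120 Hz) are provided in :data:`CANONICAL_BANDS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "TimeSeries",
    "BandSpec",
    "CANONICAL_BANDS",
    "PacfieldError",
    "ConfigError",
    "ParameterError",
    "DataError",
    "FormatError",
    "InsufficientDataError",
    "DegenerateDataError",
    "EmptyBinError",
]


class PacfieldError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(PacfieldError, ValueError):
    """A configuration violates one of its invariants."""


class ParameterError(PacfieldError, ValueError):
    """An operation parameter is out of its valid range."""


class DataError(PacfieldError, ValueError):
    """Input data violates a contract (non-finite values, length mismatch...)."""


class FormatError(PacfieldError, ValueError):
    """A file does not conform to the expected delimited-text format."""


class InsufficientDataError(DataError):
    """Too little data for a statistically meaningful estimate."""


class DegenerateDataError(DataError):
    """Input is degenerate (e.g. all-zero amplitudes: MI undefined)."""


class EmptyBinError(DataError):
    """One or more phase bins received no samples."""


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band [f_low, f_high] in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not (0.0 < self.f_low < self.f_high):
            raise ParameterError(
                f"band {self.name!r}: need 0 < f_low < f_high, got "
                f"[{self.f_low}, {self.f_high}]"
            )

    @property
    def centre(self) -> float:
        return 0.5 * (self.f_low + self.f_high)

    @property
    def bandwidth(self) -> float:
        return self.f_high - self.f_low

    def validate_for_fs(self, fs: float) -> None:
        if self.f_high >= fs / 2:
            raise ParameterError(
                f"band {self.name!r} upper edge {self.f_high} Hz is at or above "
                f"the Nyquist frequency {fs / 2} Hz"
            )


CANONICAL_BANDS: Mapping[str, BandSpec] = {
    "delta": BandSpec("delta", 1.0, 4.0),
    "theta": BandSpec("theta", 4.0, 12.0),
    "beta": BandSpec("beta", 12.0, 30.0),
    "low_gamma": BandSpec("low_gamma", 30.0, 70.0),
    "high_gamma": BandSpec("high_gamma", 70.0, 120.0),
}


@dataclass
class TimeSeries:
    """A uniformly sampled voltage trace.

    Parameters
    ----------
    samples : array of float
        Voltage in microvolts.
    fs : float
        Sampling rate in Hz, > 0.
    t0 : float
        Time of the first sample in seconds.
    region : str
        Anatomical label ("mPFC", "BLA" or "other").
    edge_margin_s : float
        Span at each end, in seconds, contaminated by filter/Hilbert edge
        transients. Estimators that are sensitive to phase and amplitude
        exclude these margins.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    region: str = "other"
    edge_margin_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise DataError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 1:
            raise DataError("samples must be one-dimensional")
        if self.samples.size < 2:
            raise DataError("a time series needs at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise DataError("samples contain non-finite values")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Span covered by the samples, in seconds (n/fs)."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    def margin_mask(self) -> np.ndarray:
        """Boolean mask that is True outside the edge margins."""
        n = self.samples.size
        k = int(round(self.edge_margin_s * self.fs))
        mask = np.ones(n, dtype=bool)
        if k > 0:
            mask[:k] = False
            mask[n - k:] = False
        return mask

    def with_samples(self, samples: np.ndarray, **changes) -> "TimeSeries":
        """Copy of this series with new samples (metadata preserved)."""
        out = replace(self, **changes)
        out.samples = np.asarray(samples, dtype=float)
        return out

    def slice_time(self, t_start: float, t_end: float) -> "TimeSeries":
        """Sub-series covering [t_start, t_end), cut at sample precision."""
        i0 = int(round((t_start - self.t0) * self.fs))
        i1 = int(round((t_end - self.t0) * self.fs))
        if i0 < 0 or i1 > self.samples.size or i1 - i0 < 2:
            raise DataError(
                f"slice [{t_start}, {t_end}) s outside the series support "
                f"[{self.t0}, {self.t0 + self.duration}) s"
            )
        out = replace(self, t0=self.t0 + i0 / self.fs, edge_margin_s=0.0)
        out.samples = self.samples[i0:i1].copy()
        return out
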