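"""Spike-train spectral analysis: population-rate signals, Welch spectra,
band powers and firing-rate summaries.

Spectral estimates are based on pyramidal-population spiking only: the spike
trains are binned into a population rate signal (mean-subtracted spike counts
per bin), and the power spectrum is a Welch-averaged periodogram of that
signal.  Band powers reduce the spectrum over named frequency bands — delta
0.5–5 Hz is the primary readout; theta, alpha, beta and gamma are reported
alongside.  LOESS smoothing is provided for presentation only and is never
used in statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from statsmodels.nonparametric.smoothers_lowess import lowess

from .exceptions import ValidationError

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "CAPTION_BANDS",
    "SpectralConfig",
    "PowerSpectrum",
    "RateSignal",
    "population_rate_signal",
    "power_spectrum",
    "band_power",
    "delta_power_ratio",
    "firing_rate",
    "loess_smooth",
]


@dataclass(frozen=True)
class BandDefinition:
    """Named, non-overlapping [low, high) frequency bands in Hz."""

    bands: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        prev_high = -np.inf
        for name, lo, hi in self.bands:
            if not lo < hi:
                raise ValidationError(f"band {name}: need low < high")
            if lo < prev_high:
                raise ValidationError(f"band {name}: bands overlap")
            prev_high = hi

    def __getitem__(self, name: str) -> tuple[float, float]:
        for n, lo, hi in self.bands:
            if n == name:
                return (lo, hi)
        raise KeyError(name)

    def names(self) -> list[str]:
        return [n for n, _, _ in self.bands]


#: Default edges; the beta band follows the 12–30 Hz convention.
DEFAULT_BANDS = BandDefinition((
    ("delta", 0.5, 5.0),
    ("theta", 5.0, 8.0),
    ("alpha", 8.0, 12.0),
    ("beta", 12.0, 30.0),
    ("gamma", 30.0, 150.0),
))

#: Variant with beta starting at 13 Hz (figure-caption convention).
CAPTION_BANDS = BandDefinition((
    ("delta", 0.5, 5.0),
    ("theta", 5.0, 8.0),
    ("alpha", 8.0, 12.0),
    ("beta", 13.0, 30.0),
    ("gamma", 30.0, 150.0),
))


@dataclass(frozen=True)
class SpectralConfig:
    """Estimator settings; persisted with every spectrum for reproducibility."""

    bin_ms: float = 1.0
    segment_ms: float = 8192.0  # Welch segment; resolves 0.5 Hz comfortably
    overlap: float = 0.5
    window: str = "hann"
    transient_ms: float = 1000.0  # discarded before analysis


@dataclass
class RateSignal:
    """Binned, mean-subtracted population spike-count series."""

    values: np.ndarray
    bin_ms: float
    t0_ms: float  # start of the analysis window (post transient)
    total_count: int  # raw spike count in the window

    @property
    def fs(self) -> float:
        """Sampling rate, Hz."""
        return 1000.0 / self.bin_ms


@dataclass
class PowerSpectrum:
    frequencies: np.ndarray  # Hz, strictly increasing
    power: np.ndarray  # >= 0, arbitrary units
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValidationError("frequency grid must be strictly increasing")
        if np.any(self.power < 0):
            raise ValidationError("negative spectral power")

    def save(self, path) -> None:
        np.savetxt(path, np.column_stack([self.frequencies, self.power]),
                   header=f"frequency_Hz power  # {self.metadata}")


def population_rate_signal(spikes, population: str = "PC",
                           bin_ms: float = 1.0,
                           transient_ms: float | None = None) -> RateSignal:
    """Population spike-count series over the post-transient window.

    ``spikes`` is a SpikeTrainSet (see network module).  Counts are summed over
    all neurons of ``population`` per bin and mean-subtracted.
    """
    idx = [i for i, p in enumerate(spikes.populations) if p == population]
    if not idx:
        raise ValidationError(f"population {population!r} is empty")
    t0 = spikes.transient if transient_ms is None else transient_ms
    t1 = spikes.duration
    if t1 <= t0:
        raise ValidationError("duration must exceed the transient")
    n_bins = int(np.floor((t1 - t0) / bin_ms))
    edges = t0 + np.arange(n_bins + 1) * bin_ms
    counts = np.zeros(n_bins)
    total = 0
    for i in idx:
        st = spikes.spike_times[i]
        st = st[(st > t0) & (st <= edges[-1])]
        total += st.size
        if st.size:
            counts += np.histogram(st, bins=edges)[0]
    return RateSignal(values=counts - counts.mean(), bin_ms=bin_ms, t0_ms=t0,
                      total_count=total)


def power_spectrum(rate: RateSignal, config: SpectralConfig = SpectralConfig(),
                   seed: int | None = None) -> PowerSpectrum:
    """Welch-averaged periodogram of a rate signal (Parseval-consistent PSD)."""
    nperseg = int(round(config.segment_ms / rate.bin_ms))
    noverlap = int(round(nperseg * config.overlap))
    min_len = nperseg + (nperseg - noverlap)  # at least two segments
    if rate.values.size < min_len:
        raise ValidationError(
            f"series of {rate.values.size} samples is too short for "
            f"{nperseg}-sample Welch segments (need >= {min_len})"
        )
    f, p = sps.welch(rate.values, fs=rate.fs, window=config.window,
                     nperseg=nperseg, noverlap=noverlap, detrend="constant")
    return PowerSpectrum(f[1:], p[1:], metadata={
        "bin_ms": rate.bin_ms, "segment_ms": config.segment_ms,
        "overlap": config.overlap, "window": config.window, "seed": seed,
    })


def band_power(ps: PowerSpectrum, band: tuple[float, float] | str,
               bands: BandDefinition = DEFAULT_BANDS,
               reduction: str = "mean") -> float:
    """Mean (or, optionally, summed) power over frequencies in [low, high)."""
    lo, hi = bands[band] if isinstance(band, str) else band
    mask = (ps.frequencies >= lo) & (ps.frequencies < hi)
    if not np.any(mask):
        raise ValidationError(f"no frequencies in band [{lo}, {hi}) Hz")
    if reduction == "mean":
        return float(np.mean(ps.power[mask]))
    if reduction == "sum":
        return float(np.sum(ps.power[mask]))
    raise ValueError(f"unknown reduction {reduction!r}")


def delta_power_ratio(test: PowerSpectrum, control: PowerSpectrum,
                      band: tuple[float, float] | str = "delta",
                      bands: BandDefinition = DEFAULT_BANDS) -> float:
    """Band power of ``test`` as a percentage of ``control``."""
    return 100.0 * band_power(test, band, bands) / band_power(control, band, bands)


def firing_rate(spikes, population: str,
                transient_ms: float | None = None) -> float:
    """Mean firing rate per neuron (Hz) over the post-transient window."""
    idx = [i for i, p in enumerate(spikes.populations) if p == population]
    if not idx:
        raise ValidationError(f"population {population!r} is empty")
    t0 = spikes.transient if transient_ms is None else transient_ms
    window_s = (spikes.duration - t0) / 1000.0
    total = sum(
        int(np.sum((spikes.spike_times[i] > t0) & (spikes.spike_times[i] <= spikes.duration)))
        for i in idx
    )
    return total / (len(idx) * window_s)


def loess_smooth(ps: PowerSpectrum, span: float = 0.15) -> PowerSpectrum:
    """Locally weighted regression smoothing of a spectrum (presentation only)."""
    if not 0.0 < span <= 1.0:
        raise ValidationError("span must be in (0, 1]")
    sm = lowess(ps.power, ps.frequencies, frac=span, it=0, return_sorted=False)
    return PowerSpectrum(ps.frequencies.copy(), np.maximum(sm, 0.0),
                         metadata={**ps.metadata, "loess_span": span})
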