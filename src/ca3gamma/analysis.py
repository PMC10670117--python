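"""LFP construction and spectral statistics.

The LFP proxy is the pyramidal-population mean of the distal-apical minus
basal dendritic voltage; γ power is the sum of Welch spectral power over
30–100 Hz.  "Raster γ" applies the same band-power measure to the pooled
all-neuron spike train smoothed with a 5 ms boxcar, which captures the
spiking rhythmicity while ignoring subthreshold voltage structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "LfpTrace",
    "PowerSpectrum",
    "ConditionResult",
    "compute_lfp",
    "welch_power",
    "band_power",
    "peak_frequency",
    "delta_gamma",
    "raster_gamma",
    "mean_rate",
    "GAMMA_BAND",
]

GAMMA_BAND = (30.0, 100.0)


@dataclass
class LfpTrace:
    values: np.ndarray  # mV
    fs: float  # Hz
    window: tuple[float, float]  # (start, end) ms


@dataclass
class PowerSpectrum:
    frequencies: np.ndarray  # Hz, increasing
    power: np.ndarray  # Welch density per bin

    def __post_init__(self) -> None:
        if np.any(np.diff(self.frequencies) <= 0) or self.frequencies[0] < 0:
            raise ValueError("frequencies must be nonnegative and increasing")


@dataclass
class ConditionResult:
    """Per-run metrics for one (krec, kext, seed) condition."""

    krec: float
    kext: float
    seed: int
    lfp_gamma: float
    raster_gamma: float
    delta_gamma: float
    pyr_rate: float  # Hz, mean over pyramidal cells
    epileptic: bool = False


def compute_lfp(result) -> LfpTrace:
    """Pyramidal-averaged distal-minus-basal dendritic voltage, analysis
    window only (equilibration excluded)."""
    if result.v_adend3 is None or result.v_bdend is None:
        raise ValueError("dendritic voltage traces were not recorded")
    t = result.rec_times
    lo, hi = result.analysis_window
    sel = (t >= lo) & (t < hi)
    diff = result.v_adend3[sel].astype(float) - result.v_bdend[sel].astype(float)
    values = diff.mean(axis=1)
    fs = 1000.0 / (t[1] - t[0])
    return LfpTrace(values=values, fs=fs, window=(lo, hi))


def welch_power(trace, fs: float | None = None, segment_len: float = 1.0,
                overlap: float = 0.5) -> PowerSpectrum:
    """Welch periodogram (Hann window, `segment_len` s segments).

    `trace` may be an :class:`LfpTrace` or a plain array with `fs` given.
    """
    if isinstance(trace, LfpTrace):
        x, fs = trace.values, trace.fs
    else:
        x = np.asarray(trace, dtype=float)
        if fs is None:
            raise ValueError("fs required for a plain array")
    nperseg = int(round(segment_len * fs))
    if x.size < nperseg:
        raise ValueError(
            f"trace of {x.size} samples shorter than one {nperseg}-sample segment"
        )
    f, p = sps.welch(x, fs=fs, window="hann", nperseg=nperseg,
                     noverlap=int(nperseg * overlap), detrend="constant")
    return PowerSpectrum(frequencies=f, power=p)


def band_power(spec: PowerSpectrum, lo: float = GAMMA_BAND[0],
               hi: float = GAMMA_BAND[1]) -> float:
    """Sum of spectral power over bins with lo <= f <= hi."""
    sel = (spec.frequencies >= lo) & (spec.frequencies <= hi)
    if not np.any(sel):
        raise ValueError(f"no spectral bins inside [{lo}, {hi}] Hz")
    return float(np.sum(spec.power[sel]))


def peak_frequency(spec: PowerSpectrum, lo: float = 1.0,
                   hi: float | None = None) -> float:
    """Frequency of maximum power, optionally restricted to [lo, hi]."""
    sel = spec.frequencies >= lo
    if hi is not None:
        sel &= spec.frequencies <= hi
    f, p = spec.frequencies[sel], spec.power[sel]
    return float(f[np.argmax(p)])


def delta_gamma(gamma_cond: float, gamma_ctrl: float) -> float:
    """Relative γ-power change of a condition vs. its control: ratio − 1."""
    if gamma_ctrl <= 0:
        raise ValueError("control γ power must be positive")
    return gamma_cond / gamma_ctrl - 1.0


def pooled_rate_signal(spike_times: np.ndarray, window: tuple[float, float],
                       kernel_width: float = 5.0, bin_ms: float = 1.0
                       ) -> tuple[np.ndarray, float]:
    """Boxcar-smoothed pooled spike counts on the analysis grid.

    Returns (signal, sample rate Hz).  The boxcar has unit area, so the
    signal is in spikes per bin.
    """
    lo, hi = window
    t = np.asarray(spike_times, dtype=float)
    t = t[(t >= lo) & (t < hi)]
    n_bins = int(round((hi - lo) / bin_ms))
    counts, _ = np.histogram(t, bins=n_bins, range=(lo, lo + n_bins * bin_ms))
    k = max(1, int(round(kernel_width / bin_ms)))
    boxcar = np.full(k, 1.0 / k)
    smoothed = np.convolve(counts.astype(float), boxcar, mode="same")
    return smoothed, 1000.0 / bin_ms


def raster_gamma(spike_times: np.ndarray, window: tuple[float, float],
                 kernel_width: float = 5.0, bin_ms: float = 1.0,
                 band: tuple[float, float] = GAMMA_BAND,
                 segment_len: float = 1.0) -> float:
    """γ band power of the pooled spike train.

    Spikes of all neurons (already pooled in `spike_times`, ms) inside
    `window` are binned at `bin_ms`, convolved with a unit-area boxcar of
    `kernel_width` ms, and the result is treated exactly like an LFP:
    Welch spectrum, then band power.  Empty rasters yield 0.
    """
    t = np.asarray(spike_times, dtype=float)
    t = t[(t >= window[0]) & (t < window[1])]
    if t.size == 0:
        return 0.0
    smoothed, fs = pooled_rate_signal(spike_times, window, kernel_width,
                                      bin_ms)
    spec = welch_power(smoothed, fs=fs, segment_len=segment_len)
    return band_power(spec, *band)


def mean_rate(result, population: str,
              window: tuple[float, float] | None = None) -> float:
    """Population mean firing rate (Hz) in the analysis window."""
    if window is None:
        window = result.analysis_window
    if window[1] <= window[0]:
        raise ValueError("window must have positive length")
    t, _ = result.spikes_of(population, window=window)
    n_cells = {"pyr": result.n_pyr, "bas": result.n_bas, "olm": result.n_olm}[
        population
    ]
    return float(t.size / n_cells / ((window[1] - window[0]) / 1000.0))
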