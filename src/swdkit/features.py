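"""Per-epoch detection features.

Filtered segments are divided into 500-ms non-overlapping epochs, and
four features are computed per epoch:

* **amp_corr** — amplitude correlation: the lag-0 Pearson correlation
  between an epoch and its successor. Rhythmic discharges repeat almost
  identically across consecutive 500-ms windows (three cycles of a 6 Hz
  spike-wave pattern), driving this toward 1, while background noise
  decorrelates. The phrase "autocorrelation between successive epochs" is
  read as lag-0 Pearson correlation; a sliding-lag maximum is available
  via ``max_lag``.
* **rms** — root-mean-square amplitude of the epoch (µV).
* **spike_density** — count of sharp extrema exceeding a robust
  amplitude criterion (multiples of the parent segment's 1.4826 x MAD),
  with a refractory spacing, divided by the epoch length (spikes/s).
* **band_ratio** — spectral power in the upper band (20–50 Hz) contrasted
  with the lower band (0.5–20 Hz); a ratio by default. With 500-ms epochs
  the frequency resolution is 2 Hz, so the lower band effectively starts
  at 2 Hz; an optional longer Welch context window restores band
  fidelity.

Band edges are half-open ``[low, high)`` so the 20 Hz bin is not counted
twice.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import signal as sps

from .config import DetectionConfig
from .preprocessing import Segment

__all__ = [
    "epoch_signal",
    "amplitude_correlation",
    "rms",
    "robust_sd",
    "spike_density",
    "band_power_ratio",
    "feature_matrix",
]


def epoch_signal(
    samples: np.ndarray, sampling_rate: float, epoch_length: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Cut a 1-D signal into non-overlapping epochs.

    Returns ``(epochs, starts)`` where ``epochs`` has shape
    ``(n_epochs, epoch_samples)`` and ``starts`` holds epoch onsets in
    seconds from the start of ``samples``. A trailing partial window is
    discarded; a signal shorter than one epoch yields zero epochs with a
    warning.
    """
    x = np.asarray(samples, dtype=np.float64)
    n_per = round(epoch_length * sampling_rate)
    n_epochs = x.size // n_per
    if n_epochs == 0:
        warnings.warn("signal shorter than one epoch; no epochs produced", stacklevel=2)
        return np.empty((0, n_per)), np.empty(0)
    epochs = x[: n_epochs * n_per].reshape(n_epochs, n_per)
    starts = np.arange(n_epochs) * epoch_length
    return epochs, starts


def amplitude_correlation(
    x: np.ndarray,
    y: np.ndarray,
    max_lag: int = 0,
    return_flag: bool = False,
) -> float | tuple[float, bool]:
    """Pearson correlation of two equal-length epochs at lag 0.

    With ``max_lag > 0`` the maximum correlation over integer lags in
    ``[-max_lag, max_lag]`` is returned instead. If either epoch has zero
    variance the correlation is undefined; 0.0 is returned (with
    ``degenerate=True`` when ``return_flag``).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"epoch length mismatch: {x.size} vs {y.size}")

    def _pearson(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
        a = a - a.mean()
        b = b - b.mean()
        na = np.sqrt(np.dot(a, a))
        nb = np.sqrt(np.dot(b, b))
        if na == 0 or nb == 0:
            return 0.0, True
        return float(np.dot(a, b) / (na * nb)), False

    if max_lag == 0:
        r, flag = _pearson(x, y)
    else:
        best, flag = _pearson(x, y)
        for lag in range(1, max_lag + 1):
            for a, b in ((x[lag:], y[: y.size - lag]), (x[: x.size - lag], y[lag:])):
                r, f = _pearson(a, b)
                if r > best:
                    best, flag = r, f
        r = best
    return (r, flag) if return_flag else r


def rms(x: np.ndarray) -> float:
    """Root-mean-square amplitude, sqrt(mean(x^2))."""
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty epoch")
    return float(np.sqrt(np.mean(x**2)))


def robust_sd(x: np.ndarray) -> float:
    """Robust SD estimate: 1.4826 x median absolute deviation."""
    x = np.asarray(x, dtype=np.float64)
    return float(1.4826 * np.median(np.abs(x - np.median(x))))


def spike_density(
    epoch: np.ndarray,
    threshold_multiplier: float = 5.0,
    refractory: float = 0.03,
    segment_scale: float = 1.0,
    sampling_rate: float = 2000.0,
) -> float:
    """Spikes per second within one epoch.

    A spike is a local maximum of ``|epoch|`` above
    ``threshold_multiplier * segment_scale`` (the scale being the robust
    SD of the parent filtered segment). Extrema closer than ``refractory``
    seconds are resolved in favour of the larger one.
    """
    if segment_scale <= 0:
        raise ValueError("segment_scale must be positive (robust SD of the parent segment)")
    x = np.abs(np.asarray(epoch, dtype=np.float64))
    distance = max(1, round(refractory * sampling_rate))
    peaks, _ = sps.find_peaks(x, height=threshold_multiplier * segment_scale, distance=distance)
    return peaks.size / (epoch.size / sampling_rate)


def band_power_ratio(
    epoch: np.ndarray,
    sampling_rate: float,
    band_low: tuple[float, float] = (0.5, 20.0),
    band_high: tuple[float, float] = (20.0, 50.0),
    mode: str = "ratio",
) -> float:
    """Upper-band power contrasted with lower-band power.

    Powers are integrated from a Hann-windowed periodogram over bins whose
    centers fall in each half-open band ``[low, high)``. In ``"ratio"``
    mode the result is ``P_high / (P_low + eps)`` with
    ``eps = 1e-12 x total power`` guarding the division; ``"difference"``
    mode returns ``P_high - P_low``.
    """
    f, p = sps.periodogram(np.asarray(epoch, dtype=np.float64), fs=sampling_rate, window="hann")
    low = p[(f >= band_low[0]) & (f < band_low[1])].sum()
    high = p[(f >= band_high[0]) & (f < band_high[1])].sum()
    if mode == "difference":
        return float(high - low)
    eps = 1e-12 * p.sum()
    if low + eps == 0:
        return 0.0
    return float(high / (low + eps))


def _context_band_power(
    samples: np.ndarray,
    i0: int,
    i1: int,
    context_samples: int,
    sampling_rate: float,
    band_low: tuple[float, float],
    band_high: tuple[float, float],
    mode: str,
) -> float:
    """Band contrast over a longer window centered on epoch [i0, i1)."""
    mid = (i0 + i1) // 2
    lo = max(0, mid - context_samples // 2)
    hi = min(samples.size, lo + context_samples)
    lo = max(0, hi - context_samples)
    return band_power_ratio(samples[lo:hi], sampling_rate, band_low, band_high, mode)


def feature_matrix(segment: Segment, config: DetectionConfig | None = None) -> pd.DataFrame:
    """Compute the four features for every epoch of a filtered segment.

    Returns one row per epoch with columns ``epoch_start_s``, ``amp_corr``,
    ``rms``, ``spike_density``, ``band_ratio``, plus bookkeeping flags:
    ``amp_corr_copied`` (the final epoch has no successor, so it copies the
    previous pair's value) and ``amp_corr_degenerate`` (a zero-variance
    epoch was involved). ``epoch_start_s`` is absolute, i.e. includes the
    segment offset.
    """
    config = config or DetectionConfig()
    fs = segment.sampling_rate
    epochs, rel_starts = epoch_signal(segment.samples, fs, config.epoch_length)
    n = epochs.shape[0]
    scale = robust_sd(segment.samples)

    amp = np.zeros(n)
    copied = np.zeros(n, dtype=bool)
    degenerate = np.zeros(n, dtype=bool)
    rms_v = np.zeros(n)
    dens = np.zeros(n)
    ratio = np.zeros(n)

    n_per = epochs.shape[1] if n else round(config.epoch_length * fs)
    context_samples = (
        round(config.band_context * fs) if config.band_context is not None else None
    )

    for i in range(n):
        e = epochs[i]
        rms_v[i] = rms(e)
        if scale > 0:
            dens[i] = spike_density(
                e, config.spike.threshold_multiplier, config.spike.refractory, scale, fs
            )
        if context_samples is None:
            ratio[i] = band_power_ratio(
                e, fs, config.band_low, config.band_high, config.band_mode
            )
        else:
            ratio[i] = _context_band_power(
                segment.samples, i * n_per, (i + 1) * n_per, context_samples,
                fs, config.band_low, config.band_high, config.band_mode,
            )
        if i < n - 1:
            amp[i], degenerate[i] = amplitude_correlation(
                e, epochs[i + 1], max_lag=config.amp_corr_max_lag, return_flag=True
            )
    if n >= 2:
        amp[n - 1] = amp[n - 2]
        degenerate[n - 1] = degenerate[n - 2]
        copied[n - 1] = True
    elif n == 1:
        copied[0] = True

    return pd.DataFrame(
        {
            "epoch_start_s": segment.start + rel_starts,
            "amp_corr": amp,
            "rms": rms_v,
            "spike_density": dens,
            "band_ratio": ratio,
            "amp_corr_copied": copied,
            "amp_corr_degenerate": degenerate,
        }
    )
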