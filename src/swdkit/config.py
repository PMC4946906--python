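"""Configuration objects for simulation and detection.

Every algorithm constant is carried by a small frozen-default dataclass so
that a run is fully described by (config, seed). Configs round-trip through
YAML via :func:`load_yaml` / :func:`dump_yaml`.

Defaults mirror the acquisition and analysis conditions the toolkit
emulates: 2 kHz sampling, a 3rd-order 0.5–400 Hz Butterworth bandpass,
10-minute analysis segments, and 500-ms non-overlapping feature epochs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "BackgroundParams",
    "SWDParams",
    "SimConfig",
    "FilterSpec",
    "SpikeCriteria",
    "FeatureThreshold",
    "ThresholdSpec",
    "DetectionConfig",
    "load_yaml",
    "dump_yaml",
    "config_hash",
]


@dataclass
class BackgroundParams:
    """Colored-noise background model at a target RMS.

    The power spectrum follows the standard aperiodic form for cortical
    field potentials, ``S(f) = 1 / (1 + (f / knee_freq)^alpha)``: flat
    below the knee, ``1/f^alpha`` above it. The default exponent of 2
    reproduces the steep, delta-dominated spectrum of rodent cortical EEG
    (little relative power above 20 Hz); ``knee_freq = 0`` gives a pure
    power law. ``line_noise_amplitude`` adds an optional mains-frequency
    sinusoid (peak amplitude, µV) at ``line_noise_freq`` Hz.
    """

    rms_amplitude: float = 50.0  # µV
    spectral_exponent: float = 2.0  # alpha in 1/f^alpha above the knee
    knee_freq: float = 1.0  # Hz; 0 = pure power law
    line_noise_amplitude: float = 0.0  # µV peak
    line_noise_freq: float = 60.0  # Hz

    def validate(self) -> None:
        if self.rms_amplitude < 0:
            raise ValueError("rms_amplitude must be >= 0")
        if not (0 <= self.spectral_exponent <= 3):
            raise ValueError("spectral_exponent must be in [0, 3]")
        if self.knee_freq < 0:
            raise ValueError("knee_freq must be >= 0")


@dataclass
class SWDParams:
    """Generative model of a spike-and-wave discharge (SWD).

    Episodes arrive as a homogeneous Poisson process at ``rate`` per hour;
    durations are normal(``duration_mean``, ``duration_sd``) truncated below
    at ``duration_min``. The waveform repeats at ``fundamental`` Hz; each
    cycle is a slow sinusoid plus a sharp raised-cosine spike whose width
    (1 / (fundamental * n_harmonics)) sets how much power lands in the
    20–50 Hz band. ``spike_amplitude_ratio`` scales the discharge RMS as a
    multiple of the background RMS.
    """

    rate: float = 3.3  # episodes per hour
    duration_mean: float = 4.1  # s
    duration_sd: float = 0.4  # s
    duration_min: float = 2.0  # s
    fundamental: float = 6.0  # Hz
    spike_amplitude_ratio: float = 4.0  # x background RMS
    n_harmonics: int = 5

    def validate(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if self.duration_min <= 0:
            raise ValueError("duration_min must be > 0")
        if self.duration_mean < self.duration_min:
            raise ValueError("duration_mean must be >= duration_min")
        if not (0 < self.fundamental < 20):
            raise ValueError("fundamental must be in (0, 20) Hz so harmonics reach the upper band")
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")


@dataclass
class SimConfig:
    """Full synthetic-recording description: background + SWD schedule."""

    sampling_rate: float = 2000.0  # Hz
    duration: float = 3600.0  # s
    n_channels: int = 1
    channel_labels: list[str] = field(default_factory=list)
    seed: int = 0
    background: BackgroundParams = field(default_factory=BackgroundParams)
    swd: SWDParams = field(default_factory=SWDParams)
    #: if set, inject exactly this many events instead of drawing a Poisson count
    n_events: int | None = None

    def validate(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        nyquist = self.sampling_rate / 2
        top = self.swd.fundamental * max(self.swd.n_harmonics, 1)
        if nyquist <= top:
            raise ValueError(
                f"sampling_rate {self.sampling_rate} too low for highest synthesized "
                f"frequency {top} Hz"
            )
        self.background.validate()
        self.swd.validate()

    def labels(self) -> list[str]:
        if self.channel_labels:
            return list(self.channel_labels)
        return [f"ch{i}" for i in range(self.n_channels)]


@dataclass
class FilterSpec:
    """Butterworth bandpass: 3rd order, 0.5–400 Hz, zero-phase by default.

    Zero-phase (forward-backward) application squares the magnitude
    response but introduces no group delay, so candidate timestamps are
    not skewed; single-pass causal filtering is available via
    ``zero_phase=False``.
    """

    order: int = 3
    low_cutoff: float = 0.5  # Hz
    high_cutoff: float = 400.0  # Hz
    zero_phase: bool = True

    def validate(self, sampling_rate: float) -> None:
        if not (0 < self.low_cutoff < self.high_cutoff):
            raise ValueError("need 0 < low_cutoff < high_cutoff")
        if self.high_cutoff >= sampling_rate / 2:
            raise ValueError(
                f"high_cutoff {self.high_cutoff} Hz >= Nyquist ({sampling_rate / 2} Hz)"
            )


@dataclass
class SpikeCriteria:
    """Spike definition for the spike-density feature.

    A spike is a local extremum of the filtered signal whose absolute
    amplitude exceeds ``threshold_multiplier`` times the robust SD
    (1.4826 x MAD) of the parent segment; extrema closer than
    ``refractory`` seconds are resolved in favour of the larger one.
    """

    threshold_multiplier: float = 5.0
    refractory: float = 0.03  # s

    def validate(self) -> None:
        if self.threshold_multiplier <= 0:
            raise ValueError("threshold_multiplier must be > 0")
        if self.refractory < 0:
            raise ValueError("refractory must be >= 0")


#: canonical feature order used throughout detection
FEATURES = ("amp_corr", "rms", "spike_density", "band_ratio")


@dataclass
class FeatureThreshold:
    """One feature's threshold rule: absolute value, or robust z multiplier."""

    mode: str = "robust_z"  # "absolute" | "robust_z"
    value: float = 3.0

    def validate(self) -> None:
        if self.mode not in ("absolute", "robust_z"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")


def _default_thresholds() -> dict[str, FeatureThreshold]:
    return {
        "amp_corr": FeatureThreshold("absolute", 0.5),
        "rms": FeatureThreshold("robust_z", 3.0),
        "spike_density": FeatureThreshold("robust_z", 3.0),
        "band_ratio": FeatureThreshold("robust_z", 3.0),
    }


@dataclass
class ThresholdSpec:
    """Per-feature thresholds; an epoch is flagged only if it exceeds all four."""

    per_feature: dict[str, FeatureThreshold] = field(default_factory=_default_thresholds)

    def validate(self) -> None:
        missing = set(FEATURES) - set(self.per_feature)
        if missing:
            raise ValueError(f"thresholds missing for features: {sorted(missing)}")
        for t in self.per_feature.values():
            t.validate()


@dataclass
class DetectionConfig:
    """Every constant of the detection pipeline."""

    filter: FilterSpec = field(default_factory=FilterSpec)
    segment_length: float = 600.0  # s
    epoch_length: float = 0.5  # s
    spike: SpikeCriteria = field(default_factory=SpikeCriteria)
    thresholds: ThresholdSpec = field(default_factory=ThresholdSpec)
    max_gap_epochs: int = 1
    min_duration: float = 1.0  # s
    band_low: tuple[float, float] = (0.5, 20.0)  # Hz, half-open [low, high)
    band_high: tuple[float, float] = (20.0, 50.0)  # Hz
    band_mode: str = "ratio"  # "ratio" | "difference"
    #: Welch context window (s) for band power; None = per-epoch periodogram
    band_context: float | None = None
    #: maximum lag (samples) searched when correlating successive epochs;
    #: 0 = plain lag-0 Pearson correlation
    amp_corr_max_lag: int = 0
    seed: int = 0

    def validate(self, sampling_rate: float) -> None:
        self.filter.validate(sampling_rate)
        self.spike.validate()
        self.thresholds.validate()
        if self.epoch_length <= 0 or self.segment_length < self.epoch_length:
            raise ValueError("need 0 < epoch_length <= segment_length")
        if self.max_gap_epochs < 0:
            raise ValueError("max_gap_epochs must be >= 0")
        if self.band_mode not in ("ratio", "difference"):
            raise ValueError(f"unknown band_mode {self.band_mode!r}")


# ---------------------------------------------------------------------------
# YAML (de)serialization


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def _from_plain(cls: type, data: dict[str, Any]) -> Any:
    kwargs: dict[str, Any] = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        val = data[f.name]
        if f.name == "per_feature":
            val = {k: FeatureThreshold(**v) for k, v in val.items()}
        elif f.name in ("band_low", "band_high"):
            val = tuple(val)
        elif dataclasses.is_dataclass(f.type) if isinstance(f.type, type) else False:
            val = _from_plain(f.type, val)
        else:
            nested = _NESTED.get(f.name)
            if nested is not None and isinstance(val, dict):
                val = _from_plain(nested, val)
        kwargs[f.name] = val
    return cls(**kwargs)


_NESTED: dict[str, type] = {
    "background": BackgroundParams,
    "swd": SWDParams,
    "filter": FilterSpec,
    "spike": SpikeCriteria,
    "thresholds": ThresholdSpec,
}


def dump_yaml(config: Any, path: str | Path) -> None:
    """Write a config dataclass to YAML."""
    Path(path).write_text(yaml.safe_dump(_to_plain(config), sort_keys=False))


def load_yaml(cls: type, path: str | Path) -> Any:
    """Load a config dataclass of type ``cls`` from YAML."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return _from_plain(cls, data)


def config_hash(config: Any) -> str:
    """Short stable hash of a config, recorded in output-file headers."""
    blob = json.dumps(_to_plain(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
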