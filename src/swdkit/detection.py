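"""Seizure-candidate detection by joint thresholding of epoch features.

An epoch is flagged when it strictly exceeds the threshold for *all four*
features (logical AND); maximal runs of flagged epochs, bridging gaps of
at most one epoch, become :class:`SeizureCandidate` intervals; candidates
shorter than a minimum duration are discarded. Thresholds default to
robust z-scores computed per recording (median + z x 1.4826 x MAD over
all epochs), so per-animal baseline differences and contamination by the
seizures themselves are tolerated; absolute thresholds are available per
feature.

The object-oriented surface follows the model/results convention:
``SWDDetector(recording, config).fit()`` estimates the per-channel
thresholds and returns an :class:`SWDDetectionResults` carrying the
candidates, the per-epoch feature table, episode statistics and accuracy
evaluation against ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from .config import FEATURES, DetectionConfig, ThresholdSpec, config_hash
from .features import feature_matrix
from .preprocessing import bandpass, segment_signal
from .recording import EEGRecording, EventAnnotation

__all__ = [
    "SeizureCandidate",
    "EpisodeStats",
    "DetectionAccuracy",
    "compute_thresholds",
    "flag_epochs",
    "merge_candidates",
    "detect",
    "episode_statistics",
    "evaluate_detection",
    "SWDDetector",
    "SWDDetectionResults",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SeizureCandidate:
    """A detected seizure-candidate interval on one channel."""

    channel: str
    start: float  # s
    end: float  # s
    n_epochs: int  # epochs spanned, including bridged gaps
    peak_amp_corr: float = np.nan
    peak_rms: float = np.nan
    peak_spike_density: float = np.nan
    peak_band_ratio: float = np.nan

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass(frozen=True)
class EpisodeStats:
    """Rate and duration statistics over detected episodes."""

    n_events: int
    episodes_per_hour: float
    mean_duration: float  # s; nan if no events
    sem_duration: float  # s; nan (undefined) if fewer than 2 events

    @property
    def sem_defined(self) -> bool:
        return np.isfinite(self.sem_duration)


@dataclass(frozen=True)
class DetectionAccuracy:
    """Candidate-vs-truth agreement under one-to-one interval matching."""

    sensitivity: float
    false_discovery_rate: float  # nan (undefined) if there are no candidates
    mean_onset_error: float  # s, over matched pairs
    mean_duration_error: float  # s, over matched pairs
    n_truth: int
    n_candidates: int
    n_matched: int


def compute_thresholds(
    table: pd.DataFrame, spec: ThresholdSpec | None = None
) -> dict[str, float]:
    """Resolve the per-feature thresholds for one recording.

    ``absolute`` thresholds pass through; ``robust_z`` thresholds are
    ``median + z x scale`` with ``scale = max(1.4826 x MAD,
    1e-9 x |median|)`` computed over all epochs of the recording (the
    floor guards degenerate all-but-constant features). Robust mode
    requires at least 100 epochs.
    """
    spec = spec or ThresholdSpec()
    spec.validate()
    out: dict[str, float] = {}
    for feat in FEATURES:
        rule = spec.per_feature[feat]
        if rule.mode == "absolute":
            out[feat] = float(rule.value)
            continue
        values = table[feat].to_numpy(dtype=np.float64)
        if values.size < 100:
            raise ValueError(
                f"robust_z thresholds need >= 100 epochs (got {values.size}); "
                "use absolute mode for short recordings"
            )
        med = float(np.median(values))
        mad = float(np.median(np.abs(values - med)))
        scale = max(1.4826 * mad, 1e-9 * abs(med))
        out[feat] = med + rule.value * scale
    return out


def flag_epochs(table: pd.DataFrame, thresholds: dict[str, float]) -> np.ndarray:
    """Boolean flag per epoch: all four features strictly above threshold."""
    flags = np.ones(len(table), dtype=bool)
    for feat in FEATURES:
        flags &= table[feat].to_numpy(dtype=np.float64) > thresholds[feat]
    return flags


def merge_candidates(
    flags: np.ndarray,
    epoch_length: float = 0.5,
    max_gap_epochs: int = 1,
    min_duration: float = 1.0,
    channel: str = "ch0",
    start_offset: float = 0.0,
    table: pd.DataFrame | None = None,
) -> list[SeizureCandidate]:
    """Merge flagged epochs into candidate intervals.

    Maximal runs of flagged epochs become candidates; unflagged gaps of at
    most ``max_gap_epochs`` between flagged epochs are bridged. Candidates
    shorter than ``min_duration`` seconds are dropped. When the feature
    ``table`` is supplied, each candidate carries the peak value of every
    feature over its spanned epochs.
    """
    flags = np.asarray(flags, dtype=bool)
    idx = np.flatnonzero(flags)
    candidates: list[SeizureCandidate] = []
    if idx.size == 0:
        return candidates
    runs: list[tuple[int, int]] = []
    first = prev = int(idx[0])
    for i in idx[1:]:
        if i - prev - 1 <= max_gap_epochs:
            prev = int(i)
        else:
            runs.append((first, prev))
            first = prev = int(i)
    runs.append((first, prev))
    for lo, hi in runs:
        n_epochs = hi - lo + 1
        duration = n_epochs * epoch_length
        if duration < min_duration:
            continue
        peaks = {}
        if table is not None:
            window = table.iloc[lo : hi + 1]
            peaks = {f"peak_{f}": float(window[f].max()) for f in FEATURES}
        candidates.append(
            SeizureCandidate(
                channel=channel,
                start=start_offset + lo * epoch_length,
                end=start_offset + (hi + 1) * epoch_length,
                n_epochs=n_epochs,
                **peaks,
            )
        )
    return candidates


def detect(
    recording: EEGRecording, config: DetectionConfig | None = None
) -> tuple[list[SeizureCandidate], pd.DataFrame]:
    """Run the full detection pipeline on every channel.

    Each channel is segmented into 10-minute blocks, bandpass filtered,
    featurized per 500-ms epoch, thresholded (thresholds resolved per
    channel over all its epochs) and merged into candidates. Returns the
    candidates sorted by start time and the per-epoch feature table (with
    a ``channel`` column and a ``flagged`` column) for audit.
    """
    config = config or DetectionConfig()
    config.validate(recording.sampling_rate)
    all_candidates: list[SeizureCandidate] = []
    tables: list[pd.DataFrame] = []
    per_channel = segment_signal(recording, config.segment_length, config.epoch_length)
    for label, segments in per_channel.items():
        logger.info("channel %s: %d segment(s)", label, len(segments))
        seg_tables = []
        for seg in segments:
            filtered = bandpass(seg, config.filter)
            seg_tables.append(feature_matrix(filtered, config))
            logger.debug("  segment %d: %d epochs", seg.index, len(seg_tables[-1]))
        table = pd.concat(seg_tables, ignore_index=True)
        thresholds = compute_thresholds(table, config.thresholds)
        flags = flag_epochs(table, thresholds)
        candidates = merge_candidates(
            flags,
            epoch_length=config.epoch_length,
            max_gap_epochs=config.max_gap_epochs,
            min_duration=config.min_duration,
            channel=label,
            start_offset=float(table["epoch_start_s"].iloc[0]) if len(table) else 0.0,
            table=table,
        )
        all_candidates.extend(candidates)
        table = table.copy()
        table.insert(0, "channel", label)
        table["flagged"] = flags
        tables.append(table)
    all_candidates.sort(key=lambda c: (c.start, c.channel))
    features = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    return all_candidates, features


def episode_statistics(
    candidates: list[SeizureCandidate] | list[EventAnnotation],
    recorded_hours: float,
) -> EpisodeStats:
    """Episode rate (per hour) and duration mean ± SEM.

    SEM uses the sample SD (ddof=1) over n >= 2 events and is NaN
    (undefined) otherwise.
    """
    if recorded_hours <= 0:
        raise ValueError("recorded_hours must be > 0")
    durations = np.array([c.duration for c in candidates], dtype=np.float64)
    n = durations.size
    mean = float(durations.mean()) if n else float("nan")
    sem = float(durations.std(ddof=1) / np.sqrt(n)) if n >= 2 else float("nan")
    return EpisodeStats(n, n / recorded_hours, mean, sem)


def _match_channel(
    cands: list, truth: list, tolerance: float
) -> list[tuple[int, int]]:
    """Maximum one-to-one matching between candidates and truth intervals.

    A candidate is eligible for a truth interval when its midpoint lies
    within ``tolerance`` seconds of that interval.
    """
    rows, cols = [], []
    for i, c in enumerate(cands):
        mid = 0.5 * (c.start + c.end)
        for j, t in enumerate(truth):
            if t.start - tolerance <= mid <= t.end + tolerance:
                rows.append(i)
                cols.append(j)
    if not rows:
        return []
    graph = csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(cands), len(truth))
    )
    col_of_row = maximum_bipartite_matching(graph, perm_type="column")
    return [(i, int(j)) for i, j in enumerate(col_of_row) if j >= 0]


def evaluate_detection(
    candidates: list[SeizureCandidate],
    truth: list[EventAnnotation],
    match_tolerance: float = 2.0,
) -> DetectionAccuracy:
    """Score candidates against ground-truth annotations.

    Matching is one-to-one and maximal per channel; eligibility requires
    the candidate midpoint to fall within ``match_tolerance`` seconds of
    the truth interval. Sensitivity = matched truth / total truth; FDR =
    unmatched candidates / total candidates (NaN when there are no
    candidates). Onset and duration errors average |difference| over
    matched pairs.
    """
    channels = sorted({c.channel for c in candidates} | {t.channel for t in truth})
    n_matched = 0
    onset_err: list[float] = []
    dur_err: list[float] = []
    for ch in channels:
        cands = [c for c in candidates if c.channel == ch]
        tr = [t for t in truth if t.channel == ch]
        for i, j in _match_channel(cands, tr, match_tolerance):
            n_matched += 1
            onset_err.append(abs(cands[i].start - tr[j].start))
            dur_err.append(abs(cands[i].duration - tr[j].duration))
    n_truth = len(truth)
    n_cand = len(candidates)
    sensitivity = n_matched / n_truth if n_truth else float("nan")
    fdr = (n_cand - n_matched) / n_cand if n_cand else float("nan")
    return DetectionAccuracy(
        sensitivity=sensitivity,
        false_discovery_rate=fdr,
        mean_onset_error=float(np.mean(onset_err)) if onset_err else float("nan"),
        mean_duration_error=float(np.mean(dur_err)) if dur_err else float("nan"),
        n_truth=n_truth,
        n_candidates=n_cand,
        n_matched=n_matched,
    )


# ---------------------------------------------------------------------------
# Model / Results objects


class SWDDetector:
    """Spike-and-wave discharge detection model for one EEG recording.

    Parameters
    ----------
    recording : EEGRecording
        The signal to analyse (µV, channels x time).
    config : DetectionConfig, optional
        Algorithm constants; defaults reproduce the standard pipeline
        (3rd-order 0.5–400 Hz Butterworth, 10-min segments, 500-ms
        epochs, robust-z thresholds, AND of four features).

    ``fit()`` estimates the per-channel feature thresholds from the
    recording itself and returns an :class:`SWDDetectionResults`.
    """

    def __init__(self, recording: EEGRecording, config: DetectionConfig | None = None):
        self.recording = recording
        self.config = config or DetectionConfig()
        self.config.validate(recording.sampling_rate)

    @classmethod
    def from_edf(cls, path, config: DetectionConfig | None = None) -> "SWDDetector":
        from .io import read_edf

        return cls(read_edf(path), config)

    def fit(self) -> "SWDDetectionResults":
        candidates, features = detect(self.recording, self.config)
        thresholds = {
            ch: compute_thresholds(
                features[features["channel"] == ch], self.config.thresholds
            )
            for ch in self.recording.channel_labels
        }
        return SWDDetectionResults(self, candidates, features, thresholds)


class SWDDetectionResults:
    """Results of :meth:`SWDDetector.fit`.

    Attributes
    ----------
    candidates : list of SeizureCandidate
    features : pandas.DataFrame
        Per-epoch audit table (one row per epoch per channel).
    thresholds : dict
        Resolved per-channel, per-feature threshold values.
    """

    def __init__(self, model, candidates, features, thresholds):
        self.model = model
        self.config = model.config
        self.candidates = candidates
        self.features = features
        self.thresholds = thresholds

    @property
    def recorded_hours(self) -> float:
        return self.model.recording.duration / 3600.0

    @property
    def candidates_frame(self) -> pd.DataFrame:
        rows = [
            {
                "channel": c.channel,
                "start_s": c.start,
                "end_s": c.end,
                "duration_s": c.duration,
                "n_epochs": c.n_epochs,
                "peak_amp_corr": c.peak_amp_corr,
                "peak_rms": c.peak_rms,
                "peak_spike_density": c.peak_spike_density,
                "peak_band_ratio": c.peak_band_ratio,
            }
            for c in self.candidates
        ]
        cols = [
            "channel", "start_s", "end_s", "duration_s", "n_epochs",
            "peak_amp_corr", "peak_rms", "peak_spike_density", "peak_band_ratio",
        ]
        return pd.DataFrame(rows, columns=cols)

    def episode_statistics(self, channel: str | None = None) -> EpisodeStats:
        """Pooled (or per-channel) episode rate and duration statistics."""
        cands = self.candidates
        hours = self.recorded_hours
        if channel is not None:
            cands = [c for c in cands if c.channel == channel]
        else:
            # pooled across channels: rate normalizes by total channel-hours
            hours *= self.model.recording.n_channels
        return episode_statistics(cands, hours)

    def evaluate(
        self, truth: list[EventAnnotation], match_tolerance: float = 2.0
    ) -> DetectionAccuracy:
        return evaluate_detection(self.candidates, truth, match_tolerance)

    def summary(self) -> str:
        """Human-readable report of the fit."""
        stats = self.episode_statistics()
        rec = self.model.recording
        lines = [
            "Spike-and-wave discharge detection",
            "=" * 50,
            f"Recording: {rec.n_channels} channel(s), {rec.duration:.1f} s "
            f"at {rec.sampling_rate:g} Hz",
            f"Config hash: {config_hash(self.config)}",
            "",
            "Per-channel thresholds (epoch flagged iff all exceeded):",
        ]
        for ch, thr in self.thresholds.items():
            vals = ", ".join(f"{f}={thr[f]:.4g}" for f in FEATURES)
            lines.append(f"  {ch}: {vals}")
        lines += [
            "",
            f"Candidates: {stats.n_events}",
            f"Episode rate: {stats.episodes_per_hour:.2f} /h "
            f"over {self.recorded_hours * rec.n_channels:.2f} channel-hours",
        ]
        if stats.n_events:
            sem = f"{stats.sem_duration:.2f}" if stats.sem_defined else "n/a"
            lines.append(f"Mean duration: {stats.mean_duration:.2f} s (SEM {sem} s)")
        return "\n".join(lines)

    def plot(self, channel: str | None = None, ax=None):
        """Quick-look trace with detected candidates shaded."""
        import matplotlib.pyplot as plt

        rec = self.model.recording
        channel = channel or rec.channel_labels[0]
        x = rec.channel(channel)
        t = np.arange(x.size) / rec.sampling_rate
        if ax is None:
            _, ax = plt.subplots(figsize=(12, 3))
        ax.plot(t, x, lw=0.3, color="k")
        for c in self.candidates:
            if c.channel == channel:
                ax.axvspan(c.start, c.end, color="tab:red", alpha=0.3)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("µV")
        ax.set_title(f"{channel}: {sum(c.channel == channel for c in self.candidates)} "
                     "candidate(s)")
        return ax
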