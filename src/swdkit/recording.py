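"""Core in-memory containers for EEG signals and event annotations.

An :class:`EEGRecording` holds a ``channels x time`` array of sampled
potentials in microvolts together with the sampling rate and channel
labels. An :class:`EventAnnotation` is a labelled half-open time interval
``[start, end)`` on one channel, used both for simulation ground truth and
for detector output. Times are seconds from recording start; sample
indexing is 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["EEGRecording", "EventAnnotation", "events_to_frame", "frame_to_events"]

#: Column order used whenever events are tabulated or written to CSV.
EVENT_COLUMNS = ["channel", "start_s", "end_s", "label"]


@dataclass
class EEGRecording:
    """Multi-channel sampled EEG signal.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Signal in microvolts (µV).
    sampling_rate : float
        Sampling rate in Hz; must be positive.
    channel_labels : list of str
        One label per channel.
    start_time : float
        Offset of the first sample in seconds (default 0).
    """

    samples: np.ndarray
    sampling_rate: float
    channel_labels: list[str] = field(default_factory=list)
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.samples.shape[0])]
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.samples.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def channel(self, label: str) -> np.ndarray:
        """Return the 1-D sample vector for one channel by label."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"no channel labelled {label!r}") from None
        return self.samples[idx]

    def copy(self) -> "EEGRecording":
        return EEGRecording(
            self.samples.copy(),
            self.sampling_rate,
            list(self.channel_labels),
            self.start_time,
        )


@dataclass(frozen=True)
class EventAnnotation:
    """Labelled half-open time interval ``[start, end)`` on one channel."""

    channel: str
    start: float
    end: float
    label: str = "swd"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"need 0 <= start < end, got [{self.start}, {self.end})")

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


def events_to_frame(events: list[EventAnnotation]) -> pd.DataFrame:
    """Tabulate annotations, sorted by (channel, start)."""
    rows = [(e.channel, e.start, e.end, e.label) for e in events]
    frame = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return frame.sort_values(["channel", "start_s"], kind="stable").reset_index(drop=True)


def frame_to_events(frame: pd.DataFrame) -> list[EventAnnotation]:
    """Inverse of :func:`events_to_frame`; validates each row."""
    events = []
    for i, row in enumerate(frame.itertuples(index=False)):
        if row.end_s <= row.start_s:
            raise ValueError(f"row {i}: end_s ({row.end_s}) <= start_s ({row.start_s})")
        events.append(
            EventAnnotation(str(row.channel), float(row.start_s), float(row.end_s), str(row.label))
        )
    return events
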