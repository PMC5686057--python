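"""In-memory containers: recordings, condition annotations, artifact labels.

All signal values are microvolts, all times are seconds from recording start,
and every time span is a half-open interval ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

#: the five-class taxonomy of gross non-physiological artifacts seen with
#: dry-electrode mobile EEG: transient electrode pops, repeated saturating
#: poor-contact square waves, ADC-step digitization error, wireless
#: transmission loss (all channels hold the last value), and flat lines.
ARTIFACT_TYPES = ("pop", "poor_contact", "digitization", "wireless_loss", "flat")

#: sentinel channel set meaning "every channel of the recording"
ALL_CHANNELS = "ALL"


class SchemaError(ValueError):
    """Input structure does not match its declared schema."""


@dataclass
class Recording:
    """A multichannel EEG recording in microvolts.

    Attributes
    ----------
    subject_id : str
        Identifier of the recorded subject/session.
    headset : str
        Name of the headset profile the recording was made with.
    signal : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    sampling_rate : float
        Hz.
    channel_labels : tuple of str
        One label per signal row.
    start_time : float
        Offset of the first sample in seconds (default 0).
    """

    subject_id: str
    headset: str
    signal: np.ndarray
    sampling_rate: float
    channel_labels: tuple[str, ...]
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise SchemaError("signal must be a 2-D channels x samples array")
        if self.signal.shape[0] != len(self.channel_labels):
            raise SchemaError(
                f"{self.signal.shape[0]} signal rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        if not np.all(np.isfinite(self.signal)):
            raise SchemaError("signal contains non-finite values")
        if self.sampling_rate <= 0:
            raise SchemaError("sampling_rate must be positive")
        self.channel_labels = tuple(self.channel_labels)

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"no channel {label!r} in recording") from None

    def time_to_sample(self, t: float) -> int:
        """Sample index of time ``t`` (clipped into the valid range)."""
        return int(np.clip(round(t * self.sampling_rate), 0, self.n_samples))

    def copy(self) -> "Recording":
        return replace(self, signal=self.signal.copy())

    def pick(self, labels: Sequence[str]) -> "Recording":
        """Sub-recording restricted to ``labels`` (kept in the given order)."""
        idx = [self.channel_index(l) for l in labels]
        return replace(self, signal=self.signal[idx].copy(),
                       channel_labels=tuple(labels))


@dataclass(frozen=True)
class Interval:
    """One labeled condition interval ``[start_s, end_s)``."""

    label: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise SchemaError(f"interval end {self.end_s} <= start {self.start_s}")
        if self.label != "baseline" and not self.label.startswith("piece:"):
            raise SchemaError(
                f"condition label {self.label!r} must be 'baseline' or 'piece:<id>'"
            )

    @property
    def condition(self) -> str:
        """``baseline`` or ``piece_viewing``."""
        return "baseline" if self.label == "baseline" else "piece_viewing"

    @property
    def piece_id(self) -> str | None:
        return self.label.split(":", 1)[1] if self.label.startswith("piece:") else None


@dataclass
class AnnotationTrack:
    """Ordered, non-overlapping condition intervals for one session."""

    intervals: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        ivs = sorted(self.intervals, key=lambda iv: iv.start_s)
        for a, b in zip(ivs, ivs[1:]):
            if b.start_s < a.end_s - 1e-9:
                raise SchemaError(
                    f"intervals {a.label}[{a.start_s},{a.end_s}) and "
                    f"{b.label}[{b.start_s},{b.end_s}) overlap"
                )
        self.intervals = ivs

    def __iter__(self):
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True)
class ArtifactLabel:
    """A ground-truth or detected artifact span.

    ``channels`` is a tuple of channel labels, or :data:`ALL_CHANNELS` for
    artifacts that affect every channel simultaneously (wireless loss).
    """

    type: str
    channels: tuple[str, ...] | str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.type not in ARTIFACT_TYPES:
            raise SchemaError(
                f"artifact type {self.type!r} not in {ARTIFACT_TYPES}"
            )
        if self.end_s <= self.start_s:
            raise SchemaError("artifact span must have end_s > start_s")
        if self.channels != ALL_CHANNELS:
            object.__setattr__(self, "channels", tuple(self.channels))

    def covers_channel(self, label: str) -> bool:
        return self.channels == ALL_CHANNELS or label in self.channels


def overlapping_labels(labels: Iterable[ArtifactLabel], start_s: float,
                       end_s: float) -> list[ArtifactLabel]:
    """Labels whose span intersects ``[start_s, end_s)``."""
    return [l for l in labels if l.start_s < end_s and l.end_s > start_s]
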