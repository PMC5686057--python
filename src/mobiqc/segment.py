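"""Condition epochs and overlapping analysis windows.

Sessions are partitioned into condition epochs from the annotation track,
then each epoch is cut into fixed-length windows (default 4 s, 2 s overlap).
Windows never span condition boundaries and trailing partial windows are
dropped, so a 60 s baseline yields floor((60-4)/2)+1 = 29 windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .recording import AnnotationTrack, Recording

__all__ = ["Epoch", "Window", "partition_conditions", "slide_windows",
           "window_count"]


@dataclass(frozen=True)
class Epoch:
    """One condition interval of a recording, ``[start_s, end_s)``."""

    label: str            # 'baseline' or 'piece:<id>'
    condition: str        # 'baseline' or 'piece_viewing'
    piece_id: str | None
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class Window:
    """One fixed-length analysis window inside an epoch."""

    epoch: Epoch
    start_s: float
    duration_s: float

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s

    def slice(self, rec: Recording) -> np.ndarray:
        i0 = rec.time_to_sample(self.start_s)
        return rec.signal[:, i0:i0 + int(round(self.duration_s * rec.sampling_rate))]


def partition_conditions(rec: Recording, track: AnnotationTrack) -> list[Epoch]:
    """One epoch per annotation interval; intervals past the end are clipped."""
    epochs: list[Epoch] = []
    for iv in track:
        start, end = iv.start_s, iv.end_s
        if start >= rec.duration_s:
            warnings.warn(
                f"interval {iv.label}[{start},{end}) starts past the end of "
                f"the {rec.duration_s:.1f} s recording; dropped")
            continue
        if end > rec.duration_s:
            warnings.warn(
                f"interval {iv.label}[{start},{end}) exceeds the "
                f"{rec.duration_s:.1f} s recording; clipped")
            end = rec.duration_s
        epochs.append(Epoch(label=iv.label, condition=iv.condition,
                            piece_id=iv.piece_id, start_s=start, end_s=end))
    return epochs


def window_count(duration_s: float, window_s: float, step_s: float) -> int:
    """Number of full windows: floor((duration - window)/step) + 1, or 0."""
    if duration_s < window_s:
        return 0
    return int(np.floor((duration_s - window_s) / step_s + 1e-9)) + 1


def slide_windows(epoch: Epoch, window_s: float = 4.0,
                  overlap_s: float = 2.0) -> list[Window]:
    """Cut an epoch into overlapping full-length windows.

    Windows start at the epoch start and advance by ``window_s - overlap_s``;
    only windows fully inside the epoch are emitted.
    """
    if not (window_s > overlap_s >= 0):
        raise ValueError("need window_s > overlap_s >= 0")
    step = window_s - overlap_s
    n = window_count(epoch.duration_s, window_s, step)
    return [Window(epoch=epoch, start_s=epoch.start_s + i * step,
                   duration_s=window_s) for i in range(n)]
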