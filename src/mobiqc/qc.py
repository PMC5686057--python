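"""Threshold-based quality control and artifact classification.

Gross non-physiological artifacts are screened with two amplitude
thresholds: an upper threshold of 300 uV (physiological EEG does not reach
this amplitude, even with dry electrodes) and a lower threshold of 10x the
device's ADC resolution (signals that never clear it are flat lines,
digitization error or transmission loss).  Channels are rejected on an
occupancy rule — above the upper threshold for more than 20% of the
session, or above the lower threshold for less than 20% of the session —
and retained-channel windows containing any supra-upper excursion are
rejected with 0.5 s of padding on each side.  A rule-based classifier
assigns the five-class taxonomy to detected spans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiles import HeadsetProfile
from .recording import ALL_CHANNELS, ArtifactLabel, Recording
from .segment import Window

__all__ = [
    "ChannelDecision", "WindowMask", "QCReport",
    "thresholds_for", "reject_channels", "reject_windows",
    "classify_artifacts", "qc_report",
]

UPPER_UV_DEFAULT = 300.0
LOWER_MULTIPLIER_DEFAULT = 10.0
OCCUPANCY_DEFAULT = 0.20
PAD_S_DEFAULT = 0.5


@dataclass(frozen=True)
class ChannelDecision:
    """Keep/reject verdict for one channel with its threshold occupancies."""

    channel: str
    keep: bool
    reason: str  # 'none' | 'upper' | 'lower'
    upper_fraction: float  # fraction of samples with |x| > upper
    lower_fraction: float  # fraction of samples with |x| < lower

    def __post_init__(self) -> None:
        if self.keep != (self.reason == "none"):
            raise ValueError("reason must be consistent with keep")


@dataclass
class WindowMask:
    """Per-window keep/reject verdicts over the retained channel set."""

    windows: list[Window]
    keep: np.ndarray  # bool, aligned with windows

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)
        if self.keep.shape != (len(self.windows),):
            raise ValueError("keep mask must align with windows")

    @property
    def n_rejected(self) -> int:
        return int((~self.keep).sum())

    def kept_windows(self) -> list[Window]:
        return [w for w, k in zip(self.windows, self.keep) if k]


@dataclass
class QCReport:
    decisions: list[ChannelDecision]
    mask: WindowMask
    channel_rejection_rate: float
    data_rejection_rate: float

    def retained_channels(self) -> list[str]:
        return [d.channel for d in self.decisions if d.keep]

    def to_dict(self) -> dict:
        return {
            "channel_rejection_rate": self.channel_rejection_rate,
            "data_rejection_rate": self.data_rejection_rate,
            "channels": [
                {"channel": d.channel, "keep": d.keep, "reason": d.reason,
                 "upper_fraction": d.upper_fraction,
                 "lower_fraction": d.lower_fraction}
                for d in self.decisions
            ],
            "n_windows": len(self.mask.windows),
            "n_windows_rejected": self.mask.n_rejected,
        }


def thresholds_for(profile: HeadsetProfile, upper_uv: float = UPPER_UV_DEFAULT,
                   lower_multiplier: float = LOWER_MULTIPLIER_DEFAULT,
                   ) -> tuple[float, float]:
    """(upper, lower) amplitude thresholds in microvolts for a device.

    The lower threshold is ``lower_multiplier`` (default 10) times the ADC
    resolution, so e.g. a 0.29 uV/step system gets 2.9 uV and a 0.05 uV/step
    system gets 0.5 uV; the upper threshold is device-independent.
    """
    return upper_uv, lower_multiplier * profile.resolution


def reject_channels(rec: Recording, upper_uv: float, lower_uv: float,
                    occupancy: float = OCCUPANCY_DEFAULT,
                    ) -> list[ChannelDecision]:
    """Apply the occupancy rules channel-wise.

    A channel is rejected with reason ``upper`` when ``|x| > upper`` for more
    than ``occupancy`` of the session, and with reason ``lower`` when
    ``|x| >= lower`` for less than ``occupancy`` of the session (i.e. the
    signal sits below the lower threshold at least 80% of the time at the
    default occupancy).  ``upper`` takes precedence when both hold.
    """
    if rec.n_samples == 0:
        raise ValueError("empty recording")
    if upper_uv <= 0 or lower_uv <= 0:
        raise ValueError("thresholds must be positive")
    absx = np.abs(rec.signal)
    decisions: list[ChannelDecision] = []
    for ch, label in enumerate(rec.channel_labels):
        upper_frac = float((absx[ch] > upper_uv).mean())
        lower_frac = float((absx[ch] < lower_uv).mean())
        above_lower_frac = float((absx[ch] >= lower_uv).mean())
        if upper_frac > occupancy:
            keep, reason = False, "upper"
        elif above_lower_frac < occupancy:
            keep, reason = False, "lower"
        else:
            keep, reason = True, "none"
        decisions.append(ChannelDecision(
            channel=label, keep=keep, reason=reason,
            upper_fraction=upper_frac, lower_fraction=lower_frac))
    return decisions


def reject_windows(rec: Recording, windows: list[Window], upper_uv: float,
                   pad_s: float = PAD_S_DEFAULT) -> WindowMask:
    """Reject windows touching supra-upper excursions (padded by ``pad_s``).

    ``rec`` should already be restricted to the retained channels.  Every
    sample with ``|x| > upper`` on any channel marks an artifactual region;
    regions are dilated by ``pad_s`` on each side (clipped at the recording
    edges) and every window intersecting a dilated region is rejected.
    """
    bad = np.any(np.abs(rec.signal) > upper_uv, axis=0)
    keep = np.ones(len(windows), dtype=bool)
    if bad.any():
        fs = rec.sampling_rate
        bad_times = np.flatnonzero(bad) / fs
        spans = _merge_spans([(t - pad_s, t + 1.0 / fs + pad_s)
                              for t in bad_times])
        for i, w in enumerate(windows):
            for (a, b) in spans:
                if w.start_s < b and w.end_s > a:
                    keep[i] = False
                    break
    return WindowMask(windows=list(windows), keep=keep)


def qc_report(decisions: list[ChannelDecision], mask: WindowMask) -> QCReport:
    """Rejection-rate summary: channels rejected / total, windows rejected /
    total (windows are evaluated over the retained channel set only)."""
    n_ch = len(decisions)
    if n_ch == 0:
        raise ValueError("no channel decisions")
    ch_rate = sum(not d.keep for d in decisions) / n_ch
    n_win = len(mask.windows)
    data_rate = (mask.n_rejected / n_win) if n_win else 0.0
    return QCReport(decisions=decisions, mask=mask,
                    channel_rejection_rate=ch_rate,
                    data_rejection_rate=data_rate)


# ---------------------------------------------------------------------------
# five-class rule-based artifact classifier

def _merge_spans(spans: list[tuple[float, float]],
                 gap: float = 0.0) -> list[tuple[float, float]]:
    if not spans:
        return []
    spans = sorted(spans)
    merged = [list(spans[0])]
    for a, b in spans[1:]:
        if a <= merged[-1][1] + gap:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(max(a, 0.0), b) for a, b in merged]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs of True values."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def classify_artifacts(rec: Recording, profile: HeadsetProfile,
                       upper_uv: float = UPPER_UV_DEFAULT,
                       lower_multiplier: float = LOWER_MULTIPLIER_DEFAULT,
                       ) -> list[ArtifactLabel]:
    """Heuristic five-class labeling of detected artifact spans.

    * ``wireless_loss`` — all channels simultaneously constant for >= 0.1 s
      (the transmitter holds the last value until the link resumes); this
      mechanizes the study's final visual inspection for transmission loss.
    * ``flat`` — one channel constant for >= 1 s (outside wireless spans).
    * ``pop`` — an isolated supra-upper excursion shorter than 1 s on one
      channel.
    * ``poor_contact`` — >= 3 supra-upper excursions within 5 s on one
      channel (repeated saturating square waves).
    * ``digitization`` — a span where >= 95% of successive absolute
      differences are within 2 ADC steps while the amplitude stays below
      the lower threshold.
    """
    upper, lower = thresholds_for(profile, upper_uv, lower_multiplier)
    fs = rec.sampling_rate
    labels: list[ArtifactLabel] = []

    # wireless loss: all-channel zero first differences
    diffs = np.diff(rec.signal, axis=1)
    all_const = np.all(diffs == 0, axis=0)
    min_hold = max(int(round(0.1 * fs)) - 1, 1)
    wireless_spans: list[tuple[float, float]] = []
    for i0, i1 in _runs(all_const):
        if i1 - i0 >= min_hold:
            span = (i0 / fs, (i1 + 1) / fs)
            wireless_spans.append(span)
            labels.append(ArtifactLabel("wireless_loss", ALL_CHANNELS, *span))

    block = max(int(round(fs)), 1)  # 1 s analysis blocks for digitization
    for ch, label in enumerate(rec.channel_labels):
        x = rec.signal[ch]
        absx = np.abs(x)
        dch = np.abs(np.diff(x))

        # flat lines: per-channel constant runs >= 1 s, not wireless
        for i0, i1 in _runs(dch == 0):
            if (i1 + 1 - i0) / fs >= 1.0:
                a, b = i0 / fs, (i1 + 1) / fs
                if not any(a >= wa - 1e-9 and b <= wb + 1e-9
                           for wa, wb in wireless_spans):
                    labels.append(ArtifactLabel("flat", (label,), a, b))

        # supra-upper excursions -> pops / poor contact
        excursions = _merge_spans(
            [(i0 / fs, i1 / fs) for i0, i1 in _runs(absx > upper)], gap=0.2)
        used = np.zeros(len(excursions), dtype=bool)
        i = 0
        while i < len(excursions):
            j = i
            while (j + 1 < len(excursions)
                   and excursions[j + 1][0] - excursions[j][1] < 5.0):
                j += 1
            group = excursions[i:j + 1]
            if len(group) >= 3:
                labels.append(ArtifactLabel(
                    "poor_contact", (label,), group[0][0], group[-1][1]))
            else:
                for a, b in group:
                    if b - a < 1.0:
                        labels.append(ArtifactLabel("pop", (label,), a, b))
            i = j + 1

        # digitization error: tiny ADC-step staircase at sub-lower amplitude
        n_blocks = x.size // block
        good = np.zeros(n_blocks, dtype=bool)
        for b in range(n_blocks):
            seg = slice(b * block, (b + 1) * block)
            dseg = dch[b * block:(b + 1) * block - 1]
            if dseg.size == 0:
                continue
            small_steps = (dseg <= 2 * profile.resolution).mean() >= 0.95
            sub_lower = absx[seg].max() < lower
            nonconstant = dseg.max() > 0
            good[b] = small_steps and sub_lower and nonconstant
        for i0, i1 in _runs(good):
            labels.append(ArtifactLabel(
                "digitization", (label,), i0 * block / fs,
                min(i1 * block / fs, rec.duration_s)))

    return labels
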