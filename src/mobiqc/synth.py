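"""Synthetic mobile-EEG (MoBI) session generator.

No public recordings exist for the museum deployment this package models, so
every downstream stage is exercised on simulated sessions with known ground
truth.  A session is a sequence of conditions (one resting *baseline*, one or
more *piece-viewing* intervals) rendered as:

* per-channel 1/f^a colored Gaussian background (default a = 1, 10 uV RMS),
* amplitude-modulated alpha (10 Hz) oscillations on posterior channels and
  beta (20 Hz) oscillations on frontal channels, with per-condition RMS
  amplitudes — alpha dominant at rest, beta dominant during viewing,
* eye blinks as ~100 uV biphasic (difference-of-Gaussians) pulses on
  frontopolar channels at Poisson arrival times,
* gross non-physiological artifacts from the five-class dry-electrode
  taxonomy (pops, poor contact, digitization error, wireless loss, flat
  lines), injected per plan and returned as sample-exact ground truth,
* ADC quantization and clipping per headset profile.

Everything is driven by one integer seed; the same design and seed reproduce
the session bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .profiles import HeadsetProfile
from .recording import (
    ALL_CHANNELS,
    AnnotationTrack,
    ArtifactLabel,
    Interval,
    Recording,
)

__all__ = [
    "ConditionSpec",
    "ArtifactPlanItem",
    "SessionDesign",
    "DesignError",
    "FailedRecordingError",
    "baseline_viewing_design",
    "simulate_session",
    "inject_artifact",
    "quantize",
    "three_class_spectra",
]


class DesignError(ValueError):
    """A session design violates its invariants."""


class FailedRecordingError(ValueError):
    """Flat signal on every channel is a failed recording, not an artifact."""


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental condition and its spectral signature.

    ``alpha_amp`` / ``beta_amp`` are RMS amplitudes in microvolts of the
    band oscillation at posterior / frontal channels respectively;
    ``background_exponent`` is the 1/f slope of the colored background;
    ``blink_rate`` is in events per minute.
    """

    label: str
    duration_s: float
    alpha_amp: float = 2.0
    beta_amp: float = 2.0
    background_exponent: float = 1.0
    blink_rate: float = 15.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise DesignError("condition duration_s must be positive")
        if self.alpha_amp < 0 or self.beta_amp < 0:
            raise DesignError("oscillation amplitudes must be >= 0")
        if self.blink_rate < 0:
            raise DesignError("blink_rate must be >= 0")


@dataclass(frozen=True)
class ArtifactPlanItem:
    """How one artifact type is injected into a session.

    Either ``rate_per_min`` (Poisson arrivals, non-overlap enforced) or
    explicit ``spans`` must be given.  ``channels`` is ``"random"`` (one
    channel drawn per event), :data:`ALL_CHANNELS`, or an explicit tuple.
    """

    type: str
    rate_per_min: float | None = None
    spans: tuple[tuple[float, float], ...] | None = None
    channels: str | tuple[str, ...] = "random"
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SessionDesign:
    profile: HeadsetProfile
    conditions: tuple[ConditionSpec, ...]
    artifact_plan: tuple[ArtifactPlanItem, ...] = ()
    seed: int = 0
    subject_id: str = "sim"
    background_rms: float = 10.0
    blink_amp: float = 100.0
    quantize_output: bool = True

    def __post_init__(self) -> None:
        if not self.conditions:
            raise DesignError("a session design needs at least one condition")


def baseline_viewing_design(profile: HeadsetProfile, seed: int = 0,
                            viewing_s: float = 180.0,
                            artifact_plan: tuple[ArtifactPlanItem, ...] = (),
                            subject_id: str = "sim") -> SessionDesign:
    """The default two-condition museum session.

    One minute of eyes-open rest facing a wall (posterior alpha dominant),
    then free exploration of the exhibit (frontal beta dominant).
    """
    return SessionDesign(
        profile=profile,
        conditions=(
            ConditionSpec("baseline", 60.0, alpha_amp=6.0, beta_amp=1.5),
            ConditionSpec("piece:p1", viewing_s, alpha_amp=2.0, beta_amp=4.0),
        ),
        artifact_plan=artifact_plan,
        seed=seed,
        subject_id=subject_id,
    )


# ---------------------------------------------------------------------------
# channel roles

def _is_posterior(label: str) -> bool:
    return label.startswith(("P", "O", "T"))  # parietal/occipital/temporal-post


def _is_frontal(label: str) -> bool:
    return label.startswith(("F", "AF"))


def _is_frontopolar(label: str) -> bool:
    return label.startswith(("Fp", "AFp"))


# ---------------------------------------------------------------------------
# signal primitives

def _colored_noise(rng: np.random.Generator, n: int, fs: float,
                   exponent: float, rms: float) -> np.ndarray:
    """Gaussian noise shaped to a 1/f^exponent amplitude spectrum."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n=n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _band_oscillation(rng: np.random.Generator, n: int, fs: float,
                      freq_hz: float, rms: float) -> np.ndarray:
    """Amplitude-modulated sinusoid with random phases and target RMS."""
    if rms == 0:
        return np.zeros(n)
    t = np.arange(n) / fs
    mod_depth = 0.5
    env = 1.0 + mod_depth * np.sin(2 * np.pi * 0.2 * t + rng.uniform(0, 2 * np.pi))
    carrier = np.sin(2 * np.pi * freq_hz * t + rng.uniform(0, 2 * np.pi))
    x = env * carrier
    # mean square of env*carrier = (1 + mod_depth^2/2) / 2
    return x * (rms / np.sqrt((1 + mod_depth**2 / 2) / 2))


def _blink_kernel(fs: float, width_s: float = 0.3) -> np.ndarray:
    """Biphasic difference-of-Gaussians pulse, peak normalized to 1."""
    half = int(round(width_s * fs))
    t = np.arange(-half, half + 1) / fs
    s1, s2 = width_s / 6.0, width_s / 3.0
    k = np.exp(-t**2 / (2 * s1**2)) - 0.55 * np.exp(-t**2 / (2 * s2**2))
    return k / np.abs(k).max()


# ---------------------------------------------------------------------------
# artifact injection

def _snap_span(rec: Recording, span: tuple[float, float]) -> tuple[int, int]:
    i0 = rec.time_to_sample(span[0])
    i1 = rec.time_to_sample(span[1])
    if i1 <= i0:
        raise DesignError(f"artifact span {span} is empty at fs={rec.sampling_rate}")
    return i0, i1


def inject_artifact(rec: Recording, type: str,
                    channels: str | tuple[str, ...],
                    span: tuple[float, float],
                    params: dict | None = None,
                    seed: int = 0) -> tuple[Recording, ArtifactLabel]:
    """Inject one gross artifact into a copy of ``rec``.

    Artifact shapes follow what each failure mode physically produces:

    * ``pop`` — an isolated burst on one channel, default peak 400 uV;
    * ``poor_contact`` — repeated square waves alternating near-zero signal
      and the saturation value (default 1 V, i.e. amplifier rail);
    * ``digitization`` — signal replaced by an ADC-step staircase whose
      successive differences stay within a few resolution steps;
    * ``wireless_loss`` — every channel holds its last pre-span value;
    * ``flat`` — affected channels constant over the span.

    Returns the modified recording and a sample-exact ground-truth label.
    ``flat`` on every channel is refused: that is a failed recording, not an
    artifact (use a session-level flag instead).
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if span[0] < 0 or span[1] > rec.duration_s + 1e-9:
        raise DesignError(f"span {span} outside recording [0, {rec.duration_s})")

    if channels == "random":
        channels = (str(rng.choice(rec.channel_labels)),)
    if type == "wireless_loss":
        channels = ALL_CHANNELS
    if type == "flat" and (
        channels == ALL_CHANNELS
        or set(channels) == set(rec.channel_labels)
    ):
        raise FailedRecordingError(
            "flat lines on all channels constitute a failed recording, "
            "not an artifact; flag the session instead"
        )

    out = rec.copy()
    i0, i1 = _snap_span(rec, span)
    n = i1 - i0
    fs = rec.sampling_rate

    if type == "pop":
        (label,) = tuple(channels)
        ch = rec.channel_index(label)
        peak = float(params.get("peak_uv", 400.0))
        t = np.arange(n) / fs
        center = (n / 2) / fs
        tau = max((n / fs) / 6.0, 1.0 / fs)
        burst = peak * np.exp(-np.abs(t - center) / tau)
        out.signal[ch, i0:i1] += np.sign(rng.standard_normal() + 1e-12) * burst
        # guarantee the nominal peak despite background cancellation
        j = i0 + n // 2
        if np.abs(out.signal[ch, j]) < peak:
            out.signal[ch, j] = np.sign(out.signal[ch, j] + 1e-12) * peak
    elif type == "poor_contact":
        saturation = float(params.get("saturation_uv", 1.0e6))
        period_s = float(params.get("period_s", 0.5))
        half = max(int(round(period_s * fs / 2)), 1)
        for label in tuple(channels):
            ch = rec.channel_index(label)
            seg = np.zeros(n)
            phase = 0
            low = True
            while phase < n:
                stop = min(phase + half, n)
                if not low:
                    seg[phase:stop] = saturation * (1 if (phase // half) % 4 else -1)
                else:
                    seg[phase:stop] = out.signal[ch, i0 + phase:i0 + stop] * 0.1
                low = not low
                phase = stop
            out.signal[ch, i0:i1] = seg
    elif type == "digitization":
        resolution = float(params.get("resolution_uv", 0.29))
        amp_steps = float(params.get("amplitude_steps", 3.0))
        for label in tuple(channels):
            ch = rec.channel_index(label)
            walk = np.cumsum(rng.integers(-1, 2, size=n))
            walk = np.clip(walk, -amp_steps, amp_steps)
            out.signal[ch, i0:i1] = walk * resolution
    elif type == "wireless_loss":
        hold_idx = max(i0 - 1, 0)
        out.signal[:, i0:i1] = out.signal[:, hold_idx][:, None]
    elif type == "flat":
        for label in tuple(channels):
            ch = rec.channel_index(label)
            out.signal[ch, i0:i1] = float(params.get("value_uv", 0.0))
    else:
        raise DesignError(f"unknown artifact type {type!r}")

    label = ArtifactLabel(type=type, channels=channels,
                          start_s=i0 / fs, end_s=i1 / fs)
    return out, label


def quantize(rec: Recording, profile: HeadsetProfile) -> Recording:
    """Snap every sample to the ADC grid and clip to the input range.

    Values are rounded to the nearest multiple of ``profile.resolution``
    (half away from zero) and clipped to ``+- profile.input_range_uv``.
    """
    res = profile.resolution
    out = rec.copy()
    x = out.signal
    snapped = np.copysign(np.floor(np.abs(x) / res + 0.5), x) * res
    out.signal = np.clip(snapped, -profile.input_range_uv, profile.input_range_uv)
    return out


# ---------------------------------------------------------------------------
# session assembly

_ARTIFACT_DEFAULT_DUR_S = {
    "pop": 0.4,
    "poor_contact": 3.0,
    "digitization": 5.0,
    "wireless_loss": 1.5,
    "flat": 4.0,
}


def _poisson_spans(rng: np.random.Generator, rate_per_min: float,
                   total_s: float, dur_s: float,
                   occupied: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Poisson arrivals; arrivals overlapping earlier spans are shifted right."""
    n = rng.poisson(rate_per_min * total_s / 60.0)
    starts = np.sort(rng.uniform(0, max(total_s - dur_s, 0), size=n))
    spans: list[tuple[float, float]] = []
    for s in starts:
        s = float(s)
        moved = True
        while moved:
            moved = False
            for (a, b) in occupied + spans:
                if s < b + 0.5 and s + dur_s > a - 0.5:  # 0.5 s clearance
                    s = b + 0.5
                    moved = True
        if s + dur_s <= total_s:
            spans.append((s, s + dur_s))
    return spans


def simulate_session(design: SessionDesign
                     ) -> tuple[Recording, AnnotationTrack, list[ArtifactLabel]]:
    """Render a full session from a design.

    Returns the (optionally quantized) recording, the condition annotation
    track covering the conditions exactly, and the ground-truth artifact
    labels with sample-exact spans.
    """
    profile = design.profile
    fs = profile.sampling_rate
    rng = np.random.default_rng(design.seed)

    segments: list[np.ndarray] = []
    intervals: list[Interval] = []
    t0 = 0.0
    for cond in design.conditions:
        n = int(round(cond.duration_s * fs))
        seg = np.empty((profile.n_channels, n))
        for ch, label in enumerate(profile.channel_labels):
            x = _colored_noise(rng, n, fs, cond.background_exponent,
                               design.background_rms)
            if _is_posterior(label):
                x = x + _band_oscillation(rng, n, fs, 10.0, cond.alpha_amp)
            if _is_frontal(label):
                x = x + _band_oscillation(rng, n, fs, 20.0, cond.beta_amp)
            seg[ch] = x
        # eye blinks on frontopolar channels, shared timing across them
        fp = [ch for ch, l in enumerate(profile.channel_labels)
              if _is_frontopolar(l)]
        if fp and cond.blink_rate > 0:
            kernel = _blink_kernel(fs) * design.blink_amp
            n_blinks = rng.poisson(cond.blink_rate * cond.duration_s / 60.0)
            centers = np.sort(rng.integers(
                len(kernel), max(n - len(kernel), len(kernel) + 1),
                size=n_blinks))
            # physiological refractoriness: drop blinks closer than a pulse
            keep, last = [], -10 * len(kernel)
            for c in centers:
                if c - last >= len(kernel):
                    keep.append(c)
                    last = c
            for c in keep:
                lo = c - len(kernel) // 2
                hi = lo + len(kernel)
                if lo >= 0 and hi <= n:
                    for ch in fp:
                        seg[ch, lo:hi] += kernel * rng.uniform(0.8, 1.2)
        segments.append(seg)
        intervals.append(Interval(cond.label, t0, t0 + n / fs))
        t0 += n / fs

    signal = np.concatenate(segments, axis=1)
    rec = Recording(subject_id=design.subject_id, headset=profile.name,
                    signal=signal, sampling_rate=fs,
                    channel_labels=profile.channel_labels)
    track = AnnotationTrack(intervals)

    labels: list[ArtifactLabel] = []
    occupied: list[tuple[float, float]] = []
    for item in design.artifact_plan:
        dur = float(item.params.get(
            "duration_s", _ARTIFACT_DEFAULT_DUR_S.get(item.type, 1.0)))
        if item.spans is not None:
            spans = [tuple(s) for s in item.spans]
        else:
            if item.rate_per_min is None:
                raise DesignError(
                    f"artifact plan item {item.type} needs rate_per_min or spans")
            spans = _poisson_spans(rng, item.rate_per_min, rec.duration_s,
                                   dur, occupied)
        params = dict(item.params)
        if item.type == "poor_contact":
            params.setdefault("saturation_uv", profile.input_range_uv)
        if item.type == "digitization":
            params.setdefault("resolution_uv", profile.resolution)
        for span in spans:
            rec, lab = inject_artifact(
                rec, item.type, item.channels, span, params,
                seed=int(rng.integers(2**31)))
            labels.append(lab)
            occupied.append(span)

    if design.quantize_output:
        rec = quantize(rec, profile)
    return rec, track, labels


# ---------------------------------------------------------------------------
# spectral-domain generator for clustering ground truth

def three_class_spectra(n_per_class: int = 30, seed: int = 0,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Normalized PSD samples from three known spectral shape families.

    The families mirror the three PSD morphologies that recur across
    devices in mobile recordings: a plain 1/f curve, a 1/f curve with an
    alpha (10 Hz) peak, and a concave-down curve.  Per-bin multiplicative
    Gamma(7, 1/7) noise emulates the sampling variability of a 7-taper
    multitaper estimate.

    Returns ``(X, labels)`` with ``X`` of shape
    ``(3 * n_per_class, 256)`` rows summing to 1.
    """
    from .spectral import FREQ_GRID

    rng = np.random.default_rng(seed)
    f = FREQ_GRID
    shapes = (
        1.0 / f,
        1.0 / f + 0.6 * np.exp(-((f - 10.0) ** 2) / (2 * 1.5**2)),
        1.0 - 0.9 * ((f - 25.0) / 25.0) ** 2 + 0.05,
    )
    X, y = [], []
    for cls, shape in enumerate(shapes):
        base = shape / shape.sum()
        for _ in range(n_per_class):
            noisy = base * rng.gamma(7.0, 1.0 / 7.0, size=f.size)
            X.append(noisy / noisy.sum())
            y.append(cls)
    return np.asarray(X), np.asarray(y)
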