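"""Headset device profiles.

A :class:`HeadsetProfile` captures the amplifier/montage facts that drive the
quality-control thresholds and ADC quantization downstream: channel count and
labels (extended 10-20 names), sampling rate, amplitude resolution (microvolts
per ADC step), input range, ADC bit depth, reference scheme and whether the
link to the recorder is wireless.

Built-in profiles describe the five systems evaluated in the museum
deployment this package models:

========  ====================================  ====  =======  ==========
name      system                                chans  Fs (Hz)  res (uV)
========  ====================================  ====  =======  ==========
M4S       Mindo 4S JellyFish (dry)                 4      256      0.29
SS        Neuroelectrics Starstim (dry)            8      500      0.05
BPD       Brain Products actiCAP Xpress (dry)     16      512      0.05
M32       Mindo Trilobite (dry)                   32      256      0.29
BPG       Brain Products actiCAP + BrainAmp DC    32     1000      0.10
========  ====================================  ====  =======  ==========

Full per-device montages are editable defaults: the shared-electrode structure
(Fp1/Fp2 on the frontal four-channel headset; the central/parietal eight-channel
montage; O1 shared by the three largest systems) is fixed, the remaining sites
are conventional extended 10-20 choices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path


class ProfileNotFoundError(KeyError):
    """Requested built-in headset profile does not exist."""


class ProfileParseError(ValueError):
    """A profile JSON file is malformed or misses a required field."""


@dataclass(frozen=True)
class HeadsetProfile:
    """Technical specification of one EEG acquisition system.

    Parameters
    ----------
    name : str
        Short device identifier (e.g. ``"M32"``).
    channel_labels : tuple of str
        Ordered extended 10-20 electrode names; unique.
    sampling_rate : float
        Sampling frequency in Hz.
    resolution : float
        Amplitude resolution in microvolts per ADC step.
    input_range_mv : float
        Symmetric input range in millivolts (the amplifier clips at
        ``+- input_range_mv * 1000`` microvolts).
    adc_bits : int
        ADC word length in bits.
    reference : str
        Reference scheme descriptor (``earlobe``, ``mastoid``, ``neck``,
        ``FCz`` ...).
    wireless : bool
        True when data reach the recorder over a wireless link (those
        systems can exhibit transmission-loss artifacts).
    """

    name: str
    channel_labels: tuple[str, ...]
    sampling_rate: float
    resolution: float
    input_range_mv: float
    adc_bits: int
    reference: str
    wireless: bool = False

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ProfileParseError("sampling_rate must be positive")
        if self.resolution <= 0:
            raise ProfileParseError("resolution must be positive")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ProfileParseError("channel_labels must be unique")

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    @property
    def input_range_uv(self) -> float:
        """Clip level in microvolts."""
        return self.input_range_mv * 1000.0

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "channel_labels": list(self.channel_labels),
            "sampling_rate": self.sampling_rate,
            "resolution": self.resolution,
            "input_range_mv": self.input_range_mv,
            "adc_bits": self.adc_bits,
            "reference": self.reference,
            "wireless": self.wireless,
        }


# The two 32-channel systems use conventional extended 10-20 layouts that differ
# in their outermost sites; the 16-channel dry cap shares the nine analysis
# electrodes and fills up from the symmetric difference of the two.
_M32_LABELS = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6", "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2", "FT9", "FT10", "TP9", "TP10",
)
_BPG_LABELS = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6", "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2", "FC3", "FC4", "CP3", "CP4",
)
_BPD_LABELS = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1",
    "FT9", "FT10", "TP9", "TP10", "FC3", "FC4", "CP3",
)
_SS_LABELS = ("AF3", "AF4", "F3", "F4", "C3", "C4", "P3", "P4")
_M4S_LABELS = ("Fp1", "Fp2", "AFp1", "AFp2")

BUILTIN_PROFILES: dict[str, HeadsetProfile] = {
    "M4S": HeadsetProfile(
        name="M4S", channel_labels=_M4S_LABELS, sampling_rate=256.0,
        resolution=0.29, input_range_mv=2400.0, adc_bits=24,
        reference="neck", wireless=True,
    ),
    "SS": HeadsetProfile(
        name="SS", channel_labels=_SS_LABELS, sampling_rate=500.0,
        resolution=0.05, input_range_mv=410.0, adc_bits=24,
        reference="neck", wireless=True,
    ),
    "BPD": HeadsetProfile(
        name="BPD", channel_labels=_BPD_LABELS, sampling_rate=512.0,
        resolution=0.05, input_range_mv=410.0, adc_bits=24,
        reference="earlobe", wireless=False,
    ),
    "M32": HeadsetProfile(
        name="M32", channel_labels=_M32_LABELS, sampling_rate=256.0,
        resolution=0.29, input_range_mv=2400.0, adc_bits=24,
        reference="earlobe", wireless=True,
    ),
    "BPG": HeadsetProfile(
        name="BPG", channel_labels=_BPG_LABELS, sampling_rate=1000.0,
        resolution=0.1, input_range_mv=3.28, adc_bits=16,
        reference="FCz", wireless=True,
    ),
}

_REQUIRED_FIELDS = (
    "name", "channel_labels", "sampling_rate", "resolution",
    "input_range_mv", "adc_bits", "reference",
)


def load_headset_profile(name: str | Path) -> HeadsetProfile:
    """Return a built-in profile by name, or load one from a JSON file.

    Parameters
    ----------
    name : str or Path
        One of ``{"M4S", "SS", "BPD", "M32", "BPG"}``, or a path to a JSON
        file with the fields of :class:`HeadsetProfile`.

    Raises
    ------
    ProfileNotFoundError
        Unknown built-in name and no such file.
    ProfileParseError
        Malformed JSON or missing field (the message names the field).
    """
    key = str(name)
    if key in BUILTIN_PROFILES:
        return BUILTIN_PROFILES[key]
    path = Path(name)
    if not path.exists():
        raise ProfileNotFoundError(
            f"unknown headset profile {key!r}; built-ins are "
            f"{sorted(BUILTIN_PROFILES)}"
        )
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ProfileParseError(f"invalid profile JSON in {path}: {exc}") from exc
    for fname in _REQUIRED_FIELDS:
        if fname not in payload:
            raise ProfileParseError(f"profile {path} is missing field {fname!r}")
    return HeadsetProfile(
        name=payload["name"],
        channel_labels=tuple(payload["channel_labels"]),
        sampling_rate=float(payload["sampling_rate"]),
        resolution=float(payload["resolution"]),
        input_range_mv=float(payload["input_range_mv"]),
        adc_bits=int(payload["adc_bits"]),
        reference=str(payload["reference"]),
        wireless=bool(payload.get("wireless", False)),
    )


def save_headset_profile(profile: HeadsetProfile, path: str | Path) -> None:
    Path(path).write_text(json.dumps(profile.to_dict(), indent=2) + "\n")
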