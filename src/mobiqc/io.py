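"""Readers and writers for recordings, annotations and artifact labels.

Two recording formats are supported:

``csv_fixture``
    A plain-text dialect for small fixtures and tests: a ``# fs=<Hz>`` comment
    line, a header row of channel labels, then one row per sample.  Values are
    written with ``repr``-level precision so a write/read cycle is bit-exact.

``edf``
    European Data Format.  Reading goes through :mod:`mne`; writing uses a
    minimal built-in EDF writer (fixed ASCII header + 16-bit little-endian
    samples), so round-trips are exact to the 16-bit physical scaling declared
    in the header.

Annotations and artifact labels are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .recording import (
    ALL_CHANNELS,
    AnnotationTrack,
    ArtifactLabel,
    Interval,
    Recording,
    SchemaError,
)

__all__ = [
    "read_recording",
    "write_recording",
    "read_annotations",
    "write_annotations",
    "read_artifact_labels",
    "write_artifact_labels",
]


# ---------------------------------------------------------------------------
# csv fixture dialect

def _write_csv_fixture(rec: Recording, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.sampling_rate:g}\n")
        fh.write(f"# subject={rec.subject_id}\n")
        fh.write(f"# headset={rec.headset}\n")
        fh.write(",".join(rec.channel_labels) + "\n")
        np.savetxt(fh, rec.signal.T, delimiter=",", fmt="%.17g")


def _read_csv_fixture(path: Path) -> Recording:
    fs = None
    subject = path.stem
    headset = "unknown"
    header: list[str] | None = None
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    key = key.strip()
                    if key == "fs":
                        fs = float(value)
                    elif key == "subject":
                        subject = value.strip()
                    elif key == "headset":
                        headset = value.strip()
                continue
            if header is None:
                header = [c.strip() for c in line.split(",")]
                continue
            cells = line.split(",")
            if len(cells) != len(header):
                raise SchemaError(
                    f"{path}:{lineno}: row has {len(cells)} cells but header "
                    f"declares {len(header)} channels"
                )
            try:
                rows.append(np.array([float(c) for c in cells]))
            except ValueError as exc:
                raise SchemaError(f"{path}:{lineno}: non-numeric cell ({exc})") from exc
    if fs is None:
        raise SchemaError(f"{path}: missing '# fs=<Hz>' comment line")
    if header is None:
        raise SchemaError(f"{path}: missing channel-label header row")
    signal = np.array(rows).T if rows else np.empty((len(header), 0))
    return Recording(subject_id=subject, headset=headset, signal=signal,
                     sampling_rate=fs, channel_labels=tuple(header))


# ---------------------------------------------------------------------------
# EDF

def _edf_field(value, width: int) -> bytes:
    text = str(value)
    if len(text) > width:
        raise ValueError(f"EDF header field {text!r} exceeds {width} bytes")
    return text.ljust(width).encode("ascii")


def _fmt_float(x: float, width: int = 8) -> str:
    # shortest decimal representation that fits the fixed-width field
    for prec in range(width - 2, -1, -1):
        text = f"{x:.{prec}f}" if prec else f"{x:.0f}"
        if len(text) <= width:
            return text
    raise ValueError(f"cannot format {x} in {width} chars")


def _write_edf(rec: Recording, path: Path) -> None:
    """Minimal EDF writer: one or more fixed-duration data records, 16-bit."""
    n_ch, n_samp = rec.signal.shape
    fs = rec.sampling_rate
    # one-second records when they tile the recording exactly, else one record
    if fs == int(fs) and n_samp % int(fs) == 0 and n_samp > 0:
        spr = int(fs)
        n_rec = n_samp // spr
        duration = 1
    else:
        spr = n_samp
        n_rec = 1
        duration = _fmt_float(n_samp / fs)

    pmin = np.minimum(rec.signal.min(axis=1), -1.0)
    pmax = np.maximum(rec.signal.max(axis=1), 1.0)
    dmin, dmax = -32768, 32767
    scale = (pmax - pmin) / (dmax - dmin)
    digital = np.round((rec.signal - pmin[:, None]) / scale[:, None]) + dmin
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    header = b"".join([
        _edf_field(0, 8),
        _edf_field(rec.subject_id[:80], 80),
        _edf_field(f"Startdate X mobiqc {rec.headset}"[:80], 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(256 * (n_ch + 1), 8),
        _edf_field("", 44),
        _edf_field(n_rec, 8),
        _edf_field(duration, 8),
        _edf_field(n_ch, 4),
    ])
    per_signal = b"".join([
        b"".join(_edf_field(lbl[:16], 16) for lbl in rec.channel_labels),
        b"".join(_edf_field("", 80) for _ in range(n_ch)),
        b"".join(_edf_field("uV", 8) for _ in range(n_ch)),
        b"".join(_edf_field(_fmt_float(p), 8) for p in pmin),
        b"".join(_edf_field(_fmt_float(p), 8) for p in pmax),
        b"".join(_edf_field(dmin, 8) for _ in range(n_ch)),
        b"".join(_edf_field(dmax, 8) for _ in range(n_ch)),
        b"".join(_edf_field("", 80) for _ in range(n_ch)),
        b"".join(_edf_field(spr, 8) for _ in range(n_ch)),
        b"".join(_edf_field("", 32) for _ in range(n_ch)),
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        for r in range(n_rec):
            block = digital[:, r * spr:(r + 1) * spr]
            fh.write(block.tobytes())  # signal-major within each record


def _read_edf(path: Path) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    signal_uv = raw.get_data() * 1e6  # mne returns Volts
    subject = raw.info.get("subject_info") or {}
    return Recording(
        subject_id=str(subject.get("his_id", path.stem)),
        headset="unknown",
        signal=signal_uv,
        sampling_rate=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
    )


# ---------------------------------------------------------------------------
# public API

def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    return "edf" if path.suffix.lower() == ".edf" else "csv_fixture"


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read a recording from ``edf`` or ``csv_fixture`` (inferred from suffix)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "edf":
        return _read_edf(path)
    if fmt == "csv_fixture":
        return _read_csv_fixture(path)
    raise ValueError(f"unknown recording format {fmt!r}")


def write_recording(rec: Recording, path: str | Path,
                    format: str | None = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "edf":
        _write_edf(rec, path)
    elif fmt == "csv_fixture":
        _write_csv_fixture(rec, path)
    else:
        raise ValueError(f"unknown recording format {fmt!r}")


def write_annotations(track: AnnotationTrack, path: str | Path) -> None:
    payload = [
        {"label": iv.label, "start_s": iv.start_s, "end_s": iv.end_s}
        for iv in track
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_annotations(path: str | Path) -> AnnotationTrack:
    payload = json.loads(Path(path).read_text())
    return AnnotationTrack(
        [Interval(d["label"], float(d["start_s"]), float(d["end_s"]))
         for d in payload]
    )


def write_artifact_labels(labels: list[ArtifactLabel], path: str | Path) -> None:
    payload = [
        {
            "type": l.type,
            "channels": l.channels if l.channels == ALL_CHANNELS else list(l.channels),
            "start_s": l.start_s,
            "end_s": l.end_s,
        }
        for l in labels
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_artifact_labels(path: str | Path) -> list[ArtifactLabel]:
    payload = json.loads(Path(path).read_text())
    return [
        ArtifactLabel(
            type=d["type"],
            channels=d["channels"] if d["channels"] == ALL_CHANNELS
            else tuple(d["channels"]),
            start_s=float(d["start_s"]),
            end_s=float(d["end_s"]),
        )
        for d in payload
    ]
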