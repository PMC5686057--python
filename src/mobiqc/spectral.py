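"""Multitaper spectral estimation and spectral feature construction.

Each retained 4 s window is summarized by a Thomson multitaper PSD
(DPSS tapers, time-half-bandwidth NW = 4) evaluated on a 512-point FFT grid
and linearly interpolated onto 256 equally spaced bins between 1 and 50 Hz.
Per-window PSDs are normalized by their total power (each normalized PSD
sums to 1), pooled per electrode across headsets and conditions, and
standardized bin-wise to zero mean and unit variance — the feature matrix
``X (N samples x 256 bins)`` consumed by the kernel clustering stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal.windows import dpss

from .recording import Recording
from .segment import Window

__all__ = [
    "FREQ_GRID", "N_BINS", "BANDS",
    "SpectralSample", "DegenerateWindowError", "GridError",
    "multitaper_psd", "normalize_total_power", "standardize_features",
    "band_power", "select_common_electrodes", "common_electrode_membership",
    "spectral_samples", "feature_table", "write_feature_table",
    "read_feature_table",
]

N_BINS = 256
#: 256 equally spaced frequency bins on [1, 50] Hz
FREQ_GRID = np.linspace(1.0, 50.0, N_BINS)

#: band limits in Hz; alpha and beta follow the standard definitions used in
#: the museum study, delta and gamma are the package's declared defaults
#: (gamma capped by the 50 Hz low-pass)
BANDS = {
    "delta": (1.0, 4.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 50.0),
}


class DegenerateWindowError(ValueError):
    """A window carries no power; it must be dropped, not normalized."""


class GridError(ValueError):
    """The sampling rate cannot support the 1-50 Hz analysis grid."""


@dataclass
class SpectralSample:
    """One window's normalized 256-bin PSD plus its provenance."""

    psd: np.ndarray
    subject: str
    headset: str
    electrode: str
    condition: str
    gender: str = "U"
    piece_id: str | None = None
    start_s: float = 0.0
    standardized: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.psd = np.asarray(self.psd, dtype=float)
        if self.psd.shape != (N_BINS,):
            raise ValueError(f"psd must have {N_BINS} bins")
        if np.any(self.psd < -1e-12):
            raise ValueError("psd values must be non-negative")


_taper_cache: dict[tuple[int, float], tuple[np.ndarray, np.ndarray]] = {}


def _tapers(n: int, nw: float) -> tuple[np.ndarray, np.ndarray]:
    key = (n, nw)
    if key not in _taper_cache:
        k = int(2 * nw - 1)
        tapers, eigvals = dpss(n, nw, Kmax=k, return_ratios=True)
        _taper_cache[key] = (tapers, eigvals)
    return _taper_cache[key]


def multitaper_psd(window_signal: np.ndarray, fs: float, nw: float = 4.0,
                   n_points: int = 512) -> np.ndarray:
    """Thomson multitaper PSD of one window on the 256-bin 1-50 Hz grid.

    Parameters
    ----------
    window_signal : 1-D array
        One channel's samples for one analysis window, in microvolts.
    fs : float
        Sampling rate in Hz; must satisfy ``fs/2 >= 50``.
    nw : float
        Time-half-bandwidth product of the DPSS tapers (default 4;
        ``2*nw - 1`` tapers are used, eigenvalue-weighted).
    n_points : int
        Minimum FFT length (default 512); the FFT grid is
        ``max(n_points, len(window_signal))`` points, then linearly
        interpolated onto :data:`FREQ_GRID`.

    Returns
    -------
    ndarray, shape (256,)
        One-sided PSD density (uV^2/Hz) at the grid frequencies.
    """
    x = np.asarray(window_signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("window_signal must be 1-D")
    if fs / 2.0 < FREQ_GRID[-1]:
        raise GridError(
            f"fs/2 = {fs / 2:.1f} Hz cannot cover the 1-50 Hz grid")
    n = x.size
    tapers, eigvals = _tapers(n, nw)
    nfft = max(int(n_points), n)
    spec = np.fft.rfft(tapers * x[None, :], n=nfft, axis=1)
    # eigenvalue-weighted average of one-sided taper periodograms
    pxx = (np.abs(spec) ** 2 * eigvals[:, None]).sum(axis=0) / eigvals.sum()
    pxx /= fs
    pxx[1:] *= 2.0
    if nfft % 2 == 0:
        pxx[-1] /= 2.0
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    return np.interp(FREQ_GRID, freqs, pxx)


def normalize_total_power(psd: np.ndarray) -> np.ndarray:
    """Divide a PSD by its total power so the bins sum to 1."""
    psd = np.asarray(psd, dtype=float)
    total = psd.sum()
    if total <= 0:
        raise DegenerateWindowError("all-zero PSD; drop this window")
    return psd / total


def standardize_features(X: np.ndarray) -> np.ndarray:
    """Z-score each frequency bin across samples (pooled per electrode).

    Zero-variance bins are set to 0 with a warning.  Requires >= 2 rows.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    # variance that is zero up to rounding of the column mean counts as zero
    zero = sd <= 1e-12 * np.maximum(np.abs(mean), 1.0)
    if np.any(zero):
        warnings.warn(f"{int(zero.sum())} zero-variance bins set to 0")
    sd = np.where(zero, 1.0, sd)
    Z = (X - mean) / sd
    Z[:, zero] = 0.0
    return Z


def band_power(psd_normalized: np.ndarray, band: str) -> float:
    """Fraction of normalized power in a named band.

    Bands are half-open ``[lo, hi)`` on the grid; the top of the gamma band
    coincides with the grid end and is included.
    """
    if band not in BANDS:
        raise ValueError(f"unknown band {band!r}; choose from {sorted(BANDS)}")
    lo, hi = BANDS[band]
    mask = (FREQ_GRID >= lo) & (FREQ_GRID < hi)
    if hi >= FREQ_GRID[-1]:
        mask |= np.isclose(FREQ_GRID, FREQ_GRID[-1])
    return float(np.asarray(psd_normalized)[mask].sum())


# ---------------------------------------------------------------------------
# electrode commonality

def common_electrode_membership(
    montages: dict[str, tuple[str, ...]],
    min_shared: int = 3,
) -> dict[str, tuple[str, ...]]:
    """Map each analyzable electrode to the headsets that share it.

    An electrode is analyzable when at least ``min(min_shared, n_montages)``
    montages contain it; it is then analyzed across exactly the headsets
    that share it.
    """
    if len(montages) < 2:
        raise ValueError("need at least 2 headset montages")
    need = min(min_shared, len(montages))
    membership: dict[str, tuple[str, ...]] = {}
    union: list[str] = []
    for labels in montages.values():
        for l in labels:
            if l not in union:
                union.append(l)
    for electrode in union:
        sharing = tuple(name for name, labels in montages.items()
                        if electrode in labels)
        if len(sharing) >= need:
            membership[electrode] = sharing
    return membership


def select_common_electrodes(montages: dict[str, tuple[str, ...]],
                             min_shared: int = 3) -> list[str]:
    """Electrodes shared by enough headsets to be analyzed (montage order)."""
    return list(common_electrode_membership(montages, min_shared))


# ---------------------------------------------------------------------------
# feature construction

def spectral_samples(rec: Recording, windows: list[Window],
                     electrodes: list[str] | None = None,
                     gender: str = "U") -> list[SpectralSample]:
    """Normalized multitaper PSD samples for every window x electrode.

    Windows whose PSD is degenerate (zero power) are dropped.
    """
    if electrodes is None:
        electrodes = list(rec.channel_labels)
    samples: list[SpectralSample] = []
    for w in windows:
        seg = w.slice(rec)
        for electrode in electrodes:
            ch = rec.channel_index(electrode)
            raw = multitaper_psd(seg[ch], rec.sampling_rate)
            try:
                psd = normalize_total_power(raw)
            except DegenerateWindowError:
                continue
            samples.append(SpectralSample(
                psd=psd, subject=rec.subject_id, headset=rec.headset,
                electrode=electrode, condition=w.epoch.condition,
                gender=gender, piece_id=w.epoch.piece_id, start_s=w.start_s))
    return samples


_META_COLS = ["subject", "headset", "electrode", "condition", "gender",
              "piece_id", "start_s"]


def feature_table(samples: list[SpectralSample]) -> pd.DataFrame:
    """Samples as a DataFrame: metadata columns then 256 ``f<i>`` columns."""
    meta = pd.DataFrame([
        {c: getattr(s, c) for c in _META_COLS} for s in samples])
    feats = pd.DataFrame(np.vstack([s.psd for s in samples]),
                         columns=[f"f{i}" for i in range(N_BINS)])
    return pd.concat([meta.reset_index(drop=True), feats], axis=1)


def write_feature_table(samples: list[SpectralSample], path) -> None:
    feature_table(samples).to_csv(path, sep="\t", index=False)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
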