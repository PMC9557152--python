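"""Welch power-spectral estimation and dominant-frequency (DF) mapping.

The DF of a fibrillatory signal is the frequency of the highest peak of its
Welch periodogram, searched within the atrial band (3–12 Hz by default; the
canonical AF fibrillatory range).  The Welch settings — 2-s Hamming window,
4096-point FFT, 50% overlap — give a frequency resolution of fs/4096
(≈ 0.244 Hz at 1 kHz).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal as sps

from .errors import ConfigError, InsufficientDataError

__all__ = ["SpectralConfig", "welch_psd", "dominant_frequency", "df_map"]


@dataclass(frozen=True)
class SpectralConfig:
    welch_window_s: float = 2.0
    window_shape: str = "hamming"
    nfft: int = 4096
    overlap_frac: float = 0.5
    df_band_hz: tuple[float, float] = (3.0, 12.0)

    def __post_init__(self) -> None:
        if self.welch_window_s <= 0:
            raise ConfigError("welch_window_s must be positive")
        if not 0 <= self.overlap_frac < 1:
            raise ConfigError("overlap_frac must lie in [0, 1)")
        lo, hi = self.df_band_hz
        if not lo < hi:
            raise ConfigError("df_band_hz must satisfy lo < hi")

    def nperseg(self, fs: float) -> int:
        n = int(round(self.welch_window_s * fs))
        if self.nfft < n:
            raise ConfigError(
                f"nfft={self.nfft} is smaller than the Welch window of {n} samples"
            )
        return n


def welch_psd(
    x: np.ndarray, fs: float, cfg: Optional[SpectralConfig] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD of one lead (1-D) or of each column of a matrix.

    Returns ``(frequencies_hz, power_density)``; the frequency grid spacing is
    ``fs / cfg.nfft``.  No detrending is applied: inputs are assumed already
    band-passed/normalized upstream.
    """
    cfg = cfg or SpectralConfig()
    x = np.asarray(x, dtype=float)
    nper = cfg.nperseg(fs)
    if x.shape[0] < nper:
        raise InsufficientDataError(
            f"signal of {x.shape[0]} samples is shorter than the "
            f"{cfg.welch_window_s}-s Welch window ({nper} samples)"
        )
    freqs, pxx = sps.welch(
        x,
        fs=fs,
        window=cfg.window_shape,
        nperseg=nper,
        noverlap=int(round(nper * cfg.overlap_frac)),
        nfft=cfg.nfft,
        detrend=False,
        axis=0,
    )
    return freqs, pxx


def dominant_frequency(
    x: np.ndarray, fs: float, cfg: Optional[SpectralConfig] = None
) -> float:
    """DF in Hz: frequency of the maximum in-band PSD value.

    Ties break toward the lower frequency.  A flat in-band spectrum (all
    values equal within 1e-12) leaves the DF undefined; NaN is returned.
    """
    cfg = cfg or SpectralConfig()
    freqs, pxx = welch_psd(np.asarray(x, dtype=float).ravel(), fs, cfg)
    lo, hi = cfg.df_band_hz
    band = (freqs >= lo) & (freqs <= hi)
    if not band.any():
        raise ConfigError(
            f"df_band_hz {cfg.df_band_hz} contains no frequency bins at fs={fs}"
        )
    p = pxx[band]
    if p.max() - p.min() < 1e-12:
        return float("nan")
    return float(freqs[band][int(np.argmax(p))])


def df_map(x: np.ndarray, fs: float, cfg: Optional[SpectralConfig] = None) -> np.ndarray:
    """Per-lead DF vector of a ``(m, L)`` window matrix.

    Undefined DFs (flat in-band spectra) propagate as NaN.
    """
    cfg = cfg or SpectralConfig()
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    freqs, pxx = welch_psd(x, fs, cfg)
    lo, hi = cfg.df_band_hz
    band = (freqs >= lo) & (freqs <= hi)
    fb, pb = freqs[band], pxx[band]
    out = fb[np.argmax(pb, axis=0)].astype(float)
    flat = pb.max(axis=0) - pb.min(axis=0) < 1e-12
    out[flat] = np.nan
    return out
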