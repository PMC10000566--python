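"""Respiratory-wave pre-extraction and the FFT-based RR pre-estimate.

From a decomposition of a PPG window, the IMFs whose dominant frequency
falls in the respiratory band are selected, summed into a respiratory
wave, denoised by projecting onto the first principal component of the
selected-IMF matrix, and the wave's dominant in-band FFT frequency is
converted to breaths per minute: RR_P = 60 * f_peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .emd import Decomposition

__all__ = [
    "RespiratoryWave",
    "NoRespiratoryIMFError",
    "dominant_frequency",
    "select_respiratory_imfs",
    "pca_denoise",
    "estimate_rr",
]

#: Default respiratory search band in Hz (3-30 breaths/min).
DEFAULT_BAND = (0.05, 0.5)


class NoRespiratoryIMFError(RuntimeError):
    """No IMF is dominated by respiratory-band content; the window is
    discarded upstream rather than imputed."""


@dataclass
class RespiratoryWave:
    """Pre-extracted respiratory wave with its RR pre-estimate."""

    wave: np.ndarray
    fs: float
    selected_imf_indices: list[int]
    dominant_freq_hz: float

    @property
    def rr_p(self) -> float:
        """Pre-estimated respiratory rate in breaths/min (60 * f_peak)."""
        return self.dominant_freq_hz * 60.0


def dominant_frequency(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float] | None = None,
    pad_factor: int = 16,
) -> float:
    """Frequency (Hz) of the maximum-magnitude FFT bin within ``band``.

    The input is mean-removed and zero-padded by ``pad_factor`` for
    finer bin spacing; ties break toward the lower frequency.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        raise ValueError("need at least 8 samples")
    if pad_factor < 1:
        raise ValueError("pad_factor must be >= 1")
    xd = x - x.mean()
    if not np.any(xd != 0.0):
        raise ValueError("no spectral content (constant input)")
    n_fft = x.size * pad_factor
    spec = np.abs(np.fft.rfft(xd, n=n_fft))
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    if band is not None:
        lo, hi = band
        if not lo < hi <= fs / 2:
            raise ValueError(f"invalid band {band} for fs={fs}")
        mask = (freqs >= lo) & (freqs <= hi)
        if not mask.any():
            raise ValueError("band contains no FFT bins")
        spec = spec[mask]
        freqs = freqs[mask]
    return float(freqs[int(np.argmax(spec))])  # argmax: first (lowest) on ties


def select_respiratory_imfs(
    dec: Decomposition, band: tuple[float, float] = DEFAULT_BAND
) -> list[int]:
    """Indices of IMFs whose full-band dominant frequency lies in ``band``."""
    if dec.n_imfs < 1:
        raise NoRespiratoryIMFError("decomposition has no IMFs")
    lo, hi = band
    selected = []
    for k, imf in enumerate(dec.imfs):
        try:
            f = dominant_frequency(imf, dec.fs, band=None, pad_factor=16)
        except ValueError:
            continue  # flat IMF carries no dominant frequency
        if lo <= f <= hi:
            selected.append(k)
    if not selected:
        raise NoRespiratoryIMFError(
            f"no IMF with dominant frequency in [{lo}, {hi}] Hz"
        )
    return selected


def pca_denoise(imfs: list[np.ndarray]) -> np.ndarray:
    """First-principal-component reconstruction of a stack of IMFs.

    Each IMF is centred, the principal components of the (samples x
    IMFs) matrix are computed, and the score series of the leading
    component is returned.  The output sign is fixed so its correlation
    with the plain sum of the input IMFs is nonnegative.  A single IMF
    is returned centred (degenerate PCA).
    """
    if len(imfs) == 0:
        raise ValueError("need at least one IMF")
    M = np.column_stack([np.asarray(v, dtype=float) for v in imfs])
    M = M - M.mean(axis=0, keepdims=True)
    if M.shape[1] == 1:
        return M[:, 0].copy()
    # SVD of the centred matrix; leading score series = denoised wave
    u, s, vt = np.linalg.svd(M, full_matrices=False)
    wave = u[:, 0] * s[0]
    ref = M.sum(axis=1)
    if float(wave @ ref) < 0.0:
        wave = -wave
    return wave


def estimate_rr(
    dec: Decomposition,
    fs: float | None = None,
    band: tuple[float, float] = DEFAULT_BAND,
    pad_factor: int = 16,
) -> RespiratoryWave:
    """Full pre-extraction: IMF selection -> PCA denoising -> peak pick.

    Raises :class:`NoRespiratoryIMFError` when no IMF is respiratory,
    which callers treat as a discarded window.
    """
    fs = dec.fs if fs is None else fs
    selected = select_respiratory_imfs(dec, band=band)
    wave = pca_denoise([dec.imfs[k] for k in selected])
    f_peak = dominant_frequency(wave, fs, band=band, pad_factor=pad_factor)
    return RespiratoryWave(
        wave=wave, fs=fs, selected_imf_indices=selected, dominant_freq_hz=f_peak
    )
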