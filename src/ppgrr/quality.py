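"""PPG and respiratory signal-quality indices.

The PPG quality index is the skewness of 2-s subwindows averaged over
the 32-s window: clean pulsatile PPG is strongly right-skewed while
motion-corrupted segments drift toward symmetry.  The three respiratory
quality indices (RQIs) quantify periodicity of the pre-extracted
respiratory wave, down-sampled to 4 Hz, via autocorrelation (QR1),
spectral concentration (QR2), and autoregressive pole strength (QR3);
all three are normalized into [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from statsmodels.regression.linear_model import burg

__all__ = [
    "QualityIndices",
    "skewness",
    "sqi_mean",
    "resample_4hz",
    "rqi_autocorrelation",
    "rqi_fft",
    "rqi_autoregression",
]

RQI_BAND = (0.05, 0.5)


@dataclass
class QualityIndices:
    """The four quality features fed to the prediction model."""

    s_sqi_mean: float
    qr1: float
    qr2: float
    qr3: float

    def __post_init__(self) -> None:
        for name in ("qr1", "qr2", "qr3"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not np.isfinite(self.s_sqi_mean):
            raise ValueError("s_sqi_mean must be finite")


def skewness(x: np.ndarray) -> float:
    """Sample skewness with the population (divide-by-N) deviation.

    Returns (1/N) sum(((x - mean)/sd)^3); a zero-variance input returns
    0 by convention.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("skewness needs at least 3 samples")
    mu = x.mean()
    sd = x.std()  # population: divide by N
    if sd == 0.0:
        return 0.0
    return float(np.mean(((x - mu) / sd) ** 3))


def sqi_mean(ppg_window: np.ndarray, fs: float, subwindow_s: float = 2.0) -> float:
    """Mean skewness over nonoverlapping subwindows (16 for 32 s / 2 s)."""
    x = np.asarray(ppg_window, dtype=float)
    sub_n = int(round(subwindow_s * fs))
    n_sub = x.size // sub_n
    if n_sub < 1:
        raise ValueError("window shorter than one subwindow")
    vals = [skewness(x[i * sub_n : (i + 1) * sub_n]) for i in range(n_sub)]
    return float(np.mean(vals))


def resample_4hz(wave: np.ndarray, fs_in: float) -> np.ndarray:
    """Anti-alias filtered decimation of a respiratory wave to 4 Hz.

    A zero-phase Butterworth low-pass at 1.6 Hz precedes index-rounded
    decimation, which handles non-integer rate ratios (125 -> 4 Hz).
    Output length is round(n * 4 / fs_in); fs_in = 4 is the identity.
    """
    x = np.asarray(wave, dtype=float)
    if fs_in < 4:
        raise ValueError("fs_in must be >= 4 Hz")
    if fs_in == 4:
        return x.copy()
    sos = sps.butter(4, 1.6, btype="low", fs=fs_in, output="sos")
    filtered = sps.sosfiltfilt(sos, x)
    n_out = int(round(x.size * 4.0 / fs_in))
    idx = np.round(np.arange(n_out) * fs_in / 4.0).astype(int)
    idx = np.clip(idx, 0, x.size - 1)
    return filtered[idx]


def rqi_autocorrelation(wave4: np.ndarray, fs: float = 4.0) -> float:
    """QR1: peak normalized autocorrelation over respiratory periods.

    Searches lags corresponding to periods of 2-20 s (30 down to 3
    breaths/min); a perfectly periodic wave scores near 1, clipped to
    [0, 1].  Zero-variance input returns 0.
    """
    x = np.asarray(wave4, dtype=float)
    if x.size < int(8 * fs):
        raise ValueError("need at least 8 s of signal")
    x = x - x.mean()
    n = x.size
    denom = float(x @ x)
    if denom == 0.0:
        return 0.0
    acf = np.correlate(x, x, mode="full")[n - 1 :]
    # unbiased normalization: a periodic wave keeps peaks near 1 at
    # large lags instead of decaying with the overlap length
    lags = np.arange(n)
    acf = (acf / (n - lags)) / (denom / n)
    lag_lo = int(round(2.0 * fs))
    lag_hi = min(int(round(20.0 * fs)), n - 1)
    if lag_hi < lag_lo:
        return 0.0
    peak = float(np.max(acf[lag_lo : lag_hi + 1]))
    return float(np.clip(peak, 0.0, 1.0))


def rqi_fft(
    wave4: np.ndarray,
    fs: float = 4.0,
    band: tuple[float, float] = RQI_BAND,
    peak_halfwidth_hz: float = 0.05,
) -> float:
    """QR2: fraction of in-band spectral power concentrated around the
    dominant in-band peak (within +/- ``peak_halfwidth_hz``)."""
    x = np.asarray(wave4, dtype=float)
    if x.size < int(8 * fs):
        raise ValueError("need at least 8 s of signal")
    x = x - x.mean()
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    lo, hi = band
    in_band = (freqs >= lo) & (freqs <= hi)
    total = float(spec[in_band].sum())
    if total == 0.0:
        return 0.0
    f_in = freqs[in_band]
    p_in = spec[in_band]
    f_peak = f_in[int(np.argmax(p_in))]
    near = np.abs(f_in - f_peak) <= peak_halfwidth_hz
    return float(np.clip(p_in[near].sum() / total, 0.0, 1.0))


def rqi_autoregression(
    wave4: np.ndarray,
    fs: float = 4.0,
    order: int = 9,
    band: tuple[float, float] = RQI_BAND,
) -> float:
    """QR3: magnitude of the strongest AR pole in the respiratory band.

    An AR(order) model is fitted by the Burg method; among poles whose
    angular frequency maps into ``band``, the largest magnitude is
    returned (clipped to [0, 1]).  No in-band pole, or a degenerate
    fit, yields 0.
    """
    x = np.asarray(wave4, dtype=float)
    if x.size <= 2 * order:
        raise ValueError(f"need more than {2 * order} samples for order {order}")
    x = x - x.mean()
    if float(x @ x) == 0.0:
        return 0.0
    try:
        ar_coefs, _ = burg(x, order=order, demean=False)
    except Exception:  # noqa: BLE001 - degenerate fit guard
        return 0.0
    # poles of 1 - a1 z^-1 - ... - ap z^-p
    poles = np.roots(np.concatenate(([1.0], -np.asarray(ar_coefs))))
    freqs = np.abs(np.angle(poles)) * fs / (2.0 * np.pi)
    lo, hi = band
    in_band = (freqs >= lo) & (freqs <= hi)
    if not in_band.any():
        return 0.0
    return float(np.clip(np.max(np.abs(poles[in_band])), 0.0, 1.0))
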