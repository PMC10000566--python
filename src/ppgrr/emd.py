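"""Empirical mode decomposition and its noise-assisted ensemble variant.

EMD decomposes a signal into intrinsic mode functions (IMFs) by
iterative sifting: cubic-spline envelopes are fitted through the local
maxima and minima (with mirrored-extrema boundary extension), their mean
is subtracted, and the process repeats until a Cauchy-type SD criterion
is met.  EEMD averages the IMFs of an ensemble of white-noise-perturbed
copies of the signal, which suppresses mode mixing at the cost of exact
additivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = ["SiftConfig", "Decomposition", "emd", "eemd"]


@dataclass
class SiftConfig:
    """Sifting stop settings.

    ``sd_threshold`` is the Cauchy criterion: sifting of one IMF stops
    when sum((h_prev - h)^2) / sum(h_prev^2) falls below it.
    ``max_siftings`` is a hard per-IMF iteration cap.
    """

    sd_threshold: float = 0.2
    max_siftings: int = 50


@dataclass
class Decomposition:
    """Ordered IMFs (highest characteristic frequency first) plus residual."""

    imfs: list[np.ndarray]
    residual: np.ndarray
    source_length: int
    fs: float

    def __post_init__(self) -> None:
        for imf in self.imfs:
            if imf.size != self.source_length:
                raise ValueError("IMF length differs from source length")
        if self.residual.size != self.source_length:
            raise ValueError("residual length differs from source length")

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima of ``x``.

    Plateau points are collapsed to the first sample of the plateau by
    comparing against the nearest differing neighbours.
    """
    dx = np.diff(x)
    # sign of slope, carrying the last nonzero sign across plateaus
    sgn = np.sign(dx)
    nz = sgn != 0
    if not nz.any():
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    # forward-fill zero slopes with the previous nonzero slope sign
    idx = np.where(nz, np.arange(sgn.size), 0)
    np.maximum.accumulate(idx, out=idx)
    filled = sgn[idx]
    turns = np.diff(filled)
    maxima = np.flatnonzero(turns < 0) + 1
    minima = np.flatnonzero(turns > 0) + 1
    return maxima, minima


def _mirrored_knots(
    idx: np.ndarray, x: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Extend extrema beyond both ends by reflection about the endpoints."""
    pos = idx.astype(float)
    val = x[idx]
    left_src = idx[idx > 0][:2]
    lpos = -left_src[::-1].astype(float)
    lval = x[left_src[::-1]]
    right_src = idx[idx < n - 1][-2:]
    rpos = 2.0 * (n - 1) - right_src[::-1].astype(float)
    rval = x[right_src[::-1]]
    pos = np.concatenate([lpos, pos, rpos])
    val = np.concatenate([lval, val, rval])
    pos, keep = np.unique(pos, return_index=True)
    return pos, val[keep]


def _envelope_mean(x: np.ndarray) -> Optional[np.ndarray]:
    """Mean of the upper and lower cubic-spline envelopes, or None when
    the signal has too few extrema to be sifted further."""
    n = x.size
    maxima, minima = _local_extrema(x)
    if maxima.size < 2 or minima.size < 2:
        return None
    t = np.arange(n, dtype=float)
    up_pos, up_val = _mirrored_knots(maxima, x, n)
    lo_pos, lo_val = _mirrored_knots(minima, x, n)
    upper = CubicSpline(up_pos, up_val)(t)
    lower = CubicSpline(lo_pos, lo_val)(t)
    return 0.5 * (upper + lower)


def emd(
    signal: np.ndarray,
    fs: float,
    max_imfs: int = 10,
    sift_config: SiftConfig | None = None,
) -> Decomposition:
    """Plain empirical mode decomposition.

    The decomposition is complete by construction: the residual is the
    running remainder, so ``signal == sum(imfs) + residual`` to floating
    point accuracy.  A constant or monotone input yields zero IMFs with
    the input as residual.
    """
    cfg = sift_config or SiftConfig()
    x = np.asarray(signal, dtype=float)
    if x.size < 16:
        raise ValueError("signal too short for decomposition (need >= 16 samples)")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")

    imfs: list[np.ndarray] = []
    residual = x.copy()
    for _ in range(max_imfs):
        h = residual.copy()
        m = _envelope_mean(h)
        if m is None:
            break
        for _ in range(cfg.max_siftings):
            h_new = h - m
            denom = float(np.sum(h * h))
            if denom == 0.0:
                h = h_new
                break
            sd = float(np.sum((h - h_new) ** 2)) / denom
            h = h_new
            if sd < cfg.sd_threshold:
                break
            m = _envelope_mean(h)
            if m is None:
                break
        imfs.append(h)
        residual = residual - h
        mx, mn = _local_extrema(residual)
        if mx.size + mn.size < 3:
            break
    return Decomposition(imfs=imfs, residual=residual, source_length=x.size, fs=fs)


def eemd(
    signal: np.ndarray,
    fs: float,
    ensemble_size: int = 100,
    noise_sd_ratio: float = 0.2,
    seed: int = 0,
    max_imfs: int = 10,
    sift_config: SiftConfig | None = None,
) -> Decomposition:
    """Ensemble EMD: average IMFs over white-noise-perturbed trials.

    Each trial decomposes ``signal + e`` with ``e`` white Gaussian noise
    of standard deviation ``noise_sd_ratio * sd(signal)``.  Trials with
    fewer IMFs are padded with zero IMFs before averaging, so IMF k is
    always the ensemble mean of trial IMF k.  A single integer seed
    drives the whole ensemble; with ``ensemble_size=1`` and zero noise
    the result equals plain EMD.
    """
    if ensemble_size < 1:
        raise ValueError("ensemble_size must be >= 1")
    if noise_sd_ratio < 0:
        raise ValueError("noise_sd_ratio must be >= 0")
    x = np.asarray(signal, dtype=float)
    rng = np.random.default_rng(seed)
    noise_sd = noise_sd_ratio * float(np.std(x))

    trials: list[Decomposition] = []
    for _ in range(ensemble_size):
        noisy = x if noise_sd == 0.0 else x + rng.normal(0.0, noise_sd, x.size)
        trials.append(emd(noisy, fs, max_imfs=max_imfs, sift_config=sift_config))

    n_imfs = max(t.n_imfs for t in trials)
    if n_imfs == 0:
        return Decomposition(
            imfs=[], residual=x.copy(), source_length=x.size, fs=fs
        )
    imf_stack = np.zeros((ensemble_size, n_imfs, x.size))
    res_stack = np.zeros((ensemble_size, x.size))
    for i, t in enumerate(trials):
        for k, imf in enumerate(t.imfs):
            imf_stack[i, k] = imf
        res_stack[i] = t.residual
    mean_imfs = [imf_stack[:, k].mean(axis=0) for k in range(n_imfs)]
    return Decomposition(
        imfs=mean_imfs,
        residual=res_stack.mean(axis=0),
        source_length=x.size,
        fs=fs,
    )
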