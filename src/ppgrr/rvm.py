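"""Sparse Bayesian regression with a four-component hybrid kernel.

The relevance vector machine (RVM) places independent Gaussian priors
with precisions alpha_i on the weights of a kernel design matrix and
maximizes the marginal likelihood over (alpha, beta).  Most alpha_i
diverge, pruning their basis functions; the survivors are the relevance
vectors.  The hybrid kernel is a convex combination of Gaussian,
sigmoid, polynomial and Laplacian kernels,

    K(x, z) = d1 exp(-g_G ||x-z||^2) + d2 tanh(a <x,z> + c)
            + d3 (s <x,z> + 1)^p     + d4 exp(-g_L ||x-z||_1),

with d_m >= 0 and sum d_m = 1; mixing local (Gaussian, Laplacian) and
nonlocal (sigmoid, polynomial) components lets a tuner trade smooth
interpolation against global trends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist

__all__ = [
    "KernelParams",
    "FitConfig",
    "HRVMModel",
    "kernel_value",
    "gram_matrix",
    "rvm_fit",
    "rvm_predict",
]


@dataclass
class KernelParams:
    """Hybrid-kernel parameters.

    ``weights`` are the simplex-constrained mixture weights
    (Gaussian, sigmoid, polynomial, Laplacian) in that order.
    """

    weights: np.ndarray = field(
        default_factory=lambda: np.array([0.25, 0.25, 0.25, 0.25])
    )
    gaussian_gamma: float = 1.0
    laplacian_gamma: float = 1.0
    poly_scale: float = 1.0
    poly_degree: int = 2
    sigmoid_scale: float = 1.0
    sigmoid_offset: float = 0.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (4,):
            raise ValueError("weights must have exactly 4 components")
        if np.any(self.weights < 0):
            raise ValueError("kernel weights must be nonnegative")
        if abs(self.weights.sum() - 1.0) > 1e-8:
            raise ValueError("kernel weights must sum to 1")
        for name in ("gaussian_gamma", "laplacian_gamma", "poly_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.poly_degree < 1:
            raise ValueError("poly_degree must be >= 1")

    @classmethod
    def from_raw_weights(cls, raw: np.ndarray, **kwargs) -> "KernelParams":
        """Build params from unnormalized nonnegative weight coordinates,
        falling back to uniform weights when all are ~0."""
        raw = np.clip(np.asarray(raw, dtype=float), 0.0, None)
        s = raw.sum()
        w = raw / s if s > 1e-12 else np.full(4, 0.25)
        return cls(weights=w, **kwargs)

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "gaussian_gamma": self.gaussian_gamma,
            "laplacian_gamma": self.laplacian_gamma,
            "poly_scale": self.poly_scale,
            "poly_degree": self.poly_degree,
            "sigmoid_scale": self.sigmoid_scale,
            "sigmoid_offset": self.sigmoid_offset,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KernelParams":
        d = dict(d)
        d["weights"] = np.asarray(d["weights"], dtype=float)
        return cls(**d)


@dataclass
class FitConfig:
    """Evidence-maximization tolerances."""

    prune_threshold: float = 1e9
    tol: float = 1e-3
    max_iter: int = 1000
    jitter: float = 1e-8


@dataclass
class HRVMModel:
    """Trained sparse regressor.

    ``posterior_weights`` covers the retained bases with the bias first;
    ``relevance_vectors`` are the training inputs whose kernel columns
    survived pruning.  ``noise_precision`` is beta = 1/sigma^2 of the
    observation noise.  ``feature_mean``/``feature_sd`` hold the z-score
    statistics of the training features (None if unscaled).
    """

    relevance_vectors: np.ndarray
    posterior_weights: np.ndarray
    posterior_cov: np.ndarray
    noise_precision: float
    kernel_params: KernelParams
    feature_mean: Optional[np.ndarray] = None
    feature_sd: Optional[np.ndarray] = None
    ml_history: list = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "relevance_vectors": self.relevance_vectors.tolist(),
            "posterior_weights": self.posterior_weights.tolist(),
            "posterior_cov": self.posterior_cov.tolist(),
            "noise_precision": self.noise_precision,
            "kernel_params": self.kernel_params.to_dict(),
            "feature_mean": None
            if self.feature_mean is None
            else self.feature_mean.tolist(),
            "feature_sd": None
            if self.feature_sd is None
            else self.feature_sd.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HRVMModel":
        return cls(
            relevance_vectors=np.asarray(d["relevance_vectors"], dtype=float),
            posterior_weights=np.asarray(d["posterior_weights"], dtype=float),
            posterior_cov=np.asarray(d["posterior_cov"], dtype=float),
            noise_precision=float(d["noise_precision"]),
            kernel_params=KernelParams.from_dict(d["kernel_params"]),
            feature_mean=None
            if d.get("feature_mean") is None
            else np.asarray(d["feature_mean"], dtype=float),
            feature_sd=None
            if d.get("feature_sd") is None
            else np.asarray(d["feature_sd"], dtype=float),
        )


def gram_matrix(X: np.ndarray, Z: np.ndarray, p: KernelParams) -> np.ndarray:
    """Hybrid-kernel Gram matrix, entry (i, j) = K(X_i, Z_j)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if X.shape[1] != Z.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: {X.shape[1]} vs {Z.shape[1]}"
        )
    d1, d2, d3, d4 = p.weights
    K = np.zeros((X.shape[0], Z.shape[0]))
    if d1 > 0:
        K += d1 * np.exp(-p.gaussian_gamma * cdist(X, Z, "sqeuclidean"))
    if d4 > 0:
        K += d4 * np.exp(-p.laplacian_gamma * cdist(X, Z, "cityblock"))
    if d2 > 0 or d3 > 0:
        dot = X @ Z.T
        if d2 > 0:
            K += d2 * np.tanh(p.sigmoid_scale * dot + p.sigmoid_offset)
        if d3 > 0:
            K += d3 * (p.poly_scale * dot + 1.0) ** p.poly_degree
    return K


def kernel_value(x: np.ndarray, z: np.ndarray, p: KernelParams) -> float:
    """K(x, z) for a single pair of feature vectors."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    z = np.atleast_1d(np.asarray(z, dtype=float))
    if x.shape != z.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {z.shape}")
    return float(gram_matrix(x[None, :], z[None, :], p)[0, 0])


def _solve_posterior(
    A: np.ndarray, beta: float, Phi: np.ndarray, y: np.ndarray, jitter: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Posterior covariance, mean, and log|H| for H = A + beta Phi'Phi."""
    H = np.diag(A) + beta * (Phi.T @ Phi)
    try:
        c, low = cho_factor(H)
    except np.linalg.LinAlgError:
        H = H + np.eye(H.shape[0]) * max(jitter, 1e-8)
        c, low = cho_factor(H)  # second failure propagates
    Sigma = cho_solve((c, low), np.eye(H.shape[0]))
    mu = beta * (Sigma @ (Phi.T @ y))
    logdet_H = 2.0 * float(np.sum(np.log(np.diag(c))))
    return Sigma, mu, logdet_H


def rvm_fit(
    X: np.ndarray,
    y: np.ndarray,
    p: KernelParams,
    cfg: FitConfig | None = None,
) -> HRVMModel:
    """Fit an RVM by evidence maximization over the hybrid-kernel design.

    The design matrix is [1 | K(X, X)] with a constant jitter on the
    Gram diagonal (the sigmoid component can make it indefinite).  The
    MacKay fixed-point updates alpha_i <- gamma_i / mu_i^2 and
    beta <- (n - sum gamma_i) / ||y - Phi mu||^2 iterate until
    max|d log alpha| < tol; bases with alpha above the prune threshold
    are removed and never re-enter.  The bias column is never pruned.
    """
    cfg = cfg or FitConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 training samples")
    if y.size != n:
        raise ValueError("X and y length mismatch")

    K = gram_matrix(X, X, p)
    K[np.diag_indices_from(K)] += cfg.jitter
    Phi_full = np.column_stack([np.ones(n), K])  # column 0 = bias

    active = np.ones(n + 1, dtype=bool)
    alpha = np.full(n + 1, 1.0 / n**2)
    var_y = float(np.var(y))
    beta = 1.0 / (0.1 * var_y) if var_y > 0 else 1.0

    ml_history: list[float] = []
    Sigma = np.empty((0, 0))
    mu = np.empty(0)
    for _ in range(cfg.max_iter):
        idx = np.flatnonzero(active)
        Phi = Phi_full[:, idx]
        a = alpha[idx]
        Sigma, mu, logdet_H = _solve_posterior(a, beta, Phi, y, cfg.jitter)
        resid = y - Phi @ mu
        rss = float(resid @ resid)

        # log marginal likelihood via the Woodbury identity
        ml = -0.5 * (
            n * np.log(2.0 * np.pi)
            - n * np.log(beta)
            - float(np.sum(np.log(a)))
            + logdet_H
            + beta * float(y @ y)
            - beta * float(y @ (Phi @ mu))
        )
        ml_history.append(ml)

        gamma = 1.0 - a * np.diag(Sigma)
        gamma = np.clip(gamma, 1e-12, None)
        with np.errstate(divide="ignore", over="ignore"):
            alpha_new = np.where(mu**2 > 0, gamma / mu**2, np.inf)
        denom = rss if rss > 1e-300 else 1e-300
        beta = max(float(n - gamma.sum()), 1e-6) / denom

        old = alpha[idx]
        delta = np.abs(np.log(np.minimum(alpha_new, cfg.prune_threshold))
                       - np.log(np.minimum(old, cfg.prune_threshold)))
        alpha[idx] = alpha_new

        # prune diverged bases; the bias (global index 0) always stays,
        # with its precision capped to keep the system finite
        alpha[0] = min(alpha[0], cfg.prune_threshold)
        prune = alpha > cfg.prune_threshold
        prune[0] = False
        active &= ~prune
        if float(np.max(delta)) < cfg.tol:
            break

    # final posterior on the surviving bases
    idx = np.flatnonzero(active)
    Phi = Phi_full[:, idx]
    Sigma, mu, _ = _solve_posterior(alpha[idx], beta, Phi, y, cfg.jitter)

    rv_idx = idx[idx > 0] - 1  # training rows backing kernel columns
    return HRVMModel(
        relevance_vectors=X[rv_idx],
        posterior_weights=mu,
        posterior_cov=Sigma,
        noise_precision=beta,
        kernel_params=p,
        ml_history=ml_history,
    )


def rvm_predict(
    model: HRVMModel, X_star: np.ndarray, return_var: bool = False
):
    """Predictive mean (and optionally variance) at new inputs.

    The mean is [1 | K(X*, RVs)] @ posterior_weights; the predictive
    variance adds the posterior weight uncertainty to the noise floor
    1/beta, so it is never below 1/beta.
    """
    X_star = np.atleast_2d(np.asarray(X_star, dtype=float))
    if model.relevance_vectors.size:
        if X_star.shape[1] != model.relevance_vectors.shape[1]:
            raise ValueError(
                f"feature dimension mismatch: {X_star.shape[1]} vs "
                f"{model.relevance_vectors.shape[1]}"
            )
        K = gram_matrix(X_star, model.relevance_vectors, model.kernel_params)
        Phi = np.column_stack([np.ones(X_star.shape[0]), K])
    else:
        Phi = np.ones((X_star.shape[0], 1))
    mean = Phi @ model.posterior_weights
    if not return_var:
        return mean
    var = 1.0 / model.noise_precision + np.einsum(
        "ij,jk,ik->i", Phi, model.posterior_cov, Phi
    )
    return mean, var
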