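"""Whale optimization algorithm and hybrid-kernel tuning.

WOA is a population metaheuristic for box-bounded continuous
minimization.  A control parameter ``a`` decays linearly from 2 to 0;
each whale either encircles the best solution, explores toward a random
whale, or follows a logarithmic spiral around the best, chosen by coin
flips redrawn per whale per iteration.  The best-so-far solution is
elitist: it never worsens.

``tune_kernel`` wraps WOA around the hybrid-kernel RVM: whale positions
encode kernel widths (log scale), sigmoid parameters, and four raw
mixture-weight coordinates normalized onto the simplex; the objective
is k-fold cross-validated RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.model_selection import GroupKFold, KFold

from .rvm import FitConfig, KernelParams, rvm_fit, rvm_predict

__all__ = ["WOAConfig", "WOAResult", "woa_minimize", "tune_kernel",
           "KERNEL_BOUNDS", "decode_kernel_position"]


@dataclass
class WOAConfig:
    n_whales: int = 20
    n_iterations: int = 100
    bounds: Sequence[tuple[float, float]] = ()
    spiral_b: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_whales < 2:
            raise ValueError("n_whales must be >= 2")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError(f"invalid bound [{lo}, {hi}]")


@dataclass
class WOAResult:
    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray  # best fitness after each iteration (non-increasing)


def _safe_fitness(objective: Callable, x: np.ndarray) -> float:
    v = objective(x)
    return float(v) if np.isfinite(v) else np.inf


def woa_minimize(objective: Callable[[np.ndarray], float],
                 cfg: WOAConfig) -> WOAResult:
    """Minimize a black-box objective over the bounded box in ``cfg``.

    Deterministic given ``cfg.seed``; candidates with non-finite
    objective values are assigned +inf and the run continues.
    """
    bounds = np.asarray(cfg.bounds, dtype=float)
    if bounds.ndim != 2 or bounds.shape[1] != 2:
        raise ValueError("bounds must be a sequence of (lo, hi) pairs")
    lo, hi = bounds[:, 0], bounds[:, 1]
    dim = bounds.shape[0]
    rng = np.random.default_rng(cfg.seed)

    pos = lo + rng.random((cfg.n_whales, dim)) * (hi - lo)
    fit = np.array([_safe_fitness(objective, p) for p in pos])
    best_i = int(np.argmin(fit))
    best_pos = pos[best_i].copy()
    best_fit = float(fit[best_i])

    history = np.empty(cfg.n_iterations)
    for t in range(cfg.n_iterations):
        a = 2.0 - 2.0 * t / cfg.n_iterations
        for i in range(cfg.n_whales):
            r = rng.random()
            A = 2.0 * a * r - a
            C = 2.0 * rng.random()
            p = rng.random()
            if p < 0.5:
                if abs(A) < 1.0:
                    # encircle the current best
                    D = np.abs(C * best_pos - pos[i])
                    pos[i] = best_pos - A * D
                else:
                    # explore toward a random whale
                    j = int(rng.integers(cfg.n_whales))
                    D = np.abs(C * pos[j] - pos[i])
                    pos[i] = pos[j] - A * D
            else:
                # logarithmic spiral around the best
                l = rng.uniform(-1.0, 1.0)
                D = np.abs(best_pos - pos[i])
                pos[i] = D * np.exp(cfg.spiral_b * l) * np.cos(
                    2.0 * np.pi * l
                ) + best_pos
            np.clip(pos[i], lo, hi, out=pos[i])
            f = _safe_fitness(objective, pos[i])
            if f < best_fit:
                best_fit = f
                best_pos = pos[i].copy()
        history[t] = best_fit
    return WOAResult(best_position=best_pos, best_fitness=best_fit,
                     history=history)


#: Search box for kernel tuning: log10 Gaussian gamma, log10 Laplacian
#: gamma, log10 polynomial scale, sigmoid scale, sigmoid offset, and the
#: four raw mixture-weight coordinates.
KERNEL_BOUNDS: tuple[tuple[float, float], ...] = (
    (-3.0, 3.0),   # log10 gaussian_gamma
    (-3.0, 3.0),   # log10 laplacian_gamma
    (-3.0, 1.0),   # log10 poly_scale
    (-2.0, 2.0),   # sigmoid_scale
    (-2.0, 2.0),   # sigmoid_offset
    (0.0, 1.0), (0.0, 1.0), (0.0, 1.0), (0.0, 1.0),  # raw weights
)


def decode_kernel_position(x: np.ndarray, poly_degree: int = 2) -> KernelParams:
    """Map a 9-dimensional whale position to KernelParams."""
    x = np.asarray(x, dtype=float)
    return KernelParams.from_raw_weights(
        x[5:9],
        gaussian_gamma=10.0 ** x[0],
        laplacian_gamma=10.0 ** x[1],
        poly_scale=10.0 ** x[2],
        poly_degree=poly_degree,
        sigmoid_scale=x[3],
        sigmoid_offset=x[4],
    )


def _cv_error(
    X: np.ndarray,
    y: np.ndarray,
    params: KernelParams,
    cv_folds: int,
    groups: Optional[np.ndarray],
    fit_cfg: FitConfig,
    objective: str = "mae",
) -> float:
    if groups is not None and np.unique(groups).size >= cv_folds:
        splitter = GroupKFold(n_splits=cv_folds)
        splits = splitter.split(X, y, groups)
    else:
        splitter = KFold(n_splits=cv_folds, shuffle=False)
        splits = splitter.split(X, y)
    errs = []
    for tr, te in splits:
        model = rvm_fit(X[tr], y[tr], params, cfg=fit_cfg)
        pred = rvm_predict(model, X[te])
        if objective == "mae":
            errs.append(float(np.mean(np.abs(pred - y[te]))))
        else:
            errs.append(float(np.sqrt(np.mean((pred - y[te]) ** 2))))
    return float(np.mean(errs))


def tune_kernel(
    train_X: np.ndarray,
    train_y: np.ndarray,
    cfg: WOAConfig,
    cv_folds: int = 5,
    groups: Optional[np.ndarray] = None,
    fit_cfg: FitConfig | None = None,
    max_objective_rows: int = 400,
    poly_degree: int = 2,
    objective: str = "mae",
) -> KernelParams:
    """WOA search for the kernel parameters minimizing CV error.

    The objective is k-fold cross-validated MAE by default ("rmse"
    selects squared loss instead); folds are split by subject when
    ``groups`` is given (prevents a subject's windows from leaking
    across folds), else by row.  For large training sets the CV
    objective is evaluated on a deterministic subsample of
    ``max_objective_rows`` rows; the caller refits on the full set at
    the tuned parameters.
    """
    X = np.atleast_2d(np.asarray(train_X, dtype=float))
    y = np.asarray(train_y, dtype=float).ravel()
    if X.shape[0] < cv_folds * 3:
        raise ValueError(f"need at least {cv_folds * 3} training rows")
    fit_cfg = fit_cfg or FitConfig(max_iter=200)

    if X.shape[0] > max_objective_rows:
        rng = np.random.default_rng(cfg.seed)
        sel = np.sort(rng.choice(X.shape[0], max_objective_rows, replace=False))
        X_obj, y_obj = X[sel], y[sel]
        g_obj = groups[sel] if groups is not None else None
    else:
        X_obj, y_obj, g_obj = X, y, groups

    def fitness(position: np.ndarray) -> float:
        try:
            params = decode_kernel_position(position, poly_degree=poly_degree)
            return _cv_error(X_obj, y_obj, params, cv_folds, g_obj, fit_cfg,
                             objective=objective)
        except Exception:  # noqa: BLE001 - failed fits count as +inf
            return np.inf

    woa_cfg = WOAConfig(
        n_whales=cfg.n_whales,
        n_iterations=cfg.n_iterations,
        bounds=KERNEL_BOUNDS,
        spiral_b=cfg.spiral_b,
        seed=cfg.seed,
    )
    result = woa_minimize(fitness, woa_cfg)
    return decode_kernel_position(result.best_position, poly_degree=poly_degree)
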