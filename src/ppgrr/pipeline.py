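"""End-to-end orchestration: windows -> features -> split -> model.

Each analysis window yields five model features — the EEMD-PCA RR
pre-estimate RR_P, the mean 2-s skewness quality index, and the three
respiratory quality indices QR1-QR3 — with the window's reference RR as
label.  A 70/30 random row split feeds WOA kernel tuning plus a final
RVM fit; prediction applies the stored feature scaler and clips the
output to a plausible RR range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .emd import eemd
from .quality import (
    resample_4hz,
    rqi_autocorrelation,
    rqi_autoregression,
    rqi_fft,
    sqi_mean,
)
from .records import AnalysisWindow
from .respiration import DEFAULT_BAND, NoRespiratoryIMFError, estimate_rr
from .rvm import FitConfig, HRVMModel, KernelParams, rvm_fit, rvm_predict
from .woa import WOAConfig, tune_kernel

__all__ = [
    "ExtractionConfig",
    "SplitDataset",
    "TrainedBundle",
    "FEATURE_COLUMNS",
    "build_features",
    "split_train_test",
    "train",
    "predict",
]

#: Model feature columns, in the fixed order expected by the regressor.
FEATURE_COLUMNS = ["rr_p", "s_sqi_mean", "qr1", "qr2", "qr3"]

#: Plausible RR range for clipping predictions, breaths/min.
RR_CLIP = (3.0, 40.0)


@dataclass
class ExtractionConfig:
    """Tunables of the feature-extraction stage."""

    band: tuple[float, float] = DEFAULT_BAND
    pad_factor: int = 16
    ensemble_size: int = 100
    noise_sd_ratio: float = 0.2
    max_imfs: int = 10
    sqi_subwindow_s: float = 2.0
    ar_order: int = 9
    seed: int = 0

    def window_seed(self, index: int) -> int:
        """Deterministic per-window EEMD seed derived from the base seed."""
        return int((self.seed * 1_000_003 + index) % 2**31)


@dataclass
class SplitDataset:
    train: pd.DataFrame
    test: pd.DataFrame
    split_seed: int


@dataclass
class TrainedBundle:
    """Everything needed to predict: model (with scaler) + tuned kernel."""

    model: HRVMModel
    kernel_params: KernelParams

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.model.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "TrainedBundle":
        d = json.loads(Path(path).read_text())
        model = HRVMModel.from_dict(d)
        return cls(model=model, kernel_params=model.kernel_params)


def build_features(
    windows: Sequence[AnalysisWindow],
    config: ExtractionConfig | None = None,
) -> tuple[pd.DataFrame, int]:
    """Compute the per-window feature table.

    Returns the table plus the number of windows discarded because no
    IMF was dominated by respiratory-band content (discards are counted,
    never imputed).
    """
    cfg = config or ExtractionConfig()
    rows = []
    discarded = 0
    for i, w in enumerate(windows):
        dec = eemd(
            w.ppg_segment,
            w.fs,
            ensemble_size=cfg.ensemble_size,
            noise_sd_ratio=cfg.noise_sd_ratio,
            seed=cfg.window_seed(i),
            max_imfs=cfg.max_imfs,
        )
        try:
            resp = estimate_rr(dec, band=cfg.band, pad_factor=cfg.pad_factor)
        except NoRespiratoryIMFError:
            discarded += 1
            continue
        wave4 = resample_4hz(resp.wave, w.fs)
        rows.append(
            {
                "subject_id": w.subject_id,
                "start_s": w.start_s,
                "rr_p": resp.rr_p,
                "s_sqi_mean": sqi_mean(
                    w.ppg_segment, w.fs, subwindow_s=cfg.sqi_subwindow_s
                ),
                "qr1": rqi_autocorrelation(wave4),
                "qr2": rqi_fft(wave4, band=cfg.band),
                "qr3": rqi_autoregression(wave4, order=cfg.ar_order,
                                          band=cfg.band),
                "rr_label": w.rr_label,
            }
        )
    columns = ["subject_id", "start_s", *FEATURE_COLUMNS, "rr_label"]
    df = pd.DataFrame(rows, columns=columns)
    return df, discarded


def split_train_test(
    rows: pd.DataFrame, train_frac: float = 0.7, seed: int = 0
) -> SplitDataset:
    """Uniform random row-level 70/30 split, reproducible by seed."""
    if len(rows) < 10:
        raise ValueError("need at least 10 feature rows to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(rows))
    n_train = int(round(train_frac * len(rows)))
    train_df = rows.iloc[np.sort(perm[:n_train])].reset_index(drop=True)
    test_df = rows.iloc[np.sort(perm[n_train:])].reset_index(drop=True)
    return SplitDataset(train=train_df, test=test_df, split_seed=seed)


def _feature_matrix(rows: pd.DataFrame) -> np.ndarray:
    missing = [c for c in FEATURE_COLUMNS if c not in rows.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    return rows[FEATURE_COLUMNS].to_numpy(dtype=float)


def train(
    split: SplitDataset,
    woa_cfg: WOAConfig | None = None,
    cv_folds: int = 5,
    fit_cfg: FitConfig | None = None,
    group_by_subject: bool = True,
) -> TrainedBundle:
    """Tune the hybrid kernel by WOA and fit the final RVM.

    Features are z-scored with training-set statistics (stored in the
    model); the WOA objective is cross-validated RMSE with folds split
    by subject when possible.
    """
    woa_cfg = woa_cfg or WOAConfig()
    train_df = split.train
    if len(train_df) == 0:
        raise ValueError("training part is empty")
    X = _feature_matrix(train_df)
    y = train_df["rr_label"].to_numpy(dtype=float)

    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (X - mean) / sd

    groups = (
        train_df["subject_id"].to_numpy()
        if group_by_subject and "subject_id" in train_df.columns
        else None
    )
    params = tune_kernel(Xs, y, woa_cfg, cv_folds=cv_folds, groups=groups,
                         fit_cfg=fit_cfg)
    model = rvm_fit(Xs, y, params, cfg=fit_cfg)
    model.feature_mean = mean
    model.feature_sd = sd
    return TrainedBundle(model=model, kernel_params=params)


def predict(bundle: TrainedBundle, rows: pd.DataFrame) -> np.ndarray:
    """Per-window final RR prediction (RR_M), clipped to [3, 40] bpm."""
    X = _feature_matrix(rows)
    model = bundle.model
    if model.feature_mean is not None:
        X = (X - model.feature_mean) / model.feature_sd
    raw = rvm_predict(model, X)
    return np.clip(raw, *RR_CLIP)
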