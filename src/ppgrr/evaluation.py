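"""Agreement and error metrics for RR predictions.

Covers mean absolute error, root-mean-square error, Bland-Altman
limits of agreement (mean difference +/- 1.96 x sample SD), a
per-RR-range error breakdown, and per-subject Pearson correlations
between the quality indices and the pre-estimate's relative error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AgreementReport",
    "mae",
    "rmse",
    "bland_altman",
    "range_breakdown",
    "quality_error_correlation",
    "RANGE_BINS",
]


@dataclass
class AgreementReport:
    mean_diff: float
    loa_upper: float
    loa_lower: float
    mae: float
    rmse: float
    n: int
    means: np.ndarray  # (pred + ref)/2 scatter for plotting
    diffs: np.ndarray

    def to_dict(self) -> dict:
        return {
            "mean_diff": self.mean_diff,
            "loa_upper": self.loa_upper,
            "loa_lower": self.loa_lower,
            "mae": self.mae,
            "rmse": self.rmse,
            "n": self.n,
        }


def _paired(pred, ref) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=float).ravel()
    ref = np.asarray(ref, dtype=float).ravel()
    if pred.size != ref.size:
        raise ValueError(f"length mismatch: {pred.size} vs {ref.size}")
    if pred.size == 0:
        raise ValueError("empty input")
    return pred, ref


def mae(pred, ref) -> float:
    """Mean absolute error in breaths/min."""
    pred, ref = _paired(pred, ref)
    return float(np.mean(np.abs(pred - ref)))


def rmse(pred, ref) -> float:
    """Root-mean-square error in breaths/min."""
    pred, ref = _paired(pred, ref)
    return float(np.sqrt(np.mean((pred - ref) ** 2)))


def bland_altman(pred, ref) -> AgreementReport:
    """Bland-Altman agreement: mean difference and 95% limits.

    Limits use the sample (n-1) standard deviation, the Bland-Altman
    convention.
    """
    pred, ref = _paired(pred, ref)
    if pred.size < 2:
        raise ValueError("need at least 2 pairs")
    d = pred - ref
    mean_d = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementReport(
        mean_diff=mean_d,
        loa_upper=mean_d + 1.96 * sd,
        loa_lower=mean_d - 1.96 * sd,
        mae=mae(pred, ref),
        rmse=rmse(pred, ref),
        n=pred.size,
        means=(pred + ref) / 2.0,
        diffs=d,
    )


#: Reference-RR bins (label, lo, hi) on the integer-rounded reference.
RANGE_BINS = (
    ("below 12", -np.inf, 11),
    ("12-16", 12, 16),
    ("17-20", 17, 20),
    ("21-24", 21, 24),
    ("above 24", 25, np.inf),
)


def range_breakdown(pred, ref) -> pd.DataFrame:
    """Per-RR-range MAE/RMSE, binning on the rounded reference RR.

    The integer bin labels (12-16, 17-20, 21-24 with gaps at the
    boundaries) force rounding the reference to the nearest breath/min
    before binning; empty bins report n = 0 with NaN metrics.
    """
    pred, ref = _paired(pred, ref)
    ref_int = np.round(ref)
    rows = []
    for label, lo, hi in RANGE_BINS:
        mask = (ref_int >= lo) & (ref_int <= hi)
        n = int(mask.sum())
        rows.append(
            {
                "label": label,
                "n": n,
                "mae": mae(pred[mask], ref[mask]) if n else np.nan,
                "rmse": rmse(pred[mask], ref[mask]) if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


def quality_error_correlation(rows: pd.DataFrame) -> pd.DataFrame:
    """Per-subject Pearson correlation of each quality index with the
    pre-estimate's error rate.

    The error rate is |rr_p - rr_label| / rr_label per window.  Columns
    R1..R3 correlate QR1..QR3 with the error rate, R4 correlates the
    mean skewness index; a subject with zero variance in either
    argument gets NaN for that column.  A final "average" row holds the
    across-subject mean of each defined column.
    """
    required = {"subject_id", "rr_p", "rr_label", "qr1", "qr2", "qr3",
                "s_sqi_mean"}
    missing = required - set(rows.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    df = rows.copy()
    df["error_rate"] = np.abs(df["rr_p"] - df["rr_label"]) / df["rr_label"]
    index_cols = {"R1": "qr1", "R2": "qr2", "R3": "qr3", "R4": "s_sqi_mean"}
    out = []
    for subject, g in df.groupby("subject_id", sort=True):
        row = {"subject_id": subject}
        for rname, col in index_cols.items():
            if len(g) < 3 or g[col].std() == 0 or g["error_rate"].std() == 0:
                row[rname] = np.nan
            else:
                row[rname] = float(
                    stats.pearsonr(g[col], g["error_rate"]).statistic
                )
        out.append(row)
    result = pd.DataFrame(out)
    avg = {"subject_id": "average"}
    for rname in index_cols:
        avg[rname] = float(result[rname].mean(skipna=True))
    return pd.concat([result, pd.DataFrame([avg])], ignore_index=True)
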