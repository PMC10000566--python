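import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ppgrr.evaluation import (
    bland_altman,
    mae,
    quality_error_correlation,
    range_breakdown,
    rmse,
)


class TestPointErrors:
    def test_perfect_agreement(self):
        x = np.array([10.0, 15.0, 20.0])
        assert mae(x, x) == 0.0
        assert rmse(x, x) == 0.0

    def test_symmetric_unit_errors(self):
        ref = np.zeros(2)
        pred = np.array([1.0, -1.0])
        assert mae(pred, ref) == 1.0
        assert rmse(pred, ref) == 1.0

    def test_hand_arithmetic(self):
        ref = np.zeros(3)
        pred = np.array([3.0, 0.0, 0.0])
        assert mae(pred, ref) == pytest.approx(1.0, abs=1e-12)
        assert rmse(pred, ref) == pytest.approx(np.sqrt(3.0), abs=1e-12)
        assert rmse(np.array([0.0, 2.0]), np.zeros(2)) == pytest.approx(
            np.sqrt(2.0), abs=1e-12
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mae(np.ones(3), np.ones(4))

    @given(
        d=arrays(np.float64, st.integers(1, 50),
                 elements=st.floats(-100, 100)),
    )
    def test_mae_never_exceeds_rmse(self, d):
        ref = np.zeros(d.size)
        assert mae(d, ref) <= rmse(d, ref) + 1e-9


class TestBlandAltman:
    def test_zero_spread(self):
        r = bland_altman(np.array([2.0, 3.0, 4.0]), np.array([1.0, 2.0, 3.0]))
        assert r.mean_diff == 1.0
        assert r.loa_upper == 1.0
        assert r.loa_lower == 1.0

    def test_symmetric_differences(self):
        r = bland_altman(np.array([1.0, -1.0]), np.zeros(2))
        assert r.mean_diff == 0.0
        assert r.loa_upper == -r.loa_lower

    def test_hand_arithmetic(self):
        r = bland_altman(np.array([0.0, 2.0]), np.zeros(2))
        assert r.mean_diff == pytest.approx(1.0)
        assert r.loa_upper == pytest.approx(1.0 + 1.96 * np.sqrt(2.0), abs=1e-9)
        assert r.loa_lower == pytest.approx(1.0 - 1.96 * np.sqrt(2.0), abs=1e-9)

    def test_limits_bracket_95pct_of_gaussian_differences(self):
        rng = np.random.default_rng(123)
        ref = rng.uniform(10, 25, 10_000)
        pred = ref + rng.normal(0.5, 1.2, 10_000)
        r = bland_altman(pred, ref)
        inside = np.mean((r.diffs >= r.loa_lower) & (r.diffs <= r.loa_upper))
        assert inside >= 0.93

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            bland_altman(np.array([1.0]), np.array([1.0]))


class TestRangeBreakdown:
    def test_single_bin_populated(self):
        ref = np.full(5, 18.0)
        out = range_breakdown(ref, ref)
        assert out.loc[out.label == "17-20", "n"].item() == 5
        assert out.n.sum() == 5

    def test_one_row_per_bin(self):
        ref = np.array([10.0, 14.0, 18.0, 22.0, 26.0])
        out = range_breakdown(ref, ref)
        assert list(out.n) == [1, 1, 1, 1, 1]

    def test_rounding_decides_bin(self):
        # 16.4 rounds to 16 (12-16 bin); 16.6 rounds to 17 (17-20 bin)
        out = range_breakdown(np.zeros(2), np.array([16.4, 16.6]))
        assert out.loc[out.label == "12-16", "n"].item() == 1
        assert out.loc[out.label == "17-20", "n"].item() == 1

    @given(
        ref=arrays(np.float64, st.integers(1, 60),
                   elements=st.floats(3, 40)),
    )
    def test_bins_partition_all_rows(self, ref):
        out = range_breakdown(np.zeros(ref.size), ref)
        assert out.n.sum() == ref.size


class TestQualityErrorCorrelation:
    def _table(self, qr1, err_rate):
        n = len(qr1)
        rr_label = np.full(n, 20.0)
        rr_p = rr_label * (1.0 + np.asarray(err_rate))
        return pd.DataFrame(
            {
                "subject_id": ["s1"] * n,
                "rr_p": rr_p,
                "rr_label": rr_label,
                "qr1": qr1,
                "qr2": np.linspace(0, 1, n),
                "qr3": np.linspace(1, 0, n),
                "s_sqi_mean": np.linspace(-1, 1, n),
            }
        )

    def test_exact_positive_linear_gives_one(self):
        err = np.array([0.01, 0.02, 0.03, 0.04])
        df = self._table(qr1=2.0 * err + 0.1, err_rate=err)
        out = quality_error_correlation(df)
        assert out.loc[out.subject_id == "s1", "R1"].item() == pytest.approx(1.0)

    def test_exact_negative_linear_gives_minus_one(self):
        err = np.array([0.01, 0.02, 0.03, 0.04])
        df = self._table(qr1=-0.5 * err + 0.9, err_rate=err)
        out = quality_error_correlation(df)
        assert out.loc[out.subject_id == "s1", "R1"].item() == pytest.approx(-1.0)

    def test_constant_index_undefined(self):
        err = np.array([0.01, 0.02, 0.03, 0.04])
        df = self._table(qr1=np.full(4, 0.5), err_rate=err)
        out = quality_error_correlation(df)
        assert np.isnan(out.loc[out.subject_id == "s1", "R1"].item())

    def test_average_row_present(self):
        err = np.array([0.01, 0.02, 0.03, 0.04])
        df = self._table(qr1=2.0 * err, err_rate=err)
        out = quality_error_correlation(df)
        assert out.subject_id.iloc[-1] == "average"
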