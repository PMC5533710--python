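import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gyrocg import agreement_report, bland_altman, pearson_r2, rmse

paired = st.lists(
    st.tuples(st.floats(-1e3, 1e3), st.floats(-1e3, 1e3)),
    min_size=3, max_size=40,
).map(lambda ps: (np.array([p[0] for p in ps]), np.array([p[1] for p in ps])))


class TestPearsonR2:
    def test_perfect_line(self):
        x = np.arange(1.0, 11.0)
        assert pearson_r2(x, 2 * x + 1) == pytest.approx(1.0)

    def test_zero_covariance(self):
        x = np.array([-1.0, 1.0, -1.0, 1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        assert pearson_r2(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_textbook_formula_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.1, 1.9, 3.2, 3.8])
        n = len(x)
        num = n * np.sum(x * y) - np.sum(x) * np.sum(y)
        den = np.sqrt((n * np.sum(x**2) - np.sum(x)**2)
                      * (n * np.sum(y**2) - np.sum(y)**2))
        assert pearson_r2(x, y) == pytest.approx((num / den) ** 2, abs=1e-12)

    def test_matches_scipy_on_random_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.normal(size=15)
            y = 0.5 * x + rng.normal(size=15)
            assert pearson_r2(x, y) == pytest.approx(
                stats.pearsonr(x, y).statistic ** 2, abs=1e-9)

    def test_zero_variance_undefined(self):
        assert pearson_r2(np.ones(5), np.arange(5.0)) is None

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(paired, st.floats(0.1, 10), st.floats(-5, 5))
    def test_affine_invariance(self, xy, a, b):
        x, y = xy
        r2 = pearson_r2(x, y)
        if r2 is None:
            return
        assert pearson_r2(a * x + b, y) == pytest.approx(r2, abs=1e-6)


class TestRmse:
    def test_identical_series(self):
        assert rmse(np.arange(5.0), np.arange(5.0)) == 0.0

    def test_constant_difference(self):
        assert rmse(np.zeros(4), np.full(4, 3.0)) == pytest.approx(3.0)

    def test_hand_arithmetic(self):
        assert rmse(np.array([0.0, 0.0]), np.array([3.0, 4.0])) == \
            pytest.approx(np.sqrt(12.5), abs=1e-4)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse(np.zeros(3), np.zeros(4))


class TestBlandAltman:
    def test_identical_series(self):
        r = bland_altman(np.arange(3.0), np.arange(3.0))
        assert r.bias == 0 and r.rpc == 0
        assert r.loa_low == 0 and r.loa_high == 0

    def test_constant_difference(self):
        r = bland_altman(np.array([3.0, 4.0, 5.0]), np.array([1.0, 2.0, 3.0]))
        assert r.bias == pytest.approx(2.0)
        assert (r.loa_low, r.loa_high) == (pytest.approx(2.0),
                                           pytest.approx(2.0))

    def test_hand_arithmetic_oracle(self):
        x = np.array([10.0, 12.0, 14.0])
        y = np.array([9.0, 13.0, 12.0])
        d = x - y
        sd = np.sqrt(np.sum((d - d.mean()) ** 2) / 2)
        r = bland_altman(x, y)
        assert r.bias == pytest.approx(2.0 / 3.0, abs=1e-12)
        assert r.rpc == pytest.approx(1.96 * sd, abs=1e-12)
        assert r.loa_low == pytest.approx(d.mean() - 1.96 * sd, abs=1e-12)
        assert r.cv_pct == pytest.approx(100 * sd / np.mean(np.r_[x, y]),
                                         abs=1e-12)

    def test_loa_width_is_twice_rpc(self):
        rng = np.random.default_rng(0)
        r = bland_altman(rng.normal(size=30), rng.normal(size=30))
        assert r.loa_high - r.loa_low == pytest.approx(2 * r.rpc, abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(paired)
    def test_swap_symmetry(self, xy):
        x, y = xy
        a = bland_altman(x, y)
        b = bland_altman(y, x)
        assert b.bias == pytest.approx(-a.bias, abs=1e-9)
        assert b.loa_low == pytest.approx(-a.loa_high, abs=1e-9)
        assert b.loa_high == pytest.approx(-a.loa_low, abs=1e-9)
        assert b.rpc == pytest.approx(a.rpc, abs=1e-9)
        if a.cv_pct is not None:
            assert b.cv_pct == pytest.approx(a.cv_pct, abs=1e-9)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(paired)
    def test_rmse_bounds_bias(self, xy):
        x, y = xy
        assert rmse(x, y) >= abs(bland_altman(x, y).bias) - 1e-9


class TestAgreementReport:
    def _tables(self, noise_sd=0.0, n=200, seed=0):
        rng = np.random.default_rng(seed)
        ref = pd.DataFrame({"beat": np.arange(n),
                            "lvet": rng.normal(310, 25, n),
                            "pep": rng.normal(82, 9, n)})
        meas = ref.copy()
        for c in ("lvet", "pep"):
            meas[c] = meas[c] + rng.normal(0, noise_sd, n)
        return meas, ref

    def test_identical_tables(self):
        meas, ref = self._tables()
        df = agreement_report(meas, ref, keys=["beat"])
        assert (df["rmse"] == 0).all()
        assert df["r2"].astype(float).eq(1.0).all()

    def test_rmse_recovers_noise_scale(self):
        meas, ref = self._tables(noise_sd=5.0)
        df = agreement_report(meas, ref, keys=["beat"])
        assert df.loc["lvet", "rmse"] == pytest.approx(5.0, rel=0.2)

    def test_disjoint_keys_rejected(self):
        meas, ref = self._tables()
        meas["beat"] += 10_000
        with pytest.raises(ValueError):
            agreement_report(meas, ref, keys=["beat"])


def test_plot_agreement_writes_figure(tmp_path):
    rng = np.random.default_rng(1)
    x = rng.normal(310, 25, 50)
    y = x + rng.normal(0, 5, 50)
    out = tmp_path / "lvet.png"
    from gyrocg import plot_agreement
    plot_agreement(x, y, "lvet", out)
    assert out.exists() and out.stat().st_size > 0
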