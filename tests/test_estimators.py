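"""MR estimator suite: point estimates, oracles and invariances."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mrscreen import (
    InsufficientInstrumentsError,
    MRModel,
    egger,
    harmonize,
    i2_gx,
    ivw_mre,
    mr_lasso,
    ratio_table,
    synth,
    weighted_median,
    weighted_mode,
)
from mrscreen.estimators import _weighted_median, _weighted_mode
from mrscreen.sumstats import InstrumentSet


def make_inst(beta_x, beta_y, se_x=None, se_y=None):
    L = len(beta_x)
    se_x = np.full(L, 0.01) if se_x is None else np.asarray(se_x, float)
    se_y = np.full(L, 0.01) if se_y is None else np.asarray(se_y, float)
    table = pd.DataFrame({
        "rsid": [f"rs{i}" for i in range(L)], "chrom": "1",
        "pos": (np.arange(L) + 1) * 1000, "effect_allele": "A",
        "other_allele": "G", "beta_x": np.asarray(beta_x, float),
        "se_x": se_x, "beta_y": np.asarray(beta_y, float), "se_y": se_y,
        "eaf": 0.3, "proxy_of": None,
    })
    return InstrumentSet("x", "y", table)


class TestRatioTable:
    def test_arithmetic(self):
        rt = ratio_table(make_inst([0.1], [0.05], se_y=[0.01]))
        assert rt.theta[0] == pytest.approx(0.5)
        assert rt.w[0] == pytest.approx(100.0)

    def test_sign_cancellation(self):
        rt1 = ratio_table(make_inst([0.1], [0.05]))
        rt2 = ratio_table(make_inst([-0.1], [-0.05]))
        assert rt1.theta[0] == pytest.approx(rt2.theta[0])

    def test_zero_beta_x_excluded(self):
        rt = ratio_table(make_inst([0.1, 0.0], [0.05, 0.02]))
        assert len(rt) == 1
        assert rt.excluded[0]["reason"] == "beta_x_zero"

    def test_matches_brute_force(self, rng):
        bx = rng.normal(0.1, 0.02, 10)
        by = rng.normal(0.05, 0.01, 10)
        sy = rng.uniform(0.005, 0.02, 10)
        rt = ratio_table(make_inst(bx, by, se_y=sy))
        for j in range(10):
            assert rt.theta[j] == pytest.approx(by[j] / bx[j], rel=1e-12)
            assert rt.w[j] == pytest.approx(bx[j] ** 2 / sy[j] ** 2, rel=1e-12)


class TestIVW:
    def test_zero_heterogeneity(self):
        bx = np.array([0.1, 0.2, 0.15])
        res = ivw_mre(make_inst(bx, 0.3 * bx))
        assert res.theta == pytest.approx(0.3)
        assert res.extras["Q"] == pytest.approx(0.0, abs=1e-20)

    def test_single_snp_rejected(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw_mre(make_inst([0.1], [0.05]))

    def test_equals_weighted_regression_oracle(self, instruments_causal):
        inst, _ = instruments_causal
        bx, sx, by, sy = inst.arrays()
        # normal equations of WLS through the origin with weights 1/se_y^2
        w = 1.0 / sy**2
        theta_hat = (w * bx * by).sum() / (w * bx**2).sum()
        resid = by - theta_hat * bx
        scale = (w * resid**2).sum() / (len(bx) - 1)
        se_hat = np.sqrt(scale / (w * bx**2).sum())
        res = ivw_mre(inst)
        assert res.theta == pytest.approx(theta_hat, abs=1e-10)
        assert res.se == pytest.approx(se_hat, abs=1e-10)

    def test_p_consistent_with_reference_distribution(self, instruments_causal):
        inst, _ = instruments_causal
        res = ivw_mre(inst)
        expected = 2 * stats.t.sf(abs(res.theta / res.se), res.L - 1)
        assert res.pvalue == pytest.approx(expected, abs=1e-9)


class TestEgger:
    def test_exact_collinear_fit(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2])
        res = egger(make_inst(bx, 0.4 * bx))
        assert res.theta == pytest.approx(0.4, abs=1e-10)
        assert res.extras["intercept"] == pytest.approx(0.0, abs=1e-10)

    def test_constant_pleiotropy_lands_in_intercept(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2, 0.25])
        by = 0.4 * bx + 0.05
        res = egger(make_inst(bx, by))
        assert res.extras["intercept"] == pytest.approx(0.05, abs=1e-10)
        assert res.theta == pytest.approx(0.4, abs=1e-10)

    def test_matches_closed_form_wls_oracle(self, instruments_causal):
        inst, _ = instruments_causal
        bx, sx, by, sy = inst.arrays()
        sign = np.where(bx < 0, -1.0, 1.0)
        bx, by = bx * sign, by * sign
        X = np.column_stack([np.ones_like(bx), bx])
        W = np.diag(1.0 / sy**2)
        coef = np.linalg.solve(X.T @ W @ X, X.T @ W @ by)
        res = egger(inst)
        assert res.extras["intercept"] == pytest.approx(coef[0], abs=1e-12)
        assert res.theta == pytest.approx(coef[1], abs=1e-12)

    def test_requires_three(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(make_inst([0.1, 0.2], [0.05, 0.1]))


class TestI2GX:
    def test_no_dispersion_is_zero(self):
        assert i2_gx(make_inst([0.1, 0.1, 0.1], [0.0, 0.0, 0.0])) == 0.0

    def test_tiny_se_approaches_one(self):
        inst = make_inst([0.1, 0.2, 0.3], [0, 0, 0], se_x=[1e-6, 1e-6, 1e-6])
        assert i2_gx(inst) > 0.999

    def test_equals_direct_formula(self, instruments_causal):
        inst, _ = instruments_causal
        bx, sx, _, _ = inst.arrays()
        v = 1.0 / sx**2
        m = (v * bx).sum() / v.sum()
        q = (v * (bx - m) ** 2).sum()
        expected = max(0.0, (q - (len(bx) - 1)) / q)
        assert i2_gx(inst) == pytest.approx(expected, rel=1e-12)


class TestWeightedMedian:
    def test_degenerate_all_equal(self):
        bx = np.array([0.1, 0.2, 0.3])
        res = weighted_median(make_inst(bx, 0.2 * bx), boot_reps=50, seed=0)
        assert res.theta == pytest.approx(0.2)

    def test_equal_weights_plain_median(self):
        theta = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        w = np.ones(5)
        assert _weighted_median(theta, w) == pytest.approx(3.0)

    def test_unequal_weights_matches_interpolation_oracle(self, rng):
        for _ in range(20):
            theta = np.sort(rng.normal(size=7))
            w = rng.uniform(0.5, 3.0, size=7)
            # brute-force oracle over sorted prefix sums
            s = (np.cumsum(w) - w / 2) / w.sum()
            if s[0] >= 0.5:
                expected = theta[0]
            elif s[-1] <= 0.5:
                expected = theta[-1]
            else:
                k = np.searchsorted(s, 0.5)
                expected = theta[k - 1] + (theta[k] - theta[k - 1]) * (
                    0.5 - s[k - 1]) / (s[k] - s[k - 1])
            assert _weighted_median(theta, w) == pytest.approx(expected, rel=1e-10)

    def test_bootstrap_seed_reproducible(self, instruments_causal):
        inst, _ = instruments_causal
        r1 = weighted_median(inst, boot_reps=100, seed=42)
        r2 = weighted_median(inst, boot_reps=100, seed=42)
        assert r1.se == r2.se


class TestWeightedMode:
    def test_all_equal(self):
        bx = np.array([0.1, 0.2, 0.4])
        res = weighted_mode(make_inst(bx, 0.25 * bx), boot_reps=50, seed=0)
        assert res.theta == pytest.approx(0.25, abs=1e-6)

    def test_bimodal_majority_wins(self, rng):
        theta = np.concatenate([rng.normal(0.5, 0.01, 7), rng.normal(-0.3, 0.01, 3)])
        w = np.ones(10)
        mode = _weighted_mode(theta, w)
        assert abs(mode - 0.5) < 0.1

    def test_grid_resolution_stability(self, rng):
        theta = rng.normal(0.2, 0.05, 12)
        w = rng.uniform(1, 5, 12)
        sd = np.std(theta, ddof=1)
        iqr = np.subtract(*np.percentile(theta, [75, 25]))
        h = 0.9 * min(sd, iqr / 1.349) * 12 ** (-0.2)
        m1 = _weighted_mode(theta, w, grid_points=512)
        m2 = _weighted_mode(theta, w, grid_points=1024)
        assert abs(m1 - m2) < h / 10


class TestMRLasso:
    def test_reduces_to_ivw_without_pleiotropy(self, instruments_causal):
        inst, _ = instruments_causal
        res = mr_lasso(inst)
        base = ivw_mre(inst)
        assert not res.extras.get("fallback_full_set")
        assert len(res.extras["valid_rsids"]) == len(inst)
        assert res.theta == pytest.approx(base.theta, rel=1e-9)

    def test_gross_outlier_excluded(self):
        bx = np.array([0.10, 0.12, 0.11, 0.13, 0.10])
        by = 0.5 * bx
        by[2] += 0.10  # 10x the typical se
        inst = make_inst(bx, by, se_y=np.full(5, 0.01))
        res = mr_lasso(inst)
        assert "rs2" not in res.extras["valid_rsids"]
        clean = np.delete(np.arange(5), 2)
        oracle = ivw_mre(inst.subset(clean))
        assert res.theta == pytest.approx(oracle.theta, rel=1e-9)


class TestInvariances:
    @pytest.mark.parametrize("method,kwargs", [
        ("ivw_mre", {}), ("egger", {}),
        ("weighted_median", {"boot_reps": 80, "seed": 3}),
        ("weighted_mode", {"boot_reps": 80, "seed": 3}),
    ])
    def test_scale_equivariance(self, instruments_causal, method, kwargs):
        """Scaling all outcome betas and ses by c scales theta and se by c."""
        inst, _ = instruments_causal
        c = 2.5
        scaled_table = inst.table.copy()
        scaled_table["beta_y"] *= c
        scaled_table["se_y"] *= c
        scaled = InstrumentSet("x", "y", scaled_table)
        r1 = MRModel(inst).fit(method, **kwargs)
        r2 = MRModel(scaled).fit(method, **kwargs)
        assert r2.theta == pytest.approx(c * r1.theta, rel=1e-6)
        assert r2.se == pytest.approx(c * r1.se, rel=0.2 if kwargs else 1e-6)

    @pytest.mark.parametrize("method,kwargs", [
        ("ivw_mre", {}), ("egger", {}),
        ("weighted_median", {"boot_reps": 80, "seed": 3}),
        ("mr_lasso", {}),
    ])
    def test_instrument_orientation_invariance(self, instruments_causal,
                                               method, kwargs):
        """Flipping any SNP's effect allele (negating both betas) is a no-op."""
        inst, _ = instruments_causal
        flipped_table = inst.table.copy()
        flip = [0, 3, 7]
        flipped_table.loc[flip, "beta_x"] *= -1
        flipped_table.loc[flip, "beta_y"] *= -1
        flipped = InstrumentSet("x", "y", flipped_table)
        r1 = MRModel(inst).fit(method, **kwargs)
        r2 = MRModel(flipped).fit(method, **kwargs)
        assert r2.theta == pytest.approx(r1.theta, rel=1e-9)

    def test_estimators_recover_truth_at_large_n(self):
        """With no pleiotropy all five estimators agree with the truth."""
        truth = synth.make_truth(n_snps=50, theta=0.08, n_exp=2_000_000,
                                 n_out=3_000_000, seed=77)
        exp, out = synth.make_mr_pair(truth)
        inst = harmonize(exp, out)
        model = MRModel(inst)
        for res in model.fit_all(seed=5, boot_reps=100):
            assert res.theta == pytest.approx(0.08, abs=3 * max(res.se, 1e-4)), res.method


class TestResultsAPI:
    def test_summary_and_row(self, instruments_causal):
        inst, _ = instruments_causal
        res = egger(inst)
        text = res.summary()
        assert "egger" in text and "intercept" in text
        row = res.to_row()
        assert row["nsnp"] == len(inst)
        assert isinstance(row["extras_json"], str)

    def test_conf_int_covers_theta(self, instruments_causal):
        inst, _ = instruments_causal
        res = ivw_mre(inst)
        lo, hi = res.conf_int()
        assert lo < res.theta < hi
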