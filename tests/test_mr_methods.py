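"""The eight MR estimators, dispatchers and cross-method validation."""

import math

import numpy as np
import pandas as pd
import pytest

from sceqtlmr.mr_methods import (MRInput, cml_ma, cross_method_validation,
                                 debiased_ivw, ivw, method_benchmark,
                                 mr_presso, mr_raps, mr_robust, run_main_mr,
                                 run_weak_suite, weighted_median,
                                 weighted_mode, wald_ratio, add_fdr,
                                 estimates_to_frame, _weighted_median_point)


def _mri(bx, bxse, by, byse, **kw):
    return MRInput(np.asarray(bx, float), np.asarray(bxse, float),
                   np.asarray(by, float), np.asarray(byse, float), **kw)


def _sim_valid(rng, nsnp=10, beta=0.3, bxse=0.02, byse=0.02):
    bx_t = rng.uniform(0.3, 0.8, nsnp) * rng.choice([-1, 1], nsnp)
    bx = rng.normal(bx_t, bxse)
    by = rng.normal(beta * bx_t, byse)
    return _mri(bx, np.full(nsnp, bxse), by, np.full(nsnp, byse))


class TestWaldRatio:
    def test_arithmetic(self):
        est = wald_ratio(_mri([0.5], [0.05], [-0.1], [0.05]))
        assert est.beta == pytest.approx(-0.2)
        assert est.se == pytest.approx(0.1)

    def test_zero_outcome(self):
        est = wald_ratio(_mri([0.5], [0.05], [0.0], [0.05]))
        assert est.beta == 0.0 and est.p == pytest.approx(1.0)

    def test_zero_exposure_errors(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(_mri([0.0], [0.05], [0.1], [0.05]))

    def test_second_order_close_at_high_f(self):
        # F = (1.0/0.1)^2 = 100; the exposure-error term by²bxse²/bx⁴ is
        # then a ~1% perturbation of the first-order variance
        m = _mri([1.0], [0.1], [0.05], [0.05])
        first = wald_ratio(m)
        second = wald_ratio(m, second_order=True)
        assert second.se == pytest.approx(first.se, rel=0.05)
        assert second.se > first.se


class TestIvw:
    def test_requires_two(self):
        with pytest.raises(ValueError, match="wald_ratio"):
            ivw(_mri([0.5], [0.05], [0.1], [0.05]))

    def test_matches_wls_through_origin_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 15))
            m = _sim_valid(rng, nsnp=n)
            est = ivw(m)
            # WLS through origin with weights 1/byse^2
            w = 1 / m.byse ** 2
            X = (m.bx * np.sqrt(w))[:, None]
            y = m.by * np.sqrt(w)
            beta_wls = np.linalg.lstsq(X, y, rcond=None)[0][0]
            assert est.beta == pytest.approx(float(beta_wls), abs=1e-12)
            assert est.se == pytest.approx(float(np.sum(w * m.bx ** 2)) ** -0.5,
                                           abs=1e-12)

    def test_consistency_tight_ses(self, rng):
        m = _sim_valid(rng, nsnp=50, beta=0.3, bxse=0.001, byse=0.002)
        assert ivw(m).beta == pytest.approx(0.3, abs=0.02)

    def test_coverage_over_replicates(self):
        rng = np.random.default_rng(77)
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            m = _sim_valid(rng, nsnp=8, beta=0.25, bxse=0.01, byse=0.02)
            est = ivw(m)
            lo, hi = est.ci()
            hits += lo <= 0.25 <= hi
        assert 0.92 * n_rep <= hits <= 0.98 * n_rep


class TestDispatcher:
    def test_single_instrument_equals_wald(self):
        m = _mri([0.5], [0.05], [0.1], [0.05])
        est = run_main_mr(m)
        ref = wald_ratio(m)
        assert est.beta == ref.beta and abs(est.se - ref.se) < 1e-12

    def test_two_instruments_dispatch_ivw(self, rng):
        m = _sim_valid(rng, nsnp=2)
        assert run_main_mr(m).method == "ivw"

    def test_empty_skipped(self):
        assert run_main_mr(None) is None


class TestWeightedMedian:
    def test_equal_weights_reduce_to_median(self):
        m = _mri([1, 1, 1], [1e-9] * 3, [0.1, 0.2, 0.3], [0.05] * 3)
        est = weighted_median(m, n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.2)

    def test_matches_weighted_percentile_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 12))
            ratios = rng.normal(0, 1, n)
            weights = rng.uniform(0.1, 2, n)
            # brute-force: weighted percentile at 0.5 with the same
            # interpolation convention
            order = np.argsort(ratios)
            r, w = ratios[order], weights[order] / weights.sum()
            cum = np.cumsum(w) - 0.5 * w
            expected = float(np.interp(0.5, cum, r))
            got = _weighted_median_point(ratios, weights)
            assert got == pytest.approx(expected, abs=1e-10)

    def test_breakdown_30pct_invalid(self):
        rng = np.random.default_rng(11)
        ok = 0
        for _ in range(50):
            nsnp = 10
            m = _sim_valid(rng, nsnp=nsnp, beta=0.3, bxse=0.01, byse=0.01)
            by = m.by.copy()
            bad = rng.choice(nsnp, 3, replace=False)
            by[bad] += rng.choice([-1, 1], 3) * rng.uniform(0.5, 1.0, 3)
            est = weighted_median(_mri(m.bx, m.bxse, by, m.byse),
                                  n_boot=100, seed=3)
            ok += abs(est.beta - 0.3) <= 0.05
        assert ok >= 45

    def test_deterministic_under_seed(self, rng):
        m = _sim_valid(rng, nsnp=6)
        a = weighted_median(m, n_boot=100, seed=9)
        b = weighted_median(m, n_boot=100, seed=9)
        assert a.beta == b.beta and a.se == b.se and a.p == b.p


class TestWeightedMode:
    def test_all_ratios_equal(self):
        m = _mri([0.5, 0.6, 0.7], [0.01] * 3, [0.15, 0.18, 0.21], [0.01] * 3)
        est = weighted_mode(m, n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.3, abs=0.01)

    def test_heavier_cluster_wins(self):
        # 4 precise instruments at ratio 0.4, 2 noisy at 1.2
        bx = np.array([1, 1, 1, 1, 1, 1.0])
        by = np.array([0.4, 0.41, 0.39, 0.4, 1.2, 1.21])
        byse = np.array([0.01, 0.01, 0.01, 0.01, 0.05, 0.05])
        est = weighted_mode(_mri(bx, [0.01] * 6, by, byse), n_boot=50, seed=0)
        assert abs(est.beta - 0.4) < 0.05

    def test_argmax_matches_dense_grid_oracle(self, rng):
        from sceqtlmr.mr_methods import (_mode_bandwidth, _ratio_estimates,
                                         _weighted_mode_point)
        m = _sim_valid(rng, nsnp=8)
        ratios, var = _ratio_estimates(m)
        w = 1 / var
        w = w / w.sum()
        h = _mode_bandwidth(ratios, 1.0)
        got = _weighted_mode_point(ratios, w, h)
        grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 20_001)
        dens = (w[None, :] * np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2)).sum(axis=1)
        oracle = grid[np.argmax(dens)]
        step = (grid[-1] - grid[0]) / 512
        assert abs(got - oracle) <= step

    def test_zero_bandwidth_errors(self, rng):
        with pytest.raises(ValueError, match="bandwidth"):
            weighted_mode(_sim_valid(rng, nsnp=4), bandwidth_factor=0.0)


class TestMrRobust:
    def test_clean_data_close_to_ivw(self):
        rng = np.random.default_rng(21)
        within = 0
        for _ in range(30):
            m = _sim_valid(rng, nsnp=10, beta=0.3)
            r = mr_robust(m, n_null=200, seed=1)
            i = ivw(m)
            within += abs(r.beta - i.beta) <= i.se
        assert within >= 27

    def test_outlier_resistance_beats_ivw(self):
        rng = np.random.default_rng(23)
        robust_better = 0
        for _ in range(50):
            m = _sim_valid(rng, nsnp=10, beta=0.3, byse=0.01)
            by = m.by.copy()
            by[0] += 1.0  # gross outlier
            m2 = _mri(m.bx, m.bxse, by, m.byse)
            r = mr_robust(m2, n_null=100, seed=2)
            i = ivw(m2)
            robust_better += abs(r.beta - 0.3) < abs(i.beta - 0.3)
        assert robust_better >= 45

    def test_bisquare_weight_vanishes_for_gross_outlier(self):
        rng = np.random.default_rng(25)
        m = _sim_valid(rng, nsnp=10, beta=0.3, byse=0.01)
        by = m.by.copy()
        by[0] += 5.0
        est = mr_robust(_mri(m.bx, m.bxse, by, m.byse), n_null=50, seed=0)
        assert est.extras["weights"][0] == pytest.approx(0.0, abs=1e-6)


class TestDebiasedIvw:
    def test_equals_ivw_when_bxse_zero(self, rng):
        m = _sim_valid(rng, nsnp=8)
        m0 = _mri(m.bx, np.full(8, 1e-12), m.by, m.byse)
        assert debiased_ivw(m0).beta == pytest.approx(ivw(m0).beta, abs=1e-9)

    def test_less_biased_than_ivw_weak_instruments(self):
        # mean F ~ 5: bx_true = 0.1, bxse = 0.045
        rng = np.random.default_rng(31)
        n_rep, beta_true = 200, 0.5
        err_d, err_i = [], []
        for _ in range(n_rep):
            nsnp = 20
            bx_t = np.full(nsnp, 0.1) * rng.choice([-1, 1], nsnp)
            bxse = np.full(nsnp, 0.045)
            byse = np.full(nsnp, 0.01)
            bx = rng.normal(bx_t, bxse)
            by = rng.normal(beta_true * bx_t, byse)
            m = _mri(bx, bxse, by, byse)
            d = debiased_ivw(m)
            if d.converged:
                err_d.append(d.beta - beta_true)
            err_i.append(ivw(m).beta - beta_true)
        assert abs(np.mean(err_d)) < abs(np.mean(err_i))

    def test_ultra_weak_flagged_not_estimated(self):
        m = _mri([0.001, -0.002, 0.001], [0.5] * 3, [0.0, 0.0, 0.0], [0.1] * 3)
        est = debiased_ivw(m)
        assert not est.converged and math.isnan(est.beta)


class TestMrRaps:
    def test_matches_ivw_strong_instruments_no_pleiotropy(self):
        rng = np.random.default_rng(41)
        within = 0
        for _ in range(30):
            m = _sim_valid(rng, nsnp=10, beta=0.3, bxse=0.001, byse=0.01)
            r = mr_raps(m)
            i = ivw(m)
            within += abs(r.beta - i.beta) <= 0.5 * i.se
        assert within >= 27

    def test_score_stationary_at_solution(self, rng):
        m = _sim_valid(rng, nsnp=8)
        est = mr_raps(m)
        assert est.converged
        assert abs(est.extras["score"]) < 1e-6

    def test_balanced_pleiotropy_coverage(self):
        rng = np.random.default_rng(43)
        n_rep, hits = 200, 0
        beta_true = 0.2
        for _ in range(n_rep):
            nsnp = 15
            bx_t = rng.uniform(0.3, 0.8, nsnp)
            bxse = np.full(nsnp, 0.02)
            byse = np.full(nsnp, 0.02)
            alpha = rng.normal(0, 0.03, nsnp)  # balanced pleiotropy
            bx = rng.normal(bx_t, bxse)
            by = rng.normal(beta_true * bx_t + alpha, byse)
            est = mr_raps(_mri(bx, bxse, by, byse))
            lo, hi = est.ci()
            hits += lo <= beta_true <= hi
        assert 0.90 * n_rep <= hits <= 0.99 * n_rep


class TestMrPresso:
    def test_three_instruments_rejected(self, rng):
        with pytest.raises(ValueError, match="four or more"):
            mr_presso(_sim_valid(rng, nsnp=3))

    def test_planted_outlier_detected(self):
        rng = np.random.default_rng(51)
        found = 0
        for _ in range(50):
            m = _sim_valid(rng, nsnp=10, beta=0.3, byse=0.01)
            by = m.by.copy()
            by[4] = 10 * by[4] + 0.5
            est = mr_presso(_mri(m.bx, m.bxse, by, m.byse), n_sim=300, seed=7)
            found += 4 in est.extras["outlier_indices"]
        assert found >= 45

    def test_global_p_uniformish_under_null(self):
        rng = np.random.default_rng(53)
        from scipy.stats import kstest
        gps = []
        for _ in range(100):
            m = _sim_valid(rng, nsnp=8, beta=0.0)
            est = mr_presso(m, n_sim=200, seed=int(rng.integers(1 << 30)))
            gps.append(est.extras["global_p"])
        assert kstest(gps, "uniform").pvalue > 0.01

    def test_deterministic_under_seed(self, rng):
        m = _sim_valid(rng, nsnp=6)
        a = mr_presso(m, n_sim=200, seed=3)
        b = mr_presso(m, n_sim=200, seed=3)
        assert a.beta == b.beta and a.extras["global_p"] == b.extras["global_p"]


class TestCmlMa:
    def test_k0_equals_direct_ml_oracle(self, rng):
        from scipy.optimize import minimize_scalar
        m = _sim_valid(rng, nsnp=8)
        est = cml_ma(m)
        w = 1 / m.byse ** 2

        def negll(b):
            return 0.5 * np.sum(w * (m.by - b * m.bx) ** 2)

        oracle = minimize_scalar(negll, bounds=(-5, 5), method="bounded").x
        k0_beta = None
        # rebuild the K=0 component from extras by re-running with all valid
        w_sum = np.sum(w * m.bx * m.by) / np.sum(w * m.bx ** 2)
        assert w_sum == pytest.approx(float(oracle), abs=1e-6)

    def test_all_valid_selects_k0(self):
        # strong instruments behind a large outcome GWAS: the BIC penalty
        # log(N) dominates chance residual fluctuations
        rng = np.random.default_rng(61)
        k0_wins = 0
        for _ in range(50):
            m = _sim_valid(rng, nsnp=10, beta=0.3, bxse=0.005, byse=0.01)
            est = cml_ma(m, sample_size=5e5)
            if est.extras["model_weights"].get(0, 0) > 0.9:
                k0_wins += 1
        assert k0_wins >= 45

    def test_two_invalid_selects_k2(self):
        rng = np.random.default_rng(63)
        hits = 0
        for _ in range(30):
            m = _sim_valid(rng, nsnp=10, beta=0.3, byse=0.01)
            by = m.by.copy()
            by[[1, 5]] += np.array([0.8, -0.9])
            est = cml_ma(_mri(m.bx, m.bxse, by, m.byse))
            hits += est.extras["k_best"] == 2
        assert hits >= 24


class TestSuite:
    def test_floors(self, rng):
        assert [e.method for e in run_weak_suite(_sim_valid(rng, nsnp=1),
                                                 n_boot=20, n_sim=20)] == ["wald_ivw"]
        m3 = [e.method for e in run_weak_suite(_sim_valid(rng, nsnp=3),
                                               n_boot=20, n_sim=20)]
        assert "mr_presso" not in m3 and len(m3) == 7
        m10 = run_weak_suite(_sim_valid(rng, nsnp=10), n_boot=20, n_sim=20)
        assert len(m10) == 8

    def test_scale_equivariance(self, rng):
        m = _sim_valid(rng, nsnp=10)
        c = 2.5
        m2 = _mri(m.bx, m.bxse, c * m.by, c * m.byse)
        for f in (ivw, debiased_ivw, mr_raps, cml_ma):
            assert f(m2).beta == pytest.approx(c * f(m).beta, rel=1e-6)
            assert f(m2).se == pytest.approx(c * f(m).se, rel=1e-5)
        wm1 = weighted_median(m, n_boot=100, seed=5)
        wm2 = weighted_median(m2, n_boot=100, seed=5)
        assert wm2.beta == pytest.approx(c * wm1.beta, rel=1e-9)

    def test_sign_equivariance(self, rng):
        m = _sim_valid(rng, nsnp=10)
        m2 = _mri(-m.bx, m.bxse, m.by, m.byse)
        for f in (ivw, debiased_ivw, cml_ma):
            assert f(m2).beta == pytest.approx(-f(m).beta, rel=1e-9)

    def test_suite_reproducible_under_seed(self, rng):
        m = _sim_valid(rng, nsnp=8)
        a = run_weak_suite(m, n_boot=100, n_sim=100, seed=4)
        b = run_weak_suite(m, n_boot=100, n_sim=100, seed=4)
        assert [(e.method, e.beta, e.se, e.p) for e in a] == \
               [(e.method, e.beta, e.se, e.p) for e in b]


class TestValidationTables:
    def _weak_table(self):
        rows = []
        for method in ["m1", "m2", "m3", "m4", "m5", "m6"]:
            rows.append({"exposure_id": "e1", "outcome": "c1", "method": method,
                         "q": 0.01, "converged": True})
        for method in ["m1", "m2"]:
            rows.append({"exposure_id": "e2", "outcome": "c1", "method": method,
                         "q": 0.8, "converged": True})
        return pd.DataFrame(rows)

    def test_weak_only_discovery_rule(self):
        weak = self._weak_table()
        main = pd.DataFrame([{"exposure_id": "e1", "outcome": "c1", "q": 0.5},
                             {"exposure_id": "e2", "outcome": "c1", "q": 0.01}])
        v = cross_method_validation(weak, main)
        e1 = v[v["exposure_id"] == "e1"].iloc[0]
        assert e1["validated_ge5"] and e1["weak_only_discovery"]
        e2 = v[v["exposure_id"] == "e2"].iloc[0]
        assert not e2["validated_ge1"] and not e2["weak_only_discovery"]

    def test_counts_match_independent_tally(self, rng):
        methods = [f"m{k}" for k in range(8)]
        rows = []
        for e in range(20):
            for m in methods:
                rows.append({"exposure_id": f"e{e}", "outcome": "c",
                             "method": m, "q": float(rng.uniform(0, 0.2)),
                             "converged": True})
        tbl = pd.DataFrame(rows)
        v = cross_method_validation(tbl)
        for r in v.itertuples(index=False):
            manual = sum((tbl["exposure_id"] == r.exposure_id)
                         & (tbl["q"] < 0.05))
            assert r.n_significant == manual

    def test_benchmark_percentages_match_oracle(self, rng):
        methods = [f"m{k}" for k in range(4)]
        rows = []
        for e in range(30):
            for m in methods:
                rows.append({"exposure_id": f"e{e}", "outcome": "c",
                             "method": m, "q": float(rng.uniform(0, 0.15)),
                             "converged": True})
        tbl = pd.DataFrame(rows)
        bm = method_benchmark(tbl).set_index("method")
        for m in methods:
            grp = tbl[tbl["method"] == m]
            power = 100 * np.mean(grp["q"] < 0.05)
            assert bm.loc[m, "power_pct"] == pytest.approx(power)


class TestFdrFamilies:
    def test_per_method_family(self, rng):
        from sceqtlmr.core_io import bh_fdr
        rows = []
        for m in ("a", "b"):
            for e in range(10):
                rows.append({"exposure_id": f"e{e}", "outcome": "c", "method": m,
                             "nsnp": 2, "beta": 0.0, "se": 1.0,
                             "p": float(rng.uniform(0.001, 1)), "OR": 1.0,
                             "converged": True})
        tbl = add_fdr(pd.DataFrame(rows), family="method")
        for m in ("a", "b"):
            grp = tbl[tbl["method"] == m]
            assert np.allclose(grp["q"], bh_fdr(grp["p"].to_numpy()))
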