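"""Synthetic-data generator: determinism, LD structure, calibration of the
generated summary statistics, and ground-truth consistency."""

import numpy as np
import pytest

from sceqtlmr import simgen
from sceqtlmr.core_io import ExposureProfile


def _null_cfg(seed=0, n_genes=4, n_variants=6, **kw):
    genes, profiles = [], []
    rng = np.random.default_rng(seed + 99)
    for gi in range(n_genes):
        name = f"G{gi:03d}"
        start = 1_000_000 + gi * 2_000_000
        gs = simgen.GeneSpec(gene=name, chrom="1", start=start,
                             end=start + 10_000, n_variants=n_variants)
        profiles.append(ExposureProfile(name, "TN", "0h"))
        genes.append(gs)
    return simgen.SimConfig(seed=seed, genes=genes, profiles=profiles,
                            causal_genes={"cancer_a": {}}, **kw)


class TestReferencePanel:
    def test_same_seed_identical(self):
        cfg = _null_cfg(seed=3)
        p1 = simgen.simulate_reference_panel(cfg)
        p2 = simgen.simulate_reference_panel(cfg)
        assert np.array_equal(p1.dosages, p2.dosages)

    def test_dosages_in_range(self):
        panel = simgen.simulate_reference_panel(_null_cfg())
        assert panel.dosages.min() >= 0 and panel.dosages.max() <= 2

    def test_zero_rho_mean_offdiag_r2_near_null(self):
        # with no LD, E[r²] between independent variants ≈ 1/n_ref
        r2s = []
        for rep in range(25):
            cfg = _null_cfg(seed=100 + rep, n_genes=1, n_variants=8,
                            n_ref=300, ld_rho=0.0)
            panel = simgen.simulate_reference_panel(cfg)
            C = np.corrcoef(panel.dosages.T) ** 2
            iu = np.triu_indices_from(C, k=1)
            r2s.append(C[iu].mean())
        mean_r2 = np.mean(r2s)
        expect = 1 / 300
        mc_se = np.std(r2s) / np.sqrt(len(r2s))
        assert abs(mean_r2 - expect) < 3 * mc_se + 1e-4

    def test_eaf_matches_target_maf(self):
        cfg = _null_cfg(seed=7, n_genes=1, n_variants=10, n_ref=5000,
                        maf_range=(0.3, 0.3))
        panel = simgen.simulate_reference_panel(cfg)
        eaf = panel.dosages.mean(axis=0) / 2
        assert np.all(np.abs(eaf - 0.3) < 0.02)

    def test_ar1_blocks_have_ld(self):
        cfg = _null_cfg(seed=9, n_genes=2, n_variants=6, ld_rho=0.8)
        panel = simgen.simulate_reference_panel(cfg)
        d = panel.dosages
        adj = [np.corrcoef(d[:, i], d[:, i + 1])[0, 1] ** 2 for i in range(5)]
        cross = np.corrcoef(d[:, 0], d[:, 6])[0, 1] ** 2
        assert np.mean(adj) > 0.2 and cross < 0.05


class TestEqtlSumstats:
    def test_null_type_one_error_calibrated(self):
        # all true effects zero: fraction of p < 0.05 within [0.03, 0.07]
        # independent variants (no LD) so the empirical rate has full
        # effective sample size
        ps = []
        for rep in range(20):
            cfg = _null_cfg(seed=200 + rep, n_genes=5, n_variants=10,
                            ld_rho=0.0)
            stats = simgen.simulate_eqtl_sumstats(cfg)
            ps.extend(s.p for recs in stats.values() for s in recs)
        assert len(ps) >= 1000
        rate = np.mean(np.array(ps) < 0.05)
        assert 0.03 <= rate <= 0.07

    def test_effect_recovery_at_large_n(self):
        cfg = _null_cfg(seed=11, n_genes=2, n_variants=6, n_eqtl=10_000,
                        ld_rho=0.0)
        b_true = 0.25
        for g in cfg.genes:
            eid = f"{g.gene}|TN|0h"
            g.eqtl_effects[eid] = {i: b_true for i in range(6)}
        stats = simgen.simulate_eqtl_sumstats(cfg)
        betas = [s.beta for recs in stats.values() for s in recs]
        assert abs(np.mean(betas) - b_true) < 0.02

    def test_effect_regression_slope_near_one(self):
        # regressing estimated on true effects across many variants
        cfg = _null_cfg(seed=13, n_genes=10, n_variants=8, n_eqtl=10_000,
                        ld_rho=0.0)
        rng = np.random.default_rng(5)
        truth = {}
        for g in cfg.genes:
            eid = f"{g.gene}|TN|0h"
            effs = {i: float(rng.normal(0, 0.3)) for i in range(8)}
            g.eqtl_effects[eid] = effs
            truth[g.gene] = effs
        stats = simgen.simulate_eqtl_sumstats(cfg)
        xs, ys = [], []
        for eid, recs in stats.items():
            gene = eid.split("|")[0]
            for s in recs:
                vi = int(s.variant_id.split("_v")[1])
                xs.append(truth[gene][vi])
                ys.append(s.beta)
        slope = np.polyfit(xs, ys, 1)[0]
        assert 0.9 <= slope <= 1.1

    def test_pleiotropic_variant_hits_both_exposures(self):
        cfg = _null_cfg(seed=17, n_genes=2, n_variants=6)
        a, b = cfg.genes
        eid_a, eid_b = f"{a.gene}|TN|0h", f"{b.gene}|TN|0h"
        a.eqtl_effects[eid_a] = {0: 1.0}
        cfg.pleiotropy_map = {f"{a.gene}_v0": {eid_a, eid_b}}
        stats = simgen.simulate_eqtl_sumstats(cfg)
        pa = [s.p for s in stats[eid_a] if s.variant_id == f"{a.gene}_v0"][0]
        pb = [s.p for s in stats[eid_b] if s.variant_id == f"{a.gene}_v0"][0]
        assert pa < 1e-4 and pb < 1e-4


class TestOutcomeGwas:
    def test_null_lambda_gc_near_one(self):
        from scipy.stats import chi2
        zs = []
        for rep in range(5):
            cfg = _null_cfg(seed=300 + rep, n_genes=20, n_variants=10,
                            n_gwas=8_000, ld_rho=0.0)
            gwas = simgen.simulate_outcome_gwas(cfg)
            zs.extend((s.beta / s.se) ** 2 for s in gwas["cancer_a"])
        lam = np.median(zs) / chi2.ppf(0.5, 1)
        assert 0.9 <= lam <= 1.1

    def test_causal_gene_top_eqtl_signal(self):
        cfg = _null_cfg(seed=21, n_genes=3, n_variants=8, n_gwas=30_000)
        g = cfg.genes[0]
        eid = f"{g.gene}|TN|0h"
        g.eqtl_effects[eid] = {0: 1.0, 3: 0.8}
        cfg.causal_genes = {"cancer_a": {g.gene: 0.6}}
        gwas = simgen.simulate_outcome_gwas(cfg)
        p_top = min(s.p for s in gwas["cancer_a"]
                    if s.variant_id in (f"{g.gene}_v0", f"{g.gene}_v3"))
        assert p_top < 1e-4

    def test_case_counts_match_fraction(self):
        cfg = _null_cfg(seed=23, n_gwas=10_000, case_fraction=0.2)
        gwas = simgen.simulate_outcome_gwas(cfg)
        s = gwas["cancer_a"][0]
        assert s.n_cases == pytest.approx(2000, abs=5)
        assert s.n_controls == pytest.approx(8000, abs=5)

    def test_same_seed_identical(self):
        cfg = _null_cfg(seed=25)
        g1 = simgen.simulate_outcome_gwas(cfg)
        g2 = simgen.simulate_outcome_gwas(cfg)
        assert all(a == b for a, b in zip(g1["cancer_a"], g2["cancer_a"]))

    def test_invalid_case_fraction_rejected(self):
        with pytest.raises(ValueError, match="case_fraction"):
            _null_cfg(case_fraction=1.5)

    def test_unknown_causal_gene_rejected(self):
        cfg = _null_cfg()
        cfg.causal_genes = {"cancer_a": {"NOT_SIMULATED": 0.5}}
        with pytest.raises(ValueError, match="NOT_SIMULATED"):
            simgen.simulate_outcome_gwas(cfg)


class TestScCounts:
    def _sc_cfg(self, seed=0, logfc=0.0, n_cells=1200):
        cfg = _null_cfg(seed=seed)
        cfg.sc_params = {f"G{k:03d}": simgen.ScGeneParams(baseline_mean=3.0,
                                                          dispersion=2.0,
                                                          logfc=(logfc if k == 0 else 0.0),
                                                          expressed_fraction=0.9)
                         for k in range(4)}
        cfg.n_cells = n_cells
        return cfg

    def test_counts_nonnegative_integer_and_deterministic(self):
        cfg = self._sc_cfg(seed=31)
        c1, m1, g1 = simgen.simulate_sc_counts(cfg)
        c2, _, _ = simgen.simulate_sc_counts(cfg)
        assert np.array_equal(c1, c2)
        assert c1.min() >= 0 and np.issubdtype(c1.dtype, np.integer)
        assert set(m1["status"]) == {"tumor", "normal"}

    def test_planted_logfc_shifts_tumor_mean(self):
        cfg = self._sc_cfg(seed=33, logfc=1.0, n_cells=4000)
        counts, meta, genes = simgen.simulate_sc_counts(cfg)
        t = counts[meta["status"] == "tumor", 0].mean()
        n = counts[meta["status"] == "normal", 0].mean()
        assert np.log2(t / n) == pytest.approx(1.0, abs=0.25)

    def test_metadata_supports_qc(self):
        cfg = self._sc_cfg(seed=35)
        _, meta, _ = simgen.simulate_sc_counts(cfg)
        assert (meta["n_features"] <= 200).sum() > 0 or meta["n_features"].min() < 500
        assert meta["mito_fraction"].between(0, 100).all()


class TestScenarioIO:
    def test_write_scenario_roundtrip(self, tmp_path):
        cfg = simgen.default_scenario(seed=1, n_genes=3, n_causal=1,
                                      n_gwas=3000, cell_types=("TN",),
                                      time_points=("0h",))
        paths = simgen.write_scenario(cfg, tmp_path)
        from sceqtlmr.core_io import LDPanel, read_sumstats
        panel = LDPanel.from_tsv(paths["ld_panel"])
        assert panel.n_samples == cfg.n_ref
        eqtl_files = sorted(paths["eqtl_dir"].glob("*.tsv"))
        assert len(eqtl_files) == len(cfg.profiles)
        recs = read_sumstats(eqtl_files[0])
        assert len(recs) > 0
        assert (paths["truth"]).exists()

    def test_truth_consistent_with_config(self):
        cfg = simgen.default_scenario(seed=2, n_genes=4, n_causal=2)
        truth = simgen.make_truth(cfg)
        assert set(truth.causal_genes["breast_cancer"]) == {"G000", "G001"}
        assert truth.deg_logfc["G000"] != 0.0
        assert truth.deg_logfc["G003"] == 0.0
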