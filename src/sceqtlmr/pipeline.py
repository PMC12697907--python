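"""End-to-end orchestration: simulate → harmonize → instruments → MR →
FDR → colocalization/LD-check → DEG → MR-DEG → specificity → scoring.

A :class:`RunConfig` carries every path, threshold and mode flag; unknown
keys are rejected so a typo in a YAML config fails loudly.  One global seed
is fanned out to per-stage streams through a stage-name hash, so any stage
reproduces independently of the others.  ``run_all`` writes one TSV per
stage plus a JSON manifest (config hash, seed, per-stage row counts) and
returns the tables in memory.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import simgen
from .core_io import (AssocStat, ExposureProfile, LDPanel, harmonize,
                      read_sumstats)
from .instruments import InstrumentSet, select_strong, select_weak
from .mr_methods import (MRInput, add_fdr, cross_method_validation,
                         estimates_to_frame, method_benchmark, run_main_mr,
                         run_weak_suite)
from .coloc import ColocPriors, coloc_abf, coloc_evidence, ld_check
from .sc_deg import CellMatrix, DegResult, deg_results_to_frame, normalize, qc_filter, wilcoxon_deg
from .mr_deg import (attenuation_summary, build_pleiotropy_map, classify,
                     verdicts_to_frame)
from .specificity import (cell_type_enrichment, egene_signal_correlation,
                          cancer_enrichment, naive_memory_contrast,
                          t_cell_specificity, time_dependence)
from .prioritize import annotate_trials, build_ppi_graph, core_genes, score

__all__ = ["RunConfig", "run_all", "STAGES"]

STAGES = ["simulate", "harmonize", "instruments", "mr", "fdr", "coloc",
          "deg", "mrdeg", "specificity", "score"]


@dataclass
class RunConfig:
    """Everything a run needs.  When ``simulate`` is true the scenario
    parameters drive :func:`sceqtlmr.simgen.default_scenario`; otherwise the
    input paths must point at existing files."""

    seed: int = 0
    out_dir: str = "results"
    simulate: bool = True
    scenario: dict = field(default_factory=dict)
    # input paths (used when simulate is false)
    eqtl_dir: str | None = None
    gwas_dir: str | None = None
    ld_panel: str | None = None
    gene_annotation: str | None = None
    sc_mtx: str | None = None
    sc_genes: str | None = None
    sc_meta: str | None = None
    reference_expression: str | None = None
    ppi_edges: str | None = None
    trial_table: str | None = None
    # thresholds and modes
    mode: str = "both"               # strong | weak | both
    q_threshold: float = 0.05
    coloc_rule: str = "conditional"  # or "plain"
    coloc_threshold: float = 0.70
    ld_check_p: float = 1e-3
    ld_check_r2: float = 0.7
    min_pct: float = 0.1
    logfc_floor: float = 0.25
    batch_mode: str = "stouffer"     # or "none"
    pleiotropy_p: float = 1e-4
    specificity_comparator: str = "max"
    n_boot: int = 1000
    n_sim: int = 1000
    fdr_family: str = "method"

    def __post_init__(self) -> None:
        def listify(x):
            if isinstance(x, tuple):
                return [listify(v) for v in x]
            if isinstance(x, list):
                return [listify(v) for v in x]
            if isinstance(x, dict):
                return {k: listify(v) for k, v in x.items()}
            return x

        # canonical YAML-able form so write-then-read round-trips exactly
        self.scenario = listify(self.scenario)
        if self.mode not in ("strong", "weak", "both"):
            raise ValueError("mode must be strong|weak|both")
        if self.batch_mode not in ("stouffer", "none"):
            raise ValueError("batch_mode must be stouffer|none")
        if self.coloc_rule not in ("conditional", "plain"):
            raise ValueError("coloc_rule must be conditional|plain")
        if not (0 < self.q_threshold < 1):
            raise ValueError("q_threshold must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2 ** 31)


@dataclass
class RunData:
    """In-memory inputs of a run (simulated or loaded)."""

    eqtl: dict[str, list[AssocStat]]
    gwas: dict[str, list[AssocStat]]
    panel: LDPanel
    gene_annotation: pd.DataFrame
    sc: CellMatrix | None = None
    reference_expression: pd.DataFrame | None = None
    ppi_edges: pd.DataFrame | None = None
    trials: pd.DataFrame | None = None
    sim_cfg: simgen.SimConfig | None = None


def _load_or_simulate(cfg: RunConfig) -> RunData:
    if cfg.simulate:
        sim_cfg = simgen.default_scenario(seed=cfg.stage_seed("simulate"),
                                          **cfg.scenario)
        panel = simgen.simulate_reference_panel(sim_cfg)
        eqtl = simgen.simulate_eqtl_sumstats(sim_cfg, panel)
        gwas = simgen.simulate_outcome_gwas(sim_cfg, panel)
        counts, meta, genes = simgen.simulate_sc_counts(sim_cfg)
        sc = CellMatrix(counts, meta, genes)
        gene_names = [g.gene for g in sim_cfg.genes]
        causal = sorted({g for m in sim_cfg.causal_genes.values() for g in m})
        ref_expr = simgen.simulate_reference_expression(
            gene_names, t_enriched=causal, seed=cfg.stage_seed("simulate"))
        ppi = simgen.simulate_ppi_edges(gene_names, hub_genes=gene_names[:6],
                                        seed=cfg.stage_seed("simulate"))
        trials = simgen.simulate_trial_table(
            {g: c for c, m in sim_cfg.causal_genes.items() for g in m},
            seed=cfg.stage_seed("simulate"))
        return RunData(eqtl=eqtl, gwas=gwas, panel=panel,
                       gene_annotation=sim_cfg.gene_annotation(), sc=sc,
                       reference_expression=ref_expr, ppi_edges=ppi,
                       trials=trials, sim_cfg=sim_cfg)

    if not (cfg.eqtl_dir and cfg.gwas_dir and cfg.ld_panel and cfg.gene_annotation):
        raise ValueError("simulate=false requires eqtl_dir, gwas_dir, ld_panel "
                         "and gene_annotation paths")
    eqtl = {}
    for f in sorted(Path(cfg.eqtl_dir).glob("*.tsv")):
        eid = f.stem.replace("__", "|")
        eqtl[eid] = read_sumstats(f)
    gwas = {f.stem: read_sumstats(f) for f in sorted(Path(cfg.gwas_dir).glob("*.tsv"))}
    panel = LDPanel.from_tsv(cfg.ld_panel)
    genes = pd.read_csv(cfg.gene_annotation, sep="\t")
    sc = None
    if cfg.sc_mtx:
        sc = CellMatrix.from_mtx(cfg.sc_mtx, cfg.sc_genes, cfg.sc_meta)
    ref_expr = (pd.read_csv(cfg.reference_expression, sep="\t")
                if cfg.reference_expression else None)
    ppi = pd.read_csv(cfg.ppi_edges, sep="\t") if cfg.ppi_edges else None
    trials = pd.read_csv(cfg.trial_table, sep="\t") if cfg.trial_table else None
    return RunData(eqtl=eqtl, gwas=gwas, panel=panel, gene_annotation=genes,
                   sc=sc, reference_expression=ref_expr, ppi_edges=ppi,
                   trials=trials)


def run_all(cfg: RunConfig, write: bool = True) -> dict[str, Any]:
    """Execute every stage in order; returns a dict of stage tables and the
    manifest.  Partial outputs are written as soon as each stage completes,
    so a downstream failure retains everything upstream."""
    out_dir = Path(cfg.out_dir)
    if write:
        out_dir.mkdir(parents=True, exist_ok=True)
    results: dict[str, Any] = {}
    manifest = {"config_hash": cfg.config_hash(), "seed": cfg.seed, "stages": {}}

    def emit(stage: str, name: str, df: pd.DataFrame) -> None:
        manifest["stages"].setdefault(stage, {})[name] = int(len(df))
        if write:
            df.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False,
                      float_format="%.10g")

    data = _load_or_simulate(cfg)
    manifest["stages"]["simulate"] = {
        "exposures": len(data.eqtl), "outcomes": len(data.gwas),
        "panel_variants": len(data.panel.variant_ids),
    }

    anno = data.gene_annotation.set_index("gene")
    gene_of = {eid: ExposureProfile.from_id(eid).gene for eid in data.eqtl}

    # -- harmonize + instruments -------------------------------------------
    pairs: dict[tuple[str, str], Any] = {}
    strong_sets: dict[tuple[str, str], InstrumentSet] = {}
    weak_sets: dict[tuple[str, str], InstrumentSet] = {}
    n_harmonized = 0
    for eid, estats in data.eqtl.items():
        gene = gene_of[eid]
        if gene not in anno.index:
            continue
        grow = anno.loc[gene]
        for cancer, ostats in data.gwas.items():
            pair = harmonize(estats, ostats)
            if len(pair) == 0:
                continue
            pairs[(eid, cancer)] = pair
            n_harmonized += len(pair)
            if cfg.mode in ("strong", "both"):
                strong_sets[(eid, cancer)] = select_strong(pair, data.panel, grow, eid)
            if cfg.mode in ("weak", "both"):
                weak_sets[(eid, cancer)] = select_weak(pair, data.panel, grow, eid)
    manifest["stages"]["harmonize"] = {"pairs": len(pairs),
                                       "variants": n_harmonized}
    inst_rows = [s.to_frame() for s in list(strong_sets.values()) + list(weak_sets.values())
                 if len(s)]
    inst_table = (pd.concat(inst_rows, ignore_index=True) if inst_rows
                  else pd.DataFrame())
    emit("instruments", "instruments", inst_table)

    # -- MR -----------------------------------------------------------------
    def mri_for(s: InstrumentSet, cancer: str) -> MRInput | None:
        if len(s) == 0:
            return None
        pair = pairs[(s.exposure_id, cancer)]
        out_by_id = {o.variant_id: o for o in pair.outcome_stats}
        return MRInput.from_harmonized(s, out_by_id, outcome_id=cancer)

    main_ests = []
    for (eid, cancer), s in strong_sets.items():
        mri = mri_for(s, cancer)
        if mri is None:
            continue
        est = run_main_mr(mri)
        if est is not None:
            main_ests.append(est)
    main_table = estimates_to_frame(main_ests)
    if len(main_table):
        main_table = add_fdr(main_table, family="all")
    emit("mr", "mr_main", main_table)

    weak_ests = []
    mr_seed = cfg.stage_seed("mr")
    for (eid, cancer), s in weak_sets.items():
        mri = mri_for(s, cancer)
        if mri is None:
            continue
        weak_ests.extend(run_weak_suite(mri, n_boot=cfg.n_boot,
                                        n_sim=cfg.n_sim, seed=mr_seed))
    weak_table = estimates_to_frame(weak_ests)
    if len(weak_table):
        weak_table = add_fdr(weak_table, family=cfg.fdr_family)
    emit("mr", "mr_weak", weak_table)

    if len(weak_table):
        validation = cross_method_validation(weak_table, main_table if len(main_table) else None,
                                             cfg.q_threshold)
        benchmark = method_benchmark(weak_table, cfg.q_threshold)
    else:
        validation, benchmark = pd.DataFrame(), pd.DataFrame()
    emit("fdr", "cross_method_validation", validation)
    emit("fdr", "method_benchmark", benchmark)

    # -- signals: main q < threshold ---------------------------------------
    signals = (main_table[main_table["q"] < cfg.q_threshold]
               if len(main_table) else pd.DataFrame(columns=["exposure_id", "outcome"]))

    # -- coloc + LD check ---------------------------------------------------
    coloc_rows = []
    for row in signals.itertuples(index=False):
        pair = pairs[(row.exposure_id, row.outcome)]
        try:
            res = coloc_abf(pair.exposure_stats, pair.outcome_stats,
                            ColocPriors(), rule=cfg.coloc_rule,
                            threshold=cfg.coloc_threshold)
        except ValueError:
            continue
        inst = strong_sets.get((row.exposure_id, row.outcome))
        lead = min(inst.instruments, key=lambda r: r.stat.p).variant_id if inst and len(inst) else None
        if lead is not None and lead in data.panel:
            try:
                max_r2, ld_pass = ld_check(lead, pair.outcome_stats, data.panel,
                                           p_threshold=cfg.ld_check_p,
                                           r2_threshold=cfg.ld_check_r2)
            except ValueError:
                max_r2, ld_pass = math.nan, False
            res.ld_check_max_r2, res.ld_check_pass = max_r2, ld_pass
        coloc_rows.append({
            "exposure_id": row.exposure_id, "outcome": row.outcome,
            "n_variants": res.n_variants, "pp_h0": res.pp_h0, "pp_h1": res.pp_h1,
            "pp_h2": res.pp_h2, "pp_h3": res.pp_h3, "pp_h4": res.pp_h4,
            "ratio": res.ratio, "decision": res.decision,
            "ld_check_max_r2": res.ld_check_max_r2,
            "ld_check_pass": res.ld_check_pass,
            "coloc_evidence": coloc_evidence(res),
        })
    coloc_table = pd.DataFrame(coloc_rows)
    emit("coloc", "coloc", coloc_table)

    # -- DEG ----------------------------------------------------------------
    deg_results: list[DegResult] = []
    if data.sc is not None:
        m = normalize(qc_filter(data.sc))
        deg_results = wilcoxon_deg(m, min_pct=cfg.min_pct,
                                   logfc_floor=cfg.logfc_floor,
                                   batch_mode=cfg.batch_mode)
    deg_table = deg_results_to_frame(deg_results)
    emit("deg", "deg", deg_table)
    deg_by_gene = {r.gene: r for r in deg_results}

    main_beta = {(r.exposure_id, r.outcome): r.beta
                 for r in main_table.itertuples(index=False)} if len(main_table) else {}

    def signal_deg_supported(eid: str, cancer: str) -> bool:
        gene = gene_of[eid]
        deg = deg_by_gene.get(gene)
        beta = main_beta.get((eid, cancer))
        if deg is None or beta is None or beta == 0 or deg.logfc == 0:
            return False
        return deg.p < 0.05 and (deg.logfc > 0) == (beta > 0)

    # -- MR-DEG -------------------------------------------------------------
    mrdeg_rows = []
    if len(signals):
        scan_sets = list((weak_sets or strong_sets).values())
        pmap = build_pleiotropy_map([s for s in scan_sets if len(s)],
                                    data.eqtl, cfg.pleiotropy_p)
        deg_supported_genes = {
            cancer: {g for g, r in deg_by_gene.items() if r.p < 0.05}
            for cancer in data.gwas
        }
        measured = set(deg_by_gene)
        for row in signals.itertuples(index=False):
            inst = (weak_sets.get((row.exposure_id, row.outcome))
                    or strong_sets.get((row.exposure_id, row.outcome)))
            if inst is None or len(inst) == 0:
                continue
            verdict = classify(
                row.exposure_id, row.outcome, inst.variant_ids, pmap,
                deg_supported_genes, measured,
                focal_deg_supported=signal_deg_supported(row.exposure_id, row.outcome))
            mrdeg_rows.append(verdict)
    mrdeg_table = verdicts_to_frame(mrdeg_rows)
    emit("mrdeg", "mrdeg", mrdeg_table)
    emit("mrdeg", "mrdeg_summary", attenuation_summary(mrdeg_rows))

    # -- specificity --------------------------------------------------------
    spec_tables: dict[str, pd.DataFrame] = {}
    if len(signals):
        profiles = [ExposureProfile.from_id(e) for e in data.eqtl]
        stratum = lambda p: f"{p.cell_type}:{p.time_point}"
        egene_counts: dict[str, set] = {}
        for p in profiles:
            egene_counts.setdefault(stratum(p), set()).add(p.gene)
        egenes = {s: len(g) for s, g in egene_counts.items()}
        sig_counts: dict[str, set] = {}
        for row in signals.itertuples(index=False):
            p = ExposureProfile.from_id(row.exposure_id)
            sig_counts.setdefault(stratum(p), set()).add((p.gene, row.outcome))
        sig_n = {s: len(v) for s, v in sig_counts.items()}
        enr = cell_type_enrichment(sig_n, egenes)
        spec_tables["cell_type_enrichment"] = pd.DataFrame(
            [vars(r) for r in enr])
        try:
            rho = egene_signal_correlation(sig_n, egenes)
        except ValueError:
            rho = math.nan
        spec_tables["cell_type_enrichment"].attrs["spearman_rho"] = rho

        cases = {c: next((s.n_cases for s in stats if s.n_cases), None)
                 for c, stats in data.gwas.items()}
        if all(v for v in cases.values()):
            sig_per_cancer: dict[str, int] = {}
            for row in signals.itertuples(index=False):
                sig_per_cancer[row.outcome] = sig_per_cancer.get(row.outcome, 0) + 1
            # pick the case-count unit so every scaled total stays well above
            # its signal count (desk-scale GWASs have few cases per signal)
            unit = max(1, int(min(cases.values())
                              // (10 * (max(sig_per_cancer.values()) + 1))))
            spec_tables["cancer_enrichment"] = pd.DataFrame(
                [vars(r) for r in cancer_enrichment(sig_per_cancer, cases,
                                                    cases_per_unit=unit)])

        est = main_table.copy()
        prof = est["exposure_id"].map(ExposureProfile.from_id)
        est["gene"] = [p.gene for p in prof]
        est["cell_type"] = [p.cell_type for p in prof]
        est["time_point"] = [p.time_point for p in prof]
        est = est.rename(columns={"outcome": "cancer"})
        sig_keys = {(gene_of[r.exposure_id],
                     ExposureProfile.from_id(r.exposure_id).cell_type, r.outcome)
                    for r in signals.itertuples(index=False)}
        est_td = est[[(g, c, ca) in sig_keys for g, c, ca in
                      zip(est["gene"], est["cell_type"], est["cancer"])]]
        contrasts = time_dependence(est_td)
        spec_tables["time_contrasts"] = pd.DataFrame([vars(c) for c in contrasts])
        nm = naive_memory_contrast(est)
        spec_tables["naive_memory_contrasts"] = pd.DataFrame([vars(c) for c in nm])

    if data.reference_expression is not None:
        spec_tables["t_cell_specificity"] = t_cell_specificity(
            data.reference_expression, comparator=cfg.specificity_comparator)
    for name, tbl in spec_tables.items():
        emit("specificity", name, tbl)

    # -- scoring ------------------------------------------------------------
    score_rows = []
    if len(signals):
        pair_keys = sorted({(gene_of[r.exposure_id], r.outcome)
                            for r in signals.itertuples(index=False)})
        universe = {g for g, _ in pair_keys}
        core: set[str] = set()
        if data.ppi_edges is not None and len(data.ppi_edges):
            graph = build_ppi_graph(data.ppi_edges)
            core = core_genes(graph, universe=universe)
        tcell_labels = {}
        if "t_cell_specificity" in spec_tables:
            tcell_labels = dict(zip(spec_tables["t_cell_specificity"]["gene"],
                                    spec_tables["t_cell_specificity"]["label"]))
        td_pairs = set()
        if "time_contrasts" in spec_tables and len(spec_tables["time_contrasts"]):
            tc = spec_tables["time_contrasts"]
            td_pairs = {(g, c) for g, c, s in zip(tc["gene"], tc["cancer"],
                                                  tc["significant"]) if s}
        causal_verdicts = {(v.exposure_id, v.outcome): v.verdict for v in mrdeg_rows}
        for gene, cancer in pair_keys:
            exposures = [r.exposure_id for r in signals.itertuples(index=False)
                         if gene_of[r.exposure_id] == gene and r.outcome == cancer]
            deg_ok = any(signal_deg_supported(e, cancer) for e in exposures)
            mrdeg_ok = any(causal_verdicts.get((e, cancer)) in
                           ("likely_causal_single", "likely_causal_mrdeg")
                           for e in exposures)
            trial_ok = False
            if data.trials is not None and len(data.trials):
                ann = annotate_trials([gene], data.trials, cancer=cancer)
                trial_ok = bool(ann["clinical_trial"].iloc[0])
            card = score(gene, cancer, {
                "deg_validated": deg_ok,
                "mrdeg_causal": mrdeg_ok,
                "t_cell_specific": tcell_labels.get(gene, "none") != "none",
                "time_specific": (gene, cancer) in td_pairs,
                "core_gene": gene in core,
                "clinical_trial": trial_ok,
            })
            score_rows.append(card.as_dict())
    score_table = pd.DataFrame(score_rows)
    emit("score", "scorecard", score_table)

    if write:
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                          sort_keys=True))
    results.update({
        "manifest": manifest, "instruments": inst_table, "mr_main": main_table,
        "mr_weak": weak_table, "validation": validation, "benchmark": benchmark,
        "coloc": coloc_table, "deg": deg_table, "mrdeg": mrdeg_table,
        "specificity": spec_tables, "scorecard": score_table,
        "signals": signals,
    })
    return results
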