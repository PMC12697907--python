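"""Synthetic-data generator with known ground truth.

Emulates the statistical structure of the pipeline's real inputs so that
every downstream stage has a recoverable target:

* an LD reference panel with AR(1)-correlated blocks (Gaussian-copula
  haplotypes thresholded at the minor-allele frequency);
* per-profile cis-eQTL summary statistics from an individual-level
  expression model (some effects shared across profiles = pleiotropy,
  some varying across activation time);
* case-control cancer GWAS summary statistics under a liability-threshold
  model in which a known subset of genes is causal through their
  genetically regulated expression;
* negative-binomial tumor-vs-normal single-cell counts with planted
  log2 fold changes, plus the QC metadata (feature counts, mitochondrial
  fraction) the filtering stage expects.

Every generator is a pure function of ``(config, seed)``: the same config
always yields byte-identical output.  Sample-size defaults (120 eQTL
donors, 50 000 GWAS samples, 500 reference samples) mirror the scale of
single-cell eQTL cohorts and case-control cancer GWAS.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import AssocStat, ExposureProfile, LDPanel, write_sumstats

__all__ = [
    "GeneSpec",
    "ScGeneParams",
    "SimConfig",
    "SimTruth",
    "simulate_reference_panel",
    "simulate_eqtl_sumstats",
    "simulate_outcome_gwas",
    "simulate_sc_counts",
    "simulate_reference_expression",
    "simulate_ppi_edges",
    "simulate_trial_table",
    "write_scenario",
]


def child_rng(seed: int, name: str) -> np.random.Generator:
    """Deterministic per-stage generator: fans a single scenario seed out to
    independent streams keyed by stage name."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2 ** 31), zlib.crc32(name.encode())])
    )


@dataclass
class GeneSpec:
    """One simulated gene: its cis region and true eQTL architecture."""

    gene: str
    chrom: str = "1"
    start: int = 1_000_000
    end: int = 1_010_000
    n_variants: int = 10
    #: per-profile true per-variant effects on expression (variant index →
    #: effect); profiles not listed have all-zero effects for this gene.
    eqtl_effects: dict[str, dict[int, float]] = field(default_factory=dict)

    def variant_ids(self) -> list[str]:
        return [f"{self.gene}_v{i}" for i in range(self.n_variants)]

    def positions(self) -> list[int]:
        # Variants spread across the cis window, inside ±500 kb of the gene.
        span = (self.end + 400_000) - (self.start - 400_000)
        step = max(span // max(self.n_variants, 1), 1)
        return [self.start - 400_000 + i * step for i in range(self.n_variants)]


@dataclass
class ScGeneParams:
    """Negative-binomial parameters for one gene in the single-cell module."""

    baseline_mean: float = 1.0
    dispersion: float = 2.0       # NB size parameter; larger = less overdispersed
    logfc: float = 0.0            # planted log2 fold change, tumor vs normal
    expressed_fraction: float = 0.8  # target detection rate (sets the mean floor)


@dataclass
class SimConfig:
    """Full description of one synthetic study.

    ``pleiotropy_map`` routes a variant's effect into additional exposures
    (variant_id → set of exposure_ids), creating the horizontally pleiotropic
    instruments the MR-DEG stage disentangles.  ``causal_genes`` maps each
    cancer outcome to ``{gene: liability effect per unit of genetically
    regulated expression}``.
    """

    seed: int = 0
    n_ref: int = 500
    n_eqtl: int = 120
    n_gwas: int = 50_000
    maf_range: tuple[float, float] = (0.1, 0.5)
    ld_rho: float = 0.6
    genes: list[GeneSpec] = field(default_factory=list)
    profiles: list[ExposureProfile] = field(default_factory=list)
    pleiotropy_map: dict[str, set[str]] = field(default_factory=dict)
    causal_genes: dict[str, dict[str, float]] = field(default_factory=dict)
    case_fraction: float = 0.1
    gwas_model: str = "logistic"   # or "liability" (linear on the latent scale)
    sc_params: dict[str, ScGeneParams] = field(default_factory=dict)
    n_cells: int = 2000
    n_batches: int = 2
    tumor_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.n_ref < 2 or self.n_eqtl < 2 or self.n_gwas < 2:
            raise ValueError("all sample sizes must be >= 2")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0 < self.case_fraction < 1):
            raise ValueError("case_fraction must be in (0, 1)")
        for g, p in self.sc_params.items():
            if p.dispersion <= 0:
                raise ValueError(f"dispersion must be > 0 (gene {g})")

    # -- helpers -----------------------------------------------------------
    def all_variant_ids(self) -> list[str]:
        return [v for g in self.genes for v in g.variant_ids()]

    def gene_annotation(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"gene": g.gene, "chrom": g.chrom, "start": g.start, "end": g.end}
             for g in self.genes]
        )

    def variant_table(self) -> pd.DataFrame:
        rows = []
        for g in self.genes:
            for v, pos in zip(g.variant_ids(), g.positions()):
                rows.append({"variant_id": v, "chrom": g.chrom, "pos": pos,
                             "gene": g.gene})
        return pd.DataFrame(rows)

    def profile_effects(self) -> dict[str, dict[str, float]]:
        """exposure_id → {variant_id: true effect}, pleiotropy folded in."""
        out: dict[str, dict[str, float]] = {p.exposure_id: {} for p in self.profiles}
        for g in self.genes:
            vids = g.variant_ids()
            for exposure_id, effects in g.eqtl_effects.items():
                if exposure_id not in out:
                    continue
                for vi, b in effects.items():
                    out[exposure_id][vids[vi]] = out[exposure_id].get(vids[vi], 0.0) + b
        # pleiotropy: re-use the variant's largest own effect in every mapped
        # exposure that does not already carry one.
        for vid, exposures in self.pleiotropy_map.items():
            donor = max((eff.get(vid, 0.0) for eff in out.values()), key=abs, default=0.0)
            for eid in exposures:
                if eid in out and vid not in out[eid]:
                    out[eid][vid] = donor
        return out


@dataclass
class SimTruth:
    """Ground truth of a simulated scenario, for recovery checks."""

    eqtl_effects: dict[str, dict[str, float]]
    causal_genes: dict[str, dict[str, float]]
    pleiotropic_variants: dict[str, list[str]]
    deg_logfc: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "eqtl_effects": self.eqtl_effects,
            "causal_genes": self.causal_genes,
            "pleiotropic_variants": self.pleiotropic_variants,
            "deg_logfc": self.deg_logfc,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def make_truth(cfg: SimConfig) -> SimTruth:
    return SimTruth(
        eqtl_effects=cfg.profile_effects(),
        causal_genes={c: dict(g) for c, g in cfg.causal_genes.items()},
        pleiotropic_variants={v: sorted(s) for v, s in cfg.pleiotropy_map.items()},
        deg_logfc={g: p.logfc for g, p in cfg.sc_params.items()},
    )


# ---------------------------------------------------------------------------
# Genotypes

def _simulate_dosages(cfg: SimConfig, n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """Dosage matrix (n_samples × all variants) as the sum of two haplotypes.

    Within each gene block, haplotype alleles come from a Gaussian copula
    with AR(1) correlation ``ld_rho``, thresholded at the MAF quantile, so
    adjacent variants are in LD and blocks are independent.
    """
    rho = cfg.ld_rho
    cols = []
    for g in cfg.genes:
        m = g.n_variants
        mafs = rng.uniform(*cfg.maf_range, size=m)
        thresh = sps.norm.ppf(mafs)
        hap_sum = np.zeros((n_samples, m), dtype=np.int8)
        for _ in range(2):
            z = rng.standard_normal((n_samples, m))
            if rho != 0:
                for j in range(1, m):
                    z[:, j] = rho * z[:, j - 1] + math.sqrt(1 - rho ** 2) * z[:, j]
            hap_sum += (z < thresh).astype(np.int8)
        cols.append(hap_sum)
    return np.concatenate(cols, axis=1) if cols else np.zeros((n_samples, 0), dtype=np.int8)


def simulate_reference_panel(cfg: SimConfig) -> LDPanel:
    """LD reference panel of ``n_ref`` samples over every simulated variant."""
    rng = child_rng(cfg.seed, "reference_panel")
    dosages = _simulate_dosages(cfg, cfg.n_ref, rng).astype(float)
    return LDPanel(dosages, cfg.all_variant_ids())


# ---------------------------------------------------------------------------
# eQTL summary statistics

def _marginal_stats(G: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column simple linear regression of y on dosage: (beta, se, p)."""
    n = G.shape[0]
    Gc = G - G.mean(axis=0)
    yc = y - y.mean()
    sxx = (Gc ** 2).sum(axis=0)
    sxx = np.where(sxx == 0, np.nan, sxx)
    beta = Gc.T @ yc / sxx
    resid_ss = (yc ** 2).sum() - beta ** 2 * sxx
    resid_ss = np.clip(resid_ss, 1e-12, None)
    se = np.sqrt(resid_ss / (n - 2) / sxx)
    z = beta / se
    # Wald (normal) p, the convention of released summary statistics
    p = 2.0 * sps.norm.sf(np.abs(z))
    return beta, se, np.clip(p, 1e-300, 1.0)


def _records(variant_tbl: pd.DataFrame, eaf: np.ndarray, beta: np.ndarray,
             se: np.ndarray, p: np.ndarray, n: int,
             n_cases: float | None = None, n_controls: float | None = None
             ) -> list[AssocStat]:
    recs = []
    for i, row in enumerate(variant_tbl.itertuples(index=False)):
        if not np.isfinite(beta[i]) or not np.isfinite(se[i]) or se[i] <= 0:
            continue
        f = float(np.clip(eaf[i], 1e-6, 1 - 1e-6))
        recs.append(AssocStat(
            variant_id=row.variant_id, chrom=str(row.chrom), pos=int(row.pos),
            effect_allele="A", other_allele="G", eaf=f,
            beta=float(beta[i]), se=float(se[i]), p=float(p[i]), n=float(n),
            n_cases=n_cases, n_controls=n_controls,
        ))
    return recs


def simulate_eqtl_sumstats(cfg: SimConfig, panel: LDPanel | None = None
                           ) -> dict[str, list[AssocStat]]:
    """Per-profile cis-eQTL summary statistics from an individual-level model.

    For each profile, donor expression is ``G @ true_effects + N(0, 1)`` over
    ``n_eqtl`` donors; each variant in the profile's cis region is then
    tested marginally.  Pleiotropic variants (``cfg.pleiotropy_map``) inject
    their effect into every mapped exposure, including across genes.
    """
    rng = child_rng(cfg.seed, "eqtl_cohort")
    G = _simulate_dosages(cfg, cfg.n_eqtl, rng).astype(float)
    vids = cfg.all_variant_ids()
    vindex = {v: i for i, v in enumerate(vids)}
    vtbl = cfg.variant_table().set_index("variant_id", drop=False)
    eaf = G.mean(axis=0) / 2.0
    effects = cfg.profile_effects()

    out: dict[str, list[AssocStat]] = {}
    noise_rng = child_rng(cfg.seed, "eqtl_noise")
    for prof in cfg.profiles:
        eid = prof.exposure_id
        expr = noise_rng.standard_normal(cfg.n_eqtl)
        for vid, b in effects.get(eid, {}).items():
            expr = expr + b * G[:, vindex[vid]]
        # summary stats are reported for the gene's whole cis region plus any
        # cross-gene pleiotropic variants wired into this profile
        own = [v for v in vids if vtbl.loc[v, "gene"] == prof.gene]
        extra = [v for v in effects.get(eid, {}) if v not in set(own)]
        region = own + extra
        idx = [vindex[v] for v in region]
        beta, se, p = _marginal_stats(G[:, idx], expr)
        out[eid] = _records(vtbl.loc[region], eaf[idx], beta, se, p, cfg.n_eqtl)
    return out


# ---------------------------------------------------------------------------
# Outcome GWAS

def _logistic_score_stats(G: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-variant one-step logistic summary statistics (log-odds scale).

    Uses the score and information of the intercept-only logistic model —
    the standard large-sample GWAS approximation, exact to first order for
    the small per-variant effects a GWAS measures.
    """
    n = G.shape[0]
    phi = y.mean()
    w = phi * (1 - phi)
    Gc = G - G.mean(axis=0)
    score = Gc.T @ (y - phi)
    info = w * (Gc ** 2).sum(axis=0)
    info = np.where(info == 0, np.nan, info)
    beta = score / info
    se = 1.0 / np.sqrt(info)
    z = beta / se
    p = np.clip(sps.chi2.sf(z ** 2, df=1), 1e-300, 1.0)
    return beta, se, p


def simulate_outcome_gwas(cfg: SimConfig, panel: LDPanel | None = None
                          ) -> dict[str, list[AssocStat]]:
    """Case-control GWAS summary statistics per cancer outcome.

    Liability = Σ over causal genes of effect × genetically regulated
    expression (the gene's true cis effects applied to the GWAS cohort's
    genotypes) + standard-normal noise; cases are the top ``case_fraction``
    of liability.  Summary statistics are per-variant logistic (log-odds
    scale) by default, or linear-on-liability with ``gwas_model='liability'``.
    """
    vids = cfg.all_variant_ids()
    vindex = {v: i for i, v in enumerate(vids)}
    vtbl = cfg.variant_table()
    effects = cfg.profile_effects()
    for cancer, gene_effects in cfg.causal_genes.items():
        for gene in gene_effects:
            if gene not in {g.gene for g in cfg.genes}:
                raise ValueError(f"causal gene {gene} not simulated")

    rng = child_rng(cfg.seed, "gwas_cohort")
    G = _simulate_dosages(cfg, cfg.n_gwas, rng).astype(float)
    eaf = G.mean(axis=0) / 2.0

    # genetically regulated expression per gene: first profile of that gene
    # that carries effects defines its regulatory architecture
    gene_gre: dict[str, np.ndarray] = {}
    for g in cfg.genes:
        arch = None
        for prof in cfg.profiles:
            if prof.gene == g.gene and effects.get(prof.exposure_id):
                arch = effects[prof.exposure_id]
                break
        gre = np.zeros(cfg.n_gwas)
        if arch:
            for vid, b in arch.items():
                gre += b * G[:, vindex[vid]]
        gene_gre[g.gene] = gre

    noise_rng = child_rng(cfg.seed, "gwas_noise")
    out: dict[str, list[AssocStat]] = {}
    for cancer in sorted(cfg.causal_genes):
        liab = noise_rng.standard_normal(cfg.n_gwas)
        for gene, eff in cfg.causal_genes[cancer].items():
            liab = liab + eff * gene_gre[gene]
        cut = np.quantile(liab, 1 - cfg.case_fraction)
        y = (liab > cut).astype(float)
        n_cases = float(y.sum())
        n_controls = float(cfg.n_gwas - n_cases)
        if cfg.gwas_model == "logistic":
            beta, se, p = _logistic_score_stats(G, y)
        elif cfg.gwas_model == "liability":
            beta, se, p = _marginal_stats(G, liab)
        else:
            raise ValueError(f"unknown gwas_model {cfg.gwas_model!r}")
        out[cancer] = _records(vtbl, eaf, beta, se, p, cfg.n_gwas,
                               n_cases=n_cases, n_controls=n_controls)
    return out


# ---------------------------------------------------------------------------
# Single-cell counts

def simulate_sc_counts(cfg: SimConfig) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """Negative-binomial tumor/normal single-cell counts with planted logFC.

    Returns ``(counts, cell_metadata, gene_names)`` where counts is a dense
    cells × genes integer matrix.  Tumor cells' mean for gene g is scaled by
    ``2**logfc[g]``.  The metadata carries tumor/normal status, batch, cell
    type, a simulated per-cell feature count and a Beta-distributed
    mitochondrial fraction so the QC stage has something to cut.
    """
    if not cfg.sc_params:
        raise ValueError("sc_params is empty")
    rng = child_rng(cfg.seed, "sc_counts")
    genes = sorted(cfg.sc_params)
    n_cells = cfg.n_cells
    status = np.where(rng.random(n_cells) < cfg.tumor_fraction, "tumor", "normal")
    batch = rng.integers(0, cfg.n_batches, size=n_cells)
    size_factor = np.exp(rng.normal(0.0, 0.25, size=n_cells))

    counts = np.zeros((n_cells, len(genes)), dtype=np.int64)
    for j, g in enumerate(genes):
        prm = cfg.sc_params[g]
        # scale the baseline so the normal-group detection rate approximates
        # expressed_fraction under the NB zero probability
        mu0 = max(prm.baseline_mean, 1e-3)
        target = np.clip(prm.expressed_fraction, 0.05, 0.999)
        # P(X>0) = 1 - (r/(r+mu))^r ; solve for mu
        r = prm.dispersion
        mu_needed = r * ((1 - target) ** (-1.0 / r) - 1.0)
        mu = max(mu0, mu_needed)
        mean = mu * size_factor * np.where(status == "tumor", 2.0 ** prm.logfc, 1.0)
        p_nb = r / (r + mean)
        counts[:, j] = rng.negative_binomial(r, p_nb)

    n_features = np.clip(rng.normal(1500, 450, size=n_cells), 50, None).astype(int)
    mito = rng.beta(2.0, 60.0, size=n_cells) * 100.0  # percent, mostly < 5
    meta = pd.DataFrame({
        "barcode": [f"cell{i:05d}" for i in range(n_cells)],
        "status": status,
        "batch": [f"b{b}" for b in batch],
        "cell_type": "CD4_T",
        "n_features": n_features,
        "mito_fraction": mito,
    })
    return counts, meta, genes


# ---------------------------------------------------------------------------
# Auxiliary reference tables (specificity / prioritization inputs)

def simulate_reference_expression(genes: Sequence[str], t_enriched: Sequence[str] = (),
                                  t_enhanced: Sequence[str] = (), seed: int = 0
                                  ) -> pd.DataFrame:
    """Per-immune-cell-type mean expression table (TPM-like units).

    Genes in ``t_enriched`` get T-cell expression ≥5× every other cell type;
    ``t_enhanced`` genes get a ratio in [2, 5); all others ≈ 1×.
    """
    rng = child_rng(seed, "reference_expression")
    cell_types = ["T_CD4_naive", "T_CD8_naive", "B_naive", "NK", "monocyte_classical"]
    t_cols = [c for c in cell_types if c.startswith("T_")]
    rows = []
    for g in genes:
        base = rng.uniform(5, 50)
        row = {"gene": g}
        if g in t_enriched:
            ratio = rng.uniform(6, 12)
        elif g in t_enhanced:
            ratio = rng.uniform(2.5, 4.5)
        else:
            ratio = rng.uniform(0.8, 1.2)
        for c in cell_types:
            row[c] = base * ratio if c in t_cols else base
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_ppi_edges(genes: Sequence[str], hub_genes: Sequence[str] = (),
                       seed: int = 0, background_p: float = 0.05) -> pd.DataFrame:
    """Synthetic PPI edge list: hub genes form a clique (size ≥ 5 gives
    MCC = (|C|−1)! ≥ 24, past the core-gene floor), the rest sparse noise."""
    rng = child_rng(seed, "ppi")
    genes = list(genes)
    edges = set()
    hubs = [g for g in hub_genes if g in genes]
    for i, a in enumerate(hubs):
        for b in hubs[i + 1:]:
            edges.add((a, b))
    for i, a in enumerate(genes):
        for b in genes[i + 1:]:
            if (a, b) not in edges and rng.random() < background_p:
                edges.add((a, b))
    return pd.DataFrame(
        [{"gene_a": a, "gene_b": b, "confidence": round(float(rng.uniform(0.4, 0.99)), 3)}
         for a, b in sorted(edges)]
    )


def simulate_trial_table(genes_with_trials: Mapping[str, str], seed: int = 0) -> pd.DataFrame:
    """Drug-target annotation table (gene → indication currently in trials)."""
    rng = child_rng(seed, "trials")
    rows = []
    for i, (gene, indication) in enumerate(sorted(genes_with_trials.items())):
        rows.append({
            "gene": gene,
            "drug": f"CPD-{1000 + i}",
            "indication": indication,
            "indication_class": "Anticancer",
            "trial_status": "Active",
            "highest_status": rng.choice(["Preclinical", "Phase I", "Phase II", "Phase III"]),
        })
    return pd.DataFrame(rows, columns=["gene", "drug", "indication",
                                       "indication_class", "trial_status", "highest_status"])


# ---------------------------------------------------------------------------
# Scenario writer

def write_scenario(cfg: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Materialize a full scenario as plain-text files: sumstats TSVs per
    exposure and cancer, the LD panel, gene annotation, MTX counts triplet,
    cell metadata and the ground-truth JSON.  Returns the path map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    panel = simulate_reference_panel(cfg)
    panel.to_tsv(out_dir / "ld_panel.tsv")
    paths["ld_panel"] = out_dir / "ld_panel.tsv"

    eqtl = simulate_eqtl_sumstats(cfg, panel)
    eqtl_dir = out_dir / "eqtl"
    eqtl_dir.mkdir(exist_ok=True)
    for eid, stats in eqtl.items():
        f = eqtl_dir / (eid.replace("|", "__") + ".tsv")
        write_sumstats(stats, f)
    paths["eqtl_dir"] = eqtl_dir

    gwas = simulate_outcome_gwas(cfg, panel)
    gwas_dir = out_dir / "gwas"
    gwas_dir.mkdir(exist_ok=True)
    for cancer, stats in gwas.items():
        write_sumstats(stats, gwas_dir / f"{cancer}.tsv")
    paths["gwas_dir"] = gwas_dir

    cfg.gene_annotation().to_csv(out_dir / "genes.tsv", sep="\t", index=False)
    paths["gene_annotation"] = out_dir / "genes.tsv"

    if cfg.sc_params:
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix
        counts, meta, genes = simulate_sc_counts(cfg)
        sc_dir = out_dir / "sc"
        sc_dir.mkdir(exist_ok=True)
        mmwrite(sc_dir / "matrix.mtx", csr_matrix(counts))
        pd.Series(genes).to_csv(sc_dir / "genes.tsv", sep="\t", index=False, header=False)
        meta["barcode"].to_csv(sc_dir / "barcodes.tsv", sep="\t", index=False, header=False)
        meta.to_csv(sc_dir / "metadata.tsv", sep="\t", index=False)
        paths["sc_dir"] = sc_dir

    make_truth(cfg).to_json(out_dir / "truth.json")
    paths["truth"] = out_dir / "truth.json"
    return paths


# ---------------------------------------------------------------------------
# Ready-made scenarios

def null_scenario(seed: int = 0, n_genes: int = 160, n_cancers: int = 5,
                  n_variants: int = 8, n_eqtl_vars: int = 6,
                  effect_size: float = 0.8, ld_rho: float = 0.3,
                  n_gwas: int = 20_000, with_sc: bool = False,
                  n_sc_genes: int = 150) -> SimConfig:
    """Global-null scenario: every gene has genuine cis-eQTLs (so instrument
    selection works as in a real study) but no gene affects any outcome and
    no gene is differentially expressed.  Used for type-I-error calibration
    of the MR suite and the DEG test."""
    rng = child_rng(seed, "null_scenario")
    genes, profiles = [], []
    for gi in range(n_genes):
        name = f"G{gi:03d}"
        start = 1_000_000 + gi * 2_000_000
        gs = GeneSpec(gene=name, chrom="1", start=start, end=start + 10_000,
                      n_variants=n_variants)
        prof = ExposureProfile(name, "TN", "0h")
        profiles.append(prof)
        idx = rng.choice(n_variants, size=min(n_eqtl_vars, n_variants),
                         replace=False)
        gs.eqtl_effects[prof.exposure_id] = {
            int(i): float(effect_size * rng.choice([-1, 1])) for i in idx
        }
        genes.append(gs)
    sc_params = {}
    if with_sc:
        for k in range(n_sc_genes):
            sc_params[f"S{k:03d}"] = ScGeneParams(baseline_mean=3.0,
                                                  dispersion=2.0, logfc=0.0,
                                                  expressed_fraction=0.9)
    return SimConfig(seed=seed, genes=genes, profiles=profiles,
                     causal_genes={f"cancer_{c}": {} for c in range(n_cancers)},
                     n_gwas=n_gwas, ld_rho=ld_rho, sc_params=sc_params)


def default_scenario(seed: int = 0, n_genes: int = 20, n_causal: int = 1,
                     cancers: Sequence[str] = ("breast_cancer",),
                     cell_types: Sequence[str] = ("TN", "TCM"),
                     time_points: Sequence[str] = ("0h", "16h"),
                     n_variants: int = 10, effect_size: float = 0.8,
                     causal_effect: float = 0.5, deg_logfc: float = 1.0,
                     n_gwas: int = 20_000) -> SimConfig:
    """Standard recovery scenario: ``n_causal`` causal genes among
    ``n_genes``, each gene with a handful of true cis-eQTLs strong enough to
    pass weak-instrument selection at 120 donors, causal genes also given a
    planted tumor-vs-normal logFC."""
    rng = child_rng(seed, "scenario_build")
    genes = []
    profiles = []
    sc_params = {}
    causal = [f"G{g:03d}" for g in range(n_causal)]
    for gi in range(n_genes):
        name = f"G{gi:03d}"
        start = 1_000_000 + gi * 2_000_000
        gs = GeneSpec(gene=name, chrom="1", start=start, end=start + 10_000,
                      n_variants=n_variants)
        n_eqtl_vars = max(4, n_variants // 2)
        causal_idx = rng.choice(n_variants, size=n_eqtl_vars, replace=False)
        # signs are a property of the gene's regulatory architecture; only
        # the magnitude varies across cell states (dynamic eQTL effects)
        signs = rng.choice([-1.0, 1.0], size=n_eqtl_vars)
        for ct in cell_types:
            for tp in time_points:
                prof = ExposureProfile(name, ct, tp)
                profiles.append(prof)
                scale = 1.0 if (ct, tp) == (cell_types[0], time_points[0]) else rng.uniform(0.6, 1.0)
                gs.eqtl_effects[prof.exposure_id] = {
                    int(i): float(effect_size * scale * s)
                    for i, s in zip(causal_idx, signs)
                }
        genes.append(gs)
        sc_params[name] = ScGeneParams(
            baseline_mean=3.0, dispersion=2.0,
            logfc=(deg_logfc if name in causal else 0.0),
            expressed_fraction=0.9,
        )
    causal_map = {c: {g: causal_effect for g in causal} for c in cancers}
    return SimConfig(seed=seed, genes=genes, profiles=profiles,
                     causal_genes=causal_map, sc_params=sc_params,
                     n_gwas=n_gwas)
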