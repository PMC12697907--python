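"""Cell-type, cancer-type and activation-time specificity analyses.

Which cell states and cancers concentrate the MR signal, whether effects
change along the T-cell activation course (0h → LA → 16h → 40h → 5d), and
whether associated genes are expressed T-cell-specifically.

Enrichment is Fisher's exact test of signals-vs-eGenes (or signals-vs-cases)
in one stratum against the rest, BH-corrected within each analysis family.
Temporal and naive-vs-memory contrasts are pairwise Z tests between MR
estimates, with the reference time point chosen as the one whose estimate
differs most, in total absolute difference, from all others.  T-cell
specificity is two-tier: expression ≥5× every other immune cell type is
*enriched*, ≥2× is *enhanced*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import bh_fdr

__all__ = [
    "EnrichmentRow",
    "TimeContrast",
    "cell_type_enrichment",
    "egene_signal_correlation",
    "cancer_enrichment",
    "time_dependence",
    "naive_memory_contrast",
    "t_cell_specificity",
]


@dataclass
class EnrichmentRow:
    stratum: str
    n_signals: int
    n_total: int           # eGenes (cell-type analysis) or scaled cases (cancer)
    odds_ratio: float
    p: float
    q: float = math.nan


@dataclass
class TimeContrast:
    gene: str
    cell_type: str
    cancer: str
    reference: str         # reference stratum (time point, or naive/memory)
    contrast: str
    z: float
    p: float
    significant: bool


def _fisher_stratum(sig_s: int, tot_s: int, sig_r: int, tot_r: int
                    ) -> tuple[float, float]:
    if sig_s > tot_s or sig_r > tot_r:
        raise ValueError("signals exceed totals: inconsistent counts")
    table = [[sig_s, tot_s - sig_s], [sig_r, tot_r - sig_r]]
    odds, p = sps.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def cell_type_enrichment(signals: Mapping[str, int], egenes: Mapping[str, int]
                         ) -> list[EnrichmentRow]:
    """Per-stratum Fisher enrichment of MR signals relative to eGene counts.

    Stratum = a cell-type × activation-time combination.  The 2×2 table is
    [signals_s, egenes_s − signals_s; signals_rest, egenes_rest −
    signals_rest], which tests whether the stratum converts its eGenes into
    MR signals more often than the remaining strata do.
    """
    strata = sorted(egenes)
    tot_sig = sum(signals.get(s, 0) for s in strata)
    tot_eg = sum(egenes[s] for s in strata)
    rows = []
    for s in strata:
        sig_s = signals.get(s, 0)
        odds, p = _fisher_stratum(sig_s, egenes[s], tot_sig - sig_s,
                                  tot_eg - egenes[s])
        rows.append(EnrichmentRow(stratum=s, n_signals=sig_s, n_total=egenes[s],
                                  odds_ratio=odds, p=p))
    qs = bh_fdr([max(r.p, 1e-300) for r in rows]) if rows else []
    for r, q in zip(rows, qs):
        r.q = float(q)
    return rows


def egene_signal_correlation(signals: Mapping[str, int], egenes: Mapping[str, int]
                             ) -> float:
    """Spearman correlation (average-rank ties) between per-stratum eGene
    and MR-signal counts; NaN when fewer than 3 strata or constant input."""
    strata = sorted(set(signals) | set(egenes))
    if len(strata) < 3:
        raise ValueError("need at least 3 strata")
    x = np.array([egenes.get(s, 0) for s in strata], dtype=float)
    y = np.array([signals.get(s, 0) for s in strata], dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan
    rho = sps.spearmanr(x, y).statistic
    return float(rho)


def cancer_enrichment(signals: Mapping[str, int], cases: Mapping[str, int],
                      cases_per_unit: int = 1000) -> list[EnrichmentRow]:
    """Per-cancer Fisher enrichment of MR signals normalized by GWAS power.

    Case counts are rescaled to a common unit (cases per ``cases_per_unit``)
    before forming the 2×2 table, balancing out the head start that
    better-powered GWASs have in producing signals.
    """
    cancers = sorted(cases)
    scaled = {c: max(int(round(cases[c] / cases_per_unit)), 1) for c in cancers}
    tot_sig = sum(signals.get(c, 0) for c in cancers)
    tot_cs = sum(scaled.values())
    rows = []
    for c in cancers:
        sig_c = signals.get(c, 0)
        odds, p = _fisher_stratum(sig_c, scaled[c], tot_sig - sig_c,
                                  tot_cs - scaled[c])
        rows.append(EnrichmentRow(stratum=c, n_signals=sig_c, n_total=scaled[c],
                                  odds_ratio=odds, p=p))
    qs = bh_fdr([max(r.p, 1e-300) for r in rows]) if rows else []
    for r, q in zip(rows, qs):
        r.q = float(q)
    return rows


def _pairwise_z(b1: float, se1: float, b2: float, se2: float) -> tuple[float, float]:
    z = (b1 - b2) / math.sqrt(se1 ** 2 + se2 ** 2)
    p = min(max(math.erfc(abs(z) / math.sqrt(2)), 1e-300), 1.0)
    return z, p


def time_dependence(estimates: pd.DataFrame, alpha: float = 0.05
                    ) -> list[TimeContrast]:
    """Pairwise Z contrasts of MR estimates across activation time points.

    ``estimates`` needs columns gene, cell_type, cancer, time_point, beta,
    se (one row per time point for a gene-cell-cancer triplet).  The
    reference time point maximizes the summed absolute difference to the
    others (ties broken by time-point label); one contrast per other time
    point; a triplet is time-dependent when any contrast has p < alpha.
    Triplets with a single time point are skipped.
    """
    out: list[TimeContrast] = []
    for (gene, ct, cancer), grp in estimates.groupby(["gene", "cell_type", "cancer"]):
        grp = grp.sort_values("time_point", kind="mergesort")
        if len(grp) < 2:
            continue
        b = grp["beta"].to_numpy()
        tp = grp["time_point"].tolist()
        sums = np.abs(b[:, None] - b[None, :]).sum(axis=1)
        ref = int(np.argmax(sums))
        for i in range(len(grp)):
            if i == ref:
                continue
            z, p = _pairwise_z(b[ref], grp["se"].iloc[ref], b[i], grp["se"].iloc[i])
            out.append(TimeContrast(gene=gene, cell_type=ct, cancer=cancer,
                                    reference=tp[ref], contrast=tp[i],
                                    z=z, p=p, significant=p < alpha))
    return out


#: naive vs memory CD4+ T-cell subset assignment
NAIVE_CELL_TYPES = {"TN", "CD4_naive", "TN_cycling", "TN_HSP", "TN_IFN",
                    "TN_LA", "TN_NFKB"}
MEMORY_CELL_TYPES = {"TCM", "TEM", "TEMRA", "CD4_memory", "TEM_HLA",
                     "TEM_LA", "TCM_LA", "TM_cycling"}


def naive_memory_contrast(estimates: pd.DataFrame, alpha: float = 0.05
                          ) -> list[TimeContrast]:
    """Pairwise Z contrast between naive and memory estimates of the same
    gene-cancer pair (same mechanics as :func:`time_dependence` with the
    two-stratum grouping naive/memory; cell types outside either set are
    ignored)."""
    df = estimates.copy()

    def compartment(ct: str) -> str | None:
        if ct in NAIVE_CELL_TYPES:
            return "naive"
        if ct in MEMORY_CELL_TYPES:
            return "memory"
        return None

    df["compartment"] = df["cell_type"].map(compartment)
    df = df[df["compartment"].notna()]
    out: list[TimeContrast] = []
    for (gene, cancer), grp in df.groupby(["gene", "cancer"]):
        by_comp = {c: g.loc[g["se"].idxmin()] for c, g in grp.groupby("compartment")}
        if len(by_comp) < 2:
            continue
        nv, mem = by_comp["naive"], by_comp["memory"]
        z, p = _pairwise_z(nv["beta"], nv["se"], mem["beta"], mem["se"])
        out.append(TimeContrast(gene=gene, cell_type="naive_vs_memory",
                                cancer=cancer, reference="naive",
                                contrast="memory", z=z, p=p,
                                significant=p < alpha))
    return out


def t_cell_specificity(reference: pd.DataFrame, *, comparator: str = "max"
                       ) -> pd.DataFrame:
    """Two-tier T-cell expression specificity labels per gene.

    ``reference`` is a gene × immune-cell-type mean-expression table (first
    column ``gene``); T-cell columns are those starting with ``T_`` (or
    named with a leading ``T``-cell marker).  The ratio compares the mean
    over T-cell columns to the max (default, conservative) or mean over
    non-T columns: ≥5 → ``enriched``, ≥2 → ``enhanced``, else ``none``.
    A zero denominator yields ``enriched`` when the numerator is positive
    and ``none`` otherwise.
    """
    cols = [c for c in reference.columns if c != "gene"]
    t_cols = [c for c in cols if c.startswith("T_") or c.startswith("T ")]
    other = [c for c in cols if c not in t_cols]
    if not t_cols or not other:
        raise ValueError("need at least one T-cell and one non-T cell-type column")
    t_mean = reference[t_cols].to_numpy(float).mean(axis=1)
    other_vals = reference[other].to_numpy(float)
    denom = (other_vals.max(axis=1) if comparator == "max"
             else other_vals.mean(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(denom == 0,
                         np.where(t_mean > 0, np.inf, 0.0),
                         t_mean / np.where(denom == 0, 1.0, denom))
    label = np.where(ratio >= 5, "enriched",
                     np.where(ratio >= 2, "enhanced", "none"))
    return pd.DataFrame({"gene": reference["gene"], "t_cell_mean": t_mean,
                         "comparator_value": denom, "ratio": ratio,
                         "label": label})
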