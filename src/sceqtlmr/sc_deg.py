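"""Single-cell QC, normalization and tumor-vs-normal differential
expression for T cells, plus the MR-direction concordance check.

QC removes cells with ≤ 200 detected features or > 5% mitochondrial reads.
Normalization is per-cell library-size scaling to 10 000 counts followed by
log1p.  Differential expression is a two-sided Wilcoxon rank-sum test of
tumor vs normal cells on the normalized values, restricted to genes
detected in ≥ min.pct of either group, with the log2 fold change computed
on the de-logged scale with pseudocount 1 and a |logFC| reporting floor.
Batch structure is handled by running the test within each batch and
combining with Stouffer's method weighted by √cells (or ignored entirely,
by flag) — a rank test cannot take a covariate directly.

A DEG "supports" an MR signal when its p < 0.05 and its fold-change
direction matches the sign of the MR effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import bh_fdr
from .mr_methods import MREstimate

__all__ = [
    "CellMatrix",
    "DegResult",
    "qc_filter",
    "normalize",
    "wilcoxon_deg",
    "deg_support",
]

QC_MIN_FEATURES = 200      # cells with n_features <= 200 are removed
QC_MAX_MITO_PCT = 5.0      # cells with mito percentage > 5 are removed
TARGET_LIBRARY_SIZE = 1e4


@dataclass
class CellMatrix:
    """Dense cells × genes matrix with per-cell metadata.

    ``counts`` holds raw non-negative integers (or normalized floats after
    :func:`normalize`); metadata must carry ``status`` (tumor|normal),
    ``batch``, ``cell_type``, ``n_features`` and ``mito_fraction`` (percent).
    """

    counts: np.ndarray
    meta: pd.DataFrame
    genes: list[str]
    normalized: bool = False
    qc_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be cells × genes")
        if len(self.meta) != self.counts.shape[0]:
            raise ValueError("metadata rows must match matrix rows")
        if len(self.genes) != self.counts.shape[1]:
            raise ValueError("gene names must match matrix columns")
        if not self.normalized:
            if np.any(self.counts < 0):
                raise ValueError("counts must be non-negative")
            if not np.issubdtype(self.counts.dtype, np.integer):
                if not np.allclose(self.counts, np.round(self.counts)):
                    raise ValueError("raw counts must be integers")
                self.counts = self.counts.astype(np.int64)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    def subset_cells(self, mask: np.ndarray) -> "CellMatrix":
        return CellMatrix(self.counts[mask], self.meta.loc[mask].reset_index(drop=True),
                          list(self.genes), normalized=self.normalized,
                          qc_log=dict(self.qc_log))

    @classmethod
    def from_mtx(cls, mtx_path: str | Path, genes_path: str | Path,
                 meta_path: str | Path) -> "CellMatrix":
        from scipy.io import mmread
        counts = np.asarray(mmread(mtx_path).todense())
        genes = pd.read_csv(genes_path, sep="\t", header=None)[0].tolist()
        meta = pd.read_csv(meta_path, sep="\t")
        return cls(counts.astype(np.int64), meta, genes)


@dataclass
class DegResult:
    gene: str
    logfc: float
    p: float
    q: float
    pct_tumor: float
    pct_normal: float

    def __post_init__(self) -> None:
        if not (0 <= self.pct_tumor <= 1 and 0 <= self.pct_normal <= 1):
            raise ValueError("expressed fractions must be in [0, 1]")


def qc_filter(m: CellMatrix, min_features: int = QC_MIN_FEATURES,
              max_mito_pct: float = QC_MAX_MITO_PCT) -> CellMatrix:
    """Remove low-quality cells: n_features ≤ 200 (inclusive) or
    mitochondrial percentage > 5 (strict)."""
    for col in ("n_features", "mito_fraction"):
        if col not in m.meta.columns:
            raise ValueError(f"metadata missing required column {col!r}")
    feat = m.meta["n_features"].to_numpy()
    mito = m.meta["mito_fraction"].to_numpy()
    keep = (feat > min_features) & (mito <= max_mito_pct)
    if not keep.any():
        raise ValueError("QC removed every cell")
    out = m.subset_cells(keep)
    out.qc_log = {"removed_low_features": int((feat <= min_features).sum()),
                  "removed_high_mito": int((mito > max_mito_pct).sum()),
                  "kept": int(keep.sum())}
    return out


def normalize(m: CellMatrix) -> CellMatrix:
    """Library-size normalization: scale each cell to 10 000 total counts,
    then log1p.  Zero-count cells are removed with a note in the QC log."""
    totals = m.counts.sum(axis=1).astype(float)
    nonzero = totals > 0
    removed = int((~nonzero).sum())
    counts = m.counts[nonzero].astype(float)
    meta = m.meta.loc[nonzero].reset_index(drop=True)
    norm = np.log1p(counts / counts.sum(axis=1, keepdims=True) * TARGET_LIBRARY_SIZE)
    out = CellMatrix(norm, meta, list(m.genes), normalized=True,
                     qc_log=dict(m.qc_log))
    if removed:
        out.qc_log["removed_zero_count"] = removed
    return out


def _log2fc(tumor_norm: np.ndarray, normal_norm: np.ndarray) -> float:
    # fold change on the de-logged scale with pseudocount 1
    mt = np.expm1(tumor_norm).mean() + 1.0
    mn = np.expm1(normal_norm).mean() + 1.0
    return float(np.log2(mt / mn))


def _stouffer(ps: Sequence[float], signs: Sequence[float],
              weights: Sequence[float]) -> tuple[float, float]:
    """Combine two-sided p-values with direction via weighted Stouffer."""
    z = np.array([sps.norm.isf(max(p, 1e-300) / 2) * (1 if s >= 0 else -1)
                  for p, s in zip(ps, signs)])
    w = np.asarray(weights, dtype=float)
    zc = float(np.sum(w * z) / math.sqrt(np.sum(w ** 2)))
    p = float(min(max(2 * sps.norm.sf(abs(zc)), 1e-300), 1.0))
    return zc, p


def wilcoxon_deg(m: CellMatrix, min_pct: float = 0.1, logfc_floor: float = 0.25,
                 batch_mode: str = "stouffer") -> list[DegResult]:
    """Tumor-vs-normal Wilcoxon rank-sum DEG on normalized values.

    Genes detected in ≥ ``min_pct`` of either group are tested; results
    with |log2FC| below ``logfc_floor`` are suppressed.  ``batch_mode`` is
    ``'stouffer'`` (per-batch tests combined with √cells weights; batches
    lacking both groups are skipped) or ``'none'``.  BH correction within
    the tested gene set.
    """
    if not m.normalized:
        raise ValueError("wilcoxon_deg expects a normalized matrix (run normalize)")
    status = m.meta["status"].to_numpy()
    tumor = status == "tumor"
    normal = status == "normal"
    if tumor.sum() < 3 or normal.sum() < 3:
        raise ValueError("each group needs at least 3 cells")

    X = m.counts
    pct_t = (X[tumor] > 0).mean(axis=0)
    pct_n = (X[normal] > 0).mean(axis=0)
    testable = (pct_t >= min_pct) | (pct_n >= min_pct)

    results: list[tuple[str, float, float, float, float]] = []
    batches = m.meta["batch"].to_numpy() if "batch" in m.meta.columns else None
    for j in np.where(testable)[0]:
        xt_all, xn_all = X[tumor, j], X[normal, j]
        lfc = _log2fc(xt_all, xn_all)
        if batch_mode == "none" or batches is None:
            p = _mwu_p(xt_all, xn_all)
        elif batch_mode == "stouffer":
            ps, signs, ws = [], [], []
            for b in np.unique(batches):
                bt = tumor & (batches == b)
                bn = normal & (batches == b)
                if bt.sum() < 3 or bn.sum() < 3:
                    continue
                ps.append(_mwu_p(X[bt, j], X[bn, j]))
                signs.append(_log2fc(X[bt, j], X[bn, j]))
                ws.append(math.sqrt(bt.sum() + bn.sum()))
            if ps:
                _, p = _stouffer(ps, signs, ws)
            else:
                p = _mwu_p(xt_all, xn_all)
        else:
            raise ValueError(f"unknown batch_mode {batch_mode!r}")
        results.append((m.genes[j], lfc, p, float(pct_t[j]), float(pct_n[j])))

    if not results:
        return []
    qs = bh_fdr([max(r[2], 1e-300) for r in results])
    out = [DegResult(gene=g, logfc=l, p=p, q=float(q), pct_tumor=pt, pct_normal=pn)
           for (g, l, p, pt, pn), q in zip(results, qs)]
    return [r for r in out if abs(r.logfc) >= logfc_floor]


def _mwu_p(x: np.ndarray, y: np.ndarray) -> float:
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return 1.0
    return float(sps.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def deg_results_to_frame(results: Sequence[DegResult]) -> pd.DataFrame:
    return pd.DataFrame([{"gene": r.gene, "logFC": r.logfc, "p": r.p, "q": r.q,
                          "pct_tumor": r.pct_tumor, "pct_normal": r.pct_normal}
                         for r in results],
                        columns=["gene", "logFC", "p", "q", "pct_tumor", "pct_normal"])


def deg_support(deg: DegResult, mr: MREstimate, p_threshold: float = 0.05) -> bool:
    """True iff the DEG is significant (p < 0.05) and its fold change has
    the same sign as the MR effect; zero logFC or beta never supports."""
    if deg.p >= p_threshold:
        return False
    if deg.logfc == 0 or mr.beta == 0:
        return False
    return (deg.logfc > 0) == (mr.beta > 0)
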