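"""Core-gene detection on a PPI network, the six-component evidence score,
and the clinical-trial annotation join.

Maximal clique centrality (MCC) scores a node by Σ over the maximal cliques
containing it of (|C|−1)!, so membership in one large clique outweighs many
small ones; genes with MCC ≥ 9 are core genes (a triangle gives 2, K4 gives
6, K5 gives 24 — the floor requires at least a 4-clique plus extra
structure, or a 5-clique).  An isolated node scores 1 (singleton clique,
0! = 1).

Each gene-cancer pair is then scored over six evidence components:
DEG validation (+1), MR-DEG likely-causal (+1), T-cell-specific expression
(+0.5), time-point-specific effect (+0.5), core gene (+1) and clinical-trial
drug-target evidence (+1); total 5, prioritized when ≥ 4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

__all__ = [
    "ScoreCard",
    "build_ppi_graph",
    "mcc",
    "core_genes",
    "score",
    "annotate_trials",
    "MCC_CORE_THRESHOLD",
    "PRIORITIZE_THRESHOLD",
]

MCC_CORE_THRESHOLD = 9.0
PRIORITIZE_THRESHOLD = 4.0

#: component weights of the evidence score
SCORE_WEIGHTS = {
    "deg_validated": 1.0,
    "mrdeg_causal": 1.0,
    "t_cell_specific": 0.5,
    "time_specific": 0.5,
    "core_gene": 1.0,
    "clinical_trial": 1.0,
}


@dataclass
class ScoreCard:
    gene: str
    cancer: str
    deg_validated: bool = False
    mrdeg_causal: bool = False
    t_cell_specific: bool = False
    time_specific: bool = False
    core_gene: bool = False
    clinical_trial: bool = False

    @property
    def total(self) -> float:
        return sum(w for comp, w in SCORE_WEIGHTS.items() if getattr(self, comp))

    @property
    def prioritized(self) -> bool:
        return self.total >= PRIORITIZE_THRESHOLD

    def as_dict(self) -> dict:
        d = {"gene": self.gene, "cancer": self.cancer}
        d.update({c: getattr(self, c) for c in SCORE_WEIGHTS})
        d["total"] = self.total
        d["prioritized"] = self.prioritized
        return d


def build_ppi_graph(edges: pd.DataFrame, min_confidence: float = 0.4) -> nx.Graph:
    """Simple undirected PPI graph from a (gene_a, gene_b[, confidence])
    edge table; self-loops dropped, edges below the confidence floor
    skipped."""
    g = nx.Graph()
    has_conf = "confidence" in edges.columns
    for row in edges.itertuples(index=False):
        a, b = str(row.gene_a), str(row.gene_b)
        if a == b:
            continue
        conf = float(row.confidence) if has_conf else 1.0
        if conf < min_confidence:
            continue
        g.add_edge(a, b, confidence=conf)
    return g


def mcc(graph: nx.Graph) -> dict[str, float]:
    """Maximal clique centrality: MCC(v) = Σ over maximal cliques C ∋ v of
    (|C|−1)!.  Maximal cliques come from Bron–Kerbosch with pivoting; an
    isolated node scores 1."""
    out = {v: 0.0 for v in graph.nodes}
    for clique in nx.find_cliques(graph):
        contrib = math.factorial(len(clique) - 1)
        for v in clique:
            out[v] += contrib
    for v in graph.nodes:
        if graph.degree(v) == 0:
            out[v] = 1.0
    return out


def core_genes(graph: nx.Graph, threshold: float = MCC_CORE_THRESHOLD,
               universe: Iterable[str] | None = None) -> set[str]:
    """Genes with MCC ≥ threshold, restricted to the cancer-linked
    ``universe`` when given."""
    scores = mcc(graph)
    core = {g for g, v in scores.items() if v >= threshold}
    if universe is not None:
        core &= set(universe)
    return core


def score(gene: str, cancer: str, components: Mapping[str, bool]) -> ScoreCard:
    """Build a ScoreCard from resolved component flags (missing → False);
    unknown component names are rejected."""
    unknown = set(components) - set(SCORE_WEIGHTS)
    if unknown:
        raise ValueError(f"unknown score component(s): {sorted(unknown)}")
    return ScoreCard(gene=gene, cancer=cancer,
                     **{c: bool(components.get(c, False)) for c in SCORE_WEIGHTS})


def annotate_trials(genes: Iterable[str], trials: pd.DataFrame,
                    cancer_vocab: Mapping[str, str] | None = None,
                    cancer: str | None = None) -> pd.DataFrame:
    """Left-join genes against a drug-target trial table (case-insensitive
    on gene symbol).

    Returns one row per gene with ``clinical_trial`` (any matching drug row)
    and ``indication_match`` (some matched row's indication maps, through
    the controlled vocabulary, to the queried ``cancer``).  Malformed trial
    rows (missing gene or drug) are dropped and counted in
    ``annotate_trials.last_dropped``.
    """
    required = {"gene", "drug", "indication"}
    if not required <= set(trials.columns):
        raise ValueError(f"trial table must have columns {sorted(required)}")
    clean = trials.dropna(subset=["gene", "drug"])
    annotate_trials.last_dropped = len(trials) - len(clean)
    by_gene: dict[str, list] = {}
    for row in clean.itertuples(index=False):
        by_gene.setdefault(str(row.gene).upper(), []).append(row)
    vocab = {k.lower(): v for k, v in (cancer_vocab or {}).items()}
    rows = []
    for g in genes:
        matches = by_gene.get(str(g).upper(), [])
        indication_match = False
        if cancer is not None:
            for m in matches:
                mapped = vocab.get(str(m.indication).lower(),
                                   str(m.indication).lower().replace(" ", "_"))
                if mapped == cancer:
                    indication_match = True
                    break
        rows.append({"gene": g, "clinical_trial": bool(matches),
                     "n_drugs": len({m.drug for m in matches}),
                     "indication_match": indication_match})
    return pd.DataFrame(rows)
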