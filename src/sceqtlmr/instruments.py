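"""Genetic-instrument selection and validation.

Two selection pipelines over harmonized cis-eQTL/outcome statistics:

* **strong** — F ≥ 10, Steiger-pass, cis (gene ± 500 kb), LD clumping at
  r² < 0.001 (near-independence, collinearity-safe);
* **weak** — association p < 0.05, F ≥ 5, Steiger-pass, cis, clumping at
  r² < 0.1.  The relaxed thresholds recover instruments that single-cell
  eQTL sample sizes cannot push past the conventional F = 10 bar; the
  resulting weak-instrument bias is then handled by the estimators in
  :mod:`sceqtlmr.mr_methods`.

Steiger filtering keeps only variants that explain more variance in the
exposure than in the outcome (directionality: expression → disease, not the
reverse).  For case-control outcomes the variance explained uses the
effective sample size 4/(1/n_cases + 1/n_controls).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .core_io import AssocStat, HarmonizedPair, LDPanel

__all__ = [
    "InstrumentRecord",
    "InstrumentSet",
    "f_statistic",
    "steiger_filter",
    "ld_clump",
    "select_strong",
    "select_weak",
    "proxy_lookup",
    "CIS_WINDOW",
    "STRONG",
    "WEAK",
]

#: cis window around the gene body, 1-based closed interval, both sides.
CIS_WINDOW = 500_000


@dataclass(frozen=True)
class SelectionThresholds:
    mode: str
    f_min: float
    p_max: float
    clump_r2: float


STRONG = SelectionThresholds(mode="strong", f_min=10.0, p_max=1.0, clump_r2=0.001)
WEAK = SelectionThresholds(mode="weak", f_min=5.0, p_max=0.05, clump_r2=0.1)


@dataclass
class InstrumentRecord:
    """One validated instrument with its strength and directionality metrics."""

    stat: AssocStat
    f_stat: float
    r2_exposure: float
    r2_outcome: float
    steiger_pass: bool
    cis_pass: bool

    @property
    def variant_id(self) -> str:
        return self.stat.variant_id


@dataclass
class InstrumentSet:
    exposure_id: str
    mode: str
    instruments: list[InstrumentRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.instruments)

    @property
    def variant_ids(self) -> list[str]:
        return [r.variant_id for r in self.instruments]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.instruments:
            rows.append({
                "exposure_id": self.exposure_id, "mode": self.mode,
                "variant_id": r.variant_id, "beta": r.stat.beta,
                "se": r.stat.se, "p": r.stat.p, "eaf": r.stat.eaf,
                "f_stat": r.f_stat, "r2_exposure": r.r2_exposure,
                "r2_outcome": r.r2_outcome, "steiger_pass": r.steiger_pass,
                "cis_pass": r.cis_pass,
            })
        return pd.DataFrame(rows)


def f_statistic(stat: AssocStat, *, formula: str = "z2") -> float:
    """Single-variant instrument-strength F-statistic.

    Default is the squared z-score (beta/se)²; ``formula='r2'`` uses the
    variance-explained form r²(n−2)/(1−r²), which agrees with z² to within
    a factor n/(n−2) — identical in the large-n limit.
    """
    z2 = (stat.beta / stat.se) ** 2
    if formula == "z2":
        return float(z2)
    if formula == "r2":
        if stat.n is None:
            raise ValueError("n required for the r2-based F-statistic")
        r2 = z2 / (z2 + stat.n)
        return float(r2 * (stat.n - 2) / (1 - r2))
    raise ValueError(f"unknown F-statistic formula {formula!r}")


def _effective_n(stat: AssocStat) -> float:
    if stat.n_cases is not None and stat.n_controls is not None:
        return 4.0 / (1.0 / stat.n_cases + 1.0 / stat.n_controls)
    if stat.n is None:
        raise ValueError(f"{stat.variant_id}: sample size required for Steiger")
    return float(stat.n)


def steiger_filter(exposure_stat: AssocStat, outcome_stat: AssocStat
                   ) -> tuple[float, float, bool]:
    """Directionality check: variance explained in exposure vs outcome.

    r² = z²/(z² + n) for each trait (effective n for case-control outcomes);
    the variant passes when it explains strictly more variance in the
    exposure (ties fail).
    """
    zx2 = (exposure_stat.beta / exposure_stat.se) ** 2
    zy2 = (outcome_stat.beta / outcome_stat.se) ** 2
    nx = _effective_n(exposure_stat)
    ny = _effective_n(outcome_stat)
    r2_exposure = zx2 / (zx2 + nx)
    r2_outcome = zy2 / (zy2 + ny)
    return float(r2_exposure), float(r2_outcome), bool(r2_exposure > r2_outcome)


def ld_clump(stats: Sequence[AssocStat], panel: LDPanel, r2_threshold: float,
             *, missing: str = "drop") -> list[AssocStat]:
    """Greedy p-value-ordered LD clumping.

    Keep the best-p variant, discard everything with panel r² ≥ threshold
    against any kept variant, repeat.  Ties broken by (p, variant_id) for
    determinism.  Variants absent from the panel are dropped with a warning
    (``missing='error'`` raises instead).
    """
    pool = []
    for s in stats:
        if s.variant_id not in panel:
            if missing == "error":
                raise KeyError(f"variant {s.variant_id} not in LD panel")
            warnings.warn(f"variant {s.variant_id} absent from LD panel; dropped")
            continue
        pool.append(s)
    pool.sort(key=lambda s: (s.p, s.variant_id))
    kept: list[AssocStat] = []
    for s in pool:
        if all(panel.r2(s.variant_id, k.variant_id) < r2_threshold for k in kept):
            kept.append(s)
    return kept


def _cis_pass(stat: AssocStat, gene_row) -> bool:
    if str(stat.chrom) != str(gene_row["chrom"]):
        return False
    return (gene_row["start"] - CIS_WINDOW) <= stat.pos <= (gene_row["end"] + CIS_WINDOW)


def _select(pair: HarmonizedPair, panel: LDPanel, gene_row, exposure_id: str,
            thresholds: SelectionThresholds) -> InstrumentSet:
    records: dict[str, InstrumentRecord] = {}
    candidates: list[AssocStat] = []
    for e, o in zip(pair.exposure_stats, pair.outcome_stats):
        cis = _cis_pass(e, gene_row)
        f = f_statistic(e)
        r2x, r2y, steiger = steiger_filter(e, o)
        rec = InstrumentRecord(stat=e, f_stat=f, r2_exposure=r2x,
                               r2_outcome=r2y, steiger_pass=steiger, cis_pass=cis)
        if cis and f >= thresholds.f_min and e.p < thresholds.p_max and steiger:
            records[e.variant_id] = rec
            candidates.append(e)
    clumped = ld_clump(candidates, panel, thresholds.clump_r2)
    return InstrumentSet(
        exposure_id=exposure_id, mode=thresholds.mode,
        instruments=[records[s.variant_id] for s in clumped],
    )


def select_strong(pair: HarmonizedPair, panel: LDPanel, gene_row,
                  exposure_id: str) -> InstrumentSet:
    """Strong pipeline: cis, F ≥ 10, Steiger-pass, clump at r² < 0.001."""
    return _select(pair, panel, gene_row, exposure_id, STRONG)


def select_weak(pair: HarmonizedPair, panel: LDPanel, gene_row,
                exposure_id: str) -> InstrumentSet:
    """Weak pipeline: cis, p < 0.05, F ≥ 5, Steiger-pass, clump at r² < 0.1."""
    return _select(pair, panel, gene_row, exposure_id, WEAK)


def proxy_lookup(variant: str, panel: LDPanel, outcome_stats: Sequence[AssocStat],
                 r2_min: float = 0.9) -> str | None:
    """Best-LD proxy for an instrument missing from the outcome data.

    Returns the outcome variant with the highest panel r² > ``r2_min``
    (ties broken by smaller outcome p), or None when no variant qualifies.
    Used only on the sensitivity path.
    """
    best: tuple[float, float, str] | None = None
    for o in outcome_stats:
        if o.variant_id == variant or o.variant_id not in panel:
            continue
        try:
            r2 = panel.r2(variant, o.variant_id)
        except ValueError:
            continue
        if r2 > r2_min:
            key = (-r2, o.p, o.variant_id)
            if best is None or key < best:
                best = key
    return best[2] if best else None
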