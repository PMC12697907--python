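"""Colocalization of eQTL and cancer-GWAS signals in a cis region.

Distinguishes a shared causal variant (true pleiotropy of the region) from
two distinct causal variants in LD (confounding by linkage).  The model is
the single-causal-variant approximate-Bayes-factor framework: per-variant
Wakefield log-ABFs for each trait are combined over the five hypotheses

  H0 no association, H1/H2 one trait only, H3 two distinct causal
  variants, H4 one shared causal variant,

with priors p1 = p2 = 1e-4 (variant associated with one trait) and
p12 = 1e-5 (both traits).  The primary decision rule is the conditional
form PP.H4/(PP.H3 + PP.H4) > 0.70; the plain PP.H4 > 0.70 rule is available
by flag.  The cheap LD-check approximation — max r² > 0.7 between the eQTL
and any sub-threshold (p < 1e-3) outcome variant in the region — is
reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .core_io import AssocStat, LDPanel

__all__ = [
    "ColocPriors",
    "ColocResult",
    "wakefield_abf",
    "coloc_abf",
    "ld_check",
    "coloc_evidence",
]

#: prior effect variance W of the Wakefield ABF, by trait type
_W_QUANT = 0.15 ** 2
_W_CC = 0.2 ** 2


@dataclass(frozen=True)
class ColocPriors:
    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p12"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1)")
        if self.p12 > min(self.p1, self.p2):
            raise ValueError("p12 must not exceed min(p1, p2)")


@dataclass
class ColocResult:
    pp_h0: float
    pp_h1: float
    pp_h2: float
    pp_h3: float
    pp_h4: float
    n_variants: int
    decision: bool
    rule: str
    ld_check_max_r2: float = math.nan
    ld_check_pass: bool = False

    @property
    def ratio(self) -> float:
        s = self.pp_h3 + self.pp_h4
        return self.pp_h4 / s if s > 0 else math.nan

    def posteriors(self) -> np.ndarray:
        return np.array([self.pp_h0, self.pp_h1, self.pp_h2, self.pp_h3, self.pp_h4])


def wakefield_abf(stat: AssocStat, trait_type: str = "quantitative") -> float:
    """Wakefield log approximate Bayes factor for one variant.

    With V = se², z = beta/se and prior effect variance W (0.15² for a
    quantitative trait, 0.2² for case-control):
    lABF = log√(V/(V+W)) + z²·r/2 with shrinkage r = W/(V+W).
    """
    if trait_type in ("quantitative", "quant"):
        W = _W_QUANT
    elif trait_type in ("case-control", "cc"):
        W = _W_CC
    else:
        raise ValueError(f"unknown trait_type {trait_type!r}")
    V = stat.se ** 2
    z = stat.beta / stat.se
    r = W / (W + V)
    return 0.5 * (math.log(V / (V + W)) + z * z * r)


def coloc_abf(exposure_stats: Sequence[AssocStat], outcome_stats: Sequence[AssocStat],
              priors: ColocPriors = ColocPriors(), *,
              rule: str = "conditional", threshold: float = 0.70) -> ColocResult:
    """Single-causal-variant colocalization over the shared variants.

    Sums per-configuration evidence in the log domain: H1 ∝ p1·Σ e^{lABF1},
    H2 ∝ p2·Σ e^{lABF2}, H3 ∝ p1·p2·(ΣΣ − Σ_same), H4 ∝ p12·Σ e^{lABF1+lABF2}.
    With a single shared variant H3 has no admissible configuration and its
    posterior is exactly 0.
    """
    out_by_id = {s.variant_id: s for s in outcome_stats}
    shared = [(e, out_by_id[e.variant_id]) for e in exposure_stats
              if e.variant_id in out_by_id]
    if not shared:
        raise ValueError("no overlapping variants between traits")
    l1 = np.array([wakefield_abf(e, "quantitative") for e, _ in shared])
    l2 = np.array([wakefield_abf(o, "case-control" if o.n_cases is not None
                                 else "quantitative") for _, o in shared])
    n = len(shared)

    lh0 = 0.0
    lh1 = math.log(priors.p1) + logsumexp(l1)
    lh2 = math.log(priors.p2) + logsumexp(l2)
    lsum_both = logsumexp(l1[:, None] + l2[None, :])          # all (i, j)
    lsum_same = logsumexp(l1 + l2)                            # i == j
    if n == 1:
        lh3 = -math.inf
    else:
        # log(sum_{i != j}) = log(sum_all - sum_same), stable form
        diff = 1.0 - math.exp(lsum_same - lsum_both)
        lh3 = (math.log(priors.p1) + math.log(priors.p2)
               + lsum_both + math.log(max(diff, 1e-300)))
    lh4 = math.log(priors.p12) + lsum_same

    lall = np.array([lh0, lh1, lh2, lh3, lh4])
    post = np.exp(lall - logsumexp(lall))
    post /= post.sum()

    pp_h3, pp_h4 = float(post[3]), float(post[4])
    if rule == "conditional":
        s = pp_h3 + pp_h4
        decision = s > 0 and (pp_h4 / s) > threshold
    elif rule == "plain":
        decision = pp_h4 > threshold
    else:
        raise ValueError(f"unknown decision rule {rule!r}")
    return ColocResult(pp_h0=float(post[0]), pp_h1=float(post[1]),
                       pp_h2=float(post[2]), pp_h3=pp_h3, pp_h4=pp_h4,
                       n_variants=n, decision=bool(decision), rule=rule)


def ld_check(eqtl: str, outcome_stats: Sequence[AssocStat], panel: LDPanel,
             *, p_threshold: float = 1e-3, r2_threshold: float = 0.7
             ) -> tuple[float, bool]:
    """Approximate colocalization: max panel r² between the instrument and
    any outcome variant with p < 1e-3 in the region; pass when > 0.7.
    Returns (max_r2, pass); max_r2 = 0 when no outcome variant is
    sub-threshold."""
    if eqtl not in panel:
        raise KeyError(f"eQTL {eqtl} not in LD panel")
    if panel.column(eqtl).std() == 0:
        raise ValueError(f"undefined LD: {eqtl} monomorphic in panel")
    candidates = [s.variant_id for s in outcome_stats
                  if s.p < p_threshold and s.variant_id in panel]
    if not candidates:
        return 0.0, False
    max_r2 = 0.0
    for v in candidates:
        if v == eqtl:
            r2 = 1.0
        else:
            try:
                r2 = panel.r2(eqtl, v)
            except ValueError:
                continue
        max_r2 = max(max_r2, r2)
    return float(max_r2), bool(max_r2 > r2_threshold)


def coloc_evidence(result: ColocResult) -> bool:
    """Overall sensitivity verdict: formal colocalization decision OR the
    LD-check approximation."""
    return bool(result.decision or result.ld_check_pass)
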