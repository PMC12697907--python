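"""MR-DEG: pleiotropy attenuation by differential-expression triangulation.

A cis instrument that is associated with several expression profiles cannot,
by MR alone, say which gene drives the outcome.  DEG analysis measures each
candidate gene's tumor-vs-normal association through an entirely independent
data source, so it can adjudicate: if the focal gene is differentially
expressed in the right direction but none of the competing genes sharing
its instruments is, the pleiotropy is considered attenuated and the focal
signal likely causal.

Classification per MR signal (which must itself have DEG support):

* ``likely_causal_single`` — no competing exposure shares any instrument
  (at association p < 1e-4);
* ``likely_causal_mrdeg`` — competitors exist but none has DEG support for
  the same cancer;
* ``pleiotropy_unresolved`` — some competitor is also DEG-supported;
* ``no_deg_support`` — the focal signal lacks DEG support and is never
  classified causal here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .core_io import AssocStat, ExposureProfile
from .instruments import InstrumentSet

__all__ = [
    "PleiotropyMap",
    "MrDegVerdict",
    "build_pleiotropy_map",
    "classify",
    "attenuation_summary",
    "PLEIOTROPY_P",
]

PLEIOTROPY_P = 1e-4


@dataclass
class PleiotropyMap:
    """variant_id → set of exposure_ids the variant is associated with
    (association p below the cutoff).  Every instrument maps at least to
    its own exposure."""

    mapping: dict[str, set[str]] = field(default_factory=dict)
    pleiotropy_p: float = PLEIOTROPY_P

    def exposures_of(self, variant_id: str) -> set[str]:
        return self.mapping.get(variant_id, set())

    def mean_out_degree(self) -> float:
        if not self.mapping:
            return float("nan")
        return sum(len(v) for v in self.mapping.values()) / len(self.mapping)


@dataclass
class MrDegVerdict:
    exposure_id: str
    outcome: str
    verdict: str
    competing_exposures: list[str] = field(default_factory=list)
    deg_supported_competitors: list[str] = field(default_factory=list)
    unmeasured_competitors: list[str] = field(default_factory=list)


def build_pleiotropy_map(instrument_sets: Sequence[InstrumentSet],
                         eqtl_stats: Mapping[str, Sequence[AssocStat]],
                         pleiotropy_p: float = PLEIOTROPY_P) -> PleiotropyMap:
    """Scan every instrument against every exposure's summary statistics.

    An instrument maps to each exposure in which its association p-value is
    below the cutoff, and always to its own exposure.
    """
    instruments: dict[str, set[str]] = {}
    for s in instrument_sets:
        for rec in s.instruments:
            instruments.setdefault(rec.variant_id, set()).add(s.exposure_id)
    by_exposure = {
        eid: {st.variant_id: st.p for st in stats}
        for eid, stats in eqtl_stats.items()
    }
    mapping: dict[str, set[str]] = {}
    for vid, own in instruments.items():
        hits = set(own)
        for eid, pmap in by_exposure.items():
            p = pmap.get(vid)
            if p is not None and p < pleiotropy_p:
                hits.add(eid)
        mapping[vid] = hits
    return PleiotropyMap(mapping, pleiotropy_p)


def classify(exposure_id: str, outcome: str, instrument_variants: Sequence[str],
             pmap: PleiotropyMap, deg_supported_genes: Mapping[str, set[str]],
             measured_genes: set[str] | None = None, *,
             focal_deg_supported: bool = True, strict_missing: bool = False
             ) -> MrDegVerdict:
    """Classify one MR signal under the MR-DEG rule.

    ``deg_supported_genes`` maps each cancer to the set of genes whose DEG
    evidence supports an effect on it.  ``measured_genes`` is the set of
    genes present in the single-cell panel; competitors absent from it count
    as unsupported-but-flagged (default) or force ``pleiotropy_unresolved``
    in strict mode — absence of a measurement is not evidence of absence.
    """
    focal_gene = ExposureProfile.from_id(exposure_id).gene
    for v in instrument_variants:
        if v not in pmap.mapping:
            raise KeyError(f"instrument {v} absent from pleiotropy map "
                           "(instruments not scanned)")
    if not focal_deg_supported:
        return MrDegVerdict(exposure_id, outcome, "no_deg_support")

    hit: set[str] = set()
    for v in instrument_variants:
        hit |= pmap.exposures_of(v)
    # competition is at gene level: other profiles of the focal gene do not
    # count as competing genes
    competitors = {c for c in hit
                   if ExposureProfile.from_id(c).gene != focal_gene}
    competitor_genes = sorted({ExposureProfile.from_id(c).gene for c in competitors})
    if not competitor_genes:
        return MrDegVerdict(exposure_id, outcome, "likely_causal_single")

    supported = deg_supported_genes.get(outcome, set())
    deg_competitors = sorted(g for g in competitor_genes if g in supported)
    unmeasured = (sorted(g for g in competitor_genes if g not in measured_genes)
                  if measured_genes is not None else [])
    if deg_competitors:
        verdict = "pleiotropy_unresolved"
    elif strict_missing and unmeasured:
        verdict = "pleiotropy_unresolved"
    else:
        verdict = "likely_causal_mrdeg"
    return MrDegVerdict(exposure_id, outcome, verdict,
                        competing_exposures=sorted(competitors),
                        deg_supported_competitors=deg_competitors,
                        unmeasured_competitors=unmeasured)


def attenuation_summary(verdicts: Sequence[MrDegVerdict]) -> pd.DataFrame:
    """Counts and fractions per verdict class, per cancer.

    ``attenuated_fraction`` = likely_causal_mrdeg / (likely_causal_mrdeg +
    pleiotropy_unresolved) — the share of potentially pleiotropic signals
    the DEG triangulation resolved; NA when there are none.
    """
    rows = []
    df = pd.DataFrame([{"outcome": v.outcome, "verdict": v.verdict} for v in verdicts])
    if df.empty:
        return pd.DataFrame(columns=["outcome", "n_signals", "likely_causal_single",
                                     "likely_causal_mrdeg", "pleiotropy_unresolved",
                                     "no_deg_support", "attenuated_fraction"])
    for outcome, grp in df.groupby("outcome"):
        counts = grp["verdict"].value_counts().to_dict()
        mrdeg = counts.get("likely_causal_mrdeg", 0)
        unres = counts.get("pleiotropy_unresolved", 0)
        pleio = mrdeg + unres
        rows.append({
            "outcome": outcome, "n_signals": len(grp),
            "likely_causal_single": counts.get("likely_causal_single", 0),
            "likely_causal_mrdeg": mrdeg,
            "pleiotropy_unresolved": unres,
            "no_deg_support": counts.get("no_deg_support", 0),
            "attenuated_fraction": (mrdeg / pleio) if pleio else float("nan"),
        })
    return pd.DataFrame(rows)


def verdicts_to_frame(verdicts: Sequence[MrDegVerdict]) -> pd.DataFrame:
    return pd.DataFrame([{
        "exposure_id": v.exposure_id, "outcome": v.outcome, "class": v.verdict,
        "competing_exposures": ";".join(v.competing_exposures),
        "deg_supported_competitors": ";".join(v.deg_supported_competitors),
    } for v in verdicts], columns=["exposure_id", "outcome", "class",
                                   "competing_exposures",
                                   "deg_supported_competitors"])
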