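"""Domain types, summary-statistic I/O, allele harmonization, LD utilities
and multiple-testing correction shared by every analysis stage.

The atom of the whole pipeline is :class:`AssocStat`: one variant's
association with one trait (an expression profile or a cancer outcome),
carried as (beta, se, p, alleles, eaf, n).  Exposure and outcome statistics
are plain lists of these records; :func:`harmonize` aligns the two traits of
a two-sample MR analysis to a common effect allele.  LD is computed from a
reference dosage panel (:class:`LDPanel`) as squared Pearson correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AssocStat",
    "ExposureProfile",
    "LDPanel",
    "HarmonizedPair",
    "read_sumstats",
    "write_sumstats",
    "harmonize",
    "ld_r2",
    "bh_fdr",
    "CANONICAL_COLUMNS",
]

_DNA = set("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Canonical summary-statistic TSV columns.
CANONICAL_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "p", "n", "n_cases", "n_controls",
]

#: eaf band inside which a palindromic (A/T or C/G) variant is ambiguous.
PALINDROMIC_EAF_BAND = (0.42, 0.58)


def _valid_allele(a: str) -> bool:
    return isinstance(a, str) and len(a) > 0 and set(a) <= _DNA


@dataclass
class AssocStat:
    """One variant's association with one trait.

    ``beta`` is the effect per copy of ``effect_allele`` on the trait scale
    (log-odds for case-control outcomes).  ``eaf`` is the effect-allele
    frequency; it may be ``None``, in which case the variant cannot take part
    in palindromic-strand resolution.  ``n_cases``/``n_controls`` are set for
    case-control outcome statistics only.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    p: float
    eaf: float | None = None
    n: float | None = None
    n_cases: float | None = None
    n_controls: float | None = None

    def __post_init__(self) -> None:
        if not _valid_allele(self.effect_allele) or not _valid_allele(self.other_allele):
            raise ValueError(
                f"{self.variant_id}: alleles must be non-empty A/C/G/T strings, "
                f"got {self.effect_allele!r}/{self.other_allele!r}"
            )
        if self.se <= 0 or not math.isfinite(self.se):
            raise ValueError(f"{self.variant_id}: se must be > 0, got {self.se}")
        if not (0 < self.p <= 1):
            raise ValueError(f"{self.variant_id}: p must be in (0, 1], got {self.p}")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise ValueError(f"{self.variant_id}: eaf must be in (0, 1), got {self.eaf}")
        self.pos = int(self.pos)
        self._check_p_consistency()

    def _check_p_consistency(self) -> None:
        # Guards against corrupted files: the reported p must agree with the
        # two-sided normal p implied by beta/se within 10% on the -log10
        # scale (rounded inputs pass, column mix-ups do not).
        z = abs(self.beta / self.se)
        expected = max(math.erfc(z / math.sqrt(2.0)), 1e-300)
        lo_obs = -math.log10(max(self.p, 1e-300))
        lo_exp = -math.log10(expected)
        if abs(lo_obs - lo_exp) > 0.1 * max(1.0, lo_exp):
            raise ValueError(
                f"{self.variant_id}: p={self.p:.3g} inconsistent with "
                f"|beta/se|={z:.3g} (expected p≈{expected:.3g})"
            )

    @property
    def z(self) -> float:
        return self.beta / self.se

    @property
    def is_palindromic(self) -> bool:
        return self.other_allele == self.effect_allele.translate(_COMPLEMENT)

    def flipped(self) -> "AssocStat":
        """Return the same association expressed for the other allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
        )


@dataclass(frozen=True)
class ExposureProfile:
    """A gene × cell-type × activation-time expression profile.

    One profile is the unit of MR exposure: e.g. *CALR* in naive T cells
    (TN) at 40 h of activation.  Time points follow the activation course
    0h, LA (lowly active), 16h, 40h, 5d.
    """

    gene: str
    cell_type: str
    time_point: str

    @property
    def exposure_id(self) -> str:
        return f"{self.gene}|{self.cell_type}|{self.time_point}"

    @classmethod
    def from_id(cls, exposure_id: str) -> "ExposureProfile":
        gene, cell_type, time_point = exposure_id.split("|")
        return cls(gene, cell_type, time_point)


class LDPanel:
    """Reference genotype panel: sample × variant allele dosages in [0, 2]."""

    def __init__(self, dosages: np.ndarray, variant_ids: Sequence[str],
                 sample_ids: Sequence[str] | None = None):
        dosages = np.asarray(dosages, dtype=float)
        if dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D sample × variant matrix")
        if dosages.shape[1] != len(variant_ids):
            raise ValueError("variant index does not match dosage columns")
        if dosages.min() < 0 or dosages.max() > 2:
            raise ValueError("dosages must lie in [0, 2]")
        self.dosages = dosages
        self.variant_ids = list(variant_ids)
        self.sample_ids = (list(sample_ids) if sample_ids is not None
                           else [f"S{i}" for i in range(dosages.shape[0])])
        self._index = {v: i for i, v in enumerate(self.variant_ids)}
        if len(self._index) != len(self.variant_ids):
            raise ValueError("duplicate variant ids in panel")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def column(self, variant_id: str) -> np.ndarray:
        try:
            return self.dosages[:, self._index[variant_id]]
        except KeyError:
            raise KeyError(f"variant {variant_id} not in panel") from None

    def r2(self, v1: str, v2: str) -> float:
        return ld_r2(self, v1, v2)

    def r2_with(self, v1: str, others: Sequence[str]) -> np.ndarray:
        """Vector of r² of v1 against each variant in ``others``."""
        x = self.column(v1)
        if x.std() == 0:
            raise ValueError(f"undefined LD: {v1} is monomorphic in panel")
        out = np.empty(len(others))
        xc = x - x.mean()
        denom_x = (xc ** 2).sum()
        for i, v in enumerate(others):
            y = self.column(v)
            yc = y - y.mean()
            denom_y = (yc ** 2).sum()
            if denom_y == 0:
                out[i] = np.nan
            else:
                out[i] = (xc @ yc) ** 2 / (denom_x * denom_y)
        return out

    def subset(self, variant_ids: Sequence[str]) -> "LDPanel":
        idx = [self._index[v] for v in variant_ids]
        return LDPanel(self.dosages[:, idx], list(variant_ids), self.sample_ids)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.dosages, columns=self.variant_ids)
        df.insert(0, "sample_id", self.sample_ids)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LDPanel":
        df = pd.read_csv(path, sep="\t")
        sample_ids = df.iloc[:, 0].astype(str).tolist()
        return cls(df.iloc[:, 1:].to_numpy(float), list(df.columns[1:]), sample_ids)


@dataclass
class HarmonizedPair:
    """Exposure and outcome statistics aligned variant-by-variant to the
    exposure's effect allele, with per-variant harmonization flags."""

    exposure_stats: list[AssocStat]
    outcome_stats: list[AssocStat]
    flags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.exposure_stats) != len(self.outcome_stats):
            raise ValueError("exposure/outcome lists must be aligned")
        for e, o in zip(self.exposure_stats, self.outcome_stats):
            if e.variant_id != o.variant_id or e.effect_allele != o.effect_allele:
                raise ValueError(f"misaligned harmonized pair at {e.variant_id}")

    def __len__(self) -> int:
        return len(self.exposure_stats)

    @property
    def variant_ids(self) -> list[str]:
        return [s.variant_id for s in self.exposure_stats]

    def subset(self, variant_ids: Iterable[str]) -> "HarmonizedPair":
        keep = set(variant_ids)
        pairs = [(e, o) for e, o in zip(self.exposure_stats, self.outcome_stats)
                 if e.variant_id in keep]
        return HarmonizedPair([e for e, _ in pairs], [o for _, o in pairs],
                              dict(self.flags))


# ---------------------------------------------------------------------------
# Summary-statistic I/O

_NUMERIC = {"pos": int, "eaf": float, "beta": float, "se": float, "p": float,
            "n": float, "n_cases": float, "n_controls": float}
_REQUIRED = ["variant_id", "chrom", "pos", "effect_allele", "other_allele",
             "beta", "se", "p"]


def read_sumstats(path: str | Path, dialect: Mapping[str, str] | None = None,
                  *, with_dropped: bool = False):
    """Read a summary-statistic TSV into a list of :class:`AssocStat`.

    ``dialect`` maps canonical column names to the file's header names
    (e.g. ``{"variant_id": "SNP", "p": "pval"}``), allowing OpenGWAS- or
    GWAS-VCF-exported tables to be read without renaming.  Rows whose
    numeric fields do not parse (or violate the AssocStat invariants) are
    dropped and counted; set ``with_dropped=True`` to receive
    ``(records, n_dropped)``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise ValueError(f"{path}: empty summary-statistic file")
    if dialect:
        rename = {v: k for k, v in dialect.items()}
        df = df.rename(columns=rename)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")

    records: list[AssocStat] = []
    dropped = 0
    for row in df.itertuples(index=False):
        d = row._asdict()
        kwargs = {"variant_id": str(d["variant_id"]), "chrom": str(d["chrom"]),
                  "effect_allele": str(d["effect_allele"]).upper(),
                  "other_allele": str(d["other_allele"]).upper()}
        try:
            for col, typ in _NUMERIC.items():
                val = d.get(col)
                if val is None or (isinstance(val, float) and math.isnan(val)):
                    kwargs[col] = None
                else:
                    kwargs[col] = typ(float(val))
            if kwargs["pos"] is None:
                raise ValueError("missing pos")
            for col in ("beta", "se", "p"):
                if kwargs[col] is None:
                    raise ValueError(f"missing {col}")
            records.append(AssocStat(**kwargs))
        except (ValueError, TypeError):
            dropped += 1
    if with_dropped:
        return records, dropped
    return records


def write_sumstats(stats: Iterable[AssocStat], path: str | Path) -> None:
    """Write AssocStat records as the canonical 12-column TSV."""
    rows = [{c: getattr(s, c) for c in CANONICAL_COLUMNS} for s in stats]
    pd.DataFrame(rows, columns=CANONICAL_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Harmonization

def _ambiguous_palindromic(e: AssocStat, o: AssocStat) -> bool:
    lo, hi = PALINDROMIC_EAF_BAND
    for s in (e, o):
        if s.eaf is None or lo <= s.eaf <= hi:
            return True
    return False


def harmonize(exposure: Sequence[AssocStat], outcome: Sequence[AssocStat]) -> HarmonizedPair:
    """Align outcome statistics to the exposure's effect allele.

    Only variants present in both traits are kept.  Where the outcome's
    effect allele equals the exposure's other allele, the outcome beta is
    sign-flipped and its eaf complemented.  Strand flips (A↔T, C↔G) are
    resolved by complementing the outcome alleles.  Palindromic variants
    (A/T or C/G pairs) with eaf inside the ambiguous band on either side —
    or with missing eaf — are dropped and flagged; unambiguous palindromic
    variants are aligned by allele letters with an eaf-concordance check.
    Allele pairs irreconcilable by flip or strand are dropped with a flag,
    never silently kept.
    """
    out_by_id = {s.variant_id: s for s in outcome}
    exp_keep: list[AssocStat] = []
    out_keep: list[AssocStat] = []
    flags: dict[str, str] = {}

    for e in exposure:
        o = out_by_id.get(e.variant_id)
        if o is None:
            continue
        e_pair = (e.effect_allele, e.other_allele)
        if e.is_palindromic:
            if _ambiguous_palindromic(e, o):
                flags[e.variant_id] = "palindromic_dropped"
                continue
            if (o.effect_allele, o.other_allele) == e_pair:
                aligned = o
            elif (o.other_allele, o.effect_allele) == e_pair:
                aligned = o.flipped()
            else:
                flags[e.variant_id] = "incompatible_dropped"
                continue
            # For a palindromic pair the strand is unobservable; outside the
            # ambiguous band the minor allele identifies orientation.
            if aligned.eaf is not None and (e.eaf < 0.5) != (aligned.eaf < 0.5):
                # Opposite strand coding: the labels agree but the frequencies
                # disagree, so the outcome effect refers to the complement.
                aligned = replace(aligned, effect_allele=e.effect_allele,
                                  other_allele=e.other_allele,
                                  beta=-aligned.beta, eaf=1 - aligned.eaf)
                flags[e.variant_id] = "flipped"
            else:
                flags.setdefault(e.variant_id, "ok")
        else:
            o_pair = (o.effect_allele, o.other_allele)
            o_flip = (o.other_allele, o.effect_allele)
            o_strand = tuple(a.translate(_COMPLEMENT) for a in o_pair)
            o_strand_flip = tuple(a.translate(_COMPLEMENT) for a in o_flip)
            if o_pair == e_pair:
                aligned = o
                flags[e.variant_id] = "ok"
            elif o_flip == e_pair:
                aligned = o.flipped()
                flags[e.variant_id] = "flipped"
            elif o_strand == e_pair:
                aligned = replace(o, effect_allele=e.effect_allele,
                                  other_allele=e.other_allele)
                flags[e.variant_id] = "ok"
            elif o_strand_flip == e_pair:
                aligned = replace(o.flipped(), effect_allele=e.effect_allele,
                                  other_allele=e.other_allele)
                flags[e.variant_id] = "flipped"
            else:
                flags[e.variant_id] = "incompatible_dropped"
                continue
        exp_keep.append(e)
        out_keep.append(aligned)

    return HarmonizedPair(exp_keep, out_keep, flags)


# ---------------------------------------------------------------------------
# LD and multiple testing

def ld_r2(panel: LDPanel, v1: str, v2: str) -> float:
    """Squared Pearson correlation of dosages between two panel variants."""
    x, y = panel.column(v1), panel.column(v2)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("undefined LD for monomorphic variant")
    r = np.corrcoef(x, y)[0, 1]
    return float(min(r * r, 1.0))


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values.

    q_(i) = min over ranks j ≥ i of m·p_(j)/j, capped at 1; monotone in p
    and never below p.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
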