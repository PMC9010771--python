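"""GWAS summary statistics: data model, I/O and allele harmonization.

A :class:`SummaryStats` holds per-variant association records for one trait
(effect sizes signed with respect to a stated effect allele).  Before any
two-sample MR analysis, the exposure and outcome records for each instrument
SNP must be *harmonized* so that both betas refer to the same allele;
:func:`harmonize` implements the standard rules (sign flips for swapped
alleles, strand complementation, and frequency-based orientation of
palindromic A/T and C/G variants, which are dropped when the minor allele
frequency exceeds ``palindrome_maf_max`` because their strand cannot be
resolved reliably).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column order for summary-statistics files
CANONICAL_COLUMNS = [
    "rsid", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "p", "n",
]


class FormatError(ValueError):
    """Raised when an input file cannot be interpreted."""


class DuplicateVariantError(ValueError):
    """Raised when a trait contains the same variant key more than once."""

    def __init__(self, duplicates: Sequence[str]):
        self.duplicates = list(duplicates)
        super().__init__(f"duplicate rsids in summary statistics: {self.duplicates}")


class InvalidAlleleError(ValueError):
    """Raised for alleles outside {A, C, G, T}."""


class VariantKey(NamedTuple):
    """Identity of a biallelic SNP: rsid, position, and its two alleles."""

    rsid: str
    chrom: str
    pos: int
    allele_a: str
    allele_b: str


@dataclass
class SummaryStats:
    """Per-variant GWAS association records for a single trait.

    Parameters
    ----------
    trait_id : str
        Identifier of the trait (e.g. a metabolite name or GWAS accession).
    table : pandas.DataFrame
        One row per variant with the canonical columns
        ``rsid chrom pos effect_allele other_allele eaf beta se p n``.
    """

    trait_id: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"missing columns: {missing}")
        dup = self.table["rsid"][self.table["rsid"].duplicated()]
        if len(dup):
            raise DuplicateVariantError(sorted(set(dup)))
        if (self.table["se"] <= 0).any():
            raise ValueError("se must be positive; filter rows before construction")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def lookup(self, rsid: str) -> pd.Series | None:
        hit = self.table[self.table["rsid"] == rsid]
        return None if hit.empty else hit.iloc[0]

    @property
    def rsids(self) -> set[str]:
        return set(self.table["rsid"])

    def variant_keys(self) -> list[VariantKey]:
        return [
            VariantKey(r.rsid, str(r.chrom), int(r.pos), r.effect_allele, r.other_allele)
            for r in self.table.itertuples()
        ]


@dataclass
class InstrumentSet:
    """Harmonized exposure/outcome effects for a clumped instrument SNP set.

    ``table`` columns: ``rsid chrom pos effect_allele other_allele
    beta_x se_x beta_y se_y eaf proxy_of``; all betas are signed with respect
    to the same effect allele per SNP.  ``provenance`` is an append-only audit
    trail of every drop, flip and proxy substitution.
    """

    exposure_id: str
    outcome_id: str
    table: pd.DataFrame
    provenance: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def L(self) -> int:
        return len(self.table)

    def log(self, action: str, rsid: str, **details) -> None:
        self.provenance.append({"action": action, "rsid": rsid, **details})

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Return (beta_x, se_x, beta_y, se_y) as float arrays."""
        t = self.table
        return (
            t["beta_x"].to_numpy(float),
            t["se_x"].to_numpy(float),
            t["beta_y"].to_numpy(float),
            t["se_y"].to_numpy(float),
        )

    def subset(self, mask_or_index) -> "InstrumentSet":
        sub = self.table.loc[mask_or_index].reset_index(drop=True)
        return InstrumentSet(self.exposure_id, self.outcome_id, sub,
                             provenance=list(self.provenance))


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is strand-ambiguous (A/T or C/G)."""
    ea, oa = effect_allele.upper(), other_allele.upper()
    if ea not in _VALID_ALLELES or oa not in _VALID_ALLELES:
        raise InvalidAlleleError(f"non-ACGT allele pair: {effect_allele}/{other_allele}")
    return _COMPLEMENT[ea] == oa


def _complement(allele: str) -> str:
    return _COMPLEMENT[allele]


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_id: str | None = None,
    sep: str = "\t",
) -> SummaryStats:
    """Read delimited summary statistics into a validated :class:`SummaryStats`.

    ``column_map`` maps canonical names to the file's column names for foreign
    dialects (e.g. ``{"rsid": "SNP", "p": "pval"}``).  Rows with non-positive
    standard errors, missing betas, or non-SNP (indel) alleles are dropped and
    logged rather than raising.
    """
    raw = pd.read_csv(path, sep=sep, dtype={"chrom": str})
    column_map = dict(column_map or {})
    rename = {v: k for k, v in column_map.items()}
    raw = raw.rename(columns=rename)
    required = ["rsid", "chrom", "pos", "effect_allele", "other_allele", "beta", "se", "p"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    for optional in ("eaf", "n"):
        if optional not in raw.columns:
            raw[optional] = np.nan
    raw = raw[CANONICAL_COLUMNS].copy()
    raw["chrom"] = raw["chrom"].astype(str)
    raw["effect_allele"] = raw["effect_allele"].astype(str).str.upper()
    raw["other_allele"] = raw["other_allele"].astype(str).str.upper()

    snv = (raw["effect_allele"].isin(_VALID_ALLELES)
           & raw["other_allele"].isin(_VALID_ALLELES)
           & (raw["effect_allele"] != raw["other_allele"]))
    bad_se = ~(raw["se"] > 0)
    bad_beta = raw["beta"].isna()
    keep = snv & ~bad_se & ~bad_beta
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("%s: dropped %d invalid row(s) (se<=0: %d, missing beta: %d, "
                       "non-SNP alleles: %d)", path, n_dropped, int(bad_se.sum()),
                       int(bad_beta.sum()), int((~snv).sum()))
    table = raw[keep].reset_index(drop=True)
    dup = table["rsid"][table["rsid"].duplicated()]
    if len(dup):
        raise DuplicateVariantError(sorted(set(dup)))
    return SummaryStats(trait_id=trait_id or str(path), table=table)


def write_sumstats(stats: SummaryStats, path, sep: str = "\t") -> None:
    """Write :class:`SummaryStats` as delimited text with the canonical header.

    Round-trips: ``read_sumstats(write_sumstats(x)) == x``.
    """
    stats.table[CANONICAL_COLUMNS].to_csv(path, sep=sep, index=False)


def harmonize(
    exposure: SummaryStats,
    outcome: SummaryStats,
    snps: Iterable[str | VariantKey] | None = None,
    palindrome_maf_max: float = 0.42,
) -> InstrumentSet:
    """Harmonize exposure and outcome effects onto the exposure effect allele.

    Rules, applied per SNP present in both traits:

    * identical allele labels: outcome beta kept;
    * swapped labels: outcome beta negated, outcome eaf := 1 − eaf;
    * labels matching only after strand complementation: complement, then
      apply the same rule (complementation is attempted only when direct and
      swapped matching both fail);
    * palindromic SNPs: dropped when min(eaf, 1−eaf) of the *exposure* record
      exceeds ``palindrome_maf_max`` or when either eaf is missing; otherwise
      oriented by allele-frequency agreement (if one trait's eaf is < 0.5 and
      the other's is > 0.5 the outcome beta is negated);
    * irreconcilable allele pairs: dropped with a logged reason.

    Every drop/flip is recorded in the returned set's provenance.
    """
    if snps is None:
        wanted = exposure.table
    else:
        ids = {s.rsid if isinstance(s, VariantKey) else str(s) for s in snps}
        wanted = exposure.table[exposure.table["rsid"].isin(ids)]

    exp = wanted.rename(columns={
        "effect_allele": "ea_x", "other_allele": "oa_x",
        "eaf": "eaf_x", "beta": "beta_x", "se": "se_x", "p": "p_x", "n": "n_x"})
    out = outcome.table.rename(columns={
        "effect_allele": "ea_y", "other_allele": "oa_y",
        "eaf": "eaf_y", "beta": "beta_y", "se": "se_y", "p": "p_y", "n": "n_y"})
    merged = exp.merge(out.drop(columns=["chrom", "pos"]), on="rsid", how="inner")

    prov: list[dict] = []
    if snps is not None:
        for rsid in sorted(set(wanted["rsid"]) - set(merged["rsid"])):
            prov.append({"action": "drop", "rsid": rsid, "reason": "absent_from_outcome"})

    if merged.empty:
        empty = pd.DataFrame(columns=["rsid", "chrom", "pos", "effect_allele",
                                      "other_allele", "beta_x", "se_x", "beta_y",
                                      "se_y", "eaf", "proxy_of"])
        return InstrumentSet(exposure.trait_id, outcome.trait_id, empty, prov)

    ea_x = merged["ea_x"].to_numpy(object)
    oa_x = merged["oa_x"].to_numpy(object)
    ea_y = merged["ea_y"].to_numpy(object)
    oa_y = merged["oa_y"].to_numpy(object)
    comp_ea_y = np.array([_COMPLEMENT[a] for a in ea_y], dtype=object)
    comp_oa_y = np.array([_COMPLEMENT[a] for a in oa_y], dtype=object)

    palin = np.array([is_palindromic(a, b) for a, b in zip(ea_x, oa_x)])
    direct = (ea_y == ea_x) & (oa_y == oa_x)
    swapped = (ea_y == oa_x) & (oa_y == ea_x)
    comp_direct = ~direct & ~swapped & (comp_ea_y == ea_x) & (comp_oa_y == oa_x)
    comp_swapped = ~direct & ~swapped & (comp_ea_y == oa_x) & (comp_oa_y == ea_x)

    beta_y = merged["beta_y"].to_numpy(float).copy()
    eaf_y = merged["eaf_y"].to_numpy(float).copy()
    eaf_x = merged["eaf_x"].to_numpy(float)

    flip = np.zeros(len(merged), dtype=bool)
    drop = np.zeros(len(merged), dtype=bool)
    reasons = np.empty(len(merged), dtype=object)

    # non-palindromic resolution
    np_mask = ~palin
    flip |= np_mask & (swapped | comp_swapped)
    unmatched = np_mask & ~(direct | swapped | comp_direct | comp_swapped)
    drop |= unmatched
    reasons[unmatched] = "irreconcilable_alleles"

    # palindromic resolution: allele labels are uninformative, use frequency
    eaf_missing = palin & (np.isnan(eaf_x) | np.isnan(eaf_y))
    drop |= eaf_missing
    reasons[eaf_missing] = "palindromic_missing_eaf"
    maf_x = np.minimum(eaf_x, 1.0 - eaf_x)
    high_maf = palin & ~eaf_missing & (maf_x > palindrome_maf_max)
    drop |= high_maf
    reasons[high_maf] = "palindromic_maf_above_threshold"
    resolvable = palin & ~drop
    disagree = resolvable & ((eaf_x < 0.5) != (eaf_y < 0.5))
    flip |= disagree

    beta_y[flip] = -beta_y[flip]
    eaf_y[flip] = 1.0 - eaf_y[flip]

    for i in np.flatnonzero(drop):
        prov.append({"action": "drop", "rsid": merged["rsid"].iat[i],
                     "reason": str(reasons[i])})
    for i in np.flatnonzero(flip & ~drop):
        prov.append({"action": "flip_outcome", "rsid": merged["rsid"].iat[i]})

    keep = ~drop
    result = pd.DataFrame({
        "rsid": merged["rsid"][keep].to_numpy(),
        "chrom": merged["chrom"][keep].to_numpy(),
        "pos": merged["pos"][keep].to_numpy(),
        "effect_allele": ea_x[keep],
        "other_allele": oa_x[keep],
        "beta_x": merged["beta_x"][keep].to_numpy(float),
        "se_x": merged["se_x"][keep].to_numpy(float),
        "beta_y": beta_y[keep],
        "se_y": merged["se_y"][keep].to_numpy(float),
        "eaf": eaf_x[keep],
        "proxy_of": [None] * int(keep.sum()),
    })
    return InstrumentSet(exposure.trait_id, outcome.trait_id,
                         result.reset_index(drop=True), prov)
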