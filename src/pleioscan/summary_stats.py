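"""Reading, validation and allele harmonization of GWAS summary statistics.

A GWAS summary-statistics table reports, per SNP, an odds ratio (OR) and
p-value *per copy of a designated effect allele*. Two studies of different
diseases rarely designate the same allele, and may even report on opposite
strands, so any cross-study comparison of effect direction must first put
both ORs on a shared allele orientation. That harmonization step is the
purpose of this module: comparing raw ORs without it can fabricate or erase
an "opposite direction" signal, which is exactly the signal the downstream
pleiotropy scan looks for.

Conventions
-----------
* An allele *swap* (study B's effect allele is study A's other allele on the
  same strand) inverts B's OR: an OR of x per allele G is an OR of 1/x per
  the alternate allele.
* A *strand flip* (B reports on the opposite strand) complements B's alleles
  before alignment and leaves the OR untouched.
* Palindromic SNPs (A/T or C/G) are strand-ambiguous: swap and flip are
  indistinguishable without allele-frequency information. They are flagged,
  kept as-read by default, and can be dropped by the caller.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Default column mapping: field name -> column header in the delimited file.
DEFAULT_DIALECT: dict[str, str] = {
    "snp_id": "snp_id",
    "chrom": "chrom",
    "pos": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "odds_ratio": "odds_ratio",
    "p_value": "p_value",
}

MANDATORY_FIELDS = tuple(DEFAULT_DIALECT)


class ColumnMappingError(KeyError):
    """A mandatory column is absent from the input file."""


class AlleleMismatchError(ValueError):
    """Two records claimed to describe one variant have irreconcilable alleles."""


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's association result in one study.

    ``odds_ratio`` is the multiplicative disease risk per copy of
    ``effect_allele``; ``pos`` is 1-based, as GWAS tables print it.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    odds_ratio: float
    p_value: float
    trait: str = ""

    def __post_init__(self) -> None:
        if self.odds_ratio <= 0:
            raise ValueError(f"{self.snp_id}: odds_ratio must be > 0")
        if not (0 < self.p_value <= 1):
            raise ValueError(f"{self.snp_id}: p_value must be in (0, 1]")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele identical")
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: pos must be >= 1")

    @property
    def is_palindromic(self) -> bool:
        """True for A/T and C/G SNPs, whose strand cannot be inferred."""
        return COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass(frozen=True)
class HarmonizedPair:
    """Two studies' effects for one variant, expressed on one effect allele."""

    snp_id: str
    effect_allele: str
    other_allele: str
    or_trait_a: float
    p_trait_a: float
    or_trait_b: float
    p_trait_b: float
    flip_applied: bool
    ambiguous_strand: bool


def read_summary_stats(
    path: str | Path,
    trait: str,
    dialect: Mapping[str, str] | None = None,
    sep: str = "\t",
) -> tuple[list[SnpAssociation], pd.DataFrame]:
    """Read a delimited summary-statistics file into :class:`SnpAssociation` records.

    Parameters
    ----------
    path
        Delimited text file with one row per SNP.
    trait
        Label stored on every record (e.g. ``"RA"``).
    dialect
        Mapping from canonical field names (see :data:`DEFAULT_DIALECT`) to
        the file's column headers. Unmapped fields fall back to the default
        header names.
    sep
        Field separator; defaults to tab.

    Returns
    -------
    records, rejects
        ``records`` preserves file order. ``rejects`` is a DataFrame of the
        dropped rows with a ``reject_reason`` column (unparseable OR or
        p-value, missing position, invalid alleles ...). An empty file yields
        an empty list, not an error.
    """
    mapping = dict(DEFAULT_DIALECT)
    if dialect:
        mapping.update(dialect)

    try:
        frame = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError:
        return [], _empty_rejects()

    missing = [mapping[f] for f in MANDATORY_FIELDS if mapping[f] not in frame.columns]
    if missing:
        raise ColumnMappingError(
            f"{path}: missing mandatory column(s) {missing}; "
            f"available: {list(frame.columns)}"
        )

    records: list[SnpAssociation] = []
    rejects: list[dict] = []
    for row in frame.itertuples(index=False):
        raw = {f: getattr(row, mapping[f]) for f in MANDATORY_FIELDS}
        try:
            rec = SnpAssociation(
                snp_id=str(raw["snp_id"]),
                chrom=str(raw["chrom"]),
                pos=int(raw["pos"]),
                effect_allele=str(raw["effect_allele"]).upper(),
                other_allele=str(raw["other_allele"]).upper(),
                odds_ratio=float(raw["odds_ratio"]),
                p_value=float(raw["p_value"]),
                trait=trait,
            )
        except (TypeError, ValueError, KeyError) as exc:
            rejects.append({**raw, "reject_reason": str(exc)})
            continue
        if not math.isfinite(rec.odds_ratio) or not math.isfinite(rec.p_value):
            rejects.append({**raw, "reject_reason": "non-finite OR or p"})
            continue
        records.append(rec)

    reject_frame = pd.DataFrame(rejects) if rejects else _empty_rejects()
    if rejects:
        logger.warning("%s: rejected %d of %d rows", path, len(rejects), len(frame))
    return records, reject_frame


def _empty_rejects() -> pd.DataFrame:
    return pd.DataFrame(columns=[*MANDATORY_FIELDS, "reject_reason"])


def write_summary_stats(
    records: Iterable[SnpAssociation], path: str | Path, sep: str = "\t"
) -> None:
    """Write records back to a delimited file using the default column names.

    Numeric fields are emitted with :func:`repr`-grade precision so that a
    read/write cycle round-trips every retained field exactly.
    """
    rows = [
        {
            "snp_id": r.snp_id,
            "chrom": r.chrom,
            "pos": r.pos,
            "effect_allele": r.effect_allele,
            "other_allele": r.other_allele,
            "odds_ratio": repr(r.odds_ratio),
            "p_value": repr(r.p_value),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(MANDATORY_FIELDS)).to_csv(path, sep=sep, index=False)


def harmonize_alleles(a: SnpAssociation, b: SnpAssociation) -> HarmonizedPair:
    """Express two studies' effects for one variant on a shared effect allele.

    Study ``a`` fixes the orientation; study ``b`` is swapped (OR inverted),
    strand-complemented, or both, as needed. Raises
    :class:`AlleleMismatchError` when the two allele sets cannot describe the
    same biallelic variant.
    """
    ambiguous = a.is_palindromic or b.is_palindromic

    b_eff, b_oth, b_or = b.effect_allele, b.other_allele, b.odds_ratio
    a_set = {a.effect_allele, a.other_allele}

    if {b_eff, b_oth} != a_set:
        b_eff_c, b_oth_c = COMPLEMENT[b_eff], COMPLEMENT[b_oth]
        if {b_eff_c, b_oth_c} != a_set:
            raise AlleleMismatchError(
                f"{a.snp_id}: alleles {a.effect_allele}/{a.other_allele} vs "
                f"{b.effect_allele}/{b.other_allele} cannot be reconciled"
            )
        b_eff, b_oth = b_eff_c, b_oth_c  # strand flip; OR unchanged

    flip = b_eff != a.effect_allele
    if flip:
        b_eff, b_oth = b_oth, b_eff
        b_or = 1.0 / b_or

    return HarmonizedPair(
        snp_id=a.snp_id,
        effect_allele=a.effect_allele,
        other_allele=a.other_allele,
        or_trait_a=a.odds_ratio,
        p_trait_a=a.p_value,
        or_trait_b=b_or,
        p_trait_b=b.p_value,
        flip_applied=flip,
        ambiguous_strand=ambiguous,
    )


def harmonized_b_association(pair: HarmonizedPair, b: SnpAssociation) -> SnpAssociation:
    """Return study B's record re-expressed in the harmonized orientation."""
    return replace(
        b,
        effect_allele=pair.effect_allele,
        other_allele=pair.other_allele,
        odds_ratio=pair.or_trait_b,
    )
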