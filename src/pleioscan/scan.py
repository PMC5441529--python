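"""The cascaded cross-trait pleiotropy scan.

Given two diseases A and B with published GWAS summary statistics, the scan
searches for SNPs whose alleles push risk in *opposite* directions for the
two diseases. The cascade:

1. **Threshold + prune** disease A's SNPs: keep genome-wide-significant hits
   (p < 1e-8 by default) and LD-prune them (r^2 <= 0.6) to a quasi-independent
   set. Only disease A is thresholded — the procedure is deliberately
   asymmetric, so disease-B members of a pair may carry p-values above the
   genome-wide threshold.
2. **Pair** each retained A SNP with every B SNP in strong LD with it
   (r^2 >= 0.8 within a physical window); a SNP present in both studies
   pairs with itself at r^2 = 1.
3. **Deduplicate**: when several B SNPs match one A SNP, keep the pair with
   the highest r^2, breaking ties by the smaller B p-value, then position.
4. **Opposite-effect filter**: after allele harmonization, keep pairs where
   one odds ratio is < 1 and the other > 1.
5. **Same-SNP verification**: genuine (putative) pleiotropy requires the
   *same* physical variant to show opposite directions when looked up in
   both studies' tables; pairs of two distinct SNPs in LD cannot be
   cross-verified and are excluded from the pleiotropic set.
6. **Gene mapping**: classify each pleiotropic SNP against gene models as
   exonic / intronic / flanking (within ``flank_bp`` of the transcript) /
   intergenic; intergenic SNPs are reported separately, not discarded.

Coordinates: GWAS positions are 1-based; gene models are stored half-open
0-based (BED convention) and the conversion happens inside
:func:`map_to_genes`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from pleioscan.ld import HaplotypePanel, compute_r2
from pleioscan.summary_stats import (
    AlleleMismatchError,
    SnpAssociation,
    harmonize_alleles,
)
from pleioscan import ld as _ld

logger = logging.getLogger(__name__)

REGION_PRIORITY = {"exon": 0, "intron": 1, "flanking": 2}


@dataclass(frozen=True)
class ScanConfig:
    """Thresholds of the cascade; defaults are the standard scan settings.

    ``p_threshold_a`` applies to disease A only (the asymmetric design);
    ``r2_prune_max`` bounds LD inside the pruned A set; ``r2_pair_min`` is
    the minimum LD for an A-B pair; ``flank_bp`` extends transcripts for the
    flanking-region class; ``window_bp`` bounds the physical search radius
    for both pruning and pairing.
    """

    p_threshold_a: float = 1e-8
    r2_prune_max: float = 0.6
    r2_pair_min: float = 0.8
    flank_bp: int = 5000
    window_bp: int = 1_000_000
    drop_ambiguous: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold_a <= 1) and self.p_threshold_a != 0:
            raise ValueError("p_threshold_a must be in [0, 1]")
        for name in ("r2_prune_max", "r2_pair_min"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be >= 0")


@dataclass
class SnpPair:
    """A cross-trait (r, z) candidate pair: r from disease A, z from disease B."""

    r: SnpAssociation
    z: SnpAssociation
    r2: float
    same_snp: bool
    opposite_effects: bool = False
    cross_verified: bool = False
    #: z's odds ratio re-expressed on r's effect allele (same-SNP pairs only).
    z_or_harmonized: float | None = None
    ambiguous_strand: bool = False


@dataclass(frozen=True)
class GeneModel:
    """A transcript model with half-open 0-based coordinates."""

    gene_name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.tx_start >= self.tx_end:
            raise ValueError(f"{self.gene_name}: empty transcript interval")
        prev_end = None
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"{self.gene_name}: empty exon [{s}, {e})")
            if not (self.tx_start <= s and e <= self.tx_end):
                raise ValueError(f"{self.gene_name}: exon outside transcript")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_name}: exons overlap or unsorted")
            prev_end = e

    @property
    def midpoint(self) -> float:
        return (self.tx_start + self.tx_end) / 2


@dataclass(frozen=True)
class GeneHit:
    """One gene's classification of a SNP position."""

    gene_name: str
    region_class: str  # exon | intron | flanking
    distance_to_midpoint: float


@dataclass
class PleiotropyRecord:
    """One putatively pleiotropic SNP with both diseases' effects and its gene."""

    snp_id: str
    chrom: str
    pos: int
    allele_pair: str  # "effect/other" in the harmonized orientation
    or_a: float
    p_a: float
    or_b: float
    p_b: float
    gene: str | None = None
    region_class: str = "intergenic"
    all_hits: tuple[GeneHit, ...] = ()


# ---------------------------------------------------------------------------
# gene model I/O (BED12)
# ---------------------------------------------------------------------------

BED12_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "thick_start", "thick_end", "rgb", "block_count", "block_sizes", "block_starts",
]


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read transcript models from a BED12 file (blocks = exons)."""
    frame = pd.read_csv(path, sep="\t", header=None, names=BED12_COLUMNS,
                        dtype={"chrom": str}, comment="#")
    models = []
    for row in frame.itertuples(index=False):
        sizes = [int(x) for x in str(row.block_sizes).rstrip(",").split(",")]
        offsets = [int(x) for x in str(row.block_starts).rstrip(",").split(",")]
        exons = tuple(
            (int(row.start) + off, int(row.start) + off + size)
            for off, size in zip(offsets, sizes)
        )
        models.append(
            GeneModel(
                gene_name=str(row.name),
                chrom=str(row.chrom),
                strand=str(row.strand),
                tx_start=int(row.start),
                tx_end=int(row.end),
                exons=exons,
            )
        )
    return models


def write_gene_models(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write transcript models as BED12."""
    rows = []
    for m in models:
        sizes = ",".join(str(e - s) for s, e in m.exons)
        offsets = ",".join(str(s - m.tx_start) for s, e in m.exons)
        rows.append(
            [m.chrom, m.tx_start, m.tx_end, m.gene_name, 0, m.strand,
             m.tx_start, m.tx_end, "0,0,0", len(m.exons), sizes, offsets]
        )
    pd.DataFrame(rows, columns=BED12_COLUMNS).to_csv(
        path, sep="\t", index=False, header=False
    )


# ---------------------------------------------------------------------------
# cascade stages
# ---------------------------------------------------------------------------


def pair_cross_trait(
    pruned_a: Sequence[SnpAssociation],
    all_b: Sequence[SnpAssociation],
    panel: HaplotypePanel | None,
    cfg: ScanConfig,
) -> list[SnpPair]:
    """Pair each pruned A SNP with every B SNP in strong LD with it.

    A SNP present in both studies pairs with itself at r^2 = 1 without a
    panel lookup. With ``panel=None`` ("self-pair mode") only such identity
    pairs are formed — useful when re-analysing a published table of
    same-SNP effects without a reference panel.
    """
    pairs: list[SnpPair] = []
    skipped_panel = 0
    b_by_chrom: dict[str, list[SnpAssociation]] = {}
    for b in all_b:
        b_by_chrom.setdefault(b.chrom, []).append(b)

    for a in pruned_a:
        for b in b_by_chrom.get(a.chrom, []):
            if b.snp_id == a.snp_id:
                pairs.append(SnpPair(r=a, z=b, r2=1.0, same_snp=True))
                continue
            if panel is None:
                continue
            if abs(b.pos - a.pos) > cfg.window_bp:
                continue
            if a.snp_id not in panel or b.snp_id not in panel:
                skipped_panel += 1
                continue
            r2 = compute_r2(panel, a.snp_id, b.snp_id).r2
            if r2 >= cfg.r2_pair_min:
                pairs.append(SnpPair(r=a, z=b, r2=r2, same_snp=False))
    if skipped_panel:
        logger.warning("pair_cross_trait: %d candidate pair(s) skipped, SNP not in panel",
                       skipped_panel)
    return pairs


def dedupe_pairs(pairs: Sequence[SnpPair]) -> list[SnpPair]:
    """Keep one pair per A SNP: max r^2, then min B p-value, then position/id."""
    best: dict[str, SnpPair] = {}
    for p in pairs:
        key = p.r.snp_id
        cur = best.get(key)
        if cur is None or _pair_rank(p) < _pair_rank(cur):
            best[key] = p
    return sorted(best.values(), key=lambda p: (p.r.chrom, p.r.pos, p.r.snp_id))


def _pair_rank(p: SnpPair) -> tuple:
    return (-p.r2, p.z.p_value, p.z.pos, p.z.snp_id)


def opposite_effect_filter(
    pairs: Sequence[SnpPair], drop_ambiguous: bool = False
) -> list[SnpPair]:
    """Keep pairs whose harmonized odds ratios straddle 1 in opposite directions.

    Same-SNP pairs are allele-harmonized first (the B odds ratio is
    re-expressed on the A effect allele); distinct-SNP pairs are compared
    as-read, since their alleles are not comparable. An OR of exactly 1 has
    no direction and never passes. Palindromic same-SNP pairs are flagged
    strand-ambiguous and kept unless ``drop_ambiguous``.
    """
    kept: list[SnpPair] = []
    for p in pairs:
        or_b = p.z.odds_ratio
        ambiguous = False
        if p.same_snp:
            try:
                harm = harmonize_alleles(p.r, p.z)
            except AlleleMismatchError as exc:
                logger.warning("opposite_effect_filter: %s", exc)
                continue
            or_b = harm.or_trait_b
            ambiguous = harm.ambiguous_strand
            if ambiguous and drop_ambiguous:
                continue
            if ambiguous:
                logger.warning(
                    "opposite_effect_filter: %s is palindromic; orientation as-read",
                    p.r.snp_id,
                )
        if (p.r.odds_ratio - 1) * (or_b - 1) < 0:
            p = replace_pair(p, opposite_effects=True, z_or_harmonized=or_b,
                             ambiguous_strand=ambiguous)
            kept.append(p)
    return kept


def replace_pair(p: SnpPair, **kw) -> SnpPair:
    new = SnpPair(r=p.r, z=p.z, r2=p.r2, same_snp=p.same_snp,
                  opposite_effects=p.opposite_effects,
                  cross_verified=p.cross_verified,
                  z_or_harmonized=p.z_or_harmonized,
                  ambiguous_strand=p.ambiguous_strand)
    for k, v in kw.items():
        setattr(new, k, v)
    return new


def verify_same_snp(
    pairs: Sequence[SnpPair],
    stats_a: Sequence[SnpAssociation],
    stats_b: Sequence[SnpAssociation],
) -> list[SnpPair]:
    """Cross-verify opposite directions for the shared variant of same-SNP pairs.

    A same-SNP pair is cross-verified iff looking the SNP up in *both*
    studies' full tables (after harmonization onto the A orientation) still
    shows opposite effect directions. Pairs of two distinct SNPs cannot be
    verified this way and keep ``cross_verified=False``; the pleiotropic set
    downstream is the same-SNP, cross-verified pairs.
    """
    a_by_id = {a.snp_id: a for a in stats_a}
    b_by_id = {b.snp_id: b for b in stats_b}
    out: list[SnpPair] = []
    for p in pairs:
        verified = False
        if p.same_snp:
            a_rec = a_by_id.get(p.r.snp_id)
            b_rec = b_by_id.get(p.r.snp_id)
            if a_rec is None or b_rec is None:
                logger.warning("verify_same_snp: %s missing from a study table",
                               p.r.snp_id)
            else:
                try:
                    harm = harmonize_alleles(a_rec, b_rec)
                except AlleleMismatchError as exc:
                    logger.warning("verify_same_snp: %s", exc)
                else:
                    verified = (harm.or_trait_a - 1) * (harm.or_trait_b - 1) < 0
        out.append(replace_pair(p, cross_verified=verified))
    return out


def pleiotropic_records(pairs: Sequence[SnpPair]) -> list[PleiotropyRecord]:
    """Materialize same-SNP, cross-verified pairs as pleiotropy records."""
    recs = []
    for p in pairs:
        if not (p.same_snp and p.cross_verified):
            continue
        or_b = p.z_or_harmonized if p.z_or_harmonized is not None else p.z.odds_ratio
        recs.append(
            PleiotropyRecord(
                snp_id=p.r.snp_id,
                chrom=p.r.chrom,
                pos=p.r.pos,
                allele_pair=f"{p.r.effect_allele}/{p.r.other_allele}",
                or_a=p.r.odds_ratio,
                p_a=p.r.p_value,
                or_b=or_b,
                p_b=p.z.p_value,
            )
        )
    return recs


# ---------------------------------------------------------------------------
# gene mapping
# ---------------------------------------------------------------------------


def _build_trees(
    genes: Sequence[GeneModel], flank_bp: int
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        tree = trees.setdefault(g.chrom, IntervalTree())
        lo = max(0, g.tx_start - flank_bp)
        tree.addi(lo, g.tx_end + flank_bp, g)
    return trees


def classify_position(
    pos0: int, gene: GeneModel, flank_bp: int
) -> str | None:
    """Region class of a 0-based position relative to one gene model."""
    if gene.tx_start <= pos0 < gene.tx_end:
        for s, e in gene.exons:
            if s <= pos0 < e:
                return "exon"
        return "intron"
    if gene.tx_start - flank_bp <= pos0 < gene.tx_end + flank_bp:
        return "flanking"
    return None


def map_to_genes(
    records: Sequence[PleiotropyRecord],
    genes: Sequence[GeneModel],
    flank_bp: int = 5000,
) -> list[PleiotropyRecord]:
    """Annotate records with a primary gene and region class.

    GWAS positions (1-based) are converted to 0-based before interval
    lookup. When several genes hit, the primary is chosen by class priority
    exon > intron > flanking, ties broken by distance to the transcript
    midpoint, then gene name; all hits are retained in ``all_hits``.
    A record on a chromosome absent from the gene models is classified
    intergenic (with a warning).
    """
    trees = _build_trees(genes, flank_bp)
    known_chroms = {g.chrom for g in genes}
    out: list[PleiotropyRecord] = []
    for rec in records:
        pos0 = rec.pos - 1
        if rec.chrom not in known_chroms:
            logger.warning("map_to_genes: chromosome %s absent from gene models",
                           rec.chrom)
        hits: list[GeneHit] = []
        for iv in trees.get(rec.chrom, IntervalTree()).at(pos0):
            g: GeneModel = iv.data
            cls = classify_position(pos0, g, flank_bp)
            if cls is not None:
                hits.append(GeneHit(g.gene_name, cls, abs(pos0 - g.midpoint)))
        hits.sort(key=lambda h: (REGION_PRIORITY[h.region_class],
                                 h.distance_to_midpoint, h.gene_name))
        new = PleiotropyRecord(**{**rec.__dict__})
        if hits:
            new.gene = hits[0].gene_name
            new.region_class = hits[0].region_class
        else:
            new.gene = None
            new.region_class = "intergenic"
        new.all_hits = tuple(hits)
        out.append(new)
    return out


# ---------------------------------------------------------------------------
# the full cascade
# ---------------------------------------------------------------------------


def run_scan(
    stats_a: Sequence[SnpAssociation],
    stats_b: Sequence[SnpAssociation],
    panel: HaplotypePanel | None,
    genes: Sequence[GeneModel],
    cfg: ScanConfig = ScanConfig(),
) -> tuple[list[PleiotropyRecord], list[PleiotropyRecord], dict[str, int]]:
    """Run the whole cascade; returns (gene-region records, intergenic records, audit).

    The audit dict records the collection size after every stage. With
    ``panel=None`` the prune stage reduces to the p-value threshold and
    pairing is identity-only (see :func:`pair_cross_trait`).
    """
    audit: dict[str, int] = {
        "input_a": len(stats_a),
        "input_b": len(stats_b),
    }
    if cfg.p_threshold_a <= 0:
        pruned: list[SnpAssociation] = []
    elif panel is None:
        pruned = sorted(
            (a for a in stats_a if a.p_value < cfg.p_threshold_a),
            key=lambda a: (a.p_value, a.chrom, a.pos, a.snp_id),
        )
    else:
        pruned = _ld.ld_prune(
            stats_a, panel,
            p_threshold=cfg.p_threshold_a,
            r2_max=cfg.r2_prune_max,
            window_bp=cfg.window_bp,
        )
    audit["pruned_a"] = len(pruned)

    pairs = pair_cross_trait(pruned, stats_b, panel, cfg)
    audit["pairs"] = len(pairs)

    deduped = dedupe_pairs(pairs)
    audit["deduped_pairs"] = len(deduped)

    opposite = opposite_effect_filter(deduped, drop_ambiguous=cfg.drop_ambiguous)
    audit["opposite_pairs"] = len(opposite)

    verified = verify_same_snp(opposite, stats_a, stats_b)
    records = pleiotropic_records(verified)
    audit["pleiotropic_snps"] = len(records)

    annotated = map_to_genes(records, genes, flank_bp=cfg.flank_bp)
    gene_region = [r for r in annotated if r.region_class != "intergenic"]
    intergenic = [r for r in annotated if r.region_class == "intergenic"]
    audit["gene_region_snps"] = len(gene_region)
    audit["intergenic_snps"] = len(intergenic)
    return gene_region, intergenic, audit


def records_to_frame(records: Sequence[PleiotropyRecord]) -> pd.DataFrame:
    """Tabular view of pleiotropy records (one row per SNP)."""
    rows = []
    for r in records:
        rows.append(
            {
                "snp_id": r.snp_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "gene": r.gene if r.gene is not None else ".",
                "region": r.region_class,
                "allele": r.allele_pair,
                "or_a": r.or_a,
                "p_a": r.p_a,
                "or_b": r.or_b,
                "p_b": r.p_b,
                "all_hits": ";".join(
                    f"{h.gene_name}:{h.region_class}" for h in r.all_hits
                ),
            }
        )
    cols = ["snp_id", "chrom", "pos", "gene", "region", "allele",
            "or_a", "p_a", "or_b", "p_b", "all_hits"]
    return pd.DataFrame(rows, columns=cols)
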