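"""Packaged reference fixtures: the published 18-SNP pleiotropy table.

``load_table1`` returns the published table of 18 putatively pleiotropic
SNPs in the extended HLA region of chromosome 6p, with each SNP's gene,
region class (exon/intron/flanking), shared allele pair, and the odds
ratio and p-value in each disease (RA = rheumatoid arthritis,
SZ = schizophrenia). The two diseases' effects sit on opposite sides of
OR = 1 in every row — the defining pattern the scan searches for.

``table1_associations`` re-expresses the table as two per-study record
lists so it can be fed through the cascade in self-pair mode, and
``table1_gene_models`` builds *synthetic* schematic transcript models laid
out so that every SNP classifies to its printed gene and region class —
they are geometric stand-ins for the real hg19 transcript annotations, not
real gene structures, and are intended for structural tests and worked
examples only.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

from pleioscan.scan import GeneModel, classify_position
from pleioscan.summary_stats import SnpAssociation


def load_table1() -> pd.DataFrame:
    """The packaged 18-SNP table as a DataFrame (one row per SNP)."""
    ref = importlib.resources.files("pleioscan.data").joinpath("table1.tsv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def table1_associations() -> tuple[list[SnpAssociation], list[SnpAssociation]]:
    """The table split into (RA records, SZ records) on the shared allele pair."""
    frame = load_table1()
    ra, sz = [], []
    for row in frame.itertuples(index=False):
        effect, other = str(row.allele).split("/")
        common = dict(
            snp_id=str(row.snp_id), chrom=str(row.chrom), pos=int(row.pos),
            effect_allele=effect, other_allele=other,
        )
        ra.append(SnpAssociation(**common, odds_ratio=float(row.ra_or),
                                 p_value=float(row.ra_p), trait="RA"))
        sz.append(SnpAssociation(**common, odds_ratio=float(row.sz_or),
                                 p_value=float(row.sz_p), trait="SZ"))
    return ra, sz


# Geometry of the synthetic stand-in models: a transcript reaches this far
# on each side of the SNPs assigned to it, and flanking-class SNPs must fall
# within flank_bp outside the transcript body.
_PAD = 600


def table1_gene_models(flank_bp: int = 5000) -> list[GeneModel]:
    """Synthetic schematic transcript models consistent with the table.

    For each gene, the transcript body spans its exon/intron SNPs with a
    small pad; every exon-class SNP gets a dedicated 100-bp exon, intron
    SNPs fall between exons, and flanking SNPs are left outside the body
    but within ``flank_bp`` of it. The layout is verified geometry, not
    biology: real transcripts are replaced by minimal interval structures.
    """
    frame = load_table1()
    models: list[GeneModel] = []
    for gene, rows in frame.groupby("gene", sort=False):
        chrom = str(rows["chrom"].iloc[0])
        inside = rows[rows["region"].isin(["exon", "intron"])]
        flanking = rows[rows["region"] == "flanking"]
        pos0 = {int(p) - 1 for p in rows["pos"]}

        if len(inside):
            tx_start = int(inside["pos"].min()) - 1 - _PAD
            tx_end = int(inside["pos"].max()) - 1 + _PAD
        else:  # flanking-only gene: put the body just upstream of the SNPs
            tx_start = int(flanking["pos"].min()) - 1 - 3000
            tx_end = tx_start + 2000
        # flanking SNPs must end up outside [tx_start, tx_end) but in range
        for p in flanking["pos"]:
            p0 = int(p) - 1
            if tx_start <= p0 < tx_end:
                tx_end = min(tx_end, p0)  # shrink body to expose the SNP
        raw_exons = sorted(
            (int(p) - 1 - 50, int(p) - 1 + 50)
            for p in inside.loc[inside["region"] == "exon", "pos"]
        )
        exons: list[tuple[int, int]] = []
        for s, e in raw_exons:  # merge overlapping exon windows
            if exons and s <= exons[-1][1]:
                exons[-1] = (exons[-1][0], max(e, exons[-1][1]))
            else:
                exons.append((s, e))
        model = GeneModel(gene_name=str(gene), chrom=chrom, strand="+",
                          tx_start=tx_start, tx_end=max(tx_end, tx_start + 100),
                          exons=tuple(exons))
        # geometric self-check: every assigned SNP classifies as printed
        for row in rows.itertuples(index=False):
            got = classify_position(int(row.pos) - 1, model, flank_bp)
            if got != row.region:
                raise AssertionError(
                    f"fixture geometry broken: {row.snp_id} -> {got}, "
                    f"expected {row.region}"
                )
        models.append(model)
    return models
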