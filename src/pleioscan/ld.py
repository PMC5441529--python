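"""Linkage disequilibrium from phased haplotypes, and greedy LD pruning.

The squared LD coefficient between two biallelic loci is computed from
phased haplotype frequencies::

    r^2 = D^2 / (pA (1-pA) pB (1-pB)),   D = pAB - pA pB

where ``pA``, ``pB`` are the alternate-allele frequencies of the two loci
across haplotypes and ``pAB`` the frequency of haplotypes carrying both
alternate alleles. Equivalently, r^2 is the squared Pearson correlation of
the two 0/1 haplotype columns — the implementation uses the frequency form,
and the test-suite oracle enumerates the 2x2 haplotype contingency table.

Pruning uses the standard greedy "clumping" order: sort associations by
ascending p-value (ties by position, then SNP id, so the result is a total
order independent of input row order), then accept a SNP iff its r^2 with
every already-accepted SNP within a physical window on the same chromosome
is at or below the cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from pleioscan.summary_stats import SnpAssociation

logger = logging.getLogger(__name__)

VARIANT_COLUMNS = ["snp_id", "chrom", "pos", "ref", "alt"]


class MonomorphicSnpError(ValueError):
    """LD is undefined for a SNP with allele frequency 0 or 1."""


@dataclass(frozen=True)
class LdStatistic:
    """Pairwise LD record; symmetric in its two SNPs."""

    snp_a: str
    snp_b: str
    r2: float


@dataclass
class HaplotypePanel:
    """Phased reference panel: variant metadata plus an H x V 0/1 matrix.

    ``variants`` must carry columns ``snp_id, chrom, pos, ref, alt`` and be
    strictly sorted by (chrom, pos); ``haplotypes[h, v]`` is 1 when
    haplotype ``h`` carries the alternate allele of variant ``v``.
    """

    variants: pd.DataFrame
    haplotypes: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D matrix")
        if self.haplotypes.shape[0] < 2:
            raise ValueError("need at least 2 haplotypes")
        if self.haplotypes.shape[1] != len(self.variants):
            raise ValueError("haplotype columns must match variant rows")
        vals = np.unique(self.haplotypes)
        if not np.isin(vals, [0, 1]).all():
            raise ValueError("haplotype entries must be 0/1")
        v = self.variants
        order = list(zip(v["chrom"].astype(str), v["pos"].astype(int)))
        if any(order[i] >= order[i + 1] for i in range(len(order) - 1)):
            raise ValueError("variants must be strictly increasing by (chrom, pos)")
        self._index = {s: i for i, s in enumerate(v["snp_id"])}

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def column(self, snp_id: str) -> np.ndarray:
        try:
            return self.haplotypes[:, self._index[snp_id]]
        except KeyError:
            raise KeyError(f"SNP {snp_id!r} not in panel") from None

    def position(self, snp_id: str) -> tuple[str, int]:
        i = self._index[snp_id]
        row = self.variants.iloc[i]
        return str(row["chrom"]), int(row["pos"])

    # ---- I/O ------------------------------------------------------------

    def to_tsv(self, matrix_path: str | Path, variants_path: str | Path) -> None:
        """Write the 0/1 matrix and its variant-metadata sidecar as TSV."""
        pd.DataFrame(self.haplotypes).to_csv(
            matrix_path, sep="\t", index=False, header=False
        )
        self.variants[VARIANT_COLUMNS].to_csv(variants_path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, matrix_path: str | Path, variants_path: str | Path
    ) -> "HaplotypePanel":
        """Read a panel written by :meth:`to_tsv`."""
        mat = pd.read_csv(matrix_path, sep="\t", header=None).to_numpy(dtype=np.uint8)
        variants = pd.read_csv(variants_path, sep="\t", dtype={"chrom": str})
        return cls(variants=variants, haplotypes=mat)

    @classmethod
    def from_phased_vcf(cls, path: str | Path) -> "HaplotypePanel":
        """Ingest a phased VCF: every GT must use '|' separators.

        Requires the optional ``cyvcf2`` dependency. Multi-allelic sites and
        records with missing or unphased genotypes are rejected.
        """
        from cyvcf2 import VCF  # optional dependency, imported lazily

        rows, cols = [], []
        vcf = VCF(str(path))
        for var in vcf:
            if len(var.ALT) != 1:
                raise ValueError(f"{var.ID}: only biallelic sites supported")
            gts = var.genotypes  # [[a0, a1, phased], ...]
            if any(len(g) < 3 or not g[2] for g in gts):
                raise ValueError(f"{var.ID}: unphased genotype encountered")
            hap = [allele for g in gts for allele in g[:2]]
            if any(a < 0 for a in hap):
                raise ValueError(f"{var.ID}: missing genotype")
            cols.append(hap)
            rows.append(
                {
                    "snp_id": var.ID or f"{var.CHROM}:{var.POS}",
                    "chrom": str(var.CHROM),
                    "pos": int(var.POS),
                    "ref": var.REF,
                    "alt": var.ALT[0],
                }
            )
        variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
        mat = np.array(cols, dtype=np.uint8).T
        return cls(variants=variants, haplotypes=mat)


def _r2_from_columns(x: np.ndarray, y: np.ndarray) -> float:
    h = x.shape[0]
    p_a = x.sum() / h
    p_b = y.sum() / h
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise MonomorphicSnpError("monomorphic SNP: LD undefined")
    p_ab = (x & y).sum() / h
    d = p_ab - p_a * p_b
    return float(d * d / (p_a * (1 - p_a) * p_b * (1 - p_b)))


def compute_r2(panel: HaplotypePanel, snp_a: str, snp_b: str) -> LdStatistic:
    """r^2 between two panel SNPs from phased haplotype frequencies.

    Raises :class:`MonomorphicSnpError` when either SNP is fixed in the
    panel, and ``KeyError`` when a SNP is absent.
    """
    x = panel.column(snp_a).astype(np.int64)
    y = panel.column(snp_b).astype(np.int64)
    return LdStatistic(snp_a=snp_a, snp_b=snp_b, r2=_r2_from_columns(x, y))


def ld_prune(
    assocs: Sequence[SnpAssociation],
    panel: HaplotypePanel,
    p_threshold: float = 1e-8,
    r2_max: float = 0.6,
    window_bp: int = 1_000_000,
) -> list[SnpAssociation]:
    """Greedy p-value-ordered LD pruning ("clumping").

    Keeps only associations with ``p < p_threshold``, then walks them in
    ascending-p order accepting each SNP whose r^2 with every previously
    accepted SNP within ``window_bp`` on the same chromosome is
    ``<= r2_max``. Cross-chromosome and out-of-window r^2 is treated as 0.
    SNPs absent from the panel are excluded (logged, not fatal); the output
    is in acceptance (ascending-p) order.
    """
    candidates = sorted(
        (a for a in assocs if a.p_value < p_threshold),
        key=lambda a: (a.p_value, a.chrom, a.pos, a.snp_id),
    )
    missing = [a for a in candidates if a.snp_id not in panel]
    if missing:
        logger.warning("ld_prune: %d SNP(s) absent from panel, excluded", len(missing))
        candidates = [a for a in candidates if a.snp_id in panel]

    accepted: list[SnpAssociation] = []
    for cand in candidates:
        ok = True
        for kept in accepted:
            if kept.chrom != cand.chrom:
                continue
            if abs(kept.pos - cand.pos) > window_bp:
                continue
            if compute_r2(panel, cand.snp_id, kept.snp_id).r2 > r2_max:
                ok = False
                break
        if ok:
            accepted.append(cand)
    return accepted
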