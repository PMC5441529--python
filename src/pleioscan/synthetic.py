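"""Seeded generators for every input the pipeline consumes, with ground truth.

The generators stand in for the external resources a real cross-disorder
study draws on — phased reference haplotypes, two diseases' GWAS summary
statistics, gene models, curated/predicted PPI edge lists, and
differential-expression resources — at desk scale and with a
machine-readable :class:`SyntheticTruth` describing exactly what was
planted. All randomness flows from a single integer seed through
``numpy.random.default_rng``; identical arguments give byte-identical
outputs.

What is emulated, and how:

* **Haplotype panels** use founder-copy-with-flips block LD: each block
  draws one founder 0/1 column and copies it into its member SNPs, flipping
  a small controlled fraction of entries so that within-block pairwise r^2
  lands inside a requested range (verified against :func:`pleioscan.ld.compute_r2`
  and resampled on miss); different blocks are sampled independently, so
  cross-block r^2 is near 0. This is deliberately not a coalescent
  simulation — the pipeline uses LD only as a filter statistic.
* **Two-trait GWAS tables** simulate, per SNP and trait, case/control
  alternate-allele counts from the frequencies implied by a planted
  per-allele odds ratio (OR = 1 at null SNPs), then report the sample OR
  and the two-sided Wald p-value on the log odds ratio from the 2x2 allele
  table, with the Haldane–Anscombe 0.5 correction when a cell is empty.
* **Gene models** are placed around chosen SNPs so that each lands in a
  requested region class (exon / intron / flanking / intergenic).
* **PPI networks** plant an exact shared-interactor set between the two
  disease nets and split edge tags known/novel at a requested ratio.
* **Expression fixtures** plant exact reciprocal up/down gene sets and,
  optionally, a perturbagen column constructed to reverse the query
  signature.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from pleioscan.ld import HaplotypePanel, _r2_from_columns
from pleioscan.scan import GeneModel
from pleioscan.summary_stats import SnpAssociation

TINY_P = 5e-324  # smallest subnormal double; keeps p-values in (0, 1]


class GenerationError(RuntimeError):
    """A generator could not satisfy its post-conditions (e.g. infeasible r^2)."""


@dataclass
class LdBlock:
    """Specification of one LD block: ``n_snps`` SNPs with pairwise r^2 in
    ``r2_range`` (ignored for single-SNP blocks)."""

    n_snps: int
    r2_range: tuple[float, float] = (0.8, 1.0)


@dataclass
class SyntheticTruth:
    """Ground truth serialized alongside every synthetic data set."""

    seed: int
    planted_pleiotropic_snps: list[tuple[str, float, float]] = field(default_factory=list)
    planted_block_structure: list[dict] = field(default_factory=list)
    planted_gene_classes: dict[str, str] = field(default_factory=dict)
    planted_overlap_genes: list[str] = field(default_factory=list)
    planted_reciprocal: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            raw = json.load(fh)
        raw["planted_pleiotropic_snps"] = [
            tuple(t) for t in raw.get("planted_pleiotropic_snps", [])
        ]
        return cls(**raw)


# ---------------------------------------------------------------------------
# haplotype panel
# ---------------------------------------------------------------------------


def gen_haplotype_panel(
    n_haplotypes: int,
    blocks: Sequence[LdBlock],
    seed: int,
    chrom: str = "6",
    start_pos: int = 1_000_000,
    spacing_bp: int = 2000,
    snp_prefix: str = "snp",
    max_retries: int = 200,
) -> tuple[HaplotypePanel, SyntheticTruth]:
    """Generate a phased panel realizing the requested block-LD structure.

    SNPs are laid out left to right, ``spacing_bp`` apart, blocks contiguous.
    Within-block pairwise r^2 is guaranteed (by rejection sampling) to fall
    inside each block's ``r2_range``; raises :class:`GenerationError` when a
    block's request is infeasible at the given haplotype count.
    """
    if n_haplotypes < 20 or n_haplotypes % 2:
        raise ValueError("n_haplotypes must be even and >= 20")
    rng = np.random.default_rng(seed)
    n_snps = sum(b.n_snps for b in blocks)
    mat = np.empty((n_haplotypes, n_snps), dtype=np.uint8)
    truth_blocks = []
    snp_ids = [f"{snp_prefix}{i:05d}" for i in range(n_snps)]

    col = 0
    for b in blocks:
        lo, hi = b.r2_range
        members = snp_ids[col : col + b.n_snps]
        if b.n_snps == 1:
            mat[:, col] = _polymorphic_column(rng, n_haplotypes)
            col += 1
        else:
            # per-copy correlation c gives pairwise r ~ c^2; aim mid-range
            c = (0.5 * (lo + hi)) ** 0.25
            flip_frac = (1.0 - c) / 2.0
            block_cols = _block_columns(
                rng, n_haplotypes, b.n_snps, flip_frac, lo, hi, max_retries
            )
            mat[:, col : col + b.n_snps] = block_cols
            col += b.n_snps
        truth_blocks.append({"members": members, "r2_range": [lo, hi]})

    variants = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": chrom,
            "pos": [start_pos + i * spacing_bp for i in range(n_snps)],
            "ref": "A",
            "alt": "G",
        }
    )
    panel = HaplotypePanel(variants=variants, haplotypes=mat)
    truth = SyntheticTruth(seed=seed, planted_block_structure=truth_blocks)
    return panel, truth


def _polymorphic_column(rng: np.random.Generator, h: int) -> np.ndarray:
    for _ in range(100):
        maf = rng.uniform(0.2, 0.5)
        col = (rng.random(h) < maf).astype(np.uint8)
        if 0 < col.sum() < h:
            return col
    raise GenerationError("could not draw a polymorphic column")


def _block_columns(
    rng: np.random.Generator,
    h: int,
    n_snps: int,
    flip_frac: float,
    lo: float,
    hi: float,
    max_retries: int,
) -> np.ndarray:
    for _ in range(max_retries):
        founder = _polymorphic_column(rng, h)
        cols = np.empty((h, n_snps), dtype=np.uint8)
        for j in range(n_snps):
            flips = rng.random(h) < flip_frac
            cols[:, j] = founder ^ flips.astype(np.uint8)
        if any(not (0 < cols[:, j].sum() < h) for j in range(n_snps)):
            continue
        ok = True
        for i in range(n_snps):
            for j in range(i + 1, n_snps):
                r2 = _r2_from_columns(
                    cols[:, i].astype(np.int64), cols[:, j].astype(np.int64)
                )
                if not (lo <= r2 <= hi):
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return cols
    raise GenerationError(
        f"could not realize pairwise r^2 in [{lo}, {hi}] for a {n_snps}-SNP "
        f"block with {h} haplotypes after {max_retries} attempts"
    )


# ---------------------------------------------------------------------------
# two-trait GWAS
# ---------------------------------------------------------------------------


def gen_two_trait_gwas(
    panel: HaplotypePanel,
    effects: Mapping[str, tuple[float, float]],
    n_cases_a: int,
    n_controls_a: int,
    n_cases_b: int,
    n_controls_b: int,
    seed: int,
    trait_a: str = "A",
    trait_b: str = "B",
) -> tuple[list[SnpAssociation], list[SnpAssociation]]:
    """Simulate two case/control association tables over the panel's SNPs.

    ``effects`` maps planted SNP ids to their true per-allele odds ratios
    ``(or_a, or_b)``; every other SNP is null (OR = 1) in both traits. The
    control alternate-allele frequency of each SNP is its panel frequency;
    the case frequency follows from the planted OR on the odds scale.
    Sample OR and two-sided Wald p come from the simulated 2x2 allele table.
    """
    for name, n in (("n_cases_a", n_cases_a), ("n_controls_a", n_controls_a),
                    ("n_cases_b", n_cases_b), ("n_controls_b", n_controls_b)):
        if n <= 0:
            raise ValueError(f"{name} must be positive")
    missing = [s for s in effects if s not in panel]
    if missing:
        raise ValueError(f"planted SNP(s) not in panel: {missing}")

    rng = np.random.default_rng(seed)
    variants = panel.variants
    p0 = panel.haplotypes.mean(axis=0)
    n_v = len(variants)
    or_a = np.ones(n_v)
    or_b = np.ones(n_v)
    idx = {s: i for i, s in enumerate(variants["snp_id"])}
    for snp, (oa, ob) in effects.items():
        or_a[idx[snp]] = oa
        or_b[idx[snp]] = ob

    stats_a = _simulate_trait(rng, variants, p0, or_a, n_cases_a, n_controls_a, trait_a)
    stats_b = _simulate_trait(rng, variants, p0, or_b, n_cases_b, n_controls_b, trait_b)
    return stats_a, stats_b


def _simulate_trait(
    rng: np.random.Generator,
    variants: pd.DataFrame,
    p0: np.ndarray,
    true_or: np.ndarray,
    n_cases: int,
    n_controls: int,
    trait: str,
) -> list[SnpAssociation]:
    odds_case = true_or * p0 / (1 - p0)
    p_case = odds_case / (1 + odds_case)
    a = rng.binomial(2 * n_cases, p_case).astype(float)       # case alt
    c = rng.binomial(2 * n_controls, p0).astype(float)        # control alt
    b = 2 * n_cases - a
    d = 2 * n_controls - c
    empty = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    a, b, c, d = (x + 0.5 * empty for x in (a, b, c, d))
    or_hat = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = np.log(or_hat) / se
    p = np.maximum(2 * ndtr(-np.abs(z)), TINY_P)
    return [
        SnpAssociation(
            snp_id=str(row.snp_id),
            chrom=str(row.chrom),
            pos=int(row.pos),
            effect_allele=str(row.alt),
            other_allele=str(row.ref),
            odds_ratio=float(or_hat[i]),
            p_value=float(p[i]),
            trait=trait,
        )
        for i, row in enumerate(variants.itertuples(index=False))
    ]


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


def gen_gene_models(
    snp_positions: Mapping[str, tuple[str, int]],
    classes: Mapping[str, str],
    seed: int,
    n_background_genes: int = 0,
    gene_half_width: int = 1500,
    flank_bp: int = 5000,
) -> tuple[list[GeneModel], dict[str, str]]:
    """Place transcript models so each chosen SNP lands in a requested class.

    ``classes`` maps SNP ids to one of exon/intron/flanking/intergenic;
    ``snp_positions`` gives each SNP's (chrom, 1-based pos). Intergenic SNPs
    get no gene. Background genes are laid out well beyond the last SNP so
    they cannot interfere. Callers must keep classed SNPs farther apart than
    ``2 * (gene_half_width + flank_bp)``; violations raise
    :class:`GenerationError`. Returns the models and the intended class per
    SNP (the recorded ground truth).
    """
    rng = np.random.default_rng(seed)
    models: list[GeneModel] = []
    truth: dict[str, str] = {}

    positions = sorted(
        ((snp, *snp_positions[snp]) for snp in classes), key=lambda t: (t[1], t[2])
    )
    min_sep = 2 * (gene_half_width + flank_bp)
    for (s1, c1, p1), (s2, c2, p2) in zip(positions, positions[1:]):
        if c1 == c2 and p2 - p1 < min_sep:
            raise GenerationError(
                f"classed SNPs {s1} and {s2} are {p2 - p1} bp apart; need "
                f">= {min_sep} to avoid overlapping gene territories"
            )

    for i, (snp, chrom, pos) in enumerate(positions):
        cls = classes[snp]
        truth[snp] = cls
        pos0 = pos - 1
        name = f"GENE_{snp}"
        if cls == "exon":
            tx = (pos0 - gene_half_width, pos0 + gene_half_width)
            exons = ((tx[0], tx[0] + 100), (pos0 - 50, pos0 + 50),
                     (tx[1] - 100, tx[1]))
        elif cls == "intron":
            tx = (pos0 - gene_half_width, pos0 + gene_half_width)
            exons = ((tx[0], tx[0] + 100), (tx[1] - 100, tx[1]))
        elif cls == "flanking":
            # transcript upstream; SNP sits inside the downstream flank
            offset = int(rng.integers(500, flank_bp - 500))
            tx = (pos0 + offset, pos0 + offset + 2 * gene_half_width)
            exons = ((tx[0], tx[0] + 100), (tx[1] - 100, tx[1]))
        elif cls == "intergenic":
            continue
        else:
            raise ValueError(f"unknown region class {cls!r} for {snp}")
        models.append(
            GeneModel(gene_name=name, chrom=chrom, strand="+",
                      tx_start=tx[0], tx_end=tx[1], exons=exons)
        )

    if n_background_genes:
        far = max((p for _, _, p in positions), default=0) + 200_000
        chrom_bg = positions[0][1] if positions else "1"
        for j in range(n_background_genes):
            start = far + j * 30_000 + int(rng.integers(0, 5_000))
            width = int(rng.integers(2_000, 10_000))
            models.append(
                GeneModel(
                    gene_name=f"BG{j:04d}", chrom=chrom_bg, strand="+",
                    tx_start=start, tx_end=start + width,
                    exons=((start, start + 200), (start + width - 200, start + width)),
                )
            )
    return models, truth


# ---------------------------------------------------------------------------
# PPI networks
# ---------------------------------------------------------------------------


def gen_ppi_networks(
    n_seeds_a: int,
    n_seeds_b: int,
    n_interactors_a: int,
    n_interactors_b: int,
    seed: int,
    n_shared_interactors: int | None = None,
    overlap_fraction: float | None = None,
    known_fraction: float = 0.65,
    extra_edge_prob: float = 0.3,
) -> tuple[
    list[tuple[str, str, str]],
    list[tuple[str, str, str]],
    list[str],
    list[str],
    SyntheticTruth,
]:
    """Two disease PPI edge lists with an exactly planted shared-interactor set.

    Seed genes of the two nets are disjoint by construction; the planted
    overlap is a set of interactors wired to at least one seed of *each*
    net, so the realized node overlap of the two interactomes equals the
    planted set exactly. Give either ``n_shared_interactors`` or
    ``overlap_fraction`` (of the smaller interactor count). Edge tags are
    known/novel with exactly ``round(known_fraction * n_edges)`` known edges
    per net (the requested ratio within +/-1). ``extra_edge_prob`` is the
    chance an interactor gets a second seed attachment within its net.

    Returns ``(edges_a, edges_b, seeds_a, seeds_b, truth)``.
    """
    if (n_shared_interactors is None) == (overlap_fraction is None):
        raise ValueError("give exactly one of n_shared_interactors / overlap_fraction")
    if n_shared_interactors is None:
        n_shared_interactors = round(
            overlap_fraction * min(n_interactors_a, n_interactors_b)
        )
    if n_shared_interactors > min(n_interactors_a, n_interactors_b):
        raise ValueError("shared interactors exceed an interactor count")

    rng = np.random.default_rng(seed)
    seeds_a = [f"GA{i:04d}" for i in range(n_seeds_a)]
    seeds_b = [f"GB{i:04d}" for i in range(n_seeds_b)]
    shared = [f"IC{i:04d}" for i in range(n_shared_interactors)]
    excl_a = [f"IA{i:04d}" for i in range(n_interactors_a - n_shared_interactors)]
    excl_b = [f"IB{i:04d}" for i in range(n_interactors_b - n_shared_interactors)]

    def wire(interactors: list[str], seeds: list[str]) -> list[tuple[str, str]]:
        pairs = []
        for node in interactors:
            first = seeds[rng.integers(len(seeds))]
            pairs.append((first, node))
            if len(seeds) > 1 and rng.random() < extra_edge_prob:
                second = seeds[rng.integers(len(seeds))]
                if second != first:
                    pairs.append((second, node))
        return pairs

    pairs_a = wire(excl_a + shared, seeds_a)
    pairs_b = wire(excl_b + shared, seeds_b)
    edges_a = _tag_edges(rng, pairs_a, known_fraction)
    edges_b = _tag_edges(rng, pairs_b, known_fraction)

    truth = SyntheticTruth(seed=seed, planted_overlap_genes=sorted(shared))
    return edges_a, edges_b, seeds_a, seeds_b, truth


def _tag_edges(
    rng: np.random.Generator, pairs: list[tuple[str, str]], known_fraction: float
) -> list[tuple[str, str, str]]:
    n_known = round(known_fraction * len(pairs))
    tags = np.array(["known"] * n_known + ["novel"] * (len(pairs) - n_known))
    rng.shuffle(tags)
    return [(a, b, str(t)) for (a, b), t in zip(pairs, tags)]


# ---------------------------------------------------------------------------
# pathway gene sets
# ---------------------------------------------------------------------------


def gen_gene_sets(
    gene_pool: Sequence[str],
    n_pathways: int,
    size_range: tuple[int, int],
    seed: int,
) -> dict[str, set[str]]:
    """Random pathway gene sets (GMT content) drawn from ``gene_pool``."""
    rng = np.random.default_rng(seed)
    pool = list(gene_pool)
    gmt = {}
    for i in range(n_pathways):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        members = rng.choice(len(pool), size=min(size, len(pool)), replace=False)
        gmt[f"PATHWAY_{i:03d}"] = {pool[j] for j in members}
    return gmt


# ---------------------------------------------------------------------------
# expression fixtures
# ---------------------------------------------------------------------------


def gen_expression_fixtures(
    n_genes: int,
    n_reciprocal_up_down: int,
    n_reciprocal_down_up: int,
    n_perturbagens: int,
    seed: int,
    include_reverser: bool = True,
) -> tuple[dict[str, float], dict[str, float], pd.DataFrame, SyntheticTruth]:
    """Two DE score tables with planted reciprocal sets, plus a perturbagen matrix.

    Returns ``(scores_a, scores_b, matrix, truth)``. Genes outside the
    planted reciprocal sets get same-sign scores in the two diseases, so the
    reciprocal sets recovered from the tables equal the planted sets
    exactly. When ``include_reverser`` is set, the last matrix column
    (``REVERSER``) is the negated disease-A query signature, i.e. a
    perturbagen constructed to oppose it.
    """
    n_planted = n_reciprocal_up_down + n_reciprocal_down_up
    if n_planted > n_genes:
        raise ValueError("more reciprocal genes requested than genes")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    up_down = genes[:n_reciprocal_up_down]
    down_up = genes[n_reciprocal_up_down:n_planted]
    rest = genes[n_planted:]

    mag = lambda n: rng.uniform(0.5, 3.0, size=n)
    scores_a: dict[str, float] = {}
    scores_b: dict[str, float] = {}
    for g, m1, m2 in zip(up_down, mag(len(up_down)), mag(len(up_down))):
        scores_a[g], scores_b[g] = m1, -m2
    for g, m1, m2 in zip(down_up, mag(len(down_up)), mag(len(down_up))):
        scores_a[g], scores_b[g] = -m1, m2
    signs = rng.choice([-1.0, 1.0], size=len(rest))
    for g, s, m1, m2 in zip(rest, signs, mag(len(rest)), mag(len(rest))):
        scores_a[g], scores_b[g] = s * m1, s * m2

    matrix = pd.DataFrame(
        rng.normal(size=(n_genes, n_perturbagens)),
        index=genes,
        columns=[f"PERT_{j:03d}" for j in range(n_perturbagens)],
    )
    if include_reverser:
        matrix["REVERSER"] = [-scores_a[g] for g in genes]

    truth = SyntheticTruth(
        seed=seed,
        planted_reciprocal={
            "up_a_down_b": sorted(up_down),
            "down_a_up_b": sorted(down_up),
        },
    )
    return scores_a, scores_b, matrix, truth


# ---------------------------------------------------------------------------
# full study bundle (preset scenarios)
# ---------------------------------------------------------------------------

#: Study-condition presets. "mini" is the default desk-scale study: five
#: opposite-direction SNPs planted among 2,000 null SNPs, 20k cases / 20k
#: controls per trait, 200 reference haplotypes; the reciprocal-expression
#: counts mirror a published neuron-vs-synovium comparison (58 up/down, 48
#: down/up). "tiny" is a fast smoke-scale variant of the same design.
PRESETS: dict[str, dict] = {
    "mini": dict(
        n_haplotypes=200, n_null_snps=2000, n_planted=5,
        planted_or=(0.7, 1.4), n_cases=20_000, n_controls=20_000,
        n_seeds_a=20, n_seeds_b=15, n_interactors_a=120, n_interactors_b=80,
        n_shared_interactors=30, n_pathways=25,
        n_expr_genes=1000, n_up_down=58, n_down_up=48, n_perturbagens=20,
    ),
    "tiny": dict(
        n_haplotypes=100, n_null_snps=200, n_planted=3,
        planted_or=(0.7, 1.4), n_cases=20_000, n_controls=20_000,
        n_seeds_a=6, n_seeds_b=5, n_interactors_a=25, n_interactors_b=18,
        n_shared_interactors=8, n_pathways=8,
        n_expr_genes=200, n_up_down=12, n_down_up=9, n_perturbagens=8,
    ),
}


@dataclass
class StudyBundle:
    """In-memory result of :func:`generate_study`."""

    panel: HaplotypePanel
    stats_a: list[SnpAssociation]
    stats_b: list[SnpAssociation]
    genes: list[GeneModel]
    edges_a: list[tuple[str, str, str]]
    edges_b: list[tuple[str, str, str]]
    seeds_a: list[str]
    seeds_b: list[str]
    gmt: dict[str, set[str]]
    expr_scores_a: dict[str, float]
    expr_scores_b: dict[str, float]
    perturbagen_matrix: pd.DataFrame
    truth: SyntheticTruth


def generate_study(seed: int, preset: str = "mini") -> StudyBundle:
    """Generate one full synthetic study under a named preset.

    The planted pleiotropic SNPs sit at the head of 3-SNP LD blocks
    (pairwise r^2 >= 0.8) spread evenly through otherwise-independent null
    SNPs; their planted odds ratios alternate direction between the two
    traits. Planted SNPs are assigned gene classes cycling through
    exon/intron/flanking/intergenic.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; have {sorted(PRESETS)}")
    p = PRESETS[preset]
    rng_seeds = np.random.SeedSequence(seed).generate_state(8) % (2**31)

    n_planted = p["n_planted"]
    n_null = p["n_null_snps"]
    # planted blocks of 3 (planted SNP + 2 null mates) evenly interleaved
    singles_per_gap = (n_null - 2 * n_planted) // n_planted
    leftover = (n_null - 2 * n_planted) - singles_per_gap * n_planted
    blocks: list[LdBlock] = []
    planted_positions_idx: list[int] = []
    idx = 0
    for i in range(n_planted):
        planted_positions_idx.append(idx)
        blocks.append(LdBlock(n_snps=3, r2_range=(0.8, 1.0)))
        idx += 3
        n_singles = singles_per_gap + (1 if i < leftover else 0)
        blocks.extend(LdBlock(n_snps=1) for _ in range(n_singles))
        idx += n_singles
    panel, truth = gen_haplotype_panel(
        n_haplotypes=p["n_haplotypes"], blocks=blocks, seed=int(rng_seeds[0])
    )

    snp_ids = list(panel.variants["snp_id"])
    planted_ids = [snp_ids[i] for i in planted_positions_idx]
    or_lo, or_hi = p["planted_or"]
    effects = {
        s: ((or_lo, or_hi) if i % 2 == 0 else (or_hi, or_lo))
        for i, s in enumerate(planted_ids)
    }
    truth.planted_pleiotropic_snps = [
        (s, *effects[s]) for s in planted_ids
    ]
    stats_a, stats_b = gen_two_trait_gwas(
        panel, effects,
        n_cases_a=p["n_cases"], n_controls_a=p["n_controls"],
        n_cases_b=p["n_cases"], n_controls_b=p["n_controls"],
        seed=int(rng_seeds[1]), trait_a="diseaseA", trait_b="diseaseB",
    )

    pos_by_id = {
        str(r.snp_id): (str(r.chrom), int(r.pos))
        for r in panel.variants.itertuples(index=False)
    }
    class_cycle = ["exon", "intron", "flanking", "intergenic"]
    classes = {s: class_cycle[i % 4] for i, s in enumerate(planted_ids)}
    genes, gene_truth = gen_gene_models(
        pos_by_id, classes, seed=int(rng_seeds[2]), n_background_genes=10
    )
    truth.planted_gene_classes = gene_truth

    edges_a, edges_b, seeds_a, seeds_b, ppi_truth = gen_ppi_networks(
        n_seeds_a=p["n_seeds_a"], n_seeds_b=p["n_seeds_b"],
        n_interactors_a=p["n_interactors_a"], n_interactors_b=p["n_interactors_b"],
        n_shared_interactors=p["n_shared_interactors"], seed=int(rng_seeds[3]),
    )
    truth.planted_overlap_genes = ppi_truth.planted_overlap_genes

    pool = sorted(
        {g for e in edges_a + edges_b for g in e[:2]} | set(seeds_a) | set(seeds_b)
    )
    gmt = gen_gene_sets(pool, p["n_pathways"], (8, 30), seed=int(rng_seeds[4]))

    sa, sb, matrix, expr_truth = gen_expression_fixtures(
        p["n_expr_genes"], p["n_up_down"], p["n_down_up"], p["n_perturbagens"],
        seed=int(rng_seeds[5]),
    )
    truth.planted_reciprocal = expr_truth.planted_reciprocal

    return StudyBundle(
        panel=panel, stats_a=stats_a, stats_b=stats_b, genes=genes,
        edges_a=edges_a, edges_b=edges_b, seeds_a=seeds_a, seeds_b=seeds_b,
        gmt=gmt, expr_scores_a=sa, expr_scores_b=sb,
        perturbagen_matrix=matrix, truth=truth,
    )
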