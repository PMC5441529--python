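"""The cascaded cross-trait scan: pairing, dedup, filters, gene mapping."""

import numpy as np
import pytest

from pleioscan import synthetic
from pleioscan.scan import (
    GeneModel,
    ScanConfig,
    SnpPair,
    classify_position,
    dedupe_pairs,
    map_to_genes,
    opposite_effect_filter,
    pair_cross_trait,
    pleiotropic_records,
    read_gene_models,
    run_scan,
    verify_same_snp,
    write_gene_models,
    PleiotropyRecord,
)
from tests.conftest import assoc, make_panel


def pair(r, z, r2, same_snp=None):
    return SnpPair(r=r, z=z, r2=r2,
                   same_snp=r.snp_id == z.snp_id if same_snp is None else same_snp)


class TestPairing:
    def test_self_pair_emitted_at_r2_one(self):
        a = assoc(snp_id="rs1", pos=1000)
        b = assoc(snp_id="rs1", pos=1000, odds=0.8, trait="B")
        pairs = pair_cross_trait([a], [b], panel=None, cfg=ScanConfig())
        assert len(pairs) == 1
        assert pairs[0].r2 == 1.0 and pairs[0].same_snp

    def test_linked_b_snp_paired_distinct_unlinked_not(self):
        rng = np.random.default_rng(2)
        x = (rng.random(400) < 0.5).astype(np.uint8)
        y = x.copy()
        y[rng.choice(400, size=10, replace=False)] ^= 1  # r2 ~ 0.9
        z = (rng.random(400) < 0.5).astype(np.uint8)
        panel = make_panel({"a": list(x), "b": list(y), "c": list(z)})
        pos = {s: panel.position(s)[1] for s in "abc"}
        a = assoc(snp_id="a", pos=pos["a"])
        bs = [assoc(snp_id="b", pos=pos["b"], trait="B"),
              assoc(snp_id="c", pos=pos["c"], trait="B")]
        pairs = pair_cross_trait([a], bs, panel, ScanConfig(window_bp=10_000))
        assert [p.z.snp_id for p in pairs] == ["b"]
        assert pairs[0].r2 >= 0.8 and not pairs[0].same_snp

    def test_no_b_within_window_means_no_pairs(self):
        panel = make_panel({"a": [0, 1, 0, 1], "b": [0, 1, 1, 0]})
        a = assoc(snp_id="a", pos=1000)
        far_b = assoc(snp_id="b", pos=2000, trait="B")
        pairs = pair_cross_trait([a], [far_b], panel,
                                 ScanConfig(window_bp=500))
        assert pairs == []


class TestDedupe:
    def test_highest_r2_wins(self):
        a = assoc(snp_id="a")
        p1 = pair(a, assoc(snp_id="b1", pos=10, p=1e-9, trait="B"), 0.90)
        p2 = pair(a, assoc(snp_id="b2", pos=20, p=1e-8, trait="B"), 0.95)
        assert dedupe_pairs([p1, p2]) == [p2]

    def test_r2_tie_broken_by_smaller_b_pvalue(self):
        a = assoc(snp_id="a")
        p1 = pair(a, assoc(snp_id="b1", pos=10, p=1e-12, trait="B"), 0.90)
        p2 = pair(a, assoc(snp_id="b2", pos=20, p=1e-9, trait="B"), 0.90)
        assert dedupe_pairs([p2, p1]) == [p1]

    def test_full_tie_broken_by_position(self):
        a = assoc(snp_id="a")
        p1 = pair(a, assoc(snp_id="b1", pos=10, p=1e-9, trait="B"), 0.9)
        p2 = pair(a, assoc(snp_id="b2", pos=20, p=1e-9, trait="B"), 0.9)
        assert dedupe_pairs([p2, p1]) == [p1]

    def test_single_candidate_unchanged(self):
        a = assoc(snp_id="a")
        p1 = pair(a, assoc(snp_id="b", pos=10, trait="B"), 0.9)
        assert dedupe_pairs([p1]) == [p1]


class TestOppositeFilter:
    def test_reference_row_retained(self):
        """RA OR 0.89 / SZ OR 1.07423 on the same T/G orientation passes."""
        r = assoc(snp_id="rs915894", ea="T", oa="G", odds=0.89, p=2.1e-17)
        z = assoc(snp_id="rs915894", ea="T", oa="G", odds=1.07423,
                  p=1.23e-8, trait="B")
        kept = opposite_effect_filter([pair(r, z, 1.0)])
        assert len(kept) == 1 and kept[0].opposite_effects

    @pytest.mark.parametrize("or_a,or_b", [(1.2, 1.3), (0.8, 0.9), (1.0, 0.9),
                                           (1.1, 1.0)])
    def test_same_direction_or_boundary_excluded(self, or_a, or_b):
        r = assoc(snp_id="x", odds=or_a)
        z = assoc(snp_id="x", odds=or_b, trait="B")
        assert opposite_effect_filter([pair(r, z, 1.0)]) == []

    def test_allele_swap_is_harmonized_before_the_sign_test(self):
        """ORs 0.9 and 0.85 on swapped alleles are truly opposite (0.9 vs 1.18)."""
        r = assoc(snp_id="x", ea="T", oa="C", odds=0.9)
        z = assoc(snp_id="x", ea="C", oa="T", odds=0.85, trait="B")
        kept = opposite_effect_filter([pair(r, z, 1.0)])
        assert len(kept) == 1
        assert kept[0].z_or_harmonized == pytest.approx(1 / 0.85)

    def test_palindromic_pair_dropped_only_on_request(self):
        r = assoc(snp_id="x", ea="A", oa="T", odds=1.2)
        z = assoc(snp_id="x", ea="A", oa="T", odds=0.9, trait="B")
        assert len(opposite_effect_filter([pair(r, z, 1.0)])) == 1
        assert opposite_effect_filter([pair(r, z, 1.0)], drop_ambiguous=True) == []


class TestVerifySameSnp:
    def test_same_snp_with_opposite_lookups_verifies(self):
        r = assoc(snp_id="s", odds=0.89)
        z = assoc(snp_id="s", odds=1.07, trait="B")
        out = verify_same_snp([pair(r, z, 1.0)], [r], [z])
        assert out[0].cross_verified

    def test_distinct_snp_pair_never_verifies(self):
        r = assoc(snp_id="s1", odds=0.89)
        z = assoc(snp_id="s2", pos=2000, odds=1.07, trait="B")
        out = verify_same_snp([pair(r, z, 0.9)], [r], [z])
        assert not out[0].cross_verified
        assert pleiotropic_records(out) == []

    def test_flipped_allele_lookup_is_harmonized_first(self):
        """B's table reports the other allele; after inversion directions agree,
        so the pair fails verification."""
        r = assoc(snp_id="s", ea="T", oa="C", odds=0.89)
        z_flipped = assoc(snp_id="s", ea="C", oa="T", odds=1.07, trait="B")
        out = verify_same_snp([pair(r, z_flipped, 1.0, same_snp=True)],
                              [r], [z_flipped])
        assert not out[0].cross_verified

    def test_missing_lookup_fails_verification(self):
        r = assoc(snp_id="s", odds=0.89)
        z = assoc(snp_id="s", odds=1.07, trait="B")
        out = verify_same_snp([pair(r, z, 1.0)], [r], [])
        assert not out[0].cross_verified


def toy_record(pos, chrom="1"):
    return PleiotropyRecord(snp_id=f"r{pos}", chrom=chrom, pos=pos,
                            allele_pair="A/G", or_a=0.9, p_a=1e-10,
                            or_b=1.1, p_b=1e-9)


class TestGeneMapping:
    GENE = GeneModel(gene_name="G", chrom="1", strand="+",
                     tx_start=10_000, tx_end=20_000,
                     exons=((10_000, 11_000), (15_000, 15_500)))

    @pytest.mark.parametrize(
        "pos1,expected",
        [
            (10_500, "exon"),       # inside exon 1
            (15_100, "exon"),       # inside exon 2
            (12_000, "intron"),     # in body, between exons
            (8_000, "flanking"),    # 2000+1 bp upstream of tx_start
            (22_500, "flanking"),   # within 5000 bp past tx_end
            (30_001, "intergenic"), # 10001 bp past tx_end
        ],
    )
    def test_region_classes(self, pos1, expected):
        [rec] = map_to_genes([toy_record(pos1)], [self.GENE], flank_bp=5000)
        assert rec.region_class == expected
        assert (rec.gene is None) == (expected == "intergenic")

    def test_priority_exon_over_intron_over_flanking(self):
        exonic = GeneModel(gene_name="E", chrom="1", strand="+",
                           tx_start=9_000, tx_end=11_000,
                           exons=((10_400, 10_600),))
        [rec] = map_to_genes([toy_record(10_500)], [self.GENE, exonic])
        assert rec.gene == "E" and rec.region_class == "exon"
        assert {h.gene_name for h in rec.all_hits} == {"E", "G"}

    def test_unknown_chromosome_is_intergenic(self):
        [rec] = map_to_genes([toy_record(10_500, chrom="99")], [self.GENE])
        assert rec.region_class == "intergenic"

    def test_agrees_with_naive_interval_scan_on_random_models(self):
        """Interval-tree classification matches a brute-force scan oracle."""
        rng = np.random.default_rng(17)
        for _ in range(25):
            models = []
            for g in range(rng.integers(1, 6)):
                start = int(rng.integers(0, 200_000))
                width = int(rng.integers(1_000, 20_000))
                n_ex = int(rng.integers(1, 4))
                bounds = sorted(
                    int(v) for v in rng.integers(start, start + width, size=2 * n_ex)
                )
                exons = tuple(
                    (bounds[2 * i], bounds[2 * i + 1])
                    for i in range(n_ex)
                    if bounds[2 * i] < bounds[2 * i + 1]
                )
                models.append(
                    GeneModel(gene_name=f"g{g}", chrom="1", strand="+",
                              tx_start=start, tx_end=start + width, exons=exons)
                )
            positions = [int(p) for p in rng.integers(1, 230_000, size=40)]
            recs = map_to_genes([toy_record(p) for p in positions], models)
            for rec, pos1 in zip(recs, positions):
                classes = [
                    (c, m.gene_name)
                    for m in models
                    if (c := classify_position(pos1 - 1, m, 5000)) is not None
                ]
                if not classes:
                    assert rec.region_class == "intergenic"
                else:
                    order = {"exon": 0, "intron": 1, "flanking": 2}
                    best = min(classes, key=lambda t: order[t[0]])[0]
                    assert rec.region_class == best
                    assert {h.gene_name for h in rec.all_hits} == {
                        g for _, g in classes
                    }

    def test_bed12_round_trip(self, tmp_path):
        write_gene_models([self.GENE], tmp_path / "g.bed")
        [back] = read_gene_models(tmp_path / "g.bed")
        assert back == self.GENE


class TestRunScan:
    def test_reference_table_self_pair_run(self, table1_records, table1_models):
        """The 18 published SNPs fed as both studies map to 8 genes, all retained."""
        ra, sz = table1_records
        gene_region, intergenic, audit = run_scan(ra, sz, None, table1_models)
        assert audit["pleiotropic_snps"] == 18
        assert len(gene_region) == 18 and not intergenic
        assert len({r.gene for r in gene_region}) == 8

    def test_zero_threshold_empties_stage_one(self, table1_records, table1_models):
        ra, sz = table1_records
        gene_region, intergenic, audit = run_scan(
            ra, sz, None, table1_models, ScanConfig(p_threshold_a=0)
        )
        assert audit["pruned_a"] == 0 and not gene_region and not intergenic

    def test_asymmetry_b_side_not_thresholded(self, table1_records, table1_models):
        """Pairs whose disease-B p-value exceeds 1e-8 must NOT be dropped:
        only disease A is thresholded."""
        ra, sz = table1_records
        weak_b = [s for s in sz if s.p_value >= 1e-8]
        assert weak_b  # the reference table does contain such rows
        gene_region, _, _ = run_scan(ra, sz, None, table1_models)
        kept_ids = {r.snp_id for r in gene_region}
        assert {s.snp_id for s in weak_b} <= kept_ids

    def test_stage_counts_monotone_non_increasing(self):
        bundle = synthetic.generate_study(seed=3, preset="tiny")
        _, _, audit = run_scan(bundle.stats_a, bundle.stats_b, bundle.panel,
                               bundle.genes)
        stages = ["pruned_a", "deduped_pairs", "opposite_pairs",
                  "pleiotropic_snps"]
        counts = [audit[s] for s in stages]
        assert counts == sorted(counts, reverse=True)
        assert audit["gene_region_snps"] + audit["intergenic_snps"] == audit[
            "pleiotropic_snps"
        ]

    def test_planted_snps_recovered_exactly(self):
        """Parameter recovery: the planted opposite-direction SNPs, and only
        they, come out of the cascade; their gene classes match the truth."""
        bundle = synthetic.generate_study(seed=12, preset="mini")
        gene_region, intergenic, _ = run_scan(
            bundle.stats_a, bundle.stats_b, bundle.panel, bundle.genes
        )
        got = {r.snp_id for r in gene_region} | {r.snp_id for r in intergenic}
        assert got == {s for s, _, _ in bundle.truth.planted_pleiotropic_snps}
        for rec in [*gene_region, *intergenic]:
            assert rec.region_class == bundle.truth.planted_gene_classes[rec.snp_id]

    def test_null_pleiotropy_calls_shrink_with_sample_size(self):
        """With only null SNPs, spurious calls vanish as case counts grow."""
        blocks = [synthetic.LdBlock(n_snps=1) for _ in range(150)]
        panel, _ = synthetic.gen_haplotype_panel(100, blocks, seed=9)
        calls = []
        for n in (500, 50_000):
            stats_a, stats_b = synthetic.gen_two_trait_gwas(
                panel, {}, n, n, n, n, seed=21
            )
            gr, ig, _ = run_scan(stats_a, stats_b, panel, [])
            calls.append(len(gr) + len(ig))
        assert calls[1] <= calls[0]
        assert calls[1] == 0
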