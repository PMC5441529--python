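# Methods

This note documents the models, procedures, numerical choices, and known
limitations of `pleioscan`. It describes what the code computes and why the
open design choices were resolved the way they were; every number quoted
here is produced by the package's own tests, examples, or acceptance
script.

## The cascaded pleiotropy scan

The scan looks for single variants with *apparently pleiotropic,
opposite-direction* effects on two diseases A and B, using only published
per-SNP summary statistics (odds ratio OR and p-value per effect allele)
and a phased haplotype reference panel for linkage disequilibrium (LD).
"Apparently" matters: LD with a causal variant and allele-orientation
mismatches can both mimic pleiotropy, which is why the cascade ends with a
same-SNP cross-verification step rather than stopping at pairs in LD.

Stages and their parameters (all defaults collected in `ScanConfig`):

| stage | rule | default |
|---|---|---|
| threshold + prune (A only) | keep p < `p_threshold_a`, then greedy LD pruning | 1e-8, r² ≤ 0.6 |
| pair | every B SNP with r² ≥ `r2_pair_min` to a pruned A SNP, within `window_bp`; identical SNP ids self-pair at r² = 1 | 0.8, 1 Mb |
| deduplicate | per A SNP keep max r², then min B p, then smallest B position, then id | — |
| opposite filter | after harmonization, (OR_A − 1)(OR_B − 1) < 0; OR = 1 never passes | — |
| same-SNP verification | the shared variant must show opposite directions when looked up in *both* full tables; distinct-SNP pairs cannot verify | — |
| gene mapping | exon / intron / flanking (± `flank_bp` around the transcript) / intergenic | 5 kb |

The procedure is deliberately **asymmetric**: only disease A is thresholded
and pruned, so B-side members of retained pairs may have p-values above
1e-8. The test suite asserts this explicitly (the reference table contains
B-side p-values up to ~4e-7, and none are dropped). A symmetric variant can
be had by running the scan twice with the traits swapped.

### Design choices the inputs leave open

* **Allele harmonization.** Summary-statistics tables rarely share an
  effect-allele convention. We align study B onto study A's orientation:
  an allele *swap* inverts B's OR (an OR of x per allele G is 1/x per the
  other allele); a *strand flip* complements B's alleles and leaves the OR
  alone. Palindromic SNPs (A/T, C/G) are strand-ambiguous — swap and flip
  are indistinguishable without allele frequencies — so they are flagged,
  kept as-read by default, and excluded under `drop_ambiguous=True`.
  Silent exclusion would change headline counts (the reference table
  itself contains A/T SNPs), hence flag-and-keep as the default.
* **Greedy pruning order.** Sort ascending by p, break ties by (chrom,
  pos, snp id); accept a SNP iff its r² with every already-accepted SNP
  within the window is at or below the cutoff. This is standard clumping
  semantics and makes the output a pure function of the input set (order
  independence is property-tested).
* **Pruning/pairing window.** 1 Mb by default. Cross-chromosome and
  out-of-window r² is treated as 0. The motivating study's signals all lie
  in one ~4 Mb region, so a window bounds cost without changing results;
  it is configurable for genome-wide pairing.
* **Deduplication tie-breaks.** The published rule (max r², then min B p)
  is extended with position-then-id tie-breaks purely so output never
  depends on input order.
* **Gene-mapping priority.** When a SNP hits several gene models, the
  primary gene is chosen by class priority exon > intron > flanking, then
  smallest distance to the transcript midpoint, then name; *all* hits are
  retained in a secondary list, since a one-gene-per-SNP report is a
  presentation choice, not a biological fact. Intergenic SNPs are written
  to their own output, not discarded.
* **Coordinates.** GWAS positions are 1-based (the convention of published
  tables); gene models are stored half-open 0-based (BED convention) and
  conversion happens at the mapping boundary only.

## LD from phased haplotypes

r² is the standard haplotype-frequency form D²/(p_A(1−p_A)p_B(1−p_B)) with
D = p_AB − p_A·p_B, computed from the 0/1 haplotype matrix. Monomorphic
SNPs raise an error (LD undefined) rather than returning a sentinel. There
is deliberately no EM estimator for unphased genotypes and no D′: the
pipeline consumes phased panels (0/1 matrix TSV + variant sidecar, or
phased VCF via `cyvcf2`) and uses r² only as a filter statistic. The
implementation is pinned, to 1e-12, against a brute-force 2×2
haplotype-contingency oracle on 1,000 random panels, and r² is
property-tested to be invariant under 0/1 relabeling at either locus.

## Interactome overlap and bridges

A disease interactome is the star union of its seed (disease-associated)
genes and every protein linked to a seed by a PPI edge; edges carry a
known/novel provenance tag that is preserved end to end. Novel edges are
*consumed as labeled input* — this package does not predict PPIs.

Overlap significance is the upper-tail hypergeometric probability
P(X ≥ k) for k shared genes between node sets of sizes K and n drawn from
a universe of N genes, computed in log space (`scipy`'s log survival
function) so that extreme tails remain representable; results are reported
as log10 p alongside the linear value when the latter underflows. Two
independent oracles pin the implementation in tests: a direct log-gamma
summation of the tail pmf, and an exact big-integer enumeration via
`math.comb` (agreement to better than 6 significant figures in log10
space; at the published interactome sizes — 2058 and 1045 nodes sharing
316 — all three routes give log10 p = −75.3046, comfortably below the
−72 bound).

Open choices:

* **Universe N** defaults to 20,000, the approximate number of human
  protein-coding genes; the published bound is insensitive to any N in the
  18k–25k range. N is recorded in every report and overridable.
* **Seeds+interactors vs interactors-only.** Published overlap counts at
  these sizes imply the full node sets (seeds + interactors) were
  compared; both modes are implemented, full is the default.
* **Gene identity** is the case-preserved symbol string with an optional
  alias map; composite labels (e.g. "FCGR3A/FCGR3B") are opaque single
  symbols. No identifier-mapping service is embedded.

Bridges are enumerated exhaustively on the union graph: direct seed–seed
edges, common interactors (non-seed nodes adjacent to seeds of both
sides), and every (seedA, intermediate, seedB) two-step path. The
candidate-connectivity report applies the same machinery to an external
candidate gene set with its own edge list (how many interactors each
candidate has, which A/B seeds it reaches through exactly one
intermediate, which interactors it shares with each net), reporting
edge-less candidates as isolated.

## Enrichment and the merged pathway table

Per pathway: hypergeometric upper tail for k hits of an n-gene query on a
K-gene pathway in an N-gene universe, then Benjamini–Hochberg step-up
across all pathways with ≥ 1 hit. All hit pathways are reported regardless
of significance. The BH implementation is `statsmodels`'
`multipletests(method="fdr_bh")`, pinned in tests to a hand-rolled
sort/scale/cummin oracle on random p-vectors.

The universe defaults to the GMT's unique-gene count; in that mode the
query is first intersected with the annotated universe (a query gene no
pathway could contain carries no evidence under the model, and keeping it
would violate the hypergeometric precondition). An explicit `universe_n`
keeps the full query. The universe used is declared in output metadata.

The merged table partitions each pathway's hits into exclusive-A / common /
exclusive-B (disjoint by construction, union complete — property-tested);
a pathway hit on one side only gets p = 1 and an empty set on the other.
Note that this package does not attempt to reproduce any proprietary
pathway tool's p-values: pathway content is user-supplied GMT, and
published tables produced with such tools are used only for structural
checks. One documented oddity in the motivating study's own report — a
pathway described in prose as having 43 common genes while its table lists
19 — is left unreconciled; nothing in this package depends on it.

## Reciprocal expression and connectivity

Direction calls come from the sign of a per-gene score, with a
configurable dead-zone ε (default 0) under which a gene is dropped as
unchanged. `reciprocal_genes` intersects two signatures over their shared
gene universe into (up-A/down-B, down-A/up-B); it is antisymmetric under
input swap by construction.

Connectivity scoring uses Spearman rank correlation between the query's
signed scores and each perturbagen column over shared genes (≥ 3 required,
else the perturbagen is skipped with a warning). Rank correlation was
chosen over weighted Kolmogorov–Smirnov-style enrichment for determinism
and easy oracle testing — it is invariant under monotone transforms of
either side, which the suite verifies — and the scoring function is the
single hook to replace for an alternative metric.

## The synthetic-data generators

The generators define the study conditions under which the pipeline is
validated; their defaults are fixed, not tuning knobs.

* **Haplotype panels**: founder-copy-with-flips block LD. Each block draws
  a founder column (allele frequency uniform on 0.2–0.5) and copies it to
  members, flipping a fraction f ≈ (1 − (r²_target)^¼)/2 of entries;
  realized within-block pairwise r² is checked against `compute_r2` and
  the block resampled on a miss, so the requested range is guaranteed or a
  `GenerationError` raised (infeasible requests fail loudly). Blocks are
  mutually independent, so cross-block r² is near 0 but not constrained.
  This is not a coalescent simulation and makes no attempt at realistic
  human LD maps, allele-frequency spectra, or MHC haplotype structure —
  the pipeline uses LD only as a filter, so what matters is controllable
  r², not population realism.
* **GWAS tables**: per SNP and trait, control alternate-allele counts are
  binomial at the panel frequency, case counts binomial at the frequency
  implied by the planted per-allele OR on the odds scale (OR = 1 at
  nulls); the emitted OR and two-sided p are the sample Wald statistics of
  the 2×2 allele-count table, with the Haldane–Anscombe 0.5 correction
  when a cell is empty. p-values are floored at the smallest positive
  double to stay in (0, 1].
* **Study preset "mini"** (the default validation condition): 5 planted
  opposite-direction SNPs (OR 0.7 vs 1.4, alternating which trait gets
  which) each heading a 3-SNP r² ≥ 0.8 block, among 2,000 null SNPs, 200
  haplotypes, 20,000 cases and 20,000 controls per trait; planted SNPs are
  assigned gene classes cycling exon/intron/flanking/intergenic. At these
  sample sizes a planted OR of 0.7 is detected at p < 10⁻⁸ with
  opposite-direction sample ORs in ≥ 95% of replicates (calibrated over
  200 seeds in the test suite), so cascade recovery is expected to be
  near-perfect; the acceptance run measures it at 100% over 50 seeds.
  A "tiny" preset scales the same design down for smoke tests.
* **PPI networks**: disjoint seed name spaces, an exactly planted
  shared-interactor set wired to at least one seed on each side, edge tags
  split known/novel at the requested ratio within ±1.
* **Expression fixtures**: exact planted reciprocal sets; non-planted
  genes get same-sign scores in both diseases so recovery is exact; an
  optional perturbagen column is the negated query (a perfect reverser,
  Spearman −1).

Everything is a pure function of (arguments, integer seed) via
`numpy.random.default_rng`; byte-level determinism of a full
simulate-then-scan run is asserted in the acceptance tests.

**What passing on synthetic data does and does not show.** Recovery of
planted effects demonstrates the cascade's logic (thresholding, LD
handling, deduplication, direction tests, gene mapping) is correct under
clean, independent-block LD and well-powered two-arm sampling. It does not
demonstrate robustness to the pathologies of real data — pervasive
long-range LD (as in the MHC), allele-frequency-dependent power,
population stratification, overlapping study samples, or miscalled
strands beyond the palindromic flagging — and the headline counts of any
real study depend on its specific inputs and thresholds.

## Reference fixture

The packaged 18-SNP table transcribes a published cross-disorder result
(18 HLA-region SNPs with opposite RA/SZ odds ratios, 8 genes, 4 of them
hit in exons). The accompanying gene models are **synthetic schematic
stand-ins**: minimal interval structures placed so each SNP classifies to
its printed gene and region class (the construction self-checks this).
They let the mapping logic be exercised against the published tallies
without redistributing genome annotation; they are not real transcript
structures.

The published supplementary list of 46 opposite-direction SNP pairs (29 of
them same-SNP) is likewise not redistributable; the acceptance suite
exercises the same-SNP partition on a constructed synthetic stand-in with
that exact planted structure, which validates the partition arithmetic, not
the original data.

## Numerical notes and degenerate inputs

* p-values parse into ordinary doubles (the smallest published value
  handled, 3.7e-151, is representable); comparisons always use parsed
  values, never string order.
* Empty summary-statistics files yield empty collections, not errors;
  unparseable rows are dropped and counted in a rejects report.
* OR = 1 has no direction and never passes the opposite filter; p
  thresholds are strict inequalities.
* Hypergeometric k = 0 returns p = 1 exactly; overlap tests validate
  universe ≥ |union| and k ≤ min(K, n).
* Self-loops, blank symbols, and unknown tags in edge lists are rejected
  row-wise and counted, never silently fixed.

## Problem sizes used in the shipped runs

The test suite and acceptance script run the "mini" study (2,005 SNPs ×
200 haplotypes, 20k/20k samples per trait, 50 seeds for the recovery
rate), 1,000 random panels for the LD oracle, random graphs up to 50 nodes
for bridge enumeration, and the published interactome sizes (2058/1045/316
in N = 20,000) for the overlap bound — sizes chosen so the full
validation completes in seconds on one CPU while still exercising every
code path at the study's stated conditions.
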