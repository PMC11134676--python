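# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions. Coordinates are 0-based half-open
internally; GFF3 (1-based inclusive) is converted once, at the I/O boundary.

## Cytosine contexts and weighted methylation levels

Every cytosine on both strands is assigned one of the plant methylation
contexts — CpG, CHG, CHH with H ∈ {A, C, T} — from its two downstream bases
on its own strand. A cytosine with fewer than two downstream bases, or with
an N in its trinucleotide, is labelled `ambiguous` and excluded from level
computation; the four labels partition all cytosines. On the minus strand
the downstream bases are the forward-strand bases at pos−1 and pos−2,
complemented, so the classifier never materialises a reverse-complemented
sequence. The two strands of a symmetric CpG are kept as separate sites,
matching per-strand caller output.

The methylation level of a region is the **weighted (pooled-count) level**
Σ methylated / Σ coverage over qualifying sites, not the mean of per-site
fractions. The pooled ratio is robust to coverage heterogeneity and is
invariant to splitting a site's reads across rows; the per-site mean is
neither. Sites need coverage ≥ `min_cov` (default 4, a typical floor for
long-read callers) to qualify, and a region with no qualifying site has a
*missing* level rather than zero.

Gene regions are strand-oriented: upstream is the `flank` bp (default
2000) 5′ of the TSS on the gene's strand, downstream the flank 3′ of the
TTS, truncated at chromosome starts. Metagene profiles use 20 equal-width
bins per flank and 40 proportional bins across the body (typical metaplot
resolution); minus-strand genes are mirrored so bin 0 is always the farthest
upstream bin, and genes shorter than the bin count simply populate a subset
of body bins. Per-gene per-bin pooled levels are averaged across genes, so
long genes do not dominate. A 1 kb flank variant is a parameter away
(`flank=1000`); 2 kb is the default.

## DMR calling

Two call sets are compared per context (contexts are biologically distinct
pathways and are corrected separately). Sites covered ≥ `min_cov` in *both*
samples are pooled within sliding windows (default 1000 bp, step 500 bp,
≥ 5 sites), and each window gets a two-sided **pooled two-proportion
z-test**; Benjamini–Hochberg is applied across all tested windows of the
context. Windows with q ≤ α (0.05) and |Δ| ≥ `delta_min` (0.1) that share
the sign of Δ and lie within one step of each other are merged.

Two conventions and one refinement matter:

* **Zero pooled variance** (both proportions 0 or 1 and equal) gives p = 1 —
  identical samples can never be significant.
* **Merged statistics** are recomputed from pooled counts over the merged
  span; p and q are the minimum over member windows.
* **Boundary refinement** (on by default): the union of significant windows
  over-extends a region by up to a window width per side, because a window
  overlapping the true region by as little as the `delta_min` floor allows
  is still called. Within each merged span, the maximal-scoring run of sites
  under the per-site score `sign·(p̂_a − p̂_b) − delta_min` (Kadane's
  algorithm) trims the span to the sites that carry the difference; refined
  DMRs must still satisfy `min_sites` and `delta_min`.

The pooled z-test is deliberately transparent rather than a smoothed
dispersion-shrinkage model: it is exactly calibrated on binomial counts,
dependency-free and directly testable against planted truth. Its cost is
anti-conservativeness under biological overdispersion — with beta-binomial
counts the raw type-I rate exceeds the nominal level, which the `delta_min`
effect floor and BH step keep in check; calibration claims in the test suite
are therefore made under binomial sampling, and effect-size floors should be
used in practice. The caller is a generic two-sample comparison: the user
names the contrast (tissues within a haplotype, or the two haplotypes).

DMR annotation is a partition with priority promoter > gene body >
intergenic, where the promoter is the 2 kb strand-aware region upstream of
the TSS and any 1 bp overlap triggers a category.

## Allelic gene pairing

Genes are ranked by position along each chromosome. Within each chromosome
pair, anchors are chained by a weighted longest-increasing-subsequence
dynamic program (score-sum objective, both orientations tried, rank gaps
capped at `max_gap` = 25); the best chain is extracted, its anchors removed,
and the process repeats, so each anchor belongs to at most one block. Chains
shorter than `min_anchors` = 5 are discarded — the classic minimum for
declaring collinearity. Input order never matters: anchors are canonically
sorted first.

Within blocks, each gene is paired with its highest-scoring in-block anchor
partner under a greedy one-to-one constraint (descending score; ties broken
by smaller rank distance, then lexicographic ids; cross-block conflicts go
to the longer block). Greedy matching mirrors the "best homolog" notion;
optimal bipartite matching would maximise total score instead but can pair a
gene with its second-best homolog, which is not what the rule means. Anchor
scores (e.g. alignment bit-scores) come from the input table; homology
search is out of scope.

## Expression filters and allelic DE

Two filters precede any comparison, in this order: (1) genes with mean TPM 0
in every tissue are discarded as non-expressed; (2) within every *expressed*
tissue the replicate spread d = (max − min)/mean must stay below 0.5. The
mean is used as the denominator because "percent difference" needs a
reference and the mean is the least biased of the candidates (min inflates
d, max deflates it); the rule is applied per tissue, so a gene silent in one
tissue is not penalised there. The filter is idempotent.

Allelic DE compares replicate-mean TPM of the two alleles in one tissue:
r = (max + ε)/(min + ε) with pseudocount ε = 0.1 must *strictly exceed* the
fold threshold (default 2). The pseudocount prevents division by zero and
spurious calls at trace expression; classes are stable under joint rescaling
of TPM and ε, and swapping the haplotype labels swaps A_high and B_high
exactly. Pairs with both means zero are `not_expressed`; a pair is
"expressed" when at least one allele mean exceeds `expressed_min`
(default 0), and per-tissue expressed-pair percentages are reported to two
decimals.

## Integration

Only A_high/B_high pairs contribute. For each pair the two alleles' region
levels are oriented by expression, and per tissue × region × context the
summary reports the mean level of the higher- and lower-expressed alleles, a
**paired one-sided Wilcoxon signed-rank** p-value for "higher expression ⇒
lower methylation" (a paired nonparametric test matches the paired-allele
design and makes no distributional assumption on levels), and the
**Spearman correlation** between the signed log2 expression ratio and the
A−B methylation difference. Both statistics are invariant to relabelling
the haplotypes. Pairs missing a level are dropped from that cell only, with
counts; all-tied differences give p = 1 and a constant input leaves the
correlation undefined (reported missing). The assembly-metric report is
plain per-key arithmetic means of the two haplotypes' values, to three
decimals.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, not
the sequences of any real genome:

* **Genomes and genes.** Two haplotypes with identical gene order; gene
  sequences are shared between haplotypes (true homologs), intergenic
  sequence is independent. Genes are placed non-overlapping on a uniform
  grid with jitter, both strands with probability 0.5, spaced so that the
  2 kb flanks never collide. Defaults: 2 chromosomes × 300 kb, 80 genes of
  1–3 kb.
* **Methylation.** Context base levels follow the plant pattern CG > CHH >
  CHG (defaults 0.62/0.33/0.22 scale), with small tissue differences (one
  haplotype slightly more methylated in flowers, the other in leaves). Reads
  are beta-binomial around the site level (overdispersion ρ = 0.05 — pure
  binomial is unrealistically tight for power benchmarks) at Poisson
  coverage with mean 30, typical of a well-covered long-read methylome.
* **Planted DMRs.** Non-overlapping intervals (default 50 × 1 kb, Δ = 0.3,
  one haplotype's flower vs leaf) where the two tissues' levels are
  recentred symmetrically so the planted Δ is preserved exactly even near
  the [0.02, 0.98] clipping bounds.
* **Expression and coupling.** Each pair draws a baseline log2 TPM
  (mean log2 20, SD 1), a per-tissue effect, and log-normal replicate noise
  (σ = 0.2, which makes the replicate-spread filter genuinely selective). A
  `de_fraction` of pairs (default 0.25) receives a planted log2 allelic
  ratio drawn from ±U(1.2, 2.5) — clearly above the two-fold decision
  threshold, so recovery measures the caller rather than boundary noise.
  The allelic promoter/body methylation difference is then *derived from the
  expression ratio* as d = log2ratio / slope (default slope −6 log2 TPM per
  unit methylation), so log expression decreases in methylation at exactly
  the configured slope, a slope of 0 decouples the two layers exactly (the
  null-calibration condition), and the downstream flank — which carries no
  coupling — acts as a built-in negative control. Per-gene jitter
  (SD 0.03 per gene × region × tissue) adds biological level variation.
* **Anchors.** All true pairs (scores U(200, 1000)) plus 10% decoy anchors
  with random partners and lower scores (U(50, 400)), exercising the
  chainer; a truth table records every planted DMR, DE pair and per-gene
  region level.

Determinism is a contract: one `numpy` generator seeded from `seed` drives
everything, and identical configs produce byte-identical files.

**What passing tests do and do not show.** The generator has collinear gene
order, independent sites, no repeats or TEs, no copy-number differences, no
mapping bias between haplotypes, and clean per-site calls. Benchmarks on it
validate the *statistical machinery* — calibration, recovery, orientation,
determinism — not robustness to assembly artefacts, alignment bias or
paralogy, which real allodiploid data add on top. Two benchmark configs
deliberately simplify further: calibration and planted-DMR benchmarks set
the per-gene tissue jitter to zero and equal tissue base means, because
genuine simulated tissue differences are true positives that a planted-truth
oracle would miscount as false calls; and DMR null calibration uses binomial
sampling (ρ = 0), the regime in which the z-test is nominally calibrated.

## Numerical conventions and edge cases

* Weighted levels: missing (NaN), never 0, when no site qualifies.
* Two-proportion test: p = 1 at zero pooled variance; BH per context.
* Window grid starts at multiples of `step` from position 0; `window <
  step` is a configuration error (the grid would leave gaps).
* Chaining DP resolves ties toward the earliest candidate in canonical
  anchor order, making block extraction deterministic.
* `pair_expression_coverage` and the metric report round half-even via
  Python's `round` (2 and 3 decimals respectively).
* Truth tables round-trip losslessly: floats are written with full repr
  precision and parsed back exactly.

## Problem sizes

Default benchmarks use 2 × 300 kb genomes with 80 genes (~600 k cytosines
per haplotype), 2 × 500 kb with 40 genes for null calibration (≥ 2000
windows per replicate), three replicates or seeds per stochastic claim, and
a 2 × 100 kb end-to-end determinism run — sizes at which every planted
effect is measurable with comfortable margins while the full suite and the
acceptance script each run in well under a minute of compute per stage.

## Known limitations

* The DMR caller's nominal calibration assumes binomial counts; under
  overdispersion it is anti-conservative and should be used with an effect
  floor (`delta_min`), as the defaults do.
* Merged-window DMR coordinates are resolution-limited by `step`; boundary
  refinement recovers ~site-level precision only where site density allows.
* Greedy one-to-one pairing is order-dependent only through scores; exact
  ties across blocks resolve by block length, then id, which is arbitrary
  but deterministic.
* The expressed-pair definition (`expressed_min = 0`: any positive mean)
  is permissive; raise it for noisy quantifications.
* CpG strand merging is not performed; callers that report merged CpG
  counts should be split or the levels interpreted per strand.
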