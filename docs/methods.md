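# Methods

## Problem setting

The package operationalizes a comparative-epigenomics design: gene
lists derived from differential DNA-methylation studies in two lineages
(a recently domesticated fish and humans) are compared for overlap
against the fish genome's gene count, directly at the orthologue level
and through a paralogue-widened "homologue" route, and then at the level
of functionally enriched terms. All stages work from local files; no
web service is queried.

## Coordinates and DMR-to-gene assignment

Intervals are 1-based inclusive (the GTF convention) throughout; BED
input (0-based half-open) is shifted at read time. A gene is assigned to
a DMR when the gene body shares at least one base pair with the DMR
extended by a symmetric flank on both sides, clipped at position 1. The
flank defaults to 5000 bp — the window the underlying methylation
studies used for promoter-proximal signal — and is exposed as a
parameter because different source datasets applied the window on
different sides (gene body plus upstream promoter vs. symmetric).
Strand is ignored: a regulatory methylation change is not assumed to act
on one strand. A gene hit by DMRs in several tissues counts once; the
per-tissue payloads (methylation difference in percentage points,
tissue) stay attached to the intervals, not the gene list. The
implementation queries an interval tree; the test suite checks it
against an all-pairs scan, including placements that touch or miss the
flank boundary by exactly 1 bp.

Gene extents come from `gene` feature rows where the GTF has them,
otherwise from the min start / max end over the gene's features.
Identifier handling trims whitespace, preserves case, and deduplicates
keeping first occurrence, so list order is deterministic.

## Homology expansion

Orthologue translation maps each list member to all of its targets in a
local many-to-many table and drops members with no target (counted in
provenance). This is how a 588-gene source list can translate to 589
targets: one-to-many orthology can outweigh the drops. The homologue
route first widens the list by its within-genome paralogues — one hop
only, no transitive closure, matching how a single homology-table export
is built — then translates the widened list. By construction the
homologue list is a superset of the plain orthologue translation; a
brute-force two-step set expansion is the oracle in tests.

## Overlap statistics

The 2×2 table against a background of N genes is tested two ways.

**Fisher's exact test.** The headline effect size is the sample odds
ratio ad/(bc) (reported as +inf when bc = 0 and ad > 0, and 0 when
ad = 0), because that is the statistic conventionally printed for these
tables; the conditional maximum-likelihood odds ratio is always reported
alongside. The default p-value is the one-sided greater tail — overlap
enrichment is a directional question — with the two-sided p also
reported. The background defaults to 23,382 genes (the target genome's
annotated gene count) and is configurable.

**Monte-Carlo permutation test.** Each iteration draws two subsets of
sizes |A| and |B|, each without replacement, independently of each
other, from the background, and records their intersection size. Over
n_perm = 10,000 iterations the null mean and sd (n−1 denominator: it is
a sample estimate of the null sd) give z = (observed − mean)/sd, and the
empirical p counts strictly greater permuted overlaps divided by n_perm
— so p = 0 is possible; a smoothed (r+1)/(n+1) variant sits behind a
flag, off by default. When sd = 0 (a list as large as the background) z
is reported as NaN and p is still computed.

The intersection of two independent uniform subsets is exactly
Hypergeometric(N, |A|, |B|); the closed-form moments
(mean = |A||B|/N, var = |B|·(|A|/N)(1−|A|/N)(N−|B|)/(N−1)) serve as an
independent oracle, and a `counts` sampling path draws the intersection
size directly from that law. The `counts` path is distributionally
identical to the literal two-subset draw (a test asserts their
agreement) and is used for calibration studies that need millions of
permutations; headline analyses use the literal draw.

Note that with the strict-inequality p and a finite n_perm the
null rejection rate at a cut q is slightly above q: the discrete tail
P(K > k) jumps across the cut, and Monte-Carlo noise in the p estimate
adds a further inflation that shrinks as n_perm grows (for the
1181 × 589 × 23,382 configuration the exact rate at the 0.05 cut is
0.0520 in the infinite-permutation limit, 0.0525 at n_perm = 50,000).
The type-I calibration therefore runs the fast path deep (50,000
permutations per replicate) and wide (thousands of replicates) so the
estimate's own error is small against the band being checked.

## Enrichment and term-set comparison

Enrichment of an n-gene query against a K-gene term in an N-gene
universe is the hypergeometric upper tail P(X ≥ k) — the documented core
of the popular web enrichment tools; rank-based composite scores are
deliberately not reproduced, as only p and adjusted p feed any decision
here. P-values are Benjamini–Hochberg adjusted across each library's
terms (statsmodels' step-up, validated against hand-computed examples),
and results are ranked by ascending p with ties broken by term id for
determinism. The enrichment universe is configurable (the annotation's
gene count is the natural choice) since public enrichment services do
not document their internal background.

The second-order comparison takes the term sets enriched in two
analyses (default cut: unadjusted p < 0.05, configurable) as "lists" and
the library's total term count as the background, reusing the Fisher
machinery. No permutation stage is attached there.

No multiple-testing correction is applied across the pairwise list
comparisons themselves; they are a handful of planned contrasts.

## Synthetic data

The generator emulates the *structure* of the real inputs, not their
biology:

* **Annotation** — non-overlapping genes of uniform random length
  (1–15 kb) separated by at least 2·flank + 200 bp, so a DMR inside one
  gene body can never fall within the flank of a neighbour. Real genomes
  have overlapping and nested genes and clustered gene families; passing
  tests therefore certify the interval arithmetic, not robustness to
  every annotation pathology (the mapper itself handles overlapping
  genes; only the generator's recovery guarantee needs the spacing).
* **DMRs** — one per target gene, placed inside the gene body, plus
  decoys at least flank + 1 bp from every gene, with synthetic
  methylation differences (±10–60 percentage points) and tissue labels.
  The construction guarantees that mapping the DMRs back recovers
  exactly the planted list, which turns the whole simulate → map →
  compare chain into a self-checking pipeline.
* **Homology** — each source gene gets an orthologue with probability
  0.8 (roughly the fraction of protein-coding genes with a fish
  orthologue), a second target with probability 0.1, and paralogue
  families of 2–5 genes partition a subset of sources.
* **List pairs** — the overlap count k is drawn from Fisher's
  noncentral hypergeometric distribution with odds ω, then k shared and
  |A|−k / |B|−k exclusive labels are assigned. Planting on the odds
  scale makes parameter recovery meaningful: the sample odds ratio of
  the resulting table is a consistent estimator of ω at study sizes
  (mean recovered OR 1.597 over 500 replicates at ω = 1.6, within the
  5% band the acceptance suite asserts). ω = 1 reproduces the
  permutation null exactly.
* **GMT libraries** — terms drawn uniformly from the universe, plus an
  optional planted term equal to a chosen gene set, which then
  necessarily tops that query's ranking.

Defaults mirror the study conditions (background 23,382; list sizes
1181/589; flank 5000 bp; 10,000 permutations); tests run the same
machinery at a few hundred genes.

## Problem sizes and numerical choices

The acceptance checks run at the study's own sizes: all seven published
2×2 tables exactly; the permutation null at n_perm = 10,000 with the
literal subset draw; OR recovery over 500 replicates; type-I calibration
over thousands of replicates on the counts path (the literal draw at
that scale would be pointlessly slow for a distributionally identical
answer). Oracle-equivalence tests enumerate hypergeometric pmfs
exhaustively for backgrounds up to 60.

All randomness flows through numpy `default_rng` seeds; fixture
generation spawns per-stage child seeds from one top-level seed via
`SeedSequence`, and every output is byte-reproducible under seed reuse.
Ties in enrichment ranking break by term id; gene-list order is
first-occurrence; intervals are validated on construction (start ≥ 1,
end ≥ start, non-empty sequence name).

## Known limitations

* The published permutation z-scores for this design are not
  reproducible from the described procedure (the closed-form null gives
  z ≈ 2.9 for the 1181 × 589 comparison where a far larger value is
  printed, and the printed z/p pairs are mutually inconsistent under a
  normal-tail reading); the package asserts the internally consistent
  properties of the procedure as described instead of those figures.
  Likewise one published one-sided p (0.88 for a table with OR 1.233)
  is inconsistent under either sidedness convention and is not asserted.
* Real-data counts (which genes end up in which list) depend on
  external annotation releases and curated methylation tables; the
  package validates the machinery on synthetic inputs and accepts the
  real files when a user supplies them.
* The generator does not simulate methylation levels, read counts, or
  tissue effects — only gene-list structure.
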