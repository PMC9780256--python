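# Methods

## Counting model

Each mutation class is modeled as independent per-site Bernoulli events:
a site (or indel breakpoint) either carries a mutation of that class or
it does not.  A count table therefore stores, per k-mer, the number of
mutated (m) and unmutated/background (u) observations, and the
table-wide mean rate is μ = Σm / Σ(m + u).

**SNVs.**  Only callable positions (inside the region mask) with an
N-free k-mer window contribute.  Central purines are strand-collapsed:
the window is reverse complemented and the alleles complemented, leaving
six classes with central A or C.  Every usable position contributes one
background count to each of the three tables sharing its collapsed
central base; an observed SNV adds one mutated count to exactly one
table and removes that site's background contribution there, at most
once per site, so m + u per site and table is always 1 and recurrent
records cannot drive u negative.  A mutation whose flanks extend outside
the mask still counts as long as the site itself is callable; windows
containing N are skipped.

**Indels.**  An indel's placement is usually ambiguous: every breakpoint
that reproduces the observed alternative sequence is equivalent, and the
equivalent placements form a contiguous range that we enumerate exactly
(verified against a string-equality oracle).  One placement is drawn
uniformly per event; the draw is seeded from (global seed, chrom, pos,
ref, alt) so counting is invariant to input order.  Insertion contexts
are the k/2 bases on each side of the inter-base breakpoint (k even,
default 4); deletion contexts are odd k-mers (default 5) centered on the
first and last deleted base.  Every counted context also counts its
reverse complement — this makes the tables reverse-complement symmetric
by construction and makes "the reverse complement of a deletion start
k-mer is a deletion end k-mer" literally true, so both orientations are
covered without tracking strand.  Background counts are the context
k-mers (plus reverse complements) of every masked breakpoint; observed
events are not subtracted from the indel background, which is a
negligible correction at realistic rates.  Length-stratified tables
(3n vs non-3n) repeat the procedure on the relevant events and feed the
inframe/frameshift split downstream.

## Partition optimization

The loss is the penalized binomial deviance

    loss(P) = Σᵢ [ −2 (Mᵢ log rᵢ + Uᵢ log(1 − rᵢ)) + c ],
    rᵢ = (Mᵢ + α)/(Mᵢ + Uᵢ + α/μ)

with natural logarithms and the 0·log 0 = 0 convention; at c = 2 it is
the AIC of the corresponding model, which the tests verify against an
independent likelihood routine.  μ is computed once from the full table
and held fixed for every pattern; a table with μ ∈ {0, 1} is refused,
since no rate model is identifiable from one-sided counts.  An empty
pattern (M = U = 0) gets r = μ exactly.

The exact optimizer enumerates every pattern reachable from the root by
recursive two-partition splits, sorted by coarseness (number of matched
k-mers) ascending, so both children of a split are solved before their
parent; pattern counts for all 15^k patterns are obtained in one pass by
contracting the count tensor with the IUPAC membership matrix.  Each
SNV class's root fixes the central position to the class's collapsed
reference base (the 16 C-central 3-mers of a C>* class); indel roots are
all-N.  Ties prefer not splitting, and among equal splits the first in
(position, canonical table order) wins, so results are deterministic.
The pattern space grows as 15^(k−1)·1 for SNV tables and 15^k for indel
tables; a memory guard refuses exact optimization beyond a configurable
pattern budget and points to the greedy variant, which evaluates only
the single most promising split of each pattern (by the immediate loss
of the two children) and recurses on the winners.  Greedy partitions are
always valid and never beat the exact optimum; the tests check dominance
on 100 random instances.

One extraction note: the published two-partition listing we reimplement
contains, for code B = {C,G,T}, a first pair that is not a disjoint
cover as printed; set algebra forces (C, K), which is what the package
uses, and the test suite checks every code's listing against exhaustive
enumeration of codable splits.

## Hyperparameter selection

α and c are fitted by repeated 2-fold cross-validation (default 5
repeats) over a grid, with folds created by multivariate hypergeometric
sampling: half of the mutated counts and, independently, half of the
unmutated counts go to fold 1 without replacement, so fold sums always
reproduce the original table and each k-mer's fold count follows the
hypergeometric law (checked by a χ² test against scipy's pmf).  The
same seeded splits are reused at every grid point, making grid points
independent units of work with order-invariant results.  The default
grids are α ∈ {0.1, 0.5, 1, 2, 5, 10, 20} and
c ∈ {0.5, 1, 2, 5, 10, 20, 50, 100} — a geometric ladder bracketing the
unregularized and AIC regimes; the selection rule is the lowest mean
out-of-sample negative log-likelihood, with ties resolved toward the
stronger regularization (larger c, then larger α).  Held-out scores use
training-fold rates only; the null likelihood in Nagelkerke's r² uses
the test table's own mean rate by default, so r² = 0 means "no better
than a constant fitted to the test data" (a flag switches to the
training μ).  The joint multi-class r² pools ℓ_M, ℓ₀ and n across
classes before applying the formula.

## Gene-level engine

For each transcript the engine enumerates all 3 substitutions at every
coding and essential-splice position.  Essential splice sites are the 2
intronic bases on each side of every internal CDS junction, the standard
width for the category.  Classification translates the mutated codon
(reverse complemented for minus-strand transcripts, context k-mers
always read from the genomic strand and collapsed by the model's own
rule); category precedence where definitions overlap is
start_disruption > stop_disruption > splice_disruption > nonsense >
missense > synonymous, with a stop→stop change counted synonymous.

Indel opportunities are an explicit modeling choice of this package:
every inter-base breakpoint strictly inside a coding exon is one
insertion opportunity (scored with the 3n model as inframe and the
non-3n model as frameshift), and every coding base anchors deletion
opportunities of lengths 1–3 (configurable), classified by length mod 3.

**Rate scaling.**  Trained rates live on the scale of the training
cohort.  They are rescaled so the site-count-weighted genome-wide mean
total substitution rate equals 1.28 × 10⁻⁸ per base per generation, and
insertion + deletion models are rescaled jointly so the mean combined
per-breakpoint rate equals 0.68 × 10⁻⁹.  The self-consistency of both
means is re-derived by an independent pass in the tests (relative error
below 10⁻¹⁰).  Per-generation rates become observation probabilities
via r_scaled = 1 − (1 − r)^(2·n_gen); n_gen is either given (trio
cohorts) or calibrated by monotone root finding so the exome-wide
expected synonymous count matches the observed one (relative tolerance
10⁻⁶; the expectation is strictly increasing and bounded by the number
of synonymous sites, so the bracketed solve is safe).

**Burden test.**  With heterogeneous per-site probabilities the null
count is Poisson-binomial.  We sample it by pooling sites with equal
probability into binomial draws (distributionally identical, far
faster), and report p = (1 + #{samples ≥ observed})/(1 + n_samples) —
never zero, valid under sampling — plus the empirical 5th–95th
percentile of the sampled counts as the 90% interval of the expectation.
The samplers are validated against an exact convolution oracle.

**Coverage correction and constraint.**  Expected counts are divided by
a LOWESS fit (statsmodels, default fraction 0.05) of per-transcript
synonymous O/E against mean allele number, after dropping transcripts
with AN ≤ 50,000.  LoF = nonsense + essential-splice + frameshift;
O/E = (obs + 0.5)/(exp + 0.5) and LOEUF = (obs + 0.5)/(lower90 + 0.5),
the 0.5 pseudo score keeping zero-observation transcripts finite.

## Synthetic data

The generator draws i.i.d. genomes at a given GC fraction (default
0.41, autosome-like), mutates each callable site at most once with the
true pattern rate of its collapsed context (alt chosen by a single
uniform draw against the three cumulative class rates), and places
indels per breakpoint the same way.  The built-in example truth uses
3-mer classes with a 4-pattern C→T partition dominated by a CpG pattern
at 0.02 per site and class means in the 3 × 10⁻⁴ – 7 × 10⁻³ range —
per-site event probabilities on the scale of a large aggregated trio
cohort — and 2-pattern insertion/deletion models around 10⁻⁴.  Toy
transcriptomes embed non-overlapping multi-exon genes with valid
start/stop codons, no internal stops and GT–AG introns on both strands.

What the generator does not emulate: regional rate covariates
(replication timing, chromatin), C→G-enriched clustered regions,
mutation-rate heterogeneity within a pattern, sequencing error, or
selection.  Passing tests therefore demonstrate correctness of the
estimator and calibration of the tests under the model's own
assumptions, not performance on real cohorts.

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale by design:
k = 3 partitions (the DP is exact for any k that fits the pattern-space
budget), genomes of 0.2–1 Mb, 500-gene transcriptomes, Monte-Carlo
sizes of 3 × 10³ – 10⁵ (the burden CLI default is 10⁷).  The burden
calibration study sets n_gen so genes carry expected LoF counts around
30 — the segregating-variant regime the constraint analysis targets,
and coarse enough count support for a meaningful uniformity test.
Losses are reported as plain deviances (natural log).  Exact-DP
tie-breaking, the seeded per-record placement draws, and the reused CV
splits make every pipeline stage bit-reproducible under a fixed seed.

## Known limitations

The exact optimizer is exponential in k (the practical ceiling is
k = 9 for SNV tables on a large machine); the greedy heuristic trades
accuracy for reach.  Complex substitutions (MNVs, non-anchored
ref/alt pairs) and structural variants are out of scope, as are UTR,
intronic and regulatory consequence categories, liftover between
assemblies, and per-sample genotype handling.  The indel opportunity
enumeration (breakpoints and length set) is a package convention, not a
community standard; absolute indel expectations should be compared only
across transcripts scored with the same convention.
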