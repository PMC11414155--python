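# Methods

This note documents the models and procedures implemented in `clonescan`,
the assumptions they make, and the choices taken where the design was
genuinely open.

## The inferential contrast

The package tests one hypothesis pair. Under clonal reproduction all loci
of a haploid genome descend through the same genealogy, so pairwise
divergence measured at a mating-type (MAT) locus, at an unrelated
protein-coding gene (PTG), and across genome-wide SNPs must co-vary across
isolates. Under sexual reproduction, recombination reassorts loci every
generation and the three divergence matrices become independent. The
package therefore computes the three matrices, tests each pair for
association, and classifies the dataset: all three tests significant →
*congruent-clonal-like*; none → *decoupled-sexual-like*; anything else →
*mixed*. The three-way AND/NOR rule deliberately refuses to over-claim on
partial evidence. No multiple-testing correction is applied across the
three tests; the report says so.

## Distances

**Tamura 3-parameter.** For a sequence pair, columns containing `-` or `N`
in either sequence are excluded (pairwise deletion; whether complete
deletion would be preferable is data-dependent, and pairwise deletion keeps
each pair's information maximal). With transition proportion P,
transversion proportion Q and pooled G+C fraction θ of the two sequences at
the usable sites, `h = 2θ(1-θ)` and

    d = -h·ln(1 - P/h - Q) - ½(1-h)·ln(1 - 2Q).

θ is pooled per pair, not per alignment, matching the pairwise definition
of the model and keeping pairs independent. Saturated pairs (either log
argument ≤ 0, or h = 0 with transitions present) raise an error naming the
pair rather than emitting NaN or a clamped value — silent truncation would
corrupt the permutation tests downstream.

**SNP filtering.** Genotype calls need depth ≥ 10 (inclusive, "at least")
and read support strictly > 0.8 ("more than 80%"); failing calls become
missing rather than deleting the locus. Loci are then dropped when they
overlap an excluded region (0-based half-open intervals; used to remove
the MAT and PTG regions before genome-wide distances so the tested loci
cannot drive the genome signal), when their minor-allele count over
non-missing isolates falls below 2, or when within-isolate heterozygosity
exceeds 0 — vacuous for single-call haploid data, retained for multi-call
input. Filtering is idempotent and logs per-rule removal counts. Input
without depth/support metadata (genepop) skips those rules with a warning.

**Jaccard.** For isolates i, j over loci non-missing in both:
`d = (b+c)/(a+b+c)` with a = shared presence of allele 1 and b+c =
mismatches. Shared absence is non-informative, the standard binary-Jaccard
convention; a pair with zero informative loci gets d = 0 with a warning,
and a pair with no shared called loci at all is an error.

## Congruence tests

**Mantel.** Pearson correlation of the n(n-1)/2 upper-triangle entries,
with the null generated by jointly permuting rows and columns of the second
matrix. The test is one-tailed (greater), because the claim under test is
directional: clonality predicts positive association. p uses the
`(1 + exceedances)/(1 + n_perm)` estimator, so p is never 0 and the
minimum attainable p is 1/(n_perm+1); the default n_perm = 9999 makes
p < 1e-3 resolvable. Matrices covering different isolate panels are
restricted to their label intersection (≥ 3 required), and the
intersection size is reported — analyses on nested isolate subsets are
normal use. The parametric Pearson p on distance vectors is also reported,
always alongside the permutation p and flagged as anti-conservative, since
distance-pair entries are not independent.

**Ward dendrograms.** Agglomerative clustering under the Ward.D2
convention: Lance–Williams updates on squared distances, merge height =
square root of the minimised criterion. This operates on the distances as
given without a pre-squaring ambiguity and matches scipy's `ward` on
condensed distances; an alternative from-scratch formulation (height² =
2 × within-cluster sum-of-squares increase) is used as an independent
oracle in the tests. Ties break toward the pair whose lexicographically
smallest member labels sort first, making output independent of input
order.

**Baker's gamma.** For every unordered leaf pair, the merge depth is the
number of clusters present when the pair first co-clusters; gamma is the
Spearman rank correlation between the two trees' depth vectors. (The
original Goodman–Kruskal formulation is a close relative; Spearman is the
common implementation choice and the one taken here.) Significance comes
from permuting the leaf labels of one tree, 1000 permutations by default,
two-sided on |gamma|.

**PERMANOVA.** One-factor pseudo-F in Anderson's formulation:
`SS_total = Σd²/n` over all pairs, `SS_within` the group-wise analogue,
`F = (SS_between/(a-1))/(SS_within/(n-a))`, with group labels permuted for
the null (999 permutations, the long-standing default of the reference
implementation). Applied to the SNP Jaccard matrix with geographic origin
and MAT-type as factors.

## Codon evolution

**Nei–Gojobori.** Per codon, each position contributes one site split into
synonymous/non-synonymous fractions over its non-stop single-base mutants,
so syn + nonsyn = 3 exactly. Between two codons, difference counts average
over all orderings of the changed positions with equal weight, discarding
orderings that pass through a stop codon (the plain, unweighted variant of
the method — not the transition/transversion-weighted modification).
Proportions pN = Σnd/N and pS = Σsd/S (sites averaged over the two
sequences) are Jukes–Cantor corrected, `d = -¾ ln(1 - 4p/3)`, with p ≥ ¾
raising a saturation error.

**Z-test.** dN and dS are averaged over all unordered sequence pairs;
variances come from resampling codon columns with replacement (999
replicates by default) and recomputing the pair-averaged values — the
standard bootstrap for codon-based Z-tests, resampling columns rather than
sequence pairs. `Z = (dN - dS)/√(Var dN + Var dS)`; both one-tailed
p-values are reported (purifying: lower tail, positive: upper tail),
since either direction can be of interest. Identical sequences give
zero variance and a flagged-undefined Z instead of a division by zero.

**CAI / eCAI.** Relative adaptiveness w = codon count / max count within
its synonymous family, computed from a pooled reference CDS collection;
unobserved codons receive a pseudo-count of 0.5 before w so a single rare
codon cannot annihilate the geometric mean (each application is logged).
CAI is the geometric mean of w over the query's codons, excluding Met, Trp
and stops (single-codon families carry no usage information). The eCAI
null preserves the query's exact amino-acid sequence and draws each codon
from its family with probability proportional to the product of the
query's overall nucleotide frequencies over the codon's three positions —
a composition-matched null. The threshold is the normal-approximation
upper 95% point, mean + 1.645·sd, with the empirical 95th percentile
reported alongside for transparency; at least 30 null draws are required.

## MAT typing

Queries are assigned the type of their nearest reference by p-distance
when that distance is ≤ `max_dist` (default 0.03); the remainder are
single-linkage clustered at the same threshold into novel types. This
replaces posterior-probability clustering on a Bayesian tree — the typing
decision itself only needs a similarity rule, and a fixed, surfaced
threshold makes it auditable; `max_dist` appears in every report and is
deliberately a tunable proxy rather than a calibrated constant. Within a
type, isolates split into alleles only on exact amino-acid differences of
the translated partial protein, so synonymous variants share an allele;
allele groups are numbered by decreasing size then lexicographic
representative. Identical nucleotide sequences are deduplicated before
typing and re-expanded after, which both speeds the computation and
guarantees input-order invariance.

## The simulator

A discrete-generation haploid Wright–Fisher population of N individuals,
each carrying a MAT coding haplotype (87 codons by default, matching a
~261 bp amplicon), a PTG coding haplotype (213 codons, ~639 bp CDS) and
`n_snps` unlinked biallelic loci (2000 by default). The population starts
monomorphic from a single random stop-free ancestor, so every observed
polymorphism arises in-run and the genealogical-coupling contrast is clean.

Mutation: each coding base mutates with probability `mu_coding` per
generation to a uniformly random different base; synonymous proposals are
always accepted, non-synonymous ones with probability `omega` (purifying
selection as biased acceptance — this produces dN/dS < 1 without a fitness
machinery), premature stops never. SNP loci flip 0↔1 with probability
`mu_snp`. Reproduction: clonal mode copies one uniformly chosen parent per
child; sexual mode rejection-samples parent pairs whose MAT haplotypes
differ at ≥ 1 nucleotide (the simplest faithful reading of MAT-based
non-self recognition) and reassorts the MAT locus, the PTG locus and every
SNP locus independently by fair coin — free recombination, which makes the
sexual null maximally decoupled. If the population is MAT-monomorphic, a
generation falls back to clonal copying and is recorded. Identical
configurations produce bit-identical output.

The defaults (N = 200, 500 generations, `mu_coding` = 1e-4, `mu_snp` =
5e-4, `omega` = 0.3, 20 isolates sampled) are chosen to give pairwise
coding divergence of a few percent and ample SNP polymorphism at
desk-scale run times (about a second per simulation); they are working
parameters for signal, not biological estimates — no quantitative
mutation or selection rates are available for these fungi. What the
simulator does *not* emulate: diploid or dikaryotic genomes, linkage among
SNPs, population structure or migration, indels, sequencing error
(emitted depth is constant 12 and support 1.0 — the depth/support filters
are exercised by dedicated corrupted fixtures instead). Passing tests on
simulated data therefore demonstrate that the statistics recover the
reproductive mode under the model's idealisations, not that any particular
real dataset is clonal.

## Numerical and degenerate-input policy

All permutation p-values use `(1+exceed)/(1+n_perm)`. Distance matrices
assert symmetry, zero diagonal and non-negativity on every construction.
Saturation (Tamura or Jukes–Cantor) is an error, never a clamp; bootstrap
replicates that saturate are skipped and counted. Dendrogram heights are
made non-decreasing (cumulative maximum) to absorb floating-point jitter
in the Lance–Williams recursion. Seeds: every stochastic routine takes an
explicit seed; the pipeline derives per-stage seeds by fixed offsets from
one master seed so a report is reproducible end to end.

## Problem sizes used in validation

The test suite validates calibration with 200-seed null batches
(Kolmogorov–Smirnov against uniform), scenario recovery with 20 replicate
simulations per mode at the default population size, and selection
recovery with 30 replicates at `omega` = 0.3 plus 200 at `omega` = 1 on
reduced populations (N = 50, 150 generations) — sizes at which the whole
suite runs in a couple of minutes on one CPU. The acceptance script uses
8 replicates per scenario at the full default size with 27 sampled
isolates, mirroring the isolate count of a realistic panel.

## Known limitations

- The neutral Z-test calibration carries a slight purifying bias from the
  simulator's absolute rejection of stop codons at stop-adjacent codons;
  at the validated divergences the effect stays within the binomial noise
  band of the calibration check.
- Baker's gamma depends on both tree shapes; its permutation null
  conditions on shapes, so gamma values are not comparable across datasets
  with very different cluster structure.
- Nearest-reference MAT typing with a fixed threshold is a proxy for
  phylogenetic cluster support; type counts on real data depend on
  `max_dist` and should be read together with that setting.
- The parametric Pearson p on distance vectors is reported for continuity
  with common practice but is anti-conservative; conclusions rest on the
  permutation tests.
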