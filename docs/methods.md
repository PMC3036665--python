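# Methods

This note documents the models, numerical choices and synthetic-data
design behind `esudelim`, in the spirit of the model documentation of
simulation and inference packages.

## Substitution models and corrected distances

All models are time-reversible members of the GTR+I hierarchy over
{JC, K2P, HKY, TrN, GTR}. A model carries base frequencies π (empirical
counts with a +1 pseudocount when estimated from data), six
exchangeabilities with the GTR normalisation r(GT) = 1, and a
proportion of invariant sites pᵢₙᵥ ∈ [0, 1). The rate matrix
Q(i,j) = r(i,j)·π(j) is normalised to one expected substitution per
unit time among variable sites; transition probabilities come from the
symmetrised eigendecomposition (exact for reversible Q), cached per
model.

**Distances.** JC and K2P (without +I) use their closed forms
(d = −¾ ln(1 − 4p/3); d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)). Every
other model maximises the two-sequence likelihood over the divergence
time t ∈ [0, 10] (bounded Brent, tolerance 1e-8) with the model fixed;
with invariant sites the per-site likelihood is the proper mixture
pᵢₙᵥ·πₓ·δₓᵧ + (1 − pᵢₙᵥ)·πₓ·Pₓᵧ(t), and the reported distance is
(1 − pᵢₙᵥ)·t, the expected number of substitutions per site averaged
over all sites. A closed-form argument ≤ 0, or a numeric optimum
pinned at the t = 10 bound, raises a saturation error naming the pair.

Distances use **pairwise deletion**: a site counts only when both
sequences carry an unambiguous base. This matches the per-pair *n*
reported by standard distance software. Likelihood computations, in
contrast, keep gaps and ambiguity codes as partial-state vectors (a
gap is compatible with all four bases).

The model is estimated **once per locus** on a fixed topology and held
fixed for all pairwise optimisations; distances are never re-fitted
per pair. One practical consequence, verified empirically: the
guarantee "corrected distance ≥ p-distance" holds when the model
describes the data (the pipeline's regime), but can fail under gross
base-composition misspecification — the ML time trades off pattern
frequencies, it does not match mismatch counts.

## Tree likelihood and model choice

`tree_log_likelihood` is Felsenstein pruning over compressed site
patterns with per-node rescaling (log-scaler accumulation), the +I
mixture applied at the site level, and branch lengths interpreted as
expected substitutions per site averaged over all sites (the variable
class therefore evolves for t/(1 − pᵢₙᵥ)). It is checked against
exhaustive sums over internal states to 1e-10.

`select_model_aic` fits all ten candidates on a fixed topology (NJ
from JC distances by default), optimising exchangeabilities, pᵢₙᵥ and
all branch lengths jointly with L-BFGS-B (500-iteration cap;
non-converged fits are flagged and excluded from "best"). Base
frequencies are the empirical counts and are counted among the free
parameters (3 for HKY/TrN/GTR), the convention of the classical model
selection tools; optimising them numerically changes AIC rankings
negligibly at barcode scale while tripling the search dimension.
AIC = 2k − 2 lnL; ties within 1e-6 break toward fewer parameters.

## Trees, support and parsimony

Neighbor joining is the canonical Studier–Keppler formulation;
negative branch-length estimates are clamped to zero with the deficit
moved to the sister edge, preserving the joined pair's path length.
NJ deliberately replaces heavyweight ML/Bayesian tree searches: the
delimitation logic consumes only split supports and congruence, which
NJ plus bootstrap provide deterministically at desk scale, and
externally computed posterior probabilities can still be attached to
splits and are honoured by the thresholding rule.

Bootstrap support resamples sites with replacement, rebuilds the NJ
tree per replicate, and reports the percentage of usable replicates
containing each original-tree bipartition. Replicates with undefined
or saturated distances are dropped (warning above 10%). Splits on
zero-length internal edges — including clamped NJ estimates — carry no
resolution and are excluded on both the original tree and replicates;
an alignment of identical sequences therefore supports nothing.

Support thresholds are strict (> 70 bootstrap, > 0.95 posterior), and
a split qualifies if *either* available support type passes.

Fitch parsimony treats gaps and ambiguity codes as zero-cost
wildcards. `parsimony_best` enumerates all unrooted topologies up to 9
taxa (vectorised over topologies and site patterns; memory-chunked),
and falls back to an NJ starting tree with first-improvement NNI
hill-climbing under a deterministic edge ordering beyond that.

## ILD congruence test

The partition-homogeneity test of Farris: D_obs is the combined-data
best parsimony length minus the sum of per-partition best lengths
(non-negative by construction); each replicate re-partitions the
pooled site columns, without replacement, into pseudo-partitions of
the original sizes; constant sites are retained so sizes are
preserved. The p-value uses the add-one convention
(1 + #{D_null ≥ D_obs})/(1 + n_reps), so p is never 0 and p = 1 is
attainable. The pooled columns are put into a canonical (lexicographic)
order before permutation, which makes the p-value exactly invariant to
relabelling sites within a partition.

Because parsimony lengths are integers the test is conservative when
data carry little homoplasy (D_obs ties the null mass at zero). The
calibration preset (`ild_sim_pair`: six taxa, JC, 300 sites, terminal
branches 0.5, internals 0.05) deliberately sits in the homoplasy-rich
regime where the statistic spreads over many values and the empirical
type-I error at α = 0.05 is statistically indistinguishable from
nominal; with short terminals the same machinery is valid but
conservative, which is a property of the Farris test itself.

## Delineation rule

Candidate units come from haplotype collapse, supported clades, user
input, or single-linkage clustering of a specimen-level matrix at a
barcoding-gap cut (`candidates_from_gap`). The rule, per unit pair and
per locus:

  accept u iff min-between(u, v) > max(within(u), within(v)) for all v

with strict inequality by default (a non-strict mode exists behind a
flag), singleton within-divergence 0 by convention (printed tables
mark singletons '-'), and the conservative per-pair reading
max(within(u), within(v)) as the gap floor. Supported splits act as a
**veto**: a unit is rejected if any qualifying split in any locus
conflicts with its monophyly, but positive support in every locus is
not required — slow loci often cannot resolve every unit yet should
not block it. On unit-level matrices a merged candidate's within
divergence includes the between-member cells, since those pairs lie
inside the candidate. Units absent from a locus are flagged, never
silently dropped, and cannot be accepted. Failed pairs are reported as
merge suggestions.

`cluster_parts` names the deep parts via connected components of the
graph joining units with d < cut (single linkage); the bundled COI
table splits into its two printed parts at cut 0.10 with a wide margin
(0.059 within versus 0.145 between).

## Morphology

Four controlled-vocabulary characters; the chela character is
pre-binarised at 30 µm (the underlying size ranges, 15–25 versus 30+,
do not overlap, so raw micrometries add nothing). Modal profiles take
the per-character majority state per unit; ties are recorded as
ambiguous, never silently broken, and deviant specimens are listed
individually rather than averaged away. Diagnosability groups units
with identical modal profiles. The key to species requires the small
chela state for the *P. microcionides* group, so the one large-chela
deviant keys out as unassigned individually while its unit's modal
profile still keys to the group — both behaviours are asserted in the
tests, mirroring how a single aberrant spicule measurement should be
surfaced, not absorbed.

## Synthetic data

`simulate_alignment` draws root states from π, holds a fraction pᵢₙᵥ
of sites invariant across the whole tree, and evolves the rest
edge-wise through P(t·rate/(1 − pᵢₙᵥ)), so branch lengths are expected
substitutions per site on the same scale the distance estimators
report. Within-species variation is a star-like extension of each
species tip: every specimen hangs from the species node on an
exponential branch of mean θ/2, giving expected within-species
pairwise diversity θ at locus rate 1. This is deliberately not a
coalescent — the pipeline consumes distances and supports, not
genealogy shape — so θ is the single interpretable knob.

The default preset (`plocamionida_like`) emulates the motivating
study's structure: 8 species in two parts separated by ~0.18 expected
substitutions/site at the fast locus, minimum between-species path
0.04, sampling {27, 6, 5, 3, 2, 1, 1, 1} specimens (46 total, so the
singleton code paths always run), a GTR+I fast locus (AT-rich, pᵢₙᵥ =
0.4, rate 1) and an HKY+I slow locus (pᵢₙᵥ = 0.6, rate 0.1). The slow
locus is monomorphic within species (θ-scale 0), as ribosomal markers
typically are at this depth — in the motivating data all 27 specimens
of the largest unit shared one 28S genotype. Default θ = 0.002 keeps
within-species diversity near the low intra-unit values seen in
mitochondrial barcodes of such sponges. Loci default to 2,000 sites:
long enough that the slow locus accumulates ≥ several substitutions on
even the shortest species path, so the strict gap rule is decidable in
both loci; the morphology deviation rate defaults to 0.02 (≈ 1 deviant
in 46). All randomness flows from one seed through named substreams
(trees / sequences / morphology / metadata).

With these defaults the full pipeline — simulate, corrected distance
matrices under the true per-locus models, candidate units by single
linkage at cut 0.02 on the fast locus, two-locus gap-rule delineation —
recovers the generating species partition exactly (adjusted Rand
index 1) across 20 seeded replicates, and that is asserted in the
acceptance tests. Parameter-recovery checks (species-pair mean
corrected distances within 15% of true patristic paths) are asserted
on the 20-seed aggregate, because a single seed's estimate of the
shortest path carries ~15% sampling noise on its own at 2,000 sites
under GTR+I.

What the simulator does **not** emulate: coalescent gene-tree
discordance, indels and alignment error, contamination, base-composition
heterogeneity across lineages, and rate variation beyond the
invariant-sites class. Passing tests on synthetic data therefore
demonstrate correctness of the machinery under the stated model, not
robustness to those real-data pathologies.

## Scope notes

Published sequence-level numbers for the motivating dataset (alignment
lengths, ts/tv ratios, haplotype counts, the exact tree figures)
require the archived sequences plus unstated alignment/trimming
choices, so the package validates those operations against simulations
with known truth instead of asserting the printed values. The ts/tv
statistic reported by `alignment_stats` is the observed pooled ratio
over all sequence pairs; an ML κ estimate is available through the
fitted models, and the two need not coincide.
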