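# Methods

This note documents the statistical machinery, the synthetic-data
generator, and the numerical and design choices behind `phytocolon`.
Everything stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is quoted from external results.

## Data model

The canonical object is an integer ASV × sample count table with a
sample metadata table (tissue, ordered developmental stage, site, year,
plant individual, preparation plate, sequencing run, plant/soil
material), a seven-rank taxonomy (Kingdom … Species, with an explicit
`unassigned` token), and a rooted phylogeny whose tips are the ASVs.
All files are plain TSV/Newick.

Quality control follows the standard amplicon workflow: ASVs with total
frequency below 2 are removed, then samples with fewer than 10 reads;
for dissimilarity analyses the table is additionally pruned to samples
with ≥ 100 counts over ≥ 20 ASVs, and rarefied to 1,000 counts per
sample by multivariate-hypergeometric subsampling (samples shallower
than the depth are dropped; a rarefied cell can never exceed its
original count). Filters are applied features-first and are idempotent.
Whether rarefaction should be redrawn per analysis is a user choice;
the pipeline draws it once per run from the global seed.

## Dissimilarities

**Raup-Crick.** For presence sets A and B against a pool of all N ASVs
in the analysed table, the index is the exact hypergeometric tail
P(X ≥ |A∩B|) with X ~ Hypergeometric(N, |A|, |B|). Design choices:

- *Analytic by default.* The tail is evaluated with `scipy.stats.
  hypergeom.sf`, which the tests verify against exhaustive enumeration
  of all subsets for pools up to N = 12 (agreement to 1e-12). A
  null-simulation mode draws richness-preserving random assemblages
  (uniform inclusion, or proportional to occurrence frequency) and is
  shown to converge to the analytic value; which variant an analysis
  wants is exposed, since both are in circulation.
- *Diagonal.* A sample against itself has d = P(X ≥ a), not 0: the
  index is a probability and forcing a zero diagonal would break the
  null-model semantics. `DistanceMatrix.zeroed_diagonal()` exists for
  consumers (e.g. PCoA) that need a hollow matrix; PCoA zeroes the
  diagonal by default.
- *Pool.* The species pool is the filtered table's own ASV set,
  matching standard practice.

**Bray-Curtis** is delegated to `scipy.spatial.distance` (zero-total
samples are rejected by name).

**UniFrac.** Both variants are computed from a branch decomposition of
the rooted tree (branch length vector + branch × tip membership
matrix), making each metric a dense linear-algebra expression:
unweighted d = unique/union subtended branch length; weighted
d = Σ len(b)·|p_A(b) − p_B(b)|, normalised by Σ len(b)·(p_A + p_B) when
requested. Both match scikit-bio's implementations to ~1e-16 in the
test suite (scikit-bio is the cross-check, never the implementation).
On star trees the unweighted form provably equals the Jaccard
complement, which the tests assert.

**PCoA.** Gower-centre −½ J D∘D J and eigendecompose; coordinates are
eigenvectors scaled by √λ for positive eigenvalues. Negative
eigenvalues (non-Euclidean inputs such as Bray-Curtis) are reported but
excluded from the proportion-explained denominator. Eigenvalues below
1e-12 (relative) are treated as null axes.

## PERMANOVA

Sequential (Type I) sums of squares on the centred inner-product matrix
G: SS_k = tr((H_k − H_{k−1})G), where H_k projects onto the column space
of the cumulative dummy-coded design. The nested formula operator `A/B`
expands to the main effect A followed by the full-combination
interaction A:B, so "plates nested in runs" style designs are coded
without hand bookkeeping; a term's df is the rank increment it
contributes (rank via SVD with a max(m,n)·eps·σ₁ tolerance), and terms
adding no rank are dropped with a warning. Only a sequential
decomposition is meaningful for such nested chains, which is why Type I
is the only option.

p-values use free (unrestricted) permutation of sample identities —
rows and columns of D permuted together — with the +1 convention, so p
is floored at 1/(n_perm+1); an exhaustive mode enumerates all n!
relabelings and reports the exact fraction (used by the oracle tests:
on the two-cluster toy the single-factor R² is exactly 1 and the
exhaustive p is 8/24). For a one-way design on Euclidean distances of
univariate data, pseudo-F equals the classical ANOVA F; the tests
assert this identity and the calibration of the type-I error under
exchangeable nulls. No restricted/strata permutation or dispersion test
is provided (out of scope).

Pairwise tissue contrasts subset the samples to a stage window and two
tissues and run the single-term form.

## Shared membership

Shared proportion defaults to Jaccard similarity |A∩B|/|A∪B|; the
overlap coefficient |A∩B|/min(|A|,|B|) is a config switch, since the
"proportion shared" denominator is a genuine modelling choice. Pair
universes: all plant-sample pairs (random), pairs agreeing on one
variable, or same-plant/different-tissue pairs. The universe is used
exhaustively up to 10,000 pairs, otherwise sampled uniformly without
replacement (seeded). Conditioned-vs-random contrasts use the
Mann-Whitney rank-sum test, one-sided "greater" by default (the
scientific claim is a right shift); two-sided is available for the
same-plant comparison, whose direction is not prescribed.

## Indicator ASVs

IndVal = A·B from the presence-absence table (A = specificity,
B = fidelity, estimated by direct counting per habitat level). The
permutation null shuffles sample-to-habitat assignment, preserving each
ASV's prevalence; p_hi and p_lo are the ≥/≤ tail counts with the +1
convention and p_two = min(1, 2·min(p_hi, p_lo)). Consequences worth
knowing:

- at α = 0.01 the two-tailed floor means n_perm must exceed 199 for any
  cell to be significant; n_perm < 99 is refused outright and a
  warning is emitted whenever the floor cannot beat α (the pipeline
  default is 499);
- the discrete null makes the test mildly conservative; under
  exchangeable nulls the realised flag rate sits at or just below α
  (asserted within a binomial 99% band in the acceptance tests);
- no multiple-testing correction is applied by default (selection is at
  raw α, reported per habitat level); a Šidák-corrected α is available
  via the `alpha` argument if desired.

Discriminating ASVs are those with any significant level; each is
assigned the significant level of maximal IndVal, ties broken by
habitat label order (deterministic).

## Prevalence-peak consistency

Per (site, year) cell, an ASV's peak is the strict argmax of prevalence
over tissues (or stages). Exact ties mark the cell "tied" and remove it
from the vote rather than being broken arbitrarily — tie-breaking would
manufacture consistency. An ASV is *consistent* when ≥ 2 evaluable
cells all share one untied peak; ASVs evaluable in a single cell are
labelled `single_cell` and excluded from both numerator and denominator
by default (a flag counts them as trivially consistent), because one
observation cannot show repetition. `min_prevalence` defaults to 0;
prevalence floors akin to plotting filters are report options, not
analysis defaults.

## α-diversity

Weighted phylogenetic diversity is PD_w = Σ_b len(b)·p(b) with p(b) the
relative abundance descending through branch b — algebraically the
abundance-weighted mean root-to-tip depth. It is invariant to count
scaling and bounded by the unweighted PD of the same tip set. Shannon
H′ uses the natural log (a base option exists) and is computed on
rarefied counts so library depth does not masquerade as evenness.
Stage contrasts use the unpaired two-sample rank-sum test — samples at
different stages are different plants, so a paired signed-rank form
would be wrong — with star tiers at p < 0.05/0.01/0.001/0.0001 (strict
inequalities).

## Synthetic-data generator

The generator emulates the factorial survey the pipeline targets:
2 sites × 2 years × 6 ordered stages, with stage-dependent tissue
availability (roots + rosettes through vegetative growth; stems,
cauline leaves, flowers and siliques appearing at flowering; roots,
stems and siliques at senescence). Defaults: 300 ASVs, 10 samples per
site × year × stage × tissue cell, log-normal library sizes around
exp(7.6) ≈ 2,000 reads (so the 1,000-count rarefaction keeps most
samples), occupancy base logit −2.5, stage slope 0.3, tissue/site/year
effect SDs 1.5/0.5/0.5, 25% consistent and 25% inconsistent ASVs.

It is a two-part (hurdle) model: presence is Bernoulli in a logistic
occupancy model, and counts given presence are a multinomial draw of
the library size over iid gamma relative weights (negative-binomial-
style overdispersion). Presence and abundance are separated so that
both the presence-based (Raup-Crick, unweighted UniFrac, IndVal,
prevalence) and abundance-based (Bray-Curtis, weighted UniFrac, H′)
machinery sees realistic structure. Consistent ASVs draw one tissue-
preference vector shared by every site × year cell; inconsistent ASVs
draw an independent vector per cell; neutral ASVs have none. The drawn
effects are returned as ground truth, including each ASV's planted
logit gap (top tissue minus runner-up), which is what recovery tests
condition on.

Two deliberate phylogenetic choices make diversity trends mechanistic
rather than decorative. First, the Yule topology's branch lengths are
relaxed with lognormal lineage-rate variation: real 16S gene trees are
not clock-like, and on an exactly ultrametric tree PD_w (a weighted
mean tip depth) would be constant by construction. Second, the stage
response is phylogenetically graded — each ASV's stage slope is scaled
by a gain in [0.5, 1.5] ordered by its root-to-tip depth — so
assemblages do not merely get richer with host age: lineages from
across the tree disperse in progressively, and PD_w rises alongside H′.
With stage_slope = 0 (a soil-like control) both the richness trend and
the grading vanish.

Taxonomy is generated by cutting the tree at seven increasing depth
thresholds, so finer ranks strictly refine coarser ones and congeneric
ASVs always share their full coarser lineage (the aggregation and
subgenus-heterogeneity analyses depend on this). Per-rank unassignment
is applied independently at the requested rate.

What the generator does *not* emulate: read-level error, chimeras, PCR
or copy-number bias, spatial autocorrelation within a site, plate/run
batch effects (plate and run columns exist but carry no planted
effect), or soil communities as a distinct pool. Passing tests
therefore demonstrate that the estimators recover the structure the
model plants at realistic sparsity and depth — not that field data
satisfy the model.

## Problem sizes and determinism

Validation uses deliberately small problems: PERMANOVA calibration runs
500 exchangeable nulls of 24 samples at 199 permutations; IndVal
calibration uses 1,000 null ASVs over 120 samples at 499 permutations;
effect recovery uses 20 replicate surveys at 3 samples per cell
(Bray-Curtis + two-term PERMANOVA) and sensitivity uses 20 samples per
cell with the stage slope off; trend recovery uses one 200-ASV survey
at 4 samples per cell. These sizes give the binomial bands and
regression tests adequate resolution while keeping the whole suite fast.
Every stochastic routine takes an explicit seed; identical configs give
byte-identical outputs, which the pipeline tests assert file-by-file.

## Known limitations

- Raup-Crick's analytic form conditions only on richness; the
  frequency-weighted null is simulation-only (no closed form).
- Free permutation ignores the nesting when generating the PERMANOVA
  null; with strong plate/run structure a restricted scheme would be
  more faithful, but none is implemented.
- The unassigned-taxa policy at aggregation ("keep" as singletons by
  default, "pool"/"drop" as options) materially changes coarse-rank
  tables with many unassigned ASVs; results at Genus level should be
  read with the chosen policy in mind.
- `within_between_distributions` and the pairwise tissue contrasts do
  not correct for multiple stage windows; interpret families of
  contrasts jointly.
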