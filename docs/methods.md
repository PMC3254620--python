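# Methods

`unguis` implements three quantitative pipelines around a single
palaeontological question: did a fossil primate foot bear a grooming claw
on its second pedal digit, and what does its overall pedal anatomy say
about its affinities?  This note records the models, the defaults and why,
the synthetic-data assumptions, and the numerical choices.

## 1. Distal-phalanx shape (`unguis.phalanx`)

### Size standardization

Nine measurements describe one distal phalanx: eight linear distances in
mm (base height BH, base width BW, total length TPL, shaft heights/widths
at 1/4 and 3/4 of shaft length SH-1/4, SW-1/4, SH-3/4, SW-3/4, volar
feature length VFL) and the facet–shaft angle FSA in degrees.  Size is
removed by dividing each linear measurement by the specimen's geometric
mean GM = (∏ xᵢ)^(1/8), computed in the log domain.  By construction the
eight standardized values multiply to 1, and every downstream shape
quantity is invariant under uniform scaling of a specimen.  Three simple
indices are also carried: VFL/TPL (relative volar length), SH-1/4 / SH-3/4
(shaft tapering), SW-3/4 / TPL (relative tuft width).

### Single-specimen t-test

A fossil is a sample of one, and the extant raw data behind the published
group summaries were never released, so fossils are compared with groups
through the single-specimen special case of the two-sample t-test
(Sokal & Rohlf):

    t = (x − x̄) / ( s · sqrt((n + 1)/n) ),   df = n − 1,

two-tailed p.  This needs only the group mean, variance and n — exactly
what the published tables print.  Group sizes are the comparative sample's
counts: nails n = 21, grooming claws n = 10, tegulae n = 4, claws n = 7,
applied to every variable (per-variable counts were not published; these
counts reproduce the published t-values to within their printed rounding,
e.g. 0.95 exactly, 4.56 vs 4.58, −3.14 vs −3.17, 4.73 vs 4.74).  As
n → ∞ the statistic converges to the z-score.

### Classification rule

For each fossil and each variable, the nearest group minimises |t|.  The
combined verdict is *grooming-like* only when the fossil is nearer the
grooming baseline on all three of FSA, VFL/TPL and SH-1/4 / SH-3/4 —
a dorsally canted shaft, a short volar process and strong distal tapering
jointly diagnose a grooming claw; no single trait does (short VFL/TPL
alone would misclassify several nail-bearing phalanges).  Relative tuft
width SW-3/4/TPL is reported but excluded from the verdict: grooming
claws have narrow tufts, yet every fossil in the packaged table is
nail-like in this variable, so it carries no discriminating power for
these specimens.  Significance flags use a Bonferroni-adjusted alpha,
default 0.05/12 ≈ 0.0042 for the twelve sequential comparisons.

### PCA and hulls

The PCA operates on the 9×9 Pearson correlation matrix (so eigenvalues
sum to 9 and "53% of variance" means eigenvalue 4.8 of 9), with loadings
reported as correlations between variables and component scores.  Signs
are fixed so BH/GM loads positively on component 1; other components take
the sign of their largest-magnitude loading.  The specimen set for the
fit is all measured specimens by default (a config switch restricts the
fit to extant specimens and projects fossils afterwards).  Group
membership of fossils in the first two component dimensions is assessed
against each extant group's convex hull (SciPy Qhull), with points within
a tolerance (default 1e-9 score units) of a facet reported as "edge".

### Group statistics

One-way ANOVA and Kruskal–Wallis come from SciPy; the overall MANOVA is
Wilks' lambda via statsmodels.  Pairwise Hotelling T² uses the pooled
two-group covariance with F conversion F = T²(n₁+n₂−p−1)/((n₁+n₂−2)p); if
the pooled covariance is singular and the ridge policy is enabled, a
fixed ridge of 1e-8·trace/p is added with a warning.  "Tamhane T2" is
realised as pairwise Welch t with Satterthwaite df and a Sidak
multiplicity adjustment 1−(1−p)^m over the m pairs; statistical packages
differ in the exact Tamhane multiplier, and the Sidak form is the
standard conservative unequal-variance choice.  All p-values are
two-tailed.

## 2. Pedal proportions (`unguis.foot`)

Six indices capture the prosimian/anthropoid contrast and grooming-claw
digit reduction: pp4/mt4 (prehensility), mt1/mt2 (hallux hypertrophy),
mt3/mt4 (foot axis), mt4/mt5, pp2/pp5 (digit-II reduction), pp3/pp4.
Metatarsal indices are compared across two gradistic groups with Welch t
(plus Mann–Whitney U); the phalanx indices across five clades (tarsioids,
lorises, galagos, lemuroids, anthropoids) with ANOVA F, Kruskal–Wallis H,
and post hoc Tukey HSD plus pairwise Mann–Whitney at a Bonferroni-adjusted
alpha.  Fossils are placed with the same single-specimen t as above.

The discriminant analyses standardize element lengths by a geometric mean
— of all 13 elements (mt1–5, pp1–5, ip2, ip3, ip5), or of the phalangeal
set only, with its own GM.  The phalanx-only analysis uses seven
variables although eight phalangeal lengths exist; this package drops the
hallucal proximal phalanx pp1 (dominated by hallux size rather than digit
formula) and warns on first use, since the published variable list is
ambiguous.  LDA uses equal priors (group sizes are collection artifacts),
complete cases only, and scikit-learn's SVD solver behind the module
surface; an exactly singular pooled within-group covariance raises unless
a shrinkage ridge is requested.  Standardized canonical coefficients are
the eigen-scalings multiplied by the pooled within-group standard
deviations.  Jackknife (leave-one-out) validation refits the model once
per record, by construction.

A fossil fourth metatarsal reported anomalously short is re-estimated
from its mt3 and mt5: the extant sample gives the distributions of
mt4/mt3 and mt4/mt5, and the default "conservative-min" policy returns
the smaller of mt3·min(mt4/mt3) and mt5·min(mt4/mt5) — the shortest mt4
any sampled extant proportion would imply — together with both full
predictive intervals.  The exact published estimation procedure lives in
unreproduced supplementary material, so the operation is parameterized by
an estimator policy (a plain ratio-mean policy is also provided).

## 3. Ordered-character parsimony (`unguis.parsimony`)

### Lengths

Unordered characters are scored by Fitch set operations (intersection
else union at cost 1), ordered characters by the Farris interval method —
each node carries the interval of optimal states; disjoint child
intervals cost their gap — which equals Sankoff dynamic programming with
linear costs |i−j|.  Trees are scored rooted at their first leaf; the
result is invariant to root placement and character order (tested).
Missing cells are unconstrained (full set / full interval) and never
force steps.

Polymorphic and ambiguous codings such as "0/1" are treated as
uncertainty (minimum-cost resolution) by default.  The alternative
"as-both" costing charges each polymorphic terminal the steps needed to
realise every recorded state (state range for ordered, set size − 1 for
unordered), a tree-independent surcharge applied consistently to observed
steps and to both bounds, so CI/RI stay coherent.  Historic parsimony
software distinguishes these readings; printed tree lengths adjudicate
once a matrix is transcribed.

### Bounds and ensemble statistics

Per character, m = minimum conceivable steps on any tree (ordered:
smallest achievable observed range after resolving ambiguity; unordered:
smallest hitting set of the cell sets minus one, found exactly — the
alphabets are tiny) and g = best star-tree score over all central states.
With observed steps s on an MP tree: TL = Σs, CI = Σm/Σs, HI = 1 − CI,
RI = (Σg − Σs)/(Σg − Σm) with RI = 1 when Σg = Σm, RC = CI·RI.
A character with m = g contributes identical steps to every topology and
is flagged parsimony-uninformative; CI/RI include all characters by
default (matching the common software default), with a flag to recompute
excluding uninformative ones.

### Search

Both searches enumerate unrooted binary topologies by stepwise leaf
insertion (each of the (2n−5)!! topologies generated exactly once).
Exhaustive search scores every complete topology; branch-and-bound
additionally scores partial trees and prunes a subtree when the partial
length already exceeds the best complete length (parsimony length is
monotone under leaf addition), keeping ties.  The two return identical MP
sets (tested 50/50 on random matrices).  Exhaustive mode refuses beyond
11 taxa; branch-and-bound has no ceiling.  MP trees are emitted in
canonical newick order.  The search inner loop is plain integer Python:
tie-heavy low-homoplasy searches must evaluate every topology, and
per-merge array overhead dominated at realistic character counts.

### Consensus and formats

Strict and majority-rule consensus count bipartitions (clades measured on
the side away from the outgroup); strict keeps frequency-1 clades,
majority keeps frequency > threshold (default 0.5; majority clades are
mutually compatible, so the tree assembles by nesting).  Newick output
roots on the outgroup as first child of the root and annotates clades
with support frequencies.  NEXUS I/O covers DATA/CHARACTERS blocks with
SYMBOLS/MISSING/GAP, "(01)"/"{01}" ambiguity, interleaved rows, quoted or
underscore names, ASSUMPTIONS TYPESET ord/unord assignments and an
OUTGROUP command; parse errors carry 1-based line numbers.  NEXUS
declares one global symbol list, so per-character alphabets are recovered
as 0..max observed state; write-then-parse is the identity on matrices in
that normalized form (`CharacterMatrix.normalized()`), and trimming
unobserved top states never changes lengths or statistics.  Published
matrix revisions (ten character re-codings, nine added characters with
taxon codings) ship as replayable `MatrixEdit` data with an audit log.

## 4. Synthetic data (`unguis.simulate`)

### Phalanx specimens

Each group draws its eight standardized shape variables and FSA from
independent normals at the published group means/variances (nails and
grooming claws; claw and tegula groups were never summarised in print, so
synthetic specs are supplied and labelled as such).  Raw millimetre
measurements are back-synthesised by multiplying with a log-normal size
factor.  Draws violating the record invariants (VFL > TPL, shaft height >
TPL, non-positive lengths, FSA outside (0,180)) are rejected and
resampled, with an error after 10,000 consecutive rejections.  An
exchangeable-correlation mode (single rho across variables) supports
robustness checks; independence is the default because only marginal
moments were published.

Two systematic consequences, measured at n = 10,000 and documented rather
than hidden: (i) re-standardizing a generated record divides by its own
GM, shifting recomputed marginal means by up to ~2% from the drawn
targets; (ii) for the nail group, whose VFL/TPL distribution places ~5%
of probability above the hard bound VFL ≤ TPL, rejection truncates the
upper tail and the recomputed mean lands near 0.78 rather than the
published 0.817.  No generator with the published normal marginals can
satisfy the bound without this shift (a normal N(0.817, 0.013) truncated
at 1 has mean ≈ 0.804).  Convergence tests therefore target quantities
the truncation does not touch (grooming-group ratios, FSA, the drawn
standardized variables).

### Foot skeletons

mt4 sets individual size (log-normal); the six target indices are drawn
from truncated-positive normals at the published group moments, and the
remaining elements are filled through accessory proportions loosely
shaped on the packaged fossil foot, each jittered log-normally (sd 0.04)
so no element column is an exact multiple of another.  Recomputing any
target index from the generated lengths recovers the drawn value exactly;
group means converge to the published values within 0.01 at n = 10,000.
Ratios left unspecified by a spec receive a small default variance
(0.002) for the same non-degeneracy reason; passing explicit zeros (plus
zero size and jitter scales) produces identical individuals.

### Character evolution

A uniform random unrooted binary topology is grown by random stepwise
insertion.  Ordered characters start at the middle state and take ±1
steps (reflecting at the ends) whenever an edge changes (probability
`change_prob` per character per edge); unordered characters jump
uniformly to a different state.  Missing cells and two-state polymorphism
are injected at given rates.  The first taxon is the outgroup.

What "low homoplasy" means for this model is computable: with c
characters and E edges, the expected number of characters carrying two or
more changes is ≈ c·(1 − e^(−pE)(1 + pE)), and half of the ±1 collision
pairs land on the same state, each such pair able to strictly shorten a
wrong topology.  Requiring well under one colliding pair per matrix
(25 characters × 13 edges) gives p ≲ 0.0075.  The parameter-recovery
experiment therefore runs at p = 0.005, where the generating tree sits in
the MP set in ≥95/100 seeded replicates; at p = 0.05 (the generator's
default, a moderate-homoplasy regime) recovery is ~60%, which is a
property of the evolutionary model, not of the search (the search is
exact).

## 5. Problem sizes and reproducibility

Every generator is deterministic under a seed, and every analysis can
emit a JSON manifest (inputs, seed, configuration, package version).  The
test suite runs oracle comparisons at 6–7 taxa (where exhaustive
ancestral-state enumeration is feasible), search equivalence at 7 taxa,
recovery at 8 taxa × 25 characters × 100 replicates, and calibration at
1000 null replicates — sizes chosen so the full suite completes in a few
minutes while keeping every check exact or tightly powered.
`scripts/acceptance.py` recomputes the fossil-vs-extant t statistics from
the packaged published tables at run time.

## 6. Known limitations

- The 30-character base cladistic matrix and the published supplementary
  NEXUS files are not packaged (never reproduced in print); only the
  published revision lists ship as data, so the printed tree statistics
  (TL = 42/58/63 etc.) cannot be recomputed until a transcription is
  supplied.  The corresponding end-to-end test is deliberately left
  failing rather than fed a reconstruction.
- The raw extant measurement matrices behind the published PCA
  eigenvalues (4.8, 1.5), the 97.1%/78.9% jackknife rates, the fossil
  posteriors and the printed F/H statistics are unpublished; these are
  covered by simulation-mode analogues at the published summary moments,
  which show the pipeline's behaviour, not the original sample's.
- Synthetic phalanx groups are marginally specified; real covariance
  structure among shape variables is unknown and not emulated beyond the
  optional exchangeable mode.
- Passing tests on synthetic data demonstrate correctness of the
  computations and calibration of the tests under the stated sampling
  models — not that real measurement error, allometry or phylogenetic
  autocorrelation behave like those models.
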