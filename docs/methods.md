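# Methods

This note documents the models and procedures implemented in
`retina_atlas`, the assumptions behind them, the parameters that matter,
and what the synthetic test bed does and does not establish.

## The synthetic atlas

The generator (`retina_atlas.synthetic`) emulates a developing-retina
multiome study at desk scale. Its defaults define the demo dataset used
throughout the tests.

**Sampling design.** Sixteen samples: eight ages (56–154 days post
conception, 14-day spacing, i.e. PCW 8–22) in both macula and periphery.
Per-sample cell counts are proportional to the total birth density at the
sample's age and location — early samples are small, as in real tissue.
This choice is load-bearing: with equal-size samples, conditioning a cell's
class on its sample age weights the class-conditional age distribution by
the inverse of the total density, which biases birth-mean recovery; with
density-proportional samples the per-class age distribution is exactly
proportional to that class's own Gaussian on the grid, and the
macula–periphery shift is preserved.

**Classes and birth ages.** Nine major classes (PRPC, NRPC, RGC, AC, HC,
Cone, Rod, BC, MG) with macula birth-age means staggered from 78 to 118
days (sd 10–12 days); the periphery mean is the macula mean plus
`macula_lag_days` (default 14). Cell class at a sample is drawn with
probability proportional to the class's Gaussian birth density at that age
and location.

**Maturation and latent time.** Each cell carries a maturation in [0, 1]
rising logistically with age around a class- and location-specific
midpoint; the macula is ahead of the periphery by the planted lag.
Differentiated classes use a midpoint 10 days past the birth mean and a
time constant of 18 days. Progenitors use their birth mean and a 10-day
constant, so progenitor latent time traverses the whole unit interval over
the sampled window — needed for the peaked gene module to be
distinguishable from the monotone ones. A 6-day age jitter gives
within-sample heterogeneity.

**Counts.** Negative binomial in the mean–dispersion parameterization
(variance = μ + μ²/θ, θ = 10 by default — a typical single-nucleus
dispersion), sampled as gamma–Poisson with a log-normal cell size factor
(sd 0.2). Gene panel per the demo config (600 genes): 24 markers per class
(14 maturing, 10 immature) whose log-rates switch on/off at staggered
maturation onsets (sequential activation — this makes a group's similarity
to the adult grow smoothly and monotonically; markers linear in maturity
put the trajectory on an arc in log space and made the adult correlation
non-monotone); 3 × 40 module genes over latent time (decreasing /
early-interior peak / increasing; the peak sits at 0.42 so a linear trend
test can detect it); 2 fate-biased TFs per terminal class at 2× effect in
fated NRPCs; 30 location DEGs in PRPCs at a planted natural-log fold change
of 2 (half per direction); the remainder housekeeping.

**Embedding and velocities.** Ten dimensions. Classes have random
centroids (scale 8); every cell sits on a corridor parameterized by its
maturation — PRPCs run from the PRPC pole to the NRPC pole, fated NRPCs
from the NRPC pole toward their fate's centroid, and differentiated cells
continue the same corridor from the NRPC pole to their class pole — so the
kNN graph is connected from progenitors to terminal cells. Velocity is the
unit vector toward the cell's target centroid plus isotropic noise (0.05).
Terminal sets follow the rule "class C cells above the 0.75 latent-time
quantile of their class".

**Chromatin.** Linked peaks (120) attach to structured genes; their
pseudobulk accessibility is the z-scored pseudobulk expression plus
Gaussian noise (sd 0.35, sample r ≈ 0.9). Decoy peaks sit 280 kb from the
nearest anchor, outside every linkage window (gene anchors are spaced
600 kb apart on synthetic contigs). The gene-level accessibility matrix
re-evaluates each gene's expression program at latent time + 0.15, so
chromatin leads expression.

**What the generator does not emulate:** batch effects, doublets, ambient
RNA, realistic gene–gene correlation beyond the planted programs, genome
sequence, or fragment-level ATAC structure. Passing tests therefore
demonstrate that each estimator recovers the structure it targets under its
own model assumptions at realistic noise — not robustness to the
technical artifacts of real data.

## Maturation scores

Developmental and adult cells of one class are pooled; the top 50
principal components of the pooled, feature-centered (not variance-scaled)
matrix define the embedding; the score for each (location, PCW) group is
the Pearson correlation between its mean embedding vector and the adult
mean vector. Highly variable gene selection before PCA is a config knob
(default top 2,000; a no-op at demo scale). Component signs are fixed by a
largest-loading-positive convention so scores do not depend on cell order
through arbitrary SVD sign choices.

Groups below `min_cells` are reported as missing rather than extrapolated.
The default floor is 100 cells: the correlation of 50-dimensional group
means is attenuated toward zero roughly by 1/√(1 + σ²/s²) with σ² ∝ 1/n,
and below ~100 cells this attenuation is large enough to invert adjacent
groups of unequal size. The floor is a parameter for callers with larger
groups per unit of signal.

## Birth-rate curves

"Fitting a Gaussian" to member ages is implemented as the method-of-moments
parametric fit (sample mean and sd), not a KDE — the moments determine the
Gaussian uniquely and make the curve's integral exactly the group
proportion. Cells are downsampled per sample to at most `n_downsample`
(default 20,000) without replacement; smaller samples are used in full.
Proportions are shares of downsampled cells of the same location; cells
with undetermined fate are excluded from fate-grouped denominators.
Groups with < 2 cells or zero age variance are omitted with a warning.

## Fate inference

The velocity kernel is a cosine-similarity softmax over kNN displacements
(k = 30, temperature τ = 1 — both configurable; the kernel family is
standard, its internals are a documented choice). Zero-velocity cells get
uniform rows. The connectivity kernel row-normalizes the symmetrized kNN
adjacency. The combined kernel weights velocity 0.8 / connectivity 0.2.

Absorption probabilities make terminal cells absorbing and solve the
sparse system (I − Q)B = R aggregated per fate with a direct solver; the
correctness contract is agreement with Monte-Carlo random-walk frequencies,
checked in the tests. Transient cells that cannot reach any terminal set
are flagged and reported with missing probabilities, never silently zeroed.
Cluster fate = argmax of the cluster's mean fate probability when it
reaches the threshold (default 0.5), else "undetermined".

TF specification: per TF, the mean log1p-CPM expression per fate group of
neurogenic progenitors; the predicted class is the argmax (ties broken
lexicographically and flagged; log scale by default). Validation counts a
prediction as matched when the predicted class is among the TF's
literature classes; TFs with no literature record are excluded from the
match-rate denominator.

## Latent-time modules

Informative-gene selection is a Pearson correlation against latent time
with BH correction at FDR 0.05 — a documented stand-in for the
graph-autocorrelation selection of the original tooling; it tests the same
null (no association with the latent-time covariate) with a linear
statistic, so purely symmetric non-monotone profiles are outside its power.
Constant genes are excluded.

Grouping: average-linkage hierarchical clustering on 1 − r. A plain k-cut
of such a dendrogram tends to shave off outlier singletons and leave one
giant cluster, so the cut is deepened until k clusters clear the
`min_gene_threshold` size floor and the k largest are kept (deterministic
given the data). With `core_only`, genes whose mean correlation with their
module is below 0.3 stay unassigned. Modules are relabeled 1..k by the
expression-weighted latent time of their genes, so module 1 is always the
earliest program. `min_gene_threshold` defaults to 160 (the scale of a
full-size analysis); the demo-scale runs pass 10.

Module scores are the first-principal-component cell loadings of the
kNN-smoothed (k = 30), centered module submatrix, sign-oriented to
correlate positively with mean module expression. Expression-weighted time
is Σ (normalized expression) × age in days.

The latent-time location tests use a two-sided Pearson product-moment test
(PCW as numeric) and per-PCW two-sided Welch t-tests of macula vs
periphery, corrected over PCW groups (Bonferroni by default; the correction
method is an argument). Groups missing a location are skipped and listed.

## Spatial differential expression

The class-marker test divides both group variances by the focal group's
size (the "overestimated variance" variant — conservative for the
focal-vs-rest comparison) with Welch–Satterthwaite degrees of freedom on
those same terms, BH within each group.

The two-stage location procedure fits per-gene NB GLMs (log link,
log-total-count offset) with a batched IRLS across genes: parameter-change
convergence at 1e−6, at most 50 iterations, per-gene method-of-moments
dispersion seeded from a Poisson fit and shared between the full and
reduced models of each likelihood-ratio test. Per-gene agreement with
statsmodels GLM fits (coefficients, standard errors, LRT statistics) is
asserted in the tests. Stage 1 passes at BH q < 0.01, |Location
coefficient| > 1 (natural-log scale — the "normalized effect"), and
detection in strictly more than 2,000 cells; q-values are computed over the
post-abundance-filter gene set. Stage 2 is a 1-df LRT of Location + Age
(age in integer days, untransformed) against Age, q < 0.01. The final set
is the intersection; non-converged fits are flagged and excluded from both
stages.

## Chromatin procedures

DARs: one-sided (greater) Wilcoxon rank-sum of the focal class's
log2-normalized pseudobulk accessibility against the rest, BH across peaks
within the class; a DAR requires q < 0.01 and log2 fold change strictly
greater than 1 (the fold-change boundary is exclusive; the FDR boundary
follows the "< 0.01" wording).

Overlap classification merges the reference set per contig and counts the
bases of each query covered by the union ("any reference peak" semantics);
a peak overlaps when coverage ≥ 20% of its length, boundary inclusive.
Coordinates are 0-based half-open throughout.

Peak-to-gene linkage anchors each gene at its transcription start
(configurable), takes candidate peaks within 250 kb (inclusive; distance
is from the anchor to the nearest base of the peak), and emits pairs with
Pearson r ≥ 0.45 (inclusive) across matched pseudobulk units
(sample × major class aggregates with ≥ 10 cells).

Phase segmentation is a descriptive classifier over smoothed trajectories
on a shared gene-time grid — no dynamical model is fitted. Per grid point:
primed if chromatin exceeds 50% of its max while expression is below 5% of
its max; otherwise coupled-on / coupled-off when the forward differences
of chromatin and expression agree in sign (both positive / both negative);
otherwise decoupled (the last grid point inherits its predecessor's
differences; zero differences that are not concordant fall to decoupled).
Percentages are grid-point shares and sum to 100. Both thresholds are
relative to each trajectory's maximum, so the classification is invariant
to uniform rescaling of either trajectory. Class summaries average
percentages across genes; gene-set comparisons of one phase's shares use a
two-sided Welch t-test.

## Problem sizes and determinism

The demo atlas is 12,000 cells × 600 genes and runs the full pipeline in a
few minutes on one CPU; birth-curve recovery uses 20,000 cells, the DEG
calibration uses 2,000 genes × 5,000 cells per replicate, and the
absorption oracle uses sub-100-cell chains with 10⁵ random walks per
transient state. All randomness flows through `numpy.random.default_rng`
seeds carried in configs; regenerating with the same config reproduces
byte-identical outputs, and every writer is deterministic given its
inputs.

## Known limitations

Latent time and velocities are consumed as inputs (here: planted); no
dynamical model, macrostate analysis, or GRN inference is performed. The
module-selection stand-in has no power against symmetric non-monotone
profiles. The maturation score inherits the usual instability of
correlation between high-dimensional group means for small groups, handled
by the reporting floor rather than shrinkage. Dataset-level counts from
full-size atlases (numbers of DEGs, linked peaks, module genes) are
functions of data scale and are not meaningful at demo scale.
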