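# Methods

## Model and assumptions

The analysis assumes a perturbation-propagation model in the tradition of
nested effects models: knocking down a regulator silences it together with
everything reachable downstream in that population's activation graph, and
the targets of a regulator respond coherently in every experiment that
affects it. The pathway topology is static, purely activatory, and may be
cyclic or disconnected; perturbations are knock-downs only (one experiment
per regulator per population). Regulator *activity* is derived from the
model, never from the regulator's own expression — activity is modulated
post-translationally and regulator mRNA is a poor proxy.

Regulator sets must be identical across the two populations (enforced at
load time); topologies are otherwise independent per population. The
reflexive transitive closure is computed with networkx; matrices are
indexed in the order regulators first appear in the regulators file.
Self-loops in input topologies are no-ops, duplicate edges are dropped
with a warning.

## Differential-expression mixture

Per experiment, log ratios are modelled as a two-component Gaussian
mixture: a narrow "unchanged" component and a wide "differential" one
(differential genes move in both tails around zero, hence one
wide zero-centred component rather than separate up/down components).

Known targets are soft labels. For a labelled gene with belief *b* the
E-step responsibility of the differential component is proportional to
*b·N(x; μ₁, σ₁)* and of the unchanged component to *(1−b)·N(x; μ₀, σ₀)* —
the belief replaces the mixing proportions as that gene's prior, and the
reported posterior for labelled genes keeps that belief weighting.
Unlabelled genes use the fitted mixing proportions. With no labels the
procedure is exactly unsupervised EM. The published description of the
belief-based estimator this follows does not fix every update; this
package's reading (beliefs fixed throughout EM, standard weighted M-step
for means and variances) is documented here as its own choice.

Numerical choices:

* **Initialisation** (deterministic): both means at the median; unchanged
  sd from the central 50% of the data (IQR/1.349); differential sd = 3 ×
  the full-sample sd (floored at 1.5 × the unchanged sd); proportions
  (0.9, 0.1). Optional random restarts are off by default.
* **Convergence**: relative objective change < 1e-8 or 1000 iterations
  (non-convergence returns the best iterate with a warning).
* **Variance floor** 1e-6 (squared log-ratio units), applied with a warning.
* **Weight prior** (`weight_prior`, default 0.05): Dirichlet-type
  pseudo-counts, 5% of the sample split as the initial proportions, added
  in the weight M-step (MAP-EM). Rationale: with no differential signal in
  the data the two-component likelihood is flat in the proportions, and
  plain ML-EM drifts to an arbitrary fit-dependent split, making posterior
  magnitudes incomparable between experiments; the prior anchors degenerate
  fits near (0.9, 0.1) while any real signal swamps it. The reported
  objective trace includes the prior term, so it is non-decreasing.
* **Identifiability**: the differential component is *defined* as the wider
  one. The constraint σ₁ ≥ σ₀ is enforced inside the M-step: if an update
  would cross the variances they are pooled (the constrained optimum — a
  generalized M-step, preserving monotonicity). Ties label component 1
  (the minority, belief-carrying component) differential.
* **Missing ratios** are excluded from fitting and propagate as missing
  signed probabilities; a mixture fit requires ≥ 20 finite values.

Signed probability = posterior × sign(log ratio); an exactly zero ratio
gives 0.

## Scoring

Regulation scores average each gene's signed probabilities over the
affecting-experiment set; missing entries are dropped from the average
(preserving the [−1, 1] bound) and an all-missing set yields a missing
score with a warning. Deregulation is second-population minus
first-population (configurable order; damaged − healthy by convention).
Ranked deregulation lists sort decreasingly with ties broken by gene id,
so output is deterministic. The per-gene average of deregulation over
regulators is the default enrichment ranking.

The decorrelation baseline uses all arrays of a population (knock-downs
and controls pooled) as the expression profile; Pearson correlations
require ≥ 3 arrays and zero-variance profiles give missing values.

## Permutation test

All finite entries of both populations' signed-probability matrices are
pooled, shuffled (`numpy` Generator, caller-supplied seed), placed back
into the original layout, and re-propagated through both pathway models;
the p-value is (1 + #{|D_perm| ≥ |D_obs|}) / (B + 1) with B = 1000 by
default. Ties count as exceedances and the add-one estimator never reports
zero (a raw-frequency switch exists). A within-population shuffling scheme
is available as an alternative.

The permutation argument is exact when the pooled entries are
exchangeable. Mixture fits are made per experiment, so experiment-to-
experiment fit variability introduces mild heterogeneity between columns;
on no-signal data the pipeline-level p-values meet a binomial-bound check
of the fraction below 0.05, but a sensitive pooled Kolmogorov–Smirnov test
can still detect slight anticonservativeness. This is a property of
pooling separately fitted experiments, not of the permutation machinery,
which is exactly valid (and so verified) on exchangeable input.

## Best hyper test

For each gene set and each list extreme (top/bottom), upper-tail
hypergeometric tests are evaluated at every k in 10..500 (configurable
stride); the minimum p over admissible (extreme, k) pairs is reported with
its location. Sets with fewer than 15 members are excluded; (set, k) pairs
whose overlap with the k-extreme is below 10 are skipped (the per-k filter
counts overlap with the current k-extreme). The universe defaults to the
number of genes analysed. The min-p statistic is anticonservative by
construction and is left uncorrected; significance is therefore declared
only at p ≤ 1e-5.

## Synthetic data

The generator emulates the assumed mechanism: per population, each
regulator carries a signed target set; gene g's log ratio in experiment e
is the sum of s·μ over its targeting regulators affected by e under that
population's model, plus Normal(0, σ₁) noise for targets and
Normal(0, σ₀) for background genes (cancelling multi-regulator effects are
summed and logged). Damaged-population target sets are re-wired copies of
the healthy ones — half of the re-wired targets flip sign, half are
swapped for fresh genes — and the ground-truth deregulated set is the
symmetric difference of signed memberships, always derived, never stored.

Defaults (the study conditions): 500 genes, three regulators in a hub
topology active only in the damaged population, 40 targets per regulator
(balanced signs), μ = 2, σ₁ = 0.4, σ₀ = 0.3, 25% of targets re-wired,
belief 0.95, belief-list contamination 0. Replicate-level matrices for the
decorrelation baseline use 3 arrays per knock-down plus 6 controls per
population; values are baseline (Normal(8, 1) per gene, shared across
populations) plus the planted effect plus per-array Normal(0, 0.3) noise,
with a knocked-down regulator's own expression lowered by 2 log units on
its arrays. These last three constants are not dictated by the modelled
design; they were fixed once at magnitudes typical of normalised
microarray data.

What the generator does *not* emulate: probe-level artefacts,
normalisation effects, correlated noise between arrays, post-translational
regulation of the targets themselves. Passing tests therefore demonstrate
correctness of the machinery under the model's own assumptions, not
robustness to real-data violations of them.

The deterministic miniature fixture encodes the four canonical gene fates
(regulation switched / lost / kept / absent) with noise-free focal values;
because a mixture fit needs ≥ 20 finite ratios, the fixture carries a
deterministic background of null genes plus a few model-independent strong
responders per experiment, and the discrimination claim is asserted on the
focal genes.

## Problem sizes used in validation

The test-suite simulations use the default 500-gene conditions (30 seeds
for recovery medians), 2000-point mixtures (20 seeds for the supervision
comparison, labelling the 50 strongest-responding true differential genes
as the known targets, mirroring how target lists arise experimentally),
B = 1000 permutations on 500 null genes, and exhaustive {−1, 0, +1} grids
over the six experiments of the hub design. These sizes were chosen to be
comfortably informative at interactive run times.

## Known limitations

* Activatory edges only; over-expression perturbations and logical/dynamic
  pathway models are out of scope.
* Exactly one knock-down experiment per regulator per population.
* The min-p enrichment statistic is uncorrected for the k-scan or across
  sets (by design, matching its stringent 1e-5 cut-off).
* Pipeline-level permutation p-values inherit mild anticonservativeness
  from per-experiment mixture-fit variability (see above).
* Results are conditional on the supplied topologies being correct;
  with no prior knowledge, disconnected topologies and no beliefs reduce
  the method to independent per-regulator unsupervised analyses.
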