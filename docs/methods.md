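# Methods

## Scope and data model

`zoochimera` operates on per-modality tables of pre-extracted feature
vectors: each row is one sample of one individual in one acquisition
session (`individual, session, sample, f1..fd`). Raw signals and images are
out of scope — the package evaluates representations, not extractors.
Session order is declared explicitly; the first session is the *training*
session (gallery), the second the *test* session (probe). Delimited text
(comma or tab) is used for feature tables and JSON for build recipes; both
round-trip losslessly (`%.17g` floats, `float_precision="round_trip"` on
read).

## Menagerie labeling

Individuals missing a sample in any session are discarded. For each valid
individual, two training-session statistics are computed:

* **intra-class dispersion** — the mean pairwise distance over all
  unordered pairs of the individual's own training samples;
* **inter-class separation** — the mean distance from the individual's
  training samples to every other valid individual's training samples
  (one-against-all).

The mean is used as the aggregator for both statistics; it is the only
aggregator consistent with treating the two statistics symmetrically, and
it is robust to the small per-cell sample counts (2–6) typical here.

With N individuals and percentile p, the fractional 1-based rank is
`index = p/100·N + 1/2`. Sorting ascending (ties broken by id for
determinism):

* **goat candidates** — ranks strictly greater than the *fractional*
  70th-percentile index. With N=10 that index is 7.5, so ranks 8–10
  qualify; with N=1 the index is 1.2 and nobody qualifies.
* **lamb candidates** — ranks at or below the *round-half-up* of the
  30th-percentile index (N=10 → index 3.5 → ranks 1–4; N=56 → index
  17.3 → ranks 1–17).

The asymmetric rounding follows from the selection semantics: "above the
index" is an exclusive lower bound, naturally compared fractionally, while
"the lower percentile" is an inclusive count, naturally rounded to the
nearest integer rank.

An individual qualifying as both goat and lamb becomes a goat; precedence
had to be fixed somewhere, and resolving toward the scarcer, more
evaluation-distorting category is conservative. Per animal, a seeded
permutation of the candidates is drawn and the first
`round_half_up(0.10 · N)` kept, so repeated executions sample different
menageries reproducibly; all remaining valid individuals are sheep, and the
build aborts if sheep are not the strict majority.

When all modalities observe the *same* individuals (shared-pool data),
per-modality labelings are reconciled: unanimous labels stand; if a
minority category falls short of its target count, the divergently-labeled
individuals are pooled, permuted with the seed, and drawn to fill the
category (goats first, then lambs, never reusing an id).

## Chimeric assembly

Category caps are the per-label minimum across modalities — two modalities
with (10, 10, 80) and (5, 5, 400) goats/lambs/sheep support exactly
(5, 5, 80). Per label, each modality's individuals are independently
permuted with the build seed and the first `cap` entries paired
positionally, which makes the assignment injective per modality by
construction. Samples are paired sequentially *within* each session
(train with train, test with test); the per-session chimeric sample count
is the minimum across the sources. Pairing across sessions would let a
training sample of one modality ride along with a test sample of another
and corrupt the inter-session scenario, so it is not offered.

Chimeric ids are label-prefixed ordinals (`goat001`, `sheep012`). Source
individuals beyond the caps are simply unused in that build. The build is a
pure function of (inputs, master seed): the master seed spawns the
assignment seed through `numpy.random.SeedSequence`, and every seed and
assignment is stored in the recipe, whose replay reconstructs the dataset
bit-for-bit.

## Matching, fusion, decision

Supported metrics: Euclidean, Manhattan, Spearman distance (1 − Spearman
rank correlation, midranks for ties, range [0, 2], undefined for constant
vectors), and Hamming (fraction of differing coordinates). Mahalanobis is
deliberately absent: it requires a covariance estimator whose training
population and regularization are unspecified in this protocol, and an
arbitrary choice would silently dominate results.

All decisions are made in dissimilarity space: a probe is genuine for a
claimed identity iff its minimum gallery distance is strictly below the
threshold. Score-level fusion applies sum, min, or product to per-modality
scores after per-modality min-max normalization over the current
evaluation run's pairs — the rules are scale-sensitive and raw distance
scales differ across metrics and dimensions, so unnormalized fusion would
implicitly weight modalities by scale. Feature-level fusion min-max scales
each modality per dimension with training-session statistics (constant
training dimensions map to 0), then concatenates in declared modality
order.

## Evaluation

Scenarios: `train_intra` and `test_intra` enumerate all unordered sample
pairs within the respective session; `inter` takes the full cross-product
of test (probe) × training (gallery) samples, so every pair spans sessions.
Optional per-class pair limits draw a seeded uniform subsample. Genuine
means same chimeric individual.

Decidability uses sample moments (ddof = 1). The DET curve evaluates
FAR(t) = fraction of impostor scores < t and FRR(t) = fraction of genuine
scores ≥ t at every distinct score plus a +∞ sentinel, which makes FAR
non-decreasing and FRR non-increasing in t with endpoints (0, 1) and
(1, 0). The EER is found by linear interpolation of (FAR, FRR) between the
two adjacent thresholds where FAR − FRR changes sign — stable for small
pair counts, where the nearest-point convention can be off by half a step.

The experiment harness reruns the entire random process (relabel, rebuild,
re-enumerate, rescore) `n_runs` times (default 30), with per-run seeds
spawned from the master seed (`SeedSequence.generate_state`, masked to 31
bits, bumped on the astronomically unlikely collision), and reports mean ±
sd of decidability and EER per method and scenario. Methods are compared
per scenario by Welch's unequal-variance two-sample t-test of per-run EERs
against the lowest-mean-EER method; Welch is the robust default when run
variances differ between methods (fused methods typically have smaller
variance). A method is flagged equivalent to the best when p ≥ 0.05.

## Synthetic modality generator

The generator emulates multi-session embedding tables with a controllable
menagerie; it is the package's test bed, not a model of any particular
sensor. Per modality, individual j has center c_j ~ N(0, σ_between² I_d);
each session adds a per-individual drift offset N(0, σ_drift² I_d); samples
add N(0, σ_within² I_d) noise. Planted lambs have their center multiplied
by λ ∈ (0,1) (shrunk toward the population mean, directly lowering their
one-against-all distance); planted goats have σ_within multiplied by g > 1.
Sample counts per (individual, session) are uniform on a configured range.

Defaults: three modalities of 56/60/70 individuals (independent pools),
d = 16, σ_between = 1, σ_within = 0.5, σ_drift = 0.25, two sessions, 4–6
samples per individual per session, 10% goats, 10% lambs. The default goat
multiplier is **g = 2** and lamb shrink **λ = 0.5**: goats are then clearly
harder to match (double noise) yet their genuine scores still lie mostly
below typical impostor scores, and lambs are clearly closer to the
population without collapsing onto each other — matching how
percentile-defined goats and lambs behave in real galleries, which remain
verifiable subjects. Much larger multipliers (e.g. g = 5, λ = 0.1, used in
the stress tests for planted-label *recovery*) produce subjects whose
genuine comparisons score worse than impostor comparisons; such
outlier/wolf-grade subjects are aligned across modalities by the
label-homogeneity constraint, so no fusion rule can absorb them, and they
say nothing about ordinary fusion behavior.

What the generator does *not* emulate: non-Gaussian embedding geometry,
correlated feature dimensions, heteroscedastic per-subject noise, session
counts ≫ 2, and cross-modality dependence of difficulty (a goat in one
modality is no more likely to be a goat in another). Passing tests
therefore demonstrate the correctness and the internal mechanics of the
protocol — capping, homogeneity, seeding, the √m sum-fusion gain for
independent comparable modalities — not performance figures transferable
to any real biometric dataset.

## Problem sizes

The repeated-run acceptance check uses the default suite (56/60/70
individuals, d = 16, ~10⁴–10⁵ scored pairs per scenario per run, 30 runs),
which the package evaluates in well under a minute on one core; unit and
oracle tests use populations of 4–16 individuals where exhaustive
enumeration is feasible.

## Known limitations

* Two-session logic is hard-wired into the scenarios (more sessions parse
  fine; only the first two are evaluated).
* Score normalization statistics come from the evaluated run itself; a
  deployment would need to freeze normalization on training data.
* The t-test treats per-run EERs as independent; runs share the underlying
  unimodal feature tables, so the test is exact only under the protocol's
  own randomization, as intended.
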