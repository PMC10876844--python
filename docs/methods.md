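# Methods

## Model and procedure

The package implements post-hoc last-layer Bayesification of a 3D
convolutional classifier, plus the selective-classification and
explainability machinery that makes the uncertainty useful.

**Classifier.** Input volumes are single-channel 3D images with values in
[0, 1] and sides divisible by 8. The body is three residual blocks; block
*i* maps `C_{i-1} → C_i` channels and halves each side via a stride-2 first
convolution. Each block is two depthwise-separable convolutions
(depthwise `K=3` grouped convolution, groups = input channels, then a
pointwise `1×1×1` mix) each followed by a PReLU with one learnable shared
slope; the shortcut is a stride-2 pointwise projection without bias. A
flatten and a single linear head produce two logits. Default channel
widths are (4, 8, 16) for 32³ inputs and (8, 16, 32) for 96³; kernel size,
widths and the stride-2 downsampling mechanism are engineering choices —
the architecture family fixes only the block structure, PReLU, and the
per-block halving.

**Training.** Adam (β₁=0.9, β₂=0.999, ε=1e-8), learning rate 3e-4, five
epochs, two-class cross-entropy, per-epoch reshuffling from the training
seed. Default batch size is 4 so that a ~100-subject training split still
provides on the order of a hundred optimizer steps within five epochs. No
augmentation, schedules, normalisation layers or early stopping: the head
perturbation should be the only stochastic element at inference.

**Bayesification.** After training, the head's weights *and biases* w* are
treated as means of independent Gaussians N(w*, s), s = 0.01 by default —
an absolute, not relative, standard deviation, and a single knob.
Inference draws a complete head per pass; with N = 100 passes the per-class
softmax probabilities are summarised by their mean and population
(divisor-N) standard deviation. Population std makes N = 1 well defined
(std 0) and differs from the sample convention by <0.5% at N = 100. The
reported uncertainty is the standard deviation of the class with the
highest mean probability; with two classes the two per-class stds agree to
numerical error, so the distinction only matters if the head is widened to
more classes. Random streams are counter-based — draw *j* for test case
*i* under seed *g* comes from `SeedSequence([g, i, j])` — so batch size and
evaluation order cannot change results. At s = 0 the sampling loop is
bypassed and the deterministic probabilities with exactly zero stds are
returned.

**Rejection.** `accepted ⇔ uncertainty ≤ t` (closed comparison: equality is
accepted, i.e. a case is rejected only *over* the threshold). Metrics on
the retained subset use class 1 (disease) as positive; AUC is the
rank-based ROC area of the mean class-1 probability, ties averaged
(sklearn). Empty retained subsets raise a distinct `EmptySubsetError`, and
the threshold sweep converts them into NaN-flagged rows so extreme
thresholds never abort a sweep; single-class subsets flag only the AUC.
The default grid is (0.002, 0.005, 0.01, 0.02, 0.05, 0.10, 0.15, 0.2).
No automatic threshold selection is offered — t encodes the operator's
accuracy/coverage preference.

**Integrated gradients.** The estimator is the standard inclusive-endpoint
Riemann average: attribution = `(x − x0) ⊙ (1/m) Σᵢ ∇ₓ f_target(xᵢ)` with
`xᵢ = x0 + αᵢ(x − x0)`, αᵢ linearly spaced on [0, 1], default m = 50 and a
zero baseline. It is exact for linear scorers at any m and satisfies
completeness within 1% by m = 256 on the networks used here (verified in
tests; raise m if tighter completeness is needed). The "repeat 10 times
and average" step re-samples the stochastic head per repeat — the only
source of randomness in an otherwise deterministic procedure; with a
deterministic network the repeats would be identical and are computed
once. Post-processing: Gaussian smoothing (σ = 4 voxels, reflect
boundaries, 4σ truncation, which conserves the map's total mass away from
edges), then a binary mask of values strictly above the 95th percentile.
The percentile is computed over in-brain voxels when a brain mask is
supplied, because background zeros would otherwise dominate the cutoff; a
constant field therefore yields an empty mask (deterministic tie rule).

## Synthetic cohorts

The generator emulates the *outputs* of a morphometry preprocessing chain
(registration → Jacobian determinant → MNI masking → global [0,1]
normalisation), not the chain itself. Per subject:

* base field: white Gaussian noise convolved with an isotropic Gaussian of
  width `smoothness` (default 2.0 voxels) — the cheapest field with a
  controllable correlation length resembling smoothed JD maps;
* class effect: disease cases (label 1) receive an additive offset of
  magnitude `effect_size · (1 + N(0, subject_sd))` confined to a central
  "ventricle" ellipsoid (semi-axes 0.15 of each side) inside the brain
  ellipsoid (semi-axes 0.45) — additive rather than multiplicative so the
  planted signal is independent of the local base-field value;
* ambiguity: a seeded `round(ambiguous_fraction · n)` subjects have the
  magnitude multiplied by U(0, 0.1), producing genuinely near-unclassifiable
  cases whose ground-truth flags are kept in the dataset metadata;
* voxel noise N(0, `noise_sd`), brain masking, then min–max normalisation
  with **dataset-global** extremes (per the global-normalisation
  convention for JD cohorts), so the dataset min is 0 and max is 1.

Defaults — 120 subjects, 32³ voxels, effect 0.4, subject_sd 0.2, noise_sd
0.05, ambiguous fraction 0.25 — are the desk-scale study conditions used
by the test suite and acceptance script. subject_sd and noise_sd were set
once to give a clearly learnable but imperfect problem: the planted effect
is several base-field standard deviations strong, while 25% ambiguity caps
attainable accuracy near 0.88 and leaves errors for the rejection stage to
remove. With these conditions the 75th-percentile rejection threshold
raises test accuracy by roughly +0.04 on average over ten seeds while
retaining 75% of the test set.

What the generator does **not** emulate: registration artifacts, spatially
varying noise, anatomical asymmetry and covariate structure (age, sex),
multi-site effects, or realistic JD marginal distributions (unspecified
beyond the [0, 1] range; the smoothed-Gaussian marginal is a free choice).
Passing tests therefore demonstrate the *mechanics* of the method —
uncertainty tracks planted ambiguity, rejection trades coverage for
accuracy, attributions localise a known effect — not clinical performance
on real cohorts.

## Numerical choices

* All tensors are float64; convolutions are explicit numpy operations
  (27-offset shift-and-add for depthwise, einsum for pointwise), and every
  backward pass is verified against central finite differences at 1e-6.
* Initialisation: He-style Gaussian fan-in scaling for convolution
  weights, zero biases, PReLU slope 0.25; deterministic per seed.
* Head input gradients for attribution reuse the training backward pass
  with a one-hot logit seed.
* Checkpoints are numpy archives holding the architecture description,
  seed, training log and all parameter arrays; round-trips are bit-exact.
* Pipeline runs derive every stage seed from one global seed by CRC-32 of
  `"{seed}:{stage}"`, keeping derived seeds under 2³¹.
* Problem sizes in tests (16³ fixtures, 32³ study runs, N=100, 10 seeds)
  were chosen so the whole suite completes in well under a minute of
  compute per study seed on a single core.

## Known limitations

* Only the head is stochastic; a sharp body miscalibration invisible to
  head perturbation will not register as uncertainty.
* s is a single absolute scale; heads with very differently scaled
  features may need per-feature scaling, which is out of scope.
* The statistical acceptance checks (rejection benefit, attribution
  localisation) are properties of distributions over seeds; any single new
  seed can fall outside the typical range.
* The per-weight "mean within 3 standard errors" sampling check is applied
  as a 99% coverage criterion across weights, since with thousands of
  weights a literal all-weights bound would be violated by a perfect
  sampler ~0.3% of the time per weight.
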