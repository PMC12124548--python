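# Methods

This note documents the models, losses, synthetic data, numerical choices and
known limitations behind `mdann`. Everything stated here is computed by the
package's tests or by `scripts/acceptance.py`; nothing is quoted from external
results.

## Problem setting

Given a cohort of grayscale 2-D images with a binary disease label and K
binary sensitive attributes (sex, handedness, age group, ...), the goal is a
predictor whose decisions are accurate *and* group-fair: selection rates,
true-positive rates and true-negative rates should not differ systematically
between the majority (coded 0) and minority (coded 1) category of each
attribute. Each attribute's coding is derived from observed counts — the
larger category is the majority — and the imbalance ratio
`count_majority / count_minority` is recorded; ratios up to ~12.33:1 are the
regime of interest.

## Model

The architecture has three cooperating parts.

**Feature extractor.** A convolutional autoencoder with `depth` ∈ {1, 2, 3}
strided convolution stages (5×5 kernels, stride 2, ReLU), mirrored by
transposed convolutions with a final sigmoid. Channel width doubles per
stage (`base_channels · 2^(i−1)`), so the bottleneck of a depth-d model on an
(H, W) input is `(H/2^d, W/2^d, base_channels · 2^(d−1))`; with
`base_channels = 128` on 128×128 inputs that is 64×64×128, 32×32×256 and
16×16×512 for depths 1–3. The autoencoder is pretrained on the training fold
by mean squared reconstruction error (Adam, lr 1e−3, batch 32); MSE is the
standard choice for plain convolutional autoencoders. After pretraining the
decoder is discarded and the encoder initializes — and is fine-tuned by —
the adversarial model. Reconstruction quality can be tracked as the Fréchet
distance between Gaussian fits of features of real and reconstructed images;
the feature map is pluggable and defaults to flattened pixels, because a
pretrained natural-image embedding is ill-suited to grayscale slices and
makes scores incomparable across feature choices. The distance itself is
`||μ1−μ2||² + tr(Σ1+Σ2−2(Σ1Σ2)^{1/2})`, evaluated through the symmetric form
`tr((S1 Σ2 S1)^{1/2})`, with matrix square roots by symmetric
eigendecomposition and eigenvalues below 1e−10 clipped to zero.

**Predictor and adversarial components.** The bottleneck is global-average
pooled into a channel-length embedding shared by a predictor head (three
fully connected layers: C→128→32→1, sigmoid) and K adversarial components
(ACs; two fully connected layers C→64→1, sigmoid), one per sensitive
attribute. Pooling is used because feeding a flattened bottleneck to dense
heads would be enormous and size-fragile; global average pooling is the
standard size-robust reduction. An averaged gradient-reversal layer joins
the parts: identity in the forward pass; in the backward pass the mean of
the ACs' embedding gradients is multiplied by −λ before entering the
encoder, while the predictor's gradient passes unmodified. The encoder
therefore descends the prediction loss while ascending the attribute losses,
pushing the representation toward attribute-invariance. With K = 0 (or
λ = 0) the model is exactly a plain classifier — verified as bit-identical
encoder trajectories.

**AUC saddle loss.** Class imbalance breaks accuracy-driven losses; the
pairwise squared AUC surrogate `mean over (+,−) pairs of (1 − (f⁺ − f⁻))²`
is robust but couples all sample pairs. Its saddle-point reformulation
introduces per-head scalars (μ1, μ2 minimized, θ maximized) and the
per-sample objective

    (1−p)(f−μ1)²·1[b=1] + p(f−μ2)²·1[b=0] − p(1−p)θ²
      + 2(1+θ)(p·f·1[b=0] − (1−p)·f·1[b=1]),

with p the positive proportion of the training fold, computed once and
frozen. At the inner optimum (μ1* = m1, μ2* = m0, θ* = m0 − m1) the
objective equals `p(1−p)·(pairwise surrogate − 1)` with population (1/n)
class-conditional variances — the saddle identity used as the module's
correctness contract (machine-precision agreement on random batches). The
scalars are trained by descent (μ1, μ2) and ascent (θ, implemented by
flipping its gradient); a per-batch closed-form refresh is available as an
alternative mode. Scores pass through a sigmoid so the quadratic terms stay
well-scaled. A class-weighted cross-entropy baseline (weights n/(2n_c),
mean over the batch, probabilities clamped at 1e−7) is selectable per head.

## Training dynamics of the adversarial game

Two failure modes of naive simultaneous descent-ascent were observed on
synthetic cohorts and shaped the defaults:

* **Pursuit oscillation.** With a strong reversal and equal learning rates
  the encoder can raise an AC's loss by *flipping* the sign of the group
  separation faster than the AC re-fits — the AC's validation AUC crashes to
  ≈0 (perfectly anti-predictive), which means the information is fully
  retained. The remedy is a two-time-scale rule: AC parameters use
  `learning_rate · ac_lr_scale` (default 5), keeping the ACs near-optimal so
  the only way to raise their loss persistently is to genuinely remove
  attribute information.
* **Encoder collapse.** Occasionally the reversed gradient overwhelms the
  prediction gradient and drives the representation into a dead region
  (constant scores). `reversal_norm_cap` optionally rescales the reversed
  gradient per batch so its norm is at most `cap · ||predictor gradient||`
  — an adaptive reversal strength. It is off by default (the exact
  −λ·mean contract is the documented backward semantics and is verified by
  finite differences); the end-to-end fairness recipe enables it (cap 1.5,
  λ = 3) because it prevents rare collapses without changing the
  equilibrium.

Under confounding there is a floor on what removal can achieve: if the
attribute correlates with the label (bias strength 0.8 gives
P(label=1 | minority) ≈ 0.9), an AC can always decode the attribute from the
label content of the embedding alone (AC AUC ≈ 0.77 in that regime). A
well-trained adversarial model drives the AC down to that floor, not to 0.5.

Batches are stratified by the predictor's label (minority samples dealt
round-robin across batches); a batch containing a single class under the
saddle loss is skipped and counted.

## Synthetic cohorts

The generator emulates the structure of restricted clinical imaging cohorts
so every mechanism is testable without any download:

* **Disease signal:** a centered Gaussian blob (σ = min(H,W)/5) whose
  per-subject amplitude is drawn from N(0.06·y, 0.10). The heterogeneity
  emulates biological variability and makes the image-only task deliberately
  imperfect (blob-only AUC ceiling ≈ 0.66 at the defaults) — the regime in
  which loss choice and shortcut learning matter. Amplitudes for unaffected
  subjects scatter around zero.
* **Attribute signatures:** each attribute owns one image corner
  (H/3 × W/3 block; at most four attributes) with a crisp amplitude
  (0.30 · attribute value by default; optional per-attribute amplitude and
  per-subject heterogeneity), emulating scanner- or demography-linked
  signatures that are easy for a model to latch onto.
* **Imbalance and confounding:** minority count is round(n/(ratio+1))
  exactly; with bias strength b the expected fraction of the minority drawn
  from positives is (1−b)·prevalence + b, so b = 0 gives exact independence
  (φ ≈ 0) and b = 1 packs the minority into the positive class (subject to
  group sizes).
* **Noise and intensities:** additive Gaussian pixel noise (sd 0.05) on a
  0.35 background, clipped to [0, 1].

A region-mean "shortcut oracle" returns each attribute's corner mean — a
deliberately biased predictor used to validate that the fairness metrics
detect injected bias. Because the two attributes are conditionally
independent given the label, the oracle for one attribute shows EO ≈ 0
against the *other* attribute at any bias, while its cross-attribute DI
deviation grows monotonically with bias strength.

What the generator does **not** emulate: anatomy, registration artifacts,
3-D structure, continuous attributes, site effects beyond a single corner
signature, or intersectional structure. Passing tests therefore demonstrate
the mechanisms (imbalance-robust loss, multi-attribute adversarial removal,
metric behavior), not clinical performance.

## Evaluation protocol

k-fold cross-validation stratified on the joint (label × attributes) cells;
within each cell samples are dealt round-robin across folds after a seeded
shuffle, so per-fold cell counts differ by ≤1; cells smaller than k merge
into their label-only cell with a warning. At k = 5 each fold serves once as
the 20% held-out split, which reconciles the 80/20 description with 5-fold
CV. Each experiment is repeated over 5 seeds; summaries report the mean and
sample standard deviation (n−1) across seeds of fold-averaged values. The
whole results table is a pure function of the experiment configuration.

SMOTE (minority points interpolated toward one of their k = 5 nearest
minority neighbors, u ~ U(0,1), until the minority reaches
round(0.5 · n_majority)) is provided as a tabular baseline intended for
pooled embeddings, not raw pixels.

Fairness metrics: DI = Sr_min/Sr_maj (1 = parity), EO = |TPR_min − TPR_maj|,
TNRD = |TNR_min − TNR_maj| (signed variants exposed; positive = higher rate
for the minority). Undefined group rates return NaN with a warning so
multi-seed reporting never aborts. AUC uses the Mann-Whitney convention
(ties ½). The embedding-bias audit aggregates each sample's embedding to
its mean over all dimensions and reports the Pearson r (and |r|) against
each attribute; this single-projection statistic is coarse — under strong
confounding it mixes an irreducible through-label component with the direct
leak, and is reported alongside DI/EO on predictions rather than instead of
them.

## Problem sizes used in tests and the acceptance script

Pretraining and adversarial training run on 32×32 images with
`base_channels = 8` (a scaled version of the reference geometry, which
remains available by configuration), cohorts of 300–400 samples, 12–15
autoencoder epochs and 30–60 adversarial epochs, 5 seeds, and up to 3
evaluation folds of the 5-fold partition. These sizes were chosen so the
full suite runs comfortably on a single CPU while leaving the qualitative
contrasts (minimax vs weighted cross-entropy at 12.33:1; K = 2 vs K = 0
under bias 0.8) clearly resolved.

## Known limitations

* Marginal fairness only: each AC handles one attribute; intersectional
  subgroups are out of scope.
* The adversarial equilibrium trades prediction AUC for fairness (typically
  a few points of AUC at the defaults); λ controls the trade-off.
* The saddle loss assumes a frozen fold-level p; heavy distribution shift
  between folds would violate it.
* The Fréchet monitor with the pixel feature map measures distributional
  reconstruction quality, not perceptual quality, and its values are not
  comparable to scores computed with other feature maps.
* NumPy-based training is exact but not fast; the geometry is desk-scale by
  design.
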