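# Methods

This note documents the models, the numerical choices, and the scope of
what the synthetic benchmarks can and cannot show.  It is the package's own
account of its science; every number quoted here is computed by the test
suite or by `scripts/acceptance.py`.

## Problem setting

Driver-fatigue detection from multi-channel EEG faces two coupled
obstacles: labeled vigilance data are scarce (labels come from synchronized
eye tracking), and class frequencies are imbalanced (drivers are awake most
of the time).  The package addresses both with a conditional generative
adversarial network whose discriminator doubles as the fatigue classifier,
plus a feature representation that preserves the frequency, spatial, and
temporal structure of the signal.

## 4D differential-entropy features

A recording (17 channels of the 10–20 montage, 200 Hz) is trimmed, cut
into non-overlapping 8-s segments — the labeling cadence of vigilance
datasets — and each segment into 2T = 16 half-second frames.  Five
Butterworth band-passes (order 4, zero-phase forward–backward, −3 dB
corners) isolate the classic rhythms: δ 1–4, θ 4–8, α 8–14, β 14–31,
γ 31–51 Hz.  Filtering is applied to the whole 8-s segment before framing;
applying an order-4 zero-phase IIR filter to a 100-sample frame in the δ
band would be numerically meaningless (the filter's settling time exceeds
the frame).

Per frame and band the feature is differential entropy.  For a Gaussian
variable DE has the closed form ½·ln(2πeσ²); band-limited short EEG frames
are well modeled as Gaussian, so the estimator is the closed form evaluated
at the frame's sample variance (variance floor 1e−12 inside the logarithm;
degenerate frames warn).  The general definition −∫f·ln f dx is kept in the
test suite as a quadrature oracle.

DE values are scattered onto a 6×9 grid ordered like the scalp (rows
front-to-back FT/T/TP/CP/P/(PO+O), columns left-to-right); unused cells are
exactly zero.  The published cell-level layout of the montage is not
recoverable from text, so the mapping ships as an editable CSV with the
documented default; a sparse 11×17 variant (zeros interleaved) supports the
grid-density ablation.  One segment thus becomes an h×w×d×2T = 6×9×5×16
tensor.

No within-segment normalization is applied at feature level; the
estimators z-score features against the real training set at fit time (and
invert the scaling when emitting generated samples).

## Labels

PERCLOS — the fraction of an 8-s window with eyes closed — is the
vigilance ground truth.  Binary labeling splits awake/fatigue at 0.35;
the ternary scheme adds drowsy at 0.7.  A value exactly on a threshold is
assigned to the more fatigued class; a strict-inequality switch is
provided because boundary conventions differ between datasets.

## Architecture

Generator and discriminator share three blocks.

**Attention.**  The spatial branch compresses the band axis with a 1×1
convolution and gates each grid cell through a sigmoid; the frequency
branch pools globally over the grid, passes a two-layer pointwise
bottleneck (5→2→5), and gates each band.  Branch outputs are averaged, so
two saturated gates reproduce the input exactly — the squeeze-and-
excitation reading of "merge with the original features".

**Inverted bottleneck residual blocks.**  Pointwise expansion by factor
k = 6 (ReLU6), 3×3 depthwise convolution (stride 1, same padding, ReLU6),
linear pointwise projection, residual add when input and output widths
match.  The discriminator's module runs, per half-second frame:
5→128 (expand), 128→64 (halve), a two-branch stage (one block vs. two
blocks, merged by addition), a fusion block, and two reduction blocks down
to 32 channels — eight blocks in total — then a single 3×4 average pooling
(6×9 → 2×2) and a 64-unit fully connected layer, producing the token
sequence Q ∈ R^{64×16}.  The generator's mirror stack omits pooling and
the fully connected layer and projects back to the 5 band channels.
A standard dense 3×3 convolution can be swapped in per block for the
lightweight-convolution ablation.

**Transformer encoder.**  Convolutions act per frame with weights shared
across frames; all temporal mixing happens in a pre-norm Transformer over
the 16 time tokens (width 64): N = 2 blocks, 4 heads, MLP width 128, GELU,
dropout 0.1, learned positional embeddings (time order matters, and the
tokens carry none of it otherwise).

The generator maps concat(z, one-hot label) with z ∈ R^64 through a linear
layer to 64×16 tokens, the Transformer, a per-token linear to a 2×3 coarse
map and a kernel-3/stride-3 transposed convolution up to the 6×9 grid,
then attention and the bottleneck stack.  The discriminator ends in two
heads off the mean-pooled Transformer output: a linear Wasserstein critic
(no activation) and a softmax class head.  Both heads share the trunk.

## Losses and optimization

Critic: WGAN with gradient penalty,
GP = E[(‖∇x̂ D_adv(x̂)‖₂ − 1)²] on per-sample uniform mixtures of real and
fake, λ_gp = 10.  The discriminator minimizes
L_D = −(E[D_adv(real)] − E[D_adv(fake)]) + λ_gp·GP + λ·L_cls^r and the
generator L_G = −E[D_adv(fake)] + λ·L_cls^f with λ = 1; the classification
terms are cross-entropies on the auxiliary head (real samples with true
labels for D; generated samples with their conditioning labels for G).
As printed, folding the penalty into the adversarial term with a negative
sign keeps the L_D = −L_adv + λ·L_cls^r composition exact while the
optimizer still *penalizes* gradient norms away from one — the only
reading under which WGAN-GP training is stable.

Whether D's auxiliary head should also be trained on generated samples is
a genuinely open design point; both variants are implemented
(`cls_on_fake_for_d`).  The default follows the real-samples-only
composition of the loss; the benchmark protocol below enables the
fake-sample term because, at small problem sizes, it is what makes the
class-conditioning of the generator converge inside the step budget (this
is also the original auxiliary-classifier GAN formulation).

Optimization: AdamW, weight decay 0.02, learning rates 1e−4 (G) and 3e−4
(D), one critic step per generator step (configurable), batch size capped
at 150.  All randomness flows from explicit seeds; two runs with the same
seed produce identical loss trajectories.

Because the engine differentiates the gradient penalty with respect to the
critic's weights, the autodiff core supports second-order gradients: every
vector-Jacobian product is itself expressed in traced primitives.  The
network runs in float32 by default; analytic oracle tests switch the
engine to float64.

## Evaluation

Classification: accuracy, precision, recall, F1 and Cohen's κ from the
standard contingency table (binary averaging with fatigue as the positive
class; macro beyond two classes).  κ is NaN with a warning when the truth
is single-class.

Similarity of generated and real signals: magnitude-squared wavelet
coherence wc = |S(C̄ₓ·C_y)|² / (S|Cₓ|²·S|C_y|²) with an analytic Morlet
wavelet (ω₀ = 6), 32 logarithmic scales spanning periods from 4 samples to
n/4, and smoothing S = boxcar in time of width ≈ 0.6·scale (min 3) plus a
3-voice boxcar across scales — without smoothing the ratio is identically
1.  The matrix is collapsed by averaging along time and then across
scales, keeping the score in [0, 1]; raw summation would make it
length-dependent.  Feature tensors are reduced to one trace per band by
flattening the mapped grid cells across frames; the reduction is a
pluggable function because no canonical choice exists.  Multichannel
scores average over bands; group scores average over all cross-set pairs.
Cone-of-influence exclusion is available but off by default.

## Confidence-based selection and mixing scenarios

A generated sample conditioned on class c is retained iff its maximum
class posterior (from the discriminator's head) is ≥ 0.90 *and* the argmax
equals c.  The argmax condition extends the plain threshold rule: without
it, confidently wrong samples would enter training under a wrong label.
Retention is monotone non-increasing in the threshold by construction.

The mixing experiment trains a fresh classifier per scenario — the
discriminator architecture with the adversarial head disabled — on:
all-real at the full budget, all-synthetic at the full budget, the few
(20%) real samples alone, and few-real topped up to the budget with
selected synthetic samples.  The three full scenarios share the total
budget exactly; "few" defaults to 20% because the source studies never
quantify it.  Scenario orderings are reported, never enforced.

## Synthetic study conditions

The synthetic generator emulates a 17-channel, 200 Hz vigilance recording:
per 8-s window, class-dependent RMS amplitudes over the five rhythms
(awake: δ4, θ3, α4, β6, γ3 µV; fatigue: δ4, θ6, α12, β3, γ1.5 µV — the
conventional drowsiness signature with a 3× α contrast), per-channel
spatial gains (α emphasized posteriorly, θ over fronto-temporal sites),
narrowband-filtered-noise oscillations (pure sinusoids would give
degenerate frame variances), and pink background noise (σ = 1 µV, 20%
white floor).  Eye closure per window is Beta-distributed per class —
awake Beta(2, 16), fatigue Beta(9, 4) — putting ≈ 99% of windows on the
correct side of the 0.35 threshold, so recomputed labels agree with the
requested classes at that rate.  Everything is a deterministic function of
the seed.

Not emulated: inter-channel volume-conduction correlations, artifacts,
within-window non-stationarity, real class overlap.  Passing benchmarks on
this fixture therefore demonstrates that the pipeline is wired correctly
and can learn a strong band-power signature at desk scale — not that it
reaches any particular accuracy on real vigilance recordings.

## Problem sizes

The synthetic benchmark uses 200 segments per class; five-fold stratified
cross-validation with five training epochs per fold reaches mean accuracy
≥ 0.95 and κ ≥ 0.9 with the compact network.  The compact configuration
(channel path 5→32→16→8, k = 2, one Transformer block) is the package's
desk-scale problem size for CPU training; the full-width architecture
(5→128→64→32, k = 6, two blocks) is what the shape contracts and the FLOP
audit instantiate.  The audited forward pass of the full discriminator
counts 0.37 GFLOPs under the multiply-accumulate convention of the common
profilers (elementwise and attention-gating operations excluded).

## Known limitations

* Best-epoch checkpoint selection on the fold's test split (the reported
  cross-validation convention here) is optimistic; a held-out-validation
  mode (`selection="final"`, or an explicit eval split) is provided.
* The GAN at desk scale is trained for hundreds, not tens of thousands, of
  steps; generated samples are class-informative but visually far from
  converged feature tensors.
* The electrode-grid cell assignment is a documented default, not a
  published ground truth; swap the CSV to change it.
* Wavelet-coherence smoothing parameters trade variance against the
  identically-1 degenerate case; the defaults follow standard
  wavelet-coherence practice, not a fit to data.
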