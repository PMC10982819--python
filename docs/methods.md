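# Methods

## The weak-supervision model

A patient is a bag of `n` MRI-visible lymph-node instances; the pathology
report provides only the bag-level binary label `y` (any metastatic node
among the resected nodes) and the proportion `ρ = n_metastatic /
n_resected`. Each instance receives a metastatic probability
`p_i = σ(f(x_i))` from the instance scorer, and two pooling heads connect
the instance scores to the bag labels:

* **Multiple-instance (max-pooling) head.** `p_max = max_i p_i` is matched
  to `y` by binary cross-entropy: if any node is metastatic the most
  suspicious one should score high; in an all-benign patient every node,
  including the maximum, should score low.
* **Label-proportion (average-pooling) head.** `p_avg = mean_i p_i` is
  matched to `ρ` by soft-target cross-entropy
  `BCE(p, t) = −[t·ln p + (1−t)·ln(1−p)]`, which is minimised at
  `p = t`. A squared-error head (`proportion_loss="mse"`) is provided as
  an alternative; cross-entropy is the default because both targets live
  in [0, 1] and it subsumes the binary case.

The total bag loss is `λ_mil·BCE(p_max, y) + λ_llp·BCE(p_avg, ρ)` with
`λ_mil = λ_llp = 1` by default; probabilities are clamped at 1e-7 inside
the logarithms. Both heads are differentiable almost everywhere: the max
head routes gradient to the arg-max node only, the average head spreads
`1/n` of its gradient to every node.

A deliberate asymmetry is preserved: `p_avg` averages over the
*MRI-visible* nodes while `ρ` counts among the *resected* nodes. These
denominators coincide only when every resected node is visible; the
simulator's `hidden_node_rate` controls the mismatch so its effect on the
proportion head can be stress-tested (default 0 for clean recovery
experiments).

### Instance scorers

* **Intensity network** (`M_I`): a small residual CNN for 32×32
  robust-normalised T2 patches — a stride-2 stem to 8 channels at 16×16,
  one residual stage there, a stride-2 transition to 16 channels at 8×8,
  and two further residual stages, closed by global average pooling and a
  linear logit. All convolutions are 3×3 with He initialisation; rectifiers are leaky (slope 0.1), which keeps gradient flowing through units a hard rectifier would silence and measurably reduced seed-to-seed optimisation variance. The
  output bias is initialised at `logit(mean ρ)` so that training starts
  from the cohort's base rate rather than 0.5; this removes an early
  tug-of-war between the two heads and was the single most effective
  stabiliser of seed-to-seed variation.
* **Fusion perceptron** (`M_IS`, `M_ISA`): one hidden ReLU layer (16
  units) over `[logit(p_int), long, short, ratio(, ADC)]`. Passing the
  *logit* of the intensity probability (rather than the probability)
  makes the intensity evidence linearly accessible; the perceptron is
  warm-started at an exact pass-through of that logit (two hidden units
  implement the pass-through `(g(z) − g(−z))/(1+α) = z` for the leaky
  rectifier `g`; the rest start near zero), so a
  fused variant begins precisely where the intensity model stopped and
  the extra features can only pull it toward a lower weakly supervised
  loss. Feature standardisation statistics are frozen from the training
  split (leakage guard).

### Training

Mini-batches are whole bags (16 per batch by default). Adam (lr 3e-3 for
the CNN, 2e-2 for the perceptron) with global-norm gradient clipping at 5;
a step decay to 0.3× the base rate at 60% and 0.09× at 85% of the epoch
budget settles the max-pooling head late in training. 15% of the training
bags form an internal validation split used for early stopping (patience
10) and best-state selection. Default epoch budgets: 14–18 for the CNN
(18 is used in the acceptance experiments), 120 for the perceptron. All
randomness — weight initialisation, shuffling, splits — derives from the
single configuration seed, so a fit is reproducible bit-for-bit on a
fixed build.

### Inference and staging

The decision threshold τ maximises Youden's J of `p_max` against `y` on
the training bags (candidates are midpoints of consecutive distinct
scores; ties prefer the more sensitive threshold) and is then reused for
per-node counting — it is never re-optimised on test data. The patient
ROC score is `p_max`, consistent with the MIL head; the metastatic-count
estimate is `k̂ = #{i : p_i ≥ τ}`; the ternary stage is N0 (`k̂ = 0`),
N1 (1–3), N2 (≥ 4). The ordinal score used for the concordance index is
`k̂` (the discrete predicted stage is also supported).

## Morphometry

Long and short axis are the side lengths of the minimum-area rotated
bounding rectangle of the node mask, with every foreground pixel treated
as a unit square (its four corners enter the convex hull); this matches
the caliper convention radiologists use and makes an axis-aligned
40×10 px mask at 0.5 mm/px measure exactly 20×5 mm. An alternative
definition (maximum pairwise corner distance plus minimum directional
width) is available behind `method="calipers"`; on eccentric rotated
rasterised ellipses the two definitions can differ by a few pixels — they
are different geometric quantities, so tests verify each against its own
brute force. Anisotropic spacing is handled by converting pixel indices
to millimetres before any geometry. Mean ADC is the arithmetic mean of
the ADC map over foreground pixels. Patch extraction crops a square of
side `margin_factor × bbox_side` (default 2, so perinodal tissue is
visible to the network and the hotspot analysis) centred on the mask
bounding box, edge-padding at image borders, and resamples to 32×32
(bilinear for the image, nearest-neighbour for the mask). Intensity
normalisation is a robust z-score (median/IQR, clipped at ±5), which is
invariant to affine intensity rescaling — scanner gain never reaches the
network. When 3-D volumes are supplied, analysis uses the axial slice of
largest nodal cross-section.

## Interpretability

Grad-CAM weights each feature map of the last residual stage by the
spatial mean of the metastasis-logit gradient, rectifies the weighted
sum, upsamples to the patch grid and min–max normalises; an all-zero map
stays all-zero. Because global average pooling feeds a linear head, these
weights coincide with the head weights — the implementation still
computes them by backpropagation so any head architecture works. The
hotspot classifier thresholds the map at 50% of its maximum and assigns
the label of the region holding the largest share of supra-threshold
pixels: intranodal (the mask), perinodal (a morphological dilation ring
covering 3 mm of surrounding tissue, i.e. `ceil(3 mm / spacing)` pixels),
or outside; ties break intranodal > perinodal > outside, and a map with
no positive values is labelled "none". The 50% level and 3 mm ring are
fixed, documented defaults; the classification is invariant to monotone
rescaling of the map. Only the convolutional intensity network is
attributed — the fusion perceptron has no spatial structure.

## Evaluation suite

All metrics follow brute-force-verifiable definitions: AUC is the
pairwise probability `P(score⁺ > score⁻) + ½P(tie)` (computed via
midranks); the ordinal C index extends the same credit scheme to all
patient pairs with different true stages; DeLong's test uses placement
values and their empirical covariance, returning a two-sided normal
p-value (identical scores degenerate to `z = 0, p = 1`); Cohen's κ uses
marginal-product expected agreement; per-class F1 uses the zero
convention for empty classes; net benefit at threshold `p_t` is
`TP/n − (FP/n)·p_t/(1−p_t)` with treat-all `π − (1−π)·p_t/(1−p_t)` and
treat-none ≡ 0; the calibration table uses equal-width bins, emitting
empty bins with count 0. Confidence intervals are percentile bootstrap
with 2000 seed-controlled resamples, stratified by class for the AUC.
Half-credit tie handling is used everywhere for internal consistency, so
the binary reduction of the C index equals the AUC exactly.

## Synthetic cohort

The generator emulates the population structure of a large rectal-cancer
surgery series: visible nodes per patient from a truncated normal
(mean 14, SD 5, range 5–50, rounded); 39% of patients node-positive;
among positive patients a zero-truncated negative binomial metastatic
count (mean 4.1, dispersion 1.4, capped at 35 and at the resected count)
— chosen because a Poisson cannot reproduce an SD of 3.2 at an
all-patient mean of 1.6, while the negative binomial's heavy tail can.
With `hidden_node_rate = h > 0`, `Poisson(V·h/(1−h))` additional resected
-but-invisible nodes are drawn and metastatic status is assigned
uniformly over all resected nodes, so hidden nodes may carry metastases
and the visible latent count can fall below the pathology count.

Per-node features: benign long axis log-normal (median 6.5 mm, log-SD
0.3, clipped to fit the patch), short/long ratio uniform on
[0.45, 0.90] — a benign short-axis mode near 4 mm; benign mean ADC
normal (1.10 ± 0.12 ×10⁻³ mm²/s). Metastatic nodes multiply the long
axis by `size_effect` and shift ADC by `adc_effect` (positive by
default — the configurable direction reflects that the diffusion shift
of truly metastatic nodes is the less settled of the two effects).
Patches are Gaussian background noise plus a uniform in-node contrast on
a randomly oriented rasterised ellipse; metastatic patches add a Gaussian
texture blob of amplitude `texture_effect`, placed intranodally or
perinodally by coin flip. Setting an effect to its neutral value removes
that signal channel exactly: `null_signal()` (texture 0, size 1, ADC 0)
produces bags whose labels are statistically independent of every node
feature, the negative control for recovery experiments;
`strong_signal()` (texture 3.0, size 1.6, ADC +0.40) gives clearly
separable nodes. Recorded features are *measured back* from the rendered
mask and ADC patch with the package's own morphometry, so the simulator
and feature pipeline agree by construction.

One global seed drives a hierarchical per-patient stream
(`SeedSequence.spawn`), making cohorts reproducible and
order-independent.

What the simulator does **not** emulate: 3-D anatomy, scanner noise
spectra and bias fields, inter-centre protocol differences, mucinous
nodes, and spatial correlation between nodes of one patient. Passing
tests on this phantom therefore demonstrates that the weak-supervision
machinery can recover instance labels and feature benefits *when the
assumed signal is present* — it does not certify clinical performance on
real MRI.

## Problem sizes in the validation experiments

The label-recovery experiments use 300 training and 100 held-out bags
(≈4 300/1 450 nodes) across 5 seeds for the strong-texture and null
cohorts; the variant-ordering experiment uses 160/80 bags with a weaker
texture (0.6) so that size and ADC carry independent headroom; the
DeLong calibration uses 1 000 null datasets of n = 100. The acceptance
script runs one seed at 200/80 bags. These sizes give stable means on a
single CPU; the package itself has no scale-dependent logic.

## Known limitations

* The intensity network is sized for 32×32 patches and CPU training; it
  is not a general-purpose medical-imaging backbone.
* Weak-supervision recovery depends on the MIL assumption (at least one
  visible metastatic node in positive patients); with large
  `hidden_node_rate` the binary head's premise degrades by design.
* The Youden threshold is a heuristic link between the patient-level ROC
  and node-level counting; the underlying count calibration rests on the
  proportion head.
* DeLong's test is asymptotic; at very small n its p-values drift from
  exact resampling references.
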