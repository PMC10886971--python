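# Methods

`ripplecam` implements a five-stage analysis of hippocampal CA1 *ripple
firings* — brief (~20–90 ms) synchronized multi-unit bursts recorded
extracellularly in the 300 Hz–10 kHz band at 25 kHz — whose waveform shape is
hypothesized to carry a signature of the episode the animal recently
experienced (restraint stress, contact with a female rat, contact with a male
rat, contact with a novel object, or no episode yet, "Before").

## 1. Similarity-based event selection

Raw events are variable-length amplitude sequences. Selection proceeds as:

1. **Duration filter.** Events shorter than 15 ms (375 samples at 25 kHz) are
   removed; events exactly at the bound are kept.
2. **Standardization.** Each event is z-scored over its own extent,
   `y(t) = (x(t) − m)/σ`, with the *population* (divide-by-n) SD. The choice
   of population vs sample SD is immaterial at n ≥ 375 but is fixed for
   cross-implementation determinism. Z-scoring removes the per-animal
   amplitude gain, which is a pure nuisance. Constant events (σ = 0) raise a
   labeled error and are excluded with a logged warning.
3. **Log compression.** `z = sign(y)·log10(|y| + 1)`. The transform is odd,
   strictly monotone, contractive, and maps 0 → 0, ±9 → ±1. Its purpose is to
   stop one large spike from dominating the cross-correlation. (Printed
   versions of the negative branch are sometimes garbled; the sign-symmetric
   form is the only one that is finite, odd, and anchored at z(0)=0.)
4. **Similarity score.** For log-compressed events, the score of event *j*
   against reference *i* is the peak lagged inner product over all integer
   lags with at least one overlapping sample (out-of-range samples are zero),
   divided by the reference's zero-lag self inner product:
   `sim(i,j) = max_τ Σ_t z_i(t) z_j(t−τ) / Σ_t z_i(t)²`. The numerator is
   symmetric in (i, j); the denominator makes the matrix asymmetric, and
   values can exceed 1. The full matrix is computed with batched FFT
   correlation (one forward transform per event, one inverse per row) and is
   bit-checked in tests against the direct per-pair computation.
5. **Selection.** Event *i* is kept iff some *j* ≠ *i* has
   `max(sim(i,j), sim(j,i)) > 0.6` (strict). The symmetric max is used
   because the row/column convention of the asymmetric matrix is inherently
   ambiguous; this is a documented choice.
6. **Zero padding.** Selected standardized events get trailing zeros to the
   fixed network input length of 2205 samples (88.2 ms). Padding is
   trailing-only (events start at t = 0), and the original extent is kept so
   that downstream overlap computations can exclude the padding. Events
   longer than 2205 samples are rejected rather than truncated.

Lag ties in the peak search break toward the smallest |τ|, negative first —
deterministic and alignment-preferring.

## 2. The CNN classifier

Standardized (not log-compressed) zero-padded waveforms feed a
one-conv-layer network:

    1×2205 → Conv1D(128 filters, kernel 500, stride 10) → ReLU → 171×128
           → MaxPool1D(size 10, stride 5) → 33×128 → flatten → 4224
           → FC 500 → ReLU → FC 5 → softmax

The conv stride (10) and pool stride (5) are the unique integers consistent
with the layer sizes 2205 → 171 and 171 → 33 under valid windows; they are
derived, not free choices. Training minimizes mean softmax cross-entropy
(natural log) with classical momentum SGD and coupled L2 weight decay:
`v ← μv − η(∇E + λw)`, `w ← w + v`, decay applied to weight matrices but not
biases. Defaults: batch 64, 400 epochs, η = 0.001, μ = 0.5, λ = 0.005,
mini-batches disjoint within an epoch and reshuffled every epoch. Weights are
He-uniform initialized (seeded), biases zero. Epoch-level accuracy/loss are
recorded by a full forward pass after the epoch's updates (a "final pass"
convention). Probabilities vanishing below 1e-12 are clamped inside the loss
with a logged warning.

Forward and backward passes are plain NumPy matrix products (the network is
small enough that no autodiff framework is needed); every parameter gradient
and the Grad-CAM feature-map gradient are verified against central finite
differences at relative error < 1e-4 in the test suite. Finite-difference
checks avoid inputs whose feature maps contain tied ReLU zeros inside a pool
window — genuine nondifferentiable points where any subgradient choice
disagrees with finite differences. Training is bit-reproducible given the
(init, shuffle) seeds on a fixed platform; float32 is the default parameter
dtype, float64 is used for gradient verification.

Evaluation reports the confusion matrix (rows = true category), accuracy,
micro precision/recall/F1 (identical to accuracy for single-label data —
asserted as an identity in tests), balanced accuracy (macro recall), and
micro one-vs-rest AUC over the softmax scores. Argmax ties resolve to the
lowest class index.

## 3. Grad-CAM partial-waveform extraction

For class k, filter importances are the spatially averaged gradients of the
pre-softmax class score with respect to the post-ReLU conv feature maps
A ∈ R^(171×128): `α_l = (1/171) Σ_i ∂y_k/∂A_il`. The heatmap is
`L = ReLU(Σ_l α_l A^l)`, normalized per heatmap to peak 1 (all-zero heatmaps
stay zero and are flagged as "no focus"). Differentiating the logit rather
than the softmax output is the standard, gradient-stable choice.
Per-heatmap (rather than across-heatmap) normalization is used because each
extraction needs its own L = 1.0 region; this is an interpretation of an
ambiguous convention.

Heatmap pixel i corresponds to the conv receptive field starting at input
sample 10·i; the extracted *partial waveform* is the 500-sample (20 ms)
window anchored there — the window length equals the conv kernel. The
earliest pixel wins ties at L = 1.0. Extraction uses the predicted class's
heatmap and is applied to correctly classified test events.

## 4. Embedding and centroid geometry

Full inputs (2205-d) and partial waveforms (500-d) are embedded separately
with t-SNE (scikit-learn; perplexity 30 capped at (n−1)/3 for small sets,
1000 iterations, PCA init, exact method for n ≤ 1000, seeded). Category
structure is summarized by exact centroid arithmetic: per-category centroid,
mean point-to-centroid distance (spread), and the symmetric between-centroid
distance matrix. Two qualitative observations are then evaluated:

* per category pair, whether the partial-waveform between-centroid distance
  exceeds the full-waveform one;
* whether every between-centroid distance exceeds the *mean* within-category
  spread. (The mean-spread reading is used because the every-vs-every
  comparison is falsified by the published tables themselves.)

t-SNE coordinates are seed- and implementation-dependent; absolute distances
are not reproducible quantities, only these relative statements are
meaningful. On synthetic data the partial-vs-full increase holds for the
majority of category pairs in the majority of t-SNE seeds at the default
study seed, but not for every data seed — it is a stochastic tendency, not
an invariant, and the tests treat it as such.

## 5. Pairwise cross-correlation statistics

Within one category, every ordered pair (i ≠ j) of standardized events is
scored with the overlap-normalized peak cross-correlation
`R_ij = max_τ (1/L(τ)) Σ_t y_i(t) y_j(t−τ)`, where L(τ) counts overlapping
non-padding samples at shift τ. L is τ-dependent, and shifts with
L(τ) < 25% of the shorter event's extent are excluded to avoid spurious
maxima from tiny overlaps (both choices documented; the source convention is
silent). R is symmetric under τ ↔ −τ, so a category with n events yields
n² − n values in which each unordered pair appears twice; group SEMs use the
sample (n−1) SD over those ordered pairs, matching the printed sample sizes.

Group means are compared with a one-way ANOVA (explicit between/within
sum-of-squares decomposition; cross-checked against `scipy.stats.f_oneway`)
and Scheffé's post-hoc method:
`F_ij = (m_i − m_j)² / (MSW (1/n_i + 1/n_j)(k−1))`, significant iff F_ij
exceeds the F critical value at (k−1, N−k). Treating the n² − n pairwise
values as independent observations replicates the published analysis but is
anti-conservative: pairs sharing an event are dependent. This is a known
limitation, reproduced deliberately.

## 6. The synthetic generator

Real recordings are not distributable, so the generator emulates their
statistical structure. One event is
`scale_rat × (noise + burst + motif)` where:

* **noise** is white Gaussian with SD 0.3 relative to the unit spike
  amplitude;
* **burst** is a train of biphasic difference-of-Gaussians spikes (~1 ms
  wide) locked to a 200 Hz ripple rhythm (Poisson 1–3 spikes per cycle,
  sub-millisecond jitter), amplitude-modulated by a Gaussian envelope so the
  event waxes and wanes; ~40 spikes per event on average;
* **motif** (absent in "Before") is a fixed per-category 500-sample spike
  pattern, drawn once per generator seed, scaled to peak amplitude 3 (the
  `motif_snr`) and added at a uniformly drawn position recorded as ground
  truth;
* **scale_rat** is a per-animal log-uniform gain in [0.2, 5] — exactly the
  nuisance standardization removes.

Durations are uniform in [20, 85] ms (the lower bound clears the 15 ms
filter; the upper bound fits the 2205-sample input; how longer real events
were handled upstream is unknowable, so the generator does not produce
them). Every draw is keyed by `SeedSequence(seed, category, index)`, making
datasets bit-reproducible and order-independent. At `motif_snr` ≥ ~1.5 a
brute-force matched filter recovers the planted position within ±50 samples
in ≥95% of events; at the default 3.0 recovery is essentially perfect, which
is what makes the planted motif a usable ground truth for Grad-CAM
localization.

What the generator does **not** emulate: continuous MUA background, the
150–300 Hz sharp-wave band, event detection thresholds, electrode drift,
correlated noise across events, or within-category motif variability beyond
additive noise. Passing tests therefore demonstrate that the pipeline's
machinery is correct and that it recovers structure *of the kind assumed*;
they say nothing about whether real ripple firings contain such structure.

## 7. Problem sizes and numerical choices

* The reference synthetic study uses 150 events/category (~700 training
  events after holding out 10 per category) and 100 epochs — the same order
  as the original 810-event training set, and past the point where training
  accuracy saturates. At 60 events/category the classifier generalizes
  poorly (~45–50% test accuracy) even though a matched filter separates the
  classes nearly perfectly; the gap is sample size, not information content.
* Similarity and pairwise-R computations are FFT-batched; tests pin them to
  direct per-pair references at 1e-9 relative tolerance and to exhaustive
  O(n²) brute-force oracles on short random waveforms.
* Softmax and cross-entropy are computed in float64 regardless of parameter
  dtype, so probability rows sum to 1 within 1e-12.
* Degenerate inputs (constant waveforms, empty groups, all-zero heatmaps,
  categories with too few events) raise labeled `RippleError`s rather than
  propagating NaNs.

## Known limitations

* The ANOVA independence violation described under "Pairwise
  cross-correlation statistics" above.
* The centroid-separation comparison inherits t-SNE's seed sensitivity.
* Synthetic motifs are additive and fixed per category; real episode
  signatures, if present, are surely less stereotyped.
* The CNN is the published architecture; no cross-validation,
  regularization tuning, or deeper variants (explicit non-goals).
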