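# Methods

This note documents the models, numerical choices and limitations of
`eegconcepts`, in the spirit of a package methods appendix. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Model and training

The classifier is EEGNet with its canonical hyperparameters: F1 = 8
temporal filters (kernel 64 samples ≙ 0.5 s at 128 Hz, 'same' padding),
D = 2 spatial filters per temporal filter constrained to unit L2 norm over
channels, a separable block of 16-sample depthwise kernels followed by an
F2 = 16-filter pointwise convolution, batch normalization (momentum 0.99,
eps 1e-3), ELU, average pooling by 4 then 8, dropout 0.25, and a 2-class
dense head with a 0.25 max-norm constraint. Training is Adam at its
customary defaults (lr 1e-3, β = 0.9/0.999) on softmax cross-entropy,
batch size 128, no validation stops. The reference regime is 500 epochs;
the scaled-down studies in this repository use 200 (lateralized cohort)
and 150 (two-concept cohort) — sizes chosen so one leave-one-out
repetition remains a desk-scale computation while the planted effects are
still recovered.

The implementation is NumPy with Numba kernels for the two tensors that are
actually large (the temporal convolution and its batch norm); everything
runs in float32 for training and float64 inside the relevance engine.
Determinism: all randomness of a model (initialization, shuffling, dropout)
flows from a single `numpy` Generator seeded per (repetition, fold), so the
"same seed" LOO condition is exactly reproducible on CPU; execution is
deterministic by construction rather than by flags. This deliberately
idealizes away the hardware nondeterminism that GPU training exhibits: the
same-seed condition here isolates training-set variation with *zero*
residual stochastic variance.

Leave-one-out cross-validation holds out one subject per fold. Seed
regimes: `unique` derives one seed per (repetition, fold); `same` shares
one seed per repetition across folds.

## Preprocessing

Continuous data: 50 Hz zero-phase IIR notch, 1–60 Hz FIR bandpass,
polyphase resampling to 128 Hz (all via `mne.filter`), then non-overlapping
left-aligned 3-s windows (half-open sample intervals). Epoched data:
common average reference, then per-channel standardization over batches of
128 consecutive epochs, the final partial batch on its own statistics
(mimicking an online system without lookahead). Standardization batches
never cross subject boundaries, so no statistic leaks between
leave-one-out folds; this is the package's resolution of an ambiguity in
the original recipe. Zero-variance channels are floored at 1e-8 and
logged.

## Relevance engine

Propagation requires a canonical model: batch norm is folded into the
adjacent convolution using its running statistics (introducing a per-map
bias in trained models; conservation statements below therefore refer to
bias-free models, where folding an untrained batch norm leaves the network
bias-free).

Rules. ε-rule with ε relative to the per-sample mean |denominator|
(default 1e-6); LRP-0 as the ε → 0 limit with a 1e-12 guard; αβ with the
four-way sign split `z⁺ = a⁺w⁺ + a⁻w⁻`, `z⁻ = a⁺w⁻ + a⁻w⁺` so that inputs
of either sign are handled. Outputs whose positive (or negative) part is
exactly absent route their full relevance through the other part with net
weight α − β = 1; without this the stabilized rule loses or doubles the
relevance of such outputs and per-layer conservation fails at the percent
level. The default composite assigns α2β1 to all convolutions and ε to
dense and pooling layers, mirroring the reference convention for this
composite; ELU and dropout are relevance-transparent, bias relevance is
absorbed (not redistributed). The initial relevance is the *raw logit* of
the conditioned class, not the softmax score — conservation bookkeeping is
cleanest in logit units, and softmax normalization would couple the two
classes' evidence.

CRP masks relevance outside the conditioning set θ at the output of the
condition layer ("last convolutional layer" = the 16-filter pointwise
convolution). Because every rule is linear in the incoming relevance at
fixed activations, singleton conditions partition the unconditioned
heatmap exactly; the suite asserts this at 1e-6 relative.

Degenerate inputs: a zero logit yields an all-zero heatmap; dead outputs
(no contributions of either sign) propagate nothing and their relevance is
dropped.

## Virtual inspection layer

Each epoch is parameterized by the real and imaginary coordinates of its
one-sided DFT (193 bins at 1/3 Hz for 3-s windows; no zero-padding); the
inverse transform is a bias-free linear map through which the ε-rule
propagates input relevance into the frequency domain. The adjoint is
computed analytically via the rFFT, with the one-sided doubling carried by
the map itself. Per-bin relevance is the sum of the bin's real and
imaginary coordinate relevances; totals are conserved up to the ε
stabilization (asserted at 1e-5 relative). Band aggregation uses the
conventional half-open bands δ 0–4, θ 4–8, α 8–12, β 12–30, γ 30–60 Hz;
bins at or above 60 Hz belong to no band and are reported as a remainder.

## Relevance maximization and concepts

Per condition (filter, class), only held-out test samples of that class are
scored, by the *signed* sum of the CRP heatmap (the α2β1 composite already
emphasizes positive evidence). k is the smallest prefix of the descending
scores holding ≥ 20 % of the total positive mass, clipped to [1, 10]; ties
break by sample index; conditions with no positive mass yield an empty
concept that downstream stages exclude. The concept representation is the
mean activation map of the conditioned filter over the selected samples —
a 96-sample time course (384 / pool 4) at the pointwise convolution.

## Clustering and consistency

Concepts are clustered per class (the class is part of the condition, so
mixing classes would conflate concepts): cosine-metric UMAP to 2-D
(n_neighbors 15, min_dist 0.1, fixed seed), then DBSCAN with eps 0.4.
DBSCAN's min_samples 15 presumes on the order of 16 models × 16 filters;
for fewer than 100 concepts it is scaled proportionally (×n/256) with a
floor of 5. Noise-labelled concepts are excluded from composition,
coverage and downstream views. Model coverage of a cluster is the fraction
of models contributing ≥ 1 filter.

Consistency between two models: cosine similarities between the models'
mean activation maps are fed to an optimal bipartite assignment (removing
the order-dependence a greedy matching would have), model B's maps are
reordered, both stacks flattened, and Pearson correlation taken. Per
repetition the statistic is the mean over all unordered model pairs;
matching and correlation are computed per class. Confidence intervals over
repetitions are t-based at a configurable level (default 95 %; 90 % is
also in common use).

## ICA relevance projection

Cluster data (the concatenated representative epochs) is channel-wise
scaled to unit variance, PCA-whitened (rank-reduced; average-referenced
data retains C − 1 components, logged), decomposed with extended infomax
(`mne.preprocessing.infomax`, the variant matching the ICLabel training
regime), and sources are rescaled to unit variance. Cluster relevance is
projected through the same linear chain — signed projection first, absolute
value and time-sum afterwards, making the per-component score invariant to
sign flips and permutations. Component labelling is pluggable: a
ground-truth labeler matches component topographies to planted source
loadings by absolute correlation (threshold 0.6, below which 'other'); an
adapter interface is provided for an external ICLabel implementation and
degrades to 'unlabelled' when that is unavailable.

## Synthetic cohorts

The generator emulates epoched binary-class EEG as a linear source model:
class-conditional band-limited oscillations (per-epoch carrier drawn from
the band, random phase, optional Gaussian within-epoch envelope), channel
-independent 1/f^1 background noise, stereotyped biphasic eye blinks
(Poisson onsets, frontal loading), 50 Hz line noise, and high-frequency
muscle bursts. The background spectrum is restricted to 1–60 Hz: the
generator emulates data that has already passed the preprocessing
bandpass, so it plants no power the real chain would have removed
(sub-1-Hz drift in particular, which small-sample training otherwise
latches onto). Per-subject variability is one multiplicative amplitude
jitter (±20 %) and one additive center-frequency jitter (σ 0.5 Hz) per
(subject, source). Ground truth (loadings and time courses) is retrievable
and reconstructs the data exactly.

Study conditions. The study cohorts use 6 subjects × 24 epochs/class on a
compact 20-channel 10-20 montage (all functional-grouping region channels
plus F3/F4; montages of this size are routine in BCI practice) at 128 Hz,
3-s epochs, over 10 µV pink noise. The lateralized cohort plants a
*bilateral* 10 Hz rhythm with contralateral contrast (9 µV on the strong
side, 4.5 µV on the weak side — an ERD-like construction) and one shared
per-epoch amplitude gain (±50 %, emulating arousal-driven rhythm-strength
variation) so that single-hemisphere power alone is ambiguous between
classes while the left/right contrast stays informative. The two-concept
cohort plants two burst signatures per class (early 10 Hz temporal, late
22 Hz occipital, Gaussian envelopes at 25 %/75 % of the epoch, 14 µV peak
compensating the short envelope, mirrored across classes) whose amplitudes
draw *independent* per-epoch gains (±60 %), so neither signature alone is a
reliable cue and classifiers are pushed to encode both concepts. These
choices were calibrated with full leave-one-out runs before the acceptance
suite was frozen. The package-wide `CohortConfig` default montage remains
the fuller 32-channel set. The
lateralized cohort plants 10 Hz left vs right temporal; the two-concept
cohort plants two signatures per class (early 10 Hz temporal burst, late
22 Hz occipital burst, mirrored across classes). The envelopes matter:
with strictly stationary oscillations every filter's pooled activation map
is near-constant in time and cosine similarity cannot distinguish concept
types; event-locked band-power modulation (ERD/ERS-like) is both closer to
real event-related EEG and gives concept clustering structure to find.

What passing these tests does *not* show: the generator has no volume
conduction (loadings are binary, channels' noise is independent), no
realistic ERPs, no non-stationary artifacts correlated with class, and
subject variability is a two-parameter caricature. Recovery here validates
the *machinery* — conservation, conditioning, domain transport, selection,
clustering, projection — not performance on real recordings.

## Known limitations

* Positive relevance under the ε-α2-β1 composite follows the *locally*
  positively contributing inputs of each layer. Two consequences at
  scaled-down cohort sizes, both verified on the planted studies: (a) even
  for models whose temporal filters are demonstrably alpha-tuned, the
  α-band share of positive frequency relevance saturates well below a
  majority (≈0.3–0.5 here; the α band still receives 5–8× its uniform bin
  share) because input-amplitude weighting spreads mass over the 1/f
  spectrum; (b) when a model encodes one shared left-minus-right contrast
  feature, positive relevance for *both* classes sits on the same
  hemisphere — class-swapped lateralization requires class-specific
  detectors, which small cohorts do not reliably produce.
* At 6 models (≈96 concepts per class) the UMAP embedding is sparser than
  in the 16-model regime the DBSCAN radius presumes; concept clusters are
  family-pure but fragment, so per-cluster model coverage understates how
  well concepts generalize.
* Trained (biased) models conserve relevance only approximately; the bias
  share is absorbed by design.
* Dense-layer neurons are not given concept representations (scalar
  activations would need train+test data and tend to be subject-specific);
  concepts are defined for convolutional layers.
* UMAP's embedding is stable only under a fixed seed; cosine *topology* is
  scale-invariant but exact coordinates are not.
* The ICLabel adapter requires an external implementation; the built-in
  oracle labeler only exists for synthetic data.
* Band-limited ICA variants are deliberately not offered.
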