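# Methods

## Model family

All nine variants are instances of one parameterized stack
(`architectures.ModelConfig`): conv1 (11×11, stride 4, no padding, 32
channels, **fixed analytic weights**) → ReLU → max pool → LRN → conv2 (5×5,
stride 1, resolution-preserving padding, 64 channels) → ReLU → max pool →
LRN → FC1 (32) → ReLU → dropout 0.5 → FC2 (7) → softmax. "Deep" variants
insert a trainable 3×3/stride-1/pad-1 convolution with unchanged channel
count after each of the first two convolutions, before pooling. Gabor
variants replace the conv1 bank; the first convolution layer is frozen in
every variant. The 3 input channels are a formality: kernels are replicated
across channels and scaled by 1/3, so grayscale images replicated to 3
channels see exactly the single-channel filter response.

Conventions that the printed layer sizes force:

* **Pooling is ceiling-mode** (`out = ceil((in − window)/stride) + 1`,
  overhanging windows padded by −inf). This is the only convention mapping
  55×55 → 14×14 under (5, 4) pooling and 14×14 → 4×4 for the second block.
* **conv2 and added 3×3 layers pad to preserve resolution** (pad 2 for 5×5,
  pad 1 for 3×3); otherwise the second block could not end at 4×4.
* LRN (`b_c = a_c/(k + α Σ_{j∈win(c,n)} a_j²)^β`, k=1, n=5, α=2·10⁻⁵,
  β=0.75) uses the un-normalized cross-channel sum, truncated at channel
  boundaries, and is placed after pooling. ReLU is applied conv → ReLU →
  pool → LRN; the alternative placement (LRN before ReLU) is not exposed
  because none of the analyses distinguish them at these parameter values.

### Filter banks

Kernels are sampled on an 11×11 grid mapped linearly onto the coordinate
square [−0.5, 0.5]², so σ values and carrier frequencies are in
filter-width units and f ∈ {2, 4} means 2 or 4 carrier cycles across the
filter. DoG enumeration: for A₁ = 0.4 (A₂ = 0) the four σ₁ values
{1/(2√2), 1/(4√2), 1/(8√2), 1/(16√2)} × 2 polarities; for each A₁ ∈
{0.67, 0.8, 1.0} the two widest σ₁ × σ₁/σ₂ ∈ {0.5, 0.25} × 2 polarities —
8 kernels per amplitude, 32 total, ordered lexicographically so channel
indices are stable. The Gabor σ = 0.125 is taken at face value even though
it is not exactly consistent with a half-amplitude width of half the filter
width under any common convention (2σ√(2 ln 2) ≈ 0.29). No DC correction is
applied to the kernels.

## Inputs and the luminance-centering choice

`prepare_input` resizes a square grayscale image bilinearly to 227×227,
replicates it to 3 channels, scales by 1/255 and **subtracts the background
gray level** (128/255), so the uniform background maps to exactly 0. The
centering matters: several DoG bank members are low-pass with DC gain of
order 10, so on non-centered inputs every image produces a large, nearly
image-independent background response; under the fixed training protocol
(constant lr 0.001) that common mode either silences all FC1 ReLUs within a
few iterations or stalls learning entirely. Centering makes the front end a
contrast code — which is also the physiologically sensible reading of a
retina/collicular front end, and the standard mean-subtraction step of
AlexNet-era training pipelines.

## Training protocol

Plain minibatch SGD on mean cross-entropy: batches of 32 drawn with
replacement per iteration, constant learning rate 0.001, dropout 0.5 before
FC2 during training only, conv1 frozen. Trainable weights are initialized
Normal(0, √(2/N)) with **N the layer's total weight count**, biases 0. The
fan-in reading of N was tried and rejected: it starts FC1 pre-activations at
SD ≈ 10, and the first few SGD steps at lr 0.001 drive every FC1 unit
permanently negative (loss pinned at ln 7 ≈ 1.946 — the same "no learning"
failure the protocol shows at lr 0.01). With the total-weight-count reading
the initial softmax is near-uniform, training starts at the chance-level
loss and decreases. Argmax ties in evaluation break to the lowest class
index; a non-finite loss aborts with a diagnostic.

The reference protocol length is 240,000 iterations; the desk-scale profile
used by the test suite is 20,000 iterations on a 40-identity synthetic set
(19,600 augmented images), which runs on one CPU by caching the outputs of
the frozen prefix (conv1 → ReLU → pool → LRN for shallow variants) once per
image and resuming every minibatch from the first trainable layer. The
cache is exact, not an approximation: those layers have no trainable
parameters and dropout does not touch them.

## Stimuli

Augmentation is the deterministic 70-fold product of 7 sizes
{28, 56, 85, 113, 141, 170, 198} px × 5 positions (center and four
diagonals displaced 10 px) × horizontal flip, pasted on the gray-128
198×198 canvas, clipped (never wrapped) at edges. Splits are at identity
granularity, so expression balance within splits follows from each identity
carrying one image per expression, and no identity leaks across splits.

Bandpass SF probes: the face image is rescaled to the probe size s (the
"object"), its amplitude spectrum is flattened to unity (phase preserved)
and multiplied by an isotropic Gaussian in log₂ radial frequency, SD 2.4
octaves, centered at the requested SF in cycles per s-pixel width, with
peak amplitude ∝ 1/center_sf to balance total contrast across center SFs;
the DC term is set so the mean stays at gray 128; the filtered patch is
pasted centered on the 198×198 canvas. "Log scale" is log₂ throughout (the
only reading under which 1→64 cycles/object in 0.1 steps gives 61 values),
and "variance at 2.4 octaves" is read as the Gaussian SD. A global gain
(400/center_sf spectral peak, with an n²/198 size compensation) puts the
pixel SD of low-SF probes near 30 gray levels and makes pixel contrast
independent of probe size. Center SFs above the probe's Nyquist limit (the
top of the ladder at s = 99) are allowed — the Gaussian is simply truncated,
as it must have been in the original two-size design — so the stated
"center SF below Nyquist" precondition is enforced only as center_sf > 0.

## SF reference-frame analysis

FC1 responses (after ReLU) are averaged across individuals per (expression,
size, center SF); peaks are the raw grid argmax (no interpolation; the
0.1-log₂ grid bounds quantization error), with exclusions in precedence
order: *unresponsive* (max ≤ 0), *sf_insensitive* ((max−min)/max < ε = 0.1;
the threshold is a package choice, exposed as a parameter, and exclusion
counts are monotone in it), *boundary_peak* (argmax at either ladder end).
Analysis granularity is the (unit, expression) pair, pooled across models;
excluded pairs are dropped, never zero-filled. Peak shifts are not clamped
to [0, 1]. The 2-D histogram of (peak_large, peak_small) uses bins centered
on the log₂ ladder.

Because peaks live on the discrete 0.1-log₂ ladder, peak-shift samples carry
many exact ties, which would inflate the empirical excess mass (a zero-length
interval captures a whole tied cluster at any λ) against the continuous
bootstrap null; the test therefore dithers tied samples with seeded uniform
noise at the quantization step (the smallest inter-value gap above float-
rounding tolerance) before computing the statistic. Mode counting on gridded
shifts remains unreliable when the true mode scatter falls at or below the
grid step (~0.1), and genuinely overlapping modes (scatter ≳ 0.4 octaves for
modes one octave apart) are merged — both expected behaviors, not defects.

KDE mode locations are local maxima of a Gaussian KDE (Silverman bandwidth
by default) on a 2048-point grid, sorted by height. The excess-mass test of
H₀ "exactly k modes" uses the statistic Δ = max_λ [E_{k+1}(λ) − E_k(λ)],
where E_m(λ) is the empirical excess mass over m disjoint intervals,
computed exactly per λ by an O(n·m) dynamic program over the sorted sample
and maximized over a 40-point geometric λ grid scaled to the sample's KDE
peak density. Calibration is the smoothed bootstrap from the critical-
bandwidth k-modal KDE (smallest Gaussian bandwidth giving ≤ k modes, found
by bisection — valid because the Gaussian-kernel mode count is monotone in
bandwidth) with Silverman's variance rescaling; p = (1 + #{Δ* ≥ Δ})/(B+1).
The estimated mode count is the smallest k not rejected at α = 0.05.
Degenerate (constant) samples and samples below n = 30 are rejected.

## Pooling / size-invariance analysis

For each (center SF, expression, individual) the flattened population
response of a layer — conv1 after ReLU, pool1 after pooling and before LRN —
is compared between sizes 198 and 99 by D(x,y) = ‖x−y‖/(N·M). M defaults to
the maximum raw distance over the layer's own evaluation family (61 × 7 ×
n_individuals), making max D·N = 1 exactly; a shared-M mode normalizes
across the layers of one call for cross-layer comparability. Before/after
ratios are taken evaluation-wise with zero-denominator evaluations reported
missing. The conv1/pool1 analysis needs no training — both layers sit at or
below the frozen bank — so untrained models are used.

## Synthetic data

Faces are procedural geometry (anti-aliased ellipse/bar/band primitives on
the gray-128 canvas): a face ellipse, two eyes, two brows and a curved
mouth band, with class-conditioned means for mouth curvature/opening/width,
brow angle/raise and eye aperture, identity-level jitter shared across an
individual's expressions, and smaller per-expression jitter. "Happy" and
"surprised" have the largest geometric deviations, "sad"/"neutral" the
smallest. A built-in check verifies the geometry parameters are linearly
separable (>0.95 held-out accuracy of a multinomial-logistic read-out).
What the generator emulates: canvas format, label structure (7 expressions ×
identities, one image per pair), class-discriminative local features at
multiple spatial scales, identity variation. What it does not: photographic
texture, hair/skin statistics, within-class diversity of real posed
expressions, ethnicity structure. Tests passing on these faces therefore
validate bookkeeping, invariances and recovery properties of the pipeline —
not classification rates on photographs.

Planted SF-tuned units respond with a Gaussian in log₂ of
c·(198/size)^λ around a preferred SF (default 8 cycles/object, mid-grid;
bandwidth 1 octave), so λ = 0 is exactly size-invariant (object-based),
λ = 1 exactly retina-locked, and the expected peak shift equals λ. Additive
Gaussian response noise is optional; all randomness flows through seeded
generators passed per call.

## Problem sizes used by the test suite

Deliberate desk-scale choices: training smoke uses 40 identities
(19,600 augmented images, 30/2/8 identity split) and 20,000 iterations;
λ-recovery uses 200 units; the excess-mass checks use n = 500 samples and
500 bootstrap replicates; the dissimilarity analysis uses 15 synthetic
individuals (6,405 evaluations per layer) on an untrained base model;
gradient checks and layer-semantics tests run on reduced input sizes, which
change no layer semantics.

## Known limitations

* Correct rates on the restricted photographic databases are out of reach by
  construction; the package asserts qualitative regimes (above chance, far
  from perfect) and exact bookkeeping, not the published rates.
* The excess-mass λ-grid maximization is a discretization; it is calibrated
  and validated on simulated unimodal/bimodal examples rather than proven
  exact.
* Training the deep (add-layer) variants cannot use the frozen-feature cache
  beyond conv1's output and is correspondingly slower; the suite exercises
  them at small scale only.
* The NumPy conv/pool/LRN stack is float32 and single-threaded BLAS-bound;
  it is sized for desk-scale experiments, not for the 240,000-iteration
  reference protocol.
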