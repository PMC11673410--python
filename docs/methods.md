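# Methods

This note records the modeling choices behind `graphaad`, the knobs that
matter, and what the synthetic experiments do and do not demonstrate.

## Pipeline model

A trial is a labeled multichannel EEG recording (channels × samples,
microvolts, attended side ∈ {left, right}). Processing is strictly
per-trial:

1. **Normalization** — z-score per channel per trial (population divisor
   n). Per-trial statistics were chosen because cross-trial amplitude
   drift is the dominant nuisance in EEG classification; nothing is pooled
   across trials or subjects, so no statistics leak across
   cross-validation boundaries. Zero-variance channels are mapped to zeros
   and flagged rather than raising.
2. **Segmentation** — windows of `window_s` seconds at stride
   (1 − overlap)·window, tapered by a periodic Hann window
   0.5(1 − cos 2πk/N). The periodic convention makes the first sample
   exactly zero and the last ~zero, and is the standard choice for
   segmentation. Default overlap 0; windows never cross trial boundaries;
   a trailing partial window is discarded. EDF/BDF input sampled at
   512 Hz is normally decimated to 64 Hz first (polyphase resampling with
   built-in anti-alias low-pass); the synthetic generator produces 64 Hz
   directly.
3. **Graph construction** — the Pearson correlation is computed for every
   electrode pair of the tapered segment, in the raw-sums form with the
   denominator guarded: a zero-variance channel gets r = 0 against all
   partners (it carries no linear information and must never divide by
   zero). Edges survive where r > 0.7 (strict inequality, signed; an
   `absolute` mode using |r| > 0.7 is provided as an ablation because
   strong anti-correlation is plausibly informative). Electrodes with no
   surviving edge are removed. A node that passes with one partner and
   fails with another is kept (degree ≥ 1 rule) — the alternative strict
   reading, deleting any node involved in a failing pair, would almost
   always empty the graph. Per-segment (not per-trial) correlation is
   used, so each training sample carries its own topology. Segments whose
   graph is empty are skipped with a logged manifest entry; if *every*
   segment is skipped the dataset build fails loudly, naming the
   threshold.

## Network

Node features entering the spatial module are each surviving electrode's
own windowed, normalized series, contextualized by a temporal transformer.

**Temporal module.** Tokens are non-overlapping time patches (default 16
samples), with the full montage's channels inside a patch as the token
feature vector; channels pruned from the segment's graph are zeroed, so
the encoder only sees surviving electrodes. Patch tokens, rather than one
token per sample, keep self-attention cost quadratic in a ~40-token
sequence instead of a ~640-sample one — at 64 Hz this is what makes
15-epoch × 4-fold training practical on a single CPU — while the linear
patch embedding can still express any per-sample weighting. Two post-norm
encoder layers (multi-head self-attention + LeakyReLU feed-forward,
residual connections, layer normalization, sinusoidal positional encoding,
switchable off) are the default. An `encoder_decoder` mode adds a decoder
block whose single learned query cross-attends to the encoder states and
adds the resulting global context back onto every token; with no target
sequence in a classification task, a one-query decoder is the minimal
well-defined form of an encoder–decoder temporal module. The encoder
output is un-projected to the patch layout and added to the input series
(residual refinement), so each electrode leaves the module with its own
contextualized series.

**Spatial module.** Each node's series is linearly projected to
`node_dim`, and a learned per-electrode embedding (indexed by montage
position) is added. This embedding is essential given the readout: after
global mean pooling, the only class information a correlation-pruned graph
carries is *which* electrodes survived, and anonymous node features cannot
encode that. It is switchable off (`electrode_embedding=False`) for
ablation. The stack is two GraphSAGE layers (mean aggregator; an empty
neighborhood contributes a zero vector, though isolated nodes are removed
upstream), one symmetric-renormalized graph convolution (self-loops added,
D̃^−1/2ÃD̃^−1/2), and two graph-attention layers whose neighborhoods
include a self-loop — without it a node's own features would be discarded
entirely and degree-1 graphs become brittle. Hidden GAT layers concatenate
their K = 4 heads (activation applied per head before concatenation); the
final layer averages heads and then applies the activation. All
activations are LeakyReLU with negative slope 0.01. Readout is global mean
pooling over nodes, dropout, and a linear two-class head; batches of
graphs are processed as one block-diagonal node table with
sample-membership bookkeeping, so variable node counts are native.

Default widths (d_model 64, 4 temporal heads, hidden 64, GAT head dim 16)
are engineering choices, all exposed in `ModelConfig`.
`small_model_config()` (d_model 32, hidden 32, head dim 8) is the compact
variant used by the shipped experiments; on the synthetic task the larger
defaults buy nothing.

**Autodiff.** No deep-learning framework is used: the package contains a
~300-line reverse-mode engine over float64 NumPy arrays
(`graphaad.autodiff`) with exactly the operations the network needs, plus
Adam with the canonical constants (β₁ 0.9, β₂ 0.999, ε 1e-8). Gradients
are verified against central finite differences in the test suite, and
every layer formula against scalar-loop brute-force evaluation to 1e-10.

## Training protocol

Mini-batch Adam on softmax cross-entropy, learning rate 0.001, batch 64,
15 epochs per fold, dropout 0.2 (training only), 4-fold cross-validation.
Each fold trains a fresh model from a fold-specific seeded
initialization; with the learning rate set to zero the parameters are
bitwise those of the seeded initialization, which the tests assert.
Splitting is trial-grouped by default: overlapping windows of one trial
never straddle the train/validation boundary (segment-level splitting is
available via `group_by="none"`, but it leaks when windows overlap).
Metrics follow the confusion-count definitions; precision/recall/F1 are
anchored to the attend-left class (configurable) and undefined ratios are
reported as flagged zeros rather than NaN. Reported loss is the per-epoch
mean over batches. Segment-level evaluation is used throughout;
trial-level majority voting is deliberately not built in.

## Synthetic data model

Each trial mixes unit-variance latent sources into channels:

    block channel:  √(ρ_in − ρ_out)·s + √ρ_out·g + √(1 − ρ_in)·e_c
    other channel:  √ρ_out·g + √(1 − ρ_out)·e_c

where s is shared by the attended side's electrode block (left block
{T7, C3, P7, P3}, right block {T8, C4, P8, P4} on the reduced 16-channel
montage; mirrored temporal groups of six on the 64-channel cap), g is a
global background source and e_c is per-channel noise. This yields
within-block correlation ρ_in = 0.9 and ρ_out = 0.1 elsewhere, with
channel means and variances identical across classes — the class signal
exists *only* in correlation structure, which is exactly the mechanism a
PCC-pruned graph pipeline can exploit. A white sensor-noise floor of
0.5 µV rides on a 10 µV signal scale (correlation shrinkage < 0.3%).

All sources are spectrally colored with power ∝ 1/f above a 1 Hz corner
and flat below it, emulating EEG background activity seen through an
acquisition high-pass filter. The corner matters: with 1/f power extending
to arbitrarily low frequencies, a 10-s window is dominated by a handful of
slow fluctuations and the correlation estimator becomes heavy-tailed
enough that background pairs occasionally cross the 0.7 threshold, which
would defeat the generator's design requirement that pruning separate the
planted block from the background almost surely (ρ_out < 0.7 < ρ_in).
With the corner, the surviving edge set equals the planted block's pairs
in 100/100 fresh 10-s windows across root seeds.

What passing these tests shows: the implementation trains, the pruning
mechanism recovers planted second-order structure, and the classifier can
read topology differences at the stated training configuration. What it
does not show: performance on real EEG, where attention effects are far
weaker and entangled with artifacts, volume conduction makes neighboring
electrodes correlated regardless of attention, and no clean block
structure exists. The synthetic accuracy numbers are upper bounds by
construction, not forecasts.

## Problem sizes of the shipped experiments

The cross-validated learnability experiment uses 16 channels, 4 subjects ×
50 trials of 50 s at 64 Hz (1000 ten-second segments) with the compact
architecture; its label-shuffled twin re-runs the identical protocol on
permuted labels and lands at chance. The duration sweep uses 2 subjects ×
10 trials per seed over 5 seeds at 10 s and 1 s windows. These sizes were
chosen so the full suite re-runs in minutes on a single core while keeping
≥ 100 evaluation segments per fold in the main experiment.

## Numerical and degenerate-input policies

- Correlations are clamped to [−1, 1] only against floating-point
  overshoot; the matrix is computed on the upper triangle and mirrored, so
  it is bitwise symmetric.
- Attention softmaxes (temporal and GAT) are stabilized by max
  subtraction, which is mathematically identical to the plain form.
- The GCN asserts (rather than handles) a zero-degree node: impossible
  after self-loops.
- Empty graphs never reach the network; `collate` rejects them loudly.
- Checkpoints embed the model configuration; loading with a mismatched
  expected configuration or parameter shape raises instead of reshaping.
- In eval mode the forward pass is a deterministic function of (sample,
  parameters): repeated calls are bitwise identical, and full CV runs with
  the same seed and configuration serialize to identical JSON.

## Known limitations

- The temporal decoder mode is a design interpretation (single learned
  query); no claim is made that it matches any particular reference
  system.
- Precision/recall/F1 on small trial-grouped datasets can hit folds with
  no positive-class sample; the flagged-zero policy is explicit but means
  class-anchored aggregates need care (see the README example).
- The EDF/BDF path trusts the container's channel labels; only 10-20
  family names resolve to montage positions, everything else is carried
  with a warning and dropped at montage restriction.
- Edge weights are discarded by design (binary adjacency after pruning);
  directed/effective connectivity is out of scope.
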