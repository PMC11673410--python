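# graphaad — graph-based selective auditory attention decoding from EEG

In a cocktail-party setting a listener attends to one of two competing
speakers, and the attended side (left vs. right) leaves a signature in
scalp EEG. `graphaad` decodes that signature end-to-end, without any speech
stimulus: each EEG segment is turned into an electrode graph by
Pearson-correlation pruning, and a hybrid temporal-transformer /
graph-neural-network classifier predicts the attended side. The intended
users are auditory-neuroscience and BCI researchers who want a
stimulus-free attention decoder plus a fully controlled synthetic testbed
for it.

## Method

**Graph construction.** A trial (channels × samples, 10–20 montage) is
z-scored per channel, cut into Hann-windowed segments of configurable
duration, and for each segment the Pearson correlation

r<sub>xy</sub> = (n Σxᵢyᵢ − Σxᵢ Σyᵢ) / (√(n Σxᵢ² − (Σxᵢ)²) · √(n Σyᵢ² − (Σyᵢ)²))

is computed for every electrode pair. Pairs with r > 0.7 keep their edge;
electrodes left without any edge are dropped. The surviving topology plus
each electrode's own windowed series form one training sample.

**Classifier.** A transformer encoder (scaled dot-product self-attention,
softmax(QKᵀ/√d<sub>k</sub>)V) contextualizes the series along the time
axis; the per-electrode outputs then pass through a spatial stack of

- two GraphSAGE layers, x′ᵢ = W₁xᵢ + W₂·mean<sub>j∈N(i)</sub> xⱼ,
- one graph convolution, H⁽ˡ⁺¹⁾ = σ(D̃<sup>−1/2</sup> Ã D̃<sup>−1/2</sup> H⁽ˡ⁾ W⁽ˡ⁾) with Ã = A + I,
- two multi-head graph-attention layers with
  α<sub>ij</sub> = softmax<sub>j∈N(i)</sub> LeakyReLU(aᵀ[Wxᵢ ∥ Wxⱼ]),

followed by global mean pooling and a linear two-class head. Training is
mini-batch Adam on cross-entropy (lr 0.001, batch 64, 15 epochs per fold,
dropout 0.2, LeakyReLU activations) under 4-fold cross-validation, with
accuracy, precision, recall and F1 computed from the held-out confusion
counts. The whole network, including a small reverse-mode autodiff engine
it trains on, lives in this package (`graphaad.autodiff`,
`graphaad.layers`, `graphaad.model`).

**Synthetic testbed.** `graphaad.synthdata` generates dichotic-listening
style EEG (10–20 labels, ~50 s trials, left/right labels) in which the
class signal lives *only* in second-order spatial structure: the attended
side's electrode block shares a latent 1/f source giving within-block
correlation ρ_in = 0.9 against a ρ_out = 0.1 background, with identical
channel means and variances across classes. Pruning at r > 0.7 recovers the
planted block almost surely, so every pipeline stage is testable without
any external recording.

## Worked example

```python
import graphaad as g

synth = g.SynthConfig(n_subjects=2, trials_per_subject=6, seed=3)
recordings, _ = g.generate_dataset(synth)
montage = g.standard_montage(16)
samples, manifest = g.build_dataset(recordings, montage,
                                    g.GraphConfig(window_s=10.0))
print(f"{len(samples)} graph samples, "
      f"median surviving nodes {int(manifest['n_nodes'].median())}, "
      f"median edges {int(manifest['n_edges'].median())}")

report = g.run_cv(samples, g.small_model_config(), g.TrainConfig(seed=1),
                  montage)
acc = report.aggregate["accuracy"]
print(f"4-fold CV accuracy {acc['mean']:.3f} +/- {acc['sd']:.3f}")
```

prints

```
60 graph samples, median surviving nodes 4, median edges 6
4-fold CV accuracy 1.000 +/- 0.000
```

Twelve 50-second trials yield 60 ten-second segments; in each one the
pruned graph is exactly the planted 4-electrode block (6 edges), and the
classifier separates the two attention states perfectly. Precision, recall
and F1 are anchored to the attend-left class, so a fold whose held-out
trials happen to be all attend-right reports them as flagged zeros — check
`report.per_fold[i].metrics.flags` before averaging class-anchored metrics
on small datasets.

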