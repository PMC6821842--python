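# facespace

Analysis pipeline for comparing the *face space* of human intracranial EEG
(iEEG) with the layer-wise activation geometry of a deep convolutional
network, exercised end to end on synthetic data with planted ground truth.

## The problem

Face-selective sites in human ventral visual cortex respond with different
high-frequency amplitude (HFA, 48–154 Hz — a proxy for aggregate local
firing) to different face exemplars. The geometry those responses induce —
the set of pairwise distances between the population patterns evoked by N
face images — can be compared with the geometry each layer of a
face-trained convolutional network induces over the same images
(representational similarity analysis). The package implements the whole
chain for that comparison:

* **signal** — common average reference; HFA estimation (nine 10-Hz
  sub-bands inside 48–154 Hz, Hilbert amplitude, per-band mean
  normalization, band average); epoching to % signal change from a global
  −200–0 ms baseline; ERP and 8–13 Hz band-limited-power controls.
* **contacts** — visual-responsiveness screening (paired t-test,
  Benjamini–Hochberg FDR, Glass' Δ > 1), face-selectivity screening
  (one-sided rank-sum tests vs two contrast categories, anatomical
  constraints), the exemplar-selectivity index

  d′ = (μ_best − μ_worst) / √(½(σ²_best + σ²_worst)),

  and the grand response matrix **G** (exemplars × contacts × trials, each
  cell a 50–500 ms time series).
* **decoding** — greedy template matching: per iteration one random trial
  per (exemplar, contact) forms a test matrix **T**, the remaining trials
  average into a reference **R**; row pairs are retired at the global
  minimal Euclidean distance until all labels are assigned; accuracy is the
  mean fraction of fixed points over 1000 iterations, with an
  exemplar-label permutation test.
* **rsa** — pairwise distance vectors (N(N−1)/2 = 45 at N = 10), Spearman
  correlation profiles over 22 evaluation layers with exemplar-label
  permutation p-values and FDR; Fisher-z weighted cross-set pooling
  R̂_z = Σᵢ R_zⁱ nⁱ / Σᵢ nⁱ; image-pairs bootstrap s.e.m.; sliding-window
  and time-averaged variants; partial correlations controlling the
  low-level image parameters (luminance, RMS contrast, gradient,
  saturation); per-patient and region-of-interest analyses.
* **manipulations** — luminance matching on the HSV value plane, ITU-R 601
  grayscale, network preprocessing; the permutation/bootstrap test of how a
  manipulation changes the brain-to-layer match; nearest-neighbor identity
  decoding across manipulation conditions; frontal-versus-profile
  viewpoint-invariance matrices.
* **model_units** — leave-one-out search for single network units whose
  exemplar tuning predicts a single contact's responses (same best unit in
  all folds + significant held-out linear prediction), with cluster-level
  correction of per-layer counts.
* **rf_viz** — deconvolution (transposed convolution with unpooling
  switches and the deconvnet ReLU rule) and iterative activation
  maximization on a small, fully inspectable numpy convnet.
* **synthdata** — generators for all of the above: the three 1-back task
  protocols (360/205/260 trials), procedural face stimuli with controlled
  low-level statistics, forward-modelled continuous recordings (1/f²
  background, line noise, stimulus-locked 70–150 Hz bursts driven by a
  latent face space), and synthetic 22-layer activation stacks whose
  per-layer geometric fidelity α to the latent space is planted.

Since the underlying patient recordings and pre-trained network weights are
not redistributable, every analysis is validated against synthetic data
where the truth is known: planted matching layers must be recovered, null
data must stay null, and planted model units must be found.

## Worked example

```python
import numpy as np
from facespace import synthdata, rsa, decoding

# latent ground-truth face space for 10 exemplars
latent = synthdata.LatentFaceSpace.random([f"face_{i:02d}" for i in range(1, 11)], k=4, seed=7)

# 40 synthetic face contacts tuned to that space, 5 repetitions each
rm, tuning = synthdata.simulate_response_matrix(latent, n_contacts=40, n_trials=5, seed=7)

# 22-layer stack with the latent geometry planted at layer 12 (conv5_3)
stack = synthdata.simulate_layer_stack(
    latent, synthdata.planted_match_profile(12, 0.95, 0.2), seed=7)

profile = rsa.correlate_profile(rsa.neural_distance_vector(rm), stack, n_perm=1000, seed=7)
print(profile.table.loc[["conv5_2", "conv5_3", "pool5"]].round(3))
print("best layer:", profile.best_layer)
print("decoding accuracy:", decoding.decode_exemplars(rm, n_iter=1000, seed=7).accuracy)
```

prints

```
           rho  p_perm  p_fdr  significant
layer
conv5_2  0.008   0.458  0.840        False
conv5_3  0.883   0.000  0.000         True
pool5    0.145   0.262  0.640        False
best layer: conv5_3
decoding accuracy: 1.0
```

The planted layer is the unique FDR-significant maximum of the layer
profile (rho is the Spearman correlation between the 45 neural and 45 layer
pair distances), and the exemplar identity of single left-out trials is
decoded perfectly from the 40-contact ensemble.

The same analyses run from the shell against a fully simulated recording
(protocol → continuous signal → HFA → screening → decoding → profiles):

```sh
facespace run-all --seed 1 --outdir results_demo
```

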