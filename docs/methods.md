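# Methods

## Pipeline model and assumptions

The package treats image classification as a fixed three-stage feature
pipeline followed by a kernel-SVM evaluation protocol. The stages are
deliberately decoupled: any registered backbone can feed any reduction,
and any set of sample-aligned reduced matrices can be fused. The core
assumption is that a tapped intermediate CNN activation is a useful
fixed embedding — the SVM stages never backpropagate into the backbone,
and augmentation is reserved for the end-to-end fine-tuning scenario
(experiment I), where small training sets overfit; feature extraction
for the SVM scenarios always sees un-augmented images.

## Backbones

AlexNet, ResNet-50, DarkNet-19 and DenseNet-201 are constructed from
their published layer definitions in a small numpy framework (im2col
convolutions in float32, inference-mode batch normalisation, He
initialisation). Taps: `fc7` (4,096), the global average pool (2,048),
the class-sized head after global pooling, and the final average pool
(1,920) respectively. Weights are random unless injected: every
dimension contract and pipeline behaviour the tests assert is
weight-independent, which keeps the repository download-free. Channel
normalisation uses the conventional ImageNet mean/std constants,
configurable per `BackboneSpec`.

`fine_tune` implements SGDM (momentum 0.9, weight decay 5·10⁻⁴,
initial learning rate 10⁻⁴, mini-batch 10, 10 epochs by default) with
softmax cross-entropy. Networks whose every layer has a backward pass
(`tinycnn`: conv / ReLU / 2×2 max-pool / GAP / linear, all verified by
finite-difference gradient checks) train end-to-end; for the four deep
forward-only architectures the replaced head is trained on frozen tap
features — the standard transfer-learning split. The reported
"final training accuracy" is measured by a post-training forward pass,
not the running average during the last epoch.

## Spectral reduction

Both stage-2 transforms are authored from first principles because they
are the package's numerical core; external libraries (pywt, scipy.fft)
appear only as independent oracles in the tests.

- **DWT, level 1.** Orthonormal analysis filters with periodic boundary
  extension, so |CA| = |CD| = ⌈d/2⌉ exactly and the analysis operator is
  orthogonal (Parseval holds; the inverse is the adjoint, and perfect
  reconstruction is tested to 1e−8 for even and odd lengths). The
  default wavelet is Haar — the simplest filter that halves the
  dimension exactly; a 4-tap Daubechies (`db2`) is provided. The filter
  alignment is chosen to match pywt's `periodization` convention for
  Haar coefficient-for-coefficient. Odd-length inputs are extended by
  repeating the last sample.

- **DCT.** Orthonormal DCT-II computed by the FFT factorisation
  (even/odd reordering), verified against the O(d²) cosine-sum oracle
  and scipy's `norm="ortho"` variant. Orthonormality makes truncation
  energy-interpretable and scale-stable for the SVM stage.

- **Coefficient selection.** Default keeps the 500 lowest-frequency DCT
  coefficients; vectors with d ≤ 500 (e.g. class-sized taps) pass
  through whole. A frequency-ordered 1-D coefficient vector has no
  canonical 2-D zigzag geometry, so low-frequency-first truncation is
  the default — it realises the zigzag scan's purpose (retain
  low-frequency energy first); a literal mode that re-lays the vector
  into the smallest near-square block and walks the JPEG zigzag is
  provided (`dct_order="zigzag2d"`).

## Fusion

Pure column-wise concatenation of sample-aligned matrices, homogeneous
per transform kind (CA with CA, CD with CD, DCT with DCT) as the default
experiment grid; no re-scaling at fusion time, since standardisation
happens per training fold inside the classifier. Enumeration emits every
subset of the requested sizes in lexicographic component-name order —
deterministic report rows; 11 sets for four backbones at sizes {2,3,4}.

## Evaluation protocol

Stratified k-fold (k = 5) with shuffling controlled by a single seed;
fold assignments are computed once per run and shared by every kernel
and feature set, so accuracy differences are paired. Each fold:
standardise on the training split (population SD; constant columns map
to 0), fit a one-vs-one SVM with kernel (γ⟨x,y⟩ + c₀)ᵖ
(γ = 1/(d·mean feature variance), c₀ = 0 for linear and 1 otherwise,
C = 1 — conventional defaults, all configurable), predict the held-out
fold. The headline accuracy is overall correct/n; the per-class
one-vs-rest (TP+TN)/n variant is also emitted in the detail block
because the two differ for more than two classes. Zero-denominator rates
are reported as 0 with a `degenerate` flag — deterministic and
conservative.

## Synthetic study conditions

The generator emulates a balanced multi-class endoscopy-style corpus:
class c of K gets hue c/K, a sinusoidal texture at orientation πc/K and
frequency 3 + 2(c mod 4) cycles/frame, per-image random phase and small
hue jitter, and i.i.d. Gaussian pixel noise (default SD 0.05 on the
[0,1] scale). `signal_strength` scales only the class-dependent hue
saturation and texture contrast, so 0 makes every class identically
distributed — the chance-level control — and 1 (the default) gives
clean separation. Default sizes: 8 classes × 50 images at 64×64 px —
large enough for stable 5-fold estimates, small enough that the full
pipeline runs in seconds. Determinism is per-image: one child RNG
stream per image spawned in fixed order from the single seed, so
identical specs give byte-identical uint8 PNGs.

What the generator does **not** model: lesion morphology, specular
highlights, vignetting, the green endoscope-position overlay, class
imbalance, or inter-patient variability. Passing tests therefore
demonstrate the pipeline's mechanics and statistical protocol, not
clinical performance; accuracies on these fixtures say nothing about
accuracy on real endoscopy data.

The complementary-sets fixture places class means on coordinate axes at
separation 8 with unit spherical noise, collapsing half the classes in
each set; with 4 balanced classes either set alone is capped at the
Bayes rate (2 + 2·½)/4 = 0.75, while the concatenation resolves all
four — a construction whose fused-beats-components outcome is
guaranteed, making the stage-3 claim testable rather than anecdotal.

## Numerical choices and edge cases

- float32 forward passes (BLAS matmuls); float64 for transforms,
  metrics and SVMs.
- Transform tolerances: 1e−8 for reconstruction/oracle/Parseval checks
  (comfortably above float64 round-off at d = 4096).
- Augmentation ranges are closed intervals sampled uniformly:
  translation (−30, 30) px independently in x and y, rotation
  (0, 180)°; rotation is about the centre with the frame size kept and
  zero-filled corners; degenerate ranges collapse to constants.
  "Transformation" is realised as the translate∘rotate affine
  composition (no shear). Bilinear interpolation throughout.
- Labels: class names are sorted lexicographically wherever an index
  order is needed (head construction, metric tables) — deterministic
  tie-break.
- Empty inputs, single-class training sets, non-finite features,
  misaligned fusion components and undersized classes all raise typed
  errors rather than degrading silently.

## Acceptance-run problem sizes

`scripts/acceptance.py` uses the default study conditions (8 × 50
images, four tinycnn variants of widths 32/24/16/12 standing in for the
four-CNN structure, 3 kernels, 5 folds) plus a 240-image zero-signal
control; the full run takes about a minute on one CPU. Larger corpora
and the four deep backbones are supported through the same interfaces
via explicit dataset paths and backbone names.

## Known limitations

- Random-weight backbones make tap features random projections; they
  separate the synthetic hue/texture classes but are not meaningful
  embeddings of natural images without pretrained weights.
- Deep-architecture fine-tuning updates only the classification head
  (no backward pass through bottleneck/dense blocks).
- Batch normalisation runs in inference mode everywhere; fine-tuning
  does not update running statistics.
- The DWT is single-level by design; multi-level decompositions and 2-D
  image-domain transforms are out of scope — the transforms operate on
  feature vectors, not images.
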