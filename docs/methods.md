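# Methods

## Data model

A scan is a `HyperCube` (H × W × B float intensities plus a strictly
increasing spectral axis, a scan id and a subject id) paired with a
`LabelMap` (H × W integer class codes, ordered class names, and the set of
*masked* classes). Scans smaller than a common grid are zero-padded at the
bottom/right (`pad_to_grid`); padded pixels get all-zero spectra and the
dataset's zero class. Where the original data sit inside the common grid is
not knowable from padded data alone, so the top-left convention is a fixed
package choice.

Two task relabelings of the original 8-class colorectal annotation are
built in. Epithelial-tissue detection merges carcinoma/adenoma/hyperplasia/
normal into "epithelial tissue" and question/zero into a zero-spectrum
"rest class" (4 task classes); colorectal-cancer detection keeps the four
tissue grades and merges artifact/other tissue/question/zero into a
zero-spectrum "others" class (5 task classes). `relabel` remaps codes,
zeroes the spectra of merged-away pixels, and conserves pixel counts under
the mapping; masked pixels stay in the maps (and in the U-Net loss) but are
excluded from all evaluation metrics.

## Preprocessing

Applied per pixel spectrum, in the fixed order **despike → background
subtraction → normalize**; spikes are removed first because they corrupt
any baseline estimate. All-zero (masked) spectra pass through untouched.

**Despiking.** Cosmic-ray spikes are isolated, sharp, single-spectrum
events. A point is replaced by its running median (window 7 bins,
edge-replicated) when its robust z-score exceeds 8, with the scale
1.4826·MAD(residuals) + 0.01·MAD(|x − median(x)|): the second term floors
the scale at 1 % of the overall signal scale so that smooth, nearly
noise-free spectra — where the residual MAD collapses to zero — are never
modified. The pass is iterated to a fixed point (bounded at 10 passes),
which makes despiking exactly idempotent.

**SNIP background.** The statistics-sensitive nonlinear iterative
peak-clipping estimate of the smooth fluorescence background: for
half-widths m = 1…M, synchronously clip
v[i] ← min(v[i], (v[i−m] + v[i+m])/2) over interior points. By default
(M = 40) clipping runs inside the log-log-square-root compression
y = log(log(√(v+1)+1)+1) (inverted afterwards), which stabilises
high-dynamic-range fluorescence; spectra are shifted to be non-negative
before the LLS transform. The half-width is capped at (B−1)/2 so short
spectra remain processable. The baseline is monotone non-increasing in M at
every bin, since each extra pass can only lower values.

**Normalization.** Default L2 (unit-norm spectra are scale-free network
inputs); unit absolute area, unit max, and none are available. An all-zero
spectrum cannot be normalized and raises; callers route masked pixels
around the chain. The iteration count, despiking rule and normalization
variant are package choices — upstream processing pipelines for such data
typically do not publish these parameters — and all are exposed in
`PreprocessConfig`.

## Training units

`unfold_1d` turns a scan into H·W independent spectra; `extract_patches`
turns it into H·W patches of shape w × w × B (default 3 × 3), each labeled
by its central pixel. Border halos are zero-filled by default — consistent
with the zero padding already present in the data and keeping one patch per
pixel so reassembled maps are complete; `reflect` and `drop` are options.
`fold_predictions` inverts unfolding, keyed by (scan, row, col) provenance,
so prediction order is irrelevant; duplicate or missing pixels are errors.

## Architectures

All three networks are expressed as declarative `ModelSpec` layer lists
through which shapes propagate analytically, so trainable-parameter counts
are exact closed-form sums: conv (∏k·c_in + 1)·c_out, batch norm 2·C, dense
(n_in + 1)·n_out, 1×1 2D head (c_in + 1)·n_classes.

* **1D CNN**: four blocks [conv1d(kernels 128/64/32/16, sizes 3/5/7/9,
  same padding) → batchnorm → leakyReLU(0.3) → maxpool ÷2 (floor)], then
  flatten → dense(n_classes) → softmax.
* **3D patch CNN**: the same four blocks with 3 × 3 × {3,5,7,9} kernels;
  pooling acts on the spectral axis only, preserving the 3 × 3 spatial
  extent.
* **Simplified 3D U-Net**: conv3d(base, 3×3×5)+bn+relu (skip tap) →
  spectral pool ÷2 → conv3d+bn+relu → spectral upsample ×2 → crop the skip
  tensor's spectral axis to the upsampled length (leading bins kept) →
  concatenate channels → conv3d+bn+relu → stack spectral bins into channels
  → 1×1 2D conv to n_classes → per-pixel softmax, yielding an H × W map.

Several internals (same padding, floor pooling, batch-norm placement, the
U-Net's crop-then-concat and spectral-to-channel reshape) are a *calibrated
reconstruction*: they are the unique set of conventions that reproduces all
six published reference parameter counts exactly (1D/3D/U-Net at 677 bands,
5 classes, base 128: 64,373 / 573,557 / 2,651,397; at 60 bands, 2 classes,
base 64: 61,106 / 544,178 / 564,098). The published epithelial-task counts
are consistent with these rules only at an input length of ≈740 rather than
the stated 677 bands — likely an upstream cropping difference — so they are
recorded here but asserted nowhere. The activations after the U-Net's
conv+bn blocks are parameter-free and do not affect the calibration; a
purely linear encoder would be untrainable.

`instantiate` compiles a spec into a trainable network on the package's
numpy engine (channels-last layouts, im2col/offset-GEMM convolutions,
reverse-mode gradients, Adam). The engine's allocated-weight count must
equal the analytic counter for every spec; gradients of every layer kind,
including the skip path with odd spectral length, are verified against
central finite differences in the test suite.

## Training and cross-validation

Folds are assigned at the subject level by a greedy balance: subjects in
decreasing spectra-count order each go to the currently lightest fold
(seeded tie-break). Exact equality is impossible under the subject
constraint; on ~150 subjects the max/min fold load ratio stays within a few
percent. `run_cv` trains on K−1 folds and predicts full segmentation maps
on the held-out fold, asserting on every run that no subject appears on
both sides.

Training is minibatch Adam at a fixed learning rate (default 3 × 10⁻⁴) on
categorical cross-entropy, default 50 epochs, batch 256 for spectra and
patches and one scan per batch for the U-Net. The U-Net's loss averages
over all pixels including masked ones (they are a predictable background
class in the output maps); evaluation always excludes them. Class
weighting (inverse-frequency "balanced") is available but off by default.
Runs are reproducible: initialization, shuffling and subsampling all
derive from explicit seeds. `TrainConfig.max_units` subsamples the
training units once (seeded) — the control used to scale experiments to a
single CPU.

## Metrics

`confusion` drops pixels whose *true* class is masked, then tallies a K×K
table. Accuracy is trace/total — the multiclass reading of the binary
(TP+TN)/(TP+TN+FP+FN) form, to which it reduces for two classes. Balanced
accuracy averages recalls over classes with at least one true pixel;
zero-count classes are dropped rather than scored 0 to avoid 0/0. DSC is
computed per class one-vs-rest from (|A| = predicted positives,
|B| = annotated positives, |A∩B| = TP) and reported per class plus as a
macro mean, on the ×100 scale; for 2-class tasks both the positive-class
and macro values are available since either convention appears in the
literature.

## The phantom

`make_scan` emulates the statistical structure the pipeline assumes:

* blob-shaped contiguous class regions (Gaussian-smoothed seeded white
  noise cut at equal-area quantiles; smoothness 3 px);
* one signature per class: 5 Gaussian peaks with seeded positions, heights
  0.5–1.5 and widths ~3 bins; signatures are regenerated until every
  normalized pair is at least min_class_separation·√(B/64) apart (0.5 at
  the default 64 bands — the floor shrinks with the band count because few
  bands leave less room for distinct smooth signatures);
* a subject-specific degree-2 polynomial baseline (amplitude 0.5) — the
  only subject effect, standing in for instrument/sample fluorescence
  drift;
* Gaussian spectral noise (σ = 0.05), Poisson cosmic-ray spikes
  (0.02/spectrum, ~20× signal scale);
* and the key ingredient: a fraction (default 8 %) of isolated pixels whose
  *spectrum* is generated from a wrong class while the annotation stays
  correct — spatially uncorrelated corruption that per-spectrum classifiers
  cannot fix but spatial context can. A 3×3 majority-vote oracle over the
  spectrum-evidence map beats per-pixel evidence on every phantom, which
  certifies the reward for spatial context independently of any network.

The default desk-scale dataset is 16 scans of 24 × 24 × 64 from 8 subjects
with 3 classes. What the phantom does *not* model: real Raman band
positions and widths, detector response, spatially correlated annotation
error, inter-subject signature variability, and class imbalance at real
ratios. Passing tests therefore demonstrate the pipeline's mechanics and
the direction of the spatial-context effect, not clinical performance.

## Desk-scale experiment sizes

The directional check (3D patch CNN vs 1D CNN) uses three replicate
phantoms with K = 4 grouped splits, evaluating fold 0 of each: the 1D CNN
trains 4 epochs on all ~6,900 training spectra, the 3D CNN 2 epochs on
1,200 subsampled patches (both far below the 50-epoch full schedule). At
these sizes the run takes ~5 minutes on one CPU and reproduces the expected
ordering with a clear margin (mean validation balanced accuracy ≈ 0.91 for
1D vs ≈ 0.96 for 3D): the 1D model is capped near 1 − pixel_label_noise by
construction, while the patch model sees past corrupted centres. U-Net
training is exercised at small grid sizes; at full scan sizes its
per-parameter data ratio is tiny and single-CPU forward passes are slow, so
full-scale U-Net runs are out of desk scope.

## Numerical choices and degenerate inputs

float32 weights/activations with float64 loss and batch-norm statistics;
batch norm ε = 10⁻⁵, momentum 0.9; leaky-ReLU slope 0.3; Adam β = (0.9,
0.999), ε = 10⁻⁷. Max pooling floors odd spectral lengths (the trailing bin
is dropped) and routes gradients to the argmax (first maximum on ties).
Upsampling repeats bins; the skip crop keeps leading bins. Empty training
sets, shape mismatches, non-finite spectra, all-zero spectra under
normalization, oversized windows, and folds without validation subjects
all raise typed errors rather than degrading silently.
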