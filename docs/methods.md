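# Methods

This note records the models, numerical choices and known limitations of
`spermqpi`, stage by stage.

## Phantom generator

A cell is a thickness field `t(x, y)` (µm) built from three
compartments in a local frame (head centred at a pose-dependent origin,
long axis along +u), converted to phase by the double-pass relation
`φ = (4π/λ)·Δn·t`. The double pass reflects the imaging geometry of a
cell on a reflective substrate; a transmission user should halve the
prefactor.

* **Head** — ellipse 4.5 × 3.0 µm (WHO-typical), flat-top thickness of
  1.8 µm with a raised-cosine rolloff over the outer 40 % of the
  normalized radius. The flat top makes "head area" well defined: the
  half-maximum contour sits at `r = 1 − 0.4/2 = 0.8` of the ellipse, so
  segmentation can be validated against closed-form geometry. Peak head
  phase is ≈ 1.8 rad at Δn = 0.05 and λ = 0.6328 µm (He–Ne line).
* **Midpiece** — 4.0 × 1.0 µm, 0.6 µm thick, cos² transverse profile and
  smoothstep longitudinal taper (C¹ everywhere).
* **Tail** — 40 µm centerline with a small random quadratic bend plus a
  sinusoidal waviness (amplitude 1.5 µm × `tail_waviness`, period
  12–18 µm), Gaussian cross-section of width 0.5 µm and thickness
  0.1 µm, giving the ~0.1 rad tail phase that makes the tail the hard
  part of the imaging problem. Longitudinal smoothstep ends avoid step
  edges.
* **Optical blur** — a Gaussian PSF of σ = 0.3 µm is applied to the
  phase map, standing in for the diffraction and residual aberrations of
  a high-NA water-immersion objective. It also keeps the phantom
  band-limited, which the Fourier demodulation stage requires: all
  profile choices above (flat-top width, C¹ tapers, midpiece width) were
  made so that the phantom's spectrum fits inside the sideband filter
  passband; sharper profiles leak outside it and reappear as a diffuse
  mrad-scale halo in the reconstruction.

Condition classes perturb generator parameters, scaled by
`effect_size ∈ [0, 1]` (0 reproduces the normal class bit-for-bit, since
every random stream is consumed identically regardless of condition):

| condition | perturbation at effect_size = 1 | separating statistic |
|---|---|---|
| cryo | head phase −30 %, boundary roughness +0.10 | head-phase deficit vs normal |
| h2o2 | tail waviness ×3, head texture ±15 % | tail curvature energy |
| ethanol | head eccentricity +20 %, boundary roughness +0.10 | head eccentricity |

These are quantitative proxies for qualitative membrane/tail damage
mechanisms; they make the classes learnable and tunable and claim no
biophysical fidelity. The separating statistics are defined as
deviations from the normal class so each is monotone non-decreasing in
effect size (the raw cryo statistic, mean head phase, decreases — the
deficit form keeps the monotonicity convention uniform). The tail
statistic assumes the canonical axis-aligned pose and is used for
generator validation only.

Datasets draw per-cell pose (rotation uniform in [0, 2π), translation
within the central 40 % of the field, ±10 % isotropic size jitter) from
per-cell seeded streams, so any subset is reproducible from the dataset
seed alone.

## Interferogram synthesis

`I = a(x,y) + b₀·cos(2π(fx·x + fy·y) + φ + η)` with defaults
a₀ = 600, b₀ = 400 camera counts, 16-bit quantization (`bit_depth = 0`
models an ideal unquantized detector), optional Poisson shot noise, and
a fixed low-order polynomial illumination non-uniformity (amplitude 10 %
of a₀) that exercises the background-subtraction stage.

The default carrier is (0.25, 0.25) cycles/pixel. This is a deliberate
choice: the head's ~1.8 rad phase produces local fringe-frequency
excursions of ~0.07 cycles/pixel, and the sideband filter radius is
0.45 × |carrier|; at |carrier| = 0.354 the filter passband (0.159
cycles/pixel) contains the whole cell spectrum, while a half-as-dense
fringe pattern would clip it and push the round-trip error above a
milliradian. Synthesis refuses carriers smaller than 3× the radius
containing 95 % of the phase map's AC spectral energy.

Noise regimes:

* `psc` (partially spatially coherent source): η is white Gaussian noise
  smoothed to a 10 px correlation length and rescaled to
  `phase_noise_std` (default 20 mrad, the sensitivity set-point). Its
  spectrum lies well inside the demodulation passband, so the
  reconstructed empty-field std matches the set-point to within a few
  percent.
* `coherent` (direct laser): the psc field plus unfiltered speckle-like
  phase noise (σ = 80 mrad, mostly rejected by the sideband filter) and
  one parasitic fringe (30 mrad, placed 0.03–0.02 cycles/pixel from the
  carrier, i.e. inside the passband, so it survives reconstruction).
  The empty-field sensitivity is then roughly twice the psc value,
  reproducing the laser-vs-psc sensitivity gap qualitatively.
* `none`: η = 0; with quantization off the round trip is exact to
  ~0.5 mrad.

## Fourier demodulation

The sideband filter is flat out to 0.7 × radius with a Gaussian skirt of
σ = 0.1 × radius (support truncated where the weight falls below 1e-8,
and required to exclude the DC bin). A pure Gaussian profile attenuates
in-band head content (~6 mrad round-trip error); a hard disk rings at
the tail's low amplitude (~3 mrad); the flat-core/soft-skirt compromise
reaches ~0.5 mrad. The sideband is shifted to DC by an integer-bin roll
plus a residual phase ramp, so off-bin carriers are handled exactly.
The arctangent keeps +π and maps −π to +π, making the wrap interval
(−π, π] half-open. A 16 px border is excluded from all quantitative
comparisons (FFT edge effects). Filters wider than half the carrier
distance are allowed but recorded as a provenance warning.

Background subtraction fits a 2-D polynomial (total degree 2 by
default) to cell-free pixels and subtracts it everywhere; the cell-free
mask comes from a fixed 0.05 rad silhouette threshold (above the 20 mrad
noise floor, below the 0.1 rad tail) with closing and dilation — the
Otsu mask used for cell counting deliberately keeps only the bright head
and would let the fit lean on tail pixels. The fit refuses to run with
fewer than 10 background pixels per coefficient. A reference-frame mode
(pixel-wise subtraction of an empty-field reconstruction) is available
when such a frame exists.

## Goldstein unwrapping

Residues are computed by summing the four wrapped differences around
every 2×2 loop; the sum is ±2π or 0 and the charge is stored on the dual
lattice (top-left pixel indexes the loop). Branch cuts discharge
residues by nearest-neighbour pairing of opposite charges, grounding to
the border when it is closer (or when no partner exists within the
search radius). Determinism is guaranteed by scanning residues row-major
and breaking distance ties row-major; cuts are rasterized 4-connected so
a 4-connected integration path cannot cross them. Integration is a
breadth-first flood fill adding wrapped neighbour differences; the seed
is the off-cut pixel of maximum fringe modulation |c| when available.
Pixels on cuts (or walled off by them) are filled afterwards by the same
wave propagation ignoring barriers and flagged low-confidence. The
output is congruent to the input modulo 2π at every pixel, and on
residue-free inputs equals Itoh line integration up to a global 2π·k
piston. This is the simplified nearest-neighbour variant of the
branch-cut algorithm, adequate for the residue densities QPI images of
single cells produce; dense-noise fields are flagged by QC rather than
unwrapped heroically.

## Quality control

Three retention flags, ANDed: residue density ≤ 1 per kilopixel and
≤ 0.1 % of neighbour jumps above π (unwrapping trustworthy); background
RMS ≤ 50 mrad outside the silhouette (flattening succeeded); exactly one
8-connected component with a white-pixel count in [200, 30 % of the
field] after Otsu binarization, closing with a 3 px disk (which joins
the faint tail to the head) and removal of components under 50 px. The
Otsu threshold on the positive-phase histogram keeps the bright head
core (~300–500 px at 0.108 µm/px for a WHO-typical head), which sets the
200 px floor. The spatial-sensitivity estimator removes piston and tilt
per map, excludes the 16 px border and averages the spatial std over the
stack.

## Classification

The stratified split draws per-class test sets of size
`round(0.3·n)` — 2,400 images per class yield exactly 720 test and
1,680 training images, 2,880/6,720 over four classes.

Feature path: 11 features of the segmented head (threshold at 50 % of
the 99th-percentile phase, opening, largest component): area, perimeter
(Crofton estimator, whose bias on smooth convex shapes is far below the
chain-code estimator's), major/minor axis, eccentricity, circularity,
and phase mean/max/variance/skewness/entropy (32-bin, bits). Geometric
features are in physical units via the pixel pitch. Classifiers are
sklearn pipelines (standardization + RBF-SVM C=10 / GaussianNB /
kNN k=5).

CNN path: phase maps are pose-normalized (principal-axis rotation,
mirror so the head sits left), cropped to the silhouette bounding box,
zero-padded square and resampled to 48×48 real-valued inputs —
quantitative phase is never quantized to 8 bits. Pose normalization is
essential at desk scale: without it the fixed training protocol
memorizes a few hundred arbitrarily rotated training cells (98 % train,
32 % test accuracy); with it the same protocol generalizes (>95 % test
accuracy at 200 cells/class). The network is four conv(3×3)/ReLU/
max-pool blocks (8-16-32-32 channels) plus a 64-unit dense layer
(~34 k parameters), implemented as NumPy im2col matrix products, He
initialization, trained with SGD-with-momentum (momentum 0.9, the
conventional value), initial learning rate 1e-4, batch size 16, 30
epochs, softmax cross-entropy. Everything is seeded, so confusion
matrices are bit-reproducible. Training at 200 cells/class takes about
40 s on one CPU.

Confusion matrices fix rows = ground truth, columns = predictions,
class order (normal, ethanol, h2o2, cryo). Per-class metrics are
one-vs-rest sensitivity TP/(TP+FN), specificity TN/(TN+FP) and accuracy
(TP+TN)/total; macro averages are unweighted means over classes, with
zero-support classes flagged and excluded.

## Problem sizes

The test suite and the acceptance script run the instrument geometry
(512×512 at 0.108 µm/px) for reconstruction-fidelity checks, a 256×256
field for sensitivity calibration (20 empty-field trials per regime),
64×64 fields for the unwrapping oracle comparisons (100 seeded fields),
and a 192×192 field at 0.2 µm/px with 200 cells per class for the
classification studies — sizes chosen so every check completes in
minutes on a single CPU while exercising the same code paths as the
full-scale geometry.

## What the synthetic data does and does not show

The generator emulates the geometry, phase scale, carrier structure,
illumination non-uniformity and noise statistics of off-axis
interferograms of sperm cells, and the class differences are planted
with known, tunable effect sizes. It does not emulate motile cells,
debris and multi-cell clutter beyond injected fixtures, refractive-index
heterogeneity inside compartments, defocus or diffraction beyond a
Gaussian PSF, or biological within-class variability beyond pose/size
jitter and seeded micro-structure. Passing tests therefore demonstrate
the correctness and calibration of the pipeline — demodulation fidelity,
unwrapping exactness, filter behaviour, protocol arithmetic, and the
classifiers' ability to recover planted effects (with chance-level
nulls) — not clinical classification performance on human data.

## Known limitations

* The nearest-neighbour branch-cut placement can, like all greedy
  variants, choose suboptimal cuts in dense residue fields; such fields
  fail QC anyway.
* The round-trip error budget assumes the band-limit conventions above;
  user phantoms with sharper features will show larger (documented, not
  hidden) sideband-truncation errors.
* Classical and CNN paths share the synthetic generator; their accuracy
  figures measure recovery of its planted effects, not transferability.
* `calibrate_phase_noise` reports the achieved empty-field std for the
  configured regime; it does not iterate to force the set-point.
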