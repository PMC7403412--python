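# spermqpi

Quantitative phase imaging (QPI) resolves the optical thickness of
unstained cells — refractive index × physical thickness, reported in
radians — and so can see the subtle head, midpiece and tail changes that
stress conditions (cryopreservation, oxidative stress, ethanol exposure)
inflict on human sperm cells, changes that bright-field microscopy
misses. Because no imaging data from such studies is publicly deposited,
`spermqpi` provides the full computational pipeline as a desk-scale,
fully synthetic reimplementation: it simulates sperm-shaped phase
objects and the off-axis interferograms a digital holographic microscope
would record, reconstructs the phase, applies the image-retention
quality filters, and classifies the four condition classes.

It is aimed at people building or validating QPI reconstruction and
classification code: every stage has a known ground truth, so round-trip
errors, unwrapping failures and classifier behaviour can be measured
exactly.

## The model

An off-axis interferogram is

```
I(x, y) = a(x, y) + b(x, y) · cos[2π(fx·x + fy·y) + φ(x, y)]
```

with spatial carrier `(fx, fy)`, background `a`, modulation `b` and the
specimen phase `φ`. For a cell of thickness `t(x, y)` and refractive
index contrast `Δn` on a reflecting substrate (double optical pass),

```
φ(x, y) = (4π / λ) · Δn · t(x, y).
```

The pipeline recovers `φ` from `I` by the Fourier-transform method:
isolate one spectral sideband, shift it to DC, inverse-transform to the
analytic signal `c(x, y) = b·exp(iφ)` and take
`φ_w = arctan2(Im c, Re c) ∈ (−π, π]`. The wrapped phase is unwrapped
with the Goldstein residue/branch-cut algorithm (residue detection on
2×2 loops, nearest-neighbour discharge of opposite charges, flood-fill
integration that never crosses a cut), and a low-order polynomial fit to
the cell-free region removes residual background.

Retained images must satisfy three criteria: correct unwrapping (low
residue density, no spurious 2π jumps), a flat background (RMS below
50 mrad), and exactly one cell in the field of view (component count on
the binarized phase image). Classification runs either on 11
morphological + phase-texture features of the segmented head (SVM,
Gaussian Naive Bayes, kNN) or on a compact convolutional network trained
on pose-normalized phase crops with SGD-with-momentum, initial learning
rate 1e-4, for 30 epochs, with a stratified 70/30 train/test split.
Results are reported as a 4×4 confusion matrix (rows = ground truth;
class order normal, ethanol, H₂O₂, cryo) with per-class sensitivity,
specificity and accuracy.

## Worked example

```python
import numpy as np
from spermqpi import (
    PhantomParams, CarrierSpec, NoiseModel, SplitSpec,
    generate_phantom, generate_dataset, synthesize, demodulate,
    unwrap_goldstein, subtract_background, calibrate_phase_noise,
    train_classical, confusion_metrics,
)
from spermqpi.classify import features_from_maps
from spermqpi.reconstruct import remove_piston_tilt

# 1. simulate one cell and recover its phase through the full pipeline
truth = generate_phantom(PhantomParams(), seed=1)
igram = synthesize(truth, CarrierSpec(), NoiseModel(regime="none", bit_depth=0), seed=0)
unwrapped, report = unwrap_goldstein(demodulate(igram))
recovered = subtract_background(unwrapped)
err = remove_piston_tilt(recovered.values - truth.values, border=16)[16:-16, 16:-16]
print(f"round-trip RMS error: {1e3 * np.sqrt(np.mean(err**2)):.2f} mrad "
      f"({report.residue_count} residues)")

# 2. empty-field phase sensitivity of the two illumination regimes
psc = calibrate_phase_noise(NoiseModel(regime="psc"), n_trials=10, seed=0)
coh = calibrate_phase_noise(NoiseModel(regime="coherent"), n_trials=10, seed=0)
print(f"spatial phase sensitivity: psc {1e3*psc:.1f} mrad, laser {1e3*coh:.1f} mrad")

# 3. classify 4 condition classes from 11 head features
params = PhantomParams(image_height_px=192, image_width_px=192,
                       pixel_pitch=0.2, tail_length=25.0)
maps = generate_dataset(50, params, effect_size=1.0, seed=31)
X, y = features_from_maps(maps)
_, cm = train_classical(X, y, "svm", SplitSpec(seed=0))
m = confusion_metrics(cm)
print(f"SVM test accuracy: {100*m['overall_accuracy']:.1f}%")
```

This prints:

```
round-trip RMS error: 0.52 mrad (0 residues)
spatial phase sensitivity: psc 18.3 mrad, laser 37.8 mrad
SVM test accuracy: 98.3%
```

The 0.52 mrad round-trip error says the demodulate → unwrap → flatten
chain recovers the synthetic cell — including its ~0.1 rad tail —
essentially exactly. The sensitivity numbers show why a partially
spatially coherent (psc) source matters: its empty-field phase noise
(~20 mrad) is half that of direct laser illumination, which is what
makes the 100 nm tail visible at all. The classifier numbers quantify
how separable the four stress conditions are at the generator's full
effect size.

The same stages are available as a CLI:

```
spermqpi phantom --n-per-class 12 --effect-size 1.0 --seed 3 --out phase/
spermqpi simulate --phase-dir phase/ --regime psc --seed 3 --out igram/
spermqpi reconstruct --in igram/ --out rec/
spermqpi qc --in rec/ --out qc.csv
spermqpi classify --mode features --model svm --in rec/ --seed 0 --out metrics.json
```

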