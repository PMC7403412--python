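"""Synthetic sperm-cell phase phantoms.

A phantom is a thickness model ``t(x, y)`` (µm) of a cell lying on a
reflecting substrate, converted to optical phase by the double-pass
relation

    phi(x, y) = (4 pi / lambda) * dn * t(x, y)

where ``dn`` is the refractive-index contrast between cell and medium.
The anatomy has three compartments: an elliptical head with a smooth
raised-cosine thickness profile, a short midpiece, and a long thin wavy
tail (~100 nm thick, producing tens of mrad of phase).

Four condition classes are modelled.  ``normal`` is the baseline; the
other three apply perturbations whose magnitude scales with
``effect_size`` in [0, 1] (``effect_size = 0`` reproduces the normal
class bit-for-bit):

* ``cryo``   — head phase reduced by up to 30 % plus boundary roughness
  (membrane/ultrastructure damage after freezing);
* ``h2o2``   — tail waviness up to 3× plus increased head phase-texture
  variance (oxidative membrane damage, disrupted tail);
* ``ethanol`` — head eccentricity raised by up to 20 % plus boundary
  roughness (membrane-protein distortion).

These perturbations are quantitative proxies chosen to make the classes
learnable and tunable; they are not biophysically validated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, stats

from .types import CONDITIONS, CLASS_ORDER, PhaseMap

__all__ = [
    "PhantomParams",
    "generate_phantom",
    "apply_condition",
    "generate_dataset",
    "mean_head_phase",
    "head_eccentricity",
    "boundary_roughness",
    "tail_curvature_energy",
    "class_statistic",
]

#: fraction of the head's normalized radius occupied by the edge rolloff;
#: the half-max contour therefore sits at r = 1 - HEAD_EDGE_TAPER/2
HEAD_EDGE_TAPER = 0.4

# perturbation scales at effect_size = 1
_CRYO_PHASE_DROP = 0.30
_H2O2_WAVINESS_GAIN = 2.0  # multiplier becomes 1 + 2 = 3x
_H2O2_TEXTURE_AMP = 0.15
_ETHANOL_ECC_GAIN = 0.20
_ROUGHNESS_AMP = 0.10


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, optics and condition parameters of one phantom.

    Lengths are µm.  Defaults follow WHO-typical sperm dimensions imaged
    at 60× on a 6.5 µm-pixel camera (0.108 µm/px) with a He–Ne source.
    """

    image_height_px: int = 512
    image_width_px: int = 512
    pixel_pitch: float = 0.108
    wavelength: float = 0.6328
    refractive_index_contrast: float = 0.05
    head_axes: tuple[float, float] = (4.5, 3.0)
    head_max_thickness: float = 1.8
    midpiece_length: float = 4.0
    midpiece_width: float = 1.0
    midpiece_thickness: float = 0.6
    tail_length: float = 40.0
    tail_width: float = 0.5
    tail_thickness: float = 0.1
    tail_waviness: float = 1.0
    psf_sigma: float = 0.3
    condition: str = "normal"
    effect_size: float = 0.0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if not 0.0 <= self.effect_size <= 1.0:
            raise ValueError("effect_size must be in [0, 1]")
        for name in (
            "pixel_pitch",
            "wavelength",
            "head_axes",
            "midpiece_length",
            "midpiece_width",
            "tail_length",
            "tail_width",
        ):
            v = getattr(self, name)
            vals = v if isinstance(v, tuple) else (v,)
            if any(x <= 0 for x in vals):
                raise ValueError(f"{name} must be positive")
        for name in ("head_max_thickness", "midpiece_thickness", "tail_thickness"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        field_h = self.image_height_px * self.pixel_pitch
        field_w = self.image_width_px * self.pixel_pitch
        if self.head_axes[0] > field_w or self.head_axes[1] > field_h:
            raise ValueError("head axes do not fit inside the field of view")

    @property
    def phase_per_um(self) -> float:
        """Phase per µm of thickness (reflection: double optical path)."""
        return 4.0 * math.pi * self.refractive_index_contrast / self.wavelength


class GeometryError(ValueError):
    """Cell geometry does not fit the field of view."""


def _roughness_profile(theta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Smooth zero-mean periodic radius modulation, unit std."""
    prof = np.zeros_like(theta)
    for m in range(2, 7):
        a, b = rng.standard_normal(2)
        prof += a * np.cos(m * theta) + b * np.sin(m * theta)
    # 5 harmonics of unit-variance coefficients -> std sqrt(5) in expectation;
    # normalise deterministically by the drawn coefficients' actual norm
    return prof / max(np.std(prof), 1e-12)


def _condition_knobs(condition: str, e: float) -> dict:
    """Translate (condition, effect_size) into generator perturbation knobs."""
    knobs = dict(head_scale=1.0, ecc_gain=0.0, rough=0.0, wav_gain=1.0, texture=0.0)
    if condition == "normal" or e == 0.0:
        return knobs
    if condition == "cryo":
        knobs["head_scale"] = 1.0 - _CRYO_PHASE_DROP * e
        knobs["rough"] = _ROUGHNESS_AMP * e
    elif condition == "h2o2":
        knobs["wav_gain"] = 1.0 + _H2O2_WAVINESS_GAIN * e
        knobs["texture"] = _H2O2_TEXTURE_AMP * e
    elif condition == "ethanol":
        knobs["ecc_gain"] = _ETHANOL_ECC_GAIN * e
        knobs["rough"] = _ROUGHNESS_AMP * e
    else:  # pragma: no cover - guarded by PhantomParams
        raise ValueError(f"unknown condition {condition!r}")
    return knobs


def generate_phantom(
    params: PhantomParams,
    seed: int,
    *,
    center: tuple[float, float] | None = None,
    angle: float = 0.0,
    scale: float = 1.0,
) -> PhaseMap:
    """Render one sperm-cell phase phantom.

    The cell is drawn in a local frame (head centred at ``center``, long
    axis rotated by ``angle``) and converted to phase via the double-pass
    relation.  ``seed`` drives the random micro-structure (tail bend and
    waviness phase, boundary-roughness harmonics, head texture); the same
    random streams are consumed for every condition so that
    ``effect_size = 0`` is bit-identical to the normal class.

    Returns a :class:`PhaseMap` with ``provenance="phantom"`` whose
    ``meta`` records the parameters and pose (used by
    :func:`apply_condition` to regenerate perturbed versions).
    """
    H, W = params.image_height_px, params.image_width_px
    pp = params.pixel_pitch
    if center is None:
        center = (0.35 * W, 0.5 * H)
    cx, cy = center
    if not (0 <= cx < W and 0 <= cy < H):
        raise GeometryError("head center lies outside the field of view")
    a_ax = 0.5 * params.head_axes[0] * scale
    b_ax = 0.5 * params.head_axes[1] * scale
    if 2 * a_ax > W * pp or 2 * b_ax > H * pp:
        raise GeometryError("scaled head does not fit the field of view")

    knobs = _condition_knobs(params.condition, params.effect_size)

    # independent, condition-agnostic random streams
    rng_tail = np.random.default_rng([seed & 0x7FFFFFFF, 11])
    rng_rough = np.random.default_rng([seed & 0x7FFFFFFF, 13])
    rng_tex = np.random.default_rng([seed & 0x7FFFFFFF, 17])

    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    ca, sa = math.cos(angle), math.sin(angle)
    u = ((xx - cx) * ca + (yy - cy) * sa) * pp  # µm along the cell axis
    v = (-(xx - cx) * sa + (yy - cy) * ca) * pp  # µm across

    # ethanol: raise eccentricity by shrinking the minor axis
    ecc0 = math.sqrt(max(0.0, 1.0 - (b_ax / a_ax) ** 2))
    ecc = min(ecc0 * (1.0 + knobs["ecc_gain"]), 0.97)
    b_eff = a_ax * math.sqrt(max(1e-6, 1.0 - ecc * ecc))

    # head: flat-top thickness (paddle shape) with a raised-cosine rolloff
    # over the outer HEAD_EDGE_TAPER of the (roughness-modulated) ellipse
    theta = np.arctan2(v / b_eff, u / a_ax)
    rough = _roughness_profile(theta, rng_rough)
    r = np.hypot(u / a_ax, v / b_eff) / np.maximum(1.0 + knobs["rough"] * rough, 0.5)
    w_edge = HEAD_EDGE_TAPER
    s = np.clip((1.0 - r) / w_edge, 0.0, 1.0)
    head = params.head_max_thickness * scale * 0.5 * (1.0 - np.cos(np.pi * s))
    # smooth multiplicative texture (always drawn so every condition consumes
    # the same random stream; amplitude is 0 except under h2o2)
    tex = ndimage.gaussian_filter(rng_tex.standard_normal((H, W)), 3.0)
    tex /= max(np.std(tex), 1e-12)
    head = head * (1.0 + knobs["texture"] * tex) * knobs["head_scale"]

    # midpiece: cosine cross-profile, raised-cosine longitudinal taper
    u0 = 0.92 * a_ax
    Lm = params.midpiece_length * scale
    wm = params.midpiece_width * scale
    um = (u - u0) / Lm
    # cos^2 across-profile and smoothstep plateau: C1 everywhere, so the
    # phantom stays band-limited enough for sideband demodulation
    across = np.cos(np.pi * np.clip(v / wm, -0.5, 0.5)) ** 2
    edge = np.clip(np.minimum(um, 1.0 - um) / 0.15, 0.0, 1.0)
    taper = edge * edge * (3.0 - 2.0 * edge)
    mid = params.midpiece_thickness * scale * across * taper

    # tail: quadratic bend + sinusoidal waviness, Gaussian cross-section
    bend = rng_tail.uniform(-1.0, 1.0) * 0.002  # µm^-1 curvature scale
    wav_phase = rng_tail.uniform(0.0, 2.0 * np.pi)
    wav_period = rng_tail.uniform(12.0, 18.0)  # µm
    u1 = u0 + Lm
    Lt = params.tail_length * scale
    ut = u - u1
    amp = 1.5 * params.tail_waviness * knobs["wav_gain"]  # µm transverse amplitude
    env = np.clip(ut / 5.0, 0.0, 1.0)  # waviness grows over the first 5 µm
    envelope = env * env * (3 - 2 * env)
    v_center = bend * ut * ut + amp * envelope * np.sin(
        2.0 * np.pi * ut / wav_period + wav_phase
    )
    sig_t = 0.5 * params.tail_width * scale
    # smooth longitudinal envelope: rises over 1.5 µm at the neck, falls
    # over 1.5 µm at the tip (no step edges)
    rise = np.clip(ut / 1.5, 0.0, 1.0)
    fall = np.clip((Lt - ut) / 1.5, 0.0, 1.0)
    longi = (rise * rise * (3 - 2 * rise)) * (fall * fall * (3 - 2 * fall))
    tail = (
        params.tail_thickness
        * scale
        * np.exp(-0.5 * ((v - v_center) / sig_t) ** 2)
        * longi
    )

    thickness = head + mid + tail
    phase = params.phase_per_um * thickness
    if params.psf_sigma > 0:
        phase = ndimage.gaussian_filter(phase, params.psf_sigma / pp)
        if phase.any():
            # clip the PSF's far skirt to keep the background exactly zero;
            # relative threshold preserves exact linearity in thickness
            phase[np.abs(phase) < 1e-9 * np.abs(phase).max()] = 0.0

    meta = {
        "params": params,
        "seed": int(seed),
        "pose": {"center": (float(cx), float(cy)), "angle": float(angle), "scale": float(scale)},
        "label": params.condition,
        "wavelength": params.wavelength,
    }
    return PhaseMap(values=phase, pixel_pitch=pp, provenance="phantom", meta=meta)


def apply_condition(
    base: PhaseMap, condition: str, effect_size: float, seed: int
) -> PhaseMap:
    """Return ``base`` perturbed to the given condition class.

    Perturbations act on the generator parameters, so the base must be a
    phantom-provenance map carrying its generator metadata.  Magnitude is
    monotone in ``effect_size``; ``effect_size = 0`` (or the normal
    condition) returns the base unchanged.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if base.provenance != "phantom" or "params" not in base.meta:
        raise ValueError("apply_condition requires a phantom-provenance phase map")
    if condition == "normal" or effect_size == 0.0:
        out = base.copy()
        out.meta["label"] = condition
        return out
    params: PhantomParams = replace(
        base.meta["params"], condition=condition, effect_size=effect_size
    )
    pose = base.meta["pose"]
    return generate_phantom(
        params, seed, center=pose["center"], angle=pose["angle"], scale=pose["scale"]
    )


def generate_dataset(
    n_per_class: int,
    params: PhantomParams,
    effect_size: float,
    seed: int,
) -> list[PhaseMap]:
    """Generate a labelled 4-class dataset with random pose and size jitter.

    Each cell gets rotation uniform in [0, 2π), a translation keeping the
    head comfortably in-field, and ±10 % isotropic size jitter.  Output is
    ordered class-by-class (``CLASS_ORDER``) and deterministic given
    ``seed``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    H, W = params.image_height_px, params.image_width_px
    maps: list[PhaseMap] = []
    for ci, condition in enumerate(CLASS_ORDER):
        cparams = replace(params, condition=condition, effect_size=effect_size)
        for i in range(n_per_class):
            rng = np.random.default_rng([seed & 0x7FFFFFFF, ci, i])
            angle = rng.uniform(0.0, 2.0 * np.pi)
            scale = 1.0 + rng.uniform(-0.1, 0.1)
            cx = rng.uniform(0.3, 0.7) * W
            cy = rng.uniform(0.3, 0.7) * H
            cell_seed = int(rng.integers(0, 2**31 - 1))
            pm = generate_phantom(
                cparams, cell_seed, center=(cx, cy), angle=angle, scale=scale
            )
            pm.meta["index"] = i
            maps.append(pm)
    return maps


# ---------------------------------------------------------------------------
# summary statistics used to validate the condition perturbations
# ---------------------------------------------------------------------------


def _head_mask(phase: PhaseMap) -> np.ndarray:
    v = phase.values
    pos = v[v > 0]
    if pos.size == 0:
        raise ValueError("empty phase map")
    thr = 0.5 * np.percentile(pos, 99)
    mask = v >= thr
    lbl, n = ndimage.label(mask)
    if n == 0:
        raise ValueError("no head component found")
    sizes = ndimage.sum_labels(np.ones_like(v), lbl, index=np.arange(1, n + 1))
    return lbl == (1 + int(np.argmax(sizes)))


def mean_head_phase(phase: PhaseMap) -> float:
    """Mean phase (rad) over the segmented head; drops under cryo damage."""
    m = _head_mask(phase)
    return float(phase.values[m].mean())


def head_eccentricity(phase: PhaseMap) -> float:
    """Eccentricity of the segmented head region (0 = circle)."""
    from skimage.measure import regionprops

    m = _head_mask(phase)
    props = regionprops(m.astype(int))[0]
    return float(props.eccentricity)


def boundary_roughness(phase: PhaseMap) -> float:
    """Std (px) of the head boundary's radial deviation from a smooth outline.

    The boundary radius r(θ) is fit with harmonics up to order 2 (which
    absorb the ellipse itself); the residual std is the roughness metric.
    """
    m = _head_mask(phase)
    er = ndimage.binary_erosion(m)
    border = m & ~er
    rr, cc = np.nonzero(border)
    if rr.size < 16:
        raise ValueError("head boundary too small")
    r0, c0 = rr.mean(), cc.mean()
    theta = np.arctan2(rr - r0, cc - c0)
    rad = np.hypot(rr - r0, cc - c0)
    A = np.column_stack(
        [np.ones_like(theta)]
        + [f(k * theta) for k in (1, 2) for f in (np.cos, np.sin)]
    )
    coef, *_ = np.linalg.lstsq(A, rad, rcond=None)
    return float(np.std(rad - A @ coef))


def tail_curvature_energy(phase: PhaseMap) -> float:
    """Mean squared transverse deviation (µm²) of the tail centerline.

    Assumes the canonical axis-aligned pose produced by
    :func:`generate_phantom` with ``angle = 0`` (used for generator
    validation, not on arbitrarily posed cells).  The per-column phase
    centroid beyond the head is detrended with a quadratic (absorbing the
    smooth bend); the residual mean square grows with tail waviness.
    """
    v = phase.values
    m = _head_mask(phase)
    cols_head = np.nonzero(m.any(axis=0))[0]
    start = cols_head.max() + 5
    pp = phase.pixel_pitch
    rows = np.arange(v.shape[0])
    xs, ys = [], []
    for c in range(start, v.shape[1]):
        w = v[:, c].clip(min=0.0)
        tot = w.sum()
        if tot < 1e-3:
            continue
        xs.append(c)
        ys.append((w * rows).sum() / tot)
    if len(xs) < 20:
        raise ValueError("tail not found (is the cell axis-aligned?)")
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float) * pp
    coef = np.polyfit(xs, ys, 2)
    resid = ys - np.polyval(coef, xs)
    return float(np.mean(resid**2))


def class_statistic(phase: PhaseMap, condition: str, baseline_head_phase: float | None = None) -> float:
    """Class-separating summary statistic, monotone non-decreasing in effect size.

    cryo → head-phase deficit relative to a normal baseline; h2o2 → tail
    curvature energy; ethanol → head eccentricity.
    """
    if condition == "cryo":
        base = 0.0 if baseline_head_phase is None else baseline_head_phase
        return base - mean_head_phase(phase)
    if condition == "h2o2":
        return tail_curvature_energy(phase)
    if condition == "ethanol":
        return head_eccentricity(phase)
    raise ValueError(f"no separating statistic for condition {condition!r}")
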