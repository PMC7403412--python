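"""Image-retention quality control and phase-sensitivity estimation.

Three retention criteria are applied to every reconstructed phase map:
correct phase unwrapping, successful background subtraction, and a
single cell in the field of view.  An image is retained only when all
three hold.  The single-cell test binarizes the phase image and counts
8-connected components after morphological cleanup (a closing joins the
faint tail to the head so one cell is not fragmented into many
components).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .reconstruct import remove_piston_tilt
from .types import PhaseMap, QCReport, UnwrapReport

__all__ = [
    "binarize_phase",
    "cell_silhouette",
    "check_unwrap",
    "check_background",
    "select_single_cell",
    "estimate_sensitivity",
    "run_qc",
]

DEFAULT_RESIDUE_DENSITY_MAX = 1.0  # residues per kilopixel
DEFAULT_JUMP_FRACTION_MAX = 1e-3  # fraction of neighbour jumps > pi
DEFAULT_BACKGROUND_RMS_MAX = 0.05  # rad
# Otsu on the positive-phase histogram keeps the bright head core
# (~300-500 px for a WHO-typical head at 0.108 µm/px), so the white-pixel
# floor sits below that.
DEFAULT_MIN_PIXELS = 200
FALLBACK_THRESHOLD = 0.1  # rad, when Otsu is not applicable
MIN_COMPONENT_PX = 50
CLOSING_RADIUS = 3
SILHOUETTE_THRESHOLD = 0.05  # rad; above background noise, below tail phase


def cell_silhouette(values: np.ndarray, threshold: float = SILHOUETTE_THRESHOLD,
                    dilate: int = 8) -> np.ndarray:
    """Whole-cell silhouette mask (head, midpiece and faint tail).

    A fixed low threshold — above the background noise floor but below
    the ~0.1 rad tail phase — followed by a closing and a dilation, so
    background statistics and fits never lean on cell or cell-edge
    pixels.  (Otsu, used for the single-cell count, deliberately favours
    the bright head and is unsuitable here.)
    """
    mask = values > threshold
    mask = ndimage.binary_closing(mask, structure=np.ones((5, 5)))
    if dilate:
        mask = ndimage.binary_dilation(mask, iterations=dilate)
    return mask


def binarize_phase(values: np.ndarray, threshold: float | str = "otsu") -> np.ndarray:
    """Binarize a phase image with cleanup suitable for component counting."""
    if threshold == "otsu":
        pos = values[values > 0]
        if pos.size < 2 or float(pos.max() - pos.min()) < 1e-6:
            thr = FALLBACK_THRESHOLD
        else:
            thr = float(threshold_otsu(pos))
    else:
        thr = float(threshold)
        if thr <= 0:
            raise ValueError("binarize threshold must be positive")
    mask = values > thr
    r = CLOSING_RADIUS
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    selem = xx * xx + yy * yy <= r * r
    mask = ndimage.binary_closing(mask, structure=selem)
    # drop components below the minimum size (8-connected)
    lbl, n = ndimage.label(mask, structure=np.ones((3, 3)))
    if n:
        sizes = np.bincount(lbl.ravel())
        small = np.nonzero(sizes < MIN_COMPONENT_PX)[0]
        mask &= ~np.isin(lbl, small[small > 0])
    return mask


def residue_density(report: UnwrapReport, shape: tuple[int, int]) -> float:
    """Residues per kilopixel."""
    return 1000.0 * report.residue_count / (shape[0] * shape[1])


def check_unwrap(
    report: UnwrapReport,
    phase: PhaseMap,
    residue_density_max: float = DEFAULT_RESIDUE_DENSITY_MAX,
    jump_fraction_max: float = DEFAULT_JUMP_FRACTION_MAX,
) -> bool:
    """Was the unwrapping trustworthy?

    True iff the residue density is at most ``residue_density_max`` per
    kilopixel and at most ``jump_fraction_max`` of neighbouring-pixel
    differences exceed π in magnitude.
    """
    dens = residue_density(report, phase.shape)
    v = phase.values
    jumps = np.concatenate(
        [np.abs(np.diff(v, axis=0)).ravel(), np.abs(np.diff(v, axis=1)).ravel()]
    )
    frac = float(np.mean(jumps > np.pi)) if jumps.size else 0.0
    return dens <= residue_density_max and frac <= jump_fraction_max


def check_background(
    phase: PhaseMap,
    cell_mask: np.ndarray,
    rms_max: float = DEFAULT_BACKGROUND_RMS_MAX,
) -> bool:
    """True iff the RMS of the phase outside the cell mask is ≤ ``rms_max``."""
    bg = phase.values[~cell_mask]
    if bg.size == 0:
        raise ValueError("empty background region")
    return float(np.sqrt(np.mean(bg**2))) <= rms_max


def select_single_cell(
    phase: PhaseMap,
    binarize_threshold: float | str = "otsu",
    min_pixels: int = DEFAULT_MIN_PIXELS,
    max_pixels: int | None = None,
) -> tuple[bool, int, int]:
    """Single-cell criterion: one component, plausible white-pixel count.

    Returns ``(ok, white_pixel_count, component_count)``.
    """
    if max_pixels is None:
        max_pixels = int(0.3 * phase.values.size)
    if min_pixels >= max_pixels:
        raise ValueError("min_pixels must be < max_pixels")
    mask = binarize_phase(phase.values, binarize_threshold)
    _, n_comp = ndimage.label(mask, structure=np.ones((3, 3)))  # 8-connected
    white = int(mask.sum())
    ok = n_comp == 1 and min_pixels <= white <= max_pixels
    return ok, white, n_comp


def estimate_sensitivity(phase_stack: list[PhaseMap], border: int = 16) -> float:
    """Spatial phase sensitivity of the instrument (radians).

    Mean over the stack of the per-map spatial standard deviation after
    piston/tilt removal, computed on the interior (a ``border``-pixel rim
    is excluded to avoid FFT edge effects).
    """
    if len(phase_stack) == 0:
        raise ValueError("empty phase stack")
    stds = []
    for pm in phase_stack:
        flat = remove_piston_tilt(pm.values, border=border)
        inner = flat[border:-border or None, border:-border or None]
        stds.append(float(np.std(inner)))
    return float(np.mean(stds))


def run_qc(
    phases: list[PhaseMap],
    reports: list[UnwrapReport] | None = None,
    residue_density_max: float = DEFAULT_RESIDUE_DENSITY_MAX,
    background_rms_max: float = DEFAULT_BACKGROUND_RMS_MAX,
    min_pixels: int = DEFAULT_MIN_PIXELS,
    max_pixels: int | None = None,
) -> tuple[list[PhaseMap], pd.DataFrame]:
    """Apply the three retention criteria to a dataset.

    ``reports`` carries per-image unwrap diagnostics when the maps came
    through the reconstruction path; phantom ground-truth maps (which
    never passed through unwrapping) get a zero-residue report.

    Returns the retained subset and a per-image QC table.
    """
    rows = []
    retained: list[PhaseMap] = []
    for i, pm in enumerate(phases):
        rep = reports[i] if reports is not None else UnwrapReport(0, 0, 0.0, (0, 0))
        unwrap_ok = check_unwrap(rep, pm, residue_density_max=residue_density_max)
        bg = pm.values[~cell_silhouette(pm.values)]
        bg_rms = float(np.sqrt(np.mean(bg**2))) if bg.size else np.inf
        background_ok = bg.size > 0 and bg_rms <= background_rms_max
        single_ok, white, n_comp = select_single_cell(
            pm, min_pixels=min_pixels, max_pixels=max_pixels
        )
        report = QCReport(
            unwrap_ok=unwrap_ok,
            background_ok=background_ok,
            single_cell_ok=single_ok,
            white_pixel_count=white,
            component_count=n_comp,
            residue_density=residue_density(rep, pm.shape),
            background_rms=bg_rms,
        )
        rows.append(
            {
                "index": i,
                "label": pm.meta.get("label", ""),
                "unwrap_ok": report.unwrap_ok,
                "background_ok": report.background_ok,
                "single_cell_ok": report.single_cell_ok,
                "retained": report.retained,
                "white_pixel_count": report.white_pixel_count,
                "component_count": report.component_count,
                "residue_density": report.residue_density,
                "background_rms": report.background_rms,
            }
        )
        if report.retained:
            retained.append(pm)
    return retained, pd.DataFrame(rows)
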