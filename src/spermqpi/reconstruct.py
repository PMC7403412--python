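"""Fourier-transform phase recovery from off-axis interferograms.

The single-shot demodulation path: FFT the interferogram, isolate one
interference sideband with a soft mask, shift its center to DC, inverse
transform to the complex analytic signal ``c(x, y) = b exp(i phi)`` and
take ``phi = arctan2(Im c, Re c)``, giving the wrapped phase in (−π, π].
A polynomial (or reference-frame) background subtraction then flattens
residual tilt and low-order aberrations.

Coordinates are row-major with the origin top-left; ``x`` is the column
index and spatial frequencies are in cycles/pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import CarrierSpec, Interferogram, PhaseMap, WrappedPhase

__all__ = [
    "SidebandFilter",
    "locate_carrier",
    "demodulate",
    "subtract_background",
    "remove_piston_tilt",
]

#: default sideband filter radius as a fraction of the carrier magnitude
DEFAULT_RADIUS_FRAC = 0.45
#: DC exclusion radius (cycles/px) used when locating the carrier peak
DC_EXCLUSION = 0.05


@dataclass
class SidebandFilter:
    """Spectral mask isolating one interference sideband.

    ``gaussian_soft`` is a flat passband out to 0.7·radius with a Gaussian
    skirt (sigma = 0.1·radius) beyond it — soft enough not to ring at the
    tail's low phase amplitude, flat enough not to attenuate the head's
    in-band content.  ``hard`` is a binary disk.
    """

    center: tuple[float, float]
    radius: float
    profile: str = "gaussian_soft"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("filter radius must be positive")
        if self.profile not in ("hard", "gaussian_soft"):
            raise ValueError(f"unknown filter profile {self.profile!r}")

    def weights(self, shape: tuple[int, int]) -> np.ndarray:
        fy = np.fft.fftfreq(shape[0])
        fx = np.fft.fftfreq(shape[1])
        FX, FY = np.meshgrid(fx, fy)
        # wrapped frequency distance to the filter center
        dx = (FX - self.center[0] + 0.5) % 1.0 - 0.5
        dy = (FY - self.center[1] + 0.5) % 1.0 - 0.5
        d = np.hypot(dx, dy)
        if self.profile == "hard":
            W = (d <= self.radius).astype(float)
        else:
            core = 0.7 * self.radius
            sig = 0.1 * self.radius
            W = np.where(d <= core, 1.0, np.exp(-0.5 * ((d - core) / sig) ** 2))
            W[W < 1e-8] = 0.0
        if W[0, 0] != 0.0:
            raise ValueError("sideband filter support overlaps the DC bin")
        return W


def locate_carrier(igram: Interferogram) -> tuple[float, float]:
    """Locate the spatial carrier from the magnitude spectrum.

    Returns the peak outside a DC exclusion disk, reported in the
    half-plane ``fy > 0`` (or ``fy == 0, fx > 0``) since a real image's
    spectrum is conjugate-symmetric.

    Raises
    ------
    ValueError
        "no carrier detected" when no sideband peak rises above the DC
        floor (e.g. a constant image).
    """
    I = igram.intensity
    if min(I.shape) < 16:
        raise ValueError("image too small to locate a carrier")
    F = np.abs(np.fft.fft2(I - I.mean()))
    fy = np.fft.fftfreq(I.shape[0])
    fx = np.fft.fftfreq(I.shape[1])
    FX, FY = np.meshgrid(fx, fy)
    R = np.hypot(FX, FY)
    cand = F.copy()
    cand[R < DC_EXCLUSION] = 0.0
    peak = cand.max()
    dc_mag = np.abs(np.fft.fft2(I))[0, 0]
    if peak <= 1e-3 * max(dc_mag, 1.0):
        raise ValueError("no carrier detected")
    iy, ix = np.unravel_index(int(np.argmax(cand)), cand.shape)
    cfx, cfy = float(FX[iy, ix]), float(FY[iy, ix])
    if cfy < 0 or (cfy == 0 and cfx < 0):
        cfx, cfy = -cfx, -cfy
    return (cfx, cfy)


def demodulate(
    igram: Interferogram, filt: SidebandFilter | None = None
) -> WrappedPhase:
    """Recover the wrapped phase from one sideband of ``igram``.

    If no filter is given, the carrier is located automatically and a
    ``gaussian_soft`` filter of radius ``0.45 × |carrier|`` is used.  The
    returned :class:`WrappedPhase` carries the fringe modulation ``|c|``
    and a provenance dict (carrier estimate, filter, warnings) in its
    ``meta``.
    """
    if filt is None:
        cfx, cfy = locate_carrier(igram)
        filt = SidebandFilter(
            center=(cfx, cfy), radius=DEFAULT_RADIUS_FRAC * float(np.hypot(cfx, cfy))
        )
    warnings: list[str] = []
    cmag = float(np.hypot(*filt.center))
    if filt.radius > 0.5 * cmag:
        warnings.append(
            f"filter radius {filt.radius:.3f} exceeds half the carrier distance {cmag:.3f}"
        )
    I = igram.intensity
    W = filt.weights(I.shape)  # raises if the support touches DC
    F = np.fft.fft2(I)
    # shift the sideband center to DC: integer-bin roll + residual ramp
    ky = int(np.rint(filt.center[1] * I.shape[0]))
    kx = int(np.rint(filt.center[0] * I.shape[1]))
    Fs = np.roll(F * W, (-ky, -kx), axis=(0, 1))
    c = np.fft.ifft2(Fs)
    res_fy = filt.center[1] - ky / I.shape[0]
    res_fx = filt.center[0] - kx / I.shape[1]
    if res_fx != 0.0 or res_fy != 0.0:
        yy, xx = np.mgrid[0 : I.shape[0], 0 : I.shape[1]].astype(float)
        c = c * np.exp(-2j * np.pi * (res_fx * xx + res_fy * yy))
    phi = np.angle(c)
    phi[phi == -np.pi] = np.pi  # half-open wrap interval (−π, π]
    return WrappedPhase(
        values=phi,
        pixel_pitch=igram.pixel_pitch,
        meta={
            "modulation": np.abs(c),
            "carrier": filt.center,
            "filter": {"radius": filt.radius, "profile": filt.profile},
            "warnings": warnings,
        },
    )


def _poly_design(shape: tuple[int, int], order: int) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    X = 2.0 * xx / max(shape[1] - 1, 1) - 1.0
    Y = 2.0 * yy / max(shape[0] - 1, 1) - 1.0
    cols = [
        (X**i * Y**j).ravel()
        for total in range(order + 1)
        for i in range(total + 1)
        for j in [total - i]
    ]
    return np.column_stack(cols)


def remove_piston_tilt(values: np.ndarray, border: int = 0) -> np.ndarray:
    """Subtract the best-fit plane (piston + tilt).

    The plane is fit on the interior (excluding ``border`` pixels on each
    side) but subtracted over the full frame.
    """
    A = _poly_design(values.shape, 1)
    mask = np.zeros(values.shape, bool)
    mask[border : values.shape[0] - border or None, border : values.shape[1] - border or None] = True
    coef, *_ = np.linalg.lstsq(A[mask.ravel()], values[mask].ravel(), rcond=None)
    return values - (A @ coef).reshape(values.shape)


def subtract_background(
    phase: PhaseMap,
    mode: str = "polynomial",
    reference: PhaseMap | None = None,
    poly_order: int = 2,
    cell_mask: np.ndarray | None = None,
) -> PhaseMap:
    """Flatten the background of a reconstructed phase map.

    ``polynomial`` fits a 2-D polynomial of total degree ``poly_order``
    to the cell-free pixels (mask derived automatically from the phase
    image when not supplied) and subtracts it everywhere.
    ``reference_frame`` subtracts a cell-free reconstructed field
    pixel-wise.
    """
    if mode == "reference_frame":
        if reference is None:
            raise ValueError("reference_frame mode requires a reference map")
        if reference.values.shape != phase.values.shape:
            raise ValueError("reference shape mismatch")
        out = phase.values - reference.values
    elif mode == "polynomial":
        if cell_mask is None:
            from .qc import cell_silhouette

            cell_mask = cell_silhouette(phase.values)
        bg = ~cell_mask
        A = _poly_design(phase.values.shape, poly_order)
        ncoef = A.shape[1]
        if bg.sum() < 10 * ncoef:
            raise ValueError(
                f"underdetermined background fit: {int(bg.sum())} background pixels "
                f"for {ncoef} coefficients (need >= {10 * ncoef})"
            )
        coef, *_ = np.linalg.lstsq(A[bg.ravel()], phase.values[bg], rcond=None)
        out = phase.values - (A @ coef).reshape(phase.values.shape)
    else:
        raise ValueError(f"unknown background mode {mode!r}")
    meta = dict(phase.meta)
    meta["background"] = {"mode": mode, "poly_order": poly_order if mode == "polynomial" else None}
    return PhaseMap(values=out, pixel_pitch=phase.pixel_pitch, provenance="reconstructed", meta=meta)
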