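"""Core container types shared across the pipeline.

The central quantity is the :class:`PhaseMap` — a 2-D array of optical phase
delays in radians with physical pixel-pitch metadata.  Interferograms carry
their spatial-carrier and noise-regime metadata so that downstream
demodulation can validate its assumptions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: Fixed class order used everywhere a per-class array or confusion matrix
#: is produced.
CLASS_ORDER = ("normal", "ethanol", "h2o2", "cryo")

CONDITIONS = frozenset(CLASS_ORDER)


@dataclass
class PhaseMap:
    """2-D optical phase map.

    Parameters
    ----------
    values : ndarray
        Phase in radians, finite everywhere.
    pixel_pitch : float
        Object-plane sampling in µm/pixel.
    provenance : str
        Either ``"phantom"`` (synthetic ground truth) or ``"reconstructed"``.
    meta : dict
        Free-form metadata (wavelength, label, generator parameters, ...).
    """

    values: np.ndarray
    pixel_pitch: float
    provenance: str = "phantom"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("phase map must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("phase map contains non-finite values")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if self.provenance not in ("phantom", "reconstructed"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "PhaseMap":
        return replace(self, values=self.values.copy(), meta=dict(self.meta))


@dataclass
class WrappedPhase:
    """Phase known modulo 2π, every value strictly in (−π, π]."""

    values: np.ndarray
    pixel_pitch: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("wrapped phase must be 2-D")
        v = self.values
        if v.size and (v.min() <= -np.pi or v.max() > np.pi):
            raise ValueError("wrapped phase must lie in (-pi, pi]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class CarrierSpec:
    """Spatial carrier frequencies in cycles/pixel.

    The carrier must sit strictly between DC and Nyquist so the two
    interference sidebands separate from the background term.
    """

    fx: float = 0.25
    fy: float = 0.25

    def __post_init__(self) -> None:
        m = self.magnitude
        if not 0.0 < m < 0.5:
            raise ValueError(
                f"carrier magnitude {m:.4f} must lie strictly in (0, 0.5) cycles/px"
            )

    @property
    def magnitude(self) -> float:
        return float(np.hypot(self.fx, self.fy))


@dataclass(frozen=True)
class NoiseModel:
    """Noise regime of the simulated interferometer.

    ``psc`` emulates the partially spatially coherent source: a smooth
    correlated background phase field calibrated to a target empty-field
    phase standard deviation (default 20 mrad).  ``coherent`` adds
    speckle-like uncorrelated phase noise and one parasitic fringe on top,
    reproducing the lower spatial phase sensitivity of direct laser
    illumination.  ``none`` is the ideal noise-free instrument.
    """

    regime: str = "psc"
    background_dc: float = 600.0
    modulation: float = 400.0
    dc_nonuniformity: float = 0.1
    phase_noise_std: float = 0.020
    speckle_amplitude: float = 0.08
    parasitic_fringe_amplitude: float = 0.03
    shot_noise: bool = False
    bit_depth: int = 16  # 0 disables camera quantization (ideal detector)

    def __post_init__(self) -> None:
        if self.regime not in ("psc", "coherent", "none"):
            raise ValueError(f"unknown noise regime {self.regime!r}")
        if not (self.background_dc > 0 and 0 <= self.modulation < self.background_dc):
            raise ValueError("require background_dc > modulation >= 0")
        if self.phase_noise_std < 0:
            raise ValueError("phase_noise_std must be >= 0")
        if self.bit_depth < 0:
            raise ValueError("bit_depth must be >= 0")


@dataclass
class Interferogram:
    """Simulated camera frame of an off-axis interferogram."""

    intensity: np.ndarray
    carrier: CarrierSpec
    noise: NoiseModel
    pixel_pitch: float

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("interferogram must be 2-D")
        if self.intensity.size and self.intensity.min() < 0:
            raise ValueError("interferogram intensity must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape


@dataclass
class ResidueMap:
    """Charged points (±1) on the dual lattice of a wrapped-phase array.

    ``positions[k] = (row, col)`` indexes the top-left pixel of the 2×2 loop
    carrying charge ``charges[k]``; zero-charge loops are omitted.
    """

    positions: np.ndarray  # (n, 2) int
    charges: np.ndarray  # (n,) int, each ±1
    shape: tuple[int, int]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int).reshape(-1, 2)
        self.charges = np.asarray(self.charges, dtype=int).reshape(-1)
        if len(self.positions) != len(self.charges):
            raise ValueError("positions and charges length mismatch")
        if self.charges.size and not np.all(np.isin(self.charges, (-1, 1))):
            raise ValueError("residue charges must be ±1")

    def __len__(self) -> int:
        return len(self.charges)

    @property
    def total_charge(self) -> int:
        return int(self.charges.sum())


@dataclass
class CutMask:
    """Branch-cut barrier pixels plus the individual cut segments."""

    mask: np.ndarray  # bool, image shape
    segments: list  # [((r0, c0), (r1, c1)), ...]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def cut_length(self) -> int:
        return int(self.mask.sum())


@dataclass
class UnwrapReport:
    """Diagnostics from Goldstein unwrapping."""

    residue_count: int
    cut_length: int
    low_confidence_fraction: float
    seed_pixel: tuple[int, int]

    @property
    def residue_density(self) -> float:
        """Residues per kilopixel; requires ``n_pixels`` set via report table."""
        raise AttributeError("use qc.residue_density(report, shape)")


@dataclass(frozen=True)
class SplitSpec:
    """Stratified train/test split specification (70/30 by default)."""

    train_fraction: float = 0.7
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")

    def test_count(self, n_class: int) -> int:
        # round-half-up: 0.3 * 2400 -> 720
        return int(np.floor((1.0 - self.train_fraction) * n_class + 0.5))


@dataclass(frozen=True)
class TrainConfig:
    """CNN training protocol: SGD with momentum, lr 1e-4, 30 epochs."""

    initial_learning_rate: float = 1e-4
    max_epochs: int = 30
    momentum: float = 0.9
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass
class ConfusionMatrix:
    """4×4 confusion matrix; rows are ground truth, columns predictions."""

    counts: np.ndarray
    class_names: tuple = CLASS_ORDER

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        n = len(self.class_names)
        if self.counts.shape != (n, n):
            raise ValueError(f"confusion matrix must be {n}x{n}")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix entries must be >= 0")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass
class QCReport:
    """Per-image quality-control outcome.

    ``retained`` is by construction the AND of the three criterion flags.
    """

    unwrap_ok: bool
    background_ok: bool
    single_cell_ok: bool
    white_pixel_count: int
    component_count: int
    residue_density: float
    background_rms: float

    @property
    def retained(self) -> bool:
        return self.unwrap_ok and self.background_ok and self.single_cell_ok
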