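"""Disk formats: float32 TIFF phase maps and 16-bit TIFF interferograms,
each with a JSON sidecar carrying physical metadata."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import tifffile

from .types import CarrierSpec, Interferogram, NoiseModel, PhaseMap


def _params_hash(params) -> str:
    payload = json.dumps(dataclasses.asdict(params), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def save_phase(pm: PhaseMap, path: str | Path) -> Path:
    path = Path(path).with_suffix(".tif")
    tifffile.imwrite(path, pm.values.astype(np.float32))
    sidecar = {
        "pixel_pitch": pm.pixel_pitch,
        "provenance": pm.provenance,
        "wavelength": pm.meta.get("wavelength"),
        "label": pm.meta.get("label"),
        "seed": pm.meta.get("seed"),
    }
    if "params" in pm.meta:
        sidecar["params_hash"] = _params_hash(pm.meta["params"])
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def load_phase(path: str | Path) -> PhaseMap:
    path = Path(path)
    values = tifffile.imread(path).astype(float)
    meta = {}
    sidecar = path.with_suffix(".json")
    pixel_pitch = 1.0
    provenance = "reconstructed"
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
        pixel_pitch = info.get("pixel_pitch") or 1.0
        provenance = info.get("provenance") or "reconstructed"
        meta = {k: info.get(k) for k in ("wavelength", "label", "seed") if info.get(k) is not None}
    return PhaseMap(values=values, pixel_pitch=pixel_pitch, provenance=provenance, meta=meta)


def save_interferogram(igram: Interferogram, path: str | Path) -> Path:
    path = Path(path).with_suffix(".tif")
    tifffile.imwrite(path, igram.intensity.astype(np.uint16))
    sidecar = {
        "pixel_pitch": igram.pixel_pitch,
        "carrier": {"fx": igram.carrier.fx, "fy": igram.carrier.fy},
        "noise": dataclasses.asdict(igram.noise),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def load_interferogram(path: str | Path) -> Interferogram:
    path = Path(path)
    intensity = tifffile.imread(path).astype(float)
    sidecar = path.with_suffix(".json")
    carrier, noise, pp = CarrierSpec(), NoiseModel(), 1.0
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
        pp = info.get("pixel_pitch") or 1.0
        c = info.get("carrier") or {}
        if c:
            carrier = CarrierSpec(fx=c["fx"], fy=c["fy"])
        n = info.get("noise")
        if n:
            noise = NoiseModel(**n)
    return Interferogram(intensity=intensity, carrier=carrier, noise=noise, pixel_pitch=pp)
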