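"""Deterministic synthetic structures and density maps.

Everything here is generated from an explicit seed — no global random
state, no external data files — so the whole test surface (and the CLI
examples) runs self-contained.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import elements
from .core import Structure
from .io import DensityMap

#: helical geometry parameters: rise per residue (Å) and twist per residue (deg)
HELIX_RISE = 1.5
HELIX_TWIST = 100.0
HELIX_RADIUS = 2.3

#: straight-geometry spacing along z (Å)
STRAIGHT_STEP = 3.8

GEOMETRIES = ("helix", "straight", "random-coil")


@dataclasses.dataclass(frozen=True)
class ToySpec:
    """Recipe for a synthetic polymer."""

    n_residues: int
    geometry: str = "helix"
    seed: int = 0
    atom_pattern: tuple[str, ...] = ("CA",)

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        if self.geometry not in GEOMETRIES:
            raise ValueError(
                f"geometry must be one of {GEOMETRIES}, got {self.geometry!r}"
            )
        if not self.atom_pattern:
            raise ValueError("atom_pattern must name at least one atom")


def make_toy_polymer(spec: ToySpec) -> Structure:
    """Generate a deterministic toy polymer.

    Residue backbone positions follow the requested geometry (helix:
    1.5 Å rise, 100° twist about z; straight: collinear along z;
    random-coil: seeded random walk).  Each residue carries the atoms of
    ``atom_pattern``, offset deterministically around the backbone site.
    """
    n = spec.n_residues
    if spec.geometry == "straight":
        backbone = np.column_stack([
            np.zeros(n), np.zeros(n), STRAIGHT_STEP * np.arange(n)])
    elif spec.geometry == "helix":
        i = np.arange(n)
        theta = np.deg2rad(HELIX_TWIST) * i
        backbone = np.column_stack([
            HELIX_RADIUS * np.cos(theta),
            HELIX_RADIUS * np.sin(theta),
            HELIX_RISE * i,
        ])
    else:  # random-coil
        rng = np.random.default_rng(spec.seed)
        steps = rng.normal(size=(n - 1, 3)) if n > 1 else np.zeros((0, 3))
        norms = np.linalg.norm(steps, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        steps = steps / norms * STRAIGHT_STEP
        backbone = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])

    n_per = len(spec.atom_pattern)
    # fixed intra-residue offsets, small and deterministic
    offsets = 0.5 * np.column_stack([
        np.cos(2 * np.pi * np.arange(n_per) / max(n_per, 1)),
        np.sin(2 * np.pi * np.arange(n_per) / max(n_per, 1)),
        np.zeros(n_per),
    ]) if n_per > 1 else np.zeros((1, 3))

    coords = (backbone[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
    names = list(spec.atom_pattern) * n
    resids = np.repeat(np.arange(1, n + 1), n_per)
    elems = [elements.guess_element(a) for a in names]
    meta = pd.DataFrame({
        "atom_name": names,
        "residue_name": "ALA",
        "residue_id": resids,
        "chain_id": "A",
        "element": elems,
    })
    return Structure(coords[None, :, :], meta)


def make_gaussian_blob_map(
    center,
    sigma: float,
    amplitude: float = 1.0,
    voxel: float = 1.0,
    extent: float = 10.0,
) -> DensityMap:
    """Analytic isotropic Gaussian evaluated at voxel centers.

    Useful property: the isovalue enclosing a target volume ``V`` is
    ``amplitude * exp(-R^2 / (2 sigma^2))`` with ``R = (3V / 4pi)^(1/3)``,
    which makes exact inverse problems testable.
    """
    if sigma <= 0 or voxel <= 0 or extent <= 0:
        raise ValueError("sigma, voxel and extent must be > 0")
    center = np.asarray(center, dtype=float).reshape(3)
    n = 2 * int(np.floor(extent / voxel)) + 1  # symmetric about the center
    axes = [center[d] + voxel * (np.arange(n) - n // 2) for d in range(3)]
    gx = np.exp(-((axes[0] - center[0]) ** 2) / (2 * sigma * sigma))
    gy = np.exp(-((axes[1] - center[1]) ** 2) / (2 * sigma * sigma))
    gz = np.exp(-((axes[2] - center[2]) ** 2) / (2 * sigma * sigma))
    values = amplitude * gx[:, None, None] * gy[None, :, None] * gz[None, None, :]
    origin = np.array([axes[0][0], axes[1][0], axes[2][0]])
    return DensityMap(origin=origin, delta=np.full(3, float(voxel)), values=values)


def blob_isovalue_for_volume(volume: float, sigma: float, amplitude: float = 1.0) -> float:
    """Closed-form isovalue of a Gaussian blob enclosing the given volume."""
    radius = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    return float(amplitude * np.exp(-radius * radius / (2.0 * sigma * sigma)))
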