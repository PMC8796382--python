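"""Symmetric multimer construction on polyhedral scaffolds, cyclic
multimers, and super-coarse-grained sphere/ellipsoid generators.

Polyhedra act as deformable scaffolds: scale the scaffold, and subunits
follow its vertices.  Each vertex carries a deterministic local frame —
z-axis pointing from the vertex toward the centroid (inward), x-axis
toward the lowest-index neighbouring vertex projected orthogonally, y
completing a right-handed frame.  Subunit orientations are intrinsic
z-y-z Euler angles in degrees, applied about the subunit centroid.
"""
from __future__ import annotations

import dataclasses
import itertools
import logging
import string

import numpy as np
import pandas as pd

from .core import (
    RigidTransform,
    Structure,
    centroid,
    euler_zyz,
    rotation_about_axis,
)
from .errors import SizeMismatchError

logger = logging.getLogger(__name__)

_PHI = (1.0 + np.sqrt(5.0)) / 2.0

# unit-scale vertex sets; edge length before normalization noted inline
_RAW_VERTICES = {
    "tetrahedron": (
        np.array([
            [1.0, 1.0, 1.0],
            [1.0, -1.0, -1.0],
            [-1.0, 1.0, -1.0],
            [-1.0, -1.0, 1.0],
        ]),
        2.0 * np.sqrt(2.0),
    ),
    "cube": (
        np.array(list(itertools.product([-1.0, 1.0], repeat=3))),
        2.0,
    ),
    "octahedron": (
        np.array([
            [1.0, 0.0, 0.0], [-1.0, 0.0, 0.0],
            [0.0, 1.0, 0.0], [0.0, -1.0, 0.0],
            [0.0, 0.0, 1.0], [0.0, 0.0, -1.0],
        ]),
        np.sqrt(2.0),
    ),
    "icosahedron": (
        np.array([
            [0.0, s1, s2 * _PHI]
            for s1 in (-1.0, 1.0) for s2 in (-1.0, 1.0)
        ] + [
            [s1, s2 * _PHI, 0.0]
            for s1 in (-1.0, 1.0) for s2 in (-1.0, 1.0)
        ] + [
            [s2 * _PHI, 0.0, s1]
            for s1 in (-1.0, 1.0) for s2 in (-1.0, 1.0)
        ]),
        2.0,
    ),
    "dodecahedron": (
        np.array(list(itertools.product([-1.0, 1.0], repeat=3)) + [
            [0.0, s1 / _PHI, s2 * _PHI]
            for s1 in (-1.0, 1.0) for s2 in (-1.0, 1.0)
        ] + [
            [s1 / _PHI, s2 * _PHI, 0.0]
            for s1 in (-1.0, 1.0) for s2 in (-1.0, 1.0)
        ] + [
            [s2 * _PHI, 0.0, s1 / _PHI]
            for s1 in (-1.0, 1.0) for s2 in (-1.0, 1.0)
        ]),
        2.0 / _PHI,
    ),
}

VERTEX_COUNTS = {
    "tetrahedron": 4,
    "cube": 8,
    "octahedron": 6,
    "dodecahedron": 20,
    "icosahedron": 12,
}


@dataclasses.dataclass
class Polyhedron:
    """A regular polyhedron used as a deformable assembly scaffold."""

    kind: str
    edge_length: float
    vertices: np.ndarray
    edges: list[tuple[int, int]]

    def neighbours(self, vertex: int) -> list[int]:
        out = sorted(
            {j for i, j in self.edges if i == vertex}
            | {i for i, j in self.edges if j == vertex}
        )
        return out

    def vertex_frame(self, vertex: int) -> np.ndarray:
        """Local frame at a vertex as a rotation matrix (columns x, y, z).

        z points from the vertex toward the scaffold centroid (inward); x
        points toward the lowest-index neighbouring vertex, projected
        orthogonal to z; y completes a right-handed frame.
        """
        v = self.vertices[vertex]
        z = -v
        nz = np.linalg.norm(z)
        if nz < 1e-12:
            z = np.array([0.0, 0.0, 1.0])
        else:
            z = z / nz
        nb = self.neighbours(vertex)[0]
        d = self.vertices[nb] - v
        x = d - np.dot(d, z) * z
        nx = np.linalg.norm(x)
        if nx < 1e-12:  # degenerate: neighbour along z; pick any perpendicular
            x = np.array([1.0, 0.0, 0.0])
            x = x - np.dot(x, z) * z
            nx = np.linalg.norm(x)
        x = x / nx
        y = np.cross(z, x)
        return np.column_stack([x, y, z])


def make_polyhedron(kind: str, edge_length: float) -> Polyhedron:
    """Build a regular polyhedron centered at the origin with the given edge."""
    if kind not in _RAW_VERTICES:
        raise ValueError(
            f"unknown polyhedron kind {kind!r}; choose from "
            f"{sorted(_RAW_VERTICES)}"
        )
    if edge_length <= 0:
        raise ValueError("edge_length must be > 0")
    raw, raw_edge = _RAW_VERTICES[kind]
    vertices = raw * (edge_length / raw_edge)
    vertices = vertices - vertices.mean(axis=0)
    # edges are the minimal pairwise distances
    n = len(vertices)
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if abs(np.linalg.norm(vertices[i] - vertices[j]) - edge_length) < 1e-9 * max(1.0, edge_length):
                edges.append((i, j))
    return Polyhedron(kind=kind, edge_length=float(edge_length),
                      vertices=vertices, edges=edges)


def scale_scaffold(p: Polyhedron, factor: float) -> Polyhedron:
    """Uniformly scale a scaffold about the origin."""
    if factor <= 0:
        raise ValueError("scale factor must be > 0")
    return Polyhedron(
        kind=p.kind,
        edge_length=p.edge_length * factor,
        vertices=p.vertices * factor,
        edges=list(p.edges),
    )


@dataclasses.dataclass
class Assembly:
    """An ordered list of placed subunits, optionally tied to a scaffold."""

    subunits: list[Structure]
    placements: list[RigidTransform]
    scaffold: Polyhedron | None = None

    def __post_init__(self) -> None:
        if len(self.subunits) != len(self.placements):
            raise SizeMismatchError(
                f"{len(self.subunits)} subunits but {len(self.placements)} placements"
            )

    @property
    def n_subunits(self) -> int:
        return len(self.subunits)


def _chain_labels(n: int) -> list[str]:
    alphabet = string.ascii_uppercase + string.ascii_lowercase + string.digits
    if n <= len(alphabet):
        return list(alphabet[:n])
    logger.warning(
        "%d subunits exhaust single-character chain ids; using two-character ids", n
    )
    doubles = ["".join(p) for p in itertools.product(alphabet, repeat=2)]
    return (list(alphabet) + doubles)[:n]


def flatten(a: Assembly) -> Structure:
    """Concatenate all subunits into one Structure, remapping chain ids.

    Subunits get chains A, B, C, ... (two-character ids past 62 subunits,
    with a warning).  Total point count and mass are conserved exactly.
    """
    if a.n_subunits < 1:
        raise ValueError("assembly has no subunits")
    labels = _chain_labels(a.n_subunits)
    coords = []
    metas = []
    m = a.subunits[0].n_conformations
    for label, sub in zip(labels, a.subunits):
        if sub.n_conformations != m:
            raise SizeMismatchError(
                "all subunits must have the same number of conformations"
            )
        coords.append(sub.coordinates)
        meta = sub.metadata.copy()
        meta["chain_id"] = label
        metas.append(meta)
    return Structure(
        np.concatenate(coords, axis=1),
        pd.concat(metas, ignore_index=True),
        current=a.subunits[0].current,
    )


def assemble_on_scaffold(
    monomer: Structure,
    p: Polyhedron,
    orientation=(0.0, 0.0, 0.0),
) -> Assembly:
    """Place one copy of the monomer at each scaffold vertex.

    Each copy is centered at its centroid, rotated by its z-y-z Euler
    orientation (degrees) composed with the vertex local frame, then
    translated to the vertex.  ``orientation`` is either a single angle
    triple applied "in concert" to every copy, or a per-vertex list of
    triples.
    """
    if monomer.n_points < 1:
        raise ValueError("monomer must be nonempty")
    nv = len(p.vertices)
    orient = np.asarray(orientation, dtype=float)
    if orient.shape == (3,):
        orient = np.tile(orient, (nv, 1))
    if orient.shape != (nv, 3):
        raise SizeMismatchError(
            f"orientation must be one angle triple or {nv} triples, "
            f"got shape {orient.shape}"
        )
    c = centroid(monomer)
    subunits = []
    placements = []
    for vi in range(nv):
        frame = p.vertex_frame(vi)
        R = frame @ euler_zyz(*orient[vi])
        t = RigidTransform(R, p.vertices[vi] - R @ c)
        sub = monomer.apply_transform(t, conformation="all")
        subunits.append(sub)
        placements.append(t)
    return Assembly(subunits=subunits, placements=placements, scaffold=p)


def cyclic_multimer(monomer: Structure, n: int, radius: float) -> Assembly:
    """Place n copies with exact Cn symmetry about the z axis.

    Copy i is the centroid-centered monomer rotated by ``2*pi*i/n`` about z
    and translated to angle ``2*pi*i/n`` on a circle of the given radius in
    the xy-plane.
    """
    if n < 2:
        raise ValueError("cyclic multimer needs n >= 2")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    c = centroid(monomer)
    subunits = []
    placements = []
    for i in range(n):
        angle = 360.0 * i / n
        R = rotation_about_axis((0.0, 0.0, 1.0), angle)
        rad = np.deg2rad(angle)
        pos = np.array([radius * np.cos(rad), radius * np.sin(rad), 0.0])
        t = RigidTransform(R, pos - R @ c)
        subunits.append(monomer.apply_transform(t, conformation="all"))
        placements.append(t)
    return Assembly(subunits=subunits, placements=placements)


def append_conformation(dst: Structure, src: Structure) -> Structure:
    """Append src's conformations to dst (matching atom ordering required).

    Ordering is verified via metadata equality on atom_name, residue_id
    and chain_id; the first mismatching row is reported on failure.
    """
    if dst.n_points != src.n_points:
        raise SizeMismatchError(
            f"point counts differ: {dst.n_points} vs {src.n_points}"
        )
    for col in ("atom_name", "residue_id", "chain_id"):
        a = dst.metadata[col].to_numpy()
        b = src.metadata[col].to_numpy()
        neq = a != b
        if neq.any():
            i = int(np.argmax(neq))
            raise SizeMismatchError(
                f"metadata mismatch at row {i}: {col} {a[i]!r} != {b[i]!r}"
            )
    return Structure(
        np.concatenate([dst.coordinates, src.coordinates], axis=0),
        dst.metadata.copy(),
        current=dst.current,
    )


# ---------------------------------------------------------------------------
# super-coarse-grained generators
# ---------------------------------------------------------------------------

def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform points on the unit sphere (golden-angle spiral)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    theta = np.pi * (3.0 - np.sqrt(5.0)) * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def ellipsoid_cloud(
    semiaxes,
    n_points: int,
    mode: str = "surface",
    seed: int = 0,
    center=(0.0, 0.0, 0.0),
) -> Structure:
    """Quasi-uniform point cloud on or inside an ellipsoid.

    Surface mode scales a Fibonacci sphere to the semiaxes (fast and
    deterministic; the slight anisotropy distortion for non-spherical
    axes is accepted).  Volume mode rejection-samples the bounding box
    with a generator seeded by ``seed``.
    """
    a, b, c = (float(v) for v in semiaxes)
    if min(a, b, c) <= 0:
        raise ValueError("semiaxes must be > 0")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if mode == "surface":
        pts = fibonacci_sphere(n_points) * np.array([a, b, c])
    elif mode == "volume":
        rng = np.random.default_rng(seed)
        pts_list = []
        remaining = n_points
        while remaining > 0:
            batch = rng.uniform(-1.0, 1.0, size=(max(2 * remaining, 64), 3))
            keep = batch[(batch ** 2).sum(axis=1) <= 1.0]
            pts_list.append(keep[:remaining])
            remaining -= len(keep[:remaining])
        pts = np.concatenate(pts_list) * np.array([a, b, c])
    else:
        raise ValueError(f"mode must be 'surface' or 'volume', got {mode!r}")
    pts = pts + np.asarray(center, dtype=float)
    meta = pd.DataFrame({
        "atom_name": "SCG",
        "residue_name": "SCG",
        "residue_id": np.arange(1, n_points + 1),
        "chain_id": "A",
        "element": "C",
    })
    return Structure(pts[None, :, :], meta)


def sphere_chain(
    n_subunits: int,
    radius: float,
    overlap_fraction: float,
    n_points: int = 100,
) -> Assembly:
    """A linear chain of sphere-surface point clouds along the x axis.

    Center spacing is ``2 * radius * (1 - overlap_fraction)``, so the
    end-to-end center distance is ``(n - 1) * spacing``.
    """
    if n_subunits < 1:
        raise ValueError("n_subunits must be >= 1")
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValueError("overlap_fraction must be in [0, 1)")
    if radius <= 0:
        raise ValueError("radius must be > 0")
    spacing = 2.0 * radius * (1.0 - overlap_fraction)
    base = ellipsoid_cloud((radius, radius, radius), n_points, mode="surface")
    subunits = []
    placements = []
    for i in range(n_subunits):
        t = RigidTransform(np.eye(3), np.array([i * spacing, 0.0, 0.0]))
        subunits.append(base.apply_transform(t, conformation="all"))
        placements.append(t)
    return Assembly(subunits=subunits, placements=placements)
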