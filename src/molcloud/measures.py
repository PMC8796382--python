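"""Physical observables on point clouds.

* Collision cross section (CCS) by the projection approximation: the mean
  projected shadow area of atom+probe disks over uniformly random
  orientations.  This systematically underestimates trajectory-method CCS
  for large molecules; a linear ``calibration`` factor (default 1.0) is
  provided to match published scales.
* Solvent-accessible surface area (Shrake-Rupley test-point method).
* Solvent-accessible shortest paths on a cubic lattice with 26-neighbour
  connectivity — a lower bound on the length a cross-linker must span.

Default probes: 1.0 Å for CCS (helium-like), 1.4 Å for SASA/accessibility
(water).
"""
from __future__ import annotations

import dataclasses
import heapq
import logging

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation
from scipy import sparse

from .assembly import fibonacci_sphere
from .core import Structure
from .errors import (
    BuriedEndpointError,
    EmptyStructureError,
    NoPathError,
    RasterError,
)

logger = logging.getLogger(__name__)

CCS_PROBE = 1.0
SASA_PROBE = 1.4

_NEIGHBOUR_OFFSETS = np.array([
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
])


# ---------------------------------------------------------------------------
# collision cross section (projection approximation)
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class CCSResult:
    """Projection-approximation CCS with its Monte-Carlo uncertainty."""

    ccs: float          # Å², mean projected area (× calibration)
    sem: float          # Å², standard error of the mean over orientations
    n_rotations: int

    def __float__(self) -> float:
        return self.ccs


def _shadow_area(xy: np.ndarray, radii: np.ndarray, raster: float) -> float:
    """Area of the union of disks, by counting raster cells whose center
    falls inside any disk."""
    lo = (xy - radii[:, None]).min(axis=0)
    hi = (xy + radii[:, None]).max(axis=0)
    nx = int(np.ceil((hi[0] - lo[0]) / raster)) + 1
    ny = int(np.ceil((hi[1] - lo[1]) / raster)) + 1
    occupied = np.zeros((nx, ny), dtype=bool)
    for (px, py), r in zip(xy, radii):
        i0 = max(int(np.floor((px - r - lo[0]) / raster)), 0)
        i1 = min(int(np.ceil((px + r - lo[0]) / raster)) + 1, nx)
        j0 = max(int(np.floor((py - r - lo[1]) / raster)), 0)
        j1 = min(int(np.ceil((py + r - lo[1]) / raster)) + 1, ny)
        gx = lo[0] + raster * np.arange(i0, i1) - px
        gy = lo[1] + raster * np.arange(j0, j1) - py
        occupied[i0:i1, j0:j1] |= (
            gx[:, None] ** 2 + gy[None, :] ** 2 <= r * r
        )
    return float(np.count_nonzero(occupied)) * raster * raster


def ccs_projection(
    s: Structure,
    probe: float = CCS_PROBE,
    n_rotations: int = 300,
    raster: float = 0.2,
    seed: int = 0,
    calibration: float = 1.0,
) -> CCSResult:
    """Rotationally averaged projected area (Å²) of atom+probe disks.

    Orientations are uniform random rotations from a seeded generator, so
    results are reproducible for a given seed.
    """
    if s.n_points < 1:
        raise EmptyStructureError("CCS of an empty structure is undefined")
    if n_rotations < 1:
        raise ValueError("n_rotations must be >= 1")
    radii = s.metadata["vdw_radius"].to_numpy(dtype=float) + probe
    if raster >= radii.min():
        raise RasterError(
            f"raster {raster} A is coarser than the smallest disk radius "
            f"{radii.min():.3g} A"
        )
    logger.info(
        "ccs_projection: probe %.2f A, %d rotations, raster %.2f A, seed %d",
        probe, n_rotations, raster, seed,
    )
    rng = np.random.default_rng(seed)
    xyz = s.xyz - s.xyz.mean(axis=0)
    areas = np.empty(n_rotations)
    for k in range(n_rotations):
        R = Rotation.random(rng=rng).as_matrix()
        xy = (xyz @ R.T)[:, :2]
        areas[k] = _shadow_area(xy, radii, raster)
    mean = float(areas.mean()) * calibration
    sem = float(areas.std(ddof=1) / np.sqrt(n_rotations)) if n_rotations > 1 else 0.0
    return CCSResult(ccs=mean, sem=sem * calibration, n_rotations=n_rotations)


# ---------------------------------------------------------------------------
# solvent-accessible surface area (Shrake-Rupley)
# ---------------------------------------------------------------------------

def sasa(
    s: Structure,
    probe: float = SASA_PROBE,
    n_sphere_points: int = 960,
) -> tuple[np.ndarray, float]:
    """Shrake-Rupley solvent-accessible surface area.

    Per-atom area is ``4*pi*(r+probe)**2`` times the fraction of test
    points on the expanded sphere not buried inside any other expanded
    atom sphere.  Returns (per-atom Å² array, total Å²).
    """
    if s.n_points < 1:
        return np.zeros(0), 0.0
    logger.info("sasa: probe %.2f A, %d test points per atom", probe, n_sphere_points)
    xyz = s.xyz
    radii = s.metadata["vdw_radius"].to_numpy(dtype=float) + probe
    unit = fibonacci_sphere(n_sphere_points)
    tree = cKDTree(xyz)
    rmax = radii.max()
    areas = np.empty(s.n_points)
    for i in range(s.n_points):
        pts = xyz[i] + radii[i] * unit
        neighbours = [j for j in tree.query_ball_point(xyz[i], radii[i] + rmax)
                      if j != i]
        exposed = np.ones(n_sphere_points, dtype=bool)
        for j in neighbours:
            d2 = np.sum((pts - xyz[j]) ** 2, axis=1)
            exposed &= d2 > radii[j] ** 2
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * exposed.mean()
    return areas, float(areas.sum())


# ---------------------------------------------------------------------------
# solvent-accessible lattice paths
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class LatticeGraph:
    """Cubic lattice around a structure with solvent accessibility flags.

    A node is accessible iff its distance to every atom center is at least
    that atom's vdW radius plus the probe.  Adjacency (built lazily) uses
    26-neighbour connectivity among accessible nodes with Euclidean edge
    weights.
    """

    spacing: float
    origin: np.ndarray          # position of lattice node (0,0,0)
    shape: tuple[int, int, int]
    accessible: np.ndarray      # boolean, full grid shape
    probe: float

    _adjacency: "sparse.csr_matrix | None" = dataclasses.field(
        default=None, repr=False, compare=False)
    _acc_index: np.ndarray | None = dataclasses.field(
        default=None, repr=False, compare=False)

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.shape))

    @property
    def n_accessible(self) -> int:
        return int(np.count_nonzero(self.accessible))

    def node_position(self, ijk: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(ijk) * self.spacing

    def accessible_positions(self) -> np.ndarray:
        ijk = np.argwhere(self.accessible)
        return self.node_position(ijk)

    def adjacency(self):
        """CSR matrix over accessible nodes (ordered by grid index) with
        Euclidean edge weights."""
        if self._adjacency is None:
            self._build_adjacency()
        return self._adjacency

    def accessible_ijk(self) -> np.ndarray:
        if self._acc_index is None:
            self._build_adjacency()
        return self._acc_index  # type: ignore[return-value]

    def _build_adjacency(self) -> None:
        ijk = np.argwhere(self.accessible)
        self._acc_index = ijk
        n = len(ijk)
        flat_to_acc = -np.ones(self.n_nodes, dtype=np.int64)
        flat = np.ravel_multi_index(ijk.T, self.shape)
        flat_to_acc[flat] = np.arange(n)
        rows, cols, weights = [], [], []
        for off in _NEIGHBOUR_OFFSETS:
            nb = ijk + off
            ok = np.all((nb >= 0) & (nb < np.array(self.shape)), axis=1)
            src = np.nonzero(ok)[0]
            nb_flat = np.ravel_multi_index(nb[ok].T, self.shape)
            dst = flat_to_acc[nb_flat]
            good = dst >= 0
            rows.append(src[good])
            cols.append(dst[good])
            w = self.spacing * np.linalg.norm(off)
            weights.append(np.full(int(good.sum()), w))
        self._adjacency = sparse.csr_matrix(
            (np.concatenate(weights),
             (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        )


@dataclasses.dataclass(frozen=True)
class AccessiblePath:
    """An ordered walk over accessible lattice nodes between two atoms."""

    node_positions: np.ndarray   # (k, 3) Å
    length: float                # Å, sum of consecutive gaps
    straight_line: float         # Å, endpoint atom distance
    endpoints: tuple[int, int]   # query atom indices


def build_lattice(
    s: Structure,
    spacing: float = 1.0,
    probe: float = SASA_PROBE,
    margin: float = 10.0,
) -> LatticeGraph:
    """Cubic accessibility lattice over the structure's padded bounding box."""
    if s.n_points < 1:
        raise EmptyStructureError("cannot build a lattice around an empty structure")
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    if margin < 0:
        raise ValueError("margin must be >= 0")
    logger.info(
        "build_lattice: spacing %.2f A, probe %.2f A, margin %.1f A",
        spacing, probe, margin,
    )
    xyz = s.xyz
    radii = s.metadata["vdw_radius"].to_numpy(dtype=float)
    lo = xyz.min(axis=0) - margin
    hi = xyz.max(axis=0) + margin
    shape = tuple(np.ceil((hi - lo) / spacing).astype(int) + 1)
    accessible = np.ones(shape, dtype=bool)
    # mark nodes clashing with any atom+probe sphere
    axes = [lo[d] + spacing * np.arange(shape[d]) for d in range(3)]
    for (px, py, pz), r in zip(xyz, radii):
        cut = r + probe
        i0, i1 = np.searchsorted(axes[0], [px - cut, px + cut])
        j0, j1 = np.searchsorted(axes[1], [py - cut, py + cut])
        k0, k1 = np.searchsorted(axes[2], [pz - cut, pz + cut])
        i1 = min(i1 + 1, shape[0]); j1 = min(j1 + 1, shape[1]); k1 = min(k1 + 1, shape[2])
        if i0 >= i1 or j0 >= j1 or k0 >= k1:
            continue
        dx = axes[0][i0:i1] - px
        dy = axes[1][j0:j1] - py
        dz = axes[2][k0:k1] - pz
        d2 = (dx[:, None, None] ** 2 + dy[None, :, None] ** 2
              + dz[None, None, :] ** 2)
        accessible[i0:i1, j0:j1, k0:k1] &= d2 >= cut * cut
    return LatticeGraph(
        spacing=float(spacing),
        origin=lo,
        shape=shape,
        accessible=accessible,
        probe=float(probe),
    )


def _snap(g: LatticeGraph, pos: np.ndarray, cutoff: float, label: str) -> int:
    """Index (into the accessible-node ordering) of the nearest accessible
    node within cutoff; deterministic tie-break by grid index order."""
    ijk = g.accessible_ijk()
    positions = g.node_position(ijk)
    d2 = np.sum((positions - pos) ** 2, axis=1)
    best = int(np.argmin(d2))  # argmin returns the first (lowest index) tie
    if d2[best] > cutoff * cutoff:
        raise BuriedEndpointError(
            f"{label}: no accessible lattice node within {cutoff} A "
            f"(nearest at {np.sqrt(d2[best]):.2f} A)"
        )
    return best


def shortest_accessible_path(
    g: LatticeGraph,
    s: Structure,
    atom_a: int,
    atom_b: int,
    snap_cutoff: float = 5.0,
) -> AccessiblePath:
    """Minimal-Euclidean-length path between two atoms over accessible nodes.

    Endpoints snap to their nearest accessible node within ``snap_cutoff``.
    A* search with the (admissible) Euclidean heuristic; ties broken
    deterministically by node index.  Disconnected endpoints raise
    :class:`NoPathError` — the cross-link is infeasible.
    """
    for atom in (atom_a, atom_b):
        if not 0 <= atom < s.n_points:
            raise IndexError(f"atom index {atom} out of range [0, {s.n_points})")
    pa = s.xyz[atom_a]
    pb = s.xyz[atom_b]
    straight = float(np.linalg.norm(pb - pa))
    start = _snap(g, pa, snap_cutoff, f"atom {atom_a}")
    goal = _snap(g, pb, snap_cutoff, f"atom {atom_b}")
    ijk = g.accessible_ijk()
    positions = g.node_position(ijk)

    if start == goal:
        return AccessiblePath(
            node_positions=positions[start][None, :],
            length=0.0,
            straight_line=straight,
            endpoints=(atom_a, atom_b),
        )

    adj = g.adjacency()
    n = adj.shape[0]
    dist = np.full(n, np.inf)
    dist[start] = 0.0
    prev = np.full(n, -1, dtype=np.int64)
    goal_pos = positions[goal]
    heur = np.linalg.norm(positions - goal_pos, axis=1)
    # heap entries: (f, node) — node index breaks ties deterministically
    heap = [(heur[start], start)]
    done = np.zeros(n, dtype=bool)
    indptr, indices, data = adj.indptr, adj.indices, adj.data
    while heap:
        f, u = heapq.heappop(heap)
        if done[u]:
            continue
        if u == goal:
            break
        done[u] = True
        du = dist[u]
        for ptr in range(indptr[u], indptr[u + 1]):
            v = indices[ptr]
            nd = du + data[ptr]
            if nd < dist[v] - 1e-12:
                dist[v] = nd
                prev[v] = u
                heapq.heappush(heap, (nd + heur[v], v))
    if not np.isfinite(dist[goal]):
        raise NoPathError(
            f"atoms {atom_a} and {atom_b} lie in disconnected accessible "
            "regions: no solvent-accessible path exists"
        )
    path = [goal]
    while path[-1] != start:
        path.append(int(prev[path[-1]]))
    path.reverse()
    return AccessiblePath(
        node_positions=positions[np.array(path)],
        length=float(dist[goal]),
        straight_line=straight,
        endpoints=(atom_a, atom_b),
    )
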