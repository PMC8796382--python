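"""Multi-conformation point-cloud data model and rigid-body geometry.

A :class:`Structure` stores an ``(M, N, 3)`` coordinate tensor — ``M``
alternative conformations of the same ``N`` points — plus an ``N``-row
pandas metadata table (atom names, residues, chains, masses, radii, ...).
Geometry operations act on the *current* conformation unless told
otherwise.  All lengths are Å.
"""
from __future__ import annotations

import dataclasses
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from . import elements
from .errors import (
    MassError,
    SelectionError,
    SizeMismatchError,
    TransformError,
)

METADATA_COLUMNS = (
    "atom_name",
    "residue_name",
    "residue_id",
    "insertion_code",
    "chain_id",
    "element",
    "mass",
    "vdw_radius",
    "occupancy",
    "beta",
)

_ORTHONORMAL_TOL = 1e-9


# ---------------------------------------------------------------------------
# rigid transforms
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class RigidTransform:
    """A proper rotation followed by a translation: ``x -> R x + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise TransformError(f"rotation must be 3x3, got {R.shape}")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise TransformError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise TransformError(
                "rotation matrix has determinant -1 (reflection not allowed)"
            )
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        """Apply to an (..., 3) array of positions."""
        return np.asarray(xyz, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then self."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)


def rotation_about_axis(axis: Sequence[float], angle_deg: float) -> np.ndarray:
    """Rotation matrix about an arbitrary axis (degrees, right-handed)."""
    ax = np.asarray(axis, dtype=float)
    n = np.linalg.norm(ax)
    if n == 0:
        raise TransformError("rotation axis must be nonzero")
    ax = ax / n
    theta = np.deg2rad(angle_deg)
    K = np.array([
        [0.0, -ax[2], ax[1]],
        [ax[2], 0.0, -ax[0]],
        [-ax[1], ax[0], 0.0],
    ])
    return np.eye(3) + np.sin(theta) * K + (1.0 - np.cos(theta)) * (K @ K)


def euler_zyz(alpha_deg: float, beta_deg: float, gamma_deg: float) -> np.ndarray:
    """Intrinsic z-y-z Euler rotation matrix, angles in degrees."""
    Rz1 = rotation_about_axis((0, 0, 1), alpha_deg)
    Ry = rotation_about_axis((0, 1, 0), beta_deg)
    Rz2 = rotation_about_axis((0, 0, 1), gamma_deg)
    return Rz1 @ Ry @ Rz2


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Selection:
    """A predicate over per-point metadata and/or an explicit index list.

    Parameters
    ----------
    where:
        A pandas ``DataFrame.query`` expression over the metadata columns,
        e.g. ``"atom_name == 'CA' and chain_id == 'A'"``.
    indices:
        Explicit point indices. Combined with ``where``/``predicate`` by
        intersection.
    predicate:
        Callable receiving the metadata frame and returning a boolean mask.
    """

    where: str | None = None
    indices: Sequence[int] | None = None
    predicate: Callable[[pd.DataFrame], Iterable[bool]] | None = None

    def resolve(self, metadata: pd.DataFrame) -> np.ndarray:
        """Return the sorted, unique point indices selected from ``metadata``."""
        n = len(metadata)
        mask = np.ones(n, dtype=bool)
        if self.where is not None:
            try:
                sub = metadata.query(self.where)
            except pd.errors.UndefinedVariableError as exc:
                raise SelectionError(
                    f"unknown metadata column in selection: {exc}"
                ) from exc
            except Exception as exc:  # malformed expression
                raise SelectionError(f"bad selection expression: {exc}") from exc
            m = np.zeros(n, dtype=bool)
            m[metadata.index.get_indexer(sub.index)] = True
            mask &= m
        if self.predicate is not None:
            pm = np.asarray(list(self.predicate(metadata)), dtype=bool)
            if pm.shape != (n,):
                raise SelectionError(
                    f"predicate mask has shape {pm.shape}, expected ({n},)"
                )
            mask &= pm
        idx = np.nonzero(mask)[0]
        if self.indices is not None:
            explicit = np.unique(np.asarray(self.indices, dtype=int))
            if explicit.size and (explicit.min() < 0 or explicit.max() >= n):
                raise SelectionError(
                    f"explicit indices out of range [0, {n})"
                )
            idx = np.intersect1d(idx, explicit)
        return idx

    @classmethod
    def all(cls) -> "Selection":
        return cls()


def _coerce_selection(sel) -> Selection:
    if sel is None:
        return Selection.all()
    if isinstance(sel, Selection):
        return sel
    if isinstance(sel, str):
        return Selection(where=sel)
    return Selection(indices=list(sel))


# ---------------------------------------------------------------------------
# Structure
# ---------------------------------------------------------------------------

class Structure:
    """``N`` points with ``M`` alternative conformations and per-point metadata.

    Parameters
    ----------
    coordinates:
        ``(M, N, 3)`` or ``(N, 3)`` array of positions in Å. A 2D array is
        promoted to a single conformation.
    metadata:
        ``N``-row DataFrame; missing standard columns are filled with
        defaults and masses/radii derived from the ``element`` column.
    current:
        Index of the conformation that geometry operations act on.
    """

    def __init__(
        self,
        coordinates: np.ndarray,
        metadata: pd.DataFrame | None = None,
        current: int = 0,
    ) -> None:
        coords = np.array(coordinates, dtype=float)
        if coords.ndim == 2:
            coords = coords[None, :, :]
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError(
                f"coordinates must have shape (M, N, 3) or (N, 3), got {coords.shape}"
            )
        if coords.size and not np.isfinite(coords).all():
            raise ValueError("coordinates contain non-finite values")
        m, n, _ = coords.shape
        if m < 1:
            raise ValueError("at least one conformation required")
        if not 0 <= current < m:
            raise ValueError(f"current conformation {current} outside [0, {m})")

        self.coordinates = coords
        self.current = int(current)
        self.metadata = _normalize_metadata(metadata, n)

    # -- basic introspection ------------------------------------------------

    @property
    def n_points(self) -> int:
        return self.coordinates.shape[1]

    @property
    def n_conformations(self) -> int:
        return self.coordinates.shape[0]

    @property
    def xyz(self) -> np.ndarray:
        """Coordinates of the current conformation, shape (N, 3)."""
        return self.coordinates[self.current]

    def __len__(self) -> int:
        return self.n_points

    def __repr__(self) -> str:
        return (
            f"<Structure N={self.n_points} M={self.n_conformations} "
            f"current={self.current}>"
        )

    def copy(self) -> "Structure":
        return Structure(
            self.coordinates.copy(),
            self.metadata.copy(),
            current=self.current,
        )

    # -- convenience methods (functional API below is canonical) ------------

    def select(self, sel) -> "Structure":
        return select(self, sel)

    def apply_transform(self, t: RigidTransform, conformation="current") -> "Structure":
        return apply_transform(self, t, conformation)

    def center_of_mass(self, sel=None) -> np.ndarray:
        return center_of_mass(self, sel)


def _normalize_metadata(metadata: pd.DataFrame | None, n: int) -> pd.DataFrame:
    if metadata is None:
        metadata = pd.DataFrame(index=range(n))
    else:
        metadata = metadata.reset_index(drop=True).copy()
    if len(metadata) != n:
        raise ValueError(
            f"metadata has {len(metadata)} rows, expected {n} (one per point)"
        )
    defaults = {
        "atom_name": "CA",
        "residue_name": "UNK",
        "residue_id": lambda: np.arange(1, n + 1),
        "insertion_code": "",
        "chain_id": "A",
        "element": "C",
        "occupancy": 1.0,
        "beta": 0.0,
    }
    for col, default in defaults.items():
        if col not in metadata.columns:
            metadata[col] = default() if callable(default) else default
    if "mass" not in metadata.columns:
        metadata["mass"] = [elements.mass_of(e) for e in metadata["element"]]
    if "vdw_radius" not in metadata.columns:
        metadata["vdw_radius"] = [
            elements.vdw_radius_of(e) for e in metadata["element"]
        ]
    if n:
        if (metadata["vdw_radius"] <= 0).any():
            raise ValueError("all vdw_radius values must be > 0")
        if (metadata["mass"] < 0).any():
            raise ValueError("all mass values must be >= 0")
    metadata["residue_id"] = metadata["residue_id"].astype(int)
    # canonical column order first, extras preserved after
    extras = [c for c in metadata.columns if c not in METADATA_COLUMNS]
    return metadata[list(METADATA_COLUMNS) + extras]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def select(s: Structure, sel) -> Structure:
    """Return a new Structure containing only the selected points.

    All ``M`` conformations are preserved; metadata rows stay aligned with
    the retained points. An empty match yields an empty Structure (N=0),
    not an error.
    """
    sel = _coerce_selection(sel)
    idx = sel.resolve(s.metadata)
    return Structure(
        s.coordinates[:, idx, :].copy(),
        s.metadata.iloc[idx].reset_index(drop=True),
        current=s.current,
    )


def apply_transform(s: Structure, t: RigidTransform, conformation="current") -> Structure:
    """Apply ``x -> R x + t`` to one conformation (default: current) or "all"."""
    if not isinstance(t, RigidTransform):
        raise TransformError("expected a RigidTransform")
    out = s.copy()
    if conformation == "all":
        out.coordinates = t.apply(out.coordinates)
    else:
        if conformation == "current":
            conformation = s.current
        conformation = int(conformation)
        if not 0 <= conformation < s.n_conformations:
            raise ValueError(
                f"conformation {conformation} outside [0, {s.n_conformations})"
            )
        out.coordinates[conformation] = t.apply(out.coordinates[conformation])
    return out


def superpose(mobile: Structure, target: Structure, sel=None):
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Uses the SVD (Kabsch) solution with determinant sign correction so
    only proper rotations are returned — mirror fits are disallowed.

    Returns
    -------
    (RigidTransform, float)
        The optimal transform and the post-superposition RMSD (Å) over the
        selection, computed on the current conformations.
    """
    sel = _coerce_selection(sel)
    ia = sel.resolve(mobile.metadata)
    ib = sel.resolve(target.metadata)
    if len(ia) != len(ib):
        raise SizeMismatchError(
            f"selection sizes differ: {len(ia)} (mobile) vs {len(ib)} (target)"
        )
    if len(ia) < 3:
        raise SizeMismatchError(
            f"superposition needs >= 3 points, got {len(ia)}"
        )
    P = mobile.xyz[ia]
    Q = target.xyz[ib]
    t = kabsch(P, Q)
    diff = t.apply(P) - Q
    rms = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    return t, rms


def kabsch(P: np.ndarray, Q: np.ndarray) -> RigidTransform:
    """Optimal proper-rotation transform mapping point set P onto Q."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, cq - R @ cp)


def rmsd(
    a: Structure,
    b: Structure,
    sel=None,
    superpose_first: bool = False,
    mass_weighted: bool = False,
) -> float:
    """RMSD (Å) over selected points of the current conformations.

    Unweighted by default; with ``mass_weighted`` each point's squared
    deviation is weighted by its mass in ``a``.
    """
    sel = _coerce_selection(sel)
    ia = sel.resolve(a.metadata)
    ib = sel.resolve(b.metadata)
    if len(ia) != len(ib):
        raise SizeMismatchError(
            f"selection sizes differ: {len(ia)} vs {len(ib)}"
        )
    P = a.xyz[ia]
    Q = b.xyz[ib]
    if superpose_first:
        t = kabsch(P, Q)
        P = t.apply(P)
    sq = np.sum((P - Q) ** 2, axis=1)
    if mass_weighted:
        w = a.metadata["mass"].to_numpy(dtype=float)[ia]
        if w.sum() <= 0:
            raise MassError("mass-weighted RMSD requires positive total mass")
        return float(np.sqrt(np.sum(w * sq) / w.sum()))
    return float(np.sqrt(np.mean(sq)))


def rmsf(s: Structure) -> np.ndarray:
    """Per-point root-mean-square fluctuation (Å) about the mean conformation.

    With a single conformation the result is all zeros.
    """
    mean = s.coordinates.mean(axis=0)
    disp = s.coordinates - mean[None, :, :]
    return np.sqrt(np.mean(np.sum(disp * disp, axis=2), axis=0))


def center_of_mass(s: Structure, sel=None) -> np.ndarray:
    """Mass-weighted mean position (Å) of the current conformation."""
    sel = _coerce_selection(sel)
    idx = sel.resolve(s.metadata)
    masses = s.metadata["mass"].to_numpy(dtype=float)[idx]
    total = masses.sum()
    if total <= 0:
        raise MassError("total selected mass must be > 0 for center_of_mass")
    return (s.xyz[idx] * masses[:, None]).sum(axis=0) / total


def centroid(s: Structure, sel=None) -> np.ndarray:
    """Unweighted mean position of the current conformation."""
    sel = _coerce_selection(sel)
    idx = sel.resolve(s.metadata)
    return s.xyz[idx].mean(axis=0)


def distance_matrix(a: Structure, b: Structure) -> np.ndarray:
    """|a| x |b| Euclidean distance matrix between current conformations."""
    return cdist(a.xyz, b.xyz)
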