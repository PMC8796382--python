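"""Readers and writers for multi-model PDB files and OpenDX scalar fields.

PDB parsing is fixed-column: both ATOM and HETATM records are read, ANISOU
and CONECT are ignored, and only the first altLoc encountered per atom is
kept (with a logged warning).  MODEL/ENDMDL blocks become alternative
conformations.

The OpenDX dialect is the common molecular "gridpositions / gridconnections"
scalar field.  **Convention:** ``origin`` is the position of the *center* of
voxel (0, 0, 0) — the main hazard with DX files is an off-by-half-voxel
shift, so this is asserted throughout the package.
"""
from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import elements
from .core import Structure
from .errors import DXError, FieldOverflowError, ModelMismatchError, PDBError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# density map container
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DensityMap:
    """A regular axis-aligned 3D scalar field.

    Attributes
    ----------
    origin:
        Position (Å) of the center of voxel ``(0, 0, 0)``.
    delta:
        Voxel edge lengths (Å) along x, y, z; strictly positive.
    values:
        Rank-3 grid of scalar values, indexed ``[i, j, k]`` along x, y, z.
    """

    origin: np.ndarray
    delta: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.delta = np.asarray(self.delta, dtype=float).reshape(3)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise DXError(f"values must be rank-3, got rank {self.values.ndim}")
        if (self.delta <= 0).any():
            raise DXError("all voxel edge lengths must be > 0")
        if not np.isfinite(self.values).all():
            raise DXError("grid values contain non-finite entries")
        if not np.isfinite(self.origin).all() or not np.isfinite(self.delta).all():
            raise DXError("origin/delta contain non-finite entries")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.delta))

    def voxel_centers(self) -> np.ndarray:
        """All voxel center positions, shape ``(*grid_shape, 3)``."""
        axes = [
            self.origin[d] + self.delta[d] * np.arange(self.shape[d])
            for d in range(3)
        ]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def read_pdb(path) -> Structure:
    """Parse a (possibly multi-model) PDB file into a Structure.

    One conformation per MODEL block; a file without MODEL records yields
    M=1.  Metadata columns are populated from the fixed-column fields; the
    element is inferred from the atom name when the element column is
    blank; masses/radii come from the internal element table.
    """
    path = Path(path)
    models: list[list[np.ndarray]] = []
    rows: list[dict] = []
    coords: list[list[float]] = []
    in_model = False
    seen_altloc: set[tuple] = set()
    first_model = True

    def close_model():
        nonlocal coords, first_model
        if coords:
            models.append(coords)  # type: ignore[arg-type]
            coords = []
            first_model = False
        seen_altloc.clear()

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                close_model()
                in_model = True
            elif rec == "ENDMDL":
                close_model()
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                try:
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                except ValueError as exc:
                    raise PDBError(
                        f"{path}:{lineno}: malformed coordinate fields"
                    ) from exc
                altloc = line[16:17].strip()
                atom_name = line[12:16].strip()
                chain_id = line[21:22].strip()
                resid = line[22:26].strip()
                icode = line[26:27].strip()
                key = (chain_id, resid, icode, atom_name)
                if altloc:
                    if key in seen_altloc:
                        if first_model:
                            logger.warning(
                                "%s:%d: skipping alternate location %r for atom %s",
                                path, lineno, altloc, atom_name,
                            )
                        continue
                    seen_altloc.add(key)
                coords.append([x, y, z])
                if first_model:
                    element = line[76:78].strip() if len(line) >= 78 else ""
                    if not element:
                        element = elements.guess_element(atom_name)
                    occ = line[54:60].strip()
                    beta = line[60:66].strip()
                    rows.append({
                        "atom_name": atom_name,
                        "residue_name": line[17:20].strip(),
                        "residue_id": int(resid) if resid else 0,
                        "insertion_code": icode,
                        "chain_id": chain_id,
                        "element": element,
                        "occupancy": float(occ) if occ else 1.0,
                        "beta": float(beta) if beta else 0.0,
                    })
    close_model()

    if not models or not rows:
        raise PDBError(f"{path}: no ATOM/HETATM records found")
    n = len(models[0])
    for i, m in enumerate(models):
        if len(m) != n:
            raise ModelMismatchError(
                f"{path}: model {i + 1} has {len(m)} atoms, expected {n}"
            )
    meta = pd.DataFrame(rows)
    meta["mass"] = [elements.mass_of(e) for e in meta["element"]]
    meta["vdw_radius"] = [elements.vdw_radius_of(e) for e in meta["element"]]
    return Structure(np.asarray(models, dtype=float), meta)


def write_pdb(s: Structure, path, conformations="all") -> None:
    """Write a Structure as fixed-column PDB text.

    Multiple conformations are wrapped in MODEL/ENDMDL blocks; coordinates
    are written at 3 decimals, occupancy/beta at 2; serials restart from 1
    in each model; TER is emitted after each chain.
    """
    path = Path(path)
    if conformations == "all":
        conf_indices = list(range(s.n_conformations))
    else:
        conf_indices = [int(c) for c in np.atleast_1d(conformations)]
        for c in conf_indices:
            if not 0 <= c < s.n_conformations:
                raise ValueError(f"conformation {c} out of range")
    if s.n_points and np.abs(s.coordinates[conf_indices]).max() >= 1e4:
        raise FieldOverflowError(
            "coordinates >= 10^4 A cannot be represented in fixed PDB columns"
        )
    meta = s.metadata
    multi = len(conf_indices) > 1
    lines: list[str] = []
    for block, ci in enumerate(conf_indices, start=1):
        if multi:
            lines.append(f"MODEL     {block:4d}")
        xyz = s.coordinates[ci]
        serial = 0
        for i in range(s.n_points):
            serial += 1
            row = meta.iloc[i]
            name = str(row["atom_name"])
            # short names start in column 14 unless 4 chars long
            name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
            element = str(row["element"])[:2]
            lines.append(
                "ATOM  {serial:5d} {name}{alt}{res:<3s} {chain}{resid:4d}{icode}   "
                "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{beta:6.2f}          {elem:>2s}".format(
                    serial=serial % 100000,
                    name=name_field,
                    alt=" ",
                    res=str(row["residue_name"])[:3],
                    chain=(str(row["chain_id"]) or "A")[:1],
                    resid=int(row["residue_id"]) % 10000,
                    icode=(str(row["insertion_code"]) or " ")[:1],
                    x=xyz[i, 0], y=xyz[i, 1], z=xyz[i, 2],
                    occ=float(row["occupancy"]), beta=float(row["beta"]),
                    elem=element,
                )
            )
            last = i == s.n_points - 1
            if last or meta.iloc[i + 1]["chain_id"] != row["chain_id"]:
                serial += 1
                lines.append(
                    "TER   {serial:5d}      {res:<3s} {chain}{resid:4d}".format(
                        serial=serial % 100000,
                        res=str(row["residue_name"])[:3],
                        chain=(str(row["chain_id"]) or "A")[:1],
                        resid=int(row["residue_id"]) % 10000,
                    )
                )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# OpenDX
# ---------------------------------------------------------------------------

def read_dx(path) -> DensityMap:
    """Read an OpenDX "gridpositions" scalar field.

    Only axis-aligned (diagonal-delta) grids are supported; data values
    follow the DX convention of last axis (z) varying fastest.
    """
    path = Path(path)
    counts = None
    origin = None
    deltas: list[np.ndarray] = []
    data: list[float] = []
    n_expected = None
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split()
            if stripped.startswith("object"):
                if "gridpositions" in stripped:
                    try:
                        counts = tuple(int(t) for t in tokens[-3:])
                    except ValueError as exc:
                        raise DXError(f"{path}: bad counts line: {stripped!r}") from exc
                continue
            if tokens[0] == "origin":
                origin = np.array([float(t) for t in tokens[1:4]])
                continue
            if tokens[0] == "delta":
                deltas.append(np.array([float(t) for t in tokens[1:4]]))
                continue
            if tokens[0] == "attribute" or tokens[0] == "component":
                continue
            # otherwise: data values
            try:
                data.extend(float(t) for t in tokens)
            except ValueError as exc:
                raise DXError(f"{path}: unparseable line: {stripped!r}") from exc

    if counts is None or origin is None or len(deltas) != 3:
        raise DXError(f"{path}: missing gridpositions header, origin or deltas")
    D = np.vstack(deltas)
    if not np.allclose(D, np.diag(np.diag(D)), atol=1e-12):
        raise DXError(f"{path}: non-orthogonal delta vectors are unsupported")
    delta = np.diag(D)
    n_expected = counts[0] * counts[1] * counts[2]
    if len(data) != n_expected:
        raise DXError(
            f"{path}: {len(data)} data values but header promises {n_expected}"
        )
    values = np.asarray(data, dtype=float).reshape(counts)  # z fastest == C order
    return DensityMap(origin=origin, delta=delta, values=values)


def write_dx(d: DensityMap, path) -> None:
    """Write a DensityMap as standard OpenDX text (z axis fastest)."""
    path = Path(path)
    nx, ny, nz = d.shape
    out = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        "origin {:.6e} {:.6e} {:.6e}".format(*d.origin),
        f"delta {d.delta[0]:.6e} 0.000000e+00 0.000000e+00",
        f"delta 0.000000e+00 {d.delta[1]:.6e} 0.000000e+00",
        f"delta 0.000000e+00 0.000000e+00 {d.delta[2]:.6e}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {nx * ny * nz} data follows",
    ]
    flat = d.values.reshape(-1)  # C order: z fastest
    for start in range(0, flat.size, 3):
        out.append(" ".join(f"{v:.6e}" for v in flat[start:start + 3]))
    out.append('attribute "dep" string "positions"')
    out.append('object "density" class field')
    out.append('component "positions" value 1')
    out.append('component "connections" value 2')
    out.append('component "data" value 3')
    path.write_text("\n".join(out) + "\n")
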