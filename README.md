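# molcloud

A toolbox for manipulating biomolecular structures as **multi-conformation
point clouds**. The central object is a `Structure`: an `(M, N, 3)`
coordinate tensor (`M` alternative conformations of `N` points, in Å)
paired with an `N`-row pandas metadata table (atom names, residues,
chains, elements, masses, van der Waals radii).

Features:

- **I/O** — multi-model PDB (fixed-column, MODEL/ENDMDL) and OpenDX
  scalar-field text files. DX convention: `origin` is the *center* of
  voxel `(0,0,0)`.
- **Geometry** — pandas-query atom selection, rigid transforms,
  SVD (Kabsch) superposition restricted to proper rotations, RMSD, RMSF,
  distance matrices, centers of mass.
- **Density** — point cloud → simulated Gaussian density map (sigma =
  `sigma_per_resolution × resolution`, default ½), density map → point
  cloud at an isovalue, enclosed-volume contours, and mass-based isovalue
  selection (target volume = mass × 1.21 Å³/Da, configurable).
- **Assembly** — the five regular polyhedra as deformable scaffolds with
  subunits placed on vertices (per-vertex or in-concert z-y-z Euler
  orientations), cyclic Cn multimers, conformation appending, and
  super-coarse-grained sphere/ellipsoid clouds and sphere chains.
- **Measures** — collision cross section by the rotationally averaged
  projection approximation (with SEM and a calibration hook),
  Shrake–Rupley SASA, and solvent-accessible shortest paths on a cubic
  lattice (26-connectivity, A* with an admissible Euclidean heuristic) —
  a lower bound on the length a chemical cross-linker must span.

## Test

```sh
python -m pytest tests/
```

## CLI

The `molcloud` entry point chains the typical workflow. Output is
machine-readable `key=value` lines; exit codes are 0 (success),
1 (computation error), 2 (usage error).

```sh
molcloud info input.pdb
molcloud assemble input.pdb --kind tetrahedron --edge 100 --out assembly.pdb
molcloud densify assembly.pdb --resolution 8 --voxel 2 --out map.dx
molcloud contour map.dx --mass 48000
molcloud ccs input.pdb --probe 1.0 --n-rotations 300 --seed 1
molcloud xlpath input.pdb --residue-a 1 --residue-b 12 --spacing 1.0
```

Defaults: CCS probe 1.0 Å (helium-like), SASA/accessibility probe 1.4 Å
(water), lattice spacing 1.0 Å, margin 10 Å, snap cutoff 5 Å.

## Conventions and caveats

- Units are Å everywhere; user-facing angles in degrees.
- Conformation indexing is 0-based; `current` defaults to 0.
- The projection approximation systematically underestimates
  trajectory-method CCS for large molecules; use the `calibration`
  factor to match published scales.
- Isovalue comparisons are strictly greater-than: voxels equal to the
  isovalue are excluded, making voxel counts deterministic.
- Unknown elements get mass 0 Da and radius 1.7 Å with a logged warning.
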