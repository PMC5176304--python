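"""Solvent-accessible surface area by the Shrake-Rupley sphere-point method.

Each atom's van der Waals sphere is inflated by the probe radius (default
1.4 Å, a water molecule) and covered with a deterministic, quasi-uniform
golden-spiral point set.  The accessible area is the inflated-sphere area
times the fraction of points not falling inside any neighbouring atom's
inflated sphere.  No random numbers are involved: results are exactly
reproducible for a fixed point count.

Two query strategies are provided — a KD-tree neighbour search (default)
and a brute-force all-pairs sweep — which must, and do, give identical
areas; the brute-force path doubles as the in-repo oracle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structio import Atom, Structure

__all__ = ["SasaResult", "golden_spiral_points", "compute_sasa", "compute_structure_sasa", "residue_sasa"]


def golden_spiral_points(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points via the golden-angle spiral.

    Deterministic; area-uniform in the z bands, azimuth stepped by the
    golden angle so consecutive points avoid each other.
    """
    if n < 1:
        raise ValueError("n_points must be >= 1")
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = math.pi * (3.0 - math.sqrt(5.0)) * k
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


@dataclass
class SasaResult:
    per_atom: dict[int, float]          # index into the atom list -> Å²
    per_residue: dict[tuple[str, int], float]
    probe_radius: float
    n_points: int
    radii_set_name: str = "default"

    def atom_area(self, i: int) -> float:
        return self.per_atom[i]


def _local_frame(coords: np.ndarray, i: int, nbrs_sorted: list[int]) -> np.ndarray:
    """Right-handed orthonormal frame anchored to atom i's neighbourhood.

    Orienting each atom's point set in a frame built from its neighbour
    geometry (rather than the laboratory axes) makes the computed areas
    exactly invariant under rigid motion of the whole molecule: the frame
    co-rotates, so the occlusion pattern is unchanged.  When every
    neighbour is collinear with the first, occlusion is axially symmetric
    about that axis and the azimuthal choice cannot matter.
    """
    e1 = None
    for j in nbrs_sorted:
        v = coords[j] - coords[i]
        norm = np.linalg.norm(v)
        if norm > 1e-9:
            e1 = v / norm
            break
    if e1 is None:  # all neighbours coincide with atom i
        return np.eye(3)
    e2 = None
    for j in nbrs_sorted:
        v = coords[j] - coords[i]
        w = v - (v @ e1) * e1
        norm = np.linalg.norm(w)
        if norm > 1e-6 * max(np.linalg.norm(v), 1.0):
            e2 = w / norm
            break
    if e2 is None:  # collinear neighbourhood: any azimuth is equivalent
        pick = np.argmin(np.abs(e1))
        v = np.zeros(3)
        v[pick] = 1.0
        w = v - (v @ e1) * e1
        e2 = w / np.linalg.norm(w)
    e3 = np.cross(e1, e2)
    return np.column_stack([e1, e2, e3])


def _check_atoms(atoms: list[Atom]) -> None:
    if not atoms:
        raise ValueError("need at least one atom")
    seen: dict[tuple, int] = {}
    for i, a in enumerate(atoms):
        if a.vdw_radius <= 0:
            raise ValueError(f"atom {i} ({a.name}) has non-positive radius {a.vdw_radius}")
        key = (round(a.x, 4), round(a.y, 4), round(a.z, 4))
        if key in seen:
            warnings.warn(
                f"atoms {seen[key]} and {i} share coordinates {key}; SASA computed anyway",
                stacklevel=3,
            )
        else:
            seen[key] = i


def compute_sasa(
    atoms: list[Atom],
    probe_radius: float = 1.4,
    n_points: int = 960,
    use_neighbor_search: bool = True,
    radii_set_name: str = "default",
) -> SasaResult:
    """Per-atom and per-residue solvent-accessible surface area (Å²).

    ``use_neighbor_search=False`` forces the all-pairs occlusion sweep; the
    result is bitwise identical to the KD-tree path by construction.
    """
    _check_atoms(atoms)
    coords = np.array([[a.x, a.y, a.z] for a in atoms], dtype=float)
    radii = np.array([a.vdw_radius for a in atoms], dtype=float) + probe_radius
    n = len(atoms)
    unit = golden_spiral_points(n_points)

    if use_neighbor_search and n > 1:
        tree = cKDTree(coords)
        max_reach = 2.0 * radii.max()
        pairs = tree.query_pairs(max_reach, output_type="ndarray")
        neighbors: list[list[int]] = [[] for _ in range(n)]
        for i, j in pairs:
            if np.linalg.norm(coords[i] - coords[j]) < radii[i] + radii[j]:
                neighbors[i].append(j)
                neighbors[j].append(i)
    else:
        neighbors = []
        for i in range(n):
            close = []
            for j in range(n):
                if j != i and np.linalg.norm(coords[i] - coords[j]) < radii[i] + radii[j]:
                    close.append(j)
            neighbors.append(close)

    per_atom: dict[int, float] = {}
    for i in range(n):
        sphere_area = 4.0 * math.pi * radii[i] ** 2
        nbrs = sorted(neighbors[i], key=lambda j: (np.linalg.norm(coords[j] - coords[i]), j))
        if not nbrs:
            per_atom[i] = sphere_area
            continue
        frame = _local_frame(coords, i, nbrs)
        pts = coords[i] + radii[i] * (unit @ frame.T)  # (n_points, 3)
        nc = coords[nbrs]                              # (m, 3)
        nr2 = radii[nbrs] ** 2                         # (m,)
        d2 = ((pts[:, None, :] - nc[None, :, :]) ** 2).sum(axis=2)
        accessible = ~(d2 < nr2[None, :]).any(axis=1)
        per_atom[i] = sphere_area * accessible.sum() / n_points

    per_residue: dict[tuple[str, int], float] = {}
    for i, a in enumerate(atoms):
        key = (a.chain_id, a.residue_number)
        per_residue[key] = per_residue.get(key, 0.0) + per_atom[i]

    return SasaResult(
        per_atom=per_atom,
        per_residue=per_residue,
        probe_radius=probe_radius,
        n_points=n_points,
        radii_set_name=radii_set_name,
    )


def compute_structure_sasa(
    structure: Structure,
    probe_radius: float = 1.4,
    n_points: int = 960,
    include_hetero: bool = False,
    use_neighbor_search: bool = True,
    radii_set_name: str = "default",
) -> SasaResult:
    """SASA over a structure's protein atoms.

    By default the bound ligand (all hetero atoms) is stripped before the
    calculation so candidate conjugation sites are not artificially shielded
    by the substrate; pass ``include_hetero=True`` to keep it as occluder.
    """
    atoms = list(structure.iter_all_atoms()) if include_hetero else list(structure.iter_protein_atoms())
    return compute_sasa(
        atoms,
        probe_radius=probe_radius,
        n_points=n_points,
        use_neighbor_search=use_neighbor_search,
        radii_set_name=radii_set_name,
    )


def residue_sasa(result: SasaResult, structure: Structure) -> dict[int, dict[str, float]]:
    """Re-key per-residue totals as position -> {chain_id: Å²}.

    The total is over ALL of a residue's atoms, backbone included.
    Raises if the structure contains a residue the result does not cover.
    """
    out: dict[int, dict[str, float]] = {}
    for chain_id, residues in structure.protein_chains.items():
        for res in residues:
            key = (chain_id, res.residue_number)
            if key not in result.per_residue:
                raise ValueError(f"SASA result does not cover residue {key}; structure/result mismatch")
            out.setdefault(res.residue_number, {})[chain_id] = result.per_residue[key]
    return out


def residue_sasa_table(result: SasaResult, structure: Structure):
    """Per-residue SASA as a DataFrame: chain, residue_number, residue_name, area."""
    import pandas as pd

    rows = []
    for chain_id, residues in structure.protein_chains.items():
        for res in residues:
            rows.append(
                {
                    "chain": chain_id,
                    "residue_number": res.residue_number,
                    "residue_name": res.residue_name,
                    "area_A2": result.per_residue.get((chain_id, res.residue_number), 0.0),
                }
            )
    return pd.DataFrame(rows)
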