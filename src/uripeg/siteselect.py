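"""Selection of cysteine-substitution (PEG conjugation) sites on an oligomer.

A residue position qualifies as a candidate conjugation site when, in EVERY
subunit of the oligomer, (1) its total solvent-accessible surface area
exceeds a threshold (surface exposure, default > 100 Å²) and (2) its
alpha-carbon lies farther than a threshold from every copy of the bound
substrate's reference atom (active-site distance, default > 25 Å to each
ligand C5).  A final subset is then chosen whose alpha-carbons are mutually
well separated across the whole oligomer (default >= 19.5 Å for all pairs),
so a PEG chain attached at one site cannot sterically mask another.

Candidate counts are small (single digits on a real tetramer), so the subset
search is exhaustive and exact.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .structio import Structure, map_equivalent_residues

__all__ = [
    "SiteCriteria",
    "CandidateSite",
    "SelectionReport",
    "candidate_metrics",
    "filter_candidates",
    "pairwise_ca_matrix",
    "select_sites",
    "run_site_selection",
]


@dataclass(frozen=True)
class SiteCriteria:
    """Thresholds of the three-site criteria; strict ``>`` for exposure and
    ligand distance, ``>=`` for pair separation."""

    sasa_min: float = 100.0          # Å², per subunit, strict >
    ligand_min_dist: float = 25.0    # Å  Cα to every ligand reference atom, strict >
    pair_min_dist: float = 19.5      # Å  min cross-oligomer Cα–Cα, >=
    require_all_subunits: bool = True

    def __post_init__(self):
        if min(self.sasa_min, self.ligand_min_dist, self.pair_min_dist) <= 0:
            raise ValueError("all thresholds must be positive")


@dataclass
class CandidateSite:
    residue_number: int
    residue_name: str
    sasa_per_chain: dict[str, float]
    min_ligand_dist_per_chain: dict[str, float]
    passes_sasa: bool = False
    passes_ligand: bool = False

    def evaluate(self, criteria: SiteCriteria) -> "CandidateSite":
        sasa_ok = [v > criteria.sasa_min for v in self.sasa_per_chain.values()]
        lig_ok = [v > criteria.ligand_min_dist for v in self.min_ligand_dist_per_chain.values()]
        if criteria.require_all_subunits:
            self.passes_sasa = all(sasa_ok)
            self.passes_ligand = all(lig_ok)
        else:
            self.passes_sasa = any(sasa_ok)
            self.passes_ligand = any(lig_ok)
        return self


@dataclass
class SelectionReport:
    criteria: SiteCriteria
    candidates: list[CandidateSite]
    passing_positions: list[int]
    pair_matrix: dict[tuple[int, int], float]
    self_pair: dict[int, float]
    selected: list[int]
    skipped_positions: list[int] = field(default_factory=list)
    n_positions_scanned: int = 0

    def to_json(self, **kwargs) -> str:
        d = {
            "criteria": asdict(self.criteria),
            "n_positions_scanned": self.n_positions_scanned,
            "skipped_positions": self.skipped_positions,
            "candidates": [asdict(c) for c in self.candidates],
            "passing_positions": self.passing_positions,
            "pair_matrix": {f"{i}-{j}": v for (i, j), v in sorted(self.pair_matrix.items())},
            "self_pair": self.self_pair,
            "selected": self.selected,
        }
        return json.dumps(d, indent=2, **kwargs)


def _ca_coords(structure: Structure) -> dict[int, dict[str, np.ndarray]]:
    """position -> chain -> Cα coordinate, for positions shared by all chains."""
    mapping, _ = map_equivalent_residues(structure)
    out: dict[int, dict[str, np.ndarray]] = {}
    for pos, members in mapping.items():
        cas = {}
        for res in members:
            ca = res.get_atom("CA")
            if ca is None:
                break
            cas[res.chain_id] = np.array(ca.coord)
        else:
            out[pos] = cas
    return out


def candidate_metrics(
    structure: Structure,
    sasa_by_residue: dict[int, dict[str, float]],
    ligand_points: list[np.ndarray],
    criteria: SiteCriteria | None = None,
) -> tuple[list[CandidateSite], list[int]]:
    """Per-position exposure and active-site-distance metrics across subunits.

    Returns ``(candidates, skipped)``; positions missing a Cα in any chain
    (incompletely modelled residues) are skipped and reported, not guessed.
    """
    if not ligand_points:
        raise ValueError("ligand point set is empty; cannot evaluate active-site distances")
    criteria = criteria or SiteCriteria()
    mapping, skipped_numbering = map_equivalent_residues(structure)
    if not mapping:
        raise ValueError("no residue positions shared by all chains")
    lig = np.vstack(ligand_points)

    candidates: list[CandidateSite] = []
    skipped: list[int] = list(skipped_numbering)
    for pos in sorted(mapping):
        members = mapping[pos]
        sasa_pc: dict[str, float] = {}
        dist_pc: dict[str, float] = {}
        ok = True
        for res in members:
            ca = res.get_atom("CA")
            if ca is None:
                ok = False
                break
            d = np.linalg.norm(lig - np.array(ca.coord), axis=1)
            dist_pc[res.chain_id] = float(d.min())
            sasa_pc[res.chain_id] = float(sasa_by_residue.get(pos, {}).get(res.chain_id, 0.0))
        if not ok:
            skipped.append(pos)
            continue
        candidates.append(
            CandidateSite(
                residue_number=pos,
                residue_name=members[0].residue_name,
                sasa_per_chain=sasa_pc,
                min_ligand_dist_per_chain=dist_pc,
            ).evaluate(criteria)
        )
    return candidates, sorted(skipped)


def filter_candidates(candidates: list[CandidateSite], criteria: SiteCriteria | None = None) -> list[int]:
    """Positions passing BOTH criteria in every subunit, sorted by number."""
    criteria = criteria or SiteCriteria()
    passing = []
    for c in candidates:
        c.evaluate(criteria)
        if c.passes_sasa and c.passes_ligand:
            passing.append(c.residue_number)
    return sorted(passing)


def pairwise_ca_matrix(
    structure: Structure, positions: list[int]
) -> tuple[dict[tuple[int, int], float], dict[int, float]]:
    """Minimum Cα–Cα distances across the whole oligomer.

    ``pair_matrix[(i, j)]`` (i < j) is the minimum over ALL chain pairs,
    same-chain included — PEG clash is a physical whole-oligomer constraint.
    ``self_pair[i]`` is the minimum distance between copies of position i on
    distinct chains, reported as a diagnostic only.
    """
    cas = _ca_coords(structure)
    for pos in positions:
        if pos not in cas:
            raise ValueError(f"position {pos} lacks a Cα in at least one chain")
    chain_ids = sorted(next(iter(cas.values())).keys()) if cas else []

    pair_matrix: dict[tuple[int, int], float] = {}
    for i, j in itertools.combinations(sorted(positions), 2):
        pi = np.vstack([cas[i][c] for c in chain_ids])
        pj = np.vstack([cas[j][c] for c in chain_ids])
        d = np.linalg.norm(pi[:, None, :] - pj[None, :, :], axis=2)
        pair_matrix[(i, j)] = float(d.min())

    self_pair: dict[int, float] = {}
    for i in sorted(positions):
        pts = np.vstack([cas[i][c] for c in chain_ids])
        if len(pts) < 2:
            self_pair[i] = float("inf")
            continue
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        self_pair[i] = float(d.min())
    return pair_matrix, self_pair


def _pair_dist(pair_matrix: dict[tuple[int, int], float], i: int, j: int) -> float:
    return pair_matrix[(i, j)] if (i, j) in pair_matrix else pair_matrix[(j, i)]


def _subset_feasible(subset: tuple[int, ...], pair_matrix, threshold: float) -> bool:
    return all(_pair_dist(pair_matrix, i, j) >= threshold for i, j in itertools.combinations(subset, 2))


def select_sites(
    passing_positions: list[int],
    pair_matrix: dict[tuple[int, int], float],
    criteria: SiteCriteria | None = None,
    k: int | str = "max",
    sasa_by_position: dict[int, float] | None = None,
) -> list[int]:
    """Exhaustively pick a mutually well-separated subset of passing sites.

    Every pair in the returned subset is >= ``pair_min_dist`` apart (minimum
    over all subunit combinations).  Among feasible subsets of the requested
    size, the one maximising summed minimum per-chain SASA wins
    (``sasa_by_position``: position -> min-over-chains SASA); remaining ties
    go to the lexicographically smallest residue-number tuple.
    """
    criteria = criteria or SiteCriteria()
    positions = sorted(passing_positions)
    if k == "max":
        sizes = range(len(positions), 0, -1)
    else:
        if not isinstance(k, int) or k < 1:
            raise ValueError(f"k must be a positive integer or 'max', got {k!r}")
        sizes = [k]

    sasa_score = sasa_by_position or {}
    for size in sizes:
        best: tuple[float, tuple[int, ...]] | None = None
        for subset in itertools.combinations(positions, size):
            if not _subset_feasible(subset, pair_matrix, criteria.pair_min_dist):
                continue
            score = sum(sasa_score.get(p, 0.0) for p in subset)
            # maximise score; tie -> lexicographically smallest tuple
            key = (-score, subset)
            if best is None or key < (-best[0], best[1]):
                best = (score, subset)
        if best is not None:
            return list(best[1])
    if k == "max":
        return []
    largest = 0
    for size in range(len(positions), 0, -1):
        if any(
            _subset_feasible(s, pair_matrix, criteria.pair_min_dist)
            for s in itertools.combinations(positions, size)
        ):
            largest = size
            break
    raise ValueError(f"no feasible subset of size {k}; largest feasible size is {largest}")


def run_site_selection(
    structure: Structure,
    sasa_by_residue: dict[int, dict[str, float]],
    ligand_points: list[np.ndarray],
    criteria: SiteCriteria | None = None,
    k: int | str = "max",
) -> SelectionReport:
    """Full scan: metrics -> filter -> pair matrix -> exhaustive selection."""
    criteria = criteria or SiteCriteria()
    candidates, skipped = candidate_metrics(structure, sasa_by_residue, ligand_points, criteria)
    passing = filter_candidates(candidates, criteria)
    pair_matrix, self_pair = pairwise_ca_matrix(structure, passing) if passing else ({}, {})
    sasa_by_position = {
        c.residue_number: min(c.sasa_per_chain.values()) for c in candidates if c.residue_number in passing
    }
    selected = (
        select_sites(passing, pair_matrix, criteria, k=k, sasa_by_position=sasa_by_position) if passing else []
    )
    return SelectionReport(
        criteria=criteria,
        candidates=candidates,
        passing_positions=passing,
        pair_matrix=pair_matrix,
        self_pair=self_pair,
        selected=selected,
        skipped_positions=skipped,
        n_positions_scanned=len(candidates),
    )
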