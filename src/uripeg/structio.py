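"""Read and write protein structures in fixed-column PDB format.

The structure model is deliberately small: atoms grouped into residues,
residues grouped into protein chains, plus a flat list of non-water hetero
residues (ligand copies).  Hydrogens and waters are always dropped — the
downstream surface-area scan is heavy-atom based — and alternate locations
are resolved to a single conformer at parse time so that every later
computation is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "PDBFormatError",
    "ChainMismatchError",
    "VDW_RADII",
    "read_pdb",
    "parse_pdb_text",
    "write_pdb",
    "assign_radii",
    "select_ligand_atoms",
    "map_equivalent_residues",
]

#: Element-based van der Waals radii (Å).  The default set; a Bondi-flavoured
#: alternate is shipped because per-residue areas near a threshold can be
#: sensitive to the radii convention.
VDW_RADII: dict[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}
VDW_RADII_ALT: dict[str, float] = {"C": 1.77, "N": 1.64, "O": 1.46, "S": 1.77, "P": 1.80}
DEFAULT_RADIUS = 1.70

WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})


class PDBFormatError(ValueError):
    """Raised when a PDB record cannot be parsed; carries the line number."""


class ChainMismatchError(ValueError):
    """Raised when chains disagree on residue identity at a shared position."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    alt_loc: str
    residue_name: str
    chain_id: str
    residue_number: int
    insertion_code: str
    x: float
    y: float
    z: float
    occupancy: float
    is_hetero: bool
    vdw_radius: float = 0.0

    @property
    def coord(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass
class Residue:
    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atoms: list[Atom] = field(default_factory=list)

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)


@dataclass
class Structure:
    protein_chains: dict[str, list[Residue]]
    ligand_groups: list[Residue]
    source_id: str = ""

    def iter_protein_atoms(self) -> Iterator[Atom]:
        for residues in self.protein_chains.values():
            for res in residues:
                yield from res.atoms

    def iter_all_atoms(self) -> Iterator[Atom]:
        yield from self.iter_protein_atoms()
        for res in self.ligand_groups:
            yield from res.atoms

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.iter_all_atoms())


def _infer_element(name_field: str) -> str:
    """Fall back to the atom-name convention when columns 77-78 are blank.

    In a standard name field the element is right-justified in the first two
    columns; a leading digit (e.g. '1HG1') marks a hydrogen variant.
    """
    stripped = name_field.strip()
    if not stripped:
        return ""
    if name_field[:1].strip().isdigit():
        return "H"
    two = name_field[:2].strip()
    if len(two) == 2 and two.isalpha() and two.upper() in ("FE", "ZN", "MG", "MN", "CU", "NA", "CL", "CA", "BR"):
        return two.capitalize().upper()
    return stripped[0].upper()


def _parse_atom_line(line: str, lineno: int) -> Atom:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        alt_loc = line[16].strip()
        residue_name = line[17:20].strip()
        chain_id = line[21].strip() or " "
        residue_number = int(line[22:26])
        insertion_code = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element = line[76:78].strip().upper() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PDBFormatError(f"unparseable ATOM/HETATM record at line {lineno}: {exc}") from exc
    if not element:
        element = _infer_element(line[12:16])
    if not all(math.isfinite(v) for v in (x, y, z)):
        raise PDBFormatError(f"non-finite coordinate at line {lineno}")
    return Atom(
        serial=serial,
        name=name,
        element=element,
        alt_loc=alt_loc,
        residue_name=residue_name,
        chain_id=chain_id,
        residue_number=residue_number,
        insertion_code=insertion_code,
        x=x,
        y=y,
        z=z,
        occupancy=max(0.0, min(1.0, occupancy)),
        is_hetero=line.startswith("HETATM"),
    )


def _resolve_altlocs(atoms: list[Atom], policy: str) -> list[Atom]:
    """Keep exactly one conformer per (residue, atom name).

    ``highest_occupancy`` (default): largest occupancy wins, ties broken by
    the alphabetically first alt_loc.  ``first``: first record encountered.
    """
    if policy not in ("highest_occupancy", "first"):
        raise ValueError(f"unknown altloc policy: {policy!r}")
    chosen: dict[tuple, Atom] = {}
    order: list[tuple] = []
    for atom in atoms:
        key = (atom.chain_id, atom.residue_number, atom.insertion_code, atom.residue_name, atom.name)
        if key not in chosen:
            chosen[key] = atom
            order.append(key)
        elif policy == "highest_occupancy":
            incumbent = chosen[key]
            if (atom.occupancy, _altloc_rank(atom.alt_loc)) > (
                incumbent.occupancy,
                _altloc_rank(incumbent.alt_loc),
            ):
                chosen[key] = atom
    return [chosen[k] for k in order]


def _altloc_rank(alt: str) -> float:
    # alphabetically first wins on an occupancy tie, so rank it highest
    return -ord(alt) if alt else 0.0


def parse_pdb_text(text: str, altloc_policy: str = "highest_occupancy", source_id: str = "") -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    ATOM records populate protein chains; non-water HETATM records become
    ligand groups; waters and hydrogens are dropped.
    """
    raw: list[Atom] = []
    n_atom_records = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            n_atom_records += 1
            atom = _parse_atom_line(line, lineno)
            if atom.element == "H" or atom.element == "D":
                continue
            if atom.residue_name in WATER_NAMES:
                continue
            raw.append(atom)
    if n_atom_records == 0:
        raise PDBFormatError("no ATOM or HETATM records found")
    atoms = _resolve_altlocs(raw, altloc_policy)

    chains: dict[str, dict[tuple, Residue]] = {}
    ligands: dict[tuple, Residue] = {}
    for atom in atoms:
        if atom.is_hetero:
            key = (atom.chain_id, atom.residue_number, atom.insertion_code, atom.residue_name)
            res = ligands.setdefault(
                key, Residue(atom.chain_id, atom.residue_number, atom.insertion_code, atom.residue_name)
            )
            res.atoms.append(atom)
        else:
            res_key = (atom.residue_number, atom.insertion_code, atom.residue_name)
            chain = chains.setdefault(atom.chain_id, {})
            res = chain.setdefault(
                res_key, Residue(atom.chain_id, atom.residue_number, atom.insertion_code, atom.residue_name)
            )
            res.atoms.append(atom)
    if not chains:
        raise PDBFormatError("no protein (ATOM) records found")

    protein_chains: dict[str, list[Residue]] = {}
    for chain_id in sorted(chains):
        residues = sorted(chains[chain_id].values(), key=lambda r: (r.residue_number, r.insertion_code))
        protein_chains[chain_id] = residues
    return Structure(
        protein_chains=protein_chains,
        ligand_groups=sorted(ligands.values(), key=lambda r: (r.chain_id, r.residue_number, r.insertion_code)),
        source_id=source_id,
    )


def read_pdb(path: str | Path, altloc_policy: str = "highest_occupancy") -> Structure:
    """Read a PDB file from disk.  See :func:`parse_pdb_text`."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"PDB file not found: {p}")
    return parse_pdb_text(p.read_text(), altloc_policy=altloc_policy, source_id=p.stem)


def write_pdb(structure: Structure, path: str | Path | None = None) -> str:
    """Emit canonical 80-column ATOM/HETATM records; returns the text."""
    lines: list[str] = []
    serial = 0
    for atom in structure.iter_all_atoms():
        serial += 1
        record = "HETATM" if atom.is_hetero else "ATOM  "
        name = atom.name
        # column-13 convention: atom names of <4 chars start in column 14
        name_field = name if len(name) >= 4 else f" {name:<3s}"
        lines.append(
            f"{record}{serial:>5d} {name_field}{atom.alt_loc or ' '}"
            f"{atom.residue_name:>3s} {atom.chain_id}{atom.residue_number:>4d}"
            f"{atom.insertion_code or ' '}   "
            f"{atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
            f"{'':10s}{atom.element:>2s}"
        )
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def assign_radii(structure: Structure, radii: dict[str, float] | None = None, default: float = DEFAULT_RADIUS) -> Structure:
    """Assign element-based van der Waals radii in place; returns the structure."""
    table = VDW_RADII if radii is None else radii
    for atom in structure.iter_all_atoms():
        atom.vdw_radius = table.get(atom.element, default)
    return structure


def select_ligand_atoms(structure: Structure, residue_name: str, atom_name: str):
    """Return one 3-D point per ligand copy carrying the named atom.

    Order follows chain / residue-number order; an empty list is a valid
    result (the ligand code or atom name simply was not found).
    """
    import numpy as np

    points = []
    for res in structure.ligand_groups:
        if res.residue_name != residue_name:
            continue
        atom = res.get_atom(atom_name)
        if atom is not None:
            points.append([atom.x, atom.y, atom.z])
    return [np.asarray(p, dtype=float) for p in points]


def map_equivalent_residues(structure: Structure) -> tuple[dict[int, tuple[Residue, ...]], list[int]]:
    """Pair up equivalent residues across subunits by residue number.

    Returns ``(mapping, skipped)`` where ``mapping[pos]`` is the tuple of
    per-chain residues at that number (chain order = sorted chain ids) and
    ``skipped`` lists numbers absent from at least one chain.  Chains that
    disagree on the residue name at a shared number raise
    :class:`ChainMismatchError` — correspondence is by numbering, never by
    alignment guesswork.
    """
    chain_ids = sorted(structure.protein_chains)
    per_chain: list[dict[int, Residue]] = []
    for cid in chain_ids:
        # insertion-coded duplicates of a number are not equivalence-mappable;
        # keep the first by insertion-code order
        d: dict[int, Residue] = {}
        for res in structure.protein_chains[cid]:
            d.setdefault(res.residue_number, res)
        per_chain.append(d)

    all_numbers = sorted(set().union(*(d.keys() for d in per_chain)))
    shared = [n for n in all_numbers if all(n in d for d in per_chain)]
    skipped = [n for n in all_numbers if n not in shared]

    mismatches = []
    mapping: dict[int, tuple[Residue, ...]] = {}
    for n in shared:
        members = tuple(d[n] for d in per_chain)
        names = {r.residue_name for r in members}
        if len(names) > 1:
            mismatches.append((n, sorted(names)))
        else:
            mapping[n] = members
    if mismatches:
        detail = "; ".join(f"position {n}: {names}" for n, names in mismatches)
        raise ChainMismatchError(f"chains disagree on residue identity at shared positions: {detail}")
    return mapping, skipped
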