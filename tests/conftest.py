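"""Shared fixtures: tiny hand-built structures and the default toy oligomer."""

from __future__ import annotations

import numpy as np
import pytest

from uripeg import sasa, structio, synth
from uripeg.structio import Atom, Residue, Structure, assign_radii


def build_structure(chains: dict, ligands: list | None = None) -> Structure:
    """Assemble a Structure from a compact literal description.

    ``chains``: chain_id -> list of (resnum, resname, {atom_name: (x, y, z)}).
    ``ligands``: list of (chain_id, resnum, resname, {atom_name: xyz}).
    Elements are inferred from the first letter of the atom name; radii are
    assigned from the default set.
    """
    serial = 1
    protein_chains: dict[str, list[Residue]] = {}
    for cid, residues in chains.items():
        lst = []
        for resnum, resname, atoms in residues:
            res = Residue(cid, resnum, "", resname)
            for aname, (x, y, z) in atoms.items():
                elem = "C" if aname.startswith("C") or aname.startswith("X") else aname[0]
                res.atoms.append(
                    Atom(serial, aname, elem, "", resname, cid, resnum, "", float(x), float(y),
                         float(z), 1.0, False)
                )
                serial += 1
            lst.append(res)
        protein_chains[cid] = lst
    ligand_groups = []
    for cid, resnum, resname, atoms in ligands or []:
        res = Residue(cid, resnum, "", resname)
        for aname, (x, y, z) in atoms.items():
            res.atoms.append(
                Atom(serial, aname, aname[0], "", resname, cid, resnum, "", float(x), float(y),
                     float(z), 1.0, True)
            )
            serial += 1
        ligand_groups.append(res)
    return assign_radii(Structure(protein_chains=protein_chains, ligand_groups=ligand_groups, source_id="test"))


@pytest.fixture(scope="session")
def toy_default():
    """Default C4 toy oligomer with its planted truth and computed SASA."""
    spec = synth.ToyOligomerSpec()
    structure, truth = synth.make_toy_oligomer(spec)
    result = sasa.compute_structure_sasa(structure)
    by_residue = sasa.residue_sasa(result, structure)
    ligand_points = structio.select_ligand_atoms(structure, "LIG", "C5")
    return {
        "spec": spec,
        "structure": structure,
        "truth": truth,
        "sasa_result": result,
        "by_residue": by_residue,
        "ligand_points": ligand_points,
    }
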