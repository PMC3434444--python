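"""Shared builders for in-memory models and contact sets."""
from __future__ import annotations

import numpy as np
import pytest

from conscontacts.contacts import ContactSet
from conscontacts.structure_io import AtomRecord, ComplexModel, ResidueKey


def rk(number: int, chain: str = "A", icode: str = "", name: str = "ALA") -> ResidueKey:
    return ResidueKey("receptor", chain, number, icode, name)


def lk(number: int, chain: str = "B", icode: str = "", name: str = "ALA") -> ResidueKey:
    return ResidueKey("ligand", chain, number, icode, name)


def make_atom(
    name: str,
    chain: str,
    number: int,
    xyz,
    resname: str = "ALA",
    element: str | None = None,
    **kwargs,
) -> AtomRecord:
    if element is None:
        element = name[0]
    return AtomRecord(
        name=name,
        element=element,
        chain_id=chain,
        residue_number=number,
        insertion_code=kwargs.pop("insertion_code", ""),
        residue_name=resname,
        altloc=kwargs.pop("altloc", ""),
        coords=tuple(float(v) for v in xyz),
        **kwargs,
    )


def model_from_points(
    receptor_points, ligand_points, model_id: str = "m", atom_names=None
) -> ComplexModel:
    """Build a model from per-residue atom coordinate lists.

    Each element of receptor_points / ligand_points is either a single xyz
    (one-atom residue) or a list of xyz (multi-atom residue).
    """

    def build(points, partner, chain, key_fn):
        residues = {}
        for i, entry in enumerate(points, start=1):
            coords = np.atleast_2d(np.asarray(entry, dtype=float))
            names = atom_names or [f"C{j}" if j else "CA" for j in range(len(coords))]
            residues[key_fn(i, chain)] = [
                make_atom(names[j], chain, i, coords[j]) for j in range(len(coords))
            ]
        return residues

    return ComplexModel(
        model_id=model_id,
        receptor_residues=build(receptor_points, "receptor", "A", rk),
        ligand_residues=build(ligand_points, "ligand", "B", lk),
    )


def contact_set(pairs, model_id: str = "m", cutoff: float = 5.0) -> ContactSet:
    """ContactSet from abstract (receptor_number, ligand_number) int pairs."""
    mapped = frozenset((rk(i), lk(j)) for i, j in pairs)
    return ContactSet(
        model_id=model_id,
        cutoff=cutoff,
        contacts=mapped,
        min_distances={pair: 0.0 for pair in mapped},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
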