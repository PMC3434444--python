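"""PDB input/output and the receptor/ligand partition of a docking model.

A docking model of a two-partner complex is loaded into a :class:`ComplexModel`
holding its atoms grouped by residue, split into a "receptor" side and a
"ligand" side according to a user-declared chain partition.  Residues are
identified across models by (chain id, residue number, insertion code), the
shared-numbering convention of blind docking assessments; no sequence
alignment fallback is attempted.

Parsing is delegated to :mod:`gemmi`; this module applies the filtering
policy (hydrogens, waters, hetero groups, alternate locations) and flattens
the hierarchy into plain records.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .errors import DataError, UsageError

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}
HYDROGEN_ELEMENTS = {"H", "D"}


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a model: identity plus Cartesian coordinates in Å."""

    name: str
    element: str
    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    altloc: str
    coords: tuple[float, float, float]
    is_hetero: bool = False
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.coords)):
            raise DataError(f"non-finite coordinates for atom {self.name}")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in HYDROGEN_ELEMENTS


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Identity of one residue within a partner.

    Equality and ordering use (partner, chain_id, residue_number,
    insertion_code); the residue name is carried along for reporting only.
    """

    partner: str  # "receptor" | "ligand"
    chain_id: str
    residue_number: int
    insertion_code: str = ""
    residue_name: str = field(default="", compare=False)

    def __str__(self) -> str:
        icode = self.insertion_code.strip()
        return f"{self.chain_id}:{self.residue_number}{icode}"


@dataclass
class ComplexModel:
    """One docking model split into receptor and ligand residue sets.

    Residues are stored in stable order (chain id, residue number,
    insertion code); every residue has at least one atom.
    """

    model_id: str
    receptor_residues: dict[ResidueKey, list[AtomRecord]]
    ligand_residues: dict[ResidueKey, list[AtomRecord]]

    def residues(self, partner: str) -> dict[ResidueKey, list[AtomRecord]]:
        if partner == "receptor":
            return self.receptor_residues
        if partner == "ligand":
            return self.ligand_residues
        raise UsageError(f"unknown partner {partner!r}")

    @property
    def n_atoms(self) -> int:
        return sum(len(a) for a in self.receptor_residues.values()) + sum(
            len(a) for a in self.ligand_residues.values()
        )

    def partner_coords(self, partner: str) -> tuple[np.ndarray, np.ndarray, list[ResidueKey]]:
        """Flatten one partner to (coords[n,3], residue_index[n], keys)."""
        residues = self.residues(partner)
        keys = list(residues)
        coords, index = [], []
        for i, key in enumerate(keys):
            for atom in residues[key]:
                coords.append(atom.coords)
                index.append(i)
        return np.asarray(coords, dtype=float), np.asarray(index, dtype=int), keys


def _resolve_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one conformer per atom name: highest occupancy, first on tie."""
    best: dict[str, AtomRecord] = {}
    order: list[str] = []
    for atom in atoms:
        prev = best.get(atom.name)
        if prev is None:
            best[atom.name] = atom
            order.append(atom.name)
        elif atom.occupancy > prev.occupancy:
            best[atom.name] = atom
    return [best[name] for name in order]


def read_model(
    path: str | Path,
    receptor_chains: Iterable[str],
    ligand_chains: Iterable[str],
    model_index: int | None = None,
    include_hydrogens: bool = False,
    include_hetero: bool = True,
) -> ComplexModel:
    """Read one PDB file into a :class:`ComplexModel`.

    Parameters
    ----------
    path:
        PDB-format coordinate file.
    receptor_chains, ligand_chains:
        Disjoint, non-empty chain-id sets defining the two partners.
    model_index:
        0-based MODEL block to read.  Required if the file holds more than
        one MODEL; a single-model file needs none.
    include_hydrogens:
        Keep hydrogen/deuterium atoms (dropped by default: docking models
        carry them inconsistently).
    include_hetero:
        Keep non-water HETATM groups such as ions and cofactors (default);
        waters are always dropped.
    """
    receptor_chains = set(receptor_chains)
    ligand_chains = set(ligand_chains)
    if not receptor_chains or not ligand_chains:
        raise UsageError("receptor and ligand chain sets must be non-empty")
    overlap = receptor_chains & ligand_chains
    if overlap:
        raise UsageError(f"receptor/ligand chain sets overlap: {sorted(overlap)}")

    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    try:
        structure = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise DataError(f"cannot parse {path}: {exc}") from exc

    if len(structure) == 0:
        raise DataError(f"{path}: no coordinate models found")
    if len(structure) > 1 and model_index is None:
        raise UsageError(
            f"{path}: file holds {len(structure)} MODEL blocks; a model_index is required"
        )
    index = model_index if model_index is not None else 0
    if not 0 <= index < len(structure):
        raise UsageError(f"{path}: model_index {index} out of range (0..{len(structure) - 1})")
    model = structure[index]

    wanted = {c: "receptor" for c in receptor_chains}
    wanted.update({c: "ligand" for c in ligand_chains})
    collected: dict[str, dict[ResidueKey, list[AtomRecord]]] = {
        "receptor": {},
        "ligand": {},
    }
    for chain in model:
        partner = wanted.get(chain.name)
        if partner is None:
            continue
        for residue in chain:
            if residue.name.strip().upper() in WATER_NAMES:
                continue
            is_het = residue.het_flag == "H"
            if is_het and not include_hetero:
                continue
            atoms: list[AtomRecord] = []
            for atom in residue:
                element = atom.element.name.strip().upper()
                if element in HYDROGEN_ELEMENTS and not include_hydrogens:
                    continue
                atoms.append(
                    AtomRecord(
                        name=atom.name,
                        element=element,
                        chain_id=chain.name,
                        residue_number=residue.seqid.num,
                        insertion_code=residue.seqid.icode.strip(),
                        residue_name=residue.name,
                        altloc=atom.altloc.replace("\x00", "").strip(),
                        coords=(atom.pos.x, atom.pos.y, atom.pos.z),
                        is_hetero=is_het,
                        occupancy=atom.occ,
                    )
                )
            atoms = _resolve_altlocs(atoms)
            if not atoms:
                continue
            key = ResidueKey(
                partner=partner,
                chain_id=chain.name,
                residue_number=residue.seqid.num,
                insertion_code=residue.seqid.icode.strip(),
                residue_name=residue.name,
            )
            collected[partner].setdefault(key, []).extend(atoms)

    for partner, chains in (("receptor", receptor_chains), ("ligand", ligand_chains)):
        present = {key.chain_id for key in collected[partner]}
        missing = chains - present
        if missing:
            raise DataError(f"{path}: no atoms for chain(s) {sorted(missing)}")

    return ComplexModel(
        model_id=path.stem if model_index is None else f"{path.stem}#{index}",
        receptor_residues=dict(sorted(collected["receptor"].items())),
        ligand_residues=dict(sorted(collected["ligand"].items())),
    )


def read_ensemble(
    paths: Sequence[str | Path],
    receptor_chains: Iterable[str],
    ligand_chains: Iterable[str],
    **kwargs,
) -> list[ComplexModel]:
    """Read ≥2 models, in input order, checking residue-set consistency.

    The conservation scores assume a residue numbering shared by every model;
    residues missing from some models are reported as a warning (not an
    error) so that a truncated model does not abort ensemble analysis.
    """
    if len(paths) < 2:
        raise UsageError("ensemble requires >=2 models")
    models = []
    for path in paths:
        try:
            models.append(read_model(path, receptor_chains, ligand_chains, **kwargs))
        except (DataError, UsageError) as exc:
            raise type(exc)(f"{path}: {exc}") from exc

    universe: set[ResidueKey] = set()
    for model in models:
        universe |= set(model.receptor_residues) | set(model.ligand_residues)
    not_shared = set()
    for model in models:
        not_shared |= universe - (set(model.receptor_residues) | set(model.ligand_residues))
    if not_shared:
        listing = ", ".join(str(k) for k in sorted(not_shared)[:20])
        more = "" if len(not_shared) <= 20 else f" (+{len(not_shared) - 20} more)"
        warnings.warn(
            f"{len(not_shared)} residue(s) not shared by all models: {listing}{more}",
            stacklevel=2,
        )
    return models


def _pdb_atom_name(name: str, element: str) -> str:
    # Column alignment convention: names start in column 14 unless the
    # element symbol is two characters or the name fills four columns.
    if len(name) >= 4 or len(element) == 2:
        return f"{name:<4.4s}"
    return f" {name:<3s}"


def write_model(model: ComplexModel, path: str | Path) -> None:
    """Write a ComplexModel as a fixed-column PDB file (deterministic bytes)."""
    lines = []
    serial = 0
    for residues in (model.receptor_residues, model.ligand_residues):
        for key, atoms in residues.items():
            for atom in atoms:
                serial += 1
                record = "HETATM" if atom.is_hetero else "ATOM  "
                x, y, z = atom.coords
                lines.append(
                    f"{record}{serial:5d} {_pdb_atom_name(atom.name, atom.element)}"
                    f"{atom.altloc or ' '}{key.residue_name:<3.3s} {key.chain_id:1.1s}"
                    f"{key.residue_number:4d}{key.insertion_code or ' ':1.1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2.2s}"
                )
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
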