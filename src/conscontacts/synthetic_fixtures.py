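"""Synthetic toy complexes and docking-model ensembles with planted truth.

Real docking decoys are bulky and not redistributable, so every part of the
package is exercised on generated stand-ins: two-chain PDB files of
pseudo-residues (three atoms each, named N/CA/C) whose interface geometry is
simple enough that the exact contact set is known by construction and by an
exhaustive oracle.

Two generators are provided:

* ``make_toy_complex`` — a random receptor blob (chain A) facing a ligand
  blob (chain B) across an adjustable gap; the ground-truth contact set is
  computed by the naive all-atom-pairs oracle and written next to the file.

* ``make_ensemble`` — an ensemble of rigid-body ligand placements around a
  fixed receptor with a controllable fraction of conserved contacts.  The
  receptor is a central hub residue plus an annular lattice of rim
  residues; the ligand is a compact "core" cluster over the hub plus a
  radial "arm" over the rim.  Each model rotates the ligand about the
  interface normal to a distinct lattice slot: core contacts survive every
  rotation (distances to the on-axis hub are rotation-invariant), arm
  contacts land on a model-specific rim column and are shared by no other
  model.  Every pair of models therefore shares exactly the core, so the
  pairwise conservation score of every model pair equals
  round(target_overlap * n) / n by construction.  Alternatively a
  displacement ladder of pure ligand translations is planted for RMSD
  checks.

All randomness flows from the seed; a fixed spec reproduces byte-identical
files.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .contacts import ContactSet, ContactPair
from .errors import UsageError
from .structure_io import AtomRecord, ComplexModel, ResidueKey, write_model

_ATOM_NAMES = ("N", "CA", "C")
_ELEMENTS = {"N": "N", "CA": "C", "C": "C"}


def naive_contacts(model: ComplexModel, cutoff: float = 5.0) -> ContactSet:
    """Exhaustive all-atom-pairs contact oracle (no spatial indexing).

    Computes every receptor-atom/ligand-atom distance and takes the minimum
    per residue pair; a pair is a contact iff that minimum is strictly
    below the cutoff.  Used as ground truth for the k-d-tree implementation.
    """
    r_xyz, r_idx, r_keys = model.partner_coords("receptor")
    l_xyz, l_idx, l_keys = model.partner_coords("ligand")
    dists = cdist(r_xyz, l_xyz)
    nr, nl = len(r_keys), len(l_keys)
    per_pair = np.full(nr * nl, np.inf)
    codes = r_idx[:, None] * nl + l_idx[None, :]
    np.minimum.at(per_pair, codes.ravel(), dists.ravel())
    per_pair = per_pair.reshape(nr, nl)
    min_dist: dict[ContactPair, float] = {}
    for i, j in zip(*np.nonzero(per_pair < cutoff)):
        min_dist[(r_keys[i], l_keys[j])] = float(per_pair[i, j])
    return ContactSet(
        model_id=model.model_id,
        cutoff=cutoff,
        contacts=frozenset(min_dist),
        min_distances=min_dist,
    )


def _residue(
    partner: str,
    chain: str,
    number: int,
    center: np.ndarray,
    offsets: np.ndarray,
) -> tuple[ResidueKey, list[AtomRecord]]:
    key = ResidueKey(partner, chain, number, "", "ALA")
    atoms = [
        AtomRecord(
            name=name,
            element=_ELEMENTS[name],
            chain_id=chain,
            residue_number=number,
            insertion_code="",
            residue_name="ALA",
            altloc="",
            coords=tuple(np.round(center + offsets[i], 3)),
        )
        for i, name in enumerate(_ATOM_NAMES)
    ]
    return key, atoms


def make_toy_complex(
    residues_per_side: int,
    seed: int,
    gap: float | None = None,
    out_path: str | Path | None = None,
    cutoff: float = 5.0,
) -> tuple[ComplexModel, ContactSet]:
    """Random two-blob complex with its oracle-computed ground-truth contacts.

    Receptor residues fill a cube; ligand residues fill a cube displaced
    along +x by the cube edge plus ``gap`` Å (random in [-3, 2] when not
    given, which yields a populated interface).  If ``out_path`` is given
    the PDB file and a ``.contacts.tsv`` ground-truth sidecar are written.
    """
    if residues_per_side < 2:
        raise UsageError("residues_per_side must be >=2")
    rng = np.random.default_rng(seed)
    edge = 5.5 * residues_per_side ** (1.0 / 3.0)
    if gap is None:
        gap = float(rng.uniform(-6.0, 0.0))

    receptor: dict[ResidueKey, list[AtomRecord]] = {}
    ligand: dict[ResidueKey, list[AtomRecord]] = {}
    for side, (partner, chain, shift) in enumerate(
        (("receptor", "A", 0.0), ("ligand", "B", edge + gap))
    ):
        for num in range(1, residues_per_side + 1):
            center = rng.uniform(0.0, edge, 3) + np.array([shift, 0.0, 0.0])
            offsets = rng.uniform(-0.7, 0.7, (3, 3))
            key, atoms = _residue(partner, chain, num, center, offsets)
            (receptor if side == 0 else ligand)[key] = atoms

    model = ComplexModel(
        model_id=f"toy_{seed}",
        receptor_residues=dict(sorted(receptor.items())),
        ligand_residues=dict(sorted(ligand.items())),
    )
    truth = naive_contacts(model, cutoff)
    if out_path is not None:
        out_path = Path(out_path)
        write_model(model, out_path)
        from .contacts import write_contacts_tsv

        write_contacts_tsv(truth, out_path.with_suffix(".contacts.tsv"))
    return model, truth


@dataclass
class EnsembleSpec:
    """Recipe for a planted docking-model ensemble."""

    n_models: int
    residues_per_side: int = 40
    target_overlap: float = 0.5
    displacement_ladder: list[float] | None = None
    seed: int = 0
    cutoff: float = 5.0


# geometry constants of the hub/rim construction (Å)
_CHORD = 9.0  # arc spacing between rim lattice slots
_RING_GAP = 9.0  # radial spacing between rim rings
_HUB_Z = (0.0, 0.8, 1.6)  # hub atom heights on the rotation axis


def _rotate_z(coords: np.ndarray, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return coords @ rot.T


def _overlap_ensemble(spec: EnsembleSpec, rng: np.random.Generator) -> tuple[list[ComplexModel], list[dict]]:
    n_total = spec.residues_per_side
    n_core = int(round(spec.target_overlap * n_total))
    n_arm = n_total - n_core
    n_slots = max(24, spec.n_models + 4)
    radius0 = _CHORD * n_slots / (2.0 * np.pi)

    # receptor: one hub residue on the rotation axis + rim rings, fixed
    receptor: dict[ResidueKey, list[AtomRecord]] = {}
    hub_offsets = np.column_stack([np.zeros(3), np.zeros(3), np.array(_HUB_Z)])
    key, atoms = _residue("receptor", "A", 1, np.zeros(3), hub_offsets)
    receptor[key] = atoms
    for ring in range(n_arm):
        radius = radius0 + _RING_GAP * ring
        for slot in range(n_slots):
            theta = 2.0 * np.pi * slot / n_slots
            center = np.array([radius * np.cos(theta), radius * np.sin(theta), 0.0])
            offsets = rng.uniform(-0.3, 0.3, (3, 3))
            number = 2 + ring * n_slots + slot
            key, atoms = _residue("receptor", "A", number, center, offsets)
            receptor[key] = atoms
    receptor = dict(sorted(receptor.items()))

    # ligand template at azimuth slot 0: core cluster over the hub + radial arm
    centers, offsets_list = [], []
    for _ in range(n_core):
        rho = rng.uniform(0.0, 1.2)
        psi = rng.uniform(0.0, 2.0 * np.pi)
        z = rng.uniform(3.0, 4.2)
        centers.append([rho * np.cos(psi), rho * np.sin(psi), z])
        offsets_list.append(rng.uniform(-0.25, 0.25, (3, 3)))
    for ring in range(n_arm):
        radius = radius0 + _RING_GAP * ring + rng.uniform(-0.3, 0.3)
        z = rng.uniform(3.2, 3.8)
        centers.append([radius, 0.0, z])
        offsets_list.append(rng.uniform(-0.25, 0.25, (3, 3)))
    template = np.asarray(centers) if centers else np.zeros((0, 3))

    slots = [0] + list(rng.permutation(np.arange(1, n_slots))[: spec.n_models - 1])
    models, manifest = [], []
    for m, slot in enumerate(slots):
        angle = 2.0 * np.pi * slot / n_slots
        rotated = _rotate_z(template, angle)
        ligand: dict[ResidueKey, list[AtomRecord]] = {}
        for i in range(n_total):
            key, atoms = _residue(
                "ligand", "B", i + 1, rotated[i], _rotate_z(offsets_list[i], angle)
            )
            ligand[key] = atoms
        models.append(
            ComplexModel(
                model_id=f"model_{m:03d}",
                receptor_residues=receptor,
                ligand_residues=dict(sorted(ligand.items())),
            )
        )
        manifest.append(
            {
                "model": f"model_{m:03d}",
                "slot": int(slot),
                "azimuth_deg": round(float(np.degrees(angle)), 3),
                "displacement_A": None,
            }
        )
    return models, manifest


def _ladder_ensemble(spec: EnsembleSpec, rng: np.random.Generator) -> tuple[list[ComplexModel], list[dict]]:
    # a small positive gap keeps every ligand atom on the +x side of the
    # receptor, so translating the ligand along +x shrinks the contact set
    # monotonically and the planted offset equals the ligand RMSD exactly
    base, _ = make_toy_complex(
        spec.residues_per_side, seed=int(rng.integers(0, 2**31 - 1)), gap=1.0
    )
    direction = np.array([1.0, 0.0, 0.0])
    displacements = [0.0] + [float(d) for d in spec.displacement_ladder or []]
    models, manifest = [], []
    for m, disp in enumerate(displacements):
        shift = direction * disp
        ligand = {
            key: [
                AtomRecord(
                    name=atom.name,
                    element=atom.element,
                    chain_id=atom.chain_id,
                    residue_number=atom.residue_number,
                    insertion_code=atom.insertion_code,
                    residue_name=atom.residue_name,
                    altloc=atom.altloc,
                    coords=tuple(np.round(atom.xyz + shift, 3)),
                )
                for atom in atoms
            ]
            for key, atoms in base.ligand_residues.items()
        }
        models.append(
            ComplexModel(
                model_id=f"model_{m:03d}",
                receptor_residues=base.receptor_residues,
                ligand_residues=ligand,
            )
        )
        manifest.append(
            {
                "model": f"model_{m:03d}",
                "slot": None,
                "azimuth_deg": None,
                "displacement_A": disp,
            }
        )
    return models, manifest


def make_ensemble(
    spec: EnsembleSpec, out_dir: str | Path | None = None
) -> tuple[list[ComplexModel], dict]:
    """Generate a planted ensemble; optionally write PDB files + manifest.

    With ``displacement_ladder`` set, model 0 is the reference pose and each
    further model translates the ligand rigidly by the given offset (so the
    planted offset equals the ligand RMSD exactly).  Otherwise the hub/rim
    construction plants a conserved-contact fraction of
    round(target_overlap * residues_per_side) / residues_per_side between
    every pair of models.
    """
    if spec.n_models < 2:
        raise UsageError("an ensemble needs n_models >= 2")
    if spec.residues_per_side < 2:
        raise UsageError("residues_per_side must be >= 2")
    if not 0.0 <= spec.target_overlap <= 1.0:
        raise UsageError(
            f"target_overlap {spec.target_overlap} unreachable; achievable range is [0, 1]"
        )
    rng = np.random.default_rng(spec.seed)
    if spec.displacement_ladder is not None:
        models, entries = _ladder_ensemble(spec, rng)
    else:
        models, entries = _overlap_ensemble(spec, rng)

    manifest = {"spec": asdict(spec), "models": entries}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for model, entry in zip(models, entries):
            entry["file"] = f"{model.model_id}.pdb"
            write_model(model, out_dir / entry["file"])
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    return models, manifest
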