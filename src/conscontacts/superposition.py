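"""Least-squares superposition and the pairwise ligand RMSD (L_rmsd).

L_rmsd follows the blind-docking assessment convention: superpose the two
models on the backbone atoms (N, CA, C, O) of the receptor residues they
share, then measure the RMSD over all heavy atoms of the ligand.  The
optimal rotation is the Kabsch solution (proper rotation only, no
reflection), obtained through scipy's ``Rotation.align_vectors``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .contacts import compute_contacts
from .conservation import cpair
from .errors import DataError, ScoreUndefinedError, UsageError
from .structure_io import AtomRecord, ComplexModel, ResidueKey

BACKBONE_ATOMS = ("N", "CA", "C", "O")  # OXT deliberately excluded


@dataclass
class RigidTransform:
    """A proper rigid motion x -> R @ x + t (rotation det +1, translation in Å)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise UsageError("rigid transform needs a 3x3 rotation and a 3-vector")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise DataError("rotation matrix is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise DataError("reflections are not rigid motions of a chiral molecule")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def kabsch_fit(ref: np.ndarray, mov: np.ndarray) -> tuple[RigidTransform, float]:
    """Optimal rigid superposition of ``mov`` onto ``ref``.

    Returns the transform minimising the RMSD of the moved points onto the
    reference, and that minimal RMSD.  Requires >=3 non-collinear points in
    each set; reflections are excluded.
    """
    ref = np.asarray(ref, dtype=float)
    mov = np.asarray(mov, dtype=float)
    if ref.shape != mov.shape:
        raise UsageError(f"point sets differ in shape: {ref.shape} vs {mov.shape}")
    if ref.ndim != 2 or ref.shape[1] != 3:
        raise UsageError("point sets must be (n, 3) arrays")
    n = ref.shape[0]
    if n < 3:
        raise UsageError(f"superposition requires >=3 points, got {n}")
    ref_center = ref.mean(axis=0)
    mov_center = mov.mean(axis=0)
    ref_c = ref - ref_center
    mov_c = mov - mov_center
    for label, pts in (("reference", ref_c), ("moving", mov_c)):
        if np.linalg.matrix_rank(pts, tol=1e-8) < 2:
            raise DataError(f"{label} points are collinear; the fit is degenerate")

    with warnings.catch_warnings():
        # scipy warns when the point sets are exactly superposable
        warnings.simplefilter("ignore", UserWarning)
        rotation, _ = Rotation.align_vectors(ref_c, mov_c)
    matrix = rotation.as_matrix()
    moved = mov_c @ matrix.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref_c) ** 2, axis=1))))
    translation = ref_center - matrix @ mov_center
    return RigidTransform(rotation=matrix, translation=translation), rmsd


def _atoms_by_name(atoms: list[AtomRecord]) -> dict[str, AtomRecord]:
    return {atom.name: atom for atom in atoms}


def _receptor_backbone_pairs(
    a: ComplexModel, b: ComplexModel, restrict_to: set[ResidueKey] | None
) -> tuple[np.ndarray, np.ndarray]:
    shared = set(a.receptor_residues) & set(b.receptor_residues)
    if restrict_to is not None:
        shared &= restrict_to
    ref_pts, mov_pts = [], []
    dropped = []
    for key in sorted(shared):
        atoms_a = _atoms_by_name(a.receptor_residues[key])
        atoms_b = _atoms_by_name(b.receptor_residues[key])
        names = [n for n in BACKBONE_ATOMS if n in atoms_a and n in atoms_b]
        if not names:
            dropped.append(key)
            continue
        for name in names:
            ref_pts.append(atoms_a[name].coords)
            mov_pts.append(atoms_b[name].coords)
    if dropped:
        listing = ", ".join(str(k) for k in dropped[:10])
        warnings.warn(
            f"{len(dropped)} shared receptor residue(s) have no matchable "
            f"backbone atoms and were dropped from the fit: {listing}",
            stacklevel=3,
        )
    used = len(shared) - len(dropped)
    if used < 3:
        raise DataError(
            f"too few shared receptor residues with backbone atoms ({used}); "
            "need >=3 for the superposition"
        )
    return np.asarray(ref_pts), np.asarray(mov_pts)


def _ligand_heavy_pairs(
    a: ComplexModel, b: ComplexModel
) -> tuple[np.ndarray, np.ndarray]:
    ref_pts, mov_pts = [], []
    unmatched = 0
    keys = set(a.ligand_residues) | set(b.ligand_residues)
    for key in sorted(keys):
        atoms_a = _atoms_by_name(a.ligand_residues.get(key, []))
        atoms_b = _atoms_by_name(b.ligand_residues.get(key, []))
        names_a = {n for n, atom in atoms_a.items() if not atom.is_hydrogen}
        names_b = {n for n, atom in atoms_b.items() if not atom.is_hydrogen}
        for name in sorted(names_a & names_b):
            ref_pts.append(atoms_a[name].coords)
            mov_pts.append(atoms_b[name].coords)
        unmatched += len(names_a ^ names_b)
    if unmatched:
        warnings.warn(
            f"{unmatched} ligand heavy atom(s) present in only one model "
            "were dropped from the RMSD",
            stacklevel=3,
        )
    if not ref_pts:
        raise DataError("no shared ligand heavy atoms between the two models")
    return np.asarray(ref_pts), np.asarray(mov_pts)


def l_rmsd(
    a: ComplexModel,
    b: ComplexModel,
    invariant_residues: set[ResidueKey] | None = None,
) -> float:
    """Pairwise ligand RMSD after a receptor-backbone least-squares fit.

    The fit uses backbone atoms of the receptor residues shared by the two
    models (optionally restricted to an ensemble-wide invariant set); the
    RMSD is taken over ligand heavy atoms matched by residue key and atom
    name.
    """
    ref_bb, mov_bb = _receptor_backbone_pairs(a, b, invariant_residues)
    transform, _ = kabsch_fit(ref_bb, mov_bb)
    ref_lig, mov_lig = _ligand_heavy_pairs(a, b)
    moved = transform.apply(mov_lig)
    return float(np.sqrt(np.mean(np.sum((moved - ref_lig) ** 2, axis=1))))


def cpair_vs_lrmsd_table(
    ensemble: list[ComplexModel], cutoff: float = 5.0
) -> pd.DataFrame:
    """One row per unordered model pair: (model_i, model_j, cpair, l_rmsd).

    This is the data behind a conservation-versus-RMSD scatter plot; pairs
    where either quantity is undefined are reported in a warning and
    skipped.
    """
    if len(ensemble) < 2:
        raise UsageError("need >=2 models")
    contact_sets = [compute_contacts(m, cutoff) for m in ensemble]
    rows = []
    failures = []
    for i, j in combinations(range(len(ensemble)), 2):
        try:
            score = cpair(contact_sets[i], contact_sets[j])
            rmsd = l_rmsd(ensemble[i], ensemble[j])
        except (DataError, ScoreUndefinedError) as exc:
            failures.append((ensemble[i].model_id, ensemble[j].model_id, str(exc)))
            continue
        rows.append(
            {
                "model_i": ensemble[i].model_id,
                "model_j": ensemble[j].model_id,
                "cpair": score,
                "l_rmsd": rmsd,
            }
        )
    if failures:
        warnings.warn(f"{len(failures)} pair(s) skipped: {failures[:5]}", stacklevel=2)
    return pd.DataFrame(rows, columns=["model_i", "model_j", "cpair", "l_rmsd"])
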