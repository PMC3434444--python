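"""Contact-conservation scores over an ensemble of docking models.

Given N models of the same complex with contact sets computed at a common
cutoff, this module provides:

* ``cpair`` — pairwise conservation score between models i and j::

      Cpair_ij = nc_ij / ((nc_i + nc_j) / 2)

  the number of shared contacts normalised by the mean contact count, so
  0.5 means one out of two interface contacts is conserved between the two
  models.

* ``cpair_av`` — Cpair_ij averaged over all N(N-1)/2 unordered pairs.

* ``conservation_score`` — the ensemble generalisation C_P: the number of
  distinct contacts conserved in at least P% of the models, divided by the
  mean per-model contact count.  C_100 uses contacts common to every model;
  for small P the score can exceed 1.

* ``total_contacts`` — Nt, the summed per-model contact counts.

* ``conservation_rates`` — the per-contact conservation rate
  CR_kl = nc_kl / N, the fraction of models in which residues k and l are
  in contact; this is the quantity shaded in consensus maps.

* ``q_score`` — the predictor quality tally summing 0/1/2/3 per
  incorrect/acceptable/medium/high model, per blind-assessment tiers.
"""
from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .contacts import ContactPair, ContactSet, contact_intersection
from .errors import DataError, ScoreUndefinedError, UsageError

QUALITY_VALUES = {"incorrect": 0, "acceptable": 1, "medium": 2, "high": 3}


@dataclass
class EnsembleConservation:
    """Per-contact occurrence counts over an ensemble of N models."""

    n_models: int
    cutoff: float
    occurrence: dict[ContactPair, int]
    per_model_nc: list[int]

    @property
    def nt(self) -> int:
        """Total number of contacts in the ensemble (Nt), duplicates counted."""
        return sum(self.per_model_nc)

    def rate(self, pair: ContactPair) -> float:
        """Conservation rate CR_kl of one contact (0 if never observed)."""
        return self.occurrence.get(pair, 0) / self.n_models

    def rates(self) -> dict[ContactPair, float]:
        return {pair: count / self.n_models for pair, count in self.occurrence.items()}


@dataclass
class ScoreReport:
    """All scalar conservation scores of one ensemble."""

    model_ids: list[str]
    cpair_matrix: np.ndarray
    cpair_av: float
    c_at: dict[float, float]
    nt: int
    top_contacts: list[tuple[ContactPair, float]] = field(default_factory=list)


def _check_ensemble(ensemble: Sequence[ContactSet], minimum: int = 2) -> None:
    if len(ensemble) < minimum:
        raise UsageError(f"ensemble requires >={minimum} models, got {len(ensemble)}")
    cutoffs = {cs.cutoff for cs in ensemble}
    if len(cutoffs) > 1:
        raise UsageError(f"mixed cutoffs in ensemble: {sorted(cutoffs)}")


def cpair(a: ContactSet, b: ContactSet) -> float:
    """Pairwise conservation score Cpair_ij = nc_ij / ((nc_i + nc_j)/2)."""
    shared = contact_intersection(a, b)
    denom = (a.nc + b.nc) / 2.0
    if denom == 0:
        raise ScoreUndefinedError("undefined score: no contacts in either model")
    return shared / denom


def cpair_matrix(ensemble: Sequence[ContactSet]) -> np.ndarray:
    """Symmetric N×N matrix of Cpair_ij; NaN where the score is undefined."""
    _check_ensemble(ensemble)
    n = len(ensemble)
    matrix = np.full((n, n), np.nan)
    undefined = 0
    for i in range(n):
        if ensemble[i].nc > 0:
            matrix[i, i] = 1.0
    for i, j in combinations(range(n), 2):
        try:
            matrix[i, j] = matrix[j, i] = cpair(ensemble[i], ensemble[j])
        except ScoreUndefinedError:
            undefined += 1
    if undefined:
        warnings.warn(
            f"{undefined} model pair(s) had no contacts in either model; "
            "excluded from the average",
            stacklevel=2,
        )
    return matrix

def cpair_av(ensemble: Sequence[ContactSet]) -> float:
    """Mean Cpair_ij over all unordered model pairs (undefined pairs skipped)."""
    matrix = cpair_matrix(ensemble)
    upper = matrix[np.triu_indices(len(ensemble), k=1)]
    valid = upper[~np.isnan(upper)]
    if valid.size == 0:
        raise ScoreUndefinedError("no model pair has a defined pairwise score")
    return float(valid.mean())


def conservation_rates(ensemble: Sequence[ContactSet]) -> EnsembleConservation:
    """Count, for every contact, the number of models containing it."""
    _check_ensemble(ensemble)
    occurrence: Counter[ContactPair] = Counter()
    for cs in ensemble:
        occurrence.update(cs.contacts)
    return EnsembleConservation(
        n_models=len(ensemble),
        cutoff=ensemble[0].cutoff,
        occurrence=dict(occurrence),
        per_model_nc=[cs.nc for cs in ensemble],
    )


def _conserved_threshold(percentage: float, n_models: int) -> int:
    """Minimum model count meaning "conserved in P% of the models".

    The threshold is a model count: ceil(P*N/100), so that at least the
    stated share of the ensemble carries the contact.  A small slack guards
    against binary-float noise in P*N/100 for exact products.
    """
    return max(1, math.ceil(percentage * n_models / 100.0 - 1e-9))


def conservation_score(ensemble: Sequence[ContactSet], percentage: float) -> float:
    """Ensemble conservation score C_P = nc_P / (Nt / N).

    ``nc_P`` is the number of distinct contacts present in at least P% of
    the models; the denominator is the mean per-model contact count.
    """
    if not 0 < percentage <= 100:
        raise UsageError(f"percentage must be in (0, 100], got {percentage}")
    cons = conservation_rates(ensemble)
    if cons.nt == 0:
        raise ScoreUndefinedError("no contacts in ensemble")
    threshold = _conserved_threshold(percentage, cons.n_models)
    nc_p = sum(1 for count in cons.occurrence.values() if count >= threshold)
    return nc_p / (cons.nt / cons.n_models)


def total_contacts(ensemble: Sequence[ContactSet]) -> int:
    """Nt: the summed per-model contact counts of the ensemble."""
    if not ensemble:
        raise UsageError("ensemble requires >=1 model")
    _check_ensemble(ensemble, minimum=1)
    return sum(cs.nc for cs in ensemble)


def rank_contacts(
    cons: EnsembleConservation, k: int
) -> list[tuple[ContactPair, float]]:
    """The k most conserved contacts, by CR_kl descending.

    Ties are broken by (receptor key, ligand key) lexicographic order so the
    ranking is deterministic.
    """
    if k < 1:
        raise UsageError(f"k must be >=1, got {k}")
    ranked = sorted(cons.rates().items(), key=lambda item: (-item[1], item[0]))
    return ranked[:k]


def q_score(labels: Iterable[str]) -> int:
    """Quality tally: sum 0/1/2/3 per incorrect/acceptable/medium/high model."""
    labels = list(labels)
    if not labels:
        raise UsageError("q_score requires at least one label")
    total = 0
    for label in labels:
        try:
            total += QUALITY_VALUES[label.strip().lower()]
        except KeyError:
            raise DataError(
                f"unknown quality label {label!r}; expected one of "
                f"{sorted(QUALITY_VALUES)}"
            ) from None
    return total


def compute_report(
    ensemble: Sequence[ContactSet],
    percentages: Sequence[float] = (5, 10, 15, 20, 30, 50, 70, 100),
    top_k: int = 10,
) -> ScoreReport:
    """All ensemble scores in one pass: Cpair matrix/average, C_P, Nt, top contacts."""
    _check_ensemble(ensemble)
    matrix = cpair_matrix(ensemble)
    upper = matrix[np.triu_indices(len(ensemble), k=1)]
    valid = upper[~np.isnan(upper)]
    if valid.size == 0:
        raise ScoreUndefinedError("no model pair has a defined pairwise score")
    cons = conservation_rates(ensemble)
    c_at = {float(p): conservation_score(ensemble, p) for p in percentages}
    return ScoreReport(
        model_ids=[cs.model_id for cs in ensemble],
        cpair_matrix=matrix,
        cpair_av=float(valid.mean()),
        c_at=c_at,
        nt=cons.nt,
        top_contacts=rank_contacts(cons, top_k),
    )
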