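"""Ensemble conservation scores: Eq.-level oracles and bookkeeping invariants."""
import numpy as np
import pytest

from conscontacts.conservation import (
    compute_report,
    conservation_rates,
    conservation_score,
    cpair,
    cpair_av,
    cpair_matrix,
    q_score,
    rank_contacts,
    total_contacts,
)
from conscontacts.errors import DataError, ScoreUndefinedError, UsageError

from conftest import contact_set, lk, rk


def _random_ensemble(rng, n_models=6, universe=30):
    pool = [(int(i), int(j)) for i in range(universe) for j in range(universe // 3)]
    ensemble = []
    for m in range(n_models):
        size = int(rng.integers(1, len(pool) // 2))
        picks = rng.choice(len(pool), size=size, replace=False)
        ensemble.append(contact_set({pool[i] for i in picks}, model_id=f"m{m}"))
    return ensemble


class TestCpair:
    def test_identical_sets_score_one(self):
        a = contact_set({(1, 1), (2, 2)})
        assert cpair(a, a) == 1.0

    def test_disjoint_sets_score_zero(self):
        assert cpair(contact_set({(1, 1)}), contact_set({(2, 2)})) == 0.0

    def test_hand_worked_fraction(self):
        # nc_a=4, nc_b=6, shared=2 -> 2 / ((4+6)/2) = 0.4
        a = contact_set({(1, 1), (1, 2), (2, 1), (2, 2)})
        b = contact_set({(1, 1), (1, 2), (3, 1), (3, 2), (3, 3), (4, 1)})
        assert cpair(a, b) == pytest.approx(0.4)

    def test_both_empty_is_undefined(self):
        with pytest.raises(ScoreUndefinedError):
            cpair(contact_set(set()), contact_set(set()))

    def test_one_empty_scores_zero(self):
        assert cpair(contact_set(set()), contact_set({(1, 1)})) == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_bounds_symmetry_diagonal(self, seed):
        rng = np.random.default_rng(seed)
        ensemble = _random_ensemble(rng)
        matrix = cpair_matrix(ensemble)
        assert np.allclose(matrix, matrix.T, equal_nan=True)
        finite = matrix[~np.isnan(matrix)]
        assert ((finite >= 0) & (finite <= 1)).all()
        for i, cs in enumerate(ensemble):
            if cs.nc > 0:
                assert matrix[i, i] == 1.0


class TestCpairAv:
    def test_identical_models(self):
        a = contact_set({(1, 1), (2, 2)})
        assert cpair_av([a, a, a, a]) == 1.0

    def test_pairwise_disjoint(self):
        ensemble = [contact_set({(i, 1)}, model_id=f"m{i}") for i in range(3)]
        assert cpair_av(ensemble) == 0.0

    def test_mean_of_pairwise_scores(self):
        # pairwise cpair values {1.0, 0.4, 0.4} -> mean 0.6
        a = contact_set({(1, 1), (1, 2), (2, 1), (2, 2)})
        b = contact_set({(1, 1), (1, 2), (2, 1), (2, 2)}, model_id="m2")
        c = contact_set({(1, 1), (1, 2), (3, 1), (3, 2), (3, 3), (4, 1)}, model_id="m3")
        assert cpair(a, b) == 1.0
        assert cpair(a, c) == pytest.approx(0.4)
        assert cpair_av([a, b, c]) == pytest.approx(0.6)

    def test_matches_upper_triangle_mean(self, rng):
        ensemble = _random_ensemble(rng)
        matrix = cpair_matrix(ensemble)
        upper = matrix[np.triu_indices(len(ensemble), k=1)]
        assert cpair_av(ensemble) == pytest.approx(np.nanmean(upper))

    def test_empty_pairs_skipped_with_warning(self):
        ensemble = [
            contact_set({(1, 1)}, model_id="a"),
            contact_set(set(), model_id="b"),
            contact_set(set(), model_id="c"),
        ]
        with pytest.warns(UserWarning, match="excluded"):
            value = cpair_av(ensemble)
        assert value == 0.0  # the two defined pairs both score 0

    def test_single_model_rejected(self):
        with pytest.raises(UsageError):
            cpair_av([contact_set({(1, 1)})])


class TestConservationScore:
    def test_identical_models_score_one_at_any_percentage(self):
        a = contact_set({(1, 1), (2, 2), (3, 3)})
        for p in (5, 50, 70, 100):
            assert conservation_score([a, a, a], p) == pytest.approx(1.0)

    def test_hand_worked_four_model_case(self):
        """X in all 4 models, Y in 3: C100 = 1 / (7/4) = 4/7."""
        with_y = contact_set({(1, 1), (2, 2)})
        without_y = contact_set({(1, 1)})
        ensemble = [with_y, with_y, with_y, without_y]
        assert conservation_score(ensemble, 100) == pytest.approx(4 / 7)

    def test_no_common_contacts_at_100(self):
        a = contact_set({(1, 1)})
        b = contact_set({(2, 2)})
        assert conservation_score([a, b], 100) == 0.0

    def test_can_exceed_one_for_small_percentage(self):
        # many distinct contacts each in 1 of 10 models clears a 5% threshold
        ensemble = [contact_set({(m, j) for j in range(5)}, model_id=f"m{m}") for m in range(10)]
        assert conservation_score(ensemble, 5) == pytest.approx(10.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_non_increasing_in_percentage(self, seed):
        rng = np.random.default_rng(seed)
        ensemble = _random_ensemble(rng)
        values = [conservation_score(ensemble, p) for p in (5, 10, 30, 50, 70, 100)]
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))

    def test_matches_brute_force_recount(self, rng):
        ensemble = _random_ensemble(rng)
        n = len(ensemble)
        for p in (10, 40, 75, 100):
            threshold = int(np.ceil(p * n / 100 - 1e-9))
            conserved = {
                pair
                for pair in set().union(*(cs.contacts for cs in ensemble))
                if sum(pair in cs.contacts for cs in ensemble) >= threshold
            }
            expected = len(conserved) / (sum(cs.nc for cs in ensemble) / n)
            assert conservation_score(ensemble, p) == pytest.approx(expected)

    def test_all_empty_is_an_error(self):
        with pytest.raises(ScoreUndefinedError):
            conservation_score([contact_set(set()), contact_set(set())], 50)


class TestOccurrenceBookkeeping:
    def test_nt_is_sum_of_counts(self):
        sizes = (5, 7, 9)
        ensemble = [
            contact_set({(m, j) for j in range(s)}, model_id=f"m{m}")
            for m, s in enumerate(sizes)
        ]
        assert total_contacts(ensemble) == 21

    def test_single_and_empty(self):
        assert total_contacts([contact_set({(1, 1), (1, 2), (2, 1), (2, 2)})]) == 4
        assert total_contacts([contact_set(set()), contact_set(set())]) == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_occurrence_sums_to_nt(self, seed):
        rng = np.random.default_rng(seed)
        ensemble = _random_ensemble(rng)
        cons = conservation_rates(ensemble)
        assert sum(cons.occurrence.values()) == cons.nt == total_contacts(ensemble)
        assert all(1 <= c <= cons.n_models for c in cons.occurrence.values())

    def test_rates(self):
        shared = contact_set({(1, 1)})
        ensemble = [shared] * 3 + [contact_set({(2, 2)})] * 7
        cons = conservation_rates(ensemble)
        assert cons.rate((rk(1), lk(1))) == pytest.approx(0.3)
        assert cons.rate((rk(2), lk(2))) == pytest.approx(0.7)
        assert cons.rate((rk(9), lk(9))) == 0.0


class TestRanking:
    def test_fewer_contacts_than_k(self):
        cons = conservation_rates(
            [contact_set({(1, 1), (2, 2)}), contact_set({(1, 1), (3, 3), (4, 4)})]
        )
        assert len(rank_contacts(cons, 10)) == 4

    def test_ties_broken_by_residue_key(self):
        cons = conservation_rates([contact_set({(2, 1), (1, 1)})] * 2)
        ranked = rank_contacts(cons, 2)
        assert [pair for pair, _ in ranked] == [(rk(1), lk(1)), (rk(2), lk(1))]

    def test_planted_gradient_matches_sort_oracle(self, rng):
        ensemble = []
        n = 10
        for m in range(n):
            # contact (j, j) appears in models 0..j: CR gradient 1/n .. 1
            ensemble.append(contact_set({(j, j) for j in range(m, n)}, model_id=f"m{m}"))
        cons = conservation_rates(ensemble)
        ranked = rank_contacts(cons, n)
        expected = sorted(cons.rates().items(), key=lambda kv: (-kv[1], kv[0]))
        assert ranked == expected
        assert ranked[0][1] == pytest.approx(1.0)


class TestQScore:
    def test_all_incorrect(self):
        assert q_score(["incorrect"] * 10) == 0

    def test_one_of_each(self):
        assert q_score(["incorrect", "acceptable", "medium", "high"]) == 6

    def test_predictor_tally(self):
        # 1 acceptable + 2 medium + 5 high + 2 incorrect = 1 + 4 + 15 + 0
        labels = ["acceptable"] + ["medium"] * 2 + ["high"] * 5 + ["incorrect"] * 2
        assert q_score(labels) == 20

    def test_unknown_label(self):
        with pytest.raises(DataError, match="unknown quality label"):
            q_score(["excellent"])

    def test_empty_rejected(self):
        with pytest.raises(UsageError):
            q_score([])


def test_report_bundles_all_scores(rng):
    ensemble = _random_ensemble(rng)
    report = compute_report(ensemble, percentages=(10, 50, 100), top_k=5)
    assert report.nt == total_contacts(ensemble)
    assert report.cpair_av == pytest.approx(cpair_av(ensemble))
    for p in (10, 50, 100):
        assert report.c_at[float(p)] == pytest.approx(conservation_score(ensemble, p))
    assert len(report.top_contacts) == 5
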