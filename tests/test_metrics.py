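"""Rank metrics, spatial block holdout and the pseudo-absence AUC protocol."""

import numpy as np
import pandas as pd
import pytest

from convsdm import metrics as M


# --------------------------------------------------------------------------
# independent brute-force oracles (explicit sorting / all-pairs counting)

def oracle_rank(scores, true_index):
    """Build the explicit descending sorted list, true species last among ties."""
    order = sorted(
        range(len(scores)),
        key=lambda i: (-scores[i], i == true_index),
    )
    return order.index(true_index) + 1


def oracle_auc(pres, absn):
    """All-pairs counting with half-credit for ties."""
    wins = sum(1.0 if p > a else 0.5 if p == a else 0.0 for p in pres for a in absn)
    return wins / (len(pres) * len(absn))


class TestRanks:
    def test_unique_maximum_is_rank_one(self):
        assert M.rank_true_species([0.1, 0.9, 0.2], 1) == 1

    def test_all_equal_scores_rank_last(self):
        assert M.rank_true_species([0.25] * 4, 2) == 4

    def test_tied_score_placed_after_ties(self):
        assert M.rank_true_species([0.5, 0.3, 0.3, 0.1], 2) == 3

    def test_unknown_species_rejected(self):
        with pytest.raises(ValueError):
            M.rank_true_species([0.5, 0.5], 7)

    def test_matches_oracle_on_random_instances(self, rng):
        for _ in range(200):
            s = rng.integers(2, 20)
            scores = np.round(rng.random(s), 1)  # coarse grid forces ties
            t = int(rng.integers(0, s))
            assert M.rank_true_species(scores, t) == oracle_rank(list(scores), t)

    def test_vectorized_matches_scalar(self, rng):
        scores = rng.random((50, 12))
        true = rng.integers(0, 12, size=50)
        ranks = M.ranks_from_scores(scores, true)
        for i in range(50):
            assert ranks[i] == M.rank_true_species(scores[i], true[i])


class TestTopK:
    def test_hand_enumerated_example(self):
        assert M.top_k_accuracy(np.array([1, 3, 5]), 3) == pytest.approx(2 / 3)

    def test_k_at_least_species_count_is_one(self, rng):
        ranks = rng.integers(1, 11, size=30)
        assert M.top_k_accuracy(ranks, 10) == 1.0

    def test_k_zero_is_zero(self):
        assert M.top_k_accuracy(np.array([1, 2]), 0) == 0.0

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError):
            M.top_k_accuracy(np.array([]), 5)

    def test_nondecreasing_in_k(self, rng):
        ranks = rng.integers(1, 31, size=100)
        accs = [M.top_k_accuracy(ranks, k) for k in range(1, 31)]
        assert all(a <= b for a, b in zip(accs, accs[1:]))
        assert accs[-1] == 1.0


class TestSpeciesTopK:
    def test_species_weighting_differs_from_occurrence_weighting(self):
        # species A ranks (1, 99), species B rank (2), k=30
        ranks = np.array([1, 99, 2])
        species = np.array([0, 0, 1])
        sa, msa = M.mean_species_top_k(ranks, species, 30)
        assert sa[0] == 0.5 and sa[1] == 1.0
        assert msa == pytest.approx(0.75)
        assert M.top_k_accuracy(ranks, 30) == pytest.approx(2 / 3)

    def test_one_occurrence_per_species_equals_plain_accuracy(self, rng):
        ranks = rng.integers(1, 11, size=20)
        species = np.arange(20)
        _, msa = M.mean_species_top_k(ranks, species, 5)
        assert msa == M.top_k_accuracy(ranks, 5)

    def test_all_hits_give_one(self):
        _, msa = M.mean_species_top_k(np.array([1, 2, 1]), np.array([0, 0, 1]), 5)
        assert msa == 1.0


class TestSpatialSplit:
    def make_occ(self, rng, n, extent=100.0):
        return pd.DataFrame({
            "occ_id": np.arange(n),
            "species_id": rng.integers(0, 5, size=n),
            "x": rng.uniform(0, extent, n),
            "y": rng.uniform(0, extent, n),
        })

    def test_no_leakage_between_test_quadrats_and_train(self, rng):
        occ = self.make_occ(rng, 5000)
        res = M.spatial_block_split(occ, 5.0, 0.025, seed=3)
        df = pd.DataFrame({"q": res.quadrat, "s": res.split})
        for _, g in df.groupby("q"):
            kinds = set(g["s"])
            assert not ({"test"} & kinds and {"train", "val"} & kinds)

    def test_realized_fraction_near_target(self, rng):
        occ = self.make_occ(rng, 5000)
        res = M.spatial_block_split(occ, 5.0, 0.025, seed=4)
        assert 0.02 <= res.test_fraction_realized <= 0.035

    def test_single_quadrat_degenerates_to_all_test(self, rng):
        occ = self.make_occ(rng, 50, extent=1.0)
        with pytest.warns(UserWarning):
            res = M.spatial_block_split(occ, 10.0, 0.1, seed=5)
        assert (res.split == "test").all()

    def test_val_fraction_drawn_from_train(self, rng):
        occ = self.make_occ(rng, 4000)
        res = M.spatial_block_split(occ, 5.0, 0.1, val_fraction=0.05, seed=6)
        n_nontest = (res.split != "test").sum()
        assert (res.split == "val").sum() == round(0.05 * n_nontest)

    def test_invalid_parameters_rejected(self, rng):
        occ = self.make_occ(rng, 10)
        with pytest.raises(ValueError):
            M.spatial_block_split(occ, -1.0, 0.1)
        with pytest.raises(ValueError):
            M.spatial_block_split(occ, 5.0, 1.5)


class TestPseudoAbsences:
    def make_test_df(self, counts):
        rows = []
        i = 0
        for sid, c in counts.items():
            for _ in range(c):
                rows.append((i, sid))
                i += 1
        return pd.DataFrame(rows, columns=["occ_id", "species_id"])

    def test_minimum_of_hundred_draws(self):
        df = self.make_test_df({0: 30, 1: 40, 2: 40})
        assert len(M.draw_pseudo_absences(0, df, seed=1)) == 100

    def test_matches_presence_count_above_hundred(self):
        df = self.make_test_df({0: 150, 1: 40, 2: 40})
        assert len(M.draw_pseudo_absences(0, df, seed=1)) == 150

    def test_target_never_among_absences(self):
        df = self.make_test_df({0: 10, 1: 10, 2: 10})
        ids = M.draw_pseudo_absences(0, df, seed=2)
        sp_of = df.set_index("occ_id")["species_id"]
        assert (sp_of[ids] != 0).all()

    def test_no_eligible_species_rejected(self):
        df = self.make_test_df({0: 10})
        with pytest.raises(ValueError):
            M.draw_pseudo_absences(0, df, seed=3)

    def test_count_rule_boundary(self):
        assert M.pseudo_absence_count(100) == 100
        assert M.pseudo_absence_count(101) == 101
        assert M.pseudo_absence_count(1) == 100


class TestAUC:
    def test_perfect_separation(self):
        assert M.species_auc([0.9, 0.8], [0.1, 0.2]) == 1.0

    def test_all_tied_scores(self):
        assert M.species_auc([0.5, 0.5], [0.5, 0.5, 0.5]) == 0.5

    def test_hand_counted_pairs(self):
        # pairs: (.9,.6)+ (.9,.1)+ (.4,.6)- (.4,.1)+ => 3/4
        assert M.species_auc([0.9, 0.4], [0.6, 0.1]) == pytest.approx(0.75)

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            M.species_auc([], [0.5])

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(100):
            pres = np.round(rng.random(rng.integers(1, 20)), 1)
            absn = np.round(rng.random(rng.integers(1, 20)), 1)
            assert M.species_auc(pres, absn) == pytest.approx(
                oracle_auc(list(pres), list(absn)), abs=1e-12
            )

    def test_invariance_under_increasing_transform(self, rng):
        pres, absn = rng.normal(size=15), rng.normal(size=25)
        a = M.species_auc(pres, absn)
        b = M.species_auc(1 / (1 + np.exp(-pres)), 1 / (1 + np.exp(-absn)))
        assert a == b


class TestMeanAUC:
    def test_single_species_identity(self):
        assert M.mean_auc({3: 0.8}) == 0.8

    def test_arithmetic_mean(self):
        assert M.mean_auc({0: 1.0, 1: 0.5}) == 0.75

    def test_empty_reported_absent(self):
        assert M.mean_auc({}) is None

    def test_regional_evaluation_skips_unevaluable_regions(self, rng):
        n = 60
        occ = pd.DataFrame({
            "occ_id": np.arange(n),
            "species_id": rng.integers(0, 3, size=n),
        })
        scores = rng.random((n, 3))
        regions = np.where(np.arange(n) < 55, "A", "B")
        occ_b = occ[regions == "B"]
        if occ_b["species_id"].nunique() < 2:
            occ.loc[occ.index[-1], "species_id"] = 2  # ensure B evaluable
        overall, by_region, per_species = M.evaluate_mean_auc(
            scores, occ, seed=1, region_tags=regions
        )
        assert overall is not None
        assert set(by_region) <= {"A", "B"}
        assert all(0 <= v <= 1 for v in by_region.values())
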