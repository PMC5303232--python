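"""Repertoire similarity, traditions, cumulative change and significance."""

import math

import numpy as np
import pandas as pd
import pytest

from culturesim import analysis
from culturesim.engine import RunResult, Snapshot


def brute_force_similarity(A, B, ids_a=None, ids_b=None):
    """Independent oracle: explicit double loop over forager pairs."""
    total, n = 0.0, 0
    for i in range(len(A)):
        for j in range(len(B)):
            if ids_a is not None and ids_b is not None and ids_a[i] == ids_b[j]:
                continue
            na = math.sqrt(sum(v * v for v in A[i]))
            nb = math.sqrt(sum(v * v for v in B[j]))
            if na == 0 or nb == 0:
                continue
            total += sum(x * y for x, y in zip(A[i], B[j])) / (na * nb)
            n += 1
    return total / n


def make_snapshot(year, d_by_forager, groups, R=6, Q=None, t_by_forager=None):
    """Build a synthetic snapshot from per-forager count vectors."""
    ids = sorted(d_by_forager)
    foragers = pd.DataFrame({
        "forager_id": ids,
        "group_id": [groups[f] for f in ids],
        "age_years": 1.0, "energy": 100.0, "a_env": 0.1,
    })
    rows = []
    for f in ids:
        d = d_by_forager[f]
        t = t_by_forager[f] if t_by_forager else d
        for r in range(R):
            if d[r] > 0 or t[r] > 0:
                rows.append({"forager_id": f, "type_id": r, "d": d[r],
                             "t": float(t[r]), "a": 0.1})
    reps = pd.DataFrame(rows, columns=["forager_id", "type_id", "d", "t", "a"])
    if Q is None:
        Q = np.full(R, 0.1)
    return Snapshot(year=year, foragers=foragers, repertoires=reps, R=R,
                    type_Q=np.asarray(Q, dtype=float), type_H=np.ones(R),
                    type_S=np.ones(R, dtype=int), env_census={})


def make_run(snapshots, seed_env=1):
    return RunResult(config=None, snapshots=snapshots,
                     manifest={"seed_env": seed_env})


class TestRepertoireSimilarity:
    def test_identical_repertoires_give_one(self):
        rep = np.array([[3, 1, 0, 2, 0]] * 3)
        assert analysis.repertoire_similarity(rep, rep.copy()) == pytest.approx(1.0)

    def test_disjoint_support_gives_zero(self):
        a = np.array([[1, 2, 3, 0, 0, 0]] * 2)
        b = np.array([[0, 0, 0, 4, 5, 6]] * 2)
        assert analysis.repertoire_similarity(a, b) == 0.0

    def test_hand_computed_cosine(self):
        a = np.array([[1, 1, 0]])
        b = np.array([[0, 1, 1]])
        assert analysis.repertoire_similarity(a, b) == pytest.approx(0.5)

    def test_matches_brute_force_oracle_on_random_tables(self):
        gen = np.random.default_rng(0)
        for _ in range(50):
            a = gen.integers(0, 10, size=(5, 8))
            b = gen.integers(0, 10, size=(4, 8))
            a[0, :] += 1   # guarantee at least one nonzero row
            b[0, :] += 1
            keep_a = a.sum(axis=1) > 0
            keep_b = b.sum(axis=1) > 0
            expected = brute_force_similarity(a[keep_a], b[keep_b])
            got = analysis.repertoire_similarity(a, b)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_same_group_excludes_self_pairs(self):
        # group compared with itself: 6 ordered cross pairs, not 9
        reps = np.array([[2, 0], [0, 2], [1, 1]])
        ids = np.array([10, 11, 12])
        got = analysis.repertoire_similarity(reps, reps, ids, ids)
        expected = brute_force_similarity(reps, reps, ids, ids)
        assert got == pytest.approx(expected)
        assert got < 1.0

    def test_symmetry_and_range(self):
        gen = np.random.default_rng(3)
        a = gen.integers(0, 5, size=(4, 6)) + 1
        b = gen.integers(0, 5, size=(3, 6)) + 1
        s1 = analysis.repertoire_similarity(a, b)
        s2 = analysis.repertoire_similarity(b, a)
        assert s1 == pytest.approx(s2)
        assert 0.0 <= s1 <= 1.0

    def test_zero_repertoires_dropped_with_warning(self):
        a = np.array([[1, 1, 0], [0, 0, 0]])
        b = np.array([[1, 1, 0]])
        with pytest.warns(UserWarning):
            got = analysis.repertoire_similarity(a, b)
        assert got == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            analysis.repertoire_similarity(np.empty((0, 3)), np.ones((1, 3)))


class TestTraditionMetrics:
    def frozen_run(self):
        d = {1: [4, 2, 0, 0, 0, 0], 2: [3, 3, 0, 0, 0, 0]}
        groups = {1: 0, 2: 0}
        d2 = {3: [4, 2, 0, 0, 0, 0], 4: [3, 3, 0, 0, 0, 0]}
        groups2 = {3: 0, 4: 0}
        return make_run([make_snapshot(10.0, d, groups),
                         make_snapshot(15.0, d2, groups2)])

    def test_frozen_repertoires_give_within_similarity_near_one(self):
        run = self.frozen_run()
        got = analysis.within_group_similarity_over_time(run, 0, 10.0, 15.0)
        expected = brute_force_similarity(
            [[4, 2, 0, 0, 0, 0], [3, 3, 0, 0, 0, 0]],
            [[4, 2, 0, 0, 0, 0], [3, 3, 0, 0, 0, 0]])
        assert got == pytest.approx(expected)

    def test_disjoint_generations_give_zero(self):
        run = make_run([
            make_snapshot(10.0, {1: [1, 1, 0, 0, 0, 0]}, {1: 0}),
            make_snapshot(15.0, {2: [0, 0, 0, 1, 1, 0]}, {2: 0}),
        ])
        assert analysis.within_group_similarity_over_time(run, 0, 10.0, 15.0) == 0.0

    def test_missing_group_reported_as_none(self):
        run = self.frozen_run()
        assert analysis.within_group_similarity_over_time(run, 9, 10.0, 15.0) is None

    def test_two_by_two_toy_matches_pair_mean(self):
        d1 = {1: [1, 0, 0, 0, 0, 0], 2: [1, 1, 0, 0, 0, 0]}
        d2 = {3: [0, 1, 0, 0, 0, 0], 4: [1, 0, 1, 0, 0, 0]}
        run = make_run([make_snapshot(0.0, d1, {1: 0, 2: 0}),
                        make_snapshot(5.0, d2, {3: 0, 4: 0})])
        got = analysis.within_group_similarity_over_time(run, 0, 0.0, 5.0)
        expected = brute_force_similarity(list(d1.values()), list(d2.values()))
        assert got == pytest.approx(expected)

    def test_between_similarity_requires_shared_environment(self):
        run = self.frozen_run()
        other = make_run(self.frozen_run().snapshots, seed_env=99)
        with pytest.raises(ValueError):
            analysis.between_group_similarity_paired(run, other, 0, 15.0)

    def test_between_similarity_self_pairing_is_one(self):
        run = self.frozen_run()
        # a paired run with identical diets but different forager ids
        got = analysis.between_group_similarity_paired(run, run, 0, 10.0)
        assert got < 1.0    # same ids: self-pairs excluded, off-pairs differ
        paired = make_run([make_snapshot(10.0, {7: [4, 2, 0, 0, 0, 0],
                                                8: [3, 3, 0, 0, 0, 0]},
                                         {7: 0, 8: 0})])
        got2 = analysis.between_group_similarity_paired(run, paired, 0, 10.0)
        expected = brute_force_similarity(
            [[4, 2, 0, 0, 0, 0], [3, 3, 0, 0, 0, 0]],
            [[4, 2, 0, 0, 0, 0], [3, 3, 0, 0, 0, 0]])
        assert got2 == pytest.approx(expected)

    def test_between_similarity_averages_over_partner_groups(self):
        focal = make_run([make_snapshot(5.0, {1: [1, 0, 0, 0, 0, 0]}, {1: 0})])
        paired = make_run([make_snapshot(5.0, {2: [1, 0, 0, 0, 0, 0],
                                               3: [0, 1, 0, 0, 0, 0]},
                                         {2: 0, 3: 1})])
        got = analysis.between_group_similarity_paired(focal, paired, 0, 5.0)
        assert got == pytest.approx((1.0 + 0.0) / 2)

    def test_traditional_difference_subtraction(self):
        # within = 1 (frozen), between = 0 (disjoint paired diets) -> 1
        run = self.frozen_run()
        paired = make_run([
            make_snapshot(10.0, {5: [0, 0, 0, 2, 1, 0]}, {5: 0}),
            make_snapshot(15.0, {6: [0, 0, 0, 2, 1, 0]}, {6: 0}),
        ])
        within = analysis.within_group_similarity_over_time(run, 0, 10.0, 15.0)
        got = analysis.traditional_difference(run, paired, 0, 10.0, 15.0)
        assert got == pytest.approx(within - 0.0)

    def test_population_convergence_scores_near_zero(self):
        # all groups in both runs share one diet: high within-similarity but
        # no group-specific tradition
        diet = [5, 3, 0, 0, 0, 0]
        run = make_run([
            make_snapshot(10.0, {1: diet, 2: diet}, {1: 0, 2: 1}),
            make_snapshot(15.0, {3: diet, 4: diet}, {3: 0, 4: 1}),
        ])
        paired = make_run([
            make_snapshot(10.0, {5: diet, 6: diet}, {5: 0, 6: 1}),
            make_snapshot(15.0, {7: diet, 8: diet}, {7: 0, 8: 1}),
        ])
        scores = analysis.traditional_differences_all(run, paired, 10.0, 15.0)
        assert scores and all(abs(v) < 1e-12 for v in scores.values())


class TestCulturalMeasures:
    def test_single_type_diet_has_zero_diversity(self):
        m = analysis.cultural_measures(np.array([0, 7, 0]), np.full(3, 0.2),
                                       np.full(3, 0.5))
        assert m.repertoire_diversity == pytest.approx(0.0)

    def test_two_equal_types_have_log_two_diversity(self):
        m = analysis.cultural_measures(np.array([5, 5, 0]), np.full(3, 0.2),
                                       np.full(3, 0.5))
        assert m.repertoire_diversity == pytest.approx(math.log(2))

    def test_quality_is_proportion_weighted_mean(self):
        m = analysis.cultural_measures(np.array([5, 5]), np.array([0.1, 0.3]),
                                       np.ones(2))
        assert m.repertoire_quality == pytest.approx(0.2)

    def test_total_energy_uses_current_per_item_reward(self):
        d = np.array([2, 3])
        Q = np.array([0.1, 0.2])
        s = np.array([0.5, 1.0])
        m = analysis.cultural_measures(d, Q, s)
        assert m.total_energy == pytest.approx(2 * 0.05 + 3 * 0.2)
        assert m.average_skill == pytest.approx(0.4 * 0.5 + 0.6 * 1.0)

    def test_empty_repertoire_is_undefined(self):
        m = analysis.cultural_measures(np.zeros(3), np.full(3, 0.1), np.ones(3))
        assert all(np.isnan([m.total_energy, m.repertoire_quality,
                             m.repertoire_diversity, m.average_skill]))


class TestCumulativeChange:
    def runs_with_means(self, early_d, late_d):
        run = make_run([
            make_snapshot(5.0, {1: early_d}, {1: 0}),
            make_snapshot(15.0, {2: late_d}, {2: 0}),
        ])
        return run

    def test_identical_means_give_zero(self):
        run = self.runs_with_means([4, 4, 0, 0, 0, 0], [4, 4, 0, 0, 0, 0])
        got = analysis.cumulative_change(run, "repertoire_diversity", 5.0, 15.0)
        assert got == pytest.approx(0.0)

    def test_fifty_percent_increase(self):
        # diversity log2 -> log(8/3^(3/4)...) use quality instead: 0.1 -> 0.15
        run = make_run([
            make_snapshot(5.0, {1: [1, 0, 0, 0, 0, 0]}, {1: 0}),
            make_snapshot(15.0, {2: [1, 1, 0, 0, 0, 0]}, {2: 0}),
        ])
        run.snapshots[0].type_Q = np.array([0.1, 0.2, 0, 0, 0, 0])
        run.snapshots[1].type_Q = np.array([0.1, 0.2, 0, 0, 0, 0])
        got = analysis.cumulative_change(run, "repertoire_quality", 5.0, 15.0)
        assert got == pytest.approx(0.5)

    def test_decline_is_negative(self):
        run = make_run([
            make_snapshot(5.0, {1: [1, 1, 0, 0, 0, 0]}, {1: 0}),
            make_snapshot(15.0, {2: [1, 0, 0, 0, 0, 0]}, {2: 0}),
        ])
        got = analysis.cumulative_change(run, "repertoire_diversity", 5.0, 15.0)
        assert got == pytest.approx(-1.0)


class TestSignificance:
    def test_bonferroni_alpha_for_four_conditions(self):
        scores = {f"H{k}": np.array([0.1, 0.2, 0.15, 0.12, 0.3]) for k in range(4)}
        report = analysis.significance_summary(scores, familywise_alpha=0.05)
        assert np.allclose(report["alpha"], 0.0125)

    def test_ten_positive_scores_are_significant(self):
        scores = {"c": np.linspace(0.05, 0.5, 10)}
        report = analysis.significance_summary(scores, familywise_alpha=0.0125)
        assert bool(report["significant"].iloc[0])
        assert report["p_value"].iloc[0] < 0.0125

    def test_symmetric_scores_not_significant(self):
        gen = np.random.default_rng(1)
        x = gen.normal(0, 1, 40)
        scores = {"c": x - np.median(x)}
        report = analysis.significance_summary(scores)
        assert not bool(report["significant"].iloc[0])

    def test_all_zero_scores_undefined(self):
        report = analysis.significance_summary({"c": np.zeros(6)})
        assert np.isnan(report["p_value"].iloc[0])
        assert not bool(report["significant"].iloc[0])

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            analysis.significance_summary({"c": np.array([1.0, 2.0])})
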