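"""Spherical search operators and the full detection loop."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from episphere.config import RunConfig
from episphere.engine import (
    Archive,
    HistoryMemory,
    Individual,
    crossover,
    decode_position,
    initialize_population,
    mutate,
    pareto_front,
    run_search,
    sample_scale_factor,
    spherical_step,
    update_archive,
    update_memory,
)
from episphere.exhaustive import exhaustive_best_k2, exhaustive_front
from episphere.scoring import DatasetScorer, ObjectivePair, score_combination

finite_floats = st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False)


class TestDecode:
    @pytest.mark.parametrize(
        "position, n_snps, expected",
        [
            ((3.7, 10.2), 20, (3, 10)),
            ((5.1, 5.9), 10, (5, 6)),  # duplicate repaired upward
            ((9.9, 9.1), 10, (0, 9)),  # repair wraps cyclically
            ((-4.0, 25.0), 10, (0, 9)),  # clipped into range
            ((2.5, 0.1, 2.9), 10, (0, 2, 3)),
        ],
    )
    def test_examples(self, position, n_snps, expected):
        assert decode_position(np.array(position), n_snps) == expected

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        st.lists(finite_floats, min_size=2, max_size=4),
        st.integers(4, 50),
    )
    def test_distinct_sorted_in_range_and_idempotent(self, pos, n_snps):
        decoded = decode_position(np.array(pos), n_snps)
        assert len(set(decoded)) == len(decoded)
        assert decoded == tuple(sorted(decoded))
        assert all(0 <= i < n_snps for i in decoded)
        again = decode_position(np.array(decoded, dtype=float), n_snps)
        assert again == decoded


class TestSphericalStep:
    def test_zero_radius(self, rng):
        a = np.array([3.0, 4.0])
        step = spherical_step(a, a, 0.7, rng)
        assert np.linalg.norm(step) == 0.0

    @pytest.mark.parametrize("dim", [1, 2, 3, 4])
    def test_norm_preservation(self, dim, rng):
        a = rng.normal(size=dim)
        b = rng.normal(size=dim)
        for f in (0.1, 0.5, 1.0):
            step = spherical_step(a, b, f, rng)
            assert np.linalg.norm(step) == pytest.approx(
                f * np.linalg.norm(a - b), rel=1e-12
            )

    def test_direction_uniform_on_circle(self, rng):
        """At dim 2 the mean direction over many draws vanishes."""
        a, b = np.array([0.0, 0.0]), np.array([2.0, 0.0])
        n = 10_000
        steps = np.array([spherical_step(a, b, 1.0, rng) for _ in range(n)])
        resultant = np.linalg.norm(steps.mean(axis=0)) / 2.0
        # Rayleigh-style bound: under uniformity E‖mean unit vector‖ ≈ n^-1/2
        assert resultant < 4.0 / math.sqrt(n)
        # all four quadrants visited
        assert (steps[:, 0] > 0).any() and (steps[:, 0] < 0).any()
        assert (steps[:, 1] > 0).any() and (steps[:, 1] < 0).any()


class TestMutateCrossover:
    def test_all_equal_vectors_give_identity(self, rng):
        x = np.array([5.0, 7.0])
        t = mutate(x, x, x, x, 0.8, 20, rng)
        assert t == pytest.approx(x)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.data())
    def test_step_bounded_by_triangle_inequality(self, data):
        dim = data.draw(st.integers(2, 4))
        vecs = [
            np.array(
                data.draw(
                    st.lists(
                        st.floats(0, 50, allow_nan=False),
                        min_size=dim,
                        max_size=dim,
                    )
                )
            )
            for _ in range(4)
        ]
        f = data.draw(st.floats(0.01, 1.0))
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        xi, pbest, r1, r2 = vecs
        # before reflection the displacement obeys the triangle bound
        s1 = spherical_step(xi, pbest, f, rng)
        s2 = spherical_step(r1, r2, f, rng)
        bound = f * (np.linalg.norm(xi - pbest) + np.linalg.norm(r1 - r2))
        assert np.linalg.norm(s1 + s2) <= bound + 1e-9

    def test_mutate_respects_bounds(self, rng):
        for _ in range(200):
            vecs = rng.uniform(0, 30, size=(4, 2))
            t = mutate(vecs[0], vecs[1], vecs[2], vecs[3], 1.0, 30, rng)
            assert (t >= 0).all() and (t < 30).all()

    def test_crossover_cr_one_copies_trial(self, rng):
        xi, ti = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        assert crossover(xi, ti, 1.0, rng) == pytest.approx(ti)

    def test_crossover_cr_zero_changes_exactly_one(self, rng):
        xi, ti = np.zeros(4), np.ones(4)
        for _ in range(50):
            u = crossover(xi, ti, 0.0, rng)
            assert int(u.sum()) == 1

    def test_crossover_rate_empirical(self, rng):
        xi, ti = np.zeros(2), np.ones(2)
        cr = 0.3
        n = 10_000
        taken = sum(crossover(xi, ti, cr, rng).sum() for _ in range(n))
        # each coordinate: P(take) = cr + (1-cr)·(1/dim forced)
        expected = 2 * (cr + (1 - cr) * 0.5)
        assert taken / n == pytest.approx(expected, rel=0.05)


class TestSelect:
    def _ind(self, k2, lr):
        return Individual(np.zeros(2), (0, 1), ObjectivePair(k2, lr, abs(lr)))

    def test_tie_keeps_parent(self):
        from episphere.decomposition import ReferencePoint
        from episphere.engine import select

        parent, trial = self._ind(1.0, -1.0), self._ind(1.0, -1.0)
        fx = np.array([0.4, 0.4])
        survivor, success, delta = select(
            parent, trial, fx, fx, np.array([0.5, 0.5]),
            ReferencePoint(np.zeros(2)), 5.0,
        )
        assert survivor is parent and not success and delta == 0.0

    def test_strict_improvement_wins_with_positive_delta(self):
        from episphere.decomposition import ReferencePoint, pbi_aggregate
        from episphere.engine import select

        parent, trial = self._ind(2.0, -1.0), self._ind(1.0, -2.0)
        ref = ReferencePoint(np.zeros(2))
        omega = np.array([0.5, 0.5])
        fx_p, fx_t = np.array([0.8, 0.8]), np.array([0.2, 0.2])
        survivor, success, delta = select(
            parent, trial, fx_p, fx_t, omega, ref, 5.0
        )
        assert survivor is trial and success
        assert delta == pytest.approx(
            pbi_aggregate(fx_p, omega, ref, 5.0)
            - pbi_aggregate(fx_t, omega, ref, 5.0)
        )
        assert delta > 0


class TestArchiveAndMemory:
    def test_capacity_enforced(self, rng):
        archive = Archive(capacity=4)
        ind = Individual(np.zeros(2), (0, 1), ObjectivePair(1.0, -1.0, 1.0))
        for _ in range(5):
            update_archive(archive, ind, rng)
        assert len(archive) == 4

    def test_single_insert(self, rng):
        archive = Archive(capacity=4)
        ind = Individual(np.zeros(2), (0, 1), ObjectivePair(1.0, -1.0, 1.0))
        update_archive(archive, ind, rng)
        assert len(archive) == 1

    def test_eviction_never_removes_newest(self, rng):
        archive = Archive(capacity=3)
        for i in range(50):
            ind = Individual(
                np.full(2, float(i)), (0, 1), ObjectivePair(1.0, -1.0, 1.0)
            )
            update_archive(archive, ind, rng)
            assert archive.members[-1].position[0] == float(i)

    def test_sample_scale_factor_contract(self, rng):
        memory = HistoryMemory.initial(5)
        draws = np.array([sample_scale_factor(memory, rng) for _ in range(20_000)])
        assert ((draws > 0) & (draws <= 1)).all()
        assert np.median(draws) == pytest.approx(0.5, abs=0.02)

    def test_sample_scale_factor_clamps_high_memory(self, rng):
        memory = HistoryMemory(values=np.full(3, 1.5))
        draws = [sample_scale_factor(memory, rng) for _ in range(2_000)]
        # Cauchy centered at 1.5 lands above 1 more than half the time
        assert np.mean([d == 1.0 for d in draws]) > 0.5

    def test_memory_single_success(self):
        memory = HistoryMemory.initial(3)
        update_memory(memory, [(0.7, 1.0)])
        assert memory.values[0] == pytest.approx(0.7)
        assert memory.k_index == 1

    def test_memory_lehmer_mean(self):
        memory = HistoryMemory.initial(3)
        update_memory(memory, [(0.2, 1.0), (0.8, 1.0)])
        assert memory.values[0] == pytest.approx(0.68)

    def test_memory_empty_copies_previous_slot(self):
        memory = HistoryMemory(values=np.array([0.3, 0.9, 0.5]), k_index=1)
        update_memory(memory, [])
        assert memory.values[1] == pytest.approx(0.3)
        update_memory(memory, [])  # slot 2 copies slot 1
        assert memory.values[2] == pytest.approx(0.3)
        update_memory(memory, [])  # wraps to slot 0, copies slot 2 (cyclic)
        assert memory.k_index == 1

    def test_memory_values_stay_in_unit_interval(self, rng):
        memory = HistoryMemory.initial(4)
        for _ in range(100):
            successes = [
                (float(rng.uniform(0.01, 1.0)), float(rng.uniform(0, 2)))
                for _ in range(int(rng.integers(0, 5)))
            ]
            update_memory(memory, successes)
            assert ((memory.values > 0) & (memory.values <= 1)).all()


class TestParetoFront:
    def test_componentwise_minimum_dominates_all(self):
        scored = {
            (0, 1): ObjectivePair(1.0, -9.0, 9.0),
            (0, 2): ObjectivePair(2.0, -5.0, 5.0),
            (1, 2): ObjectivePair(3.0, -1.0, 1.0),
        }
        front = pareto_front(scored)
        assert [c for c, _ in front] == [(0, 1)]

    def test_trade_off_points_all_kept_sorted_by_k2(self):
        scored = {
            (0, 1): ObjectivePair(1.0, -2.0, 2.0),
            (0, 2): ObjectivePair(2.0, -5.0, 5.0),
            (1, 2): ObjectivePair(3.0, -4.0, 4.0),  # dominated by (0,2)
        }
        front = pareto_front(scored)
        assert [c for c, _ in front] == [(0, 1), (0, 2)]

    def test_against_quadratic_oracle(self, rng):
        pts = rng.random((60, 2))
        scored = {
            (i, i + 100): ObjectivePair(float(p[0]), float(p[1]), 0.0)
            for i, p in enumerate(pts)
        }
        front = {c for c, _ in pareto_front(scored)}
        for combo, pair in scored.items():
            dominated = any(
                o.k2 <= pair.k2
                and o.lr <= pair.lr
                and (o.k2 < pair.k2 or o.lr < pair.lr)
                for o in scored.values()
            )
            if not dominated:
                assert combo in front or any(
                    scored[c].k2 == pair.k2 and scored[c].lr == pair.lr
                    for c in front
                )
            else:
                assert combo not in front


class TestRunSearch:
    def test_initial_population_bounds_and_mean(self, tiny_dataset, rng):
        scorer = DatasetScorer(tiny_dataset)
        pop = initialize_population(1000, 2, 2, scorer, rng)
        positions = np.array([ind.position for ind in pop])
        assert (positions >= 0).all() and (positions < 2).all()
        # uniform over [0, 2): mean 1, sd of the mean = (2/√12)/√1000
        assert positions.mean() == pytest.approx(1.0, abs=3 * 0.577 * 2 / 31.6)

    def test_budget_of_one_population_returns_initial_front(self, dnme_dataset):
        dataset, _ = dnme_dataset
        cfg = RunConfig(population_size=30, max_evaluations=30, seed=1)
        result = run_search(dataset, cfg)
        assert result.n_evaluations == 30
        assert result.n_unique_evaluated <= 30
        assert len(result.records) >= 1

    def test_determinism_and_seed_sensitivity(self, null_dataset):
        cfg = RunConfig(population_size=20, max_evaluations=600, seed=3)
        a = run_search(null_dataset, cfg)
        b = run_search(null_dataset, cfg)
        assert a.combinations() == b.combinations()
        assert [r.k2 for r in a.records] == [r.k2 for r in b.records]
        c = run_search(null_dataset, cfg.replace(seed=4))
        assert c.n_evaluations == a.n_evaluations  # same budget either way

    def test_reported_scores_are_fresh(self, dnme_dataset, quick_config):
        dataset, _ = dnme_dataset
        result = run_search(dataset, quick_config)
        for rec in result.records[:5]:
            again = score_combination(dataset, rec.snp_indices)
            assert rec.k2 == pytest.approx(again.k2, rel=1e-12)
            assert rec.raw_g == pytest.approx(again.raw_g, rel=1e-12)

    def test_recovers_embedded_pair(self, dnme_dataset):
        dataset, truth = dnme_dataset
        cfg = RunConfig(seed=11)  # auto budget: 4×C(100,2)
        result = run_search(dataset, cfg)
        assert truth.snp_indices in result.combinations()

    def test_matches_exhaustive_best_k2_on_small_panel(self, dnme_dataset):
        dataset, _ = dnme_dataset
        best_combo, best_k2 = exhaustive_best_k2(dataset)
        result = run_search(dataset, RunConfig(seed=2))
        assert result.records[0].snp_indices == best_combo
        assert result.records[0].k2 == pytest.approx(best_k2, rel=1e-12)

    def test_front_is_subset_of_exhaustive_front(self, dnme_dataset):
        dataset, _ = dnme_dataset
        full = {c for c, _ in exhaustive_front(dataset)}
        result = run_search(dataset, RunConfig(seed=5))
        # every reported point must be globally nondominated or only
        # beaten by combinations the budgeted run never evaluated
        assert result.records[0].snp_indices in full

    def test_rejects_order_exceeding_panel(self, tiny_dataset):
        with pytest.raises(ValueError):
            run_search(tiny_dataset, RunConfig(order_k=2, population_size=4))
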