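import numpy as np
import pandas as pd
import pytest

from mmaselect import (
    DataTable,
    FeatureSubset,
    FitnessEvaluator,
    MetaList,
    SearchConfig,
    exhaustive_select,
    mmas_select,
    neighborhood,
    relevance_scores,
)


def mask(*bits) -> FeatureSubset:
    return FeatureSubset(tuple(bool(b) for b in bits))


class TestFeatureSubset:
    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            FeatureSubset((False, False))

    def test_indices_and_size(self):
        s = mask(1, 0, 1)
        assert s.indices == (0, 2)
        assert s.size == 2


class TestNeighborhood:
    def test_d3_mask_101_neighbors(self):
        got = {n.mask for n in neighborhood(mask(1, 0, 1))}
        assert got == {(False, False, True), (True, True, True), (True, False, False)}

    def test_singleton_has_d_minus_1_neighbors(self):
        s = FeatureSubset.from_indices([2], 6)
        neigh = neighborhood(s)
        assert len(neigh) == 5
        assert all(n.size == 2 for n in neigh)  # only additions possible

    def test_full_subset_has_d_neighbors(self):
        neigh = neighborhood(FeatureSubset.full(4))
        assert len(neigh) == 4
        assert all(n.size == 3 for n in neigh)


class TestMetaList:
    def test_capacity_respected_and_eviction_fifo(self):
        ml = MetaList(capacity=3)
        subsets = [FeatureSubset.from_indices([i], 5) for i in range(5)]
        evicted = []
        for s in subsets:
            out = ml.push(s)
            if out is not None:
                evicted.append(out)
        assert len(ml) == 3
        assert evicted == subsets[:2]  # oldest leave first
        assert ml.entries == tuple(subsets[2:])

    def test_membership(self):
        ml = MetaList(capacity=2)
        a, b = mask(1, 0), mask(0, 1)
        ml.push(a)
        assert a in ml and b not in ml


class TestFitness:
    def test_memoized_and_deterministic(self, planted_table, small_search_config):
        table, _ = planted_table
        ev = FitnessEvaluator(table, small_search_config)
        s = FeatureSubset.full(table.n_cols)
        first = ev(s)
        evals = ev.n_evaluations
        assert ev(s) == first
        assert ev.n_evaluations == evals  # cache hit, no recomputation
        ev2 = FitnessEvaluator(table, small_search_config)
        assert ev2(s) == first  # same seed -> same folds -> same value

    def test_informative_beats_noise_subsets(self, planted_table, small_search_config):
        table, truth = planted_table
        ev = FitnessEvaluator(table, small_search_config)
        d = table.n_cols
        informative = FeatureSubset.from_indices(truth.informative, d)
        noise = FeatureSubset.from_indices(truth.noise[: len(truth.informative)], d)
        assert ev(informative) > ev(noise)

    def test_constant_features_favor_singletons(self):
        frame = pd.DataFrame({f"c{j}": [1.0] * 20 for j in range(4)})
        table = DataTable(
            frame, ("numeric",) * 4, np.arange(20) % 2, ("0", "1")
        )
        config = SearchConfig(seed=0, parsimony_weight=0.1, inner_cv_folds=5)
        ev = FitnessEvaluator(table, config)
        single = FeatureSubset.from_indices([0], 4)
        pair = FeatureSubset.from_indices([0, 1], 4)
        assert ev(single) > ev(pair)


class TestMmasSelect:
    def test_best_trajectory_non_decreasing(self, planted_table, small_search_config):
        table, _ = planted_table
        result = mmas_select(table, small_search_config)
        best_col = [b for _, b in result.trajectory]
        assert all(x <= y for x, y in zip(best_col, best_col[1:]))
        assert result.best_fitness == max(best_col)

    def test_deterministic_under_identical_config(self, planted_table, small_search_config):
        table, _ = planted_table
        a = mmas_select(table, small_search_config)
        b = mmas_select(table, small_search_config)
        assert a.best_subset == b.best_subset
        assert a.best_fitness == b.best_fitness
        assert a.trajectory == b.trajectory
        assert a.move_history == b.move_history

    def test_no_tabu_move_without_aspiration(self, planted_table):
        """Replay the walk against an independent FIFO buffer: a buffered
        subset may only be moved to when flagged as aspiration or forced."""
        table, _ = planted_table
        config = SearchConfig(seed=13, restarts=3, max_iter=80, tenure=5)
        result = mmas_select(table, config)
        buffer = MetaList(config.tenure)
        for m, kind in result.move_history:
            subset = FeatureSubset(m)
            if kind == "init":
                buffer = MetaList(config.tenure)
            elif kind == "move":
                assert subset not in buffer
            # "aspiration" and "forced" legitimately land on buffered subsets
            buffer.push(subset)

    def test_infinite_tenure_never_revisits_until_forced(self, planted_table):
        table, _ = planted_table
        config = SearchConfig(seed=17, restarts=2, max_iter=200, tenure=10**6,
                              stall_limit=200)
        result = mmas_select(table, config)
        seen: set = set()
        for m, kind in result.move_history:
            if kind == "init":
                seen = set()
            if kind in ("init", "move"):
                assert m not in seen
            seen.add(m)

    def test_single_iteration_returns_evaluated_initials(self, planted_table):
        table, _ = planted_table
        config = SearchConfig(seed=19, restarts=1, max_iter=1)
        result = mmas_select(table, config)
        # with one iteration, best is either the initial subset or its best neighbor
        assert result.iterations_run == 1
        assert len(result.trajectory) == 2

    def test_fewer_than_two_features_rejected(self):
        table = DataTable(
            pd.DataFrame({"x": [0.0, 1.0, 0.0, 1.0]}),
            ("numeric",),
            np.array([0, 1, 0, 1]),
            ("0", "1"),
        )
        with pytest.raises(ValueError, match="at least 2"):
            mmas_select(table, SearchConfig(inner_cv_folds=2))


class TestExhaustive:
    def test_d3_makes_exactly_seven_evaluations(self):
        rng = np.random.default_rng(23)
        frame = pd.DataFrame({f"x{j}": rng.normal(size=40) for j in range(3)})
        table = DataTable(frame, ("numeric",) * 3, np.arange(40) % 2, ("0", "1"))
        config = SearchConfig(seed=1, inner_cv_folds=4)
        ev = FitnessEvaluator(table, config)
        result = exhaustive_select(table, config, evaluator=ev)
        assert result.iterations_run == 7
        assert ev.n_evaluations == 7

    def test_oracle_dominates_mmas(self, planted_table, small_search_config):
        table, _ = planted_table
        ev = FitnessEvaluator(table, small_search_config)
        oracle = exhaustive_select(table, small_search_config, evaluator=ev)
        walk = mmas_select(table, small_search_config, evaluator=ev)
        assert oracle.best_fitness >= walk.best_fitness

    def test_perfect_feature_wins_singleton_at_d2(self):
        rng = np.random.default_rng(29)
        y = np.arange(60) % 2
        frame = pd.DataFrame(
            {"signal": y * 10.0 + rng.normal(0, 0.01, 60), "junk": rng.normal(size=60)}
        )
        table = DataTable(frame, ("numeric", "numeric"), y, ("0", "1"))
        result = exhaustive_select(table, SearchConfig(seed=2, parsimony_weight=0.05))
        assert result.best_subset.mask == (True, False)

    def test_guard_on_wide_tables(self):
        frame = pd.DataFrame(np.zeros((4, 21)), columns=[f"c{j}" for j in range(21)])
        table = DataTable(frame, ("numeric",) * 21, np.array([0, 1, 0, 1]), ("0", "1"))
        with pytest.raises(ValueError, match="guarded"):
            exhaustive_select(table, SearchConfig(inner_cv_folds=2))


class TestRelevance:
    def test_scores_in_range_and_flagging(self, planted_table):
        table, truth = planted_table
        config = SearchConfig(seed=31, restarts=6, max_iter=60)
        rel = relevance_scores(table, config)
        assert np.all((rel.scores >= 0) & (rel.scores <= 10))
        # every informative feature outranks every noise feature
        assert min(rel.scores[i] for i in truth.informative) > max(
            rel.scores[i] for i in truth.noise
        )
        for i in rel.low_relevance:
            assert rel.scores[i] < rel.drop_threshold

    def test_restarts_below_two_rejected(self, planted_table):
        table, _ = planted_table
        with pytest.raises(ValueError, match="restarts"):
            relevance_scores(table, SearchConfig(restarts=1))
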