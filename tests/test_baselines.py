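import numpy as np
import pandas as pd
import pytest

from mmaselect import (
    BaselineConfig,
    DataTable,
    FitnessEvaluator,
    SearchConfig,
    best_first,
    exhaustive_select,
    genetic_select,
    greedy_stepwise,
    pso_select,
)
from mmaselect.baselines import BASELINES, _sigmoid


def perfect_feature_table(n=60, noise_features=3, seed=0) -> DataTable:
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 2
    cols = {"signal": y * 10.0 + rng.normal(0, 0.01, n)}
    for j in range(noise_features):
        cols[f"junk{j}"] = rng.normal(size=n)
    frame = pd.DataFrame(cols)
    return DataTable(frame, ("numeric",) * frame.shape[1], y, ("0", "1"))


@pytest.fixture(scope="module")
def search_config():
    return SearchConfig(seed=3, inner_cv_folds=5)


class TestGreedyStepwise:
    def test_perfect_feature_added_first(self, search_config):
        table = perfect_feature_table()
        result = greedy_stepwise(table, search_config=search_config)
        assert 0 in result.best_subset.indices  # "signal" is column 0
        assert result.trajectory[0][0] == result.best_fitness or len(
            result.trajectory
        ) >= 1

    def test_accepted_fitness_strictly_increasing(self, planted_table, search_config):
        table, _ = planted_table
        result = greedy_stepwise(table, search_config=search_config)
        accepted = [f for f, _ in result.trajectory]
        assert all(a < b for a, b in zip(accepted, accepted[1:]))

    def test_single_feature_table_returns_it(self, search_config):
        rng = np.random.default_rng(1)
        table = DataTable(
            pd.DataFrame({"only": rng.normal(size=40)}),
            ("numeric",),
            np.arange(40) % 2,
            ("0", "1"),
        )
        result = greedy_stepwise(table, search_config=search_config)
        assert result.best_subset.mask == (True,)


class TestBestFirst:
    def test_matches_exhaustive_with_generous_stall(self, search_config):
        table = perfect_feature_table(n=80, noise_features=4, seed=5)
        ev = FitnessEvaluator(table, search_config)
        oracle = exhaustive_select(table, search_config, evaluator=ev)
        result = best_first(
            table, BaselineConfig(bfs_stall_limit=50), search_config, evaluator=ev
        )
        assert result.best_fitness == oracle.best_fitness

    def test_deterministic(self, planted_table, search_config):
        table, _ = planted_table
        a = best_first(table, search_config=search_config)
        b = best_first(table, search_config=search_config)
        assert a.best_subset == b.best_subset and a.best_fitness == b.best_fitness

    def test_stall_limit_one_stops_after_first_non_improvement(
        self, planted_table, search_config
    ):
        table, _ = planted_table
        result = best_first(
            table, BaselineConfig(bfs_stall_limit=1), search_config
        )
        best_col = [b for _, b in result.trajectory]
        # the final expansion is the single allowed non-improving one
        assert best_col[-1] == best_col[-2] or len(best_col) == 1


class TestGenetic:
    def test_elitist_best_non_decreasing(self, planted_table, search_config):
        table, _ = planted_table
        result = genetic_select(
            table, BaselineConfig(generations=15, seed=7), search_config
        )
        best_col = [b for _, b in result.trajectory]
        assert all(x <= y for x, y in zip(best_col, best_col[1:]))

    def test_no_variation_operators_keep_population_fixed(self, search_config):
        table = perfect_feature_table(n=40, noise_features=2, seed=9)
        config = BaselineConfig(
            crossover_rate=0.0, mutation_rate=0.0, generations=5, population=6, seed=11
        )
        result = genetic_select(table, config, search_config)
        # without variation, the best found in generation 0 can never improve
        best_col = [b for _, b in result.trajectory]
        assert best_col[-1] == best_col[0]

    def test_finds_optimum_on_small_planted_signal(self, search_config):
        table = perfect_feature_table(n=80, noise_features=4, seed=13)
        ev = FitnessEvaluator(table, search_config)
        oracle = exhaustive_select(table, search_config, evaluator=ev)
        result = genetic_select(table, BaselineConfig(seed=15), search_config, evaluator=ev)
        assert result.best_fitness == oracle.best_fitness


class TestPso:
    def test_global_best_non_decreasing(self, planted_table, search_config):
        table, _ = planted_table
        result = pso_select(
            table, BaselineConfig(pso_iterations=15, seed=17), search_config
        )
        best_col = [b for _, b in result.trajectory]
        assert all(x <= y for x, y in zip(best_col, best_col[1:]))

    def test_velocity_clamp_keeps_sigmoid_unsaturated(self):
        v = np.array([-6.0, 6.0])
        s = _sigmoid(v)
        assert 0.002 < s[0] < 0.003 and 0.997 < s[1] < 0.998

    def test_finds_optimum_on_small_planted_signal(self, search_config):
        table = perfect_feature_table(n=80, noise_features=4, seed=19)
        ev = FitnessEvaluator(table, search_config)
        oracle = exhaustive_select(table, search_config, evaluator=ev)
        result = pso_select(table, BaselineConfig(seed=21), search_config, evaluator=ev)
        assert result.best_fitness == oracle.best_fitness


class TestSharedContract:
    def test_all_methods_return_valid_subsets_and_share_fitness(
        self, planted_table, search_config
    ):
        table, _ = planted_table
        ev = FitnessEvaluator(table, search_config)
        for name, method in BASELINES.items():
            result = method(
                table, BaselineConfig(seed=23), search_config, evaluator=ev
            )
            assert result.best_subset.size >= 1
            # reported fitness is exactly the shared evaluator's value
            assert ev(result.best_subset) == result.best_fitness

    def test_identical_seeds_identical_results(self, planted_table, search_config):
        table, _ = planted_table
        for method in (genetic_select, pso_select):
            a = method(table, BaselineConfig(seed=29), search_config)
            b = method(table, BaselineConfig(seed=29), search_config)
            assert a.best_subset == b.best_subset
            assert a.trajectory == b.trajectory
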