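"""Design grid bookkeeping, arm running, ranking and MCB."""

import math

import numpy as np
import pandas as pd
import pytest

from oncorestrict.experiment import (
    DesignGrid,
    analyze_dataset,
    build_grid,
    dataset_for_point,
    mcb,
    rank_combinations,
    run_arm,
    summarize,
)


class TestGridBookkeeping:
    def test_full_factorial_counts(self):
        grid = build_grid("study")
        assert grid.n_among_combinations == 4 * 2 * 3 * 2 * 3 * 3 * 2 == 864
        assert grid.n_datasets == 864 * 20
        assert grid.n_factor_combinations_known == 5184
        assert grid.n_factor_combinations_unknown == 20736

    def test_analyses_per_method_family(self):
        grid = build_grid("study")
        assert grid.n_analyses_per_family == 172800

    def test_per_cell_aggregation_counts(self):
        grid = build_grid("study")
        assert grid.cell_count_known("method", "conjunction") == 8640
        assert grid.cell_count_known("method", "model") == 4320
        assert grid.cell_count_known("model", "sh") == 12960
        assert grid.cell_count_genes_selected(
            "model", "filter", "s_time", "n_nodes"
        ) == 720

    def test_test_profile_is_small_and_deterministic(self):
        grid = build_grid("test")
        assert grid.n_among_combinations <= 16
        assert grid.design_points() == build_grid("test").design_points()

    def test_single_level_grid(self):
        grid = build_grid(
            "test", models=("McF_4",), sh_levels=(0.0,), n_nodes=(7,),
            conjunction=(True,), s_sizes=(100,), s_types=("singleC",),
            s_times=("last",),
        )
        assert grid.n_among_combinations == 1


@pytest.fixture(scope="module")
def tiny_grid():
    return build_grid(
        "test", sh_levels=(math.inf,), conjunction=(True,),
        replicates=2, s_sizes=(30,),
    )


class TestRunArm:

    def test_known_arm_rows_per_dataset(self, tiny_grid):
        res = run_arm(tiny_grid, "known", master_seed=0, methods=("OT", "OT-A"))
        # 1 design point x 2 replicates x 2 methods
        assert len(res) == 4
        assert set(res["method"]) == {"OT", "OT-A"}
        assert res["Diff"].notna().all()

    def test_unknown_arm_rows_and_filters(self, tiny_grid):
        res = run_arm(tiny_grid, "unknown", master_seed=0, methods=("OT",))
        assert len(res) == 2 * 4  # replicates x filters
        assert set(res["filter"]) == {"S1", "S5", "J1", "J5"}

    def test_rerun_identical(self, tiny_grid):
        r1 = run_arm(tiny_grid, "known", master_seed=5, methods=("OT",))
        r2 = run_arm(tiny_grid, "known", master_seed=5, methods=("OT",))
        pd.testing.assert_frame_equal(r1, r2)

    def test_failures_recorded_not_raised(self, tiny_grid):
        def boom(_):
            raise RuntimeError("synthetic failure")

        grid = tiny_grid
        graph, ds = dataset_for_point(
            grid, grid.design_points()[0], 0, 0, "known"
        )
        rows = analyze_dataset(
            ds, graph, methods=("OT",), filters=None, registry={"OT": boom}
        )
        assert len(rows) == 1
        assert math.isnan(rows[0]["Diff"])
        assert "synthetic failure" in rows[0]["error"]


class TestRanking:
    def test_average_rank_arithmetic(self):
        df = pd.DataFrame({
            "method": ["a", "b", "c"] * 2,
            "s_time": ["last"] * 6,
            "s_type": ["singleC"] * 6,
            "model": ["m1"] * 3 + ["m2"] * 3,
            "sh": [0.0] * 6,
            "n_nodes": [7] * 6,
            "conjunction": [True] * 6,
            "s_size": [100] * 6,
            "Diff": [1, 2, 3, 2, 1, 3],
        })
        ranks = rank_combinations(df, "Diff")
        assert ranks["a, last, singleC"] == 1.5
        assert ranks["b, last, singleC"] == 1.5
        assert ranks["c, last, singleC"] == 3.0

    def test_single_cell_equals_its_ranks(self):
        df = pd.DataFrame({
            "method": ["a", "b"], "s_time": ["last"] * 2,
            "s_type": ["singleC"] * 2, "model": ["m"] * 2, "sh": [0.0] * 2,
            "n_nodes": [7] * 2, "conjunction": [True] * 2, "s_size": [100] * 2,
            "Diff": [5, 1],
        })
        ranks = rank_combinations(df, "Diff")
        assert ranks["b, last, singleC"] == 1.0

    def test_cell_order_invariance(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "method": list("abc") * 4,
            "s_time": ["last"] * 12, "s_type": ["singleC"] * 12,
            "model": ["m1"] * 6 + ["m2"] * 6, "sh": [0.0] * 12,
            "n_nodes": [7] * 12, "conjunction": [True] * 12,
            "s_size": [100] * 6 + [200] * 6,
            "Diff": rng.integers(0, 10, 12),
        })
        shuffled = df.sample(frac=1.0, random_state=1)
        pd.testing.assert_series_equal(
            rank_combinations(df, "Diff"), rank_combinations(shuffled, "Diff")
        )

    def test_empty_results_rejected(self):
        df = pd.DataFrame({"method": [], "s_time": [], "s_type": [],
                           "Diff": []})
        with pytest.raises(ValueError):
            rank_combinations(df, "Diff")


class TestMCB:
    def _frame(self, scores_by_method):
        rows = []
        for method, vals in scores_by_method.items():
            for i, v in enumerate(vals):
                rows.append({"replicate": i, "method": method, "Diff": v})
        return pd.DataFrame(rows)

    def test_identical_treatments_both_kept(self):
        df = self._frame({"m1": [1.0] * 20, "m2": [1.0] * 20})
        assert mcb(df, "Diff") == ["m1", "m2"]

    def test_dominant_treatment_singleton(self):
        rng = np.random.default_rng(0)
        df = self._frame({
            "good": rng.normal(0, 0.1, 20),
            "bad": rng.normal(5, 0.1, 20),
            "worse": rng.normal(6, 0.1, 20),
        })
        assert mcb(df, "Diff") == ["good"]

    def test_confidence_set_never_empty(self):
        rng = np.random.default_rng(1)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            df = self._frame({
                m: rng.normal(rng.uniform(0, 3), 1.0, 20)
                for m in ("a", "b", "c", "d")
            })
            assert len(mcb(df, "Diff")) >= 1

    def test_coverage_of_true_best_under_null(self):
        # all treatments equal: the (arbitrary) first treatment must stay in
        # the confidence set at least ~coverage of the time
        hits = 0
        n_rep = 120
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            df = self._frame({
                m: rng.normal(0.0, 1.0, 20) for m in ("a", "b", "c")
            })
            if "a" in mcb(df, "Diff", coverage=0.90):
                hits += 1
        assert hits / n_rep >= 0.85

    def test_summarize_frequencies_normalized(self):
        rng = np.random.default_rng(2)
        rows = []
        for model in ("m1", "m2"):
            for rep in range(20):
                for method in ("x", "y"):
                    rows.append({
                        "model": model, "sh": 0.0, "n_nodes": 7,
                        "conjunction": True, "s_size": 100,
                        "s_type": "singleC", "s_time": "last",
                        "replicate": rep, "method": method,
                        "Diff": rng.normal(0 if method == "x" else 3, 1),
                        "PFD": 0.0, "PND": 0.0, "FPF": 0.0,
                    })
        tables = summarize(pd.DataFrame(rows), "Diff")
        freq = tables["confidence_set_frequencies"]["frequency"]
        assert freq.sum() == pytest.approx(1.0)
        assert set(tables["mean_scores"].index) == {"x", "y"}

    def test_summarize_empty_results(self):
        tables = summarize(pd.DataFrame(), "Diff")
        assert tables["mean_scores"].empty
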