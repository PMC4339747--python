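"""Factorial study orchestration, ranking and comparisons with the best.

The study crosses among-data-set factors — evolutionary Model (4 levels),
sh (2), number of driver nodes (3), Conjunction (2), sample size S.Size
(3), sampling type S.Type (3) and sampling time S.Time (2) — for 864
combinations, each with 20 replicate data sets at study scale.  Within
each data set the within-data-set factors are Method (six slots in the
design: OT, OT-A, CBN, CBN-A, DiP, DiP-A; the DiP pair requires an
external MILP solver and is a plug-in slot here) and, in the
Drivers-Unknown arm only, the Filtering procedure (S1, S5, J1, J5).

``build_grid("test")`` gives a reduced profile that runs on one CPU;
``rank_combinations`` and ``mcb`` implement the overall ranking and the
multiple-comparisons-with-the-best summaries of the results table.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cbn import CBNEstimator
from .filtering import FILTER_NAMES, augment, filter_genes
from .graphs import GenomeSpec, RestrictionGraph, fixture_graph
from .metrics import scores
from .ot import OncotreeEstimator
from .sampling import Dataset, SampleSpec, build_dataset
from .simulate import ModelParams

MEASURES = ("Diff", "PFD", "PND", "FPF")

METHOD_ROSTER = ("OT", "OT-A", "CBN", "CBN-A", "DiP", "DiP-A")
IMPLEMENTED_METHODS = ("OT", "OT-A", "CBN", "CBN-A")

AMONG_FACTORS = (
    "model",
    "sh",
    "n_nodes",
    "conjunction",
    "s_size",
    "s_type",
    "s_time",
)


@dataclass(frozen=True)
class DesignGrid:
    models: tuple = ("Bozic", "exp", "McF_4", "McF_6")
    sh_levels: tuple = (0.0, math.inf)
    n_nodes: tuple = (7, 9, 11)
    conjunction: tuple = (True, False)
    s_sizes: tuple = (100, 200, 1000)
    s_types: tuple = ("singleC", "wholeT_0.5", "wholeT_0.01")
    s_times: tuple = ("last", "unif")
    replicates: int = 20
    methods: tuple = METHOD_ROSTER
    filters: tuple = FILTER_NAMES
    # scaled-down simulation knobs (test profile only; None = model default)
    pop_threshold: float = 1e9
    mutation_rate: float | None = None
    init_size: int = 500

    # -- design arithmetic (the printed bookkeeping identities) ------------

    @property
    def n_among_combinations(self) -> int:
        return (
            len(self.models)
            * len(self.sh_levels)
            * len(self.n_nodes)
            * len(self.conjunction)
            * len(self.s_sizes)
            * len(self.s_types)
            * len(self.s_times)
        )

    @property
    def n_datasets(self) -> int:
        return self.n_among_combinations * self.replicates

    @property
    def n_factor_combinations_known(self) -> int:
        return self.n_among_combinations * len(self.methods)

    @property
    def n_factor_combinations_unknown(self) -> int:
        return self.n_among_combinations * len(self.methods) * len(self.filters)

    @property
    def n_analyses_known(self) -> int:
        return self.n_datasets * len(self.methods)

    @property
    def n_analyses_unknown(self) -> int:
        return self.n_datasets * len(self.methods) * len(self.filters)

    @property
    def n_analyses_per_family(self) -> int:
        """Analyses run by one method family (a plain + augmented pair)
        across both arms."""
        per_method = self.n_datasets * (1 + len(self.filters))
        return per_method * 2

    def cell_count_known(self, *factors: str) -> int:
        """Values averaged in one Drivers-Known cell of the given factors
        (e.g. ("method", "conjunction") -> 8640 at study scale)."""
        sizes = {
            "method": len(self.methods),
            "model": len(self.models),
            "sh": len(self.sh_levels),
            "conjunction": len(self.conjunction),
            "n_nodes": len(self.n_nodes),
            "s_size": len(self.s_sizes),
            "s_type": len(self.s_types),
            "s_time": len(self.s_times),
        }
        total = self.n_analyses_known
        for f in factors:
            total //= sizes[f]
        return total

    def cell_count_genes_selected(self, *factors: str) -> int:
        """Values averaged per cell in the genes-selected summaries
        (Drivers Unknown; one value per dataset x filter)."""
        sizes = {
            "filter": len(self.filters),
            "model": len(self.models),
            "sh": len(self.sh_levels),
            "conjunction": len(self.conjunction),
            "n_nodes": len(self.n_nodes),
            "s_size": len(self.s_sizes),
            "s_type": len(self.s_types),
            "s_time": len(self.s_times),
        }
        total = self.n_datasets * len(self.filters)
        for f in factors:
            total //= sizes[f]
        return total

    # -- enumeration -------------------------------------------------------

    def design_points(self) -> list[dict]:
        pts = []
        for model, sh, nn, conj, size, stype, stime in itertools.product(
            self.models,
            self.sh_levels,
            self.n_nodes,
            self.conjunction,
            self.s_sizes,
            self.s_types,
            self.s_times,
        ):
            pts.append(
                {
                    "model": model,
                    "sh": sh,
                    "n_nodes": nn,
                    "conjunction": conj,
                    "s_size": size,
                    "s_type": stype,
                    "s_time": stime,
                }
            )
        return pts


def build_grid(scale: Literal["study", "test"] = "study", **overrides) -> DesignGrid:
    """Full study grid, or the reduced single-CPU test profile."""
    if scale == "study":
        return replace(DesignGrid(), **overrides)
    if scale == "test":
        test = DesignGrid(
            models=("McF_4",),
            sh_levels=(0.0, math.inf),
            n_nodes=(7,),
            conjunction=(True, False),
            s_sizes=(100,),
            s_types=("singleC",),
            s_times=("last",),
            replicates=3,
            methods=IMPLEMENTED_METHODS,
            pop_threshold=5e4,
            mutation_rate=1e-5,
        )
        return replace(test, **overrides)
    raise ValueError(f"unknown scale {scale!r}")


def _graph_for(point: dict) -> RestrictionGraph:
    suffix = "A" if point["conjunction"] else "B"
    return fixture_graph(f"{point['n_nodes']}-{suffix}")


def point_key(point: dict, replicate: int) -> str:
    return (
        f"{point['model']}|{point['sh']}|{point['n_nodes']}|"
        f"{point['conjunction']}|{point['s_size']}|{point['s_type']}|"
        f"{point['s_time']}|rep{replicate}"
    )


def make_params(grid: DesignGrid, point: dict) -> ModelParams:
    return ModelParams(
        model=point["model"],
        sh=point["sh"],
        pop_threshold=grid.pop_threshold,
        mutation_rate=grid.mutation_rate,
        init_size=grid.init_size,
    )


def dataset_for_point(
    grid: DesignGrid,
    point: dict,
    replicate: int,
    master_seed: int,
    arm: Literal["known", "unknown"],
) -> tuple[RestrictionGraph, Dataset]:
    graph = _graph_for(point)
    if arm == "known":
        genome = GenomeSpec(graph.drivers)
    else:
        genome = GenomeSpec.with_passengers(graph.drivers, ratio=4)
    params = make_params(grid, point)
    sample = SampleSpec(
        s_time=point["s_time"],
        s_type=point["s_type"],
        n_subjects=point["s_size"],
    )
    ds = build_dataset(
        graph,
        genome,
        params,
        sample,
        master_seed=master_seed,
        design_key=arm + "|" + point_key(point, replicate),
    )
    return graph, ds


def _default_registry(seed: int) -> dict[str, Callable]:
    def run_ot(data):
        return OncotreeEstimator().fit(data).tree_

    def run_cbn(data):
        return CBNEstimator(random_state=seed).fit(data).model_

    return {"OT": run_ot, "CBN": run_cbn}


def analyze_dataset(
    dataset: Dataset,
    graph: RestrictionGraph,
    methods: Sequence[str],
    filters: Sequence[str] | None,
    seed: int = 0,
    registry: dict[str, Callable] | None = None,
) -> list[dict]:
    """Run every method (x filter, if Drivers Unknown) on one dataset.

    The "-A" variant of a method augments with 10% zero rows first; in the
    unknown arm augmentation always follows filtering.  Failures are
    recorded as rows with NaN scores rather than raised.
    """
    registry = registry or _default_registry(seed)
    rows = []
    filter_list: Sequence = list(filters) if filters else [None]
    for filt in filter_list:
        if filt is None:
            selected, data = dataset.gene_labels, dataset
        else:
            selected, data = filter_genes(dataset, filt)
        for method in methods:
            base = method.removesuffix("-A")
            if base not in registry:
                continue
            row = {
                "method": method,
                "filter": filt,
                "n_genes_selected": len(selected),
            }
            try:
                inp = augment(data) if method.endswith("-A") else data
                inferred = registry[base](inp)
                row.update(scores(graph, inferred).as_dict())
            except Exception as exc:  # noqa: BLE001 - sweep must not abort
                row.update(dict.fromkeys(MEASURES, np.nan))
                row["error"] = repr(exc)
            rows.append(row)
    return rows


def run_arm(
    grid: DesignGrid,
    arm: Literal["known", "unknown"],
    master_seed: int = 0,
    methods: Sequence[str] | None = None,
    registry: dict[str, Callable] | None = None,
    progress: Callable[[str], None] | None = None,
) -> pd.DataFrame:
    """Run one study arm over the grid; one row per analysis."""
    methods = tuple(methods or [m for m in grid.methods if m in IMPLEMENTED_METHODS])
    filters = grid.filters if arm == "unknown" else None
    records = []
    for point in grid.design_points():
        for rep in range(grid.replicates):
            key = point_key(point, rep)
            if progress:
                progress(f"{arm}:{key}")
            graph, ds = dataset_for_point(grid, point, rep, master_seed, arm)
            rows = analyze_dataset(
                ds, graph, methods, filters, seed=master_seed, registry=registry
            )
            for row in rows:
                records.append(
                    {**point, "replicate": rep, "arm": arm, **row}
                )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Ranking and multiple comparisons with the best
# ---------------------------------------------------------------------------


def rank_combinations(
    results: pd.DataFrame,
    measure: str,
    combo_factors: Sequence[str] = ("method", "s_time", "s_type"),
    cell_factors: Sequence[str] = ("model", "sh", "n_nodes", "conjunction", "s_size"),
) -> pd.Series:
    """Rank treatment combinations by their average within-cell rank.

    In every cell (a combination of the remaining among-data-set factors)
    the mean score of each treatment combination is ranked (ties get the
    average rank); ranks are averaged over cells and the averages ranked
    again (smaller score = better = rank 1).
    """
    df = results.dropna(subset=[measure]).copy()
    if df.empty:
        raise ValueError("no results for requested measure")
    cell_factors = [f for f in cell_factors if f in df.columns and df[f].nunique() > 0]
    combo = df[list(combo_factors)].astype(str).agg(", ".join, axis=1)
    df["_combo"] = combo
    df["_cell"] = df[list(cell_factors)].astype(str).agg("|".join, axis=1)
    per_cell = (
        df.groupby(["_cell", "_combo"])[measure].mean().unstack("_combo")
    )
    ranks = per_cell.rank(axis=1, method="average")
    mean_rank = ranks.mean(axis=0)
    return mean_rank.rank(method="average").sort_values()


def mcb(
    results: pd.DataFrame,
    measure: str,
    treatment_factors: Sequence[str] = ("method",),
    block_factor: str = "replicate",
    coverage: float = 0.90,
) -> list[str]:
    """Confidence set of treatments not distinguishable from the best.

    Hsu-style constrained comparisons for a block design: each treatment
    is compared against the best of the others with a one-sided paired
    Wilcoxon signed-rank test on per-block scores (blocks = data sets),
    Bonferroni-adjusted to level (1 - coverage)/(m - 1) per comparison so
    joint coverage is at least ``coverage``.  Smaller scores are better.
    Treatments whose test rejects are excluded; the empirically best
    treatment is always retained, so the set is never empty.
    """
    df = results.dropna(subset=[measure]).copy()
    df["_treat"] = df[list(treatment_factors)].astype(str).agg(", ".join, axis=1)
    table = df.pivot_table(
        index=block_factor, columns="_treat", values=measure, aggfunc="mean"
    )
    table = table.dropna(axis=0)
    treatments = list(table.columns)
    m = len(treatments)
    if m < 2:
        return treatments
    alpha = (1.0 - coverage) / (m - 1)
    means = table.mean(axis=0)
    incumbent = means.idxmin()
    keep = []
    for t in treatments:
        others = table.drop(columns=t)
        rival = others.mean(axis=0).idxmin()
        diffs = table[t].to_numpy() - table[rival].to_numpy()
        if np.allclose(diffs, 0):
            keep.append(t)
            continue
        # H1: t is worse (larger) than the best of the others
        stat = stats.wilcoxon(
            diffs, alternative="greater", zero_method="zsplit"
        )
        if stat.pvalue >= alpha:
            keep.append(t)
    if incumbent not in keep:
        keep.append(incumbent)
    return sorted(keep)


def mcb_by_combination(
    results: pd.DataFrame,
    measure: str,
    treatment_factors: Sequence[str] = ("method",),
    among_factors: Sequence[str] = AMONG_FACTORS,
    coverage: float = 0.90,
) -> pd.DataFrame:
    """MCB confidence set per among-data-set factor combination."""
    among = [f for f in among_factors if f in results.columns]
    rows = []
    for key, sub in results.groupby(among, dropna=False):
        members = mcb(
            sub, measure, treatment_factors=treatment_factors, coverage=coverage
        )
        rows.append(
            dict(zip(among, key if isinstance(key, tuple) else (key,)))
            | {"confidence_set": ", ".join(members)}
        )
    return pd.DataFrame(rows)


def summarize(
    results: pd.DataFrame,
    measure: str = "Diff",
    treatment_factors: Sequence[str] = ("method",),
    coverage: float = 0.90,
) -> dict[str, pd.DataFrame]:
    """Confidence-set frequencies and per-cell mean-score tables."""
    if results.empty:
        return {
            "confidence_set_frequencies": pd.DataFrame(),
            "mean_scores": pd.DataFrame(),
        }
    sets = mcb_by_combination(
        results, measure, treatment_factors=treatment_factors, coverage=coverage
    )
    freq = (
        sets["confidence_set"].value_counts(normalize=True).rename("frequency")
    ).to_frame()
    treat = results[list(treatment_factors)].astype(str).agg(", ".join, axis=1)
    mean_scores = (
        results.assign(_treat=treat)
        .groupby("_treat")[list(MEASURES)]
        .mean()
    )
    return {"confidence_set_frequencies": freq, "mean_scores": mean_scores}
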