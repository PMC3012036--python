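"""Monte-Carlo benchmarking of imputation and testing pipelines.

Two experiments, both starting from a complete matrix with known
values:

1. *Accuracy*: repeatedly mask cells at random, impute with each
   method, and score the normalized root-mean-square error over the
   masked cells together with the average within-spot variance of the
   completed matrix (imputation shrinks it — how much is a method
   property).
2. *Discovery stability*: repeatedly mask → impute → test each spot →
   threshold at alpha, and summarize per-method/per-test discovery
   sets by their median size, the consensus set (significant in at
   least half the replicates), and the overlap with the complete-data
   discoveries.

Replicate ``r`` draws its mask with seed ``base_seed + r`` and every
method (and test) sees the identical masked matrix, so method
contrasts are paired and Monte-Carlo noise cancels in comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .impute import ImputationResult, get_imputer
from .matrix import SpotMatrix
from .multitest import select_per_comparison
from .simulate import RemovalRecord, remove_at_random
from .stattests import ResamplingConfig, test_matrix

__all__ = [
    "normalized_rmse",
    "average_variance",
    "RmseExperimentResult",
    "run_rmse_experiment",
    "DiscoveryExperimentResult",
    "run_discovery_experiment",
    "consensus_discoveries",
    "overlap_summary",
    "median_discoveries",
]


def normalized_rmse(
    record: RemovalRecord, result: ImputationResult, divisor: str = "global_sd"
) -> float:
    """RMSE over the masked cells, normalized to be scale-free.

    The default divisor is the standard deviation of the *complete*
    data (the imputed matrix with the recorded truths restored), which
    is independent of the particular mask draw, so comparisons across
    missing fractions are not distorted by the spread of the masked
    subsample.  ``divisor="sd"`` uses the SD of the true masked values
    and ``divisor="mean"`` their mean.  A zero divisor (constant
    truths) returns the raw RMSE with a warning.
    """
    imputed_map = {(s, g): v for s, g, v in result.imputed_cells}
    try:
        imputed = np.array([imputed_map[cell] for cell in record.cells])
    except KeyError as exc:
        raise ValueError(f"masked cell {exc} missing from imputation result") from None
    truth = record.true_values
    rmse = float(np.sqrt(np.mean((imputed - truth) ** 2)))
    if divisor == "global_sd":
        full = result.matrix.values.copy()
        for (r, c), v in zip(record.index_cells, truth):
            full[r, c] = v
        scale = float(full.std(ddof=1))
    elif divisor == "sd":
        scale = float(truth.std(ddof=1)) if truth.size > 1 else 0.0
    elif divisor == "mean":
        scale = float(truth.mean())
    else:
        raise ValueError("divisor must be 'global_sd', 'sd' or 'mean'")
    if scale == 0.0:
        warnings.warn("constant true values; returning un-normalized RMSE", stacklevel=2)
        return rmse
    return rmse / scale


def average_variance(matrix: SpotMatrix) -> float:
    """Mean over spots of the across-gel sample variance (ddof=1)."""
    if not matrix.is_complete:
        raise ValueError("average_variance requires a complete matrix")
    return float(matrix.values.var(axis=1, ddof=1).mean())


@dataclass
class RmseExperimentResult:
    """Tidy per-(method, fraction, replicate) accuracy table."""

    table: pd.DataFrame
    base_seed: int

    def summary(self) -> pd.DataFrame:
        """Mean and SD of NRMSE and average variance per method × fraction."""
        return (
            self.table.groupby(["method", "fraction"], sort=False)
            .agg(
                mean_nrmse=("nrmse", "mean"),
                sd_nrmse=("nrmse", "std"),
                mean_avg_variance=("avg_variance", "mean"),
                complete_avg_variance=("complete_avg_variance", "first"),
                n_replicates=("replicate", "count"),
            )
            .reset_index()
        )


def run_rmse_experiment(
    source: SpotMatrix,
    methods: Sequence[str],
    fractions: Sequence[float],
    n_reps: int,
    base_seed: int = 0,
    divisor: str = "global_sd",
    min_per_group: int = 2,
) -> RmseExperimentResult:
    """Masked-cell accuracy experiment over methods × fractions × replicates."""
    if not source.is_complete:
        raise ValueError("source matrix must be complete")
    complete_var = average_variance(source)
    imputers = {m: get_imputer(m, seed=base_seed) for m in methods}
    rows = []
    for r in range(n_reps):
        seed = base_seed + r
        for frac in fractions:
            masked, record = remove_at_random(
                source, frac, seed=seed, min_per_group=min_per_group
            )
            for label, imputer in imputers.items():
                try:
                    result = imputer(masked)
                    nrmse = normalized_rmse(record, result, divisor=divisor)
                    av = average_variance(result.matrix)
                    err = ""
                except Exception as exc:  # method failure: record, continue
                    nrmse, av, err = np.nan, np.nan, str(exc)
                rows.append((label, frac, r, seed, nrmse, av, complete_var, err))
    table = pd.DataFrame(
        rows,
        columns=[
            "method",
            "fraction",
            "replicate",
            "seed",
            "nrmse",
            "avg_variance",
            "complete_avg_variance",
            "error",
        ],
    )
    return RmseExperimentResult(table, base_seed)


@dataclass
class DiscoveryExperimentResult:
    """Per-replicate p-values and discovery sets for tests × methods.

    ``pvalues`` has one row per (test, method, replicate, spot);
    ``complete_pvalues`` holds the single unmasked-source run per test.
    """

    pvalues: pd.DataFrame
    complete_pvalues: pd.DataFrame
    spot_ids: tuple[str, ...]
    alpha: float
    n_reps: int

    def rejection_sets(self) -> dict[tuple[str, str, int], set[str]]:
        out: dict[tuple[str, str, int], set[str]] = {}
        rej = self.pvalues[self.pvalues["p_value"] < self.alpha]
        for (test, method, rep), grp in self.pvalues.groupby(
            ["test", "method", "replicate"], sort=False
        ):
            out[(test, method, rep)] = set(
                grp.loc[grp["p_value"] < self.alpha, "spot_id"]
            )
        return out

    def complete_rejections(self) -> dict[str, set[str]]:
        out = {}
        for test, grp in self.complete_pvalues.groupby("test", sort=False):
            out[test] = set(grp.loc[grp["p_value"] < self.alpha, "spot_id"])
        return out

    def consensus(self, min_fraction: float = 0.5) -> dict[tuple[str, str], set[str]]:
        """Spots significant in at least ceil(min_fraction * n_reps) replicates."""
        out: dict[tuple[str, str], set[str]] = {}
        for (test, method), grp in self.pvalues.groupby(["test", "method"], sort=False):
            grid = grp.pivot_table(
                index="replicate", columns="spot_id", values="p_value"
            )
            out[(test, method)] = consensus_discoveries(
                grid, self.alpha, min_fraction
            )
        return out

    def median_discoveries(self) -> pd.DataFrame:
        rows = []
        for (test, method, _), spots in sorted(self.rejection_sets().items()):
            rows.append((test, method, len(spots)))
        df = pd.DataFrame(rows, columns=["test", "method", "n_discoveries"])
        out = (
            df.groupby(["test", "method"], sort=False)["n_discoveries"]
            .median()
            .reset_index(name="median_discoveries")
        )
        return out

    def overlap(self, test: str, min_fraction: float = 0.5) -> dict[tuple[str, ...], int]:
        """Venn-region counts for complete-data vs per-method consensus sets."""
        sets: dict[str, set[str]] = {"complete": self.complete_rejections()[test]}
        for (t, method), spots in self.consensus(min_fraction).items():
            if t == test:
                sets[method] = spots
        return overlap_summary(sets)


def run_discovery_experiment(
    source: SpotMatrix,
    methods: Sequence[str],
    tests: Sequence[str],
    fraction: float = 0.10,
    n_reps: int = 20,
    alpha: float = 0.05,
    base_seed: int = 0,
    resampling: ResamplingConfig | None = None,
    min_per_group: int = 2,
) -> DiscoveryExperimentResult:
    """Mask → impute → test → threshold, replicated with paired masks."""
    if not source.is_complete:
        raise ValueError("source matrix must be complete")
    resampling = resampling or ResamplingConfig()
    complete_rows = []
    for test in tests:
        tbl = test_matrix(
            source, test, ResamplingConfig(resampling.n_boot, resampling.n_perm, base_seed)
        )
        for _, row in tbl.iterrows():
            complete_rows.append((test, row["spot_id"], row["p_value"]))
    complete_df = pd.DataFrame(complete_rows, columns=["test", "spot_id", "p_value"])

    imputers = {m: get_imputer(m, seed=base_seed) for m in methods}
    rows = []
    for r in range(n_reps):
        seed = base_seed + r
        masked, _ = remove_at_random(source, fraction, seed=seed, min_per_group=min_per_group)
        for label, imputer in imputers.items():
            completed = imputer(masked).matrix
            for test in tests:
                tbl = test_matrix(
                    completed,
                    test,
                    ResamplingConfig(resampling.n_boot, resampling.n_perm, seed),
                )
                for _, row in tbl.iterrows():
                    rows.append((test, label, r, row["spot_id"], row["p_value"]))
    pv = pd.DataFrame(rows, columns=["test", "method", "replicate", "spot_id", "p_value"])
    return DiscoveryExperimentResult(
        pv, complete_df, source.spot_ids, alpha, n_reps
    )


def consensus_discoveries(
    per_replicate_pvals: pd.DataFrame | np.ndarray,
    alpha: float = 0.05,
    min_fraction: float = 0.5,
    spot_ids: Sequence[str] | None = None,
) -> set[str]:
    """Spots with p < alpha in at least ceil(min_fraction * n_reps) replicates.

    Accepts a replicate × spot DataFrame (columns are spot ids) or a
    plain array plus ``spot_ids``.
    """
    if isinstance(per_replicate_pvals, pd.DataFrame):
        grid = per_replicate_pvals.to_numpy(dtype=float)
        ids = list(per_replicate_pvals.columns)
    else:
        grid = np.asarray(per_replicate_pvals, dtype=float)
        if spot_ids is None:
            raise ValueError("spot_ids required with an array grid")
        ids = list(spot_ids)
    if np.isnan(grid).any():
        raise ValueError("p-value grid must be complete")
    n_reps = grid.shape[0]
    need = int(np.ceil(min_fraction * n_reps))
    hits = (grid < alpha).sum(axis=0)
    return {s for s, h in zip(ids, hits) if h >= need}


def overlap_summary(sets: Mapping[str, set]) -> dict[tuple[str, ...], int]:
    """Counts of every region of the inclusion–exclusion partition.

    Keys are sorted tuples of the labels whose sets contain the region
    exclusively; counts sum to the size of the union.  Limited to 2–4
    sets (the practical rendering limit of a Venn diagram).
    """
    labels = list(sets)
    if not 2 <= len(labels) <= 4:
        raise ValueError("overlap_summary supports 2 to 4 labelled sets")
    universe = set().union(*sets.values())
    out: dict[tuple[str, ...], int] = {}
    for k in range(1, len(labels) + 1):
        for combo in combinations(labels, k):
            inside = set.intersection(*(sets[l] for l in combo)) if combo else universe
            outside = set().union(*(sets[l] for l in labels if l not in combo), set())
            out[tuple(sorted(combo))] = len(inside - outside)
    return out


def median_discoveries(per_replicate_sets: Iterable[set]) -> float:
    """Median rejection-set size across replicates."""
    sizes = [len(s) for s in per_replicate_sets]
    if not sizes:
        raise ValueError("need at least one replicate")
    return float(np.median(sizes))
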