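"""Missing-value imputation for spot-volume matrices.

Four families, registered under the labels used throughout configs and
reports:

``RowAve``
    Each missing cell is replaced by the mean of the spot's observed
    cells.  Maximally shrinks within-spot variance.
``KNN(k)``
    Weighted average over the k most similar spots (Euclidean distance
    over mutually observed gels, rescaled by sqrt(n_gels/n_shared) so
    distances are comparable across overlap sizes).
``LSM.LS.G`` / ``LSM.LS.A``
    Least-squares regression imputation using spot-spot ("gene") or
    gel-gel ("array") correlation: a weighted average of single
    regressions on the most correlated spots/gels, weights
    ``(r^2/(1-r^2+eps))^2``.
``LSM.EM.G`` / ``LSM.EM.A``
    EM refinement of the LS estimates under a Gaussian model with
    covariance across spots (G) or gels (A): missing cells are
    iteratively replaced by their conditional expectations while the
    mean and covariance are re-estimated.
``LSM.LS.C`` / ``LSM.LS.Ad``
    Convex combinations of the gene- and array-wise LS estimates with a
    single global mixing weight fitted on a seeded 5% hold-out of
    observed cells (C) or a per-cell weight from the relative weight
    mass of the two sides (Ad).
``NIPALS(n)``
    Iterative PCA tolerant of missing entries; missing cells are read
    off the rank-n reconstruction plus the removed spot means.

All imputers are deterministic given matrix and config, are the
identity on complete matrices, and never modify observed cells.
Regression-based imputers may extrapolate below zero; such values are
kept (clipping would bias error comparisons) but flagged.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, replace
from typing import Callable, Iterable

import numpy as np

from .matrix import SpotMatrix, ValidationError

__all__ = [
    "KnnConfig",
    "LsimputeConfig",
    "NipalsConfig",
    "ImputationResult",
    "impute_row_average",
    "impute_knn",
    "impute_ls_gene",
    "impute_ls_array",
    "impute_em",
    "impute_ls_combined",
    "impute_nipals",
    "get_imputer",
    "METHOD_LABELS",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KnnConfig:
    k: int = 5
    metric: str = "euclidean"  # or "pearson"
    weighting: str = "inverse_distance"  # or "uniform"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if self.metric not in ("euclidean", "pearson"):
            raise ValidationError(f"unknown metric {self.metric!r}")
        if self.weighting not in ("inverse_distance", "uniform"):
            raise ValidationError(f"unknown weighting {self.weighting!r}")


@dataclass(frozen=True)
class LsimputeConfig:
    """Settings for the least-squares / EM family.

    ``n_neighbors=10`` is the fixed neighbor count of the regression
    variants; ``seed`` governs the LS.C hold-out draw.
    """

    variant: str = "LS.G"
    n_neighbors: int = 10
    em_tol: float = 1e-4
    em_max_iter: int = 100
    ridge_eps: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in ("LS.G", "EM.G", "LS.A", "EM.A", "LS.C", "LS.Ad"):
            raise ValidationError(f"unknown LSM variant {self.variant!r}")
        if self.n_neighbors < 1:
            raise ValidationError("n_neighbors must be >= 1")
        if self.em_tol <= 0:
            raise ValidationError("em_tol must be > 0")


@dataclass(frozen=True)
class NipalsConfig:
    n_components: int = 5
    tol: float = 1e-6
    max_iter: int = 500
    center: bool = True

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValidationError("n_components must be >= 1")


@dataclass
class ImputationResult:
    """A completed matrix plus provenance of every imputed cell."""

    matrix: SpotMatrix
    imputed_cells: list[tuple[str, str, float]]
    method_label: str
    warning_flags: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.matrix.is_complete:
            raise ValidationError("imputation result must be complete")
        if self.warning_flags is None:
            self.warning_flags = []


def _require_rows_observed(X: np.ndarray, spot_ids) -> None:
    empty = np.flatnonzero(np.all(np.isnan(X), axis=1))
    if empty.size:
        raise ValidationError(
            f"spot(s) with no observed cells: {[spot_ids[i] for i in empty]}"
        )


def _result(matrix: SpotMatrix, filled: np.ndarray, label: str, flags=None) -> ImputationResult:
    miss = np.isnan(matrix.values)
    rows, cols = np.nonzero(miss)
    cells = [
        (matrix.spot_ids[r], matrix.gel_ids[c], float(filled[r, c]))
        for r, c in zip(rows, cols)
    ]
    flags = list(flags or [])
    if any(v < 0 for _, _, v in cells):
        flags.append("negative_imputed_values")
    out = matrix.values.copy()
    out[miss] = filled[miss]
    # bypass the non-negativity check: extrapolated negatives are kept on purpose
    completed = SpotMatrix.__new__(SpotMatrix)
    completed.spot_ids = matrix.spot_ids
    completed.design = matrix.design
    completed.values = out
    return ImputationResult(completed, cells, label, flags)


# ---------------------------------------------------------------------------
# Row average
# ---------------------------------------------------------------------------

def impute_row_average(matrix: SpotMatrix) -> ImputationResult:
    """Replace each missing cell by the mean of its spot's observed cells."""
    X = matrix.values
    _require_rows_observed(X, matrix.spot_ids)
    row_means = np.nanmean(X, axis=1)
    filled = np.where(np.isnan(X), row_means[:, None], X)
    return _result(matrix, filled, "RowAve")


# ---------------------------------------------------------------------------
# K nearest neighbors
# ---------------------------------------------------------------------------

def _knn_fill(X: np.ndarray, config: KnnConfig) -> tuple[np.ndarray, list[str]]:
    n_spots, n_gels = X.shape
    obs = ~np.isnan(X)
    row_means = np.nanmean(X, axis=1)
    X0 = np.where(obs, X, 0.0)
    filled = X.copy()
    flags: list[str] = []
    for i in np.flatnonzero(~obs.all(axis=1)):
        # distances from spot i to every other spot over shared gels
        W = obs & obs[i][None, :]
        ns = W.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            if config.metric == "euclidean":
                d2 = (np.where(W, X0 - X0[i][None, :], 0.0) ** 2).sum(axis=1)
                dists = np.sqrt(d2) * np.sqrt(n_gels / ns)
                usable = ns >= 1
            else:  # pearson: 1 - r over shared gels
                Xm = np.where(W, X0, 0.0)
                Ym = np.where(W, X0[i][None, :], 0.0)
                sx, sy = Xm.sum(axis=1), Ym.sum(axis=1)
                cov = (Xm * Ym).sum(axis=1) - sx * sy / ns
                varx = (Xm**2).sum(axis=1) - sx**2 / ns
                vary = (Ym**2).sum(axis=1) - sy**2 / ns
                r = cov / np.sqrt(varx * vary)
                dists = 1.0 - r
                usable = (ns >= 2) & (varx > 0) & (vary > 0) & np.isfinite(r)
        usable = usable.copy()
        usable[i] = False
        for j in np.flatnonzero(~obs[i]):
            cand = np.flatnonzero(usable & obs[:, j])
            if cand.size == 0:
                filled[i, j] = row_means[i]
                flags.append(f"knn_fallback_row_average:{i},{j}")
                continue
            k = min(config.k, cand.size)
            order = cand[np.argsort(dists[cand], kind="stable")[:k]]
            d_sel = dists[order]
            zero = d_sel == 0.0
            if config.weighting == "inverse_distance" and zero.any():
                # a perfect twin short-circuits: use only zero-distance neighbors
                filled[i, j] = float(X[order[zero], j].mean())
            elif config.weighting == "inverse_distance":
                w = 1.0 / d_sel
                filled[i, j] = float(np.sum(w * X[order, j]) / np.sum(w))
            else:
                filled[i, j] = float(X[order, j].mean())
    return filled, flags


def impute_knn(matrix: SpotMatrix, config: KnnConfig | None = None) -> ImputationResult:
    """KNN imputation over the most similar spots (see module docstring)."""
    config = config or KnnConfig()
    if config.k >= matrix.n_spots:
        raise ValidationError("k must be < n_spots")
    _require_rows_observed(matrix.values, matrix.spot_ids)
    filled, flags = _knn_fill(matrix.values, config)
    if flags:
        logger.info("KNN fell back to row average for %d cell(s)", len(flags))
    return _result(matrix, filled, f"KNN({config.k})", flags)


# ---------------------------------------------------------------------------
# LSimpute: regression on correlated spots (gene) or gels (array)
# ---------------------------------------------------------------------------

def _ls_core(
    X: np.ndarray, n_neighbors: int, ridge_eps: float
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Gene-wise LS fill of ``X`` (rows are the correlated records).

    Returns the filled matrix, the per-cell un-normalized weight mass
    (zero where the row-average fallback fired), and flag strings.
    Transposing the input turns this into the array-wise variant.

    The per-target regression statistics (correlation, slope,
    intercept against every other row over mutually observed columns)
    are computed in one vectorized pass per target row.
    """
    n_rows, n_cols = X.shape
    obs = ~np.isnan(X)
    row_means = np.nanmean(X, axis=1)
    X0 = np.where(obs, X, 0.0)
    filled = X.copy()
    mass = np.zeros_like(X)
    flags: list[str] = []
    for i in np.flatnonzero(~obs.all(axis=1)):
        # stats of every candidate row against target i over shared columns
        W = obs & obs[i][None, :]
        ns = W.sum(axis=1)
        Xm = np.where(W, X0, 0.0)
        Ym = np.where(W, X0[i][None, :], 0.0)
        sx = Xm.sum(axis=1)
        sy = Ym.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cov = (Xm * Ym).sum(axis=1) - sx * sy / ns
            varx = (Xm**2).sum(axis=1) - sx**2 / ns
            vary = (Ym**2).sum(axis=1) - sy**2 / ns
            r = cov / np.sqrt(varx * vary)
            b = cov / varx
            a = (sy - b * sx) / ns
        valid = (ns >= 3) & (varx > 0) & (vary > 0) & np.isfinite(r)
        valid[i] = False
        r = np.clip(r, -1.0, 1.0)
        w_all = (r**2 / (1.0 - r**2 + ridge_eps)) ** 2
        for j in np.flatnonzero(~obs[i]):
            cand = valid & obs[:, j]
            idx = np.flatnonzero(cand)
            if idx.size == 0:
                filled[i, j] = row_means[i]
                flags.append(f"ls_fallback_row_average:{i},{j}")
                continue
            order = idx[np.argsort(-np.abs(r[idx]), kind="stable")][:n_neighbors]
            w = w_all[order]
            preds = a[order] + b[order] * X[order, j]
            if w.sum() == 0.0:
                filled[i, j] = float(preds.mean())
            else:
                filled[i, j] = float(np.sum(w * preds) / w.sum())
            mass[i, j] = float(w.sum())
    return filled, mass, flags


def impute_ls_gene(matrix: SpotMatrix, config: LsimputeConfig | None = None) -> ImputationResult:
    """LS regression on the most correlated spots (LSM.LS.G)."""
    config = config or LsimputeConfig(variant="LS.G")
    _require_rows_observed(matrix.values, matrix.spot_ids)
    filled, _, flags = _ls_core(matrix.values, config.n_neighbors, config.ridge_eps)
    return _result(matrix, filled, "LSM.LS.G", flags)


def impute_ls_array(matrix: SpotMatrix, config: LsimputeConfig | None = None) -> ImputationResult:
    """LS regression on the most correlated gels (LSM.LS.A)."""
    config = config or LsimputeConfig(variant="LS.A")
    _require_rows_observed(matrix.values, matrix.spot_ids)
    filled_t, _, flags = _ls_core(matrix.values.T, config.n_neighbors, config.ridge_eps)
    return _result(matrix, filled_t.T, "LSM.LS.A", flags)


# ---------------------------------------------------------------------------
# EM refinement under a Gaussian covariance model
# ---------------------------------------------------------------------------

def _em_core(
    X_init: np.ndarray,
    miss: np.ndarray,
    tol: float,
    max_iter: int,
    ridge_eps: float,
) -> tuple[np.ndarray, bool]:
    """EM for a column-covariance Gaussian; rows are independent records.

    E-step: replace each row's missing cells by their conditional
    expectation given the observed cells, and accumulate the
    conditional covariance of the missing block (without this
    correction, iterated regression imputation progressively
    underestimates residual variance and over-extrapolates).
    M-step: re-estimate the mean vector and covariance from the
    completed rows plus the accumulated corrections.

    Convergence is the maximum change of an imputed cell relative to
    its magnitude, floored at the matrix's observed standard deviation
    so that cells imputed near zero cannot stall the iteration.
    """
    X = X_init.copy()
    n_rows, n_cols = X.shape
    scale = float(X_init[~miss].std()) or 1.0
    converged = max_iter == 0
    corr = np.zeros((n_cols, n_cols))  # summed conditional covariances
    for _ in range(max_iter):
        mu = X.mean(axis=0)
        S = (X - mu).T @ (X - mu) / n_rows + corr / n_rows
        S += ridge_eps * np.eye(n_cols)
        X_new = X.copy()
        corr = np.zeros((n_cols, n_cols))
        for i in np.flatnonzero(miss.any(axis=1)):
            m = miss[i]
            o = ~m
            if not o.any():
                continue
            Soo = S[np.ix_(o, o)]
            Smo = S[np.ix_(m, o)]
            try:
                sol = np.linalg.solve(Soo, X[i, o] - mu[o])
                gain = np.linalg.solve(Soo, Smo.T).T
            except np.linalg.LinAlgError:
                sol = np.linalg.lstsq(Soo, X[i, o] - mu[o], rcond=None)[0]
                gain = np.linalg.lstsq(Soo, Smo.T, rcond=None)[0].T
            X_new[i, m] = mu[m] + Smo @ sol
            corr[np.ix_(m, m)] += S[np.ix_(m, m)] - gain @ Smo.T
        old_imp = X[miss]
        new_imp = X_new[miss]
        denom = np.maximum(np.abs(old_imp), scale)
        delta = float(np.max(np.abs(new_imp - old_imp) / denom)) if old_imp.size else 0.0
        X = X_new
        if delta < tol:
            converged = True
            break
    return X, converged


def impute_em(matrix: SpotMatrix, config: LsimputeConfig | None = None) -> ImputationResult:
    """EM imputation with gel (EM.A) or spot (EM.G) covariance structure.

    Missing cells are initialized from the corresponding LS variant and
    then iteratively replaced by their conditional expectations under a
    Gaussian whose mean and covariance are re-estimated each pass.
    """
    config = config or LsimputeConfig(variant="EM.A")
    if config.variant not in ("EM.A", "EM.G"):
        config = replace(config, variant="EM.A")
    _require_rows_observed(matrix.values, matrix.spot_ids)
    miss = np.isnan(matrix.values)
    if config.variant == "EM.A":
        init = impute_ls_array(matrix, replace(config, variant="LS.A")).matrix.values
        filled, converged = _em_core(
            init, miss, config.em_tol, config.em_max_iter, config.ridge_eps
        )
    else:
        init = impute_ls_gene(matrix, replace(config, variant="LS.G")).matrix.values
        filled_t, converged = _em_core(
            init.T, miss.T, config.em_tol, config.em_max_iter, config.ridge_eps
        )
        filled = filled_t.T
    flags = [] if converged else ["em_not_converged"]
    if not converged:
        logger.info(
            "EM tolerance %.0e not reached within %d iterations; "
            "returning current estimates", config.em_tol, config.em_max_iter,
        )
    return _result(matrix, filled, f"LSM.{config.variant}", flags)


# ---------------------------------------------------------------------------
# Combined and adaptive mixtures of the gene- and array-wise estimates
# ---------------------------------------------------------------------------

def _fit_global_p(
    matrix: SpotMatrix, config: LsimputeConfig
) -> tuple[float, list[str]]:
    """Least-squares mixing weight from a seeded 5% hold-out of observed cells."""
    obs_rows, obs_cols = np.nonzero(~np.isnan(matrix.values))
    n_obs = obs_rows.size
    n_hold = int(round(0.05 * n_obs))
    if n_hold < 1:
        return 0.5, ["holdout_infeasible_p_half"]
    rng = np.random.default_rng(config.seed)
    pick = rng.choice(n_obs, size=n_hold, replace=False)
    hr, hc = obs_rows[pick], obs_cols[pick]
    truth = matrix.values[hr, hc].copy()
    vals2 = matrix.values.copy()
    vals2[hr, hc] = np.nan
    if np.any(np.all(np.isnan(vals2), axis=1)):
        return 0.5, ["holdout_infeasible_p_half"]
    m2 = SpotMatrix(matrix.spot_ids, matrix.design, vals2)
    g = impute_ls_gene(m2, config).matrix.values[hr, hc]
    a = impute_ls_array(m2, config).matrix.values[hr, hc]
    denom = float(np.sum((g - a) ** 2))
    if denom == 0.0:
        return 0.5, ["holdout_degenerate_p_half"]
    p = float(np.sum((truth - a) * (g - a)) / denom)
    return float(np.clip(p, 0.0, 1.0)), []


def impute_ls_combined(
    matrix: SpotMatrix,
    config: LsimputeConfig | None = None,
    global_p: float | None = None,
) -> ImputationResult:
    """Combined (LS.C) or adaptive (LS.Ad) mixture of gene/array LS estimates.

    ``global_p`` overrides the fitted LS.C mixing weight (diagnostics:
    p=1 reproduces the gene-wise fill, p=0 the array-wise fill).
    """
    config = config or LsimputeConfig(variant="LS.C")
    if config.variant not in ("LS.C", "LS.Ad"):
        raise ValidationError("impute_ls_combined handles variants LS.C and LS.Ad")
    _require_rows_observed(matrix.values, matrix.spot_ids)
    gene, gene_mass, gflags = _ls_core(matrix.values, config.n_neighbors, config.ridge_eps)
    arr_t, arr_mass_t, aflags = _ls_core(matrix.values.T, config.n_neighbors, config.ridge_eps)
    arr, arr_mass = arr_t.T, arr_mass_t.T
    miss = np.isnan(matrix.values)
    filled = matrix.values.copy()
    flags = list(gflags) + list(aflags)
    if config.variant == "LS.C":
        if global_p is not None:
            p, pflags = float(global_p), []
        else:
            p, pflags = _fit_global_p(matrix, config)
        flags += pflags
        filled[miss] = p * gene[miss] + (1.0 - p) * arr[miss]
        label = "LSM.LS.C"
        flags.append(f"global_p={p:.4f}")
    else:
        gm, am = gene_mass[miss], arr_mass[miss]
        tot = gm + am
        p_cell = np.where(tot > 0, gm / np.where(tot > 0, tot, 1.0), 0.5)
        filled[miss] = p_cell * gene[miss] + (1.0 - p_cell) * arr[miss]
        label = "LSM.LS.Ad"
    return _result(matrix, filled, label, flags)


# ---------------------------------------------------------------------------
# NIPALS PCA imputation
# ---------------------------------------------------------------------------

def _nipals_core(
    Xc: np.ndarray, n_components: int, tol: float, max_iter: int
) -> tuple[np.ndarray, bool]:
    """Rank-n reconstruction of a (centered) matrix with missing entries."""
    obs = ~np.isnan(Xc)
    R = np.where(obs, Xc, 0.0)
    recon = np.zeros_like(R)
    all_converged = True
    for _ in range(n_components):
        # initialize the score vector with the column of largest observed SS
        col = int(np.argmax((R**2 * obs).sum(axis=0)))
        t = R[:, col].astype(float).copy()
        if not np.any(t):
            t = np.ones(R.shape[0])
        converged = False
        for _ in range(max_iter):
            # loadings: per-column regression on t over observed cells
            num = (R * t[:, None] * obs).sum(axis=0)
            den = ((t**2)[:, None] * obs).sum(axis=0)
            p = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
            norm = np.linalg.norm(p)
            if norm == 0.0:
                converged = True
                break
            p /= norm
            # scores: per-row regression on p over observed cells
            num_t = (R * p[None, :] * obs).sum(axis=1)
            den_t = ((p**2)[None, :] * obs).sum(axis=1)
            t_new = np.where(den_t > 0, num_t / np.where(den_t > 0, den_t, 1.0), 0.0)
            change = np.linalg.norm(t_new - t) / max(np.linalg.norm(t_new), 1e-300)
            t = t_new
            if change < tol:
                converged = True
                break
        all_converged &= converged
        comp = np.outer(t, p)
        recon += comp
        R = R - comp * obs
    return recon, all_converged


def impute_nipals(matrix: SpotMatrix, config: NipalsConfig | None = None) -> ImputationResult:
    """PCA imputation via NIPALS with missing-cell-aware inner regressions."""
    config = config or NipalsConfig()
    if config.n_components > min(matrix.n_spots, matrix.n_gels):
        raise ValidationError("n_components must be <= min(n_spots, n_gels)")
    _require_rows_observed(matrix.values, matrix.spot_ids)
    X = matrix.values
    if config.center:
        row_means = np.nanmean(X, axis=1)
        Xc = X - row_means[:, None]
    else:
        row_means = np.zeros(matrix.n_spots)
        Xc = X
    recon, converged = _nipals_core(Xc, config.n_components, config.tol, config.max_iter)
    filled = np.where(np.isnan(X), recon + row_means[:, None], X)
    flags = [] if converged else ["nipals_component_not_converged"]
    if not converged:
        logger.info("NIPALS component did not converge; using current vectors")
    return _result(matrix, filled, f"NIPALS({config.n_components})", flags)


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

METHOD_LABELS = [
    "RowAve",
    "KNN(k)",
    "LSM.LS.G",
    "LSM.EM.G",
    "LSM.LS.A",
    "LSM.EM.A",
    "LSM.LS.C",
    "LSM.LS.Ad",
    "NIPALS(nPR)",
]

_KNN_RE = re.compile(r"^KNN\((\d+)\)$")
_NIPALS_RE = re.compile(r"^NIPALS\((\d+)\)$")


def get_imputer(label: str, seed: int = 0) -> Callable[[SpotMatrix], ImputationResult]:
    """Resolve a method label (e.g. ``"KNN(5)"``, ``"LSM.EM.A"``) to a callable.

    ``seed`` only matters for ``LSM.LS.C``, whose hold-out draw is seeded.
    """
    if label == "RowAve":
        return impute_row_average
    m = _KNN_RE.match(label)
    if m:
        cfg = KnnConfig(k=int(m.group(1)))
        return lambda mat: impute_knn(mat, cfg)
    m = _NIPALS_RE.match(label)
    if m:
        cfg = NipalsConfig(n_components=int(m.group(1)))
        return lambda mat: impute_nipals(mat, cfg)
    if label.startswith("LSM."):
        variant = label[4:]
        if variant not in ("LS.G", "EM.G", "LS.A", "EM.A", "LS.C", "LS.Ad"):
            raise KeyError(
                f"unknown imputation method {label!r}; valid forms: {METHOD_LABELS}"
            )
        cfg = LsimputeConfig(variant=variant, seed=seed)
        if variant in ("LS.G",):
            return lambda mat: impute_ls_gene(mat, cfg)
        if variant in ("LS.A",):
            return lambda mat: impute_ls_array(mat, cfg)
        if variant in ("EM.A", "EM.G"):
            return lambda mat: impute_em(mat, cfg)
        if variant in ("LS.C", "LS.Ad"):
            return lambda mat: impute_ls_combined(mat, cfg)
    raise KeyError(
        f"unknown imputation method {label!r}; valid forms: {METHOD_LABELS}"
    )
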