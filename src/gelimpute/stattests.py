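"""Per-spot two-group tests for differential spot abundance.

Six tests, all two-sided, all built around the unequal-variance
comparison of two small samples (typically six gels per condition):

``t.welch``
    Welch's t with Satterthwaite degrees of freedom.
``t.perm``
    Permutation test on the Welch statistic; exact enumeration of all
    group relabellings when feasible, seeded Monte-Carlo otherwise.
``chebby``
    A distribution-free bound on the two-sided p-value via Chebyshev's
    inequality applied to the Welch statistic: p = min(1, 1/t^2).
``boot.normal`` / ``boot.percentile`` / ``boot.pivotal``
    Bootstrap tests obtained by inverting the corresponding confidence
    interval for the raw mean difference.  With the small default of 25
    resamples the achievable p-value resolution is 2/25 = 0.08 for the
    count-based variants.

Zero-variance degenerate rows return p = 1 (statistic 0) rather than
NaN so that downstream discovery counting never silently drops spots.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations
from math import comb
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "EXACT",
    "ResamplingConfig",
    "TestResult",
    "welch_t",
    "permutation_t",
    "chebby_checker",
    "bootstrap_t",
    "test_matrix",
    "TESTS",
    "get_test",
]

#: Sentinel for forcing exhaustive permutation enumeration.
EXACT = "exact"

#: Enumerate all relabellings whenever their count is at most this.
_EXACT_LIMIT = 200_000


@dataclass(frozen=True)
class ResamplingConfig:
    """Resampling sizes and the seed shared by bootstrap/permutation tests.

    ``n_boot=25`` follows the small-sample practice for six-gel groups;
    raising it sharpens the p-value resolution of the count-based
    bootstrap variants (resolution is 1/n_boot for one tail).
    ``n_perm`` is the Monte-Carlo permutation count, or :data:`EXACT`.
    """

    n_boot: int = 25
    n_perm: int | str = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.n_perm != EXACT and int(self.n_perm) < 1:
            raise ValueError("n_perm must be >= 1 or EXACT")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    test_label: str
    spot_id: str | None = None
    detail: dict = field(default_factory=dict)


def _as_sample(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < 2:
        raise ValueError(f"sample {name} must contain at least 2 values")
    if np.isnan(arr).any():
        raise ValueError(f"sample {name} contains missing values")
    return arr


def _welch_statistic(a: np.ndarray, b: np.ndarray) -> tuple[float, float, bool]:
    """Welch t, Satterthwaite df, and a degenerate (zero-variance) flag."""
    na, nb = a.size, b.size
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    if se2 == 0.0:
        # both groups constant: no evidence either way unless means differ
        if ma == mb:
            return 0.0, float(na + nb - 2), True
        return float(np.copysign(np.inf, ma - mb)), float(na + nb - 2), True
    t = (ma - mb) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return float(t), float(df), False


def welch_t(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Welch (unequal-variance) t-test."""
    a, b = _as_sample(a, "a"), _as_sample(b, "b")
    t, df, degenerate = _welch_statistic(a, b)
    if degenerate:
        p = 1.0 if t == 0.0 else 0.0
    else:
        p = float(2.0 * sps.t.sf(abs(t), df))
    return TestResult(t, p, "t.welch", detail={"df": df, "degenerate": degenerate})


@lru_cache(maxsize=16)
def _exact_masks(n: int, na: int) -> np.ndarray:
    """All C(n, na) boolean group-A assignments as a (P, n) array."""
    masks = np.zeros((comb(n, na), n), dtype=bool)
    for p, idx in enumerate(combinations(range(n), na)):
        masks[p, list(idx)] = True
    return masks


def _welch_t_vectorized(pooled: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Welch t for every assignment row of ``masks`` over ``pooled``."""
    na = int(masks[0].sum())
    nb = pooled.size - na
    x, x2 = pooled, pooled**2
    sa = masks @ x
    sa2 = masks @ x2
    sb = x.sum() - sa
    sb2 = x2.sum() - sa2
    ma, mb = sa / na, sb / nb
    va = (sa2 - sa**2 / na) / (na - 1)
    vb = (sb2 - sb**2 / nb) / (nb - 1)
    va = np.maximum(va, 0.0)  # guard tiny negative round-off
    vb = np.maximum(vb, 0.0)
    se2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
    # zero-variance splits: t = 0 when means agree, +-inf otherwise
    degen = se2 == 0.0
    if degen.any():
        diff = ma[degen] - mb[degen]
        t[degen] = np.where(diff == 0.0, 0.0, np.copysign(np.inf, diff))
    return t


def permutation_t(
    a: Sequence[float],
    b: Sequence[float],
    config: ResamplingConfig | None = None,
) -> TestResult:
    """Permutation test using the Welch t as the test statistic.

    All ``C(n_a+n_b, n_a)`` relabellings are enumerated when that count
    is at most 200,000 or when ``config.n_perm`` is :data:`EXACT`;
    otherwise ``n_perm`` seeded random relabellings are drawn with the
    observed assignment always included.  The p-value counts
    relabellings whose \\|t\\| reaches the observed \\|t\\| (the observed
    one included), so exact p-values are multiples of 1/#relabellings.
    """
    config = config or ResamplingConfig()
    a, b = _as_sample(a, "a"), _as_sample(b, "b")
    na, n = a.size, a.size + b.size
    pooled = np.concatenate([a, b])
    t_obs, _, _ = _welch_statistic(a, b)
    total = comb(n, na)
    exact = config.n_perm == EXACT or total <= _EXACT_LIMIT
    if exact:
        masks = _exact_masks(n, na)
    else:
        n_perm = int(config.n_perm)
        rng = np.random.default_rng(config.seed)
        masks = np.zeros((n_perm, n), dtype=bool)
        masks[0, :na] = True  # the observed assignment
        for r in range(1, n_perm):
            masks[r, rng.permutation(n)[:na]] = True
    t_all = _welch_t_vectorized(pooled, masks)
    # tolerance so the mirror of the observed split is always counted
    thresh = abs(t_obs) * (1 - 1e-12) - 1e-12
    if np.isinf(t_obs):
        n_ge = int(np.sum(np.isinf(t_all)))
    else:
        n_ge = int(np.sum(np.abs(t_all) >= thresh))
    p = n_ge / masks.shape[0]
    return TestResult(
        t_obs,
        float(p),
        "t.perm",
        detail={"n_resamples": int(masks.shape[0]), "exact_flag": bool(exact)},
    )


def chebby_checker(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Chebyshev-inequality bound on the two-sided p of the Welch statistic.

    For any distribution of a standardized statistic t,
    P(|T| >= |t|) <= 1/t^2, so p = min(1, 1/t^2).  The bound is
    distribution-free and conservative: it never rejects unless
    |t| > 1/sqrt(alpha) (about 4.47 at alpha = 0.05).
    """
    a, b = _as_sample(a, "a"), _as_sample(b, "b")
    t, df, degenerate = _welch_statistic(a, b)
    if t == 0.0:
        p = 1.0
    elif np.isinf(t):
        p = 0.0
    else:
        p = min(1.0, 1.0 / t**2)
    return TestResult(t, float(p), "chebby", detail={"df": df, "degenerate": degenerate})


_BOOT_VARIANTS = ("normal", "percentile", "pivotal")


def bootstrap_p_from_draws(
    d_hat: float, d_star: np.ndarray, variant: str
) -> tuple[float, float, bool]:
    """p-value from bootstrap mean differences; returns (statistic, p, degenerate).

    Split out of :func:`bootstrap_t` so the interval-inversion formulas
    can be checked directly against hand-counted draws.
    """
    d_star = np.asarray(d_star, dtype=float)
    degenerate = False
    if variant == "normal":
        sd = float(d_star.std(ddof=1))
        if sd == 0.0:
            degenerate = True
            p = 1.0 if d_hat == 0.0 else 0.0
            stat = 0.0 if d_hat == 0.0 else float(np.copysign(np.inf, d_hat))
        else:
            stat = d_hat / sd
            p = float(2.0 * sps.norm.sf(abs(stat)))
    elif variant == "percentile":
        lo = float(np.mean(d_star <= 0.0))
        hi = float(np.mean(d_star >= 0.0))
        stat = d_hat
        p = min(1.0, 2.0 * min(lo, hi))
    elif variant == "pivotal":
        lo = float(np.mean(d_star >= 2.0 * d_hat))
        hi = float(np.mean(d_star <= 2.0 * d_hat))
        stat = d_hat
        p = min(1.0, 2.0 * min(lo, hi))
    else:
        raise ValueError(f"unknown bootstrap variant {variant!r}; use {_BOOT_VARIANTS}")
    return float(stat), float(p), degenerate


def bootstrap_t(
    a: Sequence[float],
    b: Sequence[float],
    variant: str = "percentile",
    config: ResamplingConfig | None = None,
) -> TestResult:
    """Bootstrap test for the mean difference via confidence-interval inversion.

    Within-group resampling (with replacement) yields ``n_boot``
    bootstrap mean differences ``d*`` around the observed difference
    ``d``.  The p-value is the smallest level at which the chosen
    interval excludes zero:

    - ``normal``: p = 2(1 - Phi(|d| / sd(d*)))
    - ``percentile``: p = 2 min(frac(d* <= 0), frac(d* >= 0))
    - ``pivotal``: p = 2 min(frac(d* >= 2d), frac(d* <= 2d)), the
      inversion of the basic interval [2d - q(1-a/2), 2d - q(a/2)]
    """
    if variant not in _BOOT_VARIANTS:
        raise ValueError(f"unknown bootstrap variant {variant!r}; use {_BOOT_VARIANTS}")
    config = config or ResamplingConfig()
    a, b = _as_sample(a, "a"), _as_sample(b, "b")
    B = config.n_boot
    d_hat = float(a.mean() - b.mean())
    # each group's resampling stream is keyed by its own content, so
    # exchanging the group labels is an exact symmetry of the p-value
    rng_a = np.random.default_rng([config.seed, zlib.crc32(a.tobytes())])
    rng_b = np.random.default_rng([config.seed, zlib.crc32(b.tobytes())])
    ia = rng_a.integers(0, a.size, size=(B, a.size))
    ib = rng_b.integers(0, b.size, size=(B, b.size))
    d_star = a[ia].mean(axis=1) - b[ib].mean(axis=1)
    stat, p, degenerate = bootstrap_p_from_draws(d_hat, d_star, variant)
    return TestResult(
        float(stat),
        float(p),
        f"boot.{variant}",
        detail={"n_resamples": B, "d_hat": d_hat, "degenerate": degenerate},
    )


# ---------------------------------------------------------------------------
# Registry and whole-matrix application
# ---------------------------------------------------------------------------

def _make_boot(variant: str) -> Callable:
    def run(a, b, config=None):
        return bootstrap_t(a, b, variant=variant, config=config)

    return run


TESTS: dict[str, Callable] = {
    "t.welch": lambda a, b, config=None: welch_t(a, b),
    "t.perm": permutation_t,
    "chebby": lambda a, b, config=None: chebby_checker(a, b),
    "boot.normal": _make_boot("normal"),
    "boot.percentile": _make_boot("percentile"),
    "boot.pivotal": _make_boot("pivotal"),
}


def get_test(label: str) -> Callable:
    try:
        return TESTS[label]
    except KeyError:
        raise KeyError(
            f"unknown test {label!r}; valid labels: {sorted(TESTS)}"
        ) from None


def test_matrix(matrix, test_label: str, config: ResamplingConfig | None = None) -> pd.DataFrame:
    """Apply one test to every spot of a complete two-group matrix.

    Returns a tidy table (one row per spot, input order) with columns
    ``spot_id, statistic, p_value, test_label, degenerate``.  Resampling
    for spot ``i`` is seeded with ``config.seed + i`` so the table is
    reproducible and rows are independent of each other's draws.
    Per-spot failures become degenerate rows (p = 1) rather than
    aborting the whole table.
    """
    if not matrix.is_complete:
        raise ValueError("test_matrix requires a complete matrix (impute first)")
    config = config or ResamplingConfig()
    func = get_test(test_label)
    g1, g2 = matrix.design.groups
    ia = matrix.design.indices(g1)
    ib = matrix.design.indices(g2)
    rows = []
    for i, sid in enumerate(matrix.spot_ids):
        a = matrix.values[i, ia]
        b = matrix.values[i, ib]
        spot_cfg = ResamplingConfig(config.n_boot, config.n_perm, config.seed + i)
        try:
            res = func(a, b, config=spot_cfg)
            degenerate = bool(res.detail.get("degenerate", False))
            rows.append((sid, res.statistic, res.p_value, degenerate))
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"test failed for spot {sid}: {exc}", stacklevel=2)
            rows.append((sid, np.nan, 1.0, True))
    out = pd.DataFrame(rows, columns=["spot_id", "statistic", "p_value", "degenerate"])
    out.insert(3, "test_label", test_label)
    return out
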