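"""Multiple-testing selection procedures.

Three ways to turn a vector of per-spot p-values into a rejection set:

``per_comparison``
    Uncorrected thresholding, ``p < alpha`` (strict).  Appropriate only
    for comparing analysis pipelines, not for claiming discoveries.
``gfwer``
    Generalized family-wise error rate control by augmentation: run a
    Holm FWER procedure at level alpha, then add the ``k_allow``
    next-smallest p-values.  With ``k_allow=0`` this is exactly Holm.
    Controls P(more than k_allow false rejections) <= alpha.
``bh_fdr``
    Benjamini–Hochberg step-up, included as the comparator that gFWER
    is usually argued against for small spot panels.

All procedures return a boolean rejection mask aligned with the input.
The Holm step-down (the base of the gFWER augmentation) is implemented
here; BH delegates to
:func:`statsmodels.stats.multitest.multipletests`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SelectionConfig",
    "holm",
    "select_per_comparison",
    "select_gfwer",
    "select_bh_fdr",
    "select",
    "selection_table",
    "PROCEDURES",
]

PROCEDURES = ("per_comparison", "gfwer", "bh_fdr")


@dataclass(frozen=True)
class SelectionConfig:
    alpha: float = 0.05
    procedure: str = "per_comparison"
    k_allow: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.procedure not in PROCEDURES:
            raise ValueError(f"unknown procedure {self.procedure!r}; use {PROCEDURES}")
        if self.k_allow < 0:
            raise ValueError("k_allow must be >= 0")


def _as_pvals(pvals: Sequence[float]) -> np.ndarray:
    p = np.asarray(pvals, dtype=float).ravel()
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return p


def select_per_comparison(pvals: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Reject exactly the hypotheses with p strictly below alpha."""
    return _as_pvals(pvals) < alpha


def holm(pvals: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Holm step-down FWER control at level alpha (non-strict thresholds).

    Sorted p-values are compared with alpha/(m-i); the first failure
    stops the procedure and everything before it is rejected.
    """
    p = _as_pvals(pvals)
    m = p.size
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p, kind="stable")
    thresholds = alpha / (m - np.arange(m))
    fail = p[order] > thresholds
    n_reject = int(np.argmax(fail)) if fail.any() else m
    rejected = np.zeros(m, dtype=bool)
    rejected[order[:n_reject]] = True
    return rejected


def select_gfwer(pvals: Sequence[float], alpha: float = 0.05, k_allow: int = 0) -> np.ndarray:
    """Holm at level alpha, augmented by the k_allow next-smallest p-values.

    Ties among the augmentation candidates break by input order (stable
    sort), so the procedure is deterministic.
    """
    p = _as_pvals(pvals)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    rejected = holm(p, alpha)
    if k_allow > 0 and (~rejected).any():
        remaining = np.flatnonzero(~rejected)
        order = remaining[np.argsort(p[remaining], kind="stable")]
        rejected = rejected.copy()
        rejected[order[:k_allow]] = True
    return rejected


def select_bh_fdr(pvals: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up at level alpha."""
    p = _as_pvals(pvals)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    return multipletests(p, alpha=alpha, method="fdr_bh")[0]


def select(pvals: Sequence[float], config: SelectionConfig | None = None) -> np.ndarray:
    """Dispatch on ``config.procedure``."""
    config = config or SelectionConfig()
    if config.procedure == "per_comparison":
        return select_per_comparison(pvals, config.alpha)
    if config.procedure == "gfwer":
        return select_gfwer(pvals, config.alpha, config.k_allow)
    return select_bh_fdr(pvals, config.alpha)


def selection_table(
    spot_ids: Sequence[str],
    pvals: Sequence[float],
    config: SelectionConfig | None = None,
) -> pd.DataFrame:
    """Tidy per-spot selection table ready for TSV export."""
    config = config or SelectionConfig()
    mask = select(pvals, config)
    return pd.DataFrame(
        {
            "spot_id": list(spot_ids),
            "p_value": np.asarray(pvals, dtype=float),
            "rejected": mask,
            "procedure": config.procedure,
            "alpha": config.alpha,
            "k_allow": config.k_allow,
        }
    )
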