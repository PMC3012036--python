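"""Synthetic two-group spot matrices with known truth.

Real 2-DE studies of the kind this package targets are small: two
conditions, half a dozen gels each, and from tens to a few hundred
matched spots whose volumes are positive, right-skewed, and carry
residual gel-to-gel scale differences that survive upstream
normalization.  The generator emulates exactly that structure on the
log scale::

    log x[i, j] = log_mean + s_i + g_j + delta * 1[spot i DE, gel j in B] + e_ij

with spot effects ``s_i ~ N(0, log_sd)``, gel effects
``g_j ~ N(0, gel_effect_sd)`` (the residual loading/staining scale of
each gel), a log-scale mean shift ``delta = effect_size`` for the
truly differential spots in condition B, and residual noise
``e_ij ~ N(0, spot_noise_sd)``.

The two masking operators turn a complete matrix into a benchmark
input with recorded truth: uniform masking (missing completely at
random) and intensity-dependent masking in which low-abundance spots
are more likely to lose cells, as observed in real gel data.  Both
reject masks that would leave a spot with fewer than two observed
cells in either group, because row-average imputation and the
two-sample tests are undefined below that.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .matrix import GroupDesign, SpotMatrix, ValidationError, mean_normalize

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "RemovalRecord",
    "generate_complete_dataset",
    "remove_at_random",
    "remove_intensity_dependent",
    "restore",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the generator; defaults are the package's study conditions.

    ``de_fraction`` defaults to 10/70 so the default 70-spot matrix
    carries 10 truly differential spots; ``effect_size`` is the
    log-scale shift of those spots in condition B (1.5 is roughly a
    4.5-fold change).  ``normalize=True`` re-applies in-matrix mean
    normalization, which removes the gel effects exactly; the default
    leaves values in already-normalized units with residual gel-scale
    variation retained, which is what real matched-spot submatrices
    look like.
    """

    n_spots: int = 70
    n_per_group: int = 6
    de_fraction: float = 10 / 70
    effect_size: float = 1.5
    log_mean: float = 0.0
    log_sd: float = 1.0
    gel_effect_sd: float = 0.2
    spot_noise_sd: float = 0.2
    seed: int = 0
    normalize: bool = False

    def __post_init__(self) -> None:
        if self.n_spots < 1:
            raise ValidationError("n_spots must be >= 1")
        if self.n_per_group < 2:
            raise ValidationError("n_per_group must be >= 2")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValidationError("de_fraction must be in [0, 1]")
        for name in ("log_sd", "gel_effect_sd", "spot_noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return path


@dataclass
class SyntheticDataset:
    """A complete matrix plus the identity of the truly differential spots."""

    matrix: SpotMatrix
    truth_de: dict[str, bool]
    config: SyntheticConfig

    @property
    def de_spots(self) -> set[str]:
        return {s for s, de in self.truth_de.items() if de}


@dataclass
class RemovalRecord:
    """The masked cells of one benchmark round and their true values."""

    cells: list[tuple[str, str]]
    true_values: np.ndarray
    fraction: float
    seed: int
    index_cells: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.true_values = np.asarray(self.true_values, dtype=float)
        if len(self.cells) != self.true_values.size:
            raise ValidationError("cells and true_values must align")
        if len(set(self.cells)) != len(self.cells):
            raise ValidationError("masked cells must be unique")


def generate_complete_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Draw a complete two-group matrix under ``config`` (deterministic per seed)."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    n, m = config.n_spots, 2 * config.n_per_group
    spot_ids = tuple(f"S{i + 1:03d}" for i in range(n))
    gel_ids = tuple(
        [f"A{j + 1}" for j in range(config.n_per_group)]
        + [f"B{j + 1}" for j in range(config.n_per_group)]
    )
    design = GroupDesign(gel_ids, {g: g[0] for g in gel_ids})

    spot_effect = rng.normal(0.0, config.log_sd, size=n)
    gel_effect = rng.normal(0.0, config.gel_effect_sd, size=m)
    n_de = int(round(config.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    noise = rng.normal(0.0, config.spot_noise_sd, size=(n, m))

    log_x = config.log_mean + spot_effect[:, None] + gel_effect[None, :] + noise
    b_cols = design.indices("B")
    shift = np.zeros((n, m))
    shift[np.ix_(de_idx, b_cols)] = config.effect_size
    matrix = SpotMatrix(spot_ids, design, np.exp(log_x + shift))
    if config.normalize:
        matrix = mean_normalize(matrix)
    truth = {s: bool(i in set(de_idx.tolist())) for i, s in enumerate(spot_ids)}
    return SyntheticDataset(matrix, truth, config)


def _check_retention(
    observed: np.ndarray, design: GroupDesign, min_per_group: int
) -> bool:
    for grp in design.groups:
        idx = design.indices(grp)
        if (observed[:, idx].sum(axis=1) < min_per_group).any():
            return False
    return True


def _make_record(
    matrix: SpotMatrix, mask: np.ndarray, fraction: float, seed: int
) -> tuple[SpotMatrix, RemovalRecord]:
    rows, cols = np.nonzero(mask)
    cells = [(matrix.spot_ids[r], matrix.gel_ids[c]) for r, c in zip(rows, cols)]
    true_values = matrix.values[rows, cols].copy()
    masked = matrix.values.copy()
    masked[mask] = np.nan
    record = RemovalRecord(
        cells=cells,
        true_values=true_values,
        fraction=fraction,
        seed=seed,
        index_cells=list(zip(rows.tolist(), cols.tolist())),
    )
    return SpotMatrix(matrix.spot_ids, matrix.design, masked), record


def remove_at_random(
    matrix: SpotMatrix,
    fraction: float,
    seed: int,
    min_per_group: int = 2,
    max_attempts: int = 10_000,
) -> tuple[SpotMatrix, RemovalRecord]:
    """Mask exactly ``round(fraction * n_cells)`` cells uniformly at random.

    Draws are rejected (and redrawn) if any spot would be left with
    fewer than ``min_per_group`` observed cells in either group; set
    ``min_per_group=1`` for the weaker any-observation-at-all rule.
    """
    if not matrix.is_complete:
        raise ValidationError("removal requires a complete matrix")
    if not 0.0 < fraction < 1.0:
        raise ValidationError("fraction must be in (0, 1)")
    n_cells = matrix.n_spots * matrix.n_gels
    n_remove = int(round(fraction * n_cells))
    max_removable = sum(
        matrix.n_spots * max(0, matrix.design.group_size(g) - min_per_group)
        for g in matrix.design.groups
    )
    if n_remove > max_removable:
        raise ValidationError(
            f"cannot mask {n_remove} cells while keeping {min_per_group} "
            f"observed per spot per group (max {max_removable})"
        )
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        flat = rng.choice(n_cells, size=n_remove, replace=False)
        mask = np.zeros(n_cells, dtype=bool)
        mask[flat] = True
        mask = mask.reshape(matrix.n_spots, matrix.n_gels)
        if _check_retention(~mask, matrix.design, min_per_group):
            return _make_record(matrix, mask, fraction, seed)
    raise ValidationError(
        f"no admissible mask found in {max_attempts} draws at fraction {fraction}"
    )


def remove_intensity_dependent(
    matrix: SpotMatrix,
    steepness: float = 2.0,
    target_fraction: float = 0.2,
    seed: int = 0,
    min_per_group: int = 2,
    max_attempts: int = 10_000,
) -> tuple[SpotMatrix, RemovalRecord]:
    """Mask cells with probability decreasing in spot intensity.

    Each spot's cells are masked independently with probability
    proportional to ``logistic(-steepness * z_i)`` where ``z_i`` is the
    z-score of the spot's mean intensity, rescaled so the expected
    masked fraction equals ``target_fraction`` (probabilities are capped
    at 0.95 before rescaling converges; with ``steepness=0`` this is
    exactly MCAR Bernoulli masking).  The same per-spot-per-group
    retention constraint as :func:`remove_at_random` applies.
    """
    if not matrix.is_complete:
        raise ValidationError("removal requires a complete matrix")
    if not 0.0 < target_fraction < 1.0:
        raise ValidationError("target_fraction must be in (0, 1)")
    means = matrix.values.mean(axis=1)
    sd = means.std()
    z = (means - means.mean()) / sd if sd > 0 else np.zeros_like(means)
    base = 1.0 / (1.0 + np.exp(steepness * z))
    # rescale so the mean masking probability hits the target; iterate
    # because capping at 0.95 feeds mass back to the other spots
    probs = np.clip(base * (target_fraction / base.mean()), 0.0, 0.95)
    for _ in range(25):
        err = target_fraction / probs.mean()
        if abs(err - 1.0) < 1e-12:
            break
        probs = np.clip(probs * err, 0.0, 0.95)
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        mask = rng.random(size=matrix.values.shape) < probs[:, None]
        if mask.sum() == 0:
            continue
        if _check_retention(~mask, matrix.design, min_per_group):
            return _make_record(matrix, mask, target_fraction, seed)
    raise ValidationError(
        f"no admissible mask found in {max_attempts} draws at target {target_fraction}"
    )


def restore(masked: SpotMatrix, record: RemovalRecord) -> SpotMatrix:
    """Put the recorded true values back; inverse of the removal operators."""
    vals = masked.values.copy()
    for (r, c), v in zip(record.index_cells, record.true_values):
        vals[r, c] = v
    return SpotMatrix(masked.spot_ids, masked.design, vals)
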