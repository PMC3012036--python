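"""Spot-volume matrices from two-group 2-DE experiments.

The central object mirrors the output of gel image analysis software:
rows are matched protein spots, columns are gels, and cells hold
normalized spot volumes.  A spot that was detected on the reference gel
but not matched on another gel yields a missing cell (``NaN``
internally, a configurable token such as ``"NA"`` on disk).  Zeros are
*not* treated as missing by default: zero-substitution conflates
"absent" with "undetected" and is exactly the practice this package is
meant to replace.

Besides I/O the module provides the standard pre-processing steps:
mean normalization (each gel column divided by its total observed
volume), per-gel missingness summaries, completeness-by-intensity
quartile counts, and the majority-present spot filter that limits how
much imputation a downstream analysis has to lean on.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "GroupDesign",
    "SpotMatrix",
    "MissingnessSummary",
    "read_matrix",
    "write_matrix",
    "read_design",
    "write_design",
    "mean_normalize",
    "missingness_by_gel",
    "completeness_by_quartile",
    "filter_majority_present",
]

#: Default on-disk marker for a missing cell.
DEFAULT_MISSING_TOKEN = "NA"

#: Default float format for writers: 6 significant digits.
DEFAULT_FLOAT_FORMAT = "%.6g"


class FormatError(ValueError):
    """Malformed input table: ragged rows, empty file, unparsable cell."""


class ValidationError(ValueError):
    """Well-formed input that violates a domain invariant."""


@dataclass(frozen=True)
class GroupDesign:
    """Assignment of gels to the two experimental conditions.

    Parameters
    ----------
    gel_ids
        Ordered gel identifiers (the matrix column order).
    group_of
        Mapping from gel id to one of exactly two group labels.  Each
        group must contain at least two gels so that within-group
        variances exist.
    """

    gel_ids: tuple[str, ...]
    group_of: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "gel_ids", tuple(str(g) for g in self.gel_ids))
        object.__setattr__(
            self, "group_of", {str(k): str(v) for k, v in dict(self.group_of).items()}
        )
        if len(set(self.gel_ids)) != len(self.gel_ids):
            raise ValidationError("duplicate gel ids in design")
        unassigned = [g for g in self.gel_ids if g not in self.group_of]
        if unassigned:
            raise ValidationError(f"gels without a group assignment: {unassigned}")
        labels = sorted({self.group_of[g] for g in self.gel_ids})
        if len(labels) != 2:
            raise ValidationError(f"expected exactly two groups, got {labels!r}")
        for lab in labels:
            n = sum(1 for g in self.gel_ids if self.group_of[g] == lab)
            if n < 2:
                raise ValidationError(f"group {lab!r} has {n} gel(s); need at least 2")

    @property
    def groups(self) -> tuple[str, str]:
        """The two group labels, sorted."""
        return tuple(sorted({self.group_of[g] for g in self.gel_ids}))  # type: ignore[return-value]

    def labels(self) -> np.ndarray:
        """Group label per gel, aligned with :attr:`gel_ids`."""
        return np.array([self.group_of[g] for g in self.gel_ids])

    def indices(self, group: str) -> np.ndarray:
        """Column indices of the gels in ``group``."""
        idx = np.flatnonzero(self.labels() == group)
        if idx.size == 0:
            raise KeyError(f"unknown group {group!r}")
        return idx

    def group_size(self, group: str) -> int:
        return int(self.indices(group).size)


@dataclass
class SpotMatrix:
    """A spots × gels table of non-negative normalized volumes.

    ``values`` is a float array of shape ``(n_spots, n_gels)`` with
    ``NaN`` marking missing cells.  Observed values must be
    non-negative; spot ids must be unique.
    """

    spot_ids: tuple[str, ...]
    design: GroupDesign
    values: np.ndarray

    def __post_init__(self) -> None:
        self.spot_ids = tuple(str(s) for s in self.spot_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D array")
        if self.values.shape != (len(self.spot_ids), len(self.design.gel_ids)):
            raise ValidationError(
                f"value grid {self.values.shape} does not match "
                f"{len(self.spot_ids)} spots x {len(self.design.gel_ids)} gels"
            )
        if len(set(self.spot_ids)) != len(self.spot_ids):
            raise ValidationError("duplicate spot ids")
        with np.errstate(invalid="ignore"):
            if np.any(self.values < 0):
                raise ValidationError("negative spot volumes are not allowed")

    # -- basic introspection -------------------------------------------------
    @property
    def gel_ids(self) -> tuple[str, ...]:
        return self.design.gel_ids

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    @property
    def n_gels(self) -> int:
        return len(self.design.gel_ids)

    def observed(self) -> np.ndarray:
        """Boolean mask of observed (non-missing) cells."""
        return ~np.isnan(self.values)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    @property
    def is_complete(self) -> bool:
        return self.n_missing == 0

    def copy(self) -> "SpotMatrix":
        return SpotMatrix(self.spot_ids, self.design, self.values.copy())

    def spot_index(self, spot_id: str) -> int:
        try:
            return self.spot_ids.index(spot_id)
        except ValueError:
            raise KeyError(f"unknown spot id {spot_id!r}") from None

    def gel_index(self, gel_id: str) -> int:
        try:
            return self.design.gel_ids.index(gel_id)
        except ValueError:
            raise KeyError(f"unknown gel id {gel_id!r}") from None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.spot_ids), columns=list(self.gel_ids)
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, design: GroupDesign) -> "SpotMatrix":
        df = df.loc[:, list(design.gel_ids)]
        return cls(tuple(df.index.astype(str)), design, df.to_numpy(dtype=float))


@dataclass(frozen=True)
class MissingnessSummary:
    """Per-gel missing-cell counts and the between-group comparison.

    ``between_group_p`` is the Welch t p-value comparing the two groups'
    per-gel missing counts; when both groups' counts are constant and
    equal it is 1 by convention (no signal).
    """

    per_gel_missing: Mapping[str, int]
    group_means: Mapping[str, float]
    group_sds: Mapping[str, float]
    between_group_p: float


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _parse_body(
    text: str, missing_token: str, delimiter: str
) -> tuple[list[str], list[str], np.ndarray]:
    rows = [r for r in csv.reader(io.StringIO(text), delimiter=delimiter) if r]
    if not rows:
        raise FormatError("empty matrix file")
    header = rows[0]
    if len(header) < 2:
        raise FormatError("header must contain at least one gel column")
    gel_ids = [c.strip() for c in header[1:]]
    width = len(header)
    spot_ids: list[str] = []
    data: list[list[float]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise FormatError(
                f"ragged row at line {lineno}: {len(row)} fields, expected {width}"
            )
        spot_ids.append(row[0].strip())
        vals: list[float] = []
        for cell in row[1:]:
            cell = cell.strip()
            if cell == missing_token:
                vals.append(np.nan)
            else:
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise FormatError(
                        f"unparsable cell {cell!r} at line {lineno}"
                    ) from None
        data.append(vals)
    if not data:
        raise FormatError("matrix file has a header but no spot rows")
    return gel_ids, spot_ids, np.array(data, dtype=float)


def read_matrix(
    path: str | Path,
    design: GroupDesign | str | Path,
    missing_token: str = DEFAULT_MISSING_TOKEN,
    delimiter: str = "\t",
    zero_as_missing: bool = False,
) -> SpotMatrix:
    """Read a spots × gels table.

    The first row holds gel ids, the first column spot ids.  ``design``
    is either a :class:`GroupDesign` or a path to a two-column
    gel-id/group table.  ``zero_as_missing`` additionally converts exact
    zeros to missing; it is off by default because zero-substitution is
    a known artifact of some image software, not a measurement.
    """
    text = Path(path).read_text()
    gel_ids, spot_ids, values = _parse_body(text, missing_token, delimiter)
    if not isinstance(design, GroupDesign):
        design = read_design(design, delimiter=delimiter)
    if list(design.gel_ids) != gel_ids:
        # accept any column order consistent with the design
        if sorted(design.gel_ids) != sorted(gel_ids):
            raise ValidationError(
                f"design gels {design.gel_ids} do not match file columns {gel_ids}"
            )
        order = [gel_ids.index(g) for g in design.gel_ids]
        values = values[:, order]
    if zero_as_missing:
        values = np.where(values == 0.0, np.nan, values)
    return SpotMatrix(tuple(spot_ids), design, values)


def write_matrix(
    matrix: SpotMatrix,
    path: str | Path,
    missing_token: str = DEFAULT_MISSING_TOKEN,
    delimiter: str = "\t",
    float_format: str = DEFAULT_FLOAT_FORMAT,
) -> Path:
    """Write a matrix as delimited text; output is bit-stable given the format."""
    path = Path(path)
    lines = [delimiter.join(["spot_id", *matrix.gel_ids])]
    for i, sid in enumerate(matrix.spot_ids):
        cells = [
            missing_token if np.isnan(v) else float_format % v
            for v in matrix.values[i]
        ]
        lines.append(delimiter.join([sid, *cells]))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_design(path: str | Path, delimiter: str = "\t") -> GroupDesign:
    """Read a two-column (gel_id, group) table, ``#`` comments allowed."""
    gel_ids: list[str] = []
    group_of: dict[str, str] = {}
    for row in csv.reader(io.StringIO(Path(path).read_text()), delimiter=delimiter):
        if not row or row[0].lstrip().startswith("#"):
            continue
        if len(row) != 2:
            raise FormatError(f"design rows need two fields, got {row!r}")
        gel, grp = row[0].strip(), row[1].strip()
        gel_ids.append(gel)
        group_of[gel] = grp
    return GroupDesign(tuple(gel_ids), group_of)


def write_design(design: GroupDesign, path: str | Path, delimiter: str = "\t") -> Path:
    path = Path(path)
    lines = [delimiter.join([g, design.group_of[g]]) for g in design.gel_ids]
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# Pre-processing operations
# ---------------------------------------------------------------------------

def mean_normalize(raw: SpotMatrix) -> SpotMatrix:
    """Divide each cell by its gel's total observed volume.

    After normalization the observed volumes of every gel sum to 1;
    missing cells stay missing.  The divisor is the sum of *observed*
    cells (missing cells cannot contribute volume).  Idempotent.
    """
    vals = raw.values
    all_missing = np.all(np.isnan(vals), axis=0)
    if np.any(all_missing):
        bad = [g for g, m in zip(raw.gel_ids, all_missing) if m]
        raise ValidationError(f"gel(s) with no observed spots: {bad}")
    totals = np.nansum(vals, axis=0)
    if np.any(totals <= 0):
        bad = [g for g, t in zip(raw.gel_ids, totals) if t <= 0]
        raise ValidationError(f"gel(s) with non-positive total volume: {bad}")
    return SpotMatrix(raw.spot_ids, raw.design, vals / totals)


def missingness_by_gel(matrix: SpotMatrix) -> MissingnessSummary:
    """Count missing cells per gel and compare the two groups' counts.

    The group comparison is a Welch t-test on the per-gel counts,
    answering whether missingness is associated with the condition.
    """
    from . import stattests  # local import: stattests is matrix-agnostic

    counts = np.isnan(matrix.values).sum(axis=0)
    per_gel = {g: int(c) for g, c in zip(matrix.gel_ids, counts)}
    g1, g2 = matrix.design.groups
    c1 = counts[matrix.design.indices(g1)].astype(float)
    c2 = counts[matrix.design.indices(g2)].astype(float)
    res = stattests.welch_t(c1, c2)
    return MissingnessSummary(
        per_gel_missing=per_gel,
        group_means={g1: float(c1.mean()), g2: float(c2.mean())},
        group_sds={g1: float(c1.std(ddof=1)), g2: float(c2.std(ddof=1))},
        between_group_p=res.p_value,
    )


def completeness_by_quartile(matrix: SpotMatrix) -> dict[int, int]:
    """Complete-spot counts per quartile of mean observed intensity.

    Spots are binned by the empirical 25/50/75 percentiles of their mean
    observed volume (boundary ties go to the lower quartile); each bin's
    count is the number of spots with no missing cell.  A rising profile
    from Q1 to Q4 is the signature of intensity-dependent missingness.
    """
    if matrix.n_spots < 4:
        raise ValidationError("need at least 4 spots to form quartiles")
    means = np.nanmean(matrix.values, axis=1)
    q25, q50, q75 = np.percentile(means, [25, 50, 75])
    quart = 1 + (means > q25).astype(int) + (means > q50) + (means > q75)
    complete = ~np.isnan(matrix.values).any(axis=1)
    return {q: int(np.sum(complete & (quart == q))) for q in (1, 2, 3, 4)}


def filter_majority_present(
    matrix: SpotMatrix, per_group: bool = True
) -> SpotMatrix:
    """Keep spots observed in a strict majority of gels.

    With ``per_group=True`` (default) the strict-majority rule is
    applied within each group separately — imputation and testing both
    operate within groups, so a spot must be anchored by real
    observations on both sides.  ``per_group=False`` applies the rule to
    the whole gel panel instead.  Spot order is preserved.
    """
    obs = matrix.observed()
    if per_group:
        keep = np.ones(matrix.n_spots, dtype=bool)
        for grp in matrix.design.groups:
            idx = matrix.design.indices(grp)
            keep &= obs[:, idx].sum(axis=1) > idx.size / 2
    else:
        keep = obs.sum(axis=1) > matrix.n_gels / 2
    if not keep.any():
        warnings.warn("majority-present filter removed every spot", stacklevel=2)
    spot_ids = tuple(s for s, k in zip(matrix.spot_ids, keep) if k)
    return SpotMatrix(spot_ids, matrix.design, matrix.values[keep])
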