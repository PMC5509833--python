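"""EQ-5D-3L tariff scoring and bounded-outcome transforms.

The EQ-5D-3L descriptive system has five dimensions (mobility, self-care,
usual activities, pain/discomfort, anxiety/depression), each at level 1
(no problems), 2 (some problems) or 3 (severe problems): 243 distinct health
profiles.  A country value set ("tariff") maps each profile to a utility
index on (-inf, 1], with (1,1,1,1,1) -> 1 by convention.  Tariffs here are
additive: a constant subtracted for any departure from full health, an
optional extra constant when any dimension is at level 3, and per
(dimension, level) decrements.

Two transforms prepare the outcomes for beta-distributed modelling:

* ``shrink_transform`` maps [0, 1] into the open interval (0, 1) using the
  sample size N:  (y * (N - 1) + 0.5) / N.  VAS is divided by 100 first.
* ``normalize_index`` rescales non-one EQ-5D index values linearly so the
  observed minimum maps to 0 and the observed maximum non-one value to 1;
  the shrink transform is then applied on top.

Both are strictly increasing and invertible, so fitted means can be
reported back on the original scale.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from itertools import product
from typing import Iterable

import numpy as np
import pandas as pd

from ._util import ConfigurationError, DegenerateRangeError, ValidationError

DIMENSIONS = (
    "mobility",
    "self_care",
    "usual_activities",
    "pain_discomfort",
    "anxiety_depression",
)

PERFECT_HEALTH = (1, 1, 1, 1, 1)


def validate_profile(profile: Iterable[int]) -> tuple[int, ...]:
    levels = tuple(int(v) for v in profile)
    if len(levels) != 5:
        raise ValidationError(f"EQ-5D-3L profile needs 5 levels, got {len(levels)}")
    if any(v not in (1, 2, 3) for v in levels):
        raise ValidationError(f"profile levels must be in {{1,2,3}}: {levels}")
    return levels


def all_profiles() -> list[tuple[int, ...]]:
    """All 243 EQ-5D-3L profiles in lexicographic order."""
    return list(product((1, 2, 3), repeat=5))


@dataclass(frozen=True)
class TariffTable:
    """Additive EQ-5D-3L value set.

    index(profile) = 1 - any_problem * 1{profile != 11111}
                       - any_level3  * 1{any level == 3}
                       - sum of decrement[(dimension, level)] over levels > 1
    """

    decrements: dict[tuple[str, int], float]
    any_problem: float = 0.0
    any_level3: float = 0.0

    def __post_init__(self):
        for (dim, level), value in self.decrements.items():
            if dim not in DIMENSIONS:
                raise ConfigurationError(f"unknown dimension {dim!r} in tariff")
            if level not in (2, 3):
                raise ConfigurationError(f"decrement level must be 2 or 3, got {level}")
            if not np.isfinite(value):
                raise ConfigurationError(f"non-finite decrement for {(dim, level)}")

    def score(self, profile: Iterable[int]) -> float:
        levels = validate_profile(profile)
        if levels == PERFECT_HEALTH:
            return 1.0
        total = 1.0 - self.any_problem
        if 3 in levels:
            total -= self.any_level3
        for dim, level in zip(DIMENSIONS, levels):
            if level == 1:
                continue
            key = (dim, level)
            if key not in self.decrements:
                raise ConfigurationError(f"tariff has no decrement for {key}")
            total -= self.decrements[key]
        return total

    def score_range(self) -> tuple[float, float]:
        """(min, max) of the index over all 243 profiles."""
        values = [self.score(p) for p in all_profiles()]
        return float(min(values)), float(max(values))


def score_eq5d(profile: Iterable[int], tariff: TariffTable) -> float:
    """Utility index for one profile under a tariff; (1,1,1,1,1) -> 1.0."""
    return tariff.score(profile)


def score_table(dim_levels: pd.DataFrame, tariff: TariffTable) -> np.ndarray:
    """Score a table with columns eq5d_dim1..eq5d_dim5; NaN rows score NaN."""
    cols = [f"eq5d_dim{i}" for i in range(1, 6)]
    arr = dim_levels[cols].to_numpy(dtype=float)
    out = np.full(len(arr), np.nan)
    ok = ~np.isnan(arr).any(axis=1)
    for i in np.flatnonzero(ok):
        out[i] = tariff.score(arr[i].astype(int))
    return out


def load_tariff(path) -> TariffTable:
    """Read a tariff from CSV with header ``term,dimension,level,value``.

    Recognised terms: ``decrement`` (dimension and level required),
    ``any_problem`` and ``any_level3`` (constants, dimension/level empty).
    """
    df = pd.read_csv(path, dtype={"term": str, "dimension": str})
    required = {"term", "dimension", "level", "value"}
    if not required.issubset(df.columns):
        raise ConfigurationError(f"tariff file must have columns {sorted(required)}")
    decrements: dict[tuple[str, int], float] = {}
    any_problem = 0.0
    any_level3 = 0.0
    for _, row in df.iterrows():
        term = str(row["term"]).strip()
        if term == "any_problem":
            any_problem = float(row["value"])
        elif term == "any_level3":
            any_level3 = float(row["value"])
        elif term == "decrement":
            decrements[(str(row["dimension"]).strip(), int(row["level"]))] = float(row["value"])
        else:
            raise ConfigurationError(f"unknown tariff term {term!r}")
    return TariffTable(decrements=decrements, any_problem=any_problem, any_level3=any_level3)


def example_tariff() -> TariffTable:
    """Synthetic Belgian-like tariff shipped with the package.

    The real Belgian value set is an external input whose coefficients are
    not redistributed here; this synthetic stand-in is calibrated only to
    reproduce the Belgian index range [-0.074, 1] over the 243 profiles.
    """
    ref = importlib.resources.files("qolnorm.data") / "synthetic_belgium_like_tariff.csv"
    with importlib.resources.as_file(ref) as path:
        return load_tariff(path)


# ---------------------------------------------------------------------------
# outcome transforms


@dataclass(frozen=True)
class TransformSpec:
    """Frozen transform parameters so predictions can be back-transformed.

    n is the number of respondent rows in the dataset being transformed
    (after row filtering, before imputation); min_index/max_index are the
    observed minimum and maximum of the *non-one* EQ-5D index values.
    """

    n: int
    min_index: float | None = None
    max_index: float | None = None

    def __post_init__(self):
        if self.n < 2:
            raise ValidationError("TransformSpec.n must be >= 2")
        if self.min_index is not None and self.max_index is not None:
            if not self.min_index < self.max_index:
                raise DegenerateRangeError("min_index must be < max_index")

    @classmethod
    def from_data(cls, n: int, index: np.ndarray | None = None) -> "TransformSpec":
        if index is None:
            return cls(n=int(n))
        index = np.asarray(index, dtype=float)
        non_one = index[~np.isnan(index) & (index < 1.0)]
        if non_one.size < 2:
            raise DegenerateRangeError("need >= 2 non-one index values to set the range")
        return cls(n=int(n), min_index=float(non_one.min()), max_index=float(non_one.max()))


def shrink_transform(y, n: int):
    """(y*(N-1) + 0.5)/N: maps [0,1] strictly into (0,1); increasing in y."""
    y = np.asarray(y, dtype=float)
    if n < 2:
        raise ValidationError("sample size N must be >= 2")
    valid = np.isnan(y) | ((y >= 0.0) & (y <= 1.0))
    if not valid.all():
        raise ValidationError("shrink_transform input must lie in [0, 1]")
    return (y * (n - 1) + 0.5) / n


def inverse_shrink(z, n: int):
    """Invert the shrink transform: z -> (z*N - 0.5)/(N-1)."""
    z = np.asarray(z, dtype=float)
    if n < 2:
        raise ValidationError("sample size N must be >= 2")
    valid = np.isnan(z) | ((z > 0.0) & (z < 1.0))
    if not valid.all():
        raise ValidationError("inverse_shrink input must lie strictly in (0, 1)")
    return (z * n - 0.5) / (n - 1)


def normalize_index(y, min_index: float, max_index: float):
    """Linear map of non-one index values: min -> 0, max -> 1."""
    if max_index == min_index:
        raise DegenerateRangeError("max_index equals min_index")
    y = np.asarray(y, dtype=float)
    in_range = np.isnan(y) | ((y >= min_index) & (y <= max_index))
    if not in_range.all():
        raise ValidationError("index value outside the [min_index, max_index] range")
    return (y - min_index) / (max_index - min_index)


def denormalize_index(z, min_index: float, max_index: float):
    if max_index == min_index:
        raise DegenerateRangeError("max_index equals min_index")
    return np.asarray(z, dtype=float) * (max_index - min_index) + min_index


def transform_vas(vas, spec: TransformSpec):
    """VAS on [0, 100] -> strictly interior (0, 1) outcome."""
    vas = np.asarray(vas, dtype=float)
    valid = np.isnan(vas) | ((vas >= 0) & (vas <= 100))
    if not valid.all():
        raise ValidationError("VAS must lie in [0, 100]")
    return shrink_transform(vas / 100.0, spec.n)


def inverse_transform_vas(z, spec: TransformSpec):
    return inverse_shrink(z, spec.n) * 100.0


def transform_eq5d(index, spec: TransformSpec):
    """EQ-5D index -> (transformed values, is_one mask).

    Exact ones keep their point mass (returned as 1.0 with is_one True);
    non-one values are normalised to [0, 1] with the spec range and then
    shrunk into the open interval.
    """
    index = np.asarray(index, dtype=float)
    is_one = index == 1.0
    out = np.full_like(index, np.nan)
    out[is_one] = 1.0
    non_one = ~is_one & ~np.isnan(index)
    if non_one.any():
        if spec.min_index is None or spec.max_index is None:
            raise ConfigurationError("TransformSpec lacks min_index/max_index for EQ-5D")
        z = normalize_index(index[non_one], spec.min_index, spec.max_index)
        out[non_one] = shrink_transform(z, spec.n)
    return out, is_one


def inverse_transform_eq5d(z, spec: TransformSpec):
    """Back-transform interior (non-one) values to the original index scale."""
    if spec.min_index is None or spec.max_index is None:
        raise ConfigurationError("TransformSpec lacks min_index/max_index for EQ-5D")
    return denormalize_index(inverse_shrink(z, spec.n), spec.min_index, spec.max_index)
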