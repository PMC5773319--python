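"""Island table input/output and conversion to the ordinal modeling dataset.

The analysis operates on a per-island table: island name, surface area
(km²), isolation from the peninsular mainland (km), an optional island
age, and species counts for two taxonomic groups (rattlesnakes and
colubrid snakes).  Counts may be given directly (two count columns) or
as a wide presence/absence block (one 0/1 column per species together
with a map assigning species to groups), which is reduced to counts on
load.

All predictors are log10-transformed for modeling, so areas and
isolations must be strictly positive.  Occupancy is bucketed into three
ordered states: 0, 1, and 2-or-more species present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GROUPS = ("rattlesnakes", "colubrids")

#: Highest ordered occupancy state; counts above it are bucketed into it.
MAX_STATE = 2

DEFAULT_SCHEMA = {
    "name": "island",
    "area_km2": "area_km2",
    "isolation_km": "isolation_km",
    "age": "age",
    "count_rattlesnakes": "n_rattlesnakes",
    "count_colubrids": "n_colubrids",
}


class IslandTableError(ValueError):
    """Raised when an island table fails validation."""


@dataclass(frozen=True)
class IslandRecord:
    """One island's geography and per-group species counts.

    ``age`` may be ``None`` (reliable island ages are sparse); such
    islands participate in every analysis except the age-residual check.
    """

    name: str
    area_km2: float
    isolation_km: float
    count_rattlesnakes: int
    count_colubrids: int
    age: float | None = None

    def __post_init__(self) -> None:
        if not (self.area_km2 > 0):
            raise IslandTableError(
                f"island {self.name!r}: area_km2 must be > 0 "
                f"(got {self.area_km2!r}); log10 is undefined otherwise"
            )
        if not (self.isolation_km > 0):
            raise IslandTableError(
                f"island {self.name!r}: isolation_km must be > 0 "
                f"(got {self.isolation_km!r}); log10 is undefined otherwise"
            )
        for group in GROUPS:
            count = getattr(self, f"count_{group}")
            if not (isinstance(count, (int, np.integer)) and count >= 0):
                raise IslandTableError(
                    f"island {self.name!r}: count_{group} must be a "
                    f"non-negative integer (got {count!r})"
                )
        if self.age is not None and not math.isfinite(self.age):
            raise IslandTableError(
                f"island {self.name!r}: age must be finite or absent"
            )

    def count(self, group: str) -> int:
        _check_group(group)
        return getattr(self, f"count_{group}")


@dataclass(frozen=True)
class OrdinalDataset:
    """Modeling dataset: log10 predictors and ordered occupancy states.

    ``y[i] = min(count, 2)`` for the chosen group, so the states are
    0, 1 and 2+ species present, with islands as the functional unit.
    """

    x_area: np.ndarray
    x_isolation: np.ndarray
    y: np.ndarray
    group: str
    names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "x_area", np.asarray(self.x_area, dtype=float))
        object.__setattr__(
            self, "x_isolation", np.asarray(self.x_isolation, dtype=float)
        )
        object.__setattr__(self, "y", np.asarray(self.y, dtype=int))
        _check_group(self.group)
        n = len(self.y)
        if len(self.x_area) != n or len(self.x_isolation) != n:
            raise IslandTableError("predictor and response lengths differ")
        if n == 0:
            raise IslandTableError("empty dataset")
        if not (np.isfinite(self.x_area).all() and np.isfinite(self.x_isolation).all()):
            raise IslandTableError("non-finite log10 predictor values")
        if self.y.min() < 0 or self.y.max() > MAX_STATE:
            raise IslandTableError(f"states must lie in 0..{MAX_STATE}")

    @property
    def n(self) -> int:
        return len(self.y)

    def subset(self, idx: np.ndarray) -> "OrdinalDataset":
        """Row subset / resample (used by the bootstrap)."""
        names = tuple(np.asarray(self.names)[idx]) if self.names else ()
        return OrdinalDataset(
            x_area=self.x_area[idx],
            x_isolation=self.x_isolation[idx],
            y=self.y[idx],
            group=self.group,
            names=names,
        )


def _check_group(group: str) -> None:
    if group not in GROUPS:
        raise IslandTableError(f"group must be one of {GROUPS}, got {group!r}")


def load_island_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    species_groups: Mapping[str, str] | None = None,
    isolation_floor_km: float | None = None,
) -> list[IslandRecord]:
    """Read and validate a per-island CSV/TSV table.

    Parameters
    ----------
    path
        CSV or TSV file (delimiter sniffed from the extension) with a
        header row.
    schema
        Mapping from canonical field names (``name``, ``area_km2``,
        ``isolation_km``, ``age``, ``count_rattlesnakes``,
        ``count_colubrids``) to the file's column names.  Defaults to
        :data:`DEFAULT_SCHEMA`.
    species_groups
        If given, the table is in wide presence/absence form: each key
        is a species column holding 0/1 flags and each value is the
        group (``rattlesnakes`` or ``colubrids``) it belongs to.  Counts
        are the per-group row sums of the flags; the two count columns
        of the schema are then ignored.
    isolation_floor_km
        Islands with isolation recorded as 0 (touching the mainland at
        low tide) are rejected by default because log10(0) is undefined.
        Passing an explicit positive floor substitutes it for recorded
        zeros.  Flooring is never applied silently.

    Returns
    -------
    list of validated :class:`IslandRecord`, in file order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    frame = pd.read_csv(path, sep=sep, float_precision="round_trip")
    schema = {**DEFAULT_SCHEMA, **(schema or {})}

    required = ["name", "area_km2", "isolation_km"]
    if species_groups is None:
        required += ["count_rattlesnakes", "count_colubrids"]
    missing = [
        schema[key] for key in required if schema[key] not in frame.columns
    ]
    if missing:
        raise IslandTableError(
            f"missing required column(s) {missing} in {path.name}; "
            f"present: {list(frame.columns)}"
        )
    if species_groups is not None:
        bad = [c for c in species_groups if c not in frame.columns]
        if bad:
            raise IslandTableError(f"species columns {bad} not in {path.name}")
        for col, group in species_groups.items():
            _check_group(group)
            flags = frame[col]
            if not flags.isin([0, 1]).all():
                raise IslandTableError(
                    f"species column {col!r} must contain only 0/1 flags"
                )

    records: list[IslandRecord] = []
    errors: list[str] = []
    has_age = schema["age"] in frame.columns
    for i, row in frame.iterrows():
        rownum = int(i) + 2  # 1-based, after the header row
        try:
            name = str(row[schema["name"]])
            area = float(row[schema["area_km2"]])
            iso = float(row[schema["isolation_km"]])
            if iso == 0 and isolation_floor_km is not None:
                if not isolation_floor_km > 0:
                    raise IslandTableError("isolation_floor_km must be > 0")
                iso = float(isolation_floor_km)
            if species_groups is None:
                counts = {
                    g: _as_count(row[schema[f"count_{g}"]]) for g in GROUPS
                }
            else:
                counts = {g: 0 for g in GROUPS}
                for col, group in species_groups.items():
                    counts[group] += int(row[col])
            age = None
            if has_age:
                raw = row[schema["age"]]
                age = None if pd.isna(raw) else float(raw)
            records.append(
                IslandRecord(
                    name=name,
                    area_km2=area,
                    isolation_km=iso,
                    count_rattlesnakes=counts["rattlesnakes"],
                    count_colubrids=counts["colubrids"],
                    age=age,
                )
            )
        except (IslandTableError, TypeError, ValueError) as exc:
            errors.append(f"row {rownum}: {exc}")
    if errors:
        raise IslandTableError(
            "island table failed validation:\n  " + "\n  ".join(errors)
        )
    names = [r.name for r in records]
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise IslandTableError(f"duplicate island names: {dupes}")
    return records


def _as_count(value) -> int:
    f = float(value)
    if not f.is_integer() or f < 0:
        raise IslandTableError(f"count must be a non-negative integer, got {value!r}")
    return int(f)


def write_island_table(records: Sequence[IslandRecord], path: str | Path) -> None:
    """Write records as a loader-compatible CSV (default schema names).

    Floats are written with 17 significant digits so a write/load
    round-trip reproduces values exactly.
    """
    frame = records_to_frame(records)
    frame.to_csv(path, index=False, float_format="%.17g")


def records_to_frame(records: Sequence[IslandRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            DEFAULT_SCHEMA["name"]: [r.name for r in records],
            DEFAULT_SCHEMA["area_km2"]: [r.area_km2 for r in records],
            DEFAULT_SCHEMA["isolation_km"]: [r.isolation_km for r in records],
            DEFAULT_SCHEMA["age"]: [
                np.nan if r.age is None else r.age for r in records
            ],
            DEFAULT_SCHEMA["count_rattlesnakes"]: [
                r.count_rattlesnakes for r in records
            ],
            DEFAULT_SCHEMA["count_colubrids"]: [r.count_colubrids for r in records],
        }
    )


def to_ordinal_dataset(
    records: Iterable[IslandRecord], group: str
) -> OrdinalDataset:
    """Convert validated records into the modeling dataset for one group.

    States are bucketed at 2+ (``y = min(count, 2)``); area and isolation
    are log10-transformed; island order is preserved.
    """
    records = list(records)
    if not records:
        raise IslandTableError("cannot build a dataset from zero islands")
    _check_group(group)
    return OrdinalDataset(
        x_area=np.log10([r.area_km2 for r in records]),
        x_isolation=np.log10([r.isolation_km for r in records]),
        y=np.minimum([r.count(group) for r in records], MAX_STATE),
        group=group,
        names=tuple(r.name for r in records),
    )


def ages_log10(records: Sequence[IslandRecord]) -> np.ndarray:
    """Per-island log10 age, NaN where age is missing (order preserved)."""
    return np.array(
        [np.log10(r.age) if r.age is not None and r.age > 0 else np.nan
         for r in records]
    )
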