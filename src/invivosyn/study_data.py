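"""Data model and IO for 4-group longitudinal tumor-volume studies.

A study is a long-format table with one row per mouse per measurement day:
mouse id, treatment group (vehicle control C, drug A, drug B, combination
AB), day since treatment start, and tumor volume in mm^3.  The unit of
analysis is the per-mouse growth curve; the unit dataset is the 4-group
collection of curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import (
    ConsistencyError,
    DomainError,
    SchemaError,
    StudyStructureError,
)

#: Canonical treatment-group labels, in conventional order.
GROUPS = ("C", "A", "B", "AB")

#: Case-insensitive aliases for group labels found in the wild.
GROUP_ALIASES = {
    "c": "C", "control": "C", "ctrl": "C", "vehicle": "C", "veh": "C",
    "a": "A", "drug a": "A", "druga": "A", "drug_a": "A", "treatment a": "A",
    "b": "B", "drug b": "B", "drugb": "B", "drug_b": "B", "treatment b": "B",
    "ab": "AB", "a+b": "AB", "a_b": "AB", "combo": "AB",
    "combination": "AB", "drug a+b": "AB", "a + b": "AB",
}

#: Default CSV column names for each logical field.
DEFAULT_COLUMNS = {"mouse": "mouse", "group": "group", "day": "day", "volume": "tv"}


def canonical_group(label: object) -> str:
    """Map a raw group label onto the canonical set {C, A, B, AB}."""
    key = str(label).strip().lower()
    if key in GROUP_ALIASES:
        return GROUP_ALIASES[key]
    raise SchemaError(
        f"unrecognized group label {label!r}; expected one of C/A/B/AB or an "
        f"alias such as 'vehicle' or 'combo'"
    )


@dataclass(frozen=True)
class Measurement:
    """One tumor-volume measurement of one mouse."""

    mouse_id: str
    group: str
    day: float
    volume: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise SchemaError(f"group must be one of {GROUPS}, got {self.group!r}")
        if not self.volume > 0:
            raise DomainError(
                f"volume must be positive, got {self.volume} for mouse {self.mouse_id}"
            )
        if self.day < 0:
            raise DomainError(f"day must be >= 0, got {self.day}")


@dataclass
class GrowthCurve:
    """One mouse's ordered (day, tumor volume) measurements.

    ``days`` must be strictly increasing; ``volumes`` positive.  A curve with
    fewer than two points is kept in the dataset but flagged non-analyzable
    (it cannot support a growth-rate estimate).
    """

    mouse_id: str
    group: str
    days: np.ndarray
    volumes: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.group not in GROUPS:
            raise SchemaError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.days.shape != self.volumes.shape or self.days.ndim != 1:
            raise ConsistencyError(
                f"days and volumes must be matching 1-d sequences for mouse "
                f"{self.mouse_id}"
            )
        if self.days.size and np.any(np.diff(self.days) <= 0):
            raise ConsistencyError(
                f"days must be strictly increasing for mouse {self.mouse_id}"
            )
        if np.any(~(self.volumes > 0)):
            raise DomainError(
                f"volumes must be positive for mouse {self.mouse_id}"
            )

    @property
    def n_points(self) -> int:
        return int(self.days.size)

    @property
    def analyzable(self) -> bool:
        """True if the curve supports a growth-rate estimate (>= 2 points)."""
        return self.n_points >= 2

    @property
    def duration(self) -> float:
        """Study duration d for this mouse (last day minus first day)."""
        if self.n_points == 0:
            return 0.0
        return float(self.days[-1] - self.days[0])

    def truncated(self, max_day: float) -> "GrowthCurve":
        """Curve restricted to measurements at day <= ``max_day``."""
        keep = self.days <= max_day
        return GrowthCurve(self.mouse_id, self.group, self.days[keep], self.volumes[keep])


@dataclass
class StudyDataset:
    """A 4-group collection of growth curves.

    This is both the unit of analysis and the unit of stratified bootstrap
    resampling (strata = treatment groups, resampled element = mouse).
    """

    curves: list[GrowthCurve] = field(default_factory=list)
    n_dropped_rows: int = 0

    @property
    def group_sizes(self) -> dict[str, int]:
        sizes = {g: 0 for g in GROUPS}
        for c in self.curves:
            sizes[c.group] += 1
        return sizes

    def curves_by_group(self, group: str) -> list[GrowthCurve]:
        return [c for c in self.curves if c.group == group]

    def analyzable_by_group(self, group: str) -> list[GrowthCurve]:
        return [c for c in self.curves if c.group == group and c.analyzable]

    def measurement_days(self, group: str | None = None) -> np.ndarray:
        """Sorted unique measurement days, optionally for one group."""
        days: set[float] = set()
        for c in self.curves:
            if group is None or c.group == group:
                days.update(c.days.tolist())
        return np.array(sorted(days))

    def to_frame(self, columns: Mapping[str, str] | None = None) -> pd.DataFrame:
        """Long-format table with one row per measurement."""
        names = dict(DEFAULT_COLUMNS)
        if columns:
            names.update(columns)
        rows = []
        for c in self.curves:
            for d, v in zip(c.days, c.volumes):
                rows.append((c.mouse_id, c.group, d, v))
        return pd.DataFrame(
            rows,
            columns=[names["mouse"], names["group"], names["day"], names["volume"]],
        )


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "fatal" | "warning"
    message: str


def read_study(
    path,
    column_map: Mapping[str, str] | None = None,
    align_days: bool = True,
) -> StudyDataset:
    """Read a long-format tumor-volume CSV into a :class:`StudyDataset`.

    Parameters
    ----------
    path
        CSV file (header row required).  Default column names are ``mouse``,
        ``group``, ``day``, ``tv``.
    column_map
        Optional mapping from logical field names (``mouse``, ``group``,
        ``day``, ``volume``) to the actual column names in the file.
    align_days
        If True (default), shift each mouse's days so its first measurement
        is at day 0.  The growth-rate and synergy formulas assume a common
        treatment-start origin.

    Rows with missing or non-positive volume are dropped and counted in
    ``StudyDataset.n_dropped_rows``.  Duplicated (mouse, day) rows are a hard
    error: silently averaging would hide an upstream data problem.
    """
    names = dict(DEFAULT_COLUMNS)
    if column_map:
        unknown = set(column_map) - set(names)
        if unknown:
            raise SchemaError(
                f"column_map keys must be among {sorted(names)}, got {sorted(unknown)}"
            )
        names.update(column_map)

    df = pd.read_csv(path)
    for field_name, col in names.items():
        if col not in df.columns:
            raise SchemaError(
                f"required column {col!r} (for {field_name}) not found; "
                f"available columns: {list(df.columns)}"
            )
    df = df[[names["mouse"], names["group"], names["day"], names["volume"]]].copy()
    df.columns = ["mouse", "group", "day", "volume"]

    df["group"] = df["group"].map(canonical_group)
    df["day"] = pd.to_numeric(df["day"], errors="coerce")
    df["volume"] = pd.to_numeric(df["volume"], errors="coerce")
    if df["day"].isna().any():
        raise SchemaError("non-numeric or missing values in the day column")

    n_before = len(df)
    df = df[df["volume"].notna() & (df["volume"] > 0)]
    n_dropped = n_before - len(df)

    per_mouse_groups = df.groupby("mouse")["group"].nunique()
    multi = per_mouse_groups[per_mouse_groups > 1]
    if len(multi):
        raise ConsistencyError(
            f"mouse assigned to more than one group: {sorted(multi.index.astype(str))}"
        )

    dup = df.duplicated(subset=["mouse", "day"])
    if dup.any():
        bad = df.loc[dup, ["mouse", "day"]].drop_duplicates()
        first = bad.iloc[0]
        raise ConsistencyError(
            f"duplicate day {first['day']:g} for mouse {first['mouse']}"
            + (f" (and {len(bad) - 1} more)" if len(bad) > 1 else "")
        )

    curves: list[GrowthCurve] = []
    for mouse, sub in df.groupby("mouse", sort=True):
        sub = sub.sort_values("day")
        days = sub["day"].to_numpy(dtype=float)
        if align_days and days.size and days[0] != 0:
            days = days - days[0]
        curve = GrowthCurve(str(mouse), sub["group"].iloc[0], days,
                            sub["volume"].to_numpy(dtype=float))
        if not curve.analyzable:
            warnings.warn(
                f"mouse {mouse} has fewer than 2 measurements and is excluded "
                f"from growth-rate analysis",
                stacklevel=2,
            )
        curves.append(curve)

    ds = StudyDataset(curves=curves, n_dropped_rows=n_dropped)
    missing = [g for g in GROUPS if ds.group_sizes[g] == 0]
    if missing:
        raise StudyStructureError(f"group(s) absent from study: {missing}")
    return ds


def write_study(ds: StudyDataset, path, column_map: Mapping[str, str] | None = None) -> None:
    """Write a dataset back to the standard long-format CSV."""
    ds.to_frame(column_map).to_csv(path, index=False)


def validate_study(ds: StudyDataset) -> list[ValidationIssue]:
    """Report structural issues without mutating the dataset.

    Fatal issues preclude synergy estimation (absent group, no analyzable
    curve in a group); warnings flag individual curves that are skipped or
    suspicious.
    """
    issues: list[ValidationIssue] = []
    sizes = ds.group_sizes
    for g in GROUPS:
        if sizes[g] == 0:
            issues.append(ValidationIssue("fatal", f"group {g} absent"))
        elif not ds.analyzable_by_group(g):
            issues.append(
                ValidationIssue("fatal", f"group {g} has no analyzable curve")
            )
    for c in ds.curves:
        if c.n_points < 2:
            issues.append(
                ValidationIssue(
                    "warning",
                    f"mouse {c.mouse_id} has {c.n_points} measurement(s); "
                    f"excluded from analysis",
                )
            )
        if c.n_points and c.days[0] != 0:
            issues.append(
                ValidationIssue(
                    "warning",
                    f"mouse {c.mouse_id} first measurement at day {c.days[0]:g}, "
                    f"not day 0",
                )
            )
        seen: dict[float, int] = {}
        for d in c.days:
            seen[d] = seen.get(d, 0) + 1
        for d, n in seen.items():
            if n > 1:
                issues.append(
                    ValidationIssue(
                        "fatal", f"duplicate day {d:g} for mouse {c.mouse_id}"
                    )
                )
    return issues


def dataset_from_frame(df: pd.DataFrame, align_days: bool = True) -> StudyDataset:
    """Build a dataset from an in-memory long-format frame.

    Convenience for programmatic use; applies the same rules as
    :func:`read_study` (columns ``mouse``, ``group``, ``day``, ``tv`` or
    ``volume``).
    """
    import io

    buf = io.StringIO()
    df2 = df.rename(columns={"volume": "tv"})
    df2.to_csv(buf, index=False)
    buf.seek(0)
    return read_study(buf, align_days=align_days)
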