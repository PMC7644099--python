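"""Domain types and I/O for plate-reader growth curve data.

A growth experiment is a collection of optical-density time series, each
annotated with the experimental factors applied to the well (e.g. stress
level, pH, acid concentration), the batch (one run of the plate reader)
and a replicate identifier that is unique within its batch.  Modelling
operates on natural-log OD with time affinely standardised to [0, 1];
both transforms are recorded on the dataset so user-facing output can be
reported in hours and on the raw OD scale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GrowthCurve",
    "GrowthDataset",
    "DesignIndex",
    "ValidationReport",
    "SchemaError",
    "DataError",
    "TransformError",
    "read_growth_table",
    "write_growth_table",
    "preprocess",
    "validate_design",
]


class SchemaError(ValueError):
    """A required column is missing or the column map is malformed."""


class DataError(ValueError):
    """Rows violate the data contract (duplicates, non-numeric entries)."""


class TransformError(ValueError):
    """A preprocessing transform cannot be applied (e.g. log of OD <= 0)."""


@dataclass(frozen=True)
class GrowthCurve:
    """One well's time series.

    ``values`` are natural-log OD after :func:`preprocess`; before that
    they hold whatever scale the input table used (raw OD by default).
    """

    times: np.ndarray
    values: np.ndarray
    factors: Mapping[str, str]
    batch: str
    replicate: str

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "factors", dict(self.factors))
        if times.ndim != 1 or values.ndim != 1 or len(times) != len(values):
            raise DataError("times and values must be 1-D and equal length")
        if len(times) < 2:
            raise DataError("a growth curve needs at least 2 observations")
        if not np.all(np.diff(times) > 0):
            raise DataError("times must be strictly increasing")
        if not self.batch or not self.replicate:
            raise DataError("batch and replicate identifiers must be non-empty")

    @property
    def key(self) -> tuple:
        return (tuple(sorted(self.factors.items())), self.batch, self.replicate)

    @property
    def n_obs(self) -> int:
        return len(self.times)


@dataclass
class GrowthDataset:
    """A set of growth curves sharing a factor schema.

    ``time_scale = (offset, scale)`` maps raw hours ``t`` to model time
    ``(t - offset) * scale``; identity until time standardisation.
    ``log_transformed`` records whether values are natural-log OD.
    """

    curves: list[GrowthCurve]
    factor_names: list[str]
    time_scale: tuple[float, float] = (0.0, 1.0)
    log_transformed: bool = False

    def __post_init__(self):
        if self.time_scale[1] <= 0:
            raise DataError("time_scale scale must be positive")
        seen = set()
        for c in self.curves:
            if set(c.factors) != set(self.factor_names):
                raise DataError(
                    f"curve {c.batch}/{c.replicate} factors {sorted(c.factors)} "
                    f"do not match schema {sorted(self.factor_names)}"
                )
            if c.key in seen:
                raise DataError(f"duplicate curve identity {c.key}")
            seen.add(c.key)

    @property
    def n_curves(self) -> int:
        return len(self.curves)

    @property
    def n_obs(self) -> int:
        return sum(c.n_obs for c in self.curves)

    def factor_levels(self, name: str) -> list[str]:
        """Observed levels of a factor, sorted (numeric-aware)."""
        levels = {c.factors[name] for c in self.curves}
        return sorted(levels, key=_level_sort_key)

    @property
    def batches(self) -> list[str]:
        return sorted({c.batch for c in self.curves}, key=_level_sort_key)

    def times_hours(self, curve: GrowthCurve) -> np.ndarray:
        """Back-transform a curve's model times to raw hours."""
        offset, scale = self.time_scale
        return curve.times / scale + offset

    def to_hours(self, model_times: np.ndarray) -> np.ndarray:
        offset, scale = self.time_scale
        return np.asarray(model_times) / scale + offset

    def from_hours(self, hours: np.ndarray) -> np.ndarray:
        offset, scale = self.time_scale
        return (np.asarray(hours) - offset) * scale

    @property
    def time_range(self) -> tuple[float, float]:
        lo = min(c.times[0] for c in self.curves)
        hi = max(c.times[-1] for c in self.curves)
        return lo, hi


def _level_sort_key(label: str):
    try:
        return (0, float(label), "")
    except (TypeError, ValueError):
        return (1, 0.0, str(label))


@dataclass(frozen=True)
class DesignIndex:
    """Dense integer codes for the dataset design.

    Per-curve codes for each factor, batch and replicate; the level
    dictionaries round-trip codes to labels losslessly.
    """

    factor_levels: dict[str, list[str]]
    batch_levels: list[str]
    factor_codes: dict[str, np.ndarray]
    batch_codes: np.ndarray
    replicate_codes: np.ndarray

    @classmethod
    def from_dataset(cls, dataset: GrowthDataset) -> "DesignIndex":
        factor_levels = {f: dataset.factor_levels(f) for f in dataset.factor_names}
        batch_levels = dataset.batches
        factor_codes = {
            f: np.array([factor_levels[f].index(c.factors[f]) for c in dataset.curves])
            for f in dataset.factor_names
        }
        batch_codes = np.array([batch_levels.index(c.batch) for c in dataset.curves])
        replicate_codes = np.arange(dataset.n_curves)
        return cls(factor_levels, batch_levels, factor_codes, batch_codes, replicate_codes)

    def labels(self, curve_index: int, factor: str) -> str:
        return self.factor_levels[factor][self.factor_codes[factor][curve_index]]


_DEFAULT_SCHEMA = {"time": "time", "value": "od", "batch": "batch", "replicate": "replicate"}


def read_growth_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    factors: Sequence[str] = (),
    delimiter: str | None = None,
) -> GrowthDataset:
    """Read a long-format growth table into a :class:`GrowthDataset`.

    Parameters
    ----------
    path
        CSV/TSV file with a header row.  Delimiter is inferred from the
        extension (``.tsv`` → tab) unless ``delimiter`` is given.
    schema
        Column-name map with keys ``time``, ``value``, ``batch``,
        ``replicate``; defaults to ``time, od, batch, replicate``.
    factors
        Names of the factor columns (zero or more).

    One curve is formed per distinct (factors, batch, replicate)
    combination, rows sorted by time; values are left untransformed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    colmap = dict(_DEFAULT_SCHEMA)
    if schema:
        unknown = set(schema) - set(_DEFAULT_SCHEMA)
        if unknown:
            raise SchemaError(f"unknown schema keys: {sorted(unknown)}")
        colmap.update(schema)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    needed = [colmap["time"], colmap["value"], colmap["batch"], colmap["replicate"], *factors]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns {missing} in {path.name} (found {list(df.columns)})")

    for col, kind in [(colmap["time"], "time"), (colmap["value"], "value")]:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() | df[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataError(
                f"non-numeric {kind} {df[col].iloc[row]!r} at data row {row + 1} of {path.name}"
            )
        df[col] = numeric

    group_cols = [*factors, colmap["batch"], colmap["replicate"]]
    curves = []
    for key, sub in df.groupby(group_cols, sort=True, dropna=False):
        if len(group_cols) == 1:
            key = (key,)
        sub = sub.sort_values(colmap["time"])
        times = sub[colmap["time"]].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise DataError(
                f"duplicate time points for curve {dict(zip(group_cols, map(str, key)))}"
            )
        curves.append(
            GrowthCurve(
                times=times,
                values=sub[colmap["value"]].to_numpy(dtype=float),
                factors={f: str(k) for f, k in zip(factors, key)},
                batch=str(key[len(factors)]),
                replicate=str(key[len(factors) + 1]),
            )
        )
    return GrowthDataset(curves=curves, factor_names=list(factors))


def write_growth_table(
    dataset: GrowthDataset,
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    delimiter: str | None = None,
    raw_scale: bool = True,
) -> None:
    """Serialise a dataset back to the long CSV/TSV dialect.

    With ``raw_scale`` (default) the stored log/time transforms are
    inverted so the file round-trips with :func:`read_growth_table`.
    """
    path = Path(path)
    colmap = dict(_DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    rows = []
    for c in dataset.curves:
        times = dataset.times_hours(c) if raw_scale else c.times
        values = np.exp(c.values) if (raw_scale and dataset.log_transformed) else c.values
        for t, v in zip(times, values):
            row = {colmap["time"]: t, colmap["value"]: v}
            row.update(c.factors)
            row[colmap["batch"]] = c.batch
            row[colmap["replicate"]] = c.replicate
            rows.append(row)
    cols = [colmap["time"], colmap["value"], *dataset.factor_names, colmap["batch"], colmap["replicate"]]
    pd.DataFrame(rows)[cols].to_csv(path, sep=delimiter, index=False)


def preprocess(
    dataset: GrowthDataset,
    log: bool = True,
    standardize_time: bool = True,
    blank: float = 0.0,
) -> GrowthDataset:
    """Natural-log transform OD and standardise time to [0, 1].

    ``blank`` is subtracted from OD before the log transform (blank-well
    correction, default off).  Idempotent on the time map: standardising
    an already standardised dataset leaves it unchanged.
    """
    curves = dataset.curves
    if log and not dataset.log_transformed:
        new_curves = []
        for c in curves:
            od = c.values - blank
            if np.any(od <= 0):
                t_bad = c.times[np.flatnonzero(od <= 0)[0]]
                raise TransformError(
                    f"non-positive OD for curve batch={c.batch} replicate={c.replicate} "
                    f"factors={c.factors} at time {t_bad}"
                )
            new_curves.append(dataclasses.replace(c, values=np.log(od)))
        curves = new_curves
        log_done = True
    else:
        log_done = dataset.log_transformed

    offset, scale = dataset.time_scale
    if standardize_time:
        lo = min(c.times[0] for c in curves)
        hi = max(c.times[-1] for c in curves)
        if hi > lo and not (lo == 0.0 and hi == 1.0):
            curves = [
                dataclasses.replace(c, times=(c.times - lo) / (hi - lo)) for c in curves
            ]
            # compose with any existing map: raw -> current -> [0,1]
            offset = offset + lo / scale
            scale = scale / (hi - lo)
    return GrowthDataset(
        curves=list(curves),
        factor_names=list(dataset.factor_names),
        time_scale=(offset, scale),
        log_transformed=log_done,
    )


@dataclass
class ValidationReport:
    """Design diagnostics: hard errors, warnings, replicate counts."""

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    replicate_counts: pd.DataFrame | None = None

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_design(dataset: GrowthDataset, model_kind: str = "M_full") -> ValidationReport:
    """Check a dataset's design supports the requested model kind.

    A single batch makes batch-effect variances unidentifiable
    (M_batch/M_full → error); a factor level observed in only one batch
    is flagged as a warning; replicates per (condition, batch) are
    tabulated.
    """
    report = ValidationReport()
    batches = dataset.batches
    if model_kind in {"M_batch", "M_full"} and len(batches) < 2:
        report.errors.append(
            f"{model_kind} requires >= 2 batches: batch effects unidentifiable with "
            f"{len(batches)} batch"
        )
    for f in dataset.factor_names:
        for level in dataset.factor_levels(f):
            in_batches = {c.batch for c in dataset.curves if c.factors[f] == level}
            if len(batches) > 1 and len(in_batches) == 1:
                report.warnings.append(
                    f"factor {f!r} level {level!r} observed in only one batch "
                    f"({next(iter(in_batches))})"
                )
    counts: dict[tuple, int] = {}
    for c in dataset.curves:
        cond = tuple(c.factors[f] for f in dataset.factor_names)
        counts[(cond, c.batch)] = counts.get((cond, c.batch), 0) + 1
    report.replicate_counts = pd.DataFrame(
        [
            {"condition": "/".join(cond) if cond else "(none)", "batch": b, "n_replicates": n}
            for (cond, b), n in sorted(counts.items())
        ]
    )
    return report
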