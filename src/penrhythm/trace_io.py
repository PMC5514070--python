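"""Reading, validating and writing digitizer pen-trace files.

A *trace* is the time-ordered sequence of samples (t, x, y, pressure)
recorded by a graphics tablet for one trial, together with trial metadata
(participant, grade group, script, task condition).  The on-disk dialect is
plain delimited text: one CSV per trial block (columns ``t,x,y,pressure``,
optionally a ``trial`` column separating several trials in one file) plus a
sidecar manifest CSV with one row per trial.  Positions are stored in cm,
time in seconds; a dialect config can rescale device units on read.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

GROUPS = ("G1", "G2", "G3", "G4", "G5")
SCRIPTS = ("block", "cursive")
CONDITIONS = ("Spontaneous", "Small", "Big", "Slow", "Fast")

#: conditions that enter the statistical analyses (Small and Slow are
#: recorded but excluded: they are unreliable at tablet resolution)
ANALYZED_CONDITIONS = ("Spontaneous", "Big", "Fast")

MANIFEST_COLUMNS = [
    "file", "trial_id", "participant_id", "group", "script", "condition",
    "nominal_rate", "word",
]


class TraceFormatError(ValueError):
    """Raised when a trace file cannot be parsed with the given dialect."""


class TraceValidationError(ValueError):
    """Raised when parsed samples or metadata violate a trace invariant."""


@dataclass(frozen=True)
class Dialect:
    """Column names, delimiter and unit scale factors of a trace file.

    ``t_scale`` multiplies the raw time column to obtain seconds;
    ``xy_scale`` multiplies raw positions to obtain cm (e.g. 2.54/5080 for a
    tablet reporting 5080 lines per inch).
    """

    delimiter: str = ","
    t_col: str = "t"
    x_col: str = "x"
    y_col: str = "y"
    pressure_col: str = "pressure"
    trial_col: str = "trial"
    t_scale: float = 1.0
    xy_scale: float = 1.0

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "Dialect":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass(frozen=True)
class TraceMeta:
    participant_id: str
    group: str
    script: str
    condition: str
    nominal_rate: float = 200.0
    word: str = "burle"
    trial_id: str = ""

    def __post_init__(self):
        if self.group not in GROUPS:
            raise TraceValidationError(
                f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.script not in SCRIPTS:
            raise TraceValidationError(
                f"unknown script {self.script!r}; expected one of {SCRIPTS}")
        if self.condition not in CONDITIONS:
            raise TraceValidationError(
                f"unknown condition {self.condition!r}; "
                f"expected one of {CONDITIONS}")
        if not self.nominal_rate > 0:
            raise TraceValidationError("nominal_rate must be > 0")


@dataclass
class Trace:
    """One trial: sample arrays plus metadata.

    ``t`` is strictly increasing (seconds), ``x``/``y`` are positions in cm
    and ``pressure`` is the non-negative device pressure channel; pressure 0
    marks pen-in-air samples.
    """

    meta: TraceMeta
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    pressure: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        validate_trace(self)

    def __len__(self) -> int:
        return len(self.t)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Trace):
            return NotImplemented
        return self.meta == other.meta and all(
            np.array_equal(getattr(self, f), getattr(other, f))
            for f in ("t", "x", "y", "pressure"))


def validate_trace(trace: Trace) -> None:
    """Check every trace invariant; raise TraceValidationError on the first hit."""
    n = len(trace.t)
    if not (len(trace.x) == len(trace.y) == len(trace.pressure) == n):
        raise TraceValidationError("sample columns have unequal lengths")
    if n < 2:
        raise TraceValidationError("a trace needs at least 2 samples")
    dt = np.diff(trace.t)
    bad = np.nonzero(dt <= 0)[0]
    if bad.size:
        i = int(bad[0]) + 1
        raise TraceValidationError(
            f"time not strictly increasing at row {i} "
            f"(t[{i - 1}]={trace.t[i - 1]!r}, t[{i}]={trace.t[i]!r})")
    if not (np.all(np.isfinite(trace.x)) and np.all(np.isfinite(trace.y))):
        raise TraceValidationError("non-finite x or y coordinate")
    if np.any(trace.pressure < 0) or not np.all(np.isfinite(trace.pressure)):
        raise TraceValidationError("pressure must be finite and >= 0")


def read_trace_file(
    path: str | os.PathLike,
    dialect: Dialect = Dialect(),
    meta: TraceMeta | list[TraceMeta] | None = None,
) -> list[Trace]:
    """Read one trace file; return one Trace per trial block.

    ``meta`` supplies the trial metadata (a single TraceMeta, or a list with
    one entry per trial block when the file carries a trial column); it
    normally comes from the sidecar manifest via :func:`read_cohort`.
    """
    try:
        df = pd.read_csv(path, sep=dialect.delimiter,
                         float_precision="round_trip")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise TraceFormatError(f"cannot parse {path}: {exc}") from exc
    for col in (dialect.t_col, dialect.x_col, dialect.y_col,
                dialect.pressure_col):
        if col not in df.columns:
            raise TraceFormatError(
                f"{path}: missing column {col!r} (have {list(df.columns)})")

    if dialect.trial_col in df.columns:
        blocks = [g for _, g in df.groupby(dialect.trial_col, sort=False)]
    else:
        blocks = [df]

    if meta is None:
        metas: list[TraceMeta | None] = [None] * len(blocks)
    elif isinstance(meta, TraceMeta):
        metas = [meta] * len(blocks)
    else:
        if len(meta) != len(blocks):
            raise TraceValidationError(
                f"{path}: {len(blocks)} trial blocks but {len(meta)} metadata rows")
        metas = list(meta)

    traces = []
    for block, m in zip(blocks, metas):
        if m is None:
            raise TraceValidationError(
                f"{path}: no metadata supplied for a trial block")
        traces.append(Trace(
            meta=m,
            t=block[dialect.t_col].to_numpy(float) * dialect.t_scale,
            x=block[dialect.x_col].to_numpy(float) * dialect.xy_scale,
            y=block[dialect.y_col].to_numpy(float) * dialect.xy_scale,
            pressure=block[dialect.pressure_col].to_numpy(float),
        ))
    return traces


def write_trace_file(
    traces: list[Trace],
    path: str | os.PathLike,
    dialect: Dialect = Dialect(),
) -> str:
    """Write traces in the same dialect read_trace_file accepts (round-trip safe).

    Values are printed with ``repr`` precision so read(write(x)) == x.
    """
    frames = []
    for i, tr in enumerate(traces):
        frames.append(pd.DataFrame({
            dialect.trial_col: tr.meta.trial_id or str(i),
            dialect.t_col: tr.t / dialect.t_scale,
            dialect.x_col: tr.x / dialect.xy_scale,
            dialect.y_col: tr.y / dialect.xy_scale,
            dialect.pressure_col: tr.pressure,
        }))
    cols = [dialect.trial_col, dialect.t_col, dialect.x_col, dialect.y_col,
            dialect.pressure_col]
    out = (pd.concat(frames) if frames
           else pd.DataFrame(columns=cols))
    out.to_csv(path, sep=dialect.delimiter, index=False,
               float_format="%.17g")
    return os.fspath(path)


def _meta_from_row(row: pd.Series) -> TraceMeta:
    return TraceMeta(
        participant_id=str(row["participant_id"]),
        group=str(row["group"]),
        script=str(row["script"]),
        condition=str(row["condition"]),
        nominal_rate=float(row.get("nominal_rate", 200.0)),
        word=str(row.get("word", "burle")),
        trial_id=str(row.get("trial_id", "")),
    )


def write_cohort(
    traces: list[Trace],
    directory: str | os.PathLike,
    dialect: Dialect = Dialect(),
    traces_per_file: int = 50,
) -> str:
    """Write a cohort as chunked trace files plus a manifest CSV.

    Returns the manifest path.  Trials are grouped ``traces_per_file`` to a
    file to keep directory sizes sane for large cohorts.
    """
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    rows = []
    for start in range(0, len(traces), traces_per_file):
        chunk = traces[start:start + traces_per_file]
        fname = f"traces_{start // traces_per_file:04d}.csv"
        write_trace_file(chunk, os.path.join(directory, fname), dialect)
        for tr in chunk:
            m = tr.meta
            rows.append([fname, m.trial_id, m.participant_id, m.group,
                         m.script, m.condition, m.nominal_rate, m.word])
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest_path = os.path.join(directory, "manifest.csv")
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def read_cohort(
    manifest_path: str | os.PathLike,
    dialect: Dialect = Dialect(),
) -> list[Trace]:
    """Read every trial listed in a manifest, in manifest order."""
    manifest = pd.read_csv(manifest_path)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise TraceFormatError(
            f"{manifest_path}: manifest missing columns {missing}")
    base = os.path.dirname(os.fspath(manifest_path))
    traces = []
    for fname, grp in manifest.groupby("file", sort=False):
        metas = [_meta_from_row(r) for _, r in grp.iterrows()]
        traces.extend(
            read_trace_file(os.path.join(base, fname), dialect, metas))
    return traces


__all__ = [
    "Dialect", "Trace", "TraceMeta", "TraceFormatError",
    "TraceValidationError", "validate_trace", "read_trace_file",
    "write_trace_file", "read_cohort", "write_cohort",
    "GROUPS", "SCRIPTS", "CONDITIONS", "ANALYZED_CONDITIONS",
]
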