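"""Domain types and file I/O for cumulative drug-release curves.

A release experiment produces, per copolymer sample and per release-medium
pH, a time series of cumulative released drug expressed as a percentage of
the encapsulated amount (``Mt/Minf x 100``).  Curves are exchanged as plain
comma-delimited UTF-8 tables with a mandatory header
``time_h,released_pct,sample_id,pH``; times are hours, the decimal mark is
".".  Unit conversion is the caller's responsibility.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ReleaseCurve",
    "FitReport",
    "ReleaseTableError",
    "read_release_table",
    "write_release_table",
]

REQUIRED_COLUMNS = ("time_h", "released_pct", "sample_id", "pH")

#: released_pct above this is rejected outright (small experimental
#: overshoot above 100 is tolerated and merely flagged).
RELEASED_HARD_MAX = 110.0


class ReleaseTableError(ValueError):
    """Malformed release table (missing column, bad cell, duplicate time)."""


@dataclass
class ReleaseCurve:
    """One cumulative release time series for a (sample, pH) condition.

    Parameters
    ----------
    sample_id : str
        Copolymer sample label (e.g. "A", "B", "C").
    pH : float
        pH of the release medium (e.g. 2, 6.8, 7.4).
    times : array of float
        Sampling times in hours, strictly increasing, >= 0.
    released : array of float
        Cumulative released drug, % of encapsulated amount. Raw data need
        not be monotone; synthetic curves are non-decreasing.
    temperature_C : float
        Bath temperature metadata (release assays run at 37 C).
    medium : str
        Free-text description of the release medium.
    """

    sample_id: str
    pH: float
    times: np.ndarray
    released: np.ndarray
    temperature_C: float = 37.0
    medium: str = ""
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.released = np.asarray(self.released, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.released.shape:
            raise ValueError("times and released must be 1-D arrays of equal length")
        if self.times.size and self.times[0] < 0:
            raise ValueError("negative time in release curve")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(
                f"times must be strictly increasing for ({self.sample_id}, pH {self.pH})"
            )
        if np.any(self.released < 0) or np.any(self.released > RELEASED_HARD_MAX):
            raise ValueError(
                f"released values outside [0, {RELEASED_HARD_MAX}] for "
                f"({self.sample_id}, pH {self.pH})"
            )
        if np.any(self.released > 100.0) and "overshoot" not in self.flags:
            self.flags.append("overshoot")
        # a positive value at t=0 is kept but marks burst release
        if self.times.size and self.times[0] == 0.0 and self.released[0] > 0:
            if "burst" not in self.flags:
                self.flags.append("burst")

    @property
    def key(self) -> tuple:
        return (self.sample_id, float(self.pH))

    @property
    def plateau(self) -> float:
        """Final observed release (%), used as the Minf surrogate."""
        return float(self.released[-1])

    @property
    def duration_h(self) -> float:
        return float(self.times[-1])

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class FitReport:
    """Tabular per-curve fit summary (one row per curve).

    ``rows`` is a DataFrame with at least columns pH, sample_id, Ef_pct,
    duration_h plus model parameter estimates and r_squared.
    """

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        if "r_squared" in self.rows.columns:
            r2 = self.rows["r_squared"].to_numpy(dtype=float)
            if np.any((r2 < 0) | (r2 > 1)):
                raise ValueError("r_squared outside [0, 1] in fit report")

    def to_csv(self, path, *, header_comment: str | None = None,
               round_spec: dict | None = None) -> None:
        """Write the report; efficiencies/exponents are rounded per round_spec."""
        df = self.rows.copy()
        if round_spec:
            for col, nd in round_spec.items():
                if col in df.columns:
                    df[col] = df[col].round(nd)
        with open(path, "w", encoding="utf-8") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            df.to_csv(fh, index=False)


def _fail(path, line_no: int, msg: str) -> None:
    raise ReleaseTableError(f"{path}: line {line_no}: {msg}")


def read_release_table(path) -> list[ReleaseCurve]:
    """Read a release-curve table, returning one curve per (sample_id, pH).

    The file must be comma-delimited with header columns ``time_h``,
    ``released_pct``, ``sample_id``, ``pH``.  Rows are grouped by
    (sample_id, pH) and sorted by time within each group; a duplicated time
    within a group is a parse error naming the offending line.
    """
    df = pd.read_csv(path, dtype=str, comment="#", skip_blank_lines=True)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ReleaseTableError(f"{path}: missing column(s) {missing}")
    # line numbers in the file: header is line 1
    df["_line"] = df.index + 2
    for col in ("time_h", "released_pct", "pH"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.loc[vals.isna() & df[col].notna(), "_line"]
        if len(bad):
            _fail(path, int(bad.iloc[0]), f"non-numeric value in column {col!r}")
        if df[col].isna().any():
            _fail(path, int(df.loc[df[col].isna(), "_line"].iloc[0]),
                  f"empty cell in column {col!r}")
        df[col] = vals
    curves = []
    for (sample, ph), grp in df.groupby(["sample_id", "pH"], sort=True):
        grp = grp.sort_values("time_h")
        dup = grp["time_h"].duplicated()
        if dup.any():
            _fail(path, int(grp.loc[dup, "_line"].iloc[0]),
                  f"duplicate time for group ({sample}, pH {ph})")
        curves.append(
            ReleaseCurve(
                sample_id=str(sample),
                pH=float(ph),
                times=grp["time_h"].to_numpy(),
                released=grp["released_pct"].to_numpy(),
            )
        )
    return curves


def write_release_table(curves: list[ReleaseCurve], path) -> None:
    """Write curves as a release table; inverse of :func:`read_release_table`.

    Floats are printed with 12 significant digits so that a read/write
    round-trip reproduces the curves exactly at that precision.  Duplicate
    (sample_id, pH) keys are rejected.
    """
    keys = [c.key for c in curves]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (sample_id, pH) keys in curve list")
    frames = [
        pd.DataFrame(
            {
                "time_h": c.times,
                "released_pct": c.released,
                "sample_id": c.sample_id,
                "pH": c.pH,
            }
        )
        for c in curves
    ]
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=list(REQUIRED_COLUMNS))
    buf = io.StringIO()
    out.to_csv(buf, index=False, float_format="%.12g")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(buf.getvalue())
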