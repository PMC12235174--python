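"""Core containers for plate-luminometer time series.

A recording is one 96-well plate monitored for several days: each well holds a
population of luciferase-reporter nematodes whose light output is integrated
briefly (10 s) every sampling interval (nominally 30 min). The first days run
under an entraining light/temperature cycle, the rest under constant
(free-running) conditions. Times are hours from the start of recording; the
zeitgeber time of the first sample is carried as ``zt_offset`` so phases can be
reported in ZT/CT hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

Condition = Literal["entrained", "freerun"]


class PlateFormatError(ValueError):
    """Malformed plate CSV."""


class DuplicateTimestampError(PlateFormatError):
    """The same (well, time) pair appears more than once."""


class NonMonotonicTimeError(PlateFormatError):
    """Sample times for a well are not strictly increasing."""


class NumericParseError(PlateFormatError):
    """A time or luminescence field could not be parsed as a number."""


@dataclass
class TraceSeries:
    """One well's luminescence time course.

    Parameters
    ----------
    well_id, strain
        Plate-well label and genotype/reporter label.
    times
        Hours from recording start, strictly increasing.
    values
        Luminescence (raw counts, or normalized units downstream).
    zt_offset
        Zeitgeber time (hours) of recording start; the assay places plates in
        the luminometer at ZT12.
    entrained_until
        Hours from recording start at which the plate is released into
        free-running conditions. Samples before it are "entrained", the rest
        "freerun". ``None`` labels every sample entrained.
    """

    well_id: str
    strain: str
    times: np.ndarray
    values: np.ndarray
    zt_offset: float = 12.0
    entrained_until: float | None = 72.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise NonMonotonicTimeError(
                f"well {self.well_id}: sample times must be strictly increasing"
            )

    @property
    def n_samples(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        """Span of the recording in hours."""
        return float(self.times[-1] - self.times[0]) if self.n_samples else 0.0

    @property
    def sampling_interval(self) -> float:
        """Median spacing between consecutive samples, hours."""
        if self.n_samples < 2:
            raise ValueError("need >= 2 samples to infer a sampling interval")
        return float(np.median(np.diff(self.times)))

    @property
    def segment_labels(self) -> np.ndarray:
        """Per-sample condition tag ('entrained' or 'freerun')."""
        if self.entrained_until is None:
            return np.full(self.n_samples, "entrained", dtype=object)
        return np.where(self.times < self.entrained_until, "entrained", "freerun")

    def with_values(self, values: np.ndarray) -> "TraceSeries":
        """Copy of this trace with new values on the same time grid."""
        return replace(self, values=np.asarray(values, dtype=float))

    def slice_time(self, t_min: float, t_max: float) -> "TraceSeries":
        """Samples with t_min <= t < t_max; absolute times are preserved."""
        keep = (self.times >= t_min) & (self.times < t_max)
        return replace(self, times=self.times[keep], values=self.values[keep])

    def segment(self, condition: Condition) -> "TraceSeries":
        """Sub-trace for one recording condition."""
        if self.entrained_until is None:
            if condition == "entrained":
                return self
            raise ValueError("trace has no free-running segment")
        if condition == "entrained":
            return self.slice_time(-np.inf, self.entrained_until)
        return self.slice_time(self.entrained_until, np.inf)

    def zt(self, t: float | np.ndarray) -> np.ndarray:
        """Map recording time (h) to ZT/CT hours mod 24."""
        return np.mod(np.asarray(t, dtype=float) + self.zt_offset, 24.0)


@dataclass
class PlateRecording:
    """A collection of well traces sharing one protocol."""

    traces: list[TraceSeries]
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self) -> Iterable[TraceSeries]:
        return iter(self.traces)

    def wells(self) -> list[str]:
        return [t.well_id for t in self.traces]

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for tr in self.traces:
            rows.append(
                pd.DataFrame(
                    {
                        "well": tr.well_id,
                        "strain": tr.strain,
                        "time_h": tr.times,
                        "lum": tr.values,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _require_numeric(series: pd.Series, name: str) -> np.ndarray:
    out = pd.to_numeric(series, errors="coerce")
    if out.isna().any() and not series.isna().any():
        bad = series[out.isna()].iloc[0]
        raise NumericParseError(f"unparseable {name} value: {bad!r}")
    if out.isna().any():
        raise NumericParseError(f"missing {name} value")
    return out.to_numpy(dtype=float)


def read_plate_csv(
    path: str | Path,
    dialect: Literal["long", "wide"] = "long",
    zt_offset: float = 12.0,
    entrained_until: float | None = 72.0,
) -> PlateRecording:
    """Read a plate recording from CSV.

    Long dialect: columns ``well, strain, time_h, lum``. Wide dialect: first
    column ``time_h``; remaining column headers are well ids, with a second
    header row giving each well's strain. Gaps (missing rows) are tolerated;
    duplicated (well, time) pairs and non-monotone times are errors.
    """
    path = Path(path)
    if dialect == "long":
        df = pd.read_csv(path)
        required = {"well", "strain", "time_h", "lum"}
        if not required.issubset(df.columns):
            raise PlateFormatError(
                f"long plate CSV needs columns {sorted(required)}; got {list(df.columns)}"
            )
        traces = []
        for well, grp in df.groupby("well", sort=True):
            times = _require_numeric(grp["time_h"], "time_h")
            values = _require_numeric(grp["lum"], "lum")
            order = np.argsort(times, kind="stable")
            times, values = times[order], values[order]
            if np.any(np.diff(times) == 0):
                raise DuplicateTimestampError(f"well {well}: duplicated timestamp")
            strains = grp["strain"].unique()
            if len(strains) != 1:
                raise PlateFormatError(f"well {well}: inconsistent strain labels")
            traces.append(
                TraceSeries(
                    well_id=str(well),
                    strain=str(strains[0]),
                    times=times,
                    values=values,
                    zt_offset=zt_offset,
                    entrained_until=entrained_until,
                )
            )
    elif dialect == "wide":
        head = pd.read_csv(path, header=None, nrows=2)
        wells = [str(w) for w in head.iloc[0, 1:]]
        strains = [str(s) for s in head.iloc[1, 1:]]
        body = pd.read_csv(path, header=None, skiprows=2)
        times = _require_numeric(body.iloc[:, 0], "time_h")
        if np.any(np.diff(times) == 0):
            raise DuplicateTimestampError("duplicated timestamp row")
        if not np.all(np.diff(times) > 0):
            raise NonMonotonicTimeError("time_h rows must increase")
        traces = []
        for j, (well, strain) in enumerate(zip(wells, strains), start=1):
            values = _require_numeric(body.iloc[:, j], "lum")
            traces.append(
                TraceSeries(
                    well_id=well,
                    strain=strain,
                    times=times.copy(),
                    values=values,
                    zt_offset=zt_offset,
                    entrained_until=entrained_until,
                )
            )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if not traces:
        raise PlateFormatError("plate CSV contains no wells")
    return PlateRecording(
        traces=traces,
        meta={"path": str(path), "dialect": dialect, "zt_offset": zt_offset},
    )


def write_plate_csv(
    plate: PlateRecording, path: str | Path, dialect: Literal["long", "wide"] = "long"
) -> None:
    """Write a plate recording in one of the pipeline CSV dialects."""
    path = Path(path)
    if dialect == "long":
        plate.to_long_frame().to_csv(path, index=False)
        return
    if dialect == "wide":
        times = plate.traces[0].times
        for tr in plate.traces:
            if not np.array_equal(tr.times, times):
                raise PlateFormatError("wide dialect requires a shared time grid")
        with open(path, "w") as fh:
            fh.write("time_h," + ",".join(t.well_id for t in plate.traces) + "\n")
            fh.write("strain," + ",".join(t.strain for t in plate.traces) + "\n")
            mat = np.column_stack([t.values for t in plate.traces])
            for ti, row in zip(times, mat):
                fh.write(f"{ti:g}," + ",".join(format(float(v), ".17g") for v in row) + "\n")
        return
    raise ValueError(f"unknown dialect {dialect!r}")
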