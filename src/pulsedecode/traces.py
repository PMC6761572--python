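"""Core containers for single-cell fluorescence time series.

A :class:`SingleCellTrace` is one cell / one channel sampled on a uniform
time grid (20-min frames by default, matching time-lapse microscopy).  A
:class:`TraceSet` is a collection of traces sharing a grid, together with
metadata (regimen, channel, seed, processing history).

Trace tables are exchanged as long-format delimited text with columns
``cell_id, channel, time_h, value_au, division`` (one header line, UTF-8),
plus an optional JSON sidecar holding the metadata/processing history.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

#: default frame interval in hours (20-min sampling)
FRAME_H = 1.0 / 3.0

VALID_CHANNELS = ("p53", "reporter", "geminin", "mdm2")


@dataclass
class SingleCellTrace:
    """One cell's fluorescence time course for a single channel.

    Parameters
    ----------
    cell_id
        Identifier, unique within a :class:`TraceSet`.
    times
        Strictly increasing, uniformly spaced sample times in hours.
    values
        Fluorescence values (arbitrary units); may contain NaN before gap
        interpolation.
    channel
        One of ``p53``, ``reporter``, ``geminin``, ``mdm2``.
    division_times
        Times (h) of annotated division events, or None if unannotated.
    """

    cell_id: str
    times: np.ndarray
    values: np.ndarray
    channel: str = "p53"
    division_times: list[float] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if self.times.size >= 2:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise ValueError("times must be uniformly spaced")
        if self.channel not in VALID_CHANNELS:
            raise ValueError(
                f"unknown channel {self.channel!r}; expected one of {VALID_CHANNELS}"
            )

    @property
    def dt(self) -> float:
        """Frame interval in hours."""
        return float(self.times[1] - self.times[0])

    @property
    def span(self) -> float:
        """Total duration covered by the trace (h)."""
        return float(self.times[-1] - self.times[0])

    def value_at(self, t: float | np.ndarray) -> float | np.ndarray:
        """Linearly interpolated value at arbitrary time(s) within the span."""
        return np.interp(t, self.times, self.values)

    def copy_with(self, values: np.ndarray, channel: str | None = None) -> "SingleCellTrace":
        return SingleCellTrace(
            cell_id=self.cell_id,
            times=self.times.copy(),
            values=np.asarray(values, dtype=float),
            channel=self.channel if channel is None else channel,
            division_times=None if self.division_times is None else list(self.division_times),
        )


@dataclass
class TraceSet:
    """A collection of traces on a common time grid.

    ``metadata`` records at minimum the channel, the regimen name and the
    RNG seed used to generate the data; ``history`` appends one entry per
    processing step so a pipeline run is auditable and re-runnable.
    """

    traces: list[SingleCellTrace] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.traces:
            t0 = self.traces[0].times
            for tr in self.traces[1:]:
                if tr.times.shape != t0.shape or not np.allclose(tr.times, t0):
                    raise ValueError("all traces in a TraceSet must share one time grid")

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self) -> Iterator[SingleCellTrace]:
        return iter(self.traces)

    def __getitem__(self, i: int) -> SingleCellTrace:
        return self.traces[i]

    @property
    def times(self) -> np.ndarray:
        if not self.traces:
            raise ValueError("empty TraceSet has no time grid")
        return self.traces[0].times

    def values_matrix(self) -> np.ndarray:
        """Stack values as an (n_cells, n_frames) array."""
        return np.vstack([tr.values for tr in self.traces])

    def mean_trace(self, cell_id: str = "population_mean") -> SingleCellTrace:
        """Cross-cell mean trace (population average)."""
        if not self.traces:
            raise ValueError("cannot average an empty TraceSet")
        return SingleCellTrace(
            cell_id=cell_id,
            times=self.times.copy(),
            values=self.values_matrix().mean(axis=0),
            channel=self.traces[0].channel,
        )

    def with_history(self, step: str) -> "TraceSet":
        self.history.append(step)
        return self

    # ------------------------------------------------------------------ I/O

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: cell_id, channel, time_h, value_au, division."""
        rows = []
        for tr in self.traces:
            div = np.zeros(tr.times.size, dtype=int)
            if tr.division_times:
                for td in tr.division_times:
                    div[int(np.argmin(np.abs(tr.times - td)))] = 1
            rows.append(
                pd.DataFrame(
                    {
                        "cell_id": tr.cell_id,
                        "channel": tr.channel,
                        "time_h": tr.times,
                        "value_au": tr.values,
                        "division": div,
                    }
                )
            )
        if not rows:
            return pd.DataFrame(
                columns=["cell_id", "channel", "time_h", "value_au", "division"]
            )
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, metadata: dict | None = None) -> "TraceSet":
        required = {"cell_id", "channel", "time_h", "value_au"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"trace table missing columns: {sorted(missing)}")
        traces = []
        for (cid, chan), grp in df.groupby(["cell_id", "channel"], sort=False):
            grp = grp.sort_values("time_h")
            div = None
            if "division" in grp.columns and grp["division"].sum() > 0:
                div = list(grp.loc[grp["division"] == 1, "time_h"].to_numpy(float))
            traces.append(
                SingleCellTrace(
                    cell_id=str(cid),
                    times=grp["time_h"].to_numpy(float),
                    values=grp["value_au"].to_numpy(float),
                    channel=str(chan),
                    division_times=div,
                )
            )
        return cls(traces=traces, metadata=dict(metadata or {}))

    def write(self, path: str | Path, sep: str = "\t") -> None:
        """Write the long-format table plus a JSON metadata sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, sep=sep, index=False)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps({"metadata": self.metadata, "history": self.history}, indent=2)
        )

    @classmethod
    def read(cls, path: str | Path) -> "TraceSet":
        path = Path(path)
        text = path.read_text()
        sep = "\t" if "\t" in text.splitlines()[0] else ","
        df = pd.read_csv(path, sep=sep)
        ts = cls.from_frame(df)
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            ts.metadata = meta.get("metadata", {})
            ts.history = meta.get("history", [])
        return ts


def time_grid(total_time_h: float, dt_h: float = FRAME_H) -> np.ndarray:
    """Uniform sampling grid from 0 to total_time_h inclusive."""
    n = int(round(total_time_h / dt_h))
    return np.linspace(0.0, n * dt_h, n + 1)
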