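"""Nutlin-3 dosing regimens as square-wave drug inputs.

Six canonical regimens modulate p53 pulse amplitude, duration or frequency
by switching the perfusion medium between Nutlin-3-containing and drug-free
states.  The natural-dynamics schedule (10 uM, 3 h on / 2.5 h off) mimics
the ~5.5-h-period pulsing seen after DNA double-strand breaks; the other
five vary one feature at a time:

==================  =========  ========  =========
regimen             dose (uM)  on (h)    off (h)
==================  =========  ========  =========
natural             10         3         2.5
low_frequency       10         3         8
high_frequency      10         2.5       2
long_duration       10         8         3
low_amplitude       5          3         2.5
high_amplitude      15         3         2.5
==================  =========  ========  =========

Regimens are plain data and can be round-tripped through a small key/value
config file, so custom schedules are expressed without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

DEFAULT_TOTAL_TIME_H = 24.0
CELLCYCLE_TOTAL_TIME_H = 40.0


@dataclass(frozen=True)
class PulseRegimen:
    """A square-wave drug-input schedule.

    The drug level is ``dose`` for the first ``t_on`` hours of each period
    and 0 for the following ``t_off`` hours; the cycle repeats until
    ``total_time`` and is truncated there mid-phase if necessary.  Values at
    switch instants follow the right-continuous convention (the value at a
    switch time is the new phase), which makes sampling on the 20-min frame
    grid unambiguous.
    """

    name: str
    dose: float  # uM
    t_on: float  # h
    t_off: float  # h
    total_time: float = DEFAULT_TOTAL_TIME_H  # h

    def __post_init__(self) -> None:
        if self.t_on <= 0:
            raise ValueError("t_on must be > 0")
        if self.t_off < 0:
            raise ValueError("t_off must be >= 0")
        if self.dose < 0:
            raise ValueError("dose must be >= 0")
        if self.total_time <= 0:
            raise ValueError("total_time must be > 0")

    @property
    def period(self) -> float:
        """Pulse period in hours (on + off)."""
        return self.t_on + self.t_off

    @property
    def n_complete_pulses(self) -> int:
        """Number of on-phases that complete (start + t_on <= total_time)."""
        n = 0
        start = 0.0
        while start + self.t_on <= self.total_time + 1e-9:
            n += 1
            start += self.period
        return n

    def on_phase_starts(self) -> np.ndarray:
        """Start times of all on-phases beginning before total_time."""
        starts = np.arange(0.0, self.total_time - 1e-9, self.period)
        return starts

    def with_total_time(self, total_time: float) -> "PulseRegimen":
        return PulseRegimen(self.name, self.dose, self.t_on, self.t_off, total_time)


# Canonical schedules; amplitude regimens reuse the natural timing.
_CANONICAL: dict[str, tuple[float, float, float]] = {
    "natural": (10.0, 3.0, 2.5),
    "low_frequency": (10.0, 3.0, 8.0),
    "high_frequency": (10.0, 2.5, 2.0),
    "long_duration": (10.0, 8.0, 3.0),
    "low_amplitude": (5.0, 3.0, 2.5),
    "high_amplitude": (15.0, 3.0, 2.5),
}

REGIMEN_NAMES = tuple(_CANONICAL)


def make_regimen(name: str, total_time: float = DEFAULT_TOTAL_TIME_H) -> PulseRegimen:
    """Return one of the six canonical Nutlin-3 regimens by label.

    Labels are case-insensitive; spaces and hyphens are treated as
    underscores.  ``total_time`` defaults to 24 h; pass 40 h for cell-cycle
    experiments.
    """
    key = name.strip().lower().replace(" ", "_").replace("-", "_")
    if key not in _CANONICAL:
        raise ValueError(
            f"unknown regimen {name!r}; valid names are: {', '.join(REGIMEN_NAMES)}"
        )
    dose, t_on, t_off = _CANONICAL[key]
    return PulseRegimen(key, dose, t_on, t_off, total_time)


def drug_input(regimen: PulseRegimen, t: float | np.ndarray) -> float | np.ndarray:
    """Drug level (uM) at time(s) ``t`` under a square-wave regimen.

    Right-continuous at switch times: at the instant the medium switches,
    the returned level is that of the new phase.  ``t`` outside
    [0, total_time] raises.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < -1e-9) or np.any(t_arr > regimen.total_time + 1e-9):
        raise ValueError(
            f"t must lie within [0, {regimen.total_time}] h for regimen {regimen.name!r}"
        )
    phase = np.mod(t_arr, regimen.period)
    out = np.where(phase < regimen.t_on - 1e-12, regimen.dose, 0.0)
    # guard against mod returning period-epsilon at exact multiples
    out = np.where(np.isclose(phase, regimen.period), regimen.dose, out)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


# ------------------------------------------------------------------- config

def save_regimens(regimens: list[PulseRegimen], path: str | Path) -> None:
    """Serialize regimens to a YAML config (fields name, dose_uM, t_on_h,
    t_off_h, total_time_h)."""
    payload = [
        {
            "name": r.name,
            "dose_uM": r.dose,
            "t_on_h": r.t_on,
            "t_off_h": r.t_off,
            "total_time_h": r.total_time,
        }
        for r in regimens
    ]
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_regimens(path: str | Path) -> list[PulseRegimen]:
    """Load regimens from a YAML config written by :func:`save_regimens`."""
    payload = yaml.safe_load(Path(path).read_text())
    out = []
    for item in payload:
        out.append(
            PulseRegimen(
                name=str(item["name"]),
                dose=float(item["dose_uM"]),
                t_on=float(item["t_on_h"]),
                t_off=float(item["t_off_h"]),
                total_time=float(item.get("total_time_h", DEFAULT_TOTAL_TIME_H)),
            )
        )
    return out


def regimen_to_dict(regimen: PulseRegimen) -> dict:
    return asdict(regimen)
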