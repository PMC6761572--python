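"""Cell-cycle scoring from geminin-mCherry reporter traces.

Geminin accumulates from late G1 through S/G2 and is degraded at mitosis,
so its reporter distinguishes arrest from progression over a 40-h movie:
cells at basal geminin for more than 25 of the 40 h are scored arrested;
cells with elevated episodes are progressing, either *pulsatile* (the
signal returns to basal before trace end, typically at division) or
*sustained*.  Division events come from annotations (visual tracking or
the synthetic generator); automatic drop detection is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .traces import SingleCellTrace, TraceSet

#: arrest rule: basal geminin for more than this many hours of the movie
ARREST_BASAL_H = 25.0
#: expected experiment span for cell-cycle scoring (h)
CELLCYCLE_SPAN_H = 40.0
#: elevated threshold as a multiple of the per-cell baseline
DEFAULT_THRESHOLD_FACTOR = 1.5
#: minimum contiguous elevated time to count as a geminin episode (h);
#: shorter excursions are treated as noise, not S/G2 entry
MIN_EPISODE_H = 5.0
#: frames averaged for the per-cell baseline
BASELINE_FRAMES = 3

STATUSES = ("arrested", "progressing_sustained", "progressing_pulsatile")


@dataclass
class CellCycleLabel:
    cell_id: str
    status: str
    divided: bool
    n_divisions: int
    basal_hours: float


def _elevated_episodes(elevated: np.ndarray, dt: float) -> list[tuple[int, int]]:
    """Contiguous runs of elevated frames as (start, stop) index pairs
    (stop exclusive)."""
    runs = []
    start = None
    for i, e in enumerate(elevated):
        if e and start is None:
            start = i
        elif not e and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, elevated.size))
    return runs


def classify_cellcycle(
    geminin_trace: SingleCellTrace,
    basal_threshold_factor: float = DEFAULT_THRESHOLD_FACTOR,
    min_episode_h: float = MIN_EPISODE_H,
    allow_short: bool = False,
) -> CellCycleLabel:
    """Score one geminin trace as arrested / progressing.

    The elevated threshold is ``basal_threshold_factor`` times the cell's
    own first-hour baseline (making the rule invariant to positive
    scaling).  basal_hours is the total time spent below threshold.  A
    cell progresses if it shows at least one contiguous elevated episode
    of ``min_episode_h`` or longer (S/G2 geminin accumulation); it is
    *pulsatile* if such an episode returns to basal before trace end
    (mitotic geminin degradation) and *sustained* otherwise.  Cells with
    no qualifying episode and more than 25 basal hours (prorated for
    shorter traces) are arrested.
    """
    if basal_threshold_factor <= 1:
        raise ValueError("basal_threshold_factor must be > 1")
    if geminin_trace.span < CELLCYCLE_SPAN_H - 1e-6 and not allow_short:
        raise ValueError(
            f"trace spans {geminin_trace.span:.1f} h < {CELLCYCLE_SPAN_H} h; "
            "pass allow_short=True to score anyway"
        )
    v = geminin_trace.values
    baseline = float(v[:BASELINE_FRAMES].mean())
    threshold = basal_threshold_factor * baseline
    below = v < threshold
    basal_hours = float(below.mean() * geminin_trace.span)

    elevated = ~below
    dt = geminin_trace.dt
    episodes = [
        (lo, hi) for lo, hi in _elevated_episodes(elevated, dt)
        if (hi - lo) * dt >= min_episode_h
    ]
    arrest_cutoff = ARREST_BASAL_H * geminin_trace.span / CELLCYCLE_SPAN_H

    n_div = len(geminin_trace.division_times or [])
    if not episodes and basal_hours > arrest_cutoff:
        status = "arrested"
    elif any(hi < elevated.size for _, hi in episodes):
        status = "progressing_pulsatile"
    else:
        status = "progressing_sustained"
    return CellCycleLabel(
        cell_id=geminin_trace.cell_id,
        status=status,
        divided=n_div > 0,
        n_divisions=n_div,
        basal_hours=basal_hours,
    )


def count_divisions(trace: SingleCellTrace, t_max: float = CELLCYCLE_SPAN_H) -> int:
    """Number of annotated division events within [0, t_max]."""
    if trace.division_times is None:
        raise ValueError(
            "trace has no division annotations; annotate divisions "
            "(division column in the trace table) before counting"
        )
    return int(sum(0 <= td <= t_max + 1e-9 for td in trace.division_times))


def label_traceset(
    traceset: TraceSet,
    basal_threshold_factor: float = DEFAULT_THRESHOLD_FACTOR,
    allow_short: bool = False,
) -> list[CellCycleLabel]:
    return [
        classify_cellcycle(tr, basal_threshold_factor, allow_short=allow_short)
        for tr in traceset
    ]


def summarize_population(labels: list[CellCycleLabel]) -> dict[str, float]:
    """Population fractions: percent divided, percent geminin-positive
    (progressing sustained or pulsatile), and the per-status breakdown."""
    if not labels:
        raise ValueError("no labels to summarize")
    n = len(labels)
    out: dict[str, float] = {
        "percent_divided": 100.0 * sum(l.divided for l in labels) / n,
        "percent_geminin_positive": 100.0
        * sum(l.status != "arrested" for l in labels)
        / n,
    }
    for st in STATUSES:
        out[f"percent_{st}"] = 100.0 * sum(l.status == st for l in labels) / n
    return out


def labels_table(labels: list[CellCycleLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_id": l.cell_id,
                "status": l.status,
                "divided": l.divided,
                "n_divisions": l.n_divisions,
                "basal_hours": l.basal_hours,
            }
            for l in labels
        ]
    )
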