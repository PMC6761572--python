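"""Promoter-activation metrics and group comparisons.

A cell *responds* if its final reporter level is at least twice its trace
minimum.  Responding traces are characterized by three metrics: the time
to half-maximal activation (*timing*), the level at half-maximal
activation (*magnitude*) and the initial accumulation slope (*rate*).
Duration- and frequency-modulation effects are compared across regimens
with equal-variance two-sample t-tests (significance at P < 0.05), and
duration sensitivity is additionally probed by comparing activation rates
at times of matched cumulative p53 exposure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import find_peaks

from .trace_processing import cumulative_curve
from .traces import SingleCellTrace, TraceSet

#: frames averaged for the activation baseline (3 frames = 1 h)
BASELINE_FRAMES = 3
#: onset threshold for the rate window, as a fraction of dynamic range
ONSET_FRAC = 0.1
#: natural p53 pulse period (h)
NATURAL_PERIOD_H = 5.5
#: responder rule: final level must reach this multiple of the minimum
RESPONDER_FOLD = 2.0
ALPHA = 0.05


@dataclass
class PromoterMetrics:
    """Per-cell activation summary.

    Timing/magnitude/rate are NaN for non-responders, which carry only the
    label and baseline/peak levels.
    """

    cell_id: str
    responder: bool
    timing: float = float("nan")  # h
    magnitude: float = float("nan")  # AU
    rate: float = float("nan")  # AU/h
    baseline: float = float("nan")  # AU
    peak: float = float("nan")  # AU


@dataclass
class MatchedRateSpec:
    """Bookkeeping for the matched-cumulative-p53 rate comparison."""

    t_peak: float  # first p53 pulse peak of the comparison trace (h)
    t_X: float  # time of cumulative-p53 equality (h)
    tau_period: float = NATURAL_PERIOD_H
    c_star: float = float("nan")  # reference cumulative p53 (AU*h)


def classify_responder(mcherry_trace: SingleCellTrace) -> bool:
    """Responder iff final value >= 2 x trace minimum.

    Scale-invariant for positive traces.  If the minimum is non-positive
    the ratio rule is undefined; fall back to requiring the final rise
    (final - min) to exceed the trace's dynamic-range floor.
    """
    v = mcherry_trace.values
    vmin = float(np.min(v))
    final = float(v[-1])
    if vmin <= 0:
        floor = 0.5 * float(np.ptp(v))
        return final - vmin >= floor and floor > 0
    return final >= RESPONDER_FOLD * vmin


def _first_crossing(times: np.ndarray, values: np.ndarray, level: float) -> float:
    """Earliest time the series reaches ``level``, linearly interpolated."""
    above = values >= level
    if not above.any():
        raise ValueError("trace never reaches the requested level")
    i = int(np.argmax(above))
    if i == 0:
        return float(times[0])
    t0, t1 = times[i - 1], times[i]
    v0, v1 = values[i - 1], values[i]
    if v1 == v0:
        return float(t1)
    return float(t0 + (level - v0) / (v1 - v0) * (t1 - t0))


def compute_metrics(
    mcherry_trace: SingleCellTrace,
    baseline_frames: int = BASELINE_FRAMES,
    onset_frac: float = ONSET_FRAC,
) -> PromoterMetrics:
    """Timing, magnitude and rate of promoter activation for one cell.

    baseline = mean of the first ``baseline_frames`` frames; peak = trace
    maximum; magnitude = the half-maximal level baseline + (peak-baseline)/2;
    timing = first crossing of that level (linear interpolation between
    frames); rate = least-squares slope of the trace between activation
    onset (first crossing of baseline + onset_frac x dynamic range) and the
    timing point.
    """
    t, v = mcherry_trace.times, mcherry_trace.values
    baseline = float(v[:baseline_frames].mean())
    peak = float(v.max())
    if peak <= baseline:
        raise ValueError("no activation: peak does not exceed baseline")
    responder = classify_responder(mcherry_trace)
    half_level = baseline + (peak - baseline) / 2.0
    timing = _first_crossing(t, v, half_level)
    onset_level = baseline + onset_frac * (peak - baseline)
    t_on = _first_crossing(t, v, onset_level)
    mask = (t >= t_on - 1e-9) & (t <= timing + 1e-9)
    if mask.sum() >= 2:
        slope = float(np.polyfit(t[mask], v[mask], 1)[0])
    else:  # onset and half-max within one frame: secant slope
        v_on = float(np.interp(t_on, t, v))
        slope = (half_level - v_on) / max(timing - t_on, mcherry_trace.dt * 1e-3)
    return PromoterMetrics(
        cell_id=mcherry_trace.cell_id,
        responder=responder,
        timing=timing,
        magnitude=half_level,
        rate=slope,
        baseline=baseline,
        peak=peak,
    )


def metrics_table(traceset: TraceSet, **kwargs) -> pd.DataFrame:
    """Per-cell metrics as a table (non-responders carry NaN metrics)."""
    rows = []
    for tr in traceset:
        if classify_responder(tr):
            m = compute_metrics(tr, **kwargs)
        else:
            v = tr.values
            m = PromoterMetrics(
                cell_id=tr.cell_id,
                responder=False,
                baseline=float(v[:BASELINE_FRAMES].mean()),
                peak=float(v.max()),
            )
        rows.append(
            {
                "cell_id": m.cell_id,
                "responder": m.responder,
                "timing_h": m.timing,
                "magnitude_au": m.magnitude,
                "rate_au_per_h": m.rate,
                "baseline_au": m.baseline,
                "peak_au": m.peak,
            }
        )
    return pd.DataFrame(rows)


def percent_responding(traceset: TraceSet) -> float:
    """Percentage of cells classified as responders."""
    if not len(traceset):
        raise ValueError("percent_responding of an empty TraceSet")
    n_resp = sum(classify_responder(tr) for tr in traceset)
    return 100.0 * n_resp / len(traceset)


# ----------------------------------------------- matched-cumulative-p53 rate

def first_pulse_peak_time(p53_trace: SingleCellTrace, prominence_frac: float = 0.2) -> float:
    """Time of the first p53 pulse peak (prominence-filtered local max)."""
    v = p53_trace.values
    rng = float(np.ptp(v))
    if rng == 0:
        raise ValueError("flat p53 trace has no pulse peak")
    peaks, _ = find_peaks(v, prominence=prominence_frac * rng)
    if peaks.size == 0:
        # monotone rise within span: take the maximum
        return float(p53_trace.times[int(np.argmax(v))])
    return float(p53_trace.times[peaks[0]])


def matched_rate(
    p53_ref: SingleCellTrace,
    p53_cmp: SingleCellTrace,
    mcherry_cmp: SingleCellTrace,
    tau_period: float = NATURAL_PERIOD_H,
) -> tuple[float, MatchedRateSpec]:
    """Reporter activation rate at matched cumulative p53 exposure.

    The reference (long-duration) trace fixes the exposure C* = cumulative
    p53 at its first pulse peak.  For the comparison regimen, t_X is the
    earliest time its cumulative p53 reaches C*; the returned rate is the
    mean reporter slope between the comparison's first p53 peak and
    t_X + tau_period (tau_period = 5.5 h, the natural pulse period).
    Self-comparison reduces to the plain slope over
    [t_peak, t_peak + tau_period].
    """
    t_peak_ref = first_pulse_peak_time(p53_ref)
    cum_ref = cumulative_curve(p53_ref)
    c_star = float(np.interp(t_peak_ref, p53_ref.times, cum_ref))

    cum_cmp = cumulative_curve(p53_cmp)
    if cum_cmp[-1] < c_star - 1e-9:
        raise ValueError(
            f"comparison cumulative p53 never reaches reference level "
            f"{c_star:.3g} (attained {cum_cmp[-1]:.3g})"
        )
    t_X = _first_crossing(p53_cmp.times, cum_cmp, c_star)

    t_peak_cmp = first_pulse_peak_time(p53_cmp)
    t_end = t_X + tau_period
    if t_end > mcherry_cmp.times[-1] + 1e-9:
        raise ValueError(f"t_X + tau_period = {t_end:.2f} h exceeds trace span")
    if t_end <= t_peak_cmp:
        raise ValueError("matched-rate interval is empty")
    m0 = float(mcherry_cmp.value_at(t_peak_cmp))
    m1 = float(mcherry_cmp.value_at(t_end))
    rate = (m1 - m0) / (t_end - t_peak_cmp)
    return rate, MatchedRateSpec(t_peak=t_peak_cmp, t_X=t_X,
                                 tau_period=tau_period, c_star=c_star)


# ------------------------------------------------------- group comparisons

def compare_groups(values_a, values_b) -> tuple[float, float, bool]:
    """Equal-variance two-sample t-test; significant iff p < 0.05."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError("both groups are degenerate (zero variance)")
    t_stat, p_value = stats.ttest_ind(a, b, equal_var=True)
    return float(t_stat), float(p_value), bool(p_value < ALPHA)


def fold_change(values_num, values_den) -> float:
    """Ratio of group means (used for duration-modulation summaries)."""
    num = float(np.mean(values_num))
    den = float(np.mean(values_den))
    if den == 0:
        raise ValueError("denominator group mean is zero")
    return num / den


def duration_fold_changes(
    metrics_short: pd.DataFrame, metrics_long: pd.DataFrame
) -> dict[str, float]:
    """Fold changes (long vs short duration) for the three metrics.

    Magnitude and rate are reported long/short; timing, which decreases
    with longer pulses, is reported short-over-long so every entry is a
    fold *increase* in responsiveness.  Only responders enter.
    """
    s = metrics_short[metrics_short["responder"]]
    l = metrics_long[metrics_long["responder"]]
    if s.empty or l.empty:
        raise ValueError("need responders in both duration groups")
    return {
        "magnitude_fold": fold_change(l["magnitude_au"], s["magnitude_au"]),
        "rate_fold": fold_change(l["rate_au_per_h"], s["rate_au_per_h"]),
        "timing_fold": fold_change(s["timing_h"], l["timing_h"]),
    }
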