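"""Post-segmentation trace processing.

Reproduces the standard pipeline applied to mean-nuclear-fluorescence
traces after manual segmentation: histogram-mode background subtraction,
linear interpolation of missing frames, smoothing, normalization to the
population mean at t = 0, pulse-count quality control, and cumulative
signal integration.

Missing frames are represented as NaN.  Division-frame fluorescence spikes
are handled by marking the affected frames missing and re-interpolating.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy.signal import find_peaks

from .regimens import PulseRegimen
from .traces import SingleCellTrace, TraceSet

#: default smoothing window, frames (3 frames = 1 h at 20-min sampling)
DEFAULT_SMOOTH_WINDOW = 3
#: default relative prominence for pulse counting
DEFAULT_PROMINENCE_FRAC = 0.2
#: default spike threshold: frame-to-frame jump as a fraction of trace range
DEFAULT_SPIKE_FRAC = 0.5


def subtract_background(values: np.ndarray, bins: int = 256) -> np.ndarray:
    """Subtract the histogram mode (tallest-bin center) and floor at 0.

    The background estimate mimics taking the highest peak of the
    all-pixel intensity histogram: most pixels (or frames, for a trace)
    sit at background, so the modal bin center estimates it.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot estimate background of empty input")
    if not np.all(np.isfinite(v)):
        raise ValueError("background subtraction requires finite values")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if np.ptp(v) == 0:
        background = float(v.flat[0])
    else:
        counts, edges = np.histogram(v.ravel(), bins=bins)
        i = int(np.argmax(counts))
        background = float((edges[i] + edges[i + 1]) / 2)
    return np.maximum(v - background, 0.0)


def interpolate_gaps(trace: SingleCellTrace) -> SingleCellTrace:
    """Fill missing (NaN) frames by linear interpolation.

    Interior gaps are interpolated between the nearest measured neighbors;
    leading/trailing gaps take the nearest measured value.  Idempotent.
    """
    v = trace.values
    measured = np.isfinite(v)
    if measured.sum() < 2:
        raise ValueError("need at least 2 measured frames to interpolate")
    if measured.all():
        return trace.copy_with(v.copy())
    filled = np.interp(trace.times, trace.times[measured], v[measured])
    return trace.copy_with(filled)


def omit_division_frames(trace: SingleCellTrace, half_window_frames: int = 1) -> SingleCellTrace:
    """Mark frames around annotated divisions missing, then re-interpolate.

    Division rounding produces transient fluorescence spikes; the affected
    frames are treated as unmeasured.
    """
    if not trace.division_times:
        return trace.copy_with(trace.values.copy())
    v = trace.values.copy()
    for td in trace.division_times:
        i = int(np.argmin(np.abs(trace.times - td)))
        lo = max(i - half_window_frames, 0)
        hi = min(i + half_window_frames + 1, v.size)
        v[lo:hi] = np.nan
    return interpolate_gaps(trace.copy_with(v))


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge shrinkage (window shrinks
    symmetrically near the ends so output length equals input length)."""
    half = window // 2
    out = np.empty_like(values, dtype=float)
    n = values.size
    for i in range(n):
        k = min(half, i, n - 1 - i)
        out[i] = values[i - k : i + k + 1].mean()
    return out


def smooth(
    trace: SingleCellTrace,
    method: str | Callable[[np.ndarray, int], np.ndarray] = "moving_average",
    window: int = DEFAULT_SMOOTH_WINDOW,
) -> SingleCellTrace:
    """Smooth a trace; default is a centered moving average over 3 frames.

    ``method`` may be a name or any callable ``(values, window) -> values``
    of matching length, so alternative smoothers plug in without pipeline
    changes.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window > trace.values.size:
        raise ValueError("window exceeds trace length")
    fn = moving_average if method == "moving_average" else method
    if not callable(fn):
        raise ValueError(f"unknown smoothing method {method!r}")
    out = fn(trace.values, window)
    if np.shape(out) != trace.values.shape:
        raise ValueError("smoothing method changed the trace length")
    return trace.copy_with(np.asarray(out, dtype=float))


def normalize_to_t0(traceset: TraceSet) -> TraceSet:
    """Divide every value by the cross-cell mean fluorescence at t = 0.

    Corrects for session-to-session lamp variation; afterwards the
    cross-cell mean at the first frame is exactly 1.
    """
    if not len(traceset):
        raise ValueError("cannot normalize an empty TraceSet")
    t0_mean = float(np.mean([tr.values[0] for tr in traceset]))
    if t0_mean <= 0:
        raise ValueError(f"mean fluorescence at t=0 is {t0_mean}; must be > 0")
    out = TraceSet(
        traces=[tr.copy_with(tr.values / t0_mean) for tr in traceset],
        metadata=dict(traceset.metadata),
        history=list(traceset.history),
    )
    out.metadata["t0_divisor"] = t0_mean
    return out.with_history(f"normalize_to_t0(divisor={t0_mean:.6g})")


def count_pulses(trace: SingleCellTrace, prominence_frac: float = DEFAULT_PROMINENCE_FRAC) -> int:
    """Count local maxima with prominence above a fraction of trace range."""
    rng = float(np.ptp(trace.values))
    if rng == 0:
        return 0
    peaks, _ = find_peaks(trace.values, prominence=prominence_frac * rng)
    return int(peaks.size)


def has_spike(trace: SingleCellTrace, spike_frac: float = DEFAULT_SPIKE_FRAC) -> bool:
    """True if any frame-to-frame jump exceeds spike_frac x trace range."""
    rng = float(np.ptp(trace.values))
    if rng == 0:
        return False
    return bool(np.max(np.abs(np.diff(trace.values))) > spike_frac * rng)


def qc_select(
    traceset: TraceSet,
    regimen: PulseRegimen,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
    spike_frac: float = DEFAULT_SPIKE_FRAC,
) -> tuple[TraceSet, dict[str, str]]:
    """Keep cells whose p53 trace matches the regimen's expected pulse count.

    Expected count = number of completed on-phases within total_time.
    Cells with the wrong pulse count (non-responsive or non-pulsatile) or
    with single-frame fluorescence spikes are rejected; the returned dict
    maps rejected cell_id -> reason.
    """
    expected = regimen.n_complete_pulses
    kept = []
    rejected: dict[str, str] = {}
    for tr in traceset:
        if has_spike(tr, spike_frac):
            rejected[tr.cell_id] = "spike"
            continue
        n = count_pulses(tr, prominence_frac)
        if n != expected:
            rejected[tr.cell_id] = f"pulse_count={n},expected={expected}"
            continue
        kept.append(tr)
    out = TraceSet(traces=kept, metadata=dict(traceset.metadata),
                   history=list(traceset.history))
    return out.with_history(
        f"qc_select(regimen={regimen.name},kept={len(kept)},rejected={len(rejected)})"
    ), rejected


def cumulative_signal(trace: SingleCellTrace, t_end: float | None = None) -> float:
    """Trapezoidal integral of the trace from t = 0 to t_end (AU*h)."""
    if t_end is None:
        t_end = float(trace.times[-1])
    if t_end < trace.times[0] - 1e-9 or t_end > trace.times[-1] + 1e-9:
        raise ValueError(f"t_end={t_end} outside trace span")
    mask = trace.times <= t_end + 1e-12
    t = trace.times[mask]
    v = trace.values[mask]
    total = float(np.trapezoid(v, t))
    if t[-1] < t_end - 1e-12:  # partial final interval
        v_end = float(trace.value_at(t_end))
        total += 0.5 * (v[-1] + v_end) * (t_end - t[-1])
    return total


def cumulative_curve(trace: SingleCellTrace) -> np.ndarray:
    """Running trapezoidal integral at every frame (AU*h)."""
    from scipy.integrate import cumulative_trapezoid

    return cumulative_trapezoid(trace.values, trace.times, initial=0.0)


def process_traceset(
    traceset: TraceSet,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    normalize: bool = False,
) -> TraceSet:
    """Standard chain: division-frame omission, gap interpolation,
    smoothing, optional t0 normalization; steps recorded in history."""
    out = TraceSet(
        traces=[
            smooth(interpolate_gaps(omit_division_frames(tr)), window=smooth_window)
            for tr in traceset
        ],
        metadata=dict(traceset.metadata),
        history=list(traceset.history),
    )
    out.with_history(f"interpolate_gaps+smooth(window={smooth_window})")
    if normalize:
        out = normalize_to_t0(out)
    return out
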