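"""Synthetic single-cell trace generator.

Emulates the statistical structure of the time-lapse data the analysis
consumes: per-cell p53-Venus pulse trains under the six Nutlin-3 regimens
(with the ~70% pulse-amplitude coefficient of variation seen in damage
responses), promoter-mCherry reporter traces driven through the delayed
Hill model, and geminin-mCherry cell-cycle traces with division events.
A minimal p53-MDM2 negative-feedback ODE reproduces — qualitatively only —
the refractory behavior of long-duration pulses.

p53 pulse shape is phenomenological: a linear rise at a fixed accumulation
timescale (``rise_time``, default 3 h = the natural on-duration) capped at
the pulse amplitude for the remainder of the on-phase, then exponential
decay after washout.  Because the rise timescale is a property of p53
stabilization kinetics rather than of the dosing schedule, on-phases
shorter than ``rise_time`` yield proportionally lower pulse peaks, matching
the reduced amplitude observed under high-frequency dosing.  Peak amplitude
scales linearly with dose relative to the 10-uM reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.integrate import solve_ivp

from .hillmodel import HillParams, simulate_reporter
from .regimens import PulseRegimen, drug_input
from .traces import FRAME_H, SingleCellTrace, TraceSet, time_grid

#: reference dose for the amplitude scale (uM)
REFERENCE_DOSE_UM = 10.0


@dataclass
class GeneratorConfig:
    """Parameters of the p53 pulse-train emulator.

    Defaults target the study conditions: 20-min sampling, pulse-amplitude
    CV of 0.70, a 3-h rise matching the natural on-duration, and a p53
    scale on which the natural 10-uM pulse peaks near 600 normalized AU
    (basal + pulse_amp_mean * dose_scale).
    """

    n_cells: int = 50
    basal: float = 20.0  # baseline fluorescence (AU)
    pulse_amp_mean: float = 580.0  # mean pulse amplitude above basal at 10 uM (AU)
    amp_cv: float = 0.70  # per-pulse amplitude coefficient of variation
    rise_time: float = 3.0  # p53 accumulation timescale (h)
    decay_halflife: float = 1.0  # post-washout decay half-life (h)
    noise_sd: float = 5.0  # additive measurement noise (AU)
    seed: int = 0
    dose_scale: float = 1.0  # AU per (dose/10 uM) unit
    dt: float = FRAME_H  # frame interval (h)

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        for name in ("basal", "pulse_amp_mean", "amp_cv", "rise_time",
                     "decay_halflife", "noise_sd", "dose_scale", "dt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.rise_time == 0 or self.decay_halflife == 0 or self.dt == 0:
            raise ValueError("rise_time, decay_halflife and dt must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)


def _lognormal_unit_mean(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Lognormal draws with mean 1 and the requested CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    mu = -sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=size)


def pulse_shape(t: np.ndarray, t_start: float, t_on: float, amp: float,
                rise_time: float, decay_halflife: float) -> np.ndarray:
    """Single-pulse waveform above baseline.

    Linear rise from ``t_start`` at rate amp/rise_time, capped at the peak
    attainable within the on-phase (amp * min(1, t_on/rise_time)); held at
    that level until washout at t_start + t_on, then exponential decay with
    half-life ``decay_halflife``.
    """
    peak = amp * min(1.0, t_on / rise_time)
    rel = t - t_start
    rise = amp * np.clip(rel / rise_time, 0.0, None)
    on = np.minimum(rise, peak)
    decay = peak * np.exp2(-(rel - t_on) / decay_halflife)
    out = np.where(rel < 0, 0.0, np.where(rel <= t_on, on, decay))
    return out


def generate_p53_traces(regimen: PulseRegimen, config: GeneratorConfig) -> TraceSet:
    """Generate per-cell p53-Venus pulse trains under a dosing regimen.

    Each on-phase triggers one pulse whose amplitude above basal is
    pulse_amp_mean * (dose / 10 uM) * dose_scale * L with L drawn per pulse
    from a unit-mean lognormal of CV ``amp_cv``.  Additive Gaussian noise
    of sd ``noise_sd`` emulates measurement error.  Deterministic given
    ``config.seed``; ground-truth pulse amplitudes are recorded in the
    metadata.
    """
    rng = np.random.default_rng(config.seed)
    times = time_grid(regimen.total_time, config.dt)
    starts = regimen.on_phase_starts()
    amp_base = (
        config.pulse_amp_mean * (regimen.dose / REFERENCE_DOSE_UM) * config.dose_scale
    )
    traces = []
    true_amps: dict[str, list[float]] = {}
    for i in range(config.n_cells):
        cid = f"cell{i:04d}"
        L = _lognormal_unit_mean(rng, config.amp_cv, starts.size)
        values = np.full(times.shape, config.basal)
        amps = []
        for s, l in zip(starts, L):
            t_on = min(regimen.t_on, regimen.total_time - s)
            a = amp_base * l
            values = values + pulse_shape(
                times, s, t_on, a, config.rise_time, config.decay_halflife
            )
            amps.append(float(a * min(1.0, t_on / config.rise_time)))
        if config.noise_sd > 0:
            values = values + rng.normal(0.0, config.noise_sd, times.shape)
        traces.append(SingleCellTrace(cid, times, values, channel="p53"))
        true_amps[cid] = amps
    return TraceSet(
        traces=traces,
        metadata={
            "channel": "p53",
            "regimen": regimen.name,
            "seed": config.seed,
            "generator": config.to_dict(),
            "true_pulse_amplitudes": true_amps,
        },
    )


def generate_reporter_traces(
    p53_traces: TraceSet,
    params: HillParams,
    noise_sd: float = 0.0,
    seed: int = 0,
    initial_mcherry: float = 0.0,
) -> TraceSet:
    """Forward-simulate promoter-mCherry traces from p53 inputs.

    Each cell's reporter trace is the deterministic delayed-Hill ODE
    solution plus additive Gaussian noise; with noise_sd = 0 the output is
    exactly the model trajectory.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    for tr in p53_traces:
        if tr.channel != "p53":
            raise ValueError(f"expected p53 channel traces, got {tr.channel!r}")
    rng = np.random.default_rng(seed)
    out = []
    if len(p53_traces):
        from .hillmodel import _simulate_reporter_matrix

        sims = _simulate_reporter_matrix(
            p53_traces.times, p53_traces.values_matrix(), params,
            initial_mcherry, substeps=20,
        )
        if noise_sd > 0:
            sims = sims + rng.normal(0.0, noise_sd, sims.shape)
        out = [
            tr.copy_with(v, channel="reporter") for tr, v in zip(p53_traces, sims)
        ]
    return TraceSet(
        traces=out,
        metadata={
            "channel": "reporter",
            "regimen": p53_traces.metadata.get("regimen"),
            "seed": seed,
            "hill_params": params.to_dict(),
            "noise_sd": noise_sd,
        },
    )


# ----------------------------------------------------------- geminin traces

def generate_geminin_traces(
    n_cells: int,
    frac_arrested: float,
    config: GeneratorConfig | None = None,
    seed: int = 0,
    total_time: float = 40.0,
) -> tuple[TraceSet, dict[str, str]]:
    """Generate geminin-mCherry traces for cell-cycle scoring.

    Arrested cells stay at basal geminin for the whole 40 h.  Progressing
    cells show an elevated episode starting at a random G1/S time; half of
    them (pulsatile) divide — geminin drops back to basal at mitosis, with
    the division event annotated — and the rest (sustained) remain
    elevated through trace end.  Ground-truth labels are returned as a
    cell_id -> status mapping.
    """
    if not 0 <= frac_arrested <= 1:
        raise ValueError("frac_arrested must be in [0, 1]")
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    times = time_grid(total_time, cfg.dt)
    n_arrested = int(round(frac_arrested * n_cells))
    status = ["arrested"] * n_arrested + [
        ("progressing_pulsatile" if i % 2 == 0 else "progressing_sustained")
        for i in range(n_cells - n_arrested)
    ]
    rng.shuffle(status)

    basal = cfg.basal
    elevated = basal * 6.0
    traces = []
    labels: dict[str, str] = {}
    for i, st in enumerate(status):
        cid = f"cell{i:04d}"
        labels[cid] = st
        values = np.full(times.shape, basal)
        div_times: list[float] | None = None
        if st != "arrested":
            onset = rng.uniform(2.0, 10.0)
            if st == "progressing_pulsatile":
                # elevated episode ending in division before trace end
                division = onset + rng.uniform(10.0, 18.0)
                mask = (times >= onset) & (times < division)
                ramp = (times[mask] - onset) / max(division - onset, 1e-9)
                values[mask] = basal + (elevated - basal) * np.sqrt(ramp)
                div_times = [float(times[times >= division][0])]
            else:
                mask = times >= onset
                ramp = np.clip((times[mask] - onset) / 12.0, 0.0, 1.0)
                values[mask] = basal + (elevated - basal) * ramp
        if cfg.noise_sd > 0:
            values = values + rng.normal(0.0, cfg.noise_sd, times.shape)
        traces.append(
            SingleCellTrace(cid, times, np.maximum(values, 0.0),
                            channel="geminin", division_times=div_times)
        )
    ts = TraceSet(
        traces=traces,
        metadata={
            "channel": "geminin",
            "seed": seed,
            "frac_arrested": frac_arrested,
            "labels": labels,
        },
    )
    return ts, labels


# ------------------------------------------------------- feedback emulator

@dataclass
class FeedbackParams:
    """Minimal p53-MDM2 negative-feedback loop (qualitative emulator).

    dp/dt = beta_p - p * (delta_p + alpha * M / (1 + N(t)/K_I))
    dM/dt = k_m * p(t - tau_m)^h / (K_m^h + p(t - tau_m)^h) + eps_m
            - gamma_m * M

    Nutlin (N, uM) inhibits MDM2-mediated p53 degradation with inhibition
    constant K_I; MDM2 is produced through a delayed Hill term in p53.
    Only directional behavior is meaningful (refractoriness under long
    pulses); rates are not fitted to data.
    """

    beta_p: float = 2.0      # p53 production (AU/h)
    delta_p: float = 0.1     # MDM2-independent p53 decay (1/h)
    alpha: float = 3.0       # MDM2-mediated p53 decay (1/(AU*h))
    K_I: float = 1.0         # Nutlin inhibition constant (uM)
    k_m: float = 1.0         # maximal MDM2 production (AU/h)
    h: float = 4.0           # Hill coefficient of MDM2 induction
    K_m: float = 4.0         # p53 level at half-maximal MDM2 production (AU)
    eps_m: float = 0.05      # basal MDM2 production (AU/h)
    gamma_m: float = 0.25    # MDM2 decay (1/h)
    tau_m: float = 1.0       # MDM2 induction delay (h)

    def __post_init__(self) -> None:
        for name in ("beta_p", "delta_p", "alpha", "K_I", "k_m", "h", "K_m",
                     "gamma_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.eps_m < 0 or self.tau_m < 0:
            raise ValueError("eps_m and tau_m must be >= 0")


def feedback_fixed_point(params: FeedbackParams) -> tuple[float, float]:
    """Drug-free (N = 0) steady state of the feedback loop, by bisection."""

    def m_of_p(p: float) -> float:
        hill = p**params.h / (params.K_m**params.h + p**params.h)
        return (params.k_m * hill + params.eps_m) / params.gamma_m

    def f(p: float) -> float:
        return params.beta_p - p * (params.delta_p + params.alpha * m_of_p(p))

    lo, hi = 1e-9, params.beta_p / params.delta_p
    for _ in range(200):
        mid = (lo + hi) / 2
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
    p = (lo + hi) / 2
    return p, m_of_p(p)


def simulate_feedback(
    regimen: PulseRegimen,
    params: FeedbackParams | None = None,
    seed: int = 0,
    dt: float = FRAME_H,
    substeps: int = 20,
) -> TraceSet:
    """Deterministic p53/MDM2 trajectories under a dosing regimen.

    Fixed-step RK4 with the delayed p53 read from the integration history
    (linear interpolation; pre-history clamped to the initial state).  The
    system starts at its drug-free fixed point, so with Nutlin identically
    zero both species stay flat.
    """
    fp = params or FeedbackParams()
    times = time_grid(regimen.total_time, dt)
    h_step = dt / substeps
    p0, m0 = feedback_fixed_point(fp)

    # dense history for the delay term
    hist_t = [0.0]
    hist_p = [p0]

    def p_delayed(t: float) -> float:
        td = t - fp.tau_m
        if td <= 0:
            return p0
        return float(np.interp(td, hist_t, hist_p))

    def nutlin(t: float) -> float:
        return float(drug_input(regimen, min(t, regimen.total_time)))

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        p, m = y
        inhib = 1.0 + nutlin(t) / fp.K_I
        dp = fp.beta_p - p * (fp.delta_p + fp.alpha * m / inhib)
        pd = p_delayed(t)
        hill = pd**fp.h / (fp.K_m**fp.h + pd**fp.h)
        dm = fp.k_m * hill + fp.eps_m - fp.gamma_m * m
        return np.array([dp, dm])

    y = np.array([p0, m0])
    out = np.empty((times.size, 2))
    out[0] = y
    t = 0.0
    for i in range(times.size - 1):
        for _ in range(substeps):
            k1 = rhs(t, y)
            k2 = rhs(t + h_step / 2, y + h_step / 2 * k1)
            k3 = rhs(t + h_step / 2, y + h_step / 2 * k2)
            k4 = rhs(t + h_step, y + h_step * k3)
            y = y + h_step / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h_step
            hist_t.append(t)
            hist_p.append(float(y[0]))
        out[i + 1] = y
    meta = {"regimen": regimen.name, "seed": seed, "feedback_params": asdict(fp)}
    return TraceSet(
        traces=[
            SingleCellTrace("feedback", times, out[:, 0], channel="p53"),
            SingleCellTrace("feedback", times, out[:, 1], channel="mdm2"),
        ],
        metadata=meta,
    )
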