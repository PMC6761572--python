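# pulsedecode

Tools for studying how pulsatile p53 dynamics are decoded by target gene
promoters in single cells.

The p53 tumor suppressor responds to DNA damage with a train of expression
pulses (period ~5.5 h in breast carcinoma cells). Different target
promoters read different features of that signal — pulse amplitude,
duration, and frequency — and produce distinct activation patterns that
feed distinct cell fates (p53 autoregulation via MDM2, cell-cycle arrest
via CDKN1A/p21). Experimentally these features can be modulated
independently by washing Nutlin-3 (an MDM2 inhibitor that stabilizes p53)
in and out of a microfluidic culture on square-wave schedules while p53
and a promoter-driven fluorescent reporter are imaged every 20 minutes.

`pulsedecode` packages the full analysis pipeline for such experiments,
plus a synthetic-data generator so every stage is testable without any
microscope:

- **regimens** — the six canonical Nutlin-3 dosing schedules (natural,
  low/high frequency, long duration, low/high amplitude) as square-wave
  drug inputs.
- **synthetic_data** — per-cell p53 pulse trains with realistic
  amplitude variability (CV ≈ 0.70), reporter traces driven through the
  promoter model, geminin cell-cycle traces with division events, and a
  minimal p53–MDM2 negative-feedback emulator of the refractory effect of
  long pulses.
- **trace_processing** — background subtraction, gap interpolation,
  smoothing, t₀ normalization, pulse-count QC, cumulative signal.
- **hillmodel** — the promoter activation model and its fitting.
- **metrics** — responder classification, timing/magnitude/rate of
  activation, matched-cumulative-exposure rate comparisons, t-tests.
- **cluster_filter** — k-means clustering of activation traces under
  correlation distance, and all-pass/band-pass/low-pass classification of
  promoter frequency responses.
- **cellcycle** — arrest vs progression scoring of geminin-mCherry
  traces and division counting over 40-h movies.

## The promoter activation model

Reporter accumulation from a p53 target promoter is modeled as a delayed
Hill process:

```
d[mCherry]/dt = k_max · p53(t−τ)ʰ / (Kʰ + p53(t−τ)ʰ) − γ·[mCherry]
```

where `k_max` is the maximal production rate (AU/h), `h` the Hill
coefficient, `K` the p53 level at half-maximal production, τ ≈ 2 h the
transcription/translation/maturation delay, and γ the reporter decay rate
(6.7 × 10⁻⁴ min⁻¹; negligible over the 15-h dose–response window). The
dose–response is constructed by pairing the delayed p53 level with the
reporter production rate frame by frame, and `(k_max, h, K)` are fitted by
multi-start nonlinear least squares, cross-checked against a brute-force
grid search.

## Worked example

Simulate an MDM2-promoter experiment under the long-duration regimen and
extract the activation metrics:

```python
from pulsedecode import (
    GeneratorConfig, MDM2_PROMOTER_PARAMS,
    generate_p53_traces, generate_reporter_traces, make_regimen,
    metrics_table, percent_responding, process_traceset,
)

regimen = make_regimen("long_duration")
config = GeneratorConfig(n_cells=60, seed=1)
p53 = generate_p53_traces(regimen, config)
reporter = generate_reporter_traces(p53, MDM2_PROMOTER_PARAMS, noise_sd=5.0, seed=2)

reporter = process_traceset(reporter)
print(f"{percent_responding(reporter):.1f}% of cells responding")
table = metrics_table(reporter)
resp = table[table.responder]
print(f"median timing    {resp.timing_h.median():.2f} h")
print(f"median magnitude {resp.magnitude_au.median():.1f} AU")
print(f"median rate      {resp.rate_au_per_h.median():.1f} AU/h")
```

prints

```
100.0% of cells responding
median timing    10.17 h
median magnitude 433.7 AU
median rate      114.3 AU/h
```

Every cell at least doubles its reporter over basal (the responder rule),
crossing half-maximal activation ~10 h into the movie at a median level of
~434 AU, accumulating at ~114 AU/h between activation onset and half-max.

To verify the fitting machinery, drive the model with a known parameter
set and refit from the rebuilt dose–response (this is what
`scripts/acceptance.py` automates):

```python
from pulsedecode import GeneratorConfig, HillParams, generate_p53_traces, \
    make_regimen, recovery_experiment

p53 = generate_p53_traces(
    make_regimen("long_duration"),
    GeneratorConfig(n_cells=1, basal=20, pulse_amp_mean=680, amp_cv=0,
                    noise_sd=0, seed=1, dt=1 / 30),
)[0]
fit, curve = recovery_experiment(p53, HillParams(k_max=135, h=7.5, K=407))
print(f"k_max={fit.k_max:.2f}  h={fit.h:.3f}  K={fit.K:.2f}")
```

prints

```
k_max=135.02  h=7.488  K=407.01
```

recovering the generating parameters to within a fraction of a percent.

A command-line interface mirrors the library
(`pulsedecode simulate|process|fit|metrics|cluster|filter|cellcycle|report`);
each subcommand writes its resolved configuration and seed next to its
outputs.

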