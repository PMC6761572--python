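import numpy as np
import pytest

from pulsedecode import (
    GeneratorConfig,
    HillParams,
    SingleCellTrace,
    generate_p53_traces,
    make_regimen,
)

MDM2_LIKE = HillParams(k_max=135.0, h=7.5, K=407.0)
CDKN1A_LIKE = HillParams(k_max=40.0, h=7.0, K=490.0)


@pytest.fixture(scope="session")
def natural_regimen():
    return make_regimen("natural")


@pytest.fixture(scope="session")
def clean_p53_trace(natural_regimen):
    """One noiseless p53 pulse train under the natural regimen."""
    cfg = GeneratorConfig(n_cells=1, amp_cv=0.0, noise_sd=0.0, seed=0)
    return generate_p53_traces(natural_regimen, cfg)[0]


@pytest.fixture(scope="session")
def fine_longduration_p53():
    """Noiseless long-duration p53 input on a 2-min grid, spanning the
    normalized-AU range the reference dose-response fits cover."""
    reg = make_regimen("long_duration")
    cfg = GeneratorConfig(
        n_cells=1, basal=20.0, pulse_amp_mean=680.0, amp_cv=0.0,
        noise_sd=0.0, seed=0, dt=1.0 / 30.0,
    )
    return generate_p53_traces(reg, cfg)[0]


def constant_trace(value: float, total_h: float = 24.0, dt: float = 1 / 3,
                   channel: str = "p53", cell_id: str = "c0") -> SingleCellTrace:
    n = int(round(total_h / dt))
    t = np.linspace(0.0, n * dt, n + 1)
    return SingleCellTrace(cell_id, t, np.full(n + 1, float(value)), channel=channel)
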