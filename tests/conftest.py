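import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import monofilm as mf

settings.register_profile(
    "monofilm",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("monofilm")


@pytest.fixture
def membrane_record():
    """Noise-free condensed model-membrane isotherm (two-segment EOS)."""
    eos = mf.EOSSpec(model="two_segment")
    grid = mf.pressure_spaced_area_grid(eos, 0.5, 30.0, 300, spacing="linear")
    return mf.generate_pure_isotherm(eos, grid, composition=mf.make_composition(0.0), label="membrane")


@pytest.fixture
def volmer_record():
    eos = mf.EOSSpec(model="volmer", a0=20.0)
    grid = mf.pressure_spaced_area_grid(eos, 1.0, 30.0, 400)
    return mf.generate_pure_isotherm(eos, grid, label="volmer")


@pytest.fixture
def additive_series():
    """Noise-free, ideally mixing membrane/drug family (omega = 0)."""
    spec = mf.membrane_apc_preset(omega=0.0, noise_sigma=0.0, collapse_span=None)
    return spec, mf.generate_mixture_series(spec, pi_max=22.0)


@pytest.fixture
def attractive_series():
    """Noise-free family with a negative (attractive) interaction."""
    spec = mf.membrane_apc_preset(omega=-4.0, noise_sigma=0.0, collapse_span=None)
    return spec, mf.generate_mixture_series(spec, pi_max=22.0)


def series_records(series):
    d = dict(series)
    interior = [rec for x3, rec in series if 0.0 < x3 < 1.0]
    return d[0.0], d[1.0], interior


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
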