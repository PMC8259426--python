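import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import wingvar as wv

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210706)


@pytest.fixture(scope="session")
def small_config():
    """A small but complete study design: 6 families, both sexes, both
    treatments, nuisance transforms on."""
    return wv.SimulationConfig(n_families=6, n_per_cell=(4, 6), seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return wv.generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_gpa(small_dataset):
    sets, meta, truth = small_dataset
    return wv.gpa_fit(sets)


def clean_layer_config(**overrides):
    """Config with nuisance off and size variability disabled, so raw
    coordinates follow the additive Gaussian layer model exactly: every
    coordinate is size_baseline * (template + layers + noise)."""
    defaults = dict(
        n_families=1,
        n_per_cell=(8, 8),
        size_baseline=1.0,
        treatment_size_effect=0.0,
        treatment_shape_effect=np.zeros((10, 2)),
        sigma_G=0.0,
        sigma_GxT=0.0,
        sigma_I=0.0,
        da_vector=np.zeros((10, 2)),
        sigma_FA=0.0,
        sigma_ME=0.0,
        variance_multipliers={},
        family_scale_sd=0.0,
        iv_inflation_sd=0.0,
        size_noise_factor=0.0,
        nuisance=None,
        seed=0,
    )
    defaults.update(overrides)
    return wv.SimulationConfig(**defaults)


def flat_coords(sets):
    """Stack landmark sets into an (n, 2k) value matrix (x1 y1 x2 y2 ...)."""
    return np.stack([s.coords.ravel() for s in sets])


def sides_anova_from_sets(sets, **kw):
    """Sides ANOVA on raw coordinates of one family/treatment subset."""
    vals = flat_coords(sets)
    return wv.sides_anova(
        vals,
        specimen=[s.specimen_id for s in sets],
        side=[s.side for s in sets],
        replicate=[s.replicate for s in sets],
        trait="shape",
        shape_dim=vals.shape[1],
        **kw,
    )
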