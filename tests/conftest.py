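"""Shared fixtures: one default synthetic study reused across test modules."""

from __future__ import annotations

import warnings

import pytest
from hypothesis import HealthCheck, settings

import esoxtrace as ex
from esoxtrace import transect_io

# deterministic property testing: same examples in every run
settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# the mixed models in this suite routinely sit on the boundary of the
# random-effect parameter space (tiny planted intercept variance); the
# statsmodels warnings about that are expected, not actionable
warnings.filterwarnings(
    "ignore", category=UserWarning, module="statsmodels"
)
try:
    from statsmodels.tools.sm_exceptions import ConvergenceWarning
    warnings.filterwarnings("ignore", category=ConvergenceWarning)
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def default_dataset() -> ex.SyntheticDataset:
    """The generator's default study: 20 fish per archetype, seed 0."""
    return ex.simulate_population(ex.SynthConfig(seed=0))


@pytest.fixture(scope="session")
def corrected_transects(default_dataset):
    paired = {
        fid: transect_io.pair_channels(t)
        for fid, t in default_dataset.transects.items()
    }
    corrected, coefs = transect_io.correct_temperature_proxy(paired)
    return corrected, coefs


@pytest.fixture(scope="session")
def annual_table(corrected_transects):
    corrected, _ = corrected_transects
    return transect_io.annual_means_table(corrected)


@pytest.fixture(scope="session")
def default_distance_matrix(corrected_transects):
    from esoxtrace import dtw_core

    corrected, _ = corrected_transects
    series = dtw_core.build_multiseries(corrected)
    return dtw_core.distance_matrix(series)
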