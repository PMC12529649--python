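"""Shared fixtures: printed-parameter curves and small synthetic experiments.

Heavy artifacts (a processed synthetic experiment) are session-scoped; the
coarse-sampling design keeps slope estimation cheap without changing the
exact-inversion algebra.
"""

import numpy as np
import pytest

from thermoniche.models import GPP_PARAMS, RR_PARAMS
from thermoniche.respirometry import process_experiment, rates_to_frame
from thermoniche.synthetic import ExperimentDesign, gen_respirometry
from thermoniche.tpc import TPCFit


@pytest.fixture(scope="session")
def rr_curve() -> TPCFit:
    """The respiration curve at the study's printed parameters."""
    return TPCFit.from_parameters(RR_PARAMS)


@pytest.fixture(scope="session")
def gpp_curve() -> TPCFit:
    return TPCFit.from_parameters(GPP_PARAMS)


@pytest.fixture(scope="session")
def coarse_design() -> ExperimentDesign:
    """Full 15-temperature design sampled every 30 s (fast slope fits),
    with replicate-level biology switched off so rates are exactly the
    generator curve plus measurement noise."""
    return ExperimentDesign(
        sampling_interval=30.0, mortality=False, biological_cv=0.0
    )


@pytest.fixture(scope="session")
def noiseless_rates(coarse_design):
    """Replicate rates recovered from a noise-free synthetic experiment."""
    traces, meta = gen_respirometry(coarse_design, noise_sd=0.0, seed=11)
    return rates_to_frame(process_experiment(traces, meta))


@pytest.fixture(scope="session")
def noisy_rates(coarse_design):
    """Replicate rates from a measurement-noise synthetic experiment."""
    traces, meta = gen_respirometry(coarse_design, noise_sd=0.01, seed=7)
    return rates_to_frame(process_experiment(traces, meta))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
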