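"""Shared synthetic-session fixtures.

Sessions are expensive to generate, so each canonical fixture is built
once per test run (session scope) and shared across test modules.
"""

import warnings

import numpy as np
import pytest

from respgamma import pipeline
from respgamma.synth import ablate_recurrence, generate_session

warnings.filterwarnings("ignore", message="empty .* set")
warnings.filterwarnings("ignore", message="fewer than 10 anchors")


@pytest.fixture(scope="session")
def spont():
    """Odorless 120 s control session + ground truth."""
    return generate_session(pipeline.spontaneous_config(101))


@pytest.fixture(scope="session")
def spont_gamma(spont):
    session, _ = spont
    return pipeline.gamma_signal(session)


@pytest.fixture(scope="session")
def odor_pair():
    """(control, ablated) odor sessions from the same configuration."""
    cfg = pipeline.odor_config(202, duration_s=600.0)
    return generate_session(cfg), generate_session(ablate_recurrence(cfg))


@pytest.fixture(scope="session")
def odor_rates(odor_pair):
    (ctrl, _), (abl, _) = odor_pair
    return pipeline.session_rates(ctrl), pipeline.session_rates(abl)


@pytest.fixture(scope="session")
def assembly_results(odor_pair, odor_rates):
    (ctrl, truth_c), (abl, truth_a) = odor_pair
    rates_c, rates_a = odor_rates
    res_c = pipeline.assembly_analysis(
        ctrl, rates=rates_c, seed=0,
        envelope=truth_c.gamma_envelope, env_fs=ctrl.fs)
    res_a = pipeline.assembly_analysis(
        abl, rates=rates_a, use_all_cells=True, seed=0,
        envelope=truth_a.gamma_envelope, env_fs=abl.fs)
    return res_c, res_a


@pytest.fixture(scope="session")
def gated_session():
    return generate_session(pipeline.phase_gated_config(303))


@pytest.fixture(scope="session")
def flat_session():
    return generate_session(pipeline.phase_flat_config(404))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
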