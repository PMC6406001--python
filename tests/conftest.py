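"""Shared fixtures: small synthetic panels, flows and behavior tables.

Everything is generated at test time with fixed seeds; heavyweight objects
are session-scoped so the flow computation runs once.
"""

import numpy as np
import pandas as pd
import pytest

from flowgc.atlas_io import TimeSeriesPanel
from flowgc.ggc import compute_flow_matrix
from flowgc.group import stack_group
from flowgc.synthetic import (
    default_network,
    default_score_spec,
    mock_atlas,
    simulate_panel,
    simulate_scores,
)


@pytest.fixture(scope="session")
def network():
    return default_network()


@pytest.fixture(scope="session")
def score_spec(network):
    return default_score_spec(network)


@pytest.fixture(scope="session")
def small_panels(network):
    """12 subjects on the default 20-node testbed, one short run each."""
    panels, truth = simulate_panel(network, n_subjects=12, T=600, n_runs=1, seed=301)
    return panels, truth


@pytest.fixture(scope="session")
def small_flows(small_panels):
    panels, _ = small_panels
    return {s: compute_flow_matrix(p, lag_max=5) for s, p in panels.items()}


@pytest.fixture(scope="session")
def small_stack(small_flows):
    return stack_group(small_flows)


@pytest.fixture(scope="session")
def atlas20():
    return mock_atlas(20, n_regions=4, n_networks=2)


@pytest.fixture(scope="session")
def behavior12(score_spec, network, small_panels):
    _, truth = small_panels
    return simulate_scores(score_spec, network, truth, seed=302)


@pytest.fixture()
def rng():
    return np.random.default_rng(99)


def make_panel(data, subject_id="s0", boundaries=(0,)):
    return TimeSeriesPanel(subject_id=subject_id, data=np.asarray(data, float),
                           run_boundaries=boundaries)


@pytest.fixture()
def behavior_frame():
    """Hand-built behavioral table exercising the exclusion arithmetic."""
    return pd.DataFrame(
        {
            "subject_id": ["a", "b", "c", "d"],
            "score": [100.0, 100.0, 50.0, 80.0],
            "age": [25.0, 30.0, 35.0, 28.0],
            "sex": ["male", "female", "male", "female"],
            "head_motion": [0.12, 0.05, 0.0, 0.08],
        }
    )
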