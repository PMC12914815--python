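import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from bridgenet import (
    CohortTable,
    EstimationConfig,
    LayerSpec,
    PcorNetwork,
    make_multilayer_precision,
    make_planted_bridge_model,
    sample_cohort,
)


@pytest.fixture(scope="session")
def bilayer_spec() -> LayerSpec:
    return LayerSpec(
        {"mh1": "mental_health", "mh2": "mental_health", "cog1": "cognition", "cog2": "cognition"}
    )


def network_from_weights(W, layer_spec, n=457, lam=0.1) -> PcorNetwork:
    """Wrap a raw weight matrix as a PcorNetwork for unit tests."""
    nodes = layer_spec.node_names
    return PcorNetwork(
        weights=pd.DataFrame(np.asarray(W, dtype=float), index=nodes, columns=nodes),
        layer_spec=layer_spec,
        n=n,
        selected_lambda=lam,
        ebic_path=pd.DataFrame({"lambda": [lam], "ebic": [0.0], "n_edges": [0]}),
    )


@pytest.fixture(scope="session")
def four_node_network(bilayer_spec) -> PcorNetwork:
    """w(mh1,cog1)=0.3, w(mh1,cog2)=-0.2, w(mh1,mh2)=0.9, w(cog1,cog2)=0.5."""
    W = np.zeros((4, 4))
    W[0, 2] = W[2, 0] = 0.3
    W[0, 3] = W[3, 0] = -0.2
    W[0, 1] = W[1, 0] = 0.9
    W[2, 3] = W[3, 2] = 0.5
    return network_from_weights(W, bilayer_spec)


@pytest.fixture(scope="session")
def default_model():
    return make_multilayer_precision([4, 6, 8], seed=0)


@pytest.fixture(scope="session")
def default_table(default_model) -> CohortTable:
    return sample_cohort(default_model, n=457, seed=1)


@pytest.fixture(scope="session")
def planted_model():
    return make_planted_bridge_model(seed=0)


@pytest.fixture(scope="session")
def fast_config() -> EstimationConfig:
    """Shorter penalty path for bootstrap-heavy tests."""
    return EstimationConfig(n_lambdas=30)
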