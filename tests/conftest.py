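import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from wtcascade import (  # noqa: E402
    DegreeSpec,
    WeightScheme,
    WeightedNetwork,
    assign_weights,
    build_configuration_model,
    discretise_weights,
    sample_degree_sequence,
)
from wtcascade.fixtures import complete_graph  # noqa: E402


@pytest.fixture(scope="session")
def benchmark_P_k():
    """Degree distribution of the 7-regular benchmark network."""
    return {7: 1.0}


@pytest.fixture(scope="session")
def benchmark_basis():
    """Two-type basis of the bimodal benchmark (mu=1, sigma=0.5, delta=0.5)."""
    return discretise_weights(WeightScheme("bimodal", mu=1.0, sigma=0.5, delta=0.5), 2)


@pytest.fixture(scope="session")
def k8():
    return complete_graph(8)


@pytest.fixture(scope="session")
def small_networks():
    """A mixed bag of tiny (<= 10 node) weighted networks for exact oracles."""
    nets = [complete_graph(8)]
    # path and star
    nets.append(WeightedNetwork(5, [(i, i + 1, 1.0) for i in range(4)]))
    nets.append(WeightedNetwork(7, [(0, i, 1.0) for i in range(1, 7)]))
    # small random regular/irregular nets with bimodal weights
    rng_seeds = [11, 12, 13]
    for seed in rng_seeds:
        degrees = sample_degree_sequence(DegreeSpec("regular", N=10, k=3), seed)
        net = build_configuration_model(degrees, seed)
        net = assign_weights(
            net, WeightScheme("bimodal", mu=1.0, sigma=0.6, delta=0.4), seed
        )
        nets.append(net)
    return nets


@pytest.fixture(scope="session")
def regular_net_factory():
    """Build a weighted 7-regular network of given size/sigma, cached."""
    cache = {}

    def build(N=2000, sigma=0.5, mu=1.0, delta=0.5, seed=0):
        key = (N, sigma, mu, delta, seed)
        if key not in cache:
            degrees = sample_degree_sequence(DegreeSpec("regular", N=N, k=7), seed)
            net = build_configuration_model(degrees, seed)
            if sigma == 0:
                net = net.with_weights(np.full(net.n_edges, mu))
            else:
                net = assign_weights(
                    net, WeightScheme("bimodal", mu=mu, sigma=sigma, delta=delta),
                    seed + 1,
                )
            cache[key] = net
        return cache[key]

    return build
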