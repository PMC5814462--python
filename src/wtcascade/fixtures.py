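"""Small deterministic fixture networks for tests and examples."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import netgen
from .netgen import DegreeSpec, WeightScheme, WeightedNetwork


def complete_graph(n: int = 8, weight: float = 1.0) -> WeightedNetwork:
    edges = [(u, v, weight) for u in range(n) for v in range(u + 1, n)]
    return WeightedNetwork(n, edges)


def regular_network(k: int = 7, N: int = 100, seed: int = 0) -> WeightedNetwork:
    degrees = netgen.sample_degree_sequence(DegreeSpec("regular", N=N, k=k), seed)
    return netgen.build_configuration_model(degrees, seed)


def powerlaw_network(
    N: int = 500, tau: float = 2.5, k_min: int = 2, k_max: int = 100, seed: int = 0
) -> WeightedNetwork:
    spec = DegreeSpec("powerlaw", N=N, tau=tau, k_min=k_min, k_max=min(k_max, N - 1))
    degrees = netgen.sample_degree_sequence(spec, seed)
    return netgen.build_configuration_model(degrees, seed)


def signed_edges(
    delta: float = 0.88, N: int = 120, k: int = 6, seed: int = 0
) -> list[tuple[int, int, int]]:
    """Signed edge list of a small regular network with an exact count of
    round(delta * E) positive (strong) edges."""
    net = regular_network(k=k, N=N, seed=seed)
    E = net.n_edges
    n_plus = int(round(delta * E))
    signs = np.array([1] * n_plus + [-1] * (E - n_plus))
    np.random.default_rng(seed).shuffle(signs)
    return [(u, v, int(s)) for (u, v, _), s in zip(net.edges, signs)]


def make_fixtures(seed: int, outdir) -> dict[str, Path]:
    """Write the bundled fixture set as TSV edge lists; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    k8 = complete_graph(8)
    paths["k8_complete"] = outdir / "k8_complete.tsv"
    netgen.write_edge_list(k8, paths["k8_complete"])

    reg = regular_network(k=7, N=100, seed=seed)
    scheme = WeightScheme("bimodal", mu=1.0, sigma=0.5, delta=0.5)
    reg = netgen.assign_weights(reg, scheme, seed)
    paths["regular_k7_n100"] = outdir / "regular_k7_n100.tsv"
    netgen.write_edge_list(reg, paths["regular_k7_n100"])

    pl = powerlaw_network(N=500, seed=seed)
    pl = netgen.assign_weights(pl, scheme, seed + 1)
    paths["powerlaw_n500"] = outdir / "powerlaw_n500.tsv"
    netgen.write_edge_list(pl, paths["powerlaw_n500"])

    signed = signed_edges(delta=0.88, seed=seed)
    paths["signed_delta088"] = outdir / "signed_delta088.tsv"
    netgen.write_signed_edge_list(signed, paths["signed_delta088"])
    return paths
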