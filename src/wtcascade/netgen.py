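"""Configuration-model weighted networks.

Generates the synthetic substrates on which the threshold contagion runs:
degree sequences (regular, truncated power law, explicit), simple
configuration-model graphs, and i.i.d. edge weights from bimodal,
lognormal or empirical distributions.  Also handles TSV edge-list I/O and
the mapping of signed (+/-) networks onto strong/weak bimodal weights.

Weights are assigned independently of topology, so the ensemble is fully
specified by the degree distribution P(k) and weight distribution P(w).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np


class NetworkError(ValueError):
    """Raised for infeasible or malformed network specifications."""


# --------------------------------------------------------------------------
# specifications
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DegreeSpec:
    """Degree distribution specification for a configuration model.

    kind
        ``"regular"`` (every node has degree ``k``), ``"powerlaw"``
        (P(k) proportional to k**-tau on [k_min, k_max]) or ``"explicit"``
        (a caller-supplied degree list).
    N
        Number of nodes.
    """

    kind: str
    N: int
    k: int | None = None
    tau: float | None = None
    k_min: int = 2
    k_max: int = 1000
    degrees: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.N < 1:
            raise NetworkError("N must be a positive integer")
        if self.kind == "regular":
            if self.k is None or self.k < 0:
                raise NetworkError("regular spec requires a non-negative k")
            if self.k >= self.N:
                raise NetworkError(
                    f"regular degree k={self.k} requires at least k+1={self.k + 1} nodes"
                )
        elif self.kind == "powerlaw":
            if self.tau is None or self.tau <= 1:
                raise NetworkError("powerlaw spec requires tau > 1")
            if self.k_min < 1:
                raise NetworkError("powerlaw spec requires k_min >= 1")
            if self.k_max > self.N - 1:
                raise NetworkError("powerlaw spec requires k_max <= N - 1")
            if self.k_max < self.k_min:
                raise NetworkError("powerlaw spec requires k_max >= k_min")
        elif self.kind == "explicit":
            if self.degrees is None or len(self.degrees) != self.N:
                raise NetworkError("explicit spec requires len(degrees) == N")
            if any(d < 0 for d in self.degrees):
                raise NetworkError("degrees must be non-negative")
        else:
            raise NetworkError(f"unknown degree spec kind {self.kind!r}")


@dataclass(frozen=True)
class WeightScheme:
    """Edge-weight distribution P(w).

    * ``bimodal`` — strong weight w1 with probability delta, weak weight w2
      otherwise, parameterised by mean ``mu``, standard deviation ``sigma``
      and strong-link fraction ``delta``.
    * ``lognormal`` — continuous lognormal with mean ``mu`` and standard
      deviation ``sigma`` of the weight itself.
    * ``empirical`` — resampling of a given weight list, optionally
      contracted towards its mean by ``alpha`` (sd scales as alpha*sd).
    """

    kind: str
    mu: float = 1.0
    sigma: float = 0.0
    delta: float = 0.5
    weight_list: tuple[float, ...] | None = None
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.kind == "bimodal":
            if self.mu <= 0 or self.sigma < 0:
                raise NetworkError("bimodal scheme requires mu > 0 and sigma >= 0")
            if not 0 < self.delta < 1:
                raise NetworkError("bimodal delta must lie strictly in (0, 1)")
            # beyond the diluted limit the weak weight would be negative
            limit = self.mu * math.sqrt((1 - self.delta) / self.delta)
            if self.sigma > limit * (1 + 1e-12):
                raise NetworkError(
                    f"sigma={self.sigma} exceeds the diluted limit "
                    f"mu*sqrt((1-delta)/delta)={limit:.6g}"
                )
        elif self.kind == "lognormal":
            if self.mu <= 0 or self.sigma <= 0:
                raise NetworkError("lognormal scheme requires mu > 0 and sigma > 0")
        elif self.kind == "empirical":
            if not self.weight_list:
                raise NetworkError("empirical scheme requires a non-empty weight list")
            if any(w <= 0 for w in self.weight_list):
                raise NetworkError("empirical weights must be positive")
            if not 0 <= self.alpha <= 1:
                raise NetworkError("alpha must lie in [0, 1]")
        else:
            raise NetworkError(f"unknown weight scheme kind {self.kind!r}")


@dataclass
class WeightedNetwork:
    """Undirected weighted network: node ids 0..N-1 plus an edge list.

    Edges are stored canonically with u < v, without duplicates or
    self-loops.  Weights must be non-negative; zero weights are allowed so
    that the diluted bimodal limit (weak weight exactly 0) is representable.
    """

    N: int
    edges: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        canon: list[tuple[int, int, float]] = []
        seen: set[tuple[int, int]] = set()
        for u, v, w in self.edges:
            u, v = int(u), int(v)
            if u == v:
                raise NetworkError(f"self-loop ({u},{u}) is not allowed")
            if not (0 <= u < self.N and 0 <= v < self.N):
                raise NetworkError(f"node id out of range in edge ({u},{v})")
            if w < 0:
                raise NetworkError(f"negative weight {w} on edge ({u},{v})")
            if u > v:
                u, v = v, u
            if (u, v) in seen:
                raise NetworkError(f"duplicate undirected edge ({u},{v})")
            seen.add((u, v))
            canon.append((u, v, float(w)))
        self.edges = canon

    # -- derived quantities ------------------------------------------------

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.N, dtype=np.int64)
        for u, v, _ in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg

    def strengths(self) -> np.ndarray:
        """Node strength q_k(i) = sum of incident edge weights."""
        q = np.zeros(self.N)
        for u, v, w in self.edges:
            q[u] += w
            q[v] += w
        return q

    def weight_array(self) -> np.ndarray:
        return np.array([w for _, _, w in self.edges], dtype=float)

    def adjacency_csr(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Symmetric CSR arrays (indptr, indices, weights) for fast traversal."""
        deg = self.degrees()
        indptr = np.zeros(self.N + 1, dtype=np.int64)
        np.cumsum(deg, out=indptr[1:])
        indices = np.empty(indptr[-1], dtype=np.int64)
        weights = np.empty(indptr[-1], dtype=np.float64)
        cursor = indptr[:-1].copy()
        for u, v, w in self.edges:
            indices[cursor[u]] = v
            weights[cursor[u]] = w
            cursor[u] += 1
            indices[cursor[v]] = u
            weights[cursor[v]] = w
            cursor[v] += 1
        return indptr, indices, weights

    def with_weights(self, new_weights: np.ndarray) -> "WeightedNetwork":
        if len(new_weights) != self.n_edges:
            raise NetworkError("weight array length does not match edge count")
        return WeightedNetwork(
            self.N, [(u, v, float(w)) for (u, v, _), w in zip(self.edges, new_weights)]
        )


# --------------------------------------------------------------------------
# degree sequences and topology
# --------------------------------------------------------------------------

def powerlaw_pmf(tau: float, k_min: int, k_max: int) -> tuple[np.ndarray, np.ndarray]:
    """Support and probabilities of the truncated power law P(k) ~ k**-tau."""
    support = np.arange(k_min, k_max + 1)
    probs = support.astype(float) ** (-tau)
    probs /= probs.sum()
    return support, probs


def sample_degree_sequence(spec: DegreeSpec, seed: int) -> list[int]:
    """Draw a degree sequence with an even sum from the spec.

    For sampled (power-law) sequences an odd total is repaired by
    redrawing the last degree; the retry count is bounded so a pathological
    distribution cannot loop forever.
    """
    rng = np.random.default_rng(seed)
    if spec.kind == "regular":
        if (spec.k * spec.N) % 2 != 0:
            raise NetworkError(
                f"k*N = {spec.k * spec.N} is odd: no k-regular graph exists"
            )
        return [spec.k] * spec.N
    if spec.kind == "explicit":
        return list(spec.degrees)
    support, probs = powerlaw_pmf(spec.tau, spec.k_min, spec.k_max)
    degrees = rng.choice(support, size=spec.N, p=probs)
    for _ in range(1000):
        if degrees.sum() % 2 == 0:
            return [int(d) for d in degrees]
        degrees[-1] = rng.choice(support, p=probs)
    raise NetworkError("could not repair degree-sequence parity")


def build_configuration_model(degrees: list[int], seed: int) -> WeightedNetwork:
    """Stub-matched simple graph with exactly the requested degrees.

    Self-loops and multi-edges from the stub matching are removed by
    degree-preserving double-edge swaps against randomly chosen simple
    edges.  Dense sequences for which local swaps stall (e.g. the unique
    complete realisation) fall back to Havel-Hakimi construction followed
    by randomising double-edge swaps.
    """
    degrees = [int(d) for d in degrees]
    N = len(degrees)
    total = sum(degrees)
    if total % 2 != 0:
        raise NetworkError(f"degree sum {total} is odd: sequence is not graphical")
    if any(d >= N for d in degrees):
        raise NetworkError(
            f"maximum degree {max(degrees)} exceeds N-1={N - 1}: "
            "impossible in a simple graph"
        )
    if not nx.is_graphical(degrees):
        raise NetworkError("degree sequence fails the Erdos-Gallai condition")
    if total == 0:
        return WeightedNetwork(N, [])

    rng = np.random.default_rng(seed)
    stubs = np.repeat(np.arange(N), degrees)
    rng.shuffle(stubs)
    edges = [
        (min(int(a), int(b)), max(int(a), int(b)))
        for a, b in zip(stubs[::2], stubs[1::2])
    ]
    count = Counter(edges)

    bad: list[int] = []
    seen: set[tuple[int, int]] = set()
    for idx, (u, v) in enumerate(edges):
        if u == v or (u, v) in seen:
            bad.append(idx)
        else:
            seen.add((u, v))

    max_attempts = 100 * len(edges)
    attempts = 0
    while bad and attempts < max_attempts:
        attempts += 1
        i = bad[-1]
        a, b = edges[i]
        j = int(rng.integers(len(edges)))
        if j == i:
            continue
        c, d = edges[j]
        if c == d or count[(c, d)] > 1:
            continue  # partner must be a clean simple edge
        if rng.random() < 0.5:
            c, d = d, c
        e1 = (min(a, c), max(a, c))
        e2 = (min(b, d), max(b, d))
        if a == c or b == d or e1 == e2 or count[e1] or count[e2]:
            continue
        count[(a, b)] -= 1
        count[(min(c, d), max(c, d))] -= 1
        count[e1] += 1
        count[e2] += 1
        edges[i] = e1
        edges[j] = e2
        bad.pop()

    if bad:
        return _havel_hakimi_fallback(degrees, seed)

    return WeightedNetwork(N, [(u, v, 1.0) for u, v in edges])


def _havel_hakimi_fallback(degrees: list[int], seed: int) -> WeightedNetwork:
    """Guaranteed simple realisation, randomised by double-edge swaps."""
    G = nx.havel_hakimi_graph(degrees)
    n_edges = G.number_of_edges()
    if n_edges > 1:
        try:
            nx.double_edge_swap(
                G, nswap=4 * n_edges, max_tries=200 * n_edges, seed=int(seed) % (2**31)
            )
        except nx.NetworkXException:
            pass  # rigid sequence (e.g. complete graph): keep the realisation
    return WeightedNetwork(len(degrees), [(u, v, 1.0) for u, v in G.edges()])


# --------------------------------------------------------------------------
# weights
# --------------------------------------------------------------------------

def bimodal_weight_values(mu: float, sigma: float, delta: float) -> tuple[float, float]:
    """Strong/weak weights (w1, w2) of the bimodal distribution.

    w1 = mu + sigma*sqrt((1-delta)/delta), w2 = mu - sigma*sqrt(delta/(1-delta)),
    so that the mean is mu and the population standard deviation is sigma.
    sigma = mu*sqrt((1-delta)/delta) is the diluted limit where w2 = 0.
    """
    WeightScheme("bimodal", mu=mu, sigma=sigma, delta=delta)  # validates
    w1 = mu + sigma * math.sqrt((1 - delta) / delta)
    w2 = mu - sigma * math.sqrt(delta / (1 - delta))
    return w1, max(w2, 0.0)


def lognormal_underlying(mu: float, sigma: float) -> tuple[float, float]:
    """Parameters (mean, sd) of log-weight giving weight mean mu and sd sigma."""
    s2 = math.log(1 + (sigma / mu) ** 2)
    return math.log(mu) - s2 / 2, math.sqrt(s2)


def assign_weights(net: WeightedNetwork, scheme: WeightScheme, seed: int) -> WeightedNetwork:
    """Draw i.i.d. edge weights from the scheme, independent of topology."""
    rng = np.random.default_rng(seed)
    E = net.n_edges
    if scheme.kind == "bimodal":
        w1, w2 = bimodal_weight_values(scheme.mu, scheme.sigma, scheme.delta)
        w = np.where(rng.random(E) < scheme.delta, w1, w2)
    elif scheme.kind == "lognormal":
        m, s = lognormal_underlying(scheme.mu, scheme.sigma)
        w = rng.lognormal(mean=m, sigma=s, size=E)
    else:  # empirical
        pool = rescale_weight_set(list(scheme.weight_list), scheme.alpha)
        w = rng.choice(np.asarray(pool), size=E, replace=True)
    return net.with_weights(w)


def rescale_weight_set(weights: list[float], alpha: float) -> list[float]:
    """Contract weights towards their mean: w' = mu + alpha*(w - mu).

    Preserves the mean exactly and scales the standard deviation by alpha,
    so the shape of the distribution is retained while its heterogeneity is
    tuned (alpha=1 leaves the set unchanged, alpha=0 collapses it onto mu).
    """
    if not 0 <= alpha <= 1:
        raise NetworkError("alpha must lie in [0, 1]")
    arr = np.asarray(weights, dtype=float)
    if np.any(arr <= 0):
        raise NetworkError("weights must be positive")
    mu = arr.mean()
    return list(mu + alpha * (arr - mu))


def signed_to_weighted(
    edges: list[tuple[int, int, int]],
    mu: float,
    sigma: float,
    seed: int = 0,
) -> WeightedNetwork:
    """Map a signed edge list onto bimodal weights: + -> w1 (strong), - -> w2.

    The strong-link fraction delta is measured from the data; conflicting
    duplicate pairs get a seeded random sign, and self-loops are dropped.
    """
    if not edges:
        raise NetworkError("empty signed edge list")
    rng = np.random.default_rng(seed)
    signs: dict[tuple[int, int], int] = {}
    for u, v, s in edges:
        u, v = int(u), int(v)
        if s not in (1, -1):
            raise NetworkError(f"sign must be +1 or -1, got {s}")
        if u == v:
            continue
        key = (min(u, v), max(u, v))
        if key in signs and signs[key] != s:
            signs[key] = 1 if rng.random() < 0.5 else -1
        else:
            signs[key] = s
    if not signs:
        raise NetworkError("signed edge list contains only self-loops")
    n_plus = sum(1 for s in signs.values() if s == 1)
    delta = n_plus / len(signs)
    if not 0 < delta < 1:
        raise NetworkError(
            f"measured strong-link fraction delta={delta} is degenerate; "
            "a bimodal mapping needs both signs present"
        )
    w1, w2 = bimodal_weight_values(mu, sigma, delta)
    N = max(max(u, v) for u, v in signs) + 1
    return WeightedNetwork(
        N, [(u, v, w1 if s == 1 else w2) for (u, v), s in signs.items()]
    )


# --------------------------------------------------------------------------
# edge-list I/O
# --------------------------------------------------------------------------

def read_edge_list(path) -> WeightedNetwork:
    """Read a TSV weighted edge list (node, node, weight); '#' lines skipped."""
    edges: list[tuple[int, int, float]] = []
    max_node = -1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise NetworkError(f"{path}:{lineno}: expected 3 tab-separated fields")
            try:
                u, v, w = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError as exc:
                raise NetworkError(f"{path}:{lineno}: {exc}") from None
            if u == v:
                raise NetworkError(f"{path}:{lineno}: self-loop ({u},{u}) rejected")
            if w <= 0:
                raise NetworkError(f"{path}:{lineno}: non-positive weight {w}")
            key = (min(u, v), max(u, v))
            edges.append((key[0], key[1], w))
            max_node = max(max_node, u, v)
    # undirected de-duplication: keep the first occurrence
    seen: set[tuple[int, int]] = set()
    unique = []
    for u, v, w in edges:
        if (u, v) not in seen:
            seen.add((u, v))
            unique.append((u, v, w))
    return WeightedNetwork(max_node + 1, unique)


def write_edge_list(net: WeightedNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("# node\tnode\tweight\n")
        for u, v, w in net.edges:
            fh.write(f"{u}\t{v}\t{w:.12g}\n")


def read_signed_edge_list(path) -> list[tuple[int, int, int]]:
    """Read a TSV signed edge list (node, node, +1|-1)."""
    edges: list[tuple[int, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise NetworkError(f"{path}:{lineno}: expected 3 tab-separated fields")
            try:
                u, v, s = int(parts[0]), int(parts[1]), int(float(parts[2]))
            except ValueError as exc:
                raise NetworkError(f"{path}:{lineno}: {exc}") from None
            if s not in (1, -1):
                raise NetworkError(f"{path}:{lineno}: sign must be +1 or -1")
            edges.append((u, v, s))
    if not edges:
        raise NetworkError(f"{path}: empty signed edge list")
    return edges


def write_signed_edge_list(edges: list[tuple[int, int, int]], path) -> None:
    with open(path, "w") as fh:
        fh.write("# node\tnode\tsign\n")
        for u, v, s in edges:
            fh.write(f"{u}\t{v}\t{'+1' if s == 1 else '-1'}\n")
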