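"""Asynchronous Monte Carlo simulation of weighted threshold contagion.

A susceptible node i adopts either spontaneously with probability p per
update, or deterministically once the weighted influence of its infected
neighbours reaches a fraction phi of its total strength:
q_m(i) >= phi * q_k(i).  Infection is permanent (monotone dynamics), so the
system freezes in an absorbing state.  One time step (sweep) consists of N
single-node updates on uniformly chosen nodes, time advancing 1/N per
update.

The inner loop is JIT-compiled with numba; partial strengths q_m are kept
incrementally (each infection pushes its edge weights to the neighbours),
so a node update is O(1) and an infection O(degree).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numba as nb
import numpy as np

from .netgen import WeightedNetwork

#: relative tolerance used to resolve floating-point ties in the threshold
#: rule; equality counts as adoption.
THRESHOLD_TOL = 1e-12


def threshold_satisfied(q_m: float, q_k: float, phi: float) -> bool:
    """Weighted threshold rule q_m >= phi*q_k, with a tie tolerance.

    ``q_k`` must be positive; isolated nodes (q_k = 0) never receive
    influence and are handled by the caller (spontaneous channel only).
    """
    if q_k <= 0:
        raise ValueError("threshold rule needs q_k > 0")
    return q_m >= phi * q_k - THRESHOLD_TOL * q_k


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    phi        adoption threshold, in (0, 1)
    p          spontaneous infection probability per node update
    t_max      simulated window, in sweeps
    rho_stop   stop once the infected density reaches this value
    sample_dt  sampling interval of the time series, in sweeps
    seed       RNG seed (full determinism for identical inputs)
    """

    phi: float
    p: float = 2e-4
    t_max: float = 300.0
    rho_stop: float = 1.0
    sample_dt: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.phi < 1:
            raise ValueError("phi must lie in (0, 1)")
        if not 0 <= self.p <= 1:
            raise ValueError("p must lie in [0, 1]")
        if self.t_max <= 0 or self.sample_dt <= 0 or self.sample_dt > self.t_max:
            raise ValueError("need 0 < sample_dt <= t_max")
        if not 0 < self.rho_stop <= 1:
            raise ValueError("rho_stop must lie in (0, 1]")


@dataclass
class CascadeTimeSeries:
    """Sampled trajectory of one Monte Carlo run.

    E_II[t, j] (E_SI[t, j]) is the fraction of type-j edges among
    infected-infected (susceptible-infected) edges; rows are NaN while the
    corresponding edge category is empty.
    """

    times: np.ndarray
    rho: np.ndarray
    E_II: np.ndarray
    E_SI: np.ndarray
    weight_values: np.ndarray
    final_state: np.ndarray
    F_agg: dict[tuple[int, int], float] | None = field(default=None)


# --------------------------------------------------------------------------
# numba kernel
# --------------------------------------------------------------------------

@nb.njit(cache=False)
def _mc_kernel(indptr, indices, eweights, etypes, n_types, phi, p, seed,
               total_updates, sample_every, stop_count, state, q_k, q_m,
               times, rho_out, eII_out, eSI_out):  # pragma: no cover - jitted
    np.random.seed(seed)
    N = indptr.shape[0] - 1
    n_inf = 0
    for u in range(N):
        if state[u] == 1:
            n_inf += 1
    n_rec = 0
    # sample at t = 0
    times[n_rec] = 0.0
    rho_out[n_rec] = n_inf / N
    _edge_counts(indptr, indices, etypes, n_types, state, eII_out, eSI_out, n_rec)
    n_rec += 1

    stopped = False
    for step in range(total_updates):
        u = np.random.randint(0, N)
        if state[u] == 0:
            infect = False
            if p > 0.0 and np.random.random() < p:
                infect = True
            elif q_k[u] > 0.0 and q_m[u] >= phi * q_k[u] - 1e-12 * q_k[u]:
                infect = True
            if infect:
                state[u] = 1
                n_inf += 1
                for idx in range(indptr[u], indptr[u + 1]):
                    q_m[indices[idx]] += eweights[idx]
        done = n_inf >= stop_count or n_inf == N
        if (step + 1) % sample_every == 0 or done:
            times[n_rec] = (step + 1) / N
            rho_out[n_rec] = n_inf / N
            _edge_counts(indptr, indices, etypes, n_types, state,
                         eII_out, eSI_out, n_rec)
            n_rec += 1
        if done:
            stopped = True
            break
    return n_rec, stopped


@nb.njit(cache=False)
def _edge_counts(indptr, indices, etypes, n_types, state,
                 eII_out, eSI_out, row):  # pragma: no cover - jitted
    cII = np.zeros(n_types)
    cSI = np.zeros(n_types)
    N = indptr.shape[0] - 1
    for u in range(N):
        for idx in range(indptr[u], indptr[u + 1]):
            v = indices[idx]
            if v <= u:
                continue
            t = etypes[idx]
            if state[u] == 1 and state[v] == 1:
                cII[t] += 1.0
            elif state[u] != state[v]:
                cSI[t] += 1.0
    totII = cII.sum()
    totSI = cSI.sum()
    for j in range(n_types):
        eII_out[row, j] = cII[j] / totII if totII > 0 else np.nan
        eSI_out[row, j] = cSI[j] / totSI if totSI > 0 else np.nan


# --------------------------------------------------------------------------
# driver and observables
# --------------------------------------------------------------------------

def edge_weight_types(weights: np.ndarray, max_types: int = 8):
    """Map edge weights to discrete type ids, strongest type first.

    Returns (type id per edge, representative weight per type).  If there
    are more than ``max_types`` distinct weights the edges are collapsed to
    a single type (continuous distributions need an explicit basis to define
    per-type observables).
    """
    values = np.unique(weights)[::-1]  # descending: type 0 = strongest
    if len(values) > max_types:
        return np.zeros(len(weights), dtype=np.int64), np.array([weights.mean()])
    type_of = {w: j for j, w in enumerate(values)}
    return np.array([type_of[w] for w in weights], dtype=np.int64), values


def run_mc(
    net: WeightedNetwork,
    cfg: SimConfig,
    initial_infected: list[int] | None = None,
) -> CascadeTimeSeries:
    """Simulate the threshold contagion on ``net`` and sample its trajectory."""
    if net.N == 0 or (net.n_edges == 0 and net.N == 0):
        raise ValueError("empty network")
    N = net.N
    indptr, indices, eweights = net.adjacency_csr()

    # per-adjacency-entry edge types for the E^II/E^SI bookkeeping
    edge_w = net.weight_array()
    if len(edge_w) > 0:
        etype_per_edge, type_values = edge_weight_types(edge_w)
    else:
        etype_per_edge, type_values = np.zeros(0, dtype=np.int64), np.array([1.0])
    n_types = len(type_values)
    etypes = np.zeros(len(indices), dtype=np.int64)
    cursor = indptr[:-1].copy()
    for (u, v, _), t in zip(net.edges, etype_per_edge):
        etypes[cursor[u]] = t
        cursor[u] += 1
        etypes[cursor[v]] = t
        cursor[v] += 1

    state = np.zeros(N, dtype=np.int8)
    if initial_infected:
        state[np.asarray(initial_infected, dtype=np.int64)] = 1
    q_k = np.zeros(N)
    q_m = np.zeros(N)
    for u, v, w in net.edges:
        q_k[u] += w
        q_k[v] += w
        if state[v] == 1:
            q_m[u] += w
        if state[u] == 1:
            q_m[v] += w

    total_updates = int(round(cfg.t_max * N))
    sample_every = max(1, int(round(cfg.sample_dt * N)))
    stop_count = int(np.ceil(cfg.rho_stop * N))
    n_samples = total_updates // sample_every + 3

    times = np.zeros(n_samples)
    rho = np.zeros(n_samples)
    eII = np.zeros((n_samples, n_types))
    eSI = np.zeros((n_samples, n_types))
    seed = int(cfg.seed) % (2**31)
    n_rec, _ = _mc_kernel(
        indptr, indices, eweights, etypes, n_types, cfg.phi, cfg.p, seed,
        total_updates, sample_every, stop_count, state, q_k, q_m,
        times, rho, eII, eSI,
    )
    return CascadeTimeSeries(
        times=times[:n_rec].copy(),
        rho=rho[:n_rec].copy(),
        E_II=eII[:n_rec].copy(),
        E_SI=eSI[:n_rec].copy(),
        weight_values=type_values,
        final_state=state,
    )


def measure_edge_fractions_mc(
    net: WeightedNetwork, states: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-type bulk/surface edge fractions of a state snapshot.

    Returns (E_II, E_SI, weight values); a family is all-NaN while its edge
    category (infected-infected or susceptible-infected) is empty.
    """
    edge_w = net.weight_array()
    etypes, values = edge_weight_types(edge_w)
    n = len(values)
    cII = np.zeros(n)
    cSI = np.zeros(n)
    for (u, v, _), t in zip(net.edges, etypes):
        if states[u] == 1 and states[v] == 1:
            cII[t] += 1
        elif states[u] != states[v]:
            cSI[t] += 1
    E_II = cII / cII.sum() if cII.sum() > 0 else np.full(n, np.nan)
    E_SI = cSI / cSI.sum() if cSI.sum() > 0 else np.full(n, np.nan)
    return E_II, E_SI, values


def aggregated_infection_rate_mc(
    net: WeightedNetwork, states: np.ndarray, phi: float, p: float
) -> dict[tuple[int, int], float]:
    """Average infection rate F_{k,m} of susceptible nodes per (k, m) class.

    For every (degree, number of infected neighbours) pair, the mean over
    susceptible nodes of their instantaneous rate: 1 if the weighted
    threshold is met, p otherwise.  Classes with no susceptible nodes are
    absent from the result.
    """
    indptr, indices, eweights = net.adjacency_csr()
    sums: dict[tuple[int, int], list[float]] = {}
    for u in range(net.N):
        if states[u] == 1:
            continue
        k = int(indptr[u + 1] - indptr[u])
        q_k = 0.0
        q_m = 0.0
        m = 0
        for idx in range(indptr[u], indptr[u + 1]):
            q_k += eweights[idx]
            if states[indices[idx]] == 1:
                q_m += eweights[idx]
                m += 1
        if k == 0:
            rate = p
        else:
            rate = 1.0 if threshold_satisfied(q_m, q_k, phi) else p
        sums.setdefault((k, m), []).append(rate)
    return {km: float(np.mean(rates)) for km, rates in sums.items()}


def brute_force_final_state(
    net: WeightedNetwork, phi: float, initial_infected: list[int]
) -> np.ndarray:
    """Deterministic absorbing state of the p=0 dynamics.

    Repeatedly infects every susceptible node whose threshold is met until
    a fixed point is reached.  Because the dynamics is monotone, the
    absorbing set is unique and independent of update order, so this is an
    exact oracle for the stochastic simulation at p=0.
    """
    state = np.zeros(net.N, dtype=np.int8)
    state[np.asarray(initial_infected, dtype=np.int64)] = 1
    q_k = net.strengths()
    changed = True
    while changed:
        changed = False
        q_m = np.zeros(net.N)
        for u, v, w in net.edges:
            if state[v] == 1:
                q_m[u] += w
            if state[u] == 1:
                q_m[v] += w
        for u in range(net.N):
            if state[u] == 0 and q_k[u] > 0 and threshold_satisfied(q_m[u], q_k[u], phi):
                state[u] = 1
                changed = True
    return state
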