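"""Approximate master equations (AMEs) for threshold dynamics on weighted networks.

The contagion is described at the level of node classes (**k**, **m**):
nodes with k_j edges of weight type j (degree vector **k**) of which m_j
lead to infected neighbours (partial degree vector **m**).  For each class
the fractions s_{k,m}(t) and i_{k,m}(t) of k-nodes that are susceptible or
infected with that **m** obey rate equations

    ds/dt = -F s - sum_j beta_s_j (k_j - m_j) s + sum_j beta_s_j (k_j - m_j + 1) s_{m - e_j}
    di/dt = +F s - sum_j beta_i_j (k_j - m_j) i + sum_j beta_i_j (k_j - m_j + 1) i_{m - e_j}

where F is the stepwise infection rate (p below threshold, 1 at or above)
and beta_s_j, beta_i_j are the mean rates at which a j-type susceptible
neighbour of a susceptible (infected) node becomes infected, computed
self-consistently from the class occupancies.

Because F is stepwise, the full system reduces *exactly* to n+1 aggregated
equations for (nu_1..nu_n, rho), where nu_j is the probability that the
neighbour across a j-type edge of a susceptible node is infected.  Both
systems are provided and must agree; the full system additionally yields
per-class observables (aggregated rates, bulk/surface edge fractions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import product

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import gammaln
from scipy.stats import norm

from .netgen import DegreeSpec, WeightScheme, bimodal_weight_values, lognormal_underlying, powerlaw_pmf

#: relative tolerance of the threshold comparison (ties count as adoption)
_TOL = 1e-12

#: refuse to build full-AME systems beyond this many classes
_MAX_CLASSES = 500_000


# --------------------------------------------------------------------------
# weight-type basis and class enumeration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class WeightTypeBasis:
    """Discretised weight distribution: n types with weights w and link
    probabilities type_prob (the chance that a random edge has each type)."""

    w: tuple[float, ...]
    type_prob: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.w) != len(self.type_prob) or len(self.w) == 0:
            raise ValueError("w and type_prob must be non-empty and equally long")
        if abs(sum(self.type_prob) - 1.0) > 1e-9:
            raise ValueError("type_prob must sum to 1")
        if any(p < 0 for p in self.type_prob):
            raise ValueError("type_prob must be non-negative")

    @property
    def n(self) -> int:
        return len(self.w)

    @property
    def mean_weight(self) -> float:
        return float(np.dot(self.w, self.type_prob))

    def z_j(self, z: float) -> np.ndarray:
        """Mean number of j-type edges per node (uncorrelated assignment)."""
        return z * np.asarray(self.type_prob)

    def permuted(self, perm: list[int]) -> "WeightTypeBasis":
        return WeightTypeBasis(
            tuple(self.w[j] for j in perm), tuple(self.type_prob[j] for j in perm)
        )


def discretise_weights(scheme: WeightScheme, n: int) -> WeightTypeBasis:
    """Discretise P(w) into an n-type basis.

    The bimodal scheme is exact with n=2 (and collapses to its mean for
    n=1).  Continuous and empirical schemes use n equal-probability
    quantile bins, each represented by its conditional mean, so the basis
    preserves the overall mean weight.
    """
    if n < 1:
        raise ValueError("need at least one weight type")
    if n == 1:
        if scheme.kind == "empirical":
            mu = float(np.mean(scheme.weight_list))
        else:
            mu = scheme.mu
        return WeightTypeBasis((mu,), (1.0,))
    if scheme.kind == "bimodal":
        if n != 2:
            raise ValueError("the bimodal scheme has exactly two types (n=2)")
        w1, w2 = bimodal_weight_values(scheme.mu, scheme.sigma, scheme.delta)
        return WeightTypeBasis((w1, w2), (scheme.delta, 1 - scheme.delta))
    if scheme.kind == "lognormal":
        m, s = lognormal_underlying(scheme.mu, scheme.sigma)
        qs = np.linspace(0, 1, n + 1)
        cuts = norm.ppf(qs[1:-1]) * s + m  # log-space bin edges
        edges = np.concatenate(([-np.inf], cuts, [np.inf]))
        # E[W | a < log W <= b] = mu * [Phi(b*) - Phi(a*)] * n with b* shifted by s
        means = []
        for a, b in zip(edges[:-1], edges[1:]):
            mass = norm.cdf((b - m) / s - s) - norm.cdf((a - m) / s - s)
            means.append(scheme.mu * mass * n)
        means = means[::-1]  # strongest type first
        return WeightTypeBasis(tuple(means), tuple([1.0 / n] * n))
    # empirical: quantile bins of the alpha-rescaled list
    arr = np.sort(np.asarray(scheme.weight_list, dtype=float))
    mu = arr.mean()
    arr = mu + scheme.alpha * (arr - mu)
    bins = np.array_split(arr, n)
    means = [float(b.mean()) for b in bins][::-1]
    probs = np.array([len(b) for b in bins], dtype=float)[::-1]
    return WeightTypeBasis(tuple(means), tuple(probs / probs.sum()))


@dataclass(frozen=True)
class ClassIndex:
    """One AME compartment: per-type degrees k_vec and infected counts m_vec."""

    k_vec: tuple[int, ...]
    m_vec: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.k_vec) != len(self.m_vec):
            raise ValueError("k_vec and m_vec must have equal length")
        if any(m < 0 or m > k for k, m in zip(self.k_vec, self.m_vec)):
            raise ValueError("need 0 <= m_j <= k_j for every type")

    @property
    def k(self) -> int:
        return sum(self.k_vec)

    @property
    def m(self) -> int:
        return sum(self.m_vec)

    def q_k(self, w) -> float:
        return float(np.dot(self.k_vec, w))

    def q_m(self, w) -> float:
        return float(np.dot(self.m_vec, w))


def _compositions(k: int, n: int):
    """All ways to split degree k into n ordered non-negative parts."""
    if n == 1:
        yield (k,)
        return
    for first in range(k + 1):
        for rest in _compositions(k - first, n - 1):
            yield (first,) + rest


@lru_cache(maxsize=None)
def _log_factorial(k: int) -> float:
    return float(gammaln(k + 1))


def _multinomial_prob(k_vec: tuple[int, ...], type_prob) -> float:
    k = sum(k_vec)
    logp = _log_factorial(k) - sum(_log_factorial(kj) for kj in k_vec)
    for kj, pj in zip(k_vec, type_prob):
        if kj > 0:
            if pj == 0:
                return 0.0
            logp += kj * math.log(pj)
    return math.exp(logp)


def enumerate_classes(
    P_k: dict[int, float], basis: WeightTypeBasis
) -> list[tuple[ClassIndex, float]]:
    """All (ClassIndex, probability) pairs for a finite degree distribution.

    Degree vectors are distributed multinomially over types (uncorrelated
    weight assignment), so P(class) = P(k) * Multinomial(k_vec; type_prob);
    summing over the m_vec copies of one k_vec recovers P(k)P(k_vec).
    """
    out: list[tuple[ClassIndex, float]] = []
    total = 0
    for k, pk in sorted(P_k.items()):
        if pk < 0:
            raise ValueError("degree probabilities must be non-negative")
        for k_vec in _compositions(k, basis.n):
            pkvec = pk * _multinomial_prob(k_vec, basis.type_prob)
            n_m = 1
            for kj in k_vec:
                n_m *= kj + 1
            total += n_m
            if total > _MAX_CLASSES:
                raise ValueError(
                    "class count exceeds the supported limit; truncate the "
                    "degree support or reduce the number of weight types"
                )
            for m_vec in product(*(range(kj + 1) for kj in k_vec)):
                out.append((ClassIndex(k_vec, m_vec), pkvec))
    return out


def infection_rate_F(cls: ClassIndex, phi: float, p: float, basis: WeightTypeBasis) -> float:
    """Stepwise infection rate: p below threshold, 1 at or above (p for k=0)."""
    if cls.k == 0:
        return p
    q_k = cls.q_k(basis.w)
    q_m = cls.q_m(basis.w)
    if q_k <= 0:
        return p
    return 1.0 if q_m >= phi * q_k - _TOL * q_k else p


# --------------------------------------------------------------------------
# degree distributions
# --------------------------------------------------------------------------

def degree_distribution(spec: DegreeSpec, tail_mass: float = 1e-6) -> dict[int, float]:
    """Finite P(k) for a degree spec, for use in the AME systems.

    Power-law supports are truncated where the retained cumulative
    probability exceeds 1 - tail_mass, then renormalised, to bound the
    class count.
    """
    if spec.kind == "regular":
        return {spec.k: 1.0}
    if spec.kind == "explicit":
        vals, counts = np.unique(np.asarray(spec.degrees), return_counts=True)
        return {int(k): c / len(spec.degrees) for k, c in zip(vals, counts)}
    support, probs = powerlaw_pmf(spec.tau, spec.k_min, spec.k_max)
    cum = np.cumsum(probs)
    cut = int(np.searchsorted(cum, 1 - tail_mass)) + 1
    support, probs = support[:cut], probs[:cut]
    probs = probs / probs.sum()
    return {int(k): float(p) for k, p in zip(support, probs)}


def mean_degree(P_k: dict[int, float]) -> float:
    return float(sum(k * p for k, p in P_k.items()))


# --------------------------------------------------------------------------
# full AME system
# --------------------------------------------------------------------------

class FullAMESystem:
    """Vectorised right-hand side of the full class-level rate equations."""

    def __init__(self, P_k: dict[int, float], basis: WeightTypeBasis,
                 phi: float, p: float):
        self.basis = basis
        self.phi = phi
        self.p = p
        classes = enumerate_classes(P_k, basis)
        C = len(classes)
        n = basis.n
        self.classes = [c for c, _ in classes]
        self.k_arr = np.array([c.k_vec for c, _ in classes], dtype=np.int64)
        self.m_arr = np.array([c.m_vec for c, _ in classes], dtype=np.int64)
        self.pk = np.array([w for _, w in classes])
        self.km = (self.k_arr - self.m_arr).astype(float)
        self.F = np.array([infection_rate_F(c, phi, p, basis) for c, _ in classes])

        index = {(c.k_vec, c.m_vec): i for i, (c, _) in enumerate(classes)}
        self.down = np.full((C, n), -1, dtype=np.int64)
        for i, (c, _) in enumerate(classes):
            for j in range(n):
                if c.m_vec[j] > 0:
                    m_down = list(c.m_vec)
                    m_down[j] -= 1
                    self.down[i, j] = index[(c.k_vec, tuple(m_down))]

        # group classes by degree vector for the normalisation identity
        groups: dict[tuple[int, ...], int] = {}
        gid = []
        for c, _ in classes:
            gid.append(groups.setdefault(c.k_vec, len(groups)))
        self.group_id = np.array(gid, dtype=np.int64)
        self.n_groups = len(groups)

    @property
    def n_classes(self) -> int:
        return len(self.pk)

    def initial_state(self) -> np.ndarray:
        """All mass susceptible at m = 0 (infinitesimal random seed)."""
        s = np.where(self.m_arr.sum(axis=1) == 0, 1.0, 0.0)
        return np.concatenate([s, np.zeros_like(s)])

    def beta_rates(self, s: np.ndarray, i: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Mean infection rates of j-type susceptible neighbours of
        susceptible (beta_s) and infected (beta_i) nodes.

        Both rates average F over *susceptible* classes, since it is the
        susceptible end of the edge that flips: an S-S edge of type j is
        one of the k_j - m_j free edges of a susceptible node, while an
        I-S edge is one of its m_j infected edges, so beta_s weights
        classes by k_j - m_j and beta_i by m_j.  A category with no mass
        gets rate 0 by convention.
        """
        if np.any(s < -1e-9) or np.any(i < -1e-9):
            raise ValueError("negative class occupancy")
        wkm = self.pk[:, None] * self.km  # (C, n)
        wm = self.pk[:, None] * self.m_arr
        den_s = wkm.T @ s
        num_s = wkm.T @ (self.F * s)
        den_i = wm.T @ s
        num_i = wm.T @ (self.F * s)
        beta_s = np.divide(num_s, den_s, out=np.zeros_like(num_s), where=den_s > 0)
        beta_i = np.divide(num_i, den_i, out=np.zeros_like(num_i), where=den_i > 0)
        return beta_s, beta_i

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        C = self.n_classes
        s, i = y[:C], y[C:]
        beta_s, beta_i = self.beta_rates(np.maximum(s, 0), np.maximum(i, 0))
        s_down = np.where(self.down >= 0, s[self.down], 0.0)
        i_down = np.where(self.down >= 0, i[self.down], 0.0)
        out_s = self.km @ beta_s          # sum_j beta_s_j (k_j - m_j)
        in_s = ((self.km + 1) * s_down) @ beta_s
        in_i = ((self.km + 1) * i_down) @ beta_i
        ds = -self.F * s - out_s * s + in_s
        di = self.F * s - (self.km @ beta_i) * i + in_i
        return np.concatenate([ds, di])

    # -- observables -------------------------------------------------------

    def rho(self, s: np.ndarray) -> float:
        return 1.0 - float(self.pk @ s)

    def nu(self, s: np.ndarray) -> np.ndarray:
        """Probability that a j-type neighbour of a susceptible node is
        infected (pooled over classes)."""
        num = (self.pk[:, None] * self.m_arr).T @ s
        den = (self.pk[:, None] * self.k_arr).T @ s
        return np.divide(num, den, out=np.zeros_like(num), where=den > 0)

    def normalisation_error(self, s: np.ndarray, i: np.ndarray) -> float:
        """Max over degree vectors of |sum_m (s + i) - 1|."""
        tot = np.bincount(self.group_id, weights=s + i, minlength=self.n_groups)
        return float(np.max(np.abs(tot - 1.0)))

    def group_sums(self, s: np.ndarray, i: np.ndarray) -> np.ndarray:
        return np.bincount(self.group_id, weights=s + i, minlength=self.n_groups)

    def aggregated_rate(self, s: np.ndarray) -> dict[tuple[int, int], float]:
        """F_{k,m}: class-occupancy-weighted mean infection rate of
        susceptible nodes, aggregated over weight configurations."""
        sums: dict[tuple[int, int], list[float]] = {}
        for idx in range(self.n_classes):
            key = (int(self.k_arr[idx].sum()), int(self.m_arr[idx].sum()))
            sums.setdefault(key, []).append(idx)
        out = {}
        for key, idxs in sums.items():
            den = float(self.pk[idxs] @ s[idxs])
            if den > 1e-14:
                num = float(self.pk[idxs] @ (self.F[idxs] * s[idxs]))
                out[key] = num / den
        return out


@dataclass
class FullAMEState:
    """Class occupancies s, i bound to their system (for the operation-level
    API; trajectories store plain arrays)."""

    system: FullAMESystem
    s: np.ndarray
    i: np.ndarray


def beta_rates(state: FullAMEState) -> tuple[np.ndarray, np.ndarray]:
    return state.system.beta_rates(state.s, state.i)


def full_ame_rhs(state: FullAMEState) -> tuple[np.ndarray, np.ndarray]:
    y = np.concatenate([state.s, state.i])
    dy = state.system.rhs(0.0, y)
    C = state.system.n_classes
    return dy[:C], dy[C:]


@dataclass
class FullAMETrajectory:
    system: FullAMESystem
    times: np.ndarray
    s: np.ndarray  # (T, C)
    i: np.ndarray  # (T, C)

    @property
    def rho(self) -> np.ndarray:
        return 1.0 - self.s @ self.system.pk

    @property
    def nu(self) -> np.ndarray:
        return np.stack([self.system.nu(st) for st in self.s])

    def normalisation_error(self) -> float:
        return max(
            self.system.normalisation_error(st, it)
            for st, it in zip(self.s, self.i)
        )


def integrate_full_ame(
    P_k: dict[int, float],
    basis: WeightTypeBasis,
    phi: float,
    p: float,
    t_max: float,
    sample_dt: float = 0.1,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    y0: np.ndarray | None = None,
) -> FullAMETrajectory:
    """Integrate the full class-level system from the infinitesimal-seed
    initial condition and sample it on a regular grid."""
    system = FullAMESystem(P_k, basis, phi, p)
    if y0 is None:
        y0 = system.initial_state()
    t_eval = np.arange(0.0, t_max + sample_dt / 2, sample_dt)
    sol = solve_ivp(
        system.rhs, (0.0, t_max), y0, t_eval=t_eval, method="LSODA",
        rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"full AME integration failed: {sol.message}")
    C = system.n_classes
    return FullAMETrajectory(system, sol.t, sol.y[:C].T.copy(), sol.y[C:].T.copy())


def ame_edge_fractions(traj: FullAMETrajectory) -> tuple[np.ndarray, np.ndarray]:
    """Bulk (E^II) and surface (E^SI) per-type edge fractions along a
    trajectory; rows are NaN while the denominator (no infected mass at
    t=0) vanishes.  Each family sums to 1 where defined."""
    sysm = traj.system
    wm = sysm.pk[:, None] * sysm.m_arr  # (C, n)
    m_tot = sysm.pk * sysm.m_arr.sum(axis=1)
    num_II = traj.i @ wm
    den_II = traj.i @ m_tot
    num_SI = traj.s @ wm
    den_SI = traj.s @ m_tot
    with np.errstate(invalid="ignore", divide="ignore"):
        E_II = np.where(den_II[:, None] > 1e-14, num_II / den_II[:, None], np.nan)
        E_SI = np.where(den_SI[:, None] > 1e-14, num_SI / den_SI[:, None], np.nan)
    return E_II, E_SI


# --------------------------------------------------------------------------
# reduced AME system
# --------------------------------------------------------------------------

def _binom_pmf(m: np.ndarray, k: np.ndarray, log_c: np.ndarray, x: float) -> np.ndarray:
    """Vectorised binomial pmf B_{k,m}(x) with exact endpoint handling."""
    if x <= 0.0:
        return (m == 0).astype(float)
    if x >= 1.0:
        return (m == k).astype(float)
    return np.exp(log_c + m * math.log(x) + (k - m) * math.log1p(-x))


class _RowTable:
    """Flattened sum over threshold-satisfying (k_vec, m_vec) classes."""

    def __init__(self, weights, K, M):
        self.w = np.asarray(weights, dtype=float)
        self.K = np.asarray(K, dtype=float)
        self.M = np.asarray(M, dtype=float)
        self.log_c = gammaln(self.K + 1) - gammaln(self.M + 1) - gammaln(self.K - self.M + 1) \
            if self.w.size else np.zeros_like(self.K)

    def __call__(self, nu: np.ndarray) -> float:
        if self.w.size == 0:
            return 0.0
        prod = np.ones(len(self.w))
        for j in range(self.K.shape[1]):
            prod *= _binom_pmf(self.M[:, j], self.K[:, j], self.log_c[:, j], nu[j])
        return float(self.w @ prod)


class ReducedAMESystem:
    """The exact n+1 dimensional reduction for stepwise infection rates.

    State (nu_1..nu_n, rho) evolves as d nu_j/dt = g_j(nu, t) - nu_j and
    d rho/dt = h(nu, t) - rho, where g_j and h are threshold-restricted
    binomial sums over classes and f_t = 1 - (1-p) e^{-pt} is the
    cumulative spontaneous-infection probability.
    """

    def __init__(self, P_k: dict[int, float], basis: WeightTypeBasis,
                 phi: float, p: float):
        self.basis = basis
        self.phi = phi
        self.p = p
        n = basis.n
        w = np.asarray(basis.w)
        z = mean_degree(P_k)
        z_j = basis.z_j(z)

        h_rows: list[tuple[float, tuple, tuple]] = []
        g_rows: list[list[tuple[float, tuple, tuple]]] = [[] for _ in range(n)]
        for k, pk in sorted(P_k.items()):
            if k == 0 or pk == 0:
                continue  # isolated nodes only infect spontaneously (via f_t)
            for k_vec in _compositions(k, n):
                pkv = pk * _multinomial_prob(k_vec, basis.type_prob)
                if pkv == 0:
                    continue
                q_k = float(np.dot(k_vec, w))
                thr = phi * q_k - _TOL * q_k
                for m_vec in product(*(range(kj + 1) for kj in k_vec)):
                    if float(np.dot(m_vec, w)) >= thr:
                        h_rows.append((pkv, k_vec, m_vec))
                for j in range(n):
                    if k_vec[j] == 0 or z_j[j] == 0:
                        continue
                    wt = pkv * k_vec[j] / z_j[j]
                    ranges = [
                        range(kj) if jj == j else range(kj + 1)
                        for jj, kj in enumerate(k_vec)
                    ]
                    k_red = tuple(
                        kj - 1 if jj == j else kj for jj, kj in enumerate(k_vec)
                    )
                    for m_vec in product(*ranges):
                        if float(np.dot(m_vec, w)) >= thr:
                            g_rows[j].append((wt, k_red, m_vec))

        self.h_table = _RowTable(
            [r[0] for r in h_rows], [r[1] for r in h_rows] or np.zeros((0, n)),
            [r[2] for r in h_rows] or np.zeros((0, n)),
        )
        self.g_tables = [
            _RowTable(
                [r[0] for r in rows], [r[1] for r in rows] or np.zeros((0, n)),
                [r[2] for r in rows] or np.zeros((0, n)),
            )
            for rows in g_rows
        ]

    def f_t(self, t: float) -> float:
        """Probability that a node has been spontaneously infected by t."""
        return 1.0 - (1.0 - self.p) * math.exp(-self.p * t)

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        n = self.basis.n
        nu = np.clip(y[:n], 0.0, 1.0)
        rho = y[n]
        f = self.f_t(t)
        g = np.array([f + (1 - f) * tab(nu) for tab in self.g_tables])
        h = f + (1 - f) * self.h_table(nu)
        return np.concatenate([g - nu, [h - rho]])


@dataclass
class ReducedState:
    """Aggregated state: per-type neighbour infection probabilities nu and
    the infected density rho."""

    nu: np.ndarray
    rho: float


def reduced_rhs(
    state: ReducedState, t: float, P_k: dict[int, float],
    basis: WeightTypeBasis, phi: float, p: float,
) -> tuple[np.ndarray, float]:
    """Time derivative (d nu, d rho) of the reduced system at one point."""
    system = ReducedAMESystem(P_k, basis, phi, p)
    dy = system.rhs(t, np.concatenate([state.nu, [state.rho]]))
    return dy[:-1], float(dy[-1])


@dataclass
class ReducedTrajectory:
    times: np.ndarray
    nu: np.ndarray  # (T, n)
    rho: np.ndarray


def integrate_reduced(
    P_k: dict[int, float],
    basis: WeightTypeBasis,
    phi: float,
    p: float,
    t_max: float,
    sample_dt: float = 0.1,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    y0: np.ndarray | None = None,
) -> ReducedTrajectory:
    """Integrate the reduced system from (nu, rho) = (0, 0)."""
    system = ReducedAMESystem(P_k, basis, phi, p)
    n = basis.n
    if y0 is None:
        y0 = np.zeros(n + 1)
    t_eval = np.arange(0.0, t_max + sample_dt / 2, sample_dt)
    sol = solve_ivp(
        system.rhs, (0.0, t_max), y0, t_eval=t_eval, method="LSODA",
        rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"reduced AME integration failed: {sol.message}")
    return ReducedTrajectory(sol.t, sol.y[:n].T.copy(), sol.y[n].copy())
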