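"""Cascade-speed observables and (sigma, phi) parameter-space analysis.

* t_a — absolute time of cascade emergence: first time the infected
  density reaches a target (0.75 by default).
* t_r — relative time versus the unweighted (sigma = 0) run at the same
  threshold: positive means weights accelerate the cascade.
* Combinatorial phase boundaries: the threshold rule holds with equality
  on curves phi = (m.w)/(k.w) in the (sigma, phi) plane, one per
  (k_vec, m_vec) class; crossing such a curve flips the infection rate of
  that class between p and 1, which partitions the plane into regions of
  slow and fast cascades.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ame, mc, netgen
from .netgen import DegreeSpec, WeightScheme


# --------------------------------------------------------------------------
# cascade times
# --------------------------------------------------------------------------

def absolute_time(series, rho_target: float = 0.75) -> float:
    """First time the infected density reaches ``rho_target``.

    Accepts any object with ``times`` and ``rho`` attributes (Monte Carlo
    time series or AME trajectories) or a (times, rho) pair.  The crossing
    is linearly interpolated between samples; ``inf`` flags a partial
    cascade that never reaches the target.
    """
    if hasattr(series, "rho"):
        times, rho = np.asarray(series.times), np.asarray(series.rho)
    else:
        times, rho = (np.asarray(a, dtype=float) for a in series)
    if len(times) == 0:
        raise ValueError("empty time series")
    if rho[0] >= rho_target:
        return float(times[0])
    above = np.nonzero(rho >= rho_target)[0]
    if len(above) == 0:
        return math.inf
    i = int(above[0])
    t0, t1 = times[i - 1], times[i]
    r0, r1 = rho[i - 1], rho[i]
    return float(t0 + (rho_target - r0) / (r1 - r0) * (t1 - t0))


def relative_time(t_a_unweighted: float, t_a_weighted: float) -> float:
    """t_r = (t_a(0, phi) - t_a(sigma, phi)) / t_a(0, phi).

    Positive when the weighted dynamics is faster than the unweighted one.
    """
    if not math.isfinite(t_a_unweighted) or t_a_unweighted <= 0:
        raise ValueError("the unweighted reference time must be finite and positive")
    return (t_a_unweighted - t_a_weighted) / t_a_unweighted


# --------------------------------------------------------------------------
# combinatorial boundaries
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BoundarySpec:
    """One (k_vec, m_vec) class of a bimodal (two-type) network, whose
    threshold-equality curve is a boundary in the (sigma, phi) plane."""

    k_vec: tuple[int, int]
    m_vec: tuple[int, int]
    mu: float = 1.0
    delta: float = 0.5

    def __post_init__(self) -> None:
        if any(m < 0 or m > k for k, m in zip(self.k_vec, self.m_vec)):
            raise ValueError("need 0 <= m_j <= k_j")

    def sigma_max(self) -> float:
        return self.mu * math.sqrt((1 - self.delta) / self.delta)

    def _coefficients(self) -> tuple[float, float, float, float]:
        """phi(sigma) = (a + b*sigma) / (c + d*sigma)."""
        A = math.sqrt((1 - self.delta) / self.delta)
        B = math.sqrt(self.delta / (1 - self.delta))
        k1, k2 = self.k_vec
        m1, m2 = self.m_vec
        return (
            self.mu * (m1 + m2),
            m1 * A - m2 * B,
            self.mu * (k1 + k2),
            k1 * A - k2 * B,
        )


def boundary_phi(spec: BoundarySpec, sigma: float) -> float:
    """Threshold value on the class boundary: phi = (m.w) / (k.w)."""
    if not 0 <= sigma <= spec.sigma_max() * (1 + 1e-12):
        raise ValueError("sigma outside the valid bimodal range")
    a, b, c, d = spec._coefficients()
    den = c + d * sigma
    if abs(den) < 1e-300:
        raise ValueError("k.w vanishes: boundary undefined")
    return (a + b * sigma) / den


def boundary_sigma(spec: BoundarySpec, phi: float) -> float | None:
    """Invert the boundary curve: sigma at which the class sits exactly on
    its threshold, or None when no solution lies in [0, sigma_max]."""
    if not 0 < phi < 1:
        raise ValueError("phi must lie in (0, 1)")
    a, b, c, d = spec._coefficients()
    den = b - phi * d
    smax = spec.sigma_max()
    if abs(den) < 1e-14:
        return 0.0 if abs(phi * c - a) < 1e-14 else None
    sigma = (phi * c - a) / den
    if -1e-12 <= sigma <= smax + 1e-12:
        return float(min(max(sigma, 0.0), smax))
    return None


@dataclass
class BoundaryCurve:
    """A deduplicated boundary curve with every class that produces it."""

    labels: list[tuple[tuple[int, int], tuple[int, int]]]
    sigma: np.ndarray
    phi: np.ndarray
    specs: list[BoundarySpec] = field(default_factory=list)


def enumerate_boundaries(
    k,
    mu: float = 1.0,
    delta: float = 0.5,
    sigma_range: tuple[float, float] = (0.0, 1.0),
    phi_range: tuple[float, float] = (0.0, 1.0),
    n_samples: int = 101,
) -> list[BoundaryCurve]:
    """All class boundary curves of degree(s) k intersecting the window.

    Curves that coincide as rational functions of sigma (different classes,
    identical boundary) are merged and carry every contributing label.
    """
    degrees = [k] if np.isscalar(k) else sorted(set(int(d) for d in k))
    smax = mu * math.sqrt((1 - delta) / delta)
    lo = max(sigma_range[0], 0.0)
    hi = min(sigma_range[1], smax)
    if hi < lo:
        return []
    sigma = np.linspace(lo, hi, n_samples)
    curves: dict[tuple, BoundaryCurve] = {}
    for deg in degrees:
        for k1 in range(deg + 1):
            k2 = deg - k1
            for m1 in range(k1 + 1):
                for m2 in range(k2 + 1):
                    if m1 == m2 == 0:
                        continue
                    spec = BoundarySpec((k1, k2), (m1, m2), mu, delta)
                    a, b, c, d = spec._coefficients()
                    with np.errstate(divide="ignore", invalid="ignore"):
                        phi = (a + b * sigma) / (c + d * sigma)
                    inside = np.isfinite(phi) & (phi >= phi_range[0]) \
                        & (phi <= phi_range[1]) & (phi > 0) & (phi < 1)
                    if not inside.any():
                        continue
                    coeff = np.array([a, b, c, d])
                    coeff = coeff / np.linalg.norm(coeff)
                    nz = coeff[np.abs(coeff) > 1e-12]
                    if len(nz) and nz[0] < 0:
                        coeff = -coeff
                    key = tuple(np.round(coeff, 9))
                    if key in curves:
                        curves[key].labels.append((spec.k_vec, spec.m_vec))
                        curves[key].specs.append(spec)
                    else:
                        curves[key] = BoundaryCurve(
                            [(spec.k_vec, spec.m_vec)], sigma.copy(), phi, [spec]
                        )
    return list(curves.values())


# --------------------------------------------------------------------------
# parameter sweeps
# --------------------------------------------------------------------------

def _ame_t_a(
    P_k: dict[int, float], sigma: float, phi: float, mu: float, delta: float,
    p: float, rho_target: float, t_max: float,
) -> float:
    if sigma == 0:
        basis = ame.WeightTypeBasis((mu,), (1.0,))
    else:
        basis = ame.discretise_weights(
            WeightScheme("bimodal", mu=mu, sigma=sigma, delta=delta), 2
        )
    traj = ame.integrate_reduced(P_k, basis, phi, p, t_max)
    return absolute_time(traj, rho_target)


def parameter_sweep(
    degree_spec: DegreeSpec,
    sigma_values,
    phi_values,
    mu: float = 1.0,
    delta: float = 0.5,
    p: float = 2e-4,
    engine: str = "ame",
    reps: int = 25,
    seed: int = 0,
    rho_target: float = 0.75,
    t_max: float = 300.0,
) -> pd.DataFrame:
    """t_a and t_r over a (sigma, phi) grid, by Monte Carlo or AME engine.

    The sigma = 0 reference for t_r is always computed with the same engine
    and, for Monte Carlo, on the same topology realisations (shared seeds)
    as the weighted runs, which cancels realisation noise in t_r.  Cells
    whose cascade never reaches the target within the window carry
    ``t_a = inf`` and are excluded from t_r.

    Returns a long-format frame with columns sigma, phi, t_a, t_r, n_finite.
    """
    sigma_values = [float(s) for s in sigma_values]
    phi_values = [float(f) for f in phi_values]
    all_sigmas = sorted(set(sigma_values) | {0.0})

    if engine == "ame":
        P_k = ame.degree_distribution(degree_spec)
        t_a_grid = {
            (s, f): _ame_t_a(P_k, s, f, mu, delta, p, rho_target, t_max)
            for s in all_sigmas
            for f in phi_values
        }
        n_finite = {cell: 1 for cell in t_a_grid}
    elif engine == "mc":
        base = np.random.SeedSequence(seed)
        children = base.spawn(reps)
        samples: dict[tuple[float, float], list[float]] = {
            (s, f): [] for s in all_sigmas for f in phi_values
        }
        for rep, child in enumerate(children):
            topo_seed, weight_seed, run_seed = (
                int(x) for x in child.generate_state(3) % (2**31)
            )
            degrees = netgen.sample_degree_sequence(degree_spec, topo_seed)
            topo = netgen.build_configuration_model(degrees, topo_seed)
            for si, s in enumerate(all_sigmas):
                if s == 0:
                    net = topo.with_weights(np.full(topo.n_edges, mu))
                else:
                    scheme = WeightScheme("bimodal", mu=mu, sigma=s, delta=delta)
                    net = netgen.assign_weights(topo, scheme, weight_seed + si)
                for fi, f in enumerate(phi_values):
                    cfg = mc.SimConfig(
                        phi=f, p=p, t_max=t_max, rho_stop=min(1.0, rho_target),
                        seed=(run_seed + 1000 * si + fi) % (2**31),
                    )
                    series = mc.run_mc(net, cfg)
                    samples[(s, f)].append(absolute_time(series, rho_target))
        t_a_grid = {}
        n_finite = {}
        for cell, vals in samples.items():
            finite = [v for v in vals if math.isfinite(v)]
            n_finite[cell] = len(finite)
            # a cell counts as cascading only if most realisations reach the target
            t_a_grid[cell] = float(np.mean(finite)) if len(finite) > reps / 2 else math.inf
    else:
        raise ValueError(f"unknown engine {engine!r}")

    rows = []
    for f in phi_values:
        ref = t_a_grid[(0.0, f)]
        for s in sigma_values:
            t_a = t_a_grid[(s, f)]
            if math.isfinite(ref) and ref > 0 and math.isfinite(t_a):
                t_r = relative_time(ref, t_a)
            else:
                t_r = math.nan
            rows.append(
                {"sigma": s, "phi": f, "t_a": t_a, "t_r": t_r,
                 "n_finite": n_finite[(s, f)]}
            )
    return pd.DataFrame(rows)
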