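"""AME systems: discretisation, class bookkeeping, full and reduced dynamics."""

import math
from itertools import product

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.stats import binom

from wtcascade import (
    ClassIndex,
    WeightScheme,
    WeightTypeBasis,
    ame_edge_fractions,
    beta_rates,
    discretise_weights,
    enumerate_classes,
    full_ame_rhs,
    infection_rate_F,
    integrate_full_ame,
    integrate_reduced,
    reduced_rhs,
)
from wtcascade.ame import FullAMESystem, FullAMEState, ReducedState

PHI = 0.25
P = 2e-4


# --------------------------------------------------------------------------
# discretisation
# --------------------------------------------------------------------------

def test_discretise_bimodal_exact():
    basis = discretise_weights(WeightScheme("bimodal", 1.0, 0.5, 0.5), 2)
    assert basis.w == pytest.approx((1.5, 0.5))
    assert basis.type_prob == pytest.approx((0.5, 0.5))


def test_discretise_single_type_collapses_to_mean():
    basis = discretise_weights(WeightScheme("lognormal", 2.0, 0.5), 1)
    assert basis.w == (2.0,) and basis.type_prob == (1.0,)


def test_discretise_lognormal_preserves_mean():
    basis = discretise_weights(WeightScheme("lognormal", 1.0, 0.5), 10)
    assert basis.mean_weight == pytest.approx(1.0, abs=1e-3)
    assert all(w > 0 for w in basis.w)
    assert list(basis.w) == sorted(basis.w, reverse=True)


def test_discretise_empirical_quantile_bins():
    scheme = WeightScheme("empirical", weight_list=tuple(range(1, 101)), alpha=1.0)
    basis = discretise_weights(scheme, 4)
    assert basis.mean_weight == pytest.approx(50.5)
    with pytest.raises(ValueError):
        discretise_weights(scheme, 0)


# --------------------------------------------------------------------------
# class enumeration and rates
# --------------------------------------------------------------------------

def test_class_count_regular_two_types(benchmark_basis):
    classes = enumerate_classes({7: 1.0}, benchmark_basis)
    # sum over k1 of (k1+1)(8-k1) = 120
    assert len(classes) == sum((k1 + 1) * (8 - k1) for k1 in range(8)) == 120


def test_degree_vector_probability_is_binomial(benchmark_basis):
    classes = enumerate_classes({7: 1.0}, benchmark_basis)
    probs = {c.k_vec: p for c, p in classes}
    assert probs[(2, 5)] == pytest.approx(math.comb(7, 2) / 2**7)
    # P(k_vec) sums to 1 over degree vectors of the (single) degree
    assert sum(probs.values()) == pytest.approx(1.0)


def test_single_type_classes_are_k_m_pairs():
    basis = WeightTypeBasis((1.0,), (1.0,))
    classes = enumerate_classes({3: 1.0}, basis)
    assert [(c.k_vec[0], c.m_vec[0]) for c, _ in classes] == [
        (3, m) for m in range(4)
    ]


def test_infection_rate_examples():
    basis = discretise_weights(WeightScheme("bimodal", 1.0, 0.7, 0.5), 2)
    assert infection_rate_F(ClassIndex((0, 0), (0, 0)), PHI, P, basis) == P
    # one strong infected neighbour: 1.7 >= 0.25 * 3.5
    assert infection_rate_F(ClassIndex((1, 6), (1, 0)), PHI, P, basis) == 1.0
    assert infection_rate_F(ClassIndex((3, 2), (0, 0)), PHI, P, basis) == P


def test_class_index_invariants():
    with pytest.raises(ValueError):
        ClassIndex((2, 1), (3, 0))
    cls = ClassIndex((2, 5), (1, 2))
    assert cls.k == 7 and cls.m == 3
    assert cls.q_k((1.5, 0.5)) == pytest.approx(5.5)
    assert cls.q_m((1.5, 0.5)) == pytest.approx(2.5)


# --------------------------------------------------------------------------
# full AME right-hand side
# --------------------------------------------------------------------------

def test_beta_rates_at_t0(benchmark_P_k, benchmark_basis):
    """All mass susceptible at m=0: beta_s = p per type, beta_i = 0 by the
    zero-denominator convention."""
    system = FullAMESystem(benchmark_P_k, benchmark_basis, PHI, P)
    y0 = system.initial_state()
    C = system.n_classes
    state = FullAMEState(system, y0[:C], y0[C:])
    beta_s, beta_i = beta_rates(state)
    assert beta_s == pytest.approx([P, P])
    assert beta_i == pytest.approx([0.0, 0.0])


def test_full_rhs_conserves_class_mass(benchmark_P_k, benchmark_basis):
    """Per degree vector, sum_m d(s+i)/dt = 0 (telescoping fluxes)."""
    system = FullAMESystem(benchmark_P_k, benchmark_basis, PHI, P)
    rng = np.random.default_rng(0)
    s = rng.random(system.n_classes)
    i = rng.random(system.n_classes)
    tot = system.group_sums(s, i)
    norm = tot[system.group_id]
    state = FullAMEState(system, s / norm, i / norm)
    ds, di = full_ame_rhs(state)
    group_flux = np.bincount(system.group_id, weights=ds + di)
    assert np.max(np.abs(group_flux)) < 1e-12


def test_full_rhs_t0_outflow(benchmark_P_k, benchmark_basis):
    """At t=0 the m=0 class of each degree vector drains at p*(1+k)."""
    system = FullAMESystem(benchmark_P_k, benchmark_basis, PHI, P)
    y0 = system.initial_state()
    C = system.n_classes
    state = FullAMEState(system, y0[:C], y0[C:])
    ds, di = full_ame_rhs(state)
    for idx in range(C):
        if state.s[idx] == 1.0:  # an m=0 class
            k = system.k_arr[idx].sum()
            assert ds[idx] == pytest.approx(-P * (1 + k))


def test_all_susceptible_absorbing_when_p_zero(benchmark_P_k, benchmark_basis):
    system = FullAMESystem(benchmark_P_k, benchmark_basis, PHI, 0.0)
    dy = system.rhs(0.0, system.initial_state())
    assert np.max(np.abs(dy)) == 0.0


# --------------------------------------------------------------------------
# integration: full, reduced, and their agreement
# --------------------------------------------------------------------------

@pytest.fixture(scope="module")
def benchmark_full_traj(benchmark_P_k, benchmark_basis):
    return integrate_full_ame(benchmark_P_k, benchmark_basis, PHI, P, 50.0)


def test_full_integration_normalised(benchmark_full_traj):
    assert benchmark_full_traj.normalisation_error() < 1e-6


def test_initial_growth_rate_is_p(benchmark_full_traj):
    rho = benchmark_full_traj.rho
    t = benchmark_full_traj.times
    assert rho[0] == pytest.approx(0.0, abs=1e-12)
    assert (rho[1] - rho[0]) / (t[1] - t[0]) == pytest.approx(P, rel=0.05)


def test_states_stay_in_unit_interval(benchmark_full_traj):
    assert benchmark_full_traj.s.min() > -1e-9
    assert benchmark_full_traj.i.min() > -1e-9
    assert benchmark_full_traj.s.max() < 1 + 1e-9


def test_reduced_equals_full(benchmark_P_k, benchmark_basis, benchmark_full_traj):
    """The n+1 dimensional reduction is exact for the stepwise rate."""
    red = integrate_reduced(benchmark_P_k, benchmark_basis, PHI, P, 50.0)
    assert np.max(np.abs(benchmark_full_traj.rho - red.rho)) < 1e-4


def test_reduced_monotone(benchmark_P_k, benchmark_basis):
    red = integrate_reduced(benchmark_P_k, benchmark_basis, PHI, P, 200.0)
    assert np.all(np.diff(red.rho) >= -1e-9)
    assert np.all(np.diff(red.nu, axis=0) >= -1e-9)
    assert red.rho[-1] > 0.99  # full cascade on this benchmark


def test_reduced_rhs_at_origin(benchmark_P_k, benchmark_basis):
    """At (nu, rho) = (0, 0): no class with m=0 meets a positive threshold,
    so d(rho)/dt = f_0 = p."""
    dnu, drho = reduced_rhs(
        ReducedState(np.zeros(2), 0.0), 0.0, benchmark_P_k, benchmark_basis, PHI, P
    )
    assert drho == pytest.approx(P)
    assert dnu == pytest.approx([P, P])


def test_all_infected_is_fixed_point(benchmark_P_k, benchmark_basis):
    dnu, drho = reduced_rhs(
        ReducedState(np.ones(2), 1.0), 10.0, benchmark_P_k, benchmark_basis, PHI, P
    )
    assert np.max(np.abs(dnu)) < 1e-12 and abs(drho) < 1e-12


def test_reduced_n1_matches_independent_watts_solver(benchmark_P_k):
    """n=1 (unweighted) limit against an independently coded solver of the
    classic dynamic cascade equations with threshold ceil(phi*k)."""
    k, z, phi, p = 7, 7.0, PHI, P
    M = math.ceil(phi * k)  # 2 infected neighbours needed

    def rhs(t, y):
        nu, rho = y
        f = 1 - (1 - p) * math.exp(-p * t)
        g = f + (1 - f) * sum(
            binom.pmf(m, k - 1, nu) for m in range(M, k)
        ) * (k / z)
        h = f + (1 - f) * sum(binom.pmf(m, k, nu) for m in range(M, k + 1))
        return [g - nu, h - rho]

    t_eval = np.linspace(0, 120, 241)
    oracle = solve_ivp(rhs, (0, 120), [0.0, 0.0], t_eval=t_eval,
                       rtol=1e-8, atol=1e-10, method="LSODA")
    basis = WeightTypeBasis((1.0,), (1.0,))
    red = integrate_reduced(benchmark_P_k, basis, phi, p, 120.0, sample_dt=0.5)
    assert np.max(np.abs(red.rho - oracle.y[1])) < 1e-6


def test_sigma_zero_limit_independent_of_delta_and_n(benchmark_P_k):
    """sigma=0: the two-type system collapses onto the unweighted solution
    for any delta."""
    ref = integrate_reduced(
        benchmark_P_k, WeightTypeBasis((1.0,), (1.0,)), PHI, P, 80.0
    )
    for delta in (0.2, 0.5, 0.8):
        basis = WeightTypeBasis((1.0, 1.0), (delta, 1 - delta))
        red = integrate_reduced(benchmark_P_k, basis, PHI, P, 80.0)
        assert np.max(np.abs(red.rho - ref.rho)) < 1e-7


def test_label_permutation_symmetry(benchmark_P_k, benchmark_basis):
    perm = benchmark_basis.permuted([1, 0])
    a = integrate_reduced(benchmark_P_k, benchmark_basis, PHI, P, 60.0)
    b = integrate_reduced(benchmark_P_k, perm, PHI, P, 60.0)
    assert np.max(np.abs(a.rho - b.rho)) < 1e-7
    assert np.max(np.abs(a.nu - b.nu[:, ::-1])) < 1e-7


# --------------------------------------------------------------------------
# edge fractions
# --------------------------------------------------------------------------

def test_edge_fractions_unweighted_symmetric(benchmark_P_k):
    """sigma=0, delta=0.5: strong/weak labels are interchangeable, so
    E_II = E_SI = 1/2 wherever defined."""
    basis = WeightTypeBasis((1.0, 1.0), (0.5, 0.5))
    traj = integrate_full_ame(benchmark_P_k, basis, PHI, P, 40.0)
    E_II, E_SI = ame_edge_fractions(traj)
    assert np.nanmax(np.abs(E_II - 0.5)) < 1e-9
    assert np.nanmax(np.abs(E_SI - 0.5)) < 1e-9


def test_edge_fractions_single_type(benchmark_P_k):
    traj = integrate_full_ame(
        benchmark_P_k, WeightTypeBasis((1.0,), (1.0,)), PHI, P, 30.0
    )
    E_II, E_SI = ame_edge_fractions(traj)
    assert np.nanmax(np.abs(E_II - 1.0)) < 1e-9
    assert np.nanmax(np.abs(E_SI - 1.0)) < 1e-9


def test_edge_fractions_sum_to_one(benchmark_full_traj):
    E_II, E_SI = ame_edge_fractions(benchmark_full_traj)
    defined = ~np.isnan(E_II[:, 0])
    assert np.max(np.abs(E_II[defined].sum(axis=1) - 1)) < 1e-9
    defined = ~np.isnan(E_SI[:, 0])
    assert np.max(np.abs(E_SI[defined].sum(axis=1) - 1)) < 1e-9


def test_strong_ties_dominate_cascade_bulk(benchmark_P_k):
    """Accelerative regime (phi=0.25, sigma=0.7): strong links make up most
    of the infected cluster's interior while weak links dominate its
    surface."""
    basis = discretise_weights(WeightScheme("bimodal", 1.0, 0.7, 0.5), 2)
    traj = integrate_full_ame(benchmark_P_k, basis, PHI, P, 80.0)
    E_II, E_SI = ame_edge_fractions(traj)
    rho = traj.rho
    during = (rho > 0.05) & (rho < 0.7)
    assert np.all(E_II[during, 0] > 0.5)
    assert np.all(E_SI[during, 0] < 0.5)
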