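"""Model reduction: feasibility, closed-form map, numerical matching, MLE."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from txmodels import (
    InfeasibleReduction,
    MechanisticParams,
    SimulationConfig,
    TwoStateParams,
    build_chain,
    delta,
    effective_two_state,
    fast_switching_limit,
    is_reducible,
    match_number_moments,
    match_refractory,
    mle_fit_two_state,
    randomness_mechanistic,
    randomness_refractory,
    simulate_params,
    waiting_lt,
    waiting_moments,
)
from txmodels.reduction import _damped_newton, _two_state_number_moments

rates = st.floats(min_value=1e-3, max_value=1e3)


def test_delta_reference_values(fixtures):
    assert delta(fixtures["mapped_a"]) == pytest.approx(0.254, abs=1e-12)
    assert delta(fixtures["mapped_b"]) == pytest.approx(0.008, abs=1e-12)
    tiny_a = MechanisticParams(a=1e-9, a_rev=1.0, b=1.0, b_rev=0.3, c=0.5, d=1, tau=1)
    assert delta(tiny_a) == pytest.approx(0.8, abs=1e-8)


def test_reducibility_flags(fixtures):
    for name in ("mapped_a", "mapped_b", "mapped_c"):
        assert is_reducible(fixtures[name]) == (True, True)
    p = MechanisticParams(a=0.144, a_rev=0.032, b=0.1, b_rev=0.05, c=0.05, d=0.01, tau=1)
    assert is_reducible(p) == (False, False)  # (a/a')(a+a') = 0.792 > b'+c


@settings(max_examples=200, deadline=None)
@given(a=rates, ar=rates, b=rates, br=rates, c=rates)
def test_delta_sign_is_equivalent_to_randomness_threshold(a, ar, b, br, c):
    from hypothesis import assume

    p = MechanisticParams(a=a, a_rev=ar, b=b, b_rev=br, c=c, d=1.0, tau=1.0)
    # both sides of the equivalence round differently within a few ulps of
    # the Delta = 0 boundary; test it at points that are meaningfully off it
    assume(abs(delta(p)) > 1e-12 * (br + c + a + a**2 / ar))
    assert (delta(p) >= 0) == (randomness_mechanistic(p) >= 1.0)
    assert (delta(p) >= 0) == is_reducible(p)[0]


@pytest.mark.parametrize(
    "name, field, printed, digits",
    [
        ("mapped_b", "sigma_u", 3.8e-8, 2),
        ("mapped_c", "sigma_u", 0.012, 2),
        ("mapped_a", "sigma_b", 0.001, 1),
        ("mapped_c", "sigma_b", 0.029, 2),
        ("mapped_a", "rho", 0.092, 2),
        ("mapped_b", "rho", 0.004, 1),
    ],
)
def test_effective_map_matches_reported_values(fixtures, name, field, printed, digits):
    q = effective_two_state(fixtures[name])
    value = getattr(q, field)
    rounded = float(f"%.{digits - 1}e" % value)
    assert rounded == pytest.approx(printed, rel=1e-12)


def test_infeasible_map_raises():
    p = MechanisticParams(a=0.144, a_rev=0.032, b=0.1, b_rev=0.05, c=0.05, d=0.01, tau=1)
    with pytest.raises(InfeasibleReduction):
        effective_two_state(p)


def test_map_variant_inherits_downstream_parameter(fixtures):
    p = fixtures["mapped_c"]
    assert effective_two_state(p, variant="telegraph").d == p.d
    assert effective_two_state(p, variant="delay_telegraph").tau == p.tau


moderate_rates = st.floats(min_value=1e-2, max_value=1e2)


@settings(max_examples=60, deadline=None)
@given(a=moderate_rates, ar=moderate_rates, b=moderate_rates, br=moderate_rates, c=moderate_rates)
def test_three_moment_round_trip(a, ar, b, br, c):
    # four decades of rate stiffness: the float64 conditioning of the
    # polynomial first-passage algebra supports the 1e-9 contract here;
    # more extreme ratios degrade gracefully toward ~1e-8
    p = MechanisticParams(a=a, a_rev=ar, b=b, b_rev=br, c=c, d=1.0, tau=1.0)
    if delta(p) <= 0:
        return
    q = effective_two_state(p)
    mm = waiting_moments(waiting_lt(build_chain(p)), order=3)
    qm = waiting_moments(waiting_lt(build_chain(q)), order=3)
    assert qm.m1 == pytest.approx(mm.m1, rel=1e-9)
    assert qm.m2 == pytest.approx(mm.m2, rel=1e-9)
    assert qm.m3 == pytest.approx(mm.m3, rel=1e-9)


def test_map_is_homogeneous_of_degree_one(fixtures):
    p = fixtures["mapped_c"]
    lam = 3.7
    scaled = MechanisticParams(a=lam * p.a, a_rev=lam * p.a_rev, b=lam * p.b,
                               b_rev=lam * p.b_rev, c=lam * p.c, d=p.d, tau=p.tau)
    q, qs = effective_two_state(p), effective_two_state(scaled)
    for f in ("rho", "sigma_u", "sigma_b"):
        assert getattr(qs, f) == pytest.approx(lam * getattr(q, f), rel=1e-12)


def test_fast_switching_limit_values():
    p = MechanisticParams(a=0.01, a_rev=0.02, b=100.0, b_rev=50.0, c=10.0, d=1, tau=1)
    q = fast_switching_limit(p)
    assert q.sigma_b == pytest.approx(0.01)
    assert q.sigma_u == pytest.approx(0.0066667, abs=1e-6)
    assert q.rho == pytest.approx(6.6667, abs=1e-3)
    small_br = fast_switching_limit(
        MechanisticParams(a=0.01, a_rev=0.02, b=100.0, b_rev=1e-12, c=10.0, d=1, tau=1)
    )
    assert small_br.rho == pytest.approx(10.0, rel=1e-10)
    assert small_br.sigma_u == pytest.approx(0.0, abs=1e-13)


def test_effective_map_converges_to_fast_switching_limit():
    base = dict(a=0.01, a_rev=0.02, c=10.0, d=1.0, tau=1.0)
    gamma_c = 0.5
    errors = []
    for b in (10.0, 100.0, 1000.0):
        p = MechanisticParams(b=b, b_rev=gamma_c * b, **base)
        q, limit = effective_two_state(p), fast_switching_limit(p)
        errors.append(
            max(
                abs(q.rho / limit.rho - 1),
                abs(q.sigma_u / limit.sigma_u - 1),
                abs(q.sigma_b / limit.sigma_b - 1),
            )
        )
    assert errors[0] > errors[1] > errors[2]
    assert errors[2] < 0.02


def test_boundary_map_is_constitutive():
    a, ar = 0.05, 0.02
    c, b = 0.1, 0.3
    br = a + a**2 / ar - c  # Delta = 0 exactly
    p = MechanisticParams(a=a, a_rev=ar, b=b, b_rev=br, c=c, d=1.0, tau=1.0)
    q = effective_two_state(p)
    assert q.sigma_u == pytest.approx(0.0, abs=1e-20)


# ---------------------------------------------------------------------------
# numerical number-moment matching


def test_number_moment_matcher_recovers_two_state_parameters():
    """Self-consistency: target moments generated from a known two-state model."""
    truth = TwoStateParams(rho=0.2, sigma_u=0.02, sigma_b=0.05, tau=60.0)
    target = _two_state_number_moments(truth)

    def residual(x):
        q = TwoStateParams(rho=np.exp(x[0]), sigma_u=np.exp(x[1]), sigma_b=np.exp(x[2]), tau=60.0)
        return (_two_state_number_moments(q) - target) / target

    x0 = np.log([0.3, 0.03, 0.03])
    x, r, _, converged = _damped_newton(residual, x0)
    assert converged
    np.testing.assert_allclose(np.exp(x), [truth.rho, truth.sigma_u, truth.sigma_b], rtol=1e-6)


def test_active_moment_matching_converges_inside_feasible_region(fixtures):
    res = match_number_moments(fixtures["mapped_c"], species="active")
    assert res.diagnostics["converged"]
    assert np.abs(res.diagnostics["residuals"]).max() < 1e-8
    assert res.mapped is not None and res.mapped.variant == "delay_telegraph"


def test_moment_matching_flags_infeasible_sets(fixtures):
    res = match_number_moments(fixtures["benchmark_2"], species="active")  # Delta < 0
    assert not res.feasible_waiting
    assert not res.diagnostics["converged"]
    assert res.mapped is None


# ---------------------------------------------------------------------------
# maximum likelihood


def test_mle_recovers_telegraph_parameters_from_samples():
    truth = TwoStateParams(rho=0.5, sigma_u=0.05, sigma_b=0.1, d=0.02)
    s = simulate_params(truth, SimulationConfig(n_samples=10_000, seed=42))
    res = mle_fit_two_state(s, species="mature", d=truth.d, seed=0)
    for f in ("rho", "sigma_u", "sigma_b"):
        assert getattr(res.mapped, f) == pytest.approx(getattr(truth, f), rel=0.20)
    assert res.diagnostics["hellinger"] < 0.05


def test_mle_on_mechanistic_samples_yields_close_distribution(fixtures):
    """Fitting a delay-telegraph model to mechanistic active Pol II samples
    from a reducible set lands within a small Hellinger distance of the
    exact mechanistic distribution."""
    from txmodels import active_distribution

    p = fixtures["mapped_c"]
    s = simulate_params(p, SimulationConfig(n_samples=4000, seed=7))
    ref = active_distribution(p)
    res = mle_fit_two_state(
        s, species="active", tau=p.tau, seed=0,
        init=effective_two_state(p), reference=ref,
    )
    assert res.diagnostics["hellinger"] < 0.05


def test_mle_is_deterministic_given_seed():
    truth = TwoStateParams(rho=0.5, sigma_u=0.05, sigma_b=0.1, d=0.02)
    s = simulate_params(truth, SimulationConfig(n_samples=1000, seed=3))
    a = mle_fit_two_state(s, species="mature", d=truth.d, seed=5)
    b = mle_fit_two_state(s, species="mature", d=truth.d, seed=5)
    assert a.mapped == b.mapped


def test_mle_input_validation():
    with pytest.raises(ValueError, match="at least 100"):
        mle_fit_two_state(np.ones(10, dtype=int), species="mature", d=0.1)
    with pytest.raises(ValueError, match="degenerate"):
        mle_fit_two_state(np.zeros(200, dtype=int), species="mature", d=0.1)


# ---------------------------------------------------------------------------
# refractory four-moment matching


def test_refractory_match_reproduces_four_waiting_moments(fixtures):
    p = fixtures["mapped_a"]
    res = match_refractory(p)
    assert res.diagnostics["converged"]
    assert res.mapped is not None
    target = waiting_moments(waiting_lt(build_chain(p)), order=4)
    got = waiting_moments(waiting_lt(build_chain(res.mapped)), order=4)
    for f in ("m1", "m2", "m3", "m4"):
        assert getattr(got, f) == pytest.approx(getattr(target, f), rel=1e-6)
    assert randomness_refractory(res.mapped) >= 1.0


def test_refractory_match_flags_sets_without_a_solution(fixtures):
    # for this reducible set the four-moment system has no positive root
    # found by multistart Newton; the result must be flagged, not silently off
    res = match_refractory(fixtures["mapped_c"], n_starts=12)
    assert not res.diagnostics["converged"]
    assert res.mapped is None


@settings(max_examples=60, deadline=None)
@given(rho=rates, su=rates, sus=rates, sb=rates)
def test_refractory_randomness_always_exceeds_one(rho, su, sus, sb):
    from txmodels import RefractoryParams

    assert randomness_refractory(
        RefractoryParams(rho=rho, sigma_u=su, sigma_u_star=sus, sigma_b=sb, d=1.0)
    ) > 1.0
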