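"""Reduction of the mechanistic model to two-state and refractory models.

The feasibility criterion is ``Delta = b' + c - a - a^2/a' >= 0``,
equivalent to ``R_mec >= 1``: only then do positive two-state rates exist
whose first three waiting-time moments match the mechanistic model's.
The closed-form map is::

    D       = a'[a'(Delta a' + a^2 + 3 a Delta + Delta(b + Delta))
              + a^2 (2a + b + 2 Delta)] + a^4
    rho     = b c a' (Delta a' + a^2) / D
    sigma_u = Delta^3 a'^4 / ((Delta a' + a^2) D)
    sigma_b = a Delta a' / (Delta a' + a^2)

On the boundary ``Delta = 0`` the map degenerates gracefully to a
constitutive gene (``sigma_u = 0``).  The telegraph variant inherits the
decay rate ``d``, the delay-telegraph variant the elongation time ``tau``.

Besides the closed form, this module offers reduction by *number*
statistics (Newton matching of the first three molecule-number moments),
by maximum likelihood on molecule-number samples, and a four-moment
waiting-time match onto the refractory (two-off-state) model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .delay_ssa import SampleSet, SimulationConfig, simulate_params
from .models import (
    MechanisticParams,
    RefractoryParams,
    TwoStateParams,
    build_chain,
    production_rate,
)
from .number_stats import (
    CountDistribution,
    empirical_distribution,
    fano_mature_mechanistic,
    hellinger,
    mean_mature,
    telegraph_mature_distribution,
    window_count_distribution,
)
from .waiting_times import waiting_lt, waiting_moments

__all__ = [
    "ReductionResult",
    "InfeasibleReduction",
    "delta",
    "is_reducible",
    "effective_two_state",
    "effective_map_arrays",
    "fast_switching_limit",
    "match_number_moments",
    "mle_fit_two_state",
    "match_refractory",
]


class InfeasibleReduction(ValueError):
    """No two-state model matches the requested statistics (Delta < 0)."""


@dataclass
class ReductionResult:
    """Outcome of a model-reduction attempt."""

    delta: float
    feasible_waiting: bool
    feasible_mature_number: bool
    mapped: TwoStateParams | RefractoryParams | None
    method: str
    diagnostics: dict = field(default_factory=dict)


def delta(p: MechanisticParams) -> float:
    """Feasibility discriminant ``Delta = b' + c - a - a^2/a'`` (s^-1)."""
    return p.b_rev + p.c - p.a - p.a**2 / p.a_rev


def is_reducible(p: MechanisticParams) -> tuple[bool, bool]:
    """(waiting-time criterion, mature-number criterion).

    The first is ``b'+c >= (a/a')(a+a')`` (equivalently Delta >= 0 and
    R_mec >= 1); the second is the stricter ``b'+c >= (a/a')(a+a'+d)``
    needed for a super-Poissonian mature-mRNA Fano factor.  The first
    failing implies the second fails.
    """
    lhs = p.b_rev + p.c
    ratio = p.a / p.a_rev
    return (lhs >= ratio * (p.a + p.a_rev), lhs >= ratio * (p.a + p.a_rev + p.d))


def _map_scalars(a, ar, b, dlt):
    denom = ar * (
        ar * (dlt * ar + a**2 + 3 * a * dlt + dlt * (b + dlt)) + a**2 * (2 * a + b + 2 * dlt)
    ) + a**4
    core = dlt * ar + a**2
    return denom, core


def effective_two_state(
    p: MechanisticParams, variant: str = "delay_telegraph"
) -> TwoStateParams:
    """Closed-form two-state parameters matching three waiting-time moments.

    Raises :class:`InfeasibleReduction` when Delta < 0 (one mapped rate
    would be negative).  ``variant`` selects which downstream parameter is
    inherited: ``"telegraph"`` takes ``d``, ``"delay_telegraph"`` takes
    ``tau``.
    """
    dlt = delta(p)
    if dlt < 0:
        raise InfeasibleReduction(
            f"Delta = {dlt:.4g} < 0: no two-state model matches the waiting-time moments"
        )
    denom, core = _map_scalars(p.a, p.a_rev, p.b, dlt)
    rho = p.b * p.c * p.a_rev * core / denom
    sigma_u = dlt**3 * p.a_rev**4 / (core * denom)
    sigma_b = p.a * dlt * p.a_rev / core
    kwargs = {"d": p.d} if variant == "telegraph" else {"tau": p.tau}
    return TwoStateParams(rho=rho, sigma_u=sigma_u, sigma_b=sigma_b, **kwargs)


def effective_map_arrays(a, ar, b, br, c):
    """Vectorized closed-form map; returns (delta, rho, sigma_u, sigma_b).

    Entries with Delta < 0 come back as NaN in the mapped rates.
    """
    a, ar, b, br, c = np.broadcast_arrays(*map(np.asarray, (a, ar, b, br, c)))
    dlt = br + c - a - a**2 / ar
    denom, core = _map_scalars(a, ar, b, dlt)
    with np.errstate(invalid="ignore"):
        rho = np.where(dlt >= 0, b * c * ar * core / denom, np.nan)
        sigma_u = np.where(dlt >= 0, dlt**3 * ar**4 / (core * denom), np.nan)
        sigma_b = np.where(dlt >= 0, a * dlt * ar / core, np.nan)
    return dlt, rho, sigma_u, sigma_b


def fast_switching_limit(p: MechanisticParams, variant: str = "delay_telegraph") -> TwoStateParams:
    """Two-state parameters in the fast pausing-cycle limit min(b,b') >> max(a,a').

    ``sigma_b = a``, ``sigma_u = a' b'/(b+b')``, ``rho = c b/(b+b')`` —
    the paused and unpaused permissive states collapse into one on state.
    """
    kwargs = {"d": p.d} if variant == "telegraph" else {"tau": p.tau}
    return TwoStateParams(
        rho=p.c * p.b / (p.b + p.b_rev),
        sigma_u=p.a_rev * p.b_rev / (p.b + p.b_rev),
        sigma_b=p.a,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# numerical moment matching on molecule numbers


def _damped_newton(residual_fn, x0, max_iter=200, tol=1e-10):
    """Damped Newton with forward-difference Jacobian in the given coords."""
    x = np.asarray(x0, dtype=float)
    r = residual_fn(x)
    for iteration in range(max_iter):
        norm = np.abs(r).max()
        if norm < tol:
            return x, r, iteration, True
        jac = np.empty((len(r), len(x)))
        h = 1e-7
        for k in range(len(x)):
            xp = x.copy()
            xp[k] += h
            jac[:, k] = (residual_fn(xp) - r) / h
        try:
            step = np.linalg.solve(jac, -r)
        except np.linalg.LinAlgError:
            return x, r, iteration, False
        lam = 1.0
        for _ in range(30):
            x_new = x + lam * step
            r_new = residual_fn(x_new)
            if np.all(np.isfinite(r_new)) and np.abs(r_new).max() < norm:
                x, r = x_new, r_new
                break
            lam *= 0.5
        else:
            return x, r, iteration, False
    return x, r, max_iter, np.abs(r).max() < tol


def _two_state_number_moments(q: TwoStateParams, orders=(1, 2, 3)) -> np.ndarray:
    if q.variant == "delay_telegraph":
        dist = window_count_distribution(build_chain(q), q.tau)
    else:
        dist = telegraph_mature_distribution(q)
    return np.array([dist.moment(k) for k in orders])


def mechanistic_number_moments(
    p: MechanisticParams,
    species: str = "active",
    n_samples: int = 20000,
    seed: int = 0,
) -> np.ndarray:
    """First three raw moments of the mechanistic molecule-number distribution.

    Active Pol II moments come exactly from the window-count engine.  For
    mature mRNA the mean and variance are closed-form; the third moment
    has no printed closed form and is estimated by the delay SSA (the
    ``n_samples``/``seed`` arguments only matter in that case).
    """
    if species == "active":
        dist = window_count_distribution(build_chain(p), p.tau)
        return np.array([dist.moment(k) for k in (1, 2, 3)])
    if species == "mature":
        m1 = mean_mature(p)
        m2 = fano_mature_mechanistic(p) * m1 + m1**2
        samples = simulate_params(p, SimulationConfig(n_samples=n_samples, seed=seed))
        m3 = float(np.mean(samples.n_mature.astype(float) ** 3))
        return np.array([m1, m2, m3])
    raise ValueError("species must be 'active' or 'mature'")


def match_number_moments(
    p: MechanisticParams,
    species: str = "active",
    seed: int = 0,
) -> ReductionResult:
    """Two-state parameters matching the first three number moments.

    Newton iteration in log-parameter space (positivity by construction),
    started from the closed-form waiting-time map.  Non-convergence is
    reported in the result rather than raised: near the feasibility
    boundary the number-moment equations may have no positive solution.
    """
    variant = "delay_telegraph" if species == "active" else "telegraph"
    dlt = delta(p)
    feas = is_reducible(p)
    target = mechanistic_number_moments(p, species=species, seed=seed)
    scale = np.abs(target)

    def residual(x):
        with np.errstate(over="ignore"):
            rho, su, sb = np.exp(x)
        if not np.all(np.isfinite([rho, su, sb])) or max(rho, su, sb) > 1e6 or min(rho, su, sb) < 1e-14:
            return np.full(3, np.inf)
        try:
            q = _make_two_state(rho, su, sb, p, variant)
            mom = _two_state_number_moments(q)
        except Exception:
            return np.full(3, np.inf)
        return (mom - target) / scale

    try:
        q0 = effective_two_state(p, variant=variant)
        x0 = np.log([q0.rho, max(q0.sigma_u, 1e-12), q0.sigma_b])
    except InfeasibleReduction:
        x0 = np.log([production_rate(p) * 2, 0.01, 0.01])
    x, r, n_iter, converged = _damped_newton(residual, x0)
    rho, su, sb = np.exp(x)
    mapped = _make_two_state(rho, su, sb, p, variant) if converged else None
    return ReductionResult(
        delta=dlt,
        feasible_waiting=feas[0],
        feasible_mature_number=feas[1],
        mapped=mapped,
        method="moment-match",
        diagnostics={
            "residuals": r.tolist(),
            "iterations": n_iter,
            "converged": bool(converged),
            "target_moments": target.tolist(),
        },
    )


def _make_two_state(rho, su, sb, p: MechanisticParams, variant: str) -> TwoStateParams:
    kwargs = {"d": p.d} if variant == "telegraph" else {"tau": p.tau}
    return TwoStateParams(rho=float(rho), sigma_u=float(su), sigma_b=float(sb), **kwargs)


# ---------------------------------------------------------------------------
# maximum-likelihood fitting of two-state models to number samples


def mle_fit_two_state(
    samples: SampleSet | np.ndarray,
    species: str = "active",
    *,
    tau: float | None = None,
    d: float | None = None,
    seed: int = 0,
    n_starts: int = 5,
    init: TwoStateParams | None = None,
    reference: CountDistribution | None = None,
) -> ReductionResult:
    """Fit (rho, sigma_u, sigma_b) by maximum likelihood on count samples.

    The likelihood is evaluated with the exact two-state distribution
    engines (window-count for active Pol II given ``tau``, CME solve for
    mature mRNA given ``d``).  A Nelder-Mead search in log-parameter space
    is run from ``n_starts`` perturbed initial points; the best optimum is
    kept.  The diagnostics carry the log-likelihood and the Hellinger
    distance between the fitted distribution and the empirical one (or
    ``reference`` when given).
    """
    if isinstance(samples, SampleSet):
        counts = samples.n_active if species == "active" else samples.n_mature
    else:
        counts = np.asarray(samples, dtype=np.int64)
    if counts.size < 100:
        raise ValueError("need at least 100 samples for a meaningful fit")
    if counts.max() == 0:
        raise ValueError("degenerate sample: all counts are zero")
    variant = "delay_telegraph" if species == "active" else "telegraph"
    if variant == "delay_telegraph" and tau is None:
        raise ValueError("active-species fit needs the elongation time tau")
    if variant == "telegraph" and d is None:
        raise ValueError("mature-species fit needs the decay rate d")
    freq = np.bincount(counts)
    support = np.arange(len(freq))
    n_max = int(counts.max() + 10 + 4 * math.sqrt(counts.max()))

    def make(rho, su, sb):
        if variant == "delay_telegraph":
            return TwoStateParams(rho=rho, sigma_u=su, sigma_b=sb, tau=tau)
        return TwoStateParams(rho=rho, sigma_u=su, sigma_b=sb, d=d)

    def neg_loglik(x):
        rho, su, sb = np.exp(x)
        if max(rho, su, sb) > 1e4 or min(rho, su, sb) < 1e-12:
            return np.inf
        q = make(rho, su, sb)
        try:
            if variant == "delay_telegraph":
                dist = window_count_distribution(build_chain(q), q.tau, n_max=n_max, deficit_tol=0.5)
            else:
                dist = telegraph_mature_distribution(q, n_max=n_max, deficit_tol=0.5)
        except Exception:
            return np.inf
        probs = np.clip(dist.probabilities[support], 1e-300, None)
        return -float(np.dot(freq, np.log(probs)))

    timescale = 1.0 / tau if variant == "delay_telegraph" else d
    if init is None:
        mean = counts.mean()
        init = make(2.0 * mean * timescale, timescale, timescale)
    x0 = np.log([init.rho, max(init.sigma_u, 1e-10), init.sigma_b])
    rng = np.random.default_rng((seed, 987))
    best = None
    for start in range(n_starts):
        xs = x0 if start == 0 else x0 + rng.normal(scale=0.7, size=3)
        res = optimize.minimize(neg_loglik, xs, method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    rho, su, sb = np.exp(best.x)
    fitted = make(rho, su, sb)
    if variant == "delay_telegraph":
        fit_dist = window_count_distribution(build_chain(fitted), fitted.tau, n_max=n_max, deficit_tol=0.5)
    else:
        fit_dist = telegraph_mature_distribution(fitted, n_max=n_max, deficit_tol=0.5)
    ref = reference if reference is not None else empirical_distribution(counts)
    h = hellinger(ref, fit_dist)
    return ReductionResult(
        delta=np.nan,
        feasible_waiting=True,
        feasible_mature_number=True,
        mapped=fitted,
        method="mle",
        diagnostics={
            "loglik": -float(best.fun),
            "hellinger": h,
            "converged": bool(best.success),
            "n_samples": int(counts.size),
        },
    )


# ---------------------------------------------------------------------------
# refractory (three-state) reduction by four waiting-time moments


def match_refractory(
    p: MechanisticParams,
    variant: str = "telegraph",
    n_starts: int = 60,
    seed: int = 0,
    tol: float = 1e-10,
) -> ReductionResult:
    """Refractory-model parameters matching four waiting-time moments.

    Solves the four simultaneous moment equations numerically (multistart
    damped Newton in log space) for (rho, sigma_u, sigma_u*, sigma_b).
    Feasibility requires R_mec >= 1 just as for the two-state reduction,
    since the refractory randomness parameter always exceeds 1; even then
    the four-moment system may have no positive root for some parameter
    sets, in which case the result is flagged non-converged rather than
    raised.
    """
    dlt = delta(p)
    feas = is_reducible(p)
    target_wm = waiting_moments(waiting_lt(build_chain(p)), order=4)
    target = np.array([target_wm.m1, target_wm.m2, target_wm.m3, target_wm.m4])
    scale = np.abs(target)

    def residual(x):
        with np.errstate(over="ignore"):
            rho, su, sus, sb = np.exp(x)
        if not np.all(np.isfinite([rho, su, sus, sb])) or max(rho, su, sus, sb) > 1e6 or min(rho, su, sus, sb) < 1e-14:
            return np.full(4, np.inf)
        try:
            q = RefractoryParams(rho=rho, sigma_u=su, sigma_u_star=sus, sigma_b=sb,
                                 **({"d": p.d} if variant == "telegraph" else {"tau": p.tau}))
            wm = waiting_moments(waiting_lt(build_chain(q)), order=4)
        except Exception:
            return np.full(4, np.inf)
        return (np.array([wm.m1, wm.m2, wm.m3, wm.m4]) - target) / scale

    starts = []
    try:
        q0 = effective_two_state(p, variant=variant)
        su0 = max(q0.sigma_u, 1e-10)
        # continuation from the telegraph limit (sigma_u* large) inward
        for sus0 in (1e3 * q0.sigma_b, 10.0 * q0.sigma_b, q0.sigma_b):
            starts.append(np.log([q0.rho, su0, sus0, q0.sigma_b]))
    except InfeasibleReduction:
        starts.append(np.log([1.0 / target_wm.m1, 0.01, 0.1, 0.01]))
    rng = np.random.default_rng((seed, 271))
    while len(starts) < n_starts:
        starts.append(rng.uniform(math.log(1e-5), math.log(10.0), size=4))
    best_x, best_r, best_iter, converged = None, None, 0, False
    total_iter = 0
    for x0 in starts:
        x, r, n_iter, conv = _damped_newton(residual, x0, max_iter=80, tol=tol)
        total_iter += n_iter
        if best_r is None or np.abs(r).max() < np.abs(best_r).max():
            best_x, best_r, converged = x, r, conv
        if conv:
            break
    x, r, n_iter = best_x, best_r, total_iter
    rho, su, sus, sb = np.exp(x)
    mapped = None
    if converged:
        mapped = RefractoryParams(
            rho=float(rho), sigma_u=float(su), sigma_u_star=float(sus), sigma_b=float(sb),
            **({"d": p.d} if variant == "telegraph" else {"tau": p.tau}),
        )
    return ReductionResult(
        delta=dlt,
        feasible_waiting=feas[0],
        feasible_mature_number=feas[1],
        mapped=mapped,
        method="refractory-match",
        diagnostics={
            "residuals": r.tolist(),
            "iterations": n_iter,
            "converged": bool(converged),
            "target_moments": target.tolist(),
        },
    )
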