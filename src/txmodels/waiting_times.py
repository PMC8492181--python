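"""Waiting-time distributions between consecutive transcript productions.

The time between two consecutive production events of a production-marked
promoter chain is a phase-type-like first-passage time: starting from the
state entered right after a production, run the chain until the next
marked firing.  In the Laplace domain the per-state first-passage
transforms solve a linear system with entries affine in the Laplace
variable ``s``::

    f_i(s) = [ sum_j marked_ij  +  sum_{j != i} unmarked_ij f_j(s) ]
             / (s + exit_i)

so the transform from the restart state is an exact rational function of
``s``.  The system is solved by Cramer's rule over the polynomial ring,
which keeps the result exact up to floating-point coefficient arithmetic
(chains here have at most a handful of states).

Moments follow from the Taylor expansion of the transform at ``s = 0``
(``<t^i> = (-1)^i d^i f~/ds^i (0)``), computed by exact power-series
division.  Densities come from partial-fraction inversion of the rational
transform: a sum of (complex-)exponential terms, with repeated poles
handled through the standard multiplicity formula.

The *randomness parameter* ``R`` is the squared coefficient of variation
of the waiting time.  Closed forms are provided for all three model
families; the generic first-passage pipeline serves as their cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy import signal

from .models import (
    GeneStateChain,
    MechanisticParams,
    RefractoryParams,
    TwoStateParams,
    ValidationError,
    build_chain,
)

__all__ = [
    "RationalLT",
    "WaitingMoments",
    "waiting_lt",
    "waiting_moments",
    "randomness_telegraph",
    "randomness_mechanistic",
    "randomness_refractory",
    "density",
    "cdf",
]


@dataclass(frozen=True)
class RationalLT:
    """Rational Laplace transform ``f~(s) = num(s) / den(s)``.

    Coefficients are stored in ascending powers of ``s``.  A proper
    waiting-time transform satisfies ``f~(0) = 1`` and
    ``deg(num) < deg(den)``; ``lim s->inf  s * f~(s)`` equals the density
    at ``t = 0+``.
    """

    num: np.ndarray
    den: np.ndarray
    model: str = ""

    def __call__(self, s):
        s = np.asarray(s, dtype=complex)
        return npoly.polyval(s, self.num) / npoly.polyval(s, self.den)

    @property
    def value_at_zero(self) -> float:
        return float(self.num[0] / self.den[0])

    @property
    def density_at_zero(self) -> float:
        """``f(0+) = lim s->inf s f~(s)`` — nonzero iff deg(num) = deg(den) - 1."""
        if len(self.num) == len(self.den) - 1:
            return float(self.num[-1] / self.den[-1])
        return 0.0


@dataclass(frozen=True)
class WaitingMoments:
    """Raw waiting-time moments (s, s^2, s^3, ...) and the randomness parameter."""

    m1: float
    m2: float
    m3: float | None = None
    m4: float | None = None

    @property
    def R(self) -> float:
        """Squared coefficient of variation (m2 - m1^2) / m1^2."""
        return (self.m2 - self.m1**2) / self.m1**2


def _poly_det(matrix: list[list[np.ndarray]]) -> np.ndarray:
    """Determinant of a small matrix of polynomials (Laplace expansion)."""
    n = len(matrix)
    if n == 1:
        return matrix[0][0]
    det = np.zeros(1)
    for j in range(n):
        minor = [[row[k] for k in range(n) if k != j] for row in matrix[1:]]
        term = npoly.polymul(matrix[0][j], _poly_det(minor))
        det = npoly.polyadd(det, term if j % 2 == 0 else -term)
    return det


def _trim(coeffs: np.ndarray, rel_tol: float = 1e-13) -> np.ndarray:
    """Drop trailing coefficients that are numerically zero."""
    coeffs = np.atleast_1d(np.asarray(coeffs, dtype=float))
    scale = np.abs(coeffs).max()
    if scale == 0.0:
        return coeffs[:1]
    keep = len(coeffs)
    while keep > 1 and abs(coeffs[keep - 1]) <= rel_tol * scale:
        keep -= 1
    return coeffs[:keep]


def waiting_lt(chain: GeneStateChain) -> RationalLT:
    """Exact Laplace transform of the inter-production waiting time.

    Solves the first-passage linear system by Cramer's rule in the
    polynomial ring and returns the transform from the chain's restart
    state (``U*`` for the mechanistic model, the on state ``G`` for the
    two-state and refractory models).
    """
    n = chain.n_states
    exit_rates = chain.exit_rates
    if not np.all(exit_rates > 0):
        raise ValidationError("chain has an absorbing state; waiting time is improper")
    # A f = m with A[i][i] = s + exit_i, A[i][j] = -unmarked[i, j]
    a = [
        [
            np.array([exit_rates[i], 1.0]) if i == j else np.array([-chain.unmarked[i, j]])
            for j in range(n)
        ]
        for i in range(n)
    ]
    m = [np.array([chain.marked[i].sum()]) for i in range(n)]
    den = _poly_det(a)
    numer_matrix = [
        [m[i] if j == chain.restart else a[i][j] for j in range(n)] for i in range(n)
    ]
    num = _poly_det(numer_matrix)
    num, den = _trim(num), _trim(den)
    # Normalize so that f~(0) = 1 exactly (removes the common scale left by
    # the determinant arithmetic; a proper chain guarantees num(0) ~ den(0)).
    if den[0] == 0.0 or num[0] == 0.0:
        raise ValidationError("chain is reducible from the restart state")
    scale = den[0] / num[0]
    num = num * scale
    if len(num) >= len(den):
        raise ValidationError("improper waiting-time transform (reducible chain?)")
    return RationalLT(num=num, den=den, model=getattr(chain, "model", ""))


def _taylor_at_zero(lt: RationalLT, order: int) -> np.ndarray:
    """Taylor coefficients of ``num/den`` at ``s = 0`` by series division."""
    a = np.zeros(order + 1)
    k = min(order + 1, len(lt.num))
    a[:k] = lt.num[:k]
    b = np.zeros(order + 1)
    k = min(order + 1, len(lt.den))
    b[:k] = lt.den[:k]
    c = np.empty(order + 1)
    with np.errstate(over="ignore", invalid="ignore"):
        c[0] = a[0] / b[0]
        for i in range(1, order + 1):
            c[i] = (a[i] - np.dot(b[1 : i + 1], c[i - 1 :: -1])) / b[0]
    return c


def waiting_moments(lt: RationalLT, order: int = 3) -> WaitingMoments:
    """Raw moments ``<t^i> = (-1)^i f~^(i)(0)`` up to ``order`` (max 4)."""
    if not 1 <= order <= 4:
        raise ValueError("order must be between 1 and 4")
    order = max(order, 2)  # R always needs the second moment
    c = _taylor_at_zero(lt, order)
    fact = 1.0
    moments = []
    for i in range(1, order + 1):
        fact *= i
        moments.append((-1.0) ** i * fact * c[i])
    moments += [None] * (4 - order)
    return WaitingMoments(*moments)


def randomness_telegraph(p: TwoStateParams) -> float:
    """Closed-form randomness parameter of the (delay) telegraph model.

    ``R = 1 + 2 rho sigma_u / (sigma_b + sigma_u)^2`` — always > 1 for a
    genuinely switching gene, 1 in the constitutive limit sigma_u -> 0.
    """
    return 1.0 + 2.0 * p.rho * p.sigma_u / (p.sigma_b + p.sigma_u) ** 2


def randomness_mechanistic(p: MechanisticParams) -> float:
    """Closed-form randomness parameter of the mechanistic model.

    ``R = 1 + 2 b c [a'(b'+c-a) - a^2] / [a'(b'+c) + a(b+b'+c)]^2``.
    Unlike the two-state models, R can fall below 1 (down to 1/2: at least
    two reaction steps separate consecutive productions).
    """
    num = p.a_rev * (p.b_rev + p.c - p.a) - p.a**2
    den = p.a_rev * (p.b_rev + p.c) + p.a * (p.b + p.b_rev + p.c)
    return 1.0 + 2.0 * p.b * p.c * num / den**2


def randomness_mechanistic_arrays(a, a_rev, b, b_rev, c):
    """Vectorized form of :func:`randomness_mechanistic` for parameter sweeps."""
    num = a_rev * (b_rev + c - a) - a**2
    den = a_rev * (b_rev + c) + a * (b + b_rev + c)
    return 1.0 + 2.0 * b * c * num / den**2


def randomness_refractory(p: RefractoryParams) -> float:
    """Closed-form randomness parameter of the refractory model.

    ``R = 1 + 2 rho sigma_u (sigma_b sigma_u* + sigma_u*^2 + sigma_b^2)
    / [(sigma_b + sigma_u) sigma_u* + sigma_b sigma_u]^2`` — always > 1,
    and collapses to the telegraph value as sigma_u* -> infinity.
    """
    su, sus, sb = p.sigma_u, p.sigma_u_star, p.sigma_b
    num = sb * sus + sus**2 + sb**2
    den = (sb + su) * sus + sb * su
    return 1.0 + 2.0 * p.rho * su * num / den**2


def _partial_fractions(lt: RationalLT):
    """Residues/poles of the transform; repeated poles get ascending powers."""
    residues, poles, direct = signal.residue(lt.num[::-1], lt.den[::-1])
    if len(direct) and np.abs(direct).max() > 1e-12 * np.abs(lt.den).max():
        raise ValidationError("transform is not strictly proper")
    # scipy lists repeated poles consecutively; the k-th occurrence is the
    # residue of (s - p)^-k.
    powers = []
    seen: list[complex] = []
    for pole in poles:
        count = sum(1 for q in seen if abs(q - pole) <= 1e-9 * max(1.0, abs(pole)))
        powers.append(count + 1)
        seen.append(pole)
    return residues, poles, powers


def density(lt: RationalLT, t_grid) -> np.ndarray:
    """Waiting-time density on a grid by partial-fraction Laplace inversion.

    ``f(t) = sum_k  r_k t^(m_k - 1) e^(p_k t) / (m_k - 1)!`` where ``m_k``
    is the multiplicity index of pole ``p_k``.  Nearly degenerate roots are
    grouped into a repeated pole by the residue computation, which replaces
    the ill-conditioned simple-pole formula in that regime.
    """
    t = np.asarray(t_grid, dtype=float)
    if (t < 0).any():
        raise ValueError("waiting times are non-negative; got negative grid values")
    residues, poles, powers = _partial_fractions(lt)
    out = np.zeros(t.shape, dtype=complex)
    for r, pole, k in zip(residues, poles, powers):
        out += r * t ** (k - 1) * np.exp(pole * t) / _factorial(k - 1)
    return np.real(out)


def cdf(lt: RationalLT, t_grid) -> np.ndarray:
    """Cumulative distribution of the waiting time (term-wise integration)."""
    t = np.asarray(t_grid, dtype=float)
    if (t < 0).any():
        raise ValueError("waiting times are non-negative; got negative grid values")
    residues, poles, powers = _partial_fractions(lt)
    out = np.zeros(t.shape, dtype=complex)
    for r, pole, k in zip(residues, poles, powers):
        # integral_0^t u^(k-1) e^(p u) du / (k-1)!  via the lower incomplete
        # gamma recurrence, valid for complex p with Re(p) < 0.
        out += r * _exp_poly_integral(pole, k, t)
    return np.real(out)


def _exp_poly_integral(pole: complex, k: int, t: np.ndarray) -> np.ndarray:
    """``int_0^t u^(k-1) e^(pole u) du / (k-1)!`` by integration by parts."""
    # I_k(t) with I_1 = (e^(pt) - 1)/p;  I_k = (t^(k-1) e^(pt)/(k-1)! - I_{k-1}) / p
    acc = (np.exp(pole * t) - 1.0) / pole
    for j in range(2, k + 1):
        acc = (t ** (j - 1) * np.exp(pole * t) / _factorial(j - 1) - acc) / pole
    return acc


def _factorial(n: int) -> float:
    out = 1.0
    for i in range(2, n + 1):
        out *= i
    return out


def waiting_lt_for(params) -> RationalLT:
    """Convenience: build the chain and return its waiting-time transform."""
    lt = waiting_lt(build_chain(params))
    tag = type(params).__name__
    return RationalLT(num=lt.num, den=lt.den, model=tag)
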