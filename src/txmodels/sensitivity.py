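"""Sensitivity of the mapped two-state parameters to the mechanistic rates.

For a mechanistic parameter point with Delta > 0, the closed-form
reduction map defines the effective two-state parameters
``theta_tele = (rho, sigma_u, sigma_b)`` (and the burst size
``beta = rho/sigma_u``) as functions of ``theta_mec = (a, a', b, b', c)``.
The relative sensitivity is the log-derivative magnitude::

    sen(theta_i_tele, theta_j_mec) = | d log theta_i_tele / d log theta_j_mec |

computed here by central differences in log-parameter space.  Because the
map is homogeneous of degree one in the five rates, the *signed*
log-sensitivities of each mapped rate sum to exactly 1 — a built-in
consistency check.

The screening procedure draws mechanistic parameter sets log-uniformly,
keeps those whose mapped two-state parameters land within ``k``
experimental errors of measured values (presets for the Oct4 and Nanog
genes are provided), and tabulates which mechanistic parameters each
two-state parameter is most/least sensitive to across the accepted sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import MechanisticParams
from .reduction import InfeasibleReduction, delta, effective_map_arrays

__all__ = [
    "MECH_NAMES",
    "TELE_NAMES",
    "SensitivityRecord",
    "ScreenSpec",
    "ScreenResult",
    "relative_sensitivities",
    "sign_table",
    "screen_parameters",
    "oct4_screen_spec",
    "nanog_screen_spec",
]

MECH_NAMES = ("a", "a_rev", "b", "b_rev", "c")
TELE_NAMES = ("rho", "sigma_u", "sigma_b", "beta")


@dataclass
class SensitivityRecord:
    """Signed and absolute log-sensitivities at one mechanistic point.

    ``signed[i, j]`` is d log(theta_tele_i)/d log(theta_mec_j) with rows
    ordered (rho, sigma_u, sigma_b, beta) and columns (a, a', b, b', c).
    """

    point: MechanisticParams
    signed: np.ndarray

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.signed)

    def ranked(self, tele: str, least: bool = False) -> tuple[str, str]:
        """Ordered (first, second) most- or least-sensitive mechanistic params."""
        row = self.magnitude[TELE_NAMES.index(tele)]
        order = np.argsort(row, kind="stable")
        if not least:
            order = order[::-1]
        return MECH_NAMES[order[0]], MECH_NAMES[order[1]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.signed, index=list(TELE_NAMES), columns=list(MECH_NAMES))


def _map_with_beta(values: np.ndarray) -> np.ndarray:
    dlt, rho, su, sb = effective_map_arrays(*values)
    if np.any(np.asarray(dlt) < 0):
        raise InfeasibleReduction("Delta crossed below 0 inside the difference stencil")
    with np.errstate(divide="ignore"):
        beta = rho / su
    return np.stack([rho, su, sb, beta])


def relative_sensitivities(p: MechanisticParams, step: float = 1e-6) -> SensitivityRecord:
    """Central-difference log-derivatives of the reduction map at ``p``.

    Requires Delta > 0.  The step is halved (up to a few times) if the
    difference stencil would cross the Delta = 0 boundary.
    """
    if delta(p) <= 0:
        raise InfeasibleReduction("sensitivities are defined only inside Delta > 0")
    x0 = np.array([p.a, p.a_rev, p.b, p.b_rev, p.c])
    signed = np.empty((4, 5))
    for j in range(5):
        h = step
        for _ in range(8):
            try:
                plus = x0.copy()
                plus[j] *= np.exp(h)
                minus = x0.copy()
                minus[j] *= np.exp(-h)
                theta_p = _map_with_beta(plus)
                theta_m = _map_with_beta(minus)
                break
            except InfeasibleReduction:
                h *= 0.5
        else:  # pragma: no cover - Delta > 0 guard above makes this unreachable
            raise InfeasibleReduction("could not straddle the point inside Delta > 0")
        signed[:, j] = (np.log(theta_p) - np.log(theta_m)).ravel() / (2.0 * h)
    return SensitivityRecord(point=p, signed=signed)


def sign_table(points: list[MechanisticParams], tol: float = 1e-8) -> pd.DataFrame:
    """Empirical derivative signs across sampled Delta > 0 points.

    Entries are '+', '-', '0' (identically zero) or '+-' when both signs
    occur somewhere in the sample.
    """
    pos = np.zeros((4, 5), dtype=bool)
    neg = np.zeros((4, 5), dtype=bool)
    for p in points:
        s = relative_sensitivities(p).signed
        pos |= s > tol
        neg |= s < -tol
    out = np.where(pos & neg, "+-", np.where(pos, "+", np.where(neg, "-", "0")))
    return pd.DataFrame(out, index=list(TELE_NAMES), columns=list(MECH_NAMES))


@dataclass(frozen=True)
class ScreenSpec:
    """Constrained random screen against measured two-state parameters.

    ``targets`` maps each two-state parameter to (value, experimental
    error) in s^-1; a draw is accepted when every mapped parameter lies
    within ``k`` errors of its target.  Mechanistic rates are drawn
    log-uniformly from ``log10_range`` (powers of ten).
    """

    targets: dict
    k: float = 2.0
    log10_range: tuple[float, float] = (-4.0, 1.0)
    n_draws: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rho", "sigma_u", "sigma_b"):
            if name not in self.targets:
                raise ValueError(f"targets must include {name!r}")
            value, err = self.targets[name]
            if err <= 0:
                raise ValueError(f"experimental error for {name!r} must be positive")
        lo, hi = self.log10_range
        if not lo < hi:
            raise ValueError("log10_range must be ordered (lo, hi)")


def oct4_screen_spec(n_draws: int = 100_000, seed: int = 0, k: float = 2.0) -> ScreenSpec:
    """Measured Oct4 two-state parameters and the matching search ranges."""
    return ScreenSpec(
        targets={
            "rho": (3.2e-2, 1.0e-2),
            "sigma_u": (3e-3, 2e-3),
            "sigma_b": (1.5e-4, 0.5e-4),
        },
        k=k,
        log10_range=(-4.0, 1.0),
        n_draws=n_draws,
        seed=seed,
    )


def nanog_screen_spec(n_draws: int = 100_000, seed: int = 0, k: float = 2.0) -> ScreenSpec:
    """Measured Nanog two-state parameters and the matching search ranges."""
    return ScreenSpec(
        targets={
            "rho": (1.3e-2, 0.3e-2),
            "sigma_u": (1.2e-4, 0.2e-4),
            "sigma_b": (3.2e-5, 0.3e-5),
        },
        k=k,
        log10_range=(-5.0, -1.0),
        n_draws=n_draws,
        seed=seed,
    )


@dataclass
class ScreenResult:
    """Accepted parameter sets and most/least-sensitivity rankings."""

    accepted: pd.DataFrame
    n_draws: int
    proportions: dict = field(default_factory=dict)

    @property
    def n_accepted(self) -> int:
        return len(self.accepted)

    def modal_pair(self, tele: str, least: bool = False) -> tuple[str, str]:
        """Most frequent ordered (first, second) sensitivity pair."""
        key = ("least_" if least else "most_") + tele
        table = self.proportions[key]
        return table.index[0]


def screen_parameters(spec: ScreenSpec) -> ScreenResult:
    """Run the constrained random screen defined by ``spec``.

    Draws are vectorized; sensitivity rankings are computed per accepted
    set.  Raises if nothing is accepted (more draws or a wider ``k`` are
    then needed).
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.log10_range
    draws = 10.0 ** rng.uniform(lo, hi, size=(spec.n_draws, 5))
    dlt, rho, su, sb = effective_map_arrays(*draws.T)
    mask = dlt > 0
    for name, values in (("rho", rho), ("sigma_u", su), ("sigma_b", sb)):
        target, err = spec.targets[name]
        with np.errstate(invalid="ignore"):
            mask &= np.abs(values - target) <= spec.k * err
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise RuntimeError(
            f"no acceptances in {spec.n_draws} draws; increase n_draws or widen k"
        )
    rows = []
    for i in idx:
        p = MechanisticParams(*draws[i], d=1.0, tau=0.0)
        rec = relative_sensitivities(p)
        row = dict(zip(MECH_NAMES, draws[i]))
        row.update({"rho": rho[i], "sigma_u": su[i], "sigma_b": sb[i], "delta": dlt[i]})
        for tele in TELE_NAMES:
            row["most_" + tele] = rec.ranked(tele)
            row["least_" + tele] = rec.ranked(tele, least=True)
        rows.append(row)
    accepted = pd.DataFrame(rows)
    proportions = {
        col: accepted[col].value_counts(normalize=True)
        for col in accepted.columns
        if col.startswith(("most_", "least_"))
    }
    return ScreenResult(accepted=accepted, n_draws=spec.n_draws, proportions=proportions)
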