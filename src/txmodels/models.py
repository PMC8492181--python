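"""Parameter containers and gene-state chain algebra.

Three model families are supported:

* the *mechanistic* model — a three-state promoter (inactive ``U``,
  activator-bound ``U*``, Pol II paused ``U**``) where pause release both
  emits an actively elongating Pol II and resets the promoter to ``U*``;
  the active Pol II matures into an mRNA after a deterministic elongation
  time ``tau`` and mature mRNA decays at first order with rate ``d``;
* the *two-state* (telegraph / delay-telegraph) models — on/off promoter
  producing transcripts at rate ``rho`` from the on state, with removal
  either first-order (rate ``d``, telegraph) or after a fixed delay
  (``tau``, delay telegraph);
* the *refractory* models — a cyclic three-state promoter with two
  sequential off states, production from the on state.

All rates are in s^-1, times in s.  The promoter dynamics of every model
are encoded as a :class:`GeneStateChain`: a continuous-time Markov chain
whose transitions carry a *production mark* when the firing emits one
transcript (a Markovian arrival process).  All downstream machinery —
waiting-time distributions, window-count master equations, stationary
fluxes — operates on this chain representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

__all__ = [
    "MechanisticParams",
    "TwoStateParams",
    "RefractoryParams",
    "GeneStateChain",
    "build_chain",
    "stationary_flux",
    "params_to_dict",
    "params_from_dict",
]


class ValidationError(ValueError):
    """Raised when a parameter set or chain violates its invariants."""


def _require_positive(name: str, value: float) -> None:
    if not np.isfinite(value) or value <= 0.0:
        raise ValidationError(f"rate {name!r} must be strictly positive, got {value!r}")


def _require_nonnegative(name: str, value: float) -> None:
    if not np.isfinite(value) or value < 0.0:
        raise ValidationError(f"{name!r} must be non-negative, got {value!r}")


@dataclass(frozen=True)
class MechanisticParams:
    """Rates of the mechanistic promoter/Pol II/mRNA model.

    Parameters
    ----------
    a, a_rev
        Activation ``U -> U*`` and deactivation ``U* -> U`` rates (s^-1).
    b, b_rev
        Pol II binding + pause entry ``U* -> U**`` and premature
        termination ``U** -> U*`` rates (s^-1).
    c
        Pause-release rate (s^-1); the ``U** -> U* + A`` transition that
        emits one active Pol II.
    d
        Mature mRNA decay rate (s^-1).
    tau
        Deterministic elongation time (s); an active Pol II becomes a
        mature mRNA exactly ``tau`` after pause release.
    """

    a: float
    a_rev: float
    b: float
    b_rev: float
    c: float
    d: float = 1.0
    tau: float = 0.0

    def __post_init__(self) -> None:
        for name in ("a", "a_rev", "b", "b_rev", "c", "d"):
            _require_positive(name, getattr(self, name))
        _require_nonnegative("tau", self.tau)


@dataclass(frozen=True)
class TwoStateParams:
    """Rates of the telegraph (``d``) or delay-telegraph (``tau``) model.

    Exactly one of ``d`` / ``tau`` is active, selecting the variant.
    ``beta = rho / sigma_u`` is the mean burst size.
    """

    rho: float
    sigma_u: float
    sigma_b: float
    d: float | None = None
    tau: float | None = None

    def __post_init__(self) -> None:
        _require_positive("rho", self.rho)
        _require_positive("sigma_b", self.sigma_b)
        if not np.isfinite(self.sigma_u) or self.sigma_u < 0.0:
            raise ValidationError(f"sigma_u must be >= 0, got {self.sigma_u!r}")
        if (self.d is None) == (self.tau is None):
            raise ValidationError("exactly one of d (telegraph) or tau (delay telegraph) must be set")
        if self.d is not None:
            _require_positive("d", self.d)
        if self.tau is not None:
            _require_nonnegative("tau", self.tau)

    @property
    def beta(self) -> float:
        """Burst size rho/sigma_u (infinite for a constitutive gene)."""
        return self.rho / self.sigma_u if self.sigma_u > 0 else np.inf

    @property
    def variant(self) -> str:
        return "telegraph" if self.d is not None else "delay_telegraph"


@dataclass(frozen=True)
class RefractoryParams:
    """Rates of the cyclic three-state refractory model.

    The promoter cycles ``G -> G* -> G** -> G`` at rates ``sigma_u``,
    ``sigma_u_star``, ``sigma_b``; transcripts are produced from ``G`` at
    rate ``rho``.  Transcript removal follows the two-state convention
    (``d`` first order, or ``tau`` delayed).
    """

    rho: float
    sigma_u: float
    sigma_u_star: float
    sigma_b: float
    d: float | None = None
    tau: float | None = None

    def __post_init__(self) -> None:
        for name in ("rho", "sigma_u", "sigma_u_star", "sigma_b"):
            _require_positive(name, getattr(self, name))
        if (self.d is None) == (self.tau is None):
            raise ValidationError("exactly one of d or tau must be set")
        if self.d is not None:
            _require_positive("d", self.d)
        if self.tau is not None:
            _require_nonnegative("tau", self.tau)

    @property
    def variant(self) -> str:
        return "telegraph" if self.d is not None else "delay_telegraph"


@dataclass
class GeneStateChain:
    """Marked continuous-time Markov chain over promoter states.

    ``unmarked[i, j]`` is the rate of the silent transition i -> j (i != j);
    ``marked[i, j]`` the rate of the transcript-emitting transition i -> j
    (self-transitions allowed: the telegraph production ``G -> G + M`` is a
    marked self-loop).  ``restart`` is the state occupied immediately after
    a production event, from which the next inter-production waiting time
    starts.
    """

    states: tuple[str, ...]
    unmarked: np.ndarray
    marked: np.ndarray
    restart: int
    stationary: np.ndarray = field(init=False)
    generator: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.states)
        self.unmarked = np.asarray(self.unmarked, dtype=float)
        self.marked = np.asarray(self.marked, dtype=float)
        if self.unmarked.shape != (n, n) or self.marked.shape != (n, n):
            raise ValidationError("rate matrices must be square and match the state labels")
        if (self.unmarked < 0).any() or (self.marked < 0).any():
            raise ValidationError("transition rates must be non-negative")
        if np.diag(self.unmarked).any():
            raise ValidationError("unmarked self-transitions are meaningless")
        if not self.marked.any():
            raise ValidationError("chain needs at least one production-marked transition")
        # Marked self-loops leave the state unchanged, so they do not enter
        # the state-dynamics generator.
        q = self.unmarked + self.marked
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        self.generator = q
        self.stationary = _stationary_distribution(q)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def exit_rates(self) -> np.ndarray:
        """Total firing rate out of each state, marked self-loops included."""
        off = self.unmarked.sum(axis=1)
        return off + self.marked.sum(axis=1)


def _stationary_distribution(generator: np.ndarray) -> np.ndarray:
    """Stationary row vector of a CTMC generator by direct linear solve.

    The last balance equation is replaced by the normalization row, which
    keeps the system square and the pivoting deterministic.
    """
    n = generator.shape[0]
    a = generator.T.copy()
    a[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    try:
        pi = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate input
        raise ValidationError("gene-state chain is reducible") from exc
    if (pi < -1e-12).any():
        raise ValidationError("gene-state chain is reducible (negative stationary mass)")
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def build_chain(params: MechanisticParams | TwoStateParams | RefractoryParams) -> GeneStateChain:
    """Encode a parameter set as a production-marked promoter chain.

    Production marks sit on exactly the transitions that emit a transcript:
    the pause-release transition ``U** -> U*`` (rate ``c``) for the
    mechanistic model, and the on-state self-loop (rate ``rho``) for the
    two-state and refractory models.
    """
    if isinstance(params, MechanisticParams):
        u = np.zeros((3, 3))
        m = np.zeros((3, 3))
        u[0, 1] = params.a
        u[1, 0] = params.a_rev
        u[1, 2] = params.b
        u[2, 1] = params.b_rev  # premature termination, silent
        m[2, 1] = params.c  # pause release: emits one active Pol II
        return GeneStateChain(("U", "U*", "U**"), u, m, restart=1)
    if isinstance(params, TwoStateParams):
        u = np.zeros((2, 2))
        m = np.zeros((2, 2))
        u[0, 1] = params.sigma_u
        u[1, 0] = params.sigma_b
        m[0, 0] = params.rho
        return GeneStateChain(("G", "G*"), u, m, restart=0)
    if isinstance(params, RefractoryParams):
        u = np.zeros((3, 3))
        m = np.zeros((3, 3))
        u[0, 1] = params.sigma_u
        u[1, 2] = params.sigma_u_star
        u[2, 0] = params.sigma_b
        m[0, 0] = params.rho
        return GeneStateChain(("G", "G*", "G**"), u, m, restart=0)
    raise TypeError(f"unsupported parameter type {type(params).__name__}")


def stationary_flux(chain: GeneStateChain) -> float:
    """Stationary transcript-production rate (s^-1).

    Sum over production-marked transitions of stationary occupancy times
    rate.  For the mechanistic chain this is the closed form
    ``gamma = a*b*c / (a'*(b'+c) + a*(b'+b+c))``; for the telegraph chain
    it is ``rho * sigma_b / (sigma_b + sigma_u)``.
    """
    return float(np.einsum("i,ij->", chain.stationary, chain.marked))


def production_rate(p: MechanisticParams) -> float:
    """Closed-form stationary production rate gamma of the mechanistic model."""
    return (p.a * p.b * p.c) / (p.a_rev * (p.b_rev + p.c) + p.a * (p.b_rev + p.b + p.c))


_MODEL_FIELDS = {
    "mechanistic": MechanisticParams,
    "telegraph": TwoStateParams,
    "delay_telegraph": TwoStateParams,
    "refractory": RefractoryParams,
}


def params_to_dict(params: MechanisticParams | TwoStateParams | RefractoryParams) -> dict:
    """Flatten a parameter set to a JSON/YAML-friendly mapping with a model tag."""
    if isinstance(params, MechanisticParams):
        model = "mechanistic"
    elif isinstance(params, TwoStateParams):
        model = params.variant
    elif isinstance(params, RefractoryParams):
        model = "refractory"
    else:
        raise TypeError(f"unsupported parameter type {type(params).__name__}")
    out: dict = {"model": model}
    for f in fields(params):
        value = getattr(params, f.name)
        if value is not None:
            out[f.name] = float(value)
    return out


def params_from_dict(mapping: dict) -> MechanisticParams | TwoStateParams | RefractoryParams:
    """Inverse of :func:`params_to_dict`; rejects unknown keys."""
    data = dict(mapping)
    try:
        model = data.pop("model")
    except KeyError:
        raise ValidationError("parameter mapping needs a 'model' key") from None
    try:
        cls = _MODEL_FIELDS[model]
    except KeyError:
        raise ValidationError(
            f"unknown model {model!r}; expected one of {sorted(_MODEL_FIELDS)}"
        ) from None
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValidationError(f"unknown parameter keys for model {model!r}: {sorted(unknown)}")
    if cls is TwoStateParams:
        if model == "telegraph" and "d" not in data:
            raise ValidationError("telegraph model requires a decay rate 'd'")
        if model == "delay_telegraph" and "tau" not in data:
            raise ValidationError("delay_telegraph model requires a delay 'tau'")
    return cls(**data)
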