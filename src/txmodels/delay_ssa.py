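"""Exact stochastic simulation with fixed-delay removal (delay SSA).

Promoter dynamics are simulated by the standard SSA; every
production-marked firing pushes a scheduled completion event ``tau``
seconds ahead onto a FIFO queue (completions of a fixed delay are
necessarily time-ordered).  Whenever the earliest queued completion
precedes the next stochastic firing it is executed first: the active
Pol II is removed and — in the mechanistic model — converted into a
mature mRNA, which then decays through an ordinary first-order channel.
Ties between a completion and a stochastic firing (a probability-zero
event) are resolved in favour of the completion, for determinism.

Sampling convention: one steady-state sample per independent trajectory,
each driven by its own RNG stream derived from ``(seed, trajectory
index)`` so sample sets are reproducible and order-independent.  A
separate long-trajectory mode collects ordered production-event times
for waiting-time statistics.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .models import GeneStateChain, MechanisticParams, RefractoryParams, TwoStateParams, build_chain

__all__ = [
    "SimulationConfig",
    "SampleSet",
    "simulate",
    "simulate_params",
    "production_times",
    "waiting_times_from_trajectory",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Settings for steady-state sampling.

    ``horizon`` defaults to ``max(20 / spectral gap, 5 tau, 7 / d)`` —
    long enough that the gene marginal (started stationary), the active
    Pol II count (exactly stationary after ``tau``) and the mature mRNA
    count (relaxing at rate ``d``) have all equilibrated.
    """

    n_samples: int
    seed: int
    horizon: float | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.horizon is not None and self.horizon <= 0:
            raise ValueError("horizon must be positive")


@dataclass
class SampleSet:
    """Steady-state samples of active Pol II (``n_active``) and mature mRNA."""

    n_active: np.ndarray
    n_mature: np.ndarray
    meta: dict = field(default_factory=dict)
    event_times: np.ndarray | None = None


def _channel_tables(chain: GeneStateChain):
    """Per-state flattened transition tables for the SSA inner loop."""
    tables = []
    for i in range(chain.n_states):
        rates, targets, marked = [], [], []
        for j in range(chain.n_states):
            if chain.unmarked[i, j] > 0:
                rates.append(chain.unmarked[i, j])
                targets.append(j)
                marked.append(False)
            if chain.marked[i, j] > 0:
                rates.append(chain.marked[i, j])
                targets.append(j)
                marked.append(True)
        cum = [float(x) for x in np.cumsum(rates)]
        tables.append((cum[-1] if cum else 0.0, cum, targets, marked))
    return tables


def default_horizon(chain: GeneStateChain, tau: float | None, d: float | None) -> float:
    """Equilibration horizon: gene-state spectral gap, delay and decay scales.

    The gene marginal relaxes at the slowest non-zero generator eigenvalue
    (the chain also *starts* stationary, making this a safety margin), the
    active Pol II count is exactly stationary after ``tau``, and the mature
    pool relaxes at rate ``d``.
    """
    eigs = np.linalg.eigvals(chain.generator)
    decay = -np.real(eigs)
    nonzero = decay > 1e-9 * max(decay.max(), 1e-300)  # drop the stationary mode
    gap = decay[nonzero].min() if nonzero.any() else 1.0
    horizon = 20.0 / gap
    if tau:
        horizon = max(horizon, 5.0 * tau)
    if d:
        horizon = max(horizon, 7.0 / d)
    return horizon


_BUF = 1024


def _run_trajectory(tables, cum_pi, tau, d, convert, horizon, rng, record_events):
    """One steady-state sample; returns (n_active, n_mature, event times)."""
    state = int(np.searchsorted(cum_pi, rng.random(), side="right"))
    t = 0.0
    mature = 0
    queue: deque[float] = deque()
    events: list[float] | None = [] if record_events else None
    # chunked RNG draws keep the per-event overhead low
    exps = rng.exponential(size=_BUF).tolist()
    unis = rng.random(size=_BUF).tolist()
    ei = ui = 0
    inf = np.inf
    while True:
        total_gene, cum, targets, marked = tables[state]
        total = total_gene + d * mature if d is not None else total_gene
        if ei == _BUF:
            exps = rng.exponential(size=_BUF).tolist()
            ei = 0
        t_next = t + exps[ei] / total if total > 0.0 else inf
        ei += 1
        t_queue = queue[0] if queue else inf
        if t_queue <= t_next:
            if t_queue > horizon:
                break
            t = queue.popleft()
            if convert:
                mature += 1
            continue
        if t_next > horizon:
            break
        t = t_next
        if ui == _BUF:
            unis = rng.random(size=_BUF).tolist()
            ui = 0
        u = unis[ui] * total
        ui += 1
        if u < total_gene:
            k = 0
            while u > cum[k]:
                k += 1
            if marked[k]:
                if tau is not None:
                    queue.append(t + tau)
                else:
                    mature += 1
                if events is not None:
                    events.append(t)
            state = targets[k]
        else:
            mature -= 1
    return len(queue), mature, events


def simulate(
    chain: GeneStateChain,
    config: SimulationConfig,
    *,
    tau: float | None = None,
    d: float | None = None,
    convert: bool = False,
    record_events: bool = False,
) -> SampleSet:
    """Draw independent steady-state samples from a marked promoter chain.

    Parameters
    ----------
    tau
        Fixed delay applied to each produced transcript (active Pol II
        lifetime).  ``None`` means productions go straight to the mature
        pool (plain telegraph model).
    d
        First-order decay rate of the mature pool; ``None`` disables it
        (delay-telegraph model, where the delayed removal is terminal).
    convert
        Whether a delay completion converts the active Pol II into a
        mature mRNA (mechanistic model) instead of removing it outright.
    """
    if tau is None and d is None:
        raise ValueError("at least one of tau (delay) or d (decay) must be given")
    horizon = config.horizon if config.horizon is not None else default_horizon(chain, tau, d)
    tables = _channel_tables(chain)
    cum_pi = np.cumsum(chain.stationary)
    n_active = np.empty(config.n_samples, dtype=np.int64)
    n_mature = np.empty(config.n_samples, dtype=np.int64)
    events = [] if record_events else None
    for idx in range(config.n_samples):
        rng = np.random.default_rng((config.seed, idx))
        a, m, ev = _run_trajectory(tables, cum_pi, tau, d, convert, horizon, rng, record_events)
        n_active[idx] = a
        n_mature[idx] = m
        if events is not None:
            events.append(np.asarray(ev))
    meta = {
        "horizon": horizon,
        "seed": config.seed,
        "n_samples": config.n_samples,
        "horizon_ok": config.horizon is None or config.horizon >= default_horizon(chain, tau, d),
    }
    return SampleSet(
        n_active=n_active,
        n_mature=n_mature,
        meta=meta,
        event_times=events[0] if record_events and config.n_samples == 1 else None,
    )


def simulate_params(
    params: MechanisticParams | TwoStateParams | RefractoryParams,
    config: SimulationConfig,
    **kwargs,
) -> SampleSet:
    """Simulate directly from a parameter set, inferring the downstream wiring."""
    chain = build_chain(params)
    if isinstance(params, MechanisticParams):
        return simulate(chain, config, tau=params.tau, d=params.d, convert=True, **kwargs)
    if params.variant == "telegraph":
        return simulate(chain, config, d=params.d, **kwargs)
    return simulate(chain, config, tau=params.tau, **kwargs)


def production_times(
    chain: GeneStateChain,
    n_events: int,
    seed: int,
    burn_in_events: int = 10,
) -> np.ndarray:
    """Ordered production-event times from one long trajectory.

    The gene starts from its stationary distribution and the first
    ``burn_in_events`` productions are discarded so the retained inter-event
    intervals are drawn from the stationary waiting-time distribution.
    """
    rng = np.random.default_rng((seed, 0))
    tables = _channel_tables(chain)
    cum_pi = np.cumsum(chain.stationary)
    state = int(np.searchsorted(cum_pi, rng.random(), side="right"))
    t = 0.0
    out = np.empty(n_events + burn_in_events)
    count = 0
    exp = rng.exponential
    uni = rng.random
    while count < n_events + burn_in_events:
        total, cum, targets, marked = tables[state]
        t += exp() / total
        u = uni() * total
        k = int(np.searchsorted(cum, u, side="right"))
        if marked[k]:
            out[count] = t
            count += 1
        state = targets[k]
    return out[burn_in_events:]


def waiting_times_from_trajectory(events: np.ndarray, burn_in: int = 0) -> np.ndarray:
    """Inter-production intervals from ordered event times.

    Discards the first ``burn_in`` events; fewer than two remaining events
    yield an empty array.
    """
    events = np.asarray(events, dtype=float)[burn_in:]
    if events.size < 2:
        return np.empty(0)
    return np.diff(events)
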