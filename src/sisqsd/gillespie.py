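"""Event-driven (direct Gillespie) simulation of SIS dynamics and the two
Monte-Carlo measurement procedures built on it.

The simulator draws exponential waiting times from the total event rate
and picks the event proportionally to its rate, with per-node infection
pressures updated incrementally (O(out-degree) per event).  On top of it:

* ``estimate_qsd_marginals`` — the time-average estimator of the marginal
  quasi-prevalence ``p_i``: the proportion of (post-burn-in, pre-extinction)
  simulated time each node spends infectious.  Because the quantity is
  conditioned on non-extinction, small or weakly supercritical networks —
  whose chains die long before a useful amount of time accumulates — are
  handled by resurrection sampling: on extinction the chain restarts from
  a state drawn from the time-weighted empirical history (a reservoir of
  past configurations), whose stationary law converges to the QSD.  On
  networks where extinction is rare this reduces to the plain long-run
  time average;
* ``estimate_invasion_probability`` / ``infection_event_histogram`` — the
  dichotomised-persistence estimator: the fraction of replicates whose
  cumulative infection-event count reaches a threshold ``c`` before
  extinction, with a histogram diagnostic for whether early extinctions
  and long-lived runs actually separate;
* ``empirical_survival_curve`` — survival probability at a grid of times
  from replicate extinction times.

Reproducibility: every estimator takes one master seed; replicate ``k``
uses the stream ``SeedSequence(master, spawn_key=(k,))`` so replicate
sets are order-independent and extendable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .networks import ContactNetwork, is_strongly_connected

__all__ = [
    "SimulationTrace",
    "EstimatorResult",
    "simulate",
    "estimate_qsd_marginals",
    "estimate_invasion_probability",
    "infection_event_histogram",
    "empirical_state_probabilities",
    "empirical_survival_curve",
    "occupancy_from_trace",
    "EarlyExtinctionError",
]

DEFAULT_EVENT_THRESHOLD = 500  # infection events marking "invaded"
DEFAULT_BURNIN_FRACTION = 0.9
DEFAULT_BATCHES = 50
DEFAULT_MAX_RETRIES = 100


class EarlyExtinctionError(RuntimeError):
    """Raised when the chain keeps dying before burn-in completes.

    Persistent early extinction means quasi-stationary behaviour is never
    established, i.e. the QSD may lack practical relevance for this
    network at these rates; the time-average estimator is then invalid.
    """


@dataclass(frozen=True)
class SimulationTrace:
    """Time-ordered record of one stochastic realisation.

    ``events`` is a list of ``(time, kind, node)`` with kind ``'infection'``
    or ``'recovery'``; times strictly increase.  ``extinct`` is set (with
    ``extinction_time``) when the infected set empties; no events follow
    extinction.
    """

    initial: frozenset[int]
    events: tuple[tuple[float, str, int], ...]
    extinct: bool
    extinction_time: float | None
    end_time: float
    seed: object = None


@dataclass(frozen=True)
class EstimatorResult:
    """Monte-Carlo estimate(s) with uncertainty and configuration echo."""

    estimate: np.ndarray | float
    stderr: np.ndarray | float
    n_used: int
    config: dict = field(default_factory=dict)


class _SISEngine:
    """Mutable simulation state with incremental rate bookkeeping.

    Maintains, for the current infected set: the infection pressure
    ``lam[j] = sum_{i infectious} T[i, j]`` on every node, the total
    infection rate over susceptible nodes and the total recovery rate.
    Accumulated floating drift is purged by a full rebuild every few
    thousand events.
    """

    __slots__ = (
        "n", "rows", "g", "infected", "lam", "inf_total", "rec_total",
        "t", "n_infected", "_since_rebuild",
    )

    _REBUILD_EVERY = 4096

    def __init__(self, net: ContactNetwork, initial: Iterable[int]):
        self.n = net.n
        w = net.weights.tocoo()
        rows: list[list[tuple[int, float]]] = [[] for _ in range(self.n)]
        for i, j, v in zip(w.row, w.col, w.data):
            rows[int(i)].append((int(j), float(v)))
        self.rows = rows
        self.g = [float(x) for x in net.recovery]
        self.infected = [False] * self.n
        init = set(initial)
        for i in init:
            if not 0 <= i < self.n:
                raise ValueError(f"node {i} outside population of size {self.n}")
        self.t = 0.0
        self._since_rebuild = 0
        self.lam = [0.0] * self.n
        for i in init:
            self.infected[i] = True
        self.n_infected = len(init)
        self._rebuild()

    def set_state(self, infected: Iterable[bool]) -> None:
        """Replace the infected configuration (clock untouched) and rebuild."""
        state = list(infected)
        if len(state) != self.n:
            raise ValueError("state length does not match population size")
        self.infected = [bool(x) for x in state]
        self.n_infected = sum(self.infected)
        self._rebuild()

    def _rebuild(self) -> None:
        lam = [0.0] * self.n
        rec = 0.0
        for i in range(self.n):
            if self.infected[i]:
                rec += self.g[i]
                for j, v in self.rows[i]:
                    lam[j] += v
        self.lam = lam
        self.rec_total = rec
        self.inf_total = sum(
            lam[j] for j in range(self.n) if not self.infected[j]
        )
        self._since_rebuild = 0

    def step(self, rng: np.random.Generator) -> tuple[float, str, int] | None:
        """Execute one event; None when the state is absorbing."""
        total = self.rec_total + self.inf_total
        if self.n_infected == 0 or total <= 0:
            return None
        self._since_rebuild += 1
        if self._since_rebuild >= self._REBUILD_EVERY:
            self._rebuild()
            total = self.rec_total + self.inf_total
        self.t += rng.exponential(1.0 / total)
        u = rng.random() * total
        if u < self.rec_total:
            # recovery: scan infectious nodes
            acc = 0.0
            node = -1
            for i in range(self.n):
                if self.infected[i]:
                    acc += self.g[i]
                    node = i
                    if u < acc:
                        break
            self._recover(node)
            return (self.t, "recovery", node)
        u -= self.rec_total
        acc = 0.0
        node = -1
        for j in range(self.n):
            if not self.infected[j]:
                acc += self.lam[j]
                node = j
                if u < acc:
                    break
        self._infect(node)
        return (self.t, "infection", node)

    def _infect(self, j: int) -> None:
        self.infected[j] = True
        self.n_infected += 1
        self.inf_total -= self.lam[j]
        self.rec_total += self.g[j]
        for k, v in self.rows[j]:
            self.lam[k] += v
            if not self.infected[k]:
                self.inf_total += v

    def _recover(self, i: int) -> None:
        self.infected[i] = False
        self.n_infected -= 1
        self.rec_total -= self.g[i]
        for k, v in self.rows[i]:
            self.lam[k] -= v
            if not self.infected[k]:
                self.inf_total -= v
        self.inf_total += self.lam[i]
        if self.n_infected == 0:
            self.inf_total = 0.0
            self.rec_total = 0.0


def _rng_for(seed, replicate: int | None = None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if replicate is None:
        return np.random.default_rng(seed)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(replicate,)))


def simulate(
    net: ContactNetwork,
    initial: Iterable[int],
    max_events: int | None = None,
    max_time: float | None = None,
    seed: int | np.random.Generator | None = None,
) -> SimulationTrace:
    """Run one exact realisation of the SIS process.

    Stops at extinction, after ``max_events`` events, or at the first event
    past ``max_time`` (whose effect is not recorded), whichever comes
    first; at least one stopping rule must be given unless extinction is
    certain.  An empty initial set terminates immediately at time 0.
    """
    if max_events is None and max_time is None:
        max_events = -1  # run to extinction
    initial = frozenset(initial)
    eng = _SISEngine(net, initial)
    rng = _rng_for(seed)
    events: list[tuple[float, str, int]] = []
    if not initial:
        return SimulationTrace(
            initial=initial, events=(), extinct=True, extinction_time=0.0,
            end_time=0.0, seed=seed,
        )
    while True:
        if max_events is not None and max_events >= 0 and len(events) >= max_events:
            break
        ev = eng.step(rng)
        if ev is None:
            break
        if max_time is not None and ev[0] > max_time:
            break
        events.append(ev)
        if eng.n_infected == 0:
            break
    extinct = eng.n_infected == 0 and (max_time is None or eng.t <= max_time)
    ext_time = events[-1][0] if extinct and events else (0.0 if extinct else None)
    end = events[-1][0] if events else 0.0
    if max_time is not None and not extinct:
        end = max_time
    return SimulationTrace(
        initial=initial,
        events=tuple(events),
        extinct=extinct,
        extinction_time=ext_time,
        end_time=end,
        seed=seed,
    )


def occupancy_from_trace(
    trace: SimulationTrace, n: int, t_start: float = 0.0, t_end: float | None = None
) -> np.ndarray:
    """Per-node fraction of time infectious over a window of a trace.

    Replays the event sequence and accumulates, for each node, the time it
    spends infectious within ``[t_start, t_end]`` (default: the whole
    trace), divided by the window length — the time-average estimator
    evaluated on one recorded realisation.
    """
    if t_end is None:
        t_end = trace.end_time
    if not 0 <= t_start < t_end:
        raise ValueError("need 0 <= t_start < t_end")
    infected = [i in trace.initial for i in range(n)]
    occ = np.zeros(n)
    t_prev = 0.0
    events = list(trace.events) + [(t_end, "end", -1)]
    for s, kind, node in events:
        lo, hi = max(t_prev, t_start), min(s, t_end)
        if hi > lo:
            for i in range(n):
                if infected[i]:
                    occ[i] += hi - lo
        if kind == "infection":
            infected[node] = True
        elif kind == "recovery":
            infected[node] = False
        t_prev = s
        if s >= t_end:
            break
    return occ / (t_end - t_start)


class _OccupationHistory:
    """Exact time-weighted occupation record of every visited configuration.

    Resurrection draws a configuration with probability proportional to
    the total simulated time the chain has spent in it so far.  The
    occupation measure of a chain resurrected from its own history
    converges to the QSD, and unlike a fixed-size reservoir the draw
    distribution keeps sharpening as the run lengthens.  Configurations
    are stored as bitmask integers, so this is intended for populations
    small enough that extinction (hence resurrection) is actually common.
    """

    __slots__ = ("n", "times", "masks", "index")

    def __init__(self, n: int):
        self.n = n
        self.times: list[float] = []
        self.masks: list[int] = []
        self.index: dict[int, int] = {}

    def offer(self, state: list[bool], dt: float, rng) -> None:
        m = 0
        for i in range(self.n):
            if state[i]:
                m |= 1 << i
        k = self.index.get(m)
        if k is None:
            self.index[m] = len(self.masks)
            self.masks.append(m)
            self.times.append(dt)
        else:
            self.times[k] += dt

    def draw(self, rng: np.random.Generator) -> list[bool]:
        cum = np.cumsum(self.times)
        k = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
        k = min(k, len(self.masks) - 1)
        m = self.masks[k]
        return [bool(m >> i & 1) for i in range(self.n)]


class _HistoryReservoir:
    """Time-weighted reservoir of past configurations for large populations.

    Each of ``size`` slots independently holds a configuration sampled
    (exactly, by sequential weighted reservoir sampling) in proportion to
    the simulated time the chain spent in it.  Drawing a slot uniformly
    approximates a draw from the empirical occupation measure.  Used when
    storing per-configuration occupation times is impractical; on such
    networks extinction is typically rare, so the coarser approximation
    is exercised rarely.
    """

    __slots__ = ("slots", "t_acc")

    def __init__(self, initial: list[bool], size: int):
        self.slots = [list(initial) for _ in range(size)]
        self.t_acc = 0.0

    def offer(self, state: list[bool], dt: float, rng: np.random.Generator) -> None:
        self.t_acc += dt
        q = dt / self.t_acc
        k = rng.binomial(len(self.slots), q)
        if k:
            for s in rng.choice(len(self.slots), size=min(k, len(self.slots)),
                                replace=False):
                self.slots[s] = list(state)

    def draw(self, rng: np.random.Generator) -> list[bool]:
        return list(self.slots[rng.integers(len(self.slots))])


def estimate_qsd_marginals(
    net: ContactNetwork,
    total_events: int,
    burnin_events: int | None = None,
    initial: Iterable[int] | None = None,
    seed: int | None = None,
    n_batches: int = DEFAULT_BATCHES,
    max_retries: int = DEFAULT_MAX_RETRIES,
    on_extinction: str = "resurrect",
    reservoir_size: int = 64,
) -> EstimatorResult:
    """Time-average estimator of the marginal quasi-prevalence of each node.

    Runs one long chain for ``total_events`` events (default initial state:
    all infected), discards the first ``burnin_events`` (default 90%), and
    estimates ``p_i`` as the fraction of the remaining simulated time node
    ``i`` spends infectious.  The estimate conditions on non-extinction, so
    post-extinction data never enters the average; what happens *at*
    extinction is set by ``on_extinction``:

    ``'resurrect'`` (default)
        restart instantly from a configuration drawn from the time-weighted
        reservoir of past states.  The resurrected chain's stationary law
        converges to the QSD, so the estimator remains valid even on small
        networks where extinction is frequent; on networks whose chains
        effectively never die it coincides with the plain time average.
    ``'rerun'``
        discard the whole attempt when the chain dies before burn-in
        completes and rerun with a fresh derived seed (up to
        ``max_retries``); if extinction strikes after burn-in, keep the
        pre-extinction data and stop.  Persistent early extinction raises
        :class:`EarlyExtinctionError` — the QSD then lacks practical
        relevance for this network at these rates.

    Standard errors come from batch means over ``n_batches`` equal-event
    batches — consecutive intervals are strongly correlated, so a naive
    variance would be far too small.
    """
    if not is_strongly_connected(net):
        raise ValueError("network must be strongly connected")
    if on_extinction not in ("resurrect", "rerun"):
        raise ValueError("on_extinction must be 'resurrect' or 'rerun'")
    if burnin_events is None:
        burnin_events = int(total_events * DEFAULT_BURNIN_FRACTION)
    if not 0 <= burnin_events < total_events:
        raise ValueError("need 0 <= burn-in < total events")
    init = frozenset(initial) if initial is not None else frozenset(range(net.n))
    if not init:
        raise ValueError("initial state must be nonempty")
    n = net.n

    discarded = 0
    attempts = max_retries + 1 if on_extinction == "rerun" else 1
    for attempt in range(attempts):
        rng = _rng_for(seed, replicate=attempt)
        eng = _SISEngine(net, init)
        if on_extinction == "resurrect":
            reservoir = (
                _OccupationHistory(n)
                if n <= 32
                else _HistoryReservoir(eng.infected, reservoir_size)
            )
        else:
            reservoir = None
        resurrections = 0
        died_early = False

        def advance() -> float | None:
            """One event; returns dt, resurrecting if configured."""
            nonlocal resurrections
            t0 = eng.t
            ev = eng.step(rng)
            if ev is None:
                return None
            dt = eng.t - t0
            if reservoir is not None:
                # offer the pre-event state, then resurrect if extinct
                pre = eng.infected.copy()
                if ev[1] == "infection":
                    pre[ev[2]] = False
                else:
                    pre[ev[2]] = True
                reservoir.offer(pre, dt, rng)
                if eng.n_infected == 0:
                    eng.set_state(reservoir.draw(rng))
                    resurrections += 1
            return dt

        for _ in range(burnin_events):
            if advance() is None:
                died_early = True
                break
        if died_early:
            discarded += 1
            continue

        # accumulate occupancy over post-burn-in intervals, batched for SE
        occ = np.zeros((n_batches, n))
        batch_time = np.zeros(n_batches)
        events_per_batch = max((total_events - burnin_events) // n_batches, 1)
        k = 0
        extinct_during = False
        while k < total_events - burnin_events:
            state = eng.infected.copy()
            dt = advance()
            if dt is None:
                extinct_during = True
                break
            b = min(k // events_per_batch, n_batches - 1)
            batch_time[b] += dt
            for i in range(n):
                if state[i]:
                    occ[b, i] += dt
            k += 1
        used = batch_time > 0
        if not used.any():
            discarded += 1
            continue
        total_time = batch_time.sum()
        p_hat = occ.sum(axis=0) / total_time
        batch_means = occ[used] / batch_time[used, None]
        nb = used.sum()
        if nb > 1:
            se = batch_means.std(axis=0, ddof=1) / math.sqrt(nb)
        else:
            se = np.full(n, np.nan)
        return EstimatorResult(
            estimate=p_hat,
            stderr=se,
            n_used=k,
            config={
                "total_events": total_events,
                "burnin_events": burnin_events,
                "initial": sorted(init),
                "seed": seed,
                "n_batches": int(nb),
                "on_extinction": on_extinction,
                "resurrections": resurrections,
                "discarded_replicates": discarded,
                "extinct_during_measurement": extinct_during,
                "simulated_time": float(total_time),
            },
        )
    raise EarlyExtinctionError(
        f"chain went extinct before burn-in in {discarded} consecutive "
        "attempts; the QSD may lack practical relevance for this network "
        "(try a larger transmission multiplier, shorter burn-in, or "
        "on_extinction='resurrect')"
    )


def _count_infections_until(
    net: ContactNetwork, init: frozenset[int], threshold: int,
    rng: np.random.Generator,
) -> int:
    """Infection events before extinction, censored at ``threshold``."""
    eng = _SISEngine(net, init)
    count = 0
    while count < threshold:
        ev = eng.step(rng)
        if ev is None:
            break
        if ev[1] == "infection":
            count += 1
    return count


def infection_event_histogram(
    net: ContactNetwork,
    seed_set: Iterable[int],
    max_events: int = DEFAULT_EVENT_THRESHOLD,
    n_reps: int = 1000,
    seed: int | None = None,
) -> EstimatorResult:
    """Histogram of infection events per replicate, censored at ``max_events``.

    Dichotomised persistence shows up as a bimodal histogram: mass near
    zero (early extinction) plus mass at the censoring bin (long-lived
    runs).  The ``dichotomy_score`` in the config — the fraction of
    replicates landing in the middle third of ``[0, max_events]`` — warns
    when no clear separation exists and the censored fraction should not
    be read as an invasion probability.
    """
    if max_events < 1:
        raise ValueError("max_events must be >= 1")
    init = frozenset(seed_set)
    counts = np.zeros(max_events + 1, dtype=np.int64)
    for k in range(n_reps):
        rng = _rng_for(seed, replicate=k)
        c = _count_infections_until(net, init, max_events, rng)
        counts[c] += 1
    middle = counts[max_events // 3 + 1 : 2 * max_events // 3 + 1].sum()
    frac_censored = counts[max_events] / n_reps
    se = math.sqrt(frac_censored * (1 - frac_censored) / n_reps)
    return EstimatorResult(
        estimate=frac_censored,
        stderr=se,
        n_used=n_reps,
        config={
            "histogram": counts,
            "max_events": max_events,
            "seed_set": sorted(init),
            "seed": seed,
            "dichotomy_score": float(middle / n_reps),
        },
    )


def estimate_invasion_probability(
    net: ContactNetwork,
    seed_set: Iterable[int],
    threshold: int = DEFAULT_EVENT_THRESHOLD,
    n_reps: int = 1000,
    seed: int | None = None,
) -> EstimatorResult:
    """Dichotomised-persistence estimate of the quasi-invasion probability.

    The estimate is the fraction of replicates whose cumulative
    infection-event count reaches ``threshold`` before extinction, with an
    exact-binomial standard error.  The full censored histogram and its
    dichotomy score ride along in the config: a high score means the
    replicates did not separate into early deaths and persistent runs, in
    which case ``threshold`` should be increased.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    res = infection_event_histogram(
        net, seed_set, max_events=threshold, n_reps=n_reps, seed=seed
    )
    cfg = dict(res.config)
    cfg["threshold"] = threshold
    return EstimatorResult(
        estimate=res.estimate, stderr=res.stderr, n_used=n_reps, config=cfg
    )


def empirical_state_probabilities(
    net: ContactNetwork,
    initial: Iterable[int],
    t: float,
    n_reps: int = 10_000,
    seed: int | None = None,
) -> EstimatorResult:
    """Per-node empirical probability of being infectious at time ``t``.

    Runs ``n_reps`` independent realisations from ``initial`` and reports
    the fraction in which each node is infectious at ``t`` (binomial
    standard errors).  Converges to the exact transient marginals of the
    master equation, so it serves as a distributional check of the
    simulator against the matrix-exponential computation.
    """
    if t < 0:
        raise ValueError("time must be nonnegative")
    init = frozenset(initial)
    n = net.n
    counts = np.zeros(n)
    for k in range(n_reps):
        rng = _rng_for(seed, replicate=k)
        eng = _SISEngine(net, init)
        # `state` tracks the configuration as of the last event at or
        # before the horizon; an event past the horizon is not applied.
        state = eng.infected.copy()
        while eng.n_infected > 0:
            if eng.step(rng) is None or eng.t > t:
                break
            state = eng.infected.copy()
        for i in range(n):
            if state[i]:
                counts[i] += 1
    p = counts / n_reps
    se = np.sqrt(p * (1 - p) / n_reps)
    return EstimatorResult(
        estimate=p, stderr=se, n_used=n_reps,
        config={"initial": sorted(init), "t": t, "seed": seed},
    )


def empirical_survival_curve(
    net: ContactNetwork,
    initial: Iterable[int],
    times: Sequence[float],
    n_reps: int = 1000,
    seed: int | None = None,
) -> EstimatorResult:
    """Empirical survival probabilities at a grid of times.

    Each replicate runs until extinction or the last grid time; survival
    at ``t`` is the fraction of replicates whose extinction time exceeds
    ``t`` (non-extinct-by-horizon replicates count as surviving).  The
    curve is monotone non-increasing by construction.
    """
    times = np.asarray(times, dtype=np.float64)
    if times.ndim != 1 or times.size < 1 or (np.diff(times) <= 0).any():
        raise ValueError("time grid must be increasing with >= 1 point")
    if (times < 0).any():
        raise ValueError("times must be nonnegative")
    init = frozenset(initial)
    horizon = float(times[-1])
    ext_times = np.empty(n_reps)
    for k in range(n_reps):
        rng = _rng_for(seed, replicate=k)
        if not init:
            ext_times[k] = 0.0
            continue
        eng = _SISEngine(net, init)
        while eng.n_infected > 0 and eng.t <= horizon:
            if eng.step(rng) is None:
                break
        ext_times[k] = eng.t if eng.n_infected == 0 else np.inf
    surv = (ext_times[None, :] > times[:, None]).mean(axis=1)
    se = np.sqrt(surv * (1 - surv) / n_reps)
    return EstimatorResult(
        estimate=surv,
        stderr=se,
        n_used=n_reps,
        config={"times": times, "initial": sorted(init), "seed": seed},
    )
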