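"""Harris graphical (percolation) representation of SIS dynamics.

Each individual gets a time line on ``(0, t_max]``.  A Poisson process of
rate ``g_i`` places *points of cure* on node ``i``'s line; an independent
Poisson process of rate ``T[i, j]`` places *arrows of infection* from
``i``'s line to ``j``'s line.  Node ``j`` is infectious at time ``t``
(starting from infected set ``A``) iff a time-respecting path exists from
0 on some line in ``A`` to ``t`` on ``j``'s line — travelling up the
lines, crossing along arrows, and blocked by cure points.

Because a Poisson process is statistically identical run backwards,
turning a realisation upside down (and reversing each arrow) yields a
realisation for the transposed network.  Path existence is preserved
exactly, which is the duality property: for every single realisation the
forward indicator from ``A`` to ``W`` equals the backward indicator from
``W`` to ``A`` on the reversed diagram — not merely in distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .networks import ContactNetwork

__all__ = [
    "GraphicalRealisation",
    "sample_realisation",
    "reachable_set",
    "reverse",
    "duality_check",
]


@dataclass(frozen=True)
class GraphicalRealisation:
    """Cure points and infection arrows on a finite horizon.

    ``cures``: tuples ``(node, time)``; ``arrows``: tuples
    ``(source, target, time)``; all times in ``(0, t_max]``.  ``order``
    assigns every event a stable global index used to break (probability
    zero, but floating-point possible) time ties deterministically: the
    merged event list is processed by ``(time, order)``.
    """

    t_max: float
    cures: tuple[tuple[int, float], ...]
    arrows: tuple[tuple[int, int, float], ...]
    order: tuple[int, ...] = ()

    def __post_init__(self):
        if self.t_max <= 0:
            raise ValueError("horizon t_max must be positive")
        for _, s in self.cures:
            if not 0 < s <= self.t_max:
                raise ValueError("cure time outside (0, t_max]")
        for _, _, s in self.arrows:
            if not 0 < s <= self.t_max:
                raise ValueError("arrow time outside (0, t_max]")
        if not self.order:
            object.__setattr__(
                self, "order", tuple(range(len(self.cures) + len(self.arrows)))
            )
        elif len(self.order) != len(self.cures) + len(self.arrows):
            raise ValueError("order index length mismatch")

    def merged_events(self) -> list[tuple[float, int, str, tuple]]:
        """All events as ``(time, order, kind, payload)`` sorted for a sweep."""
        ev: list[tuple[float, int, str, tuple]] = []
        k = 0
        for node, s in self.cures:
            ev.append((s, self.order[k], "cure", (node,)))
            k += 1
        for i, j, s in self.arrows:
            ev.append((s, self.order[k], "arrow", (i, j)))
            k += 1
        ev.sort(key=lambda e: (e[0], e[1]))
        return ev


def sample_realisation(
    net: ContactNetwork,
    t_max: float,
    seed: int | np.random.Generator | None = None,
) -> GraphicalRealisation:
    """Sample independent Poisson cure points and infection arrows.

    Node ``i`` receives ``Poisson(g_i * t_max)`` cure points uniformly on
    ``(0, t_max]``; ordered pair ``(i, j)`` with positive rate receives
    ``Poisson(T[i,j] * t_max)`` arrows likewise.  Identical seeds give
    identical realisations.
    """
    if t_max <= 0:
        raise ValueError("horizon t_max must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cures: list[tuple[int, float]] = []
    for i in range(net.n):
        k = rng.poisson(net.recovery[i] * t_max)
        for s in rng.uniform(0.0, t_max, k):
            cures.append((i, float(s) if s > 0 else t_max))
    arrows: list[tuple[int, int, float]] = []
    coo = net.weights.tocoo()
    for i, j, v in zip(coo.row, coo.col, coo.data):
        k = rng.poisson(v * t_max)
        for s in rng.uniform(0.0, t_max, k):
            arrows.append((int(i), int(j), float(s) if s > 0 else t_max))
    return GraphicalRealisation(t_max=t_max, cures=tuple(cures), arrows=tuple(arrows))


def reachable_set(
    real: GraphicalRealisation, A: Iterable[int], t: float
) -> frozenset[int]:
    """The infected set at time ``t`` given initial infected set ``A``.

    Chronological sweep over merged events up to ``t``: a cure at node
    ``i`` removes ``i`` from the infected set; an arrow ``(i, j, s)`` adds
    ``j`` when ``i`` is infected just before ``s`` (an arrow into an
    already-infected target is a no-op — re-infection does not extend
    reachability).  Equivalent to time-respecting path existence from 0 on
    the lines of ``A``.
    """
    if t < 0 or t > real.t_max:
        raise ValueError("t must lie in [0, t_max]")
    infected = set(A)
    for s, _, kind, payload in real.merged_events():
        if s > t:
            break
        if kind == "cure":
            infected.discard(payload[0])
        else:
            i, j = payload
            if i in infected:
                infected.add(j)
    return frozenset(infected)


def reverse(real: GraphicalRealisation) -> GraphicalRealisation:
    """Turn the diagram upside down about its horizon.

    Cure ``(i, s)`` becomes ``(i, t_max - s)``; arrow ``(i, j, s)``
    becomes ``(j, i, t_max - s)``.  The result is a realisation for the
    transposed network, and reversing twice restores the original event
    multiset.  Order indices are negated so reversed-time ties are broken
    in the opposite sweep order, matching the original diagram.
    """
    tm = real.t_max
    k = 0
    cures = []
    cure_order = []
    for node, s in real.cures:
        cures.append((node, tm - s if s < tm else tm))
        cure_order.append(-real.order[k])
        k += 1
    arrows = []
    arrow_order = []
    for i, j, s in real.arrows:
        arrows.append((j, i, tm - s if s < tm else tm))
        arrow_order.append(-real.order[k])
        k += 1
    return GraphicalRealisation(
        t_max=tm,
        cures=tuple(cures),
        arrows=tuple(arrows),
        order=tuple(cure_order + arrow_order),
    )


def restrict(real: GraphicalRealisation, t: float) -> GraphicalRealisation:
    """Drop events after ``t`` and shrink the horizon to ``t``."""
    if not 0 < t <= real.t_max:
        raise ValueError("restriction time must lie in (0, t_max]")
    cures, cure_order, arrows, arrow_order = [], [], [], []
    k = 0
    for node, s in real.cures:
        if s <= t:
            cures.append((node, s))
            cure_order.append(real.order[k])
        k += 1
    for i, j, s in real.arrows:
        if s <= t:
            arrows.append((i, j, s))
            arrow_order.append(real.order[k])
        k += 1
    return GraphicalRealisation(
        t_max=t,
        cures=tuple(cures),
        arrows=tuple(arrows),
        order=tuple(cure_order + arrow_order),
    )


def duality_check(
    real: GraphicalRealisation,
    A: Iterable[int],
    W: Iterable[int],
    t: float,
) -> tuple[bool, bool, bool]:
    """Per-realisation duality: forward ``A -> W`` vs reversed ``W -> A``.

    ``forward`` asks whether the infected set at ``t`` started from ``A``
    meets ``W``.  ``backward`` restricts the diagram to ``(0, t]``,
    reverses it about ``t``, and asks whether the set reached from ``W``
    meets ``A`` — a sweep on the same randomness read upside down, which
    is a realisation for the transposed network.  The theorem says the two
    indicators agree for every realisation; the third element reports
    their equality.
    """
    A = frozenset(A)
    W = frozenset(W)
    if not A or not W:
        raise ValueError("A and W must be nonempty")
    if not 0 < t <= real.t_max:
        raise ValueError("t must lie in (0, t_max]")
    forward = bool(reachable_set(real, A, t) & W)
    rev = reverse(restrict(real, t))
    backward = bool(reachable_set(rev, W, t) & A)
    return forward, backward, forward == backward
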