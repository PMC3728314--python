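"""Exact finite-state computations for SIS dynamics on small networks.

The master equation over the ``2^n - 1`` non-absorbing (transient) states
is assembled as a sparse sub-generator ``Q``.  For a strongly connected
network the transient states form a single communicating class, so
Perron–Frobenius theory gives a simple dominant eigenvalue ``-alpha`` of
``Q`` with strictly positive left and right eigenvectors:

* the left eigenvector, normalised to sum one, is the quasi-stationary
  distribution (QSD) ``nu`` — the limiting law of the process conditioned
  on non-extinction;
* ``alpha > 0`` is the decay parameter — the asymptotic exponential rate
  at which survival probability decays once the QSD is reached;
* the right eigenvector ``w``, scaled to 1 at the all-infected state, is
  the invasion vector: ``w(A)`` is the limit of the ratio of the survival
  probability from initial state ``A`` to the survival probability from
  all-infected, i.e. the quasi-invasion probability.

States are encoded as bitmasks: bit ``i`` of the integer is set iff node
``i`` is infectious; transient state with mask ``m`` sits at row ``m - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import scipy.sparse as sp
from scipy.linalg import eig as dense_eig
from scipy.sparse.linalg import eigs as sparse_eigs, expm_multiply

from .networks import ContactNetwork, is_strongly_connected

__all__ = [
    "DEFAULT_STATE_CAP",
    "SISStateSpace",
    "SubGenerator",
    "QSDResult",
    "build_subgenerator",
    "compute_qsd",
    "qsd_event_probability",
    "invasion_probability_exact",
    "transient_event_probability",
    "conditioned_prevalence",
    "survival_ratio",
]

#: Default population cap for exact computations; 2^12 - 1 = 4095 transient
#: states keeps the sparse eigensolve and expm action well inside a desktop
#: memory budget.  Override explicitly at your own risk.
DEFAULT_STATE_CAP = 12

_RESIDUAL_TOL = 1e-10


@dataclass(frozen=True)
class SISStateSpace:
    """Bijection between nonempty subsets of ``{0..n-1}`` and row indices.

    Subset ``S`` maps to the integer with bit ``i`` set iff ``i in S``;
    its row index is that integer minus one.  The all-infected state is
    the last row, index ``2^n - 2``.
    """

    n: int

    @property
    def size(self) -> int:
        return (1 << self.n) - 1

    @property
    def full_mask(self) -> int:
        return (1 << self.n) - 1

    def mask(self, subset: Iterable[int]) -> int:
        m = 0
        for i in subset:
            if not 0 <= i < self.n:
                raise ValueError(f"node {i} outside population of size {self.n}")
            m |= 1 << i
        return m

    def index(self, subset: Iterable[int]) -> int:
        m = self.mask(subset)
        if m == 0:
            raise ValueError("empty subset has no transient-state index")
        return m - 1

    def subset(self, index: int) -> frozenset[int]:
        m = index + 1
        return frozenset(i for i in range(self.n) if m >> i & 1)


@dataclass(frozen=True)
class SubGenerator:
    """Rate matrix of the master equation restricted to transient states.

    ``Q`` is ``(2^n - 1) x (2^n - 1)`` with nonnegative off-diagonals;
    ``exit[s]`` is the rate from state ``s`` into the absorbing empty set,
    positive exactly for singleton-infected states.  Every row of ``Q``
    sums to ``-exit[s]``.
    """

    space: SISStateSpace
    Q: sp.csr_array
    exit: np.ndarray

    @property
    def size(self) -> int:
        return self.space.size


def build_subgenerator(
    net: ContactNetwork, cap: int = DEFAULT_STATE_CAP
) -> SubGenerator:
    """Assemble the sub-generator of the SIS master equation.

    For transient state ``S``: infection of susceptible ``j`` occurs at
    rate ``sum_{i in S} T[i, j]``; recovery of infectious ``i`` at rate
    ``g_i``.  Recovery from a singleton state exits to absorption.

    Requires a strongly connected network (so the transient class is
    irreducible and the QSD unique) with ``n`` at most ``cap``.
    """
    if not is_strongly_connected(net):
        raise ValueError("network must be strongly connected")
    n = net.n
    if n > cap:
        raise ValueError(
            f"population {n} exceeds exact-computation cap {cap}; "
            "raise `cap` explicitly or use the gillespie estimators"
        )
    space = SISStateSpace(n)
    W = net.dense()
    g = net.recovery
    nstates = space.size
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    exit_rates = np.zeros(nstates)
    for m in range(1, nstates + 1):
        s = m - 1
        members = [i for i in range(n) if m >> i & 1]
        out = 0.0
        # recoveries
        for i in members:
            m2 = m & ~(1 << i)
            out += g[i]
            if m2 == 0:
                exit_rates[s] = g[i]
            else:
                rows.append(s)
                cols.append(m2 - 1)
                vals.append(g[i])
        # infections: pressure on susceptible j from all infectious members
        pressure = W[members, :].sum(axis=0)
        for j in range(n):
            if m >> j & 1:
                continue
            rate = pressure[j]
            if rate > 0:
                out += rate
                rows.append(s)
                cols.append((m | 1 << j) - 1)
                vals.append(rate)
        rows.append(s)
        cols.append(s)
        vals.append(-out)
    Q = sp.csr_array((vals, (rows, cols)), shape=(nstates, nstates))
    return SubGenerator(space=space, Q=Q, exit=exit_rates)


@dataclass(frozen=True)
class QSDResult:
    """Dominant eigentriple of a sub-generator.

    ``nu``: quasi-stationary distribution (left eigenvector, sums to 1).
    ``alpha``: decay parameter, ``-`` the dominant eigenvalue (per unit time).
    ``w``: invasion vector (right eigenvector, 1 at the all-infected state);
    ``w[space.index(A)]`` is the quasi-invasion probability from ``A``.
    """

    space: SISStateSpace
    nu: np.ndarray
    alpha: float
    w: np.ndarray


def _dominant_pair(Q: sp.csr_array, dense_threshold: int = 127) -> tuple[float, np.ndarray, np.ndarray]:
    """Return (lambda_max, left vector, right vector) for the eigenvalue of
    largest real part; dense solver below the threshold, ARPACK above."""
    nstates = Q.shape[0]
    if nstates == 1:
        q = Q.toarray()[0, 0]
        return float(q), np.ones(1), np.ones(1)
    if nstates <= dense_threshold:
        A = Q.toarray()
        lam, vl, vr = dense_eig(A, left=True, right=True)
        k = int(np.argmax(lam.real))
        return float(lam[k].real), vl[:, k].real.copy(), vr[:, k].real.copy()
    # ARPACK at machine tolerance; 'LR' selects the eigenvalue nearest zero
    # since every eigenvalue of a sub-generator has negative real part.
    try:
        lam_r, vr = sparse_eigs(Q, k=1, which="LR", tol=0)
        lam_l, vl = sparse_eigs(Q.T.tocsr(), k=1, which="LR", tol=0)
    except Exception as exc:  # pragma: no cover - solver failure surfaced
        raise RuntimeError(f"eigensolver failed to converge: {exc}") from exc
    if abs(lam_r[0].imag) > 1e-12 or abs(lam_l[0].real - lam_r[0].real) > 1e-9:
        raise RuntimeError(
            "dominant eigenvalue mismatch between left and right solves: "
            f"{lam_l[0]} vs {lam_r[0]}"
        )
    return float(lam_r[0].real), vl[:, 0].real.copy(), vr[:, 0].real.copy()


def compute_qsd(sub: SubGenerator) -> QSDResult:
    """Quasi-stationary distribution, decay parameter and invasion vector.

    Solves the dominant eigenpair of ``Q`` on both sides and normalises:
    ``nu >= 0`` summing to 1 with ``nu Q = -alpha nu``, and ``w > 0`` with
    ``Q w = -alpha w`` scaled so the all-infected entry is 1.  Residuals
    are verified below 1e-10 in the max-norm; failure raises instead of
    returning a silently inaccurate result.
    """
    lam, vl, vr = _dominant_pair(sub.Q)
    alpha = -lam
    if alpha <= 0:
        raise RuntimeError(f"decay parameter must be positive, got {alpha}")

    nu = vl if vl.sum() >= 0 else -vl
    nu = nu / nu.sum()
    w = vr if vr[-1] >= 0 else -vr
    w = w / w[-1]
    if (nu < -1e-12).any() or (w <= 0).any():
        raise RuntimeError("dominant eigenvectors are not positive; "
                           "is the transient class irreducible?")
    nu = np.clip(nu, 0.0, None)
    nu = nu / nu.sum()

    res_l = np.abs(sub.Q.T @ nu + alpha * nu).max()
    res_r = np.abs(sub.Q @ w + alpha * w).max() / np.abs(w).max()
    if res_l > _RESIDUAL_TOL or res_r > _RESIDUAL_TOL:
        raise RuntimeError(
            f"eigen residuals too large (left {res_l:.2e}, right {res_r:.2e})"
        )
    return QSDResult(space=sub.space, nu=nu, alpha=float(alpha), w=w)


def _event_indicator(space: SISStateSpace, W: Iterable[int]) -> np.ndarray:
    """Indicator over transient states of the event ``S ∩ W ≠ ∅``."""
    wmask = space.mask(W)
    if wmask == 0:
        raise ValueError("subset W must be nonempty")
    idx = np.arange(1, space.size + 1)
    return ((idx & wmask) != 0).astype(np.float64)


def qsd_event_probability(result: QSDResult, W: Iterable[int]) -> float:
    """Probability that at least one member of ``W`` is infectious in the QSD.

    For a singleton ``W = {i}`` this is the marginal quasi-prevalence
    ``p_i``.  For ``W`` the whole population it is 1: every transient
    state has someone infectious.
    """
    f = _event_indicator(result.space, W)
    return float(result.nu @ f)


def invasion_probability_exact(result: QSDResult, A: Iterable[int]) -> float:
    """Quasi-invasion probability from initial infected set ``A``.

    Defined as the large-time limit of survival(A, t) / survival(full, t);
    computed spectrally as the invasion-vector entry ``w(A)``, which lies
    in ``(0, 1]`` and equals 1 when all individuals start infected.
    """
    idx = result.space.index(A)
    return float(result.w[idx])


def transient_event_probability(
    net: ContactNetwork,
    A: Iterable[int],
    W: Iterable[int],
    t: float,
    sub: SubGenerator | None = None,
    cap: int = DEFAULT_STATE_CAP,
) -> float:
    """Probability that some member of ``W`` is infectious at time ``t``
    when exactly the members of ``A`` are infectious at time 0.

    Computed as ``e_A^T exp(Q t) f_W`` where ``f_W`` indicates transient
    states intersecting ``W``.  With ``W`` the whole population this is
    the survival probability from ``A``.
    """
    if t < 0:
        raise ValueError("time must be nonnegative")
    if sub is None:
        sub = build_subgenerator(net, cap=cap)
    a_idx = sub.space.index(A)
    f = _event_indicator(sub.space, W)
    if t == 0:
        return float(f[a_idx])
    out = expm_multiply(sub.Q * t, f)
    return float(np.clip(out[a_idx], 0.0, 1.0))


def conditioned_prevalence(
    net: ContactNetwork,
    W: Iterable[int],
    t: float,
    sub: SubGenerator | None = None,
    cap: int = DEFAULT_STATE_CAP,
) -> float:
    """P(some member of W infectious at t | survival to t), all infected at 0.

    As ``t`` grows this converges to the QSD event probability of ``W``.
    Survival from the all-infected state is strictly positive at any
    finite ``t``, so the ratio is well defined.
    """
    if sub is None:
        sub = build_subgenerator(net, cap=cap)
    full = range(sub.space.n)
    num = transient_event_probability(net, full, W, t, sub=sub)
    den = transient_event_probability(net, full, full, t, sub=sub)
    if den <= 0:
        raise ZeroDivisionError(
            f"survival probability underflowed at t={t}; use a smaller horizon"
        )
    return min(num / den, 1.0)


def survival_ratio(
    net: ContactNetwork,
    A: Iterable[int],
    t: float,
    sub: SubGenerator | None = None,
    cap: int = DEFAULT_STATE_CAP,
) -> float:
    """Ratio of survival from ``A`` to survival from all-infected at ``t``.

    Converges to the quasi-invasion probability ``w(A)`` as ``t`` grows.
    """
    if sub is None:
        sub = build_subgenerator(net, cap=cap)
    full = range(sub.space.n)
    num = transient_event_probability(net, A, full, t, sub=sub)
    den = transient_event_probability(net, full, full, t, sub=sub)
    if den <= 0:
        raise ZeroDivisionError(
            f"survival probability underflowed at t={t}; use a smaller horizon"
        )
    return num / den
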