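"""Contact-network data model, generators, connectivity analysis and file I/O.

A :class:`ContactNetwork` is the full parameterisation of the SIS model:
a weighted directed rate matrix ``T`` whose entry ``(i, j)`` is the
Poisson rate at which individual ``i`` infects individual ``j`` (while
``i`` is infectious and ``j`` susceptible), plus a strictly positive
per-individual recovery-rate vector ``g``.  Row = infector is the
orientation convention throughout; :func:`transpose` swaps it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

__all__ = [
    "ContactNetwork",
    "NetworkParseError",
    "transpose",
    "is_strongly_connected",
    "largest_scc",
    "lattice_network",
    "complete_network",
    "random_strongly_connected_network",
    "generate_network",
    "read_network",
    "write_network",
]


class NetworkParseError(ValueError):
    """Malformed network file; message carries the offending line number."""


def _canonical(weights: sp.csr_array) -> sp.csr_array:
    """Return a canonical CSR copy (duplicates summed, indices sorted,
    explicit zeros dropped) so structurally equal matrices compare equal."""
    w = sp.csr_array(weights, dtype=np.float64)
    w.sum_duplicates()
    w.eliminate_zeros()
    w.sort_indices()
    return w


@dataclass(frozen=True)
class ContactNetwork:
    """Weighted directed contact network with per-node recovery rates.

    Parameters
    ----------
    weights
    	``n x n`` nonnegative rate matrix (stored sparse CSR); entry
    	``(i, j)`` is the rate at which ``i`` infects ``j``. The diagonal
    	must be zero: self-infection is meaningless in the SIS model.
    recovery
    	Length-``n`` strictly positive recovery rates ``g_i``.
    labels
    	Optional external node identifiers, preserved through I/O and
    	transposition; internal indices are always ``0..n-1``.
    """

    weights: sp.csr_array
    recovery: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        w = _canonical(self.weights)
        if w.shape[0] != w.shape[1]:
            raise ValueError(f"weight matrix must be square, got {w.shape}")
        if w.nnz and w.data.min() < 0:
            raise ValueError("infection rates must be nonnegative")
        if w.diagonal().any():
            raise ValueError("diagonal (self-infection) rates must be zero")
        g = np.asarray(self.recovery, dtype=np.float64)
        if g.ndim != 1 or g.shape[0] != w.shape[0]:
            raise ValueError(
                f"recovery vector length {g.shape} does not match n={w.shape[0]}"
            )
        if not (g > 0).all():
            raise ValueError("recovery rates must be strictly positive")
        if self.labels is not None:
            labels = tuple(str(x) for x in self.labels)
            if len(labels) != w.shape[0]:
                raise ValueError("labels length does not match population size")
            if len(set(labels)) != len(labels):
                raise ValueError("labels must be unique")
            object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "recovery", g)

    @property
    def n(self) -> int:
        """Population size."""
        return self.weights.shape[0]

    def dense(self) -> np.ndarray:
        """Dense copy of the rate matrix."""
        return self.weights.toarray()

    def equals(self, other: "ContactNetwork") -> bool:
        """Bit-exact equality of rates, recovery and labels."""
        if self.n != other.n or self.labels != other.labels:
            return False
        if not np.array_equal(self.recovery, other.recovery):
            return False
        a, b = self.weights, other.weights
        return (
            np.array_equal(a.indptr, b.indptr)
            and np.array_equal(a.indices, b.indices)
            and np.array_equal(a.data, b.data)
        )


def transpose(net: ContactNetwork) -> ContactNetwork:
    """Reverse every transmission route: output rate (i, j) = input rate (j, i).

    Recovery rates and labels are unchanged.  Applying ``transpose`` twice
    reproduces the original network exactly.
    """
    return ContactNetwork(
        weights=sp.csr_array(net.weights.T),
        recovery=net.recovery.copy(),
        labels=net.labels,
    )


def is_strongly_connected(net: ContactNetwork) -> bool:
    """True iff every ordered node pair is joined by a directed path of
    positive-rate edges (a single node is trivially strongly connected).

    Strong connectivity makes the transient states of the SIS master
    equation a single communicating class, guaranteeing a unique
    quasi-stationary distribution.
    """
    if net.n == 1:
        return True
    ncomp, _ = connected_components(net.weights, directed=True, connection="strong")
    return ncomp == 1


def largest_scc(net: ContactNetwork) -> tuple[ContactNetwork, np.ndarray]:
    """Induced sub-network on the largest strongly connected component.

    Ties between equally large components are broken in favour of the one
    containing the smallest original node index.  Returns the sub-network
    and the map from new indices to original indices (sorted ascending).
    """
    _, comp = connected_components(net.weights, directed=True, connection="strong")
    sizes = np.bincount(comp)
    best = None
    for c in range(sizes.shape[0]):
        members = np.flatnonzero(comp == c)
        key = (sizes[c], -members.min())
        if best is None or key > best[0]:
            best = (key, members)
    members = best[1]
    sub = net.weights[np.ix_(members, members)]
    labels = None
    if net.labels is not None:
        labels = tuple(net.labels[i] for i in members)
    out = ContactNetwork(
        weights=sp.csr_array(sub), recovery=net.recovery[members], labels=labels
    )
    return out, members


# ---------------------------------------------------------------------------
# generators


def lattice_network(
    rows: int, cols: int, beta: float, recovery: float = 1.0
) -> ContactNetwork:
    """Homogeneously weighted non-periodic square lattice.

    Nearest-neighbour 4-connectivity; every adjacency carries the symmetric
    rate ``beta`` in both directions, so the network is undirected.
    """
    if rows < 1 or cols < 1:
        raise ValueError("lattice dimensions must be positive")
    if beta <= 0:
        raise ValueError("transmission rate beta must be positive")
    n = rows * cols
    src, dst = [], []
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            if c + 1 < cols:
                src += [i, i + 1]
                dst += [i + 1, i]
            if r + 1 < rows:
                j = i + cols
                src += [i, j]
                dst += [j, i]
    w = sp.csr_array(
        (np.full(len(src), beta), (src, dst)), shape=(n, n), dtype=np.float64
    )
    return ContactNetwork(weights=w, recovery=np.full(n, float(recovery)))


def complete_network(n: int, beta: float, recovery: float = 1.0) -> ContactNetwork:
    """Fully connected network: every off-diagonal rate equals ``beta``."""
    if n < 1:
        raise ValueError("population size must be positive")
    if beta <= 0:
        raise ValueError("transmission rate beta must be positive")
    w = np.full((n, n), float(beta))
    np.fill_diagonal(w, 0.0)
    return ContactNetwork(weights=sp.csr_array(w), recovery=np.full(n, float(recovery)))


def random_strongly_connected_network(
    n: int,
    extra_edge_prob: float,
    weight_sampler: Callable[[np.random.Generator, int], np.ndarray]
    | tuple[float, float] = (0.1, 1.0),
    seed: int | np.random.SeedSequence | None = None,
    recovery: float | tuple[float, float] = 1.0,
) -> ContactNetwork:
    """Random directed network guaranteed strongly connected.

    A directed Hamiltonian cycle through a random node permutation
    guarantees strong connectivity; each remaining ordered pair receives an
    independent extra edge with probability ``extra_edge_prob``.  Weights
    are drawn from ``weight_sampler`` — either a callable
    ``(rng, size) -> array`` or a ``(low, high)`` uniform range.  Recovery
    rates are uniform in a ``(low, high)`` range or a constant.  The same
    seed reproduces the network bit-exactly.
    """
    if n < 1:
        raise ValueError("population size must be positive")
    if not 0.0 <= extra_edge_prob <= 1.0:
        raise ValueError("extra edge probability must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if callable(weight_sampler):
        draw = weight_sampler
    else:
        lo, hi = weight_sampler
        if lo <= 0:
            raise ValueError("weight range must be positive")
        draw = lambda r, size: r.uniform(lo, hi, size)  # noqa: E731

    order = rng.permutation(n)
    edges = {
        (int(order[k]), int(order[(k + 1) % n])) for k in range(n)
    } if n > 1 else set()
    if n > 1 and extra_edge_prob > 0:
        mask = rng.random((n, n)) < extra_edge_prob
        np.fill_diagonal(mask, False)
        for i, j in zip(*np.nonzero(mask)):
            edges.add((int(i), int(j)))
    edges = sorted(edges)
    if edges:
        weights = np.asarray(draw(rng, len(edges)), dtype=np.float64)
        if (weights <= 0).any():
            raise ValueError("weight sampler produced non-positive rates")
        src = [e[0] for e in edges]
        dst = [e[1] for e in edges]
        w = sp.csr_array((weights, (src, dst)), shape=(n, n))
    else:
        w = sp.csr_array((n, n), dtype=np.float64)
    if isinstance(recovery, tuple):
        g = rng.uniform(recovery[0], recovery[1], n)
    else:
        g = np.full(n, float(recovery))
    return ContactNetwork(weights=w, recovery=g)


def generate_network(kind: str, **params) -> ContactNetwork:
    """Dispatch to a named generator: ``lattice``, ``complete`` or
    ``random_strongly_connected``."""
    kinds = {
        "lattice": lattice_network,
        "complete": complete_network,
        "random_strongly_connected": random_strongly_connected_network,
    }
    if kind not in kinds:
        raise ValueError(f"unknown generator kind {kind!r}; choose from {sorted(kinds)}")
    return kinds[kind](**params)


# ---------------------------------------------------------------------------
# file I/O
#
# Edge-list dialect: delimited text, columns source/target/rate, '#' comments
# and an optional header; adjacency dialect: full square matrix.  Recovery
# rates come from a separate two-column table or a scalar default.  Duplicate
# edges are an error (silent summing can mask data faults), as are self-loops
# and negative rates.


def _parse_recovery(
    path: str | Path, labels: Sequence[str], delimiter: str | None
) -> np.ndarray:
    index = {lab: i for i, lab in enumerate(labels)}
    g = np.full(len(labels), np.nan)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter)
            if len(parts) != 2:
                raise NetworkParseError(
                    f"{path}:{lineno}: expected 2 columns (node, rate), got {len(parts)}"
                )
            node, rate = parts
            if node == "node" and lineno == 1:
                continue
            if node not in index:
                raise NetworkParseError(f"{path}:{lineno}: unknown node label {node!r}")
            try:
                val = float(rate)
            except ValueError:
                raise NetworkParseError(
                    f"{path}:{lineno}: recovery rate {rate!r} is not a number"
                ) from None
            if val <= 0:
                raise NetworkParseError(
                    f"{path}:{lineno}: recovery rate must be positive, got {val}"
                )
            if not np.isnan(g[index[node]]):
                raise NetworkParseError(f"{path}:{lineno}: duplicate node {node!r}")
            g[index[node]] = val
    if np.isnan(g).any():
        missing = [labels[i] for i in np.flatnonzero(np.isnan(g))]
        raise NetworkParseError(f"{path}: recovery rates missing for nodes {missing}")
    return g


def read_network(
    path: str | Path,
    dialect: str = "edgelist",
    recovery: str | Path | float = 1.0,
    delimiter: str | None = None,
) -> ContactNetwork:
    """Read a contact network from delimited text.

    ``dialect='edgelist'``: rows ``source target rate`` (any labels, an
    optional ``source``-headed header line, ``#`` comments).  Nodes are
    ordered by first appearance.  ``dialect='adjacency'``: a full square
    matrix; nodes are labelled ``0..n-1``.  ``recovery`` is a scalar rate
    applied to every node or the path of a two-column ``node rate`` table.
    ``delimiter=None`` splits on any whitespace.
    """
    path = Path(path)
    if dialect == "edgelist":
        labels: list[str] = []
        index: dict[str, int] = {}
        rows: list[tuple[int, int, float]] = []
        seen: set[tuple[int, int]] = set()
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split(delimiter)
                if len(parts) != 3:
                    raise NetworkParseError(
                        f"{path}:{lineno}: expected 3 columns "
                        f"(source, target, rate), got {len(parts)}"
                    )
                s, t, r = parts
                if lineno == 1 and s.lower() == "source":
                    continue
                try:
                    rate = float(r)
                except ValueError:
                    raise NetworkParseError(
                        f"{path}:{lineno}: rate {r!r} is not a number"
                    ) from None
                if rate < 0:
                    raise NetworkParseError(
                        f"{path}:{lineno}: negative rate {rate}"
                    )
                if s == t:
                    raise NetworkParseError(
                        f"{path}:{lineno}: self-loop on node {s!r}"
                    )
                for lab in (s, t):
                    if lab not in index:
                        index[lab] = len(labels)
                        labels.append(lab)
                key = (index[s], index[t])
                if key in seen:
                    raise NetworkParseError(
                        f"{path}:{lineno}: duplicate edge {s!r} -> {t!r}"
                    )
                seen.add(key)
                rows.append((key[0], key[1], rate))
        n = len(labels)
        if n == 0:
            raise NetworkParseError(f"{path}: no edges found")
        w = sp.csr_array(
            (
                [r for _, _, r in rows],
                ([i for i, _, _ in rows], [j for _, j, _ in rows]),
            ),
            shape=(n, n),
        )
        label_tuple: tuple[str, ...] | None = tuple(labels)
    elif dialect == "adjacency":
        try:
            mat = np.loadtxt(path, delimiter=delimiter, ndmin=2)
        except ValueError as exc:
            raise NetworkParseError(f"{path}: malformed adjacency matrix: {exc}") from None
        if mat.shape[0] != mat.shape[1]:
            raise NetworkParseError(
                f"{path}: adjacency matrix must be square, got {mat.shape}"
            )
        if (mat < 0).any():
            raise NetworkParseError(f"{path}: negative rate in adjacency matrix")
        if np.diagonal(mat).any():
            raise NetworkParseError(f"{path}: nonzero diagonal (self-loop) entry")
        w = sp.csr_array(mat)
        label_tuple = tuple(str(i) for i in range(mat.shape[0]))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if isinstance(recovery, (int, float)):
        g = np.full(w.shape[0], float(recovery))
    else:
        g = _parse_recovery(recovery, label_tuple, delimiter)
    return ContactNetwork(weights=w, recovery=g, labels=label_tuple)


def write_network(
    net: ContactNetwork,
    path: str | Path,
    dialect: str = "edgelist",
    recovery_path: str | Path | None = None,
) -> None:
    """Write a network as delimited text; full-precision round trip.

    Rates are written with ``repr`` precision so ``read_network`` recovers
    them bit-exactly.  If ``recovery_path`` is given the recovery table is
    written alongside as ``node<TAB>rate``.
    """
    path = Path(path)
    labels = net.labels or tuple(str(i) for i in range(net.n))
    if dialect == "edgelist":
        coo = net.weights.tocoo()
        order = np.lexsort((coo.col, coo.row))
        with open(path, "w") as fh:
            fh.write("# source\ttarget\trate\n")
            for k in order:
                fh.write(
                    f"{labels[coo.row[k]]}\t{labels[coo.col[k]]}\t{float(coo.data[k])!r}\n"
                )
    elif dialect == "adjacency":
        np.savetxt(path, net.weights.toarray(), delimiter="\t", fmt="%.17g")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if recovery_path is not None:
        with open(recovery_path, "w") as fh:
            fh.write("# node\trate\n")
            for lab, g in zip(labels, net.recovery):
                fh.write(f"{lab}\t{float(g)!r}\n")
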