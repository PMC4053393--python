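"""Bipartite modularity and its optimization by simulated annealing.

The default objective is Barber's bipartite modularity

    Q = (1/m) sum_ij [ a_ij - k_i d_j / m ] delta(g_i, g_j)

over ant-plant pairs, with m the number of edges, k_i the ant degree and
d_j the plant degree.  Ants and plants share one module label space.  A
unipartite Newman projection (the bipartite adjacency treated as an
ordinary graph) is provided as a sensitivity variant.

Both objectives reduce to a symmetric node-pair benefit matrix W plus a
partition-independent offset, so that Q(partition) = sum over same-module
node pairs of W + offset.  Single-node moves, merges and splits then have
cheap exact deltas, which the annealer and the exhaustive oracle share.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .exceptions import ConfigurationError, UndefinedMetricError

OBJECTIVES = ("barber_bipartite", "newman_projection")

_EXHAUSTIVE_MAX_NODES = 10


@dataclass(frozen=True)
class Partition:
    """Module assignment over the concatenated node set (ants first, then plants)."""

    labels: tuple

    def __post_init__(self):
        labs = tuple(int(x) for x in self.labels)
        seen: dict = {}
        norm = []
        for x in labs:
            if x not in seen:
                seen[x] = len(seen)
            norm.append(seen[x])
        object.__setattr__(self, "labels", tuple(norm))

    @property
    def n_modules(self) -> int:
        return len(set(self.labels))


@dataclass(frozen=True)
class SASchedule:
    """Annealing knobs: geometric cooling from an automatically scaled T0.

    ``proposal_factor`` (c) gives c * n^2 single-node moves plus c * n
    merge/split moves per temperature step.
    """

    t0: Optional[float] = None       # None: scaled to the spread of initial move deltas
    cooling: float = 0.95
    t_min_ratio: float = 1e-3        # stop when T < t0 * ratio
    proposal_factor: int = 1
    polish: bool = True              # deterministic greedy descent from the best state

    def __post_init__(self):
        if not (0.0 < self.cooling < 1.0):
            raise ConfigurationError(f"cooling factor must be in (0, 1), got {self.cooling}")
        if self.proposal_factor < 1:
            raise ConfigurationError("proposal_factor must be >= 1")


@dataclass(frozen=True)
class ModularityResult:
    best_q: float
    best_partition: Partition
    objective: str
    sa_trace: tuple      # (temperature, best-so-far) pairs; empty for exhaustive search
    seed: Optional[int]


def _benefit_matrix(matrix, objective: str) -> Tuple[np.ndarray, float]:
    """Symmetric W over all nodes and the constant offset for the objective."""
    if objective not in OBJECTIVES:
        raise ConfigurationError(f"objective must be one of {OBJECTIVES}, got {objective!r}")
    a = (np.asarray(matrix) > 0).astype(np.float64)
    m = a.sum()
    if a.ndim != 2 or m == 0:
        raise UndefinedMetricError("modularity needs a 2-D matrix with at least one edge")
    r, c = a.shape
    n = r + c
    w = np.zeros((n, n))
    if objective == "barber_bipartite":
        k = a.sum(axis=1)
        d = a.sum(axis=0)
        b = (a - np.outer(k, d) / m) / m
        w[:r, r:] = b
        w[r:, :r] = b.T
        offset = 0.0
    else:  # newman_projection
        full = np.zeros((n, n))
        full[:r, r:] = a
        full[r:, :r] = a.T
        deg = full.sum(axis=1)
        bn = (full - np.outer(deg, deg) / (2 * m)) / m
        np.fill_diagonal(bn, 0.0)
        w = bn
        offset = -float((deg**2).sum()) / (4 * m * m)
    return w, offset


def evaluate_modularity(matrix, partition: Partition, objective: str = "barber_bipartite") -> float:
    """Modularity of a given partition of the ants + plants node set."""
    w, offset = _benefit_matrix(matrix, objective)
    labels = np.asarray(partition.labels)
    if len(labels) != w.shape[0]:
        raise ConfigurationError(
            f"partition covers {len(labels)} nodes, matrix has {w.shape[0]}"
        )
    same = labels[:, None] == labels[None, :]
    return 0.5 * float(w[same].sum()) + offset


def _q_of_labels(w: np.ndarray, offset: float, labels: np.ndarray) -> float:
    same = labels[:, None] == labels[None, :]
    return 0.5 * float(w[same].sum()) + offset


def _greedy_polish(w: np.ndarray, offset: float, labels: np.ndarray) -> Tuple[np.ndarray, float]:
    """Deterministic best-improvement single-node descent."""
    n = len(labels)
    labels = labels.copy()
    improved = True
    passes = 0
    while improved and passes < 200:
        improved = False
        passes += 1
        for u in range(n):
            g = labels[u]
            row = w[u]
            mods = np.unique(labels)
            gain_stay = row[labels == g].sum()
            best_gain, best_mod = 0.0, g
            for gp in mods:
                if gp == g:
                    continue
                gain = row[labels == gp].sum() - gain_stay
                if gain > best_gain + 1e-12:
                    best_gain, best_mod = gain, gp
            # also try an own fresh module
            if -gain_stay > best_gain + 1e-12:
                best_gain, best_mod = -gain_stay, labels.max() + 1
            if best_mod != g:
                labels[u] = best_mod
                improved = True
    return labels, _q_of_labels(w, offset, labels)


def sa_optimize(
    matrix,
    objective: str = "barber_bipartite",
    seed: int = 0,
    schedule: Optional[SASchedule] = None,
) -> ModularityResult:
    """Simulated-annealing search for the maximum-modularity partition.

    Starts from singleton modules; per temperature step performs c*n^2
    single-node reassignments and c*n merge/split proposals with Metropolis
    acceptance, cooling geometrically.  Deterministic given ``seed``.  The
    all-in-one baseline (Q = 0) is always evaluated, so the result is never
    negative.

    Internally maintains S[u, g] = sum of W[u, v] over nodes v in module g,
    so a single-node move delta is an O(1) lookup.
    """
    schedule = schedule or SASchedule()
    w, offset = _benefit_matrix(matrix, objective)
    n = w.shape[0]
    rng = np.random.default_rng(seed)

    labels = np.arange(n)
    sizes = np.ones(n, dtype=np.int64)        # module occupancy; ids 0..n-1
    s = w.copy()                              # S[u, g]: singletons -> S = W
    q = _q_of_labels(w, offset, labels)
    best_labels, best_q = labels.copy(), q

    def move(u: int, g_new: int):
        g_old = labels[u]
        labels[u] = g_new
        s[:, g_old] -= w[u]
        s[:, g_new] += w[u]
        sizes[g_old] -= 1
        sizes[g_new] += 1

    # T0 from the spread of single-node move deltas at the start
    if schedule.t0 is None:
        us = rng.integers(n, size=max(50, 2 * n))
        gs = rng.integers(n, size=len(us))
        deltas = s[us, gs] - s[us, labels[us]]
        t0 = 2.0 * float(np.std(deltas))
        if t0 <= 0:
            t0 = 0.05
    else:
        t0 = schedule.t0

    trace: List[Tuple[float, float]] = []
    t = t0
    c = schedule.proposal_factor
    while t > t0 * schedule.t_min_ratio:
        for _ in range(c * n * n):
            u = int(rng.integers(n))
            g = int(labels[u])
            active = np.flatnonzero(sizes)
            pick = int(rng.integers(len(active) + 1))
            if pick < len(active):
                gp = int(active[pick])
            else:  # fresh module: reuse any empty id
                if sizes[g] == 1:
                    continue  # u already alone; a fresh module is a no-op
                empty = np.flatnonzero(sizes == 0)
                if len(empty) == 0:
                    continue
                gp = int(empty[0])
            if gp == g:
                continue
            delta = s[u, gp] - s[u, g]
            if delta >= 0 or rng.random() < np.exp(delta / t):
                move(u, gp)
                q += delta
                if q > best_q + 1e-12:
                    best_q, best_labels = q, labels.copy()
        for _ in range(c * n):
            active = np.flatnonzero(sizes)
            if rng.random() < 0.5 and len(active) >= 2:
                g1, g2 = (int(x) for x in rng.choice(active, size=2, replace=False))
                members2 = np.flatnonzero(labels == g2)
                delta = float(s[members2, g1].sum())
                if delta >= 0 or rng.random() < np.exp(delta / t):
                    labels[members2] = g1
                    s[:, g1] += s[:, g2]
                    s[:, g2] = 0.0
                    sizes[g1] += sizes[g2]
                    sizes[g2] = 0
                    q += delta
            else:
                big = active[sizes[active] >= 2]
                if len(big) == 0:
                    continue
                g = int(rng.choice(big))
                empty = np.flatnonzero(sizes == 0)
                if len(empty) == 0:
                    continue
                members = np.flatnonzero(labels == g)
                side = rng.random(len(members)) < 0.5
                if side.all() or not side.any():
                    continue
                part2 = members[side]
                gp = int(empty[0])
                col = w[:, part2].sum(axis=1)
                delta = -float(col[members[~side]].sum())
                if delta >= 0 or rng.random() < np.exp(delta / t):
                    labels[part2] = gp
                    s[:, gp] = col
                    s[:, g] -= col
                    sizes[gp] = len(part2)
                    sizes[g] -= len(part2)
                    q += delta
            if q > best_q + 1e-12:
                best_q, best_labels = q, labels.copy()
        trace.append((t, best_q))
        t *= schedule.cooling

    if schedule.polish:
        polished, pq = _greedy_polish(w, offset, best_labels)
        if pq > best_q:
            best_q, best_labels = pq, polished

    if best_q < 0.0:  # all-in-one baseline scores exactly 0
        best_q, best_labels = 0.0, np.zeros(n, dtype=int)
    best_q = _q_of_labels(w, offset, best_labels)  # re-evaluate: no drift from incremental updates
    return ModularityResult(best_q, Partition(tuple(best_labels)), objective, tuple(trace), seed)


def optimize_modularity(
    matrix,
    objective: str = "barber_bipartite",
    seed: int = 0,
    n_restarts: int = 5,
    schedule: Optional[SASchedule] = None,
) -> ModularityResult:
    """Best-of-k annealing restarts (seeds seed, seed+1, ...)."""
    if n_restarts < 1:
        raise ConfigurationError("n_restarts must be >= 1")
    best = None
    for i in range(n_restarts):
        res = sa_optimize(matrix, objective=objective, seed=seed + i, schedule=schedule)
        if best is None or res.best_q > best.best_q:
            best = res
    return best


def _set_partitions(n: int):
    """All set partitions of range(n) as restricted-growth label arrays."""
    labels = np.zeros(n, dtype=int)

    def rec(i: int, max_used: int):
        if i == n:
            yield labels
            return
        for g in range(max_used + 2):
            labels[i] = g
            yield from rec(i + 1, max(max_used, g))

    yield from rec(1, 0)


def exhaustive_modularity(matrix, objective: str = "barber_bipartite") -> ModularityResult:
    """Global modularity optimum by enumerating all set partitions.

    Guarded to at most 10 total nodes (Bell numbers explode beyond that);
    intended as the test oracle for the annealer.
    """
    w, offset = _benefit_matrix(matrix, objective)
    n = w.shape[0]
    if n > _EXHAUSTIVE_MAX_NODES:
        raise ConfigurationError(
            f"exhaustive search limited to {_EXHAUSTIVE_MAX_NODES} nodes, got {n}"
        )
    best_q, best_labels = -np.inf, None
    for labels in _set_partitions(n):
        q = _q_of_labels(w, offset, labels)
        if q > best_q + 1e-15:
            best_q, best_labels = q, labels.copy()
    return ModularityResult(float(best_q), Partition(tuple(best_labels)), objective, (), None)
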