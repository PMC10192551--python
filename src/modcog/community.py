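"""Louvain modularity maximization with a resolution parameter.

Implements the generalized modularity quality function

    Q(gamma) = (1/2m) * sum_ij [A_ij - gamma * k_i k_j / (2m)] * delta(c_i, c_j)

for non-negative weighted graphs (k_i = weighted degree, 2m = total weight,
and the Kronecker delta includes i = j), together with a stochastic two-phase
greedy maximizer: phase 1 sweeps nodes in a seed-shuffled order, moving each
node to the neighbouring community with the largest strictly positive
modularity gain until a full pass makes no move; phase 2 aggregates
communities into super-nodes (intra-community weight accumulates as
self-loops) and repeats. Because each run can end in a different local
optimum, per-session modularity is summarized as the median Q over many runs,
swept over a grid of resolution values.

An exact brute-force maximizer over all set partitions is provided as a test
oracle for graphs of up to 10 nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import ConnectivityMatrix
from .errors import DegenerateInputError, FormatError, ParameterError

__all__ = [
    "DEFAULT_GAMMA_GRID",
    "Partition",
    "QProfile",
    "modularity_q",
    "louvain_once",
    "brute_force_best_partition",
    "median_q",
    "gamma_sweep",
]

#: Resolution grid: 0.5 to 3 in increments of 0.5.
DEFAULT_GAMMA_GRID = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)


@dataclass
class Partition:
    """Node -> community assignment, canonicalized to contiguous ids.

    Canonical form relabels communities by order of first appearance, so two
    partitions are equal iff they group nodes identically.
    """

    assignment: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.assignment)
        if a.ndim != 1 or a.size == 0:
            raise FormatError("assignment must be a non-empty 1-D array")
        _, canon = np.unique(a, return_inverse=True)
        # relabel by first appearance rather than sorted label value
        order = {}
        out = np.empty(a.size, dtype=int)
        for i, lab in enumerate(canon):
            if lab not in order:
                order[lab] = len(order)
            out[i] = order[lab]
        self.assignment = out

    @property
    def n_nodes(self) -> int:
        return self.assignment.size

    @property
    def n_communities(self) -> int:
        return int(self.assignment.max()) + 1

    def __eq__(self, other):
        return isinstance(other, Partition) and np.array_equal(
            self.assignment, other.assignment
        )


@dataclass
class QProfile:
    """Per-resolution distribution of Q over stochastic runs."""

    gammas: tuple
    q_runs: dict  # gamma -> list of Q values, one per run
    medians: dict  # gamma -> median Q
    best_partitions: dict  # gamma -> Partition with the highest Q seen
    n_runs: int
    seed: int

    def __post_init__(self):
        g = tuple(self.gammas)
        if any(b <= a for a, b in zip(g, g[1:])):
            raise FormatError("gamma grid must be strictly increasing")
        for gamma, runs in self.q_runs.items():
            med = float(np.median(runs))
            if abs(med - self.medians[gamma]) > 1e-12:
                raise FormatError(f"median_q inconsistent with run list at gamma={gamma}")


def _check_prepared(cm: ConnectivityMatrix) -> np.ndarray:
    w = cm.weights
    if (w < 0).any():
        raise ParameterError(
            "matrix has negative weights; apply prepare_for_modularity first"
        )
    if w.sum() <= 0:
        raise DegenerateInputError("graph has no edge weight")
    return w


def modularity_q(cm: ConnectivityMatrix, p: Partition, gamma: float = 1.0) -> float:
    """Generalized modularity of a partition.

    Evaluates Q = (1/2m) * sum_ij [A_ij - gamma * k_i k_j/(2m)] delta(c_i,c_j)
    with the i = j terms of the null model included (so Q = 0 exactly for the
    all-in-one partition at gamma = 1).
    """
    w = _check_prepared(cm)
    if p.n_nodes != cm.n_nodes:
        raise FormatError(
            f"partition covers {p.n_nodes} nodes but the graph has {cm.n_nodes}"
        )
    W = w.sum()  # = 2m
    k = w.sum(axis=1)
    labels = p.assignment
    q = 0.0
    for c in range(p.n_communities):
        idx = labels == c
        s_in = w[np.ix_(idx, idx)].sum()
        s_tot = k[idx].sum()
        q += s_in / W - gamma * (s_tot / W) ** 2
    return float(q)


def _phase_one(B: np.ndarray, k: np.ndarray, W: float, gamma: float, rng) -> tuple:
    """One level of greedy local moves. Returns (labels, n_moves_total)."""
    n = B.shape[0]
    comm = np.arange(n)
    sigma_tot = k.copy()
    self_w = np.diag(B).copy()
    total_moves = 0
    while True:
        moves = 0
        for i in rng.permutation(n):
            cur = comm[i]
            links = np.bincount(comm, weights=B[i], minlength=n)
            links[cur] -= self_w[i]  # self-loop stays with the node
            sigma_tot[cur] -= k[i]
            gains = links - gamma * k[i] * sigma_tot / W
            cur_gain = gains[cur]
            # candidates: communities the node actually touches, plus its own
            cand = np.flatnonzero(links > 0)
            best = cur
            best_gain = cur_gain
            tol = 1e-12 * max(1.0, abs(float(gains.max(initial=0.0))))
            for c in cand:
                g = gains[c]
                if g > best_gain + tol or (
                    abs(g - best_gain) <= tol and best != cur and c < best
                ):
                    best, best_gain = c, g
            comm[i] = best
            sigma_tot[best] += k[i]
            if best != cur:
                moves += 1
        total_moves += moves
        if moves == 0:
            break
    return comm, total_moves


def louvain_once(
    cm: ConnectivityMatrix, gamma: float = 1.0, seed: int = 0
) -> tuple[Partition, float]:
    """One stochastic Louvain run; returns (partition, Q).

    The returned Q always equals :func:`modularity_q` recomputed for the
    returned partition on the original graph (internal consistency contract).
    """
    if gamma <= 0:
        raise ParameterError("gamma must be positive")
    w = _check_prepared(cm)
    rng = np.random.default_rng(seed)
    W = w.sum()
    B = w.copy()
    k = B.sum(axis=1)
    node_to_comm = np.arange(cm.n_nodes)
    while True:
        labels, n_moves = _phase_one(B, k, W, gamma, rng)
        _, labels = np.unique(labels, return_inverse=True)
        node_to_comm = labels[node_to_comm]
        n_comm = labels.max() + 1
        if n_moves == 0 or n_comm == B.shape[0]:
            break
        # phase 2: aggregate communities into super-nodes
        ind = np.zeros((B.shape[0], n_comm))
        ind[np.arange(B.shape[0]), labels] = 1.0
        B = ind.T @ B @ ind
        k = B.sum(axis=1)  # row sums incl. self-loop once = community strengths
    part = Partition(node_to_comm)
    return part, modularity_q(cm, part, gamma)


def _partitions(n: int):
    """Yield all set partitions of range(n) as restricted growth strings."""
    labels = np.zeros(n, dtype=int)

    def rec(i: int, m: int):
        if i == n:
            yield labels.copy()
            return
        for lab in range(m + 1):
            labels[i] = lab
            yield from rec(i + 1, max(m, lab + 1))

    yield from rec(1, 1) if n > 1 else iter([labels.copy()])


def brute_force_best_partition(
    cm: ConnectivityMatrix, gamma: float = 1.0
) -> tuple[Partition, float]:
    """Exact modularity maximizer by enumerating all set partitions (n <= 10)."""
    if cm.n_nodes > 10:
        raise ParameterError(
            f"brute force refuses {cm.n_nodes} nodes (combinatorial guard at 10)"
        )
    w = _check_prepared(cm)
    W = w.sum()
    k = w.sum(axis=1)
    best_q = -np.inf
    best_labels = None
    for labels in _partitions(cm.n_nodes):
        q = 0.0
        for c in range(labels.max() + 1):
            idx = labels == c
            q += w[np.ix_(idx, idx)].sum() / W - gamma * (k[idx].sum() / W) ** 2
        if q > best_q + 1e-15:
            best_q = q
            best_labels = labels
    return Partition(best_labels), float(best_q)


def median_q(
    cm: ConnectivityMatrix, gamma: float = 1.0, n_runs: int = 100, seed: int = 0
) -> tuple[float, list, Partition]:
    """Median Q over ``n_runs`` stochastic runs at one resolution.

    Run r uses seed ``seed + r``; returns (median, run list, best partition).
    The median is the arithmetic median (mean of the middle two for even n).
    """
    if n_runs < 1:
        raise ParameterError("n_runs must be >= 1")
    qs = []
    best_part, best_q = None, -np.inf
    for r in range(n_runs):
        part, q = louvain_once(cm, gamma, seed=seed + r)
        qs.append(q)
        if q > best_q:
            best_part, best_q = part, q
    return float(np.median(qs)), qs, best_part


def gamma_sweep(
    cm: ConnectivityMatrix,
    gammas: tuple = DEFAULT_GAMMA_GRID,
    n_runs: int = 100,
    seed: int = 0,
) -> QProfile:
    """Sweep the resolution grid, recording the median Q per gamma."""
    gammas = tuple(float(g) for g in gammas)
    if any(g <= 0 for g in gammas):
        raise ParameterError("all gamma values must be positive")
    q_runs, medians, best = {}, {}, {}
    for gi, gamma in enumerate(gammas):
        med, qs, part = median_q(cm, gamma, n_runs=n_runs, seed=seed + 10007 * gi)
        q_runs[gamma] = qs
        medians[gamma] = med
        best[gamma] = part
    return QProfile(
        gammas=gammas,
        q_runs=q_runs,
        medians=medians,
        best_partitions=best,
        n_runs=n_runs,
        seed=seed,
    )
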