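"""TMRCA estimation by Monte-Carlo averaging over rooted gene trees.

The estimator treats each of the ``s + 1`` rooted gene trees compatible
with the data as equally likely a posteriori and computes

    t_hat = (2 / M) * sum_m (1 / (s+1)) * sum_r sum_{i=2}^{n}
            (k_{r,i}^{(m)} + 1) / (i (i + theta - 1)),

where for replicate ``m`` the coalescent waiting times ``w^{(m)}`` are
drawn from their predata exponential law, allocated backward onto each
rooted tree ``T_r`` (choosing, at every step, where the next-oldest
coalescence happens with probability proportional to active leaf counts),
and the mutations of every tree segment are then scattered over the
coalescent intervals the segment spans by a multinomial draw with
probabilities proportional to the interval lengths.  ``k_{r,i}`` counts the
mutations falling in the interval during which the sample had ``i``
ancestral lineages.

The per-``k`` conditional mean

    E(t_n | k, s, theta) = 2 * sum_{i=2}^{n} (k_i + 1) / (i (i + theta - 1))

is exact (it is the conjugate Gamma posterior mean interval by interval),
so the Monte-Carlo average converges to the uniform-over-trees posterior
mean of the TMRCA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Callable, Iterator, Optional, Sequence

import numpy as np

from .coalprior import WaitingTimes, sample_waiting_times
from .genetree import RootedGeneTree, TreeNode


# ---------------------------------------------------------------------------
# flattened tree structure (static per tree, reused across replicates)


class _FlatTree:
    """Index-based view of a rooted gene tree for the allocation loop."""

    __slots__ = ("nodes", "parent", "children", "is_leaf", "mult", "n_mut")

    def __init__(self, tree: RootedGeneTree):
        nodes: list[TreeNode] = []
        parent: list[int] = []
        order: dict[int, int] = {}

        def walk(nd: TreeNode, par: int):
            idx = len(nodes)
            nodes.append(nd)
            parent.append(par)
            order[id(nd)] = idx
            for c in nd.children:
                walk(c, idx)

        walk(tree.root, -1)
        self.nodes = nodes
        self.parent = parent
        self.children = [
            [order[id(c)] for c in nd.children] for nd in nodes
        ]
        self.is_leaf = [nd.is_leaf for nd in nodes]
        self.mult = [nd.multiplicity for nd in nodes]
        self.n_mut = [len(nd.mutations) for nd in nodes]


def _allocate_events(
    flat: _FlatTree,
    n: int,
    rng: np.random.Generator,
    record_events: bool = False,
):
    """Backward allocation of the ``n - 1`` coalescences onto a tree.

    Returns ``(merge_i, resolve_i, events)``: for every node, the index of
    the coalescence at which its whole clade has merged to a single
    ancestral lineage (``resolve_i``; ``n + 1`` for multiplicity-1 leaves,
    which are "resolved" at the present) and the index at which that
    lineage itself merges within its parent scope (``merge_i``; 0 for the
    root, which never does).  The segment above a node therefore spans the
    coalescent intervals ``merge_i .. resolve_i - 1``.
    """
    K = len(flat.nodes)
    parent = flat.parent
    children = flat.children
    is_leaf = flat.is_leaf

    active = [0] * K
    unresolved = [0] * K
    reps: list[list[int]] = [[] for _ in range(K)]
    resolve_i = [0] * K
    merge_i = [0] * K
    events: list[tuple[int, int, str]] = []

    # initialise bottom-up: only multiplicity-1 leaves start resolved
    for u in range(K - 1, -1, -1):
        if is_leaf[u]:
            active[u] = flat.mult[u]
            if active[u] == 1:
                resolve_i[u] = n + 1
        else:
            active[u] = sum(active[c] for c in children[u])
            for c in children[u]:
                if is_leaf[c] and flat.mult[c] == 1:
                    reps[u].append(c)
                else:
                    unresolved[u] += 1
    if active[0] != n:
        raise ValueError(
            f"tree leaf multiplicities sum to {active[0]}, but n = {n}"
        )

    def resolve(u: int, i: int):
        resolve_i[u] = i
        p = parent[u]
        if p < 0:
            return
        unresolved[p] -= 1
        reps[p].append(u)
        if unresolved[p] == 0 and len(reps[p]) == 1:
            resolve(p, i)

    rand = rng.random
    for i in range(n, 1, -1):
        node = 0
        while True:
            kids = children[node]
            total = 0.0
            for c in kids:
                a = active[c]
                if a >= 2:
                    total += a
            n_reps = len(reps[node])
            if n_reps >= 2:
                total += n_reps
            if total <= 0:
                raise RuntimeError(
                    "internal error: no mergeable unit left before w_2 "
                    "was placed (topology violation)"
                )
            r = rand() * total
            chosen = -1
            for c in kids:
                a = active[c]
                if a >= 2:
                    r -= a
                    if r < 0:
                        chosen = c
                        break
            if chosen < 0:
                # merge two representative lineages at this scope; which
                # pair only matters for segment spans, so pick uniformly
                a = int(rand() * n_reps)
                b = int(rand() * (n_reps - 1))
                if b >= a:
                    b += 1
                for t in (reps[node][a], reps[node][b]):
                    if t >= 0:
                        merge_i[t] = i
                lo, hi = min(a, b), max(a, b)
                reps[node].pop(hi)
                reps[node].pop(lo)
                reps[node].append(-1)
                if record_events:
                    events.append((i, node, "scope"))
                u = node
                while u >= 0:
                    active[u] -= 1
                    u = parent[u]
                if unresolved[node] == 0 and len(reps[node]) == 1:
                    resolve(node, i)
                break
            if is_leaf[chosen]:
                # a pair of identical copies merges; which pair is
                # irrelevant, the active count just decrements
                active[chosen] -= 1
                if record_events:
                    events.append((i, chosen, "leaf"))
                u = node
                while u >= 0:
                    active[u] -= 1
                    u = parent[u]
                if active[chosen] == 1:
                    resolve(chosen, i)
                break
            node = chosen

    return merge_i, resolve_i, events


# ---------------------------------------------------------------------------
# public domain types


@dataclass(frozen=True)
class CalibratedTree:
    """A rooted gene tree with one replicate's waiting times allocated.

    ``merge_event[u]``/``resolve_event[u]`` index the flattened nodes (see
    ``node_list``); the segment above node ``u`` spans the coalescent
    intervals ``merge_event[u] .. resolve_event[u] - 1`` (interval ``i``
    has length ``w_i``).  ``events`` lists ``(i, node_index, kind)`` per
    coalescence, oldest event last (allocation runs ``i = n .. 2``).
    """

    tree: RootedGeneTree
    waiting: WaitingTimes
    node_list: tuple[TreeNode, ...]
    merge_event: tuple[int, ...]
    resolve_event: tuple[int, ...]
    events: tuple[tuple[int, int, str], ...]

    def spanned_intervals(self, u: int) -> range:
        """Coalescent interval indices spanned by the segment above node u."""
        if u == 0:
            return range(0)
        return range(self.merge_event[u], self.resolve_event[u])

    def segment_length(self, u: int) -> float:
        return float(
            sum(self.waiting.w_of(i) for i in self.spanned_intervals(u))
        )

    def d_of(self, u: int) -> int:
        """Number of coalescent intervals the segment above node u spans."""
        return len(self.spanned_intervals(u))


@dataclass(frozen=True)
class MutationCounts:
    """Per-coalescent-interval mutation counts ``k_2 .. k_n`` for one tree."""

    n: int
    k: np.ndarray  # k[i - 2] is the count in the i-lineage interval

    def __post_init__(self):
        k = np.asarray(self.k, dtype=np.int64)
        object.__setattr__(self, "k", k)
        if k.shape != (self.n - 1,):
            raise ValueError("need counts for i = 2 .. n")
        if (k < 0).any():
            raise ValueError("mutation counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.k.sum())


@dataclass(frozen=True)
class EstimateResult:
    """Monte-Carlo TMRCA estimate (units of N generations)."""

    t_hat: float
    mc_se: float
    M_used: int
    converged: bool
    per_tree_means: tuple[float, ...]
    trace: tuple[float, ...]
    theta: float
    n: int
    s: int
    draws: Optional[np.ndarray] = None

    def to_dict(self) -> dict:
        return {
            "schema": 1,
            "t_hat": self.t_hat,
            "units": "N generations",
            "mc_se": self.mc_se,
            "M_used": self.M_used,
            "converged": self.converged,
            "per_tree_means": list(self.per_tree_means),
            "trace": list(self.trace),
            "theta": self.theta,
            "n": self.n,
            "s": self.s,
        }


# ---------------------------------------------------------------------------
# operations


def allocate_waiting_times(
    tree: RootedGeneTree, w: WaitingTimes, rng: np.random.Generator
) -> CalibratedTree:
    """Allocate the coalescences ``w_n, ..., w_2`` backward onto a tree.

    At every step the location of the next-oldest coalescence is chosen
    among the currently mergeable units with probability proportional to
    their active leaf counts: a lineage's copies merge within their leaf
    (the count decrements), a clade whose subclades have all coalesced to
    single lineages merges those representatives (uniformly chosen pair),
    and single-leaf branches only ever merge at their parent scope.
    """
    flat = _FlatTree(tree)
    merge_i, resolve_i, events = _allocate_events(
        flat, w.n, rng, record_events=True
    )
    return CalibratedTree(
        tree=tree,
        waiting=w,
        node_list=tuple(flat.nodes),
        merge_event=tuple(merge_i),
        resolve_event=tuple(resolve_i),
        events=tuple(events),
    )


def _scatter_mutations(
    flat: _FlatTree,
    merge_i: list[int],
    resolve_i: list[int],
    w: np.ndarray,  # w[i] = w_{i+2}
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Multinomial scatter of each segment's mutations over its intervals."""
    k = np.zeros(n + 1, dtype=np.int64)
    for u in range(1, len(flat.nodes)):
        m = flat.n_mut[u]
        if m == 0:
            continue
        lo, hi = merge_i[u], resolve_i[u] - 1
        if hi > n:
            hi = n  # multiplicity-1 leaves are resolved at the present
        if lo < 2 or lo > hi:
            raise RuntimeError(
                "contract violation: a mutated segment spans no coalescent "
                "interval"
            )
        if lo == hi:
            k[lo] += m
        else:
            lens = w[lo - 2 : hi - 1]
            counts = rng.multinomial(m, lens / lens.sum())
            k[lo : hi + 1] += counts
    return k[2:]


def allocate_mutations(
    ct: CalibratedTree, rng: np.random.Generator
) -> MutationCounts:
    """Scatter each segment's mutations over the intervals it spans.

    Every segment with ``t_r`` mutations spanning ``d`` coalescent
    intervals receives a multinomial(``t_r``; interval lengths / total)
    draw; summing over segments gives the per-interval vector
    ``k_2 .. k_n``, whose total is always the number of segregating sites.
    """
    flat = _FlatTree(ct.tree)
    k = _scatter_mutations(
        flat,
        list(ct.merge_event),
        list(ct.resolve_event),
        ct.waiting.w,
        ct.waiting.n,
        rng,
    )
    return MutationCounts(n=ct.waiting.n, k=k)


def posterior_mean_given_k(
    k: MutationCounts | Sequence[int], theta: float, n: int | None = None
) -> float:
    """E(t_n | k, s, theta) = 2 * sum_i (k_i + 1) / (i (i + theta - 1)).

    Exact conditional mean of the TMRCA given the per-interval mutation
    counts; for ``theta = 0`` and all ``k_i = 0`` it telescopes to the
    predata mean ``2 (1 - 1/n)``.
    """
    if theta < 0:
        raise ValueError("theta must be nonnegative")
    kv = np.asarray(k.k if isinstance(k, MutationCounts) else k, dtype=float)
    if n is None:
        n = kv.size + 1
    if kv.size != n - 1:
        raise ValueError("k must have entries for i = 2 .. n")
    i = np.arange(2, n + 1, dtype=float)
    return float(2.0 * ((kv + 1.0) / (i * (i + theta - 1.0))).sum())


def _compositions(total: int, parts: int) -> Iterator[tuple[int, ...]]:
    """All weak compositions of ``total`` into ``parts`` ordered parts."""
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, parts - 1):
            yield (first,) + rest


def posterior_mean_given_s(
    n: int,
    s: int,
    theta: float,
    expected_k: Callable[[tuple[int, ...]], Sequence[float]] | None = None,
    max_terms: int = 500_000,
) -> float:
    """Segregating-sites-only conditional mean,

        E(t_n | s, theta) = 2/(s+1) * sum_{|k|=s} sum_i (E[k_i] + 1)
                                                   / (i (i + theta - 1)),

    with the outer sum running over all weak compositions of ``s`` into the
    ``n - 1`` coalescent intervals, exactly as the formula is written.  The
    source of ``E[k_i]`` is deliberately an explicit argument
    (``expected_k`` maps a composition to its expected counts; the default
    is the composition itself), because the conditioning law of ``k`` is
    not pinned down by the formula alone.  Note the ``2/(s+1)``
    normalisation is not ``2 /`` (number of compositions); the quantity is
    reported exactly as defined.

    Only small ``n`` and ``s`` are supported (the enumeration has
    ``C(s + n - 2, n - 2)`` terms); beyond ``max_terms`` a ``ValueError``
    advises the Monte-Carlo estimator instead.
    """
    if n < 2:
        raise ValueError("sample size n must be >= 2")
    if s < 0:
        raise ValueError("s must be nonnegative")
    n_terms = comb(s + n - 2, n - 2)
    if n_terms > max_terms:
        raise ValueError(
            f"{n_terms} compositions exceed the enumeration bound "
            f"({max_terms}); use estimate_tmrca (Monte-Carlo) instead"
        )
    i = np.arange(2, n + 1, dtype=float)
    denom = i * (i + theta - 1.0)
    total = 0.0
    for k in _compositions(s, n - 1):
        ek = np.asarray(expected_k(k) if expected_k is not None else k, dtype=float)
        total += float(((ek + 1.0) / denom).sum())
    return 2.0 / (s + 1) * total


def initial_candidate_weights(scope: TreeNode) -> list[int]:
    """First-step allocation weights at a scope: the clade multiplicities of
    its multi-leaf children (single-leaf branches only merge at the scope's
    own level, later)."""
    return [
        c.clade_multiplicity()
        for c in scope.children
        if c.clade_multiplicity() >= 2
    ]


def estimate_tmrca(
    trees: Sequence[RootedGeneTree],
    theta: float,
    M: int,
    rng: np.random.Generator,
    tol: float = 1e-3,
    keep_draws: bool = False,
) -> EstimateResult:
    """Monte-Carlo posterior-mean TMRCA over the ``s + 1`` rooted trees.

    Per replicate one waiting-time vector is drawn and shared across all
    trees; each tree gets its own event allocation and multinomial mutation
    scatter.  Convergence is monitored by batch means (batch size
    ``max(100, M // 50)``): the run stops early once the relative change of
    the running estimate between successive batches drops below ``tol``.

    Parameters
    ----------
    trees:
        The full ``s + 1`` enumeration (see
        :func:`coaltree.genetree.enumerate_rooted_trees`).
    theta:
        Scaled mutation rate ``2 N mu`` (known, never estimated here).
    M:
        Maximum number of Monte-Carlo replicates.
    rng:
        Seeded ``numpy.random.Generator``; the single source of randomness.
    tol:
        Relative-change threshold for early stopping.
    keep_draws:
        Also return the per-replicate, per-tree conditional means (row
        ``m``, column ``r``), for diagnostics.
    """
    if not trees:
        raise ValueError("need at least one rooted tree")
    if theta < 0:
        raise ValueError("theta must be nonnegative")
    if M < 1:
        raise ValueError("M must be >= 1")
    s = trees[0].s
    n = trees[0].n
    if any(t.s != s or t.n != n for t in trees):
        raise ValueError("all trees must describe the same data")
    if len(trees) != s + 1:
        raise ValueError(
            f"expected the full enumeration of s + 1 = {s + 1} rooted "
            f"trees, got {len(trees)}"
        )

    flats = [_FlatTree(t) for t in trees]
    i = np.arange(2, n + 1, dtype=float)
    inv_denom = 1.0 / (i * (i + theta - 1.0))
    base = float(inv_denom.sum())  # the sum with all k_i = 0

    batch = max(100, M // 50)
    per_rep = np.empty(M, dtype=float)
    per_tree = np.zeros(len(trees), dtype=float)
    draws = np.empty((M, len(trees)), dtype=float) if keep_draws else None
    trace: list[float] = []
    converged = False
    m_used = 0
    prev_est: float | None = None

    for m in range(M):
        w = sample_waiting_times(n, rng)
        wv = w.w
        acc = 0.0
        for r, flat in enumerate(flats):
            merge_i, resolve_i, _ = _allocate_events(flat, n, rng)
            k = _scatter_mutations(flat, merge_i, resolve_i, wv, n, rng)
            val = base + float((k * inv_denom).sum())
            acc += val
            per_tree[r] += 2.0 * val
            if keep_draws:
                draws[m, r] = 2.0 * val
        per_rep[m] = 2.0 * acc / len(trees)
        m_used = m + 1
        if m_used % batch == 0:
            est = float(per_rep[:m_used].mean())
            trace.append(est)
            if prev_est is not None and est > 0:
                if abs(est - prev_est) / abs(est) < tol:
                    converged = True
                    break
            prev_est = est

    values = per_rep[:m_used]
    t_hat = float(values.mean())
    if not trace or trace[-1] != t_hat:
        trace.append(t_hat)
    mc_se = float(values.std(ddof=1) / np.sqrt(m_used)) if m_used > 1 else float("nan")
    return EstimateResult(
        t_hat=t_hat,
        mc_se=mc_se,
        M_used=m_used,
        converged=converged,
        per_tree_means=tuple(per_tree / m_used),
        trace=tuple(trace),
        theta=theta,
        n=n,
        s=s,
        draws=draws[:m_used] if keep_draws else None,
    )
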