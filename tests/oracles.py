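"""Independent brute-force oracles used by the test suite.

These deliberately re-implement the model with different machinery than the
package: validity by direct three-gamete scanning over plain tuples, tree
enumeration by filtering all 2**s labellings, and the Monte-Carlo estimator
by tracking explicit blocks of sampled individuals (frozensets) rather than
active-count bookkeeping.  They are only usable at toy scale.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_laminar(columns: list[tuple[int, ...]]) -> bool:
    """Three-gamete test on columns given as 0/1 tuples (one entry per row)."""
    nrow = len(columns[0]) if columns else 0
    for c1, c2 in itertools.combinations(columns, 2):
        gametes = {(c1[i], c2[i]) for i in range(nrow)}
        if {(0, 1), (1, 0), (1, 1)} <= gametes:
            return False
    return True


def brute_enumerate_labelings(seg_bases: list[str], mults: list[int]):
    """All valid 0/1 labellings by exhausting the 2**s mutant-base choices.

    ``seg_bases``: per-lineage string over segregating sites.  Returns a
    list of 0/1 matrices as tuples of row tuples.
    """
    n_lin = len(seg_bases)
    s = len(seg_bases[0]) if seg_bases else 0
    per_site_bases = [sorted({row[j] for row in seg_bases}) for j in range(s)]
    out = []
    seen = set()
    for choice in itertools.product(*per_site_bases):
        mat = tuple(
            tuple(1 if seg_bases[i][j] == choice[j] else 0 for j in range(s))
            for i in range(n_lin)
        )
        if mat in seen:
            continue
        seen.add(mat)
        cols = [tuple(mat[i][j] for i in range(n_lin)) for j in range(s)]
        if all(any(c) for c in cols) and brute_laminar(cols):
            out.append(mat)
    return out


def _expand_units(mat, mults):
    """Individual-level unit sets: lineage blocks, mutation clades, root.

    Returns (units, edge_mutations, individuals_per_lineage) where
    ``edge_mutations`` maps a unit frozenset to its number of mutations.
    """
    n_lin = len(mat)
    offsets = np.concatenate([[0], np.cumsum(mults)])
    lineage_sets = [
        frozenset(range(int(offsets[i]), int(offsets[i + 1])))
        for i in range(n_lin)
    ]
    n = int(offsets[-1])
    root = frozenset(range(n))
    s = len(mat[0]) if mat else 0
    edge_mut: dict[frozenset, int] = {}
    units = set(lineage_sets) | {root}
    for j in range(s):
        clade = frozenset().union(
            *(lineage_sets[i] for i in range(n_lin) if mat[i][j])
        )
        units.add(clade)
        edge_mut[clade] = edge_mut.get(clade, 0) + 1
    return units, edge_mut, lineage_sets, root


def _children_of(unit, units):
    inside = [u for u in units if u < unit]
    return [u for u in inside if not any(u < v for v in inside)]


def brute_force_tmrca(
    seg_bases: list[str],
    mults: list[int],
    theta: float,
    M: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Monte-Carlo posterior-mean TMRCA, implemented with explicit blocks.

    Returns (estimate, Monte-Carlo standard error of the estimate).
    """
    labelings = brute_enumerate_labelings(seg_bases, mults)
    s = len(seg_bases[0]) if seg_bases else 0
    assert len(labelings) == s + 1, "enumeration sanity"
    n = int(sum(mults))
    ivals = np.arange(2, n + 1, dtype=float)
    denom = ivals * (ivals + theta - 1.0)

    prepared = [_expand_units(mat, mults) for mat in labelings]
    per_rep = np.empty(M)

    for m in range(M):
        w = np.array(
            [rng.exponential(2.0 / (i * (i - 1.0))) for i in range(2, n + 1)]
        )
        acc = 0.0
        for units, edge_mut, lineage_sets, root in prepared:
            children = {u: _children_of(u, units) for u in units}
            blocks = {frozenset([i]) for i in root}
            created: dict[frozenset, int] = {}
            consumed: dict[frozenset, int] = {}
            for u in units:
                if len(u) == 1:
                    created[u] = n + 1
            for b in blocks:
                created.setdefault(b, n + 1)

            for i in range(n, 1, -1):
                unit = root
                while True:
                    kids = children[unit]
                    direct = [
                        b
                        for b in blocks
                        if b <= unit and not any(b < c for c in kids)
                    ]
                    cand = []
                    for c in kids:
                        a = sum(1 for b in blocks if b <= c)
                        if a >= 2:
                            cand.append((c, float(a)))
                    weights = [wgt for _, wgt in cand]
                    if len(direct) >= 2:
                        weights.append(float(len(direct)))
                    total = sum(weights)
                    assert total > 0, "no mergeable unit"
                    r = rng.random() * total
                    picked = None
                    for (c, wgt) in cand:
                        r -= wgt
                        if r < 0:
                            picked = c
                            break
                    if picked is not None:
                        unit = picked
                        continue
                    direct = sorted(direct, key=sorted)
                    a_i, b_i = rng.choice(len(direct), size=2, replace=False)
                    b1, b2 = direct[int(a_i)], direct[int(b_i)]
                    merged = b1 | b2
                    blocks -= {b1, b2}
                    blocks.add(merged)
                    consumed[b1] = i
                    consumed[b2] = i
                    created[merged] = i
                    break

            k = np.zeros(n + 1)
            for unit_set, n_mut in edge_mut.items():
                hi = min(created[unit_set], n + 1) - 1
                lo = consumed[unit_set]
                lens = w[lo - 2 : hi - 1]
                totlen = lens.sum()
                for _ in range(n_mut):
                    u = rng.random() * totlen
                    idx = 0
                    while u > lens[idx] and idx < len(lens) - 1:
                        u -= lens[idx]
                        idx += 1
                    k[lo + idx] += 1
            acc += 2.0 * ((k[2:] + 1.0) / denom).sum()
        per_rep[m] = acc / len(labelings)

    est = float(per_rep.mean())
    se = float(per_rep.std(ddof=1) / math.sqrt(M))
    return est, se
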