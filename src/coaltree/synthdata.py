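"""Synthetic infinite-sites coalescent datasets with known ground truth.

The generator draws a plain Kingman genealogy (uniformly chosen merging
pair at every coalescence, waiting times ``w_j ~ Exp(j(j-1)/2)``), drops
mutations on it as a Poisson process of rate ``theta / 2`` per branch per
unit time, gives every mutation its own site (infinite sites), and encodes
the resulting binary haplotypes as transition-only base substitutions —
mirroring control-region mtDNA data, where transitions dominate.  Every
piece of the truth (waiting times, per-interval mutation counts, the true
rooted genealogy and its labelling) is kept, so parameter-recovery and
round-trip tests need no external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .coalprior import WaitingTimes, sample_waiting_times
from .genetree import RootedGeneTree, build_rooted_tree
from .seqio import (
    TRANSITION_PARTNER,
    BinaryMatrix,
    SegAlignment,
    collapse_sequences,
)


@dataclass(frozen=True)
class SyntheticDataset:
    """One simulated dataset plus all of its generating truth."""

    alignment: SegAlignment
    true_waiting_times: WaitingTimes
    true_interval_counts: np.ndarray  # k_i for i = 2..n (index 0 -> i = 2)
    true_matrix: BinaryMatrix  # the true mutant labelling, collapsed rows
    true_tree: RootedGeneTree
    theta: float
    seed: Optional[int]

    @property
    def n(self) -> int:
        return self.alignment.n

    @property
    def s(self) -> int:
        return int(self.true_interval_counts.sum())


def encode_as_bases(
    binary_haplotypes: np.ndarray,
    rng: np.random.Generator,
    transitions_only: bool = True,
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Encode 0/1 haplotypes as bases: per site an ancestral base is drawn
    uniformly from {A,C,G,T} and the mutant base is its transition partner
    (A<->G, C<->T); with ``transitions_only=False`` the mutant base is
    instead drawn uniformly among the three alternatives.

    Returns ``(ancestral_bases, sequences)``.
    """
    h = np.asarray(binary_haplotypes, dtype=np.int8)
    n, s = h.shape
    bases = "ACGT"
    anc, mut = [], []
    for _ in range(s):
        a = bases[int(rng.integers(4))]
        if transitions_only:
            b = TRANSITION_PARTNER[a]
        else:
            others = [x for x in bases if x != a]
            b = others[int(rng.integers(3))]
        anc.append(a)
        mut.append(b)
    seqs = tuple(
        "".join(mut[j] if h[i, j] else anc[j] for j in range(s))
        for i in range(n)
    )
    return tuple(anc), seqs


def simulate_infinite_sites(
    n: int,
    theta: float,
    rng: np.random.Generator,
    seed: Optional[int] = None,
    transitions_only: bool = True,
) -> SyntheticDataset:
    """Simulate one infinite-sites dataset of sample size ``n``.

    Parameters
    ----------
    n:
        Sample size (>= 2).
    theta:
        Scaled mutation rate ``2 N mu`` (>= 0); each branch of length
        ``l`` receives Poisson(theta * l / 2) mutations.
    rng:
        Seeded generator driving every random choice.
    seed:
        Optional bookkeeping tag stored in the dataset (the ``rng`` is the
        actual randomness source), so failures are replayable.
    """
    if n < 2:
        raise ValueError("sample size n must be >= 2")
    if theta < 0:
        raise ValueError("theta must be nonnegative")

    w = sample_waiting_times(n, rng)
    # backward event times: the merge ending the i-lineage interval is at
    # depth sum_{j=i}^{n} w_j
    merge_time = {i: float(w.w[i - 2 :].sum()) for i in range(2, n + 1)}

    # blocks of sampled individuals; each block has a creation depth
    blocks: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    created = {b: 0.0 for b in blocks}
    branches: list[tuple[frozenset[int], float, float]] = []  # (block, t0, t1)
    for i in range(n, 1, -1):
        a, b = rng.choice(len(blocks), size=2, replace=False)
        a, b = int(a), int(b)
        t = merge_time[i]
        for idx in (a, b):
            blk = blocks[idx]
            branches.append((blk, created[blk], t))
        merged = blocks[a] | blocks[b]
        blocks = [blk for idx, blk in enumerate(blocks) if idx not in (a, b)]
        blocks.append(merged)
        created[merged] = t

    # Poisson mutations per branch; every mutation is a fresh site carried
    # by exactly the individuals in the branch's block
    site_carriers: list[frozenset[int]] = []
    site_depths: list[float] = []
    for blk, t0, t1 in branches:
        length = t1 - t0
        m = int(rng.poisson(theta * length / 2.0)) if length > 0 else 0
        for _ in range(m):
            site_carriers.append(blk)
            site_depths.append(t0 + float(rng.random()) * length)

    s = len(site_carriers)
    order = list(range(s))
    rng.shuffle(order)  # site order along the sequence is arbitrary
    site_carriers = [site_carriers[j] for j in order]
    site_depths = [site_depths[j] for j in order]

    # truth: which coalescent interval each mutation falls in
    k_true = np.zeros(n - 1, dtype=np.int64)
    bounds = np.array(
        [0.0] + [merge_time[i] for i in range(n, 1, -1)]
    )  # depths of interval ends, intervals n, n-1, ..., 2
    for depth in site_depths:
        idx = int(np.searchsorted(bounds, depth, side="left")) - 1
        idx = min(max(idx, 0), n - 2)
        interval = n - idx  # idx 0 -> interval n, idx n-2 -> interval 2
        k_true[interval - 2] += 1

    hap = np.zeros((n, s), dtype=np.int8)
    for j, carriers in enumerate(site_carriers):
        for i in carriers:
            hap[i, j] = 1

    anc_bases, seqs = encode_as_bases(hap, rng, transitions_only)
    ids = [f"seq{i + 1}" for i in range(n)]
    aln = collapse_sequences(ids, seqs)

    # the true labelling over collapsed lineages
    row_of = {seq: i for i, seq in enumerate(aln.sequences)}
    x = np.zeros((aln.n_lineages, s), dtype=np.int8)
    for i in range(n):
        x[row_of[seqs[i]], :] = hap[i, :]
    mutant = tuple(TRANSITION_PARTNER[a] if transitions_only else None for a in anc_bases)
    if not transitions_only:
        # recover the mutant base from any carrier (or the partner if unseen)
        mutant = tuple(
            next(
                (seqs[i][j] for i in range(n) if hap[i, j]),
                TRANSITION_PARTNER[anc_bases[j]],
            )
            for j in range(s)
        )
    true_matrix = BinaryMatrix(
        x=x,
        lineage_ids=aln.lineage_ids,
        multiplicities=aln.multiplicities,
        site_positions=aln.site_positions,
        mutant_bases=mutant,
        ancestral_bases=anc_bases,
        provenance="true-simulated",
    )
    true_tree = build_rooted_tree(true_matrix, aln)

    return SyntheticDataset(
        alignment=aln,
        true_waiting_times=w,
        true_interval_counts=k_true,
        true_matrix=true_matrix,
        true_tree=true_tree,
        theta=theta,
        seed=seed,
    )


def write_dataset_tsv(ds: SyntheticDataset, path) -> None:
    """Write the alignment in the lineage-table dialect ``seqio`` reads."""
    aln = ds.alignment
    with open(path, "w") as fh:
        header = ["lineage"] + [str(p) for p in aln.site_positions] + ["freq"]
        fh.write("\t".join(header) + "\n")
        for lid, seq, mult in zip(
            aln.lineage_ids, aln.sequences, aln.multiplicities
        ):
            fh.write("\t".join([lid, *seq, str(mult)]) + "\n")


def truth_dict(ds: SyntheticDataset) -> dict:
    """JSON-serialisable record of the generating truth."""
    return {
        "schema": 1,
        "n": ds.n,
        "s": ds.s,
        "theta": ds.theta,
        "seed": ds.seed,
        "t_n": ds.true_waiting_times.t_n,
        "l_n": ds.true_waiting_times.l_n,
        "waiting_times": [float(v) for v in ds.true_waiting_times.w],
        "interval_counts": [int(v) for v in ds.true_interval_counts],
    }
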