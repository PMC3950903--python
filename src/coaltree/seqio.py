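"""Reading aligned sequence data and deriving mutation-labelled 0/1 matrices.

Input data are aligned DNA sequences assumed to evolve under the
infinite-sites model: every site mutates at most once in the history of the
sample, so each segregating site carries exactly two base types, one
ancestral and one mutant.  The sample is summarised by its distinct
haplotypes ("lineages"), each with a multiplicity (the number of sampled
copies), and by the segregating-site columns.  Choosing which base is mutant
at every site yields a 0/1 matrix; only ``s + 1`` of the ``2**s`` labellings
correspond to a rooted gene tree (see :mod:`coaltree.genetree`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

VALID_BASES = frozenset("ACGT")

#: purine <-> purine and pyrimidine <-> pyrimidine substitution partners
TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}


class InfiniteSitesViolation(ValueError):
    """A site shows three or more base types.

    Under the at-most-one-mutation-per-site assumption every segregating
    site has exactly two observed bases; data violating this need the kind
    of preprocessing that removes sequences carrying repeat mutations at a
    single site, which is out of scope here.
    """

    def __init__(self, position: int, bases: Sequence[str]):
        self.position = position
        self.bases = sorted(bases)
        super().__init__(
            f"site {position} shows {len(self.bases)} base types "
            f"({', '.join(self.bases)}); the infinite-sites model allows 2"
        )


@dataclass(frozen=True)
class SegAlignment:
    """Distinct lineages of an alignment with their multiplicities.

    Attributes
    ----------
    lineage_ids:
        Label per distinct haplotype.
    sequences:
        Base string per lineage, all of equal length, alphabet {A,C,G,T}.
    multiplicities:
        Number of sampled copies of each lineage (>= 1).
    site_positions:
        1-based coordinates of the columns in the original alignment.
    """

    lineage_ids: tuple[str, ...]
    sequences: tuple[str, ...]
    multiplicities: tuple[int, ...]
    site_positions: tuple[int, ...]

    def __post_init__(self):
        if not self.lineage_ids:
            raise ValueError("alignment has no lineages")
        if len({len(s) for s in self.sequences}) > 1:
            raise ValueError("sequences must all have equal length")
        if len(self.lineage_ids) != len(self.sequences) or len(
            self.lineage_ids
        ) != len(self.multiplicities):
            raise ValueError("lineage_ids, sequences, multiplicities must align")
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError("lineage sequences must be pairwise distinct")
        if any(m < 1 or m != int(m) for m in self.multiplicities):
            raise ValueError("multiplicities must be positive integers")
        n_sites = len(self.sequences[0]) if self.sequences else 0
        if len(self.site_positions) != n_sites:
            raise ValueError("site_positions must match sequence length")
        bad = set("".join(self.sequences)) - VALID_BASES
        if bad:
            raise ValueError(
                f"sequences contain characters outside A/C/G/T: {sorted(bad)} "
                "(ambiguity codes are rejected, not imputed)"
            )

    @property
    def n(self) -> int:
        """Total sample size (sum of multiplicities)."""
        return int(sum(self.multiplicities))

    @property
    def n_lineages(self) -> int:
        return len(self.lineage_ids)

    @property
    def n_sites(self) -> int:
        return len(self.site_positions)

    def expand(self) -> tuple[tuple[str, ...], tuple[str, ...]]:
        """Expand back to one record per sampled copy (id, sequence)."""
        ids, seqs = [], []
        for lid, seq, mult in zip(
            self.lineage_ids, self.sequences, self.multiplicities
        ):
            for c in range(mult):
                ids.append(f"{lid}_{c + 1}")
                seqs.append(seq)
        return tuple(ids), tuple(seqs)


@dataclass(frozen=True)
class SegMatrix:
    """Lineages x segregating sites, with per-column base bookkeeping.

    Columns are the alignment columns at which not all sampled sequences
    agree; each retains exactly two base types and their multiplicity-
    weighted counts.
    """

    lineage_ids: tuple[str, ...]
    multiplicities: tuple[int, ...]
    site_positions: tuple[int, ...]
    bases: tuple[str, ...]  # per-lineage string over segregating sites only

    @property
    def s(self) -> int:
        """Number of segregating sites."""
        return len(self.site_positions)

    @property
    def n(self) -> int:
        return int(sum(self.multiplicities))

    def column(self, j: int) -> str:
        """Bases of column ``j`` (0-based), one char per lineage."""
        return "".join(seq[j] for seq in self.bases)

    def column_weighted_counts(self, j: int) -> dict[str, int]:
        """Multiplicity-weighted count of each base type in column ``j``."""
        counts: dict[str, int] = {}
        for base, mult in zip(self.column(j), self.multiplicities):
            counts[base] = counts.get(base, 0) + mult
        return counts

    def to_alignment(self) -> "SegAlignment":
        """View the segregating sites as an alignment in their own right."""
        return SegAlignment(
            lineage_ids=self.lineage_ids,
            sequences=self.bases,
            multiplicities=self.multiplicities,
            site_positions=self.site_positions,
        )


@dataclass(frozen=True)
class BinaryMatrix:
    """0/1 mutation labelling of a :class:`SegMatrix`.

    ``x[i, j] == 1`` means lineage ``i`` carries the mutant base at
    segregating site ``j``.  ``mutant_bases[j]``/``ancestral_bases[j]``
    record which base type was labelled mutant; flipping a column swaps
    the two.  ``provenance`` tags how the labelling arose
    (``"least-shared"`` or ``"enumerated-root-<k>"``).
    """

    x: np.ndarray
    lineage_ids: tuple[str, ...]
    multiplicities: tuple[int, ...]
    site_positions: tuple[int, ...]
    mutant_bases: tuple[str, ...]
    ancestral_bases: tuple[str, ...]
    provenance: str = "least-shared"

    def __post_init__(self):
        x = np.asarray(self.x, dtype=np.int8)
        object.__setattr__(self, "x", x)
        if x.ndim != 2:
            raise ValueError("x must be 2-dimensional")
        if not np.isin(x, (0, 1)).all():
            raise ValueError("x must be 0/1 valued")
        if x.shape != (len(self.lineage_ids), len(self.site_positions)):
            raise ValueError("x shape must be (lineages, sites)")

    @property
    def s(self) -> int:
        return self.x.shape[1]

    @property
    def n(self) -> int:
        return int(sum(self.multiplicities))

    def column_ones(self, j: int) -> frozenset[str]:
        """Set of lineage ids carrying the mutant base at column ``j``."""
        return frozenset(
            lid for lid, v in zip(self.lineage_ids, self.x[:, j]) if v
        )

    def flip_columns(self, cols: Sequence[int], provenance: str) -> "BinaryMatrix":
        """Return a new labelling with the given columns' 0/1 roles swapped."""
        x = self.x.copy()
        mutant = list(self.mutant_bases)
        ancestral = list(self.ancestral_bases)
        for j in cols:
            x[:, j] = 1 - x[:, j]
            mutant[j], ancestral[j] = ancestral[j], mutant[j]
        return BinaryMatrix(
            x=x,
            lineage_ids=self.lineage_ids,
            multiplicities=self.multiplicities,
            site_positions=self.site_positions,
            mutant_bases=tuple(mutant),
            ancestral_bases=tuple(ancestral),
            provenance=provenance,
        )


# ---------------------------------------------------------------------------
# readers


def collapse_sequences(
    ids: Sequence[str],
    seqs: Sequence[str],
    site_positions: Sequence[int] | None = None,
) -> SegAlignment:
    """Collapse identical sequences into lineages with multiplicities.

    The lineage id is the id of the first record carrying that sequence;
    lineages are ordered by first occurrence.
    """
    if not seqs:
        raise ValueError("no sequences to collapse")
    if len({len(s) for s in seqs}) > 1:
        raise ValueError("sequences must all have equal length (aligned input)")
    order: list[str] = []
    mult: dict[str, int] = {}
    first_id: dict[str, str] = {}
    for rid, seq in zip(ids, seqs):
        if seq not in mult:
            order.append(seq)
            mult[seq] = 0
            first_id[seq] = rid
        mult[seq] += 1
    if site_positions is None:
        site_positions = tuple(range(1, len(seqs[0]) + 1))
    return SegAlignment(
        lineage_ids=tuple(first_id[s] for s in order),
        sequences=tuple(order),
        multiplicities=tuple(mult[s] for s in order),
        site_positions=tuple(site_positions),
    )


def read_lineage_table(path: str | Path, dialect: str = "auto") -> SegAlignment:
    """Read a delimited lineage-frequency table.

    Expected layout: header row with a lineage-id column, one column per
    site (labels become the 1-based site positions when numeric), and a
    final ``freq`` column; one row per distinct lineage.

    Parameters
    ----------
    path:
        File to read.
    dialect:
        ``"tsv"``, ``"csv"`` or ``"auto"`` (sniff from the header line).
    """
    path = Path(path)
    if dialect == "auto":
        with open(path) as fh:
            header = fh.readline()
        dialect = "csv" if ("," in header and "\t" not in header) else "tsv"
    sep = {"tsv": "\t", "csv": ","}[dialect]
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 3:
        raise ValueError("lineage table needs id column, site columns and freq")
    freq_col = df.columns[-1]
    if freq_col.lower() not in {"freq", "freqs", "frequency", "multiplicity"}:
        raise ValueError(f"last column must be the frequency column, got {freq_col!r}")
    site_cols = list(df.columns[1:-1])
    try:
        site_positions = tuple(int(c) for c in site_cols)
    except ValueError:
        site_positions = tuple(range(1, len(site_cols) + 1))
    freqs = []
    for v in df[freq_col]:
        f = int(v)
        if f < 1:
            raise ValueError(f"non-positive lineage frequency: {f}")
        freqs.append(f)
    seqs = tuple(
        "".join(str(row[c]).strip().upper() for c in site_cols)
        for _, row in df.iterrows()
    )
    return SegAlignment(
        lineage_ids=tuple(str(v) for v in df.iloc[:, 0]),
        sequences=seqs,
        multiplicities=tuple(freqs),
        site_positions=site_positions,
    )


def read_fasta(path: str | Path) -> SegAlignment:
    """Read an aligned FASTA file and collapse identical records."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    ids = [r.id for r in records]
    seqs = [str(r.seq).upper() for r in records]
    return collapse_sequences(ids, seqs)


def load_nuu_chah_nulth() -> SegAlignment:
    """The packaged Nuu-Chah-Nulth mtDNA control-region data.

    55 sequences sampled from a North American tribe, collapsed to 14
    distinct lineages over 18 segregating sites (transitions only).  This
    is the classic worked dataset of the coalescent-inference literature.
    """
    with resources.as_file(
        resources.files("coaltree.data") / "nuu_chah_nulth.tsv"
    ) as p:
        return read_lineage_table(p, dialect="tsv")


# ---------------------------------------------------------------------------
# segregating sites and labelling


def find_segregating_sites(aln: SegAlignment) -> SegMatrix:
    """Keep only the columns at which not all sampled sequences agree.

    Raises
    ------
    InfiniteSitesViolation
        If some column shows three or more base types.
    """
    keep: list[int] = []
    for j in range(aln.n_sites):
        observed = {seq[j] for seq in aln.sequences}
        if len(observed) > 2:
            raise InfiniteSitesViolation(aln.site_positions[j], observed)
        if len(observed) == 2:
            keep.append(j)
    return SegMatrix(
        lineage_ids=aln.lineage_ids,
        multiplicities=aln.multiplicities,
        site_positions=tuple(aln.site_positions[j] for j in keep),
        bases=tuple("".join(seq[j] for j in keep) for seq in aln.sequences),
    )


def label_least_shared(m: SegMatrix) -> BinaryMatrix:
    """Label the less common base type at every site as mutant.

    "Less common" is by multiplicity-weighted count (sequences, not distinct
    lineages).  Ties go to the lexicographically smaller base, for
    determinism.  This is the standard starting labelling; it is valid for
    any dataset generated under the infinite-sites model with the mutant
    type in the minority at every site, and in particular for the packaged
    data.
    """
    x = np.zeros((len(m.lineage_ids), m.s), dtype=np.int8)
    mutant, ancestral = [], []
    for j in range(m.s):
        counts = m.column_weighted_counts(j)
        # sort by (count, base): smallest weighted count wins, ties go to
        # the lexicographically smaller base
        (mut, _), (anc, _) = sorted(counts.items(), key=lambda kv: (kv[1], kv[0]))
        mutant.append(mut)
        ancestral.append(anc)
        col = m.column(j)
        for i, b in enumerate(col):
            if b == mut:
                x[i, j] = 1
    return BinaryMatrix(
        x=x,
        lineage_ids=m.lineage_ids,
        multiplicities=m.multiplicities,
        site_positions=m.site_positions,
        mutant_bases=tuple(mutant),
        ancestral_bases=tuple(ancestral),
        provenance="least-shared",
    )
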