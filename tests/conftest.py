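import numpy as np
import pytest

import coaltree as ct


@pytest.fixture(scope="session")
def nuu():
    """The packaged Nuu-Chah-Nulth control-region data (14 lineages, n=55)."""
    return ct.load_nuu_chah_nulth()


@pytest.fixture(scope="session")
def nuu_seg(nuu):
    return ct.find_segregating_sites(nuu)


@pytest.fixture(scope="session")
def nuu_labelled(nuu_seg):
    return ct.label_least_shared(nuu_seg)


@pytest.fixture(scope="session")
def nuu_tree(nuu_labelled, nuu):
    return ct.build_rooted_tree(nuu_labelled, nuu)


@pytest.fixture(scope="session")
def nuu_trees(nuu_labelled, nuu):
    """All s + 1 = 19 rooted trees of the packaged data."""
    return ct.enumerate_rooted_trees(nuu_labelled, nuu)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)


def make_alignment(ids, seqs, mults):
    return ct.SegAlignment(
        lineage_ids=tuple(ids),
        sequences=tuple(seqs),
        multiplicities=tuple(mults),
        site_positions=tuple(range(1, len(seqs[0]) + 1)),
    )


@pytest.fixture(scope="session")
def toy_n3():
    """Two lineages (multiplicities 2 and 1), one segregating site."""
    return ct.SegAlignment(
        lineage_ids=("A", "B"),
        sequences=("A", "G"),
        multiplicities=(2, 1),
        site_positions=(1,),
    )


@pytest.fixture(scope="session")
def toy_n4_s2():
    """Three lineages (2+1+1 copies), two segregating sites on disjoint clades."""
    return ct.SegAlignment(
        lineage_ids=("A", "B", "C"),
        sequences=("AA", "GA", "AG"),
        multiplicities=(2, 1, 1),
        site_positions=(1, 2),
    )
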