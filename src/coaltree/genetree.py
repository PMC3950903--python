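"""Rooted gene trees from 0/1 mutation matrices, and the ``s + 1`` rootings.

A 0/1 lineage x site matrix represents a rooted gene tree exactly when its
column 1-sets form a laminar family (pairwise nested or disjoint) — the
classic perfect-phylogeny condition, equivalently "no column pair shows all
three gametes (0,1), (1,0), (1,1)".  Each valid labelling corresponds to a
unique rooted tree; all of them reduce to one unrooted tree, and for data
with ``s`` segregating sites there are exactly ``s + 1`` valid labellings,
obtained by sliding the root to every vertex of the unrooted tree and into
every gap between two adjacent mutations on an edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import numpy as np

from .seqio import BinaryMatrix, SegAlignment


@dataclass
class MatrixValidity:
    """Outcome of the rooted-tree representability test."""

    ok: bool
    violating_columns: Optional[tuple[int, int]] = None  # site positions

    def __bool__(self) -> bool:
        return self.ok


def is_valid_matrix(x: BinaryMatrix) -> MatrixValidity:
    """Test whether a 0/1 matrix represents a rooted gene tree.

    For every pair of columns the 1-sets must be nested or disjoint; the
    first violating pair (by site position) is reported otherwise.  The
    check is the O(n s^2) pairwise three-gamete test — transparent, and
    cheap at the scale of segregating-site data.
    """
    m = np.asarray(x.x, dtype=bool)
    s = m.shape[1]
    for j in range(s):
        cj = m[:, j]
        for k in range(j + 1, s):
            ck = m[:, k]
            both = bool((cj & ck).any())
            only_j = bool((cj & ~ck).any())
            only_k = bool((~cj & ck).any())
            if both and only_j and only_k:
                return MatrixValidity(
                    False, (x.site_positions[j], x.site_positions[k])
                )
    return MatrixValidity(True)


@dataclass(eq=False)
class TreeNode:
    """One vertex of a rooted gene tree.

    ``mutations`` are the segregating sites on the edge above this node, in
    fixed ascending site order with index 0 nearest the root.  Leaves carry
    the lineage id and its multiplicity.
    """

    mutations: tuple[int, ...] = ()
    children: list["TreeNode"] = field(default_factory=list)
    lineage: Optional[str] = None
    multiplicity: int = 0

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def clade_multiplicity(self) -> int:
        """Total leaf multiplicity of the subtree below (and incl.) this node."""
        if self.is_leaf:
            return self.multiplicity
        return sum(c.clade_multiplicity() for c in self.children)

    def clade_lineages(self) -> frozenset[str]:
        if self.is_leaf:
            return frozenset([self.lineage])
        return frozenset().union(*(c.clade_lineages() for c in self.children))

    def canonical(self) -> tuple:
        if self.is_leaf:
            return ("leaf", self.lineage, self.multiplicity, tuple(self.mutations))
        kids = tuple(sorted(c.canonical() for c in self.children))
        return ("internal", tuple(self.mutations), kids)


@dataclass(eq=False)
class RootedGeneTree:
    """A rooted gene tree: genealogy structure with mutations on edges.

    The tree is the 1-1 counterpart of a valid :class:`BinaryMatrix`: the
    clades are exactly the distinct column 1-sets, sites with identical
    1-sets stack on one edge, and lineages whose rows are all zero hang
    directly off the root.
    """

    root: TreeNode
    matrix: BinaryMatrix

    @property
    def s(self) -> int:
        return self.matrix.s

    @property
    def n(self) -> int:
        return self.matrix.n

    @property
    def provenance(self) -> str:
        return self.matrix.provenance

    def iter_nodes(self) -> Iterator[TreeNode]:
        """Preorder traversal."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[TreeNode]:
        return [nd for nd in self.iter_nodes() if nd.is_leaf]

    def find_edge_with_site(self, site: int) -> TreeNode:
        """The node whose parent edge carries ``site``."""
        for nd in self.iter_nodes():
            if site in nd.mutations:
                return nd
        raise KeyError(f"no edge carries site {site}")

    def canonical(self) -> tuple:
        return self.root.canonical()

    def __eq__(self, other) -> bool:
        if not isinstance(other, RootedGeneTree):
            return NotImplemented
        return self.canonical() == other.canonical()

    def __hash__(self) -> int:
        return hash(self.canonical())


def build_rooted_tree(
    x: BinaryMatrix, aln: SegAlignment | None = None
) -> RootedGeneTree:
    """Build the unique rooted gene tree of a valid labelling.

    Distinct column 1-sets become internal nodes nested by containment;
    every lineage attaches as a leaf under the smallest 1-set containing it
    (the root if its row is all zero).  Sites sharing a 1-set stack on one
    edge in ascending site order.

    Raises
    ------
    ValueError
        If the matrix fails the three-gamete test (the violating site pair
        is named).
    """
    if aln is not None and tuple(aln.lineage_ids) != tuple(x.lineage_ids):
        raise ValueError("matrix and alignment disagree on lineage ids")
    validity = is_valid_matrix(x)
    if not validity:
        raise ValueError(
            f"matrix is not a rooted-tree representation: columns at sites "
            f"{validity.violating_columns} show all three gametes"
        )

    ids = x.lineage_ids
    # group sites by their 1-set; a column with no mutant carrier (only
    # possible for degenerate hand-built matrices) contributes no edge
    sets: dict[frozenset[str], list[int]] = {}
    for j in range(x.s):
        ones = x.column_ones(j)
        if ones:
            sets.setdefault(ones, []).append(x.site_positions[j])

    # nest by containment, largest first; parent = smallest strict superset
    ordered = sorted(sets, key=len, reverse=True)
    nodes: dict[frozenset[str], TreeNode] = {
        s: TreeNode(mutations=tuple(sorted(sites))) for s, sites in sets.items()
    }
    root = TreeNode()
    parent_of: dict[int, TreeNode] = {}
    for i, s in enumerate(ordered):
        parent = root
        best: frozenset[str] | None = None
        for t in ordered[:i]:
            if s < t and (best is None or len(t) < len(best)):
                best = t
        if best is not None:
            parent = nodes[best]
        parent.children.append(nodes[s])
        parent_of[id(nodes[s])] = parent

    # attach lineages under their smallest containing 1-set
    for lid, mult in zip(ids, x.multiplicities):
        best = None
        for s in sets:
            if lid in s and (best is None or len(s) < len(best)):
                best = s
        leaf = TreeNode(lineage=lid, multiplicity=int(mult))
        (nodes[best] if best is not None else root).children.append(leaf)

    # a singleton-clade internal node with its sole leaf collapses onto the
    # leaf edge (the mutations sit above that single lineage)
    def simplify(node: TreeNode) -> TreeNode:
        node.children = [simplify(c) for c in node.children]
        if not node.is_leaf and len(node.children) == 1:
            child = node.children[0]
            if not child.is_leaf:  # cannot arise from distinct 1-sets
                raise AssertionError("internal chain in laminar construction")
            child.mutations = tuple(node.mutations) + tuple(child.mutations)
            return child
        return node

    root.children = [simplify(c) for c in root.children]
    root.children.sort(
        key=lambda nd: min(nd.clade_lineages())
    )  # deterministic child order
    for nd in nodes.values():
        nd.children.sort(key=lambda c: min(c.clade_lineages()))
    return RootedGeneTree(root=root, matrix=x)


def tree_to_matrix(t: RootedGeneTree) -> BinaryMatrix:
    """Recover the 0/1 labelling: ``x[i, j] = 1`` iff site ``j`` lies on the
    root path of lineage ``i``."""
    ref = t.matrix
    col_of = {site: j for j, site in enumerate(ref.site_positions)}
    row_of = {lid: i for i, lid in enumerate(ref.lineage_ids)}
    x = np.zeros((len(ref.lineage_ids), ref.s), dtype=np.int8)

    def walk(node: TreeNode, path_sites: tuple[int, ...]):
        path = path_sites + tuple(node.mutations)
        if node.is_leaf:
            for site in path:
                x[row_of[node.lineage], col_of[site]] = 1
        else:
            for c in node.children:
                walk(c, path)

    walk(t.root, ())
    return BinaryMatrix(
        x=x,
        lineage_ids=ref.lineage_ids,
        multiplicities=ref.multiplicities,
        site_positions=ref.site_positions,
        mutant_bases=ref.mutant_bases,
        ancestral_bases=ref.ancestral_bases,
        provenance=ref.provenance,
    )


@dataclass(frozen=True)
class UnrootedGeneTree:
    """The common unrooted reduction of all ``s + 1`` rooted trees.

    Stored canonically as leaf multiplicities plus the set of edge splits:
    for every edge, the leaf bipartition side not containing the smallest
    lineage id, together with the (sorted) multiset of mutation sites on
    that edge.  Two unrooted gene trees are equal iff these agree, which is
    exactly isomorphism for leaf-labelled trees.
    """

    leaf_multiplicities: tuple[tuple[str, int], ...]
    splits: frozenset[tuple[frozenset[str], tuple[int, ...]]]

    @property
    def n_edges(self) -> int:
        return len(self.splits)


def to_unrooted(t: RootedGeneTree) -> UnrootedGeneTree:
    """Suppress the root and contract mutation-free degree-2 vertices.

    Mutation lists of merged edges concatenate in path order; the result is
    identical (up to isomorphism) for every rooting of the same data.
    """
    # adjacency over fresh integer vertex ids
    adj: dict[int, dict[int, list[int]]] = {}
    leaf_label: dict[int, tuple[str, int]] = {}
    counter = 0

    def new_vertex() -> int:
        nonlocal counter
        counter += 1
        adj[counter] = {}
        return counter

    def add_edge(u: int, v: int, sites: list[int]):
        adj[u][v] = list(sites)
        adj[v][u] = list(reversed(sites))

    def walk(node: TreeNode) -> int:
        v = new_vertex()
        if node.is_leaf:
            leaf_label[v] = (node.lineage, node.multiplicity)
        for c in node.children:
            w = walk(c)
            add_edge(v, w, list(c.mutations))
        return v

    root_v = walk(t.root)

    # contract non-leaf degree-2 vertices (the suppressed root, and any
    # mutation-free chain); degree-1 non-leaf vertices (a root with a single
    # child) are absorbed into their neighbour
    changed = True
    while changed:
        changed = False
        for v in list(adj):
            if v in leaf_label:
                continue
            nbrs = list(adj[v])
            if len(nbrs) == 2:
                a, b = nbrs
                sites = list(reversed(adj[v][a])) + adj[v][b]
                del adj[a][v], adj[b][v], adj[v]
                add_edge(a, b, sites)
                changed = True
                break
            if len(nbrs) == 1:
                (a,) = nbrs
                if adj[v][a]:
                    raise AssertionError("dangling mutations at a bare vertex")
                del adj[a][v], adj[v]
                changed = True
                break

    # leaf sets by connected side of each edge
    def side_leaves(start: int, banned_edge: tuple[int, int]) -> frozenset[str]:
        seen, stack, out = {start}, [start], []
        while stack:
            u = stack.pop()
            if u in leaf_label:
                out.append(leaf_label[u][0])
            for w in adj[u]:
                if (u, w) == banned_edge or (w, u) == banned_edge:
                    continue
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return frozenset(out)

    all_leaves = sorted(lid for lid, _ in leaf_label.values())
    smallest = all_leaves[0]
    splits = set()
    done = set()
    for u in adj:
        for v in adj[u]:
            if (v, u) in done:
                continue
            done.add((u, v))
            side = side_leaves(v, (u, v))
            if smallest in side:
                side = side_leaves(u, (u, v))
            splits.add((side, tuple(sorted(adj[u][v]))))

    return UnrootedGeneTree(
        leaf_multiplicities=tuple(sorted(leaf_label.values())),
        splits=frozenset(splits),
    )


def enumerate_rooted_trees(
    x: BinaryMatrix, aln: SegAlignment | None = None
) -> list[RootedGeneTree]:
    """All ``s + 1`` rooted gene trees compatible with the data.

    Starting from one valid labelling, every alternative rooting is obtained
    algebraically: moving the root to a new position flips exactly the
    columns of the mutations lying on the (unrooted) path between the old
    and new root positions.  Candidate positions are every vertex of the
    tree and every gap between two adjacent mutations on an edge; positions
    separated only by mutation-free edges give identical labellings and are
    deduplicated.  The count ``s + 1`` is enforced as a postcondition.
    """
    base = build_rooted_tree(x, aln)
    col_of = {site: j for j, site in enumerate(x.site_positions)}

    flip_sets: list[tuple[int, ...]] = [()]  # identity = root at old root

    def collect(node: TreeNode, above: tuple[int, ...]):
        """``above``: sites on the path from the old root to node's parent."""
        edge = tuple(node.mutations)
        # gaps between adjacent mutations on this edge, then the vertex itself
        for a in range(1, len(edge)):
            flip_sets.append(above + edge[:a])
        flip_sets.append(above + edge)
        for c in node.children:
            collect(c, above + edge)

    for c in base.root.children:
        collect(c, ())

    trees: list[RootedGeneTree] = []
    seen: set[bytes] = set()
    k = 0
    for sites in flip_sets:
        mat = (
            x
            if not sites
            else x.flip_columns(
                [col_of[s] for s in sites], provenance=f"enumerated-root-{k}"
            )
        )
        key = np.asarray(mat.x, dtype=np.int8).tobytes()
        if key in seen:
            continue
        seen.add(key)
        if not is_valid_matrix(mat):
            raise RuntimeError(
                "internal consistency error: a rerooted labelling failed the "
                "three-gamete test"
            )
        trees.append(build_rooted_tree(mat, aln))
        k += 1

    if len(trees) != x.s + 1:
        raise RuntimeError(
            f"enumeration produced {len(trees)} rooted trees; expected "
            f"s + 1 = {x.s + 1}"
        )
    return trees


# ---------------------------------------------------------------------------
# Newick output


def _newick_node(node: TreeNode) -> str:
    comment_bits = []
    if node.is_leaf:
        label = node.lineage
        comment_bits.append(f"mult={node.multiplicity}")
    else:
        label = ""
    if node.mutations:
        comment_bits.append("sites=" + "|".join(str(s) for s in node.mutations))
    comment = f"[&{' '.join(comment_bits)}]" if comment_bits else ""
    if node.is_leaf:
        return f"{label}{comment}"
    inner = ",".join(_newick_node(c) for c in node.children)
    return f"({inner}){comment}"


def write_newick(t: RootedGeneTree, path: str | Path | None = None) -> str:
    """Serialize a rooted gene tree to Newick.

    Multiplicities and per-edge mutation-site lists ride in ``[&...]``
    comment blocks (``mult=...``, ``sites=4|6|14``), which standard Newick
    readers treat as comments; the topology and leaf labels parse normally.
    """
    s = _newick_node(t.root) + ";\n"
    if path is not None:
        Path(path).write_text(s)
    return s
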