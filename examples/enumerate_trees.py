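"""Build the rooted gene tree of the packaged data and list all rootings.

The least-shared-mutations labelling (minority base = mutant at every site)
gives one valid 0/1 matrix; the other rooted trees follow by sliding the
root over the unrooted tree.  All of them reduce to the same unrooted tree.
"""

import coaltree as ct

aln = ct.load_nuu_chah_nulth()
labelled = ct.label_least_shared(ct.find_segregating_sites(aln))
print("least-shared labelling valid:", bool(ct.is_valid_matrix(labelled)))

tree = ct.build_rooted_tree(labelled, aln)
print("top-level branches of the rooted tree (lineages, leaf total, edge sites):")
for child in tree.root.children:
    lineages = ",".join(sorted(child.clade_lineages()))
    print(f"  {{{lineages}}}  leaves={child.clade_multiplicity()}  sites={list(child.mutations)}")

trees = ct.enumerate_rooted_trees(labelled, aln)
print(f"\nenumerated rooted trees: {len(trees)} (= s + 1 with s = {labelled.s})")
print("all reduce to one unrooted tree:", len({ct.to_unrooted(t) for t in trees}) == 1)

print("\nNewick of the least-shared rooting (multiplicities and edge sites in comments):")
print(ct.write_newick(trees[0]).strip())
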