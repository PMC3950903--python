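"""Estimate the TMRCA of the packaged mtDNA control-region sample.

Loads the Nuu-Chah-Nulth lineage-frequency table (55 sequences, 14 distinct
lineages, 18 segregating sites), enumerates the 19 rooted gene trees
compatible with it, and runs the Monte-Carlo posterior-mean estimator with
theta set by Watterson's moment estimate.
"""

import numpy as np

import coaltree as ct

aln = ct.load_nuu_chah_nulth()
seg = ct.find_segregating_sites(aln)
labelled = ct.label_least_shared(seg)
trees = ct.enumerate_rooted_trees(labelled, aln)
print(f"n = {aln.n} sequences, {aln.n_lineages} lineages, s = {seg.s} sites")
print(f"rooted gene trees compatible with the data: {len(trees)}")

theta = seg.s / sum(1 / j for j in range(1, aln.n))  # Watterson's estimate
res = ct.estimate_tmrca(
    trees, theta=theta, M=10_000, rng=np.random.default_rng(1), tol=1e-3
)
print(f"theta = {theta:.3f} (Watterson)")
print(f"TMRCA estimate: {res.t_hat:.4f} N generations  (MC se {res.mc_se:.4f})")
print(f"replicates used: {res.M_used}, converged: {res.converged}")

# With N = 600 breeding females (a plausible effective size for this
# population) and 20-year generations, convert to calendar time:
years = ct.to_years(res.t_hat, N=600, Y=20)
print(f"with N = 600, Y = 20 years/generation: about {years:,.0f} years")
print(f"predata mean for comparison: {ct.predata_moments(aln.n).mean_t:.4f} N generations")
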