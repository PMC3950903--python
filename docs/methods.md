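# Methods

## Model and assumptions

The sample is `n` aligned DNA sequences drawn at random from a large
Wright-Fisher population of constant size `N`.  Time is measured backward
in units of `N` generations.  Under Kingman's coalescent the time during
which the sample has exactly `j` ancestral lineages is
`w_j ~ Exp(j(j−1)/2)`, independently over `j`, so the TMRCA is
`t_n = Σ_{j=2}^{n} w_j` and the total tree length is
`l_n = Σ_{j=2}^{n} j·w_j`, with

```
E(t_n) = 2(1 − 1/n)            Var(t_n) = 8 Σ_{j=2}^{n} 1/j² − 4(1 − 1/n)²
E(l_n) = 2 Σ_{j=1}^{n−1} 1/j   Var(l_n) = 4 Σ_{j=1}^{n−1} 1/j²
```

Mutation is an infinite-sites Poisson process of rate `θ/2` per branch per
unit time, `θ = 2Nμ` with `μ` the per-sequence per-generation mutation
probability.  `θ` is always a user input; the package never estimates it.
Each site mutates at most once and irreversibly, so a segregating site has
exactly two base types (one ancestral, one mutant) and the number of
segregating sites `s` equals the number of mutations in the sample's
history; conditional on `l_n = l`, `s ~ Poisson(θl/2)`.

Conversion to calendar time is always explicit: `t · N · Y` years, with
`Y` the generation span (commonly 20–25 years for humans); no default `Y`
is applied.

## Data model and gene trees

The alignment is collapsed to distinct haplotypes (lineages) with
multiplicities; only segregating sites are kept.  A column with three or
more observed bases raises `InfiniteSitesViolation` — such data need the
preprocessing (dropping repeat-mutation sequences) that produced the
packaged dataset, which is out of scope here.

Choosing a mutant base per site gives a 0/1 matrix `X`; `X` represents a
rooted gene tree iff its column 1-sets form a laminar family (pairwise
nested or disjoint), checked by the pairwise three-gamete test.  The
*least-shared* labelling takes the multiplicity-weighted minority base as
mutant at every site; ties go to the lexicographically smaller base (the
source procedure does not address ties; determinism is the only
requirement).  Tree construction nests the distinct 1-sets by containment,
stacks sites with identical 1-sets on one edge in ascending site order,
and attaches each lineage below the smallest 1-set containing it — all-zero
rows hang off the root.  Multifurcations are kept; no artificial
binarisation happens at the topology level (time order is resolved
stochastically during allocation).

All rootings compatible with the data are generated algebraically: moving
the root across a mutation flips that column's 0/1 roles, so candidate
positions are every vertex and every gap between two adjacent mutations on
an edge, deduplicated by matrix identity.  With every edge's mutation
stack in a fixed order this yields exactly `s + 1` distinct rooted trees,
enforced as a postcondition, all reducing to the same unrooted tree
(root suppression plus contraction of mutation-free degree-2 vertices;
unrooted trees are compared by their edge splits).

**Known limitation (identifiability of stacked mutations).**  When
mutations whose 1-sets are complementary share one unrooted edge (possible
after a weighted tie), the 2^s-exhaustive count of valid labellings
exceeds `s + 1`: the interleaving of same-edge mutations is not
identifiable, and the `s + 1` enumeration fixes one order convention.  In
that situation the true genealogy's rooting may not be among the
enumerated trees, although its unrooted reduction always is.  The tests
assert the unrooted invariant and treat exact-rooting membership as the
typical, not guaranteed, case.

## The estimator

With the `s + 1` rooted trees taken as equally likely a posteriori, the
point estimate is the Monte-Carlo average

```
t̂_n ≈ (2/M) Σ_{m=1}^{M} (1/(s+1)) Σ_{r=1}^{s+1} Σ_{i=2}^{n}
        (k_{r,i}^{(m)} + 1) / (i (i + θ − 1)).
```

The inner sum is the exact conditional mean `E(t_n | k, s, θ)`: interval
`i` has an Exp(i(i−1)/2) prior and a Poisson(θ·i·w_i/2) count, so its
posterior is Gamma with mean `2(k_i + 1)/(i(i + θ − 1))`; the `n = 2` case
reduces to the textbook Gamma(k+1, 1+θ) posterior mean `(k+1)/(1+θ)`,
which the tests use as an oracle.  A related closed form conditioning only
on `s` (a normalised sum over all compositions `|k| = s`) is provided for
small `n, s` by exact composition enumeration.  Its printed normalisation
`2/(s+1)` does not equal 2/(number of compositions) in general, and the
expectation `E[k_i]` it contains is not pinned down by the formula; the
function evaluates the expression exactly as written and exposes the
expectation source as an explicit argument (default: the composition
itself) rather than guessing.

### Backward waiting-time allocation

Per replicate one waiting-time vector `w^{(m)}` is drawn (inverse-CDF
transform, one fresh uniform per `j`, in the fixed order `j = 2..n`) and
shared by all `s + 1` trees — the estimator indexes `w` by replicate only,
and sharing reduces Monte-Carlo variance.  Events are allocated oldest
sample-event first (`w_n`, then `w_{n−1}`, …, `w_2`):

- Every tree node is a *unit*.  A leaf unit's active count starts at its
  multiplicity; an internal unit's is the sum over its subtree.  A clade
  whose interior has fully coalesced becomes a single representative
  lineage of its parent scope; single-copy leaves are representatives from
  the start.
- At each step the algorithm descends from the root: among a scope's
  children with ≥ 2 active leaves (weight = active count) and, when the
  scope holds ≥ 2 representatives, the scope itself (weight = number of
  representatives), one option is chosen with probability proportional to
  weight.  Descent recurses until the event lands in a leaf unit (two
  identical copies merge — which pair is irrelevant, the count just
  decrements) or merges two representatives (chosen uniformly; the pair's
  identity is tracked only because segment spans need it).
- Single-leaf branches therefore never host events; they merge only at
  their parent scope, and the published first-step weights on the packaged
  data — multi-leaf top-level branches (3, 24, 5, 19, 3) out of 54, then
  (19, 2, 2)/23 inside the four-lineage clade, then (2, 12, 4)/18 inside
  the six-lineage clade — come out of this rule exactly (asserted in the
  acceptance tests, with a chi-square check of the empirical first-event
  frequencies).

After allocation, the segment above node `u` spans the coalescent
intervals from the event that merged `u`'s representative up to (but not
including) the event that resolved `u`'s interior; every mutated segment
spans at least one interval by construction (a defensive contract check
raises otherwise, rather than silently reallocating).  The segment's
mutations are scattered over its intervals by one multinomial draw with
probabilities proportional to the interval lengths of the current
replicate; interval totals over all segments give `k_{r,·}^{(m)}`, whose
sum is always `s`.

### Convergence and reporting

Batch means of size `max(100, M/50)`: the run stops early when the
relative change of the running estimate between successive batches falls
below `tol` (default `1e-3`); otherwise it exhausts `M` and reports
`converged = False`.  The result carries the Monte-Carlo standard error of
the replicate values, per-tree means, and the batch trace.  With `s = 0`
and `θ = 0` every replicate evaluates to `2(1 − 1/n)` exactly — a useful
degenerate end-to-end check.

## Synthetic data

`simulate_infinite_sites` draws a plain binary-merge Kingman genealogy
(uniform pair at each coalescence — the model underlying the waiting-time
law), Poisson mutations per branch, one fresh site per mutation in a
random order along the sequence, and encodes haplotypes with a uniformly
drawn ancestral base per site and its transition partner as mutant
(A↔G, C↔T), mirroring the transitions-only character of control-region
data; a flag allows arbitrary substitutions.  The generator records the
waiting times, the per-interval mutation counts, and the true labelled
genealogy, and writes the same TSV dialect the readers accept.

What the generator does *not* emulate: recombination, recurrent or
back-mutation, rate heterogeneity across sites, population growth or
structure, and sequencing error.  Passing tests therefore demonstrate
correctness of the inference machinery under the model's own assumptions,
not robustness of those assumptions on real data.

## Numerical and design choices

- Uniforms are clamped away from 0 so no waiting time is exactly zero.
- All randomness flows through one seeded `numpy.random.Generator`; the
  CLI seeds it once, making any run replayable.
- The validity test is the O(n·s²) pairwise scan — at segregating-site
  scale clarity beats the linear-time variant.
- Rootings are generated by column flipping with re-validation rather than
  geometric tree surgery; it is the checkable algebraic equivalent.
- Problem sizes in the test suite are chosen for desk-scale runs: 10⁵
  replicates for predata moment checks, 10⁴ for the full-data estimator
  (which typically stops after a few hundred replicates at `tol = 1e-3`),
  and toy datasets (`n ≤ 4`, `s ≤ 2`) for the brute-force cross-check,
  where an independently coded block-tracking simulator of the same model
  must agree within combined Monte-Carlo error.
- The closed-form composition sum is capped (default 5·10⁵ terms) and
  refers callers to the Monte-Carlo estimator beyond that.

## Known limitations

- `θ` must be supplied; a moment estimate such as Watterson's
  `s / Σ_{j<n} 1/j` is a reasonable source but is the user's choice.
- The uniform prior over the `s + 1` rooted trees is the method's defining
  simplification; trees are not weighted by their sampling probabilities,
  so the estimate differs from full-likelihood machinery exactly where
  those probabilities are far from uniform.
- Constant population size only; no growth or structure.
- The stacked-mutation identifiability caveat above.
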