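# Methods

## Model

Three species X, Y, Z are related by a rooted tree ((X,Y),Z) with
divergence times `τ1 ≤ τ2` in mutation units (`τ = t·μ`). Every ancestral
species is split into two demes. Below `τ1` extant populations are
panmictic and no coalescence happens. On `[τ1, τ2)` the two ingroup
lineages evolve on a 6-state chain (deme occupancies `x1y2, x2y1, x1y1,
x2y2` plus the coalesced pair in either deme); above `τ2` the outgroup
lineage joins deme 2 and the system evolves on a 20-state chain (8
uncoalesced states, 12 once-coalesced states grouped by which pair
coalesced) until the first coalescence, then on the 6-state pair chain to
the final one. Rates: pairwise coalescence `c_i = 2/θ_i` within deme *i*
(`θ_i = 4N_iμ`), single-lineage migration to deme *j* at `M_j = 4Nm_j/θ_j`.
When three lineages share a deme each of the three pairs coalesces at
`c_i`, total `3c_i`, a uniform choice of pair. One event per instant;
coalescence is irreversible. The deme assignment matters: either ingroup
species may share the outgroup's deme, so 3 topologies × 2 assignments = 6
model configurations.

Choices a reader should know about:

* **Time units.** Everything is parameterised in mutation units so the
  rates above are exact. An alternative diffusion-style scaling
  `τ = tθ/(2N)` differs by a factor of two and is *not* used; the
  calibration adopted here is the one under which the closed-form
  discordance `P[G≠σ] = (2/3)exp(−2Δτ/θ)` holds for a panmictic ancestral
  population of diversity θ.
* **Unstructured limit.** As `M → 4N/θ` (migrant fraction `m → 1`) the two
  demes of size N pool into one panmictic population of size 2N, i.e.
  coalescence at rate `1/θ`, *not* `2/θ`. The package's probabilities
  reproduce this limit to four significant figures, which also pins down
  the internal branch lengths behind the reference concordance values
  (2.5e-3 and 2.5e-4 mutation units).
* **Once-coalesced states are absorbing** in the 20-state generator: the
  second coalescence is handled on the 6-state chain after a deterministic
  state mapping, so first-coalescence identities are read off as hitting
  probabilities of the three absorbing blocks.
* **First-passage densities.** The density of coalescing at time *t* into
  a given absorbed state is (rate into that state) × (occupation
  probability of its unique pre-coalescent transient state), i.e. the
  derivative of the absorption probability. This is the only reading of
  the pair/triple marginal densities consistent with total probability 1,
  and it is validated against the event simulator.

## Topology probabilities: two routes

The default route is exact linear algebra: propagate the pair chain to the
root with one 6×6 matrix exponential, map uncoalesced mass into the
20-state chain, and solve `−Q_TT H = Q_TA` for the hitting probabilities of
the three coalesced blocks (8×8 solve). No integrals, no truncation; cost
is microseconds, and results are cached by parameter set.

The cross-check route integrates the joint topology/time densities
`f_j(t1, t2)` over their supports with composite Gauss–Legendre rules on
geometrically graded panels (34 panels per decade-spanning axis, order 16,
tails truncated at `e^{−46}`). The two routes agree to better than 1e-6
across a grid of `(M, Δτ)` spanning four orders of magnitude in migration
rate; the integrated densities also sum to 1, which is the total-probability
check on the density layer itself.

## Likelihood and fitting

* **Topology counts** (a multinomial in the three topology
  probabilities): only `Δτ = τ2 − τ1`
  is identifiable, so `τ1` is pinned at 0 and the fit searches
  `(M, Δτ)` with `M ∈ (0.01, 4N/θ]` and `Δτ` bounded by the length at
  which the closed-form discordance drops to `p_min = 0.05` (default,
  configurable): `Δτ_max = −(θ/2)ln(1.5 p_min) ≈ 6.5e-3` for θ = 0.005.
* **Bootstrap-weighted counts**: per-locus topology proportions are summed
  into real-valued pseudo-counts that plug into the same likelihood; hard
  assignments reduce exactly to integer counts.
* **Gene trees with times**: product over loci of `Σ_j f_j(t1, t2, g)`;
  `τ1 ≤ min t1` and `τ2 ≤ min t2` bound the search, and `(M, τ1, τ2)` are
  fitted jointly. A fit collapsing to `τ̂1 = τ̂2 = 0` (tolerance 1e-9) is a
  star tree and reported unresolved.
* **Optimiser**: a deterministic log-spaced × linear grid (20×20 by
  default) followed by Nelder–Mead refinement from the best three grid
  points, in fixed order; identical inputs give identical outputs.
* **Ties.** Configurations whose maximised log-likelihoods agree within
  1e-6 across *different* topologies yield the unresolved triple with the
  tie set attached, never a silent pick. This matters in practice: at the
  unstructured boundary a rival topology's configuration with a tiny
  internal branch can fit the empirical topology distribution exactly, so
  exact ties are a real, not hypothetical, outcome of this model family
  (an identifiability limit of topology-only data, not a numerical
  artifact). Zero-probability categories with positive counts give −∞
  rather than underflow noise.

## Simulator

`simulate_history` draws exact Gillespie paths through the three chains
(start `a1b2` at `τ1`; deterministic state mapping at the root; stop at
the final coalescence), returning topology, both coalescence times and the
full event path. It is the package's independent oracle: empirical
topology frequencies at 10^5 draws match the analytic probabilities within
three binomial standard errors, and first-passage histograms match the
density layer. `simulate_topology_counts` draws multinomial counts from
the analytic probabilities (used by the bootstrap test and the large
simulation studies). The n-taxon ladder simulator composes epochs of the
same two-deme rules (first species in deme 1, each later lineage entering
deme 2 at its divergence time) and emits ultrametric newick gene trees.
These generators emulate *known, error-free* gene trees; they do not model
sequence evolution, gene-tree estimation error, or recombination, so
passing tests say nothing about robustness to misestimated gene trees.

## Structure test

The parametric bootstrap simulates B = 100 samples of K locus topologies
at the fitted `(M̂, Δτ̂)`, scores each against null-symmetric expected
counts (observed maximum kept, minority cells averaged; argmax ties break
to the first index) with a χ² statistic on **1 degree of freedom**: a
3-cell goodness-of-fit conventionally leaves 2 df, but the maximal cell is
matched to the data exactly, which absorbs one, leaving only the
minority-symmetry contrast under test. P-values are combined
p-values with Simes' rule, rejecting panmixia at α = 0.01. Measured
behaviour with the full simulate–fit–test pipeline: empirical level ≈ α at
the unstructured boundary; power ≈ 1 in the strong minority-asymmetry
regime (M = 5, Δτ = 2.75e-3, K = 2791) but low (~0.07) at M = 0.5 with the
same K, because the statistic sees only the two minority cells, which hold
~16 of 2791 counts there. Zero expected cells raise an error rather than
silently applying a continuity correction.

## Supertree

Rooted triples are extracted per 3-subset (cherry = the pair whose MRCA
excludes the third taxon; with branch lengths, `t1`/`t2` are the induced
node heights, requiring ultrametric input within 1e-6 of tree height).
Per-subset fits feed the modified mincut assembly: pairs grouped by every
input triple containing them are contracted; edges never contradicted by
any input are made uncuttable; the union of all minimum-weight cut edges
is deleted (exact enumeration of bipartitions up to 16 contracted
vertices, a single Stoer–Wagner cut beyond) and components are recursed
on. Compatible inputs are reassembled exactly; conflicts become
multifurcations; the output is deterministic and input-order invariant.
Unresolved/tied triples are omitted from assembly with a warning. When
per-species θ estimates differ, a triple uses the maximum of its three
values (robust to recent bottlenecks). Trees are scored by FP + FN clades,
a Robinson–Foulds variant valid for multifurcating trees.

## Problem sizes in the shipped checks

The test suite uses 2–10 × 10^4 simulator draws for Monte-Carlo
comparisons, 100 replicates of 10^3 (and 10^4) loci for recovery rates,
200 repetitions for the test's level/power, and 100 random trees (n ≤ 8)
for the supertree characterisation property; these sizes put three-σ
Monte-Carlo bands well inside the asserted tolerances while keeping the
default run to minutes.

## Known limitations

Two demes only, constant θ and M per epoch (a single shared M by default;
four free rates are accepted), no gene flow between species, no
alignment-level likelihood (gene trees are taken as known), θ supplied by
the user rather than estimated, and missing-taxon gene trees are rejected
rather than accommodated. Topology-only data cannot identify `τ1`, and at
the unstructured boundary the topology itself is not always identifiable
(reported as ties, see above). The mincut fallback beyond 16 contracted
vertices may delete more edges than the exact all-min-cuts rule.
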