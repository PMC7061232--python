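"""Event-driven (Gillespie) simulation of gene trees under the structured model.

Two independent routes to gene-tree data are provided:

* :func:`simulate_history` draws a full coalescent history for a rooted
  triple by exact stochastic simulation of the three continuous-time Markov
  chains, returning the topology, both coalescence times and the event path.
  This is the Monte-Carlo oracle against which the analytic topology
  probabilities are checked.
* :func:`simulate_topology_counts` draws multinomial topology counts
  directly from the analytic probabilities (the route used for the
  parametric-bootstrap structure test and for large simulation studies).

:func:`simulate_gene_trees` generalises the event simulation to a ladder
(caterpillar) species tree on any number of taxa, composing epochs of the
same two-deme rule set: one lineage starts in deme 1, every later species'
lineage enters deme 2 at its divergence time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import dendropy
import numpy as np

from tasti.likelihood import TopologyCounts
from tasti.model import (
    PHI1,
    PHI2,
    PHI3,
    STATES_AB,
    STATES_ABC,
    STATES_XY,
    CANONICAL_TOPOLOGIES,
    ModelParameters,
    ParameterError,
    _chains,
    topology_probabilities,
)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SimulatedHistory:
    """One simulated coalescent history for a rooted triple."""

    topology: str  # canonical label ((ab)c), ((ac)b) or ((bc)a)
    t1: float
    t2: float
    path: list = field(default_factory=list)  # (time, from_label, to_label)

    @property
    def cherry(self) -> str:
        return {"((ab)c)": "ab", "((ac)b)": "ac", "((bc)a)": "bc"}[self.topology]


@lru_cache(maxsize=64)
def _jump_tables(omega: ModelParameters):
    """Per-state (total rate, target indices, cumulative probabilities)."""
    tables = {}
    for kind, (gen, _) in _chains(omega).items():
        rows = []
        for i in range(gen.matrix.shape[0]):
            rates = gen.matrix[i].copy()
            rates[i] = 0.0
            total = rates.sum()
            targets = np.nonzero(rates)[0]
            cum = np.cumsum(rates[targets]) / total if total > 0 else np.array([])
            rows.append((total, targets, cum))
        tables[kind] = rows
    return tables


def _run_chain(table, labels, state, t, t_end, stop, rng, path):
    """Advance one chain from 1-based ``state`` at time ``t``.

    Stops at the first entry into ``stop`` (returning that state and time)
    or at ``t_end`` (returning the current state).  ``t_end=None`` means run
    until absorption into ``stop``.
    """
    while True:
        total, targets, cum = table[state - 1]
        if total <= 0:
            return state, t_end if t_end is not None else t
        wait = rng.exponential(1.0 / total)
        if t_end is not None and t + wait >= t_end:
            return state, t_end
        t += wait
        nxt = int(targets[np.searchsorted(cum, rng.random())]) + 1
        path.append((t, labels[state - 1], labels[nxt - 1]))
        state = nxt
        if state in stop:
            return state, t


def simulate_history(omega: ModelParameters, seed=None) -> SimulatedHistory:
    """Draw one gene-tree history by exact event simulation.

    The pair chain starts in state a1b2 at ``tau1``; at ``tau2`` the current
    state is carried across the root by the phi mappings (the outgroup
    lineage entering deme 2) and simulation continues on the triple or pair
    chain until the final coalescence.
    """
    rng = _as_rng(seed)
    tables = _jump_tables(omega)
    path: list = []
    coalesced = {5, 6}
    # internal branch
    state, t = _run_chain(
        tables["AB"], STATES_AB, 1, omega.tau1, omega.tau2, coalesced, rng, path
    )
    if state in coalesced:
        t1 = t
        topology = "((ab)c)"
        # pair keeps migrating on the internal branch until the root
        state, _ = _run_chain(
            tables["AB"], STATES_AB, state, t, omega.tau2, set(), rng, path
        )
        xy_state = PHI1[state]
    else:
        abc_state, t = _run_chain(
            tables["ABC"],
            STATES_ABC,
            PHI2[state],
            omega.tau2,
            None,
            set(range(9, 21)),
            rng,
            path,
        )
        t1 = t
        topology = CANONICAL_TOPOLOGIES[(abc_state - 9) // 4]
        xy_state = PHI3[abc_state]
    state, t2 = _run_chain(
        tables["XY"], STATES_XY, xy_state, max(t1, omega.tau2), None, coalesced, rng, path
    )
    return SimulatedHistory(topology, t1, t2, path)


def simulate_topology_counts(
    omega: ModelParameters, K: int, seed=None
) -> TopologyCounts:
    """Multinomial draw of ``K`` locus topologies from the analytic
    probabilities, mapped onto the species names of ``omega.config``."""
    if K < 1:
        raise ParameterError("K must be a positive integer")
    rng = _as_rng(seed)
    probs = topology_probabilities(omega)
    draw = rng.multinomial(K, probs)
    counts = {
        omega.config.gene_topology(lbl): int(n)
        for lbl, n in zip(CANONICAL_TOPOLOGIES, draw)
    }
    return TopologyCounts.from_mapping(sorted(omega.config.topology), counts)


# ---------------------------------------------------------------------------
# Ladder species trees on n taxa
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LadderSpeciesTree:
    """A caterpillar species tree ``((((s0,s1),s2),s3)...`` with divergence
    times ``taus[0] < taus[1] < ...`` in mutation units.  Species ``s0``
    descends from deme 1; every other species' lineage enters deme 2 at its
    divergence time, matching the three-taxon model's deme assignment."""

    species: tuple[str, ...]
    taus: tuple[float, ...]

    def __post_init__(self):
        if len(self.species) < 2 or len(set(self.species)) != len(self.species):
            raise ParameterError("need >= 2 distinct species")
        if len(self.taus) != len(self.species) - 1:
            raise ParameterError("need one divergence time per split")
        if any(b < a for a, b in zip(self.taus, self.taus[1:])) or self.taus[0] < 0:
            raise ParameterError("divergence times must be nondecreasing and >= 0")


def simulate_gene_trees(
    ladder: LadderSpeciesTree,
    theta: float,
    M: float,
    K: int,
    seed=None,
    N: float = 5e4,
) -> list[dendropy.Tree]:
    """Simulate ``K`` ultrametric gene trees under the two-deme ladder model.

    Within the pooled ancestral population, every lineage in deme ``i``
    migrates to the other deme at rate ``M_j`` (symmetric ``M`` here) and
    every same-deme pair coalesces at rate ``c = 2/theta``; new lineages
    join deme 2 at each divergence time.  Branch lengths are in mutation
    units; node ages equal the coalescence times.
    """
    if theta <= 0 or M <= 0:
        raise ParameterError("theta and M must be positive")
    if M > 4 * N / theta * (1 + 1e-12):
        raise ParameterError("M exceeds its upper bound 4N/theta")
    rng = _as_rng(seed)
    c = 2.0 / theta
    tns = dendropy.TaxonNamespace(list(ladder.species))
    trees = []
    for _ in range(K):
        trees.append(_one_ladder_tree(ladder, c, M, rng, tns))
    return trees


def _one_ladder_tree(ladder, c, M, rng, tns) -> dendropy.Tree:
    # lineage: [node, deme]; nodes carry .age
    def leaf(name):
        nd = dendropy.Node(taxon=tns.get_taxon(name))
        nd.age = 0.0
        return nd

    sp = ladder.species
    active = [[leaf(sp[0]), 1], [leaf(sp[1]), 2]]
    pending = list(zip(sp[2:], ladder.taus[1:]))
    t = ladder.taus[0]
    while len(active) > 1 or pending:
        t_next = pending[0][1] if pending else np.inf
        n1 = sum(1 for _, d in active if d == 1)
        n2 = len(active) - n1
        rate_mig = n1 * M + n2 * M
        rate_coal = c * (n1 * (n1 - 1) // 2 + n2 * (n2 - 1) // 2)
        total = rate_mig + rate_coal
        if total <= 0:
            t = t_next
        else:
            wait = rng.exponential(1.0 / total)
            if t + wait >= t_next:
                t = t_next
            else:
                t += wait
                if rng.random() < rate_coal / total:
                    deme = 1 if rng.random() < (n1 * (n1 - 1)) / (
                        n1 * (n1 - 1) + n2 * (n2 - 1)
                    ) else 2
                    idx = [k for k, (_, d) in enumerate(active) if d == deme]
                    i, j = sorted(rng.choice(idx, size=2, replace=False))
                    parent = dendropy.Node()
                    parent.age = t
                    parent.add_child(active[i][0])
                    parent.add_child(active[j][0])
                    active[i] = [parent, deme]
                    del active[j]
                else:
                    # pick a migrating lineage uniformly (symmetric rates)
                    k = int(rng.integers(len(active)))
                    active[k][1] = 3 - active[k][1]
                continue
        if pending and t >= pending[0][1]:
            name, _ = pending.pop(0)
            active.append([leaf(name), 2])
    root = active[0][0]
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = True
    for nd in tree.preorder_node_iter():
        for ch in nd.child_nodes():
            ch.edge.length = nd.age - ch.age
    root.edge.length = None
    return tree
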