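"""Rooted-triple supertree assembly for n-taxon species-tree inference.

A rooted binary tree is characterised by its set of rooted triples, so the
n-taxon problem decomposes into (n choose 3) three-taxon inferences whose
estimated triples are assembled with the modified mincut supertree
algorithm.  Conflicting triples yield multifurcations rather than failures,
and the result is scored against a reference with a multifurcation-aware
Robinson-Foulds distance (false positive clades + false negative clades).
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import dendropy
import networkx as nx

from tasti.likelihood import (
    FitOptions,
    FitResult,
    GeneTreeObservation,
    InputError,
    TopologyCounts,
    cherry_pairs,
    infer_species_tree,
)

log = logging.getLogger(__name__)

ULTRAMETRIC_RTOL = 1e-6


class RootedTriple(NamedTuple):
    """A rooted three-taxon topology ((x,y),z), optionally with the two
    coalescence times (cherry height t1 and root height t2)."""

    pair: frozenset
    outgroup: str
    t1: Optional[float] = None
    t2: Optional[float] = None


# ---------------------------------------------------------------------------
# Tree utilities
# ---------------------------------------------------------------------------


def _leaf_labels(tree: dendropy.Tree) -> list[str]:
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise InputError("duplicate leaf labels")
    return labels


def _check_binary(tree: dendropy.Tree) -> None:
    for nd in tree.preorder_internal_node_iter():
        if len(nd.child_nodes()) != 2:
            raise InputError(
                f"input gene trees must be binary; node with "
                f"{len(nd.child_nodes())} children found"
            )


def node_ages(tree: dendropy.Tree, rtol: float = ULTRAMETRIC_RTOL) -> dict:
    """Ages (height above the leaves) of all nodes of an ultrametric tree.

    Raises :class:`InputError` with the observed deviation when root-to-leaf
    path lengths disagree by more than ``rtol`` of the tree height.
    """
    depth = {tree.seed_node: 0.0}
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        if nd.edge.length is None:
            raise InputError("tree has missing branch lengths")
        depth[nd] = depth[nd.parent_node] + nd.edge.length
    leaf_depths = [depth[lf] for lf in tree.leaf_node_iter()]
    height = max(leaf_depths)
    if height > 0 and (height - min(leaf_depths)) > rtol * height:
        raise InputError(
            f"tree is not ultrametric: root-to-leaf lengths span "
            f"[{min(leaf_depths):.6g}, {height:.6g}] "
            f"(tolerance {rtol:g} of height)"
        )
    return {nd: height - d for nd, d in depth.items()}


def extract_rooted_triples(
    tree: dendropy.Tree, with_times: bool = False
) -> dict[frozenset, RootedTriple]:
    """The rooted triple induced on every 3-subset of the leaves.

    With ``with_times=True`` the input must be ultrametric with branch
    lengths; ``t1``/``t2`` are then the cherry and root node heights of the
    induced triple.
    """
    _check_binary(tree)
    labels = _leaf_labels(tree)
    if len(labels) < 3:
        raise InputError("need at least three leaves")
    ages = node_ages(tree) if with_times else None
    # MRCA (clade, age) for every leaf pair: the pair's MRCA is the internal
    # node whose two child clades separate them.
    clades = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            clades[nd] = frozenset((nd.taxon.label,))
        else:
            clades[nd] = frozenset().union(*(clades[c] for c in nd.child_nodes()))
    mrca: dict[frozenset, tuple] = {}
    for nd in tree.preorder_internal_node_iter():
        left, right = (clades[c] for c in nd.child_nodes())
        for x in left:
            for y in right:
                mrca[frozenset((x, y))] = (clades[nd], ages[nd] if ages else None)
    out = {}
    for trio in itertools.combinations(sorted(labels), 3):
        trio_set = frozenset(trio)
        cherry = None
        for x, y in itertools.combinations(trio, 2):
            clade, age = mrca[frozenset((x, y))]
            (z,) = trio_set - {x, y}
            if z not in clade:
                cherry = (frozenset((x, y)), z, age)
        if cherry is None:  # cannot happen on a binary tree
            raise InputError(f"unresolved triple {trio}")
        pair, z, t1 = cherry
        t2 = None
        if with_times:
            x, y = pair
            t2 = max(mrca[frozenset((x, z))][1], mrca[frozenset((y, z))][1])
        out[trio_set] = RootedTriple(pair, z, t1 if with_times else None, t2)
    return out


# ---------------------------------------------------------------------------
# Modified mincut supertree
# ---------------------------------------------------------------------------


def _normalise_triples(triples) -> list[RootedTriple]:
    norm = []
    for t in triples:
        if isinstance(t, RootedTriple):
            norm.append(t)
        else:
            x, y, z = t
            norm.append(RootedTriple(frozenset((x, y)), z))
    return norm


class _UnionFind(dict):
    def find(self, x):
        while self[x] != x:
            self[x] = self[self[x]]
            x = self[x]
        return x

    def union(self, x, y):
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            # deterministic: smaller label becomes the representative
            lo, hi = sorted((rx, ry))
            self[hi] = lo


def _all_min_cut_edges(nodes: list, weights: dict) -> list[tuple]:
    """Edges lying in any minimum-weight cut, by exact enumeration of the
    2^(k-1) bipartitions (k = len(nodes), small after contraction)."""
    k = len(nodes)
    edges = list(weights)
    best = None
    cut_edge_sets = []
    for mask in range(1, 1 << (k - 1)):
        side = {nodes[i] for i in range(k) if (mask >> i) & 1}
        crossing = [e for e in edges if (min(e) in side) != (max(e) in side)]
        w = sum(weights[e] for e in crossing)
        if best is None or w < best - 1e-12:
            best = w
            cut_edge_sets = [crossing]
        elif abs(w - best) <= 1e-12:
            cut_edge_sets.append(crossing)
    out = set()
    for s in cut_edge_sets:
        out.update(s)
    return sorted(out, key=lambda e: tuple(sorted(e)))


def _stoer_wagner_cut_edges(nodes: list, weights: dict) -> list[tuple]:
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for (u, v), w in weights.items():
        g.add_edge(u, v, weight=w)
    _, (side_a, side_b) = nx.stoer_wagner(g)
    side = set(side_a)
    return [e for e in weights if (min(e) in side) != (max(e) in side)]


def mincut_supertree(triples: Iterable) -> dendropy.Tree:
    """Assemble a rooted (possibly multifurcating) tree displaying as many
    of the input rooted triples as possible.

    Follows the modified mincut recursion: pairs grouped by every input
    triple that contains them are contracted; edges never contradicted by
    any input are made uncuttable; all remaining edges that lie in some
    minimum-weight cut are deleted and the components are recursed on.  A
    compatible input set is displayed exactly; conflicts collapse into
    multifurcations.  The result is deterministic and independent of input
    order.
    """
    norm = _normalise_triples(triples)
    if not norm:
        raise InputError("no input triples")
    taxa = frozenset().union(*(t.pair | {t.outgroup} for t in norm))
    if len(taxa) < 3:
        raise InputError("input triples must cover at least three taxa")

    def build(subset: frozenset) -> str:
        if len(subset) == 1:
            return next(iter(subset))
        if len(subset) == 2:
            a, b = sorted(subset)
            return f"({a},{b})"
        active = [t for t in norm if (t.pair | {t.outgroup}) <= subset]
        together: Counter = Counter()
        both: Counter = Counter()
        contradicted: set = set()
        for t in active:
            together[t.pair] += 1
            both[t.pair] += 1
            x, y = t.pair
            for p in (frozenset((x, t.outgroup)), frozenset((y, t.outgroup))):
                both[p] += 1
                contradicted.add(p)
        uf = _UnionFind({s: s for s in subset})
        for pair in sorted(together, key=lambda p: tuple(sorted(p))):
            if together[pair] == both[pair]:
                a, b = pair
                uf.union(a, b)
        groups: dict[str, set] = {}
        for s in subset:
            groups.setdefault(uf.find(s), set()).add(s)
        reps = sorted(groups)
        weights: dict[tuple, float] = {}
        uncut: set = set()
        big = sum(together.values()) + 1.0
        for r1, r2 in itertools.combinations(reps, 2):
            w = 0.0
            contra = False
            for a in groups[r1]:
                for b in groups[r2]:
                    pair = frozenset((a, b))
                    w += together.get(pair, 0)
                    if pair in contradicted:
                        contra = True
            if w > 0:
                key = (r1, r2)
                weights[key] = w
                if not contra:
                    uncut.add(key)
        # connected components of the supernode graph
        cg = nx.Graph()
        cg.add_nodes_from(reps)
        cg.add_edges_from(weights)
        comps = [set(c) for c in nx.connected_components(cg)]
        if len(comps) == 1 and len(reps) > 1:
            eff = {
                e: (big if e in uncut else w) for e, w in weights.items()
            }
            if len(reps) <= 16:
                cut_edges = _all_min_cut_edges(reps, eff)
            else:  # exact enumeration infeasible; single Stoer-Wagner cut
                cut_edges = _stoer_wagner_cut_edges(reps, eff)
            cg.remove_edges_from(cut_edges)
            comps = [set(c) for c in nx.connected_components(cg)]
        if len(comps) == 1:
            # no informative split: unresolved star over the subset
            return "(" + ",".join(sorted(subset)) + ")"
        parts = [
            frozenset().union(*(groups[r] for r in comp)) for comp in comps
        ]
        parts.sort(key=min)
        return "(" + ",".join(build(p) for p in parts) + ")"

    newick = build(taxa) + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")
    return tree


# ---------------------------------------------------------------------------
# Robinson-Foulds with FP/FN decomposition
# ---------------------------------------------------------------------------


def tree_clades(tree: dendropy.Tree) -> set[frozenset]:
    """Nontrivial clades (proper, non-singleton leaf sets of internal
    nodes) of a rooted tree."""
    labels = set(_leaf_labels(tree))
    clades = set()
    for nd in tree.postorder_internal_node_iter():
        clade = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if 1 < len(clade) < len(labels):
            clades.add(clade)
    return clades


def rf_distance(
    estimated: dendropy.Tree, reference: dendropy.Tree
) -> tuple[int, int, int]:
    """(false positive clades, false negative clades, total).

    FP counts clades of the estimate absent from the reference, FN the
    reverse; the total is their sum, which extends the Robinson-Foulds
    distance to multifurcating trees.
    """
    if set(_leaf_labels(estimated)) != set(_leaf_labels(reference)):
        raise InputError("trees are over different leaf sets")
    est = tree_clades(estimated)
    ref = tree_clades(reference)
    fp = len(est - ref)
    fn = len(ref - est)
    return (fp, fn, fp + fn)


# ---------------------------------------------------------------------------
# n-taxon inference
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SupertreeResult:
    tree: dendropy.Tree
    triple_fits: Mapping[frozenset, FitResult]
    skipped: tuple[frozenset, ...]  # triples omitted as unresolved/tied

    def rf(self, reference: dendropy.Tree) -> tuple[int, int, int]:
        return rf_distance(self.tree, reference)


def _triple_theta(theta, trio) -> float:
    if isinstance(theta, Mapping):
        # robust to recent bottlenecks: take the largest of the three values
        return max(theta[s] for s in trio)
    return float(theta)


def infer_supertree(
    gene_trees: Sequence[dendropy.Tree],
    theta,
    N: float = 5e4,
    options: FitOptions = FitOptions(),
    use_branch_lengths: bool = False,
) -> SupertreeResult:
    """Infer an n-taxon species tree from n-taxon gene trees.

    Every gene tree is decomposed into its rooted triples; for each of the
    (n choose 3) taxon subsets the pooled triples are fed to the
    three-taxon maximum-likelihood fit, and the resolved estimates are
    assembled with :func:`mincut_supertree`.  Unresolved or tied subsets
    are omitted from the assembly (logged).  ``theta`` may be a scalar or a
    per-species mapping (the per-triple value is then the maximum of the
    three).  With three taxa this reduces to the direct three-taxon fit.
    """
    if not gene_trees:
        raise InputError("no gene trees supplied")
    labels = sorted(_leaf_labels(gene_trees[0]))
    for k, tr in enumerate(gene_trees):
        if sorted(_leaf_labels(tr)) != labels:
            raise InputError(f"gene tree {k} has a different leaf set")
    if len(labels) < 3:
        raise InputError("need at least three taxa")
    per_tree = [extract_rooted_triples(t, with_times=use_branch_lengths) for t in gene_trees]
    fits: dict[frozenset, FitResult] = {}
    resolved: list[RootedTriple] = []
    skipped: list[frozenset] = []
    for trio in itertools.combinations(labels, 3):
        trio_set = frozenset(trio)
        th = _triple_theta(theta, trio)
        triples = [pt[trio_set] for pt in per_tree]
        if use_branch_lengths:
            data = [GeneTreeObservation(t.pair, t.t1, t.t2) for t in triples]
            result = infer_species_tree(data, th, N, options, species=trio)
        else:
            cnt = Counter(t.pair for t in triples)
            data = TopologyCounts.from_mapping(trio, dict(cnt))
            result = infer_species_tree(data, th, N, options)
        fits[trio_set] = result
        if result.unresolved or result.best is None:
            log.warning("triple %s unresolved; omitted from supertree", trio)
            skipped.append(trio_set)
        else:
            cfg = result.best
            resolved.append(
                RootedTriple(frozenset(cfg.sisters), cfg.outgroup)
            )
    if not resolved:
        newick = "(" + ",".join(labels) + ");"
        tree = dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")
    else:
        tree = mincut_supertree(resolved)
        # taxa never appearing in a resolved triple must still be present
        present = set(_leaf_labels(tree))
        missing = [s for s in labels if s not in present]
        for s in missing:
            nd = dendropy.Node(taxon=dendropy.Taxon(label=s))
            tree.seed_node.add_child(nd)
        if missing:
            tree.update_taxon_namespace()
    return SupertreeResult(tree=tree, triple_fits=fits, skipped=tuple(skipped))
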