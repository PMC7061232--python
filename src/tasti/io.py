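"""Readers and writers: newick gene trees, count tables, bootstrap weights,
and flat key-value run configuration."""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy

from tasti.likelihood import InputError, TopologyCounts, cherry_pairs, topology_label

log = logging.getLogger(__name__)

_LABEL_RE = re.compile(r"^\(\(\s*([^,()\s]+)\s*,\s*([^,()\s]+)\s*\)\s*,\s*([^,()\s]+)\s*\)$")


def parse_topology_label(label: str) -> tuple[frozenset, str]:
    """Parse a canonical rooted-triple label ``((X,Y),Z)`` into its cherry
    pair and outgroup."""
    m = _LABEL_RE.match(label.strip())
    if not m:
        raise InputError(f"malformed topology label {label!r}; expected ((X,Y),Z)")
    x, y, z = m.groups()
    if len({x, y, z}) != 3:
        raise InputError(f"topology label {label!r} repeats a species")
    return frozenset((x, y)), z


def read_gene_trees(path, expect_branch_lengths: bool = False) -> list[dendropy.Tree]:
    """Read one rooted binary newick tree per line.

    Malformed, unrooted-looking (non-binary root) or non-binary lines raise
    :class:`InputError` with the offending line number.
    """
    trees = []
    tns = dendropy.TaxonNamespace()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                tree = dendropy.Tree.get(
                    data=line,
                    schema="newick",
                    rooting="force-rooted",
                    taxon_namespace=tns,
                )
            except Exception as exc:
                raise InputError(f"line {lineno}: cannot parse newick ({exc})") from exc
            labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
            if len(set(labels)) != len(labels):
                raise InputError(f"line {lineno}: duplicate leaf labels")
            for nd in tree.preorder_internal_node_iter():
                if len(nd.child_nodes()) != 2:
                    raise InputError(
                        f"line {lineno}: tree is not binary (a node has "
                        f"{len(nd.child_nodes())} children); an unrooted tree "
                        "written with a basal trifurcation must be rooted first"
                    )
            if expect_branch_lengths:
                for nd in tree.preorder_node_iter():
                    if nd is not tree.seed_node and nd.edge.length is None:
                        raise InputError(f"line {lineno}: missing branch length")
            trees.append(tree)
    if not trees:
        raise InputError(f"no trees found in {path}")
    return trees


def write_gene_trees(trees: Sequence[dendropy.Tree], path, header: Optional[str] = None):
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for tree in trees:
            fh.write(
                tree.as_string(
                    schema="newick",
                    suppress_rooting=True,
                    real_value_format_specifier=".12g",
                ).strip()
                + "\n"
            )


def read_counts(path) -> TopologyCounts:
    """Read a two-column table of (topology label, count) rows."""
    rows = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise InputError(f"row {lineno}: expected 'label<TAB>count'")
            pair, z = parse_topology_label(parts[0])
            try:
                count = float(parts[1])
            except ValueError:
                raise InputError(f"row {lineno}: bad count {parts[1]!r}") from None
            if count < 0:
                raise InputError(f"row {lineno}: negative count")
            species = tuple(sorted(pair | {z}))
            rows.setdefault(species, {})[pair] = count
    if not rows:
        raise InputError(f"no count rows found in {path}")
    if len(rows) != 1:
        raise InputError("count rows name more than one species triple")
    (species, counts), = rows.items()
    return TopologyCounts.from_mapping(species, counts)


def write_counts(y: TopologyCounts, path):
    with open(path, "w") as fh:
        for pair, n in zip(cherry_pairs(y.species), y.counts):
            fh.write(f"{topology_label(pair, y.species)}\t{n:g}\n")


def read_bootstrap_weights(path) -> tuple[list[list[float]], tuple[str, str, str]]:
    """Read per-locus bootstrap topology proportions.

    Format: a header row of three topology labels, then one row of three
    proportions per locus.  Returns the rows (ordered as
    :func:`cherry_pairs` of the sorted species) and the species triple.
    """
    with open(path) as fh:
        lines = [
            (k, ln.strip()) for k, ln in enumerate(fh, start=1)
            if ln.strip() and not ln.strip().startswith("#")
        ]
    if not lines:
        raise InputError(f"empty weights file {path}")
    _, header = lines[0]
    labels = header.split("\t") if "\t" in header else header.split()
    if len(labels) != 3:
        raise InputError("header must list three topology labels")
    parsed = [parse_topology_label(lbl) for lbl in labels]
    species = tuple(sorted(frozenset().union(*(p | {z} for p, z in parsed))))
    if len(species) != 3:
        raise InputError("topology labels name more than three species")
    order = cherry_pairs(species)
    col_of = {}
    for k, (pair, _) in enumerate(parsed):
        col_of[order.index(pair)] = k
    if len(col_of) != 3:
        raise InputError("header labels are not the three distinct topologies")
    rows = []
    for lineno, line in lines[1:]:
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 3:
            raise InputError(f"row {lineno}: expected three proportions")
        try:
            vals = [float(v) for v in parts]
        except ValueError:
            raise InputError(f"row {lineno}: non-numeric proportion") from None
        rows.append([vals[col_of[i]] for i in range(3)])
    if not rows:
        raise InputError("no proportion rows found")
    return rows, species


@dataclass
class RunConfig:
    """Flat key-value run configuration; command-line flags override file
    values.  All fields have working defaults except the species names."""

    species: tuple[str, str, str] = ("A", "B", "C")
    mode: str = "topology"  # topology | weighted | branch_lengths
    theta: float = 0.005
    N: float = 5e4
    p_min: float = 0.05
    tie_M: bool = True
    n_m: int = 20
    n_tau: int = 20
    seed: int = 0
    alpha: float = 0.01
    B: int = 100
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        values = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise InputError(f"line {lineno}: expected 'key = value'")
                key, _, val = line.partition("=")
                values[key.strip()] = val.strip()
        cfg = cls()
        for key, val in values.items():
            if key == "species":
                cfg.species = tuple(v.strip() for v in val.split(","))
            elif key == "mode":
                if val not in ("topology", "weighted", "branch_lengths"):
                    raise InputError(f"unknown mode {val!r}")
                cfg.mode = val
            elif key in ("theta", "N", "p_min", "alpha"):
                setattr(cfg, key, float(val))
            elif key in ("n_m", "n_tau", "seed", "B"):
                setattr(cfg, key, int(val))
            elif key == "tie_M":
                cfg.tie_M = val.lower() in ("1", "true", "yes")
            else:
                cfg.extras[key] = val
        return cfg
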