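"""Phylogeny handling: Newick I/O, pruning, congeneric grafting, patristic distances.

Trees are represented as :class:`dendropy.Tree` objects throughout. Tip labels
follow the ``Genus_species`` convention (exact match after trimming whitespace
and replacing internal spaces with underscores; case-sensitive). Branch lengths
are in the units of the input tree (Myr for dated trees).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "read_newick",
    "write_newick",
    "parse_newick",
    "to_newick",
    "prune_to_species",
    "graft_missing",
    "GraftReport",
    "cophenetic_matrix",
    "canonical_name",
    "genus_of",
    "node_depths",
    "is_ultrametric",
]


class NewickError(ValueError):
    """Raised for malformed Newick input or trees missing branch lengths."""


def canonical_name(name: str) -> str:
    """Normalize a taxon label: trim whitespace, spaces -> underscores."""
    return name.strip().replace(" ", "_")


def genus_of(name: str) -> str:
    """Genus part of a ``Genus_species`` label (text before the first underscore)."""
    return canonical_name(name).split("_", 1)[0]


def _check_branch_lengths(tree: dendropy.Tree) -> None:
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:  # root edge may be lengthless
            continue
        if edge.length is None:
            head = edge.head_node
            label = head.taxon.label if head.taxon else "(internal node)"
            raise NewickError(f"missing branch length on edge above {label!r}")
        if not np.isfinite(edge.length) or edge.length < 0:
            raise NewickError(f"invalid branch length {edge.length!r}")


def parse_newick(newick: str) -> dendropy.Tree:
    """Parse a Newick string into a rooted tree; every non-root edge needs a length."""
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickError(f"Newick parse error: {exc}") from exc
    for taxon in tree.taxon_namespace:
        taxon.label = canonical_name(taxon.label)
    if any(leaf.taxon is None for leaf in tree.leaf_node_iter()):
        raise NewickError("tree contains an unlabeled tip")
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise NewickError(f"duplicate tip labels: {dupes[:10]}")
    _check_branch_lengths(tree)
    return tree


def read_newick(path) -> dendropy.Tree:
    """Read a rooted tree with branch lengths from a Newick file."""
    with open(path) as fh:
        return parse_newick(fh.read())


def to_newick(tree: dendropy.Tree) -> str:
    """Serialize to a canonical one-line Newick string (unquoted labels)."""
    buf = io.StringIO()
    tree.write(file=buf, schema="newick", unquoted_underscores=True,
               suppress_rooting=True)
    return buf.getvalue().strip()


def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree) + "\n")


def node_depths(tree: dendropy.Tree) -> dict:
    """Map node -> distance from the root (sum of branch lengths)."""
    depths = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    return depths


def is_ultrametric(tree: dendropy.Tree, tol: float = 1e-6) -> bool:
    depths = node_depths(tree)
    tip_depths = [depths[leaf] for leaf in tree.leaf_node_iter()]
    return (max(tip_depths) - min(tip_depths)) <= tol


def prune_to_species(tree: dendropy.Tree, keep) -> dendropy.Tree:
    """Prune a tree down to the tips in ``keep``.

    Patristic distances among retained tips are unchanged; unifurcations left
    by the pruning are collapsed with their branch lengths summed. A single
    retained tip yields a one-tip tree.
    """
    keep = {canonical_name(k) for k in keep}
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    matched = keep & tips
    if not matched:
        missing = sorted(keep - tips)
        raise KeyError(
            f"none of the requested species are in the tree; first unmatched: {missing[:10]}"
        )
    pruned = tree.clone(depth=1)
    keep_taxa = [t for t in pruned.taxon_namespace if t.label in matched]
    pruned.retain_taxa(keep_taxa)
    pruned.purge_taxon_namespace()
    # dendropy suppresses internal unifurcations but can leave a degree-one
    # root stub; reroot at its first multifurcating (or leaf) descendant.
    root = pruned.seed_node
    while len(root.child_nodes()) == 1 and not root.child_nodes()[0].is_leaf():
        root = root.child_nodes()[0]
    if root is not pruned.seed_node:
        root.parent_node.remove_child(root)
        root.edge.length = None
        pruned.seed_node = root
    return pruned


@dataclass
class GraftRecord:
    species: str
    action: str  # "mrca" | "bisect" | "excluded"
    attach_height: float = float("nan")  # height above the tips, Myr

    def as_row(self) -> dict:
        return {"species": self.species, "action": self.action,
                "attach_height": self.attach_height}


@dataclass
class GraftReport:
    """Per-species record of how each missing name was (or was not) attached."""

    records: list = field(default_factory=list)

    @property
    def grafted(self) -> list:
        return [r.species for r in self.records if r.action != "excluded"]

    @property
    def excluded(self) -> list:
        return [r.species for r in self.records if r.action == "excluded"]

    @property
    def zero_length_pendants(self) -> list:
        return [r.species for r in self.records
                if r.action == "mrca" and r.attach_height == 0.0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.as_row() for r in self.records],
                            columns=["species", "action", "attach_height"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _tree_height(tree: dendropy.Tree) -> float:
    depths = node_depths(tree)
    return max(depths[leaf] for leaf in tree.leaf_node_iter())


def graft_missing(tree: dendropy.Tree, missing) -> tuple[dendropy.Tree, GraftReport]:
    """Attach species absent from the tree at their congeneric MRCA.

    For each missing ``Genus_species`` name, in sorted order:

    * genus has >= 2 congeners in the (growing) tree: attach at the genus MRCA
      with a pendant branch equal to the MRCA's height above the tips, so an
      ultrametric tree stays ultrametric;
    * exactly 1 congener: bisect that congener's terminal branch at half its
      length and attach a pendant of the same half-length;
    * no congeners: leave the tree unchanged and record the exclusion.

    Earlier grafts count as congeners for later ones. Distances among the
    original tips are never altered. Returns the grafted tree (a copy) and a
    :class:`GraftReport`.
    """
    out = tree.clone(depth=1)
    report = GraftReport()
    existing = {leaf.taxon.label for leaf in out.leaf_node_iter()}
    for name in sorted(canonical_name(m) for m in missing):
        if name in existing:
            raise ValueError(f"graft target {name!r} already a tip in the tree")
        genus = genus_of(name)
        congener_taxa = [leaf.taxon for leaf in out.leaf_node_iter()
                         if genus_of(leaf.taxon.label) == genus]
        if not congener_taxa:
            report.records.append(GraftRecord(name, "excluded"))
            continue
        taxon = out.taxon_namespace.new_taxon(label=name)
        depths = node_depths(out)
        height = _tree_height(out)
        if len(congener_taxa) == 1:
            # bisect the lone congener's terminal branch at half its length
            leaf = next(l for l in out.leaf_node_iter()
                        if l.taxon is congener_taxa[0])
            half = (leaf.edge.length or 0.0) / 2.0
            parent = leaf.parent_node
            knee = parent.new_child(edge_length=half)
            parent.remove_child(leaf)
            leaf.edge.length = half
            knee.add_child(leaf)
            new_leaf = knee.new_child(taxon=taxon, edge_length=half)
            report.records.append(GraftRecord(name, "bisect", half))
        else:
            mrca = out.mrca(taxa=congener_taxa)
            pendant = height - depths[mrca]
            new_leaf = mrca.new_child(taxon=taxon, edge_length=pendant)
            report.records.append(GraftRecord(name, "mrca", pendant))
        del new_leaf
        existing.add(name)
        out.update_bipartitions(suppress_unifurcations=False)
    return out, report


def cophenetic_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Square symmetric patristic (path-length) distance matrix, labeled by tip.

    ``d(i, j)`` is the sum of branch lengths along the unique i->j path; the
    diagonal is zero. Computed from root-to-tip depth vectors and MRCA depths
    via a post-order sweep, O(n^2) overall.
    """
    leaves = list(tree.leaf_node_iter())
    labels = [leaf.taxon.label for leaf in leaves]
    n = len(leaves)
    idx = {leaf: i for i, leaf in enumerate(leaves)}
    depths = node_depths(tree)
    dist = np.zeros((n, n))
    # for each internal node, tips in different child subtrees have their MRCA
    # exactly there: d(i,j) = depth_i + depth_j - 2*depth(mrca)
    tipsets: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tipsets[node] = [idx[node]]
            continue
        children = node.child_nodes()
        sets = [tipsets.pop(c) for c in children]
        for a in range(len(sets)):
            for b in range(a + 1, len(sets)):
                for i in sets[a]:
                    for j in sets[b]:
                        d = depths[leaves[i]] + depths[leaves[j]] - 2.0 * depths[node]
                        dist[i, j] = dist[j, i] = d
        merged = [i for s in sets for i in s]
        tipsets[node] = merged
    return pd.DataFrame(dist, index=labels, columns=labels)
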