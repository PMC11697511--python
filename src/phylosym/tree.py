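"""Rooted phylogenies: parsing, serialization, covariance, and genus-level pruning.

The tree is the substrate for every comparative computation in this package:
the Brownian-motion covariance between two taxa is the branch length shared
on their root-to-tip paths, so all downstream regressions (PGLS, contrasts,
ancestral states, path analysis) consume the ``PhyloTree`` defined here.
Parsing and serialization are delegated to dendropy; this module adds the
invariant checks and the array-facing views the statistics need.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed; carries a character offset."""

    def __init__(self, message: str, offset: int | None = None):
        if offset is not None:
            message = f"{message} (near character offset {offset})"
        super().__init__(message)
        self.offset = offset


@dataclass
class PhyloTree:
    """A rooted tree with branch lengths and unique tip labels.

    Wraps a :class:`dendropy.Tree`. Branch lengths are in arbitrary time
    units; a missing edge length is treated as 0 (the root edge commonly has
    none). Tip labels must be unique and non-empty.
    """

    _tree: dendropy.Tree = field(repr=False)

    def __post_init__(self) -> None:
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        if any(not l for l in labels):
            raise ValueError("empty tip label")
        for edge in self._tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError(f"negative branch length {edge.length}")

    # -- basic views ---------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    def __len__(self) -> int:
        return self.n_tips

    # -- metrics -------------------------------------------------------

    def node_depths(self) -> dict[dendropy.Node, float]:
        """Root-to-node path length for every node (root depth 0)."""
        depths: dict[dendropy.Node, float] = {}
        for node in self._tree.preorder_node_iter():
            parent = node.parent_node
            edge = node.edge.length or 0.0
            depths[node] = edge if parent is None else depths[parent] + edge
        return depths

    def tip_depths(self) -> dict[str, float]:
        depths = self.node_depths()
        return {n.taxon.label: d for n, d in depths.items() if n.is_leaf()}

    def max_depth(self) -> float:
        return max(self.tip_depths().values())

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        d = np.array(list(self.tip_depths().values()))
        return bool(np.ptp(d) <= rel_tol * max(d.max(), 1e-300))

    def vcv(self, taxa: Sequence[str] | None = None) -> tuple[list[str], np.ndarray]:
        """Brownian covariance matrix: V[i, j] = depth of the MRCA of tips i, j.

        Returns the taxon order used for rows/columns together with V.
        """
        order = list(taxa) if taxa is not None else self.tip_labels
        index = {label: i for i, label in enumerate(order)}
        missing = [l for l in order if l not in set(self.tip_labels)]
        if missing:
            raise KeyError(f"taxa not in tree: {missing}")
        n = len(order)
        V = np.zeros((n, n))
        depths = self.node_depths()
        # postorder sweep: at each internal node, tip pairs drawn from two
        # different child subtrees have that node as their MRCA
        tips_below: dict[dendropy.Node, list[int]] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                i = index.get(node.taxon.label)
                tips_below[node] = [] if i is None else [i]
                if i is not None:
                    V[i, i] = depths[node]
                continue
            children = [tips_below[c] for c in node.child_nodes()]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    for i in children[a]:
                        for j in children[b]:
                            V[i, j] = V[j, i] = depths[node]
            tips_below[node] = [i for ch in children for i in ch]
        return order, V

    # -- pruning -------------------------------------------------------

    def keep_tips(self, labels: Sequence[str]) -> "PhyloTree":
        """Subtree spanning the given tips, branch lengths preserved.

        Unary nodes introduced by pruning are suppressed with their edge
        lengths summed, so root-to-tip path lengths are unchanged.
        """
        keep = set(labels)
        missing = keep - set(self.tip_labels)
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        tree = self._tree.clone(depth=1)
        taxa = [t for t in tree.taxon_namespace if t.label in keep]
        tree.retain_taxa(taxa)
        # retain_taxa can leave a unifurcating root; fold it down
        tree.suppress_unifurcations()
        return PhyloTree(tree)

    def prune_to_genus(
        self,
        genus_of: Mapping[str, str],
        keep_genera: Sequence[str],
        seed: int,
    ) -> "PhyloTree":
        """One randomly chosen representative tip per genus, relabelled to the genus.

        ``genus_of`` maps tip label -> genus. The representative is drawn
        uniformly among the genus's tips with ``seed``; path lengths from the
        root to retained tips are unchanged.
        """
        rng = random.Random(seed)
        by_genus: dict[str, list[str]] = {}
        for tip in self.tip_labels:
            g = genus_of.get(tip)
            if g is not None:
                by_genus.setdefault(g, []).append(tip)
        chosen: dict[str, str] = {}
        empty = [g for g in keep_genera if not by_genus.get(g)]
        if empty:
            raise KeyError(f"genera with no tips in tree: {sorted(empty)}")
        for g in sorted(keep_genera):
            chosen[g] = rng.choice(sorted(by_genus[g]))
        pruned = self.keep_tips(list(chosen.values()))
        tip_to_genus = {tip: g for g, tip in chosen.items()}
        # taxa are shared with the source tree after cloning: attach fresh
        # Taxon objects instead of renaming in place
        namespace = dendropy.TaxonNamespace()
        for leaf in pruned._tree.leaf_node_iter():
            leaf.taxon = namespace.new_taxon(tip_to_genus[leaf.taxon.label])
        pruned._tree.taxon_namespace = namespace
        return pruned


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Quoted labels are supported, internal node labels are optional, and a
    trailing root length of 0 is tolerated. A malformed string raises
    :class:`NewickParseError` naming the approximate character offset.
    """
    if not text or not text.strip():
        raise NewickParseError("empty Newick string", 0)
    if text.count("(") != text.count(")"):
        # locate the first unmatched parenthesis for the error message
        depth, offset = 0, len(text) - 1
        for i, ch in enumerate(text):
            depth += ch == "("
            depth -= ch == ")"
            if depth < 0:
                offset = i
                break
        raise NewickParseError("unbalanced parentheses", offset)
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted parse errors
        offset = getattr(exc, "col", None)
        raise NewickParseError(f"malformed Newick: {exc}", offset) from exc
    tree.is_rooted = True
    return PhyloTree(tree)


def serialize_newick(tree: PhyloTree, precision: int = 12) -> str:
    """Serialize to Newick with ≥10 significant digits on branch lengths."""
    parts: list[str] = []

    def _label(node: dendropy.Node) -> str:
        label = node.taxon.label if node.taxon else None
        if not label:
            return ""
        if any(c in label for c in "()[]{}:;, '\t\n"):
            return "'" + label.replace("'", "''") + "'"
        return label

    def _write(node: dendropy.Node) -> str:
        if node.is_leaf():
            s = _label(node)
        else:
            s = "(" + ",".join(_write(c) for c in node.child_nodes()) + ")"
        if node.edge.length is not None:
            s += f":{node.edge.length:.{precision}g}"
        return s

    parts.append(_write(tree.dendropy_tree.seed_node))
    return "".join(parts) + ";"


def read_newick(path) -> PhyloTree:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(serialize_newick(tree) + "\n")
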