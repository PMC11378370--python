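"""Species tree handling and parsimony assignment of the gene-birth edge.

The analysis runs on the Saccharomyces sensu stricto tree.  Two internal
nodes are special and must be identifiable: A1, the most recent common
ancestor of S. cerevisiae and S. paradoxus, and A2, the MRCA of those two
plus S. mikatae.  A gene restricted to cerevisiae (classes S0+/S1) was born
on the edge A1 -> cerevisiae; a gene shared by cerevisiae and paradoxus
(class S2) was born on A2 -> A1.  Reconstruction never goes above A2
because the distance to S. bayanus makes deeper ancestors unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy

FOCAL = "cerevisiae"
SISTER = "paradoxus"
OUTGROUP = "mikatae"
DISTANT = "bayanus"

#: Default sensu stricto tree; branch lengths are expected substitutions/site
#: in the same regime as the per-branch divergences observed in the lineage.
DEFAULT_TREE = "((cerevisiae:0.08,paradoxus:0.08)A1:0.035,mikatae:0.15)A2;"


class UnsupportedClassError(ValueError):
    """Raised for conservation classes whose birth edge lies above A2."""


@dataclass(frozen=True)
class BirthEdge:
    """Tree edge on which a gene became genic (parent older, child younger)."""

    parent: str
    child: str


def _node_name(node: dendropy.Node) -> str | None:
    if node.taxon is not None:
        return node.taxon.label
    return node.label


class SpeciesTree:
    """Rooted species tree with labelled ancestors A1 and A2.

    Parses Newick text, locates A1/A2 as the MRCAs of the relevant leaves
    (existing internal labels are honoured and checked), and exposes the
    node/branch structure the reconstruction needs.
    """

    def __init__(self, newick: str = DEFAULT_TREE) -> None:
        try:
            self.tree = dendropy.Tree.get(
                data=newick, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise ValueError(f"malformed Newick tree: {exc}") from exc
        self.tree.is_rooted = True
        self._by_name: dict[str, dendropy.Node] = {}
        for node in self.tree:
            name = _node_name(node)
            if name:
                self._by_name[name] = node
        for leaf in (FOCAL, SISTER, OUTGROUP):
            if leaf not in self._by_name:
                raise ValueError(f"tree is missing required leaf {leaf!r}")
        a1 = self.mrca(FOCAL, SISTER)
        a2 = self.mrca(FOCAL, SISTER, OUTGROUP)
        if a1 is a2:
            raise ValueError("A1 and A2 coincide; tree topology is not resolved")
        for node, label in ((a1, "A1"), (a2, "A2")):
            if node.label not in (None, label):
                raise ValueError(
                    f"internal node labelled {node.label!r} conflicts with {label}"
                )
            node.label = label
        self._by_name["A1"] = a1
        self._by_name["A2"] = a2

    # -- structure access ------------------------------------------------
    def mrca(self, *names: str) -> dendropy.Node:
        taxa = [self._by_name[n].taxon for n in names]
        return self.tree.mrca(taxa=taxa)

    def node(self, name: str) -> dendropy.Node:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"no node named {name!r} in tree") from None

    def leaf_names(self) -> list[str]:
        return [_node_name(n) for n in self.tree.leaf_node_iter()]

    def name_of(self, node: dendropy.Node) -> str:
        return _node_name(node)

    def branch_length(self, name: str) -> float:
        length = self.node(name).edge.length
        return 0.0 if length is None else float(length)

    def parent_name(self, name: str) -> str | None:
        parent = self.node(name).parent_node
        return None if parent is None else _node_name(parent)

    def reconstruction_subtree(self) -> "SpeciesTree":
        """Subtree rooted at A2 (the deepest node ever reconstructed)."""
        a2 = self.node("A2")
        if a2.parent_node is None:
            return self

        def render(node: dendropy.Node, top: bool) -> str:
            name = _node_name(node) or ""
            length = "" if top or node.edge.length is None else f":{node.edge.length}"
            if node.is_leaf():
                return f"{name}{length}"
            inner = ",".join(render(c, False) for c in node.child_nodes())
            return f"({inner}){name}{length}"

        return SpeciesTree(render(a2, True) + ";")

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def assign_birth_edge(conservation_class: str, tree: SpeciesTree) -> BirthEdge:
    """Parsimony birth edge for a conservation class.

    S0+/S1 genes exist only in cerevisiae, so they were born on
    A1 -> cerevisiae; S2 genes are shared with paradoxus and were born on
    A2 -> A1.  Deeper classes would need ancestors above A2, which the
    reconstruction deliberately does not produce.
    """
    if conservation_class in ("S0+", "S1"):
        return BirthEdge("A1", FOCAL)
    if conservation_class == "S2":
        return BirthEdge("A2", "A1")
    raise UnsupportedClassError(
        f"class {conservation_class!r} has no birth edge at or below A2"
    )
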