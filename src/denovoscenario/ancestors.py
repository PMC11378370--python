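"""Marginal maximum-likelihood ancestral sequence reconstruction.

Per alignment column, posterior base probabilities at every internal node
are computed by Felsenstein's pruning algorithm (an up pass collecting
subtree likelihoods, then a down pass distributing the likelihood of the
rest of the tree), under an HKY model with the tree's fixed branch
lengths.  The reported ancestral base is the posterior argmax.

Whether an internal node carries a base or a gap at a column is decided
first, by Fitch parsimony on the binary gap/base character with ties
resolved toward "base present"; posteriors are only reported for
base-bearing columns.  The mean of the per-column maximum posterior is
the reconstruction confidence; sequences below 0.80 are conventionally
discarded as unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .model import SubstitutionModel
from .msa import MSA
from .sequtil import BASES, GAP
from .trees import DISTANT, FOCAL, OUTGROUP, SISTER, SpeciesTree

DEFAULT_CONFIDENCE_THRESHOLD = 0.80

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class AncestralSequence:
    """Reconstructed sequence at an internal node, with posteriors.

    ``sequence`` is gapped, over the alignment's columns.  ``posteriors``
    has one row per column (rows at gap columns are not meaningful and
    are excluded from the confidence).
    """

    node: str
    sequence: str
    posteriors: np.ndarray  # (n_columns, 4), rows sum to 1
    base_columns: np.ndarray  # bool mask of non-gap columns

    @property
    def confidence(self) -> float:
        """Mean over base columns of the maximum posterior probability."""
        if not self.base_columns.any():
            return 0.0
        return float(self.posteriors[self.base_columns].max(axis=1).mean())

    def degapped(self) -> str:
        return self.sequence.replace(GAP, "")


def confidence_filter(
    anc: AncestralSequence, threshold: float = DEFAULT_CONFIDENCE_THRESHOLD
) -> bool:
    """True if the reconstruction is confident enough to keep."""
    return anc.confidence >= threshold


def empirical_frequencies(rows: dict[str, str]) -> np.ndarray:
    """Base frequencies pooled over all alignment rows, with a pseudocount."""
    counts = np.ones(4)
    for row in rows.values():
        for ch in row:
            idx = _BASE_INDEX.get(ch)
            if idx is not None:
                counts[idx] += 1
    return counts / counts.sum()


def _node_name(node: dendropy.Node, fallback: str) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return node.label if node.label else fallback


def _gap_parsimony(
    tree: dendropy.Tree, leaf_masks: dict[int, np.ndarray], ncols: int
) -> dict[int, np.ndarray]:
    """Fitch parsimony on the gap/base character; ties prefer base.

    Masks are bitfields per column: bit 0 = base possible, bit 1 = gap
    possible.  Returns, for internal nodes, a boolean array that is True
    where the node carries a base.
    """
    prelim: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        nid = id(node)
        if node.is_leaf():
            prelim[nid] = leaf_masks[nid]
            continue
        masks = [prelim[id(c)] for c in node.child_nodes()]
        inter = masks[0].copy()
        union = masks[0].copy()
        for m in masks[1:]:
            inter &= m
            union |= m
        prelim[nid] = np.where(inter != 0, inter, union)

    final: dict[int, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        nid = id(node)
        mask = prelim[nid]
        if node.parent_node is None:
            final[nid] = (mask & 1) != 0  # tie -> base present
            continue
        parent_base = final[id(node.parent_node)]
        parent_bit = np.where(parent_base, 1, 2).astype(mask.dtype)
        agrees = (mask & parent_bit) != 0
        final[nid] = np.where(agrees, parent_base, (mask & 1) != 0)
    return final


def marginal_posteriors(
    rows: dict[str, str],
    tree: dendropy.Tree,
    model: SubstitutionModel,
) -> dict[str, AncestralSequence]:
    """Marginal ancestral reconstruction at every internal node.

    ``rows`` maps leaf names to gapped sequences of equal length; leaves
    of the tree absent from ``rows`` are treated as missing data.  Gap
    and N characters contribute no likelihood at their column.
    """
    lengths = {len(r) for r in rows.values()}
    if len(lengths) != 1:
        raise ValueError("alignment rows must have equal length")
    ncols = lengths.pop()
    pi = model.base_frequencies

    partials: dict[int, np.ndarray] = {}
    leaf_gap_masks: dict[int, np.ndarray] = {}
    pmats: dict[int, np.ndarray] = {}
    internal_names: dict[int, str] = {}
    counter = 0
    for node in tree.postorder_node_iter():
        nid = id(node)
        if node.parent_node is not None:
            t = 0.0 if node.edge.length is None else float(node.edge.length)
            pmats[nid] = model.transition_matrix(t)
        if node.is_leaf():
            name = _node_name(node, f"leaf{counter}")
            part = np.ones((ncols, 4))
            mask = np.full(ncols, 3, dtype=np.int8)  # missing: base or gap
            if name in rows:
                row = rows[name]
                mask[:] = 2  # gap unless a base is seen
                for i, ch in enumerate(row):
                    idx = _BASE_INDEX.get(ch)
                    if idx is not None:
                        part[i] = 0.0
                        part[i, idx] = 1.0
                        mask[i] = 1
                    elif ch != GAP:  # N: missing base
                        mask[i] = 1
            partials[nid] = part
            leaf_gap_masks[nid] = mask
        else:
            counter += 1
            internal_names[nid] = _node_name(node, f"node{counter}")
            part = np.ones((ncols, 4))
            for child in node.child_nodes():
                part = part * (partials[id(child)] @ pmats[id(child)].T)
            partials[nid] = part

    base_at = _gap_parsimony(tree, leaf_gap_masks, ncols)

    # down pass: likelihood of everything outside each node's subtree
    above: dict[int, np.ndarray] = {}
    results: dict[str, AncestralSequence] = {}
    for node in tree.preorder_node_iter():
        nid = id(node)
        if node.parent_node is None:
            above[nid] = np.broadcast_to(pi, (ncols, 4)).copy()
        else:
            parent = node.parent_node
            out = above[id(parent)].copy()
            for sib in parent.child_nodes():
                if sib is node:
                    continue
                out = out * (partials[id(sib)] @ pmats[id(sib)].T)
            above[nid] = out @ pmats[nid]
        if not node.is_leaf():
            post = above[nid] * partials[nid]
            norm = post.sum(axis=1, keepdims=True)
            norm[norm == 0.0] = 1.0
            post = post / norm
            is_base = base_at[nid]
            chars = [
                BASES[int(np.argmax(post[i]))] if is_base[i] else GAP
                for i in range(ncols)
            ]
            name = internal_names[nid]
            results[name] = AncestralSequence(
                node=name,
                sequence="".join(chars),
                posteriors=post,
                base_columns=is_base.copy(),
            )
    return results


def reconstruct_ancestors(
    msa: MSA,
    tree: SpeciesTree,
    model: SubstitutionModel | None = None,
    kappa: float = 2.0,
) -> dict[str, AncestralSequence]:
    """Reconstruct the ancestors A1 and A2 from an orthologue alignment.

    The alignment must cover cerevisiae, paradoxus and mikatae; a bayanus
    row is optional and contributes likelihood but no ancestor above A2
    is ever reported.  By default the model is HKY with base frequencies
    estimated from the alignment and the given kappa.
    """
    required = {FOCAL, SISTER, OUTGROUP}
    missing = required - set(msa.rows)
    if missing:
        raise ValueError(f"alignment is missing required rows: {sorted(missing)}")
    unknown = set(msa.rows) - set(tree.leaf_names())
    if unknown:
        raise ValueError(f"alignment rows not on the tree: {sorted(unknown)}")
    if model is None:
        model = SubstitutionModel(
            kappa=kappa, base_frequencies=empirical_frequencies(msa.rows)
        )
    all_nodes = marginal_posteriors(msa.rows, tree.tree, model)
    return {label: all_nodes[label] for label in ("A1", "A2")}
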