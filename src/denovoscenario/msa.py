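"""Progressive multiple sequence alignment guided by the species tree.

The orthologue sets here contain at most four sequences with a known
phylogeny, so a guide-tree progressive profile aligner is sufficient:
sequences are merged in the postorder of the species tree, each merge
being a global affine-gap alignment of two frequency profiles ("once a
gap, always a gap").  Profile columns score as the expected pairwise
substitution score; gap symbols are neutral, with the affine penalty
charged once per new gap column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import profile_dp
from .mapping import DEFAULT_SCORING, Scoring
from .sequtil import GAP, degap
from .trees import SpeciesTree


@dataclass
class MSA:
    """A multiple alignment: name -> gapped row, all rows equal length."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def degapped(self, name: str) -> str:
        return degap(self.rows[name])


def _profile(rows: dict[str, str]) -> np.ndarray:
    """(L, 5) frequency profile; indices 0..3 = A,C,G,T, 4 = gap.

    N contributes to no bin (it is scored neutrally)."""
    names = list(rows)
    length = len(rows[names[0]])
    prof = np.zeros((length, 5))
    index = {"A": 0, "C": 1, "G": 2, "T": 3, GAP: 4}
    for name in names:
        for i, ch in enumerate(rows[name]):
            j = index.get(ch)
            if j is not None:
                prof[i, j] += 1.0
    return prof / len(names)


def _merge(
    rows_a: dict[str, str], rows_b: dict[str, str], scoring: Scoring
) -> dict[str, str]:
    smat = scoring.matrix()
    smat[4, :] = 0.0  # index 4 is the gap symbol in profile space
    smat[:, 4] = 0.0
    _, moves = profile_dp(
        _profile(rows_a),
        _profile(rows_b),
        smat,
        float(scoring.gap_open),
        float(scoring.gap_extend),
    )
    merged = {name: [] for name in list(rows_a) + list(rows_b)}
    ia = ib = 0
    for move in moves:
        take_a = move in (0, 2)
        take_b = move in (0, 1)
        for name, row in rows_a.items():
            merged[name].append(row[ia] if take_a else GAP)
        for name, row in rows_b.items():
            merged[name].append(row[ib] if take_b else GAP)
        ia += int(take_a)
        ib += int(take_b)
    return {name: "".join(chars) for name, chars in merged.items()}


def build_msa(
    sequences: dict[str, str],
    guide: SpeciesTree,
    scoring: Scoring = DEFAULT_SCORING,
) -> MSA:
    """Progressively align sequences following the guide tree topology.

    ``sequences`` maps species names (guide-tree leaves) to unaligned
    sequences; species absent from the mapping are skipped.  A single
    sequence is returned as its own trivial alignment.
    """
    known = {name: seq for name, seq in sequences.items() if seq}
    if not known:
        raise ValueError("no sequences to align")

    def align_node(node) -> dict[str, str] | None:
        if node.is_leaf():
            name = guide.name_of(node)
            return {name: known[name]} if name in known else None
        blocks = [b for b in (align_node(c) for c in node.child_nodes()) if b]
        if not blocks:
            return None
        result = blocks[0]
        for block in blocks[1:]:
            result = _merge(result, block, scoring)
        return result

    rows = align_node(guide.tree.seed_node)
    extra = set(known) - set(rows or {})
    if extra:
        raise ValueError(f"sequences not on the guide tree: {sorted(extra)}")
    return MSA(rows=rows)
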