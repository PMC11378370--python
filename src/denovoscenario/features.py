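"""Evolutionary features between the two ends of a birth edge.

Four feature sets are computed from the pairwise alignment induced
between an older and a younger node of the locus alignment: (i) GC
content (third-codon positions for genic ORFs, the whole region for
non-genic sequences), (ii) mutation-class frequencies (transition /
transversion, the four GC-pressure classes, and indel events), (iii) ORF
length changes under three start-codon rules (most upstream ATG, and the
Kozak-context rules A..ATG and A..ATG.C), and (iv) appearance /
disappearance of the Kozak signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequtil import GAP

STOPS = ("TAA", "TAG", "TGA")

SUBSTITUTION_CLASSES = ("transition", "transversion", "AT>GC", "GC>AT", "AT>AT", "GC>GC")
MUTATION_CLASSES = SUBSTITUTION_CLASSES + ("indel",)

ORF_CHANGES = ("Extend", "Shrink", "NoChange")
KOZAK_TRANSITIONS = ("No", "Retain", "Disappear", "Appear")

_WEAK = {"A", "T"}  # A/T vs G/C: weak vs strong bases
_PURINES = {"A", "G"}


@dataclass(frozen=True)
class StartCodonRule:
    """An anchored start-codon pattern: an ATG plus required context bases.

    ``context`` maps offsets relative to the A of the ATG to required
    bases; context positions may fall outside the ORF (e.g. the -3 base
    of a start codon at an ORF's 5' edge is still defined in the genome).
    """

    label: str
    context: dict[int, str] = field(default_factory=dict)


RULE_ATG = StartCodonRule("ATG")
RULE_KOZAK = StartCodonRule("A..ATG", {-3: "A"})
RULE_KOZAK_FULL = StartCodonRule("A..ATG.C", {-3: "A", 4: "C"})

START_RULES = {r.label: r for r in (RULE_ATG, RULE_KOZAK, RULE_KOZAK_FULL)}


# ---------------------------------------------------------------------------
# induced pairwise alignments and mutation classes


@dataclass
class InducedPair:
    """Pairwise alignment of an older and a younger node, induced from the
    locus alignment by deleting columns gapped in both rows."""

    older: str
    younger: str
    columns: np.ndarray  # original alignment column index per retained column

    def __post_init__(self) -> None:
        if len(self.older) != len(self.younger):
            raise ValueError("induced pair rows must have equal length")


def induce_pair(
    rows: dict[str, str],
    older: str,
    younger: str,
    columns: np.ndarray | list[int] | None = None,
) -> InducedPair:
    """Extract the pairwise alignment of two rows (ancestral or leaf).

    ``columns`` optionally restricts to a subset of alignment columns
    (e.g. the catalogued ORF); columns gapped in both rows are removed,
    columns gapped in exactly one row are kept as indel evidence.
    """
    for name in (older, younger):
        if name not in rows:
            raise ValueError(f"row {name!r} missing from alignment")
    a = rows[older]
    b = rows[younger]
    idx = np.arange(len(a)) if columns is None else np.asarray(columns, dtype=int)
    keep = [i for i in idx if not (a[i] == GAP and b[i] == GAP)]
    return InducedPair(
        older="".join(a[i] for i in keep),
        younger="".join(b[i] for i in keep),
        columns=np.asarray(keep, dtype=int),
    )


@dataclass
class MutationCounts:
    """Tallies and percent frequencies of the seven mutation classes.

    Substitution classes are normalised by aligned-base columns; the
    indel class counts each maximal run of gap-in-exactly-one-row as one
    event and is normalised by total columns.
    """

    counts: dict[str, int]
    n_aligned: int  # denominator for substitution classes
    n_columns: int  # denominator for indel events

    def __post_init__(self) -> None:
        ts_tv = self.counts["transition"] + self.counts["transversion"]
        pressure = sum(self.counts[c] for c in ("AT>GC", "GC>AT", "AT>AT", "GC>GC"))
        if ts_tv != pressure:
            raise ValueError(
                f"mutation-class identity violated: {ts_tv} != {pressure}"
            )

    @property
    def frequencies(self) -> dict[str, float]:
        freqs = {}
        for cls in SUBSTITUTION_CLASSES:
            freqs[cls] = (
                100.0 * self.counts[cls] / self.n_aligned if self.n_aligned else 0.0
            )
        freqs["indel"] = (
            100.0 * self.counts["indel"] / self.n_columns if self.n_columns else 0.0
        )
        return freqs


def classify_mutations(pair: InducedPair) -> MutationCounts:
    """Classify differences between the older and younger sequences.

    Aligned mismatching bases are substitutions (direction is
    older -> younger): transition for A<->G / C<->T, else transversion;
    independently AT>GC / GC>AT / AT>AT / GC>GC by weak/strong class.
    Columns where either row is N are excluded from all denominators.
    """
    counts = {cls: 0 for cls in MUTATION_CLASSES}
    n_aligned = 0
    n_columns = 0
    in_gap_run = False
    for old, new in zip(pair.older, pair.younger):
        if old == "N" or new == "N":
            in_gap_run = False
            continue
        n_columns += 1
        gap_old = old == GAP
        gap_new = new == GAP
        if gap_old or gap_new:
            if not in_gap_run:
                counts["indel"] += 1
                in_gap_run = True
            continue
        in_gap_run = False
        n_aligned += 1
        if old == new:
            continue
        if (old in _PURINES) == (new in _PURINES):
            counts["transition"] += 1
        else:
            counts["transversion"] += 1
        if old in _WEAK and new in _WEAK:
            counts["AT>AT"] += 1
        elif old in _WEAK:
            counts["AT>GC"] += 1
        elif new in _WEAK:
            counts["GC>AT"] += 1
        else:
            counts["GC>GC"] += 1
    return MutationCounts(counts=counts, n_aligned=n_aligned, n_columns=n_columns)


# ---------------------------------------------------------------------------
# GC content


@dataclass(frozen=True)
class GcMeasure:
    value: float
    mode: str  # genic_third_codon | nongenic_whole


def gc_content(seq: str, mode: str) -> GcMeasure:
    """GC content of an ORF region.

    Genic mode uses only third codon positions (largely free of coding
    constraint, hence a proxy for the neighbourhood's composition) and
    requires a length divisible by 3; non-genic mode uses the whole
    region.  N bases count toward neither numerator nor denominator.
    """
    seq = seq.upper().replace(GAP, "")
    if not seq:
        raise ValueError("empty sequence")
    if mode == "genic_third_codon":
        if len(seq) % 3:
            raise ValueError(f"genic mode requires length % 3 == 0, got {len(seq)}")
        positions = seq[2::3]
    elif mode == "nongenic_whole":
        positions = seq
    else:
        raise ValueError(f"unknown GC mode {mode!r}")
    denom = sum(1 for c in positions if c in "ACGT")
    if denom == 0:
        raise ValueError("no unambiguous bases in the measured positions")
    gc = sum(1 for c in positions if c in "GC")
    return GcMeasure(value=gc / denom, mode=mode)


# ---------------------------------------------------------------------------
# ORF scanning and tracking


@dataclass(frozen=True)
class OrfAnnotation:
    """An ORF: start codon through stop codon, 1-based inclusive.

    ``seg_start``/``seg_end`` delimit the enclosing stop-to-stop segment
    (used when asking whether the segment carries a Kozak start).  ORFs
    whose segment runs off the sequence end have ``has_stop`` False and
    are measured to the last complete codon.
    """

    start: int
    end: int
    frame: int
    rule: str
    seg_start: int
    seg_end: int
    has_stop: bool

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __post_init__(self) -> None:
        if self.length % 3:
            raise ValueError("ORF length must be a multiple of 3")


def locate_start(
    segment: str,
    rule: StartCodonRule,
    context: str | None = None,
    segment_offset: int = 0,
) -> int | None:
    """Most upstream in-frame ATG in a codon-aligned segment, 1-based.

    ``context`` is a larger sequence containing the segment at
    ``segment_offset`` (0-based); required context bases (e.g. -3) are
    read from it and may fall outside the segment.
    """
    if context is None:
        context = segment
        segment_offset = 0
    for pos in range(0, len(segment) - 2, 3):
        if segment[pos : pos + 3] != "ATG":
            continue
        cpos = segment_offset + pos
        ok = True
        for off, base in rule.context.items():
            k = cpos + off
            if k < 0 or k >= len(context) or context[k] != base:
                ok = False
                break
        if ok:
            return pos + 1
    return None


def scan_orfs(
    seq: str,
    rule: StartCodonRule = RULE_ATG,
    context: str | None = None,
    context_offset: int = 0,
) -> list[OrfAnnotation]:
    """All ORFs of a sequence under a start-codon rule.

    For each reading frame, the sequence splits into segments bounded by
    stop codons (TAA/TAG/TGA) or the sequence ends; a segment yields an
    ORF when it contains an in-frame ATG matching the rule.  Length runs
    from the start codon through the stop codon inclusive.
    """
    orfs: list[OrfAnnotation] = []
    n = len(seq)
    for frame in range(3):
        seg_begin = frame  # 0-based
        pos = frame
        while pos + 3 <= n:
            codon = seq[pos : pos + 3]
            if codon in STOPS:
                orfs += _segment_orf(
                    seq, seg_begin, pos + 3, frame, True, rule, context, context_offset
                )
                seg_begin = pos + 3
            pos += 3
        if seg_begin < pos:  # trailing open segment (no terminal stop)
            orfs += _segment_orf(
                seq, seg_begin, pos, frame, False, rule, context, context_offset
            )
    orfs.sort(key=lambda o: (o.start, o.frame))
    return orfs


def _segment_orf(
    seq: str,
    begin: int,
    end: int,
    frame: int,
    has_stop: bool,
    rule: StartCodonRule,
    context: str | None,
    context_offset: int,
) -> list[OrfAnnotation]:
    segment = seq[begin:end]
    if context is None:
        context, context_offset = seq, 0
    start = locate_start(segment, rule, context, context_offset + begin)
    if start is None:
        return []
    start0 = begin + start - 1
    if has_stop:
        orf_end = end  # through the stop codon
    else:
        orf_end = start0 + 3 * ((end - start0) // 3)
        if orf_end <= start0:
            return []
    return [
        OrfAnnotation(
            start=start0 + 1,
            end=orf_end,
            frame=frame,
            rule=rule.label,
            seg_start=begin + 1,
            seg_end=end,
            has_stop=has_stop,
        )
    ]


def select_overlapping_orf(
    orfs: list[OrfAnnotation], interval: tuple[int, int]
) -> OrfAnnotation | None:
    """ORF with maximal overlap with a 1-based interval; ties go upstream."""
    best = None
    best_key = None
    for orf in orfs:
        overlap = min(orf.end, interval[1]) - max(orf.start, interval[0]) + 1
        if overlap <= 0:
            continue
        key = (-overlap, orf.start)
        if best_key is None or key < best_key:
            best, best_key = orf, key
    return best


def _position_columns(row: str, columns: np.ndarray) -> dict[int, int]:
    """Map 1-based degapped positions of a gapped row to column indices."""
    mapping = {}
    pos = 0
    for col, ch in zip(columns, row):
        if ch != GAP:
            pos += 1
            mapping[pos] = int(col)
    return mapping


def map_ancestral_orf(
    recent_orf: OrfAnnotation,
    pair: InducedPair,
    rule: StartCodonRule | None = None,
    ancestral_orfs: list[OrfAnnotation] | None = None,
) -> OrfAnnotation | None:
    """Find the ancestral ORF corresponding to a recent one.

    Candidates are ORFs of the older (degapped) sequence that overlap the
    recent ORF's footprint in alignment columns; the winner maximises the
    number of aligned columns at which the two ORFs agree in codon phase
    (this tolerates frame shifts introduced by indels between the nodes),
    with ties going to the most upstream candidate.
    """
    if rule is None:
        rule = START_RULES[recent_orf.rule]
    older_seq = pair.older.replace(GAP, "")
    if ancestral_orfs is None:
        ancestral_orfs = scan_orfs(older_seq, rule)
    y_cols = _position_columns(pair.younger, pair.columns)
    o_cols = _position_columns(pair.older, pair.columns)
    # column -> codon phase within the recent ORF
    recent_phase = {}
    for p in range(recent_orf.start, recent_orf.end + 1):
        col = y_cols.get(p)
        if col is not None:
            recent_phase[col] = (p - recent_orf.start) % 3
    best = None
    best_key = None
    for orf in ancestral_orfs:
        score = 0
        for p in range(orf.start, orf.end + 1):
            col = o_cols.get(p)
            if col is not None and col in recent_phase:
                if recent_phase[col] == (p - orf.start) % 3:
                    score += 1
        if score == 0:
            continue
        key = (-score, orf.start)
        if best_key is None or key < best_key:
            best, best_key = orf, key
    return best


# ---------------------------------------------------------------------------
# change classification


def classify_length_change(
    anc: OrfAnnotation | None, recent: OrfAnnotation
) -> str | None:
    """Extend / Shrink / NoChange; None when no ancestral ORF exists
    (those loci are tallied separately, not as a length change)."""
    if anc is None:
        return None
    if anc.rule != recent.rule:
        raise ValueError(
            f"rule mismatch: ancestral {anc.rule!r} vs recent {recent.rule!r}"
        )
    if recent.length > anc.length:
        return "Extend"
    if recent.length < anc.length:
        return "Shrink"
    return "NoChange"


def classify_kozak_transition(anc_has: bool, recent_has: bool) -> str:
    """No / Retain / Disappear / Appear from pattern presence at the two
    ends of the birth edge."""
    if anc_has and recent_has:
        return "Retain"
    if anc_has:
        return "Disappear"
    if recent_has:
        return "Appear"
    return "No"


def orf_start_has_kozak(
    seq: str,
    orf: OrfAnnotation,
    kozak_rule: StartCodonRule,
    context: str | None = None,
    context_offset: int = 0,
) -> bool:
    """Does the ORF's start codon carry the Kozak context?

    The signature is a property of the translation-initiation site, so it
    is evaluated at the ORF's own (most upstream) start codon rather than
    anywhere in the segment; context bases may reach outside the ORF.
    """
    if context is None:
        context, context_offset = seq, 0
    start0 = context_offset + orf.start - 1
    for off, base in kozak_rule.context.items():
        k = start0 + off
        if k < 0 or k >= len(context) or context[k] != base:
            return False
    return True
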