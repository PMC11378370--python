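"""Locus extraction and glocal ortholog mapping.

Each catalogued locus is pulled out of the focal genome together with its
flanking sequence (500 nt by default; flanks usually reach into
neighbouring conserved sequence, which is what makes the search
synteny-like).  The locus is then aligned against every chromosome of
every related genome, on both strands, with an alignment that is global
in the query and local in the target; the single best hit per genome is
kept.

For long targets the exhaustive O(len(query) * len(target)) dynamic
programme is preceded by a bit-parallel edit-distance scan (edlib in
infix mode) that locates the best-matching window exactly under unit
costs; the affine-gap glocal DP then runs inside that window only.  This
is an exact-prefilter rescoring strategy, not a seed heuristic, and it is
switchable off (``screen=False``) for fully exhaustive search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from ._kernels import glocal_dp
from .io import CatalogueEntry
from .sequtil import GAP, degap, encode, revcomp


@dataclass(frozen=True)
class Scoring:
    """DNA alignment scoring; a gap run of length k costs open + k*extend."""

    match: int = 5
    mismatch: int = -4
    gap_open: int = -12
    gap_extend: int = -4

    def matrix(self) -> np.ndarray:
        """5x5 score matrix over codes A,C,G,T,N; N is neutral (0)."""
        mat = np.full((5, 5), float(self.mismatch))
        np.fill_diagonal(mat, float(self.match))
        mat[4, :] = 0.0
        mat[:, 4] = 0.0
        return mat


DEFAULT_SCORING = Scoring()

#: Minimum fraction of the perfect-match score a hit must reach to count
#: as an ortholog; set to None to keep every best alignment.
DEFAULT_FLOOR_FRACTION = 0.3

# targets at most this long are always searched exhaustively
_SCREEN_MIN_TARGET = 5000
_SCREEN_PAD = 100


@dataclass
class Locus:
    """A catalogued gene plus the flanking sequence actually obtained."""

    entry: CatalogueEntry
    sequence: str  # gene + flanks, reverse-complemented for minus strand
    flank_left: int
    flank_right: int

    @property
    def orf_offset(self) -> int:
        """0-based offset of the catalogued ORF within ``sequence``."""
        return self.flank_left

    @property
    def orf_length(self) -> int:
        return self.entry.length


@dataclass
class GlocalAlignment:
    """Query-global / target-local alignment result."""

    query_aligned: str
    target_aligned: str
    target_interval: tuple[int, int]  # 1-based inclusive within the target
    target_strand: str
    score: float


@dataclass
class OrthologueHit:
    species: str
    chrom: str
    interval: tuple[int, int]  # 1-based inclusive, forward-strand coordinates
    strand: str
    score: float
    sequence: str  # hit sequence in query orientation


@dataclass
class OrthologueSet:
    locus: Locus
    hits: dict[str, OrthologueHit | None]

    def present(self) -> dict[str, OrthologueHit]:
        return {sp: h for sp, h in self.hits.items() if h is not None}


def filter_catalogue(
    entries: list[CatalogueEntry], min_orf_len: int = 60
) -> tuple[list[CatalogueEntry], dict[str, int]]:
    """Drop entries shorter than ``min_orf_len`` (statistics on short ORFs
    are unreliable); returns kept entries and the per-class discard tally."""
    if min_orf_len < 0:
        raise ValueError("min_orf_len must be >= 0")
    kept: list[CatalogueEntry] = []
    discarded: dict[str, int] = {}
    for entry in entries:
        if entry.length >= min_orf_len:
            kept.append(entry)
        else:
            discarded[entry.conservation_class] = (
                discarded.get(entry.conservation_class, 0) + 1
            )
    return kept, discarded


def extract_locus(
    genome: dict[str, str], entry: CatalogueEntry, flank: int = 500
) -> Locus:
    """Extract a catalogued locus with up to ``flank`` nt on each side.

    Flanks are truncated at chromosome ends.  Minus-strand loci are
    reverse-complemented after extraction so the ORF reads 5'->3'; the
    left flank of the returned locus is then the genomic right flank.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if entry.chrom not in genome:
        raise KeyError(f"unknown chromosome {entry.chrom!r}")
    chrom = genome[entry.chrom]
    if entry.end > len(chrom):
        raise ValueError(
            f"{entry.id}: end {entry.end} beyond chromosome length {len(chrom)}"
        )
    lo = max(1, entry.start - flank)
    hi = min(len(chrom), entry.end + flank)
    seq = chrom[lo - 1 : hi]
    left = entry.start - lo
    right = hi - entry.end
    if entry.strand == "-":
        seq = revcomp(seq)
        left, right = right, left
    return Locus(entry=entry, sequence=seq, flank_left=left, flank_right=right)


def glocal_align(
    query: str, target: str, scoring: Scoring = DEFAULT_SCORING
) -> GlocalAlignment:
    """Optimal affine-gap alignment of the full query against the best
    target substring (unaligned target ends are free)."""
    if not query:
        raise ValueError("query must be non-empty")
    if not target:
        raise ValueError("target must be non-empty")
    score, tstart, tend, moves = glocal_dp(
        encode(query),
        encode(target),
        scoring.matrix(),
        float(scoring.gap_open),
        float(scoring.gap_extend),
    )
    qa: list[str] = []
    ta: list[str] = []
    qi = 0
    ti = tstart - 1
    for move in moves:
        if move == 0:
            qa.append(query[qi])
            ta.append(target[ti])
            qi += 1
            ti += 1
        elif move == 1:
            qa.append(GAP)
            ta.append(target[ti])
            ti += 1
        else:
            qa.append(query[qi])
            ta.append(GAP)
            qi += 1
    return GlocalAlignment(
        query_aligned="".join(qa),
        target_aligned="".join(ta),
        target_interval=(tstart, tend),
        target_strand="+",
        score=float(score),
    )


def _search_target(
    query: str, target: str, scoring: Scoring, screen: bool
) -> GlocalAlignment:
    """Glocal-align query against one (possibly long) target sequence."""
    if not screen or len(target) <= max(_SCREEN_MIN_TARGET, 4 * len(query)):
        return glocal_align(query, target, scoring)
    hit = edlib.align(query, target, mode="HW", task="locations")
    loc_start, loc_end = hit["locations"][0]
    pad = _SCREEN_PAD + hit["editDistance"]
    lo = max(0, loc_start - pad)
    hi = min(len(target), loc_end + 1 + pad)
    aln = glocal_align(query, target[lo:hi], scoring)
    s, e = aln.target_interval
    aln.target_interval = (s + lo, e + lo)
    return aln


def find_orthologue(
    locus: Locus,
    genomes: dict[str, dict[str, str]],
    scoring: Scoring = DEFAULT_SCORING,
    score_floor: float | None = None,
    screen: bool = True,
) -> OrthologueSet:
    """Best glocal hit of a locus in each related genome.

    Searches both strands of every chromosome and keeps the single
    highest-scoring hit per genome; ties break to the lexicographically
    smallest chromosome, then the smallest start, then the plus strand.
    Hits scoring below ``score_floor`` (default: 0.3 x match x query
    length) are recorded as missing.
    """
    if not genomes:
        raise ValueError("at least one related genome is required")
    query = locus.sequence
    if score_floor is None:
        score_floor = DEFAULT_FLOOR_FRACTION * scoring.match * len(query)
    hits: dict[str, OrthologueHit | None] = {}
    for species in sorted(genomes):
        best: tuple | None = None
        for chrom in sorted(genomes[species]):
            forward = genomes[species][chrom]
            if not forward:
                continue
            for strand in ("+", "-"):
                target = forward if strand == "+" else revcomp(forward)
                aln = _search_target(query, target, scoring, screen)
                s, e = aln.target_interval
                if strand == "-":
                    interval = (len(forward) - e + 1, len(forward) - s + 1)
                else:
                    interval = (s, e)
                key = (-aln.score, chrom, interval[0], 0 if strand == "+" else 1)
                if best is None or key < best[0]:
                    best = (key, chrom, strand, interval, aln)
        assert best is not None
        _, chrom, strand, interval, aln = best
        if aln.score < score_floor:
            hits[species] = None
        else:
            hits[species] = OrthologueHit(
                species=species,
                chrom=chrom,
                interval=interval,
                strand=strand,
                score=aln.score,
                sequence=degap(aln.target_aligned),
            )
    return OrthologueSet(locus=locus, hits=hits)
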