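"""Synthetic genome evolution with ground truth.

Generates per-species genomes, a gene catalogue and a truth log with the
statistical structure the downstream analysis assumes: loci drawn at a
class-specific GC content at the root, evolved down the species tree under
a neutral HKY substitution process with Poisson indels, and gene-birth
events injected as explicit targeted edits (stop-codon removal to extend
or fuse reading frames, Kozak-context creation at an existing start codon)
on a designated edge.  Every mutation is logged, so ancestral
reconstruction and feature extraction can be validated against truth.

All randomness flows from a single ``numpy.random.Generator`` in a fixed
call order, so a fixed seed yields byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io import CatalogueEntry, write_catalogue, write_genome
from .model import SubstitutionModel, frequencies_from_gc
from .sequtil import BASES, decode, encode
from .trees import DEFAULT_TREE, FOCAL, SpeciesTree

SPACER = "AT" * 100  # inert run separating loci; prevents cross-locus hits
STOPS = ("TAA", "TAG", "TGA")
SEGMENTS = ("left", "core", "right")

SIM_CLASSES = ("S0+", "S1", "S2", "intergene")

_ID_TAG = {"S0+": "S0p", "S1": "S1", "S2": "S2", "intergene": "ig"}


@dataclass(frozen=True)
class BirthOp:
    """One injected gene-birth operation on a tree edge.

    ``time`` is the fraction of the edge's branch length elapsed before
    the edit is applied, so "extend early, recruit Kozak late" orderings
    can be synthesised.
    """

    op: str  # stop_removal | orf_fusion | kozak_creation
    edge: tuple[str, str] = ("A1", FOCAL)
    time: float = 1.0
    pattern: str = "A..ATG"  # kozak_creation only

    def __post_init__(self) -> None:
        if self.op not in ("stop_removal", "orf_fusion", "kozak_creation"):
            raise ValueError(f"unknown birth operation {self.op!r}")
        if not 0.0 <= self.time <= 1.0:
            raise ValueError(f"op time must be in [0, 1], got {self.time}")


def _default_birth_ops() -> dict[str, list[BirthOp]]:
    return {
        "S0+": [BirthOp("stop_removal", ("A1", FOCAL))],
        "S1": [BirthOp("orf_fusion", ("A1", FOCAL))],
        "S2": [BirthOp("stop_removal", ("A2", "A1"))],
        "intergene": [],
    }


@dataclass
class SimConfig:
    """Simulation parameters; defaults emulate the yeast study conditions.

    Root GC defaults reproduce the observed regime: intergenic background
    around 0.30 versus de-novo loci around 0.34-0.38.  Branch lengths in
    the default tree give per-branch substitution frequencies of a few
    percent, split into transition/transversion and GC-pressure classes
    by the HKY parameters.
    """

    tree_spec: str = DEFAULT_TREE
    n_loci_per_class: dict[str, int] = field(
        default_factory=lambda: {"S0+": 100, "S1": 60, "S2": 60, "intergene": 500}
    )
    locus_length: int = 300
    flank_length: int = 150
    root_gc: dict[str, float] = field(
        default_factory=lambda: {"S0+": 0.34, "S1": 0.38, "S2": 0.37, "intergene": 0.30}
    )
    #: per-locus spread of root GC within a class (the catalogued classes are
    #: compositionally heterogeneous, with per-class GC SDs of 0.05-0.10)
    root_gc_sd: dict[str, float] = field(
        default_factory=lambda: {"S0+": 0.09, "S1": 0.05, "S2": 0.07, "intergene": 0.05}
    )
    kappa: float = 2.0
    #: stationary G+C of the substitution process; None (default) puts every
    #: class at its own compositional equilibrium (isochore-style), so the
    #: neutral mutation spectrum is comparable across classes despite their
    #: different base compositions
    gc_equilibrium: float | None = None
    indel_rate: float = 0.3  # events per site per unit branch length
    indel_mean_len: float = 2.0
    birth_ops: dict[str, list[BirthOp]] = field(default_factory=_default_birth_ops)
    seed: int = 0

    def __post_init__(self) -> None:
        for cls, n in self.n_loci_per_class.items():
            if cls not in SIM_CLASSES:
                raise ValueError(f"unknown simulation class {cls!r}")
            if n < 0:
                raise ValueError(f"negative locus count for {cls!r}")
        for cls, gc in self.root_gc.items():
            if not 0.0 <= gc <= 1.0:
                raise ValueError(f"root_gc[{cls!r}] must be in [0, 1]")
        for cls, sd in self.root_gc_sd.items():
            if sd < 0:
                raise ValueError(f"root_gc_sd[{cls!r}] must be >= 0")
        if self.locus_length <= 0 or self.flank_length < 0:
            raise ValueError("locus_length must be > 0 and flank_length >= 0")
        if self.gc_equilibrium is not None and not 0.0 <= self.gc_equilibrium <= 1.0:
            raise ValueError("gc_equilibrium must be in [0, 1]")
        if self.kappa <= 0 or self.indel_rate < 0 or self.indel_mean_len < 1:
            raise ValueError("kappa > 0, indel_rate >= 0, indel_mean_len >= 1 required")

    def substitution_model(self, conservation_class: str = "intergene") -> SubstitutionModel:
        gc = self.gc_equilibrium
        if gc is None:
            gc = self.root_gc.get(conservation_class, 0.35)
        return SubstitutionModel.from_gc(gc, kappa=self.kappa)


@dataclass
class LocusTruth:
    """Ground truth for one locus: node sequences and the full event log."""

    id: str
    conservation_class: str
    node_seqs: dict[str, dict[str, str]]  # node -> segment -> sequence
    events: dict[str, dict[str, list[dict]]]  # "parent->child" -> segment -> events
    birth_ops: list[dict]


@dataclass
class TruthLog:
    """Simulator ground truth: replaying each edge's events transforms the
    parent's true sequence into the child's, segment by segment."""

    tree_spec: str
    loci: list[LocusTruth]

    def locus(self, locus_id: str) -> LocusTruth:
        for loc in self.loci:
            if loc.id == locus_id:
                return loc
        raise KeyError(locus_id)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "tree_spec": self.tree_spec,
            "loci": [asdict(loc) for loc in self.loci],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthLog":
        payload = json.loads(Path(path).read_text())
        return cls(
            tree_spec=payload["tree_spec"],
            loci=[LocusTruth(**loc) for loc in payload["loci"]],
        )


# ---------------------------------------------------------------------------
# elementary processes


def simulate_root(length: int, gc: float, rng: np.random.Generator) -> str:
    """Draw a root sequence with independent bases at the given GC content."""
    if length < 0:
        raise ValueError(f"length must be >= 0, got {length}")
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"gc must be in [0, 1], got {gc}")
    if length == 0:
        return ""
    freqs = frequencies_from_gc(gc)
    codes = rng.choice(4, size=length, p=freqs)
    return decode(codes.astype(np.int8))


def _sample_substitutions(
    codes: np.ndarray, p_matrix: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    cum = np.cumsum(p_matrix, axis=1)
    u = rng.random(codes.shape[0])
    rows = cum[codes]
    return (rows < u[:, None]).sum(axis=1).astype(np.int8)


def evolve_branch(
    seq: str,
    t: float,
    model: SubstitutionModel,
    rng: np.random.Generator,
    indel_rate: float = 0.0,
    indel_mean_len: float = 2.0,
) -> tuple[str, list[dict]]:
    """Evolve a sequence along a branch of length t (expected subs/site).

    Substitutions are drawn per site from the HKY transition matrix P(t)
    (multiple hits collapse into the net change); indel events are
    Poisson(t * indel_rate * L) with geometric lengths, equally likely
    insertions and deletions, inserted bases at the stationary
    composition.  Returns the descendant and the ordered event list whose
    replay reproduces it exactly.
    """
    if t < 0:
        raise ValueError(f"branch length must be >= 0, got {t}")
    if t == 0 or len(seq) == 0:
        return seq, []
    events: list[dict] = []
    codes = encode(seq)
    if np.any(codes > 3):
        raise ValueError("simulator sequences must be over {A,C,G,T}")
    new_codes = _sample_substitutions(codes, model.transition_matrix(t), rng)
    for pos in np.nonzero(new_codes != codes)[0]:
        events.append(
            {
                "kind": "sub",
                "pos": int(pos),
                "old": BASES[codes[pos]],
                "new": BASES[new_codes[pos]],
                "injected": False,
            }
        )
    current = list(decode(new_codes))
    n_indels = rng.poisson(t * indel_rate * len(seq)) if indel_rate > 0 else 0
    pi = model.base_frequencies
    for _ in range(int(n_indels)):
        is_insertion = rng.random() < 0.5
        length = int(rng.geometric(1.0 / indel_mean_len))
        if is_insertion:
            pos = int(rng.integers(0, len(current) + 1))
            inserted = decode(rng.choice(4, size=length, p=pi).astype(np.int8))
            current[pos:pos] = list(inserted)
            events.append(
                {"kind": "ins", "pos": pos, "seq": inserted, "injected": False}
            )
        else:
            if not current:
                continue
            pos = int(rng.integers(0, len(current)))
            length = min(length, len(current) - pos)
            removed = "".join(current[pos : pos + length])
            del current[pos : pos + length]
            events.append(
                {"kind": "del", "pos": pos, "len": length, "old": removed,
                 "injected": False}
            )
    return "".join(current), events


def replay_events(seq: str, events: list[dict]) -> str:
    """Apply an event list in order; the truth-log replay invariant."""
    current = list(seq)
    for ev in events:
        pos = ev["pos"]
        if ev["kind"] == "sub":
            if current[pos] != ev["old"]:
                raise ValueError(
                    f"replay mismatch at {pos}: have {current[pos]}, "
                    f"event expects {ev['old']}"
                )
            current[pos] = ev["new"]
        elif ev["kind"] == "ins":
            current[pos:pos] = list(ev["seq"])
        elif ev["kind"] == "del":
            del current[pos : pos + ev["len"]]
        else:
            raise ValueError(f"unknown event kind {ev['kind']!r}")
    return "".join(current)


# ---------------------------------------------------------------------------
# birth operations


def _find_inframe_stop(seq: str, start: int) -> int | None:
    """First stop codon at or after ``start`` in start's frame (0-based)."""
    for pos in range(start, len(seq) - 2, 3):
        if seq[pos : pos + 3] in STOPS:
            return pos
    return None


def _sub_events(seq: list[str], edits: dict[int, str]) -> list[dict]:
    events = []
    for pos, base in sorted(edits.items()):
        if seq[pos] != base:
            events.append(
                {"kind": "sub", "pos": pos, "old": seq[pos], "new": base,
                 "injected": True}
            )
            seq[pos] = base
    return events


def apply_birth_op(core: str, op: BirthOp, rng: np.random.Generator) -> tuple[str, list[dict]]:
    """Apply one targeted gene-birth edit to a core sequence.

    stop_removal / orf_fusion: take the most upstream ATG (installing one
    in-frame near the middle if the sequence has none), find its first
    in-frame stop, and convert the stop's leading T to C, extending the
    reading frame into the next downstream segment.  kozak_creation: set
    the -3 base of the most upstream eligible ATG to A (and +4 to C for
    the extended pattern).  Edits are logged as injected substitutions.
    """
    seq = list(core)
    if op.op in ("stop_removal", "orf_fusion"):
        events: list[dict] = []
        atg = core.find("ATG")
        if atg == -1:
            pos0 = 3 * (len(core) // 6)
            events += _sub_events(seq, {pos0: "A", pos0 + 1: "T", pos0 + 2: "G"})
            atg = pos0
        # stop_removal: knock out the terminating stop only (one ~neutral
        # edit extending the ORF into the next segment); orf_fusion:
        # clear every downstream in-frame stop, so the born ORF absorbs
        # all segments of its frame the way an annotated de novo gene
        # spans most of its locus
        stop = _find_inframe_stop("".join(seq), atg + 3)
        while stop is not None:
            events += _sub_events(seq, {stop: "C"})
            if op.op == "stop_removal":
                break
            stop = _find_inframe_stop("".join(seq), stop + 3)
        return "".join(seq), events
    # kozak_creation
    pos = core.find("ATG", 3)  # -3 context must exist within the core
    if pos == -1:
        return core, []
    edits = {pos - 3: "A"}
    if op.pattern == "A..ATG.C" and pos + 4 < len(core):
        edits[pos + 4] = "C"
    events = _sub_events(seq, edits)
    return "".join(seq), events


# ---------------------------------------------------------------------------
# whole-catalogue simulation


@dataclass
class SimResult:
    genomes: dict[str, dict[str, str]]  # species -> chrom -> sequence
    catalogue: list[CatalogueEntry]
    truth: TruthLog


def _evolve_edge_segments(
    segs: dict[str, str],
    t: float,
    config: SimConfig,
    model: SubstitutionModel,
    ops: list[BirthOp],
    rng: np.random.Generator,
) -> tuple[dict[str, str], dict[str, list[dict]]]:
    """Evolve the three locus segments along one edge, injecting core ops."""
    out: dict[str, str] = {}
    events: dict[str, list[dict]] = {}
    for seg in SEGMENTS:
        if seg != "core":
            out[seg], events[seg] = evolve_branch(
                segs[seg], t, model, rng, config.indel_rate, config.indel_mean_len
            )
            continue
        seq = segs[seg]
        seg_events: list[dict] = []
        elapsed = 0.0
        for op in sorted(ops, key=lambda o: o.time):
            seq, evs = evolve_branch(
                seq, (op.time - elapsed) * t, model, rng,
                config.indel_rate, config.indel_mean_len,
            )
            seg_events += evs
            seq, evs = apply_birth_op(seq, op, rng)
            seg_events += evs
            elapsed = op.time
        seq, evs = evolve_branch(
            seq, (1.0 - elapsed) * t, model, rng,
            config.indel_rate, config.indel_mean_len,
        )
        out[seg] = seq
        events[seg] = seg_events + evs
    return out, events


def simulate_catalogue(config: SimConfig) -> SimResult:
    """Simulate genomes, catalogue and truth log under the configuration.

    Each species' genome is one chromosome: the concatenation of evolved
    loci (left flank + core + right flank) separated by fixed spacer runs.
    Catalogue coordinates point at the core in the focal genome.
    """
    rng = np.random.default_rng(config.seed)
    tree = SpeciesTree(config.tree_spec)
    leaves = tree.leaf_names()

    loci: list[LocusTruth] = []
    # species -> list of locus sequences in catalogue order
    species_seqs: dict[str, list[str]] = {leaf: [] for leaf in leaves}

    for cls in SIM_CLASSES:
        n = config.n_loci_per_class.get(cls, 0)
        ops = config.birth_ops.get(cls, [])
        gc_mean = config.root_gc.get(cls, 0.35)
        gc_sd = config.root_gc_sd.get(cls, 0.0)
        for i in range(n):
            locus_id = f"{_ID_TAG[cls]}_{i:04d}"
            gc = float(np.clip(rng.normal(gc_mean, gc_sd), 0.05, 0.95))
            eq = config.gc_equilibrium if config.gc_equilibrium is not None else gc
            model = SubstitutionModel.from_gc(eq, kappa=config.kappa)
            root_name = tree.name_of(tree.tree.seed_node)
            root_segs = {
                "left": simulate_root(config.flank_length, gc, rng),
                "core": simulate_root(config.locus_length, gc, rng),
                "right": simulate_root(config.flank_length, gc, rng),
            }
            node_seqs: dict[str, dict[str, str]] = {root_name: root_segs}
            edge_events: dict[str, dict[str, list[dict]]] = {}
            applied_ops: list[dict] = []
            for node in tree.tree.preorder_node_iter():
                if node is tree.tree.seed_node:
                    continue
                parent = tree.name_of(node.parent_node)
                child = tree.name_of(node)
                t = 0.0 if node.edge.length is None else float(node.edge.length)
                edge_ops = [op for op in ops if op.edge == (parent, child)]
                segs, events = _evolve_edge_segments(
                    node_seqs[parent], t, config, model, edge_ops, rng
                )
                node_seqs[child] = segs
                edge_events[f"{parent}->{child}"] = events
                applied_ops += [asdict(op) for op in edge_ops]
            loci.append(
                LocusTruth(
                    id=locus_id,
                    conservation_class=cls,
                    node_seqs=node_seqs,
                    events=edge_events,
                    birth_ops=applied_ops,
                )
            )
            for leaf in leaves:
                segs = node_seqs[leaf]
                species_seqs[leaf].append(segs["left"] + segs["core"] + segs["right"])

    # assemble genomes and the focal-species catalogue
    genomes = {
        leaf: {"chr1": SPACER + "".join(s + SPACER for s in species_seqs[leaf])}
        for leaf in leaves
    }
    catalogue: list[CatalogueEntry] = []
    pos = len(SPACER)
    for loc in loci:
        segs = loc.node_seqs[FOCAL]
        start = pos + len(segs["left"]) + 1  # 1-based inclusive
        end = start + len(segs["core"]) - 1
        catalogue.append(
            CatalogueEntry(
                id=loc.id,
                chrom="chr1",
                start=start,
                end=end,
                strand="+",
                conservation_class=loc.conservation_class,
            )
        )
        pos += sum(len(segs[s]) for s in SEGMENTS) + len(SPACER)

    return SimResult(
        genomes=genomes,
        catalogue=catalogue,
        truth=TruthLog(tree_spec=config.tree_spec, loci=loci),
    )


def write_simulation(result: SimResult, outdir: str | Path) -> None:
    """Write genomes (one FASTA per species), catalogue TSV and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for species, genome in result.genomes.items():
        write_genome(genome, outdir / f"{species}.fa")
    write_catalogue(result.catalogue, outdir / "catalogue.tsv")
    result.truth.to_json(outdir / "truth.json")
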