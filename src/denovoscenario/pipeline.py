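"""End-to-end orchestration: map -> align -> reconstruct -> features -> stats.

``run_pipeline`` executes the whole analysis in memory from genomes, a
catalogue and a species tree, producing per-locus features, pooled
summary tables (GC, mutation frequencies, ORF length changes, Kozak
turnover), a per-locus structured log with filter tallies, and the
four-stage scenario report.  All stages are deterministic given the same
inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ancestors import AncestralSequence, confidence_filter, reconstruct_ancestors
from .features import (
    RULE_ATG,
    RULE_KOZAK,
    RULE_KOZAK_FULL,
    MUTATION_CLASSES,
    classify_kozak_transition,
    classify_length_change,
    classify_mutations,
    gc_content,
    induce_pair,
    map_ancestral_orf,
    scan_orfs,
    orf_start_has_kozak,
    select_overlapping_orf,
)
from .io import CatalogueEntry
from .mapping import (
    DEFAULT_SCORING,
    Locus,
    OrthologueSet,
    Scoring,
    extract_locus,
    filter_catalogue,
    find_orthologue,
)
from .msa import MSA, build_msa
from .sequtil import GAP, degap
from .stats import (
    IncompleteInputError,
    ScenarioReport,
    SummaryStats,
    TrendResult,
    WelchResult,
    binomial_trend_test,
    bonferroni,
    build_report,
    kozak_trend_test,
    welch_test,
)
from .trees import FOCAL, OUTGROUP, SISTER, SpeciesTree

LENGTH_RULES = (RULE_ATG, RULE_KOZAK, RULE_KOZAK_FULL)
KOZAK_PATTERNS = (RULE_KOZAK, RULE_KOZAK_FULL)

#: analysis edges per conservation class (parent, child); the intergenic
#: background is evaluated on both edges
CLASS_EDGES = {
    "S0+": [("A1", FOCAL)],
    "S1": [("A1", FOCAL)],
    "S2": [("A2", "A1")],
    "intergene": [("A1", FOCAL), ("A2", "A1")],
}

GENIC_CLASSES = ("S0+", "S1", "S2", "S3", "S4")


@dataclass
class PipelineConfig:
    """Pipeline constants; the defaults are the analysis's standard ones:
    500 nt flanks, a 60 nt minimum ORF length and a 0.80 ancestral
    confidence threshold."""

    flank_length: int = 500
    min_orf_length: int = 60
    confidence_threshold: float = 0.80
    scoring: Scoring = field(default_factory=Scoring)
    kappa: float = 2.0
    score_floor: float | None = None
    screen: bool = True
    alpha: float = 0.01
    normal_approx: bool = False
    two_sided: bool = False  # trend tests are directional by default
    seed: int = 0


@dataclass
class PipelineResult:
    features: pd.DataFrame
    ancestor_cores: pd.DataFrame
    gc_summary: pd.DataFrame
    mutation_summary: pd.DataFrame
    orf_summary: pd.DataFrame
    kozak_summary: pd.DataFrame
    report: ScenarioReport
    log: pd.DataFrame
    discarded_short: dict[str, int]


def _edge_label(edge: tuple[str, str]) -> str:
    return f"{edge[0]}->{edge[1]}"


# ---------------------------------------------------------------------------
# per-locus analysis


def _core_columns(msa_rows: dict[str, str], locus: Locus) -> np.ndarray:
    """Alignment columns covered by the catalogued ORF in the focal row."""
    row = msa_rows[FOCAL]
    lo = locus.orf_offset + 1  # 1-based degapped positions
    hi = locus.orf_offset + locus.orf_length
    cols = []
    pos = 0
    for col, ch in enumerate(row):
        if ch != GAP:
            pos += 1
            if lo <= pos <= hi:
                cols.append(col)
    return np.asarray(cols, dtype=int)


def _row_interval(row: str, columns: np.ndarray) -> tuple[int, int] | None:
    """1-based degapped interval of a row restricted to given columns."""
    colset = set(int(c) for c in columns)
    pos = 0
    found = []
    for col, ch in enumerate(row):
        if ch != GAP:
            pos += 1
            if col in colset:
                found.append(pos)
    if not found:
        return None
    return found[0], found[-1]


def _extant_gc(locus: Locus) -> tuple[float, str]:
    core = locus.sequence[locus.orf_offset : locus.orf_offset + locus.orf_length]
    genic = locus.entry.conservation_class in GENIC_CLASSES
    if genic and len(core) % 3 == 0:
        return gc_content(core, "genic_third_codon").value, "genic_third_codon"
    return gc_content(core, "nongenic_whole").value, "nongenic_whole"


def analyse_locus(
    locus: Locus,
    msa: MSA,
    ancestors: dict[str, AncestralSequence],
    config: PipelineConfig,
) -> tuple[list[dict], str, list[dict]]:
    """Feature rows (one per analysis edge) for one locus.

    Returns (rows, status, ancestor_core_rows); rows may be empty when
    e.g. every relevant ancestral reconstruction fails the confidence
    filter.  The ancestor rows carry the reconstructed A1/A2 core
    sequences with their confidences.
    """
    cls = locus.entry.conservation_class
    edges = CLASS_EDGES.get(cls)
    if edges is None:
        return [], "unsupported_class", []
    rows_all = dict(msa.rows)
    for label, anc in ancestors.items():
        rows_all[label] = anc.sequence
    core_cols = _core_columns(msa.rows, locus)
    if core_cols.size == 0:
        return [], "empty_core", []
    keep = {
        label: confidence_filter(anc, config.confidence_threshold)
        for label, anc in ancestors.items()
    }
    gc_extant, gc_extant_mode = _extant_gc(locus)
    node_gc = {}
    anc_cores = {}
    for label in ("A1", "A2"):
        core_pair = induce_pair(rows_all, label, FOCAL, columns=core_cols)
        anc_core = degap(core_pair.older)
        anc_cores[label] = anc_core
        node_gc[label] = (
            gc_content(anc_core, "nongenic_whole").value if anc_core else np.nan
        )

    out_rows: list[dict] = []
    for edge in edges:
        parent, child = edge
        needed = {parent} | ({child} if child in ancestors else set())
        if not all(keep[n] for n in needed):
            continue
        pair_core = induce_pair(rows_all, parent, child, columns=core_cols)
        if not pair_core.older:
            continue
        muts = classify_mutations(pair_core)
        row = {
            "id": locus.entry.id,
            "class": cls,
            "edge": _edge_label(edge),
            "gc_extant": gc_extant,
            "gc_extant_mode": gc_extant_mode,
            "gc_a1": node_gc["A1"],
            "gc_a2": node_gc["A2"],
            "conf_a1": ancestors["A1"].confidence,
            "conf_a2": ancestors["A2"].confidence,
        }
        anc_core = degap(pair_core.older)
        rec_core = degap(pair_core.younger)
        row["gc_anc"] = (
            gc_content(anc_core, "nongenic_whole").value if anc_core else np.nan
        )
        row["gc_recent"] = (
            gc_extant
            if child == FOCAL
            else (gc_content(rec_core, "nongenic_whole").value if rec_core else np.nan)
        )
        for mcls, freq in muts.frequencies.items():
            row[f"freq_{mcls}"] = freq

        # ORF length changes and Kozak turnover over the full locus
        pair_full = induce_pair(rows_all, parent, child)
        child_seq = degap(pair_full.younger)
        parent_seq = degap(pair_full.older)
        if child == FOCAL:
            core_interval = (locus.orf_offset + 1, locus.orf_offset + locus.orf_length)
        else:
            core_interval = _row_interval(rows_all[child], core_cols)
        for rule in LENGTH_RULES:
            tag = rule.label
            focal_orf = None
            if core_interval is not None:
                focal_orf = select_overlapping_orf(
                    scan_orfs(child_seq, rule), core_interval
                )
            if focal_orf is None:
                row[f"len_recent_{tag}"] = np.nan
                row[f"len_anc_{tag}"] = np.nan
                row[f"change_{tag}"] = None
                continue
            anc_orf = map_ancestral_orf(focal_orf, pair_full, rule)
            row[f"len_recent_{tag}"] = focal_orf.length
            row[f"len_anc_{tag}"] = anc_orf.length if anc_orf else np.nan
            row[f"change_{tag}"] = classify_length_change(anc_orf, focal_orf)
        # Kozak presence is evaluated on the plain-ATG ORF's segment
        focal_atg = None
        if core_interval is not None:
            focal_atg = select_overlapping_orf(
                scan_orfs(child_seq, RULE_ATG), core_interval
            )
        anc_atg = (
            map_ancestral_orf(focal_atg, pair_full, RULE_ATG) if focal_atg else None
        )
        for pattern in KOZAK_PATTERNS:
            recent_has = bool(
                focal_atg and orf_start_has_kozak(child_seq, focal_atg, pattern)
            )
            anc_has = bool(anc_atg and orf_start_has_kozak(parent_seq, anc_atg, pattern))
            row[f"kozak_{pattern.label}"] = classify_kozak_transition(
                anc_has, recent_has
            )
        out_rows.append(row)
    anc_rows = [
        {
            "id": locus.entry.id,
            "class": cls,
            "node": label,
            "sequence": anc_cores[label],
            "confidence": ancestors[label].confidence,
            "keep": keep[label],
        }
        for label in ("A1", "A2")
    ]
    if not out_rows:
        return [], "low_confidence", anc_rows
    return out_rows, "ok", anc_rows


# ---------------------------------------------------------------------------
# pooled summaries


def _summarise(values: pd.Series) -> SummaryStats | None:
    vals = values.dropna().to_numpy(dtype=float)
    if vals.size < 2:
        return None
    return SummaryStats.from_values(vals)


def _gc_summary(features: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    per_locus = features.drop_duplicates("id")
    rows = []
    for node, column in (("extant", "gc_extant"), ("A1", "gc_a1"), ("A2", "gc_a2")):
        groups = {
            cls: _summarise(sub[column])
            for cls, sub in per_locus.groupby("class")
        }
        background = groups.get("intergene")
        tests = {}
        for cls, summ in groups.items():
            if summ is None:
                continue
            if cls != "intergene" and background is not None:
                tests[cls] = welch_test(
                    summ, background, normal_approx=config.normal_approx
                )
        m = max(len(tests), 1)
        for cls, summ in groups.items():
            if summ is None:
                continue
            res = tests.get(cls)
            rows.append(
                {
                    "node": node,
                    "class": cls,
                    "n": summ.n,
                    "gc_ave": summ.ave,
                    "gc_sd": summ.sd,
                    "welch_t": res.t if res else np.nan,
                    "welch_p": res.p if res else np.nan,
                    "welch_p_bonferroni": bonferroni(res.p, m) if res else np.nan,
                }
            )
    return pd.DataFrame(rows)


def _mutation_summary(features: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    rows = []
    for edge, sub in features.groupby("edge"):
        groups = dict(tuple(sub.groupby("class")))
        bg = groups.get("intergene")
        n_tests = max(
            sum(1 for c in groups if c != "intergene") * len(MUTATION_CLASSES), 1
        )
        for cls, cdf in groups.items():
            for mcls in MUTATION_CLASSES:
                summ = _summarise(cdf[f"freq_{mcls}"])
                if summ is None:
                    continue
                res = None
                if cls != "intergene" and bg is not None:
                    bg_summ = _summarise(bg[f"freq_{mcls}"])
                    if bg_summ is not None:
                        res = welch_test(
                            summ, bg_summ, normal_approx=config.normal_approx
                        )
                rows.append(
                    {
                        "edge": edge,
                        "class": cls,
                        "mutation": mcls,
                        "n": summ.n,
                        "freq_ave": summ.ave,
                        "freq_sd": summ.sd,
                        "welch_t": res.t if res else np.nan,
                        "welch_p": res.p if res else np.nan,
                        "welch_p_bonferroni": (
                            bonferroni(res.p, n_tests) if res else np.nan
                        ),
                    }
                )
    return pd.DataFrame(rows)


def _change_tallies(sub: pd.DataFrame, column: str) -> dict[str, int]:
    counts = sub[column].value_counts(dropna=False).to_dict()
    return {
        "Extend": int(counts.get("Extend", 0)),
        "Shrink": int(counts.get("Shrink", 0)),
        "NoChange": int(counts.get("NoChange", 0)),
        "NoAncestor": int(sum(v for k, v in counts.items() if not isinstance(k, str))),
    }


def _orf_summary(features: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    rows = []
    for edge, sub in features.groupby("edge"):
        groups = dict(tuple(sub.groupby("class")))
        bg = groups.get("intergene")
        for cls, cdf in groups.items():
            for rule in LENGTH_RULES:
                tallies = _change_tallies(cdf, f"change_{rule.label}")
                entry = {
                    "edge": edge,
                    "class": cls,
                    "rule": rule.label,
                    **tallies,
                    "trend_p": np.nan,
                    "background_p0": np.nan,
                }
                if (
                    cls != "intergene"
                    and bg is not None
                    and tallies["Extend"] + tallies["Shrink"] > 0
                ):
                    bg_t = _change_tallies(bg, f"change_{rule.label}")
                    res = binomial_trend_test(
                        tallies["Extend"],
                        tallies["Shrink"],
                        background=(bg_t["Extend"], bg_t["Shrink"]),
                        two_sided=config.two_sided,
                    )
                    entry["trend_p"] = res.p
                    entry["background_p0"] = res.p0
                rows.append(entry)
    return pd.DataFrame(rows)


def _kozak_tallies(sub: pd.DataFrame, column: str) -> dict[str, int]:
    counts = sub[column].value_counts().to_dict()
    return {k: int(counts.get(k, 0)) for k in ("No", "Retain", "Disappear", "Appear")}


def _kozak_summary(features: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    rows = []
    for edge, sub in features.groupby("edge"):
        groups = dict(tuple(sub.groupby("class")))
        bg = groups.get("intergene")
        for cls, cdf in groups.items():
            for pattern in KOZAK_PATTERNS:
                tallies = _kozak_tallies(cdf, f"kozak_{pattern.label}")
                entry = {
                    "edge": edge,
                    "class": cls,
                    "pattern": pattern.label,
                    **tallies,
                    "trend_p": np.nan,
                    "background_p0": np.nan,
                }
                if (
                    cls != "intergene"
                    and bg is not None
                    and tallies["Appear"] + tallies["Disappear"] > 0
                ):
                    bg_t = _kozak_tallies(bg, f"kozak_{pattern.label}")
                    res = kozak_trend_test(
                        tallies["Appear"],
                        tallies["Disappear"],
                        background=(bg_t["Appear"], bg_t["Disappear"]),
                        two_sided=config.two_sided,
                    )
                    entry["trend_p"] = res.p
                    entry["background_p0"] = res.p0
                rows.append(entry)
    return pd.DataFrame(rows)


def _scenario_report(
    features: pd.DataFrame,
    gc_summary: pd.DataFrame,
    mutation_summary: pd.DataFrame,
    orf_summary: pd.DataFrame,
    kozak_summary: pd.DataFrame,
    config: PipelineConfig,
) -> ScenarioReport:
    if features.empty:
        return ScenarioReport(stages=[], alpha=config.alpha)
    a1 = gc_summary[(gc_summary["node"] == "A1")]
    bg_gc = a1[a1["class"] == "intergene"]
    gc_tests: dict[str, WelchResult] = {}
    gc_direction: dict[str, float] = {}
    for _, row in a1.iterrows():
        if row["class"] == "intergene" or np.isnan(row["welch_p"]):
            continue
        gc_tests[row["class"]] = WelchResult(
            t=row["welch_t"], df=np.nan, p=row["welch_p"]
        )
        if not bg_gc.empty:
            gc_direction[row["class"]] = row["gc_ave"] - float(bg_gc["gc_ave"].iloc[0])
    mutation_tests: dict[str, dict[str, WelchResult]] = {}
    for _, row in mutation_summary.iterrows():
        if row["class"] == "intergene" or np.isnan(row["welch_p"]):
            continue
        mutation_tests.setdefault(row["class"], {})[row["mutation"]] = WelchResult(
            t=row["welch_t"], df=np.nan, p=row["welch_p"]
        )
    orf_trends: dict[str, TrendResult] = {}
    for _, row in orf_summary.iterrows():
        if row["class"] == "intergene" or row["rule"] != "ATG":
            continue
        if np.isnan(row["trend_p"]):
            continue
        orf_trends[row["class"]] = TrendResult(
            k=row["Extend"],
            n=row["Extend"] + row["Shrink"],
            p0=row["background_p0"],
            p=row["trend_p"],
        )
    kozak_trends: dict[str, TrendResult] = {}
    for _, row in kozak_summary.iterrows():
        if row["class"] == "intergene" or row["pattern"] != "A..ATG":
            continue
        if np.isnan(row["trend_p"]):
            continue
        kozak_trends[row["class"]] = TrendResult(
            k=row["Appear"],
            n=row["Appear"] + row["Disappear"],
            p0=row["background_p0"],
            p=row["trend_p"],
        )
    return build_report(
        gc_tests=gc_tests,
        gc_direction=gc_direction,
        mutation_tests=mutation_tests,
        orf_trends=orf_trends,
        kozak_trends=kozak_trends,
        alpha=config.alpha,
    )


# ---------------------------------------------------------------------------
# orchestration


def run_pipeline(
    genomes: dict[str, dict[str, str]],
    catalogue: list[CatalogueEntry],
    tree: SpeciesTree,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full analysis in memory.

    ``genomes`` maps species names (tree leaves, including the focal
    cerevisiae genome) to chromosome dicts.  Returns per-locus features,
    pooled summaries, the scenario report and a structured per-locus log.
    """
    config = config or PipelineConfig()
    if FOCAL not in genomes:
        raise ValueError(f"missing focal genome {FOCAL!r}")
    related = {sp: g for sp, g in genomes.items() if sp != FOCAL}
    related = {sp: g for sp, g in related.items() if sp in tree.leaf_names()}
    if not related:
        raise ValueError("no related genomes on the tree")

    kept, discarded = filter_catalogue(catalogue, config.min_orf_length)
    log_rows: list[dict] = []
    feature_rows: list[dict] = []
    ancestor_rows: list[dict] = []
    for entry in kept:
        locus = extract_locus(genomes[FOCAL], entry, config.flank_length)
        if entry.conservation_class not in CLASS_EDGES:
            log_rows.append(
                {"id": entry.id, "class": entry.conservation_class,
                 "status": "unsupported_class"}
            )
            continue
        ortho = find_orthologue(
            locus,
            related,
            scoring=config.scoring,
            score_floor=config.score_floor,
            screen=config.screen,
        )
        present = ortho.present()
        if SISTER not in present or OUTGROUP not in present:
            log_rows.append(
                {"id": entry.id, "class": entry.conservation_class,
                 "status": "missing_ortholog"}
            )
            continue
        sequences = {FOCAL: locus.sequence}
        for sp, hit in present.items():
            sequences[sp] = hit.sequence
        msa = build_msa(sequences, tree, config.scoring)
        ancestors = reconstruct_ancestors(msa, tree, kappa=config.kappa)
        rows, status, anc_rows = analyse_locus(locus, msa, ancestors, config)
        feature_rows += rows
        ancestor_rows += anc_rows
        log_rows.append(
            {"id": entry.id, "class": entry.conservation_class, "status": status}
        )
    for cls, n in discarded.items():
        log_rows.append({"id": "", "class": cls, "status": f"short_orf_x{n}"})

    features = pd.DataFrame(feature_rows)
    config_local = config
    if features.empty:
        empty = pd.DataFrame()
        return PipelineResult(
            features=features,
            ancestor_cores=pd.DataFrame(ancestor_rows),
            gc_summary=empty,
            mutation_summary=empty,
            orf_summary=empty,
            kozak_summary=empty,
            report=ScenarioReport(stages=[], alpha=config.alpha),
            log=pd.DataFrame(log_rows),
            discarded_short=discarded,
        )
    gc_summary = _gc_summary(features, config_local)
    mutation_summary = _mutation_summary(features, config_local)
    orf_summary = _orf_summary(features, config_local)
    kozak_summary = _kozak_summary(features, config_local)
    try:
        report = _scenario_report(
            features, gc_summary, mutation_summary, orf_summary, kozak_summary, config
        )
    except IncompleteInputError:
        # e.g. a background-only run: nothing to test against intergenes
        report = ScenarioReport(stages=[], alpha=config.alpha)
    return PipelineResult(
        features=features,
        ancestor_cores=pd.DataFrame(ancestor_rows),
        gc_summary=gc_summary,
        mutation_summary=mutation_summary,
        orf_summary=orf_summary,
        kozak_summary=kozak_summary,
        report=report,
        log=pd.DataFrame(log_rows),
        discarded_short=discarded,
    )


def write_pipeline_outputs(result: PipelineResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.features.to_csv(outdir / "features.tsv", sep="\t", index=False)
    result.ancestor_cores.to_csv(outdir / "ancestor_cores.tsv", sep="\t", index=False)
    result.gc_summary.to_csv(outdir / "summary_gc.tsv", sep="\t", index=False)
    result.mutation_summary.to_csv(
        outdir / "summary_mutations.tsv", sep="\t", index=False
    )
    result.orf_summary.to_csv(
        outdir / "summary_orf_changes.tsv", sep="\t", index=False
    )
    result.kozak_summary.to_csv(outdir / "summary_kozak.tsv", sep="\t", index=False)
    result.log.to_csv(outdir / "locus_log.tsv", sep="\t", index=False)
    (outdir / "scenario_report.json").write_text(
        json.dumps(result.report.to_dict(), indent=2, default=float)
    )
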