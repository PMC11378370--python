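# denovoscenario

How do protein-coding genes arise *de novo* from non-genic DNA?
`denovoscenario` is a reusable pipeline for sketching that scenario in
the *Saccharomyces cerevisiae* lineage from a catalogue of young genes:
it assigns each gene's birth edge on the sensu stricto species tree by
parsimony, reconstructs the ancestral DNA sequence at both ends of that
edge, and quantifies what changed while the locus went from non-genic to
genic — with intergenic ORFs as the neutral background. It is written
for molecular-evolution researchers who have (a) a catalogue of young
genes with conservation classes, (b) a phylogeny of the close relatives,
and (c) their genome sequences.

## The analysis

For a gene present only in *S. cerevisiae* (conservation classes S0+ and
S1), parsimony places its birth on the edge A1 → cerevisiae, where A1 is
the MRCA of cerevisiae and *S. paradoxus*; a gene shared with paradoxus
(S2) was born on A2 → A1, with A2 the MRCA that adds *S. mikatae*. Per
locus the pipeline:

1. extracts the gene ± 500 nt flanks (loci < 60 nt discarded);
2. finds the orthologous region in each related genome by glocal
   alignment — global in the query, local in the target;
3. builds a guide-tree progressive multiple alignment;
4. reconstructs marginal maximum-likelihood ancestors at A1 and A2 under
   HKY by Felsenstein pruning; per column the posterior p_ij over bases
   is computed and a reconstruction is kept only if its confidence
   (1/L) Σ_i max_j p_ij ≥ 0.80;
5. measures, between the older and younger end of the birth edge:
   GC content (third-codon positions for genic ORFs, whole region for
   non-genic), the seven mutation classes (transition, transversion,
   AT>GC, GC>AT, AT>AT, GC>GC, indel events), ORF length changes under
   three start-codon rules (most upstream ATG, A..ATG, A..ATG.C), and
   Kozak-signature turnover (No/Retain/Disappear/Appear);
6. tests each feature against the intergenic background: Welch's t-test
   for GC and mutation frequencies, one-sided exact binomial trend tests
   (background probability from the intergenic tallies, Haldane ½
   pseudo-count) for extension and Kozak appearance,

and assembles a four-stage scenario report: (1) GC-rich origin →
(2) neutral mutation accumulation → (3) ORF extension/combination →
(4) Kozak recruitment (later — its trend is *not yet* significant on
the birth edge).

A fully ground-truthed synthetic-evolution module (`simulate_catalogue`)
generates genomes, catalogues and a truth log (every mutation event,
every ancestral sequence) so the whole pipeline is testable without
external data. See `docs/methods.md` for models, conventions and
limitations.

## Worked example

```python
from denovoscenario import (
    PipelineConfig, SimConfig, SpeciesTree, run_pipeline, simulate_catalogue,
)

tree_spec = "((cerevisiae:0.05,paradoxus:0.05)A1:0.03,mikatae:0.10)A2;"
sim = simulate_catalogue(SimConfig(
    tree_spec=tree_spec,
    n_loci_per_class={"S0+": 0, "S1": 150, "S2": 0, "intergene": 400},
    locus_length=300, flank_length=150, seed=5,
))
result = run_pipeline(sim.genomes, sim.catalogue, SpeciesTree(tree_spec),
                      PipelineConfig(flank_length=150))

orf = result.orf_summary
print(orf[(orf["class"] == "S1") & (orf["rule"] == "ATG")]
      [["Extend", "Shrink", "NoChange", "trend_p"]].to_string(index=False))
kozak = result.kozak_summary
print(kozak[(kozak["class"] == "S1") & (kozak["pattern"] == "A..ATG")]
      [["Appear", "Disappear", "trend_p"]].to_string(index=False))
```

prints

```
 Extend  Shrink  NoChange      trend_p
    144       3         2 4.416797e-20
 Appear  Disappear  trend_p
     16         17 0.893179
```

The 150 simulated S1-like genes carry injected stop-codon removals on
the A1 → cerevisiae edge and no Kozak edits; the pipeline recovers
exactly that ordering: a massive, highly significant extension trend
(144 extended vs 3 shrunk against the intergene-derived background
probability) while Kozak appearance stays balanced and indistinguishable
from background (16 appear vs 17 disappear, p = 0.89) — extension
first, translation signature later.
`result.report.to_dict()` gives the full staged report, and
`write_pipeline_outputs(result, outdir)` writes the per-locus features,
the four summary tables and `scenario_report.json`.

The same analysis is scriptable from the shell:

```bash
denovo-scenario simulate --out data --seed 5
denovo-scenario run --genomes data --catalogue data/catalogue.tsv --out results
```

(`map`, `align`, `reconstruct`, `features`, `stats` run the stages
individually from their on-disk inputs.)

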