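# Methods

`denovoscenario` re-implements, as a tested pipeline, an
ancestral-sequence analysis of how de novo protein-coding genes arise in
the *Saccharomyces cerevisiae* lineage. This note documents the models,
the conventions, the synthetic-data generator, and the choices made
where the design was genuinely open.

## The analysis

For each catalogued locus the pipeline:

1. **Assigns the birth edge by parsimony.** A gene found only in
   *S. cerevisiae* (classes S0+, S1) was born on the edge from A1 — the
   most recent common ancestor of *S. cerevisiae* and *S. paradoxus* —
   to the cerevisiae tip; a gene shared with *S. paradoxus* (S2) was
   born on the edge A2 → A1, where A2 is the MRCA including
   *S. mikatae*. Reconstruction never goes above A2: the distance to
   *S. bayanus* makes deeper ancestors unreliable, so classes S3/S4 are
   outside the analysis and are logged as unsupported.
2. **Extracts the locus with flanks** (default 500 nt each side,
   truncated at chromosome ends; minus-strand loci reverse-complemented)
   and discards ORFs shorter than 60 nt, whose per-locus statistics are
   too noisy.
3. **Finds orthologous regions** in each related genome with an
   alignment that is *global in the query and local in the target*
   ("glocal"): the full locus must align, unaligned target ends are
   free. Scoring is DNA-typical (match +5, mismatch −4, gap run of
   length k costs −12 − 4k). Because the flanks usually contain
   conserved neighbouring sequence, the search behaves like a
   synteny-based method. The single best hit per genome is kept
   (ties: lexicographically smallest chromosome, then smallest start,
   then + strand); hits below `0.3 × match × |query|` count as missing.
   Implementation: an exact bit-parallel edit-distance infix scan
   (edlib) locates the best window on long targets, and the exact
   affine-gap DP then runs inside that window (pad = 100 nt + the edit
   distance). This is exact-prefilter rescoring, not heuristic seeding,
   and `screen=False` forces the fully exhaustive DP.
4. **Aligns the orthologue set** with a progressive profile aligner
   that follows the species tree (merge cerevisiae+paradoxus, then
   mikatae, then bayanus when present), each merge a global affine-gap
   alignment of frequency profiles; once a gap, always a gap. With at
   most four closely related sequences per set, progressive profile
   alignment is adequate and keeps the whole pipeline self-contained.
5. **Reconstructs marginal ML ancestors at A1 and A2.** Per column,
   posterior base probabilities are computed by Felsenstein pruning
   (up pass + down pass) under HKY with the input tree's branch lengths;
   base frequencies are estimated from the alignment, and the
   transition/transversion ratio κ defaults to 2.0 (configurable).
   Branch lengths are not re-estimated per locus: loci are short
   (≥ 60 nt) and per-locus estimates would be unstable. Gap/base status
   at internal nodes is decided first by Fitch parsimony on the binary
   gap character, ties resolved toward "base present" so sites stay
   available for the likelihood; the reported base is the posterior
   argmax. The reconstruction confidence is the mean over non-gap
   columns of the maximum posterior (range [0.25, 1]); reconstructions
   below 0.80 are discarded, per node — a locus may keep A1 and lose A2.
6. **Computes features between the two ends of the birth edge** on the
   pairwise alignment induced from the locus alignment (columns gapped
   in both rows removed; columns gapped in one row kept as indel
   evidence), restricted to the catalogued ORF for composition and
   mutation statistics, and on the full locus for ORF tracking (so
   start-codon context can reach into the flanks):
   - *GC content*: third-codon positions for extant genic ORFs (the
     third position is largely unconstrained by coding and proxies the
     neighbourhood's composition), whole region for non-genic sequences.
     Reconstructed ancestors are always measured whole-region: a codon
     structure is not well-defined for a reconstructed ancestor after
     indels.
   - *Mutation classes*: aligned mismatching bases are substitutions,
     split into transition/transversion and, independently, AT>GC /
     GC>AT / AT>AT / GC>GC (weak vs strong bases); by construction
     transitions + transversions equals the sum of the four pressure
     classes, and this identity is asserted on every pair. Each maximal
     run of gap-in-exactly-one-row counts as one indel event.
     Frequencies are percentages; substitution classes are normalised by
     aligned-base columns, indels by total induced-pair columns.
     Columns containing N are excluded entirely.
   - *ORF length changes* under three start-codon rules: most upstream
     ATG, most upstream A..ATG, most upstream A..ATG.C ('.' = any base;
     the context bases sit at −3 and +4 relative to the A of ATG and
     may fall outside the ORF). ORFs are stop-to-stop segments per
     frame containing a rule-matching start; length runs start codon
     through stop codon; segments running off the sequence end are kept,
     measured to the last complete codon. The extant ("recent") ORF is
     the one maximally overlapping the catalogued interval (ties:
     upstream). Its ancestral counterpart is the ancestral-sequence ORF
     maximising the number of alignment columns at which the two ORFs
     agree in codon phase — this tolerates frame shifts from indels
     between the nodes — with ties going upstream; loci without an
     ancestral counterpart are tallied separately. Changes are Extend /
     Shrink / NoChange.
   - *Kozak turnover*: whether the ORF's own start codon (most upstream
     ATG) carries the Kozak context, at each end of the edge, giving
     No / Retain / Disappear / Appear. Evaluating the context at the
     start codon itself — rather than "any Kozak-matching ATG in the
     segment" — keeps the signature a property of the initiation site
     and decouples it from raw segment growth.
7. **Pools by class and tests.** GC and the seven mutation-class
   frequencies are compared class-vs-intergenic-background with Welch's
   two-sample t-test (Welch–Satterthwaite df; a normal-approximation
   flag exists because summary-level bounds in the source tables are
   consistent with a normal tail). Directional trends (ORF extension;
   Kozak appearance) use one-sided exact binomial tests; "no change"
   loci are not trials; the null probability is derived from the
   intergenic tallies with a Haldane-style ½ pseudo-count,
   p₀ = (bg_extend + ½)/(bg_extend + bg_shrink + 1), so it is defined
   even when a background tally is zero. Binomial tails are computed as
   exact rationals (`fractions.Fraction`), not floating-point
   approximations. Raw p-values are reported with an additional
   Bonferroni-adjusted column. The intergenic background is evaluated on
   both edges (A1→cerevisiae and A2→A1) so every class has a matched
   background.

The **scenario report** orders four stages — GC-rich origin → neutral
mutation → ORF extension/combination → Kozak recruitment — each citing
its statistics. Support rules (α = 0.01 by default): stage 1, every
class significantly GC-richer than background at A1; stage 2, fewer than
20% of the mutation-frequency tests significant (the analysis this
reproduces saw exactly one exception); stage 3, at least one class with
a significant extension trend; stage 4, *no* significant
Kozak-appearance trend on the birth edge (recruitment comes later).

## The synthetic-data generator

`simulate_catalogue` produces per-species genomes, a catalogue, and a
complete `TruthLog` (true sequences at every node; every mutation event,
with injected edits flagged; replaying an edge's events reproduces the
child exactly). Its defaults are the study conditions:

- **Tree**: `((cerevisiae:0.08,paradoxus:0.08)A1:0.035,mikatae:0.15)A2`,
  giving per-branch substitution frequencies of a few percent, the
  regime of the catalogued divergences. Recovery-style experiments use a
  short-branch variant (all branches ≤ 0.1).
- **Composition**: per-class root GC 0.34/0.38/0.37 (S0+/S1/S2) vs 0.30
  (intergenic), with per-locus spread (SD 0.05–0.09 by class) because
  the real classes are compositionally heterogeneous (per-class GC SDs
  of 0.055–0.105). Each locus evolves at its *own* compositional
  equilibrium (isochore-style) by default: under a single global
  equilibrium the GC-rich classes decay toward it and class-vs-background
  mutation comparisons reject neutrality for purely compositional
  reasons. A global `gc_equilibrium` can still be set.
- **Process**: HKY (κ = 2.0) normalised to one expected substitution per
  site per unit branch length, sampled per site from P(t) (multiple hits
  collapse); indels Poisson(t × 0.3 × L) with geometric lengths
  (mean 2 nt), insertions and deletions equally likely, inserted bases
  at stationary composition.
- **Structure**: each locus is left flank + core + right flank (defaults
  150/300/150 nt), segments evolved independently (indels never span a
  boundary — an accepted simplification); genomes are the loci joined by
  inert 200 nt AT-repeat spacers that prevent spurious cross-locus hits.
- **Birth operations**, injected on the class's birth edge and logged:
  `stop_removal` knocks out the terminating stop of the most upstream
  ATG's ORF (one near-neutral edit); `orf_fusion` iterates that removal
  over every downstream in-frame stop, the annotated-gene regime where
  the born ORF absorbs most of its locus; `kozak_creation` writes A at
  −3 (and C at +4 for the long pattern) of the most upstream eligible
  ATG. Default timing is 1.0 — the edit completes at the child node,
  where the catalogue asserts the gene exists; the neutral process does
  not model post-birth purifying selection, so earlier times let
  subsequent drift erode the edit (useful deliberately, e.g. to
  synthesise extend-now/Kozak-later orderings). Class defaults:
  S0+ stop_removal, S1 orf_fusion, S2 stop_removal (on A2→A1),
  intergenes none.
- **Determinism**: one `numpy.random.Generator`, fixed call order; a
  fixed seed gives byte-identical FASTA/TSV/JSON outputs.

### What the generator does and does not emulate

It reproduces the compositional contrast between de novo loci and
background, branch-scale divergences split into the printed mutation
classes, indel activity, missing orthologs at larger distances, and
birth events with the extend ≫ shrink asymmetry. It does **not**
reproduce: locus-length heterogeneity (uniform 300 nt cores vs real
60–3000 nt ORFs), so per-locus frequency dispersions are several-fold
smaller than the catalogue's — class-vs-background Welch tests on
synthetic data can therefore resolve small compositional rate
differences (AT>AT, GC>GC) that real data cannot, and the "neutral
mutation" stage may read unsupported on simulations even though the
simulated process is neutral by construction; selection after birth;
transcription-level evidence; recombination. Passing recovery tests
shows the pipeline's inference machinery is correct under its own model,
not that real catalogues satisfy the model.

## Numerical and convention choices

- Coordinates are 1-based inclusive everywhere user-facing; 0-based
  half-open only at string-slicing boundaries.
- Gap cost convention: a run of length k costs open + k·extend
  (open −12, extend −4); all aligners and test oracles share it.
- Alignment tie-breaks are deterministic: leftmost target end, then
  aligned-state preference, so re-runs are byte-identical.
- ORF length includes the stop codon; applied uniformly, so
  Extend/Shrink classifications are convention-invariant.
- Posterior ties at reconstruction argmax resolve in A,C,G,T order
  (first maximum); posterior rows are normalised and checked to 1e-9.
- Welch with zero pooled variance returns t = 0, p = 1 (identical
  groups), rather than dividing by zero.
- Binomial p₀ is kept rational end-to-end; tails are exact for any n
  used here (the tests check n ≤ 200 against 50-digit arithmetic).
- `SummaryStats` requires n ≥ 2 and uses the sample SD (ddof = 1).

## Problem sizes

Desk-scale runs used by the test suite and `scripts/acceptance.py`:
parameter recovery uses 500 intergenic loci of 300 nt (flank 150) on the
short-branch tree; the scenario-order experiment uses 150 S1-like loci
(default birth ops) plus 400 intergenic background loci. These sizes
give stable pooled statistics (binomial SEs of a few percent) while a
full run stays in minutes on one CPU. The published-summary Welch bounds
are computed directly from the printed (n, mean, SD) tables and are
instantaneous.

## Known limitations

- The glocal search screen assumes the best affine-score window is near
  the best edit-distance window; adversarial compositions could in
  principle differ (the exhaustive mode exists for that).
- Marginal (not joint) reconstruction; no rate heterogeneity across
  sites; no model selection.
- The ancestral ORF mapper requires at least one in-phase aligned
  column; a completely frame-shifted ancestor maps to nothing and the
  locus is tallied as "no ancestral ORF".
- Intergenic "ORF" backgrounds inherit a selection artifact — the recent
  ORF is chosen as the best match to the catalogued interval, so its
  ancestral counterpart regresses toward shorter lengths, inflating the
  background extension probability; the background-derived p₀ absorbs
  this by design (which is exactly why the trend tests use it).
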