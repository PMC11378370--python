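"""Published summary statistics for the S. cerevisiae de novo gene catalogue.

These are the printed per-group GC-content summaries (number of
sequences, mean %GC as a fraction, sample SD) for the extant cerevisiae
genome and for the reconstructed ancestral genomes at A1 and A2.  They
serve as inputs for summary-level Welch's t-tests against the intergenic
background, reproducing the reported significance bounds without access
to the original genomes.
"""

from __future__ import annotations

from .stats import SummaryStats, WelchResult, welch_test

#: extant cerevisiae genome: de novo classes, annotated ORFs, intergenes
EXTANT_GC = {
    "S0+": SummaryStats(n=448, ave=0.373, sd=0.105),
    "S1": SummaryStats(n=142, ave=0.407, sd=0.071),
    "S2": SummaryStats(n=172, ave=0.389, sd=0.077),
    "S3": SummaryStats(n=136, ave=0.402, sd=0.071),
    "S4": SummaryStats(n=301, ave=0.400, sd=0.071),
    "annotated": SummaryStats(n=6459, ave=0.393, sd=0.071),
    "intergene": SummaryStats(n=6006, ave=0.333, sd=0.055),
}

#: ancestral genome at A1 (S0+/S1 are non-genic at this node)
ANCESTRAL_GC_A1 = {
    "S0+": SummaryStats(n=274, ave=0.333, sd=0.084),
    "S1": SummaryStats(n=115, ave=0.383, sd=0.055),
    "S2": SummaryStats(n=144, ave=0.377, sd=0.089),
    "intergene": SummaryStats(n=5283, ave=0.309, sd=0.055),
}

#: ancestral genome at A2 (all de novo classes are non-genic at this node)
ANCESTRAL_GC_A2 = {
    "S0+": SummaryStats(n=259, ave=0.337, sd=0.089),
    "S1": SummaryStats(n=112, ave=0.381, sd=0.055),
    "S2": SummaryStats(n=142, ave=0.368, sd=0.071),
    "intergene": SummaryStats(n=5304, ave=0.299, sd=0.063),
}


def gc_welch_vs_intergene(
    table: dict[str, SummaryStats], normal_approx: bool = False
) -> dict[str, WelchResult]:
    """Welch's t-test of every non-intergene group against the intergenic
    background of the same table."""
    background = table["intergene"]
    return {
        group: welch_test(summary, background, normal_approx=normal_approx)
        for group, summary in table.items()
        if group != "intergene"
    }
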