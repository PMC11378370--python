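"""Scenario statistics: Welch's t-tests and exact binomial trend tests.

GC content and mutation frequencies are compared between each de novo
gene class and the intergenic background by Welch's two-sample t-test
(unequal variances, Welch-Satterthwaite degrees of freedom), computable
from raw values or from published (n, mean, SD) summaries.  Directional
trends in ORF length change and Kozak-signature turnover are tested with
one-sided exact binomial tests whose background probability comes from
the intergenic tallies with a Haldane-style half pseudo-count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import comb

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class SummaryStats:
    """Sample size, mean and sample standard deviation of one group."""

    n: int
    ave: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"need n >= 2, got {self.n}")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    @classmethod
    def from_values(cls, values) -> "SummaryStats":
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            raise ValueError(f"need at least 2 values, got {arr.size}")
        return cls(n=int(arr.size), ave=float(arr.mean()), sd=float(arr.std(ddof=1)))


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class TrendResult:
    k: int  # successes (extensions / appearances)
    n: int  # trials
    p0: float  # background success probability
    p: float  # one-sided (or two-sided if requested) p-value
    two_sided: bool = False


def _as_summary(x) -> SummaryStats:
    return x if isinstance(x, SummaryStats) else SummaryStats.from_values(x)


def welch_test(a, b, normal_approx: bool = False) -> WelchResult:
    """Two-sided Welch's t-test from summaries or raw values.

    t = (m_a - m_b) / sqrt(s_a^2/n_a + s_b^2/n_b) with
    Welch-Satterthwaite degrees of freedom; ``normal_approx`` replaces
    the t distribution by the standard normal tail.
    """
    a = _as_summary(a)
    b = _as_summary(b)
    va = a.sd * a.sd / a.n
    vb = b.sd * b.sd / b.n
    se = np.sqrt(va + vb)
    if se == 0.0:
        return WelchResult(t=0.0, df=float(a.n + b.n - 2), p=1.0)
    t = (a.ave - b.ave) / se
    df = (va + vb) ** 2 / (va * va / (a.n - 1) + vb * vb / (b.n - 1))
    if normal_approx:
        p = 2.0 * float(sps.norm.sf(abs(t)))
    else:
        p = 2.0 * float(sps.t.sf(abs(t), df))
    return WelchResult(t=float(t), df=float(df), p=min(p, 1.0))


def exact_binom_tail(k: int, n: int, p0: Fraction) -> Fraction:
    """P(X >= k) for X ~ Binomial(n, p0), by exact rational summation."""
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    q0 = 1 - p0
    return sum(
        (Fraction(comb(n, i)) * p0**i * q0 ** (n - i) for i in range(k, n + 1)),
        Fraction(0),
    )


def background_probability(bg_success: int, bg_failure: int) -> Fraction:
    """Background probability with a half pseudo-count on each side, so
    the test is defined even when one tally is zero."""
    if bg_success < 0 or bg_failure < 0:
        raise ValueError("background tallies must be >= 0")
    return Fraction(2 * bg_success + 1, 2 * (bg_success + bg_failure + 1))


def binomial_trend_test(
    k_success: int,
    k_failure: int,
    background: tuple[int, int] | None = None,
    p0: float | Fraction | None = None,
    two_sided: bool = False,
) -> TrendResult:
    """Exact binomial test for a directional trend.

    Successes are the favoured direction (ORF extensions, Kozak
    appearances), failures the opposite one; "no change" loci are not
    trials.  The null probability ``p0`` is either given directly or
    derived from the background (intergenic) tallies.
    """
    if k_success < 0 or k_failure < 0:
        raise ValueError("counts must be >= 0")
    n = k_success + k_failure
    if n == 0:
        raise ValueError("no trials: k_success + k_failure must be >= 1")
    if p0 is None:
        if background is None:
            raise ValueError("either background tallies or p0 is required")
        p0 = background_probability(*background)
    p0 = Fraction(p0)
    if not 0 < p0 < 1:
        raise ValueError(f"p0 must be in (0, 1), got {float(p0)}")
    tail = exact_binom_tail(k_success, n, p0)
    if two_sided:
        lower = 1 - exact_binom_tail(k_success + 1, n, p0)
        p = min(1, 2 * min(tail, lower))
    else:
        p = tail
    return TrendResult(
        k=k_success, n=n, p0=float(p0), p=float(p), two_sided=two_sided
    )


def kozak_trend_test(
    k_appear: int,
    k_disappear: int,
    background: tuple[int, int] | None = None,
    p0: float | Fraction | None = None,
    two_sided: bool = False,
) -> TrendResult:
    """Binomial trend test for Kozak-signature turnover (Appear is the
    success direction, Disappear the failure)."""
    return binomial_trend_test(
        k_appear, k_disappear, background=background, p0=p0, two_sided=two_sided
    )


# ---------------------------------------------------------------------------
# scenario report


class IncompleteInputError(ValueError):
    """Raised when a scenario stage has no supporting analysis."""


#: fixed stage order of the birth scenario
SCENARIO_STAGES = (
    "gc_rich_origin",
    "neutral_mutation",
    "orf_extension",
    "kozak_recruitment",
)


@dataclass
class ScenarioReport:
    """Ordered four-stage account of de novo gene birth with evidence.

    Stages: (1) loci start in GC-rich regions, (2) mutations on the birth
    edge look neutral (match the intergenic background), (3) the edge
    shows a significant ORF extension trend, (4) the Kozak signature is
    not yet recruited on that edge (its enrichment comes later).
    """

    stages: list[dict] = field(default_factory=list)
    alpha: float = 0.01

    def supported(self) -> bool:
        return all(stage["supported"] for stage in self.stages)

    def to_dict(self) -> dict:
        return {"alpha": self.alpha, "stages": self.stages}


def build_report(
    gc_tests: dict[str, WelchResult],
    gc_direction: dict[str, float],
    mutation_tests: dict[str, dict[str, WelchResult]],
    orf_trends: dict[str, TrendResult],
    kozak_trends: dict[str, TrendResult],
    alpha: float = 0.01,
) -> ScenarioReport:
    """Assemble the four-stage scenario report from pooled test results.

    ``gc_tests``: per class, ancestral GC vs intergenic background;
    ``gc_direction``: per class, mean GC difference (class - intergene);
    ``mutation_tests``: per class, per mutation class, frequency vs
    background; ``orf_trends`` / ``kozak_trends``: per class, directional
    binomial tests.  Stage support: (1) every class significantly GC-richer
    than background, (2) mutation tests overwhelmingly non-significant
    (< 20% of tests below alpha), (3) at least one class with a
    significant extension trend, (4) no significant Kozak-appearance
    trend on the birth edge.
    """
    for name, obj in (
        ("gc_tests", gc_tests),
        ("mutation_tests", mutation_tests),
        ("orf_trends", orf_trends),
        ("kozak_trends", kozak_trends),
    ):
        if not obj:
            raise IncompleteInputError(f"missing analysis: {name}")

    gc_ok = all(
        res.p <= alpha and gc_direction.get(cls, 0.0) > 0
        for cls, res in gc_tests.items()
    )
    flat_mut = [res for by_cls in mutation_tests.values() for res in by_cls.values()]
    sig_frac = sum(res.p <= alpha for res in flat_mut) / len(flat_mut)
    orf_ok = any(res.p <= alpha for res in orf_trends.values())
    kozak_ok = all(res.p > alpha for res in kozak_trends.values())

    stages = [
        {
            "stage": "gc_rich_origin",
            "supported": bool(gc_ok),
            "tests": {cls: vars(res) for cls, res in gc_tests.items()},
        },
        {
            "stage": "neutral_mutation",
            "supported": bool(sig_frac < 0.20),
            "significant_fraction": sig_frac,
            "tests": {
                cls: {m: vars(r) for m, r in by_cls.items()}
                for cls, by_cls in mutation_tests.items()
            },
        },
        {
            "stage": "orf_extension",
            "supported": bool(orf_ok),
            "tests": {cls: vars(res) for cls, res in orf_trends.items()},
        },
        {
            "stage": "kozak_recruitment",
            "supported": bool(kozak_ok),
            "tests": {cls: vars(res) for cls, res in kozak_trends.items()},
        },
    ]
    return ScenarioReport(stages=stages, alpha=alpha)


def bonferroni(p: float, m: int) -> float:
    return min(1.0, p * m)
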