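"""Independent brute-force oracles used by the test suite.

These deliberately avoid the dynamic-programming / pruning structure of
the implementations they check: alignments are scored by exhaustive
enumeration of move sequences, ancestral posteriors by explicit summation
over all internal state assignments, and p-values by arbitrary-precision
arithmetic.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np

BASES = "ACGT"


# ---------------------------------------------------------------------------
# alignment scoring by path enumeration


def _score_path(query, target_sub, moves, sc):
    """Score one alignment (move sequence) of query vs a target substring.

    Moves: 'D' consumes both, 'Q' consumes query only (gap in target row),
    'T' consumes target only (gap in query row).  A maximal gap run of
    length k costs gap_open + k * gap_extend.
    """
    qi = ti = 0
    score = 0.0
    prev = None
    for m in moves:
        if m == "D":
            score += sc.match if query[qi] == target_sub[ti] else sc.mismatch
            qi += 1
            ti += 1
        else:
            if m != prev:
                score += sc.gap_open
            score += sc.gap_extend
            if m == "Q":
                qi += 1
            else:
                ti += 1
        prev = m
    return score


def _enumerate_paths(nq, nt):
    """All monotone alignment paths consuming nq query and nt target chars."""
    if nq == 0 and nt == 0:
        yield ""
        return
    if nq > 0:
        for rest in _enumerate_paths(nq - 1, nt):
            yield "Q" + rest
    if nt > 0:
        for rest in _enumerate_paths(nq, nt - 1):
            yield "T" + rest
    if nq > 0 and nt > 0:
        for rest in _enumerate_paths(nq - 1, nt - 1):
            yield "D" + rest


def brute_global_score(query: str, target: str, sc) -> float:
    """Optimal global affine-gap alignment score by full enumeration."""
    best = -np.inf
    for moves in _enumerate_paths(len(query), len(target)):
        best = max(best, _score_path(query, target, moves, sc))
    return best


def brute_glocal_score(query: str, target: str, sc) -> float:
    """Optimal query-global/target-local score: best global alignment of
    the query against any (possibly empty) substring of the target."""
    best = -np.inf
    for a in range(len(target) + 1):
        for b in range(a, len(target) + 1):
            best = max(best, brute_global_score(query, target[a:b], sc))
    return best


# ---------------------------------------------------------------------------
# ancestral posteriors by explicit state summation (3-tip rooted tree
# with topology ((tip0, tip1) inner, tip2) root)


def brute_two_node_posteriors(tip_codes, t_tips, t_inner, model):
    """Posteriors at the inner node and root for one alignment column.

    tip_codes: base indices of the three tips (0..3, or None = missing);
    t_tips: branch lengths of tip0, tip1 (children of inner) and tip2
    (child of root); t_inner: branch length inner->root.
    Returns (posterior_inner[4], posterior_root[4]).
    """
    p0 = model.transition_matrix(t_tips[0])
    p1 = model.transition_matrix(t_tips[1])
    p2 = model.transition_matrix(t_tips[2])
    pin = model.transition_matrix(t_inner)
    pi = model.base_frequencies

    def leaf_term(pmat, state, code):
        return 1.0 if code is None else pmat[state, code]

    joint = np.zeros((4, 4))  # joint[inner, root]
    for inner in range(4):
        for root in range(4):
            joint[inner, root] = (
                pi[root]
                * pin[root, inner]
                * leaf_term(p0, inner, tip_codes[0])
                * leaf_term(p1, inner, tip_codes[1])
                * leaf_term(p2, root, tip_codes[2])
            )
    total = joint.sum()
    return joint.sum(axis=1) / total, joint.sum(axis=0) / total


# ---------------------------------------------------------------------------
# arbitrary-precision statistics


def mpmath_welch_p(n1, m1, s1, n2, m2, s2):
    """Two-sided Welch p-value at high precision (regularised beta tail)."""
    import mpmath as mp

    mp.mp.dps = 50
    v1 = mp.mpf(s1) ** 2 / n1
    v2 = mp.mpf(s2) ** 2 / n2
    t = (mp.mpf(m1) - mp.mpf(m2)) / mp.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    x = df / (df + t**2)
    p = mp.betainc(df / 2, mp.mpf(1) / 2, 0, x, regularized=True)
    return float(t), float(df), float(p)


def mpmath_binom_tail(k, n, p0):
    """P(X >= k), X ~ Binomial(n, p0), summed at 50-digit precision."""
    import mpmath as mp

    mp.mp.dps = 50
    p = mp.mpf(p0)
    total = mp.mpf(0)
    for i in range(k, n + 1):
        total += mp.binomial(n, i) * p**i * (1 - p) ** (n - i)
    return float(total)


def exact_fraction_tail(k, n, p0: Fraction) -> Fraction:
    from math import comb

    return sum(
        (Fraction(comb(n, i)) * p0**i * (1 - p0) ** (n - i) for i in range(k, n + 1)),
        Fraction(0),
    )
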