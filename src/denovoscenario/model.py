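"""HKY85 nucleotide substitution model.

The pipeline needs a concrete reversible model in two places: the neutral
sequence simulator and the marginal ancestral reconstruction.  HKY is the
smallest model that separates transitions from transversions (kappa) and
lets the stationary composition differ from uniform (so AT>GC vs GC>AT
pressure can be emulated), which is exactly the granularity of the mutation
classes this analysis tallies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

# base order everywhere: A, C, G, T
TRANSITION_PARTNER = {0: 2, 2: 0, 1: 3, 3: 1}  # A<->G, C<->T


def frequencies_from_gc(gc: float) -> np.ndarray:
    """Stationary frequencies with the given G+C fraction, strand-symmetric."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"gc must be in [0, 1], got {gc}")
    at = (1.0 - gc) / 2.0
    return np.array([at, gc / 2.0, gc / 2.0, at])


@dataclass(frozen=True)
class SubstitutionModel:
    """HKY85 model: transition/transversion ratio and stationary frequencies.

    Parameters
    ----------
    kappa
        Transition/transversion rate ratio (> 0); 1.0 collapses to F81/JC.
    base_frequencies
        Stationary frequencies in A, C, G, T order, summing to 1.
    """

    kappa: float = 2.0
    base_frequencies: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        freqs = np.asarray(self.base_frequencies, dtype=float)
        if freqs.shape != (4,) or np.any(freqs < 0) or abs(freqs.sum() - 1) > 1e-9:
            raise ValueError("base_frequencies must be 4 nonnegative values summing to 1")
        if not self.kappa > 0:
            raise ValueError(f"kappa must be > 0, got {self.kappa}")
        object.__setattr__(self, "base_frequencies", freqs)

    @classmethod
    def from_gc(cls, gc: float, kappa: float = 2.0) -> "SubstitutionModel":
        return cls(kappa=kappa, base_frequencies=frequencies_from_gc(gc))

    def rate_matrix(self) -> np.ndarray:
        """Rate matrix normalised to one expected substitution per unit time."""
        pi = self.base_frequencies
        q = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                rate = pi[j]
                if TRANSITION_PARTNER[i] == j:
                    rate *= self.kappa
                q[i, j] = rate
        np.fill_diagonal(q, -q.sum(axis=1))
        scale = -(pi * np.diag(q)).sum()
        return q / scale

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t): probability of observing base j after branch length t given i."""
        if t < 0:
            raise ValueError(f"branch length must be >= 0, got {t}")
        return expm(self.rate_matrix() * t)
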