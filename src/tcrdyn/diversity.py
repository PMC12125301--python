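"""Repertoire diversity and clonality statistics.

Shannon entropy H(P) = -sum_i p_i log2 p_i over clone frequencies (bits):
maximal for a perfectly even repertoire, decreasing as clonal expansion
concentrates cells into few clones. The Gini index of the clone-size vector
measures the same inequality on a 0 (all clones equal) to ->1 (one clone
dominates) scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import entropy as _scipy_entropy

from tcrdyn.clonotype import CloneTable


@dataclass(frozen=True)
class DiversityProfile:
    sample_id: str
    n_clones: int
    shannon_bits: float
    gini: float


def shannon_from_counts(counts, base: float = 2.0) -> float:
    """Shannon entropy of a vector of clone sizes (counts or frequencies)."""
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("empty clone-size vector")
    if np.any(counts <= 0):
        raise ValueError("clone sizes must be positive")
    return float(_scipy_entropy(counts, base=base))


def shannon_entropy(table: CloneTable, base: float = 2.0) -> float:
    """Shannon entropy (bits by default) of a sample's clone frequencies."""
    return shannon_from_counts(table.sizes(), base=base)


def gini_from_sizes(sizes, corrected: bool = False) -> float:
    """Gini index of a clone-size vector.

    Population (uncorrected) mean-absolute-difference form,
    G = sum_ij |x_i - x_j| / (2 N^2 mean(x)), computed via the O(N log N)
    sorted identity. ``corrected=True`` applies the small-sample N/(N-1)
    factor.
    """
    x = np.sort(np.asarray(sizes, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("empty clone-size vector")
    if np.any(x < 0):
        raise ValueError("clone sizes must be non-negative")
    total = x.sum()
    if total == 0:
        raise ValueError("clone sizes sum to zero")
    if n == 1:
        return 0.0
    i = np.arange(1, n + 1)
    g = (2.0 * np.sum(i * x)) / (n * total) - (n + 1) / n
    if corrected:
        g *= n / (n - 1)
    return float(g)


def gini_index(table: CloneTable, corrected: bool = False) -> float:
    """Gini index of a sample's clone sizes (distinct clonotypes only)."""
    return gini_from_sizes(table.sizes(), corrected=corrected)


def diversity_profile(table: CloneTable) -> DiversityProfile:
    return DiversityProfile(
        sample_id=table.sample_id,
        n_clones=table.n_clones,
        shannon_bits=shannon_entropy(table),
        gini=gini_index(table),
    )
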