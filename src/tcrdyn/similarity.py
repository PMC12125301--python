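"""TCR sequence similarity within and between clone sets.

The per-pair metric is normalized Levenshtein similarity on CDR3 amino-acid
sequences, 1 - d(a, b) / max(|a|, |b|): 1 for identical sequences, 0 when
every position differs. Cross-set similarity summarizes, for each clone in
set A, its best match in set B (nearest-neighbor overlap), e.g. between
pre-existing clones at baseline and clones newly arising after treatment.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib


@dataclass(frozen=True)
class SimilaritySummary:
    set_a_label: str
    set_b_label: str
    n_pairs: int
    mean_max_similarity: float
    per_clone_max: tuple[float, ...]


def cdr3_similarity(a: str, b: str, metric: str = "levenshtein") -> float:
    """Normalized similarity between two CDR3 sequences, in [0, 1].

    ``levenshtein`` (default): 1 - edit_distance/max(len); symmetric, 1 iff
    identical. ``hamming``: positional mismatch similarity for equal-length
    pairs; length-discordant pairs score 0.
    """
    if not a or not b:
        raise ValueError("CDR3 sequences must be non-empty")
    if metric == "levenshtein":
        d = edlib.align(a, b, task="distance")["editDistance"]
        return 1.0 - d / max(len(a), len(b))
    if metric == "hamming":
        if len(a) != len(b):
            return 0.0
        mismatches = sum(1 for x, y in zip(a, b) if x != y)
        return 1.0 - mismatches / len(a)
    raise ValueError(f"unknown metric {metric!r}")


def cross_set_similarity(
    set_a: list[str],
    set_b: list[str],
    exclude_identical: bool = False,
    labels: tuple[str, str] = ("A", "B"),
    metric: str = "levenshtein",
) -> SimilaritySummary:
    """Nearest-neighbor similarity of each clone in set A against set B.

    For each CDR3 in ``set_a`` the maximum similarity over ``set_b`` is taken
    (skipping sequence-identical entries when ``exclude_identical`` — used for
    within-set comparisons, where the trivial self-match would dominate). The
    summary is the mean of the per-clone maxima. Similarity depends only on
    sequence content, not clone order or clone sizes.
    """
    if not set_a or not set_b:
        raise ValueError("both clone sets must be non-empty")
    per_max: list[float] = []
    for a in set_a:
        candidates = [b for b in set_b if not (exclude_identical and b == a)]
        if not candidates:
            raise ValueError(
                f"clone {a!r} has no comparison partners after exclusions"
            )
        per_max.append(max(cdr3_similarity(a, b, metric=metric) for b in candidates))
    return SimilaritySummary(
        set_a_label=labels[0],
        set_b_label=labels[1],
        n_pairs=len(set_a) * len(set_b),
        mean_max_similarity=sum(per_max) / len(per_max),
        per_clone_max=tuple(per_max),
    )
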