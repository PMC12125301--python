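"""Per-sample clone tables, clone frequencies, and clonal-expansion classes.

A clonotype observed in >2 cells is "expanded"; in >=10 cells "highly
expanded"; 1-2 cells "not expanded". The thresholds are parameters so that
cut-off sensitivity sweeps are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tcrdyn.contig_io import CellClonotype

EXPANSION_LABELS = ("not_expanded", "expanded", "highly_expanded")


@dataclass
class CloneTable:
    """Per-sample clonotype -> cell count mapping.

    ``meta`` carries a representative CDR3beta amino-acid sequence per
    clonotype for downstream similarity analyses. ``key_level`` records the
    CDR3 level ('nt' or 'aa') the keys were built at; paired-sample matching
    refuses to mix levels.
    """

    sample_id: str
    counts: dict[str, int]
    key_level: str = "nt"
    meta: dict[str, str] = field(default_factory=dict)

    @property
    def total_cells(self) -> int:
        return sum(self.counts.values())

    @property
    def n_clones(self) -> int:
        return len(self.counts)

    def frequency(self, key: str) -> float:
        return self.counts.get(key, 0) / self.total_cells

    def frequencies(self) -> dict[str, float]:
        total = self.total_cells
        return {k: c / total for k, c in self.counts.items()}

    def sizes(self) -> np.ndarray:
        """Clone-size vector (cell counts of distinct clonotypes)."""
        return np.asarray(list(self.counts.values()), dtype=float)


def build_clone_table(
    cells: list[CellClonotype],
    sample_id: str,
    key_level: str = "nt",
) -> CloneTable:
    """Aggregate per-cell clonotype calls into a clone table.

    Raises
    ------
    ValueError
        If ``cells`` is empty (a sample with zero T cells is unusable).
    """
    if not cells:
        raise ValueError(f"sample {sample_id!r} has no cells with a clonotype")
    counts: dict[str, int] = {}
    meta: dict[str, str] = {}
    for cell in cells:
        counts[cell.clonotype_key] = counts.get(cell.clonotype_key, 0) + 1
        if cell.clonotype_key not in meta and cell.cdr3b_aa:
            meta[cell.clonotype_key] = cell.cdr3b_aa
    return CloneTable(sample_id=sample_id, counts=counts, key_level=key_level, meta=meta)


def classify_expansion(count: int, expanded_min: int = 3, highly_min: int = 10) -> str:
    """Expansion class of a clone of ``count`` cells.

    1-2 cells -> not_expanded; >=expanded_min (default >2) -> expanded;
    >=highly_min (default 10) -> highly_expanded (which implies expanded for
    fraction computations).
    """
    if count < 1:
        raise ValueError(f"clone count must be positive, got {count}")
    if count >= highly_min:
        return "highly_expanded"
    if count >= expanded_min:
        return "expanded"
    return "not_expanded"


def expanded_cell_fraction(table: CloneTable, expanded_min: int = 3) -> float:
    """Fraction of a sample's T cells sitting in expanded clones.

    Sum of cell counts over clones with ``count >= expanded_min``, divided by
    total cells. Monotonically non-increasing in ``expanded_min``.
    """
    expanded = sum(c for c in table.counts.values() if c >= expanded_min)
    return expanded / table.total_cells


def clone_table_frame(
    table: CloneTable, expanded_min: int = 3, highly_min: int = 10
) -> pd.DataFrame:
    """Tabular view of a clone table (one row per clonotype), sorted by size."""
    total = table.total_cells
    rows = [
        {
            "sample_id": table.sample_id,
            "clonotype_key": k,
            "cell_count": c,
            "frequency": c / total,
            "expansion_class": classify_expansion(c, expanded_min, highly_min),
        }
        for k, c in sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows)
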