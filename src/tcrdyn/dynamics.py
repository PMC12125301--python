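"""Paired pre/post clone matching and clonal-dynamics classification.

Clones are matched across a patient's pre- and post-treatment samples by
clonotype key. Pre-existing clones (seen at both timepoints) are classified by
frequency fold change into increased (>2-fold, treatment-resistant),
unchanged (0.5-2-fold, treatment-insensitive), and decreased (<0.5-fold,
treatment-sensitive), after filtering to clones with at least 20 cells so the
classes are backed by enough cells. A statistical alternative uses a
two-sided conditional exact (hypergeometric) test on the 2x2 clone-vs-rest by
pre-vs-post table. Clones seen only post-treatment are "new"; only
pre-treatment, "disappeared".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from scipy.stats import fisher_exact

from tcrdyn._stats import CorrelationResult, pearson_ols
from tcrdyn.clonotype import CloneTable

log = logging.getLogger(__name__)

DYNAMICS_LABELS = (
    "increased",
    "unchanged",
    "decreased",
    "new",
    "disappeared",
    "not_evaluable",
)


@dataclass
class CloneDynamics:
    """One clone's paired pre/post observation for one patient."""

    patient_id: str
    clonotype_key: str
    pre_count: int
    post_count: int
    pre_freq: float
    post_freq: float
    fold_change: float | None  # post_freq / pre_freq; None unless both counts > 0
    origin: str  # "pre_existing" or "new"
    dynamics_class: str | None = None
    cdr3b_aa: str = ""


@dataclass
class PatientCloneSummary:
    """Per-patient roll-up of clonal dynamics.

    ``total_clone_size_change`` is the change in summed expanded-clone
    frequency (post minus pre); its sign assigns the patient to the
    increased/decreased group. ``new_clone_size`` is the summed post-treatment
    frequency of clones absent at baseline.
    """

    patient_id: str
    total_clone_size_change: float
    group: str  # "increased" or "decreased"
    new_clone_size: float
    pre_existing_size_pre: float
    pre_existing_size_post: float
    evaluable: bool = True


def match_clones(
    pre: CloneTable, post: CloneTable, patient_id: str = ""
) -> list[CloneDynamics]:
    """Match clones between a patient's pre- and post-treatment clone tables.

    Returns one :class:`CloneDynamics` per clonotype in the union of the two
    repertoires, in sorted key order. Fold change is computed on frequencies
    (depth-normalized) and present only when the clone is seen at both
    timepoints.

    Raises
    ------
    ValueError
        If the two tables were built at different clonotype key levels.
    """
    if pre.key_level != post.key_level:
        raise ValueError(
            f"key-level mismatch: pre={pre.key_level!r} post={post.key_level!r}"
        )
    pre_total, post_total = pre.total_cells, post.total_cells
    out: list[CloneDynamics] = []
    for key in sorted(set(pre.counts) | set(post.counts)):
        pc = pre.counts.get(key, 0)
        qc = post.counts.get(key, 0)
        pf = pc / pre_total
        qf = qc / post_total
        fold = (qf / pf) if (pc > 0 and qc > 0) else None
        if pc == 0:
            origin, cls = "new", "new"
        elif qc == 0:
            origin, cls = "pre_existing", "disappeared"
        else:
            origin, cls = "pre_existing", None
        out.append(
            CloneDynamics(
                patient_id=patient_id,
                clonotype_key=key,
                pre_count=pc,
                post_count=qc,
                pre_freq=pf,
                post_freq=qf,
                fold_change=fold,
                origin=origin,
                dynamics_class=cls,
                cdr3b_aa=pre.meta.get(key, "") or post.meta.get(key, ""),
            )
        )
    return out


def _passes_filter(d: CloneDynamics, min_cells: int) -> bool:
    # the size filter uses the larger timepoint so clones that collapse
    # post-treatment stay evaluable
    return max(d.pre_count, d.post_count) >= min_cells


def classify_dynamics_foldchange(
    d: CloneDynamics,
    min_cells: int = 20,
    up: float = 2.0,
    down: float = 0.5,
) -> str:
    """Fold-change dynamics class of a matched clone.

    Pre-existing clones seen at both timepoints and passing the size filter
    (``max(pre, post) >= min_cells``) are classed increased (fold > up),
    decreased (fold < down) or unchanged (down <= fold <= up; both boundaries
    belong to unchanged). Filtered-out clones are marked ``not_evaluable``,
    never dropped. New/disappeared clones keep those labels.
    """
    if d.origin == "new":
        label = "new"
    elif d.post_count == 0:
        label = "disappeared"
    elif not _passes_filter(d, min_cells):
        label = "not_evaluable"
    else:
        assert d.fold_change is not None
        if d.fold_change > up:
            label = "increased"
        elif d.fold_change < down:
            label = "decreased"
        else:
            label = "unchanged"
    d.dynamics_class = label
    return label


def exact_test_pvalue(
    pre_count: int, post_count: int, pre_total: int, post_total: int
) -> float:
    """Two-sided conditional exact p for one clone's 2x2 pre/post table."""
    table = [
        [pre_count, post_count],
        [pre_total - pre_count, post_total - post_count],
    ]
    _, p = fisher_exact(table, alternative="two-sided")
    return float(p)


def classify_dynamics_exact_test(
    d: CloneDynamics,
    pre_total: int,
    post_total: int,
    alpha: float = 0.05,
    lfc: float = 1.0,
    min_cells: int = 20,
) -> str:
    """Statistical dynamics class via a two-sided conditional exact test.

    Tests the 2x2 table [clone cells vs other cells] x [pre vs post] with the
    conditional (hypergeometric) exact test; the clone is increased when
    p < alpha and log2 frequency fold change > lfc, decreased when p < alpha
    and log2 fold change < -lfc, unchanged otherwise. P-values are raw (one
    clone at a time, no multiplicity correction).
    """
    if d.pre_count > pre_total or d.post_count > post_total:
        raise ValueError("clone counts exceed sample totals")
    if d.origin == "new":
        label = "new"
    elif d.post_count == 0:
        label = "disappeared"
    elif not _passes_filter(d, min_cells):
        label = "not_evaluable"
    else:
        p = exact_test_pvalue(d.pre_count, d.post_count, pre_total, post_total)
        log2fc = math.log2((d.post_count / post_total) / (d.pre_count / pre_total))
        if p < alpha and log2fc > lfc:
            label = "increased"
        elif p < alpha and log2fc < -lfc:
            label = "decreased"
        else:
            label = "unchanged"
    d.dynamics_class = label
    return label


def post_frequency_partition(dyn: list[CloneDynamics]) -> tuple[float, float]:
    """Summed post-treatment frequency of (new, pre-existing) clones.

    For a complete matched list these partition the post repertoire: they sum
    to 1.
    """
    new = sum(d.post_freq for d in dyn if d.origin == "new")
    pre_existing = sum(d.post_freq for d in dyn if d.origin == "pre_existing")
    return new, pre_existing


def summarize_patient(
    dyn: list[CloneDynamics], expanded_min: int = 3
) -> PatientCloneSummary:
    """Roll one patient's matched clone list up into a summary.

    Expanded-clone frequency is summed per timepoint over clones expanded at
    that timepoint (count >= expanded_min); the patient's group is the sign of
    its post-minus-pre change (an exact zero ties to "decreased" and is
    logged). New-clone size is the summed post frequency of clones absent at
    baseline.
    """
    if not dyn:
        log.warning("patient summary requested with no matched clones")
        return PatientCloneSummary(
            patient_id="",
            total_clone_size_change=0.0,
            group="decreased",
            new_clone_size=0.0,
            pre_existing_size_pre=0.0,
            pre_existing_size_post=0.0,
            evaluable=False,
        )
    patient_id = dyn[0].patient_id
    expanded_pre = sum(d.pre_freq for d in dyn if d.pre_count >= expanded_min)
    expanded_post = sum(d.post_freq for d in dyn if d.post_count >= expanded_min)
    change = expanded_post - expanded_pre
    if change == 0.0:
        log.warning("patient %s: exact-zero clone-size change -> decreased", patient_id)
    new_size, _ = post_frequency_partition(dyn)
    return PatientCloneSummary(
        patient_id=patient_id,
        total_clone_size_change=change,
        group="increased" if change > 0 else "decreased",
        new_clone_size=new_size,
        pre_existing_size_pre=sum(
            d.pre_freq for d in dyn if d.origin == "pre_existing"
        ),
        pre_existing_size_post=sum(
            d.post_freq for d in dyn if d.origin == "pre_existing"
        ),
    )


def correlate_summaries(
    summaries: list[PatientCloneSummary],
    scores: dict[str, float],
    attribute: str = "new_clone_size",
) -> CorrelationResult:
    """Pearson correlation of a per-patient summary attribute against scores.

    ``scores`` maps patient_id -> value; pairing is by patient_id and patients
    missing a score are skipped. Requires at least 3 pairs.
    """
    x, y = [], []
    for s in summaries:
        if s.patient_id in scores:
            x.append(getattr(s, attribute))
            y.append(scores[s.patient_id])
    return pearson_ols(x, y)
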