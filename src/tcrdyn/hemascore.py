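"""Reference-normalized blood-count scores and the predictive/therapeutic indices.

Each analyte (absolute neutrophil count, platelet count, absolute reticulocyte
count) is converted to a score measuring its distance, in reference standard
deviations, from the reference-population median. The hematopoietic score is
the mean of the three analyte scores; the recovery score is its post-minus-pre
change. The predictive index (Pi) correlates a baseline parameter with the
post-treatment hematopoietic score; the therapeutic index (Ti) correlates a
parameter's post-minus-pre change with the recovery score. Both are Pearson
correlations with an OLS slope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from tcrdyn._stats import CorrelationResult, pearson_ols

#: Default analyte set (units: cells/uL for ANC and ARC, platelets/uL for PLT).
ANALYTES = ("anc", "plt", "arc")


@dataclass(frozen=True)
class ReferenceDistribution:
    """Reference-population location/scale for one blood-count analyte."""

    analyte: str
    median: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"reference SD for {self.analyte} must be positive")

    def score(self, value: float) -> float:
        return (value - self.median) / self.sd


@dataclass(frozen=True)
class HematopoieticPanel:
    """One patient-timepoint's analyte values and scores."""

    patient_id: str
    timepoint: str  # "pre" or "post"
    values: dict
    scores: dict
    hematopoietic_score: float


@dataclass(frozen=True)
class RecoveryScore:
    patient_id: str
    value: float  # post hematopoietic score minus pre


def load_reference(path) -> dict[str, ReferenceDistribution]:
    """Read a TSV reference table (analyte, median, sd)."""
    df = pd.read_csv(path, sep="\t")
    return {
        str(r.analyte): ReferenceDistribution(str(r.analyte), float(r.median), float(r.sd))
        for r in df.itertuples()
    }


def score_panel(
    patient_id: str,
    timepoint: str,
    values: Mapping[str, float],
    reference: Mapping[str, ReferenceDistribution],
    analytes: tuple[str, ...] = ANALYTES,
) -> HematopoieticPanel:
    """Score one patient-timepoint's blood counts against the reference.

    Each analyte score is (value - reference median) / reference SD; the
    hematopoietic score is their mean. Raises on a missing analyte value or a
    missing reference entry, naming the analyte.
    """
    scores: dict[str, float] = {}
    for a in analytes:
        if a not in values:
            raise ValueError(f"missing analyte value: {a!r}")
        if a not in reference:
            raise ValueError(f"missing reference distribution for analyte {a!r}")
        scores[a] = reference[a].score(float(values[a]))
    return HematopoieticPanel(
        patient_id=patient_id,
        timepoint=timepoint,
        values={a: float(values[a]) for a in analytes},
        scores=scores,
        hematopoietic_score=sum(scores.values()) / len(scores),
    )


def recovery_score(pre: HematopoieticPanel, post: HematopoieticPanel) -> RecoveryScore:
    """Hematopoietic recovery score: post minus pre hematopoietic score."""
    if pre.patient_id != post.patient_id:
        raise ValueError("recovery score requires panels from the same patient")
    return RecoveryScore(
        patient_id=pre.patient_id,
        value=post.hematopoietic_score - pre.hematopoietic_score,
    )


def predictive_index(
    baseline_params: Mapping[str, float], month6_scores: Mapping[str, float]
) -> CorrelationResult:
    """Pi: Pearson correlation of a baseline parameter with the 6-month score.

    Both arguments map patient_id -> value; pairing is by patient_id.
    """
    shared = sorted(set(baseline_params) & set(month6_scores))
    return pearson_ols(
        [baseline_params[p] for p in shared], [month6_scores[p] for p in shared]
    )


def therapeutic_index(
    param_changes: Mapping[str, float], score_changes: Mapping[str, float]
) -> CorrelationResult:
    """Ti: Pearson correlation of parameter changes with recovery scores."""
    shared = sorted(set(param_changes) & set(score_changes))
    return pearson_ols(
        [param_changes[p] for p in shared], [score_changes[p] for p in shared]
    )
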