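"""Severity scoring of simulated segmentation variations.

The ordinal 1-10 severity score (1 = high-quality segmentation with at most
subtle errors, 10 = low quality with multiple severe errors) is produced by
a deterministic point table rather than a human rater: each error in a
variation contributes points by family and intensity level, and the point
sum is mapped to 1-10 through fixed monotone bins. The scale's three quality
bands are high (1-2), moderate (3-6) and low (7-10).

The proxy preserves the ordinal logic of visual severity grading — boundary
errors weigh less than false-positive structures, which weigh less than
omission of a major segment, and severity levels multiply the weight — but
it is an explicit construction, not a model of any particular human rater.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from vesselbench.errors import ErrorDefinition

__all__ = [
    "SeverityScore",
    "AgreementReport",
    "severity_score",
    "error_points",
    "rater_agreement",
    "quality_band",
]

#: points per error: (family/base rule, level multiplier)
_MAJOR_OMISSION_POINTS = 6
_FP_STRUCTURE_POINTS_PER_LEVEL = 2
_BOUNDARY_POINTS_PER_LEVEL = 1
_MERGE_POINTS_PER_LEVEL = 1

#: upper point edges of severity scores 1..9; points above the last edge
#: score 10. Calibrated once so that the canonical worked examples hold:
#: {orbit_3, skull_3, merge_separation_1, ICA_missing, M1_over_3, Pcom_over_3}
#: = 25 points -> 10, and {small_vessels_3, sup_sagittal_sinus_1} = 8 -> 3.
_SCORE_EDGES = np.array([2, 5, 8, 11, 14, 17, 20, 22, 24])


def quality_band(score: int) -> str:
    if score <= 2:
        return "high"
    if score <= 6:
        return "moderate"
    return "low"


@dataclass(frozen=True)
class SeverityScore:
    variation_id: str
    score: int

    def __post_init__(self):
        if not 1 <= self.score <= 10:
            raise ValueError(f"score must be in [1, 10], got {self.score}")

    @property
    def band(self) -> str:
        return quality_band(self.score)


def error_points(edef: ErrorDefinition) -> int:
    """Severity points contributed by one error."""
    if edef.base_name.endswith("_missing"):
        return _MAJOR_OMISSION_POINTS
    if edef.family == "boundary":
        return _BOUNDARY_POINTS_PER_LEVEL * edef.level
    if edef.base_name == "merge_separation":
        return _MERGE_POINTS_PER_LEVEL * edef.level
    # structure false positives, random voxels and small-vessel omission
    return _FP_STRUCTURE_POINTS_PER_LEVEL * edef.level


def severity_score(plan, catalogue: list[ErrorDefinition]) -> SeverityScore:
    """Deterministic severity score of a variation plan."""
    by_id = {d.error_id: d for d in catalogue}
    points = 0
    for eid in plan.error_ids:
        if eid not in by_id:
            raise ValueError(f"unknown error id {eid!r} in plan {plan.variation_id}")
        points += error_points(by_id[eid])
    score = int(np.searchsorted(_SCORE_EDGES, points, side="left")) + 1
    return SeverityScore(plan.variation_id, score)


@dataclass(frozen=True)
class AgreementReport:
    median_abs_deviation: float
    iqr_of_deviation: float
    exact_overlap_fraction: float
    band_agreement_fraction: float


def rater_agreement(
    scores_a: list[SeverityScore], scores_b: list[SeverityScore]
) -> AgreementReport:
    """Agreement statistics between two scorings of the same variations.

    Reports the median and interquartile range of the absolute score
    deviation, the fraction of exactly matching scores, and the fraction of
    matching quality bands. Raises when the two lists do not cover the same
    variation ids.
    """
    a = {s.variation_id: s.score for s in scores_a}
    b = {s.variation_id: s.score for s in scores_b}
    if set(a) != set(b) or len(a) != len(scores_a) or len(b) != len(scores_b):
        raise ValueError("scorings must cover the same variation ids exactly once each")
    ids = sorted(a)
    dev = np.array([abs(a[i] - b[i]) for i in ids], float)
    q25, q75 = np.percentile(dev, [25, 75])
    return AgreementReport(
        median_abs_deviation=float(np.median(dev)),
        iqr_of_deviation=float(q75 - q25),
        exact_overlap_fraction=float(np.mean(dev == 0)),
        band_agreement_fraction=float(
            np.mean([quality_band(a[i]) == quality_band(b[i]) for i in ids])
        ),
    )
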