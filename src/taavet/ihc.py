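"""Immunohistochemistry (tissue microarray) staining quantification.

Each stained core carries an intensity score (0 negative, 1 weak, 2 moderate,
3 strong; scored independently by two raters plus a consensus value) and the
percentage of positively stained tumor cells.  The Q-Score is their product
(range 0–300); a Q-Score >= 150 implies moderate-to-strong staining in at
least half the tumor cells, making it a surrogate for high, homogeneous
antigen expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from taavet.expression_filter import ValidationError

__all__ = [
    "QScoreBin",
    "IntensityGroup",
    "TMASample",
    "StainingSummary",
    "q_score",
    "bin_q_score",
    "dichotomize_intensity",
    "staining_summary",
]


class QScoreBin(str, Enum):
    ZERO = "zero"       # Q = 0
    LOW = "low"         # 1-149
    HIGH = "high"       # 150-300


class IntensityGroup(str, Enum):
    LOW = "low"         # negative to weak (0-1)
    HIGH = "high"       # moderate to strong (2-3)


def q_score(intensity: int, percent_positive: int) -> int:
    """Q-Score = staining intensity (0-3) x percent positive cells (0-100)."""
    if intensity not in (0, 1, 2, 3):
        raise ValidationError(f"intensity must be in 0..3, got {intensity}")
    if not (0 <= percent_positive <= 100) or int(percent_positive) != percent_positive:
        raise ValidationError(
            f"percent_positive must be an integer in 0..100, got {percent_positive}"
        )
    return int(intensity) * int(percent_positive)


def bin_q_score(q: int) -> QScoreBin:
    """Bin a Q-Score: 0 / 1-149 / 150-300 (the bins partition [0, 300])."""
    if not (0 <= q <= 300) or int(q) != q:
        raise ValidationError(f"Q-Score must be an integer in 0..300, got {q}")
    if q == 0:
        return QScoreBin.ZERO
    if q < 150:
        return QScoreBin.LOW
    return QScoreBin.HIGH


def dichotomize_intensity(intensity: int) -> IntensityGroup:
    """Split intensity into low (negative/weak, 0-1) vs high (moderate/strong, 2-3)."""
    if intensity not in (0, 1, 2, 3):
        raise ValidationError(f"intensity must be in 0..3, got {intensity}")
    return IntensityGroup.LOW if intensity <= 1 else IntensityGroup.HIGH


@dataclass
class TMASample:
    """One stained tissue-microarray core with clinical annotation.

    Times are in months; ``platinum_response`` is "yes", "no" or "unknown".
    Unassessable cores carry ``assessable=False`` and are excluded from
    staining summaries but reported separately.
    """

    sample_id: str
    antigen: str
    intensity_by_rater: tuple[int, int]
    consensus_intensity: int
    percent_positive: int
    assessable: bool = True
    grade: Optional[int] = None
    figo_stage: Optional[str] = None
    t_stage: Optional[int] = None
    perit_carc: Optional[bool] = None
    residual_tumor: Optional[bool] = None
    platinum_response: str = "unknown"
    age: Optional[float] = None
    pfs_months: Optional[float] = None
    pfs_event: Optional[bool] = None
    os_months: Optional[float] = None
    os_event: Optional[bool] = None
    ttp_months: Optional[float] = None
    ttp_event: Optional[bool] = None

    def __post_init__(self) -> None:
        for i in (*self.intensity_by_rater, self.consensus_intensity):
            if i not in (0, 1, 2, 3):
                raise ValidationError(
                    f"{self.sample_id}: intensity {i} outside 0..3"
                )
        if not (0 <= self.percent_positive <= 100):
            raise ValidationError(
                f"{self.sample_id}: percent_positive {self.percent_positive} outside 0..100"
            )
        if self.platinum_response not in ("yes", "no", "unknown"):
            raise ValidationError(
                f"{self.sample_id}: platinum_response must be yes/no/unknown"
            )
        for t in (self.pfs_months, self.os_months, self.ttp_months):
            if t is not None and t < 0:
                raise ValidationError(f"{self.sample_id}: negative survival time")

    @property
    def q(self) -> int:
        return q_score(self.consensus_intensity, self.percent_positive)

    @property
    def q_bin(self) -> QScoreBin:
        return bin_q_score(self.q)

    @property
    def intensity_group(self) -> IntensityGroup:
        return dichotomize_intensity(self.consensus_intensity)

    @property
    def raters_discordant(self) -> bool:
        return self.intensity_by_rater[0] != self.intensity_by_rater[1]


@dataclass
class StainingSummary:
    """Per-antigen staining summary over assessable cores."""

    antigen: str
    n_total: int
    n_unassessable: int
    n_assessable: int
    intensity_counts: dict[int, int]
    percent_values: list[int]
    percent_median: Optional[float]
    n_q_ge_150: int
    n_discordant: int
    spearman_rho: Optional[float] = None
    spearman_p: Optional[float] = None
    correlation_note: str = ""

    def to_dict(self) -> dict:
        return {
            "antigen": self.antigen,
            "n_total": self.n_total,
            "n_unassessable": self.n_unassessable,
            "n_assessable": self.n_assessable,
            "intensity_counts": {str(k): v for k, v in sorted(self.intensity_counts.items())},
            "percent_median": self.percent_median,
            "n_q_ge_150": self.n_q_ge_150,
            "n_discordant": self.n_discordant,
            "spearman_rho": self.spearman_rho,
            "spearman_p": self.spearman_p,
            "correlation_note": self.correlation_note,
        }

    def to_text(self) -> str:
        lines = [
            f"Antigen {self.antigen}: n={self.n_total} "
            f"({self.n_unassessable} unassessable, {self.n_assessable} analyzed)",
            "intensity counts: "
            + ", ".join(f"{k}: {self.intensity_counts.get(k, 0)}" for k in range(4)),
            f"median percent positive: {self.percent_median}",
            f"Q-Score >= 150: {self.n_q_ge_150}",
            f"rater-discordant cores: {self.n_discordant}",
        ]
        if self.spearman_rho is not None:
            lines.append(
                f"intensity vs percent Spearman rho = {self.spearman_rho:.3f} "
                f"(p = {self.spearman_p:.3g})"
            )
        elif self.correlation_note:
            lines.append(f"correlation: {self.correlation_note}")
        return "\n".join(lines)


def staining_summary(samples: Sequence[TMASample]) -> StainingSummary:
    """Summarize staining for one antigen.

    Unassessable cores are excluded from every count but reported in
    ``n_unassessable``.  The intensity-vs-percent association is Spearman's
    rank correlation; with fewer than 2 assessable cores or constant input
    the correlation is reported as not computable.
    """
    import warnings

    from taavet.clinical_stats import spearman_rho

    antigens = {s.antigen for s in samples}
    if len(antigens) > 1:
        raise ValidationError(f"summary expects a single antigen, got {sorted(antigens)}")
    antigen = antigens.pop() if antigens else ""

    assessable = [s for s in samples if s.assessable]
    counts = {i: 0 for i in range(4)}
    for s in assessable:
        counts[s.consensus_intensity] += 1
    percents = [s.percent_positive for s in assessable]
    summary = StainingSummary(
        antigen=antigen,
        n_total=len(samples),
        n_unassessable=len(samples) - len(assessable),
        n_assessable=len(assessable),
        intensity_counts=counts,
        percent_values=percents,
        percent_median=float(np.median(percents)) if percents else None,
        n_q_ge_150=sum(1 for s in assessable if s.q >= 150),
        n_discordant=sum(1 for s in assessable if s.raters_discordant),
    )
    if len(assessable) < 2:
        warnings.warn(f"{antigen}: <2 assessable cores, correlation omitted")
        summary.correlation_note = "not computable (<2 assessable cores)"
        return summary
    x = [s.consensus_intensity for s in assessable]
    y = percents
    try:
        rho, p = spearman_rho(x, y)
    except ValidationError:
        warnings.warn(f"{antigen}: constant staining input, correlation omitted")
        summary.correlation_note = "not computable (constant input)"
        return summary
    summary.spearman_rho = rho
    summary.spearman_p = p
    return summary
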