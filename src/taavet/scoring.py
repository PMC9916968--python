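"""Weighted multi-criteria antigen scoring rubric, scoring and ranking.

The rubric is a modified Cheever-style prioritization scheme: seven weighted
criteria (clinical-efficacy and cellular-location criteria removed, since a
T-cell receptor only sees processed, MHC-presented peptides), renormalized so
the criterion maxima sum to 10 points.  Each criterion offers an ordered list
of mutually exclusive subcriteria; a candidate selects exactly one per
criterion (or "not applicable" / "unknown", both worth 0) and its total is
the sum of the selected point values.

Candidates for which the literature is insufficient altogether are flagged
``insufficient_data`` and carry no total; they are listed after the ranked
candidates with no rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

from taavet.expression_filter import ExpressionTier, ValidationError

__all__ = [
    "NOT_APPLICABLE",
    "UNKNOWN",
    "Subcriterion",
    "Criterion",
    "Rubric",
    "CandidateAnnotation",
    "ScoredCandidate",
    "RankedCandidate",
    "default_rubric",
    "normalize_rubric",
    "score_candidate",
    "rank_candidates",
]

NOT_APPLICABLE = "not applicable"
UNKNOWN = "unknown"


def _round2(x: float | Decimal) -> float:
    """Round to 2 decimals, half away from zero."""
    return float(Decimal(str(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Subcriterion:
    label: str
    points: float
    definition: str = ""

    def __post_init__(self) -> None:
        if self.points < 0:
            raise ValidationError(f"subcriterion {self.label!r}: points must be >= 0")


@dataclass(frozen=True)
class Criterion:
    """One rubric criterion: ordered subcriteria, first carries the maximum.

    An implicit "not applicable" subcriterion worth 0 exists in every
    criterion and need not be listed explicitly.
    """

    name: str
    subcriteria: tuple[Subcriterion, ...]

    def __post_init__(self) -> None:
        if not self.subcriteria:
            raise ValidationError(f"criterion {self.name!r} has no subcriteria")
        labels = [s.label for s in self.subcriteria]
        if len(set(labels)) != len(labels):
            raise ValidationError(f"criterion {self.name!r}: duplicate subcriterion labels")
        mx = max(s.points for s in self.subcriteria)
        if self.subcriteria[0].points != mx:
            raise ValidationError(
                f"criterion {self.name!r}: first subcriterion must carry the maximum"
            )

    @property
    def max_points(self) -> float:
        return self.subcriteria[0].points

    def points_for(self, label: str) -> float:
        if label in (NOT_APPLICABLE, UNKNOWN):
            return 0.0
        for s in self.subcriteria:
            if s.label == label:
                return s.points
        raise ValidationError(
            f"criterion {self.name!r}: unknown subcriterion label {label!r}"
        )


@dataclass(frozen=True)
class Rubric:
    criteria: tuple[Criterion, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.criteria]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate criterion names in rubric")

    @property
    def max_total(self) -> float:
        return float(sum(Decimal(str(c.max_points)) for c in self.criteria))

    def criterion(self, name: str) -> Criterion:
        for c in self.criteria:
            if c.name == name:
                return c
        raise ValidationError(f"unknown criterion {name!r}")

    def to_dict(self) -> dict:
        return {
            c.name: {s.label: s.points for s in c.subcriteria} for c in self.criteria
        }

    @staticmethod
    def from_dict(d: Mapping[str, Mapping[str, float]]) -> "Rubric":
        return Rubric(
            tuple(
                Criterion(
                    name,
                    tuple(Subcriterion(lbl, float(p)) for lbl, p in subs.items()),
                )
                for name, subs in d.items()
            )
        )


# Canonical point values of the seven-criterion rubric (maxima sum to 10.00).
_DEFAULT_RUBRIC_SPEC: list[tuple[str, list[tuple[str, float, str]]]] = [
    (
        "Immunogenicity",
        [
            ("HLA-restricted T Cell-Immunity verifiable", 2.5,
             "Experimental generation of HLA-restricted antigen-specific T cells is possible"),
            ("T Cell-Immunity detectable in humans", 2.0,
             "Spontaneous antigen-specific T-cell immunity detectable in humans"),
            ("Immunogenicity in animal models", 0.28,
             "Immunogenic in animal models with similar antigen expression to humans"),
            ("Antibodies detectable in humans", 0.25,
             "Humoral response observed in humans"),
        ],
    ),
    (
        "Oncogenicity",
        [
            ("oncogenic self-protein", 2.25,
             "Antigen is associated with an oncogenic process"),
            ("persistent viral AG", 0.77,
             "Persistently expressed viral antigen"),
            ("Correlation with unfavorable outcome", 0.56,
             "Function unknown, but expression correlates with unfavorable prognosis"),
            ("tissue-differentiation, not oncogenic", 0.27,
             "Not oncogenic, but associated with tissue differentiation"),
            ("stromal-Expression", 0.27,
             "Expression on tumor-related stroma, but not on malignant cells"),
        ],
    ),
    (
        "Specificity",
        [
            ("absolute Specificity", 2.25,
             "Absolutely tumor-specific (e.g. mutated oncogene, viral protein)"),
            ("oncofetal AG", 1.22,
             "Expressed in fetus with no or little expression in healthy adult tissue "
             "(e.g. cancer-testis antigens)"),
            ("overexpressed in Tumors", 0.79,
             "Overexpressed in cancer, but expressed in some healthy tissues"),
            ("abnormal posttranslational modifications", 0.52,
             "Expressed in normal tissue but carries cancer-unique posttranslational changes"),
            ("Tissue specific (expendable tissue)", 0.47,
             "Tissue-specific expression in relatively expendable tissue"),
            ("Tumor stroma AG", 0.23,
             "Normal antigen expressed on tumor stroma"),
        ],
    ),
    (
        "Level of Expression",
        [
            ("high, all cancer cells", 1.0, "Highly expressed on all cancer cells"),
            ("high, most cancer cells", 0.37, "Highly expressed on most cancer cells"),
            ("lower, all cancer cells", 0.23, "Lower level of expression on all cancer cells"),
            ("lower, most cancer cells", 0.08, "Lower level of expression on most cancer cells"),
        ],
    ),
    (
        "Tumor Stem Cell Expression",
        [
            ("Stem Cell Expression, presumptive", 0.8,
             "Evidence for expression on tumor stem cells"),
            ("No info about SCs, but on all stages", 0.53,
             "Present at all stages of tumor development, no stem-cell information"),
            ("No info about SCs, but most cancer cells", 0.16,
             "Expression on most cancer cells, no stem-cell information"),
        ],
    ),
    (
        "Patients with TAA-pos. Tumors",
        [
            ("many Patients, high level", 0.6,
             "High expression in a high fraction of patients"),
            ("many Patients, lower level", 0.1,
             "Lower expression in a high fraction of patients"),
            ("fewer Patients, high level", 0.07,
             "High expression in a lower fraction of patients"),
        ],
    ),
    (
        "No. of Epitopes",
        [
            ("longer Antigen", 0.6,
             "Longer antigen with multiple (potential) immunogenic epitopes"),
            ("short antigenic segment", 0.08,
             "Short antigenic segment with fewer epitopes, binding selected MHC molecules"),
        ],
    ),
]


def default_rubric() -> Rubric:
    """The canonical seven-criterion rubric; criterion maxima sum to 10.00."""
    return Rubric(
        tuple(
            Criterion(name, tuple(Subcriterion(l, p, d) for l, p, d in subs))
            for name, subs in _DEFAULT_RUBRIC_SPEC
        )
    )


def normalize_rubric(rubric: Rubric, target_total: float = 10.0) -> Rubric:
    """Rescale a rubric so its criterion maxima sum to ``target_total``.

    Every subcriterion is multiplied by ``target_total / sum-of-maxima`` and
    rounded to 2 decimals (half away from zero).  Post-round drift of the
    summed maxima beyond ±0.05 of the target raises a warning (the rubric is
    still returned).
    """
    import warnings

    if target_total <= 0:
        raise ValidationError("target_total must be positive")
    current = rubric.max_total
    if current <= 0:
        raise ValidationError("cannot normalize a rubric with zero total")
    factor = Decimal(str(target_total)) / Decimal(str(current))
    scaled = Rubric(
        tuple(
            Criterion(
                c.name,
                tuple(
                    Subcriterion(s.label, _round2(Decimal(str(s.points)) * factor), s.definition)
                    for s in c.subcriteria
                ),
            )
            for c in rubric.criteria
        )
    )
    if abs(scaled.max_total - target_total) > 0.05:
        warnings.warn(
            f"normalized rubric maxima sum to {scaled.max_total}, "
            f"not {target_total} (rounding drift)"
        )
    return scaled


@dataclass(frozen=True)
class CandidateAnnotation:
    """One subcriterion selection per rubric criterion for one candidate.

    ``selections`` maps criterion name to a subcriterion label, or to
    ``"not applicable"`` / ``"unknown"`` (no evidence found), both worth 0.
    ``insufficient_data`` marks a candidate that cannot be scored at all.
    """

    candidate_id: str
    selections: Mapping[str, str] = field(default_factory=dict)
    insufficient_data: bool = False
    tier: Optional[ExpressionTier] = None

    def validate_against(self, rubric: Rubric) -> None:
        if self.insufficient_data:
            return
        missing = [c.name for c in rubric.criteria if c.name not in self.selections]
        if missing:
            raise ValidationError(
                f"{self.candidate_id}: no selection for criteria {missing}"
            )
        extra = [k for k in self.selections if k not in {c.name for c in rubric.criteria}]
        if extra:
            raise ValidationError(f"{self.candidate_id}: unknown criteria {extra}")
        for c in rubric.criteria:
            c.points_for(self.selections[c.name])  # raises on unknown label


@dataclass(frozen=True)
class ScoredCandidate:
    candidate_id: str
    breakdown: Mapping[str, float]
    total: Optional[float]
    scored: bool
    tier: Optional[ExpressionTier] = None


@dataclass(frozen=True)
class RankedCandidate:
    rank: Optional[int]
    candidate: ScoredCandidate


def score_candidate(annotation: CandidateAnnotation, rubric: Rubric) -> ScoredCandidate:
    """Score one candidate: per-criterion points and the 2-decimal total.

    The sum is carried out in decimal arithmetic so the reported total is
    exact for the tabulated point values.
    """
    annotation.validate_against(rubric)
    if annotation.insufficient_data:
        return ScoredCandidate(
            candidate_id=annotation.candidate_id,
            breakdown={},
            total=None,
            scored=False,
            tier=annotation.tier,
        )
    breakdown: dict[str, float] = {}
    total = Decimal("0")
    for c in rubric.criteria:
        pts = c.points_for(annotation.selections[c.name])
        breakdown[c.name] = pts
        total += Decimal(str(pts))
    return ScoredCandidate(
        candidate_id=annotation.candidate_id,
        breakdown=breakdown,
        total=_round2(total),
        scored=True,
        tier=annotation.tier,
    )


def rank_candidates(scored: Sequence[ScoredCandidate]) -> list[RankedCandidate]:
    """Rank scored candidates by descending total with competition ranking.

    Equal totals share a rank and the next rank skips (1, 1, 3, ...); ties
    are displayed in ascending id order.  Unscored candidates are appended
    after the ranked list with ``rank=None``.
    """
    ranked_pool = sorted(
        (s for s in scored if s.scored),
        key=lambda s: (-s.total, s.candidate_id),  # type: ignore[operator]
    )
    out: list[RankedCandidate] = []
    prev_total: Optional[float] = None
    prev_rank = 0
    for i, s in enumerate(ranked_pool, start=1):
        if prev_total is not None and s.total == prev_total:
            rank = prev_rank
        else:
            rank = i
        out.append(RankedCandidate(rank=rank, candidate=s))
        prev_total, prev_rank = s.total, rank
    for s in sorted((s for s in scored if not s.scored), key=lambda s: s.candidate_id):
        out.append(RankedCandidate(rank=None, candidate=s))
    return out
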