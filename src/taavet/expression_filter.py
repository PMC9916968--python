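"""Three-step expression-based candidate selection cascade.

Candidates enter as a roster of previously described antigens with a class
label (self / neoantigen / viral).  The cascade

1. excludes non-self antigens (neoantigens are patient-specific; epithelial
   ovarian cancer has no oncogenic-virus association),
2. tiers the remaining candidates by their maximum per-tissue median
   expression in healthy tissue (GTEx-style TPM): low < 40 TPM in every
   tissue, medium < 400 TPM in every tissue, otherwise excluded as too
   broadly expressed for safe targeting,
3. gates low- and medium-tier candidates on tumor-cohort expression
   (TCGA-style FPKM): a candidate is retained when its cohort median or mean
   FPKM clears the tier-specific cutoff (low tier: median > 0.5 or
   mean > 1; medium tier: median > 5 or mean > 10 — the medium tier demands
   robust tumor expression to justify the higher on-target/off-tumor risk).

Every stage is audited in a :class:`FilterReport` whose counts obey
``n_in = n_excluded + n_out`` and chain across stages.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AntigenClass",
    "AntigenCandidate",
    "ExpressionTier",
    "GateStatus",
    "ExclusionReason",
    "TierCutoffs",
    "GateCutoffs",
    "HealthyExpressionProfile",
    "TumorExpressionSummary",
    "StageReport",
    "FilterReport",
    "TieredCandidate",
    "exclude_neoantigens",
    "assign_tier",
    "tumor_gate",
    "run_cascade",
    "tier_split",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


class AntigenClass(str, Enum):
    SELF = "self"
    NEOANTIGEN = "neoantigen"
    VIRAL = "viral"


class ExpressionTier(str, Enum):
    LOW = "low"
    MEDIUM = "medium"
    EXCLUDED = "excluded"


class GateStatus(str, Enum):
    RETAINED = "retained"
    OMITTED = "omitted"
    NO_DATA = "no_data"


class ExclusionReason(str, Enum):
    NEOANTIGEN = "neoantigen"
    HIGH_HEALTHY_EXPRESSION = "high_healthy_expression"
    BELOW_TUMOR_CUTOFF = "below_tumor_cutoff"
    NO_TUMOR_DATA = "no_tumor_data"


@dataclass(frozen=True)
class AntigenCandidate:
    """One antigen entering the cascade.

    Parameters
    ----------
    id : str
        Gene-symbol-like identifier, unique within a roster.
    antigen_class : AntigenClass
        ``self``, ``neoantigen`` or ``viral``.  Only self-antigens survive
        the first stage.
    aliases : tuple of str
        Alternative symbols; informational only — aliases never merge two
        ids.
    """

    id: str
    antigen_class: AntigenClass
    aliases: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("candidate id must be non-empty")
        object.__setattr__(self, "antigen_class", AntigenClass(self.antigen_class))
        object.__setattr__(self, "aliases", tuple(self.aliases))


@dataclass(frozen=True)
class TierCutoffs:
    """Healthy-tissue tier boundaries in TPM (strict ``<`` on the max tissue)."""

    low_tpm: float = 40.0
    medium_tpm: float = 400.0

    def __post_init__(self) -> None:
        if not (0 < self.low_tpm < self.medium_tpm):
            raise ValidationError(
                f"require 0 < low_tpm < medium_tpm, got {self.low_tpm}, {self.medium_tpm}"
            )


@dataclass(frozen=True)
class GateCutoffs:
    """Tumor-expression gate cutoffs per tier: (median_min, mean_min) FPKM.

    A candidate is retained when ``median > median_min OR mean > mean_min``
    (strict ``>`` on both clauses).
    """

    low: tuple[float, float] = (0.5, 1.0)
    medium: tuple[float, float] = (5.0, 10.0)

    def for_tier(self, tier: ExpressionTier) -> tuple[float, float]:
        if tier == ExpressionTier.LOW:
            return self.low
        if tier == ExpressionTier.MEDIUM:
            return self.medium
        raise ValidationError("tumor gate is undefined for the excluded tier")


class HealthyExpressionProfile:
    """Gene × tissue table of median healthy-tissue expression (TPM).

    Wraps a :class:`pandas.DataFrame` indexed by gene with one column per
    tissue.  The tissue set is identical for every gene and all values are
    non-negative.
    """

    def __init__(self, table: pd.DataFrame):
        if table.shape[1] < 1:
            raise ValidationError("healthy profile needs at least one tissue column")
        if table.index.has_duplicates:
            dups = table.index[table.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids in healthy profile: {dups}")
        values = table.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValidationError("healthy profile contains missing values")
        if (values < 0).any():
            raise ValidationError("healthy profile contains negative TPM values")
        self.table = table.astype(float)

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    @property
    def tissues(self) -> list[str]:
        return list(self.table.columns)

    def __contains__(self, gene: str) -> bool:
        return gene in self.table.index

    def row(self, gene: str) -> dict[str, float]:
        if gene not in self.table.index:
            raise KeyError(gene)
        return self.table.loc[gene].to_dict()


@dataclass(frozen=True)
class TumorExpressionSummary:
    """Per-gene cohort summary of tumor expression (FPKM)."""

    gene: str
    median_fpkm: float
    mean_fpkm: float
    n_samples: int

    def __post_init__(self) -> None:
        if self.median_fpkm < 0 or self.mean_fpkm < 0:
            raise ValidationError(f"{self.gene}: FPKM summaries must be non-negative")
        if self.n_samples < 1:
            raise ValidationError(f"{self.gene}: n_samples must be positive")

    @staticmethod
    def from_matrix_row(gene: str, values: Sequence[float]) -> "TumorExpressionSummary":
        arr = np.asarray(values, dtype=float)
        return TumorExpressionSummary(
            gene=gene,
            median_fpkm=float(np.median(arr)),
            mean_fpkm=float(np.mean(arr)),
            n_samples=int(arr.size),
        )


@dataclass
class StageReport:
    """Audit record for one cascade stage."""

    stage_name: str
    n_in: int
    n_excluded: int
    n_out: int
    exclusions: dict[str, ExclusionReason] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_in != self.n_excluded + self.n_out:
            raise AssertionError(
                f"{self.stage_name}: n_in ({self.n_in}) != "
                f"n_excluded ({self.n_excluded}) + n_out ({self.n_out})"
            )
        if len(self.exclusions) != self.n_excluded:
            raise AssertionError(
                f"{self.stage_name}: {len(self.exclusions)} exclusion reasons "
                f"for {self.n_excluded} exclusions"
            )


@dataclass
class FilterReport:
    """Ordered per-stage audit of the cascade (mirrors the selection flow chart)."""

    stages: list[StageReport] = field(default_factory=list)

    def validate(self) -> None:
        for stage in self.stages:
            stage.validate()
        for prev, nxt in zip(self.stages, self.stages[1:]):
            if nxt.n_in != prev.n_out:
                raise AssertionError(
                    f"stage chaining broken: {prev.stage_name}.n_out ({prev.n_out}) "
                    f"!= {nxt.stage_name}.n_in ({nxt.n_in})"
                )

    @property
    def n_final(self) -> int:
        return self.stages[-1].n_out if self.stages else 0

    def reason_counts(self) -> Counter:
        c: Counter = Counter()
        for stage in self.stages:
            c.update(r.value for r in stage.exclusions.values())
        return c

    def to_dict(self) -> dict:
        return {
            "stages": [
                {
                    "stage_name": s.stage_name,
                    "n_in": s.n_in,
                    "n_excluded": s.n_excluded,
                    "n_out": s.n_out,
                    "exclusions": {k: v.value for k, v in sorted(s.exclusions.items())},
                }
                for s in self.stages
            ],
            "n_final": self.n_final,
        }

    def to_text(self) -> str:
        lines = ["Candidate selection flow", "========================"]
        for s in self.stages:
            lines.append(
                f"{s.stage_name}: {s.n_in} in -> {s.n_excluded} excluded -> {s.n_out} out"
            )
            for reason, n in sorted(Counter(r.value for r in s.exclusions.values()).items()):
                lines.append(f"    {reason}: {n}")
        lines.append(f"final retained: {self.n_final}")
        return "\n".join(lines)


@dataclass(frozen=True)
class TieredCandidate:
    """A candidate that survived the cascade, with its healthy-tissue tier."""

    candidate: AntigenCandidate
    tier: ExpressionTier


def _check_unique_ids(candidates: Sequence[AntigenCandidate]) -> None:
    counts = Counter(c.id for c in candidates)
    dups = sorted(k for k, v in counts.items() if v > 1)
    if dups:
        raise ValidationError(f"duplicate candidate ids: {dups}")


def exclude_neoantigens(
    candidates: Sequence[AntigenCandidate],
) -> tuple[list[AntigenCandidate], int]:
    """Drop every non-self candidate (neoantigens and virus-associated antigens).

    Returns the retained self-antigens in input order and the number excluded.
    """
    _check_unique_ids(candidates)
    retained = [c for c in candidates if c.antigen_class == AntigenClass.SELF]
    return retained, len(candidates) - len(retained)


def assign_tier(
    profile_row: Mapping[str, float],
    low_cutoff: float = 40.0,
    medium_cutoff: float = 400.0,
) -> ExpressionTier:
    """Tier a gene by its maximum per-tissue median TPM.

    ``low`` when every tissue is below ``low_cutoff`` (strict ``<``),
    ``medium`` when every tissue is below ``medium_cutoff``, and ``excluded``
    otherwise.  "Below the cutoff in all tissues" is equivalent to the
    maximum being below the cutoff, so the rule is evaluated on the max;
    boundary values land in the next (more expressed) tier.
    """
    if not (0 < low_cutoff < medium_cutoff):
        raise ValidationError("require 0 < low_cutoff < medium_cutoff")
    if len(profile_row) == 0:
        raise ValidationError("empty tissue map")
    values = np.asarray(list(profile_row.values()), dtype=float)
    if (values < 0).any():
        raise ValidationError("negative TPM value in tissue map")
    m = float(values.max())
    if m < low_cutoff:
        return ExpressionTier.LOW
    if m < medium_cutoff:
        return ExpressionTier.MEDIUM
    return ExpressionTier.EXCLUDED


def tumor_gate(
    summary: Optional[TumorExpressionSummary],
    tier: ExpressionTier,
    cutoffs: GateCutoffs = GateCutoffs(),
) -> GateStatus:
    """Gate one candidate on tumor-cohort expression.

    ``no_data`` when no cohort summary exists; otherwise ``retained`` iff
    ``median_fpkm > median_min OR mean_fpkm > mean_min`` for the tier's
    cutoff pair (strict ``>`` on both clauses), else ``omitted``.
    """
    if tier == ExpressionTier.EXCLUDED:
        raise ValidationError("tumor gate must not be called on excluded-tier candidates")
    if summary is None:
        return GateStatus.NO_DATA
    median_min, mean_min = cutoffs.for_tier(tier)
    if summary.median_fpkm > median_min or summary.mean_fpkm > mean_min:
        return GateStatus.RETAINED
    return GateStatus.OMITTED


def run_cascade(
    candidates: Sequence[AntigenCandidate],
    healthy_profile: HealthyExpressionProfile,
    tumor_table: Mapping[str, TumorExpressionSummary],
    tier_cutoffs: TierCutoffs = TierCutoffs(),
    gate_cutoffs: GateCutoffs = GateCutoffs(),
) -> tuple[list[TieredCandidate], FilterReport]:
    """Run the full three-stage cascade and return (retained, report).

    A self-antigen missing from the healthy profile is a hard error (tiering
    is impossible without healthy-tissue data); a candidate missing from the
    tumor table is excluded softly with reason ``no_tumor_data``.
    """
    report = FilterReport()

    # Stage 1: neoantigen / viral exclusion.
    selfs, n_neo = exclude_neoantigens(candidates)
    report.stages.append(
        StageReport(
            stage_name="neoantigen_exclusion",
            n_in=len(candidates),
            n_excluded=n_neo,
            n_out=len(selfs),
            exclusions={
                c.id: ExclusionReason.NEOANTIGEN
                for c in candidates
                if c.antigen_class != AntigenClass.SELF
            },
        )
    )

    # Stage 2: healthy-tissue tiering.
    missing = [c.id for c in selfs if c.id not in healthy_profile]
    if missing:
        raise ValidationError(
            f"candidates missing from the healthy-tissue profile: {sorted(missing)}"
        )
    tiered: list[TieredCandidate] = []
    tier_exclusions: dict[str, ExclusionReason] = {}
    for c in selfs:
        tier = assign_tier(
            healthy_profile.row(c.id), tier_cutoffs.low_tpm, tier_cutoffs.medium_tpm
        )
        if tier == ExpressionTier.EXCLUDED:
            tier_exclusions[c.id] = ExclusionReason.HIGH_HEALTHY_EXPRESSION
        else:
            tiered.append(TieredCandidate(c, tier))
    report.stages.append(
        StageReport(
            stage_name="healthy_tissue_tiering",
            n_in=len(selfs),
            n_excluded=len(tier_exclusions),
            n_out=len(tiered),
            exclusions=tier_exclusions,
        )
    )

    # Stage 3: tumor-expression gate.
    retained: list[TieredCandidate] = []
    gate_exclusions: dict[str, ExclusionReason] = {}
    for tc in tiered:
        status = tumor_gate(tumor_table.get(tc.candidate.id), tc.tier, gate_cutoffs)
        if status == GateStatus.RETAINED:
            retained.append(tc)
        elif status == GateStatus.NO_DATA:
            gate_exclusions[tc.candidate.id] = ExclusionReason.NO_TUMOR_DATA
        else:
            gate_exclusions[tc.candidate.id] = ExclusionReason.BELOW_TUMOR_CUTOFF
    report.stages.append(
        StageReport(
            stage_name="tumor_expression_gate",
            n_in=len(tiered),
            n_excluded=len(gate_exclusions),
            n_out=len(retained),
            exclusions=gate_exclusions,
        )
    )

    report.validate()
    return retained, report


def tier_split(retained: Iterable[TieredCandidate]) -> Counter:
    """Count retained candidates per tier (the low/medium split of the flow chart)."""
    return Counter(tc.tier.value for tc in retained)
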