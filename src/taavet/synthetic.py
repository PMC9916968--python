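"""Synthetic cohort generators with planted ground truth.

Every input the vetting pipeline consumes can be generated here at desk
scale: healthy-tissue expression profiles with planted tiers, tumor FPKM
cohorts with planted gate statuses, rubric annotation sets with
independently computed expected totals, TMA staining cohorts with a planted
proportional-hazards effect on progression-free survival and a planted
platinum-sensitivity odds ratio across Q-Score bins, and subtype expression
matrices with planted differentially expressed genes.

Each generator returns its data together with a :class:`SyntheticTruth`
record; recovery tests run the pipeline on the data alone and compare the
result to the truth afterwards.  A single seed fixes every output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from taavet.expression_filter import (
    ExpressionTier,
    GateCutoffs,
    GateStatus,
    HealthyExpressionProfile,
    ValidationError,
)
from taavet.ihc import TMASample
from taavet.scoring import (
    NOT_APPLICABLE,
    UNKNOWN,
    CandidateAnnotation,
    Rubric,
)
from taavet.subtype import SubtypeDataset

__all__ = [
    "SyntheticTruth",
    "DEFAULT_TISSUES",
    "simulate_healthy_expression",
    "simulate_tumor_cohort",
    "simulate_annotations",
    "worked_example_annotations",
    "simulate_tma_cohort",
    "simulate_subtype_dataset",
]

# GTEx-style tissue categories used for healthy-tissue profiles.
DEFAULT_TISSUES = [
    "adipose", "brain", "breast", "colon", "heart", "kidney", "liver",
    "lung", "muscle", "ovary", "pancreas", "skin", "stomach", "testis",
]


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside every generated dataset."""

    seed: int
    tiers: dict[str, str] = field(default_factory=dict)
    gate_status: dict[str, str] = field(default_factory=dict)
    expected_totals: dict[str, Optional[float]] = field(default_factory=dict)
    hazard_ratio: Optional[float] = None
    platinum_or: Optional[float] = None
    sample_groups: dict[str, str] = field(default_factory=dict)
    de_genes: dict[str, tuple[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "tiers": dict(sorted(self.tiers.items())),
            "gate_status": dict(sorted(self.gate_status.items())),
            "expected_totals": dict(sorted(self.expected_totals.items())),
            "hazard_ratio": self.hazard_ratio,
            "platinum_or": self.platinum_or,
            "sample_groups": dict(sorted(self.sample_groups.items())),
            "de_genes": {g: list(v) for g, v in sorted(self.de_genes.items())},
        }


# Planted-max bands per tier: the max tissue value lands strictly inside.
_TIER_BANDS = {
    ExpressionTier.LOW: (0.5, 39.0),
    ExpressionTier.MEDIUM: (40.0, 395.0),
    ExpressionTier.EXCLUDED: (400.0, 3900.0),
}


def simulate_healthy_expression(
    n_low: int = 60,
    n_medium: int = 47,
    n_high: int = 60,
    tissues: Sequence[str] = tuple(DEFAULT_TISSUES),
    noise_sd: float = 0.5,
    seed: int = 0,
    gene_prefix: str = "G",
) -> tuple[HealthyExpressionProfile, SyntheticTruth]:
    """Healthy-tissue median-TPM profiles with planted low/medium/high tiers.

    For each gene a maximum tissue value is drawn log-uniformly strictly
    inside its tier band (low < 40 TPM, medium [40, 400), high >= 400); the
    remaining tissues are scaled down by log-normal factors of scale
    ``noise_sd``, so the planted maximum — and hence the tier — is exact by
    construction regardless of noise.
    """
    if min(n_low, n_medium, n_high) < 0:
        raise ValidationError("tier counts must be >= 0")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    if not tissues:
        raise ValidationError("need at least one tissue")
    rng = np.random.default_rng(seed)
    planted = (
        [ExpressionTier.LOW] * n_low
        + [ExpressionTier.MEDIUM] * n_medium
        + [ExpressionTier.EXCLUDED] * n_high
    )
    order = rng.permutation(len(planted))
    n_genes = len(planted)
    width = max(3, len(str(n_genes)))
    rows = {}
    truth = SyntheticTruth(seed=seed)
    for pos, idx in enumerate(order):
        tier = planted[idx]
        gene = f"{gene_prefix}{pos + 1:0{width}d}"
        lo, hi = _TIER_BANDS[tier]
        m = math.exp(rng.uniform(math.log(lo), math.log(hi)))
        values = m * np.exp(-np.abs(rng.normal(0.0, noise_sd, size=len(tissues))) - 1e-9)
        peak = rng.integers(len(tissues))
        values[peak] = m
        rows[gene] = values
        truth.tiers[gene] = tier.value
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(tissues))
    return HealthyExpressionProfile(table), truth


def simulate_tumor_cohort(
    gene_tiers: Mapping[str, ExpressionTier],
    n_samples: int = 373,
    n_expressed_by_tier: Mapping[str, int] | None = None,
    n_missing_by_tier: Mapping[str, int] | None = None,
    expressed_fraction_by_tier: Mapping[str, float] | None = None,
    cutoffs: GateCutoffs = GateCutoffs(),
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Tumor-cohort FPKM matrix (gene x sample) with planted gate statuses.

    ``gene_tiers`` lists the low/medium-tier genes entering the gate.  Per
    tier, the first ``n_expressed`` genes (in seeded random order) are
    planted *retained* (the sample median is rescaled to 4x the tier's
    median cutoff), the next ``n_missing`` are left out of the matrix
    entirely (no-tumor-data exclusions), and the rest are planted *omitted*
    (rescaled so both median and mean sit at half their cutoffs).  When
    ``expressed_fraction_by_tier`` is given it overrides the counts.
    """
    if n_samples < 2:
        raise ValidationError("n_samples must be >= 2")
    tiers = {g: ExpressionTier(t) for g, t in gene_tiers.items()}
    bad = [g for g, t in tiers.items() if t == ExpressionTier.EXCLUDED]
    if bad:
        raise ValidationError(f"excluded-tier genes cannot enter the tumor gate: {bad}")
    by_tier: dict[str, list[str]] = {"low": [], "medium": []}
    for g, t in tiers.items():
        by_tier[t.value].append(g)
    if n_expressed_by_tier is None:
        n_expressed_by_tier = {"low": 21, "medium": 17}
    if n_missing_by_tier is None:
        n_missing_by_tier = {"low": 2, "medium": 1}
    rng = np.random.default_rng(seed)
    rows = {}
    truth = SyntheticTruth(seed=seed)
    for tier_name in ("low", "medium"):
        genes = sorted(by_tier[tier_name])
        if not genes:
            continue
        rng.shuffle(genes)
        if expressed_fraction_by_tier is not None:
            n_exp = int(round(expressed_fraction_by_tier.get(tier_name, 0.0) * len(genes)))
        else:
            n_exp = min(int(n_expressed_by_tier.get(tier_name, 0)), len(genes))
        n_miss = min(int(n_missing_by_tier.get(tier_name, 0)), len(genes) - n_exp)
        median_min, mean_min = cutoffs.for_tier(ExpressionTier(tier_name))
        for i, gene in enumerate(genes):
            if i < n_exp:
                status = GateStatus.RETAINED
            elif i < n_exp + n_miss:
                status = GateStatus.NO_DATA
            else:
                status = GateStatus.OMITTED
            truth.gate_status[gene] = status.value
            if status == GateStatus.NO_DATA:
                continue
            raw = rng.lognormal(mean=0.0, sigma=1.0, size=n_samples)
            med, mean = float(np.median(raw)), float(np.mean(raw))
            if status == GateStatus.RETAINED:
                factor = 4.0 * median_min / med
            else:
                factor = min(0.5 * median_min / med, 0.5 * mean_min / mean)
            rows[gene] = raw * factor
    matrix = pd.DataFrame.from_dict(rows, orient="index")
    matrix.columns = [f"S{j + 1:04d}" for j in range(n_samples)]
    matrix = matrix.sort_index()
    return matrix, truth


def simulate_annotations(
    n_candidates: int,
    rubric: Rubric,
    tier_mix: Mapping[str, float] | None = None,
    n_insufficient: int = 0,
    seed: int = 0,
    id_prefix: str = "TAA",
) -> tuple[list[CandidateAnnotation], SyntheticTruth]:
    """Random valid rubric annotations with independently computed totals.

    Each candidate selects one option per criterion uniformly among the
    criterion's subcriteria plus "not applicable" and "unknown".  The
    expected total in the truth record is summed by direct point lookup
    (decimal arithmetic), independent of the scoring path.  The first
    ``n_insufficient`` candidates (after seeded shuffling) are flagged
    ``insufficient_data`` and carry no expected total.
    """
    if n_insufficient > n_candidates:
        raise ValidationError("n_insufficient cannot exceed n_candidates")
    rng = np.random.default_rng(seed)
    tiers = list((tier_mix or {"low": 0.6, "medium": 0.4}).items())
    tier_labels = [t for t, _ in tiers]
    tier_probs = np.array([p for _, p in tiers], dtype=float)
    tier_probs /= tier_probs.sum()
    insufficient_flags = np.zeros(n_candidates, dtype=bool)
    insufficient_flags[:n_insufficient] = True
    rng.shuffle(insufficient_flags)
    points_table = rubric.to_dict()
    annotations: list[CandidateAnnotation] = []
    truth = SyntheticTruth(seed=seed)
    for i in range(n_candidates):
        cid = f"{id_prefix}{i + 1:03d}"
        tier = ExpressionTier(tier_labels[rng.choice(len(tier_labels), p=tier_probs)])
        if insufficient_flags[i]:
            annotations.append(
                CandidateAnnotation(cid, {}, insufficient_data=True, tier=tier)
            )
            truth.expected_totals[cid] = None
            continue
        selections: dict[str, str] = {}
        total = Decimal("0")
        for crit in rubric.criteria:
            options = [s.label for s in crit.subcriteria] + [NOT_APPLICABLE, UNKNOWN]
            choice = options[rng.integers(len(options))]
            selections[crit.name] = choice
            total += Decimal(str(points_table[crit.name].get(choice, 0.0)))
        annotations.append(CandidateAnnotation(cid, selections, tier=tier))
        truth.expected_totals[cid] = float(total)
    return annotations, truth


def worked_example_annotations() -> dict[str, CandidateAnnotation]:
    """The three canonical worked scoring examples.

    A top-ranked cancer-testis antigen profile (maximum in every criterion
    except Specificity = oncofetal and Level of Expression = high on most
    cells) and its two variants with successively lower tumor-stem-cell
    evidence.  Their totals under the default rubric are 8.34, 8.07 and
    7.70 points.
    """
    base = {
        "Immunogenicity": "HLA-restricted T Cell-Immunity verifiable",
        "Oncogenicity": "oncogenic self-protein",
        "Specificity": "oncofetal AG",
        "Level of Expression": "high, most cancer cells",
        "Tumor Stem Cell Expression": "Stem Cell Expression, presumptive",
        "Patients with TAA-pos. Tumors": "many Patients, high level",
        "No. of Epitopes": "longer Antigen",
    }
    mid = dict(base, **{"Tumor Stem Cell Expression": "No info about SCs, but on all stages"})
    low = dict(base, **{"Tumor Stem Cell Expression": "No info about SCs, but most cancer cells"})
    return {
        "top_cta": CandidateAnnotation("top_cta", base, tier=ExpressionTier.LOW),
        "mid_cta": CandidateAnnotation("mid_cta", mid, tier=ExpressionTier.LOW),
        "low_cta": CandidateAnnotation("low_cta", low, tier=ExpressionTier.LOW),
    }


def simulate_tma_cohort(
    n_samples: int = 58,
    antigen: str = "CT45",
    hazard_ratio_high_vs_low: float = 3.0,
    platinum_or: float = 4.0,
    censoring_rate: float = 0.2,
    n_unassessable: int = 0,
    discordance_rate: float = 0.0,
    baseline_median_pfs: float = 28.0,
    seed: int = 0,
) -> tuple[list[TMASample], SyntheticTruth]:
    """A TMA staining cohort with planted survival and platinum effects.

    Staining intensity is categorical (0..3); percent positive is
    correlated with intensity (~30 points per intensity level plus noise).
    Progression-free survival is exponential under proportional hazards:
    the moderate/strong (high) intensity group's hazard is
    ``hazard_ratio_high_vs_low`` times the negative/weak group's, whose
    median PFS is ``baseline_median_pfs`` months.  Censoring is independent
    exponential, tuned so the expected censored fraction is
    ``censoring_rate``.  Platinum sensitivity is Bernoulli with odds
    multiplied by ``platinum_or`` for cores with Q-Score >= 150.  Clinical
    covariates approximate a serous, mostly grade-3, stage-III EOC cohort.
    """
    if hazard_ratio_high_vs_low <= 0:
        raise ValidationError("hazard ratio must be positive")
    if not (0 <= censoring_rate < 1):
        raise ValidationError("censoring_rate must be in [0, 1)")
    if n_unassessable > n_samples:
        raise ValidationError("n_unassessable cannot exceed n_samples")
    rng = np.random.default_rng(seed)
    lam_low = math.log(2.0) / baseline_median_pfs
    cens_factor = censoring_rate / (1.0 - censoring_rate) if censoring_rate > 0 else 0.0
    unassessable = np.zeros(n_samples, dtype=bool)
    unassessable[:n_unassessable] = True
    rng.shuffle(unassessable)
    truth = SyntheticTruth(
        seed=seed,
        hazard_ratio=hazard_ratio_high_vs_low,
        platinum_or=platinum_or,
    )
    samples: list[TMASample] = []
    for i in range(n_samples):
        sid = f"TMA{i + 1:03d}"
        intensity = int(rng.choice(4, p=[0.30, 0.20, 0.30, 0.20]))
        if intensity == 0:
            percent = 0
        else:
            percent = int(np.clip(round(30 * intensity + rng.normal(0, 12)), 1, 100))
        r2 = intensity
        if discordance_rate > 0 and rng.random() < discordance_rate:
            r2 = int(np.clip(intensity + rng.choice([-1, 1]), 0, 3))
        high = intensity >= 2
        lam = lam_low * (hazard_ratio_high_vs_low if high else 1.0)
        t_event = rng.exponential(1.0 / lam)
        if cens_factor > 0:
            t_cens = rng.exponential(1.0 / (lam * cens_factor))
            pfs = min(t_event, t_cens)
            pfs_event = t_event <= t_cens
        else:
            pfs, pfs_event = t_event, True
        q = intensity * percent
        odds = 1.5 * (platinum_or if q >= 150 else 1.0)
        if rng.random() < 0.02:
            platinum = "unknown"
        else:
            platinum = "yes" if rng.random() < odds / (1.0 + odds) else "no"
        os_months = pfs + rng.exponential(12.0)
        samples.append(
            TMASample(
                sample_id=sid,
                antigen=antigen,
                intensity_by_rater=(intensity, r2),
                consensus_intensity=intensity,
                percent_positive=percent,
                assessable=not bool(unassessable[i]),
                grade=3 if rng.random() < 0.897 else 2,
                figo_stage=str(rng.choice(["II", "III", "IV"], p=[0.052, 0.793, 0.155])),
                t_stage=int(rng.choice([1, 2, 3], p=[0.15, 0.25, 0.60])),
                perit_carc=bool(rng.random() < 0.879),
                residual_tumor=bool(rng.random() < 0.259),
                platinum_response=platinum,
                age=float(round(rng.normal(60.5, 8.0), 1)),
                pfs_months=float(round(pfs, 2)),
                pfs_event=bool(pfs_event),
                os_months=float(round(os_months, 2)),
                os_event=bool(pfs_event),
                ttp_months=float(round(pfs, 2)),
                ttp_event=bool(pfs_event),
            )
        )
        truth.sample_groups[sid] = "high" if high else "low"
    return samples, truth


def simulate_subtype_dataset(
    n_per_cluster: int = 20,
    n_genes: int = 50,
    planted_shifts: Mapping[str, tuple[str, float]] | None = None,
    probes_per_gene: int = 1,
    probe_ids: Mapping[str, Sequence[str]] | None = None,
    base_mean: float = 100.0,
    base_sd: float = 20.0,
    seed: int = 0,
) -> tuple[SubtypeDataset, SyntheticTruth]:
    """Subtype expression matrix with planted differentially expressed genes.

    Null genes are exchangeable across the four clusters (c1, c2, c4, c5);
    a planted gene's values in its named cluster are shifted by
    ``shift x base_sd``.  With ``probes_per_gene > 1`` each gene gets one
    dominant (highest-mean) probe and dimmer secondaries, exercising probe
    selection; ``probe_ids`` may name the probes per gene explicitly (the
    first listed probe is the dominant one).
    """
    if n_per_cluster < 2:
        raise ValidationError("n_per_cluster must be >= 2")
    planted_shifts = dict(planted_shifts or {})
    clusters = ["c1", "c2", "c4", "c5"]
    sample_ids = []
    labels = []
    for cl in clusters:
        for j in range(n_per_cluster):
            sample_ids.append(f"{cl}_s{j + 1:02d}")
            labels.append(cl)
    rng = np.random.default_rng(seed)
    width = max(3, len(str(n_genes)))
    gene_names = list(planted_shifts.keys())
    if probe_ids is not None:
        gene_names += [g for g in probe_ids if g not in gene_names]
    all_genes = gene_names + [
        f"NULL{k + 1:0{width}d}" for k in range(max(0, n_genes - len(gene_names)))
    ]
    truth = SyntheticTruth(seed=seed, de_genes={g: v for g, v in planted_shifts.items()})
    expr_rows: dict[str, np.ndarray] = {}
    probe_map: dict[str, str] = {}
    label_arr = np.array(labels)
    for gene in all_genes:
        base = rng.normal(base_mean, base_sd, size=len(sample_ids))
        if gene in planted_shifts:
            cl, shift = planted_shifts[gene]
            if cl not in clusters:
                raise ValidationError(f"unknown cluster {cl!r} for planted gene {gene!r}")
            base = base + (label_arr == cl) * shift * base_sd
        base = np.clip(base, 0.0, None)
        if probe_ids is not None and gene in probe_ids:
            names = list(probe_ids[gene])
        else:
            names = [f"{gene}_p{k + 1}" for k in range(probes_per_gene)]
        for k, probe in enumerate(names):
            if k == 0:
                expr_rows[probe] = base
            else:
                # secondary probes: same pattern, attenuated mean
                expr_rows[probe] = np.clip(
                    base * 0.5 + rng.normal(0, base_sd * 0.2, size=len(sample_ids)), 0.0, None
                )
            probe_map[probe] = gene
    expression = pd.DataFrame.from_dict(expr_rows, orient="index", columns=sample_ids)
    dataset = SubtypeDataset(
        expression=expression,
        clusters=pd.Series(labels, index=sample_ids, name="cluster"),
        probe_map=pd.Series(probe_map, name="gene"),
    )
    return dataset, truth
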