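"""Tabular readers/writers, pipeline configuration and the end-to-end driver.

All tables are tab-separated with a header row, UTF-8, "." decimal separator;
the TMA table is comma-separated (clinical exports commonly are).  Writers
and readers round-trip every table exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields as dataclass_fields
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from taavet import __version__
from taavet.expression_filter import (
    AntigenCandidate,
    AntigenClass,
    ExpressionTier,
    FilterReport,
    GateCutoffs,
    HealthyExpressionProfile,
    TierCutoffs,
    TieredCandidate,
    TumorExpressionSummary,
    ValidationError,
    run_cascade,
    tier_split,
)
from taavet.ihc import StainingSummary, TMASample, staining_summary
from taavet.clinical_stats import association_battery
from taavet.scoring import (
    CandidateAnnotation,
    RankedCandidate,
    Rubric,
    default_rubric,
    rank_candidates,
    score_candidate,
)
from taavet.subtype import SubtypeDataset, subtype_analysis

logger = logging.getLogger("taavet")

__all__ = [
    "PipelineConfig",
    "ReportBundle",
    "read_candidates",
    "write_candidates",
    "read_healthy_profile",
    "write_healthy_profile",
    "read_tumor_matrix",
    "write_tumor_matrix",
    "read_tumor_summary",
    "summarize_tumor_matrix",
    "read_annotations",
    "write_annotations",
    "read_rubric",
    "write_rubric",
    "read_tma",
    "write_tma",
    "read_subtype_dataset",
    "write_subtype_dataset",
    "run_pipeline",
    "write_report",
]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path: Path | str, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, **kwargs)
    except pd.errors.ParserError as exc:
        raise ValidationError(f"{path}: malformed TSV ({exc})") from exc


def read_candidates(path: Path | str) -> list[AntigenCandidate]:
    """Candidate roster TSV: ``id, antigen_class, aliases`` (aliases ';'-separated)."""
    df = _read_tsv(path)
    required = ["id", "antigen_class", "aliases"]
    if list(df.columns) != required:
        raise ValidationError(f"{path}: expected columns {required}, got {list(df.columns)}")
    out = []
    for i, row in df.iterrows():
        try:
            cls = AntigenClass(row["antigen_class"])
        except ValueError:
            raise ValidationError(
                f"{path}: line {i + 2}: unknown antigen_class {row['antigen_class']!r}"
            ) from None
        aliases = tuple(a for a in row["aliases"].split(";") if a)
        out.append(AntigenCandidate(row["id"], cls, aliases))
    return out


def write_candidates(candidates: Sequence[AntigenCandidate], path: Path | str) -> None:
    pd.DataFrame(
        {
            "id": [c.id for c in candidates],
            "antigen_class": [c.antigen_class.value for c in candidates],
            "aliases": [";".join(c.aliases) for c in candidates],
        }
    ).to_csv(path, sep="\t", index=False)


def read_healthy_profile(path: Path | str) -> HealthyExpressionProfile:
    """Healthy-tissue TSV: ``gene<TAB>tissue1<TAB>...``, values = median TPM."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)].tolist()[:5]
        raise ValidationError(f"{path}: missing/ragged values for genes {bad}")
    try:
        return HealthyExpressionProfile(df)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_healthy_profile(profile: HealthyExpressionProfile, path: Path | str) -> None:
    profile.table.rename_axis("gene").to_csv(path, sep="\t")


def read_tumor_matrix(path: Path | str) -> pd.DataFrame:
    """Gene x sample FPKM matrix, TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)].tolist()[:5]
        raise ValidationError(f"{path}: non-numeric or missing FPKM for genes {bad}")
    if (df.to_numpy() < 0).any():
        raise ValidationError(f"{path}: negative FPKM values")
    return df


def write_tumor_matrix(matrix: pd.DataFrame, path: Path | str) -> None:
    matrix.rename_axis("gene").to_csv(path, sep="\t")


def summarize_tumor_matrix(matrix: pd.DataFrame) -> dict[str, TumorExpressionSummary]:
    """Per-gene median/mean FPKM summaries recomputed from the matrix."""
    return {
        gene: TumorExpressionSummary.from_matrix_row(gene, matrix.loc[gene].to_numpy(float))
        for gene in matrix.index
    }


def read_tumor_summary(path: Path | str) -> dict[str, TumorExpressionSummary]:
    """Pre-summarized tumor TSV: ``gene, median_fpkm, mean_fpkm, n_samples``."""
    df = _read_tsv(path)
    required = ["gene", "median_fpkm", "mean_fpkm", "n_samples"]
    if list(df.columns) != required:
        raise ValidationError(f"{path}: expected columns {required}, got {list(df.columns)}")
    out = {}
    for i, row in df.iterrows():
        try:
            out[row["gene"]] = TumorExpressionSummary(
                gene=row["gene"],
                median_fpkm=float(row["median_fpkm"]),
                mean_fpkm=float(row["mean_fpkm"]),
                n_samples=int(row["n_samples"]),
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}: line {i + 2}: {exc}") from exc
    return out


_ANNOTATION_COLS = ["candidate_id", "criterion", "selection", "insufficient_data", "tier"]


def read_annotations(path: Path | str, rubric: Rubric) -> list[CandidateAnnotation]:
    """Long-format annotation TSV.

    Columns: ``candidate_id, criterion, selection, insufficient_data, tier``.
    Insufficient candidates carry a single row with empty criterion; scored
    candidates need exactly one row per rubric criterion.
    """
    df = _read_tsv(path)
    if list(df.columns) != _ANNOTATION_COLS:
        raise ValidationError(
            f"{path}: expected columns {_ANNOTATION_COLS}, got {list(df.columns)}"
        )
    out = []
    for cid, grp in df.groupby("candidate_id", sort=True):
        insufficient = set(grp["insufficient_data"]) == {"1"}
        tier_vals = set(grp["tier"]) - {""}
        tier = ExpressionTier(tier_vals.pop()) if tier_vals else None
        if insufficient:
            ann = CandidateAnnotation(cid, {}, insufficient_data=True, tier=tier)
        else:
            selections = dict(zip(grp["criterion"], grp["selection"]))
            ann = CandidateAnnotation(cid, selections, tier=tier)
        ann.validate_against(rubric)
        out.append(ann)
    return out


def write_annotations(annotations: Sequence[CandidateAnnotation], path: Path | str) -> None:
    rows = []
    for ann in annotations:
        tier = ann.tier.value if ann.tier else ""
        if ann.insufficient_data:
            rows.append((ann.candidate_id, "", "", "1", tier))
        else:
            for crit, sel in ann.selections.items():
                rows.append((ann.candidate_id, crit, sel, "0", tier))
    pd.DataFrame(rows, columns=_ANNOTATION_COLS).to_csv(path, sep="\t", index=False)


def read_rubric(path: Path | str) -> Rubric:
    """Rubric YAML: ``{criterion: {subcriterion label: points}}`` (ordered)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: rubric file must map criteria to subcriteria")
    return Rubric.from_dict(data)


def write_rubric(rubric: Rubric, path: Path | str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(rubric.to_dict(), fh, sort_keys=False)


_TMA_COLS = [
    "sample_id", "antigen", "intensity_r1", "intensity_r2", "consensus_intensity",
    "percent_positive", "assessable", "grade", "figo_stage", "t_stage", "perit_carc",
    "residual_tumor", "platinum_response", "age", "pfs_months", "pfs_event",
    "os_months", "os_event", "ttp_months", "ttp_event",
]


def _opt(val: str, conv):
    return None if val == "" else conv(val)


def _opt_bool(val: str):
    if val == "":
        return None
    if val not in ("0", "1"):
        raise ValueError(f"expected 0/1 flag, got {val!r}")
    return val == "1"


def read_tma(path: Path | str) -> list[TMASample]:
    """TMA staining + clinical table, CSV (see the documented column list)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != _TMA_COLS:
        raise ValidationError(f"{path}: expected columns {_TMA_COLS}, got {list(df.columns)}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                TMASample(
                    sample_id=row["sample_id"],
                    antigen=row["antigen"],
                    intensity_by_rater=(int(row["intensity_r1"]), int(row["intensity_r2"])),
                    consensus_intensity=int(row["consensus_intensity"]),
                    percent_positive=int(row["percent_positive"]),
                    assessable=row["assessable"] == "1",
                    grade=_opt(row["grade"], int),
                    figo_stage=row["figo_stage"] or None,
                    t_stage=_opt(row["t_stage"], int),
                    perit_carc=_opt_bool(row["perit_carc"]),
                    residual_tumor=_opt_bool(row["residual_tumor"]),
                    platinum_response=row["platinum_response"] or "unknown",
                    age=_opt(row["age"], float),
                    pfs_months=_opt(row["pfs_months"], float),
                    pfs_event=_opt_bool(row["pfs_event"]),
                    os_months=_opt(row["os_months"], float),
                    os_event=_opt_bool(row["os_event"]),
                    ttp_months=_opt(row["ttp_months"], float),
                    ttp_event=_opt_bool(row["ttp_event"]),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}: line {i + 2}: {exc}") from exc
    return out


def write_tma(samples: Sequence[TMASample], path: Path | str) -> None:
    def b(v):  # optional bool -> "0"/"1"/""
        return "" if v is None else ("1" if v else "0")

    def o(v):
        return "" if v is None else v

    rows = [
        {
            "sample_id": s.sample_id,
            "antigen": s.antigen,
            "intensity_r1": s.intensity_by_rater[0],
            "intensity_r2": s.intensity_by_rater[1],
            "consensus_intensity": s.consensus_intensity,
            "percent_positive": s.percent_positive,
            "assessable": "1" if s.assessable else "0",
            "grade": o(s.grade),
            "figo_stage": o(s.figo_stage),
            "t_stage": o(s.t_stage),
            "perit_carc": b(s.perit_carc),
            "residual_tumor": b(s.residual_tumor),
            "platinum_response": s.platinum_response,
            "age": o(s.age),
            "pfs_months": o(s.pfs_months),
            "pfs_event": b(s.pfs_event),
            "os_months": o(s.os_months),
            "os_event": b(s.os_event),
            "ttp_months": o(s.ttp_months),
            "ttp_event": b(s.ttp_event),
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=_TMA_COLS).to_csv(path, index=False)


def read_subtype_dataset(
    matrix_path: Path | str, clusters_path: Path | str, probe_map_path: Path | str
) -> SubtypeDataset:
    """Subtype trio: probe x sample TSV, ``sample, cluster`` TSV, ``probe, gene`` TSV."""
    expr = pd.read_csv(matrix_path, sep="\t", index_col=0, float_precision="round_trip")
    if expr.isna().any().any():
        raise ValidationError(f"{matrix_path}: missing values in expression matrix")
    cl = _read_tsv(clusters_path)
    if list(cl.columns) != ["sample", "cluster"]:
        raise ValidationError(f"{clusters_path}: expected columns ['sample', 'cluster']")
    pm = _read_tsv(probe_map_path)
    if list(pm.columns) != ["probe", "gene"]:
        raise ValidationError(f"{probe_map_path}: expected columns ['probe', 'gene']")
    return SubtypeDataset(
        expression=expr,
        clusters=pd.Series(cl["cluster"].values, index=cl["sample"].values, name="cluster"),
        probe_map=pd.Series(pm["gene"].values, index=pm["probe"].values, name="gene"),
    )


def write_subtype_dataset(
    dataset: SubtypeDataset,
    matrix_path: Path | str,
    clusters_path: Path | str,
    probe_map_path: Path | str,
) -> None:
    dataset.expression.rename_axis("probe").to_csv(matrix_path, sep="\t")
    pd.DataFrame(
        {"sample": dataset.clusters.index, "cluster": dataset.clusters.values}
    ).to_csv(clusters_path, sep="\t", index=False)
    pd.DataFrame(
        {"probe": dataset.probe_map.index, "gene": dataset.probe_map.values}
    ).to_csv(probe_map_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pipeline configuration and driver
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """File paths, cutoffs and switches for an end-to-end run."""

    candidates: Optional[str] = None
    healthy_profile: Optional[str] = None
    tumor_matrix: Optional[str] = None
    tumor_summary: Optional[str] = None
    annotations: Optional[str] = None
    rubric: str = "default"
    tma: Optional[str] = None
    subtype_matrix: Optional[str] = None
    subtype_clusters: Optional[str] = None
    subtype_probe_map: Optional[str] = None
    low_tpm: float = 40.0
    medium_tpm: float = 400.0
    gate_low_median: float = 0.5
    gate_low_mean: float = 1.0
    gate_medium_median: float = 5.0
    gate_medium_mean: float = 10.0
    scoring_enabled: bool = True
    test_policy: str = "auto"
    seed: int = 0
    out_dir: str = "taavet_out"

    def __post_init__(self) -> None:
        TierCutoffs(self.low_tpm, self.medium_tpm)
        for v in (self.gate_low_median, self.gate_low_mean,
                  self.gate_medium_median, self.gate_medium_mean):
            if v <= 0:
                raise ValidationError("gate cutoffs must be positive")

    @property
    def tier_cutoffs(self) -> TierCutoffs:
        return TierCutoffs(self.low_tpm, self.medium_tpm)

    @property
    def gate_cutoffs(self) -> GateCutoffs:
        return GateCutoffs(
            low=(self.gate_low_median, self.gate_low_mean),
            medium=(self.gate_medium_median, self.gate_medium_mean),
        )

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclass_fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValidationError(f"{path}: unknown config keys {unknown}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dataclass_fields(self)}


@dataclass
class ReportBundle:
    """Artifacts of one end-to-end run."""

    filter_report: Optional[FilterReport] = None
    retained: list[TieredCandidate] = field(default_factory=list)
    ranked: Optional[list[RankedCandidate]] = None
    ihc_summaries: dict[str, StainingSummary] = field(default_factory=dict)
    associations: Optional[pd.DataFrame] = None
    subtype_results: Optional[pd.DataFrame] = None
    manifest: dict = field(default_factory=dict)


def ranked_to_frame(ranked: Sequence[RankedCandidate]) -> pd.DataFrame:
    criteria = sorted({k for r in ranked for k in r.candidate.breakdown})
    rows = []
    for r in ranked:
        s = r.candidate
        row = {
            "rank": "" if r.rank is None else r.rank,
            "id": s.candidate_id,
            "total": "" if s.total is None else f"{s.total:.2f}",
        }
        for c in criteria:
            row[c] = s.breakdown.get(c, "")
        row["tier"] = s.tier.value if s.tier else ""
        rows.append(row)
    return pd.DataFrame(rows, columns=["rank", "id", "total", *criteria, "tier"])


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the configured stages in order and return the artifact bundle.

    Stage order: filter cascade -> scoring/ranking -> IHC summaries ->
    clinical association battery -> subtype differential expression.  A
    stage runs only when its inputs are configured; any failure aborts with
    the stage name and cause.
    """
    bundle = ReportBundle()
    rubric = default_rubric() if config.rubric == "default" else read_rubric(config.rubric)

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    if config.candidates and config.healthy_profile and (
        config.tumor_matrix or config.tumor_summary
    ):
        def _filter():
            candidates = read_candidates(config.candidates)
            healthy = read_healthy_profile(config.healthy_profile)
            if config.tumor_summary:
                tumor = read_tumor_summary(config.tumor_summary)
            else:
                tumor = summarize_tumor_matrix(read_tumor_matrix(config.tumor_matrix))
            retained, report = run_cascade(
                candidates, healthy, tumor, config.tier_cutoffs, config.gate_cutoffs
            )
            logger.info(
                "filter: %d in -> %d retained (%s)",
                len(candidates), len(retained), dict(tier_split(retained)),
            )
            return retained, report

        bundle.retained, bundle.filter_report = _stage("filter", _filter)

    if config.scoring_enabled and config.annotations:
        def _score():
            annotations = read_annotations(config.annotations, rubric)
            scored = [score_candidate(a, rubric) for a in annotations]
            ranked = rank_candidates(scored)
            logger.info("scoring: %d candidates, %d scored",
                        len(scored), sum(1 for s in scored if s.scored))
            return ranked

        bundle.ranked = _stage("scoring", _score)

    if config.tma:
        def _ihc():
            samples = read_tma(config.tma)
            by_antigen: dict[str, list[TMASample]] = {}
            for s in samples:
                by_antigen.setdefault(s.antigen, []).append(s)
            summaries = {a: staining_summary(v) for a, v in sorted(by_antigen.items())}
            assoc = association_battery(samples, test_policy=config.test_policy)
            logger.info("ihc: %d samples, %d antigens, %d association tests",
                        len(samples), len(summaries), len(assoc))
            return summaries, assoc

        bundle.ihc_summaries, bundle.associations = _stage("ihc", _ihc)

    if config.subtype_matrix and config.subtype_clusters and config.subtype_probe_map:
        def _subtype():
            dataset = read_subtype_dataset(
                config.subtype_matrix, config.subtype_clusters, config.subtype_probe_map
            )
            results = subtype_analysis(dataset)
            logger.info("subtype: %d probes, %d samples",
                        dataset.expression.shape[0], dataset.expression.shape[1])
            return results

        bundle.subtype_results = _stage("subtype", _subtype)

    bundle.manifest = {
        "schema_version": 1,
        "taavet_version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
    }
    return bundle


def write_report(bundle: ReportBundle, out_dir: Path | str, format: str = "json") -> list[Path]:
    """Write every artifact in the bundle to ``out_dir``; returns paths written."""
    if format not in ("json", "text"):
        raise ValidationError(f"unknown report format {format!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _dump(obj, name):
        p = out / name
        with open(p, "w") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(p)

    if bundle.filter_report is not None:
        if format == "json":
            _dump(bundle.filter_report.to_dict(), "filter_report.json")
        else:
            p = out / "filter_report.txt"
            p.write_text(bundle.filter_report.to_text() + "\n")
            written.append(p)
    if bundle.ranked is not None:
        p = out / "ranked_candidates.tsv"
        ranked_to_frame(bundle.ranked).to_csv(p, sep="\t", index=False)
        written.append(p)
    if bundle.ihc_summaries:
        if format == "json":
            _dump({a: s.to_dict() for a, s in bundle.ihc_summaries.items()},
                  "ihc_summaries.json")
        else:
            p = out / "ihc_summaries.txt"
            p.write_text(
                "\n\n".join(s.to_text() for s in bundle.ihc_summaries.values()) + "\n"
            )
            written.append(p)
    if bundle.associations is not None:
        p = out / "associations.tsv"
        bundle.associations.to_csv(p, sep="\t", index=False)
        written.append(p)
    if bundle.subtype_results is not None:
        p = out / "subtype_results.tsv"
        bundle.subtype_results.to_csv(p, sep="\t", index=False)
        written.append(p)
    _dump(bundle.manifest, "manifest.json")
    return written
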