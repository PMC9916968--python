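"""Candidate selection cascade: tiering, gating and flow accounting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taavet.expression_filter import (
    AntigenCandidate,
    AntigenClass,
    ExclusionReason,
    ExpressionTier,
    GateCutoffs,
    GateStatus,
    TumorExpressionSummary,
    ValidationError,
    assign_tier,
    exclude_neoantigens,
    run_cascade,
    tier_split,
    tumor_gate,
)
from taavet.io import summarize_tumor_matrix
from taavet.synthetic import simulate_healthy_expression, simulate_tumor_cohort


def _oracle_tier(values, low=40.0, medium=400.0):
    """Independent one-line re-statement of the tiering rule."""
    m = max(values)
    return "low" if m < low else ("medium" if m < medium else "excluded")


def _oracle_gate(median, mean, median_min, mean_min):
    return "retained" if (median > median_min or mean > mean_min) else "omitted"


class TestNeoantigenExclusion:
    def test_class_filter_preserves_order(self):
        cands = [
            AntigenCandidate("A", AntigenClass.SELF),
            AntigenCandidate("B", AntigenClass.NEOANTIGEN),
            AntigenCandidate("C", AntigenClass.SELF),
            AntigenCandidate("D", AntigenClass.VIRAL),
            AntigenCandidate("E", AntigenClass.SELF),
        ]
        retained, n = exclude_neoantigens(cands)
        assert [c.id for c in retained] == ["A", "C", "E"]
        assert n == 2

    def test_empty_roster(self):
        assert exclude_neoantigens([]) == ([], 0)

    def test_full_scale_roster(self):
        # 237 candidates of which 70 are neoantigens -> 167 self-antigens remain
        cands = [AntigenCandidate(f"S{i}", AntigenClass.SELF) for i in range(167)]
        cands += [AntigenCandidate(f"N{i}", AntigenClass.NEOANTIGEN) for i in range(70)]
        retained, n = exclude_neoantigens(cands)
        assert (len(retained), n) == (167, 70)

    def test_duplicate_ids_rejected_by_name(self):
        cands = [
            AntigenCandidate("X", AntigenClass.SELF),
            AntigenCandidate("X", AntigenClass.SELF),
        ]
        with pytest.raises(ValidationError, match="X"):
            exclude_neoantigens(cands)


class TestAssignTier:
    @pytest.mark.parametrize(
        "row, expected",
        [
            ({"liver": 0.0, "lung": 0.0}, ExpressionTier.LOW),
            ({"liver": 40.0}, ExpressionTier.MEDIUM),  # boundary -> next tier
            ({"liver": 400.0}, ExpressionTier.EXCLUDED),
            ({"liver": 5.0, "testis": 390.0}, ExpressionTier.MEDIUM),
            ({"liver": 39.999}, ExpressionTier.LOW),
            ({"liver": 399.999}, ExpressionTier.MEDIUM),
        ],
    )
    def test_max_based_rule_with_strict_boundaries(self, row, expected):
        assert assign_tier(row) == expected
        assert assign_tier(row).value == _oracle_tier(list(row.values()))

    def test_empty_and_negative_rejected(self):
        with pytest.raises(ValidationError):
            assign_tier({})
        with pytest.raises(ValidationError):
            assign_tier({"liver": -1.0})

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(
        st.lists(st.floats(min_value=0, max_value=1000), min_size=1, max_size=8),
        st.integers(min_value=0, max_value=7),
        st.floats(min_value=0.1, max_value=500),
    )
    def test_monotone_in_any_tissue(self, values, idx, bump):
        """Raising a tissue's TPM never moves a gene to a less-expressed tier."""
        order = {"low": 0, "medium": 1, "excluded": 2}
        row = {f"t{i}": v for i, v in enumerate(values)}
        before = assign_tier(row)
        key = f"t{idx % len(values)}"
        row[key] = row[key] + bump
        after = assign_tier(row)
        assert order[after.value] >= order[before.value]


class TestTumorGate:
    @pytest.mark.parametrize(
        "tier, median, mean, expected",
        [
            (ExpressionTier.LOW, 0.6, 0.9, GateStatus.RETAINED),   # median clause
            (ExpressionTier.LOW, 0.5, 1.0, GateStatus.OMITTED),    # strict >
            (ExpressionTier.LOW, 0.4, 1.1, GateStatus.RETAINED),   # mean clause
            (ExpressionTier.MEDIUM, 4.0, 9.0, GateStatus.OMITTED),
            (ExpressionTier.MEDIUM, 6.0, 2.0, GateStatus.RETAINED),
            (ExpressionTier.MEDIUM, 5.0, 10.0, GateStatus.OMITTED),  # strict >
        ],
    )
    def test_or_of_strict_clauses(self, tier, median, mean, expected):
        s = TumorExpressionSummary("g", median, mean, 100)
        assert tumor_gate(s, tier) == expected
        cut = GateCutoffs().for_tier(tier)
        assert tumor_gate(s, tier).value == _oracle_gate(median, mean, *cut)

    def test_absent_summary_is_no_data(self):
        assert tumor_gate(None, ExpressionTier.LOW) == GateStatus.NO_DATA

    def test_excluded_tier_is_usage_error(self):
        with pytest.raises(ValidationError):
            tumor_gate(None, ExpressionTier.EXCLUDED)

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(
        st.floats(min_value=0, max_value=20),
        st.floats(min_value=0, max_value=20),
        st.floats(min_value=0, max_value=10),
        st.floats(min_value=0, max_value=10),
    )
    def test_monotone_in_expression(self, median, mean, dmed, dmean):
        """Increasing median or mean FPKM never flips retained -> omitted."""
        a = tumor_gate(TumorExpressionSummary("g", median, mean, 10), ExpressionTier.MEDIUM)
        b = tumor_gate(
            TumorExpressionSummary("g", median + dmed, mean + dmean, 10),
            ExpressionTier.MEDIUM,
        )
        assert not (a == GateStatus.RETAINED and b == GateStatus.OMITTED)


class TestRunCascade:
    @pytest.fixture(scope="class")
    @staticmethod
    def full_scale_run():
        healthy, truth = simulate_healthy_expression(
            n_low=60, n_medium=47, n_high=60, seed=17
        )
        gated = {
            g: ExpressionTier(t) for g, t in truth.tiers.items() if t != "excluded"
        }
        matrix, tumor_truth = simulate_tumor_cohort(gated, n_samples=373, seed=17)
        cands = [
            AntigenCandidate(g, AntigenClass.SELF) for g in sorted(truth.tiers)
        ] + [AntigenCandidate(f"NEO{i}", AntigenClass.NEOANTIGEN) for i in range(70)]
        retained, report = run_cascade(
            cands, healthy, summarize_tumor_matrix(matrix)
        )
        return retained, report, truth, tumor_truth

    def test_flow_counts_reproduce_planted_structure(self, full_scale_run):
        retained, report, *_ = full_scale_run
        stages = {s.stage_name: s for s in report.stages}
        assert stages["neoantigen_exclusion"].n_in == 237
        assert stages["neoantigen_exclusion"].n_out == 167
        assert stages["healthy_tissue_tiering"].n_excluded == 60
        assert stages["tumor_expression_gate"].n_in == 107
        assert report.n_final == 38
        assert tier_split(retained) == {"low": 21, "medium": 17}
        assert report.reason_counts()["no_tumor_data"] == 3
        assert report.reason_counts()["below_tumor_cutoff"] == 66

    def test_count_conservation_chained(self, full_scale_run):
        _, report, *_ = full_scale_run
        report.validate()  # n_in = n_excluded + n_out at every stage, chained
        for stage in report.stages:
            assert stage.n_in == stage.n_excluded + stage.n_out

    def test_recovers_planted_truth_exactly(self, full_scale_run):
        retained, report, truth, tumor_truth = full_scale_run
        retained_ids = {tc.candidate.id for tc in retained}
        expected = {g for g, s in tumor_truth.gate_status.items() if s == "retained"}
        assert retained_ids == expected
        for tc in retained:
            assert tc.tier.value == truth.tiers[tc.candidate.id]

    def test_oracle_equivalence_per_gene(self, full_scale_run):
        """Brute-force per-gene re-evaluation matches the cascade's verdicts."""
        retained, report, truth, tumor_truth = full_scale_run
        healthy, _ = simulate_healthy_expression(n_low=60, n_medium=47, n_high=60, seed=17)
        gated = {g: ExpressionTier(t) for g, t in truth.tiers.items() if t != "excluded"}
        matrix, _ = simulate_tumor_cohort(gated, n_samples=373, seed=17)
        retained_ids = {tc.candidate.id for tc in retained}
        excluded = {}
        for s in report.stages:
            excluded.update({k: v.value for k, v in s.exclusions.items()})
        rng = np.random.default_rng(0)
        for gene in rng.choice(sorted(truth.tiers), size=100, replace=False):
            tier = _oracle_tier(list(healthy.row(gene).values()))
            if tier == "excluded":
                assert excluded[gene] == "high_healthy_expression"
            elif gene not in matrix.index:
                assert excluded[gene] == "no_tumor_data"
            else:
                vals = matrix.loc[gene].to_numpy(float)
                cut = (0.5, 1.0) if tier == "low" else (5.0, 10.0)
                verdict = _oracle_gate(np.median(vals), np.mean(vals), *cut)
                if verdict == "retained":
                    assert gene in retained_ids
                else:
                    assert excluded[gene] == "below_tumor_cutoff"

    def test_all_high_expression_degenerate(self):
        healthy, truth = simulate_healthy_expression(n_low=0, n_medium=0, n_high=6, seed=1)
        cands = [AntigenCandidate(g, AntigenClass.SELF) for g in truth.tiers]
        retained, report = run_cascade(cands, healthy, {})
        assert retained == []
        assert set(report.reason_counts()) == {"high_healthy_expression"}

    def test_missing_healthy_gene_is_hard_error(self, healthy_profile_small):
        healthy, _ = healthy_profile_small
        cands = [AntigenCandidate("NOT_IN_TABLE", AntigenClass.SELF)]
        with pytest.raises(ValidationError, match="NOT_IN_TABLE"):
            run_cascade(cands, healthy, {})

    def test_missing_tumor_gene_is_soft_exclusion(self, healthy_profile_small):
        healthy, truth = healthy_profile_small
        low_genes = [g for g, t in truth.tiers.items() if t == "low"][:3]
        cands = [AntigenCandidate(g, AntigenClass.SELF) for g in low_genes]
        retained, report = run_cascade(cands, healthy, {})
        assert retained == []
        assert report.reason_counts()["no_tumor_data"] == 3
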