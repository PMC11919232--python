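"""Decision-tree behaviour: gating, capping, thresholds, auditability."""

import pytest

from ssaso_triage import (
    DEFAULT_CONFIG,
    PatientProfile,
    RunConfig,
    SpliceEvidence,
    VerdictCategory,
    evaluate_cryptic_splice,
    evaluate_patient,
    hotspot_score,
    parse_hgvs_c,
    simulate_exon_skip,
    triage,
)
from ssaso_triage.exceptions import InputConsistencyError
from ssaso_triage.rule_engine import (
    W_ALLELE_SPECIFICITY,
    W_CANONICAL_PARTIAL,
    W_EXON_INCLUSION_EXCEPTIONAL,
    W_GOF_DN,
    W_MILDER_PHENOTYPE_OVERRIDE,
    W_PROXIMITY,
    W_SIZE_CAUTION,
    W_SPLICE_REGION_OVERLAP,
    evaluate_truncating,
)

CRYPTIC_OK = {
    "observed_effect": "cryptic_exon_inclusion",
    "canonical_splicing_intact": "yes",
    "assay": "rna_seq",
}


def _cryptic(model, hgvs, evidence=None, config=DEFAULT_CONFIG):
    ev = SpliceEvidence.from_dict(evidence or CRYPTIC_OK)
    return evaluate_cryptic_splice(model, parse_hgvs_c(hgvs), ev, config=config)


class TestCrypticTree:
    def test_distance_four_is_rejected(self, model):
        v = _cryptic(model, "c.171+4T>C")
        assert v.category is VerdictCategory.NOT_AMENABLE
        assert "distance_hard_cutoff" in v.trace.failed_mandatory()

    def test_distance_ten_is_conditional_with_proximity_caution(self, model):
        v = _cryptic(model, "c.171+10T>C")
        assert v.category is VerdictCategory.CONDITIONALLY_AMENABLE
        assert W_PROXIMITY in v.warnings

    def test_deep_intronic_is_the_ideal_case(self, model):
        v = _cryptic(model, "c.457-1340A>G")
        assert v.category is VerdictCategory.AMENABLE_CRYPTIC_SPLICE_BLOCK
        assert any("deep intronic" in n for n in v.notes)
        assert v.warnings == []

    def test_three_regime_distance_sweep(self, model):
        """Verdict as a function of distance is a step function with change
        points exactly at the hard and recommended cut-offs."""
        cats = {}
        for d in range(1, 201):
            cats[d] = _cryptic(model, f"c.171+{d}T>C").category
        for d, cat in cats.items():
            if d < DEFAULT_CONFIG.hard_cutoff_nt:
                assert cat is VerdictCategory.NOT_AMENABLE, d
            elif d < DEFAULT_CONFIG.recommended_cutoff_nt:
                assert cat is VerdictCategory.CONDITIONALLY_AMENABLE, d
            else:
                assert cat is VerdictCategory.AMENABLE_CRYPTIC_SPLICE_BLOCK, d

    def test_branch_point_window_rejects(self, model):
        v = _cryptic(model, "c.172-27T>C")
        assert v.category is VerdictCategory.NOT_AMENABLE
        assert "critical_landmark" in v.trace.failed_mandatory()

    def test_acceptor_region_caps_at_conditional(self, model):
        # 17 nt upstream: outside canonical/branch, inside the 20-nt
        # acceptor region, beyond the recommended distance cut-off
        v = _cryptic(model, "c.172-17T>C")
        assert v.category is VerdictCategory.CONDITIONALLY_AMENABLE
        assert W_SPLICE_REGION_OVERLAP in v.warnings

    def test_lost_canonical_splicing_rejects(self, model):
        v = _cryptic(
            model,
            "c.457-1340A>G",
            {**CRYPTIC_OK, "canonical_splicing_intact": "no",
             "observed_effect": "cryptic_exon_inclusion"},
        )
        assert v.category is VerdictCategory.NOT_AMENABLE

    def test_partial_canonical_splicing_caps(self, model):
        v = _cryptic(
            model,
            "c.457-1340A>G",
            {**CRYPTIC_OK, "canonical_splicing_intact": "partial"},
        )
        assert v.category is VerdictCategory.CONDITIONALLY_AMENABLE
        assert W_CANONICAL_PARTIAL in v.warnings

    def test_non_cryptic_effect_is_a_usage_error(self, model):
        with pytest.raises(InputConsistencyError):
            _cryptic(model, "c.171+40T>C", {**CRYPTIC_OK, "observed_effect": "exon_skipping"})

    def test_inconsistent_affected_exon_detected(self, model):
        with pytest.raises(InputConsistencyError):
            _cryptic(
                model,
                "c.171+40T>C",
                {**CRYPTIC_OK, "affected_exon_index": 9},
            )

    def test_thresholds_come_from_config(self, model):
        cfg = DEFAULT_CONFIG.with_overrides(hard_cutoff_nt=8)
        assert _cryptic(model, "c.171+7T>C", config=cfg).category is (
            VerdictCategory.NOT_AMENABLE
        )
        assert _cryptic(model, "c.171+7T>C").category is (
            VerdictCategory.CONDITIONALLY_AMENABLE
        )


class TestExonSkipTree:
    def test_nonsense_in_clean_internal_exon_is_amenable(self, bundle):
        a = bundle.variant(6)
        v = triage(
            bundle.model, a.variant, a.evidence,
            domains=bundle.domains, pathogenic_table=bundle.pathogenic_table,
        )
        assert v.category is VerdictCategory.AMENABLE_EXON_SKIP
        assert W_ALLELE_SPECIFICITY in v.warnings  # heterozygous carrier
        assert v.required_followups  # never a free pass

    def test_domain_overlap_rejects_missense(self, bundle):
        a = bundle.variant(7)
        v = triage(
            bundle.model, a.variant, a.evidence,
            domains=bundle.domains, pathogenic_table=bundle.pathogenic_table,
        )
        assert v.category is VerdictCategory.NOT_AMENABLE
        assert "functional_domain" in v.trace.failed_mandatory()

    def test_hotspot_rejects_missense(self, bundle):
        a = bundle.variant(8)
        v = triage(
            bundle.model, a.variant, a.evidence,
            domains=bundle.domains, pathogenic_table=bundle.pathogenic_table,
        )
        assert v.category is VerdictCategory.NOT_AMENABLE
        assert "missense_hotspot" in v.trace.failed_mandatory()

    def test_missense_never_beats_conditional(self, bundle):
        # same missense, but with no hotspot table and no domains: survives
        # every gate yet stays capped at conditionally amenable
        a = bundle.variant(8)
        v = triage(bundle.model, a.variant, a.evidence)
        assert v.category is VerdictCategory.CONDITIONALLY_AMENABLE

    def test_all_mandatory_gates_always_appear_in_the_trace(self, bundle):
        a = bundle.variant(7)
        v = triage(bundle.model, a.variant, a.evidence, domains=bundle.domains)
        ids = [n.node_id for n in v.trace.nodes]
        for gate in (
            "internal_coding_exon",
            "exon_in_frame",
            "junction_stop",
            "functional_domain",
            "population_skip_pathogenic",
        ):
            assert gate in ids

    def test_size_caution_is_a_warning_not_a_rejection(self, model):
        # exon 9 removes 120/900 nt = 13.3% of the CDS
        skip = simulate_exon_skip(model, 9)
        v = evaluate_truncating(model, parse_hgvs_c("c.800C>T"), skip)
        assert v.category is VerdictCategory.AMENABLE_EXON_SKIP
        assert W_SIZE_CAUTION in v.warnings

    def test_pathogenic_skip_rejects_unless_override(self, model, bundle):
        a = bundle.variant(6)
        v = triage(
            model, a.variant, a.evidence,
            population_evidence="skip_known_pathogenic",
        )
        assert v.category is VerdictCategory.NOT_AMENABLE

        cfg = DEFAULT_CONFIG.with_overrides(
            milder_phenotype_override=True,
            override_justification="in-frame deletion carriers show a milder course",
        )
        v2 = triage(
            model, a.variant, a.evidence,
            population_evidence="skip_known_pathogenic", config=cfg,
        )
        assert v2.category is VerdictCategory.AMENABLE_EXON_SKIP
        assert W_MILDER_PHENOTYPE_OVERRIDE in v2.warnings


class TestHotspotScore:
    def _rows(self, specs):
        return [
            {"position_c": p, "consequence": c, "classification": k,
             "functional_lof": f}
            for p, c, k, f in specs
        ]

    def test_five_clustered_pathogenic_missense_is_a_hotspot(self):
        v = parse_hgvs_c("c.650A>G")
        rows = self._rows(
            [(p, "missense", "pathogenic", "") for p in (630, 640, 650, 660, 670)]
        )
        rep = hotspot_score(v, rows, (628, 726))
        assert rep.is_hotspot
        assert rep.n_pathogenic_missense_in_exon == 5

    def test_missense_minority_is_not_a_hotspot(self):
        v = parse_hgvs_c("c.650A>G")
        rows = self._rows(
            [(630, "missense", "pathogenic", ""), (640, "missense", "pathogenic", "")]
            + [(p, "nonsense", "pathogenic", "") for p in (645, 655, 665, 675)]
        )
        rep = hotspot_score(v, rows, (628, 726))
        assert not rep.is_hotspot  # 2/6 missense: fails count and majority

    def test_functional_lof_within_window_flags(self):
        v = parse_hgvs_c("c.650A>G")
        near = self._rows([(700, "missense", "pathogenic", "yes")])
        far = self._rows([(900, "missense", "pathogenic", "yes")])
        assert hotspot_score(v, near, (628, 726)).lof_evidence_nearby
        assert not hotspot_score(v, far, (628, 726)).lof_evidence_nearby

    def test_malformed_rows_are_rejected_individually(self):
        v = parse_hgvs_c("c.650A>G")
        rows = [
            {"position_c": "not-a-number", "consequence": "missense",
             "classification": "pathogenic"},
            {"position_c": 640, "consequence": "weird", "classification": "pathogenic"},
            {"position_c": 650, "consequence": "missense", "classification": "benign"},
            {"position_c": 660, "consequence": "missense",
             "classification": "pathogenic", "functional_lof": ""},
        ]
        rep = hotspot_score(v, rows, (628, 726))
        assert len(rep.rejected_rows) == 2  # benign row is valid, just uncounted
        assert rep.n_pathogenic_missense_in_exon == 1

    def test_empty_table_scores_zero(self):
        rep = hotspot_score(parse_hgvs_c("c.650A>G"), None, (628, 726))
        assert not rep.is_hotspot and not rep.lof_evidence_nearby


class TestDispatch:
    def test_non_lof_mechanism_is_out_of_scope(self, model):
        v = triage(
            model, parse_hgvs_c("c.490C>T"),
            SpliceEvidence.from_dict({"observed_effect": "none"}),
            mechanism="gof",
        )
        assert v.category is VerdictCategory.OUT_OF_SCOPE
        assert W_GOF_DN in v.warnings

    def test_utr_variant_is_out_of_scope(self, model):
        v = triage(
            model, parse_hgvs_c("c.-12A>G"),
            SpliceEvidence.from_dict({"observed_effect": "none"}),
        )
        assert v.category is VerdictCategory.OUT_OF_SCOPE

    def test_claimed_effect_without_assay_is_insufficient(self, model):
        v = triage(
            model, parse_hgvs_c("c.457-1340A>G"),
            SpliceEvidence.from_dict(
                {"observed_effect": "cryptic_exon_inclusion", "assay": "none"}
            ),
        )
        assert v.category is VerdictCategory.INSUFFICIENT_EVIDENCE
        assert v.required_followups

    def test_intronic_without_effect_is_insufficient(self, model):
        v = triage(
            model, parse_hgvs_c("c.457-1340A>G"),
            SpliceEvidence.from_dict({"observed_effect": "none"}),
        )
        assert v.category is VerdictCategory.INSUFFICIENT_EVIDENCE

    def test_canonical_disruption_rejects_with_inclusion_flag(self, bundle):
        a = bundle.variant(5)  # exonic enhancer variant causing exon skipping
        v = triage(bundle.model, a.variant, a.evidence)
        assert v.category is VerdictCategory.NOT_AMENABLE
        assert W_EXON_INCLUSION_EXCEPTIONAL in v.warnings

    def test_synonymous_without_effect_is_out_of_scope(self, model):
        v = triage(
            model, parse_hgvs_c("c.300C>T"),
            SpliceEvidence.from_dict({"observed_effect": "none"}),
        )
        assert v.category is VerdictCategory.OUT_OF_SCOPE

    def test_identical_inputs_give_identical_reports(self, bundle):
        a = bundle.variant(3)
        r1 = triage(bundle.model, a.variant, a.evidence).to_dict()
        r2 = triage(bundle.model, a.variant, a.evidence).to_dict()
        assert r1 == r2


class TestPatientSelection:
    GOOD = {
        "severity": "life_threatening",
        "monogenic": True,
        "primary_tissue": "brain",
        "treatable_in_two_years": True,
        "outcome_measures_definable": True,
    }

    def test_all_criteria_met(self):
        res = evaluate_patient(PatientProfile.from_dict(self.GOOD))
        assert res.eligible
        assert len(res.criteria) == 5

    @pytest.mark.parametrize(
        "field, value",
        [
            ("severity", "other"),
            ("monogenic", False),
            ("primary_tissue", "other"),
            ("treatable_in_two_years", False),
            ("outcome_measures_definable", False),
        ],
    )
    def test_any_single_failure_disqualifies(self, field, value):
        profile = PatientProfile.from_dict({**self.GOOD, field: value})
        assert not evaluate_patient(profile).eligible

    def test_eye_and_spinal_cord_are_dosable_tissues(self):
        for tissue in ("eye", "spinal_cord"):
            profile = PatientProfile.from_dict({**self.GOOD, "primary_tissue": tissue})
            assert evaluate_patient(profile).eligible

    def test_missing_field_is_an_input_error(self):
        from ssaso_triage.exceptions import TriageInputError

        with pytest.raises(TriageInputError, match="monogenic"):
            PatientProfile.from_dict({k: v for k, v in self.GOOD.items() if k != "monogenic"})
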