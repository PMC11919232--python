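"""Decision-tree rule engine for ssASO amenability triage.

Two trees are implemented, mirroring clinical triage practice for
splice-switching antisense oligonucleotides:

* **Cryptic-splice tree** — for variants functionally shown to create or
  activate a cryptic splice site. A ssASO covering the variant can mask the
  cryptic site and restore canonical splicing, provided (a) canonical
  splicing is otherwise intact, (b) the variant does not sit on a canonical
  splice dinucleotide or in the branch-point window (an ASO there would
  block elements the spliceosome needs), and (c) the variant is far enough
  from the nearest splice site for an ASO to bind without interference:
  below the hard cut-off (default 5 nt) the case is rejected, between hard
  and recommended cut-off (default 15 nt) it is conditionally amenable with
  a proximity caution, at or beyond the recommended cut-off it is amenable
  (deep-intronic positions, >100 nt out, are the ideal case). Overlap with
  the extended donor/acceptor regions caps the verdict at conditionally
  amenable rather than rejecting outright: cryptic-splice variants inside
  those regions with intact canonical splicing are documented to be
  approachable, but ASO placement needs extra care.

* **Exon-skip tree** — for exonic loss-of-function variants that do not
  disrupt splicing. Skipping the variant exon is considered when the exon is
  internal (not first/last coding), in frame (length divisible by 3), free
  of known functional domains, the new junction does not create a stop
  codon, and exon skipping is not itself a known pathogenic event. Nonsense
  and frameshift variants that survive all gates are amenable; missense and
  in-frame indels are additionally screened against functional-domain
  overlap and a pathogenic-missense hotspot analysis and are never rated
  better than conditionally amenable (expert review is mandatory for them).

Every evaluation returns a :class:`Verdict` with an ordered
:class:`RuleTrace` of the nodes fired, so each call is fully auditable and
byte-identical across repeated runs on identical input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import pandas as pd

from .config import DEFAULT_CONFIG, RunConfig
from .exceptions import InputConsistencyError, TriageInputError
from .exon_skip import (
    JunctionEvent,
    PopulationEvidence,
    SkipSimulationResult,
    simulate_exon_skip,
)
from .region_classifier import RegionClass, RegionReport, classify_region
from .transcript_model import DomainAnnotation, TranscriptModel
from .variant_model import (
    Assay,
    CANONICAL_DISRUPTION_EFFECTS,
    CRYPTIC_EFFECTS,
    CanonicalSplicing,
    ConsequenceClass,
    ObservedEffect,
    SpliceEvidence,
    VariantDescriptor,
    Zygosity,
    derive_protein_consequence,
)

logger = logging.getLogger(__name__)


class VerdictCategory(str, Enum):
    AMENABLE_CRYPTIC_SPLICE_BLOCK = "AMENABLE_CRYPTIC_SPLICE_BLOCK"
    AMENABLE_EXON_SKIP = "AMENABLE_EXON_SKIP"
    CONDITIONALLY_AMENABLE = "CONDITIONALLY_AMENABLE"
    NOT_AMENABLE = "NOT_AMENABLE"
    INSUFFICIENT_EVIDENCE = "INSUFFICIENT_EVIDENCE"
    OUT_OF_SCOPE = "OUT_OF_SCOPE"


#: warning codes attached to verdicts
W_PROXIMITY = "proximity_caution"
W_SPLICE_REGION_OVERLAP = "splice_region_overlap"
W_NONSYNONYMOUS_CRYPTIC = "nonsynonymous_cryptic_caution"
W_WHOLE_EXON_SKIP_RISK = "whole_exon_skip_risk"
W_SIZE_CAUTION = "large_removal_caution"
W_JUNCTION_MISSENSE = "junction_missense"
W_JUNCTION_UNKNOWN = "junction_undeterminable"
W_ALLELE_SPECIFICITY = "allele_specificity_needed"
W_GOF_DN = "gain_of_function_or_dominant_negative"
W_EXON_INCLUSION_EXCEPTIONAL = "exon_inclusion_exceptional_option"
W_CANONICAL_PARTIAL = "canonical_splicing_not_fully_intact"
W_MILDER_PHENOTYPE_OVERRIDE = "milder_phenotype_override_applied"
W_SKIPPED_IN_HEALTHY = "exon_seen_skipped_in_healthy"

NOTE_ALLELE_NOT_NEEDED = "allele_specificity_not_needed"

F_FUNCTIONAL_VALIDATION = "functional_validation_of_skipped_protein"
F_EXPERT_CONSULT = "expert_consultation_on_protein_function"
F_CONFIRM_SPLICING = "functional_splicing_assay_required"


@dataclass(frozen=True)
class TraceNode:
    node_id: str
    question: str
    answer: str
    consequence: str

    def to_dict(self) -> dict:
        return {
            "node_id": self.node_id,
            "question": self.question,
            "answer": self.answer,
            "consequence": self.consequence,
        }


@dataclass
class RuleTrace:
    nodes: list[TraceNode] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def fire(self, node_id: str, question: str, answer, consequence: str) -> None:
        node = TraceNode(node_id, question, str(answer), consequence)
        self.nodes.append(node)
        logger.info(
            "rule node %s: %s -> %s (%s)", node_id, question, answer, consequence
        )

    def failed_mandatory(self) -> list[str]:
        return [n.node_id for n in self.nodes if n.consequence == "reject"]

    def to_dict(self) -> dict:
        return {"nodes": [n.to_dict() for n in self.nodes], "config": self.config}


@dataclass
class Verdict:
    category: VerdictCategory
    trace: RuleTrace
    warnings: list[str] = field(default_factory=list)
    required_followups: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def add_warning(self, code: str) -> None:
        if code not in self.warnings:
            self.warnings.append(code)

    def to_dict(self) -> dict:
        return {
            "category": self.category.value,
            "warnings": list(self.warnings),
            "required_followups": list(self.required_followups),
            "notes": list(self.notes),
            "trace": self.trace.to_dict(),
        }


@dataclass(frozen=True)
class HotspotReport:
    window_nt: int
    n_pathogenic_missense_in_exon: int
    n_pathogenic_missense_in_window: int
    n_pathogenic_in_exon: int
    density_per_100_nt: float
    is_hotspot: bool
    lof_evidence_nearby: bool
    rejected_rows: tuple[tuple[int, str], ...] = ()
    non_default_parameters: bool = True  # hotspot constants are not guideline values

    def to_dict(self) -> dict:
        return {
            "window_nt": self.window_nt,
            "n_pathogenic_missense_in_exon": self.n_pathogenic_missense_in_exon,
            "n_pathogenic_missense_in_window": self.n_pathogenic_missense_in_window,
            "n_pathogenic_in_exon": self.n_pathogenic_in_exon,
            "density_per_100_nt": round(self.density_per_100_nt, 4),
            "is_hotspot": self.is_hotspot,
            "lof_evidence_nearby": self.lof_evidence_nearby,
            "rejected_rows": [list(r) for r in self.rejected_rows],
            "non_default_parameters": self.non_default_parameters,
        }


# --------------------------------------------------------------------------
# cryptic-splice tree
# --------------------------------------------------------------------------


def evaluate_cryptic_splice(
    model: TranscriptModel,
    v: VariantDescriptor,
    evidence: SpliceEvidence,
    region: Optional[RegionReport] = None,
    config: RunConfig = DEFAULT_CONFIG,
) -> Verdict:
    """Run the cryptic-splice-blocking decision tree for one variant."""
    if evidence.observed_effect not in CRYPTIC_EFFECTS:
        raise InputConsistencyError(
            "cryptic-splice evaluation requires a cryptic-splice observed "
            f"effect, got {evidence.observed_effect.value}"
        )
    if region is None:
        region = classify_region(model, v, config)
    _check_evidence_consistency(model, v, evidence, region)

    trace = RuleTrace(config=config.to_dict())
    verdict = Verdict(VerdictCategory.AMENABLE_CRYPTIC_SPLICE_BLOCK, trace)
    reject = False
    cap_conditional = False

    confirmed = evidence.assay is not Assay.NONE
    trace.fire(
        "evidence_confirmed",
        "Splice-disrupting effect confirmed by a functional assay?",
        confirmed,
        "pass" if confirmed else "insufficient_evidence",
    )
    if not confirmed:
        verdict.category = VerdictCategory.INSUFFICIENT_EVIDENCE
        verdict.required_followups.append(F_CONFIRM_SPLICING)
        return verdict

    intact = evidence.canonical_splicing_intact
    trace.fire(
        "canonical_splicing_intact",
        "Is canonical splicing otherwise intact?",
        intact.value,
        "reject" if intact is CanonicalSplicing.NO else "pass",
    )
    if intact is CanonicalSplicing.NO:
        reject = True
    elif intact in (CanonicalSplicing.PARTIAL, CanonicalSplicing.UNKNOWN):
        cap_conditional = True
        verdict.add_warning(W_CANONICAL_PARTIAL)

    on_critical = (
        region.has_tag(RegionClass.CANONICAL_DONOR)
        or region.has_tag(RegionClass.CANONICAL_ACCEPTOR)
        or region.has_tag(RegionClass.BRANCH_POINT_WINDOW)
    )
    trace.fire(
        "critical_landmark",
        "Variant on a canonical splice dinucleotide or in the branch-point window?",
        on_critical,
        "reject" if on_critical else "pass",
    )
    if on_critical:
        reject = True

    d = region.distance_to_nearest_splice_site
    below_hard = d is not None and d < config.hard_cutoff_nt
    trace.fire(
        "distance_hard_cutoff",
        f"Distance to nearest splice site >= hard cut-off "
        f"({config.hard_cutoff_nt} nt)?",
        f"d={d}",
        "reject" if below_hard else "pass",
    )
    if below_hard:
        reject = True
    else:
        below_recommended = d is not None and d < config.recommended_cutoff_nt
        trace.fire(
            "distance_recommended_cutoff",
            f"Distance to nearest splice site >= recommended cut-off "
            f"({config.recommended_cutoff_nt} nt)?",
            f"d={d}",
            "caution" if below_recommended else "pass",
        )
        if below_recommended:
            cap_conditional = True
            verdict.add_warning(W_PROXIMITY)

    in_splice_region = region.has_tag(RegionClass.DONOR_REGION) or region.has_tag(
        RegionClass.ACCEPTOR_REGION
    )
    if in_splice_region and not reject:
        trace.fire(
            "splice_region_overlap",
            "Variant overlaps the extended donor/acceptor splice region?",
            True,
            "caution",
        )
        cap_conditional = True
        verdict.add_warning(W_SPLICE_REGION_OVERLAP)

    if region.primary_class is RegionClass.EXONIC:
        consequence = derive_protein_consequence(model, v)
        nonsyn = consequence not in (
            ConsequenceClass.SYNONYMOUS,
            ConsequenceClass.NONE,
            ConsequenceClass.UNKNOWN,
        )
        trace.fire(
            "exonic_nonsynonymous",
            "Exonic cryptic-splice variant also changes the protein?",
            consequence.value,
            "caution" if nonsyn else "pass",
        )
        if nonsyn:
            verdict.add_warning(W_NONSYNONYMOUS_CRYPTIC)
        verdict.add_warning(W_WHOLE_EXON_SKIP_RISK)

    if reject:
        verdict.category = VerdictCategory.NOT_AMENABLE
    elif cap_conditional:
        verdict.category = VerdictCategory.CONDITIONALLY_AMENABLE
    else:
        verdict.category = VerdictCategory.AMENABLE_CRYPTIC_SPLICE_BLOCK
        if d is not None and d > config.deep_intronic_nt:
            verdict.notes.append(
                "deep intronic position: ideal for cryptic-splice blocking"
            )
    assess_allele_specificity(v, verdict)
    return verdict


def _check_evidence_consistency(
    model: TranscriptModel,
    v: VariantDescriptor,
    evidence: SpliceEvidence,
    region: RegionReport,
) -> None:
    idx = evidence.affected_exon_index
    if idx is None:
        return
    if not (1 <= idx <= model.n_exons):
        raise InputConsistencyError(
            f"evidence references exon {idx}, transcript has {model.n_exons} exons"
        )
    touchable: set[int] = set()
    if region.exon_index is not None:
        touchable = {region.exon_index - 1, region.exon_index, region.exon_index + 1}
    elif region.intron_index is not None:
        touchable = {region.intron_index, region.intron_index + 1}
    if touchable and idx not in touchable:
        raise InputConsistencyError(
            f"evidence references exon {idx}, but the variant lies near "
            f"exon(s) {sorted(t for t in touchable if 1 <= t <= model.n_exons)}"
        )


# --------------------------------------------------------------------------
# exon-skip tree (shared mandatory gates)
# --------------------------------------------------------------------------


def _skip_gates(
    verdict: Verdict,
    skip: SkipSimulationResult,
    config: RunConfig,
) -> bool:
    """Mandatory exon-skip gates shared by the truncating and missense paths.

    All gates are always evaluated so the trace is complete; returns True
    when any mandatory gate failed.
    """
    trace = verdict.trace
    reject = False

    trace.fire(
        "internal_coding_exon",
        "Is the variant exon an internal coding exon (not first/last coding)?",
        skip.internal_exon,
        "pass" if skip.internal_exon else "reject",
    )
    if not skip.internal_exon:
        reject = True

    trace.fire(
        "exon_in_frame",
        "Is the exon's coding length divisible by 3 (frame-preserving skip)?",
        skip.frame_preserved,
        "pass" if skip.frame_preserved else "reject",
    )
    if not skip.frame_preserved:
        reject = True
        verdict.notes.append(
            "out-of-frame exon: consider multi-exon strategy (out of scope)"
        )

    stop = skip.junction_event is JunctionEvent.STOP_GAINED
    trace.fire(
        "junction_stop",
        "Does the new exon-exon junction create a stop codon?",
        skip.junction_event.value,
        "reject" if stop else "pass",
    )
    if stop:
        reject = True

    has_domain = bool(skip.domains_overlapped)
    trace.fire(
        "functional_domain",
        "Does the exon overlap a known functional domain?",
        [o.domain.name for o in skip.domains_overlapped],
        "reject" if has_domain else "pass",
    )
    if has_domain:
        reject = True

    pathogenic_skip = skip.population_flags is PopulationEvidence.SKIP_KNOWN_PATHOGENIC
    override = config.milder_phenotype_override and bool(config.override_justification)
    trace.fire(
        "population_skip_pathogenic",
        "Is skipping/deletion of this exon a known pathogenic event?",
        skip.population_flags.value,
        "reject" if (pathogenic_skip and not override) else "pass",
    )
    if pathogenic_skip:
        if override:
            verdict.add_warning(W_MILDER_PHENOTYPE_OVERRIDE)
            verdict.notes.append(
                f"override justification: {config.override_justification}"
            )
        else:
            reject = True

    # cautions (never rejections)
    if skip.fraction_cds_removed > config.size_caution_percent:
        verdict.add_warning(W_SIZE_CAUTION)
        verdict.notes.append(
            f"skip removes {skip.fraction_cds_removed:.2f}% of the coding "
            f"sequence (> {config.size_caution_percent:g}% caution threshold); "
            "tolerated removal size is highly gene/protein dependent"
        )
    if skip.junction_event is JunctionEvent.JUNCTION_MISSENSE:
        verdict.add_warning(W_JUNCTION_MISSENSE)
    if skip.junction_event is JunctionEvent.UNDETERMINABLE_NO_SEQUENCE:
        verdict.add_warning(W_JUNCTION_UNKNOWN)
    if skip.population_flags is PopulationEvidence.SEEN_SKIPPED_IN_HEALTHY:
        verdict.add_warning(W_SKIPPED_IN_HEALTHY)
        verdict.notes.append(
            "exon deletion observed in healthy individuals: supportive of skipping"
        )
    return reject


def evaluate_truncating(
    model: TranscriptModel,
    v: VariantDescriptor,
    skip: SkipSimulationResult,
    config: RunConfig = DEFAULT_CONFIG,
) -> Verdict:
    """Exon-skip tree for nonsense/frameshift variants."""
    if skip is None:
        raise TriageInputError("truncating evaluation requires a skip simulation")
    trace = RuleTrace(config=config.to_dict())
    verdict = Verdict(VerdictCategory.AMENABLE_EXON_SKIP, trace)
    reject = _skip_gates(verdict, skip, config)
    if reject:
        verdict.category = VerdictCategory.NOT_AMENABLE
        return verdict
    verdict.category = VerdictCategory.AMENABLE_EXON_SKIP
    verdict.required_followups.extend([F_FUNCTIONAL_VALIDATION, F_EXPERT_CONSULT])
    assess_allele_specificity(v, verdict)
    return verdict


def evaluate_missense(
    model: TranscriptModel,
    v: VariantDescriptor,
    skip: SkipSimulationResult,
    hotspot: HotspotReport,
    config: RunConfig = DEFAULT_CONFIG,
) -> Verdict:
    """Exon-skip tree for missense / small in-frame indel variants.

    All truncating-path gates apply; additionally the pathogenic-missense
    hotspot analysis can reject, and survivors are capped at conditionally
    amenable with mandatory expert review (these are the hardest variants to
    call: if the single residue change abolishes function, removing the whole
    exon is likely to as well).
    """
    if hotspot is None:
        raise TriageInputError("missense evaluation requires a hotspot report")
    trace = RuleTrace(config=config.to_dict())
    verdict = Verdict(VerdictCategory.CONDITIONALLY_AMENABLE, trace)
    reject = _skip_gates(verdict, skip, config)

    hotspot_fail = hotspot.is_hotspot or hotspot.lof_evidence_nearby
    trace.fire(
        "missense_hotspot",
        "Is the variant in a pathogenic-missense hotspot or near variants "
        "with functional loss-of-function evidence?",
        {
            "is_hotspot": hotspot.is_hotspot,
            "lof_evidence_nearby": hotspot.lof_evidence_nearby,
        },
        "reject" if hotspot_fail else "pass",
    )
    if hotspot_fail:
        reject = True

    if reject:
        verdict.category = VerdictCategory.NOT_AMENABLE
        return verdict
    # never auto-amenable for missense: expert review is mandatory
    verdict.category = VerdictCategory.CONDITIONALLY_AMENABLE
    verdict.required_followups.extend([F_FUNCTIONAL_VALIDATION, F_EXPERT_CONSULT])
    assess_allele_specificity(v, verdict)
    return verdict


# --------------------------------------------------------------------------
# hotspot analysis
# --------------------------------------------------------------------------

_PATHOGENIC_CLASSES = {"pathogenic", "likely_pathogenic"}
_KNOWN_CONSEQUENCES = {c.value for c in ConsequenceClass}


def hotspot_score(
    v: VariantDescriptor,
    pathogenic_table: "pd.DataFrame | Iterable[dict] | None",
    exon_interval_c: tuple[int, int],
    config: RunConfig = DEFAULT_CONFIG,
) -> HotspotReport:
    """Score the pathogenic-missense density around a variant.

    ``pathogenic_table`` rows need ``position_c`` (coding coordinate),
    ``consequence``, ``classification`` and optionally ``functional_lof``.
    Malformed rows are rejected individually with a logged reason, never
    silently dropped. The exon is called a hotspot when the in-exon
    (likely) pathogenic missense count reaches ``hotspot_min_count`` AND
    missense variants form at least ``hotspot_majority_fraction`` of all
    (likely) pathogenic variants in the exon.
    """
    rows: list[dict]
    if pathogenic_table is None:
        rows = []
    elif isinstance(pathogenic_table, pd.DataFrame):
        rows = pathogenic_table.to_dict("records")
    else:
        rows = list(pathogenic_table)

    a, b = exon_interval_c
    rejected: list[tuple[int, str]] = []
    in_exon_missense = in_exon_pathogenic = in_window_missense = 0
    lof_nearby = False
    for i, row in enumerate(rows):
        try:
            pos = int(row["position_c"])
            consequence = str(row["consequence"]).strip().lower()
            classification = str(row["classification"]).strip().lower()
        except (KeyError, TypeError, ValueError) as e:
            rejected.append((i, f"malformed row: {e}"))
            logger.warning("hotspot table row %d rejected: %s", i, e)
            continue
        if pos < 1:
            rejected.append((i, f"position_c {pos} < 1"))
            logger.warning("hotspot table row %d rejected: position %d", i, pos)
            continue
        if consequence not in _KNOWN_CONSEQUENCES:
            rejected.append((i, f"unknown consequence {consequence!r}"))
            logger.warning(
                "hotspot table row %d rejected: consequence %r", i, consequence
            )
            continue
        if classification not in _PATHOGENIC_CLASSES:
            continue  # benign/VUS rows are valid input, just not counted
        is_missense = consequence == ConsequenceClass.MISSENSE.value
        in_exon = a <= pos <= b
        in_window = abs(pos - v.anchor_c) <= config.hotspot_window_nt
        if in_exon:
            in_exon_pathogenic += 1
            if is_missense:
                in_exon_missense += 1
        if in_window and is_missense:
            in_window_missense += 1
        if in_window and _truthy(row.get("functional_lof")):
            lof_nearby = True

    exon_len = b - a + 1
    density = 100.0 * in_exon_missense / exon_len if exon_len else 0.0
    majority = (
        in_exon_pathogenic > 0
        and in_exon_missense / in_exon_pathogenic >= config.hotspot_majority_fraction
    )
    is_hotspot = in_exon_missense >= config.hotspot_min_count and majority
    return HotspotReport(
        window_nt=config.hotspot_window_nt,
        n_pathogenic_missense_in_exon=in_exon_missense,
        n_pathogenic_missense_in_window=in_window_missense,
        n_pathogenic_in_exon=in_exon_pathogenic,
        density_per_100_nt=density,
        is_hotspot=is_hotspot,
        lof_evidence_nearby=lof_nearby,
        rejected_rows=tuple(rejected),
    )


def _truthy(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in {"1", "true", "yes", "y"}
    try:
        return bool(value) and value == value  # NaN-safe
    except Exception:  # pragma: no cover
        return False


# --------------------------------------------------------------------------
# allele specificity and patient selection
# --------------------------------------------------------------------------


def assess_allele_specificity(v: VariantDescriptor, verdict: Verdict) -> Optional[str]:
    """Attach the allele-specificity warning/note to a computed verdict.

    Exon skipping of a heterozygous variant also removes the exon from the
    wild-type allele, so allele-selective design must be considered. For
    cryptic-splice blocking the ASO has no effect on the wild-type allele
    (no cryptic site to mask there), so allele specificity is not needed.
    """
    if verdict.category is VerdictCategory.AMENABLE_EXON_SKIP:
        if v.zygosity is Zygosity.HETEROZYGOUS:
            verdict.add_warning(W_ALLELE_SPECIFICITY)
            return W_ALLELE_SPECIFICITY
        return None
    if verdict.category is VerdictCategory.AMENABLE_CRYPTIC_SPLICE_BLOCK:
        if NOTE_ALLELE_NOT_NEEDED not in verdict.notes:
            verdict.notes.append(NOTE_ALLELE_NOT_NEEDED)
    return None


class Severity(str, Enum):
    LIFE_THREATENING = "life_threatening"
    SEVERELY_DEBILITATING = "severely_debilitating"
    OTHER = "other"


class Tissue(str, Enum):
    BRAIN = "brain"
    SPINAL_CORD = "spinal_cord"
    EYE = "eye"
    OTHER = "other"


@dataclass(frozen=True)
class PatientProfile:
    severity: Severity
    monogenic: bool
    primary_tissue: Tissue
    treatable_in_two_years: bool
    outcome_measures_definable: bool

    @classmethod
    def from_dict(cls, d: dict) -> "PatientProfile":
        required = [
            "severity",
            "monogenic",
            "primary_tissue",
            "treatable_in_two_years",
            "outcome_measures_definable",
        ]
        missing = [k for k in required if k not in d or d[k] is None]
        if missing:
            raise TriageInputError(
                f"patient profile missing required field(s): {missing}"
            )
        return cls(
            severity=Severity(d["severity"]),
            monogenic=bool(d["monogenic"]),
            primary_tissue=Tissue(d["primary_tissue"]),
            treatable_in_two_years=bool(d["treatable_in_two_years"]),
            outcome_measures_definable=bool(d["outcome_measures_definable"]),
        )


@dataclass(frozen=True)
class PatientEligibility:
    eligible: bool
    criteria: tuple[tuple[str, str, bool], ...]  # (criterion, value, passed)

    def to_dict(self) -> dict:
        return {
            "eligible": self.eligible,
            "criteria": [
                {"criterion": c, "value": v, "passed": p} for c, v, p in self.criteria
            ],
        }


def evaluate_patient(profile: PatientProfile) -> PatientEligibility:
    """Five-criterion patient eligibility checklist (all must hold):
    life-threatening or severely debilitating disease; monogenic; primarily
    affecting brain, spinal cord or eye (locally dosable tissues); still in a
    treatable stage two years after enrolment (ASO development time); and
    predefinable clinical outcome measures."""
    checks = [
        (
            "disease_severity",
            profile.severity.value,
            profile.severity
            in (Severity.LIFE_THREATENING, Severity.SEVERELY_DEBILITATING),
        ),
        ("monogenic", str(profile.monogenic), profile.monogenic),
        (
            "target_tissue",
            profile.primary_tissue.value,
            profile.primary_tissue in (Tissue.BRAIN, Tissue.SPINAL_CORD, Tissue.EYE),
        ),
        (
            "treatable_in_two_years",
            str(profile.treatable_in_two_years),
            profile.treatable_in_two_years,
        ),
        (
            "outcome_measures_definable",
            str(profile.outcome_measures_definable),
            profile.outcome_measures_definable,
        ),
    ]
    return PatientEligibility(
        eligible=all(p for _, _, p in checks),
        criteria=tuple(checks),
    )


# --------------------------------------------------------------------------
# top-level dispatch
# --------------------------------------------------------------------------


def triage(
    model: TranscriptModel,
    v: VariantDescriptor,
    evidence: SpliceEvidence,
    domains: Sequence[DomainAnnotation] = (),
    pathogenic_table: "pd.DataFrame | Iterable[dict] | None" = None,
    population_evidence: PopulationEvidence | str = PopulationEvidence.UNKNOWN,
    config: RunConfig = DEFAULT_CONFIG,
    mechanism: str = "lof",
) -> Verdict:
    """Route one variant through the appropriate decision tree.

    ``mechanism`` declares the pathomechanism; anything other than ``"lof"``
    (e.g. ``"gof"``, ``"dominant_negative"``) is outside the loss-of-function
    scope of this triage and returns an out-of-scope verdict with a flag.
    Identical inputs always produce identical traces.
    """
    if isinstance(population_evidence, str):
        population_evidence = PopulationEvidence(population_evidence)

    trace = RuleTrace(config=config.to_dict())

    if mechanism != "lof":
        verdict = Verdict(VerdictCategory.OUT_OF_SCOPE, trace)
        trace.fire(
            "mechanism",
            "Is the declared pathomechanism loss of function?",
            mechanism,
            "out_of_scope",
        )
        verdict.add_warning(W_GOF_DN)
        verdict.notes.append(
            "gain-of-function / dominant-negative mechanisms need different "
            "therapeutic considerations (not covered by this triage)"
        )
        return verdict

    if v.anchor_region != "cds" and v.offset == 0:
        verdict = Verdict(VerdictCategory.OUT_OF_SCOPE, trace)
        trace.fire(
            "utr_variant",
            "Is the variant inside the coding sequence or an intron?",
            f"{v.anchor_region} position",
            "out_of_scope",
        )
        verdict.notes.append(
            "UTR variants act via transcript stability, not splicing; "
            "outside the scope of splice-switching triage"
        )
        return verdict

    region = classify_region(model, v, config)

    if evidence.observed_effect is not ObservedEffect.NONE:
        if evidence.assay is Assay.NONE:
            verdict = Verdict(VerdictCategory.INSUFFICIENT_EVIDENCE, trace)
            trace.fire(
                "evidence_confirmed",
                "Splice-disrupting effect confirmed by a functional assay?",
                False,
                "insufficient_evidence",
            )
            verdict.required_followups.append(F_CONFIRM_SPLICING)
            return verdict
        if evidence.observed_effect in CRYPTIC_EFFECTS:
            return evaluate_cryptic_splice(model, v, evidence, region, config)
        if evidence.observed_effect in CANONICAL_DISRUPTION_EFFECTS:
            verdict = Verdict(VerdictCategory.NOT_AMENABLE, trace)
            trace.fire(
                "canonical_disruption",
                "Does the variant disrupt canonical splicing itself "
                "(exon skipping / intron retention / multi-exon effect)?",
                evidence.observed_effect.value,
                "reject",
            )
            verdict.notes.append(
                "blocking the variant cannot restore a canonical splice "
                "signal that no longer functions"
            )
            if not v.is_intronic and evidence.observed_effect in (
                ObservedEffect.EXON_SKIPPING,
                ObservedEffect.PARTIAL_EXON_SKIPPING,
            ):
                # splice-regulatory-element disruption: exon inclusion is the
                # only (exceptional, design-heavy) counter-strategy
                verdict.add_warning(W_EXON_INCLUSION_EXCEPTIONAL)
            return verdict
        # observed effect 'unknown' with an assay: effect not characterized
        verdict = Verdict(VerdictCategory.INSUFFICIENT_EVIDENCE, trace)
        trace.fire(
            "effect_characterized",
            "Is the observed splicing effect characterized?",
            evidence.observed_effect.value,
            "insufficient_evidence",
        )
        verdict.required_followups.append(F_CONFIRM_SPLICING)
        return verdict

    # no splicing effect: exonic consequence routes the exon-skip tree
    consequence = derive_protein_consequence(model, v)
    trace.fire(
        "protein_consequence",
        "Protein-level consequence of the variant?",
        consequence.value,
        "route",
    )
    if consequence in (ConsequenceClass.NONE, ConsequenceClass.UNKNOWN):
        verdict = Verdict(VerdictCategory.INSUFFICIENT_EVIDENCE, trace)
        verdict.required_followups.append(F_CONFIRM_SPLICING)
        verdict.notes.append(
            "intronic variant without a confirmed splicing effect cannot be triaged"
        )
        return verdict
    if consequence is ConsequenceClass.SYNONYMOUS:
        verdict = Verdict(VerdictCategory.OUT_OF_SCOPE, trace)
        verdict.notes.append(
            "synonymous variant with no observed splicing effect: no "
            "loss-of-function mechanism to address"
        )
        return verdict

    exon_index = region.exon_index
    if exon_index is None:
        raise InputConsistencyError(
            "exonic consequence derived for a variant that maps to no exon"
        )
    skip = simulate_exon_skip(model, exon_index, domains, population_evidence)

    if consequence in (ConsequenceClass.NONSENSE, ConsequenceClass.FRAMESHIFT):
        sub = evaluate_truncating(model, v, skip, config)
    else:  # missense / in-frame indel
        interval = model.exon_cds_interval(exon_index)
        hotspot = hotspot_score(v, pathogenic_table, interval, config)
        sub = evaluate_missense(model, v, skip, hotspot, config)
    # prepend the dispatch trace for a complete audit trail
    sub.trace.nodes = trace.nodes + sub.trace.nodes
    return sub
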