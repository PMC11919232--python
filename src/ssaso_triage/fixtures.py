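"""Deterministic test-input generators.

Three generators:

* :func:`build_hypothetical_transcript` — a frozen 10-exon transcript with
  sequence, two functional-domain annotations, a pathogenic-variant table
  and 8 archetype variants covering every branch of the triage trees
  (canonical splice site, branch point, deep-intronic cryptic, exonic
  cryptic, splice-regulatory element, nonsense, missense-in-domain,
  missense-in-hotspot), each with its expected amenability category.
* :func:`encode_worked_examples` — the four published real-variant
  descriptors (MFSD8 c.754+2T>A, COASY c.1486-3C>G, NUBPL c.815-27T>C,
  TIMMDC1 c.597-1340A>G) on synthetic surrogate transcripts with the
  correct exon/intron geometry around each variant (only intronic offsets
  and region classes are asserted against them, so real reference
  sequences are not needed).
* :func:`generate_random_transcript` — seeded random but always-valid
  transcripts for property tests.

All fixtures are self-contained; nothing is downloaded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .exceptions import TriageInputError
from .rule_engine import VerdictCategory
from .region_classifier import RegionClass
from .transcript_model import DomainAnnotation, Exon, TranscriptModel
from .variant_model import (
    SpliceEvidence,
    VariantDescriptor,
    parse_hgvs_c,
)

#: baked-in seed for the frozen hypothetical transcript
_FIXTURE_SEED = 20240418

# sense codons (no stop codons) for CDS generation
_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
]


@dataclass(frozen=True)
class ArchetypeVariant:
    number: int
    variant: VariantDescriptor
    evidence: SpliceEvidence
    expected_category: VerdictCategory
    description: str


@dataclass(frozen=True)
class FixtureBundle:
    model: TranscriptModel
    variants: tuple[ArchetypeVariant, ...]
    domains: tuple[DomainAnnotation, ...]
    pathogenic_table: tuple[dict, ...]

    def variant(self, number: int) -> ArchetypeVariant:
        for a in self.variants:
            if a.number == number:
                return a
        raise KeyError(number)


# --------------------------------------------------------------------------
# the frozen hypothetical transcript
# --------------------------------------------------------------------------

# exon lengths (nt) and coding contribution; 5'UTR = 100 nt in exon 1,
# 3'UTR = 146 nt in exon 10; CDS = 900 nt including the stop codon
_EXON_LENGTHS = [151, 120, 84, 96, 105, 90, 81, 99, 120, 200]
_INTRON_LENGTHS = [3100, 3200, 3300, 3400, 3400, 3600, 3700, 3800, 3900]
_UTR5 = 100
_CDS_LEN = 900
_GENOMIC_START = 100_001


def _make_sequence(rng: np.random.Generator) -> str:
    """Random transcript sequence: stop-free CDS ending in TAA, with the
    handful of codons the archetype variants rely on pinned."""
    utr5 = "".join(rng.choice(list(_BASES), size=_UTR5))
    n_codons = _CDS_LEN // 3
    codons = [str(rng.choice(_SENSE_CODONS)) for _ in range(n_codons - 1)] + ["TAA"]
    # pinned codons (0-based codon index -> codon)
    codons[70] = "CTG"   # c.211-213; c.213G>A -> CTA, synonymous (Leu)
    codons[99] = "GGC"   # c.298-300; c.300C>T -> GGT, synonymous (Gly)
    codons[163] = "CAA"  # c.490-492; c.490C>T -> TAA, nonsense
    codons[193] = "GAG"  # c.580-582; c.580G>C -> CAG, Glu->Gln missense
    codons[223] = "CGT"  # c.670-672; c.670C>G -> GGT, Arg->Gly missense
    utr3_len = sum(_EXON_LENGTHS) - _UTR5 - _CDS_LEN
    utr3 = "".join(rng.choice(list(_BASES), size=utr3_len))
    return utr5 + "".join(codons) + utr3


def _hypothetical_model() -> TranscriptModel:
    rng = np.random.default_rng(_FIXTURE_SEED)
    exons = []
    g = _GENOMIC_START
    for i, (length, intron) in enumerate(
        zip(_EXON_LENGTHS, _INTRON_LENGTHS + [0]), start=1
    ):
        exons.append(Exon(i, g, g + length - 1))
        g += length + intron
    return TranscriptModel(
        transcript_id="HYPO-TX-1",
        gene_symbol="HYPO1",
        strand="+",
        exons=exons,
        cds_start=_UTR5 + 1,
        cds_end=_UTR5 + _CDS_LEN,
        sequence=_make_sequence(rng),
    )


def build_hypothetical_transcript() -> FixtureBundle:
    """The frozen 8-archetype fixture bundle (deterministic; seed baked in)."""
    model = _hypothetical_model()
    domains = (
        DomainAnnotation("catalytic_domain", 560, 610, source="fixture"),
        DomainAnnotation("binding_domain", 100, 160, source="fixture"),
    )
    # (likely) pathogenic records clustered in exon 8 (c.628..726)
    table = (
        {"position_c": 640, "consequence": "missense", "classification": "pathogenic",
         "functional_lof": ""},
        {"position_c": 655, "consequence": "missense", "classification": "pathogenic",
         "functional_lof": ""},
        {"position_c": 668, "consequence": "missense",
         "classification": "likely_pathogenic", "functional_lof": ""},
        {"position_c": 690, "consequence": "missense", "classification": "pathogenic",
         "functional_lof": ""},
        {"position_c": 700, "consequence": "nonsense", "classification": "pathogenic",
         "functional_lof": ""},
        {"position_c": 710, "consequence": "missense", "classification": "pathogenic",
         "functional_lof": "yes"},
    )
    variants = (
        ArchetypeVariant(
            1,
            parse_hgvs_c("c.255+2T>A", zygosity="homozygous"),
            SpliceEvidence.from_dict(
                {"observed_effect": "exon_skipping",
                 "canonical_splicing_intact": "no",
                 "assay": "rt_qpcr", "affected_exon_index": 3}
            ),
            VerdictCategory.NOT_AMENABLE,
            "canonical splice donor variant: the destroyed site cannot be "
            "restored by blocking the variant",
        ),
        ArchetypeVariant(
            2,
            parse_hgvs_c("c.352-27T>C", zygosity="homozygous"),
            SpliceEvidence.from_dict(
                {"observed_effect": "cryptic_acceptor_created",
                 "canonical_splicing_intact": "partial",
                 "assay": "rt_qpcr", "affected_exon_index": 5}
            ),
            VerdictCategory.NOT_AMENABLE,
            "branch-point window variant: an ASO there would block lariat "
            "formation",
        ),
        ArchetypeVariant(
            3,
            parse_hgvs_c("c.457-1340A>G", zygosity="homozygous"),
            SpliceEvidence.from_dict(
                {"observed_effect": "cryptic_exon_inclusion",
                 "canonical_splicing_intact": "yes",
                 "assay": "rna_seq", "affected_exon_index": 6}
            ),
            VerdictCategory.AMENABLE_CRYPTIC_SPLICE_BLOCK,
            "deep intronic cryptic splice variant: masking the cryptic exon "
            "restores the native transcript",
        ),
        ArchetypeVariant(
            4,
            parse_hgvs_c("c.213G>A", zygosity="homozygous"),
            SpliceEvidence.from_dict(
                {"observed_effect": "cryptic_donor_created",
                 "canonical_splicing_intact": "yes",
                 "assay": "minigene", "affected_exon_index": 3}
            ),
            VerdictCategory.AMENABLE_CRYPTIC_SPLICE_BLOCK,
            "synonymous exonic cryptic donor, >=15 nt clear of both "
            "junctions: amenable with whole-exon-skip risk caution",
        ),
        ArchetypeVariant(
            5,
            parse_hgvs_c("c.300C>T", zygosity="homozygous"),
            SpliceEvidence.from_dict(
                {"observed_effect": "exon_skipping",
                 "canonical_splicing_intact": "no",
                 "assay": "minigene", "affected_exon_index": 4}
            ),
            VerdictCategory.NOT_AMENABLE,
            "exonic splice-enhancer disruption causing exon skipping; only "
            "exceptional exon-inclusion designs could counteract this",
        ),
        ArchetypeVariant(
            6,
            parse_hgvs_c("c.490C>T", zygosity="heterozygous"),
            SpliceEvidence.from_dict({"observed_effect": "none"}),
            VerdictCategory.AMENABLE_EXON_SKIP,
            "nonsense variant in an internal, in-frame, domain-free exon "
            "(10% of the CDS): skippable",
        ),
        ArchetypeVariant(
            7,
            parse_hgvs_c("c.580G>C", zygosity="homozygous"),
            SpliceEvidence.from_dict({"observed_effect": "none"}),
            VerdictCategory.NOT_AMENABLE,
            "missense variant inside a functional domain: skipping would "
            "remove the domain",
        ),
        ArchetypeVariant(
            8,
            parse_hgvs_c("c.670C>G", zygosity="homozygous"),
            SpliceEvidence.from_dict({"observed_effect": "none"}),
            VerdictCategory.NOT_AMENABLE,
            "missense variant in a pathogenic-missense hotspot with nearby "
            "functional LoF evidence: skipping likely also abolishes function",
        ),
    )
    return FixtureBundle(
        model=model,
        variants=variants,
        domains=domains,
        pathogenic_table=table,
    )


# --------------------------------------------------------------------------
# worked examples on surrogate transcripts
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class WorkedExample:
    gene: str
    hgvs: str
    variant: VariantDescriptor
    model: TranscriptModel
    expected_class: RegionClass


def _surrogate_model(gene: str, anchor_c: int, offset: int) -> TranscriptModel:
    """Two-exon, fully coding surrogate transcript placing ``anchor_c`` at
    the exon boundary the offset direction requires, with an intron long
    enough that only the anchoring junction constrains classification."""
    intron = max(5000, 2 * abs(offset) + 100)
    if offset > 0:  # anchor must be the last base of exon 1
        len1 = anchor_c
        len2 = 60 + (-(len1 + 60)) % 3
    else:  # anchor must be the first base of exon 2
        len1 = anchor_c - 1
        len2 = 60 + (-(len1 + 60)) % 3
        if anchor_c > len1 + len2:  # anchor must fall inside exon 2
            len2 += 3 * ((anchor_c - len1 - len2 + 2) // 3 + 1)
    g1 = 1_000
    exons = [
        Exon(1, g1, g1 + len1 - 1),
        Exon(2, g1 + len1 + intron, g1 + len1 + intron + len2 - 1),
    ]
    return TranscriptModel(
        transcript_id=f"SURROGATE-{gene}",
        gene_symbol=gene,
        strand="+",
        exons=exons,
        cds_start=1,
        cds_end=len1 + len2,
    )


def encode_worked_examples() -> list[WorkedExample]:
    """The four published real-variant descriptors on surrogate transcripts."""
    specs = [
        ("MFSD8", "c.754+2T>A", RegionClass.CANONICAL_DONOR),
        ("COASY", "c.1486-3C>G", RegionClass.ACCEPTOR_REGION),
        ("NUBPL", "c.815-27T>C", RegionClass.BRANCH_POINT_WINDOW),
        ("TIMMDC1", "c.597-1340A>G", RegionClass.DEEP_INTRONIC),
    ]
    out = []
    for gene, hgvs, expected in specs:
        v = parse_hgvs_c(hgvs)
        model = _surrogate_model(gene, v.anchor_c, v.offset)
        out.append(WorkedExample(gene, hgvs, v, model, expected))
    return out


# --------------------------------------------------------------------------
# random transcripts for property tests
# --------------------------------------------------------------------------


def generate_random_transcript(
    seed: int,
    n_exons: Optional[int] = None,
    exon_length_range: tuple[int, int] = (30, 300),
    intron_length_range: tuple[int, int] = (60, 600),
    utr5_max: int = 90,
    utr3_max: int = 120,
    with_sequence: bool = True,
    strand: Optional[str] = None,
) -> TranscriptModel:
    """A reproducible random transcript that always validates.

    The CDS is trimmed to a codon multiple, carries no internal stop codon,
    and ends in TAA, so skip simulations and consequence calls on the result
    are well defined.
    """
    rng = np.random.default_rng(seed)
    if n_exons is None:
        n_exons = int(rng.integers(1, 9))
    if n_exons < 1:
        raise TriageInputError("n_exons must be >= 1")
    lo, hi = exon_length_range
    if lo < 9 or hi < lo:
        raise TriageInputError("infeasible exon length range")
    lengths = [int(rng.integers(lo, hi + 1)) for _ in range(n_exons)]
    total = sum(lengths)
    utr5 = int(rng.integers(0, min(utr5_max, max(0, (total - 9) // 2)) + 1))
    utr3 = int(rng.integers(0, min(utr3_max, max(0, (total - 9) // 2)) + 1))
    coding = total - utr5 - utr3
    utr3 += coding % 3  # pad 3'UTR so the CDS is a codon multiple
    coding = total - utr5 - utr3
    if coding < 6:
        utr5, utr3 = 0, total % 3
        coding = total - utr3
    if strand is None:
        strand = str(rng.choice(["+", "-"]))
    g = int(rng.integers(10_000, 1_000_000))
    exons = []
    if strand == "+":
        cur = g
        for i, length in enumerate(lengths, start=1):
            exons.append(Exon(i, cur, cur + length - 1))
            cur += length + int(rng.integers(*intron_length_range))
    else:
        cur = g + 10 * total + n_exons * intron_length_range[1]
        for i, length in enumerate(lengths, start=1):
            exons.append(Exon(i, cur - length + 1, cur))
            cur -= length + int(rng.integers(*intron_length_range))
    sequence = None
    if with_sequence:
        utr5_seq = "".join(rng.choice(list(_BASES), size=utr5))
        n_codons = coding // 3
        codons = [str(rng.choice(_SENSE_CODONS)) for _ in range(n_codons - 1)]
        codons.append("TAA")
        utr3_seq = "".join(rng.choice(list(_BASES), size=utr3))
        sequence = utr5_seq + "".join(codons) + utr3_seq
    return TranscriptModel(
        transcript_id=f"RANDOM-{seed}",
        gene_symbol=f"RND{seed}",
        strand=strand,
        exons=exons,
        cds_start=utr5 + 1,
        cds_end=utr5 + coding,
        sequence=sequence,
    )
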