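"""Variant descriptors, HGVS-c subset parsing, splicing evidence, and
protein-level consequence derivation.

Supported HGVS-c grammar (everything else is a hard parse error)::

    c.POS REF>ALT                 substitution
    c.POS del[SEQ] | c.POS_POS del[SEQ]
    c.POS dup[SEQ] | c.POS_POS dup[SEQ]
    c.POS_POS ins SEQ
    c.POS delins SEQ | c.POS_POS delins SEQ

where ``POS`` is ``[-|*]N[+K|-K]`` (coding, 5'UTR ``-N`` or 3'UTR ``*N``
anchor, with optional signed intronic offset). Protein-level descriptors,
repeat notation, inversions and whole-exon/gene deletions are rejected:
silent tolerance of unsupported syntax would corrupt triage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional

from Bio.Seq import Seq

from .exceptions import (
    HgvsParseError,
    InputConsistencyError,
    MappingError,
    SequenceRequiredError,
)
from .transcript_model import CPos, Region, TranscriptModel


class VariantKind(str, Enum):
    SUBSTITUTION = "substitution"
    DELETION = "deletion"
    INSERTION = "insertion"
    DUPLICATION = "duplication"
    DELINS = "delins"


class Zygosity(str, Enum):
    HETEROZYGOUS = "heterozygous"
    HOMOZYGOUS = "homozygous"
    HEMIZYGOUS = "hemizygous"
    UNKNOWN = "unknown"


class ConsequenceClass(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SYNONYMOUS = "synonymous"
    IN_FRAME_INDEL = "in_frame_indel"
    NONE = "none"
    UNKNOWN = "unknown"


class ObservedEffect(str, Enum):
    NONE = "none"
    CRYPTIC_DONOR_CREATED = "cryptic_donor_created"
    CRYPTIC_ACCEPTOR_CREATED = "cryptic_acceptor_created"
    CRYPTIC_EXON_INCLUSION = "cryptic_exon_inclusion"
    PARTIAL_EXON_SKIPPING = "partial_exon_skipping"
    EXON_SKIPPING = "exon_skipping"
    INTRON_RETENTION = "intron_retention"
    MULTI_EXON_DISRUPTION = "multi_exon_disruption"
    UNKNOWN = "unknown"


#: effects meaning a new/activated cryptic splice site is the lesion
CRYPTIC_EFFECTS = frozenset(
    {
        ObservedEffect.CRYPTIC_DONOR_CREATED,
        ObservedEffect.CRYPTIC_ACCEPTOR_CREATED,
        ObservedEffect.CRYPTIC_EXON_INCLUSION,
    }
)

#: effects meaning canonical splicing itself is disrupted
CANONICAL_DISRUPTION_EFFECTS = frozenset(
    {
        ObservedEffect.PARTIAL_EXON_SKIPPING,
        ObservedEffect.EXON_SKIPPING,
        ObservedEffect.INTRON_RETENTION,
        ObservedEffect.MULTI_EXON_DISRUPTION,
    }
)


class CanonicalSplicing(str, Enum):
    YES = "yes"
    NO = "no"
    PARTIAL = "partial"
    UNKNOWN = "unknown"


class Assay(str, Enum):
    RT_QPCR = "rt_qpcr"
    RNA_SEQ = "rna_seq"
    MINIGENE = "minigene"
    NONE = "none"


@dataclass(frozen=True)
class SpliceEvidence:
    """Functionally observed splicing outcome for one variant.

    A splice-affecting claim only counts as confirmed when an assay backs it
    (functional confirmation, e.g. RT-qPCR, RNA-seq or a minigene assay, is a
    precondition for amenability triage of splice-altering variants).
    """

    observed_effect: ObservedEffect = ObservedEffect.NONE
    canonical_splicing_intact: CanonicalSplicing = CanonicalSplicing.UNKNOWN
    assay: Assay = Assay.NONE
    affected_exon_index: Optional[int] = None

    @property
    def confirmed(self) -> bool:
        return (
            self.observed_effect is ObservedEffect.NONE
            or self.assay is not Assay.NONE
        )

    @classmethod
    def from_dict(cls, d: dict) -> "SpliceEvidence":
        return cls(
            observed_effect=ObservedEffect(d.get("observed_effect", "none")),
            canonical_splicing_intact=CanonicalSplicing(
                d.get("canonical_splicing_intact", "unknown")
            ),
            assay=Assay(d.get("assay", "none")),
            affected_exon_index=d.get("affected_exon_index"),
        )

    def to_dict(self) -> dict:
        return {
            "observed_effect": self.observed_effect.value,
            "canonical_splicing_intact": self.canonical_splicing_intact.value,
            "assay": self.assay.value,
            "affected_exon_index": self.affected_exon_index,
        }


@dataclass(frozen=True)
class VariantDescriptor:
    """A normalized small variant in cDNA coordinates."""

    raw: str
    kind: VariantKind
    anchor_c: int
    offset: int = 0
    anchor_region: Region = "cds"
    end_anchor_c: Optional[int] = None
    end_offset: int = 0
    end_anchor_region: Region = "cds"
    ref: str = ""
    alt: str = ""
    zygosity: Zygosity = Zygosity.UNKNOWN

    @property
    def is_intronic(self) -> bool:
        return self.offset != 0

    @property
    def start(self) -> CPos:
        return CPos(self.anchor_c, self.offset, self.anchor_region)

    @property
    def end(self) -> CPos:
        if self.end_anchor_c is None:
            return self.start
        return CPos(self.end_anchor_c, self.end_offset, self.end_anchor_region)

    @property
    def span_c(self) -> int:
        """Number of reference bases the event touches (exonic, unranged=1)."""
        if self.end_anchor_c is None:
            return 1
        return self.end_anchor_c - self.anchor_c + 1

    def net_length_change(self) -> Optional[int]:
        """Net change in transcript length, when derivable for exonic events."""
        if self.kind is VariantKind.SUBSTITUTION:
            return 0
        if self.is_intronic or self.end_offset != 0:
            return None
        if self.kind is VariantKind.DELETION:
            return -self.span_c
        if self.kind is VariantKind.DUPLICATION:
            return self.span_c
        if self.kind is VariantKind.INSERTION:
            return len(self.alt)
        if self.kind is VariantKind.DELINS:
            return len(self.alt) - self.span_c
        return None

    def format(self) -> str:
        """Canonical HGVS-c-style string (re-parses to an equal descriptor)."""

        def pos(p: int, off: int, region: Region) -> str:
            prefix = {"cds": "", "utr5": "-", "utr3": "*"}[region]
            s = f"{prefix}{p}"
            if off:
                s += f"{off:+d}"
            return s

        loc = pos(self.anchor_c, self.offset, self.anchor_region)
        if self.end_anchor_c is not None:
            loc += "_" + pos(self.end_anchor_c, self.end_offset, self.end_anchor_region)
        if self.kind is VariantKind.SUBSTITUTION:
            return f"c.{loc}{self.ref}>{self.alt}"
        if self.kind is VariantKind.DELETION:
            return f"c.{loc}del{self.ref}"
        if self.kind is VariantKind.DUPLICATION:
            return f"c.{loc}dup{self.ref}"
        if self.kind is VariantKind.INSERTION:
            return f"c.{loc}ins{self.alt}"
        return f"c.{loc}delins{self.alt}"


_POS_RE = r"(?P<{n}sign>[-*])?(?P<{n}pos>\d+)(?P<{n}off>[+-]\d+)?"
_HGVS_RE = re.compile(
    r"^c\."
    + _POS_RE.format(n="a")
    + r"(?:_" + _POS_RE.format(n="b") + r")?"
    + r"(?P<tail>.+)$"
)
_SUB_RE = re.compile(r"^(?P<ref>[ACGTacgt])>(?P<alt>[ACGTacgt])$")
_DEL_RE = re.compile(r"^del(?P<seq>[ACGTacgt]*)$")
_DUP_RE = re.compile(r"^dup(?P<seq>[ACGTacgt]*)$")
_INS_RE = re.compile(r"^ins(?P<seq>[ACGTacgt]+)$")
_DELINS_RE = re.compile(r"^delins(?P<seq>[ACGTacgt]+)$")


def _decode_pos(m: re.Match, n: str) -> tuple[int, int, Region]:
    sign = m.group(f"{n}sign")
    pos = int(m.group(f"{n}pos"))
    off = int(m.group(f"{n}off") or 0)
    region: Region = "cds"
    if sign == "-":
        region = "utr5"
    elif sign == "*":
        region = "utr3"
    return pos, off, region


def parse_hgvs_c(raw: str, zygosity: Zygosity | str = Zygosity.UNKNOWN) -> VariantDescriptor:
    """Parse a supported HGVS-c descriptor into a :class:`VariantDescriptor`."""
    if isinstance(zygosity, str):
        zygosity = Zygosity(zygosity)
    s = raw.strip()
    m = _HGVS_RE.match(s)
    if not m:
        raise HgvsParseError(f"unsupported HGVS-c syntax: {raw!r}")
    anchor_c, offset, region = _decode_pos(m, "a")
    has_range = m.group("bpos") is not None
    if has_range:
        end_c, end_off, end_region = _decode_pos(m, "b")
    else:
        end_c, end_off, end_region = None, 0, "cds"
    tail = m.group("tail")

    if (sub := _SUB_RE.match(tail)) is not None:
        if has_range:
            raise HgvsParseError(f"substitution cannot span a range: {raw!r}")
        ref, alt = sub.group("ref").upper(), sub.group("alt").upper()
        if ref == alt:
            raise HgvsParseError(f"substitution ref == alt in {raw!r}")
        kind, ref_s, alt_s = VariantKind.SUBSTITUTION, ref, alt
    elif (d := _DEL_RE.match(tail)) is not None:
        kind, ref_s, alt_s = VariantKind.DELETION, d.group("seq").upper(), ""
    elif (d := _DUP_RE.match(tail)) is not None:
        kind, ref_s, alt_s = VariantKind.DUPLICATION, d.group("seq").upper(), ""
    elif (d := _INS_RE.match(tail)) is not None:
        if not has_range:
            raise HgvsParseError(
                f"insertion requires a two-position range (c.X_Yins...): {raw!r}"
            )
        kind, ref_s, alt_s = VariantKind.INSERTION, "", d.group("seq").upper()
    elif (d := _DELINS_RE.match(tail)) is not None:
        kind, ref_s, alt_s = VariantKind.DELINS, "", d.group("seq").upper()
    else:
        raise HgvsParseError(f"unsupported edit token {tail!r} in {raw!r}")

    v = VariantDescriptor(
        raw=s,
        kind=kind,
        anchor_c=anchor_c,
        offset=offset,
        anchor_region=region,
        end_anchor_c=end_c,
        end_offset=end_off,
        end_anchor_region=end_region,
        ref=ref_s,
        alt=alt_s,
        zygosity=zygosity,
    )
    _check_range(v, raw)
    return v


def _check_range(v: VariantDescriptor, raw: str) -> None:
    if v.end_anchor_c is None:
        return
    if v.anchor_region != v.end_anchor_region:
        raise HgvsParseError(f"range crosses UTR/CDS regions: {raw!r}")
    key_a = (v.anchor_c, v.offset)
    key_b = (v.end_anchor_c, v.end_offset)
    if v.anchor_region == "utr5":  # 5'UTR counts backwards
        key_a, key_b = (-v.anchor_c, v.offset), (-v.end_anchor_c, v.end_offset)
    if key_b < key_a:
        raise HgvsParseError(f"range end precedes start: {raw!r}")
    if v.kind is VariantKind.INSERTION and (
        v.offset != v.end_offset and abs(v.end_offset - v.offset) != 1
        or v.offset == v.end_offset and v.end_anchor_c - v.anchor_c != 1
    ):
        # insertions go between two adjacent bases
        if not (v.offset == 0 and v.end_offset == 0 and v.end_anchor_c - v.anchor_c == 1):
            raise HgvsParseError(
                f"insertion flanks must be adjacent positions: {raw!r}"
            )


# --------------------------------------------------------------------------
# protein consequence
# --------------------------------------------------------------------------


def _apply_edit_to_cds(cds: str, v: VariantDescriptor) -> str:
    """Apply an exonic edit (CDS coordinates) and return the mutant CDS."""
    a = v.anchor_c
    b = v.end_anchor_c if v.end_anchor_c is not None else a
    if not (1 <= a <= b <= len(cds)):
        raise MappingError(
            f"variant interval [{a}, {b}] outside CDS of length {len(cds)}"
        )
    if v.kind is VariantKind.SUBSTITUTION:
        if v.ref and cds[a - 1] != v.ref:
            raise InputConsistencyError(
                f"reference base mismatch at c.{a}: descriptor says {v.ref}, "
                f"transcript has {cds[a - 1]}"
            )
        return cds[: a - 1] + v.alt + cds[a:]
    if v.kind is VariantKind.DELETION:
        if v.ref and cds[a - 1 : b] != v.ref:
            raise InputConsistencyError(
                f"deleted bases mismatch at c.{a}_{b}: descriptor says {v.ref}, "
                f"transcript has {cds[a - 1:b]}"
            )
        return cds[: a - 1] + cds[b:]
    if v.kind is VariantKind.DUPLICATION:
        return cds[:b] + cds[a - 1 : b] + cds[b:]
    if v.kind is VariantKind.INSERTION:
        return cds[:a] + v.alt + cds[a:]
    if v.kind is VariantKind.DELINS:
        return cds[: a - 1] + v.alt + cds[b:]
    raise AssertionError("unreachable")


def _translate(seq: str) -> str:
    # pad to a codon multiple so Biopython does not complain on frameshifts
    pad = (-len(seq)) % 3
    return str(Seq(seq + "N" * pad).translate())


def derive_protein_consequence(
    model: TranscriptModel, v: VariantDescriptor
) -> ConsequenceClass:
    """Protein-level consequence class by direct codon arithmetic.

    Intronic and UTR variants return ``none`` (they have no direct protein
    consequence; any effect is via splicing and is carried by the evidence
    document). Frameshift is decided purely by net length change mod 3;
    substitutions and in-frame events are classified by re-translating the
    mutant CDS against the reference CDS.
    """
    if v.is_intronic or v.end_offset != 0 or v.anchor_region != "cds":
        return ConsequenceClass.NONE
    net = v.net_length_change()
    if net is not None and net % 3 != 0:
        return ConsequenceClass.FRAMESHIFT
    if model.sequence is None:
        if v.kind is VariantKind.SUBSTITUTION:
            raise SequenceRequiredError(
                "substitution consequence needs the transcript sequence"
            )
        return ConsequenceClass.IN_FRAME_INDEL
    cds = model.coding_sequence()
    mutant = _apply_edit_to_cds(cds, v)
    p_ref = _translate(cds)
    p_mut = _translate(mutant)
    ref_stop = p_ref.find("*")
    mut_stop = p_mut.find("*")
    ref_core = p_ref[:ref_stop] if ref_stop >= 0 else p_ref
    mut_core = p_mut[:mut_stop] if mut_stop >= 0 else p_mut
    if v.kind is VariantKind.SUBSTITUTION:
        if p_mut == p_ref:
            return ConsequenceClass.SYNONYMOUS
        if mut_stop >= 0 and (ref_stop < 0 or mut_stop < ref_stop):
            return ConsequenceClass.NONSENSE
        return ConsequenceClass.MISSENSE
    # in-frame indel; a premature stop still counts as nonsense
    if mut_stop >= 0 and len(mut_core) < len(ref_core) - (len(cds) - len(mutant)) // 3:
        return ConsequenceClass.NONSENSE
    return ConsequenceClass.IN_FRAME_INDEL
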