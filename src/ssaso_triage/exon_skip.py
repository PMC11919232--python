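"""Single-exon skip simulation: reading frame, junction codons, removed
coding fraction and domain overlap.

Skipping an internal exon removes its coding contribution from the CDS.
When the removed length is a multiple of 3 the downstream frame is
preserved, but because exon boundaries need not be codon-aligned, the new
exon-exon junction can fuse two split codons into one novel codon. That
fused codon may encode a stop (skip is then unusable), a different amino
acid (junction missense) or, occasionally, the same amino acid as one of
the original split codons (junction synonymous).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from Bio.Seq import Seq

from .exceptions import SequenceRequiredError, TriageInputError
from .transcript_model import DomainAnnotation, TranscriptModel


class JunctionEvent(str, Enum):
    NONE = "none"
    STOP_GAINED = "stop_gained"
    JUNCTION_MISSENSE = "junction_missense"
    JUNCTION_SYNONYMOUS = "junction_synonymous"
    UNDETERMINABLE_NO_SEQUENCE = "undeterminable_no_sequence"


class PopulationEvidence(str, Enum):
    SEEN_SKIPPED_IN_HEALTHY = "seen_skipped_in_healthy"
    SKIP_KNOWN_PATHOGENIC = "skip_known_pathogenic"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class DomainOverlap:
    domain: DomainAnnotation
    overlap_start_c: int
    overlap_end_c: int

    @property
    def overlap_length(self) -> int:
        return self.overlap_end_c - self.overlap_start_c + 1


@dataclass(frozen=True)
class JunctionContext:
    """The <=1 fused codon created by an in-frame skip.

    ``phase`` is the codon phase at the exon's 5' coding boundary (number of
    upstream-exon bases already committed to the split codon); phase 0 means
    codon-aligned boundaries and no fused codon.
    """

    phase: int
    fused_codon: Optional[str]
    fused_aa: Optional[str]
    upstream_codon: Optional[str]
    upstream_aa: Optional[str]
    downstream_codon: Optional[str]
    downstream_aa: Optional[str]
    event: JunctionEvent


@dataclass(frozen=True)
class SkipSimulationResult:
    exon_index: int
    frame_preserved: bool
    coding_nt_removed: int
    fraction_cds_removed: float  # percent of CDS (stop codon included)
    junction_event: JunctionEvent
    domains_overlapped: tuple[DomainOverlap, ...]
    internal_exon: bool
    population_flags: PopulationEvidence
    junction: Optional[JunctionContext] = None

    def to_dict(self) -> dict:
        return {
            "exon_index": self.exon_index,
            "frame_preserved": self.frame_preserved,
            "coding_nt_removed": self.coding_nt_removed,
            "fraction_cds_removed": round(self.fraction_cds_removed, 4),
            "junction_event": self.junction_event.value,
            "domains_overlapped": [
                {
                    "name": o.domain.name,
                    "overlap_start_c": o.overlap_start_c,
                    "overlap_end_c": o.overlap_end_c,
                }
                for o in self.domains_overlapped
            ],
            "internal_exon": self.internal_exon,
            "population_flags": self.population_flags.value,
        }


def domain_overlap(
    model: TranscriptModel,
    exon_index: int,
    domains: Sequence[DomainAnnotation],
) -> list[DomainOverlap]:
    """Domains intersecting the exon's coding interval, with overlap extent."""
    interval = model.exon_cds_interval(exon_index)
    if interval is None:
        return []
    a, b = interval
    out = []
    for d in domains:
        lo, hi = max(a, d.start_c), min(b, d.end_c)
        if lo <= hi:
            out.append(DomainOverlap(d, lo, hi))
    return out


def reconstruct_junction(model: TranscriptModel, exon_index: int) -> JunctionContext:
    """Fused-codon context for an in-frame skip of ``exon_index``.

    Requires transcript sequence and an exon whose coding length is a
    multiple of 3 (otherwise there is no single well-defined junction codon).
    """
    if model.sequence is None:
        raise SequenceRequiredError(
            "junction codon reconstruction requires the transcript sequence"
        )
    interval = model.exon_cds_interval(exon_index)
    if interval is None:
        raise TriageInputError(
            f"exon {exon_index} contributes no coding sequence: nothing to skip in CDS"
        )
    a, b = interval  # CDS coordinates, 1-based inclusive
    if (b - a + 1) % 3 != 0:
        raise TriageInputError(
            f"exon {exon_index} is out of frame; junction codons are only "
            "defined for in-frame skips"
        )
    cds = model.coding_sequence()
    phase = (a - 1) % 3
    if phase == 0 or b == len(cds):
        return JunctionContext(
            phase=phase,
            fused_codon=None,
            fused_aa=None,
            upstream_codon=None,
            upstream_aa=None,
            downstream_codon=None,
            downstream_aa=None,
            event=JunctionEvent.NONE,
        )
    prefix = cds[a - 1 - phase : a - 1]
    suffix = cds[b : b + (3 - phase)]
    fused = prefix + suffix
    up_codon = cds[a - 1 - phase : a + 2 - phase]
    down_start = 3 * (b // 3)
    down_codon = cds[down_start : down_start + 3]
    fused_aa = str(Seq(fused).translate())
    up_aa = str(Seq(up_codon).translate())
    down_aa = str(Seq(down_codon).translate())
    if fused_aa == "*":
        event = JunctionEvent.STOP_GAINED
    elif fused_aa in (up_aa, down_aa):
        event = JunctionEvent.JUNCTION_SYNONYMOUS
    else:
        event = JunctionEvent.JUNCTION_MISSENSE
    return JunctionContext(
        phase=phase,
        fused_codon=fused,
        fused_aa=fused_aa,
        upstream_codon=up_codon,
        upstream_aa=up_aa,
        downstream_codon=down_codon,
        downstream_aa=down_aa,
        event=event,
    )


def simulate_exon_skip(
    model: TranscriptModel,
    exon_index: int,
    domains: Sequence[DomainAnnotation] = (),
    population_evidence: PopulationEvidence | str = PopulationEvidence.UNKNOWN,
) -> SkipSimulationResult:
    """Simulate removal of one exon and report all frame/junction/domain
    consequences the exon-skip decision tree consumes."""
    if isinstance(population_evidence, str):
        population_evidence = PopulationEvidence(population_evidence)
    removed = model.exon_coding_length(exon_index)
    if removed == 0:
        raise TriageInputError(
            f"exon {exon_index} contributes no coding sequence: nothing to skip in CDS"
        )
    frame_preserved = removed % 3 == 0
    fraction = 100.0 * removed / model.cds_length
    junction: Optional[JunctionContext] = None
    if not frame_preserved:
        # frameshifted skips report the frame failure, not junction events
        event = JunctionEvent.NONE
    elif model.sequence is None:
        event = JunctionEvent.UNDETERMINABLE_NO_SEQUENCE
    else:
        junction = reconstruct_junction(model, exon_index)
        event = junction.event
    return SkipSimulationResult(
        exon_index=exon_index,
        frame_preserved=frame_preserved,
        coding_nt_removed=removed,
        fraction_cds_removed=fraction,
        junction_event=event,
        domains_overlapped=tuple(domain_overlap(model, exon_index, domains)),
        internal_exon=model.is_internal_coding_exon(exon_index),
        population_flags=population_evidence,
        junction=junction,
    )
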