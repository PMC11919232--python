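"""Single-transcript exon/intron/CDS model with exact coordinate arithmetic.

The model is the substrate for all triage logic: it maps HGVS-c style cDNA
positions (coding position with optional signed intronic offset) to genomic
coordinates and back, and provides reading-frame bookkeeping per exon.

Conventions
-----------
* All coordinates are 1-based and inclusive, on both the genome and the
  spliced transcript.
* Exons are stored in transcript orientation (5'->3' of the mRNA). On the
  minus strand this means descending genomic coordinates.
* cDNA coding positions run 1..CDS length. 5'UTR positions are counted
  backwards from the base before the start codon (region ``utr5``, position
  1 = the base immediately 5' of the CDS), 3'UTR positions forwards from the
  base after the stop codon (region ``utr3``).
* Intronic positions are expressed as an exon-boundary anchor plus a signed
  offset: positive offsets count into the intron from a donor (exon 3' end),
  negative offsets from an acceptor (exon 5' start). When mapping a genomic
  position that sits exactly at an odd-length intron's midpoint, the
  donor-side anchor wins (documented tie-break).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

from .exceptions import (
    CdsBoundsError,
    CdsFrameError,
    ExonOverlapError,
    MappingError,
    ModelValidationError,
    SequenceRequiredError,
)

Region = Literal["cds", "utr5", "utr3"]


@dataclass(frozen=True)
class Exon:
    """One exon in transcript orientation; genomic coordinates 1-based inclusive."""

    index: int  # 1-based ordinal in transcript orientation
    genomic_start: int
    genomic_end: int

    def __post_init__(self) -> None:
        if self.genomic_start > self.genomic_end:
            raise ModelValidationError(
                f"exon {self.index}: genomic_start {self.genomic_start} > "
                f"genomic_end {self.genomic_end}"
            )

    @property
    def length(self) -> int:
        return self.genomic_end - self.genomic_start + 1


@dataclass(frozen=True)
class DomainAnnotation:
    """A functional protein domain, in coding-nucleotide coordinates (1-based,
    inclusive, relative to the CDS)."""

    name: str
    start_c: int
    end_c: int
    source: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start_c <= self.end_c):
            raise ModelValidationError(
                f"domain {self.name!r}: invalid interval "
                f"[{self.start_c}, {self.end_c}]"
            )


@dataclass(frozen=True)
class CPos:
    """A cDNA position: coding (or UTR) anchor plus optional intronic offset."""

    pos: int
    offset: int = 0
    region: Region = "cds"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise MappingError(f"cDNA anchor must be >= 1, got {self.pos}")


class TranscriptModel:
    """Exon/CDS structure of one transcript.

    Parameters
    ----------
    transcript_id, gene_symbol : str
    strand : "+" or "-"
    exons : exons in transcript orientation
    cds_start, cds_end : 1-based positions of the first/last coding base on
        the spliced transcript (``cds_end`` includes the stop codon)
    sequence : optional spliced transcript sequence (transcript orientation)
    """

    def __init__(
        self,
        transcript_id: str,
        gene_symbol: str,
        strand: str,
        exons: Sequence[Exon],
        cds_start: int,
        cds_end: int,
        sequence: Optional[str] = None,
    ) -> None:
        if strand not in ("+", "-"):
            raise ModelValidationError(f"strand must be '+' or '-', got {strand!r}")
        if not exons:
            raise ModelValidationError("transcript needs at least one exon")
        self.transcript_id = transcript_id
        self.gene_symbol = gene_symbol
        self.strand = strand
        self.exons = list(exons)
        self.cds_start = cds_start
        self.cds_end = cds_end
        self.sequence = sequence.upper() if sequence is not None else None
        self._validate()
        # cumulative transcript start position of each exon (1-based)
        self._t_starts: list[int] = []
        t = 1
        for ex in self.exons:
            self._t_starts.append(t)
            t += ex.length

    # ----- validation -------------------------------------------------

    def _validate(self) -> None:
        for i, ex in enumerate(self.exons, start=1):
            if ex.index != i:
                raise ModelValidationError(
                    f"exon indices must be 1..n in order; exon at slot {i} "
                    f"has index {ex.index}"
                )
        sign = 1 if self.strand == "+" else -1
        for a, b in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                gap = b.genomic_start - a.genomic_end - 1
            else:
                gap = a.genomic_start - b.genomic_end - 1
            if gap < 0:
                raise ExonOverlapError(
                    f"exons {a.index} and {b.index} overlap or are out of "
                    f"transcript order on strand {self.strand}"
                )
            if gap == 0:
                raise ModelValidationError(
                    f"intron between exons {a.index} and {b.index} has length 0"
                )
        length = sum(ex.length for ex in self.exons)
        if not (1 <= self.cds_start <= self.cds_end <= length):
            raise CdsBoundsError(
                f"CDS [{self.cds_start}, {self.cds_end}] outside transcript "
                f"of length {length}"
            )
        if (self.cds_end - self.cds_start + 1) % 3 != 0:
            raise CdsFrameError(
                f"CDS length {self.cds_end - self.cds_start + 1} is not a "
                "multiple of 3"
            )
        if self.sequence is not None and len(self.sequence) != length:
            raise ModelValidationError(
                f"sequence length {len(self.sequence)} != transcript length {length}"
            )
        _ = sign  # strand handled above

    # ----- basic geometry ----------------------------------------------

    @property
    def transcript_length(self) -> int:
        return sum(ex.length for ex in self.exons)

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start + 1

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon_t_interval(self, exon_index: int) -> tuple[int, int]:
        """Transcript-coordinate interval of an exon (1-based inclusive)."""
        ex = self._exon(exon_index)
        start = self._t_starts[exon_index - 1]
        return start, start + ex.length - 1

    def intron_length(self, intron_index: int) -> int:
        """Length of the intron after exon ``intron_index`` (1-based)."""
        if not (1 <= intron_index <= self.n_exons - 1):
            raise MappingError(f"no intron {intron_index}")
        a = self.exons[intron_index - 1]
        b = self.exons[intron_index]
        if self.strand == "+":
            return b.genomic_start - a.genomic_end - 1
        return a.genomic_start - b.genomic_end - 1

    def introns(self) -> list[tuple[int, int]]:
        """(index, length) of every intron, in transcript orientation."""
        return [(i, self.intron_length(i)) for i in range(1, self.n_exons)]

    def _exon(self, exon_index: int) -> Exon:
        if not (1 <= exon_index <= self.n_exons):
            raise MappingError(
                f"exon index {exon_index} out of range 1..{self.n_exons}"
            )
        return self.exons[exon_index - 1]

    # ----- transcript <-> genomic for exonic positions ------------------

    def t_to_genomic(self, tpos: int) -> int:
        if not (1 <= tpos <= self.transcript_length):
            raise MappingError(f"transcript position {tpos} out of bounds")
        for ex, tstart in zip(self.exons, self._t_starts):
            if tstart <= tpos < tstart + ex.length:
                delta = tpos - tstart
                if self.strand == "+":
                    return ex.genomic_start + delta
                return ex.genomic_end - delta
        raise AssertionError("unreachable")

    def genomic_to_t(self, gpos: int) -> Optional[int]:
        """Transcript position for an exonic genomic position, else None."""
        for ex, tstart in zip(self.exons, self._t_starts):
            if ex.genomic_start <= gpos <= ex.genomic_end:
                if self.strand == "+":
                    return tstart + (gpos - ex.genomic_start)
                return tstart + (ex.genomic_end - gpos)
        return None

    def exon_index_of_t(self, tpos: int) -> int:
        for ex, tstart in zip(self.exons, self._t_starts):
            if tstart <= tpos < tstart + ex.length:
                return ex.index
        raise MappingError(f"transcript position {tpos} out of bounds")

    # ----- cDNA (HGVS-c-style) <-> transcript ---------------------------

    def c_to_t(self, cpos: CPos) -> int:
        """Transcript position of a cDNA anchor (offset ignored)."""
        if cpos.region == "cds":
            t = self.cds_start + cpos.pos - 1
            if t > self.cds_end:
                raise MappingError(
                    f"coding position {cpos.pos} beyond CDS length {self.cds_length}"
                )
        elif cpos.region == "utr5":
            t = self.cds_start - cpos.pos
            if t < 1:
                raise MappingError(f"5'UTR position -{cpos.pos} before transcript start")
        else:  # utr3
            t = self.cds_end + cpos.pos
            if t > self.transcript_length:
                raise MappingError(f"3'UTR position *{cpos.pos} past transcript end")
        return t

    def t_to_c(self, tpos: int) -> CPos:
        if tpos < self.cds_start:
            return CPos(self.cds_start - tpos, 0, "utr5")
        if tpos > self.cds_end:
            return CPos(tpos - self.cds_end, 0, "utr3")
        return CPos(tpos - self.cds_start + 1, 0, "cds")

    # ----- cDNA <-> genomic, including intronic offsets -----------------

    def map_c_to_genomic(self, cpos: CPos) -> int:
        """Genomic coordinate of a cDNA position with optional intronic offset.

        A positive offset requires the anchor to be the last base of a
        non-terminal exon (donor side); a negative offset requires the first
        base of a non-initial exon (acceptor side). Offsets must lie inside
        the adjacent intron.
        """
        t = self.c_to_t(cpos)
        g = self.t_to_genomic(t)
        if cpos.offset == 0:
            return g
        exon_index = self.exon_index_of_t(t)
        t_start, t_end = self.exon_t_interval(exon_index)
        if cpos.offset > 0:
            if t != t_end:
                raise MappingError(
                    "positive intronic offset requires the anchor to be the "
                    f"last base of an exon (anchor maps inside exon {exon_index})"
                )
            if exon_index == self.n_exons:
                raise MappingError("no intron downstream of the last exon")
            if cpos.offset > self.intron_length(exon_index):
                raise MappingError(
                    f"offset +{cpos.offset} exceeds intron {exon_index} length "
                    f"{self.intron_length(exon_index)}"
                )
        else:
            if t != t_start:
                raise MappingError(
                    "negative intronic offset requires the anchor to be the "
                    f"first base of an exon (anchor maps inside exon {exon_index})"
                )
            if exon_index == 1:
                raise MappingError("no intron upstream of the first exon")
            if -cpos.offset > self.intron_length(exon_index - 1):
                raise MappingError(
                    f"offset {cpos.offset} exceeds intron {exon_index - 1} length "
                    f"{self.intron_length(exon_index - 1)}"
                )
        if self.strand == "+":
            return g + cpos.offset
        return g - cpos.offset

    def map_genomic_to_c(self, gpos: int) -> CPos:
        """Inverse of :meth:`map_c_to_genomic`.

        Intronic positions are anchored to the closer exon boundary; on an
        exact tie (odd-length intron midpoint) the donor-side anchor is used.
        """
        t = self.genomic_to_t(gpos)
        if t is not None:
            return self.t_to_c(t)
        # intronic: find the flanking intron
        for i in range(1, self.n_exons):
            up = self.exons[i - 1]
            down = self.exons[i]
            if self.strand == "+":
                lo, hi = up.genomic_end + 1, down.genomic_start - 1
                if lo <= gpos <= hi:
                    from_donor = gpos - up.genomic_end
                    from_acceptor = down.genomic_start - gpos
                else:
                    continue
            else:
                lo, hi = down.genomic_end + 1, up.genomic_start - 1
                if lo <= gpos <= hi:
                    from_donor = up.genomic_start - gpos
                    from_acceptor = gpos - down.genomic_end
                else:
                    continue
            if from_donor <= from_acceptor:
                anchor_t = self.exon_t_interval(i)[1]
                anchor = self.t_to_c(anchor_t)
                return CPos(anchor.pos, from_donor, anchor.region)
            anchor_t = self.exon_t_interval(i + 1)[0]
            anchor = self.t_to_c(anchor_t)
            return CPos(anchor.pos, -from_acceptor, anchor.region)
        raise MappingError(f"genomic position {gpos} outside transcript span")

    # ----- frame bookkeeping ---------------------------------------------

    def exon_coding_length(self, exon_index: int) -> int:
        """Coding nucleotides contributed by an exon (0 for pure-UTR exons)."""
        t_start, t_end = self.exon_t_interval(exon_index)
        lo = max(t_start, self.cds_start)
        hi = min(t_end, self.cds_end)
        return max(0, hi - lo + 1)

    def exon_cds_interval(self, exon_index: int) -> Optional[tuple[int, int]]:
        """CDS-coordinate interval (1-based) the exon contributes, or None."""
        t_start, t_end = self.exon_t_interval(exon_index)
        lo = max(t_start, self.cds_start)
        hi = min(t_end, self.cds_end)
        if lo > hi:
            return None
        return lo - self.cds_start + 1, hi - self.cds_start + 1

    def is_internal_coding_exon(self, exon_index: int) -> bool:
        """True iff the exon codes and is neither the first nor last coding exon."""
        if self.exon_coding_length(exon_index) == 0:
            return False
        first = self.exon_index_of_t(self.cds_start)
        last = self.exon_index_of_t(self.cds_end)
        return exon_index not in (first, last)

    def coding_sequence(self) -> str:
        if self.sequence is None:
            raise SequenceRequiredError(
                f"transcript {self.transcript_id} carries no sequence"
            )
        return self.sequence[self.cds_start - 1 : self.cds_end]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"TranscriptModel({self.transcript_id}, {self.gene_symbol}, "
            f"{self.strand}, {self.n_exons} exons, CDS {self.cds_length} nt)"
        )


def build_transcript(document: dict) -> TranscriptModel:
    """Build and validate a :class:`TranscriptModel` from a gene-model document.

    Expected keys: ``transcript_id``, ``gene``, ``strand``, ``exons`` (list of
    ``{"genomic_start": int, "genomic_end": int}`` in transcript orientation),
    ``cds_start``/``cds_end`` (spliced-transcript coordinates), and optionally
    ``sequence`` (full spliced string) or per-exon ``sequence`` entries.
    """
    try:
        exon_docs = document["exons"]
        strand = document["strand"]
    except KeyError as e:
        raise ModelValidationError(f"gene-model document missing key {e}") from None
    exons = [
        Exon(i, int(d["genomic_start"]), int(d["genomic_end"]))
        for i, d in enumerate(exon_docs, start=1)
    ]
    sequence = document.get("sequence")
    if sequence is None and exon_docs and all("sequence" in d for d in exon_docs):
        sequence = "".join(d["sequence"] for d in exon_docs)
    return TranscriptModel(
        transcript_id=document.get("transcript_id", "TX"),
        gene_symbol=document.get("gene", document.get("gene_symbol", "")),
        strand=strand,
        exons=exons,
        cds_start=int(document["cds_start"]),
        cds_end=int(document["cds_end"]),
        sequence=sequence,
    )


def model_to_document(model: TranscriptModel) -> dict:
    """Serialize a model back to the gene-model JSON document form."""
    doc = {
        "transcript_id": model.transcript_id,
        "gene": model.gene_symbol,
        "strand": model.strand,
        "exons": [
            {"genomic_start": ex.genomic_start, "genomic_end": ex.genomic_end}
            for ex in model.exons
        ],
        "cds_start": model.cds_start,
        "cds_end": model.cds_end,
    }
    if model.sequence is not None:
        doc["sequence"] = model.sequence
    return doc
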