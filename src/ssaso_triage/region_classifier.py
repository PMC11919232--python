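"""Locate a variant relative to splice-regulatory landmarks.

Landmarks, in junction-relative coordinates (all windows inclusive, defaults
from :mod:`ssaso_triage.config`):

* canonical donor dinucleotide: intronic +1,+2 after an exon;
* canonical acceptor dinucleotide: intronic -1,-2 before an exon;
* splice donor region: exonic -3..-1 plus intronic +1..+6;
* splice acceptor region: intronic -20..-1 plus exonic +1;
* branch-point window: 18..40 nt upstream of an intron's 3' end;
* deep intronic: strictly more than 100 nt from the nearest exon junction.

Primary-class precedence (most constraining landmark wins): canonical
dinucleotide > donor region > acceptor region > branch-point window > deep /
proximal intronic; exonic positions are always primary-class EXONIC (or UTR)
and carry donor/acceptor-region membership as tags only.

Distance convention: the terminal exonic base is distance 1 from the
junction, the first intronic base likewise; there are no zero distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .config import DEFAULT_CONFIG, RunConfig
from .exceptions import MappingError
from .transcript_model import CPos, TranscriptModel
from .variant_model import VariantDescriptor


class RegionClass(str, Enum):
    CANONICAL_DONOR = "CANONICAL_DONOR"
    CANONICAL_ACCEPTOR = "CANONICAL_ACCEPTOR"
    DONOR_REGION = "DONOR_REGION"
    ACCEPTOR_REGION = "ACCEPTOR_REGION"
    BRANCH_POINT_WINDOW = "BRANCH_POINT_WINDOW"
    PROXIMAL_INTRONIC = "PROXIMAL_INTRONIC"
    DEEP_INTRONIC = "DEEP_INTRONIC"
    EXONIC = "EXONIC"
    UTR = "UTR"


#: extra, non-primary tags
TAG_SPANS_JUNCTION = "SPANS_JUNCTION"

_PRECEDENCE = [
    RegionClass.CANONICAL_DONOR,
    RegionClass.CANONICAL_ACCEPTOR,
    RegionClass.DONOR_REGION,
    RegionClass.ACCEPTOR_REGION,
    RegionClass.BRANCH_POINT_WINDOW,
    RegionClass.DEEP_INTRONIC,
    RegionClass.PROXIMAL_INTRONIC,
    RegionClass.EXONIC,
    RegionClass.UTR,
]


@dataclass(frozen=True)
class RegionReport:
    primary_class: RegionClass
    tags: frozenset[str]
    distance_to_nearest_splice_site: Optional[int]
    distance_to_branch_window: Optional[int]
    near_junction_exonic: bool
    exon_index: Optional[int] = None  # exon containing the position (exonic)
    intron_index: Optional[int] = None  # intron containing the position (intronic)
    from_donor: Optional[int] = None
    from_acceptor: Optional[int] = None
    nearest_landmark: str = ""
    config: dict = field(default_factory=dict)

    def has_tag(self, tag: RegionClass | str) -> bool:
        return (tag.value if isinstance(tag, RegionClass) else tag) in self.tags

    def to_dict(self) -> dict:
        return {
            "primary_class": self.primary_class.value,
            "tags": sorted(self.tags),
            "distance_to_nearest_splice_site": self.distance_to_nearest_splice_site,
            "distance_to_branch_window": self.distance_to_branch_window,
            "near_junction_exonic": self.near_junction_exonic,
            "exon_index": self.exon_index,
            "intron_index": self.intron_index,
            "nearest_landmark": self.nearest_landmark,
        }


def _intronic_profile(
    model: TranscriptModel, cpos: CPos, config: RunConfig
) -> dict:
    """Per-position landmark membership for an intronic position."""
    model.map_c_to_genomic(cpos)  # validates anchoring and offset extent
    t_anchor = model.c_to_t(cpos)
    exon_index = model.exon_index_of_t(t_anchor)
    if cpos.offset > 0:
        intron_index = exon_index
        from_donor = cpos.offset
        from_acceptor = model.intron_length(intron_index) - cpos.offset + 1
    else:
        intron_index = exon_index - 1
        from_acceptor = -cpos.offset
        from_donor = model.intron_length(intron_index) + cpos.offset + 1
    if from_donor < 1 or from_acceptor < 1:
        raise MappingError(
            f"offset {cpos.offset} exceeds intron {intron_index} length "
            f"{model.intron_length(intron_index)}"
        )
    tags: set[str] = set()
    if from_donor <= 2:
        tags.add(RegionClass.CANONICAL_DONOR.value)
    if from_donor <= config.donor_region_intronic_nt:
        tags.add(RegionClass.DONOR_REGION.value)
    if from_acceptor <= 2:
        tags.add(RegionClass.CANONICAL_ACCEPTOR.value)
    if from_acceptor <= config.acceptor_region_intronic_nt:
        tags.add(RegionClass.ACCEPTOR_REGION.value)
    in_branch = config.branch_window_min_nt <= from_acceptor <= config.branch_window_max_nt
    if in_branch:
        tags.add(RegionClass.BRANCH_POINT_WINDOW.value)
    distance = min(from_donor, from_acceptor)
    if distance > config.deep_intronic_nt:
        tags.add(RegionClass.DEEP_INTRONIC.value)
    else:
        tags.add(RegionClass.PROXIMAL_INTRONIC.value)
    if in_branch:
        d_branch = 0
    elif from_acceptor < config.branch_window_min_nt:
        d_branch = config.branch_window_min_nt - from_acceptor
    else:
        d_branch = from_acceptor - config.branch_window_max_nt
    return {
        "tags": tags,
        "distance": distance,
        "d_branch": d_branch,
        "intron_index": intron_index,
        "from_donor": from_donor,
        "from_acceptor": from_acceptor,
    }


def _exonic_profile(model: TranscriptModel, tpos: int, config: RunConfig) -> dict:
    exon_index = model.exon_index_of_t(tpos)
    t_start, t_end = model.exon_t_interval(exon_index)
    # terminal exonic base is distance 1 from the junction
    dist_acceptor = tpos - t_start + 1 if exon_index > 1 else None
    dist_donor = t_end - tpos + 1 if exon_index < model.n_exons else None
    candidates = [d for d in (dist_acceptor, dist_donor) if d is not None]
    distance = min(candidates) if candidates else None
    tags: set[str] = set()
    if dist_donor is not None and dist_donor <= config.donor_region_exonic_nt:
        tags.add(RegionClass.DONOR_REGION.value)
    if dist_acceptor is not None and dist_acceptor <= config.acceptor_region_exonic_nt:
        tags.add(RegionClass.ACCEPTOR_REGION.value)
    return {
        "tags": tags,
        "distance": distance,
        "exon_index": exon_index,
        "dist_donor": dist_donor,
        "dist_acceptor": dist_acceptor,
    }


def _primary_from_tags(tags: set[str], exonic: bool, utr: bool) -> RegionClass:
    if exonic:
        return RegionClass.UTR if utr else RegionClass.EXONIC
    for cls in _PRECEDENCE:
        if cls.value in tags:
            return cls
    raise AssertionError("intronic position left unclassified")


def classify_region(
    model: TranscriptModel,
    v: VariantDescriptor | CPos,
    config: RunConfig = DEFAULT_CONFIG,
) -> RegionReport:
    """Classify a variant's position against all splice landmarks.

    Ranged variants are classified by the most constraining landmark touched
    by either endpoint; if the endpoints fall on different sides of an
    exon/intron boundary the report additionally carries a ``SPANS_JUNCTION``
    tag.
    """
    if isinstance(v, CPos):
        positions = [v]
    else:
        positions = [v.start]
        if v.end_anchor_c is not None and v.end != v.start:
            positions.append(v.end)

    reports = [_classify_point(model, p, config) for p in positions]
    if len(reports) == 1:
        return reports[0]
    best = min(reports, key=lambda r: _PRECEDENCE.index(r.primary_class))
    tags = set()
    for r in reports:
        tags |= r.tags
    sides = {(r.exon_index is not None, r.intron_index) for r in reports}
    if len(sides) > 1:
        tags.add(TAG_SPANS_JUNCTION)
    dists = [
        r.distance_to_nearest_splice_site
        for r in reports
        if r.distance_to_nearest_splice_site is not None
    ]
    return RegionReport(
        primary_class=best.primary_class,
        tags=frozenset(tags),
        distance_to_nearest_splice_site=min(dists) if dists else None,
        distance_to_branch_window=best.distance_to_branch_window,
        near_junction_exonic=any(r.near_junction_exonic for r in reports),
        exon_index=best.exon_index,
        intron_index=best.intron_index,
        from_donor=best.from_donor,
        from_acceptor=best.from_acceptor,
        nearest_landmark=best.nearest_landmark,
        config=config.to_dict(),
    )


def _classify_point(
    model: TranscriptModel, cpos: CPos, config: RunConfig
) -> RegionReport:
    if cpos.offset != 0:
        prof = _intronic_profile(model, cpos, config)
        tags = prof["tags"]
        primary = _primary_from_tags(tags, exonic=False, utr=False)
        nearest = (
            "donor_site" if prof["from_donor"] <= prof["from_acceptor"] else "acceptor_site"
        )
        return RegionReport(
            primary_class=primary,
            tags=frozenset(tags | {primary.value}),
            distance_to_nearest_splice_site=prof["distance"],
            distance_to_branch_window=prof["d_branch"],
            near_junction_exonic=False,
            intron_index=prof["intron_index"],
            from_donor=prof["from_donor"],
            from_acceptor=prof["from_acceptor"],
            nearest_landmark=nearest,
            config=config.to_dict(),
        )
    tpos = model.c_to_t(cpos)
    prof = _exonic_profile(model, tpos, config)
    utr = cpos.region != "cds"
    primary = RegionClass.UTR if utr else RegionClass.EXONIC
    tags = set(prof["tags"]) | {primary.value}
    near = (
        prof["distance"] is not None
        and prof["distance"] <= config.recommended_cutoff_nt
    )
    if prof["dist_donor"] is not None and (
        prof["dist_acceptor"] is None or prof["dist_donor"] <= prof["dist_acceptor"]
    ):
        nearest = "donor_site"
    elif prof["dist_acceptor"] is not None:
        nearest = "acceptor_site"
    else:
        nearest = "none"
    return RegionReport(
        primary_class=primary,
        tags=frozenset(tags),
        distance_to_nearest_splice_site=prof["distance"],
        distance_to_branch_window=None,
        near_junction_exonic=bool(near and not utr),
        exon_index=prof["exon_index"],
        nearest_landmark=nearest,
        config=config.to_dict(),
    )


def distance_to_nearest_splice_site(
    model: TranscriptModel, v: VariantDescriptor | CPos
) -> Optional[int]:
    """Minimum distance (nt) to either flanking exon/intron junction.

    Intronic offset k is distance |k| from its anchoring junction; the other
    junction of the same intron also competes. Exonic positions use the
    terminal-base-is-distance-1 convention. ``None`` for a single-exon
    transcript (no splice sites).
    """
    report = classify_region(model, v, DEFAULT_CONFIG)
    return report.distance_to_nearest_splice_site
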