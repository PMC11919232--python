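"""Run configuration: every numeric threshold the decision trees consume.

Defaults encode the published guideline values:

* canonical splice dinucleotides: intronic +1,+2 (donor) and -1,-2 (acceptor);
* splice donor region -3..+6 and splice acceptor region -20..+1 (exonic part
  negative for the donor, positive for the acceptor, following the usual
  junction-relative convention);
* branch-point window 18..40 nt upstream of the intron 3' end;
* deep-intronic territory: strictly more than 100 nt from the nearest exon
  junction;
* ASO clearance from the nearest splice landmark: 5 nt hard cut-off,
  15 nt recommended cut-off;
* large in-frame removal caution: strictly more than 10 % of the coding
  sequence removed by an exon skip.

The hotspot parameters (window 90 nt, minimum 3 in-exon pathogenic missense
records, missense majority fraction 0.5) are this package's operationalization
of the qualitative "mutational landscape" assessment and are not published
guideline values; reports flag them as such.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path


@dataclass(frozen=True)
class RunConfig:
    # distance cut-offs for cryptic-splice variants (nt)
    hard_cutoff_nt: int = 5
    recommended_cutoff_nt: int = 15
    deep_intronic_nt: int = 100  # deep intronic means distance > this

    # splice-region window extents (nt, junction-relative)
    donor_region_exonic_nt: int = 3    # last 3 exonic bases (-3..-1)
    donor_region_intronic_nt: int = 6  # first 6 intronic bases (+1..+6)
    acceptor_region_intronic_nt: int = 20  # last 20 intronic bases (-20..-1)
    acceptor_region_exonic_nt: int = 1     # first exonic base (+1)

    # branch-point window, nt upstream of the intron 3' end (inclusive)
    branch_window_min_nt: int = 18
    branch_window_max_nt: int = 40

    # exon-skip size caution: flag removals of strictly more than this % of CDS
    size_caution_percent: float = 10.0

    # hotspot scoring (non-guideline defaults; see module docstring)
    hotspot_window_nt: int = 90
    hotspot_min_count: int = 3
    hotspot_majority_fraction: float = 0.5

    # manual escape hatch: allow skipping despite pathogenic-skip reports when
    # the exon-deletion phenotype is documented to be milder; requires an
    # explicit justification string
    milder_phenotype_override: bool = False
    override_justification: str = ""

    def __post_init__(self) -> None:
        if self.hard_cutoff_nt > self.recommended_cutoff_nt:
            raise ValueError("hard cut-off must not exceed recommended cut-off")
        for name in (
            "hard_cutoff_nt", "recommended_cutoff_nt", "deep_intronic_nt",
            "donor_region_exonic_nt", "donor_region_intronic_nt",
            "acceptor_region_intronic_nt", "acceptor_region_exonic_nt",
            "branch_window_min_nt", "branch_window_max_nt",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.branch_window_min_nt > self.branch_window_max_nt:
            raise ValueError("branch window bounds inverted")
        if self.milder_phenotype_override and not self.override_justification:
            raise ValueError(
                "milder_phenotype_override requires override_justification"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def with_overrides(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


DEFAULT_CONFIG = RunConfig()
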