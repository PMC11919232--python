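"""Exception hierarchy.

All input-validation failures derive from :class:`TriageInputError` so the CLI
can map them to exit code 2; everything else is a programming error.
"""


class TriageInputError(ValueError):
    """Base class for invalid user input (transcript, variant, evidence, table)."""


class ModelValidationError(TriageInputError):
    """A transcript model violates a structural invariant."""


class ExonOverlapError(ModelValidationError):
    """Two exons overlap (or are unordered) on the genome."""


class CdsFrameError(ModelValidationError):
    """CDS length is not a multiple of 3."""


class CdsBoundsError(ModelValidationError):
    """CDS bounds fall outside the spliced transcript."""


class MappingError(TriageInputError):
    """A coordinate does not map into the transcript span."""


class SequenceRequiredError(TriageInputError):
    """Operation needs nucleotide sequence but the model carries none."""


class HgvsParseError(TriageInputError):
    """Unsupported or malformed HGVS-c descriptor."""


class InputConsistencyError(TriageInputError):
    """Mutually inconsistent inputs (e.g. evidence referencing an impossible exon,
    or a substitution whose stated reference base disagrees with the transcript)."""
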