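"""Exception hierarchy for gcscreen.

Every error raised by the package derives from :class:`GcsError` so callers
(and the CLI) can catch pipeline failures without masking programming errors.
"""


class GcsError(Exception):
    """Base class for all gcscreen errors."""


class InvalidAlphabetError(GcsError):
    """A sequence contains characters outside A/C/G/T."""


class GrammarMismatchError(GcsError):
    """An oligo is missing a required cassette element (leader, loop, ...)."""


class HairpinInvalidError(GcsError):
    """Stems flanking the loop are not reverse-complementary / equal length."""


class AmbiguousHairpinError(GcsError):
    """More than one loop placement yields a valid hairpin."""


class DesignConstraintError(GcsError):
    """A stem violates a library design rule (length, motif, T-run ...)."""


class ManifestError(GcsError):
    """A library manifest is malformed or inconsistent."""


class GenerationError(GcsError):
    """Rejection sampling could not satisfy the library design constraints."""


class ConfigurationError(GcsError):
    """Invalid or inconsistent configuration / inputs for a pipeline stage."""


class FastqParseError(GcsError):
    """A FASTQ file could not be parsed."""


class InsufficientReplicationError(GcsError):
    """Fewer than two fold-change estimates; a standard deviation is undefined."""


class EmptySampleError(GcsError):
    """No usable replicate in a sample (all replicates missing/empty)."""
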