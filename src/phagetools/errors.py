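"""Exception hierarchy shared across the package."""


class PhagetoolsError(Exception):
    """Base class for all package-specific errors."""


class InputError(PhagetoolsError):
    """A file could not be read or parsed under the named standard."""


class ConsistencyError(PhagetoolsError):
    """Paired inputs disagree (e.g. GFF3 seqid missing from the FASTA)."""


class ValidationError(PhagetoolsError, ValueError):
    """A value violates a documented invariant or precondition."""


class EstimationError(PhagetoolsError):
    """A growth-curve quantity could not be estimated from the data."""


class NoRiseWarning(UserWarning):
    """The titer series never rose above the baseline threshold."""
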