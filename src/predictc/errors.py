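"""Exception hierarchy shared across the pipeline."""


class PrediCTCError(Exception):
    """Base class for all package errors."""


class FormatError(PrediCTCError):
    """An input file is structurally malformed (e.g. a required column is missing)."""


class ValidationError(PrediCTCError, ValueError):
    """A parsed value violates a domain constraint (range, vocabulary, uniqueness)."""


class ConfigurationError(PrediCTCError):
    """The analysis configuration is incomplete or inconsistent (e.g. missing cutoff)."""


class ReferenceNotDetectedError(ValidationError):
    """The reference gene did not amplify; the sample cannot be normalized."""
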