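"""Exception hierarchy for the syndrome differentiation model."""

from __future__ import annotations


class SDMError(Exception):
    """Base class for all package errors."""


class KBFormatError(SDMError):
    """A knowledge-base file could not be parsed in the named format."""


class KBValidationError(SDMError):
    """A knowledge base failed cross-reference validation on load.

    Carries the offending findings so callers can list every dangling id.
    """

    def __init__(self, message: str, findings=None):
        super().__init__(message)
        self.findings = list(findings or [])


class UnknownSyndromeError(SDMError, LookupError):
    """A syndrome name does not exist in the knowledge base."""

    def __init__(self, names):
        self.names = sorted(names)
        super().__init__(f"unknown syndrome(s): {', '.join(self.names)}")


class TraversalError(SDMError):
    """An answer chain could not be followed at a given step."""


class PolicyError(SDMError):
    """An answer policy was mis-specified or produced an invalid answer."""


class GenerationError(SDMError):
    """A synthetic knowledge base could not be generated under the spec."""
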