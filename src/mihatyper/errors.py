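"""Exception hierarchy for mihatyper."""

from __future__ import annotations


class MihaTyperError(Exception):
    """Base class for all mihatyper errors."""


class PanelError(MihaTyperError):
    """Panel definition violates an invariant or is corrupted."""


class GenotypeParseError(MihaTyperError):
    """A genotype string cannot be interpreted for its locus."""


class InputError(MihaTyperError):
    """Structured input-file error carrying the list of offending items.

    ``offenders`` is a list of human-readable strings, one per bad row,
    well, or field, so callers can report every problem in one pass.
    """

    def __init__(self, message: str, offenders: list[str] | None = None):
        self.offenders = offenders or []
        if self.offenders:
            message = f"{message}: " + "; ".join(self.offenders)
        super().__init__(message)


class AssayFailure(MihaTyperError):
    """Every call in a run came back no_call (QC-fatal input)."""
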