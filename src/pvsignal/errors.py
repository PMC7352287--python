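"""Exception hierarchy for the pvsignal package.

All package errors derive from :class:`PvSignalError` so callers can catch
one base class at the pipeline boundary; the CLI maps subclasses to exit
codes (config errors vs. data errors).
"""


class PvSignalError(Exception):
    """Base class for all pvsignal errors."""


class SchemaError(PvSignalError):
    """An input file does not conform to the expected column layout."""


class ValidationError(PvSignalError):
    """A record carries a value outside its allowed domain."""


class IntegrityError(PvSignalError):
    """Cross-record consistency violated (conflicting parentage, run mixups)."""


class TermLookupError(PvSignalError, KeyError):
    """A reaction or hierarchy term is unknown at the requested level."""


class ArgumentError(PvSignalError, ValueError):
    """A caller-supplied argument is out of range or inconsistent."""


class UnitError(PvSignalError):
    """Dose units cannot be reconciled with the recommendation's unit."""
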