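"""Exception hierarchy for the allotrace pipeline.

Every error raised by the package derives from :class:`AllotraceError` so
callers can catch pipeline failures with a single ``except`` clause while
still discriminating the failure mode.
"""


class AllotraceError(Exception):
    """Base class for all allotrace errors."""


class FormatError(AllotraceError):
    """A table file does not conform to the expected dialect."""


class EmptyRepertoireError(AllotraceError):
    """A clonotype table contained zero usable rows."""


class ManifestError(AllotraceError):
    """A cohort manifest failed validation."""


class ContractError(AllotraceError):
    """Operation inputs violate a precondition (e.g. mismatched metadata)."""


class ConfigError(AllotraceError):
    """An invalid configuration value."""


class DepthError(AllotraceError):
    """Requested downsampling depth exceeds the available reads."""


class UndefinedMetricError(AllotraceError):
    """A metric is undefined for the given input (e.g. empty repertoire)."""


class NormalizationError(AllotraceError):
    """A probability vector does not sum to one."""
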