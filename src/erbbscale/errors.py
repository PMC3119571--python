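"""Exception hierarchy shared across the package."""


class ErbbScaleError(Exception):
    """Base class for all package errors."""


class ParseError(ErbbScaleError):
    """A file could not be parsed; the message names the offending line."""


class EmptyInputError(ErbbScaleError):
    """An input file or record set contained no usable data."""


class ShapeError(ErbbScaleError):
    """Array/atom-count mismatch between related inputs."""


class SchemaError(ErbbScaleError):
    """Tabular records do not share a common key set."""


class UsageError(ErbbScaleError):
    """An operation was invoked with arguments outside its contract."""


class LookupError_(ErbbScaleError):
    """A requested key (kinase, region, pair, species...) is not packaged."""


class RangeError(ErbbScaleError):
    """A residue position falls outside the packaged kinase-domain span."""


class GeometryError(ErbbScaleError):
    """Degenerate geometry (e.g. collinear superposition selection)."""


class StatisticsError(ErbbScaleError):
    """Too few observations, or an undefined statistic (zero mean count)."""


class PlacementError(ErbbScaleError):
    """A probe volume could not be placed under the stated constraints."""


class ConfigError(ErbbScaleError):
    """Unknown mutant/inhibitor/scenario identifier or malformed config."""


class IntegrationError(ErbbScaleError):
    """The ODE solver failed; message carries solver diagnostics."""
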