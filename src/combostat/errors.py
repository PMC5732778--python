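"""Exception hierarchy shared across the package."""


class CombostatError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CombostatError):
    """Input file does not match the documented long-format CSV schema."""


class GridMismatchError(CombostatError):
    """Replicate plates disagree on the concentration ladders."""


class DegenerateAssayError(CombostatError):
    """Control fluorescence does not exceed blank fluorescence."""


class InsufficientControlsError(CombostatError):
    """Fewer than two control wells on a plate; QC cannot be evaluated."""


class QCFailureError(CombostatError):
    """Assay-level quality control failed and forcing was not requested."""


class ConfigError(CombostatError):
    """Invalid configuration value."""


class AnalysisError(CombostatError):
    """A computation could not be completed (e.g. too many failed batches)."""
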