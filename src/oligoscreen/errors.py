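"""Exception hierarchy for the screening pipeline."""


class OligoscreenError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(OligoscreenError):
    """Invalid panel/simulation configuration."""


class TransitionNotFoundError(OligoscreenError, KeyError):
    """A transition key has no definition in the registry."""

    def __init__(self, key):
        super().__init__(f"no transition matching {key!r} in registry")
        self.key = key


class IntegrationError(OligoscreenError):
    """Chromatographic peak integration failed."""


class FormatError(OligoscreenError):
    """A tabular exchange file does not match its declared format."""


class QuantificationError(OligoscreenError):
    """Peak areas could not be converted to internal-standard ratios."""


class ReferenceError(OligoscreenError):
    """Control reference could not be built or applied."""


class ScreeningError(OligoscreenError):
    """A MoM profile could not be screened."""


class PrecisionError(OligoscreenError):
    """Precision statistics undefined for the given replicates."""


class GenerationError(OligoscreenError):
    """Synthetic data generation failed."""


class WorkflowError(OligoscreenError):
    """End-to-end run could not proceed."""
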