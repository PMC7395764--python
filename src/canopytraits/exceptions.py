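"""Exception hierarchy used across the package."""


class CanopyTraitsError(Exception):
    """Base class for all package errors."""


class DomainError(CanopyTraitsError, ValueError):
    """An input violates a documented precondition."""


class ConfigurationError(CanopyTraitsError, ValueError):
    """A configuration object is internally inconsistent."""


class EmptyMaskError(DomainError):
    """Segmentation found no plausible plant foreground."""


class PipelineError(CanopyTraitsError, RuntimeError):
    """A pipeline stage failed at run time."""
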