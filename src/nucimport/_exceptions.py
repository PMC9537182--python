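"""Exception hierarchy shared across the pipeline."""


class NucimportError(Exception):
    """Base class for all package-specific errors."""


class InvalidInput(NucimportError, ValueError):
    """An input value violates a physical or structural precondition."""


class ConfigurationError(NucimportError, ValueError):
    """A required configuration element (reference stage, background set, ...) is missing."""


class FitFailure(NucimportError, RuntimeError):
    """A curve fit or regression could not be carried out."""


class SegmentationFailure(NucimportError, RuntimeError):
    """No usable nuclear region could be segmented from a frame."""
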