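"""Exception hierarchy for the vineweed pipeline."""


class VineweedError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(VineweedError):
    """Invalid run configuration or parameter value."""


class FormatError(VineweedError):
    """Malformed or inconsistent input file."""


class LabelValidationError(VineweedError):
    """Vector/raster labels carry values outside the class vocabulary."""

    def __init__(self, message, offending=None):
        super().__init__(message)
        self.offending = list(offending or [])


class DegenerateDistributionError(VineweedError):
    """A statistic is undefined because the inputs have no spread."""


class PipelineError(VineweedError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage, message):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
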