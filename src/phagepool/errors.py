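"""Exception hierarchy."""


class PhagePoolError(Exception):
    """Base class for all phagepool errors."""


class ConfigurationError(PhagePoolError):
    """Invalid configuration value (bad library name, bad depth, bad anchor...)."""


class InputError(PhagePoolError):
    """Malformed or unusable input data (bad FASTQ record, empty file...)."""


class SimulationError(PhagePoolError):
    """Simulator failure (numeric overflow, empty pool at a sampled time point)."""


class PipelineError(PhagePoolError):
    """A pipeline stage failed; the message names the stage and the offending input."""
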