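"""Exception types used across the simulator."""


class HivesimError(Exception):
    """Base class for all hivesim errors."""


class ConfigError(HivesimError, ValueError):
    """Invalid configuration or argument value."""


class StateError(HivesimError, RuntimeError):
    """Operation applied to an object in a state that forbids it
    (e.g. mutating a collapsed colony, crossing a mated queen)."""


class FormatError(HivesimError, ValueError):
    """Malformed external input (VCF, haplotype matrix, config file)."""
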