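"""Exception hierarchy.

Argument misuse raises plain ``ValueError``; these classes mark failures the
CLI maps to distinct exit codes (config -> 2, data/parse -> 3).
"""


class HcdkitError(Exception):
    """Base class for hcdkit-specific failures."""


class ConfigError(HcdkitError):
    """Invalid configuration: unknown dialect, impossible simulation layout, ..."""


class DataError(HcdkitError):
    """Input data violates a contract: non-finite signal, overlapping bedGraph
    steps, disjoint chromosome namespaces, ..."""


class ParseError(DataError):
    """A file could not be parsed; message names the offending line."""
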