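"""Exception hierarchy.

Argument-level misuse raises plain :class:`ValueError`; the classes here mark
problems with configuration files, input file formats, or topologies.
"""


class OpidynError(Exception):
    """Base class for package-specific errors."""


class ConfigurationError(OpidynError):
    """A config entry (feature group, criteria, reference) cannot be resolved."""


class FormatError(OpidynError):
    """An input file violates its format contract (e.g. frame atom-count mismatch)."""


class TopologyError(OpidynError):
    """A required atom or residue is missing from the topology."""
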