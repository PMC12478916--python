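"""Exception hierarchy shared across the package."""


class PcipaceError(Exception):
    """Base class for all package errors."""


class DomainError(PcipaceError, ValueError):
    """A numeric argument is outside the physically meaningful domain."""


class ConfigurationError(PcipaceError, ValueError):
    """A profile/device/config combination is inconsistent."""


class FormatError(PcipaceError, ValueError):
    """An input file could not be parsed in the declared format."""


class InferenceError(PcipaceError, ValueError):
    """A regression problem is underdetermined or otherwise unsolvable."""
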