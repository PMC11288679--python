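"""Exception hierarchy for antnet."""


class AntnetError(Exception):
    """Base class for all antnet errors."""


class ConfigError(AntnetError, ValueError):
    """Invalid configuration or generator parameters."""


class DataFormatError(AntnetError, ValueError):
    """Malformed input table or matrix."""


class LookupError_(AntnetError, KeyError):
    """Unknown node / ant identifier."""


class DegenerateGroupError(AntnetError, ValueError):
    """A statistic is undefined on this group (e.g. zero variance)."""


class ContractError(AntnetError, ValueError):
    """An operation was called outside its contract (e.g. wrong k)."""


class TieError(AntnetError, ValueError):
    """Queen membership exactly 0.5: community orientation is undecidable."""


class UndefinedModularityError(AntnetError, ValueError):
    """Modularity is undefined on an empty (zero-weight) network."""
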