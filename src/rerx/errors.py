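"""Exception hierarchy.

Every error raised by this package derives from :class:`RerxError` so callers
(and the CLI) can catch one base class.
"""


class RerxError(Exception):
    """Base class for all errors raised by rerx."""


class SchemaError(RerxError):
    """A schema definition or a file/schema mismatch is invalid."""


class CohortValidationError(RerxError):
    """A cohort cell or label violates its declared variable spec."""


class ConfigError(RerxError):
    """A configuration value is out of its permitted range."""


class DegenerateInputError(RerxError):
    """An operation requiring both classes received single-class data."""


class TrainingError(RerxError):
    """Network training diverged (non-finite loss)."""


class ContractError(RerxError):
    """A caller violated an operation's precondition."""


class RuleParseError(RerxError):
    """A rule DSL file could not be parsed; carries the line number."""


class RecursionDepthError(RerxError):
    """Rule refinement exceeded max_recursion_depth; carries the rule chain."""


class GenerationError(RerxError):
    """The synthetic generator could not satisfy the requested class counts."""
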