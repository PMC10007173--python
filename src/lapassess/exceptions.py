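"""Exception hierarchy for lapassess."""


class LapassessError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LapassessError):
    """A fuzzy-system or run configuration is malformed (bad breakpoints,
    incomplete rule base, inconsistent calibration...)."""


class ContractViolationError(LapassessError):
    """A caller broke an operation's precondition (degenerate bounding box,
    wrong camera passed, missing input variable)."""


class NoRuleFiredError(LapassessError):
    """Defuzzification was asked for with every activation at zero.

    With a complete rule base and clamped inputs this cannot happen; seeing
    it means the system was built outside the validated constructors.
    """


class StreamFormatError(LapassessError):
    """A detection-stream file is malformed; the message carries the line
    number and offending fields."""
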