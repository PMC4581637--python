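"""Exception hierarchy for the package."""


class CEAError(Exception):
    """Base class for all package errors."""


class InputError(CEAError, ValueError):
    """Invalid user input: out-of-range parameter, malformed file, unknown key."""


class UndefinedICERError(CEAError):
    """The ICER is undefined: zero life-years gained, or the programme is
    dominated (positive cost, non-positive health gain)."""
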