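"""Exception types shared across the package."""


class MelbError(Exception):
    """Base class for all package errors."""


class FormatError(MelbError):
    """Malformed input file (duplicate ids, missing columns, bad enum)."""


class ValidationError(MelbError):
    """Structurally valid input violating a domain invariant."""


class DegenerateDrawError(MelbError):
    """A randomized signature derivation produced an empty candidate set.

    Callers in the iteration loops catch this and resample parameters.
    """
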