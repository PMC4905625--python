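"""Exception and warning types shared across the package."""


class TuberhistError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(TuberhistError, ValueError):
    """A generator or run specification violates its invariants."""


class PlacementInfeasibleError(TuberhistError):
    """Requested phantom objects cannot be placed in the available tissue."""


class InvalidInputError(TuberhistError, ValueError):
    """An operation received input outside its contract."""


class MissingChannelError(TuberhistError, KeyError):
    """A marker in the panel has no corresponding image."""

    def __init__(self, marker: str):
        super().__init__(marker)
        self.marker = marker

    def __str__(self) -> str:  # KeyError quotes its arg; keep it readable
        return f"no image supplied for marker {self.marker!r}"


class DegenerateGroupError(InvalidInputError):
    """A statistical group has too few samples for the requested test."""


class UndefinedValueWarning(UserWarning):
    """A measurement is undefined (e.g. zero tissue area); NaN is returned."""
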