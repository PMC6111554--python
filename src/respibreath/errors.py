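"""Exception types shared across the package."""


class RespibreathError(Exception):
    """Base class for all package errors."""


class FormatError(RespibreathError):
    """A file or record does not conform to the documented layout."""


class SaturationError(RespibreathError):
    """An acquired voltage sample is at or above the divider source voltage.

    Carries the offending channel name and sample index so the bad sample
    can be located in the recording.
    """

    def __init__(self, channel: str, index: int, value: float, v_source: float):
        self.channel = channel
        self.index = index
        self.value = value
        self.v_source = v_source
        super().__init__(
            f"channel {channel!r} sample {index}: v = {value:.6g} V >= "
            f"source voltage {v_source:.6g} V (divider saturated)"
        )


class StratificationError(RespibreathError):
    """Cross-validation folds cannot be formed with both classes present."""
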