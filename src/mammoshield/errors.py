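"""Exception types shared across the package."""


class MammoShieldError(Exception):
    """Base class for all package-specific errors."""


class InvalidCompositionError(MammoShieldError):
    """Raised for empty or non-positive material compositions."""


class EnergyOutOfRangeError(MammoShieldError):
    """Raised when a photon energy falls outside the tabulated grid."""


class UnknownMaterialError(MammoShieldError):
    """Raised when a material name is not present in the library."""


class InvalidSceneError(MammoShieldError):
    """Raised for malformed geometry (bad bounds, regions outside the world)."""


class PointOutsideWorldError(MammoShieldError):
    """Escaped signal: a point lies outside the world box."""


class InvalidSourceError(MammoShieldError):
    """Raised for degenerate source specifications."""


class InvalidMediumError(MammoShieldError):
    """Raised when free-path sampling is attempted in a non-attenuating medium."""


class TallyError(MammoShieldError):
    """Raised for scoring into unknown regions or aggregating missing ids."""


class UndefinedTransmissionError(MammoShieldError):
    """Raised when a transmission factor is requested with zero primary count."""


class InvalidPhantomError(MammoShieldError):
    """Raised when phantom and screen volumes clash."""


class NotConfiguredError(MammoShieldError):
    """Raised when an optional, externally-parameterized feature lacks its config."""
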