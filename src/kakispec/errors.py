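"""Exception hierarchy for the kakispec pipeline."""


class KakispecError(Exception):
    """Base class for all kakispec errors."""


class FormatError(KakispecError):
    """A file header is missing required fields or declares contradictory ones."""


class CorruptFileError(KakispecError):
    """A file's payload disagrees with its declared layout."""


class ContractError(KakispecError):
    """Inputs violate an operation's preconditions (shape/axis mismatch etc.)."""


class CalibrationError(KakispecError):
    """Reflectance calibration is undefined (white <= dark somewhere)."""


class ParameterError(KakispecError):
    """An operation parameter is outside its allowed range."""


class DegenerateDataError(KakispecError):
    """The data carry no usable contrast (constant image, zero variance)."""


class EmptySegmentationError(KakispecError):
    """Fruit segmentation produced no surviving component."""


class InsufficientDataError(KakispecError):
    """Too few observations to fit the requested model."""


class SceneSpecError(KakispecError):
    """A synthetic scene specification is internally inconsistent."""
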