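"""Hyperspectral cube data model, ENVI / portable I/O and reflectance calibration.

A :class:`HyperCube` is a ``(rows, cols, bands)`` array of either raw sensor
counts or relative reflectance, together with a :class:`WavelengthAxis` of
band-centre wavelengths in nanometres.  Raw cubes become reflectance cubes via
:func:`calibrate_reflectance`, which applies the standard white/dark reference
correction

    rho(x, y, l) = rho_ref * (R(x, y, l) - R_dark(x, y, l))
                           / (R_white(x, y, l) - R_dark(x, y, l))

where ``rho_ref`` is the known reflectance of the white calibration target
(0.99 for a 99% Spectralon tile).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    CalibrationError,
    ContractError,
    CorruptFileError,
    FormatError,
)

logger = logging.getLogger(__name__)

#: Upper clip bound for reflectance cubes: headroom above the 0.99 white
#: target so sensor noise on bright pixels does not abort a run.
REFLECTANCE_MAX = 1.5

RAW_COUNTS = "raw_counts"
REFLECTANCE = "reflectance"

_ORIGINS = (RAW_COUNTS, REFLECTANCE)


def default_axis() -> "WavelengthAxis":
    """The instrument's 60-band axis: 450, 460, ..., 1040 nm."""
    return WavelengthAxis(np.arange(450.0, 1041.0, 10.0))


@dataclass(frozen=True)
class WavelengthAxis:
    """Strictly increasing band-centre wavelengths in nm."""

    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 1:
            raise ContractError("wavelength axis must be a non-empty 1-D array")
        if np.any(np.diff(vals) <= 0):
            raise ContractError("wavelengths must be strictly increasing")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other) -> bool:
        return isinstance(other, WavelengthAxis) and np.array_equal(
            self.values, other.values
        )

    def nir_bands(self, cutoff_nm: float = 800.0) -> np.ndarray:
        """Boolean selector of bands at or above ``cutoff_nm``."""
        return self.values >= cutoff_nm


@dataclass
class HyperCube:
    """A (rows, cols, bands) cube with its wavelength axis and origin tag."""

    data: np.ndarray
    axis: WavelengthAxis
    origin: str = RAW_COUNTS

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3 or min(data.shape) < 1:
            raise ContractError(
                f"cube data must be 3-D with all dims >= 1, got shape {data.shape}"
            )
        if data.shape[2] != len(self.axis):
            raise ContractError(
                f"band dimension {data.shape[2]} does not match axis length {len(self.axis)}"
            )
        if self.origin not in _ORIGINS:
            raise ContractError(f"origin must be one of {_ORIGINS}, got {self.origin!r}")
        if np.any(data < 0):
            raise ContractError("cube values must be nonnegative")
        if self.origin == REFLECTANCE and np.any(data > REFLECTANCE_MAX):
            raise ContractError(
                f"reflectance cube has values above {REFLECTANCE_MAX}"
            )
        self.data = data

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def spectra(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Pixel spectra as a (n_pixels, bands) matrix, optionally masked."""
        if mask is None:
            return self.data.reshape(-1, self.n_bands)
        if mask.shape != self.data.shape[:2]:
            raise ContractError("mask shape does not match cube spatial grid")
        return self.data[mask]


@dataclass
class ReferenceSet:
    """White and dark reference cubes plus the white target's reflectance.

    Spatially flat references (synthetic fixtures) may be supplied as 1x1
    cubes; they broadcast over the raw cube's spatial grid.
    """

    white: HyperCube
    dark: HyperCube
    rho_ref: float = 0.99
    #: optional per-band reflectance of the calibration target; overrides
    #: the scalar rho_ref when the target is not spectrally flat
    rho_ref_per_band: np.ndarray | None = field(default=None)

    def __post_init__(self):
        if self.white.axis != self.dark.axis:
            raise ContractError("white and dark references have different axes")
        if self.white.shape != self.dark.shape:
            raise ContractError("white and dark references have different shapes")
        if not (0 < self.rho_ref <= 1):
            raise ContractError("rho_ref must be in (0, 1]")
        if np.any(self.white.data <= self.dark.data):
            bad = np.argwhere(self.white.data <= self.dark.data)[0]
            raise CalibrationError(
                "white reference does not exceed dark reference at "
                f"(row={bad[0]}, col={bad[1]}, band={bad[2]})"
            )
        if self.rho_ref_per_band is not None:
            arr = np.asarray(self.rho_ref_per_band, dtype=float)
            if arr.shape != (len(self.white.axis),):
                raise ContractError("rho_ref_per_band length must match axis")
            self.rho_ref_per_band = arr

    def target_reflectance(self) -> np.ndarray:
        if self.rho_ref_per_band is not None:
            return self.rho_ref_per_band
        return np.full(len(self.white.axis), self.rho_ref)


def calibrate_reflectance(raw: HyperCube, refs: ReferenceSet) -> HyperCube:
    """Convert raw counts to relative reflectance with white/dark references.

    Values are clipped to [0, REFLECTANCE_MAX]; the number of clipped entries
    (noise-driven negatives or overshoots) is logged, not errored.
    """
    if raw.axis != refs.white.axis:
        raise ContractError("raw cube and references have different wavelength axes")
    if refs.white.shape[:2] not in ((1, 1), raw.shape[:2]):
        raise ContractError(
            f"reference spatial shape {refs.white.shape[:2]} matches neither "
            f"(1, 1) nor the raw grid {raw.shape[:2]}"
        )
    white = refs.white.data
    dark = refs.dark.data
    denom = white - dark
    rho = refs.target_reflectance()[None, None, :] * (raw.data - dark) / denom
    n_clipped = int(np.count_nonzero((rho < 0) | (rho > REFLECTANCE_MAX)))
    if n_clipped:
        logger.info("calibrate_reflectance: clipped %d entries", n_clipped)
    rho = np.clip(rho, 0.0, REFLECTANCE_MAX)
    return HyperCube(rho, raw.axis, REFLECTANCE)


# ---------------------------------------------------------------------------
# I/O: ENVI (text .hdr + raw binary) and portable (.npz) containers
# ---------------------------------------------------------------------------

_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32,
                5: np.float64, 12: np.uint16, 13: np.uint32}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}

FORMAT_ENVI = "envi"
FORMAT_PORTABLE = "portable"


def _parse_envi_header(text: str) -> dict:
    """Parse an ENVI header into a dict of lower-cased keys.

    Values in ``{ }`` (possibly multi-line) become lists of strings.
    """
    if not text.lstrip().startswith("ENVI"):
        raise FormatError("not an ENVI header (missing magic line)")
    body = text.lstrip()[4:]
    fields: dict = {}
    pos = 0
    while pos < len(body):
        eq = body.find("=", pos)
        if eq < 0:
            break
        key = body[pos:eq].strip().lower()
        rest = body[eq + 1:].lstrip()
        offset = len(body) - len(rest)
        if rest.startswith("{"):
            end = rest.find("}")
            if end < 0:
                raise FormatError(f"unterminated brace list for key {key!r}")
            raw = rest[1:end]
            fields[key] = [tok.strip() for tok in raw.split(",") if tok.strip()]
            pos = offset + end + 1
        else:
            nl = rest.find("\n")
            if nl < 0:
                nl = len(rest)
            fields[key] = rest[:nl].strip()
            pos = offset + nl + 1
    return fields


def _write_envi(cube: HyperCube, path: str) -> None:
    base, _ = os.path.splitext(path)
    hdr_path = base + ".hdr"
    data = np.ascontiguousarray(cube.data, dtype=np.float32)
    rows, cols, bands = data.shape
    wl = ", ".join(f"{w:.1f}" for w in cube.axis.values)
    header = (
        "ENVI\n"
        "description = {kakispec hyperspectral cube}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[np.dtype(np.float32)]}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        f"kakispec origin = {cube.origin}\n"
        "wavelength units = nm\n"
        f"wavelength = {{{wl}}}\n"
    )
    with open(hdr_path, "w") as fh:
        fh.write(header)
    # BSQ: band-sequential, i.e. (bands, lines, samples) on disk
    with open(path, "wb") as fh:
        np.transpose(data, (2, 0, 1)).tofile(fh)


def _read_envi(path: str) -> HyperCube:
    base, _ = os.path.splitext(path)
    hdr_path = base + ".hdr"
    if not os.path.exists(hdr_path):
        raise FormatError(f"missing ENVI header {hdr_path}")
    with open(hdr_path) as fh:
        fields = _parse_envi_header(fh.read())
    try:
        cols = int(fields["samples"])
        rows = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = str(fields["interleave"]).lower()
    except KeyError as exc:
        raise FormatError(f"ENVI header missing required field: {exc}") from exc
    if dtype_code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type {dtype_code}")
    if interleave not in ("bsq", "bil", "bip"):
        raise FormatError(f"unsupported interleave {interleave!r}")
    if "wavelength" not in fields:
        raise FormatError("ENVI header missing wavelength list")
    wavelengths = np.array([float(w) for w in fields["wavelength"]])
    if wavelengths.size != bands:
        raise FormatError(
            f"header declares {bands} bands but {wavelengths.size} wavelengths"
        )
    dtype = _ENVI_DTYPES[dtype_code]
    if int(fields.get("byte order", 0)) == 1:
        dtype = np.dtype(dtype).newbyteorder(">")
    payload = np.fromfile(path, dtype=dtype)
    if payload.size != rows * cols * bands:
        raise CorruptFileError(
            f"{path}: payload holds {payload.size} values, header implies "
            f"{rows * cols * bands}"
        )
    if interleave == "bsq":
        data = payload.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bil":
        data = payload.reshape(rows, bands, cols).transpose(0, 2, 1)
    else:  # bip
        data = payload.reshape(rows, cols, bands)
    order = np.argsort(wavelengths)
    data = np.ascontiguousarray(data[:, :, order], dtype=float)
    origin = str(fields.get("kakispec origin", RAW_COUNTS))
    if origin not in _ORIGINS:
        origin = RAW_COUNTS
    return HyperCube(data, WavelengthAxis(wavelengths[order]), origin)


def write_cube(cube: HyperCube, path: str, format: str = FORMAT_PORTABLE) -> None:
    """Write a cube as ENVI (.hdr + binary) or a portable .npz container."""
    try:
        if format == FORMAT_ENVI:
            _write_envi(cube, path)
        elif format == FORMAT_PORTABLE:
            # savez appends ".npz" to bare paths; write through a handle so
            # the file lands exactly where asked
            with open(path, "wb") as fh:
                np.savez(
                    fh,
                    data=cube.data,
                    wavelengths=cube.axis.values,
                    origin=np.array(cube.origin),
                )
        else:
            raise FormatError(f"unknown cube format {format!r}")
    except OSError as exc:
        raise OSError(f"failed writing cube to {path}: {exc}") from exc


def read_cube(path: str, format: str = FORMAT_PORTABLE) -> HyperCube:
    """Read a cube written by :func:`write_cube`."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == FORMAT_ENVI:
        return _read_envi(path)
    if format == FORMAT_PORTABLE:
        try:
            with np.load(path) as payload:
                data = payload["data"]
                wavelengths = payload["wavelengths"]
                origin = str(payload["origin"])
        except (KeyError, ValueError) as exc:
            raise CorruptFileError(f"{path}: {exc}") from exc
        return HyperCube(data, WavelengthAxis(wavelengths), origin)
    raise FormatError(f"unknown cube format {format!r}")
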