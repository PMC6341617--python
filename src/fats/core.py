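"""Shared containers and error types for the lipid-scoring pipeline.

Images travel through the pipeline as :class:`PixelGrid` objects: a plain
2-D unsigned-integer array plus its physical calibration (µm per pixel).
Binarisation produces :class:`BinaryMask` objects whose alphabet is exactly
``{0, 255}``.  Fluorescence fields pair a nuclei channel (Hoechst/DAPI) with
a lipid channel (Nile Red/FITC) in a :class:`TwoChannelImage`; colorimetric
Oil Red O / haematoxylin fields arrive as an :class:`RgbImage` and are
converted by :mod:`fats.unmix`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: pixel pitch above which detection of nuclei and droplets degrades;
#: exceeding it raises :class:`ResolutionWarning`, not an error.
OPTIMAL_MAX_PITCH_UM = 2.0

_ALLOWED_DTYPES = (np.dtype(np.uint8), np.dtype(np.uint16))


class FatsError(Exception):
    """Base class for all pipeline errors."""


class InputError(FatsError):
    """Unreadable, missing or structurally invalid input."""


class CalibrationError(FatsError):
    """Inconsistent shapes or physical calibration between channels."""


class ManifestError(FatsError):
    """Malformed plate manifest."""


class ParameterError(FatsError):
    """Invalid analysis parameter."""


class AnalysisError(FatsError):
    """A computation could not be carried out on the given data."""


class DensityError(FatsError):
    """Synthetic scene too dense to place objects without overlap."""


class ResolutionWarning(UserWarning):
    """Pixel pitch coarser than the 2 µm/pixel optimum."""


@dataclass(frozen=True)
class PixelGrid:
    """Single-channel intensity image with isotropic physical pixel pitch."""

    values: np.ndarray
    pixel_pitch_um: float

    def __post_init__(self) -> None:
        v = self.values
        if not isinstance(v, np.ndarray) or v.ndim != 2:
            raise InputError("PixelGrid requires a 2-D array")
        if v.dtype not in _ALLOWED_DTYPES:
            raise InputError(
                f"PixelGrid requires uint8 or uint16 values, got {v.dtype}"
            )
        if not self.pixel_pitch_um > 0:
            raise CalibrationError("pixel_pitch_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def max_value(self) -> int:
        """Saturation value of the declared bit depth (255 or 65535)."""
        return int(np.iinfo(self.values.dtype).max)


@dataclass(frozen=True)
class BinaryMask:
    """Thresholded foreground map; every value is exactly 0 or 255."""

    values: np.ndarray
    pixel_pitch_um: float

    def __post_init__(self) -> None:
        v = self.values
        if not isinstance(v, np.ndarray) or v.ndim != 2:
            raise InputError("BinaryMask requires a 2-D array")
        if v.dtype != np.uint8:
            raise InputError("BinaryMask values must be uint8")
        if not np.isin(v, (0, 255)).all():
            raise InputError("BinaryMask values must be exactly 0 or 255")
        if not self.pixel_pitch_um > 0:
            raise CalibrationError("pixel_pitch_um must be > 0")

    @property
    def foreground(self) -> np.ndarray:
        """Boolean view of the mask (True where 255)."""
        return self.values > 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class TwoChannelImage:
    """Paired nuclei + lipid channels of one microscope field."""

    nuclei: PixelGrid
    lipid: PixelGrid

    def __post_init__(self) -> None:
        if self.nuclei.shape != self.lipid.shape:
            raise CalibrationError(
                f"channel shape mismatch: nuclei {self.nuclei.shape} "
                f"vs lipid {self.lipid.shape}"
            )
        if self.nuclei.pixel_pitch_um != self.lipid.pixel_pitch_um:
            raise CalibrationError("channels must share one pixel pitch")

    @property
    def pixel_pitch_um(self) -> float:
        return self.nuclei.pixel_pitch_um


@dataclass(frozen=True)
class RgbImage:
    """8- or 16-bit RGB bright-field image split into three channels."""

    red: PixelGrid
    green: PixelGrid
    blue: PixelGrid

    def __post_init__(self) -> None:
        shapes = {self.red.shape, self.green.shape, self.blue.shape}
        if len(shapes) != 1:
            raise InputError("RGB channels must share one shape")
        dtypes = {c.values.dtype for c in (self.red, self.green, self.blue)}
        if len(dtypes) != 1:
            raise InputError("RGB channels must share one bit depth")
        pitches = {c.pixel_pitch_um for c in (self.red, self.green, self.blue)}
        if len(pitches) != 1:
            raise CalibrationError("RGB channels must share one pixel pitch")

    @property
    def pixel_pitch_um(self) -> float:
        return self.red.pixel_pitch_um

    @classmethod
    def from_array(cls, rgb: np.ndarray, pixel_pitch_um: float) -> "RgbImage":
        """Build from an (H, W, 3) array."""
        if rgb.ndim != 3 or rgb.shape[2] != 3:
            raise InputError("expected an (H, W, 3) RGB array")
        r, g, b = (np.ascontiguousarray(rgb[..., i]) for i in range(3))
        return cls(
            PixelGrid(r, pixel_pitch_um),
            PixelGrid(g, pixel_pitch_um),
            PixelGrid(b, pixel_pitch_um),
        )
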