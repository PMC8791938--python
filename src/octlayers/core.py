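"""Shared domain types for macular OCT B-scan layer segmentation.

Conventions used throughout the package:

* images are 2-D arrays with the row axis pointing along the A-scan
  (axial) direction — increasing row index means deeper tissue — and the
  column axis pointing laterally across the B-scan;
* intensities live in ``[0, 1]``;
* a boundary curve is one (possibly fractional) row index per column.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

#: The eleven retinal boundaries in anatomical order, innermost first.
#: ``o-X`` denotes the outer (deeper) boundary of layer X.
BOUNDARY_ORDER: tuple[str, ...] = (
    "ILM",
    "o-NFL",
    "o-GCL",
    "o-IPL",
    "o-INL",
    "o-OPL",
    "o-ONL",
    "o-IS",
    "o-OSJ",
    "o-OS",
    "o-RPE",
)

#: Boundaries where reflectivity steps from dark (above) to bright (below).
DARK_TO_BRIGHT: frozenset[str] = frozenset(
    {"ILM", "o-GCL", "o-INL", "o-ONL", "o-IS", "o-OS"}
)

#: Boundaries where reflectivity steps from bright (above) to dark (below).
BRIGHT_TO_DARK: frozenset[str] = frozenset(
    {"o-NFL", "o-IPL", "o-OPL", "o-OSJ", "o-RPE"}
)

# A B-scan must admit the two lateral seed bands plus at least one centre
# column, and enough rows for the 4-tap axial gradient plus margins.
MIN_HEIGHT = 8
MIN_WIDTH = 61


class OctError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(OctError, ValueError):
    """An input (image, configuration, curve) violates a documented invariant."""


class IdentificationError(OctError, RuntimeError):
    """A named retinal boundary could not be assigned from the candidates."""


class Polarity(str, Enum):
    """Direction of the axial reflectivity step a channel is tuned to."""

    DARK_TO_BRIGHT = "dark_to_bright"
    BRIGHT_TO_DARK = "bright_to_dark"

    @property
    def template(self) -> np.ndarray:
        """4x1 axial gradient template (ascending or descending)."""
        if self is Polarity.DARK_TO_BRIGHT:
            return np.array([-1.0, -1.0, 1.0, 1.0])
        return np.array([1.0, 1.0, -1.0, -1.0])

    @property
    def boundaries(self) -> frozenset[str]:
        return DARK_TO_BRIGHT if self is Polarity.DARK_TO_BRIGHT else BRIGHT_TO_DARK


def boundary_polarity(name: str) -> Polarity:
    """Polarity of the reflectivity step at a named boundary."""
    if name in DARK_TO_BRIGHT:
        return Polarity.DARK_TO_BRIGHT
    if name in BRIGHT_TO_DARK:
        return Polarity.BRIGHT_TO_DARK
    raise ValidationError(f"unknown boundary name: {name!r}")


def as_pixels(image) -> np.ndarray:
    """Return the underlying 2-D float array of a :class:`BScan` or array."""
    if isinstance(image, BScan):
        return image.pixels
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2:
        raise ValidationError(f"expected a 2-D image, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class BScan:
    """One OCT cross-section: a 2-D intensity grid plus pixel pitch.

    Rows run along the axial (A-scan) direction, columns laterally.
    """

    pixels: np.ndarray
    pixel_size_axial: float = 3.9  # um per pixel
    pixel_size_lateral: float = 6.0  # um per pixel

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=float)
        if arr.ndim != 2:
            raise ValidationError(f"pixels must be 2-D, got shape {arr.shape}")
        h, w = arr.shape
        if h < MIN_HEIGHT:
            raise ValidationError(f"pixels: height {h} < minimum {MIN_HEIGHT} rows")
        if w < MIN_WIDTH:
            raise ValidationError(f"pixels: width {w} < minimum {MIN_WIDTH} columns")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("pixels: intensities must be finite")
        if arr.min() < -1e-9 or arr.max() > 1 + 1e-9:
            raise ValidationError("pixels: intensities must lie in [0, 1]")
        if self.pixel_size_axial <= 0 or self.pixel_size_lateral <= 0:
            raise ValidationError("pixel_size_axial/lateral: must be positive")
        object.__setattr__(self, "pixels", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "BScan":
        """A new B-scan with the same pitch metadata and new pixel data."""
        return BScan(pixels, self.pixel_size_axial, self.pixel_size_lateral)


@dataclass(frozen=True)
class Volume:
    """A stack of B-scans sharing one geometry (slices x rows x columns)."""

    pixels: np.ndarray
    pixel_size_axial: float = 3.9
    pixel_size_lateral: float = 6.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=float)
        if arr.ndim != 3:
            raise ValidationError(f"volume pixels must be 3-D, got {arr.shape}")
        object.__setattr__(self, "pixels", arr)

    @property
    def n_slices(self) -> int:
        return self.pixels.shape[0]

    def bscan(self, i: int) -> BScan:
        return BScan(self.pixels[i], self.pixel_size_axial, self.pixel_size_lateral)
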