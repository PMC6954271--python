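"""Structured-illumination optical sectioning and image-correction utilities.

In incoherent structured-illumination microscopy (SIM) a sinusoidal
pattern is projected onto the specimen and three frames are captured with
the pattern phase-shifted by one-third of its period.  In-focus signal is
modulated by the pattern while out-of-focus background is not, so the
square-law demodulation

    I_SIM = sqrt((x1 - x2)^2 + (x1 - x3)^2 + (x2 - x3)^2)

rejects any unmodulated (uniform or defocused) component exactly and
recovers the optically sectioned image.  For a sinusoidal modulation of
amplitude M the output is sqrt(9/2)*M regardless of the local pattern
phase and of any additive background.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrameTriplet",
    "SectionedFrame",
    "FlatFieldReference",
    "square_law_reconstruct",
    "flat_field_correct",
    "rescale_to_16bit",
    "optical_calibration",
]

DEFAULT_PIXEL_SIZE_UM = 0.645
DEFAULT_PHASE_STEP = 1.0 / 3.0


@dataclass
class FrameTriplet:
    """Three sequential patterned frames, phase-shifted by 1/3 period each."""

    x1: np.ndarray
    x2: np.ndarray
    x3: np.ndarray
    grid_period_px: float = 12.0
    phase_step: float = DEFAULT_PHASE_STEP

    def __post_init__(self) -> None:
        self.x1 = np.asarray(self.x1, dtype=float)
        self.x2 = np.asarray(self.x2, dtype=float)
        self.x3 = np.asarray(self.x3, dtype=float)
        if not (self.x1.shape == self.x2.shape == self.x3.shape):
            raise ValueError(
                f"triplet shapes differ: {self.x1.shape}, "
                f"{self.x2.shape}, {self.x3.shape}"
            )
        if min(self.x1.min(initial=0), self.x2.min(initial=0), self.x3.min(initial=0)) < 0:
            raise ValueError("frame intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.x1.shape

    @property
    def frames(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (self.x1, self.x2, self.x3)


@dataclass
class SectionedFrame:
    """A square-law reconstructed optical section."""

    image: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.min(initial=0) < 0:
            raise ValueError("sectioned image must be non-negative")


@dataclass
class FlatFieldReference:
    """Illumination reference image, normalized to unit mean.

    Taken of a uniformly fluorescent calibration slide; dividing a frame
    by it removes illumination non-uniformity (vignetting).
    """

    image: np.ndarray = field()

    def __post_init__(self) -> None:
        img = np.asarray(self.image, dtype=float)
        if img.min() <= 0:
            raise ValueError("flat-field reference must be strictly positive")
        self.image = img / img.mean()


def square_law_reconstruct(t: FrameTriplet) -> SectionedFrame:
    """Demodulate a phase-shifted frame triplet into an optical section.

    Pixelwise ``sqrt((x1-x2)^2 + (x1-x3)^2 + (x2-x3)^2)``.  Components
    common to all three frames (background, defocused light) cancel
    exactly; a sinusoidal modulation of amplitude M yields sqrt(9/2)*M
    independent of phase.
    """
    x1, x2, x3 = t.frames
    out = np.sqrt((x1 - x2) ** 2 + (x1 - x3) ** 2 + (x2 - x3) ** 2)
    return SectionedFrame(image=out)


def flat_field_correct(frame: np.ndarray, ref: FlatFieldReference) -> np.ndarray:
    """Divide a frame by the unit-mean illumination reference."""
    frame = np.asarray(frame, dtype=float)
    if frame.shape != ref.image.shape:
        raise ValueError(
            f"frame shape {frame.shape} does not match reference {ref.image.shape}"
        )
    return frame / ref.image


def rescale_to_16bit(image: np.ndarray) -> np.ndarray:
    """Min–max rescale to the full 16-bit range, returned as uint16.

    A constant image carries no usable contrast and maps to all zeros (a
    warning is emitted) so that batch pipelines keep running.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains NaN or Inf")
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        warnings.warn("constant image: rescale_to_16bit returns all zeros")
        return np.zeros(image.shape, dtype=np.uint16)
    scaled = (image - lo) / (hi - lo) * 65535.0
    return np.rint(scaled).astype(np.uint16)


def optical_calibration(
    group: int,
    element: int,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    n_px: int = 2048,
) -> dict[str, float]:
    """Resolve USAF-1951 target frequency and system sampling figures.

    Returns the chart spatial frequency ``2^(group + (element-1)/6)`` in
    line pairs/mm, the corresponding full pitch in µm, the single-frame
    field of view in mm, and the 3-pixel lateral resolution in µm.
    """
    if not -2 <= group <= 9:
        raise ValueError(f"USAF group out of range: {group}")
    if not 1 <= element <= 6:
        raise ValueError(f"USAF element out of range: {element}")
    if pixel_size_um <= 0 or n_px <= 0:
        raise ValueError("pixel_size_um and n_px must be > 0")
    lp_per_mm = 2.0 ** (group + (element - 1) / 6.0)
    return {
        "lp_per_mm": lp_per_mm,
        "pitch_um": 1000.0 / lp_per_mm,
        "fov_mm": n_px * pixel_size_um / 1000.0,
        "lateral_resolution_um": 3.0 * pixel_size_um,
    }
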