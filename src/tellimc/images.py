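"""In-memory containers for IMC images and derived statistics.

A mass cytometer acquisition is a set of co-registered single-channel count
images, one per mass channel.  :class:`ChannelImage` holds one channel tagged
with its element and mass number; :class:`ImageStack` holds the co-registered
set.  :class:`RatioImage`, :class:`TEBResult` and :class:`SNRResult` carry the
outputs of the ratio/bias and signal-to-noise computations.

Counts are stored as float64 even though raw instrument counts are
near-integers: background subtraction and ratio corrections produce
non-integer values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

__all__ = ["ChannelImage", "ImageStack", "RatioImage", "TEBResult", "SNRResult"]


def _as_pixel_grid(pixels, *, allow_negative: bool = False) -> np.ndarray:
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"pixel grid must be 2-D, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("pixel grid contains non-finite values")
    if not allow_negative and np.any(arr < 0):
        raise ValueError("pixel grid contains negative counts")
    return arr


@dataclass(frozen=True)
class ChannelImage:
    """One mass channel: a 2-D grid of counts plus its isotope identity.

    The grid is row-major with the origin at top-left; rows correspond to
    raster lines of the pulsed-laser acquisition (a transient contamination
    spike therefore appears as a full-row streak).

    Parameters
    ----------
    pixels : array-like, shape (H, W)
        Non-negative finite counts (arbitrary IMC units).  Pass
        ``allow_negative=True`` for intermediate unclipped subtraction output.
    element : str
        Element symbol, e.g. ``"Te"``.
    mass : int
        Mass number label (no exact m/z semantics).
    pixel_size_um : float
        Raster pitch in micrometres; the instrument default is 1.0, making
        a blur of sigma = 1 um equal to sigma = 1 pixel.
    """

    pixels: np.ndarray
    element: str
    mass: int
    pixel_size_um: float = 1.0
    allow_negative: bool = False

    def __post_init__(self):
        object.__setattr__(
            self, "pixels",
            _as_pixel_grid(self.pixels, allow_negative=self.allow_negative))
        if int(self.mass) <= 0:
            raise ValueError(f"mass number must be positive, got {self.mass}")
        object.__setattr__(self, "mass", int(self.mass))
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def label(self) -> str:
        """Canonical channel label, mass then element: ``"128Te"``."""
        return f"{self.mass}{self.element}"

    def with_pixels(self, pixels, *, allow_negative: bool = False) -> "ChannelImage":
        """Copy of this channel with new pixel values, same identity."""
        return ChannelImage(pixels, self.element, self.mass,
                            self.pixel_size_um, allow_negative=allow_negative)

    def __repr__(self) -> str:
        return (f"ChannelImage({self.label}, shape={self.shape}, "
                f"pixel_size_um={self.pixel_size_um})")


class ImageStack:
    """An ordered set of co-registered :class:`ChannelImage` objects.

    All member channels share one shape and pixel size, and (element, mass)
    pairs are unique within the stack.  ``provenance`` is free-text metadata
    accumulated by processing steps (ratios used, clipped-pixel counts, ...).
    """

    def __init__(self, channels, provenance: Mapping[str, object] | None = None):
        channels = list(channels)
        if not channels:
            raise ValueError("ImageStack requires at least one channel")
        shape = channels[0].shape
        psize = channels[0].pixel_size_um
        seen: set[tuple[str, int]] = set()
        for ch in channels:
            if ch.shape != shape:
                raise ValueError(
                    f"channel {ch.label} has shape {ch.shape}, expected {shape}")
            if ch.pixel_size_um != psize:
                raise ValueError(
                    f"channel {ch.label} has pixel size {ch.pixel_size_um}, "
                    f"expected {psize}")
            key = (ch.element, ch.mass)
            if key in seen:
                raise ValueError(f"duplicate channel {ch.label} in stack")
            seen.add(key)
        self.channels: list[ChannelImage] = channels
        self.provenance: dict[str, object] = dict(provenance or {})

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels[0].shape

    @property
    def pixel_size_um(self) -> float:
        return self.channels[0].pixel_size_um

    def labels(self) -> list[str]:
        return [ch.label for ch in self.channels]

    def has(self, element: str, mass: int) -> bool:
        return any(ch.element == element and ch.mass == int(mass)
                   for ch in self.channels)

    def get(self, element: str, mass: int) -> ChannelImage:
        for ch in self.channels:
            if ch.element == element and ch.mass == int(mass):
                return ch
        raise KeyError(f"stack has no channel {mass}{element}; "
                       f"present: {', '.join(self.labels())}")

    def masses(self, element: str) -> list[int]:
        return [ch.mass for ch in self.channels if ch.element == element]

    def replace(self, new_channel: ChannelImage) -> "ImageStack":
        """New stack with the matching (element, mass) channel swapped out."""
        out = []
        hit = False
        for ch in self.channels:
            if ch.element == new_channel.element and ch.mass == new_channel.mass:
                out.append(new_channel)
                hit = True
            else:
                out.append(ch)
        if not hit:
            raise KeyError(f"stack has no channel {new_channel.label}")
        return ImageStack(out, self.provenance)

    def __iter__(self) -> Iterator[ChannelImage]:
        return iter(self.channels)

    def __len__(self) -> int:
        return len(self.channels)

    def __repr__(self) -> str:
        return f"ImageStack({', '.join(self.labels())}, shape={self.shape})"


@dataclass(frozen=True)
class RatioImage:
    """Pixelwise ratio of two channels plus its validity mask.

    ``valid`` excludes every pixel where either (blurred) source channel fell
    below ``threshold_used``; ``values`` is NaN there and finite and positive
    wherever ``valid`` is true.
    """

    values: np.ndarray
    valid: np.ndarray
    threshold_used: float
    sigma_used: float

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        valid = np.asarray(self.valid, dtype=bool)
        if values.shape != valid.shape:
            raise ValueError("values and valid mask shapes differ")
        if not np.all(np.isfinite(values[valid])):
            raise ValueError("ratio values must be finite where valid")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "valid", valid)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]


@dataclass(frozen=True)
class TEBResult:
    """Transmission efficiency bias between two isotopes of one element.

    ``teb = median_ratio / theoretical_ratio``; 1 means the instrument detects
    both isotopes with equal efficiency, > 1 means isotope_a is over-detected
    relative to isotope_b.  Dividing the isotope_a channel by ``teb`` is the
    multiplicative correction restoring the natural-abundance expectation.
    """

    isotope_a: int
    isotope_b: int
    median_ratio: float
    theoretical_ratio: float
    teb: float
    n_valid: int
    element: str = "Te"

    def __post_init__(self):
        if self.median_ratio <= 0 or self.theoretical_ratio <= 0:
            raise ValueError("ratios must be positive")
        if self.n_valid < 0:
            raise ValueError("n_valid must be non-negative")
        expected = self.median_ratio / self.theoretical_ratio
        if not np.isclose(self.teb, expected, rtol=1e-9):
            raise ValueError(
                f"inconsistent TEB: {self.teb} != median/theoretical "
                f"{expected}")

    def to_dict(self) -> dict:
        return {
            "element": self.element,
            "isotope_a": self.isotope_a,
            "isotope_b": self.isotope_b,
            "median_ratio": self.median_ratio,
            "theoretical_ratio": self.theoretical_ratio,
            "teb": self.teb,
            "n_valid": self.n_valid,
        }


@dataclass(frozen=True)
class SNRResult:
    """Signal-to-noise ratio: mean of a signal region over the standard
    deviation (population, ddof=0) of a disjoint noise region."""

    snr: float
    signal_mean: float
    noise_std: float
    signal_mask: np.ndarray = field(repr=False)
    noise_mask: np.ndarray = field(repr=False)

    def __post_init__(self):
        if self.noise_std > 0 and not np.isclose(
                self.snr, self.signal_mean / self.noise_std, rtol=1e-9):
            raise ValueError("inconsistent SNR fields")

    def to_dict(self) -> dict:
        return {"snr": self.snr, "signal_mean": self.signal_mean,
                "noise_std": self.noise_std}
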