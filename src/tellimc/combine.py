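"""Multi-isotope channel combination for signal-to-noise improvement.

Natural-abundance tellurium spreads one probe's signal across six isotopes
with abundance above 1%.  Their channels can be fused into a single image:

* **arithmetic** — pixelwise sum.  Minimally manipulative, but IMC noise is
  non-negative (counts), so background accrues instead of cancelling.
* **geometric** — pixelwise nth root of the product of n channels.  A zero in
  any channel zeroes the output pixel, which suppresses the sparse positive
  background far more effectively; including a very low-signal isotope,
  however, skews the output towards zero.  The default isotope set is
  {126, 128, 130}, the highest-abundance isotopes.

Optionally the selected channels are stacked into a 3-D array (channel axis
first) and blurred with an isotropic 3-D Gaussian before collapsing; the
cross-channel smoothing removes single-channel outliers at some cost in
spatial resolution.

Fused images are scored with SNR = mean(signal region) / std(noise region),
the regions being user-defined masks (typically tissue vs bare slide).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import ndimage

from .images import ChannelImage, ImageStack, SNRResult

__all__ = ["arithmetic_combine", "geometric_combine", "blur_stack_3d",
           "combine", "snr", "DEFAULT_COMBINE_MASSES"]

#: Highest-abundance natural Te isotopes; safe to combine geometrically
#: without skewing the output to zero.
DEFAULT_COMBINE_MASSES = (126, 128, 130)


def _select(stack: ImageStack, masses: Sequence[int],
            element: str) -> list[ChannelImage]:
    if not masses:
        raise ValueError("no masses selected")
    return [stack.get(element, m) for m in masses]


def _fused_label(masses: Sequence[int]) -> int:
    # The fused image keeps the element tag but has no single physical mass;
    # use the smallest selected mass as a stable, unambiguous label.
    return min(int(m) for m in masses)


def arithmetic_combine(stack: ImageStack, masses: Sequence[int],
                       element: str = "Te") -> ChannelImage:
    """Pixelwise sum of the selected channels."""
    chans = _select(stack, masses, element)
    total = np.sum([c.pixels for c in chans], axis=0)
    return ChannelImage(total, element, _fused_label(masses),
                        chans[0].pixel_size_um)


def geometric_combine(stack: ImageStack, masses: Sequence[int],
                      element: str = "Te") -> ChannelImage:
    """Pixelwise geometric mean of the selected channels.

    Computed in log domain for numerical stability on all-positive pixels;
    any zero input short-circuits the pixel to exactly 0 (the property that
    makes geometric fusion suppress non-negative background noise).
    Negative inputs are rejected — clip during xenon correction upstream.
    """
    chans = _select(stack, masses, element)
    grids = np.stack([c.pixels for c in chans])
    if np.any(grids < 0):
        raise ValueError("geometric combination requires non-negative counts; "
                         "apply xenon correction with clipping first")
    positive = np.all(grids > 0, axis=0)
    out = np.zeros(grids.shape[1:])
    if positive.any():
        logs = np.log(grids[:, positive])
        out[positive] = np.exp(logs.mean(axis=0))
    return ChannelImage(out, element, _fused_label(masses),
                        chans[0].pixel_size_um)


def blur_stack_3d(stack: ImageStack, masses: Sequence[int], sigma: float = 1.0,
                  element: str = "Te") -> ImageStack:
    """Isotropic 3-D Gaussian blur of the selected channels.

    The channels are stacked along a third (channel) axis in the order given
    in ``masses`` and blurred with the same sigma (pixels) on all three
    axes, reflective boundaries everywhere including the channel axis.  The
    channel-axis order matters: adjacent channels smooth into each other, so
    the conventional order is ascending mass (adjacent masses have
    correlated signal).  With only 3-4 channels the boundary rule materially
    affects the end channels; reflection is this package's recorded choice.
    """
    chans = _select(stack, masses, element)
    if len(chans) < 2:
        raise ValueError("3-D blur needs at least 2 channels for the "
                         "channel axis to be meaningful")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    cube = np.stack([c.pixels for c in chans])
    if sigma > 0:
        cube = ndimage.gaussian_filter(cube, sigma=sigma, mode="reflect")
    blurred = [c.with_pixels(cube[i]) for i, c in enumerate(chans)]
    provenance = dict(stack.provenance)
    provenance["blur_3d"] = {"sigma": float(sigma),
                             "masses": [int(m) for m in masses]}
    return ImageStack(blurred, provenance)


def combine(stack: ImageStack, masses: Sequence[int] = DEFAULT_COMBINE_MASSES,
            mode: str = "geometric", blur_sigma: float = 0.0,
            element: str = "Te") -> ChannelImage:
    """Fuse the selected channels: optional 3-D blur, then collapse.

    ``mode`` is ``"arithmetic"`` (pixelwise sum) or ``"geometric"``
    (pixelwise geometric mean).  With ``blur_sigma > 0`` the channels are
    first blurred jointly in 3-D (see :func:`blur_stack_3d`).  Which
    isotopes to include is an empirical choice per experiment; the default
    {126, 128, 130} avoids skewing the geometric mean towards zero.
    """
    if mode not in ("arithmetic", "geometric"):
        raise ValueError(f"unknown mode {mode!r}; use 'arithmetic' or "
                         "'geometric'")
    source = stack
    if blur_sigma > 0:
        source = blur_stack_3d(stack, masses, sigma=blur_sigma, element=element)
    fn = arithmetic_combine if mode == "arithmetic" else geometric_combine
    return fn(source, masses, element=element)


def snr(image: ChannelImage, signal_mask: np.ndarray,
        noise_mask: np.ndarray) -> SNRResult:
    """Signal-to-noise ratio of an image over two user-defined regions.

    SNR = mean(signal pixels) / population standard deviation (ddof = 0) of
    the noise pixels.  The masks must be disjoint, each covering at least
    two pixels — typically tissue vs bare slide, chosen from knowledge of
    the sample.  A constant noise region is an error, not an infinite SNR.
    """
    s_mask = np.asarray(signal_mask, dtype=bool)
    n_mask = np.asarray(noise_mask, dtype=bool)
    if s_mask.shape != image.shape or n_mask.shape != image.shape:
        raise ValueError("mask shapes must match the image")
    if np.any(s_mask & n_mask):
        raise ValueError("signal and noise masks overlap")
    if s_mask.sum() < 2 or n_mask.sum() < 2:
        raise ValueError("each mask needs at least 2 pixels")
    signal_mean = float(image.pixels[s_mask].mean())
    noise_std = float(image.pixels[n_mask].std(ddof=0))
    if noise_std == 0.0:
        raise ValueError("degenerate noise region: zero standard deviation")
    return SNRResult(snr=signal_mean / noise_std, signal_mean=signal_mean,
                     noise_std=noise_std, signal_mask=s_mask, noise_mask=n_mask)
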