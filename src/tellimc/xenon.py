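"""Xenon background removal from tellurium mass channels.

Argon carrier gas can be contaminated with xenon, whose isotopes at masses
124, 126, 128 and 130 are isobars of tellurium and add background — including
full raster-row streaks when a transient xenon spike is drawn into the plasma.
The 134 mass channel contains xenon but no tellurium, so it measures the
xenon level per pixel.  Scaling it by the known natural-abundance ratio of
the contaminating xenon isotope to 134-xenon gives the xenon component of a
tellurium channel, which is then subtracted:

    observed(mass m)  =  Te component + Xe component
    Xe component      =  X134 * abundance(mXe) / abundance(134Xe)
    Te estimate       =  observed - Xe component

No blank-sample acquisition is needed; optionally the abundance ratio can be
replaced by an empirical spillover ratio measured in a tissue-free region of
the same image.
"""

from __future__ import annotations

import logging

import numpy as np

from .images import ChannelImage, ImageStack
from .isotopes import (IsotopeAbundanceTable, default_table,
                       XE_ISOBARS_OF_TE)

__all__ = [
    "estimate_xenon_component", "subtract_xenon",
    "empirical_spillover_ratio", "dexenon_stack",
    "NoXenonIsobarError",
]

logger = logging.getLogger("tellimc.xenon")

#: Fixed xenon reference mass: the 134 channel contains no tellurium.
XENON_REFERENCE_MASS = 134


class NoXenonIsobarError(ValueError):
    """The requested mass channel has no stable xenon isobar (e.g. 125)."""

    def __init__(self, mass: int):
        super().__init__(f"no xenon isobar at mass {mass}; xenon correction "
                         "is undefined for this channel")
        self.mass = mass


def _xe_ratio(target_mass: int, table: IsotopeAbundanceTable) -> float:
    if ("Xe", target_mass) not in table or \
            table.abundance("Xe", target_mass) == 0.0:
        raise NoXenonIsobarError(target_mass)
    return table.theoretical_ratio("Xe", target_mass, XENON_REFERENCE_MASS)


def estimate_xenon_component(xenon_ref: ChannelImage, target_mass: int,
                             ratio_override: float | None = None,
                             table: IsotopeAbundanceTable | None = None
                             ) -> ChannelImage:
    """Estimate the xenon image contaminating ``target_mass`` from the 134
    reference channel.

    The reference is scaled by ``abundance(mXe)/abundance(134Xe)`` — or by
    ``ratio_override`` if given (e.g. an empirically measured spillover
    ratio).  The result is labelled as the xenon isotope at ``target_mass``.
    """
    table = table or default_table()
    if xenon_ref.element != "Xe" or xenon_ref.mass != XENON_REFERENCE_MASS:
        raise ValueError(f"xenon reference must be the {XENON_REFERENCE_MASS}Xe "
                         f"channel, got {xenon_ref.label}")
    if ratio_override is not None:
        if not ratio_override > 0:
            raise ValueError("ratio_override must be positive")
        _xe_ratio(int(target_mass), table)  # still reject non-isobar masses
        r = float(ratio_override)
    else:
        r = _xe_ratio(int(target_mass), table)
    return ChannelImage(xenon_ref.pixels * r, "Xe", int(target_mass),
                        xenon_ref.pixel_size_um)


def subtract_xenon(observed: ChannelImage, xenon_ref: ChannelImage,
                   clip: bool = True, ratio_override: float | None = None,
                   table: IsotopeAbundanceTable | None = None) -> ChannelImage:
    """Subtract the estimated xenon component from an observed channel.

    Returns the tellurium estimate, element "Te" at the observed mass.  With
    ``clip`` (default), negative post-subtraction pixels are set to 0 —
    required by downstream geometric combination and ratio images; pass
    ``clip=False`` for unbiased statistics.  The ratio used and the number of
    clipped pixels are available via the returned stack provenance when
    applied through :func:`dexenon_stack`.
    """
    if observed.shape != xenon_ref.shape:
        raise ValueError(f"shape mismatch: observed {observed.shape} vs "
                         f"xenon reference {xenon_ref.shape}")
    component = estimate_xenon_component(xenon_ref, observed.mass,
                                         ratio_override, table)
    corrected = observed.pixels - component.pixels
    if clip:
        corrected = np.maximum(corrected, 0.0)
    return ChannelImage(corrected, "Te", observed.mass,
                        observed.pixel_size_um, allow_negative=not clip)


def empirical_spillover_ratio(observed: ChannelImage,
                              xenon_ref: ChannelImage,
                              background_mask: np.ndarray,
                              threshold: float = 1.0,
                              min_pixels: int = 100) -> float:
    """Measure the actual spillover ratio of a xenon isobar channel to the
    134 reference in a tissue-free image region.

    Over masked pixels where both channels are at or above ``threshold``
    counts, returns the median of the pixelwise ratio observed/reference.
    The median (rather than a mean or a sum ratio) is robust to the
    heavy-tailed per-pixel ratios that raster streaks produce.  In a region
    with no tissue there is no tellurium, so this ratio estimates the pure
    xenon isotope ratio and may replace the theoretical abundance ratio.
    """
    mask = np.asarray(background_mask, dtype=bool)
    if mask.shape != observed.shape or observed.shape != xenon_ref.shape:
        raise ValueError("mask and channel shapes must all match")
    valid = mask & (observed.pixels >= threshold) & (xenon_ref.pixels >= threshold)
    n = int(valid.sum())
    if n < min_pixels:
        raise ValueError(
            f"only {n} valid background pixels (need >= {min_pixels}); "
            "enlarge the mask or lower the threshold")
    return float(np.median(observed.pixels[valid] / xenon_ref.pixels[valid]))


def dexenon_stack(stack: ImageStack, clip: bool = True,
                  empirical_mask: np.ndarray | None = None,
                  ratio_overrides: dict[int, float] | None = None,
                  table: IsotopeAbundanceTable | None = None) -> ImageStack:
    """Remove xenon background from every Te channel of a stack that has a
    xenon isobar (124, 126, 128, 130); other Te channels pass through.

    Requires a 134Xe channel, which is retained in the output.  If
    ``empirical_mask`` is given, the spillover ratio of each corrected
    channel is measured in that tissue-free region instead of taken from the
    abundance table (falling back to the table where too few background
    pixels qualify).  Explicit ``ratio_overrides`` (mass -> ratio) win over
    both.  Per-channel ratios and clipped-pixel counts are recorded in the
    output provenance.
    """
    table = table or default_table()
    if not stack.has("Xe", XENON_REFERENCE_MASS):
        raise ValueError(f"stack has no {XENON_REFERENCE_MASS}Xe channel; "
                         "cannot estimate xenon background")
    ref = stack.get("Xe", XENON_REFERENCE_MASS)
    overrides = dict(ratio_overrides or {})

    out_channels = []
    ratios_used: dict[str, float] = {}
    clipped: dict[str, int] = {}
    for ch in stack:
        if ch.element != "Te" or ch.mass not in XE_ISOBARS_OF_TE:
            out_channels.append(ch)
            continue
        ratio = overrides.get(ch.mass)
        if ratio is None and empirical_mask is not None:
            try:
                ratio = empirical_spillover_ratio(ch, ref, empirical_mask)
            except ValueError as exc:
                logger.warning("empirical ratio for %s unavailable (%s); "
                               "using abundance table", ch.label, exc)
        corrected = subtract_xenon(ch, ref, clip=clip, ratio_override=ratio,
                                   table=table)
        used = ratio if ratio is not None else \
            table.theoretical_ratio("Xe", ch.mass, XENON_REFERENCE_MASS)
        ratios_used[ch.label] = float(used)
        if clip:
            raw = ch.pixels - ref.pixels * used
            clipped[ch.label] = int(np.count_nonzero(raw < 0))
        logger.info("dexenon %s: ratio %.6f", ch.label, used)
        out_channels.append(corrected)

    provenance = dict(stack.provenance)
    provenance["dexenon"] = {"ratios": ratios_used, "clip": clip,
                             "clipped_pixels": clipped,
                             "abundance_source": table.source}
    return ImageStack(out_channels, provenance)
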