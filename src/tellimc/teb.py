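"""Transmission efficiency bias (TEB): quantification and correction.

A mass cytometer is not equally sensitive to ions of different mass — lighter
tellurium ions are ejected from the ion beam more readily and sit further
from the quadrupole's transmission optimum, so heavier isotopes are
over-detected.  Single-isotope experiments are unaffected, but sequential
labelling with isotopologous probes (SLIP) compares two mass channels
directly and needs this bias corrected.

In a natural-abundance acquisition, the pixelwise ratio of two tellurium
channels A (mass a) and B (mass b) should equal the abundance ratio
``abundance(aTe)/abundance(bTe)`` in every pixel if detection is unbiased.
The TEB is the deviation from that expectation:

    R_ij = A_ij / B_ij          (pixelwise, on blurred, thresholded images)
    TEB  = median(R) / (abundance(aTe) / abundance(bTe))

TEB = 1 means no bias; TEB > 1 means isotope a is over-detected relative to
isotope b, and dividing channel A by the TEB is the multiplicative
correction that restores the natural-abundance expectation.  A ratio-based
estimate is used rather than a regression so that neither isotope is
designated the dependent variable; the median resists the heavy-tailed
ratios that low-count pixels produce.  Xenon background must be removed
before computing a TEB (the contamination is mass-dependent and shifts the
ratio).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .images import ChannelImage, RatioImage, TEBResult
from .isotopes import IsotopeAbundanceTable, default_table

__all__ = ["ratio_image", "compute_teb", "apply_teb",
           "slip_difference", "fraction_sign_changed"]


def _blur(pixels: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return pixels
    return ndimage.gaussian_filter(pixels, sigma=sigma, mode="reflect")


def ratio_image(a_img: ChannelImage, b_img: ChannelImage,
                threshold: float = 1.0, sigma: float = 1.0) -> RatioImage:
    """Pixelwise ratio A/B of two channels, blurred and thresholded.

    Both inputs are Gaussian-blurred (sigma in pixels; at the instrument's
    1 um raster pitch, sigma = 1 um) *before* division — a moderate blur
    removes outlier pixels from the ratio.  Pixels where either blurred
    input falls below ``threshold`` counts are excluded from the validity
    mask: zeros must be excluded to avoid division by zero, and non-zero but
    low counts create unreasonably extreme ratios.  One count per pixel is a
    robust default threshold.
    """
    if a_img.shape != b_img.shape:
        raise ValueError(f"shape mismatch: {a_img.shape} vs {b_img.shape}")
    if not threshold > 0:
        raise ValueError("threshold must be positive (it is the "
                         "division-by-zero guard)")
    a = _blur(a_img.pixels, sigma)
    b = _blur(b_img.pixels, sigma)
    valid = (a >= threshold) & (b >= threshold)
    values = np.full(a.shape, np.nan)
    np.divide(a, b, out=values, where=valid)
    return RatioImage(values, valid, float(threshold), float(sigma))


def compute_teb(a_img: ChannelImage, b_img: ChannelImage,
                threshold: float = 1.0, sigma: float = 1.0,
                table: IsotopeAbundanceTable | None = None) -> TEBResult:
    """Estimate the transmission efficiency bias between two isotopes of one
    element from a natural-abundance acquisition.

    Both channels must be natural-abundance images of the same element and
    already xenon-corrected.  Returns the median of the valid ratio-image
    pixels divided by the theoretical abundance ratio (midpoint convention
    for even-count medians, per numpy).
    """
    if a_img.element != b_img.element:
        raise ValueError(f"TEB compares isotopes of one element; got "
                         f"{a_img.label} vs {b_img.label}")
    table = table or default_table()
    theoretical = table.theoretical_ratio(a_img.element, a_img.mass, b_img.mass)
    r = ratio_image(a_img, b_img, threshold=threshold, sigma=sigma)
    if r.n_valid == 0:
        raise ValueError("no valid pixels above threshold; cannot compute TEB")
    median = float(np.median(r.valid_values()))
    return TEBResult(isotope_a=a_img.mass, isotope_b=b_img.mass,
                     median_ratio=median, theoretical_ratio=theoretical,
                     teb=median / theoretical, n_valid=r.n_valid,
                     element=a_img.element)


def apply_teb(a_img: ChannelImage, teb: float | TEBResult) -> ChannelImage:
    """Correct the over-detected channel by dividing it by the TEB.

    Division by the TEB is the unique multiplicative correction under which
    the corrected pair satisfies the natural-abundance ratio expectation.
    ``teb`` may be a bare factor or a :class:`TEBResult` (whose isotope_a
    must then match the channel's mass).
    """
    factor = _teb_factor(teb)
    if isinstance(teb, TEBResult) and teb.isotope_a != a_img.mass:
        raise ValueError(f"TEB was computed for isotope {teb.isotope_a}, "
                         f"not {a_img.mass}")
    return a_img.with_pixels(a_img.pixels / factor)


def _teb_factor(teb: float | TEBResult) -> float:
    factor = teb.teb if isinstance(teb, TEBResult) else float(teb)
    if not factor > 0:
        raise ValueError(f"TEB must be positive, got {factor}")
    return factor


def _check_slip_pair(early: ChannelImage, late: ChannelImage,
                     teb: float | TEBResult | None) -> float:
    if early.shape != late.shape:
        raise ValueError(f"shape mismatch: {early.shape} vs {late.shape}")
    if teb is None:
        return 1.0
    if isinstance(teb, TEBResult):
        if (teb.isotope_a, teb.isotope_b) != (late.mass, early.mass):
            raise ValueError(
                f"TEB pair ({teb.isotope_a}, {teb.isotope_b}) does not match "
                f"late/early channels ({late.mass}, {early.mass})")
    return _teb_factor(teb)


def slip_difference(early: ChannelImage, late: ChannelImage,
                    teb: float | TEBResult | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Difference image of a two-timepoint SLIP experiment.

    The two channels are isotopologue images of the same probe dosed at two
    timepoints; both must already be xenon-corrected.  If ``teb`` is given
    the late channel is divided by it first (a :class:`TEBResult` is
    validated against the channel masses: it must have been computed with
    the late isotope as isotope_a and the early isotope as isotope_b).

    Returns ``(difference, classes)`` where difference = corrected_late -
    early and classes is +1 where the signal increased between timepoints
    (rendered red in difference images — e.g. increasing hypoxia), -1 where
    it decreased (green), and 0 where unchanged.
    """
    factor = _check_slip_pair(early, late, teb)
    diff = late.pixels / factor - early.pixels
    classes = np.sign(diff).astype(np.int8)
    return diff, classes


def fraction_sign_changed(early: ChannelImage, late: ChannelImage,
                          teb: float | TEBResult) -> float:
    """Fraction of informative pixels whose difference-image class flips
    when TEB correction is applied.

    Compares the +1/-1/0 classification with teb = 1 against the supplied
    TEB, over pixels whose class is nonzero in at least one of the two
    classifications.  This quantifies how much of a SLIP difference image's
    interpretation the correction changes.
    """
    _, before = slip_difference(early, late, None)
    _, after = slip_difference(early, late, teb)
    informative = (before != 0) | (after != 0)
    n = int(informative.sum())
    if n == 0:
        return 0.0
    return float(np.count_nonzero(before[informative] != after[informative]) / n)
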