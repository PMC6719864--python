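"""Synthetic IMC phantoms with known ground truth.

Real tellurium IMC acquisitions are expensive (about 90 minutes per square
millimetre), so every correction in this package is validated against
phantoms whose true tellurium signal, xenon contamination and detection bias
are known by construction:

* a smooth tissue blob (thresholded smoothed noise) covers a chosen area
  fraction of the image;
* each tellurium isotope channel draws Poisson counts at a rate
  ``tissue_mask * mean_tissue_intensity * abundance(Te, i) * bias(i)`` —
  IMC noise is count noise: non-negative, not distributed around zero;
* a 134-xenon channel draws Poisson counts at a uniform baseline rate,
  multiplied on a few randomly chosen full raster rows by a streak
  amplitude (a transient xenon spike during the line-by-line acquisition
  contaminates a whole row);
* the observed channel at each tellurium mass with a xenon isobar
  (124, 126, 128, 130) is the sum of the tellurium counts and an
  independent xenon count drawn at the 134 rate scaled by the natural
  abundance ratio — so the background's expected isotope ratios match the
  abundance table exactly, by construction.

The phantom is a statistical fixture, not a biology simulator: no cell-scale
morphology, no antibody channels, no probe pharmacokinetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .images import ChannelImage, ImageStack
from .isotopes import (IsotopeAbundanceTable, default_table,
                       TE_STABLE_MASSES, XE_ISOBARS_OF_TE)
from .xenon import XENON_REFERENCE_MASS

__all__ = ["PhantomSpec", "PhantomTruth", "generate_phantom",
           "standard_phantom", "inject_teb"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic acquisition.

    ``mean_tissue_intensity`` is the expected *total* tellurium count per
    tissue pixel, split across isotopes by natural abundance.  ``bias`` maps
    mass number to a multiplicative detection factor folded into the Poisson
    rate of that isotope's tellurium component (1.0 = unbiased detection).
    ``xenon_baseline`` is the expected 134-xenon count per pixel;
    ``streak_rows`` full raster rows get that rate multiplied by
    ``streak_amplitude``.
    """

    height: int = 256
    width: int = 256
    tissue_fraction: float = 0.4
    mean_tissue_intensity: float = 50.0
    isotopes: tuple[int, ...] = (122, 124, 125, 126, 128, 130)
    bias: Mapping[int, float] = field(default_factory=dict)
    xenon_baseline: float = 2.0
    streak_rows: int = 5
    streak_amplitude: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if self.height <= 0 or self.width <= 0:
            raise ValueError("phantom dimensions must be positive")
        if not 0.0 <= self.tissue_fraction <= 1.0:
            raise ValueError("tissue_fraction must lie in [0, 1]")
        for name in ("mean_tissue_intensity", "xenon_baseline",
                     "streak_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.isotopes:
            raise ValueError("at least one tellurium isotope is required")
        bad = set(self.isotopes) - set(TE_STABLE_MASSES)
        if bad:
            raise ValueError(f"not stable Te isotopes: {sorted(bad)}")
        for m, f in self.bias.items():
            if f <= 0:
                raise ValueError(f"bias factor for mass {m} must be positive")
        object.__setattr__(self, "isotopes",
                           tuple(sorted(int(m) for m in self.isotopes)))
        object.__setattr__(self, "bias",
                           {int(m): float(f) for m, f in self.bias.items()})


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth of a generated phantom.

    ``true_te`` and ``true_xe`` map mass number to the *noiseless
    expectation* grid of the tellurium and xenon components (the xenon map
    includes the 134 reference).  ``bias`` records the injected detection
    factors.
    """

    tissue_mask: np.ndarray
    true_te: dict[int, np.ndarray]
    true_xe: dict[int, np.ndarray]
    bias: dict[int, float]


def _tissue_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth blob covering ~tissue_fraction of the image.

    Thresholded smoothed noise: the exact geometry is not a contract, only
    the area fraction (matched exactly via the empirical quantile).
    """
    if spec.tissue_fraction == 0.0:
        return np.zeros((spec.height, spec.width), dtype=bool)
    if spec.tissue_fraction == 1.0:
        return np.ones((spec.height, spec.width), dtype=bool)
    noise = rng.standard_normal((spec.height, spec.width))
    sigma = max(min(spec.height, spec.width) / 16.0, 1.0)
    smooth = ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")
    cut = np.quantile(smooth, 1.0 - spec.tissue_fraction)
    return smooth > cut


def generate_phantom(spec: PhantomSpec,
                     table: IsotopeAbundanceTable | None = None
                     ) -> tuple[ImageStack, PhantomTruth]:
    """Generate a phantom acquisition and its ground truth.

    Identical specs (including seed) produce bit-identical output.  The
    returned stack holds one observed channel per requested Te isotope plus
    the 134-xenon reference channel.
    """
    table = table or default_table()
    rng = np.random.default_rng(spec.seed)
    mask = _tissue_mask(spec, rng)

    # 134Xe rate map: uniform baseline with whole-row streaks.
    xe134_rate = np.full((spec.height, spec.width), float(spec.xenon_baseline))
    if spec.streak_rows > 0 and spec.xenon_baseline > 0:
        rows = rng.choice(spec.height, size=min(spec.streak_rows, spec.height),
                          replace=False)
        xe134_rate[rows, :] *= spec.streak_amplitude
    else:
        rows = np.array([], dtype=int)

    true_te: dict[int, np.ndarray] = {}
    true_xe: dict[int, np.ndarray] = {XENON_REFERENCE_MASS: xe134_rate}
    channels: list[ChannelImage] = []
    for m in spec.isotopes:
        factor = spec.bias.get(m, 1.0)
        te_rate = mask * (spec.mean_tissue_intensity
                          * table.abundance("Te", m) * factor)
        true_te[m] = te_rate
        counts = rng.poisson(te_rate).astype(np.float64)
        if m in XE_ISOBARS_OF_TE:
            xe_rate = xe134_rate * table.theoretical_ratio(
                "Xe", m, XENON_REFERENCE_MASS)
            true_xe[m] = xe_rate
            counts = counts + rng.poisson(xe_rate)
        channels.append(ChannelImage(counts, "Te", m))
    channels.append(ChannelImage(
        rng.poisson(xe134_rate).astype(np.float64), "Xe",
        XENON_REFERENCE_MASS))

    stack = ImageStack(channels, {
        "source": "tellimc.phantom", "seed": spec.seed,
        "streak_rows": sorted(int(r) for r in rows),
        "tissue_fraction": spec.tissue_fraction,
    })
    truth = PhantomTruth(tissue_mask=mask, true_te=true_te, true_xe=true_xe,
                         bias={m: spec.bias.get(m, 1.0) for m in spec.isotopes})
    return stack, truth


#: The fixture used throughout the test suite.
STANDARD_SPEC = PhantomSpec()


def standard_phantom() -> tuple[ImageStack, PhantomTruth]:
    """The fixed reference phantom: 256 x 256, 40% tissue at 50 expected
    counts per pixel over isotopes {122, 124, 125, 126, 128, 130}, no
    detection bias, xenon baseline 2 with 5 streak rows at 20x, seed 0."""
    return generate_phantom(STANDARD_SPEC)


def inject_teb(stack: ImageStack, bias: Mapping[int, float],
               element: str = "Te") -> ImageStack:
    """Multiply named channels by per-mass detection factors.

    Post-hoc on counts (no re-Poissonization): simulates a detector whose
    sensitivity differs between isotopes, on top of an already generated
    acquisition.  For bias folded into the Poisson rates instead, set
    :attr:`PhantomSpec.bias` before generation.
    """
    channels = []
    remaining = {int(m): float(f) for m, f in bias.items()}
    for f in remaining.values():
        if not f > 0:
            raise ValueError("bias factors must be positive")
    for ch in stack:
        if ch.element == element and ch.mass in remaining:
            channels.append(ch.with_pixels(ch.pixels * remaining.pop(ch.mass)))
        else:
            channels.append(ch)
    if remaining:
        raise KeyError(f"stack has no {element} channel(s) at masses "
                       f"{sorted(remaining)}")
    provenance = dict(stack.provenance)
    provenance["injected_teb"] = {int(m): float(f) for m, f in bias.items()}
    return ImageStack(channels, provenance)
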