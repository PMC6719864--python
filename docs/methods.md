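# Methods

This note records the models behind `tellimc`, the parameter choices that
matter, what the synthetic phantom does and does not emulate, and the
numerical conventions a user relying on the outputs should know.

## Physical setting and assumptions

An IMC acquisition rasters a pulsed UV laser over a tissue section,
pixel by pixel; ablated material enters an inductively coupled plasma mass
spectrometer and each unit mass channel is quantified per pixel. The
package assumes:

- **Unit mass resolution.** Isobars (¹²⁸Te vs ¹²⁸Xe) are indistinguishable;
  mass numbers are labels, not m/z values.
- **Count statistics.** Pixel values are non-negative instrument counts;
  shot noise is Poisson-like, so noise is not centred on zero and cannot
  cancel by summation.
- **Row-structured transients.** The acquisition is line-by-line, so a
  transient change in the carrier gas (a xenon spike) maps to a full image
  row.
- **Natural abundance is known and fixed.** The bundled table is the
  NIST/CIAAW standard isotopic composition (source and retrieval date in
  `src/tellimc/data/isotope_abundances.json`); any standard compilation
  reproduces the ¹²⁸Xe/¹³⁴Xe ratio 0.183 to three decimals, but
  fourth-decimal agreement between compilations is not guaranteed. A
  same-layout JSON can replace the table for sensitivity analysis.

## Xenon background removal

The 134 channel contains xenon but no tellurium, so it measures the xenon
level per pixel. The xenon component of a channel at mass *m* ∈ {124, 126,
128, 130} is the 134 image scaled by abundance(ᵐXe)/abundance(¹³⁴Xe), and
is subtracted pixelwise. ¹²⁵Te receives no correction (no stable xenon
isobar); ¹³⁴Xe is the fixed reference (¹³⁶Xe is deliberately not offered,
to keep provenance simple).

- **Clipping.** Subtraction of a noisy estimate makes some pixels negative.
  Default is clip-at-zero, because ratio images and geometric fusion
  require non-negative counts; `clip=False` preserves unbiasedness for
  statistics (the per-pixel expectation of the unclipped corrected
  background is zero). The clipped-pixel count per channel is recorded in
  stack provenance.
- **Empirical spillover ratio.** Instead of the table ratio, the ratio can
  be measured as the **median** of observed/reference over a user-supplied
  tissue-free mask (both channels ≥ 1 count, ≥ 100 qualifying pixels). The
  median is used because streak rows make per-pixel ratios heavy-tailed.
- The correction is purely per-pixel; no temporal model of xenon spikes is
  attempted (their physical source is not established).

## Transmission efficiency bias

Lighter ions are lost from the ion beam more readily and sit further from
the quadrupole's transmission optimum near m/z ≈ 160, so heavier tellurium
isotopes are over-detected. For channels **A** (mass a) and **B** (mass b)
of a natural-abundance acquisition:

1. blur both images with a 2-D Gaussian, σ = 1 pixel (= 1 µm at the
   instrument's raster pitch), reflective boundaries;
2. mask out pixels where either blurred image is below 1 count;
3. form R = A/B on the remaining pixels;
4. TEB = median(R) / (abundance(ᵃTe)/abundance(ᵇTe)).

TEB = 1 means unbiased detection; dividing **A** by the TEB is the unique
multiplicative correction after which the pair satisfies the
natural-abundance expectation. Parameters:

- **threshold (counts, default 1).** Excluding zeros is mandatory (division
  by zero); excluding sub-1-count pixels avoids the extreme ratios low
  denominators produce. The threshold applies to the *blurred* images,
  after xenon correction.
- **σ (pixels, default 1).** A moderate blur suppresses outlier pixels.
  This package blurs the two *input* images before division; blurring the
  ratio image instead would average ratios, a statistically different
  estimator. Which of the two a practitioner intends is genuinely open;
  inputs-first is this package's recorded choice.
- **Median convention.** numpy's midpoint convention for even counts. A
  useful consequence: median(B/A) = 1/median(A/B) for strictly positive
  data, so TEB(a,b)·TEB(b,a) = 1 up to the even-count midpoint effect.
- **Ordering.** Xenon removal must precede TEB estimation: the
  contamination is mass-dependent and shifts the ratio (verified as an
  inequality on the streaked phantom in the test suite).
- TEB is a scalar per isotope pair per acquisition — it is an instrument
  property that drifts over time, so users should re-estimate it near the
  experiment being corrected; no drift model is included.

For SLIP difference imaging, the late-timepoint channel is divided by the
TEB (computed with the late isotope as numerator), then D = late − early is
classified per pixel into +1 (increase, rendered red), −1 (decrease,
green), 0. `fraction_sign_changed` reports the share of informative pixels
(nonzero class before or after correction) whose class flips — the extent
to which the correction changes interpretation.

## Channel combination and SNR

Selected channels are optionally stacked (channel axis first, ascending
mass by default: adjacent masses have correlated signal) and blurred with
an isotropic 3-D Gaussian, σ = 1 pixel on all axes, **reflective boundaries
including the channel axis** — with only 3–4 channels the boundary rule
materially affects the end channels, so it is an explicit, recorded choice.
Collapse is arithmetic (sum) or geometric (nth root of the product,
computed in log domain with an exact-zero short-circuit so that a zero in
any channel yields exactly zero). SNR = mean over a signal mask / standard
deviation over a disjoint noise mask, with the **population** (ddof = 0)
standard deviation — the definition leaves the choice open; population is
recorded here. A constant noise region raises an error rather than
returning infinity. The default fusion set {126, 128, 130} uses the three
highest-abundance isotopes; including a low-signal isotope (e.g. ¹²⁵Te,
7.07%) drives many geometric-mean pixels to zero, and the choice should be
made per experiment.

When scoring fusion on the phantom, the signal region is the tissue mask
eroded by 4 px and the noise region the complement of the tissue mask
dilated by 8 px: a σ = 1 blur must not smear tissue counts into the noise
region, which would measure mask-boundary leakage rather than noise.

## The phantom

`PhantomSpec` defaults (the standard fixture, seed 0): 256 × 256 px, tissue
fraction 0.4, 50 expected total Te counts per tissue pixel split across
isotopes {122, 124, 125, 126, 128, 130} by natural abundance, xenon
baseline 2 counts/px in the 134 channel with 5 random full rows at 20×, no
detection bias. The tissue blob is thresholded smoothed noise (only its
area fraction is a contract). Xenon isobar counts are drawn at the 134 rate
scaled by the table ratio, so background isotope ratios match the table *by
construction*; observed isobar channels are Te + Xe sums. Bias can be
folded into the Poisson rates (`PhantomSpec.bias`) or injected post hoc on
counts (`inject_teb`; no re-Poissonization — expectations match, variances
differ slightly).

What the phantom emulates: Poisson count statistics, abundance-correct
isotope splitting, row-streak xenon contamination, multiplicative detection
bias. What it does **not** emulate:

- **No tissue-independent noise floor.** Real slides carry background in
  every channel (probe residue, slide contamination); the phantom's only
  background source is xenon. After clipped xenon removal the phantom
  background is mostly exact zeros, so un-blurred geometric fusion zeroes
  almost the whole noise region and its SNR is inflated in a way real data
  would not show. Consequence: on the standard phantom, geometric fusion's
  SNR is *not* improved further by the 3-D blur (the blur does reduce
  streak-row noise, but also builds a positive background floor), whereas
  arithmetic fusion's SNR improves and geometric-with-blur still beats
  arithmetic-with-blur and every single channel. Passing tests therefore
  demonstrate the zero-propagation mechanism, not the full SNR ranking a
  noisier real background would produce.
- No cell-scale morphology, antibody/lanthanide channels, probe kinetics,
  detector saturation, or within-run drift.

Problem sizes in the test suite are chosen for a laptop-scale run: the
256 × 256 standard phantom for recovery and ordering checks, and a
320 × 320 tissue-free phantom (≥ 10⁵ background pixels) for the
unbiasedness check of xenon removal.

## Numerical conventions and degenerate inputs

- Counts are float64 throughout (corrections produce non-integers); TIFF
  output is float32, and write→read round trips are bit-exact for values
  representable in float32 (pixel tables round-trip float64 exactly via
  17-significant-digit formatting and round-trip parsing).
- Pixel tables are 0-based; an all-1-based table is shifted with a logged
  notice. Rasters must be complete rectangles; the first missing (X, Y) is
  named in the error.
- σ = 0 disables a blur exactly (identity), and a TEB of exactly 1 is an
  identity correction.
- Ratio images carry NaN outside their validity mask; statistics use only
  valid pixels.
- Errors are raised early and name the offending channel, isotope or pixel;
  data errors exit the CLI with status 1, usage errors with status 2.
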