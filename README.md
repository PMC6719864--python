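# tellimc

Processing tools for **tellurium imaging mass cytometry (IMC)**.

Tellurium-containing small molecules (tellurophenes) are antibody-free IMC
mass tags: linked to activity-based groups they image processes such as
protein synthesis or hypoxia, and — because tellurium has six isotopes
available in enriched form — the same probe dosed twice with two
isotopologues encodes two timepoints in two mass channels (sequential
labelling with isotopologous probes, SLIP). Tellurium as an analyte brings
three data-processing problems that generic IMC software does not treat,
and this package solves each of them:

1. **Xenon background removal.** Xenon contaminating the argon carrier gas
   has isobars at tellurium masses 124, 126, 128 and 130, adding background
   and whole-row streaks when a xenon spike coincides with a raster line.
   The 134 channel contains xenon but no tellurium, so for an observed
   channel **I** at mass *m*,

   ```
   I = T + Y,    Y = X · abundance(ᵐXe) / abundance(¹³⁴Xe),    T = I − Y
   ```

   where **X** is the 134 image and **T** the recovered tellurium image. No
   blank-sample acquisition is needed; the abundance ratio can optionally be
   replaced by one measured in a tissue-free region of the same image.

2. **Transmission efficiency bias (TEB).** The instrument detects heavier
   tellurium ions more efficiently than lighter ones. From any
   natural-abundance acquisition, the pixelwise ratio image
   **R** = **A**/**B** of two isotope channels (Gaussian-blurred, σ = 1 px,
   and thresholded at 1 count) should satisfy
   R = abundance(ᵃTe)/abundance(ᵇTe) if detection were unbiased; the
   deviation

   ```
   TEB = median(R) / (abundance(ᵃTe) / abundance(ᵇTe))
   ```

   quantifies the bias (TEB = 1 ⇔ none), and dividing channel **A** by the
   TEB corrects it — essential before interpreting a SLIP difference image,
   where the correction can flip the sign of individual pixels.

3. **Channel combination.** Natural-abundance experiments can fuse several
   isotope channels — arithmetically (sum) or geometrically (nth root of the
   product), optionally after a 3-D Gaussian blur across x, y and the
   channel axis — and score the result with SNR = μ_signal / σ_noise over
   user-chosen regions. Geometric fusion propagates zeros, which suppresses
   the strictly non-negative count noise that arithmetic summing accrues.

A seeded synthetic **phantom generator** (tissue blob, Poisson counts split
across isotopes by natural abundance, xenon baseline + raster-row streaks,
injectable per-isotope bias) gives every method a known ground truth, so the
whole package is testable without instrument data.

## Worked example

Estimate and correct a known detection bias injected into a synthetic
acquisition:

```python
from tellimc import (standard_phantom, inject_teb, dexenon_stack,
                     compute_teb, apply_teb)

stack, truth = standard_phantom()                 # synthetic acquisition
stack = inject_teb(stack, {126: 1.25})            # detector over-reads 126Te
corrected = dexenon_stack(stack)                  # remove xenon background

teb = compute_teb(corrected.get("Te", 126), corrected.get("Te", 124))
print(f"theoretical 126Te/124Te ratio : {teb.theoretical_ratio:.4f}")
print(f"median observed ratio         : {teb.median_ratio:.4f}")
print(f"TEB (over {teb.n_valid} pixels)  : {teb.teb:.4f}")

fixed = apply_teb(corrected.get("Te", 126), teb)
print(f"TEB after correction          : "
      f"{compute_teb(fixed, corrected.get('Te', 124)).teb:.4f}")
```

prints

```
theoretical 126Te/124Te ratio : 3.9747
median observed ratio         : 5.0072
TEB (over 26344 pixels)  : 1.2598
TEB after correction          : 1.0000
```

The natural-abundance expectation for the 126/124 pair is 3.97; the biased
acquisition's median pixel ratio is 5.01, giving TEB = 1.26 — the injected
factor 1.25 recovered to within 1% — and dividing the 126 channel by the
estimate restores TEB = 1.

## Command line

The same pipelines are available as `tellimc` subcommands operating on
multi-page TIFF, tab-separated pixel-table or CSV exports:

```sh
tellimc simulate --seed 0 --output phantom.tiff
tellimc dexenon  --input phantom.tiff --output corrected.tiff
tellimc teb      --input corrected.tiff --a 126 --b 124 --skip-dexenon
tellimc combine  --input corrected.tiff --mode geometric --blur-sigma 1 \
                 --output fused.tiff
tellimc slipdiff --input corrected.tiff --early 125Te --late 122Te \
                 --teb 1.05 --output diff.tiff --skip-dexenon
```

Structured results (TEB, SNR, spillover ratios, fraction of sign changes)
are printed to stdout as JSON; logs go to stderr.

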