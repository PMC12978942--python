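# ommatid

Quantification of compound-eye organization for butterfly retinas:
automated ommatidial classification from opsin antibody stains, red/yellow
eyeshine surveys along the dorsoventral axis, calibrated eyeshine
reflectance spectroscopy, and inference of the probability that
blue-opsin photoreceptors co-express the long-wavelength (LW) opsin.

## The scientific problem

Nymphalid butterfly retinas tile three ommatidial classes defined by the
opsins of the two distal photoreceptors R1 and R2 — UV-UV, B-B, and UV-B.
Some species additionally carry an *expanded* mosaic: a subset of ommatidia
with red screening pigment in which B cells co-express the LW opsin.
Eyeshine color reveals the pigment (red = expanded, yellow = basic), while
immunohistochemistry reveals the R1/R2 opsin classes — but standard UV/B
antibody panels do not see LW, so the co-expression rate must be inferred.

If each B cell co-expresses LW independently with probability *p*, and an
ommatidium is red whenever at least one R1/R2 cell is LW-positive, the
yellow-eyeshine fraction is

```
Yellow = UVUV + (1 − p)² · BB + (1 − p) · UVB
```

because UV-UV ommatidia have no B cell, a B-B ommatidium stays yellow only
if neither cell co-expresses, and a UV-B ommatidium only if its single B
cell does not.  Given the observed yellow fraction and the class
proportions, the package inverts this equation for *p* by least squares
(closed-form quadratic solve, cross-checked by a grid-search minimizer).

Around this core, the package implements the full measurement pipeline:

- **`ommatid.mosaic`** — synthetic retinal mosaics on a hexagonally packed
  lattice with a dorsoventral class gradient, plus renders of all three
  image modalities (3-channel IHC sections, RGB eyeshine photographs,
  31-plane reflectance stacks) with exact ground truth.
- **`ommatid.ihc`** — per-channel binary masks, merged-mask
  connected-component segmentation with area filtering, the inclusive
  ≥ 4% fill-positivity rule, class calls, and the cross-section
  consistency QC (exclude an individual when blue-photoreceptor
  proportions differ by more than 5 points across sections).
- **`ommatid.eyeshine`** — spot detection and red/yellow calls, regional
  summaries (two most dorsal images; ventral half), repeatability checks,
  and a manual-count CSV import path.
- **`ommatid.reflectance`** — constant-photon-flux shutter times
  (10¹⁵ photons per exposure), ROI spectra from image stacks, the 50%/95%
  dynamic-range exclusion, and per-wavelength group tests with
  Holm–Bonferroni control.
- **`ommatid.coexpr`** — the model above as a statsmodels-style
  `CoexpressionModel` / `CoexpressionResults` pair with summary tables and
  an optional bootstrap over individuals.
- **`ommatid.cohort`** — UPGMA clustering of class distributions, pairwise
  t-tests with compact letter displays, two-way species × sex ANOVA, and
  qPCR triplicate QC with UV2:UV1 relative expression.

## Worked example

```python
from ommatid import (MosaicSpec, ImagingConfig, generate_mosaic,
                     render_ihc_section, render_eyeshine,
                     quantify_section, EyeshineSurvey, CoexpressionModel)

# a 3,700-ommatidium eye, 75% of B cells co-expressing LW
spec = MosaicSpec(n_rows=50, n_cols=74,
                  class_proportions_ventral=(0.10, 0.50, 0.40),
                  p_coexpress=0.75, seed=42)
eye = generate_mosaic(spec)

cfg = ImagingConfig(noise_sd=6.0)
props, _, _ = quantify_section(render_ihc_section(eye, cfg, row_band=range(30, 44)))
survey = EyeshineSurvey.from_images(render_eyeshine(eye, cfg, n_images=10))
dorsal, ventral = survey.regional_proportions()

res = CoexpressionModel([ventral], [props.as_triple()], groups=["synthetic eye"]).fit()
print(res.summary())
```

prints

```
classified proportions: UV-UV 0.110  B-B 0.492  UV-B 0.398
dorsal yellow 0.216  ventral yellow 0.230

Blue-cell LW co-expression fit
method: closed_form   groups: 1

        group   y_obs   p_uvuv     p_bb    p_uvb  p_hat residual  feasible
synthetic eye 0.23018 0.110039 0.492278 0.397683 0.7658 3.08e-33      True
```

The stained section recovers the generating class mix (0.10/0.50/0.40)
from noisy imagery, the eyeshine survey measures a ventral yellow fraction
of 0.230, and inverting the equation estimates p̂ = 0.766 against the true
0.75 — the gap reflects binomial counting noise at this eye size.

A thin CLI mirrors the stages: `ommatid simulate`, `ommatid ihc`,
`ommatid eyeshine`, `ommatid reflectance`, `ommatid coexpr`, and
`ommatid stats {cluster,pairwise,anova,qpcr}`.

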