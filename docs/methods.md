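# Methods

This note documents the models behind `ommatid`, the defaults that matter,
the numerical choices, and what the synthetic-data tests do and do not
demonstrate about real retinal data.

## The generative mosaic model

An eye is a staggered (hexagonal-like) lattice of `n_rows × n_cols`
ommatidia; odd rows are offset by half a lattice pitch, matching compound-
eye packing.  The dorsoventral coordinate of an ommatidium is
`dv = row / (n_rows − 1)` with 0 at the dorsal pole (0 for a single-row
lattice).  Each ommatidium's class (UV-UV, B-B, UV-B) is drawn from
proportions linearly interpolated between a dorsal and a ventral triple;
by default the two are equal (no gradient).  Each blue R1/R2 cell is
independently LW-positive with probability `p_coexpress`; an optional
independent dorsal value is interpolated the same way, since dorsal red
pigment could in principle follow a different rate than ventral — the
generator leaves that open rather than assuming one mechanism.

The pigment rule — an ommatidium is red iff at least one R1/R2 cell is
LW-positive — is the unique rule consistent with the inversion target

    Yellow = UVUV + (1 − p)² · BB + (1 − p) · UVB,

so the generator and the model are consistent by construction, and the
generative-consistency check (empirical yellow fraction vs the closed form,
3 binomial SDs at n = 10,000 over a 5 × 5 grid of proportions and p) is a
real test of the sampling code, not a tautology.

UV identity: `uv_mode` selects UV1-only, UV2-only, or co-expression of
both UV opsins in the same cell; in co-expression mode both UV channels
are rendered on the same footprint with intensities scaled by the mixing
weight (`uv_mix` for UV1, its complement for UV2), emulating the graded
strong/weak/absent co-expression seen in real stains.  The ground-truth
table records such cells as `UV1+UV2`.

### Renders

All three modalities share the lattice geometry (pitch `2R + 4` px for
ommatidium radius `R`, default 6 px, which keeps neighboring footprints
disjoint at 8-connectivity) and are 8-bit with additive Gaussian noise
clipped to [0, 255].

* **IHC sections.**  Each ommatidium contributes two half-disk cell
  footprints (R1 on the +x side, R2 on −x), shrunk radially so the painted
  area is `fill_fraction` (default mean 0.6, SD 0.05) times the cell area.
  Both footprints include pixels at the ommatidium center, so the merged
  stain of one ommatidium is one connected component.  Foreground
  intensity is 200 on background 0 by default.
* **Eyeshine.**  The series tiles the dv axis without overlap;
  `resolution_gradient` (default 2.0) grows the rows-per-image linearly so
  the most ventral image holds about twice the ommatidia of the most
  dorsal, the ratio observed in real surveys.  Spots are disks in a red
  (200, 40, 10) or yellow (220, 200, 60) palette chosen so the
  red/(red+green) ratio separates the classes with wide margin.
* **Reflectance.**  Spectra live on the fixed 500–800 nm grid in 10 nm
  steps (31 planes; any other grid is rejected).  The yellow spectrum is
  `peak · expit((λ − 545)/15) · expit((700 − λ)/8)`, i.e. a plateau with a
  tapetal cutoff falling to half maximum near 700 nm and nearly absent
  above 730 nm.  Red is the same spectrum times
  `1 − a · exp(−((λ − 605)/σ)²)` with attenuation `a = 0.5` and σ spanning
  the 550–660 nm band, so red ≤ yellow there and the yellow peak exceeds
  the red peak.  Moving ventrally the whole curve shifts by
  `dv_redshift_per_unit · dv` nm (default 10 nm per unit dv), emulating
  the longer optical path of ventral ommatidia.  Intensity is
  `background + reflectance · (255 − background)`; the default peak
  reflectance 0.80 places spectra inside the 50–95% dynamic-range window.

## IHC quantification

* **Binarization** is Otsu per channel by default (a fixed per-channel
  threshold is available and recorded).  Otsu always splits a histogram,
  including a stain-free channel containing only camera noise, so a
  channel is declared empty when the contrast between its two Otsu classes
  is below 30 intensity units (≈ 4 noise SDs at the default noise level
  8); exactly constant channels are empty by definition.  The merged mask
  is the pixelwise OR of the three channel masks — whether the original
  workflow thresholded a composite image instead is unknowable from the
  description, and OR is the conservative union semantics.
* **Segmentation** takes 8-connected components of the merged mask
  (the usual default in image-analysis toolboxes) and keeps areas within
  `[A_min, A_max]`; when unspecified the range defaults to
  [0.3, 3.0] × the median component area, a scale-free rule robust to
  magnification.  Surviving components are relabeled in raster-scan order
  of their topmost-leftmost pixel, making labels deterministic.  A
  brute-force flood-fill oracle checks exact label-partition equality.
* **Positivity** is inclusive: fill fraction ≥ 0.04.  UV-positive means
  positive in UV1 *or* UV2 (a UV1-and-UV2 double positive counts once as
  UV).  Calls: UV only → UV-UV, B only → B-B, both → UV-B, neither →
  unclassified.  Unclassified components are annotated and excluded from
  proportions; their count is itself a QC signal since well-stained
  retinas show few gaps.
* **Consistency QC** uses the blue-photoreceptor *cell* fraction
  `(2·BB + UVB) / (2·total)` — two R1/R2 cells per ommatidium — and
  excludes an individual when the max pairwise difference across its 2–4
  sections exceeds 0.05 strictly (with a 1e-12 epsilon so a delta exactly
  at the tolerance is kept despite floating-point representation).
  Kept individuals get unweighted mean proportions across sections.

## Eyeshine surveys

Spot detection (Otsu on the channel maximum, watershed split at distance-
transform maxima) exists for synthetic imagery and convenience; real
analyses can import manual counts from CSV, and every summary operates on
counts either way.  The color call is `red iff R/(R+G) ≥ 0.60`, scale-
invariant by construction; `R+G = 0` is reported as unclassifiable.
Regional summaries: dorsal pools the two most dorsal images, ventral the
last ⌈n/2⌉ images — "ventral half" is read by image count because the
series tiles the axis without overlap.  Repeatability reports, per
duplicated image, the absolute yellow-proportion difference (percentage
points) and the total-count difference as a percentage of the primary
count.

## Reflectance

Shutter time is `target_flux / flux_rate` per wavelength (target 10¹⁵
photons), and the calibration round-trip (delivered flux = target to 1e-6
relative) is tested.  Spectra are mean ROI intensity per plane, kept in
raw 8-bit units rather than normalized to a white standard, because a
flat-response validation makes normalization a no-op; a hook exists.  The
dynamic-range rule is exhaustive and exclusive: max < 50% of 255 →
`excluded_low`, max > 95% → `excluded_saturated`, else `kept`.  Group
comparisons are per-wavelength Welch t-tests (robust default; pooled
variance available) or one-way ANOVA across the three eye regions, with
Holm–Bonferroni over the 31 wavelengths via statsmodels; a literal
sequential-rejection oracle checks the decisions, and a 2,000-replicate
null simulation confirms familywise error ≤ 5%.  The yellow-vs-red peak
difference is reported as `(yellow − red) / red`, i.e. relative to the
red peak.

## The co-expression fit

`fit_p` solves `BB·q² + UVB·q + (UVUV − Y) = 0` for `q = 1 − p` using the
numerically stable quadratic formula (the naive form loses ~8 digits near
p = 1), keeps the root in [0, 1], and falls back to the boundary value
minimizing the squared residual when the observation lies outside the
model's range `[UVUV, 1]` (`feasible = False`).  If both roots were ever
admissible — possible only in degenerate configurations — the one nearer
q = 0.5 is chosen deterministically and flagged `ambiguous`.  With
BB = UVB = 0 the model contains no B cell and p is unidentifiable: the fit
returns NaN with `identifiable = False` (feasible only when Y = UVUV)
rather than an arbitrary value.  The grid-search cross-check minimizes the
squared residual over q at 1e-6 resolution in two stages (1e-3 coarse,
then fine around the bracketing interval), valid because the residual is
unimodal in q on [0, 1].

Fits use group means, since eyeshine and staining typically come from
different individuals of the same group; ventral means are the intended
input because the model's yellow fraction is compared to ventral eyeshine.
`CoexpressionModel.from_individuals` additionally retains per-individual
rows so `CoexpressionResults.bootstrap` can resample individuals within
groups for percentile intervals — a clearly-labeled extension, since the
group-mean fit itself carries no analytic uncertainty.

## Cohort statistics

Clustering is Euclidean distance over the (UV-UV, B-B, UV-B) triple with
average (UPGMA) linkage via scipy, validated exactly against an O(n³)
agglomeration oracle for n ≤ 12.  Pairwise comparisons are Welch t-tests
Holm-corrected over all pairs; the compact letter display assigns one
letter per maximal clique of the non-significance graph (cliques sorted
lexicographically by member names), which guarantees two groups share a
letter iff their adjusted test is non-significant.  The two-way
species × sex ANOVA uses Type-II sums of squares by model comparison — the
standard choice for unbalanced observational designs, and identical to the
textbook decomposition when balanced (tested).  Zero residual variance
with a real effect reports F = ∞ with a note; a constant response reports
F = 0.  qPCR triplicates are discarded when the sample SD (n − 1
denominator) strictly exceeds 1 cycle; the UV2:UV1 fold is
`2^(meanCt_UV1 − meanCt_UV2)` under the equal-efficiency ΔCt assumption
(primer efficiencies being unknown), with LW and EF1a used only as
presence/quality controls; log2 of the fold (= ΔCt) is the reported
scale.  A sample is `not_detected` when a UV gene is absent and `retest`
when a required record is discarded; when both a discarded and a kept
record exist for a gene, the kept (re-tested) one is used.

## Problem sizes and what the tests show

Acceptance-scale simulations use 3,700-ommatidium eyes (the per-eye scale
of a real survey), 100 replicate eyes per condition, 500 random masks for
the segmentation oracle, 2,000 null datasets for familywise error, and
10,000-ommatidium mosaics for generative consistency — sizes chosen so the
whole suite runs in minutes on one CPU while keeping Monte-Carlo error
well inside the asserted bands.

Passing tests demonstrate internal correctness: the pipeline recovers the
generator's ground truth, and the rules and statistics match their
definitions and independent oracles.  The generator does not model real
tissue: no autofluorescence, antibody cross-reactivity, section-to-section
tissue distortion, uneven illumination, optical blur between neighboring
ommatidia, or pupil-response pigment migration.  Results on real images
therefore still depend on stain and imaging quality in ways these tests
cannot certify; the manual-count import path and the manual-vs-automated
comparison (`compare_manual`) exist precisely for that validation.

## Known limitations

* The Bernoulli-p model assumes equal, independent co-expression across B
  cells; unequal R1/R2 rates are intentionally out of scope.
* The eyeshine render colors spots uniformly; it does not model mixed or
  intermediate eyeshine hues, so the τ = 0.60 color threshold is tuned to
  the synthetic palette and should be recalibrated for real cameras.
* The dorsoventral reflectance shift is a rigid spectral translation; real
  shifts may change band shape.
* Hierarchical clustering treats proportion triples as unconstrained
  Euclidean points, as is conventional, even though they live on a
  simplex.
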