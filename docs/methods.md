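# Methods

## Scope and assumptions

The framework quantifies how much of an observed difference in mediated
extracellular electron transfer (EET) between two cultures is
attributable to cell-shape differences, under these assumptions:

1. **Mass-transfer limitation.** Ferricyanide reduction is limited by
   transport through the liquid boundary layer, so the per-cell rate is
   `r = k·A·Δc` with `Δc = [Fe³⁺]_b − [Fe³⁺]_s`. This requires an
   excess of cells for the mediator concentration used; the pipeline
   warns when the cell concentration falls below 1·10⁷ cells/ml, the
   order below which limitation is not expected for cyanobacteria.
2. **Reduction at the outer membrane.** `A` is the geometric outer-
   membrane area. If the reduction site is instead the plasma membrane,
   `periplasm_correct` shrinks both projected dimensions by twice the
   periplasmic thickness (default 10 nm, the peptidoglycan layer of
   *Synechococcus*) before the stereology.
3. **Rod shape.** Cells are spherocylinders: a cylinder of length
   `L − D` capped by hemispheres of diameter `D`, giving `A = πDL` and
   `V = (π/4)D²(L − D/3)`. Real membranes are folded, so `A` is a lower
   bound on true surface area; only ratios of `A` between conditions
   enter the MER, which cancels a shape-independent bias.
4. **Fully suspended cells.** The mass-transfer correlation
   `k = 2D_AB/d_p + 0.31(D_AB²|ρ_p−ρ_c|g/μ_c)^{1/3}` is valid for
   freely suspended particles with 1 µm < d_p < 600 µm in agitated
   vessels; lengths outside that open interval are computed but flagged
   with a warning. The characteristic dimension is the cell **length**,
   because width changes little over the observed length range.

## Parameters

| Symbol | Meaning | Default | Units |
|---|---|---|---|
| `D_AB` | ferricyanide diffusivity in medium | 7.44·10⁻¹⁰ | m² s⁻¹ |
| `ρ_p`  | cell density | 1040 | kg m⁻³ |
| `ρ_c`  | medium density (~30 °C) | 995.65 | kg m⁻³ |
| `μ_c`  | medium viscosity (~30 °C) | 7.9735·10⁻⁴ | kg m⁻¹ s⁻¹ |
| `g`    | gravitational acceleration | 9.80665 | m s⁻² |
| ε | ferricyanide extinction coefficient | 1.05204 | mM⁻¹ cm A⁻¹ |
| — | OD750 → cell count conversion | 2.95·10⁻⁹ | ml cell⁻¹ cm⁻¹ A |
| — | chlorophyll a extinction factor | 12.9447 | µg ml⁻¹ cm A⁻¹ |
| — | periplasm (peptidoglycan) thickness | 10 | nm |

The default diffusivity is the tabulated working value; an
`average_diffusivity` helper averages user-supplied literature values
(the arithmetic mean of the three commonly cited measurements is
7.375·10⁻¹⁰ m² s⁻¹, slightly below the default — users preferring the
mean can pass it through `PhysicalParams`).

Unit policy: geometry is carried in µm and converted to SI only at the
mass-transfer boundary (`units.py` centralises every conversion);
concentrations are in mol m⁻³, numerically identical to mM.

## Measurement pipeline

**Morphometry.** Images are thresholded and 8-connected components are
summarised by the ellipse with the same normalised second central
moments; axis lengths follow the 4·√eigenvalue convention, and the
projected length/width of a cell are the major/minor axis lengths. Note
that this convention is a *definition* of measured length, not an
unbiased estimator of pole-to-pole distance: for an exact stadium
(spherocylinder projection) of L = 60 px, D = 20 px the moment-ellipse
major axis is 64.9 px (closed-form moments). Measured lengths are
therefore systematically ≈8% above geometric pole-to-pole lengths for
typical aspect ratios. Because the same convention is applied to every
culture and day, the fractional differences and the MER are unaffected.

The default threshold is the **triangle method**. With fluorescent
cells covering a few percent of the field of view, the intensity
histogram is dominated by the background mode; an equal-variance (Otsu)
split then lands inside the background noise and floods the mask with
spurious regions, while the triangle rule keys on the histogram peak
and recovers the cells cleanly down to signal-to-noise ratio 5. Otsu
and a fixed manual threshold remain selectable.

Quality control removes regions that are too small (debris, default
min 20 px), touch the image border (truncated dimensions), are too
round (out of focus; min eccentricity 0.6) or too wide (overlapping or
dividing cells; max minor axis 2.0 µm). The numeric defaults are
calibration choices made on the synthetic generator — the criteria,
not the values, are prescribed — and every rejection is logged with the
rule that fired.

**Population statistics.** Per-image mean dimensions are combined with
weights equal to per-image cell counts; the reported spread is the
count-weighted standard deviation of the image means (the sampling
distribution of the mean) and its SEM divides by √(number of images).
Pairwise length comparisons use a two-tailed pooled-variance Student's
t test, rate comparisons a one-tailed test (alternative: test culture
faster), both at 5%; Welch variants are available.

**Length→property regressions.** Cells pooled over the experiment are
binned by length (0.4 µm wide, left-closed, anchored at the minimum
observed length; bin abscissa = mean member length, which avoids bias
from partly filled edge bins). Bins with ≥50 cells contribute their
mean property, and an OLS polynomial (linear by default, quadratic
optional) is fitted to the bin means with pointwise 95% confidence
bands on the mean response. Predicted means at the per-day mean length
carry the half-width to the 95% band as their uncertainty. Width, area
and surface-to-volume regressions are fitted independently rather than
derived from the width model.

**Assay rates.** The per-cell rate is |OLS slope| of the filtrate
concentration vs. time over the full assay window, converted
mM min⁻¹ → mol L⁻¹ s⁻¹ and divided by the cell concentration in
cells L⁻¹. Replicate-level rates are the unit of error: the reported
SEM is across replicates.

**Error propagation** is first-order and uncorrelated throughout:
relative errors of r, k and A combine in quadrature for Δc, and
σ_k = (2D_AB/L²)·σ_L since the gravitational term is length-free.

**Growth.** The Zwietering-reparameterised Gompertz curve is fitted by
nonlinear least squares on `y = ln(N_t/N_0)` with data-driven starts
(A₀ = max y; μ₀ = steepest finite-difference slope; λ₀ = first time y
exceeds 5% of A₀) and standard errors from the fit covariance. A
`GrowthCurve` may carry an explicit reference count `N_0`; otherwise
the first sample is the reference, which shifts the curve by the
model's (small) value at the first sampling time — the reason lag
estimates from real, sparsely sampled data are reported with their
(typically large) standard errors rather than trusted point values.
Doubling times default to the **decadic** convention `24·log₁₀2/μ`,
the only convention internally consistent with the growth-rate /
doubling-time pairs this analysis is calibrated against (0.55 d⁻¹ ↔
13 h, 0.20 d⁻¹ ↔ 36 h, 0.36 d⁻¹ ↔ 20 h); the natural-log convention is
available by flag, and the discrepancy is documented rather than
resolved.

## The MER

Fractional differences are test-minus-control over control, with the
nutritionally replete (continuously diluted) culture as the default
test side. `Δ(k·A)` is composed multiplicatively,
`(1+Δ(k·A)) = (1+Δk)(1+ΔA)`, so the identity
`(1+Δr) = (1+Δk)(1+ΔA)(1+ΔΔc)` holds exactly whenever `r = k·A·Δc`
holds on both sides. The MER is the sigmoid of `|Δ(k·A)|/|Δ(Δc)|`;
dominance is classified against the balanced value sigmoid(1) ≈ 0.7311
with a 10⁻⁶ tie tolerance. A zero denominator returns the limit 1.0
flagged by a warning; per-day ratios use per-day absolute values (no
cross-day averaging).

## Synthetic data: what it emulates and what it does not

The generators produce the four pipeline inputs with known ground
truth, at defaults chosen once to mirror an exponential-phase
PCC 7942-like population: lengths from a truncated Normal(3.7, 0.7) µm
on [1.5, 8] µm; widths `D = 1.02 + 0.05·L + N(0, 0.05)` µm (so the mean
cell has D ≈ 1.20 µm and area ≈ 14 µm², and width rises ≤ 0.2 µm over
the 3–7 µm length range); assays at 1 mM mediator and 6.78·10⁸
cells/ml decaying linearly with additive Gaussian spectrophotometric
noise; Gompertz-shaped OD750 curves with multiplicative noise; images
with rasterised spherocylinder footprints, isotropic Gaussian PSF and
Gaussian (optionally Poisson) detector noise. Every generator is a pure
function of (spec, seed).

Not emulated: bleaching and autofluorescence spectra, non-Airy optics
beyond the Gaussian PSF, cell division and motion, adsorption of
mediator to cell surfaces, and any feedback of physiology on the assay.
Passing recovery tests therefore demonstrates the correctness of the
measurement chain on idealised rods, not the absence of systematic
error in real micrographs.

## Numerical choices and degenerate inputs

- Order of magnitude is `floor(log10 x)` (used for the term-size
  checks on the correlation).
- The binned regression needs ≥2 qualifying bins, else
  `InsufficientBinsError`; predictions outside the fitted length range
  warn (`ExtrapolationWarning`) but are returned.
- A constant image yields an empty mask plus a warning; a single image
  yields a degenerate (zero) sampling SD, flagged.
- OD750 readings above 0.8 warn (outside the linear calibration range)
  but convert.
- CSV outputs are written with 9 significant digits so identical runs
  are byte-identical; input schemas are strict (unknown or missing
  columns, decimal commas, negative quantities and `L < D` rows are
  rejected with line numbers).
- Problem sizes in the test suite are chosen for seconds-scale runs:
  populations of 600–3000 cells, 100–200 simulation replicates for
  recovery/calibration studies, 1000 replicates for the t-test
  type-I-error check, single 512×512 fields of view for image
  round-trips.

## Known limitations

- Only the external boundary layer is modelled; periplasmic (internal)
  diffusion limitation is out of scope.
- Only the one mass-transfer correlation is provided; users should
  verify its applicability (agitation, density contrast) to their
  system.
- Physical constants are fixed per run; no temperature dependence of
  viscosity, density or diffusivity is modelled.
- The moment-ellipse length convention overestimates pole-to-pole
  length of rods (see above); absolute geometric quantities inherit
  that bias even though the MER does not.
- 2-D projections only: no z-stack reconstruction, tracking or
  division detection.
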