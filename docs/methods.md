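# Methods

This note documents the models behind `labassay`: the colour-analysis
conventions, the simulated assay chemistry, the forward optical model,
and the calibration design, together with the numerical choices and
known limitations.

## Colour analysis

Frames are encoded sRGB (IEC primaries, decoding with the standard
linear segment below 0.04045 and the 2.4 power law above).  The CIELAB
conversion uses the 2° observer with the D65 white point taken as the
exact XYZ of sRGB white (the row sums of the primary matrix), so the
grey axis maps to a* = b* = 0 identically; against scikit-image's
`rgb2lab` the transform agrees to < 0.005 in every coordinate on a 9³
grid of encoded values.

Order of operations per frame, following plate-reader-free colorimetric
practice: (1) mask saturated pixels — any encoded channel ≥ 250/255 by
default, judged before balancing; (2) white-balance the surviving
pixels with per-channel gains `gain_k = mean_grey / mean_channel_k`
computed from a white reference region (per-channel rather than a
single scalar, because a scalar cannot neutralise a tinted illuminant);
(3) average the encoded channels over the chamber ROI and convert the
*mean colour* to L\*a\*b\*.  Per-pixel Lab values are used only for the
dispersion statistic (the homogeneity index ‖(σ_L, σ_a, σ_b)‖).
Regions of interest are 0-based, half-open rectangles in row-major
order.  Gains are estimated once, from the first frame's white patch,
and reused: per-frame balancing is available but would silently absorb
genuine colour change if the reference patch were contaminated.

## Simulated assay chemistry

State variables: undissolved spotted substrate mass m (nmol), dissolved
substrate S (mM), chromophore P (mM), integrated with fixed-step
classical Runge–Kutta (dt = 0.01 min; halving dt changes the endpoint
by < 10⁻⁴ relative, and substrate conservation holds to < 10⁻⁶).

* **Conversion**: v = kcat_app · E · f_DMSO · S/(Km_app + S), in
  μM min⁻¹.  Defaults: Km_app = 1.0 mM — above the ~0.5 mM usable
  solubility ceiling, so the enzyme is never saturated in the
  accessible range and the rate remains substrate-dependent, while
  staying linear in enzyme concentration.  kcat_app = 2.31 μM min⁻¹ per
  (mg mL⁻¹) anchors 1.0 mg mL⁻¹ at 0.1 mM substrate and 5 vol% DMSO to
  0.21 μM min⁻¹, the reference working point of the assay.
* **DMSO inhibition**: a multiplicative activity factor interpolated
  piecewise-linearly through (5 %, 1.00), (10 %, 0.78), (20 %, 0.38)
  and clamped outside; only those anchor reductions are known, so no
  mechanistic inhibition model is attempted.
* **Dissolution**: first-order in remaining mass with
  k_eff = k_ref · (V_ref/V_spot)^{1/3} / A, where the 1/3 exponent is a
  surface-to-volume scaling (the direction — smaller spots dissolve
  faster — is established; the exponent is a modelling choice), A ≥ 1
  is an agglomeration/mixing factor, and dissolution stalls linearly as
  S approaches a solubility ceiling (0.30 mM default).  k_ref =
  0.15 min⁻¹ for a 6 nL reference spot puts 95 % dissolution of a
  well-mixed 10×10 chip array near 20 min, the observed solubilization
  span.  A fraction of the spotted mass can dissolve instantly when the
  chamber fills (`initial_dissolved_frac`).

Not modelled: pH or temperature dependence, multi-enzyme synergy,
product inhibition, and the slow signal decline after 30 min attributed
to aggregation — analysis windows simply never extend past 30 min.

## Forward optical model

Transmittance on a fixed 380–740 nm grid (5 nm):
T(λ) = 10^(−ℓ·Σ ε_i(λ)·c_i − τ(λ)).  The chromophore band is a Gaussian
peaking at 572 nm scaled so ε(570) = 58.5 mM⁻¹ cm⁻¹ exactly — the one
spectral constant anchored to the real compound.  The substrate band
(Gaussian, peak 470 nm, 20 mM⁻¹ cm⁻¹) and the Rayleigh-like turbidity
term are synthetic-world parameters chosen to reproduce the yellow
appearance and b* dynamics; they are not measurements.  The effective
microwell path is 0.074 cm so the synthetic OD calibration slope equals
58.5 × 0.074 = 4.33 mM⁻¹, tying the synthetic plate to the standard
calibration; the chip path is 0.02 cm (200 μm), which is why on-chip
colour changes are ~3.7× weaker.

The camera is an idealised colorimeter: a smooth Planckian 6504 K
daylight-like illuminant under the CIE 1931 observer (the published
piecewise-Gaussian analytic fit, accurate to ~1 %).  Channel values are
normalised per-channel to the blank chamber — the camera is
white-balanced against the blank — which makes the rendered colours
insensitive to the illuminant's fine structure and renders the blank
exactly neutral; a smartphone-specific spectral response is deliberately
not emulated, because any device response is absorbed by the empirical
a*→OD conversion factor that the kinetics module estimates from data.
Exposure (default 0.85) keeps even the most strongly yellow chamber
~4σ of sensor noise below the saturation threshold.

Frames are 200×140 px with a 100×100 px chamber ROI (~77 μm/px) and a
separate white patch.  Undissolved spots are discs of 1–2 px radius
carrying the substrate column density implied by their remaining mass —
small and optically dense, like dried nanolitre droplets.  Density
matters: an opaque spot contributes a bounded amount to the mean
colour, so dissolving it into the bulk *raises* b*, reproducing the
solubilization signal; dense spots also saturate the red channel and
are masked, as saturated regions are in real spotted-run images.  Spot
edges are hard; no diffusion halo.  Noise is per-channel Gaussian
(σ = 1/255 default) with optional slightly chromatic linear
illumination drift (≤ 1 % over 60 min).  Frames are kept as floats in
memory and quantised to 8-bit PNG only on disk; identical seeds give
bit-identical series.

### Scenario catalogue

Conditions mirror the assay's documented experiments and are fixed as
the generator's study conditions: microwell soluble runs at 0.1 mM with
0.5/1/2/5 mg mL⁻¹ enzyme (dose series) and at 0.25 mM with 1 and
5 mg mL⁻¹; matched microwell spotted runs (2.5 μL of 5 mM in a 5×5
array, agglomeration factor 4 and half the mass dissolving on filling,
reflecting spots dragged to well walls); chip runs with 0.6 μL spotted
as 5×5 (agglomerated, factor 9), 10×10 and 12×12 arrays of 2 mM stock
and 10×10 of 5 mM stock (persistent spots, factor 8), at 0/1/4/5
mg mL⁻¹.  Chip dissolution carries an extra ~3× slowdown for the
confined, unstirred chamber.

## Calibration design

The a*→OD conversion factor γ is estimated, never assumed: it depends
on camera, illumination, optical path *and assay condition*, because
the yellow substrate background sets the colour operating point of the
a* axis.  In the synthetic world γ ranges from ~18 (0.1 mM plate) to
~12–16 (0.25 mM and spotted conditions).  The pipeline therefore
calibrates per condition: a noiseless replicate of the same scenario is
rendered, its image-derived a* slope is correlated with the photometric
OD slope of the same reaction (`estimate_conversion_factor`, a
through-origin least-squares proportionality), and the resulting factor
converts subsequent runs of that condition.  With this design the
noiseless loop closes exactly and noisy end-to-end recovery of the true
molar rate is within a few percent (≤ ~5 % observed across the plate
catalogue); applying one pooled factor across conditions instead incurs
errors up to tens of percent — the quantitative reason the assay must
be run at reproducibly defined substrate concentrations.

Rate fits are OLS with intercept; R² is 1 − SS_res/SS_tot about the
mean, and the uncentered analogue for through-origin dose–response
fits.  Both dose–response modes are implemented and the mode is always
reported, never silently switched (the two modes bracket typical
reported sensitivities).  Default windows: 5–20 min (plate), 10–30 min
(chip, skipping the ≤10 min solubilization lag); nothing past 30 min.
The steady-state band for b*-phase calls is ±0.01 b*-units min⁻¹.

## What the synthetic tests do and do not show

Passing the closed loop demonstrates that the analysis chain —
balancing, masking, Lab conversion, window fitting, calibration, unit
conversion — is internally consistent and recovers known rates from
rendered imagery under the modelled noise.  It does not validate the
camera model of any real device, real dried-spot morphology or
dissolution law, aggregation optics beyond a crude turbidity term, or
meniscus/reflection artefacts (the intra-ROI dispersion of real wells
is dominated by wall shadows, which are not rendered).  Problem sizes
were chosen for routine laptop use: 41 frames of 200×140 px per run and
0.01 min integration steps.
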