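# labassay

CIELAB image analysis for colorimetric enzyme-activity assays, with a
physics-based synthetic time-lapse generator for closed-loop testing.

## The problem

Cellulase activity can be assayed colorimetrically through hydrolysis of
resorufin-β-cellobioside (ReC): the yellow substrate releases resorufin, a
pink dye with an absorption maximum at 570 nm
(ε₅₇₀ = 58.5 mM⁻¹ cm⁻¹).  On a microfluidic chip there is no
spectrophotometer — the read-out is a camera watching the reaction
chamber.  `labassay` implements the full image-based quantification chain
for that setting, for assay developers and bioprocess-monitoring users:

* **colour trajectories** — each frame is white-balanced against a
  reference region (saturated pixels excluded) and converted to CIELAB;
  the mean and standard deviation of L*, a*, b* over the chamber ROI form
  the time course.  The a* (green→red) axis tracks resorufin release; the
  b* (blue→yellow) axis tracks dissolution of the spotted substrate.
* **kinetics** — an ordinary least-squares line over the initial-rate
  window (5–20 min for microwell plates, 10–30 min on chip to skip the
  solubilization lag) gives the slope k<sub>a*</sub>.  With an empirical
  a*→OD conversion factor γ and the OD calibration slope s (OD per mM,
  s = ε₅₇₀·ℓ), the volumetric activity is

  &nbsp;&nbsp;&nbsp;&nbsp;v [mU mL⁻¹] = (k<sub>a*</sub> / γ) / s × 1000,

  using 1 U = 1 μmol min⁻¹, so 1 mU mL⁻¹ ≡ 1 μM min⁻¹.  Dividing by the
  enzyme mass concentration gives the specific activity in U g⁻¹.
* **solubilization tracking** — the sign of the b* slope classifies a run
  as solubilization-dominated, steady-state, or cleavage-dominated; the
  intra-ROI colour dispersion is a homogeneity index that reports
  undissolved substrate spots.
* **synthetic data** — a forward model (spot dissolution kinetics →
  saturable enzymatic conversion with DMSO inhibition → Beer–Lambert
  transmittance → idealised camera) renders time-lapse frame series with
  paired ground truth, so every step of the analysis is testable without
  laboratory data.

## Worked example

Simulate a microwell run (0.1 mM ReC, 1.0 mg mL⁻¹ cellulase, 5 vol%
DMSO), extract the trajectory, fit the a* slope and convert to activity:

```python
from labassay import generate_scenario, extract_trajectory, ColorKineticsModel
from labassay.workflows import matched_calibration

series, truth = generate_scenario("plate_soluble_0.1mM_1mg", seed=1)
traj = extract_trajectory(series)
res = ColorKineticsModel.from_trajectory(traj, "a_star", "microwell").fit()
print(res.summary())

cal = matched_calibration("plate_soluble_0.1mM_1mg")   # a*->OD factor
act = res.to_activity(cal, enzyme_conc=1.0)
print(f"volumetric activity: {act.volumetric_activity:.3f} mU/mL")
```

prints

```
Colour kinetics (initial-rate OLS fit)
==========================================
signal            a_star
window            5-20 min
n points          16
slope             0.01634 /min (se 0.00026)
intercept         -1.141
R-squared         0.997

volumetric activity: 0.210 mU/mL
```

The fitted a* slope (0.0163 min⁻¹, R² = 0.997) is converted through the
per-condition conversion factor (γ ≈ 17.9 for this synthetic camera) and
the calibration slope (4.33 mM⁻¹ for the 0.074 cm effective plate path)
into 0.210 mU mL⁻¹ — matching the simulator's true rate of 0.21 μM min⁻¹
at these conditions.  Note that γ is a property of the imaging setup and
assay condition; it is always estimated from matched runs, never assumed.

The same pipeline is available from the shell:

```
labassay simulate chip_10x10_2mM --seed 1 --out run/
labassay analyze run/ --out analysis/
labassay calibrate pairs.csv --out calibration.json
labassay report analysis/report.json
```

`labassay simulate --list` prints the scenario catalogue (microwell
soluble/spotted runs and chip microarray layouts 5×5 / 10×10 / 12×12 at
2.0 or 5.0 mM spotting stock).

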