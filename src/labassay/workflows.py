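"""High-level end-to-end workflows over the simulate -> analyse loop.

These functions wire the synthetic generator, trajectory extraction
and kinetics together the way a bench scientist would run the assay:
calibrate the imaging read-out once per assay condition against the
photometric channel, then convert fitted a*-slopes of subsequent runs
into molar rates.

The a*->OD conversion factor is deliberately calibrated *per assay
condition* (substrate concentration, format), not globally: the
factor absorbs the colour operating point set by the yellow substrate
background, which differs between conditions.  This mirrors standard
practice — and is why colorimetric assays must be run at reproducibly
defined substrate concentrations.
"""

from __future__ import annotations

import numpy as np

from .kinetics import (
    CalibrationModel,
    ColorKineticsModel,
    estimate_conversion_factor,
    fit_rate,
    select_linear_window,
)
from .reaction import ChamberGeometry
from .synthetic import SCENARIOS, generate_scenario
from .trajectory import extract_trajectory

__all__ = [
    "od_slope_factor_for",
    "scenario_kinetic_fit",
    "matched_calibration",
    "recover_volumetric_activity",
]


def od_slope_factor_for(geometry: ChamberGeometry, epsilon_570: float = 58.5) -> float:
    """OD-per-mM calibration slope implied by the optical path (eps * l)."""
    return epsilon_570 * geometry.path_length


def scenario_kinetic_fit(name: str, seed: int = 0, overrides: dict | None = None):
    """Simulate a scenario, extract the trajectory and fit the a* slope.

    Returns ``(fit, trajectory, truth, window)``.
    """
    series, truth = generate_scenario(name, overrides=overrides, seed=seed)
    traj = extract_trajectory(series)
    window = select_linear_window(traj.times, series.metadata["format"])
    fit = ColorKineticsModel.from_trajectory(
        traj, "a_star", series.metadata["format"]
    ).fit(window).fit
    return fit, traj, truth, window


def _true_window_od_slope(truth, times: np.ndarray, window, geometry) -> float:
    """OD/min slope of the photometric channel over the fit window."""
    sampled = truth.at(times)
    od = od_slope_factor_for(geometry) * sampled.resorufin
    return fit_rate(times, od, window, signal_kind="OD").slope


def matched_calibration(name: str, overrides: dict | None = None) -> CalibrationModel:
    """Calibrate the a*->OD factor for one assay condition.

    Runs a noiseless replicate of the scenario and correlates its
    image-derived a* slope with the photometric OD slope of the same
    reaction, exactly the correlation a paired plate-reader
    measurement provides.
    """
    ov = dict(overrides or {})
    ov["noise_sd"] = 0.0
    fit, traj, truth, window = scenario_kinetic_fit(name, seed=0, overrides=ov)
    geometry = SCENARIOS[name].conditions.chamber
    od_slope = _true_window_od_slope(truth, traj.times, window, geometry)
    factor = estimate_conversion_factor([(fit.slope, od_slope)])
    return CalibrationModel(
        od_slope_factor=od_slope_factor_for(geometry), a_to_od_factor=factor
    )


def recover_volumetric_activity(
    name: str,
    seed: int = 0,
    overrides: dict | None = None,
    calibration: CalibrationModel | None = None,
) -> tuple[float, float]:
    """End-to-end recovery: (pipeline-recovered, ground-truth) rate in uM/min.

    The ground truth is the least-squares slope of the simulator's
    true resorufin time course over the same fit window.
    """
    calibration = calibration or matched_calibration(name, overrides)
    fit, traj, truth, window = scenario_kinetic_fit(name, seed=seed, overrides=overrides)
    recovered = fit.slope / calibration.a_to_od_factor / calibration.od_slope_factor * 1000.0
    sampled = truth.at(traj.times)
    true_rate = fit_rate(
        traj.times, 1000.0 * sampled.resorufin, window, signal_kind="OD"
    ).slope
    return recovered, true_rate
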