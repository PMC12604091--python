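"""Rate fitting, calibration and activity quantification.

The quantification chain mirrors standard colorimetric assay practice:

1.  a linear fit of the signal (OD at 570 nm, or the CIELAB a* value)
    over an initial-rate window gives the slope,
2.  an OD slope is converted to a molar rate with the calibration
    slope factor (OD per mM chromophore),
3.  an a* slope is first mapped to an OD slope by an empirical,
    setup-specific conversion factor estimated from matched runs,
4.  the molar rate in uM/min equals the volumetric activity in
    mU/mL (1 U releases 1 umol product per minute); dividing by the
    enzyme mass concentration gives the specific activity in U/g.

The module exposes both plain functions and statsmodels-flavoured
model/results pairs (:class:`ColorKineticsModel`,
:class:`DoseResponseModel`) that carry uncertainties and print
summary tables.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = [
    "DEFAULT_WINDOWS",
    "KineticFit",
    "CalibrationModel",
    "ActivityResult",
    "DoseResponse",
    "select_linear_window",
    "fit_rate",
    "od_rate_to_molar_rate",
    "a_slope_to_activity",
    "estimate_conversion_factor",
    "specific_activity",
    "dose_response",
    "ColorKineticsModel",
    "ColorKineticsResults",
    "DoseResponseModel",
    "DoseResponseResults",
]

#: Initial-rate windows (min) per assay format.  The plate window is the
#: standard 5-20 min linear range; the chip window starts at 10 min to
#: skip the solubilization lag and never extends past the 30 min cutoff.
DEFAULT_WINDOWS = {"microwell": (5.0, 20.0), "chip": (10.0, 30.0)}


@dataclass(frozen=True)
class KineticFit:
    """Ordinary least-squares line fit of a signal over a time window."""

    slope: float  # signal units per min
    intercept: float
    r_squared: float
    window: tuple[float, float]
    n_points: int
    signal_kind: str = "a_star"  # OD | a_star | b_star
    slope_se: float = float("nan")

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("a kinetic fit needs at least 3 points")


@dataclass(frozen=True)
class CalibrationModel:
    """Calibration constants linking image signal to molar rates.

    od_slope_factor
        OD per mM chromophore at 570 nm (extinction coefficient times
        optical path); 4.33 /mM for the reference microwell setup.
    a_to_od_factor
        Dimensionless a*-change per OD-change of the imaging setup.
        Estimated from matched runs, never assumed: it depends on
        camera, illumination and geometry.
    """

    od_slope_factor: float = 4.33
    epsilon_570: float = 58.5  # per mM per cm, reference constant
    a_to_od_factor: float | None = None

    def __post_init__(self) -> None:
        if self.od_slope_factor <= 0:
            raise ValueError("od_slope_factor must be positive")
        if self.a_to_od_factor is not None and self.a_to_od_factor <= 0:
            raise ValueError("a_to_od_factor must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        return cls(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class ActivityResult:
    """Volumetric (mU/mL) and, when possible, specific (U/g) activity."""

    volumetric_activity: float
    fit: KineticFit
    calibration: CalibrationModel
    enzyme_conc: float | None = None  # mg/mL
    specific_activity: float | None = None  # U/g

    def __post_init__(self) -> None:
        if self.specific_activity is not None and self.enzyme_conc:
            if not math.isclose(
                self.volumetric_activity,
                self.specific_activity * self.enzyme_conc,
                rel_tol=1e-9,
                abs_tol=1e-12,
            ):
                raise ValueError("volumetric != specific * enzyme_conc")


@dataclass(frozen=True)
class DoseResponse:
    """Linear dose-response of fitted slopes vs enzyme concentration."""

    points: tuple[tuple[float, float], ...]
    sensitivity: float  # slope units per (mg/mL)
    intercept: float
    fit_mode: str  # with-intercept | through-origin
    r_squared: float

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError("dose-response needs at least 2 points")


def select_linear_window(
    times: np.ndarray, assay_format: str = "microwell"
) -> tuple[float, float]:
    """Default initial-rate window for the format; errors if not spanned."""
    if assay_format not in DEFAULT_WINDOWS:
        raise ValueError(f"unknown assay format {assay_format!r}")
    t = np.asarray(times, dtype=float)
    w0, w1 = DEFAULT_WINDOWS[assay_format]
    if t.min() > w0 + 1e-9 or t.max() < w1 - 1e-9:
        raise ValueError(
            f"series [{t.min():g}, {t.max():g}] min does not span the "
            f"default {assay_format} window ({w0:g}, {w1:g}) min"
        )
    return (w0, w1)


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Slope, intercept, R^2 (about the mean), slope standard error."""
    if np.ptp(y) == 0.0:  # linregress is degenerate for constant signals
        return 0.0, float(y[0]), 1.0, 0.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2), float(res.stderr)


def fit_rate(
    times: np.ndarray,
    signal: np.ndarray,
    window: tuple[float, float],
    signal_kind: str = "a_star",
) -> KineticFit:
    """OLS line fit (with intercept) over the in-window points."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(signal, dtype=float)
    mask = (t >= window[0] - 1e-9) & (t <= window[1] + 1e-9)
    if mask.sum() < 3:
        raise ValueError(f"fewer than 3 points inside window {window}")
    slope, intercept, r2, se = _ols_line(t[mask], y[mask])
    return KineticFit(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        window=(float(window[0]), float(window[1])),
        n_points=int(mask.sum()),
        signal_kind=signal_kind,
        slope_se=se,
    )


def od_rate_to_molar_rate(od_slope: float, cal: CalibrationModel) -> float:
    """OD/min -> uM/min (== mU/mL) via the calibration slope factor."""
    if not math.isfinite(od_slope):
        raise ValueError("od_slope must be finite")
    # slope factor is OD per mM; od/factor is mM/min -> *1000 uM/min
    return od_slope / cal.od_slope_factor * 1000.0


def a_slope_to_activity(k_a: float, cal: CalibrationModel) -> float:
    """a*-slope (1/min) -> volumetric activity in mU/mL.

    Divides by the empirical a*->OD conversion factor, then applies
    the OD calibration.
    """
    if cal.a_to_od_factor is None:
        raise ValueError(
            "calibration lacks a_to_od_factor; run estimate_conversion_factor first"
        )
    return od_rate_to_molar_rate(k_a / cal.a_to_od_factor, cal)


def estimate_conversion_factor(paired: list[tuple[float, float]]) -> float:
    """a*->OD conversion factor from matched (k_a, od_slope) runs.

    Least-squares proportionality coefficient through the origin of
    k_a versus od_slope.
    """
    pairs = np.asarray(paired, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 1:
        raise ValueError("need a list of (k_a, od_slope) pairs")
    ka, od = pairs[:, 0], pairs[:, 1]
    if np.all(od <= 0):
        raise ValueError("no pair with a positive OD slope")
    return float((ka * od).sum() / (od**2).sum())


def specific_activity(volumetric: float, enzyme_conc: float) -> float:
    """mU/mL divided by mg/mL gives mU/mg, i.e. U/g."""
    if enzyme_conc <= 0:
        raise ValueError("enzyme concentration must be positive")
    return volumetric / enzyme_conc


def dose_response(
    points: list[tuple[float, float]], fit_mode: str = "with-intercept"
) -> DoseResponse:
    """Linear fit of fitted slopes vs enzyme concentration.

    ``fit_mode`` is explicit and reported with the result: for
    through-origin fits R^2 is the uncentered coefficient of
    determination.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("dose-response needs at least 2 (conc, slope) points")
    x, y = pts[:, 0], pts[:, 1]
    if fit_mode == "with-intercept":
        slope, intercept, r2, _ = _ols_line(x, y)
    elif fit_mode == "through-origin":
        slope = float((x * y).sum() / (x**2).sum())
        intercept = 0.0
        ss_res = float(((y - slope * x) ** 2).sum())
        ss_tot = float((y**2).sum())
        r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    else:
        raise ValueError("fit_mode must be 'with-intercept' or 'through-origin'")
    return DoseResponse(
        points=tuple(map(tuple, pts)),
        sensitivity=slope,
        intercept=intercept,
        fit_mode=fit_mode,
        r_squared=r2,
    )


# ---------------------------------------------------------------------------
# model/results presentation


class ColorKineticsModel:
    """Initial-rate kinetics of one colour (or OD) trajectory.

    Parameters
    ----------
    times, signal
        The time axis (min) and the signal values.
    signal_kind
        "a_star", "b_star" or "OD"; controls default behaviour of the
        activity conversion.
    assay_format
        "microwell" or "chip"; sets the default fitting window.
    """

    def __init__(self, times, signal, signal_kind="a_star", assay_format="microwell"):
        self.times = np.asarray(times, dtype=float)
        self.signal = np.asarray(signal, dtype=float)
        if self.times.shape != self.signal.shape:
            raise ValueError("times and signal must have equal length")
        self.signal_kind = signal_kind
        self.assay_format = assay_format

    @classmethod
    def from_trajectory(cls, traj, signal="a_star", assay_format="microwell"):
        return cls(traj.times, traj.signal(signal), signal_kind=signal, assay_format=assay_format)

    def fit(self, window: tuple[float, float] | None = None) -> "ColorKineticsResults":
        if window is None:
            window = select_linear_window(self.times, self.assay_format)
        kfit = fit_rate(self.times, self.signal, window, signal_kind=self.signal_kind)
        return ColorKineticsResults(self, kfit)


class ColorKineticsResults:
    """Fitted slope with uncertainty, plus conversions to activity."""

    def __init__(self, model: ColorKineticsModel, fit: KineticFit):
        self.model = model
        self.fit = fit

    @property
    def slope(self) -> float:
        return self.fit.slope

    @property
    def r_squared(self) -> float:
        return self.fit.r_squared

    def to_activity(
        self, calibration: CalibrationModel, enzyme_conc: float | None = None
    ) -> ActivityResult:
        if self.fit.signal_kind == "OD":
            vol = od_rate_to_molar_rate(self.fit.slope, calibration)
        else:
            vol = a_slope_to_activity(self.fit.slope, calibration)
        spec = specific_activity(vol, enzyme_conc) if enzyme_conc else None
        return ActivityResult(
            volumetric_activity=vol,
            fit=self.fit,
            calibration=calibration,
            enzyme_conc=enzyme_conc,
            specific_activity=spec,
        )

    def summary(self) -> str:
        f = self.fit
        lines = [
            "Colour kinetics (initial-rate OLS fit)",
            "=" * 42,
            f"signal            {f.signal_kind}",
            f"window            {f.window[0]:g}-{f.window[1]:g} min",
            f"n points          {f.n_points}",
            f"slope             {f.slope:.4g} /min (se {f.slope_se:.2g})",
            f"intercept         {f.intercept:.4g}",
            f"R-squared         {f.r_squared:.3f}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Data and fitted line; returns the matplotlib axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.model
        ax.plot(m.times, m.signal, "o", ms=3, label=m.signal_kind)
        w0, w1 = self.fit.window
        tt = np.linspace(w0, w1, 50)
        ax.plot(tt, self.fit.intercept + self.fit.slope * tt, "-", label="fit")
        ax.set_xlabel("time (min)")
        ax.set_ylabel(m.signal_kind)
        ax.legend()
        return ax


class DoseResponseModel:
    """Linear response of fitted a*-slopes to enzyme concentration."""

    def __init__(self, enzyme_concs, slopes):
        self.enzyme_concs = np.asarray(enzyme_concs, dtype=float)
        self.slopes = np.asarray(slopes, dtype=float)
        if self.enzyme_concs.shape != self.slopes.shape:
            raise ValueError("enzyme_concs and slopes must have equal length")

    def fit(self, fit_mode: str = "with-intercept") -> "DoseResponseResults":
        dr = dose_response(list(zip(self.enzyme_concs, self.slopes)), fit_mode)
        return DoseResponseResults(self, dr)


class DoseResponseResults:
    def __init__(self, model: DoseResponseModel, dose: DoseResponse):
        self.model = model
        self.dose = dose

    @property
    def sensitivity(self) -> float:
        return self.dose.sensitivity

    @property
    def r_squared(self) -> float:
        return self.dose.r_squared

    def predict(self, enzyme_conc) -> np.ndarray:
        return self.dose.intercept + self.dose.sensitivity * np.asarray(enzyme_conc, float)

    def inverse(self, k_a: float) -> float:
        """Enzyme concentration estimated from a fitted slope (mg/mL)."""
        return (k_a - self.dose.intercept) / self.dose.sensitivity

    def summary(self) -> str:
        d = self.dose
        lines = [
            "Dose-response (slope vs enzyme concentration)",
            "=" * 46,
            f"fit mode          {d.fit_mode}",
            f"n points          {len(d.points)}",
            f"sensitivity       {d.sensitivity:.4g} per (mg/mL)",
            f"intercept         {d.intercept:.4g}",
            f"R-squared         {d.r_squared:.3f}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.model
        ax.plot(m.enzyme_concs, m.slopes, "o")
        xx = np.linspace(0, m.enzyme_concs.max() * 1.05, 50)
        ax.plot(xx, self.predict(xx), "-")
        ax.set_xlabel("cellulase (mg/mL)")
        ax.set_ylabel("k_a* (1/min)")
        return ax
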