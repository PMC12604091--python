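"""Ground-truth chemistry of the resorufin-cellobioside (ReC) assay.

The cellulase assay reads out hydrolysis of ReC, a yellow chromogenic
substrate, into resorufin, a pink dye absorbing at 570 nm.  On a
microfluidic chip the substrate is deposited as a spotted microarray
and must first dissolve into the sample, so the observable couples
three processes:

* first-order dissolution of the spotted substrate (faster for
  smaller spots via surface-to-volume scaling, slower for
  agglomerated spots and near the solubility ceiling),
* saturable single-substrate enzymatic conversion, linear in enzyme
  concentration and damped by the DMSO co-solvent, and
* accumulation of the released chromophore.

Units: volumes in uL, spot volumes in nL, concentrations in mM,
amounts in nmol, rates in uM/min, time in min.  Room temperature is
assumed throughout; no temperature model is included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ChamberGeometry",
    "SpotArray",
    "ReactionConditions",
    "KineticParameters",
    "GroundTruthKinetics",
    "per_spot_volume",
    "chamber_concentration",
    "dmso_activity_factor",
    "enzymatic_rate",
    "dissolution_rate",
    "integrate_reaction",
    "MICROWELL",
    "CHIP",
]


@dataclass(frozen=True)
class ChamberGeometry:
    """Reaction chamber: liquid volume (uL) and vertical optical path (cm)."""

    volume: float
    path_length: float
    kind: str = "microwell"

    def __post_init__(self) -> None:
        if self.volume <= 0 or self.path_length <= 0:
            raise ValueError("volume and path_length must be positive")
        if self.kind not in ("microwell", "chip"):
            raise ValueError("kind must be 'microwell' or 'chip'")


#: 96-well plate well: 50 uL assay volume; effective optical path chosen so
#: that the synthetic OD calibration slope equals 58.5 * 0.074 = 4.33 / mM.
MICROWELL = ChamberGeometry(volume=50.0, path_length=0.074, kind="microwell")

#: Microfluidic chip: 12 uL metered chamber, ~200 um vertical path.
CHIP = ChamberGeometry(volume=12.0, path_length=0.02, kind="chip")


@dataclass(frozen=True)
class SpotArray:
    """Spotted substrate microarray: layout, total spotted volume, stock.

    ``agglomeration_factor`` (>= 1) slows dissolution of clumped or
    poorly mixed spot arrays; 1 means well-separated spots in a
    well-stirred chamber.
    """

    rows: int
    cols: int
    total_volume: float  # uL spotted in total
    stock_conc: float  # mM of the spotting stock
    agglomeration_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("array must have at least one spot")
        if self.total_volume <= 0:
            raise ValueError("total spotted volume must be positive")
        if self.stock_conc < 0:
            raise ValueError("stock concentration must be non-negative")
        if self.agglomeration_factor < 1:
            raise ValueError("agglomeration_factor must be >= 1")

    @property
    def n_spots(self) -> int:
        return self.rows * self.cols

    @property
    def per_spot_volume(self) -> float:
        """Volume per spot in nL."""
        return per_spot_volume(self)

    @property
    def total_mass(self) -> float:
        """Total spotted substrate in nmol."""
        return self.stock_conc * self.total_volume


@dataclass(frozen=True)
class ReactionConditions:
    """Assay conditions: enzyme load, intended final ReC, co-solvent, chamber."""

    enzyme_conc: float  # mg/mL
    rec_conc_nominal: float  # mM intended final
    dmso_frac: float = 5.0  # vol%
    chamber: ChamberGeometry = MICROWELL

    def __post_init__(self) -> None:
        if self.enzyme_conc < 0 or self.rec_conc_nominal < 0:
            raise ValueError("concentrations must be non-negative")
        if not (0.0 <= self.dmso_frac <= 100.0):
            raise ValueError("dmso_frac is a volume percentage in [0, 100]")


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants of the simulated assay chemistry.

    kcat_app
        Apparent limiting rate, uM/min per (mg/mL enzyme), at substrate
        saturation.  The default anchors 1.0 mg/mL enzyme at 0.1 mM
        ReC and 5 vol% DMSO to a rate of 0.21 uM/min.
    km_app
        Apparent half-saturation constant, mM.  Set above the ~0.5 mM
        usable ceiling of ReC so the enzyme is never saturated in the
        accessible range.
    k_diss_ref
        First-order dissolution rate constant (1/min) of a reference
        spot of ``v_ref_spot`` nL.
    dmso_activity_table
        Piecewise-linear anchors (vol%, relative activity); 5 vol% is
        the normalisation point.
    s_sat
        Solubility ceiling of dissolved ReC (mM); dissolution stalls
        as the dissolved concentration approaches it.
    """

    kcat_app: float = 2.31
    km_app: float = 1.0
    k_diss_ref: float = 0.15
    v_ref_spot: float = 6.0  # nL
    dmso_activity_table: tuple[tuple[float, float], ...] = (
        (5.0, 1.00),
        (10.0, 0.78),
        (20.0, 0.38),
    )
    s_sat: float = 0.30

    def __post_init__(self) -> None:
        if self.km_app <= 0:
            raise ValueError("km_app must be positive")
        if min(self.kcat_app, self.k_diss_ref, self.v_ref_spot, self.s_sat) < 0:
            raise ValueError("rates and reference volumes must be non-negative")


def per_spot_volume(array: SpotArray) -> float:
    """Volume per spot in nL: total volume (uL) * 1000 / number of spots."""
    return array.total_volume * 1000.0 / array.n_spots


def chamber_concentration(array: SpotArray, chamber: ChamberGeometry) -> float:
    """Final ReC concentration (mM) in the complete-dissolution limit."""
    return array.stock_conc * array.total_volume / chamber.volume


def dmso_activity_factor(dmso_frac: float, params: KineticParameters | None = None) -> float:
    """Relative enzyme activity at a given DMSO content (clamped interpolation)."""
    if dmso_frac < 0:
        raise ValueError("dmso_frac must be non-negative")
    params = params or KineticParameters()
    table = np.asarray(params.dmso_activity_table)
    return float(np.interp(dmso_frac, table[:, 0], table[:, 1]))


def enzymatic_rate(
    rec_dissolved: float,
    conditions: ReactionConditions,
    params: KineticParameters | None = None,
) -> float:
    """Resorufin release rate in uM/min at the given dissolved ReC (mM)."""
    if rec_dissolved < 0:
        raise ValueError("substrate concentration must be non-negative")
    params = params or KineticParameters()
    f = dmso_activity_factor(conditions.dmso_frac, params)
    s = rec_dissolved
    return params.kcat_app * conditions.enzyme_conc * f * s / (params.km_app + s)


def dissolution_rate(
    remaining_mass: float,
    spot_volume: float,
    params: KineticParameters | None = None,
    agglomeration_factor: float = 1.0,
    dissolved_conc: float = 0.0,
) -> float:
    """Dissolution rate (nmol/min) of the remaining spotted substrate.

    First-order in the remaining mass with an effective constant
    ``k_diss_ref * (v_ref/spot_volume)^(1/3) / agglomeration_factor``,
    so smaller spots (larger surface-to-volume ratio) dissolve faster.
    Dissolution slows linearly to zero as the dissolved concentration
    approaches the solubility ceiling.
    """
    if min(remaining_mass, spot_volume, dissolved_conc) < 0:
        raise ValueError("inputs must be non-negative")
    params = params or KineticParameters()
    if remaining_mass == 0.0:
        return 0.0
    k_eff = (
        params.k_diss_ref
        * (params.v_ref_spot / spot_volume) ** (1.0 / 3.0)
        / agglomeration_factor
    )
    headroom = max(0.0, 1.0 - dissolved_conc / params.s_sat) if params.s_sat > 0 else 1.0
    return k_eff * remaining_mass * headroom


@dataclass
class GroundTruthKinetics:
    """True concentration time courses produced by the simulator.

    ``rec_remaining_spotted`` is the fraction of the initially spotted
    mass still undissolved (0 for soluble-start runs).
    """

    times: np.ndarray  # min
    rec_dissolved: np.ndarray  # mM
    rec_remaining_spotted: np.ndarray  # fraction of initial spotted mass
    resorufin: np.ndarray  # mM
    instantaneous_rate: np.ndarray  # uM/min
    initial_spotted_mass: float  # nmol
    initial_dissolved: float  # mM
    chamber: ChamberGeometry

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.times,
                "rec_dissolved_mM": self.rec_dissolved,
                "rec_remaining_frac": self.rec_remaining_spotted,
                "resorufin_mM": self.resorufin,
                "rate_uM_per_min": self.instantaneous_rate,
            }
        )

    def at(self, times: np.ndarray) -> "GroundTruthKinetics":
        """Linear interpolation onto a new time grid."""
        t = np.asarray(times, dtype=float)
        return GroundTruthKinetics(
            times=t,
            rec_dissolved=np.interp(t, self.times, self.rec_dissolved),
            rec_remaining_spotted=np.interp(t, self.times, self.rec_remaining_spotted),
            resorufin=np.interp(t, self.times, self.resorufin),
            instantaneous_rate=np.interp(t, self.times, self.instantaneous_rate),
            initial_spotted_mass=self.initial_spotted_mass,
            initial_dissolved=self.initial_dissolved,
            chamber=self.chamber,
        )

    def mass_balance_error(self) -> float:
        """Max relative deviation from substrate conservation over time."""
        v = self.chamber.volume
        total0 = self.initial_dissolved + self.initial_spotted_mass / v
        if total0 == 0:
            return 0.0
        total = (
            self.rec_dissolved
            + self.resorufin
            + self.rec_remaining_spotted * self.initial_spotted_mass / v
        )
        return float(np.max(np.abs(total - total0)) / total0)


def integrate_reaction(
    conditions: ReactionConditions,
    array: SpotArray | None = None,
    params: KineticParameters | None = None,
    t_end: float = 40.0,
    dt: float = 0.01,
    initial_dissolved_frac: float = 0.0,
) -> GroundTruthKinetics:
    """Integrate the coupled dissolution/conversion system (fixed-step RK4).

    With ``array=None`` the run starts from fully dissolved substrate at
    ``conditions.rec_conc_nominal`` (soluble-start).  With a spot array,
    ``initial_dissolved_frac`` of the spotted mass is taken up
    instantly when the chamber fills; the rest dissolves first-order.

    State variables: undissolved mass m (nmol), dissolved ReC S (mM),
    resorufin P (mM).
    """
    if t_end <= 0 or dt <= 0:
        raise ValueError("t_end and dt must be positive")
    if not (0.0 <= initial_dissolved_frac <= 1.0):
        raise ValueError("initial_dissolved_frac must lie in [0, 1]")
    params = params or KineticParameters()
    chamber = conditions.chamber
    if array is None:
        m0 = 0.0
        s0 = conditions.rec_conc_nominal
        spot_v = 1.0
        agg = 1.0
    else:
        total = array.total_mass
        m0 = total * (1.0 - initial_dissolved_frac)
        s0 = total * initial_dissolved_frac / chamber.volume
        spot_v = array.per_spot_volume
        agg = array.agglomeration_factor

    dmso_f = dmso_activity_factor(conditions.dmso_frac, params)

    def deriv(state: np.ndarray) -> np.ndarray:
        m, s, p = state
        m = max(m, 0.0)
        s = max(s, 0.0)
        diss = dissolution_rate(m, spot_v, params, agg, dissolved_conc=s)  # nmol/min
        rate = (
            params.kcat_app * conditions.enzyme_conc * dmso_f * s / (params.km_app + s)
        )  # uM/min
        return np.array(
            [
                -diss,
                diss / chamber.volume - rate / 1000.0,
                rate / 1000.0,
            ]
        )

    n_steps = int(round(t_end / dt))
    times = np.linspace(0.0, n_steps * dt, n_steps + 1)
    states = np.empty((n_steps + 1, 3))
    states[0] = (m0, s0, 0.0)
    y = states[0].copy()
    for i in range(n_steps):
        k1 = deriv(y)
        k2 = deriv(y + 0.5 * dt * k1)
        k3 = deriv(y + 0.5 * dt * k2)
        k4 = deriv(y + dt * k3)
        y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        y = np.maximum(y, 0.0)
        states[i + 1] = y

    m, s, p = states.T
    rates = (
        params.kcat_app * conditions.enzyme_conc * dmso_f * s / (params.km_app + s)
    )
    remaining = m / m0 if m0 > 0 else np.zeros_like(m)
    return GroundTruthKinetics(
        times=times,
        rec_dissolved=s,
        rec_remaining_spotted=remaining,
        resorufin=p,
        instantaneous_rate=rates,
        initial_spotted_mass=m0,
        initial_dissolved=s0,
        chamber=chamber,
    )
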