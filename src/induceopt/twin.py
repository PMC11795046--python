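"""Digital twin of the cultivation platform and its bacteria.

Replaces the incubator/plate-reader/liquid-handler stack with a seeded
simulator: logistic growth from OD600 0.1, a saturating (Hill) GFP response
to the inducer fraction, an optional unimodal enzyme (glucose-release)
factor, multiplicative well-level noise, and plate-level drift that follows
a random walk over the plate index so that drift between distant plates is
larger than between consecutive ones.

All randomness is derived from ``(seed, plate, well)`` so a measurement is a
pure function of its coordinates — repeating a run bit-reproduces it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dose import Dose
from .errors import DomainError, LayoutError, RunError

__all__ = [
    "GrowthParams",
    "ResponseParams",
    "NoiseModel",
    "WellMeasurement",
    "simulate_growth",
    "gfp_true",
    "plate_offsets",
    "measure_well",
    "simulate_plate",
    "induction_time",
    "culture_wells",
    "control_wells",
]

#: Culture rows on a 96-well plate; rows A and H hold blanks / water.
CULTURE_ROWS = ("B", "C", "D", "E", "F", "G")
CONTROL_ROWS = ("A", "H")
N_COLUMNS = 12
#: Corner wells of the control rows hold plain water (evaporation guard).
WATER_COLUMNS = (1, 2, 11, 12)

#: Maximum relative growth-rate reduction at x=100 (expression burden).
BURDEN_AT_MAX_DOSE = 0.10
#: OD600 of a cell-free media blank.
BLANK_OD = 0.04
#: Fluorescence background of a cell-free well, arbitrary units.
BLANK_FLUORESCENCE = 1.0


@dataclass(frozen=True)
class GrowthParams:
    """Logistic growth with a lag phase.

    Defaults follow the platform's cultures: start at OD600 0.1, plateau
    around 1.6, induction threshold (0.6) reached about five hours in.
    """

    od0: float = 0.1
    mu_max: float = 0.6  # 1/h
    od_capacity: float = 1.6
    lag_h: float = 1.0

    def __post_init__(self):
        if self.od0 <= 0:
            raise DomainError("od0 must be > 0")
        if self.od_capacity <= self.od0:
            raise DomainError("od_capacity must exceed od0")
        if self.mu_max <= 0:
            raise DomainError("mu_max must be > 0")
        if self.lag_h < 0:
            raise DomainError("lag_h must be >= 0")


@dataclass(frozen=True)
class ResponseParams:
    """Noiseless GFP dose–response.

    1-D: ``basal + vmax * x^n / (k^n + x^n)`` — monotone saturating in the
    inducer fraction x.  2-D: multiplied by a unimodal enzyme factor peaking
    at ``enzyme_opt`` (a Gaussian bell of width ``enzyme_width`` with floor
    ``1 - repression_strength``), emulating catabolite repression at high
    glucose release.  ``maturation_h`` is the time after induction at which
    expression reaches its plateau; readouts taken then see the full signal.
    """

    basal: float = 2.0
    vmax: float = 100.0
    hill_k: float = 5.0
    hill_n: float = 2.0
    enzyme_opt: float = 42.0
    enzyme_width: float = 15.0
    repression_strength: float = 0.7
    maturation_h: float = 4.0

    def __post_init__(self):
        if self.hill_n < 1:
            raise DomainError("hill_n must be >= 1")
        if not (0.0 <= self.repression_strength <= 1.0):
            raise DomainError("repression_strength must be in [0, 1]")
        if not (0.0 <= self.enzyme_opt <= 100.0):
            raise DomainError("enzyme_opt must be in [0, 100]")
        if self.enzyme_width <= 0 or self.hill_k <= 0:
            raise DomainError("enzyme_width and hill_k must be > 0")
        if self.vmax < 0 or self.basal < 0:
            raise DomainError("basal and vmax must be >= 0")


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative measurement noise.

    ``sigma_well`` scales i.i.d. per-well noise; ``sigma_plate`` is the sd of
    each increment of the plate-offset random walk, so
    Var(offset_p − offset_q) = |p − q|·sigma_plate², i.e. drift grows with
    plate distance.
    """

    sigma_well: float = 0.10
    sigma_plate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.sigma_well < 0 or self.sigma_plate < 0:
            raise DomainError("noise sds must be >= 0")


@dataclass(frozen=True)
class WellMeasurement:
    """One plate-reader reading of one well at one timepoint."""

    plate_index: int
    row: str
    column: int
    time_h: float
    od600: float
    fluorescence: float
    role: str  # "culture" | "blank" | "water"
    dose: Dose | None = None

    def __post_init__(self):
        if self.od600 < 0 or self.fluorescence < 0:
            raise DomainError("od600 and fluorescence must be >= 0")
        if self.role != "culture" and self.dose is not None:
            raise DomainError("control wells carry no dose")


def culture_wells() -> list[tuple[str, int]]:
    """The 72 culture positions: rows B–G × columns 1–12, row-major."""
    return [(r, c) for r in CULTURE_ROWS for c in range(1, N_COLUMNS + 1)]


def control_wells() -> list[tuple[str, int, str]]:
    """Rows A and H: (row, column, role) with water in the corner columns."""
    return [
        (r, c, "water" if c in WATER_COLUMNS else "blank")
        for r in CONTROL_ROWS
        for c in range(1, N_COLUMNS + 1)
    ]


def simulate_growth(g: GrowthParams, t) -> np.ndarray | float:
    """Noiseless OD600 at time ``t`` hours: lag, then logistic to capacity."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError("time must be >= 0")
    return _logistic_from(g.od0, g.mu_max, g.od_capacity, t_arr - g.lag_h)


def _logistic_from(od_start, mu, capacity, dt):
    dt = np.maximum(np.asarray(dt, dtype=float), 0.0)
    ratio = (capacity - od_start) / od_start
    od = capacity / (1.0 + ratio * np.exp(-mu * dt))
    return od if od.shape else float(od)


def gfp_true(r: ResponseParams, x: float, e: float | None = None) -> float:
    """Noiseless steady-state GFP signal for inducer fraction ``x`` (and enzyme ``e``)."""
    if not (0.0 <= x <= 100.0):
        raise DomainError(f"inducer fraction {x!r} outside [0, 100]")
    hill = r.basal + r.vmax * x**r.hill_n / (r.hill_k**r.hill_n + x**r.hill_n)
    if e is None:
        return float(hill)
    if not (0.0 <= e <= 100.0):
        raise DomainError(f"enzyme fraction {e!r} outside [0, 100]")
    floor = 1.0 - r.repression_strength
    bell = floor + (1.0 - floor) * np.exp(-0.5 * ((e - r.enzyme_opt) / r.enzyme_width) ** 2)
    return float(hill * bell)


def plate_offsets(noise: NoiseModel, n_plates: int) -> np.ndarray:
    """Relative fluorescence offsets for plates 1..n: a Gaussian random walk."""
    rng = np.random.default_rng([noise.seed, 0x9E3779B9])
    return np.cumsum(rng.normal(0.0, noise.sigma_plate, size=n_plates))


def _well_rng(noise: NoiseModel, plate_index: int, row: str, column: int):
    return np.random.default_rng([noise.seed, plate_index, ord(row), column])


def induction_time(
    g: GrowthParams, od_threshold: float, dt: float = 1.0, max_h: float = 48.0
) -> float:
    """First measurement time (multiple of ``dt``) with mean culture OD >= threshold.

    Before induction every culture well follows the same noiseless curve, so
    the plate mean equals the single-well OD.
    """
    if dt <= 0:
        raise DomainError("measurement interval must be > 0")
    t = 0.0
    while t <= max_h + 1e-9:
        if simulate_growth(g, t) >= od_threshold:
            return t
        t += dt
    raise RunError(f"culture never reached OD {od_threshold} within {max_h} h")


def _od_with_burden(g: GrowthParams, x: float, t: float, t_induction: float) -> float:
    """OD trajectory: unburdened until induction, then logistic with reduced mu."""
    if t <= t_induction:
        return float(simulate_growth(g, t))
    od_at_ind = float(simulate_growth(g, t_induction))
    mu_burdened = g.mu_max * (1.0 - BURDEN_AT_MAX_DOSE * x / 100.0)
    return float(_logistic_from(od_at_ind, mu_burdened, g.od_capacity, t - t_induction))


def _fluorescence_true(r: ResponseParams, dose: Dose, t_after_induction: float) -> float:
    """Expression ramps linearly from basal to the steady-state signal over maturation_h."""
    target = gfp_true(r, dose.inducer, dose.enzyme)
    ramp = np.clip(t_after_induction / r.maturation_h, 0.0, 1.0)
    return float(r.basal + (target - r.basal) * ramp)


def measure_well(
    r: ResponseParams,
    g: GrowthParams,
    noise: NoiseModel,
    dose: Dose,
    t_after_induction: float,
    *,
    plate_index: int = 1,
    row: str = "B",
    column: int = 1,
    t_induction: float | None = None,
    time_offset: float = 0.0,
    od_threshold: float = 0.6,
) -> WellMeasurement:
    """One culture-well reading ``t_after_induction`` hours past induction.

    Fluorescence is ``true_signal · (1 + plate_offset) · (1 + ε_well)``
    clipped at zero; OD is the noiseless burdened growth curve.  The same
    ``(noise.seed, plate, well)`` always yields the same measurement.
    """
    if t_induction is None:
        t_induction = induction_time(g, od_threshold)
    t = t_induction + t_after_induction
    od = _od_with_burden(g, dose.inducer, t, t_induction)
    signal = _fluorescence_true(r, dose, t_after_induction)
    offset = plate_offsets(noise, plate_index)[-1] if noise.sigma_plate > 0 else 0.0
    rng = _well_rng(noise, plate_index, row, column)
    # one draw per (well, timepoint): advance the stream deterministically
    n_skip = int(round(t / 0.25))
    eps = rng.normal(0.0, noise.sigma_well, size=n_skip + 1)[-1] if noise.sigma_well > 0 else 0.0
    fluor = max(0.0, signal * (1.0 + offset) * (1.0 + eps))
    return WellMeasurement(
        plate_index=plate_index,
        row=row,
        column=column,
        time_h=time_offset + t,
        od600=od,
        fluorescence=fluor,
        role="culture",
        dose=dose,
    )


def simulate_plate(
    doses: Sequence[Dose],
    *,
    growth: GrowthParams,
    response: ResponseParams,
    noise: NoiseModel,
    plate_index: int = 1,
    od_threshold: float = 0.6,
    dt: float = 1.0,
    readout_delay: float = 4.0,
    time_offset: float = 0.0,
    max_h: float = 48.0,
) -> list[WellMeasurement]:
    """Hourly OD/fluorescence readings of one 96-well plate.

    ``doses`` maps row-major onto the 72 culture wells (rows B–G); rows A and
    H are media blanks with water in the corners.  The plate grows until its
    mean culture OD crosses ``od_threshold`` (the induction trigger), is
    dosed, and is then read every ``dt`` hours until ``readout_delay`` hours
    past induction.  Times in the output are ``time_offset`` + plate-local.
    """
    wells = culture_wells()
    if len(doses) != len(wells):
        raise LayoutError(f"need {len(wells)} doses for the culture wells, got {len(doses)}")
    t_ind = induction_time(growth, od_threshold, dt, max_h)
    times = np.arange(0.0, t_ind + readout_delay + 1e-9, dt)
    out: list[WellMeasurement] = []
    for t in times:
        for (row, col), dose in zip(wells, doses):
            out.append(
                measure_well(
                    response, growth, noise, dose, t - t_ind,
                    plate_index=plate_index, row=row, column=col,
                    t_induction=t_ind, time_offset=time_offset,
                )
            )
        for row, col, role in control_wells():
            rng = _well_rng(noise, plate_index, row, col)
            n_skip = int(round(t / 0.25))
            eps = (
                rng.normal(0.0, noise.sigma_well, size=n_skip + 1)[-1]
                if noise.sigma_well > 0
                else 0.0
            )
            fluor = max(0.0, BLANK_FLUORESCENCE * (1.0 + eps))
            od = BLANK_OD if role == "blank" else 0.0
            out.append(
                WellMeasurement(plate_index, row, col, time_offset + t, od, fluor, role)
            )
    return out
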