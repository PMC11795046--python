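"""The closed-loop manager: consecutive plates from master to final readout.

Each plate is cloned from its predecessor when the predecessor's mean
culture OD crosses the induction threshold, grows to its own trigger,
receives its doses (plate 1: uniform random; later plates: whatever the
configured algorithm selects from the readouts complete by decision time),
and is read out ``readout_delay`` hours after induction.  Every dose,
measurement and decision lands in an append-only :class:`RunStore`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .dose import Dose
from .errors import DomainError, RunError, StateError
from .mixology import MixRecipe, iptg_recipe_1d, lactose_enzyme_recipe_2d, snap_dose
from .optimizer import (
    AcquisitionConfig,
    BatchResult,
    Bounds,
    ObjectiveConfig,
    evaluate_objective,
    expand_batch_to_wells,
    random_batch,
    select_batch,
)
from .surrogate import KernelConfig, Observation
from .twin import (
    GrowthParams,
    NoiseModel,
    ResponseParams,
    WellMeasurement,
    gfp_true,
    induction_time,
    simulate_plate,
)

__all__ = [
    "RunConfig",
    "RunStore",
    "run_closed_loop",
    "random_search_doses",
    "check_induction_trigger",
    "target_range_hits",
    "best_observed",
    "true_optimum",
]

WELLS_PER_PLATE = 72


@dataclass(frozen=True)
class RunConfig:
    """Everything a closed-loop run needs; fully determines the run given its seed."""

    system: str = "1d"  # "1d" | "2d"
    algorithm: str = "gpr-ei"  # "random" | "gpr-ei" | "gpr-ucb"
    n_induced_plates: int = 4
    distinct_points: int = 24
    induction_od: float = 0.6
    measurement_interval: float = 1.0
    readout_delay: float = 4.0
    seed: int = 0
    randomize_layout: bool = False
    max_hours: float = 48.0
    growth: GrowthParams = field(default_factory=GrowthParams)
    response: ResponseParams = field(default_factory=ResponseParams)
    noise: NoiseModel | None = None  # None: derive seed from the run seed
    objective: ObjectiveConfig = field(default_factory=ObjectiveConfig)
    acquisition: AcquisitionConfig | None = None  # None: kind from `algorithm`
    kernel: KernelConfig = field(default_factory=KernelConfig)

    def __post_init__(self):
        if self.system not in ("1d", "2d"):
            raise DomainError("system must be '1d' or '2d'")
        if self.algorithm not in ("random", "gpr-ei", "gpr-ucb"):
            raise DomainError("algorithm must be random | gpr-ei | gpr-ucb")
        if self.n_induced_plates < 1 or self.distinct_points < 1:
            raise DomainError("plate and point counts must be >= 1")
        if self.distinct_points > WELLS_PER_PLATE:
            raise DomainError(f"at most {WELLS_PER_PLATE} distinct points per plate")
        if self.induction_od <= self.growth.od0:
            raise DomainError("induction OD must exceed the starting OD")
        ratio = self.readout_delay / self.measurement_interval
        if abs(ratio - round(ratio)) > 1e-9:
            raise DomainError("readout_delay must be a multiple of measurement_interval")

    def resolved_noise(self) -> NoiseModel:
        if self.noise is not None:
            return self.noise
        return NoiseModel(seed=self.seed)

    def resolved_acquisition(self) -> AcquisitionConfig:
        if self.acquisition is not None:
            return self.acquisition
        kind = "ucb" if self.algorithm == "gpr-ucb" else "ei"
        return AcquisitionConfig(kind=kind, batch_size=self.distinct_points)

    def bounds(self) -> Bounds:
        return Bounds() if self.system == "1d" else Bounds(enzyme=(0.0, 100.0))

    def recipe(self) -> MixRecipe:
        return iptg_recipe_1d() if self.system == "1d" else lactose_enzyme_recipe_2d()


def _config_snapshot(cfg: RunConfig) -> dict:
    raw = asdict(cfg)
    raw["resolved_noise"] = asdict(cfg.resolved_noise())
    raw["resolved_acquisition"] = asdict(cfg.resolved_acquisition())
    # canonical JSON types so store round-trips compare equal
    return json.loads(json.dumps(raw, sort_keys=True))


@dataclass
class RunStore:
    """Append-only provenance of one run.

    ``dose_records`` holds one entry per induced well: plate, well, dose
    fractions, readout fluorescence and objective value.  ``decisions`` is
    one entry per plate; ``measurements`` every plate-reader reading.
    """

    config: dict
    dose_records: list[dict] = field(default_factory=list)
    measurements: list[WellMeasurement] = field(default_factory=list)
    decisions: list[dict] = field(default_factory=list)

    @property
    def n_plates(self) -> int:
        return max((r["plate"] for r in self.dose_records), default=0)


def check_induction_trigger(
    measurements: Sequence[WellMeasurement], od_threshold: float
) -> bool:
    """True when the mean OD over *culture* wells (blanks excluded) >= threshold."""
    ods = [m.od600 for m in measurements if m.role == "culture"]
    if not ods:
        raise StateError("no culture wells in the measurement set")
    # tolerance covers float summation dust when wells sit exactly at threshold
    return float(np.mean(ods)) >= od_threshold - 1e-12


def _decide_doses(
    cfg: RunConfig,
    plate: int,
    available_obs: list[Observation],
    rng: np.random.Generator,
) -> tuple[list[Dose], BatchResult | None]:
    bounds = cfg.bounds()
    if cfg.algorithm == "random":
        return random_batch(WELLS_PER_PLATE, bounds, rng), None
    if plate == 1 or not available_obs:
        result = select_batch(
            [], cfg.resolved_acquisition(), cfg.objective, bounds, plate, rng, cfg.kernel
        )
    else:
        result = select_batch(
            available_obs,
            cfg.resolved_acquisition(),
            cfg.objective,
            bounds,
            plate,
            rng,
            cfg.kernel,
        )
    wells = expand_batch_to_wells(
        result.doses, WELLS_PER_PLATE, rng, shuffle=cfg.randomize_layout
    )
    if not cfg.randomize_layout:
        wells = sorted(wells, key=Dose.sort_key)
    return wells, result


def run_closed_loop(cfg: RunConfig) -> RunStore:
    """Run the full test–learn loop on the twin and return its provenance store.

    The run ends ``readout_delay`` hours after the last plate's induction.
    Raises :class:`RunError` carrying the partial store if a plate never
    reaches the induction OD within the time budget.
    """
    store = RunStore(config=_config_snapshot(cfg))
    noise = cfg.resolved_noise()
    recipe = cfg.recipe()
    try:
        t_rel = induction_time(
            cfg.growth, cfg.induction_od, cfg.measurement_interval, cfg.max_hours
        )
    except RunError as err:
        raise RunError(str(err), partial_store=store) from None

    readout_times: dict[int, float] = {}
    observations: dict[int, list[Observation]] = {}
    plate_start = 0.0
    for plate in range(1, cfg.n_induced_plates + 1):
        t_trigger = plate_start + t_rel
        available_plates = sorted(
            p for p, t in readout_times.items() if t <= t_trigger + 1e-9
        )
        available = [o for p in available_plates for o in observations[p]]
        decision_rng = np.random.default_rng([cfg.seed, plate, 1])
        doses, result = _decide_doses(cfg, plate, available, decision_rng)
        doses = [snap_dose(d, recipe) for d in doses]
        store.decisions.append(
            {
                "plate": plate,
                "time_h": t_trigger,
                "algorithm": cfg.algorithm,
                "available_plates": available_plates,
                "n_available_observations": len(available),
                "n_distinct": len({d.sort_key() for d in doses}),
                "fallback_engaged": bool(result.fallback_engaged) if result else False,
                "used_random": result.used_random if result else True,
                "records": result.records if result else [],
                "seed": cfg.seed,
            }
        )
        measurements = simulate_plate(
            doses,
            growth=cfg.growth,
            response=cfg.response,
            noise=noise,
            plate_index=plate,
            od_threshold=cfg.induction_od,
            dt=cfg.measurement_interval,
            readout_delay=cfg.readout_delay,
            time_offset=plate_start,
            max_h=cfg.max_hours,
        )
        store.measurements.extend(measurements)
        t_readout = t_trigger + cfg.readout_delay
        readout_times[plate] = t_readout
        obs_this_plate: list[Observation] = []
        for m in measurements:
            if m.role == "culture" and abs(m.time_h - t_readout) < 1e-9:
                f = evaluate_objective(m.dose, m.fluorescence, cfg.objective)
                obs_this_plate.append(Observation(m.dose, plate, f))
                store.dose_records.append(
                    {
                        "plate": plate,
                        "row": m.row,
                        "column": m.column,
                        "inducer": m.dose.inducer,
                        "enzyme": m.dose.enzyme,
                        "fluorescence": m.fluorescence,
                        "objective": f,
                    }
                )
        observations[plate] = obs_this_plate
        plate_start = t_trigger  # next plate cloned at this plate's trigger
    return store


def random_search_doses(cfg: RunConfig) -> list[Dose]:
    """The dose draws of a random-search run, without simulating the twin.

    Uses exactly the per-plate RNG streams and pipetting snap of
    :func:`run_closed_loop`, so the returned doses equal the ones a full
    random run would record.  Random-search hit counts depend only on these
    doses, which makes large replicate studies cheap.
    """
    if cfg.algorithm != "random":
        raise StateError("dose draws are twin-independent only for random search")
    recipe = cfg.recipe()
    bounds = cfg.bounds()
    out: list[Dose] = []
    for plate in range(1, cfg.n_induced_plates + 1):
        rng = np.random.default_rng([cfg.seed, plate, 1])
        out.extend(snap_dose(d, recipe) for d in random_batch(WELLS_PER_PLATE, bounds, rng))
    return out


def target_range_hits(
    store: RunStore, axis: str = "inducer", target_range: tuple[float, float] = (7.0, 9.0)
) -> int:
    """Number of induced wells whose dose on ``axis`` lies in the closed interval."""
    lo, hi = target_range
    vals = [r[axis] for r in store.dose_records]
    return int(sum(1 for v in vals if v is not None and lo <= v <= hi))


def best_observed(store: RunStore, obj: ObjectiveConfig | None = None) -> tuple[Dose, float]:
    """Best per-well objective value and its dose; ties go to the smallest dose."""
    if not store.dose_records:
        raise StateError("run store holds no induced wells")
    records = sorted(
        store.dose_records,
        key=lambda r: (
            -r["objective"],
            r["inducer"],
            -np.inf if r["enzyme"] is None else r["enzyme"],
        ),
    )
    top = records[0]
    dose = Dose(top["inducer"]) if top["enzyme"] is None else Dose(top["inducer"], top["enzyme"])
    return dose, float(top["objective"])


def true_optimum(cfg: RunConfig, grid_step: float = 0.1) -> tuple[Dose, float]:
    """Noiseless-objective argmax of the twin on a dense dose grid (ground truth)."""
    xs = np.arange(0.0, 100.0 + 1e-9, grid_step)
    best: tuple[float, Dose] | None = None
    if cfg.system == "1d":
        candidates = [Dose(float(x)) for x in xs]
    else:
        es = np.arange(0.0, 100.0 + 1e-9, max(grid_step, 1.0))
        candidates = [Dose(float(x), float(e)) for x in xs for e in es]
    for d in candidates:
        f = evaluate_objective(d, gfp_true(cfg.response, d.inducer, d.enzyme), cfg.objective)
        if best is None or f > best[0]:
            best = (f, d)
    return best[1], best[0]
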