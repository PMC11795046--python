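"""Induction-mix arithmetic: fractions -> pipetted volumes -> well concentrations.

The optimizer reasons about abstract fractions x, e in [0, 100].  A plate
robot, however, pipettes microlitres of stock solutions into an induction
mix, a fixed aliquot of which (``transfer_volume``) is then added to each
cultivation well (``final_well_volume``).  This module is the bridge:

* :func:`compose_mix` turns a :class:`~induceopt.dose.Dose` into per-component
  volumes (inducer, enzyme, water) that sum exactly to the mix total;
* :func:`well_concentration` dilutes a stock through mix and well;
* :func:`dose_to_final_concentrations` composes the two.

Default recipes reproduce the reference platform: a 1-D IPTG system
(20 mM stock, 100 µL mix, up to 2 mM in the well) and a 2-D lactose+enzyme
system (20 % w/v lactose and 1500 U/L enzyme in a 95 µL mix, up to
43.8 mM lactose and ~31 U/L enzyme in the well).
"""

from __future__ import annotations

from dataclasses import dataclass

from .dose import Dose
from .errors import DomainError, RecipeError

__all__ = [
    "StockSolution",
    "MixRecipe",
    "ComponentVolumes",
    "compose_mix",
    "well_concentration",
    "dose_to_final_concentrations",
    "snap_dose",
    "iptg_recipe_1d",
    "lactose_enzyme_recipe_2d",
]

#: Default liquid-handler pipetting step, µL.
PIPETTING_RESOLUTION_UL = 0.1

#: Molar mass of alpha-lactose monohydrate, g/mol (the stock powder actually weighed).
LACTOSE_MONOHYDRATE_G_MOL = 360.31


@dataclass(frozen=True)
class StockSolution:
    """A stock solution with a concentration in mM (chemicals) or U/L (enzymes)."""

    name: str
    concentration: float
    unit: str = "mM"

    def __post_init__(self):
        if self.concentration <= 0:
            raise DomainError(f"stock {self.name!r}: concentration must be > 0")

    @classmethod
    def from_mass_fraction(
        cls, name: str, percent_wv: float, molar_mass_g_mol: float
    ) -> "StockSolution":
        """Build a molar stock from a % w/v mass fraction.

        A p % w/v solution holds 10·p g/L; dividing by the molar mass (g/mol)
        and converting to mM gives 10·p·1000/M.  E.g. 20 % w/v lactose
        monohydrate (M = 360.31) is 555.1 mM.
        """
        if percent_wv <= 0 or molar_mass_g_mol <= 0:
            raise DomainError("mass fraction and molar mass must be > 0")
        return cls(name, 10.0 * percent_wv * 1000.0 / molar_mass_g_mol, "mM")


@dataclass(frozen=True)
class MixRecipe:
    """Geometry of the induction mix and its downstream dilution.

    ``max_inducer_volume`` (µL) is the volume pipetted at x=100; likewise
    ``max_enzyme_volume`` for e=100 (0 for 1-D systems).  ``transfer_volume``
    µL of the finished mix is added to a well of ``final_well_volume`` µL.
    """

    total_mix_volume: float
    max_inducer_volume: float
    max_enzyme_volume: float
    transfer_volume: float
    final_well_volume: float
    inducer_stock: StockSolution
    enzyme_stock: StockSolution | None = None
    pipetting_resolution: float = PIPETTING_RESOLUTION_UL

    def __post_init__(self):
        for name in (
            "total_mix_volume",
            "max_inducer_volume",
            "max_enzyme_volume",
            "transfer_volume",
            "final_well_volume",
        ):
            if getattr(self, name) < 0:
                raise RecipeError(f"{name} must be >= 0")
        if self.max_inducer_volume + self.max_enzyme_volume > self.total_mix_volume + 1e-9:
            raise RecipeError("max component volumes exceed the total mix volume")
        if self.transfer_volume > self.final_well_volume:
            raise RecipeError("transfer volume exceeds the final well volume")
        if self.max_enzyme_volume > 0 and self.enzyme_stock is None:
            raise RecipeError("2-D recipe requires an enzyme stock")
        if self.pipetting_resolution <= 0:
            raise RecipeError("pipetting resolution must be > 0")

    @property
    def is_2d(self) -> bool:
        return self.max_enzyme_volume > 0


@dataclass(frozen=True)
class ComponentVolumes:
    """Per-well-mix pipetting volumes (µL); always sum to the recipe total."""

    inducer_ul: float
    enzyme_ul: float
    water_ul: float

    @property
    def total(self) -> float:
        return self.inducer_ul + self.enzyme_ul + self.water_ul


def _round_to_step(volume: float, step: float) -> float:
    # round() keeps floating dust out after dividing by the step
    return round(round(volume / step) * step, 9)


def compose_mix(dose: Dose, recipe: MixRecipe) -> ComponentVolumes:
    """Translate a dose into pipetting volumes for one well's mix aliquot.

    Inducer and enzyme volumes are the linear fraction of their maxima,
    rounded to the pipetting resolution; water fills the remainder so the
    components sum exactly to ``total_mix_volume``.
    """
    inducer = _round_to_step(
        dose.inducer / 100.0 * recipe.max_inducer_volume, recipe.pipetting_resolution
    )
    if dose.enzyme is not None and recipe.max_enzyme_volume == 0 and dose.enzyme > 0:
        raise RecipeError("recipe has no enzyme component but dose requests one")
    e_frac = 0.0 if dose.enzyme is None else dose.enzyme
    enzyme = _round_to_step(
        e_frac / 100.0 * recipe.max_enzyme_volume, recipe.pipetting_resolution
    )
    water = round(recipe.total_mix_volume - inducer - enzyme, 9)
    if water < 0:
        raise RecipeError(
            f"rounded component volumes ({inducer} + {enzyme} µL) exceed the "
            f"{recipe.total_mix_volume} µL mix total"
        )
    return ComponentVolumes(inducer, enzyme, water)


def well_concentration(
    stock: StockSolution, stock_volume: float, recipe: MixRecipe
) -> float:
    """Final concentration of ``stock`` in the cultivation well.

    The stock is diluted twice: into the mix (stock_volume / total_mix_volume)
    and from the mix into the well (transfer_volume / final_well_volume).
    Returned unrounded, in the stock's own unit (mM or U/L); display rounding
    is a formatting concern.
    """
    if stock_volume < 0 or stock_volume > recipe.total_mix_volume:
        raise DomainError(
            f"stock volume {stock_volume} µL outside [0, {recipe.total_mix_volume}]"
        )
    return (
        stock.concentration
        * (stock_volume / recipe.total_mix_volume)
        * (recipe.transfer_volume / recipe.final_well_volume)
    )


def dose_to_final_concentrations(dose: Dose, recipe: MixRecipe) -> dict[str, float]:
    """Map each mix component to its final well concentration for this dose."""
    vols = compose_mix(dose, recipe)
    out = {recipe.inducer_stock.name: well_concentration(recipe.inducer_stock, vols.inducer_ul, recipe)}
    if recipe.enzyme_stock is not None:
        out[recipe.enzyme_stock.name] = well_concentration(
            recipe.enzyme_stock, vols.enzyme_ul, recipe
        )
    return out


def snap_dose(dose: Dose, recipe: MixRecipe) -> Dose:
    """Snap a dose to the nearest fraction the pipetting step can realise.

    Round-trips the dose through :func:`compose_mix` and back; the result
    differs from the input by at most half a pipetting-resolution step on
    each axis (in volume terms).
    """
    vols = compose_mix(dose, recipe)
    x = (
        0.0
        if recipe.max_inducer_volume == 0
        else round(vols.inducer_ul / recipe.max_inducer_volume * 100.0, 9)
    )
    if dose.enzyme is None:
        return Dose(min(x, 100.0))
    e = (
        0.0
        if recipe.max_enzyme_volume == 0
        else round(vols.enzyme_ul / recipe.max_enzyme_volume * 100.0, 9)
    )
    return Dose(min(x, 100.0), min(e, 100.0))


def iptg_recipe_1d() -> MixRecipe:
    """1-D IPTG system: 20 mM stock mixed with water to 100 µL.

    20 µL of mix into a 200 µL well gives final IPTG concentrations from
    0 to 2 mM as x runs 0..100.
    """
    return MixRecipe(
        total_mix_volume=100.0,
        max_inducer_volume=100.0,
        max_enzyme_volume=0.0,
        transfer_volume=20.0,
        final_well_volume=200.0,
        inducer_stock=StockSolution("IPTG", 20.0, "mM"),
    )


def lactose_enzyme_recipe_2d(
    lactose_molar_mass: float = LACTOSE_MONOHYDRATE_G_MOL,
) -> MixRecipe:
    """2-D lactose + glucose-release-enzyme system in a 95 µL mix.

    Up to 75 µL of 20 % w/v lactose (555.1 mM for the monohydrate) and up to
    20 µL of 1500 U/L enzyme; final well concentrations span 0–43.8 mM
    lactose and 0–31.6 U/L enzyme.
    """
    return MixRecipe(
        total_mix_volume=95.0,
        max_inducer_volume=75.0,
        max_enzyme_volume=20.0,
        transfer_volume=20.0,
        final_well_volume=200.0,
        inducer_stock=StockSolution.from_mass_fraction("lactose", 20.0, lactose_molar_mass),
        enzyme_stock=StockSolution("enzyme", 1500.0, "U/L"),
    )
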