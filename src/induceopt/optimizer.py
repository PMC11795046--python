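"""From surrogate to dosing decisions.

Implements the cost-adjusted objective f = αᵢ·x (+ αₑ·e) + α_g·gfp, the EI
and UCB acquisition functions, the batch-selection heuristic (constant liar
with the median observed objective as the lie, κ escalated ×20 on the
pseudo-augmented refits, grid argmax, fallback around the last pick when
the argmax degenerates), and the random-search baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .dose import Dose
from .errors import DomainError
from .surrogate import GPModel, KernelConfig, Observation, fit_gp, refit_frozen

__all__ = [
    "ObjectiveConfig",
    "AcquisitionConfig",
    "Bounds",
    "BatchResult",
    "evaluate_objective",
    "ucb",
    "expected_improvement",
    "select_batch",
    "random_batch",
    "expand_batch_to_wells",
]


@dataclass(frozen=True)
class ObjectiveConfig:
    """Prices in f = alpha_i·x + alpha_e·e + alpha_g·gfp.

    ``alpha_i`` (and ``alpha_e``) are non-positive: inducer and enzyme cost
    money, so the optimum sits where fluorescence per unit inducer is
    maximal, not at maximal fluorescence.  With the default twin response
    the noiseless optimum lies at x = 8, inside the [7, 9] target band.
    """

    alpha_i: float = -5.05
    alpha_e: float = -0.1
    alpha_g: float = 1.0

    def __post_init__(self):
        if self.alpha_g <= 0:
            raise DomainError("alpha_g must be > 0")
        if self.alpha_i > 0 or self.alpha_e > 0:
            raise DomainError("alpha_i and alpha_e must be <= 0")


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition and batch-construction knobs.

    ``kappa_escalation`` multiplies κ on every constant-liar refit that
    contains at least one pseudo-observation, pushing the later picks of a
    batch towards exploration.  ``duplicate_tolerance`` (fraction units) is
    the minimum separation between batch points before the fallback engages;
    the fallback then fills the batch with points at the last selection
    ± k·``fallback_delta``.
    """

    kind: str = "ei"  # "ei" | "ucb"
    kappa: float = 2.0
    kappa_escalation: float = 20.0
    batch_size: int = 24
    duplicate_tolerance: float = 0.5
    fallback_delta: float = 1.0
    grid_points_1d: int = 1001
    grid_points_2d: int = 101

    def __post_init__(self):
        if self.kind not in ("ei", "ucb"):
            raise DomainError("acquisition kind must be 'ei' or 'ucb'")
        if self.kappa <= 0 or self.batch_size < 1 or self.duplicate_tolerance <= 0:
            raise DomainError("invalid acquisition configuration")


@dataclass(frozen=True)
class Bounds:
    """Closed per-axis box for the dose domain; default [0, 100] per axis."""

    inducer: tuple[float, float] = (0.0, 100.0)
    enzyme: tuple[float, float] | None = None

    def __post_init__(self):
        for iv in (self.inducer, self.enzyme):
            if iv is not None and not iv[0] < iv[1]:
                raise DomainError("bounds must satisfy lower < upper")

    @property
    def ndim(self) -> int:
        return 1 if self.enzyme is None else 2

    def contains(self, dose: Dose) -> bool:
        if not (self.inducer[0] <= dose.inducer <= self.inducer[1]):
            return False
        if self.enzyme is not None:
            return dose.enzyme is not None and self.enzyme[0] <= dose.enzyme <= self.enzyme[1]
        return dose.enzyme is None


@dataclass
class BatchResult:
    """Outcome of one batch selection, with provenance for the run store."""

    doses: list[Dose]
    fallback_engaged: bool = False
    used_random: bool = False
    records: list[dict] = field(default_factory=list)


def evaluate_objective(dose: Dose, gfp_value: float, cfg: ObjectiveConfig) -> float:
    """Cost-adjusted objective for one well readout."""
    if gfp_value < 0:
        raise DomainError("gfp_value must be >= 0")
    f = cfg.alpha_i * dose.inducer + cfg.alpha_g * gfp_value
    if dose.enzyme is not None:
        f += cfg.alpha_e * dose.enzyme
    return float(f)


def ucb(mean, sd, kappa: float):
    """Upper confidence bound: mean + κ·sd."""
    sd = np.asarray(sd, dtype=float)
    if np.any(sd < 0):
        raise DomainError("sd must be >= 0")
    out = np.asarray(mean, dtype=float) + kappa * sd
    return out if out.shape else float(out)


def expected_improvement(mean, sd, f_best: float):
    """Closed-form EI over the incumbent: E[max(0, f − f_best)].

    For a Gaussian posterior N(μ, σ²) this is (μ−f*)Φ(z) + σφ(z) with
    z = (μ−f*)/σ; at σ = 0 it degenerates to max(0, μ−f*).
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if np.any(sd < 0):
        raise DomainError("sd must be >= 0")
    improve = mean - f_best
    out = np.maximum(improve, 0.0)
    pos = sd > 0
    if np.any(pos):
        z = np.divide(improve, sd, out=np.zeros_like(mean + sd), where=pos)
        ei = improve * norm.cdf(z) + sd * norm.pdf(z)
        out = np.where(pos, ei, out)
    return out if out.shape else float(out)


def random_batch(n: int, bounds: Bounds, rng: np.random.Generator) -> list[Dose]:
    """n i.i.d. continuous uniform doses over the bounded box."""
    if n < 1:
        raise DomainError("n must be >= 1")
    xs = rng.uniform(bounds.inducer[0], bounds.inducer[1], size=n)
    if bounds.enzyme is None:
        return [Dose(float(x)) for x in xs]
    es = rng.uniform(bounds.enzyme[0], bounds.enzyme[1], size=n)
    return [Dose(float(x), float(e)) for x, e in zip(xs, es)]


def _acquisition_grid(bounds: Bounds, cfg: AcquisitionConfig) -> list[Dose]:
    if bounds.enzyme is None:
        xs = np.linspace(bounds.inducer[0], bounds.inducer[1], cfg.grid_points_1d)
        return [Dose(float(x)) for x in xs]
    xs = np.linspace(bounds.inducer[0], bounds.inducer[1], cfg.grid_points_2d)
    es = np.linspace(bounds.enzyme[0], bounds.enzyme[1], cfg.grid_points_2d)
    return [Dose(float(x), float(e)) for x in xs for e in es]


def _fallback_fill(
    selected: list[Dose], n_needed: int, delta: float, bounds: Bounds
) -> list[Dose]:
    """Points surrounding the last selection: last ± k·delta on the inducer axis."""
    anchor = selected[-1]
    lo, hi = bounds.inducer
    out: list[Dose] = []
    k = 1
    seen = {d.sort_key() for d in selected}
    while len(out) < n_needed:
        for sign in (+1, -1):
            x = float(np.clip(anchor.inducer + sign * k * delta, lo, hi))
            cand = Dose(x, anchor.enzyme)
            key = cand.sort_key()
            if key not in seen:
                seen.add(key)
                out.append(cand)
                if len(out) == n_needed:
                    break
        k += 1
        if k * delta > 10 * (hi - lo):  # domain saturated; accept clipped repeats
            while len(out) < n_needed:
                out.append(Dose(lo, anchor.enzyme))
    return out


def select_batch(
    history: Sequence[Observation],
    cfg: AcquisitionConfig,
    obj: ObjectiveConfig,
    bounds: Bounds,
    next_plate: int,
    rng: np.random.Generator,
    kernel_cfg: KernelConfig | None = None,
) -> BatchResult:
    """Choose ``batch_size`` distinct doses for the next plate.

    With an empty history the points are drawn uniformly at random.
    Otherwise a constant-liar loop runs: fit the surrogate on
    history + pseudo-points, take the acquisition argmax on a fixed grid
    (evaluated at ``next_plate``), append the winner with the median of all
    truly observed objective values as its pseudo-target, and repeat.  κ is
    escalated on every refit containing pseudo-observations.  If an argmax
    lands within ``duplicate_tolerance`` of an earlier pick, the remainder
    of the batch is filled with points surrounding the last pick.
    """
    history = list(history)
    if not history:
        return BatchResult(
            doses=random_batch(cfg.batch_size, bounds, rng),
            used_random=True,
            records=[{"reason": "empty history: uniform random selection"}],
        )

    grid = _acquisition_grid(bounds, cfg)
    order = rng.permutation(len(grid))  # seeded tie-break: first max in shuffled order
    grid_shuffled = [grid[i] for i in order]

    values = [o.objective_value for o in history]
    median = float(np.median(values))
    f_best = float(np.max(values))

    base = fit_gp(history, kernel_cfg)
    selected: list[Dose] = []
    pseudo: list[Observation] = []
    records: list[dict] = []
    fallback = False

    while len(selected) < cfg.batch_size:
        if pseudo:
            model = refit_frozen(base, history + pseudo)
            kappa_eff = cfg.kappa * cfg.kappa_escalation
        else:
            model = base
            kappa_eff = cfg.kappa
        mean, sd = model.posterior(grid_shuffled, next_plate)
        if cfg.kind == "ucb":
            score = ucb(mean, sd, kappa_eff)
        else:
            score = expected_improvement(mean, sd, f_best)
        idx = int(np.argmax(score))
        winner = grid_shuffled[idx]
        if any(winner.distance(s) < cfg.duplicate_tolerance for s in selected):
            fallback = True
            n_needed = cfg.batch_size - len(selected)
            records.append(
                {
                    "event": "fallback",
                    "duplicate_of": selected[-1].as_array().tolist(),
                    "n_filled": n_needed,
                }
            )
            selected.extend(
                _fallback_fill(selected, n_needed, cfg.fallback_delta, bounds)
            )
            break
        selected.append(winner)
        pseudo.append(Observation(winner, next_plate, median))
        records.append(
            {
                "event": "acquisition",
                "dose": winner.as_array().tolist(),
                "score": float(score[idx]),
                "kappa": kappa_eff if cfg.kind == "ucb" else None,
                "n_pseudo": len(pseudo) - 1,
                "median_lie": median,
                "f_best": f_best,
            }
        )
    return BatchResult(doses=selected, fallback_engaged=fallback, records=records)


def expand_batch_to_wells(
    distinct_doses: Sequence[Dose],
    n_wells: int,
    rng: np.random.Generator,
    shuffle: bool = True,
) -> list[Dose]:
    """Replicate distinct doses round-robin to fill ``n_wells`` wells.

    With ``shuffle`` the replicated list is permuted (seeded) — the
    randomized-layout mode; without it, wells are filled in round-robin
    order for a human-readable sorted plate.
    """
    distinct_doses = list(distinct_doses)
    if not distinct_doses or n_wells < 1:
        raise DomainError("need at least one dose and one well")
    wells = [distinct_doses[i % len(distinct_doses)] for i in range(n_wells)]
    if shuffle:
        wells = [wells[i] for i in rng.permutation(n_wells)]
    return wells
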