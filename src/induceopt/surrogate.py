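"""Gaussian-process surrogate over (dose, plate-index) space.

The surrogate models the objective f as a GP with an anisotropic RBF kernel
(one length scale per dose axis plus one for the plate axis) and a white
noise term.  The plate axis is the drift-handling device: plate index enters
as a raw coordinate (1, 2, 3, ...) with its own, short length scale, so the
posterior for the next plate leans on recent plates and discounts older
ones.  Replicate wells with conflicting readouts are ordinary duplicated
inputs — the GP absorbs them as noise, inflating the posterior sd there.

Fitting is delegated to :class:`sklearn.gaussian_process.GaussianProcessRegressor`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .dose import Dose
from .errors import DomainError, StateError

__all__ = ["Observation", "KernelConfig", "GPModel", "fit_gp", "refit_frozen"]


@dataclass(frozen=True)
class Observation:
    """A (dose, plate, objective value) triple consumed by the surrogate."""

    dose: Dose
    plate_index: int
    objective_value: float

    def __post_init__(self):
        if self.plate_index < 1:
            raise DomainError("plate_index must be >= 1")


@dataclass(frozen=True)
class KernelConfig:
    """Kernel family and hyperparameter box for the surrogate.

    Length scales are in the axes' own units: fraction units for the dose
    axes, plates for the plate axis.  The short plate length scale (default
    1.5 plates) is what down-weights older plates.  ``noise_variance`` seeds
    the white-noise term; set it to 0 for a noise-free interpolator (the
    white term is then dropped entirely).
    """

    length_scale_inducer: float = 10.0
    length_scale_enzyme: float = 10.0
    length_scale_plate: float = 1.5
    # dose-axis scales are capped near the expected feature width of the
    # response: with an unbounded scale the marginal likelihood follows the
    # broad inducer-cost trend and the surrogate cannot resolve the peak,
    # which degrades every acquisition built on it
    inducer_bounds: tuple[float, float] = (1.0, 15.0)
    enzyme_bounds: tuple[float, float] = (1.0, 15.0)
    plate_bounds: tuple[float, float] = (0.3, 10.0)
    signal_variance: float = 1.0
    signal_bounds: tuple[float, float] = (1e-3, 1e3)
    noise_variance: float = 0.1
    noise_bounds: tuple[float, float] = (1e-8, 10.0)
    n_restarts: int = 5
    normalize_y: bool = True
    optimize: bool = True
    random_state: int = 0


def _design_matrix(obs: Sequence[Observation], has_enzyme: bool) -> tuple[np.ndarray, np.ndarray]:
    rows = []
    for o in obs:
        coords = [o.dose.inducer]
        if has_enzyme:
            if o.dose.enzyme is None:
                raise DomainError("mixed 1-D and 2-D doses in one training set")
            coords.append(o.dose.enzyme)
        coords.append(float(o.plate_index))
        rows.append(coords)
    X = np.asarray(rows, dtype=float)
    y = np.asarray([o.objective_value for o in obs], dtype=float)
    return X, y


def _build_kernel(cfg: KernelConfig, has_enzyme: bool):
    scales = [cfg.length_scale_inducer]
    bounds = [cfg.inducer_bounds]
    if has_enzyme:
        scales.append(cfg.length_scale_enzyme)
        bounds.append(cfg.enzyme_bounds)
    scales.append(cfg.length_scale_plate)
    bounds.append(cfg.plate_bounds)
    kernel = ConstantKernel(cfg.signal_variance, cfg.signal_bounds) * RBF(
        np.array(scales), np.array(bounds)
    )
    if cfg.noise_variance > 0:
        kernel = kernel + WhiteKernel(cfg.noise_variance, cfg.noise_bounds)
    return kernel


@dataclass
class GPModel:
    """A fitted surrogate: training set, hyperparameters, posterior queries."""

    gpr: GaussianProcessRegressor
    observations: list[Observation]
    config: KernelConfig
    has_enzyme: bool

    @property
    def fitted_kernel(self):
        return self.gpr.kernel_

    def posterior(
        self, points: Sequence[Dose], plate_index: int
    ) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and sd at ``points`` evaluated for ``plate_index``.

        Typically queried at the next plate (max observed + 1) to predict
        the drift-adjusted response there.
        """
        if plate_index < 1:
            raise DomainError("plate_index must be >= 1")
        rows = []
        for p in points:
            if (p.enzyme is not None) != self.has_enzyme:
                raise DomainError("query dose dimensionality does not match the model")
            coords = [p.inducer]
            if self.has_enzyme:
                coords.append(p.enzyme)
            coords.append(float(plate_index))
            rows.append(coords)
        mean, sd = self.gpr.predict(np.asarray(rows, dtype=float), return_std=True)
        return mean, np.maximum(sd, 0.0)

    def snapshot(self) -> dict:
        """JSON-serializable record of the training set and fitted kernel."""
        return {
            "kernel": str(self.fitted_kernel),
            "has_enzyme": self.has_enzyme,
            "n_observations": len(self.observations),
            "observations": [
                {
                    "inducer": o.dose.inducer,
                    "enzyme": o.dose.enzyme,
                    "plate": o.plate_index,
                    "objective": o.objective_value,
                }
                for o in self.observations
            ],
        }


def fit_gp(obs: Sequence[Observation], cfg: KernelConfig | None = None) -> GPModel:
    """Fit the GP surrogate on (dose axes + plate axis) -> objective.

    Duplicated inputs with conflicting targets are legitimate evidence of
    noise, not an error.  Raises :class:`StateError` on an empty training
    set — with no data the caller should fall back to random selection.
    """
    if cfg is None:
        cfg = KernelConfig()
    obs = list(obs)
    if not obs:
        raise StateError("cannot fit a surrogate on zero observations; select randomly instead")
    has_enzyme = obs[0].dose.enzyme is not None
    X, y = _design_matrix(obs, has_enzyme)
    gpr = GaussianProcessRegressor(
        kernel=_build_kernel(cfg, has_enzyme),
        alpha=1e-10,
        normalize_y=cfg.normalize_y,
        optimizer="fmin_l_bfgs_b" if cfg.optimize else None,
        n_restarts_optimizer=cfg.n_restarts if cfg.optimize else 0,
        random_state=cfg.random_state,
    )
    gpr.fit(X, y)
    return GPModel(gpr=gpr, observations=obs, config=cfg, has_enzyme=has_enzyme)


def refit_frozen(model: GPModel, obs: Sequence[Observation]) -> GPModel:
    """Refit on a new training set with hyperparameters frozen at the model's.

    Used for the constant-liar refits inside batch selection: only the
    kernel matrix is recomputed, keeping batch construction deterministic
    and cheap.
    """
    obs = list(obs)
    if not obs:
        raise StateError("cannot refit on zero observations")
    X, y = _design_matrix(obs, model.has_enzyme)
    gpr = GaussianProcessRegressor(
        kernel=model.fitted_kernel,
        alpha=1e-10,
        normalize_y=model.config.normalize_y,
        optimizer=None,
        random_state=model.config.random_state,
    )
    gpr.fit(X, y)
    return GPModel(
        gpr=gpr, observations=obs, config=model.config, has_enzyme=model.has_enzyme
    )
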