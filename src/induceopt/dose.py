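"""The optimizer's unit of decision: a point in the bounded dosing domain.

Doses are expressed as fractions on [0, 100]: 0 means no inducer (or enzyme),
100 means the maximum volume the mix recipe allows.  The mapping to physical
mM / U-per-L concentrations lives in :mod:`induceopt.mixology`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError

__all__ = ["Dose"]


@dataclass(frozen=True)
class Dose:
    """A dosing decision: inducer fraction and, for 2-D systems, enzyme fraction.

    Parameters
    ----------
    inducer : float
        Inducer fraction in [0, 100] (0 = none, 100 = maximum recipe volume).
    enzyme : float, optional
        Glucose-release-enzyme fraction in [0, 100]; ``None`` for 1-D systems.
    """

    inducer: float
    enzyme: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.inducer <= 100.0):
            raise DomainError(f"inducer fraction {self.inducer!r} outside [0, 100]")
        if self.enzyme is not None and not (0.0 <= self.enzyme <= 100.0):
            raise DomainError(f"enzyme fraction {self.enzyme!r} outside [0, 100]")

    @property
    def ndim(self) -> int:
        return 1 if self.enzyme is None else 2

    def as_array(self) -> np.ndarray:
        """Dose coordinates as a float array of length ``ndim``."""
        if self.enzyme is None:
            return np.array([self.inducer], dtype=float)
        return np.array([self.inducer, self.enzyme], dtype=float)

    def distance(self, other: "Dose") -> float:
        """Euclidean distance in fraction units over the shared dose axes."""
        a, b = self.as_array(), other.as_array()
        n = min(a.size, b.size)
        return float(np.linalg.norm(a[:n] - b[:n]))

    def sort_key(self) -> tuple[float, float]:
        return (self.inducer, -np.inf if self.enzyme is None else self.enzyme)
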