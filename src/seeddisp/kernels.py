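"""Exponential power-von Mises dispersal kernels.

The radial law is the 2-D exponential power family: as a location density on
the plane,

    f(x) = b / (2 pi a^2 Gamma(2/b)) * exp(-(d/a)^b) * c(theta)

where d = |x - origin|, ``a`` is the scale, ``b`` the shape exponent (b = 2
Gaussian, b = 1 exponential, b < 1 fat-tailed) and ``c`` an optional von
Mises angular factor (kappa = 0 isotropic).  The kernel is parameterised by
its *mean dispersal distance* delta = a * Gamma(3/b) / Gamma(2/b); published
analyses often report the reciprocal d = 1/delta.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaln, i0

__all__ = ["DispersalKernel", "DispersalParams"]


def _scale_from_mean(delta: float, b: float) -> float:
    # delta = a * Gamma(3/b)/Gamma(2/b)  =>  a = delta * Gamma(2/b)/Gamma(3/b)
    return delta * np.exp(gammaln(2.0 / b) - gammaln(3.0 / b))


@dataclass(frozen=True)
class DispersalKernel:
    """One exponential power-von Mises kernel with mean distance ``delta``."""

    delta: float          # mean dispersal distance, metres
    b: float = 1.0        # shape exponent
    kappa: float = 0.0    # von Mises concentration (0 = isotropic)
    axis: float = 0.0     # von Mises preferred direction, radians

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("mean dispersal distance delta must be > 0")
        if self.b <= 0:
            raise ValueError("shape exponent b must be > 0")
        if self.kappa < 0:
            raise ValueError("angular concentration kappa must be >= 0")

    @property
    def scale(self) -> float:
        return _scale_from_mean(self.delta, self.b)

    def log_density(self, distance: np.ndarray, angle: np.ndarray | float = 0.0) -> np.ndarray:
        """Log of the planar location density at (distance, angle) from the source."""
        d = np.asarray(distance, float)
        a, b = self.scale, self.b
        lognorm = np.log(b) - np.log(2 * np.pi) - 2 * np.log(a) - gammaln(2.0 / b)
        with np.errstate(divide="ignore"):
            out = lognorm - (d / a) ** b
        if self.kappa > 0:
            th = np.asarray(angle, float)
            # angular factor 2*pi*vonMises(theta) so that kappa=0 gives 1
            out = out + self.kappa * np.cos(th - self.axis) - np.log(i0(self.kappa))
        return out

    def density(self, distance: np.ndarray, angle: np.ndarray | float = 0.0) -> np.ndarray:
        return np.exp(self.log_density(distance, angle))

    def mean_distance(self) -> float:
        """Mean dispersal distance (equals ``delta`` by construction)."""
        return self.delta

    def sample_displacements(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n planar displacement vectors from the kernel.

        Radial draw: (d/a)^b ~ Gamma(2/b), i.e. d = a * G^(1/b).
        """
        a, b = self.scale, self.b
        d = a * rng.gamma(2.0 / b, 1.0, size=n) ** (1.0 / b)
        if self.kappa > 0:
            th = rng.vonmises(self.axis, self.kappa, size=n)
        else:
            th = rng.uniform(0, 2 * np.pi, size=n)
        return np.column_stack([d * np.cos(th), d * np.sin(th)])


@dataclass(frozen=True)
class DispersalParams:
    """Full parameter set of the neighborhood dispersal model.

    Probabilities: ``s_o`` selfing, ``m_p`` pollen immigration (background
    pollen pool), ``m_s`` seed immigration; ``s_o + m_p <= 1``.  ``seed`` and
    ``pollen`` are the two dispersal kernels.  ``e_l`` maps locus name to a
    per-locus mistyping rate.
    """

    s_o: float = 0.0
    m_p: float = 0.0
    m_s: float = 0.0
    seed: DispersalKernel = field(default_factory=lambda: DispersalKernel(300.0, 1.0))
    pollen: DispersalKernel = field(default_factory=lambda: DispersalKernel(300.0, 1.0))
    e_l: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("s_o", "m_p", "m_s"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.s_o + self.m_p > 1.0 + 1e-12:
            raise ValueError(f"s_o + m_p = {self.s_o + self.m_p} exceeds 1")
        for locus, e in self.e_l.items():
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"mistyping rate at locus {locus} outside [0, 1]")

    @property
    def d_s(self) -> float:
        """Reciprocal mean seed dispersal distance, 1/m."""
        return 1.0 / self.seed.delta

    @property
    def d_p(self) -> float:
        """Reciprocal mean pollen dispersal distance, 1/m."""
        return 1.0 / self.pollen.delta

    def with_error_rates(self, e_l: dict[str, float]) -> "DispersalParams":
        return replace(self, e_l=dict(e_l))
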