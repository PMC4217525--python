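"""Colored-noise-driven motion in a symmetric double-well potential.

A generic bistable target system for calcium noise: a single variable X in
V(X) = -a/2 X^2 + b/4 X^4 (minima at +/-sqrt(a/b), barrier a^2/4b),
integrated with a first-order Euler scheme and driven additively by a
supplied noise trajectory.  The noise samples enter as per-step increments;
scaling them by sqrt(dt) recovers the white-noise limit.  The joint
distribution of (noise, state) and their Pearson correlation quantify how
strongly the state couples to the noise, which is controlled by the noise
autocorrelation time rather than its amplitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr

from .errors import DegenerateInputError
from .simulate import Trajectory


@dataclass(frozen=True)
class DoubleWellSpec:
    """Quartic double-well parameters and integration grid.

    a, b > 0 give minima at +/-sqrt(a/b) and barrier height a^2/(4b).
    Defaults a = b = 1 are the canonical normalization (minima +/-1,
    barrier 0.25).
    """

    a: float = 1.0
    b: float = 1.0
    dt: float = 0.01
    t_end: float = 1000.0
    x0: float = 1.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("a and b must be > 0")
        if self.dt <= 0 or self.t_end <= 0:
            raise ValueError("dt and t_end must be > 0")

    @property
    def minima(self) -> tuple[float, float]:
        m = math.sqrt(self.a / self.b)
        return (-m, m)

    @property
    def barrier(self) -> float:
        return self.a * self.a / (4.0 * self.b)


def dw_gradient(x: float | np.ndarray, spec: DoubleWellSpec) -> float | np.ndarray:
    """Deterministic force -dV/dx = a x - b x^3."""
    return spec.a * x - spec.b * x**3


def dw_simulate(noise: Trajectory, spec: DoubleWellSpec) -> Trajectory:
    """Integrate the driven double well along a noise trajectory.

    X_{k+1} = X_k + (a X_k - b X_k^3) dt + xi_k, with the noise samples
    used directly as additive increments.  The noise mean is removed first
    to respect the symmetry of the potential.  The returned state series is
    aligned with the noise grid (same dt and length).
    """
    if abs(noise.dt - spec.dt) > 1e-12:
        raise ValueError(
            f"noise grid dt={noise.dt} does not match spec dt={spec.dt}"
        )
    xi = np.asarray(noise.values, dtype=float)
    if xi.ndim != 1:
        raise ValueError("noise trajectory must be scalar")
    xi = xi - xi.mean()
    n = len(xi)
    a, b, dt = spec.a, spec.b, spec.dt
    out = np.empty(n)
    x = float(spec.x0)
    out[0] = x
    for k in range(n - 1):
        x = x + (a * x - b * x * x * x) * dt + xi[k]
        out[k + 1] = x
    meta = {"engine": "double-well", "a": a, "b": b, "noise": dict(noise.meta)}
    return Trajectory(dt=spec.dt, values=out, columns=("X",), meta=meta)


@dataclass(frozen=True)
class JointDistribution:
    """Normalized 2-D histogram of (noise, state) on equal-width bins."""

    xi_edges: np.ndarray
    x_edges: np.ndarray
    density: np.ndarray

    @property
    def mass(self) -> np.ndarray:
        """Per-bin probability mass (density x bin area); sums to 1."""
        dxi = np.diff(self.xi_edges)[:, None]
        dx = np.diff(self.x_edges)[None, :]
        return self.density * dxi * dx


def joint_distribution(
    xi: Trajectory, x: Trajectory, n_bins: int = 50
) -> JointDistribution:
    """Empirical joint probability density P(xi, X)."""
    if n_bins < 10:
        raise ValueError(f"n_bins must be >= 10, got {n_bins}")
    a = np.asarray(xi.values, dtype=float)
    b = np.asarray(x.values, dtype=float)
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    density, xi_edges, x_edges = np.histogram2d(a, b, bins=n_bins, density=True)
    return JointDistribution(xi_edges=xi_edges, x_edges=x_edges, density=density)


def factorization_distance(jd: JointDistribution) -> float:
    """L1 distance between the joint mass and the product of its marginals.

    Zero for independent variables (up to sampling noise); large when the
    state is strongly coupled to the noise.
    """
    mass = jd.mass
    p = mass.sum(axis=1)
    q = mass.sum(axis=0)
    return float(np.abs(mass - np.outer(p, q)).sum())


def coupling_correlation(xi: Trajectory, x: Trajectory) -> float:
    """Pearson correlation between the driving noise and the state."""
    a = np.asarray(xi.values, dtype=float)
    b = np.asarray(x.values, dtype=float)
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if len(a) < 10_000:
        raise ValueError("need at least 10^4 samples for a stable estimate")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateInputError("zero-variance series")
    return float(pearsonr(a, b).statistic)
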