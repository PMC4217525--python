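"""Closed-form noise parameters of buffered calcium fluctuations.

Under the excess buffer approximation (free buffer pinned at its equilibrium
value) the copy number of free calcium in a voxel relaxes linearly and its
stationary fluctuations are those of an Ornstein-Uhlenbeck process with

    mean                mu    = X_eq                      (counts)
    autocorrelation time tau  = 1 / (sum_j (k+_j y_eq_j + k-_j) + c_d)   (ms)
    volatility          sigma = sqrt(sum_j (c+_j X Y_j + c-_j Z_j) + 2 c_d X)

and stationary variance sigma^2 tau / 2.  tau is evaluated with
concentration-unit rates (it is volume-free); mu and sigma are evaluated in
copy-number units, which is where they appear in the Langevin equations.
Buffer and diffusion contributions combine additively because the rates add
in the linearized drift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .chemistry import SystemSpec, equilibrium_state, stochastic_rates
from .errors import UnsupportedSystemError


@dataclass(frozen=True)
class NoiseParams:
    """Ornstein-Uhlenbeck surrogate triplet (mu, tau, sigma).

    mu in counts, tau in ms, sigma in counts/sqrt(ms).  The stationary
    variance sigma^2 tau / 2 (counts^2) is derived.
    """

    mu: float
    tau: float
    sigma: float

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")

    @property
    def variance(self) -> float:
        return ou_variance(self.sigma, self.tau)

    @property
    def sd(self) -> float:
        return math.sqrt(self.variance)


def ou_variance(sigma: float, tau: float) -> float:
    """Stationary variance of an OU process, sigma^2 tau / 2."""
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    return sigma * sigma * tau / 2.0


@dataclass(frozen=True)
class LinearKinetics:
    """Coefficients of the linearized (excess-buffer) single-buffer kinetics.

    Deterministic: dx/dt = -K1 x + K2 with K1 = k+ y_eq + k- (ms^-1) and
    K2 = k- x_T (uM ms^-1), so x_eq = K2/K1.  C1, C2 are the copy-number
    analogues: C1 equals K1 numerically (rates of monomolecular form are
    volume-free) and C2 = c- X_T (counts ms^-1).
    """

    K1: float
    K2: float
    C1: float
    C2: float


def _require_single_buffer(system: SystemSpec, what: str) -> None:
    if system.n_buffers != 1:
        raise UnsupportedSystemError(
            f"{what} requires a single-buffer system, got M={system.n_buffers}"
        )


def linear_kinetics(system: SystemSpec) -> LinearKinetics:
    """K1, K2 and their stochastic analogues for a single-buffer system."""
    _require_single_buffer(system, "linear_kinetics")
    buf = system.buffers[0]
    eq = equilibrium_state(system)
    K1 = buf.k_plus * float(eq.y_eq[0]) + buf.k_minus
    K2 = buf.k_minus * eq.x_T
    C2 = buf.k_minus * eq.X_T
    return LinearKinetics(K1=K1, K2=K2, C1=K1, C2=C2)


def deterministic_relaxation(
    x0: float, system: SystemSpec, times: np.ndarray
) -> np.ndarray:
    """Mono-exponential relaxation x(t) = (x0 - x_eq) e^(-K1 t) + x_eq (uM)."""
    lk = linear_kinetics(system)
    times = np.asarray(times, dtype=float)
    return (x0 - system.ca_eq) * np.exp(-lk.K1 * times) + system.ca_eq


def _rate_sum(system: SystemSpec) -> float:
    """sum_j (k+_j y_eq_j + k-_j) + c_d, the linearized relaxation rate."""
    eq = equilibrium_state(system)
    rates = stochastic_rates(system)
    total = rates.c_d
    for j, buf in enumerate(system.buffers):
        total += buf.k_plus * float(eq.y_eq[j]) + buf.k_minus
    return total


def tau_theory(system: SystemSpec) -> float:
    """Stationary autocorrelation time tau (ms) of free-calcium noise.

    tau = 1 / (sum_j (k+_j y_eq_j + k-_j) + c_d); volume-independent.
    """
    if system.n_buffers == 0 and not system.geometry.has_diffusion:
        raise UnsupportedSystemError(
            "tau is undefined without buffers or diffusion"
        )
    return 1.0 / _rate_sum(system)


def sigma_theory(system: SystemSpec) -> float:
    """Stationary noise volatility sigma (counts ms^-1/2).

    sigma^2 sums the equilibrium propensities of every reaction channel:
    c+_j X Y_j + c-_j Z_j per buffer, plus 2 c_d X for the diffusive
    exchange.  Scales as sqrt(volume).
    """
    eq = equilibrium_state(system)
    rates = stochastic_rates(system)
    var_rate = 2.0 * rates.c_d * eq.X
    for j in range(system.n_buffers):
        var_rate += rates.c_plus[j] * eq.X * float(eq.Y[j])
        var_rate += rates.c_minus[j] * float(eq.Z[j])
    return math.sqrt(var_rate)


def mu_theory(system: SystemSpec) -> float:
    """Stationary mean free-calcium copy number.

    Evaluates mu = [sum_j c-_j (X_T - sum_{i!=j} Z_i) + c_d X_eq] /
    [sum_j (k+_j y_eq_j + k-_j) + c_d]; algebraically identical to the
    equilibrium count X_eq for every system class.
    """
    if system.n_buffers == 0 and not system.geometry.has_diffusion:
        raise UnsupportedSystemError(
            "mu is undefined without buffers or diffusion"
        )
    eq = equilibrium_state(system)
    rates = stochastic_rates(system)
    Z = eq.Z
    num = rates.c_d * eq.X
    for j, buf in enumerate(system.buffers):
        others = float(Z.sum() - Z[j])
        num += buf.k_minus * (eq.X_T - others)
    return num / _rate_sum(system)


def noise_params(system: SystemSpec) -> NoiseParams:
    """The full OU-surrogate triplet (mu, tau, sigma) for a system."""
    return NoiseParams(
        mu=mu_theory(system), tau=tau_theory(system), sigma=sigma_theory(system)
    )
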