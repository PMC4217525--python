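"""Stochastic engines for free-calcium copy-number trajectories.

Four engines of decreasing exactness and cost:

``ssa_simulate``
    Gillespie's direct-method stochastic simulation algorithm — exact
    sampling of the chemical master equation (jump paths).
``cle_simulate``
    Chemical Langevin equation integrated by Euler-Maruyama; one Gaussian
    increment per reaction channel, variance = propensity x dt.
``cle_eba_simulate``
    The Langevin equation reduced by the excess buffer approximation (free
    buffer pinned at equilibrium); for a single buffer this is a scalar SDE
    with state-dependent volatility, one step from an OU process.
``oup_simulate``
    The Ornstein-Uhlenbeck surrogate itself, parameterized by (mu, tau,
    sigma), with either Euler-Maruyama or the exact discretization.

All engines take an integer seed and are reproducible run-to-run within
this implementation.  Langevin engines clamp propensity arguments at zero
inside square roots and species at zero after each step; clamp events are
counted in ``Trajectory.meta['n_clamped']``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .chemistry import (
    SystemSpec,
    concentration_to_count,
    equilibrium_state,
    stochastic_rates,
)
from .noise_theory import NoiseParams, sigma_theory

logger = logging.getLogger(__name__)

DEFAULT_DT = 0.01  # ms; shared sampling/integration step


def _species_columns(system: SystemSpec) -> tuple[str, ...]:
    cols = ["X"]
    for b in system.buffers:
        cols += [f"Y_{b.name}", f"Z_{b.name}"]
    return tuple(cols)


@dataclass
class Trajectory:
    """Uniformly sampled time series of species counts (or a scalar signal).

    ``values`` has shape (n,) for a scalar series or (n, k) for k species
    named in ``columns``.  ``meta`` records engine, seed and parameters.
    """

    dt: float
    values: np.ndarray
    t0: float = 0.0
    columns: tuple[str, ...] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        self.values = np.asarray(self.values)

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self))

    def component(self, name: str) -> "Trajectory":
        """Extract one species as a scalar Trajectory."""
        if self.values.ndim == 1:
            if self.columns in (None, (name,)):
                return self
            raise KeyError(name)
        if self.columns is None or name not in self.columns:
            raise KeyError(name)
        idx = self.columns.index(name)
        return Trajectory(
            dt=self.dt,
            values=self.values[:, idx].copy(),
            t0=self.t0,
            columns=(name,),
            meta=dict(self.meta),
        )


@dataclass
class JumpPath:
    """Event-driven sample path from the SSA.

    ``times[0] == 0`` holds the initial state; ``times[1:]`` are the strictly
    increasing reaction times.  ``states`` rows are integer copy-number
    vectors (X, then Y/Z per buffer) aligned with ``times``.
    """

    times: np.ndarray
    states: np.ndarray
    columns: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    @property
    def t_end(self) -> float:
        """Nominal end of the simulated horizon (>= last event time)."""
        return self.meta.get("t_end", float(self.times[-1]))

    @property
    def n_events(self) -> int:
        return len(self.times) - 1


# ---------------------------------------------------------------------------
# Exact SSA (direct method)
# ---------------------------------------------------------------------------

def _initial_counts(system: SystemSpec, x0: float | None):
    """Integer initial state: perturbed calcium, buffers at equilibrium."""
    eq = equilibrium_state(system)
    x0_conc = system.ca_eq if x0 is None else x0
    if x0_conc < 0:
        raise ValueError(f"x0 must be >= 0, got {x0_conc}")
    X = float(np.rint(concentration_to_count(x0_conc, system.volume)))
    Y = np.rint(eq.Y).astype(float)
    Z = np.rint(eq.Z).astype(float)
    return X, Y, Z, eq


def ssa_simulate(
    system: SystemSpec,
    t_end: float,
    seed: int | None = None,
    x0: float | None = None,
    max_events: int = 50_000_000,
) -> JumpPath:
    """Exact Gillespie direct-method simulation of the buffer network.

    Reaction channels: binding (rate c+_j X Y_j) and unbinding (c-_j Z_j)
    per buffer; with diffusion, efflux (c_d X) and constant-pool influx
    (c_d X_eq, with the real-valued equilibrium count).  Waiting times are
    exponential with the total propensity; one channel fires per event.

    Starts from the integer-rounded equilibrium state (free calcium
    overridden by ``x0`` in uM if given).  If the total propensity reaches
    zero the path terminates early at the absorbing state with a warning.
    """
    if t_end <= 0:
        raise ValueError(f"t_end must be > 0, got {t_end}")
    rng = np.random.default_rng(seed)
    X0, Y0, Z0, eq = _initial_counts(system, x0)
    rates = stochastic_rates(system)
    M = system.n_buffers
    cp = [float(c) for c in rates.c_plus]
    cm = [float(c) for c in rates.c_minus]
    cd = float(rates.c_d)
    diffusion = cd > 0.0
    a_in = cd * eq.X  # constant-pool influx propensity (real-valued)

    X = int(X0)
    Y = [int(v) for v in Y0]
    Z = [int(v) for v in Z0]
    n_cols = 1 + 2 * M
    cap = 1 << 16
    times = np.empty(cap, dtype=np.float64)
    states = np.empty((cap, n_cols), dtype=np.int64)

    def _record(i: int) -> None:
        times[i] = t
        states[i, 0] = X
        for j in range(M):
            states[i, 1 + 2 * j] = Y[j]
            states[i, 2 + 2 * j] = Z[j]

    t = 0.0
    n = 0
    _record(0)
    n = 1

    BLOCK = 1 << 14
    exps = rng.exponential(1.0, BLOCK).tolist()
    usel = rng.random(BLOCK).tolist()
    ri = 0
    absorbed = False
    n_events = 0

    while n_events < max_events:
        atot = 0.0
        for j in range(M):
            atot += cp[j] * X * Y[j] + cm[j] * Z[j]
        if diffusion:
            atot += cd * X + a_in
        if atot <= 0.0:
            absorbed = True
            logger.warning(
                "SSA reached an absorbing state at t=%.6g ms; path terminated",
                t,
            )
            break
        if ri >= BLOCK:
            exps = rng.exponential(1.0, BLOCK).tolist()
            usel = rng.random(BLOCK).tolist()
            ri = 0
        t_next = t + exps[ri] / atot
        if t_next > t_end:
            break
        t = t_next
        r = usel[ri] * atot
        ri += 1
        # channel selection by cumulative propensity
        fired = False
        for j in range(M):
            a = cp[j] * X * Y[j]
            if r < a:
                X -= 1
                Y[j] -= 1
                Z[j] += 1
                fired = True
                break
            r -= a
            a = cm[j] * Z[j]
            if r < a:
                X += 1
                Y[j] += 1
                Z[j] -= 1
                fired = True
                break
            r -= a
        if not fired:
            if diffusion:
                if r < cd * X:
                    X -= 1  # efflux
                else:
                    X += 1  # constant-pool influx
            else:
                # roundoff fell past the last channel: fire the final
                # unbinding reaction (probability ~machine epsilon)
                X += 1
                Y[M - 1] += 1
                Z[M - 1] -= 1
        if n == cap:
            cap *= 2
            times = np.concatenate([times, np.empty_like(times)])
            states = np.concatenate([states, np.empty_like(states)])
        _record(n)
        n += 1
        n_events += 1

    meta = {
        "engine": "ssa",
        "seed": seed,
        "t_end": t_end,
        "n_events": n_events,
        "absorbed": absorbed,
        "volume_fl": system.volume,
    }
    return JumpPath(
        times=times[:n].copy(),
        states=states[:n].copy(),
        columns=_species_columns(system),
        meta=meta,
    )


def resample_path(
    path: JumpPath, dt: float = DEFAULT_DT, kind: str = "linear"
) -> Trajectory:
    """Sample a jump path on a uniform grid spanning [0, last event time].

    ``kind='linear'`` interpolates linearly between surrounding event
    states (the convention used throughout for downstream statistics);
    ``kind='hold'`` uses the exact zero-order-hold path, which is the
    measure-theoretically correct choice for master-equation comparisons.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if len(path.times) == 0:
        raise ValueError("empty jump path")
    t_last = float(path.times[-1])
    n = int(math.floor(t_last / dt)) + 1
    grid = dt * np.arange(n)
    if kind == "linear":
        vals = np.column_stack(
            [
                np.interp(grid, path.times, path.states[:, c])
                for c in range(path.states.shape[1])
            ]
        )
    elif kind == "hold":
        idx = np.searchsorted(path.times, grid, side="right") - 1
        vals = path.states[idx].astype(float)
    else:
        raise ValueError(f"unknown interpolation kind {kind!r}")
    if vals.shape[1] == 1:
        vals = vals[:, 0]
    meta = dict(path.meta)
    meta["interpolation"] = kind
    return Trajectory(dt=dt, values=vals, columns=path.columns, meta=meta)


# ---------------------------------------------------------------------------
# Chemical Langevin equation (full)
# ---------------------------------------------------------------------------

def cle_simulate(
    system: SystemSpec,
    t_end: float,
    dt: float = DEFAULT_DT,
    seed: int | None = None,
    x0: float | None = None,
    noise: bool = True,
) -> Trajectory:
    """Euler-Maruyama integration of the chemical Langevin equation.

    Every reaction channel contributes drift (propensity x dt) and one
    Gaussian increment with variance propensity x dt, signed by its
    stoichiometry, to all species it touches; X and the Z_j evolve jointly
    and Y_j = B_T,j - Z_j.  Propensity arguments are clamped at zero before
    the square root and species at zero after each step (clamps counted).

    With ``noise=False`` this is exactly the deterministic mass-action ODE
    integrated by the Euler scheme at the same step.
    """
    _check_grid(dt, t_end)
    rng = np.random.default_rng(seed)
    X0, Y0, Z0, eq = _initial_counts(system, x0)
    rates = stochastic_rates(system)
    M = system.n_buffers
    cp = [float(c) for c in rates.c_plus]
    cm = [float(c) for c in rates.c_minus]
    cd = float(rates.c_d)
    diffusion = cd > 0.0
    a_in = cd * eq.X
    BT = [float(Y0[j] + Z0[j]) for j in range(M)]

    n_steps = int(math.floor(t_end / dt))
    n_ch = 2 * M + (2 if diffusion else 0)
    normals = rng.standard_normal((n_steps, max(n_ch, 1))) if noise else None
    sdt = math.sqrt(dt)

    X = X0
    Z = [float(z) for z in Z0]
    vals = np.empty((n_steps + 1, 1 + 2 * M))
    vals[0, 0] = X
    for j in range(M):
        vals[0, 1 + 2 * j] = BT[j] - Z[j]
        vals[0, 2 + 2 * j] = Z[j]
    n_clamped = 0

    for k in range(n_steps):
        if noise:
            row = normals[k]
        dX = 0.0
        for j in range(M):
            Yj = BT[j] - Z[j]
            ab = cp[j] * X * Yj
            if ab < 0.0:
                ab = 0.0
            au = cm[j] * Z[j]
            if au < 0.0:
                au = 0.0
            inc = (au - ab) * dt
            if noise:
                inc += (
                    math.sqrt(au) * row[2 * j + 1] - math.sqrt(ab) * row[2 * j]
                ) * sdt
            dX += inc
            Z[j] -= inc
        if diffusion:
            ae = cd * X
            if ae < 0.0:
                ae = 0.0
            inc = (a_in - ae) * dt
            if noise:
                inc += (
                    math.sqrt(a_in) * row[2 * M + 1]
                    - math.sqrt(ae) * row[2 * M]
                ) * sdt
            dX += inc
        X += dX
        if X < 0.0:
            X = 0.0
            n_clamped += 1
        for j in range(M):
            if Z[j] < 0.0:
                Z[j] = 0.0
                n_clamped += 1
        vals[k + 1, 0] = X
        for j in range(M):
            vals[k + 1, 1 + 2 * j] = BT[j] - Z[j]
            vals[k + 1, 2 + 2 * j] = Z[j]

    if n_clamped:
        logger.warning("CLE clamped %d negative excursions at zero", n_clamped)
    meta = {
        "engine": "cle",
        "seed": seed,
        "dt": dt,
        "t_end": t_end,
        "n_clamped": n_clamped,
        "volume_fl": system.volume,
    }
    return Trajectory(
        dt=dt, values=vals, columns=_species_columns(system), meta=meta
    )


# ---------------------------------------------------------------------------
# EBA-reduced Langevin
# ---------------------------------------------------------------------------

def cle_eba_simulate(
    system: SystemSpec,
    t_end: float,
    dt: float = DEFAULT_DT,
    seed: int | None = None,
    x0: float | None = None,
    noise: bool = True,
    freeze_sigma: bool = False,
) -> Trajectory:
    """Langevin dynamics under the excess buffer approximation.

    Free buffer is pinned at its equilibrium count.  For a single buffer the
    scalar form is integrated: bound calcium is eliminated via Z = X_T - X
    and the two channel noises are combined into one Wiener increment with
    the time-dependent volatility sigma_t = sqrt(c+ X Y_eq + c- Z [+ c_d
    (X + X_eq)]).  With ``freeze_sigma=True`` the volatility is pinned at
    its equilibrium value, which makes the engine an Euler-Maruyama OU
    integrator.  For M > 1 each Z_j keeps its own reduced dynamics with
    per-channel noise shared with X.
    """
    _check_grid(dt, t_end)
    if system.n_buffers == 0:
        raise ValueError("EBA engine requires at least one buffer")
    if system.n_buffers == 1:
        return _cle_eba_single(system, t_end, dt, seed, x0, noise, freeze_sigma)
    return _cle_eba_multi(system, t_end, dt, seed, x0, noise, freeze_sigma)


def _cle_eba_single(system, t_end, dt, seed, x0, noise, freeze_sigma):
    rng = np.random.default_rng(seed)
    X0, Y0, Z0, eq = _initial_counts(system, x0)
    rates = stochastic_rates(system)
    cp = float(rates.c_plus[0])
    cm = float(rates.c_minus[0])
    cd = float(rates.c_d)
    diffusion = cd > 0.0
    Yeq = float(eq.Y[0])  # pinned free buffer (real-valued counts)
    Xeq = eq.X
    C1 = cp * Yeq + cm
    R = C1 + cd  # total linear relaxation rate
    # Equilibrium total calcium; with Y pinned and Z eliminated as X_T - X
    # the reduced drift's fixed point c-/C1 X_T equals X_eq (detailed balance)
    XT = eq.X_T
    Xstar = (cm * XT + cd * Xeq) / R
    sigma_eq = sigma_theory(system)

    n_steps = int(math.floor(t_end / dt))
    normals = rng.standard_normal(n_steps) if noise else None
    sdt = math.sqrt(dt)
    vals = np.empty(n_steps + 1)
    vals[0] = X = X0
    n_clamped = 0
    for k in range(n_steps):
        dX = -R * (X - Xstar) * dt
        if noise:
            if freeze_sigma:
                s2 = sigma_eq * sigma_eq
            else:
                Zc = XT - X
                s2 = 0.0
                a = cp * X * Yeq
                if a > 0.0:
                    s2 += a
                a = cm * Zc
                if a > 0.0:
                    s2 += a
                if diffusion:
                    a = X if X > 0.0 else 0.0
                    s2 += cd * (a + Xeq)
            dX += math.sqrt(s2) * sdt * normals[k]
        X += dX
        if X < 0.0:
            X = 0.0
            n_clamped += 1
        vals[k + 1] = X
    if n_clamped:
        logger.warning(
            "CLE-EBA clamped %d negative excursions at zero", n_clamped
        )
    meta = {
        "engine": "cle-eba",
        "seed": seed,
        "dt": dt,
        "t_end": t_end,
        "n_clamped": n_clamped,
        "freeze_sigma": freeze_sigma,
        "volume_fl": system.volume,
    }
    return Trajectory(dt=dt, values=vals, columns=("X",), meta=meta)


def _cle_eba_multi(system, t_end, dt, seed, x0, noise, freeze_sigma):
    rng = np.random.default_rng(seed)
    X0, Y0, Z0, eq = _initial_counts(system, x0)
    rates = stochastic_rates(system)
    M = system.n_buffers
    cp = [float(c) for c in rates.c_plus]
    cm = [float(c) for c in rates.c_minus]
    cd = float(rates.c_d)
    diffusion = cd > 0.0
    a_in = cd * eq.X
    Yeq = [float(v) for v in eq.Y]  # pinned
    Zeq = [float(v) for v in eq.Z]
    Xeq = eq.X

    n_steps = int(math.floor(t_end / dt))
    n_ch = 2 * M + (2 if diffusion else 0)
    normals = rng.standard_normal((n_steps, n_ch)) if noise else None
    sdt = math.sqrt(dt)
    X = X0
    Z = [float(z) for z in Z0]
    vals = np.empty((n_steps + 1, 1 + M))
    vals[0, 0] = X
    vals[0, 1:] = Z
    n_clamped = 0
    for k in range(n_steps):
        if noise:
            row = normals[k]
        dX = 0.0
        for j in range(M):
            ab = cp[j] * X * Yeq[j]
            if ab < 0.0:
                ab = 0.0
            au = cm[j] * Z[j]
            if au < 0.0:
                au = 0.0
            if noise and freeze_sigma:
                ab_n = cp[j] * Xeq * Yeq[j]
                au_n = cm[j] * Zeq[j]
            else:
                ab_n, au_n = ab, au
            inc = (au - ab) * dt
            if noise:
                inc += (
                    math.sqrt(au_n) * row[2 * j + 1]
                    - math.sqrt(ab_n) * row[2 * j]
                ) * sdt
            dX += inc
            Z[j] -= inc
        if diffusion:
            ae = cd * X
            if ae < 0.0:
                ae = 0.0
            inc = (a_in - ae) * dt
            if noise:
                ae_n = cd * Xeq if freeze_sigma else ae
                inc += (
                    math.sqrt(a_in) * row[2 * M + 1]
                    - math.sqrt(ae_n) * row[2 * M]
                ) * sdt
            dX += inc
        X += dX
        if X < 0.0:
            X = 0.0
            n_clamped += 1
        for j in range(M):
            if Z[j] < 0.0:
                Z[j] = 0.0
                n_clamped += 1
        vals[k + 1, 0] = X
        vals[k + 1, 1:] = Z
    if n_clamped:
        logger.warning(
            "CLE-EBA clamped %d negative excursions at zero", n_clamped
        )
    cols = ("X",) + tuple(f"Z_{b.name}" for b in system.buffers)
    meta = {
        "engine": "cle-eba",
        "seed": seed,
        "dt": dt,
        "t_end": t_end,
        "n_clamped": n_clamped,
        "freeze_sigma": freeze_sigma,
        "volume_fl": system.volume,
    }
    return Trajectory(dt=dt, values=vals, columns=cols, meta=meta)


# ---------------------------------------------------------------------------
# Ornstein-Uhlenbeck surrogate
# ---------------------------------------------------------------------------

def oup_simulate(
    params: NoiseParams,
    x0: float,
    t_end: float,
    dt: float = DEFAULT_DT,
    seed: int | None = None,
    exact: bool = False,
) -> Trajectory:
    """Simulate dX = -(X - mu)/tau dt + sigma dW.

    Default is the Euler-Maruyama update (matching the step size used by
    the Langevin engines).  With ``exact=True`` the exact AR(1)
    discretization is used: X <- mu + (X-mu) e^(-dt/tau) +
    sigma sqrt(tau (1 - e^(-2 dt/tau)) / 2) N(0,1), which is unbiased at
    any step size.  Both recursions are evaluated as a linear filter.
    """
    _check_grid(dt, t_end)
    mu, tau, sigma = params.mu, params.tau, params.sigma
    n_steps = int(math.floor(t_end / dt))
    rng = np.random.default_rng(seed)
    shocks = rng.standard_normal(n_steps) if sigma > 0 else np.zeros(n_steps)
    if exact:
        phi = math.exp(-dt / tau)
        scale = sigma * math.sqrt(tau * (1.0 - phi * phi) / 2.0)
    else:
        phi = 1.0 - dt / tau
        scale = sigma * math.sqrt(dt)
    u = mu * (1.0 - phi) + scale * shocks
    out, _ = lfilter([1.0], [1.0, -phi], u, zi=np.array([phi * x0]))
    vals = np.concatenate([[x0], out])
    meta = {
        "engine": "oup",
        "seed": seed,
        "dt": dt,
        "t_end": t_end,
        "exact": exact,
        "mu": mu,
        "tau": tau,
        "sigma": sigma,
    }
    return Trajectory(dt=dt, values=vals, columns=("X",), meta=meta)


def _check_grid(dt: float, t_end: float) -> None:
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if t_end <= 0:
        raise ValueError(f"t_end must be > 0, got {t_end}")
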