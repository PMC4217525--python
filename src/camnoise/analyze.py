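"""Statistical characterization of noise trajectories.

Provides the sample autocorrelation function, the log-linear estimator of
the noise autocorrelation time tau, exponential relaxation fits (the
fluctuation-dissipation counterpart tau-hat), summary statistics, and an
exact chemical-master-equation stationary solver for small single-buffer
systems used as an independent oracle in tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import null_space
from statsmodels.tsa.stattools import acf as _sm_acf

from .chemistry import SystemSpec, equilibrium_state, stochastic_rates
from .errors import (
    CapacityError,
    DegenerateInputError,
    EstimationError,
    UnsupportedSystemError,
)
from .simulate import JumpPath, Trajectory

#: ACF values below this threshold are excluded from the log-linear tau fit.
ACF_FIT_THRESHOLD = 0.05


@dataclass(frozen=True)
class ACF:
    """Normalized sample autocorrelation on a uniform lag grid (ms)."""

    lags: np.ndarray
    values: np.ndarray


@dataclass(frozen=True)
class SummaryStats:
    """Mean, standard deviation and estimated autocorrelation time."""

    mean: float
    sd: float
    tau_hat: float | None
    n_samples: int


def _scalar_series(traj: Trajectory) -> np.ndarray:
    if traj.values.ndim == 1:
        return np.asarray(traj.values, dtype=float)
    return np.asarray(traj.component("X").values, dtype=float)


def autocorrelation(traj: Trajectory, max_lag: float) -> ACF:
    """Mean-removed, biased (1/N) sample autocorrelation up to ``max_lag`` ms.

    The biased normalization keeps the estimate positive semidefinite; the
    result is normalized to 1 at lag zero.  A multi-species trajectory is
    reduced to its free-calcium component.
    """
    x = _scalar_series(traj)
    n_lags = int(round(max_lag / traj.dt))
    if n_lags < 1:
        raise ValueError("max_lag must cover at least one sampling interval")
    if len(x) < 10 * n_lags:
        raise ValueError(
            f"series of length {len(x)} too short for max_lag={max_lag} ms "
            f"(need >= {10 * n_lags} samples)"
        )
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant series has no autocorrelation")
    vals = _sm_acf(x, nlags=n_lags, fft=True, adjusted=False)
    return ACF(lags=traj.dt * np.arange(n_lags + 1), values=vals)


def estimate_tau(acf: ACF) -> float:
    """Autocorrelation time from a log-linear fit to the ACF head.

    Fits an ordinary least-squares line to log(values) over the contiguous
    initial lag range where values exceed ``ACF_FIT_THRESHOLD`` and returns
    -1/slope.  Mono-exponential decay is assumed (the model class these
    processes belong to), which makes the estimator robust to tail noise.
    """
    vals = np.asarray(acf.values, dtype=float)
    below = np.nonzero(vals <= ACF_FIT_THRESHOLD)[0]
    head = int(below[0]) if below.size else len(vals)
    if head < 3:
        raise EstimationError(
            "fewer than 3 usable ACF lags above the fit threshold; "
            "use a smaller dt or a longer trajectory"
        )
    lags = np.asarray(acf.lags, dtype=float)[:head]
    slope, _ = np.polyfit(lags, np.log(vals[:head]), 1)
    if slope >= 0:
        raise EstimationError("non-decaying ACF head; tau is undefined")
    return -1.0 / slope


def fit_relaxation(traj: Trajectory, x_eq: float) -> float:
    """Relaxation time constant from a perturbed trajectory.

    Fits log|X_t - x_eq| by OLS over the initial window where the deviation
    exceeds 10% of its starting value; interior points on the wrong side of
    the asymptote are dropped.  Returns tau-hat = -1/slope (ms).
    """
    v = _scalar_series(traj)
    dev = v - x_eq
    s0 = dev[0]
    if s0 == 0:
        raise DegenerateInputError("trajectory starts at x_eq; nothing to fit")
    thresh = 0.1 * abs(s0)
    inside = np.nonzero(np.abs(dev) < thresh)[0]
    cut = int(inside[0]) if inside.size else len(dev)
    window = dev[:cut] * np.sign(s0)
    t = traj.t0 + traj.dt * np.arange(cut)
    usable = window > 0
    if usable.sum() < 5:
        raise EstimationError(
            f"only {int(usable.sum())} usable points in the relaxation window"
        )
    slope, _ = np.polyfit(t[usable], np.log(window[usable]), 1)
    if slope >= 0:
        raise EstimationError("no decay detected; tau-hat is undefined")
    return -1.0 / slope


def summary_stats(traj: Trajectory, max_lag: float | None = None) -> SummaryStats:
    """Sample mean, SD (N-1) and tau-hat of a trajectory.

    ``max_lag`` for the ACF defaults to one tenth of the trajectory span,
    capped at 1000 lags.  For a constant series sd = 0 and tau_hat = None.
    """
    x = _scalar_series(traj)
    n = len(x)
    if n < 100:
        raise ValueError(f"trajectory too short for summary stats (n={n})")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        return SummaryStats(mean=mean, sd=0.0, tau_hat=None, n_samples=n)
    if max_lag is None:
        max_lag = traj.dt * min((n - 1) // 10, 1000)
    tau_hat = estimate_tau(autocorrelation(traj, max_lag))
    return SummaryStats(mean=mean, sd=sd, tau_hat=tau_hat, n_samples=n)


# ---------------------------------------------------------------------------
# Chemical master equation oracle
# ---------------------------------------------------------------------------

def cme_stationary(
    system: SystemSpec,
    max_total: int = 200,
    max_buffer: int = 2000,
) -> pd.Series:
    """Exact stationary distribution of the free-calcium count.

    For a single-buffer system without diffusion the conservation laws
    reduce the state to X alone (Z = X_T - X, Y = B_T - Z), giving a finite
    birth-death chain on X in [max(0, X_T - B_T), X_T] with integer totals
    obtained by half-to-even rounding.  The distribution is the normalized
    null space of the (tridiagonal) generator.

    Returns a Series indexed by X with probabilities summing to 1.
    """
    if system.n_buffers != 1:
        raise UnsupportedSystemError("CME oracle supports exactly one buffer")
    if system.geometry.has_diffusion:
        raise UnsupportedSystemError(
            "CME oracle requires a closed voxel (no diffusion)"
        )
    eq = equilibrium_state(system)
    rates = stochastic_rates(system)
    cp = float(rates.c_plus[0])
    cm = float(rates.c_minus[0])
    XT = int(np.rint(eq.X + eq.Z[0]))
    BT = int(np.rint(eq.Y[0] + eq.Z[0]))
    if XT > max_total or BT > max_buffer:
        raise CapacityError(
            f"state space too large: X_T={XT} (max {max_total}), "
            f"B_T={BT} (max {max_buffer})"
        )
    lo = max(0, XT - BT)
    states = np.arange(lo, XT + 1)
    n = len(states)
    up = cm * (XT - states)            # X -> X+1 (unbinding)
    down = cp * states * (BT - XT + states)  # X -> X-1 (binding)
    Q = np.zeros((n, n))
    for i in range(n):
        if i + 1 < n:
            Q[i, i + 1] = up[i]
        if i - 1 >= 0:
            Q[i, i - 1] = down[i]
        Q[i, i] = -(up[i] * (i + 1 < n) + down[i] * (i > 0))
    ns = null_space(Q.T)
    if ns.shape[1] != 1:
        raise EstimationError("generator null space is not one-dimensional")
    pi = np.abs(ns[:, 0])
    pi /= pi.sum()
    return pd.Series(pi, index=states, name="P")


def occupancy_distribution(path: JumpPath, column: str = "X") -> pd.Series:
    """Sojourn-time-weighted occupancy of one species along a jump path.

    The exact empirical stationary histogram: each state is weighted by the
    time spent in it, including the final sojourn up to the path's nominal
    horizon.  Returns a probability Series indexed by count.
    """
    idx = path.columns.index(column)
    x = path.states[:, idx]
    bounds = np.append(path.times, path.t_end)
    durations = np.diff(bounds)
    total = durations.sum()
    if total <= 0:
        raise DegenerateInputError("jump path has zero duration")
    weights = np.bincount(x, weights=durations)
    support = np.nonzero(weights)[0]
    return pd.Series(
        weights[support] / total, index=support, name="occupancy"
    )


def total_variation(p: pd.Series, q: pd.Series) -> float:
    """Total-variation distance between two count distributions."""
    joined = pd.concat([p, q], axis=1).fillna(0.0)
    return 0.5 * float(np.abs(joined.iloc[:, 0] - joined.iloc[:, 1]).sum())
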