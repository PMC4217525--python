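"""Buffered calcium microdomains: species definitions, units, equilibria.

Unit system, fixed package-wide: concentrations in uM, time in ms, volume in
fl (1 fl = 1 um^3), length in um, bimolecular rates in uM^-1 ms^-1.  A
concentration of 1 uM in 1 fl corresponds to ``COUNTS_PER_UM_FL`` molecules
(Avogadro's number x 1e-21), so copy-number propensities reproduce the
deterministic mass-action fluxes exactly.

The central model is the reversible binding of free calcium to one or more
buffer species,

    Ca + B_j  <->  CaB_j        (on-rate k+_j, off-rate k-_j),

optionally with calcium exchange across the voxel boundary under a
constant-pool assumption (the surroundings stay at equilibrium).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .errors import UnknownBufferError

#: Molecule count of a 1 uM solute in 1 fl (N_A x 1e-21).
COUNTS_PER_UM_FL = 602.214076


def dissociation_constant(k_plus: float, k_minus: float) -> float:
    """Equilibrium dissociation constant K_D = k-/k+ in uM.

    Raises ValueError for non-positive on-rate or negative off-rate.
    """
    if k_plus <= 0:
        raise ValueError(f"k_plus must be > 0, got {k_plus}")
    if k_minus < 0:
        raise ValueError(f"k_minus must be >= 0, got {k_minus}")
    return k_minus / k_plus


def concentration_to_count(conc: float, volume: float) -> float:
    """Convert a concentration (uM) in a volume (fl) to a real-valued count.

    100 nM in 1 fl gives ~60.2 ions.  Callers that need integer copy numbers
    (SSA initial states) round half-to-even.
    """
    if conc < 0:
        raise ValueError(f"concentration must be >= 0, got {conc}")
    if volume <= 0:
        raise ValueError(f"volume must be > 0, got {volume}")
    return conc * volume * COUNTS_PER_UM_FL


def count_to_concentration(count: float, volume: float) -> float:
    """Inverse of :func:`concentration_to_count` (count -> uM)."""
    if volume <= 0:
        raise ValueError(f"volume must be > 0, got {volume}")
    return count / (volume * COUNTS_PER_UM_FL)


@dataclass(frozen=True)
class BufferSpec:
    """One calcium buffer species.

    Parameters
    ----------
    name : str
        Label, unique within a system.
    B_T : float
        Total buffer concentration (uM).
    k_plus : float
        Association rate constant (uM^-1 ms^-1).
    k_minus : float
        Dissociation rate constant (ms^-1).

    ``K_D`` is always derived as ``k_minus / k_plus`` and never stored, so
    the triplet can never become inconsistent with a rounded table value.
    """

    name: str
    B_T: float
    k_plus: float
    k_minus: float

    def __post_init__(self) -> None:
        if self.B_T <= 0:
            raise ValueError(f"B_T must be > 0, got {self.B_T}")
        dissociation_constant(self.k_plus, self.k_minus)  # validates rates

    @property
    def K_D(self) -> float:
        """Dissociation constant k-/k+ (uM)."""
        return dissociation_constant(self.k_plus, self.k_minus)

    def bound_at(self, ca: float) -> float:
        """Equilibrium bound-complex concentration at free calcium ``ca`` (uM).

        [CaB] = B_T / (1 + K_D/ca), written as B_T * ca/(ca + K_D) so it is
        well defined at ca = 0.
        """
        if ca < 0:
            raise ValueError(f"ca must be >= 0, got {ca}")
        if ca == 0 and self.K_D == 0:
            return 0.0
        return self.B_T * ca / (ca + self.K_D)


@dataclass(frozen=True)
class DomainGeometry:
    """Cubic reaction voxel: volume in fl, optional calcium diffusion.

    ``edge_length`` is V^(1/3) in um (1 fl = 1 um^3).  ``D_Ca`` is the
    calcium diffusion constant in um^2/ms; ``None`` disables diffusion.
    """

    volume: float
    D_Ca: float | None = None

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError(f"volume must be > 0, got {self.volume}")
        if self.D_Ca is not None and self.D_Ca <= 0:
            raise ValueError(f"D_Ca must be > 0 if given, got {self.D_Ca}")

    @property
    def edge_length(self) -> float:
        return self.volume ** (1.0 / 3.0)

    @property
    def has_diffusion(self) -> bool:
        return self.D_Ca is not None


@dataclass(frozen=True)
class SystemSpec:
    """Full microdomain definition: buffers, geometry, equilibrium calcium."""

    buffers: tuple[BufferSpec, ...]
    geometry: DomainGeometry
    ca_eq: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "buffers", tuple(self.buffers))
        if self.ca_eq <= 0:
            raise ValueError(f"ca_eq must be > 0, got {self.ca_eq}")
        names = [b.name for b in self.buffers]
        if len(set(names)) != len(names):
            raise ValueError(f"buffer names must be unique, got {names}")

    @property
    def n_buffers(self) -> int:
        return len(self.buffers)

    @property
    def volume(self) -> float:
        return self.geometry.volume


def make_system(
    buffers: BufferSpec | list[BufferSpec] | tuple[BufferSpec, ...],
    volume: float,
    ca_eq: float,
    D_Ca: float | None = None,
) -> SystemSpec:
    """Convenience constructor for :class:`SystemSpec`."""
    if isinstance(buffers, BufferSpec):
        buffers = (buffers,)
    return SystemSpec(tuple(buffers), DomainGeometry(volume, D_Ca), ca_eq)


@dataclass(frozen=True)
class EquilibriumState:
    """Equilibrium concentrations (uM) and real-valued copy numbers.

    Per-buffer arrays are ordered as in the originating system.  Mass
    conservation (y + z = B_T per buffer, x_T = x + sum z) holds exactly as
    constructed.  Counts are real-valued; round half-to-even where integer
    copy numbers are needed.
    """

    x_eq: float
    y_eq: np.ndarray
    z_eq: np.ndarray
    x_T: float
    volume: float

    # -- copy numbers -------------------------------------------------
    @property
    def X(self) -> float:
        """Free calcium count at equilibrium."""
        return concentration_to_count(self.x_eq, self.volume)

    @property
    def Y(self) -> np.ndarray:
        """Free buffer counts at equilibrium."""
        return self.y_eq * self.volume * COUNTS_PER_UM_FL

    @property
    def Z(self) -> np.ndarray:
        """Bound-complex counts at equilibrium."""
        return self.z_eq * self.volume * COUNTS_PER_UM_FL

    @property
    def X_T(self) -> float:
        """Total calcium count."""
        return self.x_T * self.volume * COUNTS_PER_UM_FL

    @property
    def B_T(self) -> np.ndarray:
        """Total buffer counts."""
        return (self.y_eq + self.z_eq) * self.volume * COUNTS_PER_UM_FL


def equilibrium_state(system: SystemSpec) -> EquilibriumState:
    """Equilibrium concentrations of all species given the free calcium level.

    For each buffer, [CaB] = B_T / (1 + K_D / ca_eq); free buffer and total
    calcium follow from mass conservation.
    """
    x = system.ca_eq
    z = np.array([b.bound_at(x) for b in system.buffers], dtype=float)
    y = np.array([b.B_T for b in system.buffers], dtype=float) - z
    return EquilibriumState(
        x_eq=x, y_eq=y, z_eq=z, x_T=x + float(z.sum()), volume=system.volume
    )


def totals_to_equilibrium(
    x_T: float,
    buffers: list[BufferSpec] | tuple[BufferSpec, ...],
    volume: float = 1.0,
) -> EquilibriumState:
    """Free-calcium equilibrium from a *total* calcium concentration.

    Solves x + sum_j B_T,j x/(x + K_D,j) = x_T for x on [0, x_T] by bracketed
    root search; the left side is strictly increasing in x so the bracket is
    guaranteed.  Relative tolerance ~1e-15.
    """
    if x_T < 0:
        raise ValueError(f"x_T must be >= 0, got {x_T}")
    buffers = tuple(buffers)
    zeros = np.zeros(len(buffers))

    def _state(x_eq: float) -> EquilibriumState:
        z = np.array([b.bound_at(x_eq) for b in buffers], dtype=float)
        y = np.array([b.B_T for b in buffers], dtype=float) - z
        return EquilibriumState(x_eq, y, z, x_eq + float(z.sum()), volume)

    if x_T == 0 or not buffers:
        z = zeros
        y = np.array([b.B_T for b in buffers], dtype=float)
        return EquilibriumState(0.0 if x_T == 0 else x_T, y, z, x_T, volume)

    def f(x: float) -> float:
        return x + sum(b.bound_at(x) for b in buffers) - x_T

    # f(0) = -x_T < 0, f(x_T) = sum z >= 0; strict monotonicity => unique root
    if f(x_T) <= 0:
        return _state(x_T)
    x_eq = brentq(f, 0.0, x_T, xtol=1e-300, rtol=8.9e-16, maxiter=200)
    return _state(float(x_eq))


@dataclass(frozen=True)
class StochasticRates:
    """Copy-number reaction rates: c+ (per molecule pair), c- and c_d (ms^-1).

    ``c_plus[j] = k_plus[j] / (COUNTS_PER_UM_FL * V)`` so the binding
    propensity c+ X Y with counts matches the deterministic flux k+ x y.
    Monomolecular rates are volume-free: ``c_minus[j] = k_minus[j]``, and the
    diffusion hop rate is ``c_d = D / L^2`` (zero when diffusion is off).
    """

    c_plus: np.ndarray
    c_minus: np.ndarray
    c_d: float


def stochastic_rates(system: SystemSpec) -> StochasticRates:
    """Deterministic -> stochastic rate conversion for a system."""
    v = system.volume
    c_plus = np.array(
        [b.k_plus / (COUNTS_PER_UM_FL * v) for b in system.buffers], dtype=float
    )
    c_minus = np.array([b.k_minus for b in system.buffers], dtype=float)
    geom = system.geometry
    c_d = geom.D_Ca / geom.edge_length**2 if geom.has_diffusion else 0.0
    return StochasticRates(c_plus=c_plus, c_minus=c_minus, c_d=c_d)


# ---------------------------------------------------------------------------
# Fixture table and config files
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def load_buffer_table() -> pd.DataFrame:
    """The shipped kinetics table of physiological and artificial buffers.

    Columns: name, B_T_uM, k_plus_per_uM_ms, k_minus_per_ms, cv, reference.
    The cv column is metadata only and is never recomputed.
    """
    with resources.files("camnoise.data").joinpath("buffers.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"cv": str})


def buffer_from_table(name: str) -> BufferSpec:
    """Look up a buffer by name (case-insensitive) in the shipped table.

    K_D is derived from the rate constants, never read from a table column.
    """
    table = load_buffer_table()
    match = table[table["name"].str.lower() == name.lower()]
    if match.empty:
        available = ", ".join(table["name"])
        raise UnknownBufferError(
            f"unknown buffer {name!r}; available fixtures: {available}"
        )
    row = match.iloc[0]
    return BufferSpec(
        name=str(row["name"]),
        B_T=float(row["B_T_uM"]),
        k_plus=float(row["k_plus_per_uM_ms"]),
        k_minus=float(row["k_minus_per_ms"]),
    )


def load_system(path: str | Path) -> SystemSpec:
    """Read a system definition from a YAML/JSON config file.

    Schema::

        buffers:                  # list; each item a table name or a mapping
          - CaM
          - {name: mybuf, B_T_uM: 50, k_plus: 0.1, k_minus: 0.05}
        volume_fl: 0.125
        ca_eq_uM: 0.1
        D_Ca_um2_per_ms: 0.2      # optional; omit to disable diffusion
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    buffers = []
    for item in cfg.get("buffers", []):
        if isinstance(item, str):
            buffers.append(buffer_from_table(item))
        else:
            buffers.append(
                BufferSpec(
                    name=str(item.get("name", f"buffer{len(buffers) + 1}")),
                    B_T=float(item["B_T_uM"]),
                    k_plus=float(item["k_plus"]),
                    k_minus=float(item["k_minus"]),
                )
            )
    return make_system(
        buffers,
        volume=float(cfg["volume_fl"]),
        ca_eq=float(cfg["ca_eq_uM"]),
        D_Ca=(
            float(cfg["D_Ca_um2_per_ms"])
            if cfg.get("D_Ca_um2_per_ms") is not None
            else None
        ),
    )
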