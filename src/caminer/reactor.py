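"""Pressurized batch CO2-absorption analytics and forward simulator.

A closed stirred vessel holds a carbonate solvent under a CO2/N2 headspace.
Only CO2 dissolves, so the headspace pressure drop maps one-to-one onto
absorbed moles by the ideal-gas law: n_abs(t) = (P0 - P(t)) * V_head / (R*T).
From the absorbed-CO2 series the run is summarized by the initial absorption
rate (slope of the early linear segment), the plateau time, the productivity
(absorbed CO2 per liter of solvent per minute up to the plateau), and the
removal efficiency (absorbed fraction of the initial CO2 inventory).

The forward simulator is a pseudo-first-order approach to a fixed
equilibrium CO2 partial pressure with a multiplicative enzymatic enhancement
of the volumetric mass-transfer coefficient kLa. It exists to exercise the
inverse metrics, not to claim process fidelity.

Internally: pressures absolute Pa, temperature K, time minutes, volumes L.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.constants import R as GAS_CONSTANT  # J/(mol*K)
from scipy.integrate import solve_ivp

__all__ = [
    "ReactorConfig",
    "PressureSeries",
    "AbsorptionMetrics",
    "ForwardParams",
    "gas_inventory",
    "absorbed_from_pressure",
    "initial_absorption_rate",
    "plateau_and_productivity",
    "removal_efficiency",
    "simulate_pressure",
    "analyze",
    "bar_to_pa",
    "celsius_to_kelvin",
]


def bar_to_pa(p_bar: float) -> float:
    return p_bar * 1e5


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + 273.15


@dataclass(frozen=True)
class ReactorConfig:
    """Vessel geometry and initial charge.

    Defaults follow the study rig: 150 mL vessel with 50 mL solvent,
    pressurized to 7 bar (absolute) with a 20:80 v/v CO2:N2 mixture.
    ``vapor_pressure_offset`` (Pa) can subtract a constant solvent vapor
    contribution; it defaults to zero (total-pressure-drop mass balance).
    """

    temperature: float  # K
    total_volume: float = 0.150  # L
    liquid_volume: float = 0.050  # L
    initial_pressure: float = 7e5  # Pa absolute
    co2_fraction: float = 0.20
    vapor_pressure_offset: float = 0.0

    def __post_init__(self) -> None:
        if not self.liquid_volume < self.total_volume:
            raise ValueError("liquid volume must be below total volume")
        if not (0.0 < self.co2_fraction <= 1.0):
            raise ValueError("CO2 fraction must be in (0, 1]")
        if not self.temperature > 273.0:
            raise ValueError("temperature must exceed 273 K")
        if self.initial_pressure <= 0:
            raise ValueError("initial pressure must be positive")

    @property
    def headspace_volume(self) -> float:
        return self.total_volume - self.liquid_volume


@dataclass(frozen=True)
class PressureSeries:
    """Total absolute pressure (Pa) against time (min), ascending."""

    time: np.ndarray
    pressure: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        p = np.asarray(self.pressure, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "pressure", p)
        if t.size != p.size or t.size < 2:
            raise ValueError("pressure series needs >= 2 matched points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")
        if np.any(p <= 0):
            raise ValueError("pressures must be positive")


@dataclass(frozen=True)
class AbsorptionMetrics:
    initial_rate: float  # mmol CO2/(L solvent * min)
    productivity: float  # mmol CO2/(L solvent * min), up to plateau
    removal_efficiency: float  # % of initial CO2 inventory
    plateau_time: float  # min
    total_absorbed: float  # mmol/L solvent at end of series
    plateau_found: bool = True


@dataclass(frozen=True)
class ForwardParams:
    """Pseudo-first-order forward model parameters."""

    kla: float  # 1/min volumetric mass-transfer coefficient
    enhancement: float = 1.0  # enzymatic rate enhancement, >= 1
    equilibrium_pressure: float = 0.0  # Pa CO2 partial pressure at saturation

    def __post_init__(self) -> None:
        if self.kla < 0:
            raise ValueError("kLa must be non-negative")
        if self.enhancement < 1.0:
            raise ValueError("enhancement must be >= 1")
        if self.equilibrium_pressure < 0:
            raise ValueError("equilibrium pressure must be non-negative")


def gas_inventory(config: ReactorConfig) -> Tuple[float, float]:
    """Initial headspace (n_CO2, n_N2) in mol from the ideal-gas law."""
    n_total = (config.initial_pressure - config.vapor_pressure_offset) * (
        config.headspace_volume * 1e-3
    ) / (GAS_CONSTANT * config.temperature)
    n_co2 = config.co2_fraction * n_total
    return n_co2, n_total - n_co2


def absorbed_from_pressure(series: PressureSeries, config: ReactorConfig,
                           start_tolerance: float = 0.02) -> np.ndarray:
    """Absorbed CO2 in mmol per liter of solvent, from the pressure drop.

    Requires the series to start at the configured initial pressure within
    ``start_tolerance`` (relative). Transient pressures above P0 mid-series
    are flagged with a warning (thermal fluctuation) and give small negative
    absorbed values; values exceeding the CO2 inventory are clipped with a
    warning.
    """
    p0 = config.initial_pressure
    if abs(series.pressure[0] - p0) > start_tolerance * p0:
        raise ValueError(
            f"series starts at {series.pressure[0]:.3g} Pa, expected "
            f"{p0:.3g} Pa within {start_tolerance:.0%}"
        )
    if np.any(series.pressure[1:] > p0):
        warnings.warn("pressure above initial value mid-series; flagged as fluctuation")
    n_abs = (p0 - series.pressure) * (config.headspace_volume * 1e-3) / (
        GAS_CONSTANT * config.temperature
    )
    n_co2, _ = gas_inventory(config)
    if np.any(n_abs > n_co2 * (1 + 1e-9)):
        warnings.warn("absorbed moles exceed CO2 inventory; clipping")
        n_abs = np.minimum(n_abs, n_co2)
    return n_abs * 1e3 / config.liquid_volume  # mmol per L solvent


def initial_absorption_rate(time: np.ndarray, absorbed: np.ndarray,
                            window: float = None) -> float:
    """Initial slope of the absorbed series in mmol/(L*min).

    Default window: from t = 0 until absorbed first exceeds 20% of its final
    value, capped at 15 min. Needs at least 3 points.
    """
    time = np.asarray(time, dtype=float)
    absorbed = np.asarray(absorbed, dtype=float)
    if window is None:
        final = absorbed[-1]
        if final <= 0:
            window = min(15.0, time[-1])
        else:
            over = np.nonzero(absorbed > 0.2 * final)[0]
            t_hit = time[over[0]] if over.size else time[-1]
            window = min(max(t_hit, time[2] if time.size > 2 else time[-1]), 15.0)
    mask = time <= window
    if mask.sum() < 3:
        raise ValueError("insufficient data: fewer than 3 points in initial window")
    slope = np.polyfit(time[mask], absorbed[mask], 1)[0]
    return float(slope)


def plateau_and_productivity(time: np.ndarray, absorbed: np.ndarray) -> Tuple[float, float, bool]:
    """(plateau_time, productivity, plateau_found).

    Plateau time is the earliest time from which the forward-looking 3-point
    rolling slope stays below 2% of the initial absorption rate for the rest
    of the series; productivity = absorbed(plateau)/plateau in mmol/(L*min).
    When no plateau exists the series end is returned with a flag.
    """
    time = np.asarray(time, dtype=float)
    absorbed = np.asarray(absorbed, dtype=float)
    if time[-1] - time[0] < 30.0:
        raise ValueError("series must span at least 30 min")
    rate0 = initial_absorption_rate(time, absorbed)
    threshold = 0.02 * abs(rate0)
    n = time.size
    slopes = np.empty(n)
    for i in range(n):
        j = min(i + 2, n - 1)
        lo = max(j - 2, 0)
        seg_t, seg_a = time[lo:j + 1], absorbed[lo:j + 1]
        slopes[i] = np.polyfit(seg_t, seg_a, 1)[0] if seg_t.size >= 2 else 0.0
    below = np.abs(slopes) < threshold
    plateau_idx = None
    for i in range(n):
        if below[i:].all():
            plateau_idx = i
            break
    if plateau_idx is None or time[plateau_idx] <= 0:
        t_end = float(time[-1])
        prod = float(absorbed[-1] / t_end) if t_end > 0 else 0.0
        return t_end, prod, False
    t_plateau = float(time[plateau_idx])
    return t_plateau, float(absorbed[plateau_idx] / t_plateau), True


def removal_efficiency(total_absorbed: float, config: ReactorConfig) -> float:
    """Percent of the initial CO2 inventory absorbed; capped at 100%."""
    if total_absorbed < 0:
        raise ValueError("absorbed moles must be non-negative")
    n_co2, _ = gas_inventory(config)
    eff = 100.0 * total_absorbed / n_co2
    if eff > 100.0:
        warnings.warn("absorbed moles exceed inventory; efficiency capped at 100%")
        eff = 100.0
    return eff


def simulate_pressure(config: ReactorConfig, params: ForwardParams,
                      t_grid: np.ndarray) -> PressureSeries:
    """Forward-simulate the total pressure over ``t_grid`` (min, from 0).

    Integrates dP_CO2/dt = -kLa * enhancement * (P_CO2 - P_eq) with inert N2,
    so P(t) = P_N2 + P_eq + (P_CO2,0 - P_eq) * exp(-kLa*E*t). The integration
    is numerical (tight-tolerance RK) and is validated against the analytic
    solution in tests.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] != 0 or not np.all(np.diff(t_grid) > 0):
        raise ValueError("time grid must be sorted and start at 0")
    p_co2_0 = config.co2_fraction * config.initial_pressure
    p_n2 = config.initial_pressure - p_co2_0
    k = params.kla * params.enhancement
    if k == 0:
        p_co2 = np.full_like(t_grid, p_co2_0)
    else:
        p_eq = min(params.equilibrium_pressure, p_co2_0)
        sol = solve_ivp(
            lambda t, y: [-k * (y[0] - p_eq)],
            (0.0, float(t_grid[-1])),
            [p_co2_0],
            t_eval=t_grid,
            rtol=1e-10,
            atol=1e-8,
            method="RK45",
        )
        if not sol.success:
            raise RuntimeError(f"pressure integration failed: {sol.message}")
        p_co2 = np.maximum.accumulate(sol.y[0][::-1])[::-1]  # enforce monotone (numerical)
    return PressureSeries(time=t_grid, pressure=p_n2 + p_co2)


def analyze(series: PressureSeries, config: ReactorConfig) -> AbsorptionMetrics:
    """Full metrics pipeline from a recorded pressure series."""
    absorbed = absorbed_from_pressure(series, config)
    rate0 = initial_absorption_rate(series.time, absorbed)
    plateau_time, productivity, found = plateau_and_productivity(series.time, absorbed)
    total_mmol_per_l = float(absorbed[-1])
    total_mol = total_mmol_per_l * config.liquid_volume / 1e3
    eff = removal_efficiency(max(total_mol, 0.0), config)
    return AbsorptionMetrics(
        initial_rate=rate0,
        productivity=productivity,
        removal_efficiency=eff,
        plateau_time=plateau_time,
        total_absorbed=total_mmol_per_l,
        plateau_found=found,
    )
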