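"""pH-indicator stopped-flow kinetics for CO2 hydration.

CO2 hydration releases one proton per turnover; in a weakly buffered
phenol-red solution the falling pH bleaches the deprotonated (red) form of
the indicator, and the absorbance decay rate is proportional to the
hydration rate. This module converts absorbance traces into CO2 hydration
rates via the buffering factor Q (moles of protons taken up by buffer plus
indicator per absorbance unit, from Henderson-Hasselbalch derivatives at the
working pH), subtracts the uncatalyzed background, and fits the
Michaelis-Menten model to obtain kcat and KM.

Conventions: concentrations are mol/L after mixing in the reaction cell,
time in seconds, absorbance dimensionless. The default rate window follows
the assay protocol (10-20 s after mixing) and is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "Trace",
    "AssayConditions",
    "RateEstimate",
    "NetRate",
    "MMFit",
    "FitError",
    "reaction_concentration",
    "initial_rate",
    "net_rate",
    "buffer_factor",
    "co2_rate",
    "fit_mm",
    "efficiency",
    "molar_to_mass",
    "round_sig",
]

@dataclass(frozen=True)
class Trace:
    """An absorbance-versus-time record (time in s, strictly increasing)."""

    time: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "absorbance", a)
        if t.size < 5:
            raise ValueError("trace needs at least 5 points")
        if t.size != a.size:
            raise ValueError("time and absorbance lengths differ")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")


@dataclass(frozen=True)
class AssayConditions:
    """Reaction-cell composition of the indicator assay (post-mixing).

    Defaults follow the published protocol after 1:1 mixing: 10 mM Tris
    (pKa 8.07 at 25 C), 0.1 mM phenol red (pKa 7.9), starting pH 8.3.
    ``epsilon_path`` folds the indicator extinction coefficient, its total
    concentration, and the optical path into one instrument constant:
    absorbance per mole fraction of deprotonated indicator.
    """

    buffer_total: float = 10e-3
    buffer_pKa: float = 8.07
    indicator_total: float = 0.1e-3
    indicator_pKa: float = 7.9
    epsilon_path: float = 1.0
    pH_init: float = 8.3
    mix_ratio: Tuple[float, float] = (1, 1)
    temperature: float = 25.0

    def __post_init__(self) -> None:
        if self.buffer_total < 0 or self.indicator_total < 0:
            raise ValueError("concentrations must be non-negative")
        if sum(self.mix_ratio) <= 0 or min(self.mix_ratio) < 0:
            raise ValueError("mix ratio parts must be non-negative with positive sum")


@dataclass(frozen=True)
class RateEstimate:
    dA_dt: float  # absorbance per second, sign preserved
    window: Tuple[float, float]
    r_squared: float


@dataclass(frozen=True)
class NetRate:
    """Background-subtracted absorbance rate.

    ``anomalous`` flags the unphysical case of the uncatalyzed decay being
    faster than the catalyzed one (net enzymatic rate would be negative).
    """

    dA_dt: float
    anomalous: bool


class FitError(RuntimeError):
    """Nonlinear fit failed to converge; carries diagnostics in args."""


def reaction_concentration(syringe_conc: float, mix_ratio: Tuple[float, float] = (1, 1)) -> float:
    """Concentration in the reaction cell after mixing.

    ``mix_ratio`` = (parts of the syringe carrying the species, other parts);
    1:1 mixing halves the syringe concentration.
    """
    if syringe_conc < 0:
        raise ValueError("concentration must be non-negative")
    a, b = mix_ratio
    if a <= 0 or b < 0:
        raise ValueError("mix ratio must have positive sample part")
    return syringe_conc * a / (a + b)


def initial_rate(trace: Trace, window: Tuple[float, float] = (10.0, 20.0)) -> RateEstimate:
    """Least-squares slope of absorbance vs time over the window."""
    t0, t1 = window
    if t0 >= t1:
        raise ValueError("window start must precede end")
    if t0 < trace.time[0] or t1 > trace.time[-1]:
        raise ValueError("window outside trace span")
    mask = (trace.time >= t0) & (trace.time <= t1)
    if mask.sum() < 3:
        raise ValueError("insufficient data: fewer than 3 points in window")
    t = trace.time[mask]
    a = trace.absorbance[mask]
    slope, intercept = np.polyfit(t, a, 1)
    resid = a - (slope * t + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    if ss_tot <= 1e-300:
        r2 = 1.0 if ss_res <= 1e-300 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return RateEstimate(dA_dt=float(slope), window=(t0, t1), r_squared=r2)


def net_rate(catalyzed: RateEstimate, uncatalyzed: RateEstimate) -> NetRate:
    """Catalyzed minus uncatalyzed absorbance rate (signed subtraction)."""
    net = catalyzed.dA_dt - uncatalyzed.dA_dt
    anomalous = abs(catalyzed.dA_dt) < abs(uncatalyzed.dA_dt)
    return NetRate(dA_dt=float(net), anomalous=anomalous)


def _prot_fraction(pH: float, pKa: float) -> float:
    """Henderson-Hasselbalch protonated fraction of a monoprotic species."""
    return 1.0 / (1.0 + 10.0 ** (pH - pKa))


def buffer_factor(conditions: AssayConditions) -> float:
    """Buffering factor Q in mol/(L * absorbance unit), evaluated at pH_init.

    Q = (d[protons buffered]/dpH) / (dA/dpH) with both derivatives analytic:
    for each species d(protonated)/dpH = -ln10 * C * f * (1 - f), and for the
    indicator optics dA/dpH = ln10 * epsilon_path * fd * (1 - fd) with fd the
    deprotonated fraction. Multiplying Q by the absorbance decay rate yields
    the proton-release (CO2 hydration) rate.
    """
    if conditions.indicator_total <= 0:
        raise ValueError("indicator_total must be positive")
    if conditions.epsilon_path == 0:
        raise ValueError("degenerate optics: epsilon_path is zero")
    pH = conditions.pH_init
    fb = _prot_fraction(pH, conditions.buffer_pKa)
    fi = _prot_fraction(pH, conditions.indicator_pKa)
    buffering = conditions.buffer_total * fb * (1 - fb) + conditions.indicator_total * fi * (1 - fi)
    optical = abs(conditions.epsilon_path) * fi * (1 - fi)  # fd*(1-fd) == fi*(1-fi)
    return buffering / optical


def co2_rate(net_dA_dt: float, Q: float) -> float:
    """CO2 hydration rate in mol/(L*s) from a net absorbance rate."""
    if Q <= 0:
        raise ValueError("Q must be positive")
    return Q * abs(net_dA_dt)


@dataclass(frozen=True)
class MMFit:
    """Michaelis-Menten fit: v = Vmax * S / (KM + S)."""

    kcat: float  # 1/s
    KM: float  # mol/L
    Vmax: float  # mol/(L*s)
    kcat_over_KM: float  # 1/(M*s)
    kcat_se: float
    KM_se: float
    Vmax_se: float
    enzyme_conc: float  # mol/L
    substrate: tuple = field(default=(), repr=False)
    rates: tuple = field(default=(), repr=False)

    def predict(self, S) -> np.ndarray:
        S = np.asarray(S, dtype=float)
        return self.Vmax * S / (self.KM + S)


def fit_mm(substrate: Sequence[float], rates: Sequence[float], enzyme_conc: float) -> MMFit:
    """Nonlinear least-squares Michaelis-Menten fit.

    Initialization is fixed (Vmax0 = max rate, KM0 = median substrate) so the
    fit is deterministic given the data. Standard errors come from the
    covariance of the fit; kcat = Vmax / enzyme concentration.
    """
    S = np.asarray(substrate, dtype=float)
    v = np.asarray(rates, dtype=float)
    if S.size != v.size:
        raise ValueError("substrate and rate arrays differ in length")
    if np.unique(S).size < 4:
        raise ValueError("need at least 4 distinct substrate levels")
    if np.any(v < 0):
        raise ValueError("rates must be non-negative")
    if enzyme_conc <= 0:
        raise ValueError("enzyme concentration must be positive")
    p0 = (float(v.max()), float(np.median(S)))

    def mm(s, vmax, km):
        return vmax * s / (km + s)

    try:
        # tight tolerances: with default settings the bounded solver can stop
        # well short of the optimum on rate data of magnitude ~1e-4
        popt, pcov = curve_fit(mm, S, v, p0=p0, bounds=([0.0, 0.0], [np.inf, np.inf]),
                               xtol=1e-14, ftol=1e-14, gtol=1e-14, maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - pathological data
        raise FitError(f"Michaelis-Menten fit did not converge: {exc}",
                       {"p0": p0, "n": int(S.size)}) from exc
    vmax, km = popt
    if not (vmax > 0 and km > 0):
        raise FitError("fit returned non-positive parameters", {"popt": popt.tolist()})
    se = np.sqrt(np.abs(np.diag(pcov)))
    kcat = vmax / enzyme_conc
    return MMFit(
        kcat=float(kcat),
        KM=float(km),
        Vmax=float(vmax),
        kcat_over_KM=float(kcat / km),
        kcat_se=float(se[0] / enzyme_conc),
        KM_se=float(se[1]),
        Vmax_se=float(se[0]),
        enzyme_conc=float(enzyme_conc),
        substrate=tuple(S.tolist()),
        rates=tuple(v.tolist()),
    )


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (reporting helper)."""
    if x == 0:
        return 0.0
    return float(f"{x:.{sig}g}")


def efficiency(kcat: float, KM: float, sig: Optional[int] = None) -> float:
    """Catalytic efficiency kcat/KM in 1/(M*s); KM in mol/L.

    Pass ``sig`` to round to significant figures for reporting.
    """
    if kcat <= 0 or KM <= 0:
        raise ValueError("kcat and KM must be positive")
    eff = kcat / KM
    return round_sig(eff, sig) if sig else eff


def molar_to_mass(conc: float, molecular_weight: float) -> float:
    """Mass concentration in g/L from molarity (mol/L) and MW (g/mol)."""
    if conc < 0 or molecular_weight <= 0:
        raise ValueError("concentration must be >= 0 and MW > 0")
    return conc * molecular_weight


def g_per_l_to_ug_per_ml(x: float) -> float:
    return x * 1000.0


def g_per_l_to_mg_per_ml(x: float) -> float:
    return x
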