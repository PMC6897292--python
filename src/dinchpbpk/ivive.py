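"""In vitro to in vivo extrapolation (IVIVE) of metabolic clearance.

Substrate-depletion incubations in pooled human liver microsomes yield an in
vitro half-life for the monoester MINCH.  This module turns such depletion
time courses into whole-organ intrinsic clearances and hepatic plasma
clearances, and predicts plasma protein binding from lipophilicity:

* non-specific-binding correction: a straight line is fitted to the binding
  control series and each time point is rescaled by intercept / fitted value,
  so that losses to the vessel and the microsomes do not masquerade as
  metabolism;
* exponential decay ``y = b * exp(-t / k)`` fitted by Levenberg-Marquardt
  least squares; the half-life is ``ln(2) * k``;
* ``CL_in_vitro = ln(2) / T_half * (ml incubation / mg microsomal protein)``;
* scaling to the whole organ with the microsomal protein yield (MPY,
  mg protein per g organ) and the organ mass, reported in L/h;
* the well-stirred liver model with plasma fraction unbound ``fu`` and the
  red-blood-cell to plasma concentration ratio;
* ``fu = 1 / (10**x + 1)`` with ``x = 0.4485 * logPow - 0.4782``, the
  regression for neutral chemicals at pH 7.4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .exceptions import DegenerateCorrectionError, FitError, InputError

__all__ = [
    "DepletionCurve",
    "DecayFit",
    "ClearanceScaling",
    "BindingPrediction",
    "fit_binding_scaling",
    "fit_decay",
    "cl_in_vitro",
    "scale_clint",
    "well_stirred_clearance",
    "fraction_unbound",
    "fraction_metabolized",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class DepletionCurve:
    """A microsomal substrate-depletion experiment.

    ``total_conc`` is the total-metabolism series and ``binding_conc`` the
    non-specific-binding control (no glucose-6-phosphate dehydrogenase), both
    in µM as replicate means per time point.  ``incubation_volume`` (ml) and
    ``protein_mass`` (mg) give the scaling ratio of the clearance equation.
    """

    times: np.ndarray
    total_conc: np.ndarray
    binding_conc: np.ndarray
    incubation_volume: float = 1.0
    protein_mass: float = 0.5

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        tot = np.asarray(self.total_conc, dtype=float)
        bind = np.asarray(self.binding_conc, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "total_conc", tot)
        object.__setattr__(self, "binding_conc", bind)
        if t.size < 3:
            raise InputError("need at least three depletion time points")
        if not np.all(np.diff(t) > 0):
            raise InputError("times must be strictly increasing")
        if t[0] != 0.0:
            raise InputError("depletion series must include t = 0")
        if tot.shape != t.shape or bind.shape != t.shape:
            raise InputError("concentration series must match times in length")
        if np.any(tot < 0) or np.any(bind < 0):
            raise InputError("concentrations must be non-negative")
        if self.incubation_volume <= 0 or self.protein_mass <= 0:
            raise InputError("incubation volume and protein mass must be positive")

    @property
    def volume_per_protein(self) -> float:
        """ml incubation per mg microsomal protein."""
        return self.incubation_volume / self.protein_mass


@dataclass(frozen=True)
class DecayFit:
    """Fitted exponential depletion ``y = b * exp(-t / k)``."""

    b: float
    k: float
    half_life: float
    residual_sse: float

    def __post_init__(self) -> None:
        if self.b <= 0 or self.k <= 0:
            raise InputError("fitted b and k must be positive")


@dataclass(frozen=True)
class ClearanceScaling:
    """Whole-organ intrinsic clearance derived from an in vitro clearance."""

    mpy: float
    organ_mass: float
    cl_in_vitro: float
    cl_int: float


@dataclass(frozen=True)
class BindingPrediction:
    log_pow: float
    x: float
    fu: float
    fraction_bound: float


def fit_binding_scaling(curve: DepletionCurve) -> np.ndarray:
    """Per-time-point scaling factors from the non-specific-binding control.

    A straight line ``c0 + m t`` is fitted to the binding series; the factor
    at time ``t`` is ``c0 / (c0 + m t)`` so that the rescaled control is
    constant at its intercept.  Raises
    :class:`~dinchpbpk.exceptions.DegenerateCorrectionError` if the fitted
    line is not strictly positive over the observed times.
    """
    t = curve.times
    if t.size < 2:
        raise InputError("need at least two binding time points")
    slope, intercept = np.polyfit(t, curve.binding_conc, 1)
    fitted = intercept + slope * t
    if intercept <= 0 or np.any(fitted <= 0):
        raise DegenerateCorrectionError(
            "binding line crosses zero within the observed time range"
        )
    return intercept / fitted


def fit_decay(times: Sequence[float], scaled_conc: Sequence[float]) -> DecayFit:
    """Levenberg-Marquardt fit of ``y = b exp(-t/k)`` to scaled depletion data.

    Initial values are ``b0 =`` first observation and ``k0 = t_max / ln 2``,
    robust for monotone decay.  Non-decreasing data (no measurable depletion)
    raise :class:`~dinchpbpk.exceptions.FitError`.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(scaled_conc, dtype=float)
    if t.size < 3:
        raise InputError("need at least three points for the decay fit")
    if np.any(y < 0):
        raise InputError("concentrations must be non-negative")
    if np.any(y <= 0):
        raise InputError("zero concentrations cannot be fitted by an exponential")
    # overall trend must be downward, otherwise k -> infinity
    trend = np.polyfit(t, np.log(y), 1)[0]
    if trend >= 0:
        raise FitError("depletion data are non-decreasing; decay constant undefined")

    def model(tt: np.ndarray, b: float, k: float) -> np.ndarray:
        return b * np.exp(-tt / k)

    p0 = (float(y[0]), float(t[-1] / LN2))
    try:
        popt, _ = curve_fit(
            model, t, y, p0=p0, method="lm", maxfev=10000, ftol=1e-12, xtol=1e-12
        )
    except RuntimeError as exc:  # pragma: no cover - scipy failure path
        raise FitError(f"decay fit did not converge: {exc}") from exc
    b_hat, k_hat = float(popt[0]), float(popt[1])
    if not (np.isfinite(b_hat) and np.isfinite(k_hat)) or b_hat <= 0 or k_hat <= 0:
        raise FitError("decay fit produced non-positive parameters")
    sse = float(np.sum((y - model(t, b_hat, k_hat)) ** 2))
    return DecayFit(b=b_hat, k=k_hat, half_life=LN2 * k_hat, residual_sse=sse)


def cl_in_vitro(
    half_life: float, incubation_volume: float, protein_mass: float
) -> float:
    """In vitro clearance in ml·min⁻¹·mg⁻¹ microsomal protein."""
    if half_life <= 0 or incubation_volume <= 0 or protein_mass <= 0:
        raise InputError("half-life, volume and protein mass must all be positive")
    return LN2 / half_life * (incubation_volume / protein_mass)


def scale_clint(cl_vitro: float, mpy: float, organ_mass: float) -> float:
    """Whole-organ intrinsic clearance in L·h⁻¹.

    ``cl_vitro`` [ml/min/mg] × MPY [mg/g] × organ mass [g] × 60 [min/h] gives
    ml/h; divided by 1000 to report litres per hour.
    """
    if cl_vitro <= 0 or mpy <= 0 or organ_mass <= 0:
        raise InputError("clearance scaling inputs must be positive")
    return cl_vitro * mpy * organ_mass * 60.0 / 1000.0


def scale_clint_record(
    cl_vitro: float, mpy: float, organ_mass: float
) -> ClearanceScaling:
    """As :func:`scale_clint` but returning the full record."""
    return ClearanceScaling(
        mpy=mpy,
        organ_mass=organ_mass,
        cl_in_vitro=cl_vitro,
        cl_int=scale_clint(cl_vitro, mpy, organ_mass),
    )


def well_stirred_clearance(
    q_h: float, fu: float, cl_int: float, rbc_plasma_ratio: float
) -> float:
    """Well-stirred hepatic plasma clearance in L·h⁻¹.

    ``CL_H = Q_H fu CLint / (Q_H + fu CLint / (C_RBC/C_P))``, bounded above by
    the hepatic blood flow times the red-cell/plasma ratio.
    """
    if q_h <= 0:
        raise InputError("hepatic blood flow must be positive")
    if not 0.0 <= fu <= 1.0:
        raise InputError("fraction unbound must lie in [0, 1]")
    if cl_int < 0:
        raise InputError("intrinsic clearance must be non-negative")
    if rbc_plasma_ratio <= 0:
        raise InputError("red-cell/plasma ratio must be positive")
    num = q_h * fu * cl_int
    den = q_h + fu * cl_int / rbc_plasma_ratio
    return num / den


def fraction_unbound(log_pow: float) -> BindingPrediction:
    """Plasma fraction unbound from Log Pow: ``fu = 1/(10^x + 1)``."""
    if not math.isfinite(log_pow):
        raise InputError("log Pow must be finite")
    x = 0.4485 * log_pow - 0.4782
    fu = 1.0 / (10.0**x + 1.0)
    return BindingPrediction(log_pow=log_pow, x=x, fu=fu, fraction_bound=1.0 - fu)


#: canonical metabolite names of the urinary inventory
INVENTORY_SPECIES = (
    "MINCH",
    "OH-MINCH",
    "cx-MINCH",
    "CHDA",  # cyclohexane-1,2-dicarboxylic acid
    "oxo-MINCH",
    "MCHxCH",
)


@dataclass(frozen=True)
class MetaboliteInventory:
    """Per-metabolite molar amounts (µmol) measured in urine for one subject."""

    amounts: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, v in self.amounts.items():
            if v < 0:
                raise InputError(f"negative amount for {name}")

    @property
    def total(self) -> float:
        return float(sum(self.amounts.values()))


def fraction_metabolized(inventory: MetaboliteInventory) -> tuple[float, float]:
    """Fractions of total urinary metabolites present as OH- and cx-MINCH.

    These define the split of hepatic MINCH clearance routed to each measured
    oxidation product in the kinetic model (the remainder is the lumped sink
    of unmodelled downstream metabolites).
    """
    total = inventory.total
    if total <= 0:
        raise InputError("metabolite inventory sums to zero")
    f_oh = inventory.amounts.get("OH-MINCH", 0.0) / total
    f_cx = inventory.amounts.get("cx-MINCH", 0.0) / total
    return f_oh, f_cx
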