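"""Synthetic volunteer void datasets and microsomal depletion curves.

The human biomonitoring dataset behind this model (three male volunteers,
82-90 kg, a single ~50 mg oral dose of DINCH — 0.552-0.606 mg/kg — taken
over about a quarter of an hour at breakfast, with complete urine collection
for 48 h) is not publicly deposited.  This module generates desk-scale
stand-ins with known ground truth so that every downstream analysis —
curve fitting, sensitivity analysis, calibration, reverse dosimetry — is
testable without access to the original data.

Void observations are the kinetic model's predictions at the true parameter
values corrupted by multiplicative log-normal noise, ``y = mu exp(sigma z)``
with independent standard-normal ``z`` — the same error model the
calibration assumes.  The volunteer-C preset reproduces the documented
anomaly of that subject (a large water intake at the start of the study):
the first four voids carry three-fold urine volumes and one-third creatinine
concentrations, which breaks the model's constant-production assumption in
the same qualitative way.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import InputError
from .io import VoidDataset
from .ivive import DepletionCurve
from .model import simulate
from .params import ParameterBundle, UrineParams, apply_overrides, default_bundle, \
    resolve_parameters
from .priors import VOLUNTEERS

__all__ = [
    "DEFAULT_VOID_SCHEDULE",
    "VolunteerScenario",
    "volunteer_preset",
    "generate_voids",
    "generate_depletion",
]

#: default micturition schedule over the 48 h collection window (16 voids);
#: the study's actual void times are unpublished — this is a convention
DEFAULT_VOID_SCHEDULE = (
    0.75, 1.5, 2.25, 3.0, 4.5, 6.0, 8.0, 10.0, 12.0, 16.0,
    20.0, 24.0, 30.0, 36.0, 42.0, 48.0,
)


@dataclass(frozen=True)
class VolunteerScenario:
    """Ground-truth description of one synthetic volunteer."""

    volunteer_id: str = "A"
    bw: float = 89.0  # kg
    dose: float = 0.558  # mg per kg
    drink_time: float = 0.25  # h
    void_times: tuple[float, ...] = DEFAULT_VOID_SCHEDULE
    # true kinetic parameters (calibrated-scale defaults)
    frac_dose: float = 0.74
    mpy: float = 38.0
    k1_oh: float = 0.15
    k1_cx: float = 0.10
    frac_metab_oh: float = 0.23
    frac_metab_cx: float = 0.05
    # urine behaviour: constant rates, optionally overridden per interval
    r_urine: float = 0.104  # L/h
    creat: float = 1.278  # g/L
    volumes: tuple[float, ...] | None = None
    creatinine: tuple[float, ...] | None = None
    noise_sigma: float = 0.28

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise InputError("noise sigma must be non-negative")
        vt = tuple(float(t) for t in self.void_times)
        object.__setattr__(self, "void_times", vt)
        if not all(b > a for a, b in zip(vt, vt[1:])):
            raise InputError("void schedule must be strictly increasing")

    def overrides(self) -> dict[str, float]:
        return {
            "BW": self.bw,
            "PORALDOSE": self.dose,
            "DRINKTIME": self.drink_time,
            "FracDOSE": self.frac_dose,
            "MPY": self.mpy,
            "K1_OH": self.k1_oh,
            "K1_cx": self.k1_cx,
            "FracMetabOH": self.frac_metab_oh,
            "FracMetabcx": self.frac_metab_cx,
        }


def volunteer_preset(volunteer_id: str, noise_sigma: float = 0.28) -> VolunteerScenario:
    """Scenario presets matching the three study volunteers' covariates.

    Volunteer C additionally carries the early water-drinking anomaly: the
    voids at 0.75, 1.5, 2.25 and 3 h get three-fold urine volumes and
    one-third creatinine concentrations.
    """
    if volunteer_id not in VOLUNTEERS:
        raise InputError(f"unknown volunteer {volunteer_id!r}")
    info = VOLUNTEERS[volunteer_id]
    scenario = VolunteerScenario(
        volunteer_id=volunteer_id,
        bw=info["bw"],
        dose=info["dose"],
        r_urine=info["rurine"],
        creat=info["creat"],
        noise_sigma=noise_sigma,
    )
    if volunteer_id == "C":
        times = np.asarray(scenario.void_times)
        intervals = np.diff(np.concatenate([[0.0], times]))
        vols = scenario.r_urine * intervals
        creats = np.full_like(vols, scenario.creat)
        vols[:4] *= 3.0
        creats[:4] /= 3.0
        scenario = replace(
            scenario, volumes=tuple(vols), creatinine=tuple(creats)
        )
    return scenario


def generate_voids(
    scenario: VolunteerScenario,
    seed: int | np.random.Generator = 0,
    base: ParameterBundle | None = None,
) -> tuple[VoidDataset, dict]:
    """Simulate a volunteer and emit a noisy void dataset plus ground truth.

    With ``noise_sigma = 0`` the dataset equals the model predictions
    exactly.  The returned ground-truth record carries the true parameters
    and the noiseless concentrations.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    base = base if base is not None else default_bundle()
    if scenario.void_times[0] < scenario.drink_time:
        import warnings

        warnings.warn(
            "first void precedes the end of ingestion; its concentration "
            "may be essentially zero",
            stacklevel=2,
        )
    bundle = apply_overrides(base, scenario.overrides())
    bundle = replace(
        bundle,
        urine=UrineParams(
            r_urine=scenario.r_urine,
            creat=scenario.creat,
            void_times=scenario.void_times,
            volumes=scenario.volumes,
            creatinine=scenario.creatinine,
        ),
    )
    rp = resolve_parameters(bundle)
    t_end = scenario.void_times[-1]
    res = simulate(rp, t_end, output_times=[t_end])
    voids = res.voids
    n = len(voids)
    z = rng.standard_normal((n, 2))
    noise = np.exp(scenario.noise_sigma * z)
    obs = pd.DataFrame(
        {
            "volunteer_id": scenario.volunteer_id,
            "time_h": voids["time_h"],
            "interval_h": voids["interval_h"],
            "volume_L": voids["volume_L"],
            "creatinine_g_per_L": voids["creatinine_g_per_L"],
            "conc_OH_mg_per_g_creat": voids["conc_OH_mg_per_g_creat"] * noise[:, 0],
            "conc_cx_mg_per_g_creat": voids["conc_cx_mg_per_g_creat"] * noise[:, 1],
            "bw_kg": scenario.bw,
            "dose_mg_per_kg": scenario.dose,
        }
    )
    truth = {
        "scenario": {k: v for k, v in scenario.__dict__.items()},
        "true_parameters": scenario.overrides(),
        "noise_sigma": scenario.noise_sigma,
        "noiseless": voids[
            ["time_h", "conc_OH_mg_per_g_creat", "conc_cx_mg_per_g_creat"]
        ].to_dict(orient="list"),
    }
    return VoidDataset(obs), truth


def combine(datasets: Mapping[str, VoidDataset]) -> VoidDataset:
    """Concatenate single-volunteer datasets into one."""
    return VoidDataset(
        pd.concat([d.observations for d in datasets.values()], ignore_index=True)
    )


def generate_depletion(
    b: float = 10.0,
    k: float = 44.05,
    binding_intercept: float = 8.0,
    binding_slope: float = -0.02,
    noise_sd: float = 0.0,
    times: tuple[float, ...] = (0.0, 5.0, 10.0, 20.0, 30.0, 45.0, 60.0),
    seed: int | np.random.Generator = 0,
    incubation_volume: float = 1.0,
    protein_mass: float = 0.5,
) -> tuple[DepletionCurve, dict]:
    """Synthetic substrate-depletion experiment with known decay constant.

    The non-specific-binding control declines linearly from
    ``binding_intercept``; the total-metabolism series is the true
    metabolic depletion ``b exp(-t/k)`` attenuated by the same proportional
    non-specific losses, so that applying the binding scaling factors
    restores the clean exponential — exactly the situation the correction
    is designed for.  Both series optionally carry multiplicative
    log-normal noise of standard deviation ``noise_sd``.  The default decay
    constant ``k = 44.05`` min corresponds to the measured MINCH in vitro
    half-life ``ln(2) k = 30.53`` min.
    """
    if k <= 0:
        raise InputError("decay constant must be positive")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    t = np.asarray(times, dtype=float)
    binding = binding_intercept + binding_slope * t
    if np.any(binding <= 0):
        raise InputError("binding control reaches zero within the time range")
    total = b * np.exp(-t / k) * (binding / binding_intercept)
    if noise_sd > 0:
        total = total * np.exp(noise_sd * rng.standard_normal(t.size))
        binding = binding * np.exp(noise_sd * rng.standard_normal(t.size))
    curve = DepletionCurve(
        times=t,
        total_conc=total,
        binding_conc=binding,
        incubation_volume=incubation_volume,
        protein_mass=protein_mass,
    )
    truth = {
        "b": b,
        "k": k,
        "half_life": float(np.log(2.0) * k),
        "binding_intercept": binding_intercept,
        "binding_slope": binding_slope,
        "noise_sd": noise_sd,
    }
    return curve, truth
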