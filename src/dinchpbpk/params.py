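"""Model parameters: defaults, named overrides and mass-balance closure.

Defaults reproduce the study's point values: standard male physiology
(72.3 kg), tissue:blood partition coefficients and plasma unbound fractions
predicted from Log Pow for the diester DINCH and its monoester MINCH, oral
exposure settings for a single dose taken with breakfast, and metabolic and
urinary-excretion parameters.  ``resolve_parameters`` turns the fractional
physiology into absolute volumes (L, density 1) and blood flows (L/h) with a
Bois-style closure: the slowly perfused tissue absorbs the volume residual so
compartment volumes sum to the vascularised fraction of body weight, and the
rapidly perfused flow absorbs the flow residual so tissue flows sum to the
cardiac output.  Whole-organ intrinsic clearances are computed from the in
vitro half-lives through the IVIVE chain.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from . import ivive
from .exceptions import InfeasibleParameterError, InputError

__all__ = [
    "ChemicalParams",
    "PhysiologyParams",
    "ExposureParams",
    "MetabolismParams",
    "UrineParams",
    "ParameterBundle",
    "ResolvedParams",
    "DINCH",
    "MINCH",
    "default_bundle",
    "resolve_parameters",
    "apply_overrides",
    "formula_weight",
    "MW_DINCH",
    "MW_MINCH",
    "MW_OH_MINCH",
    "MW_CX_MINCH",
]

_ATOMIC_MASS = {"C": 12.011, "H": 1.008, "O": 15.999, "N": 14.007, "S": 32.06}


def formula_weight(formula: str) -> float:
    """Molecular weight (g/mol) from a molecular formula such as C26H48O4."""
    tokens = re.findall(r"([A-Z][a-z]?)(\d*)", formula)
    mass = 0.0
    seen = False
    for sym, count in tokens:
        if not sym:
            continue
        if sym not in _ATOMIC_MASS:
            raise InputError(f"unknown element {sym!r} in formula {formula!r}")
        mass += _ATOMIC_MASS[sym] * (int(count) if count else 1)
        seen = True
    if not seen:
        raise InputError(f"could not parse formula {formula!r}")
    return mass


MW_DINCH = formula_weight("C26H48O4")
MW_MINCH = formula_weight("C17H30O4")
MW_OH_MINCH = formula_weight("C17H30O5")
MW_CX_MINCH = formula_weight("C17H28O6")

#: perfused tissue keys used for partition coefficients
PC_TISSUES = ("adipose", "liver", "gut", "stomach", "rapid", "slow", "blood_cells")


@dataclass(frozen=True)
class ChemicalParams:
    """Chemical-specific inputs for one species (DINCH or MINCH)."""

    name: str
    log_pow: float
    fu: float  # plasma fraction unbound
    mw: float  # g/mol
    pc: Mapping[str, float]  # tissue:blood partition coefficients

    def __post_init__(self) -> None:
        if not 0.0 < self.fu < 1.0:
            raise InputError("fu must lie in (0, 1)")
        for k in PC_TISSUES:
            if k not in self.pc:
                raise InputError(f"missing partition coefficient {k!r}")
            if self.pc[k] <= 0:
                raise InputError(f"partition coefficient {k!r} must be positive")

    @property
    def fraction_bound(self) -> float:
        return 1.0 - self.fu


DINCH = ChemicalParams(
    name="DINCH",
    log_pow=9.77,
    fu=0.0001249,
    mw=MW_DINCH,
    pc={
        "adipose": 49.77,
        "liver": 5.89,
        "gut": 7.40,
        "stomach": 7.40,  # gut surrogate
        "rapid": 3.70,  # spleen surrogate
        "slow": 3.29,  # muscle surrogate
        "blood_cells": 3.01,
    },
)

MINCH = ChemicalParams(
    name="MINCH",
    log_pow=5.17,
    fu=0.0146477,
    mw=MW_MINCH,
    pc={
        "adipose": 29.10,
        "liver": 54.80,
        "gut": 25.20,
        "stomach": 25.20,
        "rapid": 12.20,
        "slow": 7.51,
        "blood_cells": 6.67,
    },
)


@dataclass(frozen=True)
class PhysiologyParams:
    """Body weight, fractional organ volumes (% BW) and blood flows (% CO)."""

    bw: float = 72.3  # kg
    vt: float = 0.95  # vascularised fraction of BW
    v_li_c: float = 3.09
    v_fa_c: float = 19.5
    v_gu_c: float = 1.50
    v_st_c: float = 0.22
    v_spd_c: float = 60.7  # replaced by closure residual
    v_rpd_c: float = 3.71
    v_bld_c: float = 5.0
    v_lymph_c: float = 0.36
    qcc: float = 14.0  # cardiac output, L/h per kg
    q_hepart_c: float = 6.0  # hepatic artery
    q_fa_c: float = 5.0
    q_gu_c: float = 14.9
    q_st_c: float = 1.1
    q_spd_c: float = 27.0
    q_rpd_c: float = 42.0  # replaced by closure residual
    q_lymph_c: float = 0.04  # lymph return as % CO


@dataclass(frozen=True)
class ExposureParams:
    """Single oral dose taken with a drink over ``drink_time`` hours."""

    oral_dose: float = 0.555  # mg per kg BW (PORALDOSE)
    drink_time: float = 0.25  # h (DRINKTIME)
    frac_dose: float = 0.7  # fraction of absorbed dose routed to liver
    k_ga: float = 25.1  # gut absorption, 1/h
    k_max: float = 10.2  # gastric emptying upper bound, 1/h
    k_min: float = 0.005  # gastric emptying lower bound, 1/h
    k_ge: float | None = None  # effective emptying rate; defaults to k_max

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_dose <= 1.0:
            raise InputError("frac_dose must lie in [0, 1]")
        if self.drink_time <= 0:
            raise InputError("drink_time must be positive")
        if not self.k_max >= self.k_min > 0:
            raise InputError("need k_max >= k_min > 0")

    @property
    def gastric_emptying(self) -> float:
        return self.k_max if self.k_ge is None else self.k_ge


@dataclass(frozen=True)
class MetabolismParams:
    """Metabolic half-lives, protein yields, metabolite split and urine rates."""

    t_half_dinch: float = 30.0  # min, hepatic (assumed)
    t_half_dinch_gut: float = 30.0  # min
    t_half_minch: float = 30.53  # min, measured in vitro
    mpy: float = 34.0  # mg microsomal protein / g liver
    mpy_gut: float = 3.9  # mg / g gut
    incubation_ml_per_mg: float = 2.0  # ml incubation per mg protein (0.5 mg/ml)
    frac_metab_oh: float = 0.25
    frac_metab_cx: float = 0.0475
    k1_oh: float = 0.15  # 1/h urinary elimination
    k1_cx: float = 0.15

    def __post_init__(self) -> None:
        if min(self.t_half_dinch, self.t_half_dinch_gut, self.t_half_minch) <= 0:
            raise InputError("half-lives must be positive")
        if self.frac_metab_oh < 0 or self.frac_metab_cx < 0:
            raise InputError("metabolite fractions must be non-negative")
        if self.frac_metab_oh + self.frac_metab_cx > 1.0:
            raise InputError("frac_metab_oh + frac_metab_cx must not exceed 1")
        if self.k1_oh <= 0 or self.k1_cx <= 0:
            raise InputError("urinary elimination rates must be positive")


@dataclass(frozen=True)
class UrineParams:
    """Constant urine and creatinine production plus the micturition schedule.

    ``volumes`` and ``creatinine`` optionally override the per-interval urine
    volume (L) and creatinine concentration (g/L) of each void, emulating e.g.
    a volunteer who drank a large amount of water early in a study.
    """

    r_urine: float = 0.1  # L/h
    creat: float = 0.5  # g/L
    void_times: tuple[float, ...] = ()
    volumes: tuple[float, ...] | None = None
    creatinine: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.r_urine <= 0 or self.creat <= 0:
            raise InputError("urine and creatinine production must be positive")
        vt = tuple(float(t) for t in self.void_times)
        object.__setattr__(self, "void_times", vt)
        if vt and not all(b > a for a, b in zip(vt, vt[1:])):
            raise InputError("void times must be strictly increasing")
        if vt and vt[0] <= 0:
            raise InputError("void times must be positive")
        for name in ("volumes", "creatinine"):
            v = getattr(self, name)
            if v is not None:
                v = tuple(float(x) for x in v)
                object.__setattr__(self, name, v)
                if len(v) != len(vt):
                    raise InputError(f"{name} must align with void_times")
                if any(x <= 0 for x in v):
                    raise InputError(f"{name} entries must be positive")


@dataclass(frozen=True)
class ParameterBundle:
    """The full set of inputs required to resolve and run the kinetic model."""

    physiology: PhysiologyParams = field(default_factory=PhysiologyParams)
    dinch: ChemicalParams = DINCH
    minch: ChemicalParams = MINCH
    exposure: ExposureParams = field(default_factory=ExposureParams)
    metabolism: MetabolismParams = field(default_factory=MetabolismParams)
    urine: UrineParams = field(default_factory=UrineParams)


def default_bundle(**kwargs) -> ParameterBundle:
    return ParameterBundle(**kwargs)


@dataclass(frozen=True)
class ResolvedParams:
    """Absolute volumes, flows and clearances after mass-balance closure."""

    bundle: ParameterBundle
    volumes: Mapping[str, float]  # L: liver, adipose, gut, stomach, slow, rapid,
    #                                  blood, lymph
    flows: Mapping[str, float]  # L/h: hepart, adipose, gut, stomach, slow, rapid
    qc: float  # cardiac output, L/h
    q_liver: float  # total liver inflow = hepatic artery + stomach + gut
    q_lymph: float  # lymph return flow, L/h
    clint_h_dinch: float  # whole-liver intrinsic clearance, L/h
    clint_gut_dinch: float
    clint_h_minch: float
    cl_h_dinch: float  # well-stirred hepatic plasma clearance (Eq-5 form), L/h
    cl_gut_dinch: float
    cl_h_minch: float  # reported equivalent plasma clearance for MINCH
    dose_umol: float  # ingested dose in µmol DINCH
    dose_rate: float  # µmol/h during drink_time

    @property
    def exposure(self) -> ExposureParams:
        return self.bundle.exposure

    @property
    def metabolism(self) -> MetabolismParams:
        return self.bundle.metabolism

    @property
    def urine(self) -> UrineParams:
        return self.bundle.urine

    @property
    def dinch(self) -> ChemicalParams:
        return self.bundle.dinch

    @property
    def minch(self) -> ChemicalParams:
        return self.bundle.minch


def resolve_parameters(bundle: ParameterBundle | None = None) -> ResolvedParams:
    """Resolve fractional physiology into absolute quantities with closure.

    Raises :class:`InfeasibleParameterError` when the residual slowly-perfused
    volume or rapidly-perfused flow is non-positive (required so that global
    sensitivity designs can reject pathological parameter combinations).
    """
    b = bundle if bundle is not None else default_bundle()
    p = b.physiology
    if p.bw <= 0 or p.qcc <= 0:
        raise InputError("body weight and cardiac output must be positive")

    vols = {
        "liver": p.v_li_c / 100.0 * p.bw,
        "adipose": p.v_fa_c / 100.0 * p.bw,
        "gut": p.v_gu_c / 100.0 * p.bw,
        "stomach": p.v_st_c / 100.0 * p.bw,
        "rapid": p.v_rpd_c / 100.0 * p.bw,
        "blood": p.v_bld_c / 100.0 * p.bw,
        "lymph": p.v_lymph_c / 100.0 * p.bw,
    }
    v_slow = p.vt * p.bw - sum(vols.values())
    if v_slow <= 0:
        raise InfeasibleParameterError(
            "fractional volumes exceed the vascularised body fraction"
        )
    vols["slow"] = v_slow

    qc = p.qcc * p.bw
    flows = {
        "hepart": p.q_hepart_c / 100.0 * qc,
        "adipose": p.q_fa_c / 100.0 * qc,
        "gut": p.q_gu_c / 100.0 * qc,
        "stomach": p.q_st_c / 100.0 * qc,
        "slow": p.q_spd_c / 100.0 * qc,
    }
    q_rapid = qc - sum(flows.values())
    if q_rapid <= 0:
        raise InfeasibleParameterError("fractional blood flows exceed cardiac output")
    flows["rapid"] = q_rapid
    q_lymph = p.q_lymph_c / 100.0 * qc
    q_liver = flows["hepart"] + flows["stomach"] + flows["gut"]

    m = b.metabolism
    ratio = m.incubation_ml_per_mg
    clint_h_d = ivive.scale_clint(
        ivive.cl_in_vitro(m.t_half_dinch, ratio, 1.0), m.mpy, vols["liver"] * 1000.0
    )
    clint_gut_d = ivive.scale_clint(
        ivive.cl_in_vitro(m.t_half_dinch_gut, ratio, 1.0),
        m.mpy_gut,
        vols["gut"] * 1000.0,
    )
    clint_h_m = ivive.scale_clint(
        ivive.cl_in_vitro(m.t_half_minch, ratio, 1.0), m.mpy, vols["liver"] * 1000.0
    )

    cl_h_d = ivive.well_stirred_clearance(
        q_liver, b.dinch.fu, clint_h_d, b.dinch.pc["blood_cells"]
    )
    cl_gut_d = ivive.well_stirred_clearance(
        flows["gut"], b.dinch.fu, clint_gut_d, b.dinch.pc["blood_cells"]
    )
    cl_h_m = ivive.well_stirred_clearance(
        q_liver, b.minch.fu, clint_h_m, b.minch.pc["blood_cells"]
    )

    e = b.exposure
    dose_mg = e.oral_dose * p.bw
    dose_umol = dose_mg * 1000.0 / b.dinch.mw
    return ResolvedParams(
        bundle=b,
        volumes=vols,
        flows=flows,
        qc=qc,
        q_liver=q_liver,
        q_lymph=q_lymph,
        clint_h_dinch=clint_h_d,
        clint_gut_dinch=clint_gut_d,
        clint_h_minch=clint_h_m,
        cl_h_dinch=cl_h_d,
        cl_gut_dinch=cl_gut_d,
        cl_h_minch=cl_h_m,
        dose_umol=dose_umol,
        dose_rate=dose_umol / e.drink_time,
    )


# ---------------------------------------------------------------------------
# named parameter overrides (published abbreviations)
# ---------------------------------------------------------------------------

#: canonical name -> (sub-dataclass attribute on ParameterBundle, field name)
_SCALAR_FIELDS: dict[str, tuple[str, str]] = {
    "BW": ("physiology", "bw"),
    "VT": ("physiology", "vt"),
    "VLiC": ("physiology", "v_li_c"),
    "VFaC": ("physiology", "v_fa_c"),
    "VGuC": ("physiology", "v_gu_c"),
    "VStC": ("physiology", "v_st_c"),
    "VSpdC": ("physiology", "v_spd_c"),
    "VRpdC": ("physiology", "v_rpd_c"),
    "VBldC": ("physiology", "v_bld_c"),
    "VLymphC": ("physiology", "v_lymph_c"),
    "QCC": ("physiology", "qcc"),
    "QHepartC": ("physiology", "q_hepart_c"),
    "QFaC": ("physiology", "q_fa_c"),
    "QGuC": ("physiology", "q_gu_c"),
    "QStC": ("physiology", "q_st_c"),
    "QSpdC": ("physiology", "q_spd_c"),
    "QRpdC": ("physiology", "q_rpd_c"),
    "QLymphC": ("physiology", "q_lymph_c"),
    "PORALDOSE": ("exposure", "oral_dose"),
    "DRINKTIME": ("exposure", "drink_time"),
    "FracDOSE": ("exposure", "frac_dose"),
    "k_Ga": ("exposure", "k_ga"),
    "k_max": ("exposure", "k_max"),
    "k_min": ("exposure", "k_min"),
    "T12dinch": ("metabolism", "t_half_dinch"),
    "T12dinch_gut": ("metabolism", "t_half_dinch_gut"),
    "T12minch": ("metabolism", "t_half_minch"),
    "MPY": ("metabolism", "mpy"),
    "MPY_gut": ("metabolism", "mpy_gut"),
    "FracMetabOH": ("metabolism", "frac_metab_oh"),
    "FracMetabcx": ("metabolism", "frac_metab_cx"),
    "K1_OH": ("metabolism", "k1_oh"),
    "K1_cx": ("metabolism", "k1_cx"),
    "Rurine": ("urine", "r_urine"),
    "Creat": ("urine", "creat"),
}

# The published parameter listing labels the plasma *unbound* fractions
# FBDINCH and FBMINCH (the values are fu, not fraction bound); the keys keep
# those names but set fu.
_FU_FIELDS = {"FBDINCH": "dinch", "FBMINCH": "minch"}

_PC_NAME = re.compile(r"^PC_(dinch|minch)_(adipose|liver|gut|stomach|rapid|slow|blood_cells)$")


def parameter_names() -> list[str]:
    """All canonical override names (published abbreviations plus PCs)."""
    names = list(_SCALAR_FIELDS) + list(_FU_FIELDS)
    for sp in ("dinch", "minch"):
        for t in PC_TISSUES:
            names.append(f"PC_{sp}_{t}")
    return names


def apply_overrides(
    bundle: ParameterBundle, overrides: Mapping[str, float]
) -> ParameterBundle:
    """Return a copy of ``bundle`` with named parameters replaced.

    Names follow the published abbreviations (``BW``, ``VLiC``, ``QCC``,
    ``FracDOSE``, ``K1_OH``, ...), ``FBDINCH``/``FBMINCH`` for the plasma
    unbound fractions and ``PC_<species>_<tissue>`` for partition
    coefficients.  Unknown names raise :class:`InputError`.
    """
    groups: dict[str, dict[str, float]] = {}
    chem_updates: dict[str, dict[str, float]] = {"dinch": {}, "minch": {}}
    pc_updates: dict[str, dict[str, float]] = {"dinch": {}, "minch": {}}
    for name, value in overrides.items():
        if name in _SCALAR_FIELDS:
            attr, fieldname = _SCALAR_FIELDS[name]
            groups.setdefault(attr, {})[fieldname] = float(value)
        elif name in _FU_FIELDS:
            chem_updates[_FU_FIELDS[name]]["fu"] = float(value)
        else:
            match = _PC_NAME.match(name)
            if not match:
                raise InputError(f"unknown parameter name {name!r}")
            sp, tissue = match.groups()
            pc_updates[sp][tissue] = float(value)

    new = bundle
    for attr, kwargs in groups.items():
        new = replace(new, **{attr: replace(getattr(new, attr), **kwargs)})
    for sp in ("dinch", "minch"):
        if chem_updates[sp] or pc_updates[sp]:
            chem: ChemicalParams = getattr(new, sp)
            pc = dict(chem.pc)
            pc.update(pc_updates[sp])
            new = replace(new, **{sp: replace(chem, pc=pc, **chem_updates[sp])})
    return new


def bundle_from_named(
    overrides: Mapping[str, float], base: ParameterBundle | None = None
) -> ParameterBundle:
    return apply_overrides(base if base is not None else default_bundle(), overrides)
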