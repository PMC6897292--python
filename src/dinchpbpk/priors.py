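"""Parameter distributions, design bounds and calibration priors.

Houses the published probability distributions for every model parameter:
the physiological and kinetic distributions used for uncertainty and
sensitivity analysis (normal, lognormal and uniform families, with the
half/double rule supplying uniform ranges for parameters that have only a
point value), the volunteer-specific urine-production and creatinine
statistics, and the calibration priors — including the correlated bivariate
normal prior on (Rurine, Creat) with correlation -0.7 and the improper
scale prior p(sigma) ∝ 1/sigma.

Design-space conventions: uniform parameters contribute their stated bounds;
normal and lognormal parameters contribute their 5th/95th percentiles as
design bounds.  For sampling in sensitivity designs, normal distributions
are truncated at their 0.1/99.9 percentiles and, for strictly positive
quantities, the lower truncation point is never allowed below one tenth of
the mean (a positivity safeguard for parameters such as the urine production
rate whose normal left tail would otherwise reach zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InputError
from .params import DINCH, MINCH, PC_TISSUES

__all__ = [
    "ParameterDistribution",
    "PriorSpec",
    "half_double_bounds",
    "uniform",
    "normal",
    "lognormal",
    "table3_distributions",
    "screening_distributions",
    "top11_distributions",
    "GSA_TOP11",
    "VOLUNTEERS",
    "prior_set",
    "sample",
    "log_prior",
]


def half_double_bounds(point_value: float) -> tuple[float, float]:
    """Uniform range for a parameter with only a point value: (v/2, 2v)."""
    if point_value <= 0:
        raise InputError("half/double rule requires a positive point value")
    return point_value / 2.0, point_value * 2.0


@dataclass(frozen=True)
class ParameterDistribution:
    """One marginal distribution with truncation-aware sampling helpers.

    ``a``/``b`` are family-specific: bounds for ``uniform``, mean/sd for
    ``normal``, log-scale mean/sd (natural log) for ``lognormal``.  ``lower``
    and ``upper`` truncate sampling and inverse-CDF mapping (used for
    sensitivity designs); the prior density ``logpdf`` is the plain family
    density, matching how the priors are published.
    """

    name: str
    family: str  # uniform | normal | lognormal | improper_reciprocal
    a: float = 0.0
    b: float = 1.0
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.family == "uniform":
            if not self.b > self.a:
                raise InputError(f"{self.name}: degenerate uniform bounds")
        elif self.family in ("normal", "lognormal"):
            if self.b <= 0:
                raise InputError(f"{self.name}: sd must be positive")
        elif self.family != "improper_reciprocal":
            raise InputError(f"{self.name}: unknown family {self.family!r}")

    # -- scipy frozen distribution (built once, cached) ----------------------
    def _frozen(self):
        frz = getattr(self, "_frz", None)
        if frz is None:
            if self.family == "uniform":
                frz = stats.uniform(self.a, self.b - self.a)
            elif self.family == "normal":
                frz = stats.norm(self.a, self.b)
            elif self.family == "lognormal":
                frz = stats.lognorm(s=self.b, scale=math.exp(self.a))
            else:
                raise InputError(f"{self.name}: family {self.family!r} has no CDF")
            object.__setattr__(self, "_frz", frz)
        return frz

    def _trunc_q(self) -> tuple[float, float]:
        d = self._frozen()
        qlo = d.cdf(self.lower) if self.lower is not None else 0.0
        qhi = d.cdf(self.upper) if self.upper is not None else 1.0
        return float(qlo), float(qhi)

    def ppf(self, q: np.ndarray | float) -> np.ndarray | float:
        """Inverse CDF of the (truncated) distribution, for [0,1] designs."""
        qlo, qhi = self._trunc_q()
        return self._frozen().ppf(qlo + (qhi - qlo) * np.asarray(q, dtype=float))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.asarray(self.ppf(rng.uniform(0.0, 1.0, size=n)), dtype=float)

    def logpdf(self, x: float) -> float:
        # closed forms: this sits in the sampler's innermost loop
        if self.family == "improper_reciprocal":
            return -math.inf if x <= 0 else -math.log(x)
        if self.family == "uniform":
            if self.a <= x <= self.b:
                return -math.log(self.b - self.a)
            return -math.inf
        if self.family == "normal":
            z = (x - self.a) / self.b
            return -0.5 * math.log(2.0 * math.pi) - math.log(self.b) - 0.5 * z * z
        if x <= 0:
            return -math.inf
        z = (math.log(x) - self.a) / self.b
        return (
            -math.log(x * self.b) - 0.5 * math.log(2.0 * math.pi) - 0.5 * z * z
        )

    def median(self) -> float:
        if self.family == "improper_reciprocal":
            return 1.0
        return float(self.ppf(0.5))

    def scale(self) -> float:
        """Characteristic spread, used to size proposal steps."""
        if self.family == "uniform":
            return (self.b - self.a) / math.sqrt(12.0)
        if self.family == "normal":
            return self.b
        if self.family == "lognormal":
            return float(self._frozen().std())
        return 0.3

    def design_bounds(self) -> tuple[float, float]:
        """Bounds for space-filling designs: stated bounds for uniforms,
        the 5th/95th percentiles for normal and lognormal families."""
        if self.family == "uniform":
            return self.a, self.b
        d = self._frozen()
        return float(d.ppf(0.05)), float(d.ppf(0.95))


def uniform(name: str, a: float, b: float) -> ParameterDistribution:
    return ParameterDistribution(name, "uniform", a, b)


def normal(
    name: str, mean: float, sd: float, positive: bool = True
) -> ParameterDistribution:
    """Normal distribution truncated (for sampling) at the 0.1/99.9
    percentiles, with the positivity safeguard on the lower bound."""
    lo = mean + stats.norm.ppf(0.001) * sd
    hi = mean + stats.norm.ppf(0.999) * sd
    if positive:
        lo = max(lo, mean / 10.0)
    return ParameterDistribution(name, "normal", mean, sd, lower=lo, upper=hi)


def lognormal(name: str, mu_ln: float, sd_ln: float) -> ParameterDistribution:
    d = stats.lognorm(s=sd_ln, scale=math.exp(mu_ln))
    return ParameterDistribution(
        name, "lognormal", mu_ln, sd_ln,
        lower=float(d.ppf(0.001)), upper=float(d.ppf(0.999)),
    )


def half_double_uniform(name: str, point: float) -> ParameterDistribution:
    lo, hi = half_double_bounds(point)
    return ParameterDistribution(name, "uniform", lo, hi)


# ---------------------------------------------------------------------------
# published distribution tables
# ---------------------------------------------------------------------------

def table3_distributions() -> dict[str, ParameterDistribution]:
    """The physiological/kinetic parameter distributions used for UA/GSA."""
    return {
        "BW": normal("BW", 72.3, 9.05),
        "VLiC": normal("VLiC", 3.09, 0.8),
        "VFaC": lognormal("VFaC", 3.42, 0.43),
        "VGuC": uniform("VGuC", 1.19, 1.84),
        "VStC": normal("VStC", 0.22, 0.07),
        "VSpdC": normal("VSpdC", 60.7, 9.4),
        "VRpdC": normal("VRpdC", 3.7, 0.26),
        "VBldC": uniform("VBldC", 2.5, 10.0),
        "VLymphC": uniform("VLymphC", 0.18, 0.72),
        "QCC": normal("QCC", 13.8, 2.5),
        "QHepartC": normal("QHepartC", 6.89, 0.52),
        "QFaC": normal("QFaC", 5.3, 0.3),
        "QGuC": uniform("QGuC", 13.2, 16.6),
        "QStC": normal("QStC", 1.1, 0.08),
        "QSpdC": normal("QSpdC", 28.7, 1.91),
        "QRpdC": normal("QRpdC", 43.1, 2.78),
        "QLymphC": uniform("QLymphC", 0.02, 0.08),
        "T12dinch": uniform("T12dinch", 15.0, 60.0),
        "T12minch": normal("T12minch", 30.54, 2.39),
        "T12dinch_gut": uniform("T12dinch_gut", 15.0, 60.0),
        "MPY": normal("MPY", 34.0, 15.0),
        "MPY_gut": uniform("MPY_gut", 1.95, 7.8),
        "FBDINCH": uniform("FBDINCH", 1e-5, 0.01),
        "FBMINCH": uniform("FBMINCH", 0.001, 0.01),
        "k_max": uniform("k_max", 5.1, 20.4),
        "k_min": uniform("k_min", 0.0025, 0.01),
        "k_Ga": uniform("k_Ga", 12.55, 50.2),
        "DRINKTIME": uniform("DRINKTIME", 0.125, 0.5),
        "FracDOSE": uniform("FracDOSE", 0.0, 1.0),
        "FracMetabOH": normal("FracMetabOH", 0.25, 0.05),
        "FracMetabcx": normal("FracMetabcx", 0.0475, 0.01),
        "Rurine": normal("Rurine", 0.104, 0.053),
        "Creat": normal("Creat", 1.278, 0.605),
        "K1_OH": uniform("K1_OH", 0.05, 2.0),
        "K1_cx": uniform("K1_cx", 0.05, 2.0),
    }


def screening_distributions() -> dict[str, ParameterDistribution]:
    """The full screening set: every kinetic/physiological parameter plus the
    predicted partition coefficients (half/double ranges).  The resulting
    count is documented by the suite rather than forced to a given total."""
    d = table3_distributions()
    for chem, tag in ((DINCH, "dinch"), (MINCH, "minch")):
        for tissue in PC_TISSUES:
            name = f"PC_{tag}_{tissue}"
            d[name] = half_double_uniform(name, chem.pc[tissue])
    return d


#: the eleven parameters retained after elementary-effects screening
GSA_TOP11 = (
    "BW", "MPY", "T12minch", "FracDOSE", "DRINKTIME",
    "FracMetabOH", "FracMetabcx", "K1_OH", "K1_cx", "Rurine", "Creat",
)


def top11_distributions() -> dict[str, ParameterDistribution]:
    t3 = table3_distributions()
    return {k: t3[k] for k in GSA_TOP11}


# ---------------------------------------------------------------------------
# volunteer registry and calibration priors
# ---------------------------------------------------------------------------

#: per-volunteer covariates: body weight (kg), dose (mg/kg), urine production
#: rate mean/sd (L/h) and creatinine concentration mean/sd (g/L)
VOLUNTEERS: dict[str, dict[str, float]] = {
    "A": {"bw": 89.0, "dose": 0.558, "rurine": 0.104, "rurine_sd": 0.053,
          "creat": 1.278, "creat_sd": 0.605},
    "B": {"bw": 90.0, "dose": 0.552, "rurine": 0.158, "rurine_sd": 0.086,
          "creat": 0.962, "creat_sd": 0.672},
    "C": {"bw": 82.0, "dose": 0.606, "rurine": 0.190, "rurine_sd": 0.242,
          "creat": 1.278, "creat_sd": 0.831},
}

#: prior correlation between the urine production rate and the creatinine
#: concentration (dilute urine is produced faster)
RURINE_CREAT_CORR = -0.7


@dataclass(frozen=True)
class PriorSpec:
    """Joint prior: independent marginals plus correlated (Rurine, Creat)
    bivariate-normal blocks and an improper 1/sigma scale prior."""

    marginals: dict[str, ParameterDistribution]
    mvn_pairs: tuple[tuple[str, str, float], ...] = ()
    sigma_name: str = "sigma"

    @property
    def names(self) -> list[str]:
        return list(self.marginals) + [self.sigma_name]

    def mvn_members(self) -> set[str]:
        out: set[str] = set()
        for n1, n2, _ in self.mvn_pairs:
            out.update((n1, n2))
        return out


def prior_set(
    name: str,
    volunteers: Sequence[str] | None = None,
    frac_metab_flat: bool = False,
) -> PriorSpec:
    """Named prior sets for calibration.

    ``table4_free_dose`` / ``table4_fixed_dose``: the two-volunteer (A, B)
    calibration with the oral dose either free with a weakly informative
    U(0.1, 0.9) prior or fixed.  ``table5_volunteerC``: the fixed-dose
    volunteer-C calibration with its own fraction-metabolised priors.
    ``frac_metab_flat`` swaps the informative fraction-metabolised priors
    for flat U(0, 1) priors (the preliminary-analysis variant under which
    the dose posterior becomes very wide).
    """
    if name == "table5_volunteerC":
        vols = tuple(volunteers) if volunteers is not None else ("C",)
        fm_oh = normal("FracMetabOH", 0.202, 0.05)
        fm_cx = normal("FracMetabcx", 0.049, 0.01)
        free_dose = False
    elif name in ("table4_free_dose", "table4_fixed_dose"):
        vols = tuple(volunteers) if volunteers is not None else ("A", "B")
        fm_oh = normal("FracMetabOH", 0.25, 0.05)
        fm_cx = normal("FracMetabcx", 0.0475, 0.01)
        free_dose = name == "table4_free_dose"
    else:
        raise InputError(f"unknown prior set {name!r}")
    if frac_metab_flat:
        fm_oh = uniform("FracMetabOH", 0.0, 1.0)
        fm_cx = uniform("FracMetabcx", 0.0, 1.0)

    marg: dict[str, ParameterDistribution] = {}
    if free_dose:
        marg["PORALDOSE"] = uniform("PORALDOSE", 0.1, 0.9)
    marg["FracDOSE"] = uniform("FracDOSE", 0.0, 1.0)
    marg["MPY"] = normal("MPY", 34.0, 15.0)
    marg["K1_OH"] = uniform("K1_OH", 0.05, 2.0)
    marg["K1_cx"] = uniform("K1_cx", 0.05, 2.0)
    marg["FracMetabOH"] = fm_oh
    marg["FracMetabcx"] = fm_cx
    pairs = []
    for v in vols:
        info = VOLUNTEERS[v]
        rn, cn = f"Rurine_{v}", f"Creat_{v}"
        marg[rn] = normal(rn, info["rurine"], info["rurine_sd"])
        marg[cn] = normal(cn, info["creat"], info["creat_sd"])
        pairs.append((rn, cn, RURINE_CREAT_CORR))
    return PriorSpec(marginals=marg, mvn_pairs=tuple(pairs))


# ---------------------------------------------------------------------------
# sampling and densities
# ---------------------------------------------------------------------------

def sample(
    distributions: Mapping[str, ParameterDistribution],
    n: int,
    seed: int | np.random.Generator,
    mvn_pairs: Iterable[tuple[str, str, float]] = (),
) -> pd.DataFrame:
    """Draw ``n`` joint samples; reproducible given the seed.

    Parameters listed in ``mvn_pairs`` are drawn jointly from a bivariate
    normal with the requested correlation (their marginal means/sds come
    from the corresponding entries of ``distributions``); everything else is
    drawn independently from its marginal.
    """
    if n < 1:
        raise InputError("n must be at least 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    pairs = list(mvn_pairs)
    paired = {nm for n1, n2, _ in pairs for nm in (n1, n2)}
    out: dict[str, np.ndarray] = {}
    for name, dist in distributions.items():
        if name in paired:
            continue
        out[name] = dist.sample(rng, n)
    for n1, n2, corr in pairs:
        d1, d2 = distributions[n1], distributions[n2]
        if d1.family != "normal" or d2.family != "normal":
            raise InputError("correlated pairs must have normal marginals")
        cov = [
            [d1.b**2, corr * d1.b * d2.b],
            [corr * d1.b * d2.b, d2.b**2],
        ]
        draws = rng.multivariate_normal([d1.a, d2.a], cov, size=n)
        out[n1] = draws[:, 0]
        out[n2] = draws[:, 1]
    return pd.DataFrame(out)


def log_prior(theta: Mapping[str, float], spec: PriorSpec) -> float:
    """Joint log prior density (up to the improper-prior constant).

    Sums the independent marginal log densities, the bivariate-normal terms
    for each correlated (Rurine, Creat) block and ``-log sigma``; returns
    ``-inf`` outside any uniform support or for ``sigma <= 0``.
    """
    paired = spec.mvn_members()
    total = 0.0
    for name, dist in spec.marginals.items():
        if name in paired:
            continue
        if name not in theta:
            raise InputError(f"theta missing parameter {name!r}")
        total += dist.logpdf(float(theta[name]))
        if not np.isfinite(total):
            return -math.inf
    for n1, n2, corr in spec.mvn_pairs:
        d1, d2 = spec.marginals[n1], spec.marginals[n2]
        z1 = (float(theta[n1]) - d1.a) / d1.b
        z2 = (float(theta[n2]) - d2.a) / d2.b
        om = 1.0 - corr * corr
        total += (
            -math.log(2.0 * math.pi * d1.b * d2.b * math.sqrt(om))
            - (z1 * z1 - 2.0 * corr * z1 * z2 + z2 * z2) / (2.0 * om)
        )
    sigma = float(theta.get(spec.sigma_name, np.nan))
    if not np.isfinite(sigma) or sigma <= 0:
        return -math.inf
    total -= math.log(sigma)
    return total
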