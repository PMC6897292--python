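"""Uncertainty analysis and two-phase global sensitivity analysis.

Phase zero is uncertainty propagation: a maximin Latin hypercube design over
the published parameter ranges, run through the kinetic model to produce
trajectory envelopes for venous DINCH/MINCH and urinary OH-MINCH.

Phase one screens the full parameter set with Morris elementary effects
(randomised one-at-a-time trajectories; ranking by the mean absolute
elementary effect).  Phase two estimates variance-based main- and
total-effect indices for the retained subset with the extended Fourier
amplitude sensitivity test (eFAST): each parameter in turn is assigned the
highest driver frequency while the complementary set oscillates at low
frequencies; the Fourier spectrum of the model output decomposes its
variance.  Lowry summaries order the parameters and bound the variance
attributable to interactions by the cumulative main effects from below and
the cumulative total effects from above.

Distributions are mapped into the unit design cube through their
(truncated) inverse CDFs.  Parameter combinations rejected by the
mass-balance closure are resampled within their stratum (Latin hypercube)
or their trajectory is dropped (Morris), with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import qmc

from .exceptions import InfeasibleParameterError, InputError
from .model import instantaneous_urine_concentration, simulate
from .params import ParameterBundle, apply_overrides, default_bundle, resolve_parameters
from .priors import ParameterDistribution

logger = logging.getLogger(__name__)

__all__ = [
    "Design",
    "SensitivityIndices",
    "lhs_maximin",
    "run_ensemble",
    "morris_screen",
    "efast",
    "lowry_summary",
    "urine_output_functional",
    "blood_output_functional",
]


@dataclass(frozen=True)
class Design:
    """A sampling design: unit-cube matrix plus the scaled parameter values."""

    names: tuple[str, ...]
    unit: np.ndarray  # (n, p) in [0, 1]
    samples: pd.DataFrame  # scaled to parameter space
    bounds: dict[str, tuple[float, float]]
    kind: str
    seed: int

    @property
    def n(self) -> int:
        return self.unit.shape[0]


def lhs_maximin(
    bounds: Mapping[str, tuple[float, float]],
    n: int,
    seed: int,
    n_candidates: int = 20,
) -> Design:
    """Maximin-selected Latin hypercube design.

    ``n_candidates`` Latin hypercubes are generated and the one with the
    largest minimum pairwise distance (in the unit cube) is kept; each
    column retains exactly one point per stratum.
    """
    if n < 2:
        raise InputError("a space-filling design needs n >= 2")
    names = tuple(bounds)
    for nm, (lo, hi) in bounds.items():
        if not hi > lo:
            raise InputError(f"degenerate bounds for {nm!r}")
    rng = np.random.default_rng(seed)
    best = None
    best_dist = -np.inf
    for _ in range(max(1, n_candidates)):
        sampler = qmc.LatinHypercube(d=len(names), seed=rng)
        cand = sampler.random(n)
        d = pdist(cand).min()
        if d > best_dist:
            best, best_dist = cand, d
    scaled = {
        nm: bounds[nm][0] + best[:, j] * (bounds[nm][1] - bounds[nm][0])
        for j, nm in enumerate(names)
    }
    return Design(
        names=names,
        unit=best,
        samples=pd.DataFrame(scaled),
        bounds={nm: (float(lo), float(hi)) for nm, (lo, hi) in bounds.items()},
        kind="maximin-lhs",
        seed=seed,
    )


# ---------------------------------------------------------------------------
# model output functionals
# ---------------------------------------------------------------------------

def urine_output_functional(
    times: Sequence[float],
    base: ParameterBundle | None = None,
    combined: bool = True,
) -> Callable[[Mapping[str, float]], np.ndarray]:
    """Continuous urinary metabolite concentration (mg/g creatinine).

    With ``combined=True`` the OH- and cx-metabolite concentrations are
    summed into a single profile at ``times``; with ``combined=False`` the
    two per-metabolite profiles are concatenated (used for screening, so
    that parameters acting only on the minor metabolite are not masked by
    the dominant one).  Returns a callable mapping a dict of named parameter
    overrides to the output vector; ``InfeasibleParameterError`` propagates
    so design logic can handle rejected closures.
    """
    base = base if base is not None else default_bundle()
    t_arr = np.asarray(sorted(times), dtype=float)
    t_end = float(t_arr[-1])

    def func(overrides: Mapping[str, float]) -> np.ndarray:
        rp = resolve_parameters(apply_overrides(base, overrides))
        res = simulate(rp, t_end, output_times=t_arr)
        if combined:
            return instantaneous_urine_concentration(res)
        oh, cx = instantaneous_urine_concentration(res, split=True)
        return np.concatenate([oh, cx])

    return func


def blood_output_functional(
    times: Sequence[float],
    species: str = "dinch",
    base: ParameterBundle | None = None,
) -> Callable[[Mapping[str, float]], np.ndarray]:
    """Venous blood concentration (mg/L) of DINCH or MINCH at ``times``."""
    base = base if base is not None else default_bundle()
    t_arr = np.asarray(sorted(times), dtype=float)
    t_end = float(t_arr[-1])

    def func(overrides: Mapping[str, float]) -> np.ndarray:
        rp = resolve_parameters(apply_overrides(base, overrides))
        res = simulate(rp, t_end, output_times=t_arr)
        if species == "dinch":
            return res.conc_dinch_blood_mg_l
        return res.conc_minch_blood_mg_l

    return func


def run_ensemble(
    design: Design,
    func: Callable[[Mapping[str, float]], np.ndarray],
    max_resample: int = 20,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Evaluate ``func`` on every design point.

    Infeasible points (mass-balance closure failure) are resampled uniformly
    within their Latin stratum up to ``max_resample`` times; a warning is
    emitted if more than 10% of points needed intervention.  Returns the
    output matrix (n, n_out) and an envelope frame with the pointwise
    min/median/max.
    """
    rng = np.random.default_rng(seed)
    n = design.n
    rows = []
    n_infeasible = 0
    strata = (design.unit * n).astype(int)  # stratum index per point/column
    for i in range(n):
        point = {nm: float(design.samples.iloc[i][nm]) for nm in design.names}
        for attempt in range(max_resample + 1):
            try:
                rows.append(np.asarray(func(point), dtype=float))
                break
            except InfeasibleParameterError:
                n_infeasible += 1
                if attempt == max_resample:
                    raise
                # redraw within the same stratum of each column
                u = (strata[i] + rng.uniform(0.0, 1.0, size=len(design.names))) / n
                for j, nm in enumerate(design.names):
                    lo, hi = design.bounds[nm]
                    point[nm] = lo + u[j] * (hi - lo)
    if n_infeasible > 0.1 * n:
        logger.warning("%d infeasible design points were resampled", n_infeasible)
    out = np.vstack(rows)
    env = pd.DataFrame(
        {
            "min": out.min(axis=0),
            "median": np.median(out, axis=0),
            "max": out.max(axis=0),
        }
    )
    return out, env


# ---------------------------------------------------------------------------
# Morris elementary-effects screening
# ---------------------------------------------------------------------------

def morris_screen(
    func: Callable[[Mapping[str, float]], np.ndarray],
    distributions: Mapping[str, ParameterDistribution],
    r: int = 20,
    levels: int = 8,
    seed: int = 0,
    top_k: int = 11,
    aggregate: str = "max",
) -> pd.DataFrame:
    """Elementary-effects screening over randomised trajectories.

    Each of ``r`` trajectories perturbs every parameter once by
    ``delta = levels / (2 (levels - 1))`` on the ``levels``-level grid in the
    unit cube; parameters are mapped to their distributions by inverse CDF.
    Returns a frame indexed by parameter with ``mu`` (mean EE), ``mu_star``
    (mean |EE|), ``sigma`` (EE spread), a descending ``rank`` by the
    composite importance and a boolean ``retained`` flag for the ``top_k``
    leaders.  For vector-valued outputs the |EE| statistics are normalised
    per output component (so early- and late-time behaviour contribute
    comparably) and combined across components with ``aggregate``: ``max``
    (default — a parameter is retained if it is influential at any output)
    or ``mean``.
    """
    if aggregate not in ("max", "mean"):
        raise InputError("aggregate must be 'max' or 'mean'")
    if r < 4:
        raise InputError("Morris screening needs at least 4 trajectories")
    if levels < 2 or levels % 2:
        raise InputError("levels must be an even number >= 2")
    names = list(distributions)
    p = len(names)
    delta = levels / (2.0 * (levels - 1.0))
    grid = np.arange(levels) / (levels - 1.0)
    rng = np.random.default_rng(seed)

    ee_by_param: dict[str, list[np.ndarray]] = {nm: [] for nm in names}
    n_dropped = 0
    for _ in range(r):
        # base point and step directions such that x + d*delta stays in [0,1]
        direction = rng.choice([-1.0, 1.0], size=p)
        base = np.empty(p)
        for j in range(p):
            ok = grid[(grid + direction[j] * delta >= -1e-12)
                      & (grid + direction[j] * delta <= 1 + 1e-12)]
            base[j] = rng.choice(ok)
        order = rng.permutation(p)
        x = base.copy()
        try:
            y_prev = np.atleast_1d(
                np.asarray(func(_scale(x, names, distributions)), dtype=float)
            )
            effects = {}
            for j in order:
                x = x.copy()
                x[j] = min(1.0, max(0.0, x[j] + direction[j] * delta))
                y = np.atleast_1d(
                    np.asarray(func(_scale(x, names, distributions)), dtype=float)
                )
                effects[names[j]] = (y - y_prev) / (direction[j] * delta)
                y_prev = y
            if any(not np.all(np.isfinite(e)) for e in effects.values()):
                raise FloatingPointError("non-finite model output")
        except (InfeasibleParameterError, FloatingPointError) as exc:
            n_dropped += 1
            logger.warning("Morris trajectory dropped: %s", exc)
            continue
        for nm, e in effects.items():
            ee_by_param[nm].append(e)
    if not ee_by_param[names[0]]:
        raise InputError("all Morris trajectories failed")
    if n_dropped:
        logger.warning("%d of %d Morris trajectories dropped", n_dropped, r)

    ee = {nm: np.vstack(v) for nm, v in ee_by_param.items()}  # (r_ok, n_out)
    n_out = ee[names[0]].shape[1]
    mu_star_mat = np.vstack([np.abs(ee[nm]).mean(axis=0) for nm in names])
    # normalise each output component so no single time point dominates
    col_norm = mu_star_mat.sum(axis=0)
    col_norm[col_norm == 0] = 1.0
    shares = mu_star_mat / col_norm
    importance = shares.max(axis=1) if aggregate == "max" else shares.mean(axis=1)
    df = pd.DataFrame(
        {
            "mu": [ee[nm].mean() for nm in names],
            "mu_star": mu_star_mat.mean(axis=1),
            "sigma": [ee[nm].std(ddof=1 if ee[nm].shape[0] > 1 else 0)
                      for nm in names],
            "importance": importance,
        },
        index=pd.Index(names, name="parameter"),
    )
    df["rank"] = df["importance"].rank(ascending=False, method="first").astype(int)
    df["retained"] = df["rank"] <= top_k
    return df.sort_values("rank")


def _scale(
    x: np.ndarray,
    names: Sequence[str],
    distributions: Mapping[str, ParameterDistribution],
) -> dict[str, float]:
    return {nm: float(distributions[nm].ppf(x[j])) for j, nm in enumerate(names)}


# ---------------------------------------------------------------------------
# eFAST
# ---------------------------------------------------------------------------

@dataclass
class SensitivityIndices:
    """Main- and total-effect indices per parameter and output component."""

    names: tuple[str, ...]
    outputs: np.ndarray  # output grid (e.g. times)
    s_main: np.ndarray  # (p, n_out)
    s_total: np.ndarray  # (p, n_out)

    def interaction(self) -> np.ndarray:
        return self.s_total - self.s_main

    def frame(self) -> pd.DataFrame:
        rows = []
        for i, nm in enumerate(self.names):
            for j, t in enumerate(np.atleast_1d(self.outputs)):
                rows.append(
                    {
                        "parameter": nm,
                        "output": t,
                        "s_main": self.s_main[i, j],
                        "s_total": self.s_total[i, j],
                    }
                )
        return pd.DataFrame(rows)


def efast(
    func: Callable[[Mapping[str, float]], np.ndarray],
    distributions: Mapping[str, ParameterDistribution],
    n_per_curve: int = 65,
    interference: int = 4,
    resamples: int = 1,
    seed: int = 0,
    outputs: Sequence[float] | None = None,
) -> SensitivityIndices:
    """Extended Fourier amplitude sensitivity test.

    For each parameter a search curve assigns it the driver frequency
    ``omega = (N - 1) // (2 M)`` while the complementary parameters move at
    frequencies no higher than ``omega / (2 M)``; the main effect is the
    spectral mass at the driver frequency and its first ``M`` harmonics, the
    total effect is one minus the low-frequency (complementary) mass.
    ``resamples`` independent random-phase curves are pooled: spectral
    masses are summed across curves before ratios are taken, which removes
    the large per-curve fluctuation of the path variance caused by
    phase-locked low-frequency complementary parameters.  Requires
    ``N >= 4 M^2 + 1`` so the driver harmonics stay below Nyquist.
    """
    names = list(distributions)
    p = len(names)
    N = int(n_per_curve)
    M = int(interference)
    omega_max = (N - 1) // (2 * M)
    if omega_max < 1 or N < 4 * M * M + 1:
        raise InputError(
            f"n_per_curve={N} too small for interference factor {M} "
            f"(need at least {4 * M * M + 1})"
        )
    m_compl = max(1, omega_max // (2 * M))
    rng = np.random.default_rng(seed)
    s = 2.0 * np.pi / N * np.arange(N)

    harmonics = [omega_max * q for q in range(1, M + 1) if omega_max * q <= N // 2]
    low = np.arange(1, omega_max // 2 + 1)
    d_main_acc = None  # (p, n_out) pooled spectral masses
    d_compl_acc = None
    var_acc = None
    for _ in range(max(1, resamples)):
        for i in range(p):
            omega = np.empty(p)
            omega[i] = omega_max
            idx = [j for j in range(p) if j != i]
            omega[idx] = (np.arange(p - 1) % m_compl) + 1
            phi = rng.uniform(0.0, 2.0 * np.pi, size=p)
            # search curve through the unit cube
            X = 0.5 + np.arcsin(np.sin(np.outer(s, omega) + phi)) / np.pi
            Y = np.vstack(
                [
                    np.atleast_1d(
                        np.asarray(
                            func(_scale(X[k], names, distributions)), dtype=float
                        )
                    )
                    for k in range(N)
                ]
            )  # (N, n_out)
            n_out = Y.shape[1]
            if d_main_acc is None:
                d_main_acc = np.zeros((p, n_out))
                d_compl_acc = np.zeros((p, n_out))
                var_acc = np.zeros((p, n_out))
            F = np.fft.rfft(Y - Y.mean(axis=0, keepdims=True), axis=0)
            spec = (np.abs(F) ** 2) / N**2  # one-sided power per frequency
            spec[0] = 0.0
            var_acc[i] += 2.0 * spec[1: N // 2 + 1].sum(axis=0)
            d_main_acc[i] += 2.0 * spec[harmonics].sum(axis=0)
            d_compl_acc[i] += 2.0 * spec[low].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sm = np.where(var_acc > 0, d_main_acc / var_acc, 0.0)
        st = np.where(var_acc > 0, 1.0 - d_compl_acc / var_acc, 0.0)
    out_grid = (
        np.asarray(outputs, dtype=float) if outputs is not None else np.arange(n_out)
    )
    return SensitivityIndices(
        names=tuple(names), outputs=out_grid, s_main=sm, s_total=st
    )


def lowry_summary(
    names: Sequence[str], s_main: Sequence[float], s_total: Sequence[float],
    coverage_tol: float = 0.05,
) -> pd.DataFrame:
    """Lowry-plot construction at one output time.

    Parameters are ordered by descending total effect.  The interaction
    ribbon is bounded below by the cumulative sum of main effects and above
    by the smaller of the cumulative total effects and one minus the main
    effects still to come, capped at 1.  ``accounts_for_variance`` flags the
    leading subset whose upper bound reaches ``1 - coverage_tol`` — the
    parameters left of the intersection line that account for ~100% of the
    output variance.
    """
    sm = np.asarray(s_main, dtype=float)
    stt = np.asarray(s_total, dtype=float)
    order = np.argsort(-stt, kind="stable")
    sm, stt = sm[order], stt[order]
    nm = [names[i] for i in order]
    cum_sm = np.cumsum(sm)
    cum_st = np.cumsum(stt)
    remaining = cum_sm[-1] - cum_sm
    upper = np.minimum(np.minimum(cum_st, 1.0 - remaining), 1.0)
    upper = np.maximum(upper, cum_sm)  # ribbon cannot dip below its floor
    reach = np.nonzero(upper >= 1.0 - coverage_tol)[0]
    cut = reach[0] if reach.size else len(nm) - 1
    return pd.DataFrame(
        {
            "parameter": nm,
            "s_main": sm,
            "s_total": stt,
            "cum_main": cum_sm,
            "cum_total": cum_st,
            "ribbon_lower": cum_sm,
            "ribbon_upper": upper,
            "accounts_for_variance": [i <= cut for i in range(len(nm))],
        }
    )


def plot_lowry(summary: pd.DataFrame, ax=None, title: str | None = None):
    """Render a Lowry plot: stacked main/interaction bars per parameter with
    the interaction ribbon between the cumulative bounds."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    x = np.arange(len(summary))
    ax.bar(x, summary["s_main"], color="0.15", label="main effect")
    ax.bar(
        x,
        summary["s_total"] - summary["s_main"],
        bottom=summary["s_main"],
        color="0.6",
        label="interaction",
    )
    ax.fill_between(
        x, summary["ribbon_lower"], summary["ribbon_upper"],
        color="tab:blue", alpha=0.25, label="interaction ribbon",
    )
    ax.set_xticks(x)
    ax.set_xticklabels(summary["parameter"], rotation=60, ha="right")
    ax.set_ylabel("proportion of output variance")
    if title:
        ax.set_title(title)
    ax.legend(loc="center right", fontsize=8)
    return ax
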