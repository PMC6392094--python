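"""Labeling kinetics: rise-to-plateau fits, condition contrasts, flux proxies.

An FC time series from a non-stationary 13C labeling experiment rises from
its time-zero baseline (natural abundance, uncorrected by default) toward a
plateau.  With only four time points the minimal identifiable model is a
mono-exponential rise::

    FC(t) = baseline + (A - baseline) * (1 - exp(-k t)),   0 <= A <= 1, k >= 0

where A is the plateau enrichment and k the apparent first-order turnover
rate of the pool.  The product of k with the per-cell pool size is a relative
flux proxy: a pool can label slowly either because flux through it is small
or because the pool is large ("large slow-moving pools"), and the proxy
separates the two.

The full cascade forward model (precursor enrichment convolved through pool
turnover, isotopologue-resolved) is re-exported from the synthetic-data
module as :func:`predict_mdv_progression` for diagnostics and plotting, so
simulation and prediction share one implementation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .synthetic_data import mdv_progression

__all__ = [
    "LabelingCurveFit",
    "FluxProxy",
    "ConditionComparison",
    "fit_labeling_curve",
    "fit_fc_table",
    "compare_conditions",
    "compare_condition_tables",
    "predict_mdv_progression",
]


@dataclass(frozen=True)
class LabelingCurveFit:
    """Result of a mono-exponential rise-to-plateau fit to an FC series."""

    plateau: float  # A, in [0, 1]
    rate: float  # k, 1/min
    baseline: float
    rss: float
    times: tuple
    fitted: tuple
    converged: bool
    flags: tuple = ()

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        return self.baseline + (self.plateau - self.baseline) * (1.0 - np.exp(-self.rate * t))


@dataclass(frozen=True)
class FluxProxy:
    """Relative flux through a pool: turnover rate x pool size."""

    metabolite: str
    rate: float
    pool: float

    @property
    def flux(self) -> float:
        return self.rate * self.pool


def _model(t, baseline, a, k):
    return baseline + (a - baseline) * (1.0 - np.exp(-k * t))


def fit_labeling_curve(
    times: Sequence[float],
    fc: Sequence[float],
    baseline: float | None = None,
) -> LabelingCurveFit:
    """Fit FC(t) = baseline + (A - baseline)(1 - e^{-kt}) by bounded least squares.

    ``baseline`` defaults to the mean observed FC at the earliest time point
    (the uncorrected natural-abundance level); pass 0 for natural-abundance
    corrected data.  The plateau is bounded to [0, 1] and k to [0, inf).
    Two k starts are used — one from a log-linear transform of the first
    rise interval and one 10x larger — because the (A, k) surface has a
    ridge when the curve saturates between samples; ties go to the lower
    RSS, then the lower k.  Degenerate inputs are flagged rather than
    fitted: an all-equal series returns k = 0 with A at the mean, and a
    series already at >= 95 % of its plateau by the first positive time
    carries a ``rate_lower_bound`` flag since k is then only bounded below.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(fc, dtype=float)
    if t.size != y.size:
        raise ValueError("times and fc must have equal length")
    if np.unique(t).size < 3:
        raise ValueError("need >= 3 distinct time points to fit a labeling curve")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("fc values must lie in [0, 1]")
    order = np.argsort(t, kind="stable")
    t, y = t[order], y[order]
    t0 = t.min()
    if baseline is None:
        baseline = float(y[t == t0].mean())

    if np.allclose(y, y[0], atol=1e-12):
        a = float(y.mean())
        fitted = np.full_like(y, a)
        # fitted(0) = baseline by the model; with flat data baseline == a
        return LabelingCurveFit(
            plateau=a,
            rate=0.0,
            baseline=float(baseline),
            rss=float(np.sum((y - fitted) ** 2)),
            times=tuple(t),
            fitted=tuple(fitted),
            converged=False,
            flags=("flat",),
        )

    a0 = float(np.clip(max(y.max(), baseline + 1e-6), 0.0, 1.0))
    # log-linear init from the first positive-time rise
    t_pos = t[t > t0]
    k_init = 1.0 / max(t_pos.min(), 1e-6)
    if a0 > baseline:
        y1 = float(y[t == t_pos.min()].mean())
        ratio = (y1 - baseline) / (a0 - baseline)
        if 0.0 < ratio < 1.0:
            k_init = -math.log(1.0 - ratio) / t_pos.min()

    best = None
    for k0 in (k_init, 10.0 * k_init):
        def resid(p):
            return _model(t, baseline, p[0], p[1]) - y

        sol = optimize.least_squares(
            resid,
            x0=[a0, max(k0, 1e-6)],
            bounds=([0.0, 0.0], [1.0, np.inf]),
        )
        rss = float(np.sum(sol.fun**2))
        cand = (rss, float(sol.x[1]), float(sol.x[0]), sol.success)
        if best is None or (rss, cand[1]) < (best[0], best[1]):
            best = cand
    rss, k_hat, a_hat, ok = best
    fitted = _model(t, baseline, a_hat, k_hat)
    flags = []
    if a_hat > baseline:
        y1 = float(y[t == t_pos.min()].mean())
        if y1 >= baseline + 0.95 * (a_hat - baseline):
            flags.append("rate_lower_bound")
    return LabelingCurveFit(
        plateau=a_hat,
        rate=k_hat,
        baseline=float(baseline),
        rss=rss,
        times=tuple(t),
        fitted=tuple(fitted),
        converged=bool(ok),
        flags=tuple(flags),
    )


def fit_fc_table(fc_table: pd.DataFrame, baseline: float | None = None) -> pd.DataFrame:
    """Fit one labeling curve per metabolite x condition from a tidy FC table.

    Expects columns metabolite, condition, time_min, fc (replicate rows are
    pooled into the fit).  Returns one row per fit with plateau, rate, rss,
    baseline, convergence and flags.
    """
    rows = []
    for (met, cond), grp in fc_table.groupby(["metabolite", "condition"], sort=True):
        fit = fit_labeling_curve(grp["time_min"].to_numpy(), grp["fc"].to_numpy(), baseline)
        rows.append(
            dict(
                metabolite=met,
                condition=cond,
                plateau=fit.plateau,
                rate=fit.rate,
                baseline=fit.baseline,
                rss=fit.rss,
                converged=fit.converged,
                flags=";".join(fit.flags),
            )
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ConditionComparison:
    """Limited-vs-replete contrast of labeling kinetics and pool size."""

    metabolite: str
    delta_rate: float  # k_limited - k_replete
    delta_plateau: float
    delta_fc: tuple  # (time, fc_limited - fc_replete) at observed times
    pool_ratio: float  # limited / replete
    flux_ratio: float  # (k * pool) limited / replete
    classification: str  # "large-slow" | "small-fast" | "mixed" | "unclassified"
    flags: tuple = ()


def compare_conditions(
    fit_limited: LabelingCurveFit,
    fit_replete: LabelingCurveFit,
    pool_limited: float,
    pool_replete: float,
    metabolite: str = "",
) -> ConditionComparison:
    """Contrast two fitted conditions for one metabolite.

    Classification by sign pattern: slower turnover with a larger pool under
    limitation is "large-slow"; faster turnover with a smaller pool is
    "small-fast"; anything else (including exact ties) is "mixed".  If either
    fit did not converge the record is flagged and left unclassified.
    """
    if pool_limited <= 0 or pool_replete <= 0:
        raise ValueError("pool sizes must be > 0")
    flags = []
    if not (fit_limited.converged and fit_replete.converged):
        flags.append("unconverged_fit")
    times = sorted(set(fit_limited.times) | set(fit_replete.times))
    delta_fc = tuple(
        (t, float(fit_limited.predict(t) - fit_replete.predict(t))) for t in times
    )
    pool_ratio = pool_limited / pool_replete
    k_l, k_r = fit_limited.rate, fit_replete.rate
    flux_ratio = (k_l * pool_limited) / (k_r * pool_replete) if k_r > 0 else float("inf")
    if flags:
        cls = "unclassified"
    elif k_l < k_r and pool_ratio > 1.0:
        cls = "large-slow"
    elif k_l > k_r and pool_ratio < 1.0:
        cls = "small-fast"
    else:
        cls = "mixed"
    return ConditionComparison(
        metabolite=metabolite,
        delta_rate=float(k_l - k_r),
        delta_plateau=float(fit_limited.plateau - fit_replete.plateau),
        delta_fc=delta_fc,
        pool_ratio=float(pool_ratio),
        flux_ratio=float(flux_ratio),
        classification=cls,
        flags=tuple(flags),
    )


def compare_condition_tables(
    fits: pd.DataFrame,
    pools: pd.DataFrame,
    limited: str = "N-limited",
    replete: str = "N-replete",
) -> pd.DataFrame:
    """Per-metabolite condition contrast from fit and pool tables.

    ``fits`` as produced by :func:`fit_fc_table`; ``pools`` with columns
    metabolite, condition, relative_abundance (replicates averaged here).
    """
    pool_mean = (
        pools.groupby(["metabolite", "condition"])["relative_abundance"].mean().unstack()
    )
    rows = []
    for met, grp in fits.groupby("metabolite", sort=True):
        by_cond = grp.set_index("condition")
        if limited not in by_cond.index or replete not in by_cond.index:
            continue
        fl, fr = by_cond.loc[limited], by_cond.loc[replete]
        k_l, k_r = float(fl["rate"]), float(fr["rate"])
        p_l = float(pool_mean.loc[met, limited])
        p_r = float(pool_mean.loc[met, replete])
        converged = bool(fl["converged"]) and bool(fr["converged"])
        if not converged:
            cls = "unclassified"
        elif k_l < k_r and p_l > p_r:
            cls = "large-slow"
        elif k_l > k_r and p_l < p_r:
            cls = "small-fast"
        else:
            cls = "mixed"
        rows.append(
            dict(
                metabolite=met,
                rate_limited=k_l,
                rate_replete=k_r,
                delta_rate=k_l - k_r,
                delta_plateau=float(fl["plateau"]) - float(fr["plateau"]),
                pool_ratio=p_l / p_r,
                flux_ratio=(k_l * p_l) / (k_r * p_r) if k_r > 0 else float("inf"),
                classification=cls,
            )
        )
    return pd.DataFrame(rows)


def predict_mdv_progression(
    t: float, k: float, k_pre: float, p_sub: float, c: int, p_na: float = 0.0
) -> np.ndarray:
    """Noise-free isotopologue distribution at time t under the cascade model.

    Thin alias of the generator's forward model (one shared implementation):
    precursor atom enrichment e(t) = p_sub (1 - e^{-k_pre t}) feeding a pool
    with first-order turnover k, natural abundance convolved onto unlabeled
    positions.
    """
    return mdv_progression(t, c, k, k_pre, p_sub, p_na=p_na)
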