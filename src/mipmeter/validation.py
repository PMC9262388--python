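"""Statistics for manual starvation-resistance validation assays.

Covers logistic survival-curve fitting with half-life (t50) extraction,
Welch t-tests comparing replicate half-lives between strains, the
detectable-effect-size calculation from a two-sample t-test power inversion,
and the difference-in-differences (delta-delta) interaction effect size for
worm-length recovery assays.

The survival model is ``p(t) = A / (1 + exp(rate * (t - t50)))`` with the
upper asymptote A fixed at 1 by default (fraction alive starts near 1 at the
first scoring day); a free-asymptote mode handles degraded day-1 viability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import MipmeterError


@dataclass
class SurvivalFit:
    """Fitted logistic survival curve; ``t50`` is the day at A/2 survival."""

    t50: float
    rate: float
    asymptote: float
    rss: float
    extrapolated: bool = False

    def predict(self, days):
        days = np.asarray(days, dtype=float)
        return self.asymptote / (1.0 + np.exp(self.rate * (days - self.t50)))


def _logistic(t, t50, rate, asymptote):
    return asymptote / (1.0 + np.exp(np.clip(rate * (t - t50), -700, 700)))


def fit_survival(days, alive_fraction, *, fix_asymptote: bool = True) -> SurvivalFit:
    """Nonlinear least squares of the declining logistic onto scored survival.

    ``days`` must be strictly increasing; at least three points are needed.
    When the series never crosses 0.5 the fit is still returned but flagged
    ``extrapolated`` (replicate-level t-tests need a value), with a warning.
    """
    t = np.asarray(days, dtype=float)
    p = np.asarray(alive_fraction, dtype=float)
    if t.size != p.size or t.size < 3:
        raise ValueError("need >=3 (day, alive_fraction) points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("days must be strictly increasing within a replicate")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("alive_fraction must lie in [0, 1]")

    crosses = p.min() <= 0.5 <= p.max()
    # initial t50: last day above 0.5, else midpoint of the series
    above = t[p > 0.5]
    t50_init = float(above.max()) if above.size else float(t.mean())
    try:
        if fix_asymptote:
            popt, _ = optimize.curve_fit(
                lambda tt, t50, rate: _logistic(tt, t50, rate, 1.0), t, p,
                p0=[t50_init, 0.3], bounds=([t.min() - 100, 1e-6], [t.max() + 100, 50]),
                maxfev=20000)
            t50, rate, asym = float(popt[0]), float(popt[1]), 1.0
        else:
            popt, _ = optimize.curve_fit(
                _logistic, t, p, p0=[t50_init, 0.3, max(p.max(), 0.5)],
                bounds=([t.min() - 100, 1e-6, 0.05], [t.max() + 100, 50, 1.5]),
                maxfev=20000)
            t50, rate, asym = map(float, popt)
    except RuntimeError as exc:
        raise MipmeterError(f"survival fit did not converge: {exc}") from exc
    rss = float(np.sum((p - _logistic(t, t50, rate, asym)) ** 2))
    if not crosses:
        warnings.warn("survival series never crosses 0.5; t50 is extrapolated")
    return SurvivalFit(t50=t50, rate=rate, asymptote=asym, rss=rss,
                       extrapolated=not crosses)


def fit_survival_table(data: pd.DataFrame, *, fix_asymptote: bool = True) -> pd.DataFrame:
    """Fit every replicate in a tidy (replicate_id, day, alive_fraction) table."""
    required = {"replicate_id", "day", "alive_fraction"}
    if not required <= set(data.columns):
        raise ValueError(f"survival table needs columns {sorted(required)}")
    rows = []
    for rep, grp in data.groupby("replicate_id"):
        grp = grp.sort_values("day")
        fit = fit_survival(grp["day"], grp["alive_fraction"], fix_asymptote=fix_asymptote)
        rows.append({"replicate_id": rep, "t50": fit.t50, "rate": fit.rate,
                     "asymptote": fit.asymptote, "rss": fit.rss,
                     "extrapolated": fit.extrapolated})
    return pd.DataFrame(rows)


def compare_half_lives(fits_a, fits_b):
    """Welch two-sample t-test on per-replicate half-lives.

    Accepts lists of :class:`SurvivalFit` or of plain t50 values. Returns
    ``(t_statistic, p_value)``; with fewer than two replicates per group a
    degenerate-test warning is raised and ``(nan, nan)`` returned.
    """
    a = np.asarray([f.t50 if isinstance(f, SurvivalFit) else float(f) for f in fits_a])
    b = np.asarray([f.t50 if isinstance(f, SurvivalFit) else float(f) for f in fits_b])
    if a.size < 2 or b.size < 2:
        warnings.warn("fewer than 2 replicate fits per group; t-test degenerate")
        return float("nan"), float("nan")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def _two_sample_t_power(d: float, n_per_group: int, sig_level: float) -> float:
    """Power of the two-sided two-sample t-test at standardized effect d."""
    df = 2 * n_per_group - 2
    ncp = d * np.sqrt(n_per_group / 2.0)
    t_crit = stats.t.ppf(1.0 - sig_level / 2.0, df)
    upper = stats.nct.sf(t_crit, df, ncp)
    lower = stats.nct.cdf(-t_crit, df, ncp)
    if np.isnan(lower):  # underflows for large noncentrality; the term is ~0
        lower = 0.0
    if np.isnan(upper):
        upper = 1.0 if ncp > t_crit else 0.0
    return float(upper + lower)


def solve_standardized_effect(n_per_group: int, sig_level: float = 0.05,
                              power: float = 0.5) -> float:
    """Invert the noncentral-t power relation for Cohen's d.

    Finds the standardized effect at which a two-sided two-sample t-test with
    ``n_per_group`` per group and level ``sig_level`` reaches ``power``.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if not (0 < sig_level < 1 and 0 < power < 1):
        raise ValueError("sig_level and power must lie in (0, 1)")
    if power <= _two_sample_t_power(0.0, n_per_group, sig_level):
        return 0.0  # requested power is no better than the type-I rate
    f = lambda d: _two_sample_t_power(d, n_per_group, sig_level) - power
    if f(10.0) < 0:
        raise MipmeterError("no standardized effect in (0, 10] reaches the requested power")
    return float(optimize.brentq(f, 1e-9, 10.0, xtol=1e-10))


def detectable_effect(n_per_group: int, sig_level: float = 0.05, power: float = 0.5,
                      sd_control: float = 1.0) -> float:
    """Smallest detectable difference on the outcome scale.

    The standardized effect d from :func:`solve_standardized_effect` times the
    control-group standard deviation (e.g. of median survival), matching the
    conventional two-sample power calculation.
    """
    if sd_control <= 0:
        raise ValueError("sd_control must be positive")
    return solve_standardized_effect(n_per_group, sig_level, power) * sd_control


def delta_delta(lengths: pd.DataFrame, strain_a: str | None = None,
                strain_b: str | None = None, early=None, late=None) -> float:
    """Difference-in-differences interaction effect size.

    ``lengths`` is a tidy (strain, day, worm_length) table with exactly two
    strains and two days (or pass them explicitly). With early/late the two
    days in increasing order,

        dd = [mean(A, late) - mean(A, early)] - [mean(B, late) - mean(B, early)]

    so a positive value means strain A (listed first) is less affected by
    starvation than strain B.
    """
    required = {"strain", "day", "worm_length"}
    if not required <= set(lengths.columns):
        raise ValueError(f"length table needs columns {sorted(required)}")
    strains = sorted(lengths["strain"].unique())
    days = sorted(lengths["day"].unique())
    if strain_a is None or strain_b is None:
        if len(strains) != 2:
            raise ValueError(f"expected exactly two strains, got {strains}")
        strain_a, strain_b = (strain_a or strains[0],
                              strain_b or [s for s in strains if s != (strain_a or strains[0])][0])
    if early is None or late is None:
        if len(days) != 2:
            raise ValueError(f"expected exactly two days, got {days}")
        early, late = days
    cell_means = {}
    for strain in (strain_a, strain_b):
        for day in (early, late):
            sub = lengths[(lengths["strain"] == strain) & (lengths["day"] == day)]
            if sub.empty:
                raise ValueError(f"missing cell: strain {strain}, day {day}")
            cell_means[(strain, day)] = float(sub["worm_length"].mean())
    return ((cell_means[(strain_a, late)] - cell_means[(strain_a, early)])
            - (cell_means[(strain_b, late)] - cell_means[(strain_b, early)]))
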