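"""Paternal-age regression on de novo counts and simulation-based power.

``fit_age_regression`` is ordinary least squares of per-trio de novo counts
on sire age at conception, with the two-sided t test on the slope
(n - 2 residual degrees of freedom).

``run_power_simulation`` asks whether the cohort's age spread suffices to
detect a positive age effect of a given strength: a reference count table
(e.g. de novo single-nucleotide counts, which do accumulate with paternal
age) is fit by OLS, then replicate count vectors are drawn around the
fitted line — Gaussian with the residual variance, or Poisson with the
fitted means — refit, and the fraction with a significant positive slope is
the power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

POISSON_MEAN_FLOOR = 1e-6  # Poisson requires positive means; fitted values may dip below 0


@dataclass
class AgeRegressionResult:
    slope: float  # de novo mutations per year of sire age
    intercept: float
    r_squared: float
    df_residual: int
    p_value: float  # two-sided, t distribution on the slope
    stderr: float


@dataclass
class PowerResult:
    model: str  # 'gaussian' | 'poisson'
    n_reps: int
    alpha: float
    n_significant_positive: int

    @property
    def power(self) -> float:
        return self.n_significant_positive / self.n_reps


def fit_age_regression(ages, counts) -> AgeRegressionResult:
    """OLS of counts on ages; errors on n < 3 or zero age variance."""
    ages = np.asarray(ages, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if ages.shape != counts.shape or ages.ndim != 1:
        raise ValueError("ages and counts must be equal-length 1-D vectors")
    n = ages.size
    if n < 3:
        raise ValueError("regression requires at least 3 trios")
    if np.ptp(ages) == 0:
        raise ValueError("zero variance in ages: slope undefined")
    if np.ptp(counts) == 0:  # degenerate: flat response, R^2 defined as 0
        return AgeRegressionResult(
            slope=0.0, intercept=float(counts[0]), r_squared=0.0,
            df_residual=n - 2, p_value=1.0, stderr=0.0,
        )
    fit = stats.linregress(ages, counts)
    return AgeRegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        df_residual=n - 2,
        p_value=float(fit.pvalue),
        stderr=float(fit.stderr),
    )


def _vectorized_slope_test(ages: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row OLS slope and two-sided p over a (reps, n) response matrix."""
    n = ages.size
    xc = ages - ages.mean()
    sxx = float(xc @ xc)
    slopes = Y @ xc / sxx
    intercepts = Y.mean(axis=1) - slopes * ages.mean()
    resid = Y - (intercepts[:, None] + slopes[:, None] * ages[None, :])
    s2 = (resid**2).sum(axis=1) / (n - 2)
    se = np.sqrt(s2 / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, slopes / se, np.inf * np.sign(slopes))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    return slopes, p


def run_power_simulation(
    ages,
    reference_counts,
    model: str = "gaussian",
    n_reps: int = 10_000,
    alpha: float = 0.01,
    seed: int | None = None,
    one_sided: bool = False,
) -> PowerResult:
    """Monte-Carlo power to detect a positive paternal-age slope.

    Fits ``reference_counts ~ ages`` by least squares, then per replicate
    draws counts around the fitted line (``gaussian``: Normal with the
    residual variance; ``poisson``: Poisson with the fitted means, floored
    at a small positive value), refits, and counts replicates whose slope is
    positive and significant.  "Significant positive" means two-sided
    p < alpha AND slope > 0 by default; ``one_sided`` switches to the
    one-sided upper-tail test at the same alpha.
    """
    if model not in ("gaussian", "poisson"):
        raise ValueError(f"model must be 'gaussian' or 'poisson', got {model!r}")
    ages = np.asarray(ages, dtype=float)
    counts = np.asarray(reference_counts, dtype=float)
    base = fit_age_regression(ages, counts)
    n = ages.size
    fitted = base.intercept + base.slope * ages
    rng = np.random.default_rng(seed)
    if model == "gaussian":
        resid = counts - fitted
        sigma = np.sqrt(float((resid**2).sum()) / (n - 2))
        Y = fitted[None, :] + rng.normal(0.0, sigma, size=(n_reps, n))
    else:
        mu = np.maximum(fitted, POISSON_MEAN_FLOOR)
        if np.all(fitted <= 0):
            raise ValueError("poisson model requires at least one positive fitted mean")
        Y = rng.poisson(mu, size=(n_reps, n)).astype(float)
    slopes, p_two = _vectorized_slope_test(ages, Y)
    if one_sided:
        significant = (p_two / 2 < alpha) & (slopes > 0)
    else:
        significant = (p_two < alpha) & (slopes > 0)
    return PowerResult(
        model=model,
        n_reps=n_reps,
        alpha=alpha,
        n_significant_positive=int(significant.sum()),
    )
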