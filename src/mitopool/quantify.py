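"""Biomass-read regression: z-transformation, ordinary least squares,
generalised least squares with an exponential variance function (varExp),
and the reads -> biomass -> counts conversion.

The residual model of :func:`gls_varexp_fit` is

    y_i = a + b x_i + e_i,   sd(e_i) = sigma * exp(delta * x_i)

fitted by maximum likelihood: for fixed ``delta`` the weighted least-squares
solution is closed-form (weights ``exp(-2 delta x_i)``), so the profile
log-likelihood is a one-dimensional function of ``delta`` maximised by
bounded scalar optimisation.  ``delta = 0`` reduces the model exactly to
ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "RegressionResult",
    "z_transform",
    "ols_fit",
    "gls_varexp_fit",
    "biomass_to_counts",
    "regression_points",
]


@dataclass(frozen=True)
class RegressionResult:
    intercept: float
    slope: float
    n: int
    r_squared: float | None = None
    delta: float | None = None
    sigma: float | None = None
    log_likelihood: float | None = None
    slope_se: float | None = None
    slope_p: float | None = None


def z_transform(values) -> np.ndarray:
    """Centre to mean 0 and scale to sample (n-1) standard deviation 1."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("z_transform needs at least 2 values")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("z_transform of a constant vector")
    return (v - v.mean()) / sd


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    sw = w.sum()
    xm = (w * x).sum() / sw
    ym = (w * y).sum() / sw
    sxx = (w * (x - xm) ** 2).sum()
    if sxx == 0:
        raise ValueError("degenerate design: x is constant")
    slope = (w * (x - xm) * (y - ym)).sum() / sxx
    return ym - slope * xm, slope


def ols_fit(x, y) -> RegressionResult:
    """Closed-form least squares with R^2 = 1 - SSE/SST and a two-sided
    slope t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("ols_fit needs n >= 3")
    a, b = _wls(x, y, np.ones(n))
    resid = y - a - b * x
    sse = float((resid**2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    s2 = sse / (n - 2)
    sxx = float(((x - x.mean()) ** 2).sum())
    se = np.sqrt(s2 / sxx)
    t = b / se if se > 0 else np.inf
    p = float(2 * stats.t.sf(abs(t), n - 2))
    return RegressionResult(a, b, n, r_squared=r2, slope_se=float(se), slope_p=p)


def _profile_loglik(delta: float, x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Maximised log-likelihood at fixed delta; returns (ll, a, b, sigma)."""
    n = x.size
    w = np.exp(-2.0 * delta * x)
    a, b = _wls(x, y, w)
    resid = y - a - b * x
    sigma2 = float((w * resid**2).sum() / n)
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) - delta * float(x.sum())
    return ll, a, b, float(np.sqrt(sigma2))


def gls_varexp_fit(
    x,
    y,
    delta_bounds: tuple[float, float] = (-20.0, 20.0),
    fix_delta: float | None = None,
) -> RegressionResult:
    """ML fit of the exponential-variance regression (see module docstring).

    ``fix_delta`` constrains the variance coefficient instead of profiling it
    (``fix_delta=0`` reduces the fit exactly to OLS).  The slope's standard
    error and two-sided p-value come from the weighted information at the
    optimum (residual variance on n-2 degrees of freedom).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 5:
        raise ValueError("gls_varexp_fit needs n >= 5")
    if fix_delta is None:
        res = optimize.minimize_scalar(
            lambda d: -_profile_loglik(d, x, y)[0],
            bounds=delta_bounds,
            method="bounded",
            options={"xatol": 1e-8, "maxiter": 500},
        )
        if not res.success:
            raise RuntimeError(f"varExp profile optimisation failed at delta={res.x:.6g}")
        delta = float(res.x)
    else:
        delta = float(fix_delta)
    ll, a, b, sigma = _profile_loglik(delta, x, y)
    w = np.exp(-2.0 * delta * x)
    resid = y - a - b * x
    s2 = float((w * resid**2).sum() / (n - 2))
    sw = w.sum()
    xm = (w * x).sum() / sw
    sxx = float((w * (x - xm) ** 2).sum())
    se = np.sqrt(s2 / sxx)
    t = b / se if se > 0 else np.inf
    p = float(2 * stats.t.sf(abs(t), n - 2))
    return RegressionResult(
        a, b, n, delta=delta, sigma=sigma, log_likelihood=ll, slope_se=float(se), slope_p=p
    )


def biomass_to_counts(
    read_freqs: pd.Series | dict,
    total_sample_biomass: float,
    biomass_per_individual: pd.Series | dict,
) -> pd.Series:
    """Convert read frequencies to estimated per-species counts.

    ``estimated_biomass_s = freq_s * total``;
    ``count_s = estimated_biomass_s / biomass_per_individual_s`` (real-valued,
    rounding left to the caller).
    """
    freqs = pd.Series(read_freqs, dtype=float)
    per_ind = pd.Series(biomass_per_individual, dtype=float).reindex(freqs.index)
    if (per_ind <= 0).any():
        raise ValueError("biomass_per_individual must be positive")
    est_biomass = freqs * float(total_sample_biomass)
    return est_biomass / per_ind


def regression_points(
    reads_matrix: pd.DataFrame,
    biomass_matrix: pd.DataFrame,
    scope: str = "sample",
    as_frequencies: bool = True,
    drop_zero: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Pool species x sample points for the biomass-read regression.

    Values are converted to within-sample frequencies (default) and then
    z-transformed within each sample (``scope='sample'``, correcting for
    sample-size differences) or over the pooled points (``scope='global'``).
    Species absent from both data sets in a sample are dropped.
    Returns (x, y) = (biomass z-scores, read z-scores).
    """
    if scope not in {"sample", "global"}:
        raise ValueError("scope must be 'sample' or 'global'")
    reads_matrix, biomass_matrix = reads_matrix.align(biomass_matrix)
    xs, ys = [], []
    for sample in reads_matrix.columns:
        r = reads_matrix[sample].astype(float)
        b = biomass_matrix[sample].astype(float)
        if drop_zero:
            keep = (r > 0) | (b > 0)
            r, b = r[keep], b[keep]
        if as_frequencies:
            if r.sum() <= 0 or b.sum() <= 0:
                raise ValueError(f"sample {sample!r} has no reads or no biomass")
            r, b = r / r.sum(), b / b.sum()
        if scope == "sample":
            if len(r) < 2:
                continue  # cannot z-score a single point within a sample
            xs.append(z_transform(b.to_numpy()))
            ys.append(z_transform(r.to_numpy()))
        else:
            xs.append(b.to_numpy())
            ys.append(r.to_numpy())
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if scope == "global":
        x, y = z_transform(x), z_transform(y)
    return x, y
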