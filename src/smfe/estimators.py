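"""Free-energy estimators for nonequilibrium work samples.

Three estimators of the Jarzynski identity e^{-dG} = <e^{-W}> (work in k_BT):

* the mean estimator  dG_MN = -log( (1/N) sum e^{-W_i} ), notoriously
  dominated by the rare smallest work values;
* the fluctuation-dissipation estimator  dG_FD = <W> - s^2/2, valid only
  when the work fluctuation is comparable to k_BT;
* the gamma estimator  dG_GA = alpha * ln((lambda+1)/lambda), exact when the
  work distribution is Gamma(alpha, lambda), with (alpha, lambda) obtained
  by maximum likelihood.

The gamma estimator follows from the gamma moment generating function:
E[e^{-W}] = (lambda/(lambda+1))^alpha, so -log E[e^{-W}] reduces to the
closed form above. In the small-fluctuation limit (large lambda) it recovers
the FD estimator, and the mean estimator converges to it as N -> infinity.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.special import digamma, gammaln, polygamma

from .curves import (
    EstimateReport,
    ForceDistanceCurve,
    GammaFit,
    ScreeningParams,
    ValidationError,
    WorkSample,
)

_NEWTON_RTOL = 1e-10
_NEWTON_MAXITER = 100


class DegenerateSampleError(ValueError):
    """The sample carries no usable variation (e.g. all values identical)."""


def _values(sample) -> np.ndarray:
    if isinstance(sample, WorkSample):
        return sample.values
    v = np.asarray(sample, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValidationError("work sample must be a non-empty 1-D array")
    return v


def dg_mean(sample) -> float:
    """Mean (exponential-average) Jarzynski estimator, in k_BT.

    Evaluated through a shifted log-sum-exp so that samples of hundreds of
    k_BT do not underflow. Always bounded above by min(W) + log N and, by
    Jensen's inequality, by the sample mean.
    """
    w = _values(sample)
    return float(-(special.logsumexp(-w) - np.log(w.size)))


def dg_fd(sample) -> float:
    """Fluctuation-dissipation estimator <W> - s^2/2 (unbiased variance), k_BT."""
    w = _values(sample)
    if w.size < 2:
        raise ValidationError("FD estimator needs at least two work values")
    return float(np.mean(w) - 0.5 * np.var(w, ddof=1))


def fd_from_moments(mean: float, sd: float) -> float:
    """FD estimator evaluated directly on summary statistics: mean - sd^2/2."""
    return float(mean - 0.5 * sd * sd)


def dg_gamma(shape: float, rate: float) -> float:
    """Closed-form gamma-work free energy alpha*ln((lambda+1)/lambda), k_BT."""
    if shape <= 0 or rate <= 0:
        raise ValidationError("gamma shape and rate must be positive")
    return float(shape * np.log1p(1.0 / rate))


def gamma_log_likelihood(sample, shape: float, rate: float) -> float:
    """Log-likelihood of a gamma model over the sample."""
    w = _values(sample)
    n = w.size
    return float(
        n * (shape * np.log(rate) - gammaln(shape))
        + (shape - 1.0) * np.sum(np.log(w))
        - rate * np.sum(w)
    )


def fit_gamma_mle(sample, with_ks: bool = True) -> GammaFit:
    """Maximum-likelihood gamma fit of a positive work sample.

    The rate is profiled out (lambda = alpha / mean) and the shape solved
    from the score equation log(alpha) - psi(alpha) = log(mean) - mean(log W)
    by Newton iteration from the closed-form initialiser
    alpha0 = (3 - s + sqrt((s-3)^2 + 24 s)) / (12 s).
    """
    w = _values(sample)
    if w.size < 5:
        raise ValidationError("gamma MLE needs at least 5 work values")
    if np.any(w <= 0):
        raise ValidationError("gamma MLE requires strictly positive work values")
    wbar = float(np.mean(w))
    s = float(np.log(wbar) - np.mean(np.log(w)))
    if s <= 1e-12:
        raise DegenerateSampleError("sample has (numerically) zero log-dispersion")
    alpha = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    for _ in range(_NEWTON_MAXITER):
        score = np.log(alpha) - digamma(alpha) - s
        step = score / (1.0 / alpha - polygamma(1, alpha))
        alpha -= step
        if abs(step) / alpha < _NEWTON_RTOL:
            break
    rate = alpha / wbar
    ll = gamma_log_likelihood(w, alpha, rate)
    if with_ks:
        ks_stat, ks_p = ks_gamma_test(w, alpha, rate)
    else:
        ks_stat, ks_p = 0.0, 1.0
    return GammaFit(
        shape=float(alpha),
        rate=float(rate),
        log_likelihood=ll,
        dg_gamma=dg_gamma(alpha, rate),
        ks_statistic=ks_stat,
        ks_pvalue=ks_p,
    )


def ks_gamma_test(sample, shape: float, rate: float) -> tuple[float, float]:
    """Kolmogorov-Smirnov statistic and asymptotic p-value against Gamma(shape, rate).

    The fitted parameters are treated as known (no correction for having
    estimated them from the same sample), so the p-value is anticonservative;
    this matches common practice for this diagnostic.
    """
    w = _values(sample)
    cdf = stats.gamma(a=shape, scale=1.0 / rate).cdf
    d = float(stats.kstest(w, cdf).statistic)
    p = float(special.kolmogorov(np.sqrt(w.size) * d))
    return d, min(max(p, 0.0), 1.0)


def empirical_cdf(sample) -> tuple[np.ndarray, np.ndarray]:
    """Hazen plotting positions: sorted values paired with (i - 0.5)/N."""
    w = np.sort(_values(sample))
    probs = (np.arange(1, w.size + 1) - 0.5) / w.size
    return w, probs


def prob_negative_gaussian(mean: float, sd: float) -> float:
    """P(W < 0) under a Gaussian work model: Phi(-mean/sd).

    A diagnostic for the FD estimator: appreciable mass at negative work
    signals that the Gaussian model (and hence FD) is not applicable.
    """
    if sd <= 0:
        raise ValidationError("sd must be positive")
    return float(stats.norm.cdf(-mean / sd))


def estimate_all(sample) -> EstimateReport:
    """Evaluate every estimator coherently on one work sample."""
    w = _values(sample)
    if w.size < 5:
        raise ValidationError("full estimation needs at least 5 work values")
    gfit = fit_gamma_mle(w)
    mean = float(np.mean(w))
    sd = float(np.std(w, ddof=1))
    return EstimateReport(
        n_events=int(w.size),
        dg_mean=dg_mean(w),
        dg_fd=dg_fd(w),
        gaussian_mean=mean,
        gaussian_sd=sd,
        prob_negative=prob_negative_gaussian(mean, sd),
        gamma_fit=gfit,
    )


# ---------------------------------------------------------------------------
# Parameter scan and subsample stability


def parameter_scan(
    curves: list[ForceDistanceCurve],
    grid: dict,
    base_params: ScreeningParams | None = None,
    min_events: int = 5,
) -> pd.DataFrame:
    """Full-factorial screening-parameter scan.

    ``grid`` maps any subset of {alpha_frac, lod, mul_base, nls_err} to
    value lists. Each cell re-screens the dataset and, when at least
    ``min_events`` curves survive, evaluates all estimators. Cells with too
    few events carry NaN estimates.
    """
    from itertools import product

    from .screening import screen_dataset

    base = base_params or ScreeningParams()
    allowed = {"alpha_frac", "lod", "mul_base", "nls_err"}
    unknown = set(grid) - allowed
    if unknown:
        raise ValidationError(f"cannot scan over: {sorted(unknown)}")
    names = sorted(grid)
    rows = []
    for combo in product(*(grid[k] for k in names)):
        params = dataclasses.replace(base, **dict(zip(names, combo)))
        events, _ = screen_dataset(curves, params)
        row = {
            "alpha_frac": params.alpha_frac,
            "lod": params.lod,
            "mul_base": params.mul_base,
            "nls_err": params.nls_err,
            "n_events": len(events),
            "dg_mean": np.nan,
            "dg_fd": np.nan,
            "dg_gamma": np.nan,
            "shape": np.nan,
            "rate": np.nan,
        }
        if len(events) >= max(min_events, 5):
            works = np.array([e.work_kbt for e in events])
            report = estimate_all(works)
            row.update(
                dg_mean=report.dg_mean,
                dg_fd=report.dg_fd,
                dg_gamma=report.gamma_fit.dg_gamma,
                shape=report.gamma_fit.shape,
                rate=report.gamma_fit.rate,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def scan_convergence(scan: pd.DataFrame, min_events: int = 5) -> dict:
    """Mean +/- SD of the gamma estimate over scan cells with enough events."""
    ok = scan[(scan["n_events"] >= min_events) & np.isfinite(scan["dg_gamma"])]
    if len(ok) == 0:
        raise ValidationError("no scan cell has enough events")
    values = ok["dg_gamma"].to_numpy()
    return {
        "n_cells": int(len(values)),
        "dg_gamma_mean": float(np.mean(values)),
        "dg_gamma_sd": float(np.std(values, ddof=1)) if len(values) > 1 else None,
    }


@dataclass
class SubsampleStats:
    """Moments of gamma-fit parameters over random subsample refits."""

    repeats: int
    fraction: float
    shape_mean: float
    rate_mean: float
    dg_gamma_mean: float
    shape_sd: float | None
    rate_sd: float | None
    dg_gamma_sd: float | None


def subsample_stability(
    sample, fraction: float = 0.9, repeats: int = 10, seed: int = 0
) -> SubsampleStats:
    """Refit the gamma model on random subsamples to probe overfitting.

    Each repeat draws ``fraction`` of the sample without replacement and
    refits; the spread of the refitted parameters against the full-sample
    fit indicates whether the fit is stable. SDs are absent for a single
    repeat.
    """
    w = _values(sample)
    if not (0 < fraction <= 1):
        raise ValidationError("fraction must be in (0, 1]")
    m = int(round(fraction * w.size))
    if m < 5:
        raise ValidationError("subsample too small for gamma MLE")
    rng = np.random.default_rng(seed)
    shapes, rates, dgs = [], [], []
    for _ in range(repeats):
        idx = rng.choice(w.size, size=m, replace=False)
        fit = fit_gamma_mle(w[idx], with_ks=False)
        shapes.append(fit.shape)
        rates.append(fit.rate)
        dgs.append(fit.dg_gamma)
    def _sd(x):
        return float(np.std(x, ddof=1)) if len(x) > 1 else None
    return SubsampleStats(
        repeats=repeats,
        fraction=fraction,
        shape_mean=float(np.mean(shapes)),
        rate_mean=float(np.mean(rates)),
        dg_gamma_mean=float(np.mean(dgs)),
        shape_sd=_sd(shapes),
        rate_sd=_sd(rates),
        dg_gamma_sd=_sd(dgs),
    )
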