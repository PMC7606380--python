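"""Langmuir kinetics of surface adsorption from SPR coverage traces.

Each trace theta(t) at analyte concentration C is fitted to the Langmuir
relaxation theta(t) = theta_eq * (1 - e^{-k_obs t}), with
theta_eq = C/(C + K_D) and k_obs = ka*C + kd. A linear regression of k_obs
on C across concentrations then yields the association rate ka (slope,
1/(M s)) and dissociation rate kd (intercept, 1/s); K_D = kd/ka and the
adsorption free energy is ln(K_D / 1 M) in k_BT (negative for sub-molar
K_D). The per-trace fit followed by regression is a two-stage procedure;
no global multi-trace fit is attempted.

High concentrations violate the Langmuir no-interaction assumption; traces
whose fit residuals are far out of family are flagged and excluded from the
regression rather than modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from .curves import KineticsFit, KineticTrace, ValidationError


class FitError(Exception):
    """A nonlinear fit failed to converge."""


def langmuir_theta(t, theta_eq, k_obs):
    """Langmuir relaxation: theta_eq * (1 - exp(-k_obs * t))."""
    return theta_eq * (1.0 - np.exp(-k_obs * np.asarray(t, dtype=float)))


class TraceFit(NamedTuple):
    theta_eq: float
    k_obs: float  # 1/s
    rmse: float
    n: int


def fit_langmuir_trace(trace: KineticTrace, t_max: float | None = None) -> TraceFit:
    """Least-squares Langmuir fit of one coverage trace truncated to [0, t_max].

    Returns the equilibrium coverage, observed rate constant, fit RMSE and
    the number of points used. theta_eq is constrained to (0, 1], k_obs > 0.
    """
    t, theta = trace.time, trace.coverage
    if t_max is not None:
        mask = t <= t_max
        t, theta = t[mask], theta[mask]
    if t.size < 10:
        raise ValidationError("Langmuir fit needs at least 10 points in the window")
    if np.any(theta < -0.2) or np.any(theta > 1.2):
        raise ValidationError("coverage outside [0, 1.2] beyond noise tolerance")
    peak = float(np.max(theta))
    if peak <= 0:
        raise ValidationError("trace never rises above zero coverage")
    # k_obs init from the time to half-saturation
    half_idx = np.argmax(theta >= 0.5 * peak)
    t_half = float(t[half_idx]) if t[half_idx] > 0 else float(t[-1]) / 2
    p0 = [min(peak, 1.0), np.log(2.0) / t_half]
    try:
        popt, _ = curve_fit(
            langmuir_theta, t, theta, p0=p0,
            bounds=([1e-9, 1e-9], [1.0, np.inf]), maxfev=10000,
        )
    except RuntimeError as exc:
        raise FitError(f"Langmuir fit did not converge: {exc}")
    resid = theta - langmuir_theta(t, *popt)
    return TraceFit(float(popt[0]), float(popt[1]), float(np.sqrt(np.mean(resid**2))), int(t.size))


@dataclass
class RateRegression:
    """OLS of k_obs on concentration: slope = ka, intercept = kd."""

    ka: float
    kd: float
    ka_se: float | None
    kd_se: float | None


def regress_kobs(points) -> RateRegression:
    """Linear regression of (concentration, k_obs) pairs.

    With exactly two concentrations the line is interpolated and standard
    errors are undefined (reported as None).
    """
    pts = [(float(c), float(k)) for c, k in points]
    if len(pts) < 2:
        raise ValidationError("need at least two concentrations")
    conc = np.array([p[0] for p in pts])
    kobs = np.array([p[1] for p in pts])
    if np.unique(conc).size < 2:
        raise ValidationError("concentrations must not all coincide")
    if len(pts) == 2:
        ka = (kobs[1] - kobs[0]) / (conc[1] - conc[0])
        kd = kobs[0] - ka * conc[0]
        return RateRegression(float(ka), float(kd), None, None)
    res = stats.linregress(conc, kobs)
    return RateRegression(
        float(res.slope), float(res.intercept),
        float(res.stderr), float(res.intercept_stderr),
    )


def dg_from_kd(kD: float, temperature: float = 293.15) -> float:
    """Adsorption free energy ln(K_D / 1 M) in k_BT.

    In k_BT units the value is independent of temperature; the argument is
    kept for interface symmetry with the dimensional form RT ln(K_D/c0).
    """
    if kD <= 0:
        raise ValidationError("K_D must be positive")
    if temperature <= 0:
        raise ValidationError("temperature must be positive")
    return float(np.log(kD))


def flag_outlier_traces(traces, t_max: float, rmse_ratio: float = 3.0) -> list[bool]:
    """Flag traces whose Langmuir fit RMSE is out of family.

    A trace is flagged when its RMSE exceeds ``rmse_ratio`` times the median
    RMSE over all traces — the signature of a systematic model deviation
    (e.g. multilayer or interacting adsorption at high concentration) rather
    than noise.
    """
    rmses = [fit_langmuir_trace(tr, t_max).rmse for tr in traces]
    med = float(np.median(rmses))
    if med <= 0:
        return [r > 1e-12 for r in rmses]
    return [r > rmse_ratio * med for r in rmses]


@dataclass
class KineticsSummary:
    """Window-averaged kinetics with across-window spreads."""

    windows: list
    flagged_concentrations: list
    ka_mean: float
    kd_mean: float
    kD_mean: float
    dg_ads_mean: float
    ka_sd: float | None
    kd_sd: float | None
    kD_sd: float | None
    dg_ads_sd: float | None


def kinetics_pipeline(
    traces: list[KineticTrace],
    windows,
    rmse_ratio: float = 3.0,
) -> tuple[list[KineticsFit], KineticsSummary]:
    """Full two-stage analysis over several truncation windows.

    For each window t_max: fit every unflagged trace, regress k_obs on C,
    and derive (ka, kd, K_D, dG). Several windows guard against overfitting
    a particular truncation; the summary reports mean +/- SD across windows.
    """
    windows = [float(w) for w in np.atleast_1d(windows)]
    if not traces:
        raise ValidationError("no traces supplied")
    if len(traces) >= 3:
        flags = flag_outlier_traces(traces, max(windows), rmse_ratio)
    else:
        flags = [False] * len(traces)
    kept = [tr for tr, f in zip(traces, flags) if not f]
    if len(kept) < 2:
        raise ValidationError("fewer than two traces survive outlier flagging")
    fits: list[KineticsFit] = []
    for w in windows:
        per_trace = []
        for tr in kept:
            tf = fit_langmuir_trace(tr, w)
            per_trace.append((tr.concentration, tf.theta_eq, tf.k_obs))
        reg = regress_kobs([(c, k) for c, _, k in per_trace])
        kD = reg.kd / reg.ka
        fits.append(
            KineticsFit(
                per_trace=per_trace,
                ka=reg.ka, kd=reg.kd, kD=kD, dg_ads=dg_from_kd(kD),
                ka_se=reg.ka_se, kd_se=reg.kd_se, window=w,
            )
        )
    def _agg(values):
        arr = np.array(values, dtype=float)
        sd = float(np.std(arr, ddof=1)) if arr.size > 1 else None
        return float(np.mean(arr)), sd
    ka_m, ka_s = _agg([f.ka for f in fits])
    kd_m, kd_s = _agg([f.kd for f in fits])
    kD_m, kD_s = _agg([f.kD for f in fits])
    dg_m, dg_s = _agg([f.dg_ads for f in fits])
    summary = KineticsSummary(
        windows=windows,
        flagged_concentrations=[tr.concentration for tr, f in zip(traces, flags) if f],
        ka_mean=ka_m, kd_mean=kd_m, kD_mean=kD_m, dg_ads_mean=dg_m,
        ka_sd=ka_s, kd_sd=kd_s, kD_sd=kD_s, dg_ads_sd=dg_s,
    )
    return fits, summary
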