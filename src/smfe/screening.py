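"""Automated detection of single binding events in retraction curves.

Five steps are applied to every curve, in order:

1. locate the rupture (state B) as the farthest significant maximum of the
   windowed-regression derivative of force versus separation;
2. align the bulk baseline to zero force with a linear fit and estimate the
   noise level sigma;
3. find the binding minimum before the rupture, deeper than -lod*sigma, on a
   kernel-smoothed curve;
4. locate the bound state A as the zero-force point closest before the
   stretch segment whose neighbourhood stays within a mul_base*sigma
   fluctuation band;
5. fit the stretch segment A -> binding minimum with the worm-like chain
   model and accept the curve only if the mean absolute residual stays
   within nls_err*sigma.

Accepted curves yield the external work W = -integral_A^B F dD_s in k_BT.
Curves showing zero or more than one rupture beyond the contact region are
rejected, never split.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import find_peaks

from .curves import (
    BindingEvent,
    ForceDistanceCurve,
    ScreeningParams,
    ValidationError,
    kbt_pn_nm,
)

_MIN_RADIUS = 2
_MAX_RADIUS = 30
_MAD_MULTIPLE = 5.0


class CurveRejected(Exception):
    """A curve failed one screening step; carries the step label and reason."""

    def __init__(self, step: str, reason: str):
        super().__init__(f"{step}: {reason}")
        self.step = step
        self.reason = reason


class FitError(Exception):
    """A nonlinear fit failed to converge."""


# ---------------------------------------------------------------------------
# Step 1: derivative and rupture detection


def _regression_slopes(x: np.ndarray, y: np.ndarray, radius: int) -> np.ndarray:
    """Per-point slope of y vs x from a local linear regression in [i-r, i+r].

    Windows are truncated at the array edges. Implemented with running sums
    so the whole curve costs O(n) per radius.
    """
    w = 2 * radius + 1
    kern = np.ones(w)
    ones = np.ones_like(x)
    n = np.convolve(ones, kern, mode="same")
    sx = np.convolve(x, kern, mode="same")
    sy = np.convolve(y, kern, mode="same")
    sxx = np.convolve(x * x, kern, mode="same")
    sxy = np.convolve(x * y, kern, mode="same")
    denom = n * sxx - sx * sx
    denom = np.where(denom <= 0, np.nan, denom)
    slope = (n * sxy - sx * sy) / denom
    return np.nan_to_num(slope, nan=0.0)


def significant_maxima(derivative: np.ndarray) -> np.ndarray:
    """Indices of local maxima exceeding median + 5*MAD of the derivative.

    A tiny scale-relative floor keeps exact plateaus (noise-free lines) from
    producing spurious peaks when the MAD collapses to zero.
    """
    med = float(np.median(derivative))
    mad = float(np.median(np.abs(derivative - med)))
    floor = 1e-9 * (float(np.max(np.abs(derivative))) + 1.0)
    threshold = med + _MAD_MULTIPLE * mad + floor
    peaks, _ = find_peaks(derivative, height=threshold)
    return peaks


def windowed_derivative(curve: ForceDistanceCurve) -> tuple[np.ndarray, int]:
    """Derivative of force vs separation with an auto-selected window radius.

    The radius grows from 2 until the number of significant maxima is
    identical for two consecutive radii (or a cap is hit); the derivative at
    the stabilised radius is returned together with that radius.
    """
    n = len(curve)
    if n < 2 * _MIN_RADIUS + 1:
        raise ValidationError(f"curve of {n} points too short for derivative radius {_MIN_RADIUS}")
    r_max = min(_MAX_RADIUS, (n - 1) // 2)
    prev_count = None
    deriv = None
    radius = _MIN_RADIUS
    for r in range(_MIN_RADIUS, r_max + 1):
        deriv = _regression_slopes(curve.separation, curve.force, r)
        count = significant_maxima(deriv).size
        radius = r
        if prev_count is not None and count == prev_count:
            break
        prev_count = count
    return deriv, radius


def detect_rupture(
    curve: ForceDistanceCurve, params: ScreeningParams
) -> tuple[int, int, int]:
    """Locate state B: the farthest significant derivative maximum.

    Maxima inside the contact region (separation below ``contact_frac`` of
    the maximum separation) are attributed to tip-surface adhesion and
    ignored. Returns (rupture_index, n_candidates, radius); zero candidates
    raises :class:`CurveRejected`.
    """
    deriv, radius = windowed_derivative(curve)
    peaks = significant_maxima(deriv)
    cutoff = params.contact_frac * float(curve.separation[-1])
    candidates = peaks[curve.separation[peaks] > cutoff]
    if candidates.size == 0:
        raise CurveRejected("rupture", "no significant derivative maximum beyond contact region")
    # peaks within two window widths belong to the same discontinuity
    gap = 2 * (2 * radius + 1)
    n_clusters = 1 + int(np.sum(np.diff(candidates) > gap))
    return int(candidates[-1]), n_clusters, radius


# ---------------------------------------------------------------------------
# Step 2: baseline alignment


def align_baseline(
    curve: ForceDistanceCurve,
    rupture_index: int,
    alpha_frac: float,
    margin: int = 5,
    min_points: int = 10,
) -> tuple[ForceDistanceCurve, float]:
    """Zero the bulk baseline with a linear fit and estimate the noise sigma.

    The baseline region starts at whichever is later: just past the rupture
    (by ``margin`` samples) or the farthest ``alpha_frac`` fraction of the
    curve. The fitted line is subtracted from the whole curve, removing any
    instrumental drift; sigma is the standard deviation of the post-alignment
    baseline forces.
    """
    n = len(curve)
    start = max(rupture_index + margin, int(round(n * (1.0 - alpha_frac))))
    if n - start < min_points:
        raise CurveRejected("baseline", f"only {n - start} baseline points (need {min_points})")
    z = curve.separation[start:]
    f = curve.force[start:]
    coeffs = np.polyfit(z, f, 1)
    aligned_force = curve.force - np.polyval(coeffs, curve.separation)
    sigma = float(np.std(aligned_force[start:], ddof=1))
    return curve.with_force(aligned_force), sigma


# ---------------------------------------------------------------------------
# Step 3: binding minimum


def _smooth(force: np.ndarray, width: int) -> np.ndarray:
    """Symmetric moving average with edge renormalisation."""
    width = max(1, int(width))
    kern = np.ones(width)
    norm = np.convolve(np.ones_like(force), kern, mode="same")
    return np.convolve(force, kern, mode="same") / norm


def detect_binding_minimum(
    curve: ForceDistanceCurve,
    rupture_index: int,
    sigma: float,
    lod: float,
    kernel_width: int = 7,
) -> int:
    """Find the binding site: the qualifying minimum closest before the rupture.

    Minima are taken on a moving-average-smoothed curve and must be deeper
    than -lod*sigma. When two candidate minima sit equally close, the deeper
    one wins.
    """
    smoothed = _smooth(curve.force, kernel_width)
    minima, _ = find_peaks(-smoothed)
    mask = (minima < rupture_index) & (smoothed[minima] < -lod * sigma)
    candidates = minima[mask]
    if candidates.size == 0:
        raise CurveRejected("binding", "no minimum deeper than -lod*sigma before rupture")
    # closest before the rupture; ties broken toward the deeper minimum
    dist = rupture_index - candidates
    best = np.lexsort((smoothed[candidates], dist))
    return int(candidates[best[0]])


# ---------------------------------------------------------------------------
# Step 4: bound state A


def locate_state_A(
    curve: ForceDistanceCurve,
    binding_index: int,
    sigma: float,
    mul_base: float,
    kernel_width: int = 7,
) -> int:
    """Locate state A: the zero-force point before the binding site.

    Scanning from the binding minimum toward the surface on the smoothed
    curve, A is the first point where the force has relaxed back to zero
    (smoothed force >= 0, up to a numerical epsilon) and whose preceding
    kernel-width neighbourhood stays inside the +/- mul_base*sigma baseline
    band — i.e. a genuine relaxed-tether baseline, not a stray noise
    excursion on the stretch or the adhesion flank.
    """
    smoothed = _smooth(curve.force, kernel_width)
    # epsilon floor well below any physical noise but above residual
    # contact-tail forces on noise-free synthetic curves
    eps = 1e-5 * (float(np.max(np.abs(curve.force))) + 1.0)
    bound = mul_base * sigma + eps
    w = max(1, int(kernel_width))
    for i in range(binding_index - 1, -1, -1):
        if smoothed[i] >= -eps:
            neighbourhood = smoothed[max(0, i - w): i + 1]
            if np.all(np.abs(neighbourhood) <= bound):
                return i
    raise CurveRejected("state_a", "no zero-force baseline point before the binding site")


# ---------------------------------------------------------------------------
# Step 5: worm-like chain fit


def wlc_force(
    extension,
    contour_length: float,
    persistence_length: float = 0.37,
    temperature: float = 298.15,
):
    """Worm-like chain restoring force (pN) at the given extension (nm).

    F(g) = (k_BT / l_p) * [ 1/4 (1 - g/L)^-2 + g/L - 1/4 ]

    Valid for 0 <= extension < contour_length; diverges at full extension.
    """
    g = np.asarray(extension, dtype=float)
    if contour_length <= 0 or persistence_length <= 0:
        raise ValidationError("contour and persistence lengths must be positive")
    if np.any(g < 0) or np.any(g >= contour_length):
        raise ValidationError("extension must satisfy 0 <= extension < contour_length")
    x = g / contour_length
    f = (kbt_pn_nm(temperature) / persistence_length) * (0.25 * (1.0 - x) ** -2 + x - 0.25)
    return float(f) if np.isscalar(extension) else f


def fit_wlc(
    extension: np.ndarray,
    force: np.ndarray,
    persistence_length: float = 0.37,
    temperature: float = 298.15,
    min_contour: float | None = None,
    origin_slack: float = 0.0,
) -> tuple[float, float]:
    """Fit the contour length of a WLC to a stretch segment.

    The persistence length is held fixed; only L varies, plus an optional
    small shift of the extension origin within ``origin_slack`` (nm) —
    state A is localised only to within the smoothing kernel, so the fit is
    allowed to refine it. The model force magnitude is compared against the
    negated (attractive) segment force; points at or before the refined
    origin contribute zero model force. Returns (contour_length, mean
    absolute residual in pN).
    """
    g = np.asarray(extension, dtype=float)
    f = np.asarray(force, dtype=float)
    if g.size < 10:
        raise ValidationError("WLC fit needs at least 10 points")
    gmax = float(np.max(g))
    if gmax <= 0:
        raise ValidationError("extension span is empty")
    slack = max(0.0, float(origin_slack))
    lower = max((gmax + slack) * (1.0 + 1e-6), (min_contour or 0.0) * (1.0 + 1e-6))
    target = -f  # attractive forces are negative; WLC magnitude is positive

    def residuals(theta):
        L = lower + np.exp(theta[0])
        g_eff = np.clip(g - theta[1], 0.0, None)
        return wlc_force(g_eff, L, persistence_length, temperature) - target

    x0 = [np.log(max(gmax * 0.3, 1e-3)), 0.0]
    if slack > 0:
        bounds = ([-np.inf, -slack], [np.inf, slack])
        kwargs = {"method": "trf", "bounds": bounds}
    else:
        x0 = x0[:1]
        kwargs = {"method": "lm"}

        def residuals(theta):  # noqa: F811 - single-parameter variant
            L = lower + np.exp(theta[0])
            return wlc_force(g, L, persistence_length, temperature) - target

    try:
        sol = least_squares(residuals, x0=x0, **kwargs)
    except Exception as exc:  # pragma: no cover - scipy internal failures
        raise FitError(f"WLC fit failed: {exc}")
    if not sol.success:
        raise FitError(f"WLC fit did not converge: {sol.message}")
    contour = lower + float(np.exp(sol.x[0]))
    mean_abs_residual = float(np.mean(np.abs(sol.fun)))
    return contour, mean_abs_residual


# ---------------------------------------------------------------------------
# Work integration


def integrate_work(
    curve: ForceDistanceCurve, index_a: int, index_b: int, temperature: float | None = None
) -> float:
    """External work W = -integral_A^B F dD_s by the trapezoid rule, in k_BT.

    Attractive (negative) forces along the pull yield positive work. The
    curve must already be baseline-aligned.
    """
    if not (0 <= index_a < index_b < len(curve)):
        raise ValidationError("invalid integration indices")
    T = temperature if temperature is not None else curve.temperature
    seg = slice(index_a, index_b + 1)
    w_pn_nm = -np.trapezoid(curve.force[seg], curve.separation[seg])
    return float(w_pn_nm / kbt_pn_nm(T))


# ---------------------------------------------------------------------------
# Full pipeline


def screen_curve(curve: ForceDistanceCurve, params: ScreeningParams) -> BindingEvent:
    """Apply the five screening steps to one curve; raise CurveRejected on failure."""
    rupture, n_candidates, radius = detect_rupture(curve, params)
    if n_candidates > 1:
        raise CurveRejected("multiple_events", f"{n_candidates} ruptures beyond contact region")
    width = 2 * radius + 1
    aligned, sigma = align_baseline(
        curve, rupture, params.alpha_frac, margin=width,
        min_points=params.min_baseline_points,
    )
    binding = detect_binding_minimum(aligned, rupture, sigma, params.lod, kernel_width=width)
    index_a = locate_state_A(aligned, binding, sigma, params.mul_base, kernel_width=width)
    seg = slice(index_a, binding + 1)
    extension = aligned.separation[seg] - aligned.separation[index_a]
    span_ab = float(aligned.separation[rupture] - aligned.separation[index_a])
    spacing = float(np.median(np.diff(aligned.separation)))
    try:
        contour, residual = fit_wlc(
            extension,
            aligned.force[seg],
            persistence_length=params.persistence_length,
            temperature=params.temperature,
            min_contour=span_ab,
            origin_slack=width * spacing,
        )
    except (FitError, ValidationError) as exc:
        raise CurveRejected("wlc", str(exc))
    # 1e-3 pN floor keeps noise-free curves acceptable despite float residue
    if residual > params.nls_err * sigma + 1e-3:
        raise CurveRejected("wlc", f"mean residual {residual:.3g} pN exceeds nls_err*sigma")
    work = integrate_work(aligned, index_a, rupture, params.temperature)
    if work <= 0:
        raise CurveRejected("work", "non-positive integrated work")
    return BindingEvent(
        index_A=index_a,
        index_B=rupture,
        sigma_baseline=sigma,
        contour_length=contour,
        wlc_residual=residual,
        work_kbt=work,
        label=curve.label,
        binding_index=binding,
        separation_A=float(aligned.separation[index_a]),
        separation_B=float(aligned.separation[rupture]),
    )


def screen_dataset(
    curves: list[ForceDistanceCurve], params: ScreeningParams | None = None
) -> tuple[list[BindingEvent], pd.DataFrame]:
    """Screen every curve; return accepted events and a per-curve QC log.

    The QC frame has one row per input curve with columns: label,
    disposition ('accepted'/'rejected'), step (first failed step, empty if
    accepted), sigma (pN, when reached), work (k_BT, when accepted), reason.
    """
    params = params or ScreeningParams()
    events: list[BindingEvent] = []
    rows = []
    for i, curve in enumerate(curves):
        label = curve.label or f"curve_{i}"
        try:
            event = screen_curve(curve, params)
        except CurveRejected as rej:
            rows.append(
                {"label": label, "disposition": "rejected", "step": rej.step,
                 "sigma": np.nan, "work": np.nan, "reason": rej.reason}
            )
        else:
            events.append(event)
            rows.append(
                {"label": label, "disposition": "accepted", "step": "",
                 "sigma": event.sigma_baseline, "work": event.work_kbt, "reason": ""}
            )
    qc = pd.DataFrame(rows, columns=["label", "disposition", "step", "sigma", "work", "reason"])
    return events, qc
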