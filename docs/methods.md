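# Methods

This note records the models behind `smfe`, the numerical choices where the
procedure left room, and what the synthetic-data tests do and do not
demonstrate about real data.

## Work, units and sign conventions

All works and energies are dimensionless multiples of k_BT; forces are pN
and distances nm, with k_BT = 4.116 pN·nm at the default 298.15 K
(`kbt_pn_nm`). The AFM bath temperature is configurable because work in
k_BT depends on it; 298.15 K is the default for room-temperature
operation. The canonical curve orientation puts the surface at separation
0 and the bulk at large separation; attractive (downward-deflecting)
forces are negative, so a binding event is a negative force minimum and
the external pulling work W = −∫ F dD_s is positive. The integration
coordinate is the tip–sample separation D_s, not the piezo displacement:
the two differ by the cantilever deflection and give different works.

## Event screening

Five steps, each with an explicit failure label recorded in the QC log
(`rupture`, `multiple_events`, `baseline`, `binding`, `state_a`, `wlc`,
`work`):

1. **Rupture (state B).** The derivative of force versus separation is
   computed by linear regression in a window [i−r, i+r]; r grows from 2
   until the number of *significant maxima* — local maxima above
   median + 5·MAD of the derivative, with a 1e−9-relative floor so exact
   plateaus yield none — is identical for two consecutive radii (cap
   r = 30). Maxima whose separation lies inside the contact region (below
   `contact_frac` = 0.1 of the maximum separation) are attributed to
   tip–surface adhesion and ignored; maxima within two window widths of
   each other are one discontinuity. One remaining cluster is required:
   zero is "no event", two or more is "multiple events" — such curves are
   rejected, never split. The farthest maximum is the rupture.
2. **Baseline.** A line is fitted to the bulk tail (whichever starts
   later: one window width past the rupture, or the farthest `alpha_frac`
   fraction of points) and subtracted from the whole curve, which removes
   any linear instrumental drift exactly; σ is the standard deviation
   (ddof 1) of the post-alignment tail. Fewer than 10 tail points is a
   rejection.
3. **Binding minimum.** Local minima of the moving-average-smoothed curve
   (kernel width = the derivative window) before the rupture qualify if
   deeper than −LOD·σ; the one closest before the rupture is the binding
   site, ties going to the deeper minimum.
4. **State A.** Scanning from the binding minimum toward the surface, A is
   the first point where the smoothed force has returned to zero (within a
   1e−5 force-scale epsilon) *and* whose preceding kernel-width
   neighbourhood stays inside ±mulBase·σ. The band membership alone is not
   sufficient: with a 0.37-nm-persistence-length tether the restoring
   force stays below a 3σ band for tens of nanometres of extension, so
   stopping at the first in-band point would systematically clip work.
   Requiring an actual zero crossing backed by a sustained baseline
   neighbourhood recovers the relaxed-tether anchor and makes the result
   insensitive to mulBase (raising mulBase can only move A toward B).
5. **WLC filter.** The segment from A to the binding minimum is fitted to
   the worm-like chain force law F(γ) = (k_BT/l_p)[¼(1−γ/L)⁻² + γ/L − ¼]
   with l_p fixed at 0.37 nm and only the contour length L free, except
   for a bounded shift of the extension origin within one kernel width
   (A is only localised to the smoothing kernel; without the shift,
   noise-free curves fail their own residual test). Acceptance requires
   the mean absolute residual ≤ nlsEr·σ + 1e−3 pN (the absolute floor
   covers float residue at σ → 0). L is constrained above the A-to-rupture
   span, which also enforces the contour-length invariant of an event.

Work is the trapezoid rule on the measured points from A to the rupture
index, no resampling. W ≤ 0 is a rejection. Raising LOD or tightening
mulBase/nlsEr can only shrink the accepted set.

## Gamma estimator

The shape MLE solves log α − ψ(α) = log W̄ − mean(log W) ≡ s by Newton
iteration from α₀ = (3 − s + √((s−3)² + 24s))/(12s), rate λ = α/W̄;
convergence |Δα|/α < 1e−10 within 100 iterations (practically 3–4).
Samples with s ≤ 1e−12 (constant to machine precision) are a degenerate-fit
error; works must be strictly positive (gamma support), and the screen
already rejects W ≤ 0. ΔG_GA = α ln((λ+1)/λ) is exactly
−log E[e^{−W}] for the fitted gamma. The mean estimator uses a shifted
log-sum-exp so samples of hundreds of k_BT cannot underflow. The KS
p-value uses the asymptotic Kolmogorov distribution with the fitted
parameters treated as known — anticonservative, but it is a descriptive
diagnostic here, not a selection gate.

`parameter_scan` re-screens the dataset over a full factorial grid of
(Alpha, LOD, mulBase, nlsEr) and reports all estimators per cell plus a
convergence summary (mean ± SD of ΔG_GA over cells with at least
`min_events` events; the contributing-cell floor is exposed because no
single convention is canonical). `subsample_stability` refits seeded
90% subsamples to probe overfitting.

## SPR kinetics

Each coverage trace is fitted unweighted to
θ(t) = θ_eq(1 − e^{−k_obs t}) with θ_eq ∈ (0,1], k_obs > 0
(initialisation: θ_eq from the trace maximum, k_obs from the
half-saturation time). The module consumes already-normalised coverage;
raw-signal normalisation is instrument-specific and deliberately outside
the math core. Slightly negative coverages (down to −0.2) are tolerated as
measurement noise around zero. Rates come from the two-stage procedure —
per-trace (θ_eq, k_obs), then OLS of k_obs on C: slope k_a, intercept
k_d — rather than a global fit, and K_D = k_d/k_a,
ΔG = ln(K_D / 1 M) < 0. Traces whose fit RMSE exceeds 3× the median RMSE
are flagged as Langmuir-model violations (the high-concentration,
interacting-adsorbate regime) and excluded from the regression. Several
truncation windows (default 300/350/400 s) guard against overfitting a
particular window; the summary is mean ± SD across windows.

## PMF post-processing

A profile may be reconstructed from per-bin mean forces as
ΔA_k = −δD·Σ_{i≤k}⟨F⟩_i on the bin edges, zero at the first edge. The
adsorption free energy partitions the coordinate at D₀ into an adsorbed
[D_min, D₀] and a solution [D₀, D_max] state:
ΔG_ads = −ln(ρ_a/ρ_s) with ρ the interval-averaged Boltzmann weight of
the profile (trapezoid quadrature on the profile's own grid; interval
endpoints interpolated linearly). Energies are k_BT (β absorbed); a
kcal/mol loader converts at a stated temperature. Defaults
D_min = 0.5 nm, D₀ = 1.0 nm, D_max = 4.2 nm place the split on the
plateau between the surface well and the diffusive approach region; all
three are exposed because ΔG_ads genuinely depends on where the adsorbed
state is declared to end (including an attractive shoulder in the
adsorbed state strengthens it). A constant shift of the profile cancels
exactly in the ratio.

## Synthetic data: what it emulates, and what it does not

`gen_fdc` builds retraction curves from: i.i.d. Gaussian baseline noise
(default 6 pN), optional linear drift, a 300 pN exponential contact
repulsion (0.8 nm decay), a −40 pN adhesion dip at 2 nm, and, for event
curves, a WLC stretch from a bound-state anchor at ~12 nm ending in a
one-sample rupture step; sampling is 0.1 nm over ≥100 nm. When a work
target is given, the rupture extension is solved from the closed-form WLC
work integral so the embedded work equals the target to solver precision
(the anchor is placed off-grid to avoid grid-snapping error). Datasets
draw works from Gamma(4.42, 0.023 k_BT⁻¹) — the work law observed for a
gold-binding peptide at a few hundred pulls per run — and draw the
per-event rupture force as ~45 + 0.35·W pN with 8 pN jitter, the contour
length following from work and rupture force. That choice encodes two
experimental facts: tether-length heterogeneity carries most of the
work variation (contours of tens of nm, matching a ~50 nm unbinding
distance at the mean work), and stronger-binding events let the tether
load to higher force, which is what makes the accepted-event count
respond to the LOD threshold.

Not emulated: cantilever ringing and hydrodynamic drag, 1/f drift beyond
linear, multiple tethers on one tip, piezo nonlinearity, or correlated
noise. Passing tests therefore show that the screening logic and
estimators behave correctly on curves with the right morphology and noise
scale — not that the screen is robust to every instrumental artefact of a
particular AFM.

Kinetic traces are the exact Langmuir forward model plus Gaussian noise,
with an optional slow linear uptake term to emulate the non-Langmuir
deviation at high concentration. PMF profiles are analytic shapes (flat,
square well, smooth well with an attractive shoulder) on a dense grid.

## Problem sizes in the shipped tests

The suite uses 100–200-curve datasets (the scale of one experimental run),
a 10⁶-draw Monte-Carlo check of the exponential-average identity, 200
replicates of N = 487 for the estimator-contrast property, and 10⁵ draws
for MLE consistency; the whole suite runs in well under a minute on one
CPU. These sizes make the stochastic assertions comfortably stable at
their stated tolerances with fixed seeds.

## Known limitations

* The screen rejects rather than decomposes multi-event curves, and a few
  percent of genuine single events are lost to spurious derivative maxima
  under heavy noise; both losses are independent of the work value, so
  the work sample is thinned, not biased.
* The KS p-values ignore parameter estimation; a parametric bootstrap
  would be the rigorous alternative and can be layered on top of
  `ks_gamma_test`.
* The FD estimator is reported for diagnosis, not for use, outside the
  small-fluctuation regime; its closed-form agreement with the gamma
  estimator holds when the work scale is large against k_BT and the
  variance is ≲ 1 k_BT².
* Mass-transport limitation and multivalent binding are outside the
  Langmuir model; such traces should fail the residual flagging rather
  than be interpreted.
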