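"""Seeded generators for every input the pipeline consumes.

The force-curve generator emulates retraction traces from a tip-tethered
peptide pulled off a flat substrate: Gaussian baseline noise, optional
linear drift, a repulsive contact rise at zero separation, a nonspecific
adhesion dip just off contact, and (for event-bearing curves) a worm-like
chain stretch ending in an abrupt rupture step back to baseline. Every
generator takes an explicit seed and returns ground-truth annotations
alongside the data.

Geometry defaults mimic a PEG-tethered peptide experiment: unbinding
separations of a few tens of nm and baseline noise of ~6 pN. When a work
target is given without a contour length, the tether contour is scaled so
the rupture occurs at a fixed 85% relative extension: rupture forces then
sit well above any realistic detection threshold for all work values, the
way a tuned experiment behaves, while tether-length heterogeneity carries
the work variation.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .curves import ForceDistanceCurve, KineticTrace, PMFProfile, ValidationError, WorkSample
from .screening import wlc_force

FDC_KINDS = ("single_event", "flat", "double_rupture", "drift_only")

_GRID_STEP = 0.1  # nm
_DEFAULT_ZMAX = 100.0  # nm
_BASELINE_TAIL = 40.0  # nm of bulk baseline guaranteed after the last rupture
_CONTACT_AMPLITUDE = 300.0  # pN
_CONTACT_DECAY = 0.8  # nm
_ADHESION_DEPTH = 40.0  # pN
_ADHESION_CENTER = 2.0  # nm
_ADHESION_WIDTH = 0.6  # nm
_RUPTURE_FRACTION = 0.85  # gamma_B / L when the contour is free


def wlc_work_kbt(extension: float, contour_length: float, persistence_length: float = 0.37) -> float:
    """Closed-form WLC stretching work from zero extension, in k_BT.

    Antiderivative of the WLC force law divided by k_BT:
    (1/l_p) [ (L/4) x/(1-x) + g^2/(2L) - g/4 ],  x = g/L.
    Independent of temperature because both force and energy scale with k_BT.
    """
    g, L, lp = float(extension), float(contour_length), float(persistence_length)
    if not (0 <= g < L):
        raise ValidationError("extension must satisfy 0 <= extension < contour_length")
    x = g / L
    return (1.0 / lp) * (0.25 * L * x / (1.0 - x) + g * g / (2.0 * L) - 0.25 * g)


def solve_rupture_extension(work_kbt: float, contour_length: float,
                            persistence_length: float = 0.37) -> float:
    """Extension at which the cumulative WLC work reaches ``work_kbt``."""
    if work_kbt <= 0:
        raise ValidationError("work target must be positive")
    L = float(contour_length)
    return float(brentq(
        lambda g: wlc_work_kbt(g, L, persistence_length) - work_kbt,
        1e-9 * L, (1.0 - 1e-9) * L, xtol=1e-12 * L,
    ))


def fraction_for_force(force_pn: float, persistence_length: float = 0.37,
                       temperature: float = 298.15) -> float:
    """Relative extension x = g/L at which the WLC force equals ``force_pn``."""
    from .curves import kbt_pn_nm

    scale = kbt_pn_nm(temperature) / persistence_length
    y = float(force_pn) / scale
    if y <= 0:
        raise ValidationError("force must be positive")
    x = brentq(lambda u: 0.25 * (1.0 - u) ** -2 + u - 0.25 - y, 1e-9, 1.0 - 1e-9)
    return float(x)


def contour_for_work(work_kbt: float, rupture_fraction: float = _RUPTURE_FRACTION,
                     persistence_length: float = 0.37) -> float:
    """Contour length whose WLC work at the given relative extension equals the target."""
    if not (0 < rupture_fraction < 1):
        raise ValidationError("rupture_fraction must be in (0, 1)")
    x = rupture_fraction
    per_unit_L = (1.0 / persistence_length) * (0.25 * x / (1.0 - x) + 0.5 * x * x - 0.25 * x)
    return float(work_kbt) / per_unit_L


def gen_work_sample(n: int, shape: float, rate: float, seed: int = 0) -> WorkSample:
    """n i.i.d. draws from Gamma(shape, rate), as a WorkSample."""
    if n < 1 or shape <= 0 or rate <= 0:
        raise ValidationError("need n >= 1 and positive gamma parameters")
    rng = np.random.default_rng(seed)
    return WorkSample(rng.gamma(shape, scale=1.0 / rate, size=n))


def _base_force(z: np.ndarray, noise_sd: float, drift_slope: float,
                rng: np.random.Generator, adhesion: bool) -> np.ndarray:
    force = np.zeros_like(z)
    force += _CONTACT_AMPLITUDE * np.exp(-z / _CONTACT_DECAY)
    if adhesion:
        force -= _ADHESION_DEPTH * np.exp(-(((z - _ADHESION_CENTER) / _ADHESION_WIDTH) ** 2))
    if drift_slope:
        force += drift_slope * z
    if noise_sd:
        force += rng.normal(0.0, noise_sd, size=z.size)
    return force


def _add_wlc_segment(z, force, z_anchor_index, gamma_b, contour, lp, temperature):
    """Paint a WLC pull ending at index ``z_anchor_index`` over the base force.

    The bound-state anchor z_A is placed off-grid at z[idx_B] - gamma_b so
    the embedded work equals the closed form at gamma_b exactly; returns the
    first on-grid index of the stretch.
    """
    idx_b = z_anchor_index
    z_a = z[idx_b] - gamma_b
    idx_a = int(np.ceil(z_a / _GRID_STEP - 1e-9))
    seg = slice(idx_a, idx_b + 1)
    force[seg] -= wlc_force(z[seg] - z_a, contour, lp, temperature)
    return idx_a


def gen_fdc(
    kind: str,
    work_target: float | None = None,
    contour_length: float | None = None,
    noise_sd: float = 6.0,
    drift_slope: float = 0.0,
    seed: int = 0,
    z_bind: float = 12.0,
    persistence_length: float = 0.37,
    temperature: float = 298.15,
    pulling_rate: float = 500.0,
    rupture_fraction: float | None = None,
) -> tuple[ForceDistanceCurve, dict]:
    """Generate one retraction curve of the requested kind plus ground truth.

    Kinds: ``single_event`` (one WLC stretch and rupture), ``flat`` (no
    event), ``double_rupture`` (two stretches — must be rejected downstream),
    ``drift_only`` (baseline drift, no event). For single events a
    ``work_target`` (k_BT) fixes the embedded WLC work to within solver
    precision; with ``contour_length`` also given, the rupture extension is
    solved on that contour instead.

    Returns (curve, annotation); annotation carries the kind and, for single
    events, true index_A/index_B, contour length, rupture extension, and the
    closed-form work in k_BT.
    """
    if kind not in FDC_KINDS:
        raise ValidationError(f"unknown curve kind {kind!r}; choose from {FDC_KINDS}")
    rng = np.random.default_rng(seed)
    lp = persistence_length
    annotation: dict = {"kind": kind, "seed": seed}

    frac = _RUPTURE_FRACTION if rupture_fraction is None else float(rupture_fraction)
    if not (0 < frac < 1):
        raise ValidationError("rupture_fraction must be in (0, 1)")
    if kind == "single_event":
        if work_target is not None:
            if contour_length is not None:
                L = float(contour_length)
                gamma_b = solve_rupture_extension(work_target, L, lp)
            else:
                L = contour_for_work(work_target, rupture_fraction=frac,
                                     persistence_length=lp)
                gamma_b = solve_rupture_extension(work_target, L, lp)
        else:
            L = float(contour_length) if contour_length is not None else 50.0
            gamma_b = frac * L
        z_rupture = z_bind + gamma_b
        z_max = max(_DEFAULT_ZMAX, z_rupture + _BASELINE_TAIL)
    elif kind == "double_rupture":
        L = None
        z_max = _DEFAULT_ZMAX
    else:
        L = None
        z_max = _DEFAULT_ZMAX

    n = int(round(z_max / _GRID_STEP)) + 1
    z = _GRID_STEP * np.arange(n)
    adhesion = kind in ("single_event", "double_rupture")
    if kind == "drift_only" and drift_slope == 0.0:
        drift_slope = 0.05
    force = _base_force(z, noise_sd, drift_slope, rng, adhesion)

    if kind == "single_event":
        idx_b = int(round((z_bind + gamma_b) / _GRID_STEP))
        idx_a = _add_wlc_segment(z, force, idx_b, gamma_b, L, lp, temperature)
        annotation.update(
            index_A=idx_a,
            index_B=idx_b,
            contour_length=L,
            rupture_extension=gamma_b,
            work_kbt=wlc_work_kbt(gamma_b, L, lp),
        )
    elif kind == "double_rupture":
        L1, L2 = 20.0, 25.0
        g1, g2 = _RUPTURE_FRACTION * L1, _RUPTURE_FRACTION * L2
        idx_b1 = int(round((z_bind + g1) / _GRID_STEP))
        idx_a1 = _add_wlc_segment(z, force, idx_b1, g1, L1, lp, temperature)
        z_a2 = z[idx_b1] + 8.0
        idx_b2 = int(round((z_a2 + g2) / _GRID_STEP))
        idx_a2 = _add_wlc_segment(z, force, idx_b2, g2, L2, lp, temperature)
        annotation.update(
            rupture_indices=[idx_b1, idx_b2],
            anchor_indices=[idx_a1, idx_a2],
            contour_lengths=[L1, L2],
        )

    curve = ForceDistanceCurve(
        separation=z, force=force, pulling_rate=pulling_rate,
        temperature=temperature, label=f"{kind}_{seed}",
    )
    return curve, annotation


def gen_dataset(
    counts: dict,
    shape: float = 4.42,
    rate: float = 0.023,
    noise_sd: float = 6.0,
    drift_slope: float = 0.0,
    seed: int = 0,
) -> tuple[list[ForceDistanceCurve], list[dict]]:
    """Generate a mixed dataset with known composition.

    ``counts`` maps each curve kind to how many curves to produce; works for
    single-event curves are drawn from Gamma(shape, rate). The rupture force
    grows with the binding work (stronger binding holds to higher force),
    F_rupt ~ 45 + 0.35*W pN plus jitter, and the per-event contour length
    follows from work and rupture force — tether-length heterogeneity
    carries the work variation, as in a PEG-linker experiment. Curves are
    returned in a deterministic shuffled order (so kinds are interleaved as
    in a real acquisition).
    """
    unknown = set(counts) - set(FDC_KINDS)
    if unknown:
        raise ValidationError(f"unknown curve kind(s): {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    jobs: list[str] = []
    for kind in FDC_KINDS:
        jobs += [kind] * int(counts.get(kind, 0))
    order = rng.permutation(len(jobs))
    curves, annotations = [], []
    child_seeds = rng.integers(0, 2**31 - 1, size=len(jobs))
    works = rng.gamma(shape, scale=1.0 / rate, size=len(jobs))
    rupture_forces = np.clip(
        45.0 + 0.35 * works + rng.normal(0.0, 8.0, size=len(jobs)), 40.0, None
    )
    fractions = np.array([fraction_for_force(f) for f in rupture_forces])
    for slot, j in enumerate(order):
        kind = jobs[j]
        target = float(works[j]) if kind == "single_event" else None
        curve, ann = gen_fdc(
            kind, work_target=target, noise_sd=noise_sd,
            drift_slope=drift_slope, seed=int(child_seeds[j]),
            rupture_fraction=float(fractions[j]),
        )
        curve.label = f"{slot:04d}_{kind}"
        ann["label"] = curve.label
        curves.append(curve)
        annotations.append(ann)
    return curves, annotations


def gen_kinetic_trace(
    concentration: float,
    ka: float,
    kd: float,
    t_grid,
    noise_sd: float = 0.0,
    seed: int = 0,
    secondary_slope: float = 0.0,
) -> KineticTrace:
    """Langmuir relaxation trace theta(t) with optional Gaussian noise.

    ``secondary_slope`` (1/s) adds a slow linear uptake on top of the
    Langmuir form, emulating the non-Langmuir deviation seen at high
    analyte concentrations.
    """
    t = np.asarray(t_grid, dtype=float)
    if ka <= 0 or kd < 0 or concentration <= 0:
        raise ValidationError("need ka > 0, kd >= 0 and positive concentration")
    kD = kd / ka
    k_obs = ka * concentration + kd
    theta = concentration / (concentration + kD) * (1.0 - np.exp(-k_obs * t))
    if secondary_slope:
        theta = theta + secondary_slope * t
    if noise_sd:
        rng = np.random.default_rng(seed)
        theta = theta + rng.normal(0.0, noise_sd, size=t.size)
    return KineticTrace(time=t, coverage=np.clip(theta, -0.19, 1.19),
                        concentration=concentration)


PMF_KINDS = ("flat", "square_well", "smooth_well_with_plateau")


def gen_pmf(
    kind: str,
    depth: float = 5.0,
    grid=None,
    well_end: float = 1.0,
    shoulder_depth: float = 3.0,
) -> PMFProfile:
    """Synthetic PMF profiles in k_BT on a distance grid (nm).

    ``square_well``: energy -depth strictly below ``well_end``, zero beyond.
    ``smooth_well_with_plateau``: a Gaussian surface well at 0.7 nm on top
    of a tanh shelf of depth ``shoulder_depth`` decaying around 1.8 nm — a
    continuous profile with a single minimum and an attractive shoulder
    mimicking a biased-diffusion approach region.
    """
    if kind not in PMF_KINDS:
        raise ValidationError(f"unknown PMF kind {kind!r}; choose from {PMF_KINDS}")
    z = np.asarray(grid, dtype=float) if grid is not None else np.arange(0.3, 4.5001, 0.002)
    if kind == "flat":
        energy = np.zeros_like(z)
    elif kind == "square_well":
        energy = np.where(z < well_end, -float(depth), 0.0)
    else:
        well = -float(depth) * np.exp(-(((z - 0.7) / 0.2) ** 2))
        shelf = -float(shoulder_depth) * 0.5 * (1.0 - np.tanh((z - 1.8) / 0.25))
        energy = well + shelf
    return PMFProfile(grid=z, energy=energy)
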