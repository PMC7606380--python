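"""Domain types, unit handling, and plain-text I/O.

The central object is the retraction force-distance curve: cantilever force
(pN) versus tip-sample separation D_s (nm). The canonical orientation puts
the surface at D_s = 0 with separation strictly increasing into the bulk;
attractive (downward-deflecting) forces are negative, so a binding signal
appears as a negative force minimum.

All work and energy values downstream are dimensionless multiples of k_BT.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

BOLTZMANN_J_PER_K = 1.380649e-23

#: Minimum number of samples for a curve to be analysable at all.
MIN_CURVE_POINTS = 50


class ValidationError(ValueError):
    """Input violates a domain invariant."""


class ParseError(ValueError):
    """A text file could not be interpreted as the expected table."""


def kbt_pn_nm(temperature: float) -> float:
    """Thermal energy k_B*T expressed in pN*nm.

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin; must be positive.

    Returns
    -------
    float
        k_B*T in pN*nm (about 4.116 at 298.15 K).
    """
    if not np.isfinite(temperature) or temperature <= 0:
        raise ValidationError(f"temperature must be positive, got {temperature!r}")
    return BOLTZMANN_J_PER_K * temperature / 1e-21


def kcal_per_mol_to_kbt(value, temperature: float):
    """Convert an energy from kcal/mol to k_BT at the given temperature."""
    r_kcal = 1.987204259e-3  # gas constant, kcal/(mol K)
    if temperature <= 0:
        raise ValidationError("temperature must be positive")
    return np.asarray(value, dtype=float) / (r_kcal * temperature)


@dataclass
class ForceDistanceCurve:
    """One retraction trace: separation (nm) and force (pN) arrays.

    Separation is brought to canonical order on construction: if the file
    stored the trace surface-last it is reversed; anything not strictly
    monotone is rejected rather than silently re-sorted.
    """

    separation: np.ndarray
    force: np.ndarray
    pulling_rate: float | None = None  # nm/s
    temperature: float = 298.15  # K
    label: str = ""

    def __post_init__(self):
        sep = np.asarray(self.separation, dtype=float)
        frc = np.asarray(self.force, dtype=float)
        if sep.ndim != 1 or frc.ndim != 1 or sep.size != frc.size:
            raise ValidationError("separation and force must be 1-D arrays of equal length")
        if sep.size < MIN_CURVE_POINTS:
            raise ValidationError(
                f"curve has {sep.size} points; at least {MIN_CURVE_POINTS} required"
            )
        if not (np.all(np.isfinite(sep)) and np.all(np.isfinite(frc))):
            raise ValidationError("separation and force must be finite")
        d = np.diff(sep)
        if np.all(d < 0):  # stored bulk-first: flip to canonical order
            sep, frc = sep[::-1].copy(), frc[::-1].copy()
        elif not np.all(d > 0):
            raise ValidationError("separation is not strictly monotone; cannot canonicalise")
        self.separation = sep
        self.force = frc
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive")

    def __len__(self) -> int:
        return self.separation.size

    def with_force(self, force: np.ndarray) -> "ForceDistanceCurve":
        """Copy of this curve with a replaced force array (same grid)."""
        return ForceDistanceCurve(
            separation=self.separation.copy(),
            force=np.asarray(force, dtype=float),
            pulling_rate=self.pulling_rate,
            temperature=self.temperature,
            label=self.label,
        )


@dataclass
class ScreeningParams:
    """Thresholds controlling single-event screening.

    alpha_frac is the fraction of farthest-from-surface points treated as
    bulk baseline; lod the detection limit in noise multiples; mul_base the
    allowed baseline fluctuation in noise multiples for locating the bound
    state; nls_err the WLC residual tolerance in noise multiples.
    """

    alpha_frac: float = 0.5
    lod: float = 5.5
    mul_base: float = 3.0
    nls_err: float = 3.0
    persistence_length: float = 0.37  # nm
    temperature: float = 298.15  # K
    contact_frac: float = 0.1  # fraction of max separation treated as contact region
    min_baseline_points: int = 10

    def __post_init__(self):
        if not (0 < self.alpha_frac < 1):
            raise ValidationError("alpha_frac must be in (0, 1)")
        for name in ("lod", "mul_base", "nls_err", "persistence_length", "temperature"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not (0 <= self.contact_frac < 1):
            raise ValidationError("contact_frac must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "ScreeningParams":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(data) - known
        if extra:
            raise ValidationError(f"unknown screening parameter(s): {sorted(extra)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class BindingEvent:
    """An accepted single-binding event extracted from one curve."""

    index_A: int
    index_B: int
    sigma_baseline: float  # pN
    contour_length: float  # nm
    wlc_residual: float  # pN, mean absolute residual of the WLC fit
    work_kbt: float
    label: str = ""
    binding_index: int | None = None
    separation_A: float | None = None  # nm
    separation_B: float | None = None  # nm

    def __post_init__(self):
        if not self.index_A < self.index_B:
            raise ValidationError("index_A must precede index_B")
        if self.work_kbt <= 0:
            raise ValidationError("work must be positive")
        if self.separation_A is not None and self.separation_B is not None:
            if self.contour_length <= self.separation_B - self.separation_A:
                raise ValidationError(
                    "contour length must exceed the A-to-B separation span"
                )


@dataclass
class WorkSample:
    """Vector of positive work values, in k_BT, feeding the JE estimators."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise ValidationError("work sample must be a non-empty 1-D array")
        if not np.all(np.isfinite(v)):
            raise ValidationError("work values must be finite")
        if np.any(v <= 0):
            raise ValidationError("work values must be strictly positive (gamma support)")
        self.values = v

    def __len__(self) -> int:
        return self.values.size


@dataclass
class GammaFit:
    """Maximum-likelihood gamma fit of a work sample plus goodness of fit."""

    shape: float
    rate: float
    log_likelihood: float
    dg_gamma: float  # k_BT
    ks_statistic: float
    ks_pvalue: float

    def __post_init__(self):
        if self.shape <= 0 or self.rate <= 0:
            raise ValidationError("gamma shape and rate must be positive")
        expected = self.shape * np.log((self.rate + 1.0) / self.rate)
        if not np.isclose(self.dg_gamma, expected, rtol=1e-9, atol=1e-12):
            raise ValidationError("dg_gamma inconsistent with shape and rate")
        if not (0 <= self.ks_statistic <= 1) or not (0 <= self.ks_pvalue <= 1):
            raise ValidationError("KS statistic and p-value must lie in [0, 1]")


@dataclass
class EstimateReport:
    """All free-energy estimators evaluated coherently on one work sample."""

    n_events: int
    dg_mean: float
    dg_fd: float
    gaussian_mean: float
    gaussian_sd: float
    prob_negative: float
    gamma_fit: GammaFit

    def __post_init__(self):
        if self.dg_mean > self.gaussian_mean + 1e-9 * max(1.0, abs(self.gaussian_mean)):
            raise ValidationError("dg_mean exceeds the sample mean (Jensen violation)")


@dataclass
class KineticTrace:
    """SPR coverage trace: time (s) versus fractional coverage at one analyte concentration (M)."""

    time: np.ndarray
    coverage: np.ndarray
    concentration: float  # M

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        c = np.asarray(self.coverage, dtype=float)
        if t.ndim != 1 or c.ndim != 1 or t.size != c.size:
            raise ValidationError("time and coverage must be 1-D arrays of equal length")
        if t.size < 2 or np.any(np.diff(t) <= 0) or t[0] < 0:
            raise ValidationError("time must be non-negative and strictly increasing")
        # Measurement noise may take coverage slightly outside [0, 1].
        if np.any(c < -0.2) or np.any(c > 1.2):
            raise ValidationError("coverage outside the plausible range [-0.2, 1.2]")
        if self.concentration <= 0:
            raise ValidationError("concentration must be positive")
        self.time, self.coverage = t, c


@dataclass
class KineticsFit:
    """Per-window Langmuir kinetics: per-trace fits plus regression-derived rates."""

    per_trace: list  # of (concentration M, theta_eq, k_obs 1/s)
    ka: float  # 1/(M s)
    kd: float  # 1/s
    kD: float  # M
    dg_ads: float  # k_BT
    ka_se: float | None = None
    kd_se: float | None = None
    window: float | None = None  # s

    def __post_init__(self):
        if not np.isclose(self.kD, self.kd / self.ka, rtol=1e-9):
            raise ValidationError("kD must equal kd/ka")
        if not np.isclose(self.dg_ads, np.log(self.kD), rtol=1e-9, atol=1e-12):
            raise ValidationError("dg_ads must equal ln(kD / 1 M)")


@dataclass
class PMFProfile:
    """Free-energy profile ΔG(z) in k_BT on a strictly increasing distance grid (nm)."""

    grid: np.ndarray
    energy: np.ndarray
    bin_forces: np.ndarray | None = None  # per-bin mean force, k_BT/nm
    bin_width: float | None = None  # nm

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=float)
        e = np.asarray(self.energy, dtype=float)
        if g.ndim != 1 or e.ndim != 1 or g.size != e.size or g.size < 2:
            raise ValidationError("grid and energy must be 1-D arrays of equal length >= 2")
        if np.any(np.diff(g) <= 0):
            raise ValidationError("grid must be strictly increasing")
        if not np.all(np.isfinite(e)):
            raise ValidationError("energy must be finite")
        if self.bin_forces is not None and e[0] != 0.0:
            raise ValidationError("profile built from bin forces must start at zero energy")
        self.grid, self.energy = g, e


# ---------------------------------------------------------------------------
# File I/O

_DEFAULT_DIALECT = {
    "distance_col": 0,
    "force_col": 1,
    "distance_scale": 1.0,  # multiply file values to obtain nm
    "force_scale": 1.0,  # multiply file values to obtain pN
    "comment": "#",
}

_TOKEN_SPLIT = re.compile(r"[,;\s]+")


def _parse_table(path, comment: str = "#"):
    """Parse a whitespace/comma separated numeric table, skipping a leading header.

    Returns (rows, first_data_line). Raises ParseError naming the offending
    line for malformed rows after data has started.
    """
    rows = []
    started = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or (comment and line.startswith(comment)):
                continue
            tokens = [t for t in _TOKEN_SPLIT.split(line) if t]
            try:
                values = [float(t) for t in tokens]
            except ValueError:
                if started:
                    raise ParseError(f"{path}: malformed numeric row at line {lineno}")
                continue  # header line(s) before the data block
            if started and len(values) != len(rows[0]):
                raise ParseError(f"{path}: inconsistent column count at line {lineno}")
            rows.append(values)
            started = True
    if not rows:
        raise ParseError(f"{path}: no numeric rows found")
    return np.asarray(rows, dtype=float)


def read_curve(path, dialect: dict | None = None) -> ForceDistanceCurve:
    """Read a plain-text force-distance curve.

    The default dialect expects two whitespace- or comma-separated columns,
    distance (nm) then force (pN), with any leading header skipped. A
    dialect mapping can reassign columns and apply unit scale factors (e.g.
    ``{"distance_scale": 1000}`` for a file storing micrometres).
    """
    d = dict(_DEFAULT_DIALECT)
    if dialect:
        unknown = set(dialect) - set(d)
        if unknown:
            raise ValidationError(f"unknown dialect key(s): {sorted(unknown)}")
        d.update(dialect)
    table = _parse_table(path, comment=d["comment"])
    if table.shape[1] < 2:
        raise ParseError(f"{path}: need at least two numeric columns")
    ncol = table.shape[1]
    if d["distance_col"] >= ncol or d["force_col"] >= ncol:
        raise ValidationError("dialect column index beyond file width")
    sep = table[:, d["distance_col"]] * d["distance_scale"]
    frc = table[:, d["force_col"]] * d["force_scale"]
    return ForceDistanceCurve(separation=sep, force=frc, label=str(Path(path).stem))


def write_curve(curve: ForceDistanceCurve, path) -> None:
    """Write a curve as two-column text (nm, pN) readable by :func:`read_curve`."""
    header = "separation_nm\tforce_pN"
    np.savetxt(path, np.column_stack([curve.separation, curve.force]),
               delimiter="\t", header=header, comments="# ")


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def write_report(report: EstimateReport, path) -> None:
    """Serialise an estimate report to JSON, losslessly and deterministically."""
    payload = _to_jsonable(report)
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=2)
        fh.write("\n")


def read_report(path) -> EstimateReport:
    """Inverse of :func:`write_report`."""
    with open(path) as fh:
        data = json.load(fh)
    try:
        gf = GammaFit(**data.pop("gamma_fit"))
        return EstimateReport(gamma_fit=gf, **data)
    except (KeyError, TypeError) as exc:
        raise ParseError(f"{path}: not a valid estimate report ({exc})")
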