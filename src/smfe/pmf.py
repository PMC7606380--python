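"""Potential-of-mean-force post-processing.

Two operations on PMF profiles along a molecule-surface distance coordinate:

* reconstruction of the profile from per-bin mean forces (the adaptive
  biasing force output): dA = -delta_D * sum_i <F>_i, cumulated from a zero
  reference at the first bin edge;
* the adsorption free energy from state-partitioned Boltzmann averages,

      rho_a = 1/(D0 - Dmin) * int_{Dmin}^{D0} e^{-dG(z)} dz
      rho_s = 1/(Dmax - D0) * int_{D0}^{Dmax} e^{-dG(z)} dz
      dG_ads = -ln(rho_a / rho_s)    [k_BT]

  where D0 splits the coordinate into an adsorbed and a solution state.
  Energies are dimensionless (k_BT), so beta is absorbed. dG_ads is
  invariant under a constant shift of the profile.

Quadrature is the trapezoid rule on the profile's own grid.
"""

from __future__ import annotations

import numpy as np

from .curves import PMFProfile, ValidationError, kcal_per_mol_to_kbt


def reconstruct_pmf(bin_forces, bin_width: float, start: float = 0.0) -> PMFProfile:
    """Cumulate per-bin mean forces into a free-energy profile.

    ``bin_forces`` are mean forces along the coordinate in k_BT/nm and
    ``bin_width`` the bin size in nm. The returned profile lives on the
    n+1 bin edges with energy zero at the first edge.
    """
    f = np.asarray(bin_forces, dtype=float)
    if f.ndim != 1 or f.size == 0:
        raise ValidationError("bin_forces must be a non-empty 1-D array")
    if not np.all(np.isfinite(f)):
        raise ValidationError("bin forces must be finite")
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    energy = np.concatenate([[0.0], -bin_width * np.cumsum(f)])
    grid = start + bin_width * np.arange(f.size + 1)
    return PMFProfile(grid=grid, energy=energy, bin_forces=f, bin_width=float(bin_width))


def profile_from_kcal(grid, energy_kcal, temperature: float = 300.0) -> PMFProfile:
    """Build a profile from energies in kcal/mol, converting to k_BT."""
    return PMFProfile(grid=np.asarray(grid, float),
                      energy=kcal_per_mol_to_kbt(energy_kcal, temperature))


def _interval_nodes(profile: PMFProfile, a: float, b: float):
    g, e = profile.grid, profile.energy
    if not (g[0] <= a < b <= g[-1]):
        raise ValidationError(f"interval [{a}, {b}] outside profile grid [{g[0]}, {g[-1]}]")
    inner = g[(g > a) & (g < b)]
    nodes = np.concatenate([[a], inner, [b]])
    energies = np.interp(nodes, g, e)
    return nodes, energies


def state_density(profile: PMFProfile, a: float, b: float) -> float:
    """Interval-averaged Boltzmann weight (1/(b-a)) * int_a^b e^{-dG(z)} dz."""
    nodes, energies = _interval_nodes(profile, a, b)
    return float(np.trapezoid(np.exp(-energies), nodes) / (b - a))


def dg_ads(
    profile: PMFProfile,
    d_min: float = 0.5,
    d0: float = 1.0,
    d_max: float = 4.2,
) -> float:
    """Adsorption free energy -ln(rho_a/rho_s) in k_BT (negative = favourable).

    ``d0`` splits adsorbed [d_min, d0] from solution [d0, d_max]; the
    defaults place the split on the plateau between the surface well and
    the diffusive approach region.
    """
    if not (d_min < d0 < d_max):
        raise ValidationError("boundaries must satisfy d_min < d0 < d_max")
    rho_a = state_density(profile, d_min, d0)
    rho_s = state_density(profile, d0, d_max)
    return float(-(np.log(rho_a) - np.log(rho_s)))
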