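"""Charge density, Gauss-law electric field, electrostatic potential and
zeta potential about the nanoparticle.

The chain is σ(r) → E(r) → φ(r) → ζ:

* σ(r): per-atom-type number densities weighted by partial charge, summed,
  on the 0.1 Å radial grid (e·Å⁻³).
* E(r): spherically symmetric Gauss law with vacuum permittivity,
  E(r) = Q_enc(r)/(4π ε₀ r²) with Q_enc(r) = Q_core + 4π ∫_{r₀}^{r} σ r′² dr′,
  trapezoidal quadrature, reported in V·Å⁻¹.
* φ(r) = ∫_r^{r_bulk} E dr′, so φ(bulk) = 0 by construction; reported in mV.
* ζ = φ(shear radius), the shear plane placed where the bulk water phase
  begins (water RDF reaches 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .core import COULOMB_VOLT_ANG, CenterConvention, Topology, Trajectory
from .profiles import DEFAULT_BIN_WIDTH, RadialProfile, bulk_onset_radius, radial_rdf


def charge_density_profile(
    traj: Trajectory,
    topology: Topology,
    sel: np.ndarray,
    center: CenterConvention | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
    r_max: float | None = None,
) -> RadialProfile:
    """Total charge density σ(r) in e·Å⁻³: charge-weighted number density of
    the selected (mobile) atoms, time-averaged over the window."""
    from .core import minimum_image

    center = center or CenterConvention()
    sel = np.asarray(sel, dtype=np.intp)
    q = topology.charges[sel]
    bad = sel[~np.isfinite(q)]
    if bad.size:
        raise ValueError(f"missing partial charges for atoms {bad.tolist()}")
    if r_max is None:
        r_max = 0.5 * min(float(f.box.min()) for f in traj)
    n_bins = int(np.ceil(r_max / bin_width - 1e-9))
    edges = bin_width * np.arange(n_bins + 1)
    charge_sum = np.zeros(n_bins)
    for frame in traj:
        c = center.resolve(frame, topology)
        d = minimum_image(frame.positions[sel] - c, frame.box)
        r = np.linalg.norm(d, axis=1)
        h, _ = np.histogram(r, bins=edges, weights=q)
        charge_sum += h
    prof = RadialProfile(edges, np.zeros(n_bins), "number_density", len(traj))
    prof.values = charge_sum / len(traj) / prof.shell_volumes
    prof.kind = "charge_density"
    return prof


def electric_field_profile(
    sigma: RadialProfile,
    r0: float,
    core_charge: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Radial electric field E(r) in V·Å⁻¹ from the Gauss law.

    Integration runs from the NP surface ``r0`` outward; ``core_charge``
    (e) adds the enclosed fixed charge of the particle itself.  Returns
    ``(r, E)`` on the portion of the bin grid with r ≥ r0.
    """
    if sigma.kind != "charge_density":
        raise ValueError("electric field requires a charge_density profile")
    r_all = sigma.r_mid
    if r0 < r_all[0] - sigma.bin_width or r0 > r_all[-1]:
        raise ValueError(f"r0 = {r0} Å lies outside the profile grid")
    mask = r_all >= r0
    r = r_all[mask]
    integrand = sigma.values[mask] * r**2
    enclosed = 4.0 * np.pi * cumulative_trapezoid(integrand, r, initial=0.0)
    q_enc = core_charge + enclosed  # e
    e_field = COULOMB_VOLT_ANG * q_enc / r**2  # volts / Å
    return r, e_field


def electrostatic_potential_profile(
    r: np.ndarray,
    e_field: np.ndarray,
    bulk_radius: float,
) -> np.ndarray:
    """φ(r) in mV by integrating the field, referenced so φ(bulk_radius) = 0."""
    r = np.asarray(r, dtype=float)
    e_field = np.asarray(e_field, dtype=float)
    if bulk_radius > r[-1] or bulk_radius < r[0]:
        raise ValueError(f"bulk radius {bulk_radius} Å beyond field grid")
    # φ(r) = -∫_{r_ref}^{r} E dr'  with the constant fixed at the bulk radius
    phi = -cumulative_trapezoid(e_field, r, initial=0.0)  # volts, zero at r[0]
    phi_bulk = float(np.interp(bulk_radius, r, phi))
    return (phi - phi_bulk) * 1000.0  # mV


def zeta_potential(r: np.ndarray, phi_mv: np.ndarray, shear_radius: float) -> float:
    """ζ (mV): the electrostatic potential at the shear plane, interpolated."""
    r = np.asarray(r, dtype=float)
    if shear_radius < r[0] or shear_radius > r[-1]:
        raise ValueError(f"shear radius {shear_radius} Å beyond potential grid")
    return float(np.interp(shear_radius, r, phi_mv))


@dataclass
class ElectrokineticProfiles:
    """σ(r), E(r), φ(r) on a common grid, with the shear radius and ζ."""

    r: np.ndarray
    sigma: np.ndarray
    e_field: np.ndarray
    potential_mv: np.ndarray
    r0: float
    shear_radius: float
    zeta_mv: float


def electrokinetics_pipeline(
    traj: Trajectory,
    topology: Topology,
    mobile_sel: np.ndarray,
    water_sel: np.ndarray,
    r0: float,
    center: CenterConvention | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
    core_charge: float = 0.0,
    bulk_radius: float | None = None,
    shear_radius: float | None = None,
) -> ElectrokineticProfiles:
    """Full σ → E → φ → ζ chain for one system.

    ``mobile_sel`` is the charged selection (coating + water + ions);
    ``water_sel`` feeds the water RDF whose bulk onset places the shear
    plane when ``shear_radius`` is not given explicitly.
    """
    center = center or CenterConvention()
    sigma = charge_density_profile(traj, topology, mobile_sel, center, bin_width)
    r, e_field = electric_field_profile(sigma, r0, core_charge=core_charge)
    if shear_radius is None:
        rdf = radial_rdf(traj, water_sel, center, topology, bin_width)
        shear_radius = bulk_onset_radius(rdf)
    if bulk_radius is None:
        bulk_radius = float(r[-1])
    phi = electrostatic_potential_profile(r, e_field, bulk_radius)
    zeta = zeta_potential(r, phi, shear_radius)
    mask = sigma.r_mid >= r[0]
    return ElectrokineticProfiles(
        r=r, sigma=sigma.values[mask], e_field=e_field, potential_mv=phi,
        r0=r0, shear_radius=float(shear_radius), zeta_mv=zeta,
    )
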