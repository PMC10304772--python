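"""Rigid-body coarse-grained protein-surface interaction model.

The total protein-surface potential is pairwise additive over residue
beads: a screened-Coulomb electrostatic term, a tabulated short-range
surface term (one PMF per residue type), and a long-range Hamaker core
term.  For each rigid orientation (theta, phi) the total potential is
evaluated along the surface-approach coordinate and reduced to a single
orientation energy by a log-Boltzmann distance integral; scanning the
orientation grid yields the adsorption heatmap, its minimum-energy pose,
and the Boltzmann-averaged adsorption energy.

Orientation convention
----------------------
(theta, phi) are spherical angles of a direction n in the protein's input
(PDB) frame; the protein is rotated about its centre of mass so that n
points along the outward surface normal (lab +z).  Equivalently, the
height of bead i above the centre of mass is the projection
(r_i - COM) . n.  theta = phi = 0 leaves the input coordinates unchanged.
The rotation applied is R = Ry(-theta) Rz(-phi), which is proper and
reduces to the identity at (0, 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .types import AdsorptionHeatmap, BeadProtein, SurfacePMFSet, SurfaceSpec

log = logging.getLogger(__name__)

__all__ = [
    "direction_from_angles", "rotation_matrix", "orient",
    "electrostatic_energy", "hamaker_sphere_sphere", "hamaker_sphere_plate",
    "short_range_energy", "EnergyProfile", "energy_profile",
    "orientation_energy", "build_heatmap", "boltzmann_average",
    "rank_proteins",
]

#: Minimum surface gap (nm) below which the diverging Hamaker term is
#: clamped inside energy profiles (a Born-repulsion style cutoff).
CONTACT_CLAMP = 0.05


def direction_from_angles(theta: float, phi: float) -> np.ndarray:
    """Unit vector at spherical angles (theta, phi), in degrees."""
    th, ph = np.radians(theta), np.radians(phi)
    return np.array([np.sin(th) * np.cos(ph),
                     np.sin(th) * np.sin(ph),
                     np.cos(th)])


def rotation_matrix(theta: float, phi: float) -> np.ndarray:
    """Proper rotation R = Ry(-theta) Rz(-phi) mapping
    ``direction_from_angles(theta, phi)`` onto lab +z."""
    return Rotation.from_euler("zy", [-phi, -theta], degrees=True).as_matrix()


def orient(protein: BeadProtein, theta: float, phi: float) -> np.ndarray:
    """Rigidly rotate the protein about its centre of mass.

    Returns the rotated bead coordinates (nm).  (0, 0) is the identity.
    """
    if not (np.isfinite(theta) and np.isfinite(phi)):
        raise ValueError("orientation angles must be finite")
    if theta % 360.0 == 0.0 and phi % 360.0 == 0.0:
        return protein.positions.copy()
    com = protein.center_of_mass
    R = rotation_matrix(theta, phi)
    return (protein.positions - com) @ R.T + com


# -- individual energy terms ------------------------------------------------

def electrostatic_energy(positions: np.ndarray, charges: np.ndarray,
                         surface: SurfaceSpec) -> float:
    """Screened-Coulomb bead-surface electrostatic energy (kBT).

    With discrete surface charges, the double sum
    ``l_B sum_ij q_i q_j exp(-kappa r_ij)/r_ij``; otherwise the
    closed-form linearised Debye-Hueckel potential of a uniform surface
    held at the spec's zeta potential.  *positions* are lab-frame bead
    coordinates (nm): flat surfaces occupy z <= 0, spheres are centred at
    the origin.
    """
    positions = np.atleast_2d(positions)
    charges = np.atleast_1d(charges)
    cond = surface.conditions
    kappa = cond.debye_kappa
    if not np.any(charges):
        return 0.0
    if surface.surface_charges is not None:
        spos, sq = surface.surface_charges
        diff = positions[:, None, :] - spos[None, :, :]
        r = np.linalg.norm(diff, axis=-1)
        if np.any(r == 0.0):
            raise ValueError("bead coincides with a surface charge (r = 0)")
        u = cond.bjerrum_length * np.exp(-kappa * r) / r
        return float((charges[:, None] * sq[None, :] * u).sum())
    zeta = surface.zeta_potential
    if zeta == 0.0:
        return 0.0
    zred = cond.zeta_to_kbt(zeta)
    if surface.is_flat:
        z = np.maximum(positions[:, 2], 1e-6)
        return float((charges * zred * np.exp(-kappa * z)).sum())
    r = np.maximum(np.linalg.norm(positions, axis=1), 1e-6)
    rnp = surface.np_radius
    return float((charges * zred * (rnp / r)
                  * np.exp(-kappa * (r - rnp))).sum())


def hamaker_sphere_sphere(r_aa: float, r_np: float, d, a123: float):
    """Hamaker energy (kBT) between two spheres at centre distance d (nm).

    U = -A/6 [ 2 R1 R2 / (d^2 - (R1+R2)^2) + 2 R1 R2 / (d^2 - (R1-R2)^2)
               + ln( (d^2-(R1+R2)^2) / (d^2-(R1-R2)^2) ) ]

    with A = *a123* supplied in kBT units.  Requires non-overlapping
    spheres (d > R1 + R2).
    """
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("centre distance must be positive")
    if np.any(d <= r_aa + r_np):
        raise ValueError("overlapping spheres in Hamaker term")
    x1 = d ** 2 - (r_np + r_aa) ** 2
    x2 = d ** 2 - (r_np - r_aa) ** 2
    rr = 2.0 * r_np * r_aa
    u = -(a123 / 6.0) * (rr / x1 + rr / x2 + np.log(x1 / x2))
    return u if u.shape else float(u)


def hamaker_sphere_plate(r_aa: float, gap, a123: float):
    """Hamaker energy (kBT) of a sphere above a half-space.

    U = -A/6 [ R/D + R/(D+2R) + ln( D / (D+2R) ) ] with D the closest gap
    between the sphere surface and the plane (nm).
    """
    gap = np.asarray(gap, dtype=float)
    if np.any(gap <= 0):
        raise ValueError("sphere-plate gap must be positive")
    u = -(a123 / 6.0) * (r_aa / gap + r_aa / (gap + 2 * r_aa)
                         + np.log(gap / (gap + 2 * r_aa)))
    return u if u.shape else float(u)


def short_range_energy(ssd: np.ndarray, residues: list[str],
                       pmf_set: SurfacePMFSet) -> float:
    """Sum of tabulated per-residue PMFs at the given bead surface
    separation distances (nm).  Distances below a table's first grid point
    are clamped to the wall value; beyond the table the contribution is 0.
    """
    ssd = np.atleast_1d(np.asarray(ssd, dtype=float))
    total = 0.0
    for code, s in zip(residues, ssd):
        total += float(pmf_set[code](s))
    return total


# -- distance profiles and orientation energies -----------------------------

@dataclass
class EnergyProfile:
    """Total and per-term potential along the surface-approach coordinate
    for one rigid orientation.

    ``z`` is the COM distance from the surface (nm); for spheres the COM
    radial coordinate is ``r = np_radius + z``.  ``contact`` is the COM
    distance at which the closest bead reaches its PMF wall.
    """

    theta: float
    phi: float
    z: np.ndarray
    total: np.ndarray
    terms: dict[str, np.ndarray]
    contact: float
    geometry: str
    np_radius: float | None = None
    closest_bead: np.ndarray | None = None  # min bead SSD at each z
    clamped: int = 0  # grid points with any bead inside the PMF wall

    @property
    def r(self) -> np.ndarray:
        if self.geometry == "sphere":
            return self.np_radius + self.z
        return self.z


def _grouped_pmf_sum(heights: np.ndarray, residues: list[str],
                     pmf_set: SurfacePMFSet) -> np.ndarray:
    """Vectorised sum of per-residue PMFs; *heights* is (n_z, n_beads)."""
    out = np.zeros(heights.shape[0])
    codes = np.array([pmf_set.resolve_code(c) for c in residues])
    for code in np.unique(codes):
        table = pmf_set.tables[code]
        cols = heights[:, codes == code]
        out += np.interp(cols, table.distance, table.energy,
                         left=table.energy[0], right=0.0).sum(axis=1)
    return out


def energy_profile(protein: BeadProtein, surface: SurfaceSpec,
                   pmf_set: SurfacePMFSet, theta: float, phi: float,
                   span: float = 5.0, step: float = 0.01,
                   wall_margin: float = 0.3) -> EnergyProfile:
    """Evaluate the total bead-additive potential along the approach
    coordinate for orientation (theta, phi).

    The grid runs from just inside the contact distance (the COM distance
    at which the closest bead reaches its PMF wall) out to
    ``contact + span``, in steps of *step* nm.  The short-range term is
    clamped at the wall; the Hamaker term is clamped below a
    ``CONTACT_CLAMP`` surface gap.
    """
    missing = pmf_set.check_protein(protein)
    if missing:
        raise KeyError(f"no PMF tables for residues: {missing}")
    centered = protein.centered_positions()
    n = direction_from_angles(theta, phi)
    proj = centered @ n  # bead height above COM along the surface normal
    walls = np.array([pmf_set[c].r_min for c in protein.residues])
    contact = float(np.max(walls - proj))
    z_lo = max(step, contact - wall_margin)
    z_hi = contact + span
    n_z = max(int(np.ceil((z_hi - z_lo) / step)) + 1, 2)
    z = z_lo + step * np.arange(n_z)
    if z.size == 0:
        raise ValueError("empty approach grid")

    radii = protein.radii
    charges = protein.charges
    cond = surface.conditions
    a123 = surface.hamaker_A123

    if surface.is_flat:
        heights = z[:, None] + proj[None, :]  # (n_z, n_beads) bead SSDs
        ssd = heights
        # Hamaker sphere-plate per bead, gap = height - bead radius
        gap = np.maximum(ssd - radii[None, :], CONTACT_CLAMP)
        if a123 == 0:
            u_ham = np.zeros(z.size)
        else:
            u_ham = np.zeros(z.size)
            for i, r_aa in enumerate(radii):
                u_ham += hamaker_sphere_plate(r_aa, gap[:, i], a123)
    else:
        R = rotation_matrix(theta, phi)
        off = centered @ R.T  # lab-frame offsets from COM
        rho2 = off[:, 0] ** 2 + off[:, 1] ** 2
        rnp = surface.np_radius
        r_com = rnp + z
        dist = np.sqrt(rho2[None, :] + (r_com[:, None] + off[None, :, 2]) ** 2)
        ssd = dist - rnp
        if a123 == 0:
            u_ham = np.zeros(z.size)
        else:
            u_ham = np.zeros(z.size)
            for i, r_aa in enumerate(radii):
                d_clamped = np.maximum(dist[:, i],
                                       rnp + r_aa + CONTACT_CLAMP)
                u_ham += hamaker_sphere_sphere(r_aa, rnp, d_clamped, a123)

    u_short = _grouped_pmf_sum(ssd, protein.residues, pmf_set)
    clamped = int(np.any(ssd < walls[None, :], axis=1).sum())
    if clamped:
        log.debug("(%g, %g): %d grid points with beads clamped at the wall",
                  theta, phi, clamped)

    # electrostatics
    u_el = np.zeros(z.size)
    if np.any(charges) and (surface.zeta_potential != 0.0
                            or surface.surface_charges is not None):
        kappa = cond.debye_kappa
        if surface.surface_charges is None and surface.is_flat:
            zred = cond.zeta_to_kbt(surface.zeta_potential)
            u_el = (charges[None, :] * zred
                    * np.exp(-kappa * np.maximum(ssd, 1e-6))).sum(axis=1)
        elif surface.surface_charges is None:
            zred = cond.zeta_to_kbt(surface.zeta_potential)
            r_bead = np.maximum(ssd + surface.np_radius, 1e-6)
            rnp = surface.np_radius
            u_el = (charges[None, :] * zred * (rnp / r_bead)
                    * np.exp(-kappa * (r_bead - rnp))).sum(axis=1)
        else:
            # discrete charges: build full 3-D bead coordinates per z
            R = rotation_matrix(theta, phi)
            off = centered @ R.T
            for j, zc in enumerate(z):
                if surface.is_flat:
                    pos = off + np.array([0.0, 0.0, zc])
                else:
                    pos = off + np.array([0.0, 0.0, surface.np_radius + zc])
                u_el[j] = electrostatic_energy(pos, charges, surface)

    total = u_short + u_ham + u_el
    return EnergyProfile(theta=theta, phi=phi, z=z, total=total,
                         terms={"short_range": u_short, "hamaker": u_ham,
                                "electrostatic": u_el},
                         contact=contact, geometry=surface.geometry,
                         np_radius=surface.np_radius,
                         closest_bead=ssd.min(axis=1), clamped=clamped)


def orientation_energy(profile: EnergyProfile, a_tol: float = 0.01,
                       a_cap: float = 5.0) -> tuple[float, float]:
    """Reduce a distance profile to the orientation energy E(theta, phi).

    Flat surfaces:  E = -kBT ln[ (1/a) int_0^a exp(-U(z)/kBT) dz ]
    Spheres:        E = -kBT ln[ int_R^{R+a} exp(-U/kBT) r^2 dr
                                 / int_R^{R+a} r^2 dr ]

    computed by trapezoidal quadrature on the profile grid (the sphere
    normalisation integral is evaluated with the same quadrature so that
    U == 0 maps to E == 0 exactly).  The integration cutoff ``a`` is the
    first distance beyond which |U| stays below *a_tol* kBT, capped at
    ``contact + a_cap`` nm.  Returns (energy kBT, a nm).
    """
    u = profile.total
    z = profile.z
    if not np.all(np.isfinite(u)):
        raise ValueError("non-finite integrand in orientation energy")
    big = np.flatnonzero(np.abs(u) >= a_tol)
    if big.size:
        a = z[min(big[-1] + 1, z.size - 1)]
    else:
        a = z[0]
    a = min(a, profile.contact + a_cap)
    a = max(a, z[0])
    sel = z <= a + 1e-12
    zs, us = z[sel], u[sel]
    u_min = us.min()
    w = np.exp(-(us - u_min))
    if profile.geometry == "sphere":
        r = profile.np_radius + zs
        num = np.trapezoid(w * r ** 2, r)
        den = np.trapezoid(r ** 2, r)
        energy = u_min - float(np.log(num / den))
    else:
        # extend to z = 0 with the (clamped, strongly repulsive) wall value
        zs = np.concatenate([[0.0], zs])
        w = np.concatenate([[w[0]], w])
        num = np.trapezoid(w, zs)
        energy = u_min - float(np.log(num / a))
    return energy, float(a)


def angular_grids(step: float = 5.0, theta_mode: str = "full"
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Orientation grids.  ``theta_mode`` "full": theta in [0, 360) like
    phi (both poles swept twice; weights use |sin theta|); "half": theta in
    [0, 180]."""
    if step <= 0 or step > 180:
        raise ValueError("angular step must be in (0, 180]")
    phi = np.arange(0.0, 360.0, step)
    if theta_mode == "full":
        theta = np.arange(0.0, 360.0, step)
    elif theta_mode == "half":
        theta = np.arange(0.0, 180.0 + step / 2, step)
    else:
        raise ValueError(f"unknown theta_mode {theta_mode!r}")
    return theta, phi


def build_heatmap(protein: BeadProtein, surface: SurfaceSpec,
                  pmf_set: SurfacePMFSet, grid_step: float = 5.0,
                  theta_mode: str = "full", span: float = 5.0,
                  step: float = 0.01, a_tol: float = 0.01,
                  a_cap: float = 5.0) -> AdsorptionHeatmap:
    """Scan the orientation grid and assemble the adsorption heatmap.

    Records E(theta, phi), the per-orientation cutoffs, the grid minimum
    and the closest bead-surface distance ``r_min`` in the minimum-energy
    pose (taken at the distance-profile minimum of that orientation).
    """
    theta, phi = angular_grids(grid_step, theta_mode)
    energies = np.empty((theta.size, phi.size))
    cutoffs = np.empty_like(energies)
    best = (np.inf, None, None)
    for k, th in enumerate(theta):
        for l, ph in enumerate(phi):
            try:
                prof = energy_profile(protein, surface, pmf_set, th, ph,
                                      span=span, step=step)
                e, a = orientation_energy(prof, a_tol=a_tol, a_cap=a_cap)
            except Exception as exc:  # noqa: BLE001 - annotate the cell
                raise RuntimeError(
                    f"orientation (theta={th}, phi={ph}) failed: {exc}"
                ) from exc
            energies[k, l] = e
            cutoffs[k, l] = a
            if e < best[0]:
                best = (e, prof, (th, ph))
        log.debug("heatmap row theta=%g done (%d cells)", th, phi.size)
    _, best_prof, _ = best
    i_min = int(np.argmin(best_prof.total))
    r_min = float(best_prof.closest_bead[i_min])
    meta = {
        "protein": protein.name,
        "surface": pmf_set.surface_id,
        "geometry": surface.geometry,
        "np_radius_nm": surface.np_radius,
        "grid_step_deg": grid_step,
        "theta_mode": theta_mode,
        "hamaker_A123_kbt": surface.hamaker_A123,
        "zeta_mV": surface.zeta_potential,
        "temperature_K": surface.conditions.temperature,
    }
    return AdsorptionHeatmap(theta=theta, phi=phi, energies=energies,
                             cutoffs=cutoffs, metadata=meta, r_min=r_min)


def boltzmann_average(heatmap: AdsorptionHeatmap) -> float:
    """Orientation-ensemble adsorption energy
    E_ads = sum P_kl E_kl / sum P_kl with P_kl = |sin theta_k| exp(-E_kl).
    """
    return heatmap.e_ads


def rank_proteins(heatmaps) -> pd.DataFrame:
    """Order heatmaps by binding strength (most negative E_min first).

    Ties are broken alphabetically by protein name.
    """
    heatmaps = list(heatmaps)
    if not heatmaps:
        raise ValueError("need at least one heatmap")
    rows = []
    for hm in heatmaps:
        th, ph = hm.argmin_angles
        rows.append({
            "protein": hm.metadata.get("protein", "?"),
            "surface": hm.metadata.get("surface", "?"),
            "e_min_kbt": hm.e_min,
            "theta_deg": th,
            "phi_deg": ph,
            "r_min_nm": hm.r_min,
            "e_ads_kbt": hm.e_ads,
        })
    df = pd.DataFrame(rows).sort_values(
        ["e_min_kbt", "protein"], kind="mergesort").reset_index(drop=True)
    return df
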