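"""Domain types for the coarse-grained protein-surface adsorption model.

Internal unit conventions (used everywhere in this package):

* lengths in nanometres,
* energies in units of kBT at the run temperature,
* angles in degrees,
* charges in elementary charges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import constants as _const

__all__ = [
    "BeadProtein",
    "PMFTable",
    "SurfacePMFSet",
    "SolutionConditions",
    "SurfaceSpec",
    "AdsorptionHeatmap",
    "DEFAULT_ALIASES",
    "PMF_RESIDUE_CODES",
]

# The 22 side-chain-analogue table keys: the 20 standard residues with
# histidine split into its two neutral tautomers (HID/HIE) and glutamate
# split into charged (GLU) and neutral (GAN) forms.
PMF_RESIDUE_CODES: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GAN", "GLN", "GLU", "GLY", "HID",
    "HIE", "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
    "TYR", "VAL",
)

#: Default residue-code aliases used when resolving a protein residue to a
#: side-chain-analogue potential table.  HIS maps to the HIE tautomer at
#: pH 7; common force-field spellings of histidine are folded in as well.
DEFAULT_ALIASES: dict[str, str] = {
    "HIS": "HIE",
    "HSD": "HID",
    "HSE": "HIE",
    "GLH": "GAN",
}


@dataclass
class BeadProtein:
    """Rigid one-bead-per-residue protein.

    One bead per residue, centred on the residue's C-alpha atom.  The
    structure is treated as rigid: only whole-body rotations/translations
    are ever applied to it.
    """

    name: str
    residues: list[str]
    positions: np.ndarray  # (N, 3) nm
    charges: np.ndarray  # (N,) elementary charges
    radii: np.ndarray  # (N,) nm
    masses: np.ndarray | None = None  # optional per-bead masses (Da)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        n = len(self.residues)
        if self.positions.shape != (n, 3):
            raise ValueError(
                f"positions shape {self.positions.shape} != ({n}, 3)"
            )
        if self.charges.shape != (n,) or self.radii.shape != (n,):
            raise ValueError("charges/radii length must match residue count")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("bead positions must be finite")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n_beads(self) -> int:
        return len(self.residues)

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())

    @property
    def center_of_mass(self) -> np.ndarray:
        """Mass-weighted centre if masses were supplied, else the unweighted
        mean of bead positions."""
        if self.masses is not None:
            w = np.asarray(self.masses, dtype=float)
            return (self.positions * w[:, None]).sum(axis=0) / w.sum()
        return self.positions.mean(axis=0)

    def centered_positions(self) -> np.ndarray:
        return self.positions - self.center_of_mass


@dataclass
class PMFTable:
    """Tabulated short-range potential of mean force for one residue type.

    The abscissa is the surface separation distance (bead centre to the top
    atomic plane of the surface) in nm; the ordinate is stored in kBT and is
    re-zeroed so the long-distance plateau sits at zero.
    """

    residue_code: str
    distance: np.ndarray  # (M,) nm, strictly increasing
    energy: np.ndarray  # (M,) kBT, plateau-subtracted

    def __post_init__(self) -> None:
        self.distance = np.asarray(self.distance, dtype=float)
        self.energy = np.asarray(self.energy, dtype=float)
        if self.distance.ndim != 1 or self.distance.shape != self.energy.shape:
            raise ValueError("distance and energy must be equal-length 1-D")
        if len(self.distance) < 4:
            raise ValueError("PMF table needs at least 4 points")
        if np.any(np.diff(self.distance) <= 0):
            raise ValueError("PMF distance grid must be strictly increasing")
        if not (np.all(np.isfinite(self.distance)) and np.all(np.isfinite(self.energy))):
            raise ValueError("PMF table values must be finite")

    @property
    def r_min(self) -> float:
        """First tabulated distance (the repulsive wall edge)."""
        return float(self.distance[0])

    @property
    def r_max(self) -> float:
        return float(self.distance[-1])

    def __call__(self, r) -> np.ndarray:
        """Interpolate the PMF at separation ``r`` (nm).

        Below the first grid point the wall value at the first point is
        returned (no downward extrapolation); beyond the table the energy
        is the plateau, i.e. zero.
        """
        r = np.asarray(r, dtype=float)
        return np.interp(r, self.distance, self.energy,
                         left=self.energy[0], right=0.0)

    def minimum(self) -> tuple[float, float]:
        """(distance, energy) of the tabulated global minimum."""
        i = int(np.argmin(self.energy))
        return float(self.distance[i]), float(self.energy[i])


class SurfacePMFSet:
    """Per-residue tabulated short-range potentials for one surface."""

    def __init__(self, surface_id: str, tables: dict[str, PMFTable],
                 aliases: dict[str, str] | None = None):
        self.surface_id = surface_id
        self.tables = dict(tables)
        self.aliases = dict(DEFAULT_ALIASES)
        if aliases:
            self.aliases.update(aliases)

    def resolve_code(self, residue_code: str) -> str:
        code = residue_code.upper()
        code = self.aliases.get(code, code)
        if code not in self.tables:
            raise KeyError(
                f"no PMF table for residue {residue_code!r} on surface "
                f"{self.surface_id!r} (resolved to {code!r})"
            )
        return code

    def __getitem__(self, residue_code: str) -> PMFTable:
        return self.tables[self.resolve_code(residue_code)]

    def __contains__(self, residue_code: str) -> bool:
        try:
            self.resolve_code(residue_code)
        except KeyError:
            return False
        return True

    def check_protein(self, protein: BeadProtein) -> list[str]:
        """Return the residue codes of *protein* with no resolvable table."""
        missing = sorted({c for c in protein.residues if c not in self})
        return missing

    @property
    def wall_minimum(self) -> float:
        """Smallest first-grid-point distance over all tables (nm)."""
        return min(t.r_min for t in self.tables.values())


@dataclass
class SolutionConditions:
    """Solvent/electrolyte state entering the electrostatic term."""

    temperature: float = 300.0  # K
    ionic_strength: float = 0.1  # mol/L
    dielectric_constant: float = 78.5
    viscosity: float = 0.85e-3  # Pa s, used by Stokes-Einstein in the KMC

    @property
    def kbt_joule(self) -> float:
        return _const.k * self.temperature

    @property
    def kbt_kj_per_mol(self) -> float:
        return _const.R * self.temperature / 1000.0

    @property
    def bjerrum_length(self) -> float:
        """l_B = e^2 / (4 pi eps eps0 kB T), in nm."""
        lb_m = _const.e ** 2 / (
            4.0 * np.pi * self.dielectric_constant * _const.epsilon_0
            * self.kbt_joule
        )
        return lb_m * 1e9

    @property
    def debye_kappa(self) -> float:
        """Inverse Debye screening length kappa in 1/nm.

        kappa^2 = 8 pi l_B N_A I for the ionic strength I = (1/2) sum c_i z_i^2.
        """
        n_per_nm3 = self.ionic_strength * _const.N_A * 1e-24  # mol/L -> nm^-3
        return float(np.sqrt(8.0 * np.pi * self.bjerrum_length * n_per_nm3))

    def zeta_to_kbt(self, zeta_mV: float) -> float:
        """Convert a zeta potential in mV to the reduced potential e*zeta/kBT."""
        return zeta_mV * 1e-3 * _const.e / self.kbt_joule

    def surface_charge_density(self, zeta_mV: float) -> float:
        """Debye-Hueckel charge density sigma = eps eps0 kappa zeta, in e/nm^2."""
        sigma_si = (self.dielectric_constant * _const.epsilon_0
                    * self.debye_kappa * 1e9 * zeta_mV * 1e-3)  # C/m^2
        return sigma_si / _const.e * 1e-18  # e per nm^2


@dataclass
class SurfaceSpec:
    """Geometry, vdW and electrostatic description of the adsorbing surface.

    ``geometry`` is ``"flat"`` (semi-infinite slab, surface plane at z = 0,
    protein above) or ``"sphere"`` (nanoparticle of radius ``np_radius``
    centred at the origin).  ``hamaker_A123`` is the Hamaker constant of the
    surface material interacting with protein through water, in kBT units;
    the default 1.0 is a placeholder that must be overridden for
    quantitative work against real materials.  ``surface_charges`` is an
    optional explicit list of discrete point charges (positions nm, charges
    e); when absent the electrostatic term uses the closed-form linearised
    Debye-Hueckel potential of a uniform surface at the given zeta
    potential.
    """

    geometry: str = "flat"
    np_radius: float | None = None  # nm, spheres only
    hamaker_A123: float = 1.0  # kBT
    zeta_potential: float = 0.0  # mV
    surface_charges: tuple[np.ndarray, np.ndarray] | None = None
    conditions: SolutionConditions = field(default_factory=SolutionConditions)

    def __post_init__(self) -> None:
        if self.geometry not in ("flat", "sphere"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.geometry == "sphere":
            if self.np_radius is None or self.np_radius <= 0:
                raise ValueError("sphere geometry requires np_radius > 0")
        if self.surface_charges is not None:
            pos, q = self.surface_charges
            pos = np.atleast_2d(np.asarray(pos, dtype=float))
            q = np.atleast_1d(np.asarray(q, dtype=float))
            if pos.shape != (len(q), 3):
                raise ValueError("surface charge positions must be (M, 3)")
            self.surface_charges = (pos, q)

    @property
    def is_flat(self) -> bool:
        return self.geometry == "flat"


class AdsorptionHeatmap:
    """Orientation-resolved adsorption energies E(theta_k, phi_l).

    Stores the angular grids (degrees), the energy matrix (kBT), the
    per-orientation integration cutoffs a(theta, phi) (nm) and metadata
    about the run.  Derived quantities: the minimum energy and its
    orientation, the closest bead-surface distance in the minimum-energy
    pose (``r_min``) and the Boltzmann-averaged adsorption energy.
    """

    def __init__(self, theta: np.ndarray, phi: np.ndarray, energies: np.ndarray,
                 cutoffs: np.ndarray | None = None,
                 metadata: dict | None = None, r_min: float | None = None):
        self.theta = np.asarray(theta, dtype=float)
        self.phi = np.asarray(phi, dtype=float)
        self.energies = np.asarray(energies, dtype=float)
        if self.energies.shape != (len(self.theta), len(self.phi)):
            raise ValueError(
                f"energy matrix shape {self.energies.shape} does not match "
                f"grids ({len(self.theta)}, {len(self.phi)})"
            )
        if cutoffs is None:
            cutoffs = np.full_like(self.energies, np.nan)
        self.cutoffs = np.asarray(cutoffs, dtype=float)
        if self.cutoffs.shape != self.energies.shape:
            raise ValueError("cutoff matrix shape must match energy matrix")
        self.metadata = dict(metadata or {})
        self.r_min = r_min

    @property
    def e_min(self) -> float:
        return float(np.nanmin(self.energies))

    @property
    def argmin_angles(self) -> tuple[float, float]:
        k, l = np.unravel_index(np.nanargmin(self.energies),
                                self.energies.shape)
        return float(self.theta[k]), float(self.phi[l])

    def weights(self, temperature_scale: float = 1.0) -> np.ndarray:
        """Boltzmann weighting factors P_kl = |sin theta_k| exp(-E_kl).

        Computed relative to the grid minimum for overflow safety; the
        common factor cancels in the weighted average.
        """
        e = self.energies / temperature_scale
        shifted = e - np.nanmin(e)
        return np.abs(np.sin(np.radians(self.theta)))[:, None] * np.exp(-shifted)

    @property
    def e_ads(self) -> float:
        """Boltzmann-averaged adsorption energy over orientations (kBT)."""
        w = self.weights()
        total = w.sum()
        if not np.isfinite(total) or total <= 0:
            raise ValueError("all-zero Boltzmann weights; cannot average")
        return float((w * self.energies).sum() / total)

    def validate(self) -> None:
        if not np.all(np.isfinite(self.energies)):
            raise ValueError("heatmap contains non-finite energies")
        e_ads = self.e_ads
        if not (self.e_min <= e_ads + 1e-12
                and e_ads <= float(np.max(self.energies)) + 1e-12):
            raise ValueError("E_ads outside [E_min, E_max]")
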