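"""Synthetic inputs: PMF tables, compact bead-proteins, toy PDB files and
the milk concentration panel.

Everything downstream of the all-atom stage can be exercised offline with
these generators.  Synthetic PMFs are a repulsive exponential wall plus
one or two Gaussian wells — chosen to mimic the canonical shape of
residue-surface free-energy curves (hard wall, minima at a few tenths of
a nm near the structured water layers, flat bulk plateau) without
imitating any particular material quantitatively.  The energy model
treats tables as opaque interpolants, so this functional form cannot leak
into results.  Synthetic proteins are rejection-sampled random bead
packings in a sphere; chain connectivity is not enforced because the
rigid-body model never uses bonds.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import PH7_CHARGES, write_beads_pdb
from .reference import MILK_PANEL
from .types import (BeadProtein, PMFTable, SurfacePMFSet, PMF_RESIDUE_CODES)

__all__ = [
    "SyntheticPMFSpec", "SyntheticProteinSpec",
    "make_pmf", "make_pmf_set", "make_protein", "make_milk_panel",
    "make_fixture_dataset",
]


@dataclass
class SyntheticPMFSpec:
    """Parameters of a synthetic residue-surface PMF (nm / kBT)."""

    well_depth: float = -5.0  # kBT, <= 0
    well_position: float = 0.25  # nm
    wall_position: float = 0.1  # nm, onset of the repulsive wall
    well_width: float = 0.05  # nm, Gaussian sigma
    secondary_well: tuple[float, float] | None = None  # (depth, position)
    decay_length: float = 0.025  # nm, wall decay
    wall_height: float = 100.0  # kBT at the wall position
    grid: tuple[float, float, float] = (0.05, 2.0, 0.005)  # min, max, step
    residue_code: str = "ALA"


@dataclass
class SyntheticProteinSpec:
    """Parameters of a random compact bead-protein."""

    n_residues: int = 100
    target_radius: float = 1.5  # nm, radius of gyration target
    composition: dict[str, int] | None = None  # residue -> count
    net_charge: float | None = None
    min_separation: float = 0.35  # nm between bead centres
    bead_radius: float = 0.5  # nm
    seed: int = 0
    name: str = "synthetic"


def make_pmf(spec: SyntheticPMFSpec) -> PMFTable:
    """Generate a tabulated PMF meeting the spec's invariants.

    The global minimum sits at ``well_position`` with value ``well_depth``
    (a short fixed-point adjustment of the Gaussian amplitude absorbs the
    wall's contribution at the well), and the energy is zero at the far
    end of the grid.  ``well_depth > 0`` is rejected: a positive "well"
    would be a repulsive bump, not a well.
    """
    if spec.well_depth > 0:
        raise ValueError("well_depth must be <= 0 (use 0 for a pure wall)")
    lo, hi, step = spec.grid
    if not (lo < spec.wall_position < spec.well_position < hi):
        if spec.well_depth < 0:
            raise ValueError("need grid min < wall < well < grid max")
    r = np.arange(lo, hi + step / 2, step)
    wall = spec.wall_height * np.exp(-(r - lo) / spec.decay_length)

    def build(amplitudes):
        u = wall.copy()
        for amp, pos, width in amplitudes:
            u += amp * np.exp(-((r - pos) ** 2) / (2.0 * width ** 2))
        return u

    wells = []
    if spec.well_depth < 0:
        wells.append([spec.well_depth, spec.well_position, spec.well_width])
    if spec.secondary_well is not None:
        d2, p2 = spec.secondary_well
        if d2 > 0:
            raise ValueError("secondary well depth must be <= 0")
        wells.append([d2, p2, spec.well_width])
    u = build(wells)
    if wells:
        # fixed-point on the primary amplitude so the realised global
        # minimum equals well_depth despite the wall/secondary overlap
        for _ in range(50):
            current = u.min()
            if abs(current - spec.well_depth) < 1e-12:
                break
            wells[0][0] += spec.well_depth - current
            u = build(wells)
    return PMFTable(residue_code=spec.residue_code, distance=r, energy=u)


def make_pmf_set(surface_id: str = "synthetic",
                 codes: tuple[str, ...] = PMF_RESIDUE_CODES,
                 depth_range: tuple[float, float] = (-0.35, -39.69),
                 seed: int = 0) -> SurfacePMFSet:
    """A full per-residue PMF set with depths spread over *depth_range*."""
    rng = np.random.default_rng(seed)
    tables = {}
    for code in codes:
        depth = float(rng.uniform(min(depth_range), max(depth_range)))
        pos = float(rng.uniform(0.2, 0.6))
        tables[code] = make_pmf(SyntheticPMFSpec(
            well_depth=depth, well_position=pos, residue_code=code))
    return SurfacePMFSet(surface_id=surface_id, tables=tables)


def _build_residue_list(spec: SyntheticProteinSpec) -> list[str]:
    n = spec.n_residues
    if spec.composition:
        residues: list[str] = []
        for code, count in spec.composition.items():
            residues.extend([code] * int(count))
        if len(residues) != n:
            raise ValueError(
                f"composition counts sum to {len(residues)}, expected {n}")
    else:
        residues = ["GLY"] * n
    if spec.net_charge is not None:
        current = sum(PH7_CHARGES.get(c, 0.0) for c in residues)
        delta = spec.net_charge - current
        if abs(delta - round(delta)) > 1e-9:
            raise ValueError("net_charge target must differ by an integer")
        delta = int(round(delta))
        swap_to = "LYS" if delta > 0 else "ASP"
        neutral = [i for i, c in enumerate(residues)
                   if PH7_CHARGES.get(c, 0.0) == 0.0]
        if abs(delta) > len(neutral):
            raise ValueError("not enough neutral residues to reach net charge")
        for i in range(abs(delta)):
            residues[neutral[i]] = swap_to
    return residues


def make_protein(spec: SyntheticProteinSpec) -> BeadProtein:
    """Random compact bead-protein: uniform packing in a ball.

    Beads are rejection-sampled inside a ball sized so the expected radius
    of gyration matches ``target_radius`` (Rg^2 = 3/5 a^2 for a uniform
    ball), with a hard minimum separation.  Coordinates are quantised to
    1e-4 nm so PDB export round-trips exactly.  Deterministic for a fixed
    seed; raises if the packing is infeasible after bounded retries.
    """
    if spec.n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    residues = _build_residue_list(spec)
    rng = np.random.default_rng(spec.seed)
    if spec.n_residues == 1:
        positions = np.zeros((1, 3))
    else:
        ball_radius = spec.target_radius / np.sqrt(3.0 / 5.0)
        positions = np.empty((spec.n_residues, 3))
        placed = 0
        attempts = 0
        max_attempts = 20000 * spec.n_residues
        while placed < spec.n_residues:
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    f"could not pack {spec.n_residues} beads with separation "
                    f"{spec.min_separation} nm inside radius {ball_radius:.2f} nm")
            p = rng.uniform(-ball_radius, ball_radius, 3)
            if p @ p > ball_radius ** 2:
                continue
            if placed and np.min(np.linalg.norm(positions[:placed] - p, axis=1)) \
                    < spec.min_separation:
                continue
            positions[placed] = p
            placed += 1
        positions -= positions.mean(axis=0)
    positions = np.round(positions, 4)  # 1e-4 nm grid for exact PDB round trip
    charges = np.array([PH7_CHARGES.get(c, 0.0) for c in residues])
    radii = np.full(len(residues), spec.bead_radius)
    return BeadProtein(name=spec.name, residues=residues, positions=positions,
                       charges=charges, radii=radii)


def make_milk_panel() -> pd.DataFrame:
    """The six-protein milk panel: concentrations, molecular weights and an
    (empty) adsorption-energy column to be filled from heatmaps or from the
    bundled iron reference energies."""
    rows = []
    for abbrev, (uniprot, name, mw, charge, nres, conc) in MILK_PANEL.items():
        rows.append({
            "species": abbrev,
            "uniprot": uniprot,
            "name": name,
            "mw_da": mw,
            "net_charge_e": charge,
            "n_residues": nres,
            "concentration_mol_l": conc,
            "energy_kbt": np.nan,
        })
    return pd.DataFrame(rows)


def make_fixture_dataset(directory, n_proteins: int = 2,
                         n_residues: int = 30, seed: int = 0) -> dict:
    """Write a complete toy dataset (PDBs + PMF tables + panel CSV).

    Returns a manifest of the created paths.  Used by the test suite and
    the ``fixtures`` CLI subcommand.
    """
    directory = Path(directory)
    pmf_dir = directory / "pmfs"
    pdb_dir = directory / "structures"
    pmf_dir.mkdir(parents=True, exist_ok=True)
    pdb_dir.mkdir(parents=True, exist_ok=True)

    pmf_set = make_pmf_set(seed=seed)
    for code, table in pmf_set.tables.items():
        out = pmf_dir / f"{code}.dat"
        np.savetxt(out, np.column_stack([table.distance, table.energy]),
                   header="ssd_nm energy_kbt")
    pdbs = []
    for i in range(n_proteins):
        prot = make_protein(SyntheticProteinSpec(
            n_residues=n_residues, seed=seed + i, name=f"toy{i}",
            composition={"GLY": n_residues - 4, "LYS": 2, "ASP": 2}))
        path = pdb_dir / f"{prot.name}.pdb"
        write_beads_pdb(prot, path)
        pdbs.append(path)
    panel = make_milk_panel()
    panel_path = directory / "milk_panel.csv"
    panel.to_csv(panel_path, index=False)
    return {"pmf_dir": pmf_dir, "structures": pdbs, "panel": panel_path}
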