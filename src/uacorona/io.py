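"""Readers and writers: PDB structures, PMF tables, heatmap files.

PDB parsing/writing goes through Biopython's ``Bio.PDB``.  PMF tables are
whitespace-delimited two-column text with ``#`` comments.  Heatmaps are
written as self-describing delimited text: ``# key: value`` header lines
followed by ``theta  phi  energy  cutoff`` columns at full double
precision.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser, PDBIO
from Bio.PDB.StructureBuilder import StructureBuilder

from .types import (AdsorptionHeatmap, BeadProtein, PMFTable, SurfacePMFSet,
                    SolutionConditions, PMF_RESIDUE_CODES)

log = logging.getLogger(__name__)

__all__ = [
    "PH7_CHARGES",
    "read_pdb_to_beads",
    "write_beads_pdb",
    "read_pmf_table",
    "read_pmf_directory",
    "write_heatmap",
    "read_heatmap",
]

#: Integer side-chain charges at pH 7.  Residues not listed are neutral.
PH7_CHARGES: dict[str, float] = {
    "ARG": +1.0,
    "LYS": +1.0,
    "ASP": -1.0,
    "GLU": -1.0,
    "HIS": 0.0,
    "HID": 0.0,
    "HIE": 0.0,
    "GAN": 0.0,
}

DEFAULT_BEAD_RADIUS = 0.5  # nm; only the Hamaker term and KMC packing use radii


def read_pdb_to_beads(pdb_source, name: str | None = None,
                      chain_id: str | None = None,
                      charge_scheme: dict[str, float] | None = None,
                      bead_radius_scheme: dict[str, float] | float | None = None,
                      expected_net_charge: float | None = None) -> BeadProtein:
    """Coarse-grain a PDB structure into a one-bead-per-residue protein.

    Reads the first model of *pdb_source* (path or file-like), takes every
    standard residue of the selected chain (default: all chains, in file
    order), and places one bead on each residue's C-alpha atom.  Coordinates
    are converted from Angstrom to nm.  Charges come from *charge_scheme*
    (default: integer side-chain charges at pH 7); radii from
    *bead_radius_scheme* (scalar or per-residue map, default 0.5 nm).

    Raises ``ValueError`` naming the residue if a residue lacks a C-alpha
    atom, and if a residue code has no charge entry it is treated as
    neutral (unknown codes surface later, at PMF resolution time).
    """
    charge_scheme = dict(PH7_CHARGES if charge_scheme is None else charge_scheme)
    parser = PDBParser(QUIET=True)
    path = Path(pdb_source) if isinstance(pdb_source, (str, Path)) else None
    if name is None:
        name = path.stem if path is not None else "protein"
    structure = parser.get_structure(name, pdb_source)
    model = next(structure.get_models())

    residues, positions = [], []
    for chain in model:
        if chain_id is not None and chain.id != chain_id:
            continue
        for res in chain:
            if res.id[0] != " ":  # skip waters / hetero records
                continue
            code = res.get_resname().strip().upper()
            if "CA" not in res:
                raise ValueError(
                    f"residue {code} {res.id[1]} in chain {chain.id!r} "
                    "has no C-alpha atom"
                )
            residues.append(code)
            positions.append(res["CA"].coord / 10.0)  # Angstrom -> nm
    if not residues:
        raise ValueError(f"no C-alpha-bearing residues found in {name!r}")

    charges = np.array([charge_scheme.get(c, 0.0) for c in residues])
    if isinstance(bead_radius_scheme, dict):
        radii = np.array([bead_radius_scheme.get(c, DEFAULT_BEAD_RADIUS)
                          for c in residues])
    else:
        r = DEFAULT_BEAD_RADIUS if bead_radius_scheme is None else float(bead_radius_scheme)
        radii = np.full(len(residues), r)

    protein = BeadProtein(name=name, residues=residues,
                          positions=np.array(positions),
                          charges=charges, radii=radii)
    if expected_net_charge is not None and not np.isclose(
            protein.net_charge, expected_net_charge, atol=0.5):
        warnings.warn(
            f"{name}: integer pH-7 net charge {protein.net_charge:+.1f} differs "
            f"from expected {expected_net_charge:+.1f}; charges are NOT rescaled",
            stacklevel=2)
    return protein


def write_beads_pdb(protein: BeadProtein, path) -> None:
    """Export bead positions as a PDB of C-alpha pseudo-atoms.

    Coordinates are written in Angstrom at the PDB's fixed 0.001 A
    resolution; positions already quantised to 1e-4 nm round-trip exactly.
    """
    builder = StructureBuilder()
    builder.init_structure(protein.name)
    builder.init_model(0)
    builder.init_chain("A")
    builder.init_seg("    ")
    for i, (code, pos) in enumerate(zip(protein.residues, protein.positions)):
        builder.init_residue(code, " ", i + 1, " ")
        builder.init_atom("CA", np.asarray(pos) * 10.0, 0.0, 1.0, " ",
                          " CA ", i + 1, element="C")
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))


def read_pmf_table(path, residue_code: str | None = None,
                   unit: str = "kBT",
                   conditions: SolutionConditions | None = None) -> PMFTable:
    """Read a two-column (distance, energy) PMF table.

    *unit* declares the energy unit of the file: ``"kBT"`` or ``"kJ/mol"``
    (converted at the run temperature of *conditions*).  Distances are nm.
    The plateau value — the mean over the last 10% of the distance range —
    is subtracted so the stored energy goes to zero at large separation.
    """
    path = Path(path)
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: expected two numeric columns")
    r, u = data[:, 0], data[:, 1]
    if len(r) < 4:
        raise ValueError(f"{path}: fewer than 4 points")
    if np.any(np.diff(r) <= 0):
        raise ValueError(f"{path}: distance column not strictly increasing")
    if unit.lower() in ("kbt", "kt"):
        pass
    elif unit.lower() in ("kj/mol", "kj_mol", "kjmol"):
        cond = conditions or SolutionConditions()
        u = u / cond.kbt_kj_per_mol
    else:
        raise ValueError(f"unknown PMF unit declaration {unit!r}")
    # re-zero on the far plateau (mean over the last 10% of the range)
    tail = r >= r[-1] - 0.1 * (r[-1] - r[0])
    u = u - u[tail].mean()
    code = residue_code or path.stem.split("_")[0].upper()
    return PMFTable(residue_code=code, distance=r, energy=u)


def read_pmf_directory(directory, surface_id: str, unit: str = "kBT",
                       conditions: SolutionConditions | None = None,
                       aliases: dict[str, str] | None = None) -> SurfacePMFSet:
    """Load every ``*.dat``/``*.txt``/``*.pmf`` table in *directory*.

    File stems name the residue code (an optional ``_<surface>`` suffix is
    ignored), e.g. ``LYS_fe100.dat`` -> LYS.
    """
    directory = Path(directory)
    tables = {}
    for f in sorted(directory.iterdir()):
        if f.suffix.lower() not in (".dat", ".txt", ".pmf"):
            continue
        table = read_pmf_table(f, unit=unit, conditions=conditions)
        tables[table.residue_code] = table
    if not tables:
        raise ValueError(f"no PMF tables found in {directory}")
    return SurfacePMFSet(surface_id=surface_id, tables=tables, aliases=aliases)


# -- heatmap text format ----------------------------------------------------

def write_heatmap(heatmap: AdsorptionHeatmap, path) -> None:
    """Write a heatmap as self-describing delimited text (lossless)."""
    if not np.all(np.isfinite(heatmap.energies)):
        bad = np.argwhere(~np.isfinite(heatmap.energies))
        raise ValueError(
            f"refusing to write heatmap with non-finite energies at "
            f"grid indices {bad[:5].tolist()}"
        )
    path = Path(path)
    lines = ["# uacorona heatmap v1"]
    for key, value in heatmap.metadata.items():
        lines.append(f"# {key}: {value}")
    if heatmap.r_min is not None:
        lines.append(f"# r_min_nm: {heatmap.r_min!r}")
    lines.append(f"# n_theta: {len(heatmap.theta)}")
    lines.append(f"# n_phi: {len(heatmap.phi)}")
    lines.append("# columns: theta_deg phi_deg energy_kbt cutoff_nm")
    for k, th in enumerate(heatmap.theta):
        for l, ph in enumerate(heatmap.phi):
            lines.append(f"{float(th)!r}\t{float(ph)!r}"
                         f"\t{float(heatmap.energies[k, l])!r}"
                         f"\t{float(heatmap.cutoffs[k, l])!r}")
    path.write_text("\n".join(lines) + "\n")


def read_heatmap(path) -> AdsorptionHeatmap:
    path = Path(path)
    metadata: dict[str, str] = {}
    rows = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                metadata[key.strip()] = value.strip()
            continue
        rows.append([float(x) for x in line.split()])
    if not rows:
        raise ValueError(f"{path}: no heatmap records")
    n_theta = int(metadata.pop("n_theta"))
    n_phi = int(metadata.pop("n_phi"))
    metadata.pop("columns", None)
    r_min = metadata.pop("r_min_nm", None)
    arr = np.asarray(rows)
    if arr.shape[0] != n_theta * n_phi:
        raise ValueError(
            f"{path}: {arr.shape[0]} records, expected {n_theta * n_phi}"
        )
    theta = arr[::n_phi, 0]
    phi = arr[:n_phi, 1]
    energies = arr[:, 2].reshape(n_theta, n_phi)
    cutoffs = arr[:, 3].reshape(n_theta, n_phi)
    return AdsorptionHeatmap(theta=theta, phi=phi, energies=energies,
                             cutoffs=cutoffs, metadata=metadata,
                             r_min=None if r_min is None else float(r_min))
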