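import numpy as np
import pytest

from uacorona.synthetic import (SyntheticPMFSpec, SyntheticProteinSpec,
                                make_pmf, make_protein)
from uacorona.types import SolutionConditions, SurfacePMFSet, SurfaceSpec


@pytest.fixture
def conditions():
    return SolutionConditions(temperature=300.0, ionic_strength=0.1)


@pytest.fixture
def well_pmf():
    """Single synthetic PMF: -5 kBT well at 0.25 nm."""
    return make_pmf(SyntheticPMFSpec(well_depth=-5.0, well_position=0.25,
                                     residue_code="GLY"))


@pytest.fixture
def small_pmf_set(well_pmf):
    """Deterministic little PMF set: GLY -5, LYS -12, ASP -2, ALA -0.5."""
    tables = {"GLY": well_pmf}
    for code, depth, pos in [("LYS", -12.0, 0.3), ("ASP", -2.0, 0.35),
                             ("ALA", -0.5, 0.25)]:
        tables[code] = make_pmf(SyntheticPMFSpec(
            well_depth=depth, well_position=pos, residue_code=code))
    return SurfacePMFSet(surface_id="toy", tables=tables)


@pytest.fixture
def flat_surface(conditions):
    """Flat, uncharged, no Hamaker term: short-range physics only."""
    return SurfaceSpec(geometry="flat", hamaker_A123=0.0,
                       zeta_potential=0.0, conditions=conditions)


@pytest.fixture
def toy_protein():
    """Ten-bead compact synthetic protein with two charged residues."""
    return make_protein(SyntheticProteinSpec(
        n_residues=10, target_radius=0.8, seed=3, name="toy10",
        composition={"GLY": 6, "LYS": 2, "ASP": 1, "ALA": 1}))


@pytest.fixture
def single_bead():
    return make_protein(SyntheticProteinSpec(n_residues=1, name="one"))
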