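"""End-to-end run orchestration: structures + PMFs -> heatmaps -> energy
ranking -> corona composition, driven by a single YAML config.

A run directory contains, after completion:

* ``heatmaps/<protein>__<surface>.tsv`` — one heatmap file per pair,
* ``ranking.tsv`` — proteins ordered by binding strength per surface,
* ``corona.tsv`` — per-surface steady-state corona composition,
* ``corona_timeseries.tsv`` — replicate-resolved bound counts over time,
* ``manifest.yaml`` — config echo, config hash, package version, seeds.

Stages write their outputs as they finish, so a failure in a later stage
leaves earlier results intact.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import read_pdb_to_beads, read_pmf_directory, write_heatmap
from .kmc import Species, abundance_table, simulate_corona
from .reference import IRON_EMIN
from .synthetic import make_milk_panel
from .types import SolutionConditions, SurfaceSpec
from .ua import build_heatmap, rank_proteins

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Fully serialisable description of a pipeline run."""

    output_dir: str = "run"
    structures: list[str] = field(default_factory=list)  # PDB paths
    pmf_dirs: dict[str, str] = field(default_factory=dict)  # surface -> dir
    pmf_unit: str = "kBT"
    geometry: str = "sphere"
    np_radius: float = 80.0  # nm
    hamaker_A123: float = 1.0  # kBT (placeholder; set per material)
    zeta_potential: float = -5.0  # mV
    temperature: float = 300.0  # K
    ionic_strength: float = 0.1  # mol/L
    grid_step: float = 5.0  # degrees
    theta_mode: str = "full"
    profile_step: float = 0.01  # nm
    profile_span: float = 5.0  # nm
    # KMC stage
    kmc_panel: list[dict] = field(default_factory=list)
    kmc_energy_source: str = "heatmaps"  # heatmaps | panel | reference:<facet>
    kmc_t_end: float = 3600.0  # s
    kmc_replicates: int = 3
    kmc_max_events: int = 500_000
    kmc_displacement: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def conditions(self) -> SolutionConditions:
        return SolutionConditions(temperature=self.temperature,
                                  ionic_strength=self.ionic_strength)

    def surface_spec(self) -> SurfaceSpec:
        return SurfaceSpec(
            geometry=self.geometry,
            np_radius=self.np_radius if self.geometry == "sphere" else None,
            hamaker_A123=self.hamaker_A123,
            zeta_potential=self.zeta_potential,
            conditions=self.conditions(),
        )


def _panel_frame(config: RunConfig) -> pd.DataFrame:
    if config.kmc_panel:
        return pd.DataFrame(config.kmc_panel)
    return make_milk_panel()


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages of a run; returns the output directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "uacorona",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "config": yaml.safe_load(config.to_yaml()),
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest))

    conditions = config.conditions()
    surface_spec = config.surface_spec()

    # stage 1+2: heatmaps per protein x surface
    heatmaps = []
    energy_by_protein: dict[str, dict[str, float]] = {}
    if config.structures and config.pmf_dirs:
        (out / "heatmaps").mkdir(exist_ok=True)
        proteins = [read_pdb_to_beads(p) for p in config.structures]
        for surface_id, pmf_dir in config.pmf_dirs.items():
            pmf_set = read_pmf_directory(pmf_dir, surface_id=surface_id,
                                         unit=config.pmf_unit,
                                         conditions=conditions)
            for protein in proteins:
                missing = pmf_set.check_protein(protein)
                if missing:
                    raise KeyError(
                        f"{protein.name} on {surface_id}: no PMF for "
                        f"residues {missing}")
                hm = build_heatmap(protein, surface_spec, pmf_set,
                                   grid_step=config.grid_step,
                                   theta_mode=config.theta_mode,
                                   span=config.profile_span,
                                   step=config.profile_step)
                path = out / "heatmaps" / f"{protein.name}__{surface_id}.tsv"
                write_heatmap(hm, path)
                heatmaps.append(hm)
                energy_by_protein.setdefault(surface_id, {})[protein.name] = \
                    hm.e_min
                log.info("heatmap %s on %s: E_min=%.2f kBT",
                         protein.name, surface_id, hm.e_min)
        ranking = rank_proteins(heatmaps)
        # kJ/mol companion column at the run temperature
        ranking["e_min_kj_mol"] = ranking["e_min_kbt"] * conditions.kbt_kj_per_mol
        ranking.to_csv(out / "ranking.tsv", sep="\t", index=False)

    # stage 3: competitive adsorption
    panel = _panel_frame(config)
    energy_sets: dict[str, dict[str, float]] = {}
    source = config.kmc_energy_source
    if source == "heatmaps" and energy_by_protein:
        energy_sets = energy_by_protein
    elif source.startswith("reference"):
        _, _, facet = source.partition(":")
        facets = [facet] if facet else list(IRON_EMIN)
        for f in facets:
            energy_sets[f] = {k: v[0] for k, v in IRON_EMIN[f].items()}
    elif "energy_kbt" in panel.columns and panel["energy_kbt"].notna().all():
        energy_sets = {"panel": dict(zip(panel["species"],
                                         panel["energy_kbt"]))}
    else:
        log.warning("no adsorption energies available; skipping KMC stage")
        return out

    results = {}
    for surface_id, energies in energy_sets.items():
        species = []
        for _, row in panel.iterrows():
            if row["species"] not in energies:
                raise KeyError(f"no energy for {row['species']} on "
                               f"{surface_id}")
            species.append(Species(name=row["species"],
                                   concentration=row["concentration_mol_l"],
                                   mw=row["mw_da"],
                                   energy=energies[row["species"]],
                                   conditions=conditions))
        results[surface_id] = simulate_corona(
            species, np_radius=config.np_radius, t_end=config.kmc_t_end,
            seed=config.seed, n_replicates=config.kmc_replicates,
            max_events=config.kmc_max_events,
            displacement=config.kmc_displacement)
    table = abundance_table(results)
    table.to_csv(out / "corona.tsv", sep="\t", index=False)

    ts_rows = []
    for surface_id, res in results.items():
        for rep, (times, traj) in enumerate(zip(res.times, res.trajectories)):
            for t, counts in zip(times, traj):
                row = {"surface": surface_id, "replicate": rep, "time_s": t}
                row.update(dict(zip(res.names, counts)))
                ts_rows.append(row)
    pd.DataFrame(ts_rows).to_csv(out / "corona_timeseries.tsv", sep="\t",
                                 index=False)
    return out
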