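"""Hard-sphere kinetic Monte Carlo of competitive protein adsorption.

Proteins are ultra-coarse-grained to single hard spheres that adsorb on a
spherical nanoparticle.  The stochastic dynamics is an exact Gillespie
jump process with two event families per species:

* adsorption — diffusion-limited Smoluchowski arrival,
  ``k_on = 4 pi D_i R_NP c_i N_A``; the arriving sphere is placed
  uniformly at random on the surface and the event is discarded if it
  overlaps a bound particle (single-attempt thinning, so the effective
  rate is the bare arrival rate times the instantaneous acceptance
  probability of non-overlapping placement);
* desorption — Arrhenius escape per bound particle,
  ``k_off = nu0 exp(-|E|/kBT)``.

Packing geometry: bound particles occupy spherical caps; two particles of
radii R_i, R_j overlap when their great-circle separation measured on the
nanoparticle surface is below R_i + R_j.  In the flat limit
(R_NP >> R_i) this reduces to ordinary disk exclusion; on very small
nanoparticles it allows single-occupancy toy systems.

At the adsorption energies typical of bare transition-metal surfaces
(tens to hundreds of kBT) desorption underflows to zero and the process
is competitive random sequential adsorption: the stationary composition
is set by relative arrival fluxes and packing, not by the energies.  An
optional displacement move (an incoming protein may evict a single
weaker-bound particle with Metropolis probability on the energy
difference) is provided but disabled by default, since the exchange
mechanism at such surfaces is not experimentally constrained.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import constants as _const

from .types import SolutionConditions

log = logging.getLogger(__name__)

__all__ = [
    "Species", "CoronaState", "CoronaResult",
    "radius_from_mw", "stokes_einstein_diffusion",
    "adsorption_rate", "desorption_rate",
    "gillespie_step", "simulate_corona", "abundance_table",
    "species_from_panel",
]

PROTEIN_DENSITY = 1.35  # g/cm^3, compact globular protein
DEFAULT_NU0 = 1e9  # 1/s, desorption attempt frequency


def radius_from_mw(mw: float, density: float = PROTEIN_DENSITY) -> float:
    """Equivalent-sphere radius (nm) of a protein of molecular weight *mw*
    (Da) at mass density *density* (g/cm^3)."""
    volume_nm3 = mw / (density * _const.N_A) * 1e21
    return (3.0 * volume_nm3 / (4.0 * np.pi)) ** (1.0 / 3.0)


def stokes_einstein_diffusion(radius: float,
                              conditions: SolutionConditions | None = None
                              ) -> float:
    """Stokes-Einstein diffusion coefficient (nm^2/s) for a sphere of
    *radius* nm in the solvent described by *conditions*."""
    cond = conditions or SolutionConditions()
    d_m2s = cond.kbt_joule / (6.0 * np.pi * cond.viscosity * radius * 1e-9)
    return d_m2s * 1e18


@dataclass
class Species:
    """One protein species in the competitive-adsorption model."""

    name: str
    concentration: float  # mol/L
    mw: float  # Da
    energy: float  # adsorption energy, kBT (negative = binding)
    radius: float | None = None  # nm; default from MW at protein density
    diffusion: float | None = None  # nm^2/s; default Stokes-Einstein
    nu0: float = DEFAULT_NU0  # desorption attempt frequency, 1/s
    conditions: SolutionConditions = field(default_factory=SolutionConditions)

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.radius is None:
            self.radius = radius_from_mw(self.mw)
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.diffusion is None:
            self.diffusion = stokes_einstein_diffusion(self.radius,
                                                       self.conditions)


def adsorption_rate(species: Species, np_radius: float,
                    acceptance: float = 1.0) -> float:
    """Arrival rate (events/s) of *species* at a nanoparticle of radius
    *np_radius* nm, optionally scaled by a placement acceptance
    probability (the KMC realises that factor by thinning)."""
    number_density = species.concentration * _const.N_A * 1e-24  # per nm^3
    bare = 4.0 * np.pi * species.diffusion * np_radius * number_density
    return bare * acceptance


def desorption_rate(species: Species) -> float:
    """Arrhenius escape rate (events/s) per bound particle.

    ``nu0 exp(-|E|/kBT)``; for |E| beyond ~700 kBT the exponential
    underflows to exactly zero (irreversible binding)."""
    return species.nu0 * math.exp(-abs(species.energy))


class CoronaState:
    """Positions and bookkeeping of adsorbed hard spheres on one NP."""

    def __init__(self, species: list[Species], np_radius: float):
        if np_radius <= 0:
            raise ValueError("np_radius must be positive")
        self.species = list(species)
        self.np_radius = float(np_radius)
        self.time = 0.0
        radii = np.array([s.radius for s in self.species])
        # pairwise angular exclusion threshold (radians) on the NP surface
        ang = (radii[:, None] + radii[None, :]) / self.np_radius
        self._always_overlap = ang >= np.pi
        self._cos_thresh = np.cos(np.minimum(ang, np.pi))
        self._positions: dict[int, np.ndarray] = {}  # id -> unit vector
        self._sp_of: dict[int, int] = {}
        self._next_id = 0
        self.counts = np.zeros(len(self.species), dtype=int)
        self.events = {"adsorb": 0, "reject": 0, "desorb": 0, "displace": 0}
        # cell list over the embedding 3-D space; edge >= largest exclusion
        # chord so neighbours of a cell block cover all possible overlaps
        max_arc = min(2.0 * radii.max(), np.pi * self.np_radius)
        self._edge = max(2.0 * self.np_radius * np.sin(max_arc /
                                                       (2.0 * self.np_radius)),
                         1e-9)
        self._use_cells = self._edge < self.np_radius
        self._cells: dict[tuple, list[int]] = {}
        # rates are fixed by (species, np_radius); cache them once
        self.k_on = np.array([adsorption_rate(s, self.np_radius)
                              for s in self.species])
        self.k_off_unit = np.array([desorption_rate(s)
                                    for s in self.species])

    # -- geometry ----------------------------------------------------------
    def _cell_key(self, u: np.ndarray) -> tuple:
        p = u * (self.np_radius / self._edge)
        return (int(math.floor(p[0])), int(math.floor(p[1])),
                int(math.floor(p[2])))

    def _neighbour_ids(self, u: np.ndarray) -> list[int]:
        if not self._use_cells:
            return list(self._positions)
        kx, ky, kz = self._cell_key(u)
        out: list[int] = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    out.extend(self._cells.get((kx + dx, ky + dy, kz + dz), ()))
        return out

    def overlaps(self, u: np.ndarray, sp: int) -> list[int]:
        """ids of bound particles whose caps overlap a *sp* sphere at *u*."""
        hits = []
        for pid in self._neighbour_ids(u):
            other = self._sp_of[pid]
            if self._always_overlap[sp, other]:
                hits.append(pid)
                continue
            if float(u @ self._positions[pid]) > self._cos_thresh[sp, other]:
                hits.append(pid)
        return hits

    def add(self, sp: int, u: np.ndarray) -> int:
        pid = self._next_id
        self._next_id += 1
        self._positions[pid] = u
        self._sp_of[pid] = sp
        self.counts[sp] += 1
        if self._use_cells:
            self._cells.setdefault(self._cell_key(u), []).append(pid)
        return pid

    def remove(self, pid: int) -> None:
        u = self._positions.pop(pid)
        sp = self._sp_of.pop(pid)
        self.counts[sp] -= 1
        if self._use_cells:
            self._cells[self._cell_key(u)].remove(pid)

    def particles_of(self, sp: int) -> list[int]:
        return [pid for pid, s in self._sp_of.items() if s == sp]

    @property
    def n_bound(self) -> int:
        return len(self._positions)

    @property
    def area(self) -> float:
        """Bare NP surface area (nm^2) used for per-area reporting."""
        return 4.0 * np.pi * self.np_radius ** 2

    def coverage(self) -> float:
        """Area fraction covered by the bound spherical caps."""
        covered = 0.0
        for pid, sp in self._sp_of.items():
            half_angle = min(self.species[sp].radius / self.np_radius, np.pi)
            covered += 2.0 * np.pi * self.np_radius ** 2 \
                * (1.0 - np.cos(half_angle))
        return covered / self.area

    def check_invariant(self) -> None:
        """Assert no pair of bound particles overlaps (spot check).

        Uses the cell list, so only geometrically possible pairs are
        examined; cost is O(N x neighbourhood size)."""
        for pid, u in self._positions.items():
            si = self._sp_of[pid]
            for other in self._neighbour_ids(u):
                if other == pid:
                    continue
                sj = self._sp_of[other]
                dot = float(u @ self._positions[other])
                if self._always_overlap[si, sj] or \
                        dot > self._cos_thresh[si, sj] + 1e-12:
                    raise AssertionError(
                        f"hard-sphere overlap between particles {pid} "
                        f"and {other}")

    def estimate_acceptance(self, sp: int, rng: np.random.Generator,
                            n_samples: int = 200) -> float:
        """Monte-Carlo estimate of the placement acceptance probability."""
        ok = 0
        for _ in range(n_samples):
            u = _random_unit(rng)
            if not self.overlaps(u, sp):
                ok += 1
        return ok / n_samples


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def gillespie_step(state: CoronaState, rng: np.random.Generator,
                   np_radius: float | None = None,
                   placement_attempts: int = 1,
                   displacement: bool = False) -> bool:
    """One exact stochastic-simulation event.

    Draws the exponential waiting time from the total rate, picks the
    event proportionally, and executes it.  Adsorption placement is a
    uniform random point on the sphere with hard-sphere rejection
    (*placement_attempts* tries, then the event is discarded and logged).
    Returns ``True`` if the state changed.  Raises ``RuntimeError`` when
    the total rate is zero (nothing can ever happen again).
    """
    if np_radius is not None and np_radius != state.np_radius:
        raise ValueError("np_radius disagrees with the state's geometry")
    n_sp = len(state.species)
    rates = np.concatenate([state.k_on, state.k_off_unit * state.counts])
    total = rates.sum()
    if total <= 0.0:
        raise RuntimeError("total event rate is zero; simulation converged")
    state.time += rng.exponential(1.0 / total)
    choice = int(np.searchsorted(np.cumsum(rates), rng.random() * total,
                                 side="right"))
    choice = min(choice, 2 * n_sp - 1)
    if choice < n_sp:
        sp = int(choice)
        for _ in range(max(1, placement_attempts)):
            u = _random_unit(rng)
            hits = state.overlaps(u, sp)
            if not hits:
                state.add(sp, u)
                state.events["adsorb"] += 1
                return True
            if displacement and len(hits) == 1:
                pid = hits[0]
                other = state._sp_of[pid]
                victim_u = state._positions[pid]
                d_e = state.species[sp].energy - state.species[other].energy
                p_evict = 1.0 if d_e <= 0 else math.exp(-d_e)
                if rng.random() < p_evict:
                    state.remove(pid)
                    if not state.overlaps(u, sp):
                        state.add(sp, u)
                        state.events["displace"] += 1
                        return True
                    # does not fit even after eviction: put the victim back
                    state.add(other, victim_u)
        state.events["reject"] += 1
        return False
    sp = int(choice - n_sp)
    pids = state.particles_of(sp)
    state.remove(pids[rng.integers(len(pids))])
    state.events["desorb"] += 1
    return True


@dataclass
class CoronaResult:
    """Replicate-averaged outcome of a competitive-adsorption simulation."""

    species: list[Species]
    np_radius: float
    counts: np.ndarray  # (n_replicates, n_species) final bound counts
    times: list[np.ndarray]  # per replicate sample times (s)
    trajectories: list[np.ndarray]  # per replicate (n_samples, n_species)
    events: list[dict]
    converged: list[bool]

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.species]

    @property
    def area(self) -> float:
        return 4.0 * np.pi * self.np_radius ** 2

    def mean_counts(self) -> np.ndarray:
        return self.counts.mean(axis=0)

    def number_per_area(self) -> np.ndarray:
        """Mean bound number per nm^2 of bare NP surface."""
        return self.mean_counts() / self.area

    def mass_abundance(self) -> tuple[np.ndarray, np.ndarray]:
        """Relative mass abundance M_ab,i = N_i MW_i / sum_j N_j MW_j in %,
        per replicate; returns (mean, sd) over replicates."""
        mw = np.array([s.mw for s in self.species])
        mass = self.counts * mw[None, :]
        frac = 100.0 * mass / mass.sum(axis=1, keepdims=True)
        return frac.mean(axis=0), frac.std(axis=0, ddof=1 if len(frac) > 1 else 0)

    def summary(self) -> pd.DataFrame:
        mab, mab_sd = self.mass_abundance()
        df = pd.DataFrame({
            "species": self.names,
            "n_bound_mean": self.mean_counts(),
            "n_per_nm2": self.number_per_area(),
            "mass_abundance_pct": mab,
            "mass_abundance_sd": mab_sd,
        })
        return df.sort_values("mass_abundance_pct",
                              ascending=False).reset_index(drop=True)


def _composition_converged(times: np.ndarray, traj: np.ndarray,
                           window: float = 0.2, tol: float = 1.0,
                           mw: np.ndarray | None = None) -> bool:
    """True if the mass composition (%) changed by less than *tol* points
    over the trailing *window* fraction of simulated time."""
    if len(times) < 3 or traj[-1].sum() == 0:
        return False
    t_ref = times[-1] * (1.0 - window)
    i_ref = int(np.searchsorted(times, t_ref))
    i_ref = min(i_ref, len(times) - 2)
    w = np.ones(traj.shape[1]) if mw is None else mw
    ref, last = traj[i_ref] * w, traj[-1] * w
    if ref.sum() == 0:
        return False
    return bool(np.max(np.abs(100.0 * ref / ref.sum()
                              - 100.0 * last / last.sum())) < tol)


def simulate_corona(species: list[Species], np_radius: float,
                    t_end: float = 3600.0, seed: int = 0,
                    n_replicates: int = 3, max_events: int = 500_000,
                    stall_limit: int = 20_000, record_every: int = 200,
                    displacement: bool = False,
                    check_every: int = 50_000) -> CoronaResult:
    """Replicate-averaged competitive adsorption on one nanoparticle.

    Each replicate runs the Gillespie process until the simulated clock
    reaches *t_end* seconds, the total rate vanishes, *max_events*
    attempts are exhausted, or the surface stalls (no successful event in
    *stall_limit* consecutive attempts with no active desorption channel
    — the jammed random-sequential-adsorption endpoint).  The hard-sphere
    invariant is spot-checked every *check_every* events and at the end.
    Replicate r uses the independent seed ``seed + r``.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if not species:
        raise ValueError("need at least one species")
    all_counts, all_times, all_traj, all_events, conv = [], [], [], [], []
    mw = np.array([s.mw for s in species])
    for rep in range(n_replicates):
        rng = np.random.default_rng(seed + rep)
        state = CoronaState(species, np_radius)
        times = [0.0]
        traj = [state.counts.copy()]
        stall = 0
        n_events = 0
        while n_events < max_events and state.time < t_end:
            n_events += 1
            try:
                changed = gillespie_step(state, rng,
                                         displacement=displacement)
            except RuntimeError:
                break  # total rate zero: converged for good
            if changed:
                stall = 0
            else:
                stall += 1
                desorbing = float((state.k_off_unit * state.counts).sum())
                if stall >= stall_limit and desorbing == 0.0:
                    log.info("replicate %d jammed after %d events "
                             "(%d bound)", rep, n_events, state.n_bound)
                    break
            if n_events % record_every == 0:
                times.append(state.time)
                traj.append(state.counts.copy())
            if n_events % check_every == 0:
                state.check_invariant()
            if n_events % 10_000 == 0:
                log.info("replicate %d: %d events, t=%.3g s, %d bound",
                         rep, n_events, state.time, state.n_bound)
        state.check_invariant()
        times.append(state.time)
        traj.append(state.counts.copy())
        all_counts.append(state.counts.copy())
        all_times.append(np.asarray(times))
        all_traj.append(np.asarray(traj))
        all_events.append(dict(state.events))
        conv.append(_composition_converged(np.asarray(times),
                                           np.asarray(traj), mw=mw))
    return CoronaResult(species=list(species), np_radius=np_radius,
                        counts=np.asarray(all_counts), times=all_times,
                        trajectories=all_traj, events=all_events,
                        converged=conv)


def abundance_table(results: dict[str, CoronaResult]) -> pd.DataFrame:
    """Combine per-surface corona results into one tidy table.

    One row per (surface, species) with the bound number per nm^2 of bare
    NP area and the relative mass abundance in %; abundances sum to 100
    within each surface.
    """
    frames = []
    for surface, res in results.items():
        df = res.summary()
        df.insert(0, "surface", surface)
        frames.append(df)
    if not frames:
        raise ValueError("no corona results supplied")
    return pd.concat(frames, ignore_index=True)


def species_from_panel(panel: pd.DataFrame,
                       energies: dict[str, float] | None = None,
                       conditions: SolutionConditions | None = None
                       ) -> list[Species]:
    """Build KMC species from a milk-panel table.

    *panel* needs columns species/concentration_mol_l/mw_da and optionally
    energy_kbt; *energies* (name -> kBT) overrides the energy column.
    """
    cond = conditions or SolutionConditions()
    out = []
    for _, row in panel.iterrows():
        name = row["species"]
        e = energies.get(name) if energies else row.get("energy_kbt")
        if e is None or (isinstance(e, float) and np.isnan(e)):
            raise ValueError(f"no adsorption energy for species {name!r}")
        out.append(Species(name=name, concentration=row["concentration_mol_l"],
                           mw=row["mw_da"], energy=float(e), conditions=cond))
    return out
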