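# Methods

This note documents the models implemented in `uacorona`, their
assumptions, the parameters that matter, the numerical choices, and what
the synthetic-data generators do and do not emulate.

## Rigid-body united-atom adsorption model

A protein is represented by one bead per residue at the Cα position; the
structure is rigid (no flexibility, unfolding, or temperature-dependent
conformational change — these are out of scope). The protein–surface
potential is pairwise additive over beads:

* **Short-range surface term.** One tabulated potential of mean force per
  residue type, indexed by the surface separation distance (SSD) of the
  bead centre from the top atomic plane of the surface. Tables are
  treated as opaque linear interpolants. Below the first tabulated point
  the wall value at that point is used (never downward extrapolation;
  clamped points are counted and logged); beyond the table the energy is
  the plateau, which is re-zeroed on input by subtracting the mean over
  the last 10% of the distance range. The 22-key table set covers the 20
  amino acids plus the two histidine tautomers (HID/HIE) and the
  charged/neutral glutamate pair (GLU/GAN); protein residues resolve
  through an alias map whose defaults are HIS→HIE and charged GLU, both
  overridable. The deposited tables this model was built to consume are
  tabulated against the SSD of the side-chain analogue; this package
  reads the abscissa as bead-centre-to-surface-plane distance.
* **Electrostatics.** Screened Coulomb. Default: the linearised
  Debye–Hückel potential of a uniform surface held at the zeta potential,
  `U_i = q_i (eζ/kBT) e^{−κz_i}` for slabs, with an `R_NP/r` geometric
  factor for spheres; this is consistent with the surface charge density
  `σ = ε ε₀ κ ζ`. A discrete point-charge mode
  (`l_B Σ q_i q_j e^{−κ r_ij}/r_ij`) is retained and used by the
  brute-force oracle tests. Bead charges default to integer side-chain
  values at pH 7 (ARG/LYS +1, ASP/GLU −1, HIS 0); when a caller supplies
  an expected (titration-derived, fractional) net charge that disagrees,
  a warning is emitted and charges are *not* rescaled.
* **Long-range Hamaker term.** The standard two-sphere Hamaker energy
  `−A/6 [2R₁R₂/x₁ + 2R₁R₂/x₂ + ln(x₁/x₂)]`,
  `x₁ = d²−(R₁+R₂)²`, `x₂ = d²−(R₁−R₂)²`, with the sphere–half-space
  closed form for slabs. The implementation was verified against direct
  numerical pairwise integration of an `r⁻⁶` kernel over both bodies
  (machine precision). The Hamaker constant `A₁₂₃` (material–water–
  protein, in kBT) is a required configuration parameter; the default 1.0
  is an explicitly labelled placeholder, because no reliable value is
  available for bare zero-valent metals in water, and results against
  real materials should sweep it. Bead radii (default 0.5 nm, per-residue
  overridable) enter only this term and the KMC packing. Inside a 0.05 nm
  surface gap the diverging term is clamped (Born-style cutoff); the
  short-range PMF dominates there anyway.

### Orientation scan and heatmaps

An orientation (θ, φ) is the spherical direction, in the protein's input
frame, that is rotated onto the outward surface normal
(`R = Ry(−θ)Rz(−φ)`, proper, identity at 0,0). θ = φ = 0 reproduces the
input pose exactly. Both angles run over [0°, 360°) on a 5° default grid
with Boltzmann weights `|sin θ|e^{−E}`; a [0°, 180°] θ-mode is available
behind a flag. The double-covered sphere is deliberate: published
heatmaps for this class of model list θ beyond 180°, and the redundant
cells are harmless under the |sin| weighting.

For each orientation the total potential is evaluated along the approach
coordinate from just inside contact (the COM distance where the closest
bead reaches its PMF wall, minus a 0.3 nm margin) to contact + 5 nm in
0.01 nm steps, and reduced to the orientation energy by the log-Boltzmann
integral (trapezoidal quadrature; the spherical version normalises by the
same quadrature of `r²` so that `U ≡ 0` maps to `E = 0` exactly). The
integration cutoff `a(θ, φ)` is the first distance beyond which |U| stays
below 0.01 kBT, capped at contact + 5 nm; the grid-refinement test bounds
the sensitivity of this whole construction at < 0.5% under step halving,
and the square-well closed form is reproduced to < 0.1%. Deep minima are
handled in shifted log space, so energies of hundreds of kBT neither
overflow nor lose the Boltzmann average.

The heatmap records `E(θ, φ)`, per-cell cutoffs, the grid minimum
`E_min` with its pose and the closest bead–surface distance `r_min` at
that pose's profile minimum, and the Boltzmann average `E_ads`
(`E_min ≤ E_ads ≤ max E` is enforced). Affinity rankings use `E_min`;
`E_ads` is reported alongside. No curvature correction is applied to the
slab-derived PMFs when used on spheres: at the 80 nm particles of
interest the surface is locally flat on the residue scale.

## Hard-sphere corona kinetics

Each protein species is one hard sphere of radius
`R_i = (3 MW_i / 4π ρ N_A)^{1/3}` at ρ = 1.35 g/cm³ (overridable), with
Stokes–Einstein diffusion `D_i = kBT/6πη R_i` (η = 0.85 mPa·s at the
300 K default). The Gillespie process has, per species, a
diffusion-limited arrival channel `k_on = 4π D_i R_NP c_i N_A` with
uniform placement and single-attempt hard-sphere rejection — so the
effective rate is the bare flux times the instantaneous acceptance
probability, which is exactly the thinning of a Poisson stream — and an
Arrhenius desorption channel `k_off = ν₀ e^{−|E_i|/kBT}` per bound
particle (ν₀ = 10⁹ s⁻¹ default; `E_min` drives desorption by default,
switchable to `E_ads`). Overlap on the spherical surface uses
great-circle distance at the particle radius (`arc < R_i + R_j`), which
reduces to disk exclusion in the flat limit and permits single-occupancy
toy systems used by the statistical-mechanics tests. A cell list over the
embedding space keeps each placement check local.

Runs stop at a simulated-time cap, an event cap, a vanishing total rate,
or a jam (a long run of rejected placements with no active desorption
channel); composition convergence — mass composition changing by < 1
point over the trailing 20% of simulated time — is evaluated and
reported per replicate. Replicates (≥ 3 seeds) give mean ± sd of bound
numbers per nm² of bare NP area and relative mass abundance.

At the adsorption energies relevant to bare metal surfaces (−140 to
−343 kBT for the bundled milk panel), `k_off` underflows to zero and the
process is competitive random sequential adsorption: the composition is
set by arrival fluxes `c_i D_i` and packing, independent of the rate
scale (verified by an identical-trajectory test) and of the energies. An
optional displacement move — an arrival overlapping exactly one bound,
more weakly bound particle may evict it with Metropolis probability on
the energy difference — is implemented but off by default: published
corona kinetics for this system show late-stage exchange, but the
exchange mechanism is not specified, and an always-accepting exchange
drives the strongest binder toward complete takeover rather than the
reported mixed layer. Comparisons of the simulated composition with
published corona tables are therefore rate-model-sensitive, and the
bundled milk-corona validation reflects that: the flux + packing model
reproduces the published extremes qualitatively (serum albumin rarest)
but leaves the two equal-concentration, near-equal-size caseins
statistically tied near 32% each, rather than split 41%/17%.

## Synthetic data

Synthetic PMFs are an exponential repulsive wall plus one or two Gaussian
wells (default well at 0.25 nm, grid 0.05–2.0 nm in 0.005 nm steps),
with a fixed-point adjustment so the tabulated global minimum equals the
requested depth to 1e-12; depths spanning −0.35 to −39.69 kBT mimic the
realistic range for residue analogues on reactive metal surfaces. They
reproduce the canonical wall/minima/plateau shape but no particular
material — the energy model treats all tables as opaque interpolants, so
nothing downstream depends on the functional form.

Synthetic proteins are rejection-sampled uniform bead packings in a ball
sized so the expected radius of gyration matches the target (Rg² = 3a²/5),
with a 0.35 nm minimum separation (the Cα–Cα scale) and no chain
connectivity, which the rigid-body model never uses. Coordinates are
quantised to 1e-4 nm — the PDB format's own resolution — so bead
structures round-trip exactly through PDB export/import. Generators are
pure functions of (spec, seed). What these fixtures do *not* emulate:
real folds, surface-residue statistics, or sequence correlations; tests
passing on them validate the energy and kinetics machinery, not any
biological prediction.

The bundled milk panel (six proteins, molar concentrations 4, 1, 4, 0.9,
2, 0.1 ×10⁻⁴ mol/L with literature molecular weights, 28.6 g/L of protein
in total) and the per-facet iron adsorption energies used as default KMC
inputs are literature reference values shipped in
`uacorona.reference`.

## Problem sizes and determinism

Default test and acceptance workloads are sized for a single CPU: toy
heatmaps on 30–90° grids with ≤ 10-bead proteins, KMC runs of 2–6 × 10⁴
attempts on 12–25 nm particles for the property suite, and 3 × 5 × 10⁵
attempts on the 80 nm milk system for the corona composition (about
3,800 bound spheres, coverage ≈ 0.53, effectively the jammed state —
continuing to the strict RSA limit changes the composition by well under
a point). All stochastic components take explicit seeds; a rerun with the
same config and seed is bit-identical.

## Known limitations

Rigid proteins; equilibrium orientation distribution assumed by the
Boltzmann average; slab PMFs applied unchanged to spheres; linearised
electrostatics from a single zeta value; the Hamaker constant is a
placeholder by default; real metal surfaces oxidise and hydroxylate,
which lowers binding relative to the bare-metal PMFs; and corona
composition beyond the flux-dominated regime depends on an exchange
mechanism the model exposes only as an explicit, disabled-by-default
option.
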