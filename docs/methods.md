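# Methods

## Model

A single polyelectrolyte is a bead–spring chain of N monomers, each of
valence −1 and mass m = 1, in a rectangular periodic box
48.0σ × 49.36σ × 200.0σ. Every monomer dissociates one monovalent
counterion; 256 cations and 256 anions of added salt mimic a saline
reservoir. All mobile beads share the same size and mass. The membrane is
four layers of immobile beads on a triangular lattice (lattice constant
1.0σ — the only value commensurate with the printed box cross-section,
49.36 = 57·√3/2), stacked with 1.5σ spacing so the outer faces span the
4.5σ channel length; a cylindrical channel of radius 2.25σ is punched
through the center along z. Interior-layer beads that no mobile bead can
reach are dropped except for the channel lining.

Interactions (reduced units: σ, m, e, k_BT = 1, τ_u = σ√(m/k_BT)):

- **Excluded volume**: purely repulsive truncated-shifted LJ (WCA),
  4ε[(σ/r)¹² − (σ/r)⁶ + ¼] for r ≤ 2^(1/6)σ. Bead–bead: (σ_bb, ε_bb) =
  (1.0, 1.2); bead–wall: (σ_bw, ε_bw) = (1.5, 2.5), identical for monomers
  and ions.
- **Bonds**: harmonic, U = (k/2)(r − r0)² with k = 600 k_BT/σ², r0 = 1.0σ.
- **Electrostatics**: U = k_BT·λ_B·Z_iZ_j/r with Bjerrum length λ_B = 3.0σ,
  summed over periodic images by smooth Ewald (below).
- **Driving field**: E⃗ = −E ẑ, supported only inside the cylindrical
  channel volume as a step function (no taper; the discontinuity at the
  channel boundary means the field contributes force but is not part of the
  potential-energy bookkeeping). The force on a bead of valence Z inside
  the channel is −Z·E ẑ, so the −1 monomers are driven toward +z: the cis
  compartment is z < z_entrance, trans is z > z_exit.

**Intrachain exclusions.** Directly bonded neighbors interact through the
stiff spring alone (no WCA on top); the Coulomb interaction couples every
charged pair, bonded or not. This convention reproduces the equilibrium
contour length of the N = 128 chain (mean bond ≈ 1.008σ, ℓ ≈ 128σ:
Coulomb repulsion between bonded −1 charges adds ≈ 0.005σ of stretch to
the ≈ 0.003σ thermal lengthening of the k = 600 spring). We measured the
tethered-chain equilibrium under the alternative conventions (WCA and/or
Coulomb excluded for 1–2 and 1–3 neighbors): the chain-scale statistics
(R_g, condensed fraction) are insensitive, so only the contour length
discriminates. Both exclusion depths remain configurable in `ModelParams`.

## Electrostatics

Classical smooth Ewald summation (real + reciprocal + self terms) under
tinfoil boundary conditions, full 3D periodicity; the long z edge provides
the slab separation, no slab correction. The splitting parameter α, the
real-space cutoff r_cut ≤ min(box)/2, and the per-axis integer k-space
cutoffs are chosen at run time from the standard RMS force-error estimates
so the estimated error stays below the accuracy target (default 10⁻³,
interpreted as relative RMS force error against the force between two unit
charges at contact — the convention of mainstream MD codes). A safety
factor of 25 on the internal error target keeps the *energy* agreement
with the brute-force lattice sum below 10⁻³ as well; k-vectors are cheap
at these system sizes (≈ 900 charges).

The test oracle is a spherically ordered real-space lattice sum. Such a
sum converges to the vacuum-boundary result, which differs from the
tinfoil Ewald value by the dipole surface term 2πλ_B|M|²/(3V);
`direct_sum_oracle(..., tinfoil=True)` subtracts that term so the two
routes are directly comparable. The real-space kernel evaluates erfc
through the Abramowitz–Stegun 7.1.26 rational approximation (absolute
error < 1.5·10⁻⁷), which shares its Gaussian factor with the force term;
force/energy consistency is preserved because the energy and force
expressions use the same approximant.

## Dynamics

The Langevin equation m r̈ = −ζṙ − ∇U + Z e E⃗ + η with ζ = 1 m/τ_u,
⟨η_i(t)·η_j(t′)⟩ = 6 k_BT ζ δ_ij δ(t−t′), is integrated with the
Grønbech-Jensen/Farago discretization — a Verlet-family scheme chosen for
its accurate configurational sampling at the upper end of the time-step
range. In the ζ → 0, zero-noise limit it reduces exactly to velocity
Verlet. Time steps follow a field-strength schedule (overridable):
dt = 0.005 τ_u for E ≤ 1, 0.001 for 1 < E ≤ 10, 0.0005 for E > 10. Each
run draws noise from its own counter-keyed random stream, so a (seed,
configuration) pair reproduces its trajectory bit-for-bit on one platform.
Wall beads and, during equilibration, the tethered head monomer are simply
excluded from the update.

Force assembly: short-range terms (WCA + real-space Ewald) run in one
all-pairs minimum-image loop over the ≤ ~900 mobile beads — at this size
and with r_cut ≈ min(box)/2 a Verlet/cell list buys nothing — while the
static wall uses a precomputed 2D grid over its ≈ 5500 beads with a
z-window prefilter. Beads closer than 10⁻⁶σ raise a singular-configuration
error; non-finite coordinates after a step raise a blow-up error naming
the bead and dt.

## Protocol

1. **Assembly.** The head monomer sits on the pore axis at the trans-side
   opening; the chain threads straight back through the channel and ~2σ
   beyond the cis face, and the remaining monomers grow as a self-avoiding
   discrete wormlike path (unit bonds, von Mises–Fisher angles whose
   concentration is solved from coth κ − 1/κ = e^(−b/ℓ_p)) confined to the
   cis side. The persistence length ℓ_p is set to the Debye screening
   length of the ion content (κ⁻¹ ≈ 4.3σ for the standard composition) —
   the natural conformational correlation scale of a partially neutralized
   polyelectrolyte; for N = 128 this path ensemble has cis-segment
   R_g = 14 ± 4. Counterions start in a shell 1..2λ_B−1 σ around random
   monomers — near the chain they dissociated from, straddling the
   condensation radius so the condensed fraction starts at its equilibrium
   value (≈ 0.78, built by fast local exchange) rather than approaching it
   through slow bulk diffusion. Salt ions start uniform in the
   compartments. All placements exclude the wall slab and channel interior
   and respect a 0.9σ minimum separation.
2. **Equilibration.** Zero field, head monomer frozen, default 10⁶ steps
   at dt = 0.005 (configurable; the desk-scale suites use shortened runs,
   see below). Snapshots from the second half of the run provide the
   t̃ = 0 equilibrium ensemble; the run records its mean kinetic
   temperature (warning if > 5% off target) and mean bond length.
3. **Translocation.** Tether released, field on, plus a one-way barrier: a
   repulsive WCA plane (σ = 1.0, ε = 1.2) felt only by the head monomer,
   placed at z_exit − 2^(1/6)σ so the repulsion switches on exactly when
   the head dips below the exit plane and diverges one bead diameter into
   the channel — back-threading is impossible but the plane exerts no
   force while the head is on the trans side of the exit. τ is the first
   time every monomer's z exceeds the exit plane, with the crossing
   located by linear interpolation between the bracketing steps. Runs
   that hit `max_steps` return `completed=False`, never a silent drop.

## Analysis

Per-run time axes are normalized by that run's τ (t̃ = t/τ) and linearly
interpolated onto a fixed 101-point grid (spacing 0.01, matching the
spatial-profile time-window width) before ensemble averaging; missing
values (e.g. R_g of an empty region) propagate as gaps, not zeros.
Chain-shape observables first rebuild contiguous monomer coordinates by
minimum-image bond walking. P(τ) is a Gaussian kernel density with
Silverman bandwidth; the width w is the measure of {P > peak/e}, scanned
on a fine grid. Log–log scaling fits (α, δ per field regime, β on
0.5 ≤ t̃ ≤ 1) use unweighted least squares with regression standard
errors. An ion is condensed when its minimum-image distance to the
nearest monomer is below λ_B; it is attributed to that monomer's region
(condensation is a chain-relative property, so an ion's own z is not
used). z-profiles use 0.5σ bins per species, normalized to unit area;
the (y, z) density map uses 1σ × 1σ cells integrated along x.

## Synthetic ensembles

The generator module provides ground-truth data for every estimator
without MD: lognormal τ samples with median c·N^α·E^(−δ) (positive
support, single-peaked, near-Gaussian at small CV — the observed shape of
first-passage distributions); translocation-coordinate series
s(t̃) = 1 + (N−1)t̃^(β/2) plus bounded reflected-walk jitter, whose MSD is
∝ t̃^β (exactly, when the jitter is disabled); and straight-chain frames
with an exact number of condensed and free ions. These emulate only the
statistical structure the analysis assumes — no force-field physics — so
estimator-recovery tests passing says the analysis chain is correct, not
that the dynamics is.

## Desk-scale problem sizes and known limitations

The reference study runs ≥ 500 trajectories per (N, E) on chains up to
N = 384; the packaged test suite and the acceptance script instead run
minutes-scale ensembles and document what that does and does not probe:

- The equilibrium anchor ensemble uses N = 128 with the full ion
  complement, 5–8 seeds × 10 000–17 000 steps at dt = 0.005 (50–85 τ_u per
  seed), sized to fill the minutes-scale budget with as much equilibration
  as possible. Locally equilibrating quantities — contour length, kinetic
  temperature, ion condensation — are converged at this scale: 600 τ_u
  reference runs put the equilibrium condensed fraction at ≈ 0.78,
  which the shell-started short runs reproduce from the first few τ_u.
  The cis-segment R_g is different: it relaxes on (at least) the Rouse
  time (≈ 550 τ_u for N = 128; two 600 τ_u runs started compact and
  extended retained R_g ≈ 11 and ≈ 18 respectively), so at desk scale its
  ensemble statistics necessarily carry memory of the initial-path
  ensemble, and the Debye-length persistence choice makes that prior
  physically sensible rather than converged. Equilibrated runs at
  N = 32–64 (≥ 4 Rouse times each) give the model's own equilibrium
  R_g(N), whose extrapolation to N = 128 is consistent with the
  initial-path ensemble mean. The same caveats apply to the
  monomer-profile peak position, which tracks the blob location and is
  estimated as the mean of per-seed profile peaks (robust for small
  heterogeneous ensembles).
- Scaling-exponent *trends* (α rising with E, the three δ regimes,
  αβ = 2) would need hours-to-days of sweeps; the suite validates the
  full estimator chain on synthetic ensembles with prescribed truth, and
  the `peltrans sweep` command exposes the real sweeps.
- Hydrodynamic interactions are absent by construction (Langevin/Rouse
  dynamics); no bond breaking, no angular terms, no chemically structured
  pore, no Debye–Hückel effective-potential mode (ions are explicit).
- The σ = 2.4 Å, m = 100 g/mol, τ_u = 1.5 ps mapping to physical units is
  documentation only; all files and results are in reduced units.
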