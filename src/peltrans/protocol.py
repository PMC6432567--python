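"""Assembly and execution of one translocation experiment.

A run proceeds in three stages, mirroring the standard driven-translocation
protocol: (1) build the system with the head monomer threaded through the
channel and sitting at the trans-side opening, the rest of the chain laid
out on the cis side, and ions scattered through the two compartments;
(2) equilibrate at zero field with the head monomer tethered; (3) release
the tether, switch on the in-pore field and the one-way exit barrier, and
integrate until the last monomer leaves the channel exit (first passage).

The initial cis-side path is drawn as a discrete wormlike chain whose
persistence length is set to the Debye screening length of the ionic
solution — the natural correlation scale for a partially neutralized
polyelectrolyte — which starts the tethered chain inside its equilibrium
basin and keeps the zero-field equilibration burden modest.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import asdict, dataclass

import numpy as np

from .electrostatics import EwaldParams
from .forces import BarrierSpec, ForceCalculator
from .geometry import FieldSpec, Geometry
from .integrator import LangevinIntegrator, LangevinParams, dt_for_field, kinetic_temperature, run_rng
from .model import SPECIES_CODES, SPECIES_VALENCE, BondTopology, ModelParams, SystemState
from .trajio import Trajectory

__all__ = ["RunConfig", "TranslocationResult", "initialize_system", "equilibrate", "run_translocation"]


class PackingError(RuntimeError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """One run's composition and schedule.

    Defaults are the study conditions: N monomers each of valence −1, N
    dissociated counterions, plus 256 cations and 256 anions of added salt.
    """

    N: int = 128
    E: float = 0.0
    n_salt_cations: int = 256
    n_salt_anions: int = 256
    equilibration_steps: int = 1_000_000
    max_steps: int = 20_000_000
    seed: int = 0
    save_every: int = 2000

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.E < 0:
            raise ValueError("E must be >= 0")
        if self.n_salt_cations != self.n_salt_anions:
            raise ValueError("salt must be added as neutral pairs")

    @property
    def n_beads(self) -> int:
        return 2 * self.N + self.n_salt_cations + self.n_salt_anions

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TranslocationResult:
    """Outcome of one driven run: first-passage time and saved frames."""

    tau: float | None
    completed: bool
    trajectory: Trajectory
    seed: int
    dt: float

    @property
    def n_frames(self) -> int:
        return self.trajectory.n_frames


def debye_length(cfg: RunConfig, geom: Geometry, params: ModelParams) -> float:
    """Debye screening length κ⁻¹ = (4π λ_B Σ c_i Z_i²)^(−1/2) of the free ions."""
    vol = geom.box[0] * geom.box[1] * geom.box[2]
    n_ions = cfg.N + cfg.n_salt_cations + cfg.n_salt_anions
    kappa2 = 4.0 * math.pi * params.lambda_B * n_ions / vol
    return 1.0 / math.sqrt(kappa2)


def _vmf_concentration(persistence: float, bond: float = 1.0) -> float:
    """Concentration κ of the von Mises–Fisher step distribution giving a
    discrete wormlike chain the requested persistence length: solves
    coth(κ) − 1/κ = exp(−bond/persistence)."""
    target = math.exp(-bond / persistence)
    lo, hi = 1e-3, 1e3
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        val = 1.0 / math.tanh(mid) - 1.0 / mid
        if val < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _sample_wlc_direction(rng, d_prev: np.ndarray, kappa: float) -> np.ndarray:
    """von Mises–Fisher step direction with concentration ``kappa`` about d_prev."""
    xi = rng.random()
    w = 1.0 + math.log(xi + (1.0 - xi) * math.exp(-2.0 * kappa)) / kappa
    phi = 2.0 * math.pi * rng.random()
    # orthonormal frame around d_prev
    a = np.array([1.0, 0.0, 0.0]) if abs(d_prev[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d_prev, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d_prev, e1)
    s = math.sqrt(max(0.0, 1.0 - w * w))
    return w * d_prev + s * (math.cos(phi) * e1 + math.sin(phi) * e2)


def _grow_cis_path(rng, start, n_beads, bond, z_max, box, kappa, min_dist=0.9, max_restarts=200):
    """Self-avoiding wormlike path on the cis side (z below ``z_max``)."""
    for _ in range(max_restarts):
        pts = [np.asarray(start, dtype=np.float64)]
        d = np.array([0.0, 0.0, -1.0])
        ok = True
        for _k in range(n_beads):
            placed = False
            for _try in range(60):
                d_new = _sample_wlc_direction(rng, d, kappa)
                cand = pts[-1] + bond * d_new
                if cand[2] > z_max:
                    continue
                arr = np.asarray(pts[:-1])
                if len(arr):
                    delta = arr - cand
                    delta -= box * np.round(delta / box)
                    if np.min(np.einsum("ij,ij->i", delta, delta)) < min_dist * min_dist:
                        continue
                pts.append(cand)
                d = d_new
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return np.asarray(pts[1:])
    raise PackingError("could not grow a self-avoiding initial chain path")


def initialize_system(
    cfg: RunConfig, geom: Geometry, params: ModelParams, rng=None
) -> SystemState:
    """Threaded starting state: head monomer at the trans opening, chain
    threaded back through the channel and laid out cis-side, ions uniform in
    the compartments (excluding the wall slab and channel interior).
    """
    rng = rng if rng is not None else run_rng(cfg.seed)
    box = np.asarray(geom.box)
    x0, y0 = geom.pore_axis_xy
    bond = params.r0

    # head monomer on the axis at the trans-side opening; thread straight
    # back down the channel and a little beyond the cis face
    n_thread = int(math.ceil((geom.pore_length + 2.0) / bond)) + 1
    n_thread = min(n_thread, cfg.N)
    zs = geom.z_exit - bond * np.arange(n_thread)
    chain = np.column_stack([np.full(n_thread, x0), np.full(n_thread, y0), zs])
    if cfg.N > n_thread:
        kappa = _vmf_concentration(max(1.5, debye_length(cfg, geom, params)), bond)
        rest = _grow_cis_path(
            rng,
            chain[-1],
            cfg.N - n_thread,
            bond,
            z_max=geom.z_entrance - 1.8,
            box=box,
            kappa=kappa,
        )
        chain = np.vstack([chain, rest])

    # counterions are dissociated from the monomers, so they start in a
    # shell around the chain straddling the condensation radius λ_B (each at
    # 1..2λ_B−1 σ of a random monomer): the cloud is locally equilibrated
    # within a few τ_u without starting pre-condensed.  The added salt
    # starts uniform in the compartments.  Both placements exclude the wall
    # slab (hence the channel interior) and keep clear of every placed bead.
    n_ions = cfg.N + cfg.n_salt_cations + cfg.n_salt_anions
    ions = np.empty((n_ions, 3))
    occupied = chain.copy()
    slab_lo, slab_hi = geom.z_entrance - 1.6, geom.z_exit + 1.6
    count = 0
    attempts = 0
    while count < n_ions:
        attempts += 1
        if attempts > 400 * n_ions:
            raise PackingError("ion placement failed; box too crowded")
        if count < cfg.N:  # counterion: shell around a random monomer
            m = chain[int(rng.integers(0, cfg.N))]
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            shell = 1.0 + (2.0 * params.lambda_B - 2.0) * rng.random()
            cand = np.mod(m + shell * u, box)
        else:  # salt: uniform
            cand = rng.random(3) * box
        if slab_lo <= cand[2] <= slab_hi:
            continue
        delta = occupied - cand
        delta -= box * np.round(delta / box)
        if np.min(np.einsum("ij,ij->i", delta, delta)) < 0.81:
            continue
        ions[count] = cand
        occupied = np.vstack([occupied, cand])
        count += 1

    positions = np.vstack([chain, ions])
    species = np.concatenate(
        [
            np.full(cfg.N, SPECIES_CODES["monomer"]),
            np.full(cfg.N, SPECIES_CODES["counterion"]),
            np.full(cfg.n_salt_cations, SPECIES_CODES["cation"]),
            np.full(cfg.n_salt_anions, SPECIES_CODES["anion"]),
        ]
    ).astype(np.int64)
    valence_map = {SPECIES_CODES[k]: v for k, v in SPECIES_VALENCE.items()}
    charge = np.array([valence_map[int(s)] for s in species], dtype=np.int64)
    velocities = rng.normal(0.0, math.sqrt(params.T), size=(len(positions), 3))
    state = SystemState(np.mod(positions, box), velocities, charge, species)
    state.validate_neutrality()
    return state


@dataclass
class EquilibrationRecord:
    """Zero-field, tethered-head equilibration summary: the t̃ = 0 anchors."""

    frames: list  # list of position snapshots (n, 3)
    frame_times: np.ndarray
    kinetic_T: float
    mean_bond_length: float


def equilibrate(
    state: SystemState,
    cfg: RunConfig,
    geom: Geometry,
    params: ModelParams,
    lp: LangevinParams | None = None,
    ewald: EwaldParams | None = None,
    rng=None,
    record_every: int = 400,
    record_after: float = 0.5,
):
    """Zero-field dynamics with the head monomer frozen.

    Returns (state, EquilibrationRecord); snapshots are recorded every
    ``record_every`` steps once ``record_after`` (fraction) of the run has
    passed, providing the t̃ = 0 equilibrium ensemble.
    """
    lp = lp or LangevinParams(dt=0.005, zeta=params.zeta, T=params.T, seed=cfg.seed)
    rng = rng if rng is not None else run_rng(cfg.seed, 1)
    calc = ForceCalculator(
        geom, params, state.charge_valence, state.n_monomers, field=FieldSpec(0.0), ewald=ewald
    )
    mobile = np.ones(state.n_beads, dtype=bool)
    mobile[0] = False  # tether the head monomer
    state.velocities[0] = 0.0
    integ = LangevinIntegrator(lp, state.n_beads, mass=state.mass, mobile=mobile, rng=rng)
    box = np.asarray(geom.box)
    pos, vel = state.positions, state.velocities
    _, forces = calc.compute(pos)
    frames, ftimes = [], []
    n_steps = cfg.equilibration_steps
    first_record = int(record_after * n_steps)
    temp_acc, temp_n, bond_acc = 0.0, 0, 0.0
    nm = state.n_monomers
    for s in range(1, n_steps + 1):
        forces = integ.step(pos, vel, forces, calc.compute)
        np.mod(pos, box, out=pos)
        if s >= first_record and s % record_every == 0:
            frames.append(pos.copy())
            ftimes.append(s * lp.dt)
            temp_acc += kinetic_temperature(vel, mobile=mobile)
            bonds = pos[1:nm] - pos[: nm - 1]
            bonds -= box * np.round(bonds / box)
            bond_acc += float(np.linalg.norm(bonds, axis=1).mean())
            temp_n += 1
    kT = temp_acc / max(temp_n, 1)
    if temp_n and abs(kT - params.T) > 0.05 * params.T:
        warnings.warn(f"equilibration thermostat off target: <T>={kT:.3f}", RuntimeWarning)
    rec = EquilibrationRecord(
        frames=frames,
        frame_times=np.asarray(ftimes),
        kinetic_T=kT,
        mean_bond_length=bond_acc / max(temp_n, 1),
    )
    return state, rec


def run_translocation(
    state: SystemState,
    cfg: RunConfig,
    geom: Geometry,
    params: ModelParams,
    lp: LangevinParams | None = None,
    ewald: EwaldParams | None = None,
    rng=None,
    barrier: BarrierSpec | None = None,
) -> TranslocationResult:
    """Field on, tether off: integrate until the last monomer exits the pore.

    The first-passage time τ is the first instant every monomer sits beyond
    the channel exit plane, located by linear interpolation of the trailing
    monomer's z between the bracketing steps.  Hitting ``max_steps`` yields
    an incomplete result (completed=False), never a silent drop.
    """
    lp = lp or LangevinParams(dt=dt_for_field(cfg.E), zeta=params.zeta, T=params.T, seed=cfg.seed)
    rng = rng if rng is not None else run_rng(cfg.seed, 2)
    barrier = barrier or BarrierSpec()
    calc = ForceCalculator(
        geom,
        params,
        state.charge_valence,
        state.n_monomers,
        field=FieldSpec(cfg.E),
        ewald=ewald,
        barrier=barrier,
    )
    integ = LangevinIntegrator(lp, state.n_beads, mass=state.mass, rng=rng)
    box = np.asarray(geom.box)
    pos, vel = state.positions, state.velocities
    _, forces = calc.compute(pos)
    nm = state.n_monomers
    frames = [pos.copy()]
    ftimes = [0.0]
    tau = None
    z_exit = geom.z_exit
    zmin_prev = float(pos[:nm, 2].min())
    for s in range(1, cfg.max_steps + 1):
        forces = integ.step(pos, vel, forces, calc.compute)
        np.mod(pos, box, out=pos)
        zmin = float(pos[:nm, 2].min())
        if s % cfg.save_every == 0:
            frames.append(pos.copy())
            ftimes.append(s * lp.dt)
        if zmin > z_exit:
            frac = 1.0
            if zmin_prev <= z_exit and zmin > zmin_prev:
                frac = (z_exit - zmin_prev) / (zmin - zmin_prev)
            tau = (s - 1 + frac) * lp.dt
            if ftimes[-1] < s * lp.dt:
                frames.append(pos.copy())
                ftimes.append(s * lp.dt)
            break
        zmin_prev = zmin
    completed = tau is not None
    traj = Trajectory(
        times=np.asarray(ftimes),
        positions=np.asarray(frames),
        species=state.species,
        charge_valence=state.charge_valence,
        box=box,
        n_monomers=nm,
        attrs={
            "tau": tau,
            "completed": completed,
            "seed": cfg.seed,
            "dt": lp.dt,
            "E": cfg.E,
            "N": cfg.N,
        },
    )
    return TranslocationResult(tau=tau, completed=completed, trajectory=traj, seed=cfg.seed, dt=lp.dt)
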