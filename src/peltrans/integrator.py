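"""Langevin dynamics integration.

The equation of motion m r̈ = −ζ ṙ − ∇U + Z e E⃗ + η is discretized with
the Grønbech-Jensen/Farago (GJF) scheme, a Verlet-family method whose
configurational sampling is correct to all orders in the time step for
linear forces and which tolerates the upper end of the dt range used here
(0.0001–0.005 τ_u).  The noise obeys the fluctuation–dissipation relation
⟨η_i(t)·η_j(t′)⟩ = 6 k_B T ζ δ_ij δ(t−t′); in discrete form each impulse
component is Gaussian with variance 2 ζ k_B T Δt.  In the ζ → 0, zero-noise
limit the scheme reduces exactly to velocity Verlet (NVE).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import SystemState

__all__ = ["LangevinParams", "LangevinIntegrator", "step", "kinetic_temperature", "dt_for_field", "run_rng"]


class BlowUpError(RuntimeError):
    pass


@dataclass(frozen=True)
class LangevinParams:
    """Time step, friction, temperature and RNG seed for one run."""

    dt: float = 0.005
    zeta: float = 1.0
    T: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1.0e-4 <= self.dt <= 5.0e-3):
            raise ValueError(f"dt must lie in [0.0001, 0.005] tau_u, got {self.dt}")
        if self.zeta < 0.0 or self.T < 0.0:
            raise ValueError("zeta and T must be nonnegative")


def dt_for_field(E: float) -> float:
    """Default time-step schedule: stronger driving fields use smaller dt."""
    if E <= 1.0:
        return 0.005
    if E <= 10.0:
        return 0.001
    return 0.0005


def run_rng(master_seed: int, run_index: int = 0) -> np.random.Generator:
    """Independent, reproducible random stream for run ``run_index``."""
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(run_index,)))


class LangevinIntegrator:
    """GJF stepper over plain position/velocity arrays.

    ``mobile`` is a boolean mask; immobile beads (e.g. the tethered head
    monomer during equilibration) are never updated.  The stepper owns its
    random stream, so a given (seed, configuration) pair reproduces the
    trajectory bit-for-bit on one platform.
    """

    def __init__(self, lp: LangevinParams, n_beads: int, mass: float = 1.0, mobile=None, rng=None):
        self.lp = lp
        self.mass = float(mass)
        self.mobile = np.ones(n_beads, dtype=bool) if mobile is None else np.asarray(mobile, dtype=bool)
        self.rng = rng if rng is not None else np.random.default_rng(lp.seed)
        dt, zeta, m = lp.dt, lp.zeta, self.mass
        self._b = 1.0 / (1.0 + zeta * dt / (2.0 * m))
        self._a = (1.0 - zeta * dt / (2.0 * m)) * self._b
        self._noise_std = np.sqrt(2.0 * zeta * lp.T * dt)
        self._dt = dt

    def step(self, positions, velocities, forces, force_fn):
        """Advance one dt in place; returns the forces at the new positions.

        ``force_fn(positions) -> (energy, forces)`` is evaluated once, at
        the updated positions.
        """
        dt, m = self._dt, self.mass
        mob = self.mobile
        beta = np.zeros_like(positions)
        beta[mob] = self.rng.normal(0.0, self._noise_std, size=(int(mob.sum()), 3))
        positions[mob] += (
            self._b * dt * velocities[mob]
            + self._b * dt * dt / (2.0 * m) * forces[mob]
            + self._b * dt / (2.0 * m) * beta[mob]
        )
        if not np.all(np.isfinite(positions)):
            bad = int(np.argwhere(~np.isfinite(positions))[0, 0])
            raise BlowUpError(f"non-finite coordinate for bead {bad} at dt={dt}")
        _, new_forces = force_fn(positions)
        velocities[mob] = (
            self._a * velocities[mob]
            + dt / (2.0 * m) * (self._a * forces[mob] + new_forces[mob])
            + self._b / m * beta[mob]
        )
        return new_forces


def step(state: SystemState, forces: np.ndarray, lp: LangevinParams, force_fn, integrator=None):
    """One-shot functional stepping interface over a :class:`SystemState`.

    For long runs construct a :class:`LangevinIntegrator` once and reuse it
    (it owns the RNG stream); this wrapper builds a fresh one, which is
    convenient for short deterministic tests.
    """
    integ = integrator or LangevinIntegrator(lp, state.n_beads, mass=state.mass)
    new_forces = integ.step(state.positions, state.velocities, forces, force_fn)
    return state, new_forces


def kinetic_temperature(state_or_velocities, mass: float = 1.0, mobile=None) -> float:
    """Instantaneous kinetic temperature 2·E_kin/(3·n_mobile·k_B)."""
    if isinstance(state_or_velocities, SystemState):
        v = state_or_velocities.velocities
        mass = state_or_velocities.mass
    else:
        v = np.asarray(state_or_velocities, dtype=np.float64)
    if mobile is not None:
        v = v[np.asarray(mobile, dtype=bool)]
    if len(v) < 1:
        raise ValueError("need at least one mobile bead")
    return float(mass * np.sum(v * v) / (3.0 * len(v)))
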