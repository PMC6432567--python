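"""Coarse-grained force-field definitions for a bead-spring polyelectrolyte.

The model is the standard one for charged polymers in implicit solvent:
purely repulsive (WCA) excluded volume between beads and between beads and
the membrane wall, harmonic springs along the chain backbone, and Coulomb
interactions between all charged beads with the electrostatic strength set
by the Bjerrum length ``lambda_B`` (the separation at which two unit
charges interact with energy k_B T).  All quantities are in reduced units:
length σ, mass m, energy k_B T, charge e, time τ_u = σ√(m/k_B T).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "ModelParams",
    "SystemState",
    "BondTopology",
    "SPECIES_CODES",
    "wca_pair",
    "bond_pair",
    "coulomb_pair_bare",
]

#: integer codes used in arrays; labels used at the API surface
SPECIES_CODES = {"monomer": 0, "counterion": 1, "cation": 2, "anion": 3, "wall": 4}
SPECIES_LABELS = {v: k for k, v in SPECIES_CODES.items()}

#: default valence per species (wall beads are neutral)
SPECIES_VALENCE = {"monomer": -1, "counterion": +1, "cation": +1, "anion": -1, "wall": 0}


@dataclass(frozen=True)
class ModelParams:
    """Force-field parameter bundle (reduced units).

    Defaults are the study values: bead–bead WCA (σ_bb, ε_bb) = (1.0, 1.2),
    bead–wall WCA (σ_bw, ε_bw) = (1.5, 2.5), harmonic bonds with
    k = 600 k_BT/σ² and r0 = 1.0σ, Bjerrum length λ_B = 3.0σ, friction
    ζ = 1.0 m/τ_u and temperature T = 1.0.
    """

    sigma_bb: float = 1.0
    eps_bb: float = 1.2
    sigma_bw: float = 1.5
    eps_bw: float = 2.5
    k_bond: float = 600.0
    r0: float = 1.0
    lambda_B: float = 3.0
    zeta: float = 1.0
    T: float = 1.0
    #: intrachain short-range exclusions, in bonds: chain neighbors up to
    #: excl_lj (excl_coul) bonds apart skip the WCA (Coulomb) pair term.
    #: Defaults: directly bonded beads interact through the stiff spring
    #: alone (no WCA on top), while the Coulomb interaction couples every
    #: charged pair — this reproduces the equilibrium contour length
    #: (mean bond ≈ 1.008σ for k = 600, λ_B = 3); chain statistics are
    #: insensitive to the choice
    excl_lj: int = 1
    excl_coul: int = 0

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if name in ("excl_lj", "excl_coul"):
                if not 0 <= int(value) <= 3:
                    raise ValueError(f"ModelParams.{name} must be in 0..3, got {value!r}")
                continue
            if not np.isfinite(value) or value <= 0.0:
                raise ValueError(f"ModelParams.{name} must be strictly positive, got {value!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown ModelParams keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class SystemState:
    """Microstate of all mobile beads.

    ``positions``/``velocities`` have shape (n, 3); ``charge_valence`` is an
    integer per bead (−1 monomer, +1 counterion/cation, −1 anion);
    ``species`` holds the integer species codes of :data:`SPECIES_CODES`.
    Monomers occupy indices ``0..n_monomers-1`` in chain order.
    """

    positions: np.ndarray
    velocities: np.ndarray
    charge_valence: np.ndarray
    species: np.ndarray
    mass: float = 1.0

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        self.charge_valence = np.ascontiguousarray(self.charge_valence, dtype=np.int64)
        self.species = np.ascontiguousarray(self.species, dtype=np.int64)
        n = len(self.positions)
        if self.positions.shape != (n, 3) or self.velocities.shape != (n, 3):
            raise ValueError("positions and velocities must have shape (n, 3)")
        if len(self.charge_valence) != n or len(self.species) != n:
            raise ValueError("charge_valence/species length mismatch")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite positions")

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def n_monomers(self) -> int:
        return int(np.sum(self.species == SPECIES_CODES["monomer"]))

    @property
    def net_charge(self) -> int:
        return int(self.charge_valence.sum())

    def validate_neutrality(self) -> None:
        if self.net_charge != 0:
            raise ValueError(f"system is not electroneutral: net charge {self.net_charge}e")

    def copy(self) -> "SystemState":
        return SystemState(
            self.positions.copy(),
            self.velocities.copy(),
            self.charge_valence.copy(),
            self.species.copy(),
            self.mass,
        )


@dataclass(frozen=True)
class BondTopology:
    """Linear chain connectivity: bonds (i, i+1) for i = 0..N−2."""

    bonds: np.ndarray  # (N-1, 2) int

    def __post_init__(self) -> None:
        b = np.ascontiguousarray(self.bonds, dtype=np.int64).reshape(-1, 2)
        object.__setattr__(self, "bonds", b)
        if len(b) and not (
            np.array_equal(b[:, 0], np.arange(len(b))) and np.array_equal(b[:, 1], np.arange(1, len(b) + 1))
        ):
            raise ValueError("bonds must form the single unbranched path (i, i+1)")

    @classmethod
    def linear_chain(cls, n_monomers: int) -> "BondTopology":
        if n_monomers < 1:
            raise ValueError("need at least one monomer")
        i = np.arange(n_monomers - 1)
        return cls(np.column_stack([i, i + 1]))

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)


# ---------------------------------------------------------------------------
# pair potentials (scalar reference forms; the simulation kernels inline them)

_WCA_CUT_FACTOR = 2.0 ** (1.0 / 6.0)


def wca_pair(r, sigma: float, eps: float):
    """Purely repulsive shifted-truncated LJ (WCA) energy and radial force.

    U(r) = 4ε[(σ/r)^12 − (σ/r)^6 + 1/4] for r ≤ 2^(1/6)σ, 0 beyond; the
    radial force is −dU/dr (positive = repulsive).  Both vanish continuously
    at the cutoff.
    """
    r = np.asarray(r, dtype=np.float64)
    if np.any(r <= 0.0):
        raise ValueError("wca_pair requires r > 0")
    sr6 = (sigma / r) ** 6
    inside = r <= _WCA_CUT_FACTOR * sigma
    energy = np.where(inside, 4.0 * eps * (sr6 * sr6 - sr6 + 0.25), 0.0)
    force = np.where(inside, 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r, 0.0)
    if energy.ndim == 0:
        return float(energy), float(force)
    return energy, force


def bond_pair(r, params: ModelParams):
    """Harmonic bond energy (k/2)(r−r0)² and radial force −k(r−r0)."""
    r = np.asarray(r, dtype=np.float64)
    if np.any(r < 0.0):
        raise ValueError("bond_pair requires r >= 0")
    dr = r - params.r0
    energy = 0.5 * params.k_bond * dr * dr
    force = -params.k_bond * dr
    if energy.ndim == 0:
        return float(energy), float(force)
    return energy, force


def coulomb_pair_bare(r, Zi: float, Zj: float, lambda_B: float) -> float:
    """Bare (non-periodic) Coulomb energy k_BT·λ_B·Z_i·Z_j/r.

    This is the reference form used by the direct-sum oracle and unit
    tests; the simulation itself uses the periodic Ewald sum.
    """
    r = np.asarray(r, dtype=np.float64)
    if np.any(r <= 0.0):
        raise ValueError("coulomb_pair_bare requires r > 0")
    energy = lambda_B * Zi * Zj / r
    if energy.ndim == 0:
        return float(energy)
    return energy
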