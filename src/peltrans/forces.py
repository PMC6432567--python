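"""Total conservative force assembly.

Combines bead–bead WCA, bead–wall WCA, harmonic bonds, periodic Coulomb
(Ewald), the in-pore driving field, and (during a translocation run) the
one-way exit barrier felt by the head monomer.  Wall beads are immobile
scaffolding: they exert forces on mobile beads but receive no update, and
wall–wall interactions are skipped entirely.

The reported potential energy covers all conservative terms; the in-pore
field is a step-function force (uniform only inside the channel), whose potential
is discontinuous at the channel boundary and is therefore not folded into
the energy bookkeeping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .electrostatics import EwaldParams
from .geometry import FieldSpec, Geometry
from .model import BondTopology, ModelParams, SystemState

__all__ = ["ForceCalculator", "total_conservative_force", "SingularConfigurationError"]

#: beads closer than this are a singular configuration
HARD_FLOOR = 1.0e-6


class SingularConfigurationError(RuntimeError):
    pass


def _build_wall_grid(geom: Geometry, target_cell: float = 2.0):
    """Static 2D (x, y) bin structure over the wall beads, CSR layout."""
    lx, ly = geom.box[0], geom.box[1]
    ncx = max(1, int(lx / target_cell))
    ncy = max(1, int(ly / target_cell))
    csx, csy = lx / ncx, ly / ncy
    w = geom.wall_beads
    if len(w) == 0:
        return np.zeros(2, dtype=np.int64), np.zeros(0, dtype=np.int64), 1, 1, lx, ly
    cx = (np.mod(w[:, 0], lx) / csx).astype(np.int64) % ncx
    cy = (np.mod(w[:, 1], ly) / csy).astype(np.int64) % ncy
    cell = cx * ncy + cy
    order = np.argsort(cell, kind="stable")
    counts = np.bincount(cell, minlength=ncx * ncy)
    start = np.zeros(ncx * ncy + 1, dtype=np.int64)
    np.cumsum(counts, out=start[1:])
    return start, order.astype(np.int64), ncx, ncy, csx, csy


@dataclass
class BarrierSpec:
    """One-way exit barrier: repulsive WCA plane seen by the head monomer.

    The plane sits at z_exit − 2^(1/6)σ so the repulsion switches on
    exactly when the head monomer dips below the exit plane, diverging one
    bead diameter into the channel — it can never re-thread.
    """

    sigma: float = 1.0
    eps: float = 1.2


class ForceCalculator:
    """Precomputed force/energy evaluator for one system composition.

    Holds the wall grid, resolved Ewald parameters, and the k-vector table;
    ``compute(positions)`` returns (energy, forces) for mobile beads.
    """

    def __init__(
        self,
        geom: Geometry,
        params: ModelParams,
        charge_valence: np.ndarray,
        n_monomers: int,
        field: FieldSpec | None = None,
        ewald: EwaldParams | None = None,
        barrier: BarrierSpec | None = None,
        excl_lj: int | None = None,
        excl_coul: int | None = None,
    ):
        self.geom = geom
        self.params = params
        self.excl_lj = params.excl_lj if excl_lj is None else int(excl_lj)
        self.excl_coul = params.excl_coul if excl_coul is None else int(excl_coul)
        self.q = np.ascontiguousarray(charge_valence, dtype=np.float64)
        self.n_monomers = int(n_monomers)
        self.field = field if field is not None else FieldSpec(0.0)
        ewald = ewald if ewald is not None else EwaldParams()
        self.resolved = ewald.resolve(
            geom.box, int(np.sum(self.q != 0)), float(np.sum(self.q**2)), params.lambda_B
        )
        self._nvecs = self.resolved.nvecs
        self._boxa = np.asarray(geom.box, dtype=np.float64)
        (
            self._wstart,
            self._witems,
            self._ncx,
            self._ncy,
            self._csx,
            self._csy,
        ) = _build_wall_grid(geom, target_cell=max(2.0, _kernels.WCA_CUT * params.sigma_bw))
        self._wall = np.ascontiguousarray(geom.wall_beads)
        self._wall_zmin = float(geom.wall_beads[:, 2].min()) if len(geom.wall_beads) else 0.0
        self._wall_zmax = float(geom.wall_beads[:, 2].max()) if len(geom.wall_beads) else 0.0
        self._e_self = -params.lambda_B * self.resolved.alpha / math.sqrt(math.pi) * float(
            np.sum(self.q**2)
        )
        self.barrier = barrier

    def compute(self, positions: np.ndarray, with_field: bool = True):
        """Energy and per-bead forces at the given (wrapped) positions."""
        p = self.params
        pos = np.ascontiguousarray(positions, dtype=np.float64)
        forces = np.zeros_like(pos)
        e_wca, e_real, min_r2 = _kernels.pair_forces(
            pos,
            self.q,
            self.n_monomers,
            self._boxa,
            p.lambda_B,
            self.resolved.alpha,
            self.resolved.r_cut,
            p.sigma_bb,
            p.eps_bb,
            forces,
            self.excl_lj,
            self.excl_coul,
        )
        if min_r2 < HARD_FLOOR * HARD_FLOOR:
            raise SingularConfigurationError(
                f"bead pair at separation {math.sqrt(min_r2):.2e} below hard floor {HARD_FLOOR}"
            )
        e_bond = _kernels.bond_forces(pos, self._boxa, self.n_monomers, p.k_bond, p.r0, forces)
        e_wall = 0.0
        if len(self._wall):
            e_wall = _kernels.wall_forces(
                pos,
                self._wall,
                self._wstart,
                self._witems,
                self._ncx,
                self._ncy,
                self._csx,
                self._csy,
                self._boxa,
                p.sigma_bw,
                p.eps_bw,
                self._wall_zmin,
                self._wall_zmax,
                forces,
            )
        e_recip = _kernels.kspace_forces(
            pos, self.q, self._boxa, p.lambda_B, self.resolved.alpha, self._nvecs, forces
        )
        if with_field and self.field.E > 0.0:
            _kernels.field_forces(
                pos,
                self.q,
                self._boxa,
                self.field.E,
                self.geom.pore_axis_xy[0],
                self.geom.pore_axis_xy[1],
                self.geom.pore_radius,
                self.geom.z_entrance,
                self.geom.z_exit,
                forces,
            )
        e_barrier = 0.0
        if self.barrier is not None:
            z_plane = self.geom.z_exit - _kernels.WCA_CUT * self.barrier.sigma
            e_barrier, fz = _kernels.barrier_force(
                pos[0, 2], z_plane, self.barrier.sigma, self.barrier.eps
            )
            forces[0, 2] += fz
        energy = e_wca + e_real + e_recip + self._e_self + e_bond + e_wall + e_barrier
        return energy, forces


def total_conservative_force(
    state: SystemState,
    topo: BondTopology,
    geom: Geometry,
    field: FieldSpec,
    params: ModelParams,
    ewald: EwaldParams | None = None,
) -> np.ndarray:
    """Per-bead sum of all conservative forces plus the in-pore field force.

    Convenience wrapper over :class:`ForceCalculator` (which amortizes the
    wall grid and Ewald setup across many calls).  Internal (non-wall,
    non-field) forces sum to zero by Newton's third law.
    """
    if topo.n_bonds != max(state.n_monomers - 1, 0):
        raise ValueError("topology does not match the monomer count")
    calc = ForceCalculator(
        geom, params, state.charge_valence, state.n_monomers, field=field, ewald=ewald
    )
    pos = np.mod(state.positions, np.asarray(geom.box))
    return calc.compute(pos)[1]
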