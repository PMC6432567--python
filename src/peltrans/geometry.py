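"""Membrane wall, pore geometry, and region bookkeeping.

The membrane is four layers of immobile beads on a triangular (hexagonal)
lattice spanning the full x–y cross-section of a periodic box, with a
cylindrical channel of radius 2.25σ and length 4.5σ punched through it
along z.  The wall divides space into the cis compartment (region I,
z < z_entrance), the pore interval (region II), and the trans compartment
(region III, z > z_exit).  The driving electric field −E ẑ exists only
inside the cylindrical channel volume; the chain monomers carry valence −1,
so the driving force on them points toward +z and the chain exits on the
trans (high-z) side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Geometry", "FieldSpec", "build_wall", "classify_region", "in_pore"]

#: lattice constant of the wall; the printed box cross-section
#: (48.0 × 49.36 = 57·√3/2) is only commensurate with a = 1.0σ
LATTICE_A = 1.0

DEFAULT_BOX = (48.0, 49.36, 200.0)
DEFAULT_PORE_RADIUS = 2.25
DEFAULT_PORE_LENGTH = 4.5
DEFAULT_LAYERS = 4


@dataclass(frozen=True)
class Geometry:
    """Static environment: periodic box, immobile wall beads, pore."""

    box: tuple
    wall_beads: np.ndarray  # (n_wall, 3)
    pore_radius: float
    pore_length: float
    pore_axis_xy: tuple  # (x0, y0) of the channel axis
    z_entrance: float  # cis-side opening
    z_exit: float  # trans-side opening

    def __post_init__(self) -> None:
        object.__setattr__(self, "box", tuple(float(b) for b in self.box))
        object.__setattr__(
            self, "wall_beads", np.ascontiguousarray(self.wall_beads, dtype=np.float64).reshape(-1, 3)
        )
        if not np.isclose(self.z_exit - self.z_entrance, self.pore_length):
            raise ValueError("z_exit - z_entrance must equal pore_length")

    @property
    def n_wall(self) -> int:
        return len(self.wall_beads)

    def to_xyz(self, path) -> None:
        """Export the wall beads as an XYZ snapshot for visualization."""
        from . import trajio

        trajio.write_xyz_frame(path, self.wall_beads, ["W"] * self.n_wall, comment="membrane wall")


@dataclass(frozen=True)
class FieldSpec:
    """Uniform electric field of strength E ≥ 0 along −ẑ inside the channel.

    The force on a bead of valence Z inside the channel is −Z·E ẑ (so the
    −1 monomers are pushed toward +z); outside the channel the field is
    exactly zero (step function, no taper).
    """

    E: float = 0.0

    def __post_init__(self) -> None:
        if self.E < 0.0:
            raise ValueError("field strength E must be >= 0")

    def force_z(self, valence: float) -> float:
        return -valence * self.E


def build_wall(
    box=DEFAULT_BOX,
    pore_radius: float = DEFAULT_PORE_RADIUS,
    pore_length: float = DEFAULT_PORE_LENGTH,
    layers: int = DEFAULT_LAYERS,
    interaction_cutoff: float = 2.0 ** (1.0 / 6.0) * 1.5,
) -> Geometry:
    """Construct the membrane wall and punch the cylindrical pore.

    Each layer is a triangular lattice with constant 1.0σ (alternate rows
    offset by a/2); ``layers`` planes are stacked so the outermost faces
    span ``pore_length`` in z, centered at the box mid-plane.  Beads whose
    axial distance from the pore axis is below ``pore_radius`` are removed
    (the punch), and interior beads buried farther than
    ``interaction_cutoff`` from both faces and from the channel surface are
    dropped since no mobile bead can ever reach them.

    Raises ``ValueError`` if the box cross-section is not commensurate with
    the lattice.
    """
    if layers < 1:
        raise ValueError("layers must be >= 1")
    box = tuple(float(b) for b in box)
    a = LATTICE_A
    row_dy = a * np.sqrt(3.0) / 2.0
    n_cols = box[0] / a
    n_rows = box[1] / row_dy
    if abs(n_cols - round(n_cols)) > 1e-6 * max(1.0, n_cols):
        raise ValueError(f"box x = {box[0]} not commensurate with lattice constant {a}")
    if abs(n_rows - round(n_rows)) > 2e-3 * max(1.0, n_rows):
        raise ValueError(f"box y = {box[1]} not commensurate with row spacing {row_dy:.4f}")
    n_cols, n_rows = int(round(n_cols)), int(round(n_rows))

    cols = np.arange(n_cols) * a
    rows = np.arange(n_rows) * row_dy
    xx = cols[None, :] + (np.arange(n_rows)[:, None] % 2) * (a / 2.0)
    yy = np.broadcast_to(rows[:, None], xx.shape)
    layer_xy = np.column_stack([xx.ravel(), yy.ravel()])

    z_mid = box[2] / 2.0
    z_entrance = z_mid - pore_length / 2.0
    z_exit = z_mid + pore_length / 2.0
    if layers == 1:
        z_layers = np.array([z_mid])
    else:
        z_layers = np.linspace(z_entrance, z_exit, layers)

    axis_xy = (box[0] / 2.0, box[1] / 2.0)
    beads = []
    for il, zl in enumerate(z_layers):
        pts = np.column_stack([layer_xy, np.full(len(layer_xy), zl)])
        # punch: remove beads inside the channel radius (minimum-image in x, y)
        dx = _min_image_1d(pts[:, 0] - axis_xy[0], box[0])
        dy = _min_image_1d(pts[:, 1] - axis_xy[1], box[1])
        rho = np.hypot(dx, dy)
        pts = pts[rho >= pore_radius]
        rho = rho[rho >= pore_radius]
        # burial: keep a bead only if a mobile bead could reach it — the two
        # face layers stay whole, interior layers keep only the channel lining
        is_face = il == 0 or il == len(z_layers) - 1
        if is_face:
            beads.append(pts)
        else:
            beads.append(pts[rho <= pore_radius + interaction_cutoff])
    wall = np.vstack(beads) if beads else np.empty((0, 3))
    return Geometry(
        box=box,
        wall_beads=wall,
        pore_radius=pore_radius,
        pore_length=pore_length,
        pore_axis_xy=axis_xy,
        z_entrance=z_entrance,
        z_exit=z_exit,
    )


def _min_image_1d(d, L):
    return d - L * np.round(d / L)


def classify_region(z, geom: Geometry):
    """Map z to region label: 'I' (cis), 'II' (pore, closed interval), 'III' (trans).

    The pore interval is closed on both ends (region II wins ties), and the
    classification uses z only: the wall makes off-axis positions at channel
    z sterically inaccessible to mobile beads.
    """
    z = np.asarray(z, dtype=np.float64)
    out = np.where(z < geom.z_entrance, "I", np.where(z > geom.z_exit, "III", "II"))
    if out.ndim == 0:
        return str(out)
    return out


def region_codes(z, geom: Geometry) -> np.ndarray:
    """Integer version of :func:`classify_region`: 0 = I, 1 = II, 2 = III."""
    z = np.asarray(z, dtype=np.float64)
    return np.where(z < geom.z_entrance, 0, np.where(z > geom.z_exit, 2, 1)).astype(np.int64)


def in_pore(position, geom: Geometry):
    """True iff the position is inside the cylindrical channel volume."""
    p = np.asarray(position, dtype=np.float64)
    squeeze = p.ndim == 1
    p = np.atleast_2d(p)
    dx = _min_image_1d(p[:, 0] - geom.pore_axis_xy[0], geom.box[0])
    dy = _min_image_1d(p[:, 1] - geom.pore_axis_xy[1], geom.box[1])
    ok = (
        (p[:, 2] >= geom.z_entrance)
        & (p[:, 2] <= geom.z_exit)
        & (np.hypot(dx, dy) <= geom.pore_radius)
    )
    return bool(ok[0]) if squeeze else ok
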