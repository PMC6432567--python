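"""Analysis of translocation ensembles.

Covers first-passage statistics (mean, distribution width at 1/e of peak),
scaling-exponent fits (⟨τ⟩ ∝ N^α, ⟨τ⟩ ∝ E^−δ with three field regimes, MSD
of the translocation coordinate ∝ t^β on 0.5 ≤ t̃ ≤ 1), region-resolved
chain conformation on the normalized-time grid t̃ = t/τ, Manning-style ion
condensation bookkeeping, and the spatial probability/density profiles.

Every per-run curve is linearly interpolated onto a common 101-point t̃
grid (spacing 0.01, matching the time-window width used for the spatial
profiles) before ensemble averaging.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .geometry import Geometry, region_codes
from .trajio import Trajectory

__all__ = [
    "T_GRID",
    "EnsembleCurves",
    "ScalingFit",
    "CondensationRecord",
    "TauStats",
    "translocation_stats",
    "fit_alpha",
    "fit_delta",
    "region_rg",
    "chain_end_positions",
    "monomer_counts",
    "translocation_coordinate",
    "translocation_msd",
    "condensation_counts",
    "manning_reference",
    "effective_line_density",
    "z_probability_profiles",
    "peak_to_wall_distance",
    "density_map_yz",
    "radius_of_gyration",
]

#: normalized-time grid t̃ ∈ [0, 1], 101 points (spacing 0.01)
T_GRID = np.linspace(0.0, 1.0, 101)

REGIONS = ("I", "II", "III")


@dataclass
class EnsembleCurves:
    """Mean ± spread of one observable on the t̃ grid."""

    t_grid: np.ndarray
    mean: np.ndarray
    spread: np.ndarray
    n_runs: int

    def __post_init__(self) -> None:
        self.t_grid = np.asarray(self.t_grid, dtype=np.float64)
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.spread = np.asarray(self.spread, dtype=np.float64)

    def to_frame(self, name: str = "value"):
        """Tidy table: one row per t̃ grid point."""
        import pandas as pd

        return pd.DataFrame(
            {"t_norm": self.t_grid, "mean": self.mean, "spread": self.spread, "observable": name}
        )


@dataclass(frozen=True)
class ScalingFit:
    """Log–log power-law fit: exponent, regression stderr, window, regime."""

    exponent: float
    stderr: float
    window: tuple
    regime: str = ""


@dataclass
class CondensationRecord:
    """Per-region condensed-ion counts and the neutralized charge fraction."""

    nc_plus: dict  # region -> count of condensed +1 ions
    nc_minus: dict  # region -> count of condensed −1 ions
    Qc: float  # e·Nc(+1) − e·Nc(−1)
    fraction: float  # |Qc / (N e)|


@dataclass
class TauStats:
    mean: float
    width: float
    ratio: float
    grid: np.ndarray
    density: np.ndarray


def translocation_stats(taus, n_grid: int = 4001) -> TauStats:
    """Mean translocation time and distribution width at 1/e of the peak.

    P(τ) is estimated by a Gaussian kernel density (Silverman bandwidth);
    the width w is the measure of the region where P exceeds peak/e, and
    the ratio w/⟨τ⟩ measures the relative sharpness of the distribution.
    """
    taus = np.asarray(taus, dtype=np.float64)
    if len(taus) < 2:
        raise ValueError("need at least 2 translocation-time samples")
    if len(taus) < 30:
        warnings.warn("fewer than 30 samples: distribution width is noisy", RuntimeWarning)
    mean = float(taus.mean())
    if np.allclose(taus, taus[0]):
        return TauStats(mean, 0.0, 0.0, np.array([taus[0]]), np.array([np.inf]))
    kde = stats.gaussian_kde(taus, bw_method="silverman")
    bw = math.sqrt(float(kde.covariance[0, 0]))
    grid = np.linspace(taus.min() - 4 * bw, taus.max() + 4 * bw, n_grid)
    dens = kde(grid)
    thresh = dens.max() / math.e
    dx = grid[1] - grid[0]
    width = float(np.sum(dens > thresh) * dx)
    return TauStats(mean, width, width / mean, grid, dens)


def _loglog_fit(x, y, window, regime="") -> ScalingFit:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if np.any(y <= 0) or np.any(x <= 0):
        raise ValueError("power-law fit requires positive data")
    res = stats.linregress(np.log(x), np.log(y))
    stderr = float(res.stderr) if len(x) > 2 else 0.0
    return ScalingFit(exponent=float(res.slope), stderr=stderr, window=window, regime=regime)


def fit_alpha(mean_tau_by_N: dict, window=None) -> ScalingFit:
    """Chain-length scaling ⟨τ⟩ ∝ N^α over the given window of N."""
    items = sorted(mean_tau_by_N.items())
    if window is not None:
        items = [(n, t) for n, t in items if window[0] <= n <= window[1]]
    else:
        window = (items[0][0], items[-1][0])
    if len(items) < 2:
        raise ValueError("need at least 2 chain lengths in the fit window")
    N = [n for n, _ in items]
    tau = [t for _, t in items]
    return _loglog_fit(N, tau, tuple(window), regime="")


DELTA_REGIMES = (("weak", 0.0, 1.0), ("intermediate", 1.0, 10.0), ("strong", 10.0, math.inf))


def fit_delta(mean_tau_by_E: dict, regimes=DELTA_REGIMES) -> list:
    """Field scaling ⟨τ⟩ ∝ E^−δ, one fit per regime (δ = −slope).

    The three default regimes are the weak (E < 1), intermediate
    (1 < E < 10) and strong (E > 10) field windows.  Boundary points are
    shared by the adjacent regimes.  Regimes with fewer than two points are
    skipped with a warning.
    """
    fits = []
    for name, lo, hi in regimes:
        pts = sorted((e, t) for e, t in mean_tau_by_E.items() if lo <= e <= hi)
        if len(pts) < 2:
            warnings.warn(f"regime {name!r} has <2 field values; skipped", RuntimeWarning)
            continue
        f = _loglog_fit([e for e, _ in pts], [t for _, t in pts], (lo, hi), regime=name)
        fits.append(ScalingFit(exponent=-f.exponent, stderr=f.stderr, window=f.window, regime=name))
    return fits


# ---------------------------------------------------------------------------
# per-trajectory curves on the normalized-time grid


def _normalized_times(traj: Trajectory) -> np.ndarray:
    tau = traj.tau
    if tau is None:
        tau = traj.times[-1] if traj.times[-1] > 0 else 1.0
    return traj.times / tau


def _ensemble(curves: list, t_grid: np.ndarray) -> EnsembleCurves:
    arr = np.asarray(curves, dtype=np.float64)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN grid points stay NaN
        mean = np.nanmean(arr, axis=0)
        spread = np.nanstd(arr, axis=0)
    return EnsembleCurves(t_grid, mean, spread, n_runs=len(curves))


def _interp_curve(t_norm, values, t_grid):
    values = np.asarray(values, dtype=np.float64)
    good = np.isfinite(values)
    if good.sum() < 2:
        return np.full_like(t_grid, np.nan)
    out = np.interp(t_grid, t_norm[good], values[good], left=np.nan, right=np.nan)
    # NaN regions inside the run (e.g. empty region) propagate as missing
    inside = (t_grid >= t_norm[0]) & (t_grid <= t_norm[-1])
    nearest = np.searchsorted(t_norm, t_grid).clip(0, len(t_norm) - 1)
    out[inside & ~good[nearest]] = np.nan
    return out


def radius_of_gyration(points: np.ndarray) -> float:
    """Root-mean-square distance of a point set from its center of mass."""
    points = np.asarray(points, dtype=np.float64)
    if len(points) == 0:
        return float("nan")
    com = points.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((points - com) ** 2, axis=1))))


def region_rg(trajs, geom: Geometry, t_grid=T_GRID) -> dict:
    """Ensemble radius of gyration of the monomers in regions I, III and overall.

    Region membership uses the monomer z-coordinate; the chain coordinates
    are first unwrapped by bond walking so a chain straddling a periodic
    boundary is measured contiguously.  Frames with an empty region yield
    missing values, not zeros.
    """
    out = {key: [] for key in ("I", "III", "tot")}
    for traj in trajs:
        tn = _normalized_times(traj)
        vals = {key: [] for key in out}
        for f in range(traj.n_frames):
            chain = traj.unwrapped_chain(f)
            codes = region_codes(chain[:, 2], geom)
            vals["I"].append(radius_of_gyration(chain[codes == 0]))
            vals["III"].append(radius_of_gyration(chain[codes == 2]))
            vals["tot"].append(radius_of_gyration(chain))
        for key in out:
            out[key].append(_interp_curve(tn, vals[key], t_grid))
    return {key: _ensemble(v, t_grid) for key, v in out.items()}


def chain_end_positions(trajs, geom: Geometry, t_grid=T_GRID) -> dict:
    """⟨z1⟩, ⟨zN⟩ and ⟨z1 − zN⟩ relative to the exit plane (positive = trans)."""
    out = {"z1": [], "zN": [], "z1-zN": []}
    for traj in trajs:
        tn = _normalized_times(traj)
        chain0 = np.array([traj.unwrapped_chain(f)[:, 2] for f in range(traj.n_frames)])
        z1 = chain0[:, 0] - geom.z_exit
        zN = chain0[:, -1] - geom.z_exit
        out["z1"].append(_interp_curve(tn, z1, t_grid))
        out["zN"].append(_interp_curve(tn, zN, t_grid))
        out["z1-zN"].append(_interp_curve(tn, z1 - zN, t_grid))
    return {key: _ensemble(v, t_grid) for key, v in out.items()}


def monomer_counts(trajs, geom: Geometry, t_grid=T_GRID) -> dict:
    """N_m per region on the t̃ grid; N_m,III is the translocation coordinate."""
    out = {r: [] for r in REGIONS}
    for traj in trajs:
        tn = _normalized_times(traj)
        counts = {r: [] for r in REGIONS}
        for f in range(traj.n_frames):
            z = traj.positions[f, : traj.n_monomers, 2]
            codes = region_codes(z, geom)
            n1, n2, n3 = int((codes == 0).sum()), int((codes == 1).sum()), int((codes == 2).sum())
            if n1 + n2 + n3 != traj.n_monomers:
                raise RuntimeError("region counts do not sum to N (internal inconsistency)")
            counts["I"].append(n1)
            counts["II"].append(n2)
            counts["III"].append(n3)
        for r in REGIONS:
            out[r].append(_interp_curve(tn, counts[r], t_grid))
    return {r: _ensemble(v, t_grid) for r, v in out.items()}


def translocation_coordinate(traj: Trajectory, geom: Geometry):
    """(normalized times, N_m,III) series for one run."""
    tn = _normalized_times(traj)
    s = np.array(
        [int((region_codes(traj.positions[f, : traj.n_monomers, 2], geom) == 2).sum()) for f in range(traj.n_frames)],
        dtype=np.float64,
    )
    return tn, s


def translocation_msd(series, fit_window=(0.5, 1.0), t_grid=T_GRID):
    """Ensemble MSD of the translocation coordinate and its late-time exponent.

    ``series`` is a list of (t̃, s) pairs (from :func:`translocation_coordinate`
    or the synthetic generator).  Returns (EnsembleCurves of the MSD, β fit
    over the requested t̃ window).
    """
    if not (0.0 <= fit_window[0] < fit_window[1] <= 1.0):
        raise ValueError("fit window must lie inside [0, 1]")
    if len(series) < 10:
        raise ValueError("need at least 10 runs for the translocation-coordinate MSD")
    sq = []
    for tn, s in series:
        s = np.asarray(s, dtype=np.float64)
        sq.append(_interp_curve(np.asarray(tn), (s - s[0]) ** 2, t_grid))
    curves = _ensemble(sq, t_grid)
    mask = (t_grid >= fit_window[0]) & (t_grid <= fit_window[1]) & (t_grid > 0) & np.isfinite(curves.mean)
    fit = _loglog_fit(t_grid[mask], curves.mean[mask], tuple(fit_window), regime="late-time")
    return curves, fit


# ---------------------------------------------------------------------------
# ion condensation


def _min_image(d, box):
    return d - box * np.round(d / box)


def condensation_counts(
    positions: np.ndarray,
    charge_valence: np.ndarray,
    n_monomers: int,
    box,
    lambda_B: float,
    geom: Geometry | None = None,
) -> CondensationRecord:
    """Distance-criterion ion condensation bookkeeping for one frame.

    An ion is condensed when its minimum-image distance to the nearest
    monomer is below the Bjerrum length; it is attributed to the region of
    that nearest monomer (condensation is a chain-relative property).
    Q_c = e·Nc(+1) − e·Nc(−1) and fraction = |Q_c/(N e)|.
    """
    positions = np.asarray(positions, dtype=np.float64)
    box = np.asarray(box, dtype=np.float64)
    q = np.asarray(charge_valence)
    mono = positions[:n_monomers]
    ions = positions[n_monomers:]
    qi = q[n_monomers:]
    nc_plus = {r: 0 for r in REGIONS}
    nc_minus = {r: 0 for r in REGIONS}
    if len(ions):
        d = ions[:, None, :] - mono[None, :, :]
        d = _min_image(d, box)
        dist2 = np.einsum("ijk,ijk->ij", d, d)
        nearest = np.argmin(dist2, axis=1)
        condensed = dist2[np.arange(len(ions)), nearest] < lambda_B * lambda_B
        if geom is not None:
            codes = region_codes(mono[:, 2], geom)
        else:
            codes = np.zeros(n_monomers, dtype=np.int64)
        for i in np.nonzero(condensed)[0]:
            r = REGIONS[codes[nearest[i]]]
            if qi[i] > 0:
                nc_plus[r] += 1
            elif qi[i] < 0:
                nc_minus[r] += 1
    qc = float(sum(nc_plus.values()) - sum(nc_minus.values()))
    return CondensationRecord(
        nc_plus=nc_plus,
        nc_minus=nc_minus,
        Qc=qc,
        fraction=abs(qc) / n_monomers,
    )


def manning_reference(lambda_B: float) -> float:
    """Manning-condensation prediction for the residual line charge density, e/λ_B."""
    if lambda_B <= 0:
        raise ValueError("lambda_B must be positive")
    return 1.0 / lambda_B


def contour_length(chain: np.ndarray) -> float:
    """Sum of bond lengths of an (already unwrapped) chain."""
    return float(np.linalg.norm(np.diff(np.asarray(chain), axis=0), axis=1).sum())


def effective_line_density(
    positions: np.ndarray,
    charge_valence: np.ndarray,
    n_monomers: int,
    box,
    lambda_B: float,
    geom: Geometry | None = None,
):
    """Contour length ℓ and effective line charge density |(−Ne + Qc)/ℓ|.

    The bare chain charge −Ne is partially neutralized by the condensed-ion
    charge Qc; dividing by the instantaneous contour length gives the
    effective density the chain presents to its surroundings.
    """
    box = np.asarray(box, dtype=np.float64)
    steps = np.diff(np.asarray(positions[:n_monomers]), axis=0)
    steps = _min_image(steps, box)
    ell = float(np.linalg.norm(steps, axis=1).sum())
    rec = condensation_counts(positions, charge_valence, n_monomers, box, lambda_B, geom)
    density = abs(-n_monomers + rec.Qc) / ell
    return ell, density


# ---------------------------------------------------------------------------
# spatial distributions


def z_probability_profiles(
    trajs,
    geom: Geometry,
    windows=(0.0,),
    window_width: float = 0.01,
    bin_width: float = 0.5,
) -> dict:
    """Per-species normalized z-histograms within narrow t̃ windows.

    For each requested window [t̃, t̃+width] the monomer (P_m), counter-/
    cation (P_+1) and anion (P_−1) z-distributions are pooled over runs and
    normalized to unit area.  Windows that catch no frame are reported as
    missing (with a warning), never as zeros.
    """
    box = np.asarray(geom.box)
    edges = np.arange(0.0, box[2] + bin_width, bin_width)
    centers = 0.5 * (edges[1:] + edges[:-1])
    out = {}
    for w0 in windows:
        acc = {"m": np.zeros(len(centers)), "+1": np.zeros(len(centers)), "-1": np.zeros(len(centers))}
        n_frames = 0
        for traj in trajs:
            tn = _normalized_times(traj)
            sel = np.nonzero((tn >= w0) & (tn <= w0 + window_width))[0]
            q = np.asarray(traj.charge_valence)
            mono = np.zeros(len(q), dtype=bool)
            mono[: traj.n_monomers] = True
            for f in sel:
                z = np.mod(traj.positions[f, :, 2], box[2])
                acc["m"] += np.histogram(z[mono], bins=edges)[0]
                acc["+1"] += np.histogram(z[~mono & (q > 0)], bins=edges)[0]
                acc["-1"] += np.histogram(z[~mono & (q < 0)], bins=edges)[0]
                n_frames += 1
        if n_frames == 0:
            warnings.warn(f"no frames in t-window [{w0}, {w0 + window_width}]", RuntimeWarning)
            out[w0] = None
            continue
        profiles = {}
        for key, h in acc.items():
            total = h.sum()
            profiles[key] = h / (total * bin_width) if total > 0 else h
        out[w0] = {"z": centers, **profiles}
    return out


def peak_to_wall_distance(profile, geom: Geometry, species: str = "m", side: str = "cis") -> float:
    """Distance from the wall face to the species' distribution peak.

    ``side='cis'`` measures from the cis face (z_entrance) into the cis
    compartment; ``side='trans'`` from the exit plane into trans.
    """
    z = profile["z"]
    p = profile[species]
    if side == "cis":
        mask = z < geom.z_entrance
        zpk = z[mask][np.argmax(p[mask])]
        return float(geom.z_entrance - zpk)
    mask = z > geom.z_exit
    zpk = z[mask][np.argmax(p[mask])]
    return float(zpk - geom.z_exit)


def density_map_yz(
    trajs,
    geom: Geometry,
    window=(0.0, 0.01),
    cell: float = 1.0,
):
    """2D monomer number density on the (y, z) grid, integrated along x.

    Counts are normalized per frame (so values are monomers per cell per
    frame).  Returns (y_edges, z_edges, density[ny, nz]).
    """
    box = np.asarray(geom.box)
    y_edges = np.arange(0.0, box[1] + cell, cell)
    z_edges = np.arange(0.0, box[2] + cell, cell)
    h = np.zeros((len(y_edges) - 1, len(z_edges) - 1))
    n_frames = 0
    for traj in trajs:
        tn = _normalized_times(traj)
        sel = np.nonzero((tn >= window[0]) & (tn <= window[1]))[0]
        for f in sel:
            pos = traj.positions[f, : traj.n_monomers]
            h += np.histogram2d(
                np.mod(pos[:, 1], box[1]), np.mod(pos[:, 2], box[2]), bins=(y_edges, z_edges)
            )[0]
            n_frames += 1
    if n_frames:
        h /= n_frames
    return y_edges, z_edges, h
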