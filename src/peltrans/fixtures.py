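"""Synthetic ensembles with known ground truth.

These generators emulate the *statistical* structure the analysis stages
assume — single-peaked translocation-time samples whose median follows
c·N^α·E^−δ, monotone-on-average translocation-coordinate series with a
prescribed late-time MSD exponent, and particle frames with an exact number
of condensed ions — so every estimator can be validated without running
molecular dynamics.  They emulate no force-field physics.

Translocation times are drawn lognormal: positive support and a single
peak (near-Gaussian at small coefficient of variation), matching the
qualitative shape of simulated first-passage distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import SPECIES_CODES, SystemState

__all__ = ["SyntheticEnsembleSpec", "synth_tau_samples", "synth_s_trajectory", "synth_condensation_config"]


@dataclass(frozen=True)
class SyntheticEnsembleSpec:
    """Ground-truth exponents and ensemble layout for estimator tests.

    Defaults encode the reference behavior of the driven system: α between
    the weak- and strong-field values, the intermediate-field δ, and
    β = 2/α from the first-passage identity.
    """

    alpha_true: float = 1.40
    delta_true: float = 1.64
    beta_true: float = 2.0 / 1.40
    noise_cv: float = 0.10
    N_list: tuple = (64, 128, 256, 384)
    E_list: tuple = (2.0, 4.0, 8.0)
    n_runs: int = 200
    seed: int = 0
    prefactor: float = 50.0

    def __post_init__(self) -> None:
        if min(self.alpha_true, self.delta_true, self.beta_true) <= 0:
            raise ValueError("exponents must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")


def synth_tau_samples(spec: SyntheticEnsembleSpec) -> dict:
    """Lognormal τ samples per (N, E) with median c·N^α·E^−δ.

    The lognormal shape parameter is σ = √ln(1 + cv²), so the coefficient
    of variation equals ``spec.noise_cv``; cv = 0 collapses every sample to
    the median.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(spec.seed)
    sigma = math.sqrt(math.log(1.0 + spec.noise_cv**2))
    out = {}
    for N in spec.N_list:
        for E in spec.E_list:
            median = spec.prefactor * N**spec.alpha_true * E ** (-spec.delta_true)
            if sigma == 0.0:
                out[(N, E)] = np.full(spec.n_runs, median)
            else:
                out[(N, E)] = median * np.exp(sigma * rng.standard_normal(spec.n_runs))
    return out


def synth_s_trajectory(N: int, beta_true: float, n_steps: int, seed: int, noise: float = 1.0):
    """Translocation-coordinate series s(t̃) from 1 to N with MSD ∝ t̃^β.

    The drift backbone is s(t̃) = 1 + (N−1)·t̃^(β/2), whose squared
    displacement is exactly (N−1)²·t̃^β; bounded zigzag noise (a reflected
    ±`noise` random walk, rounded to integers) mimics the diffusive jitter
    of a real translocation coordinate without disturbing the late-time
    scaling.  The final value is pinned to N.  With ``noise=0`` the exact
    continuous backbone is returned.
    """
    if beta_true <= 0:
        raise ValueError("beta_true must be positive")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, n_steps + 1)
    s = 1.0 + (N - 1) * t ** (beta_true / 2.0)
    if noise > 0:
        jit = np.cumsum(rng.choice([-1.0, 1.0], size=len(t)))
        bound = max(noise, 1.0)
        jit = bound * _reflect(jit / math.sqrt(len(t)) * 3.0)
        s = np.round(np.clip(s + jit, 1.0, N))
    s[0] = 1.0
    s[-1] = N
    return t, s


def _reflect(x):
    """Fold a series into [−1, 1] by reflection."""
    y = np.mod(x + 1.0, 4.0)
    return np.where(y < 2.0, y - 1.0, 3.0 - y)


def synth_condensation_config(
    n_condensed: int,
    n_free: int,
    lambda_B: float,
    seed: int,
    n_monomers: int = 32,
    box=(40.0, 40.0, 80.0),
):
    """Straight test chain plus ions at controlled distances.

    Exactly ``n_condensed`` ions sit closer than λ_B to their nearest
    monomer and ``n_free`` ions sit farther than λ_B from every monomer.
    Ion signs alternate (+1, −1, ...) within each group.  Returns
    (SystemState, box); velocities are zero — these frames exist for the
    analysis stages only.
    """
    box = np.asarray(box, dtype=np.float64)
    if n_monomers + 2.0 * (lambda_B + 3.0) > box[2] or 2.0 * (lambda_B + 3.0) > min(box[0], box[1]):
        raise ValueError("box too small for the requested configuration")
    rng = np.random.default_rng(seed)
    z0 = box[2] / 2.0 - n_monomers / 2.0
    chain = np.column_stack(
        [np.full(n_monomers, box[0] / 2.0), np.full(n_monomers, box[1] / 2.0), z0 + np.arange(n_monomers)]
    )
    ions = []
    for k in range(n_condensed):
        m = rng.integers(0, n_monomers)
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        r = lambda_B * (0.3 + 0.6 * rng.random())
        ions.append(chain[m] + r * u)
    attempts = 0
    while len(ions) < n_condensed + n_free:
        attempts += 1
        if attempts > 10000:
            raise RuntimeError("free-ion placement failed")
        cand = rng.random(3) * box
        d = chain - cand
        d -= box * np.round(d / box)
        if np.min(np.einsum("ij,ij->i", d, d)) > (1.1 * lambda_B) ** 2:
            ions.append(cand)
    positions = np.vstack([chain] + [np.asarray(ions).reshape(-1, 3)]) if ions else chain
    n_ions = len(positions) - n_monomers
    ion_signs = np.array([+1 if k % 2 == 0 else -1 for k in range(n_condensed)] + [
        +1 if k % 2 == 0 else -1 for k in range(n_free)
    ], dtype=np.int64)
    charge = np.concatenate([np.full(n_monomers, -1, dtype=np.int64), ion_signs])
    species = np.concatenate(
        [
            np.full(n_monomers, SPECIES_CODES["monomer"]),
            np.where(ion_signs > 0, SPECIES_CODES["counterion"], SPECIES_CODES["anion"]),
        ]
    ).astype(np.int64)
    state = SystemState(positions, np.zeros_like(positions), charge, species)
    return state, box
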