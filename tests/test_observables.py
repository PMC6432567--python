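"""Analysis-stage contracts, checked against closed forms and brute force."""

import math

import numpy as np
import pytest

from peltrans.fixtures import SyntheticEnsembleSpec, synth_s_trajectory, synth_tau_samples
from peltrans.geometry import build_wall
from peltrans.observables import (
    T_GRID,
    chain_end_positions,
    condensation_counts,
    density_map_yz,
    effective_line_density,
    fit_alpha,
    fit_delta,
    manning_reference,
    monomer_counts,
    peak_to_wall_distance,
    radius_of_gyration,
    region_rg,
    translocation_msd,
    translocation_stats,
    z_probability_profiles,
)
from peltrans.trajio import Trajectory


def make_traj(geom, monomer_z, times=None, tau=None, n_extra=0, extra_q=()):
    """Scripted trajectory: monomers at given z (on the pore axis), optional ions."""
    monomer_z = np.asarray(monomer_z, dtype=np.float64)  # (F, N)
    F, N = monomer_z.shape
    x0, y0 = geom.pore_axis_xy
    pos = np.zeros((F, N + n_extra, 3))
    pos[:, :N, 0] = x0
    pos[:, :N, 1] = y0
    pos[:, :N, 2] = monomer_z
    q = np.concatenate([np.full(N, -1), np.asarray(extra_q, dtype=np.int64)])
    species = np.concatenate([np.zeros(N, dtype=np.int64), np.full(n_extra, 1, dtype=np.int64)])
    times = np.arange(F, dtype=np.float64) if times is None else np.asarray(times)
    return Trajectory(
        times=times,
        positions=pos,
        species=species,
        charge_valence=q,
        box=np.asarray(geom.box),
        n_monomers=N,
        attrs={"tau": float(times[-1]) if tau is None else tau},
    )


class TestTranslocationStats:
    def test_gaussian_width_is_2root2_sigma(self, rng):
        s = 3.0
        taus = rng.normal(100.0, s, size=20_000)
        st = translocation_stats(taus)
        assert st.mean == pytest.approx(100.0, rel=0.01)
        assert st.width == pytest.approx(2 * math.sqrt(2) * s, rel=0.05)

    def test_identical_samples(self):
        st = translocation_stats(np.full(50, 7.0))
        assert st.width == 0.0 and st.ratio == 0.0 and st.mean == 7.0

    def test_bimodal_width_counts_gap_iff_dip_above_threshold(self, rng):
        # widely separated lobes: the dip falls below peak/e, so the gap is
        # not part of the measure; close lobes keep the dip above threshold
        lobe = rng.normal(0.0, 1.0, 10_000)
        sep = 40.0
        far = np.concatenate([100.0 + lobe, 100.0 + sep + lobe])
        near = np.concatenate([100.0 + lobe, 103.0 + lobe])
        w_far = translocation_stats(far).width
        w_near = translocation_stats(near).width
        # lobes widened by the Silverman kernel: sigma_eff^2 = 1 + bw^2
        bw = (0.75 * len(far)) ** (-0.2) * far.std()
        sigma_eff = math.sqrt(1.0 + bw * bw)
        assert w_far == pytest.approx(2 * 2 * math.sqrt(2) * sigma_eff, rel=0.1)  # two lobes, no gap
        assert w_far < sep  # the dip below peak/e keeps the gap out of the measure
        assert w_near > 3.0  # dip above threshold: one interval spanning the gap

    def test_width_matches_direct_density_scan(self, rng):
        from scipy import stats as sps

        taus = rng.lognormal(3.0, 0.3, size=500)
        st = translocation_stats(taus)
        kde = sps.gaussian_kde(taus, bw_method="silverman")
        grid = np.linspace(taus.min() - 5, taus.max() + 5, 20_001)
        d = kde(grid)
        w_ref = np.sum(d > d.max() / math.e) * (grid[1] - grid[0])
        assert st.width == pytest.approx(w_ref, rel=0.01)

    def test_insufficient_data(self):
        with pytest.raises(ValueError):
            translocation_stats([1.0])


class TestScalingFits:
    def test_exact_power_law(self):
        data = {N: 2.0 * N**1.3 for N in (32, 64, 128, 256)}
        fit = fit_alpha(data)
        assert fit.exponent == pytest.approx(1.3, abs=1e-12)
        assert fit.stderr == pytest.approx(0.0, abs=1e-10)

    def test_two_point_window_is_log_ratio(self):
        data = {10: 5.0, 100: 11.0}
        fit = fit_alpha(data)
        assert fit.exponent == pytest.approx(math.log(11.0 / 5.0) / math.log(10.0))

    def test_alpha_recovery_from_noisy_means(self):
        spec = SyntheticEnsembleSpec(alpha_true=1.4, noise_cv=0.05, E_list=(4.0,), n_runs=100, seed=5)
        samples = synth_tau_samples(spec)
        means = {N: samples[(N, 4.0)].mean() for N in spec.N_list}
        fit = fit_alpha(means)
        assert abs(fit.exponent - 1.4) < max(2 * fit.stderr, 0.05)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fit_alpha({16: -1.0, 32: 2.0})

    def test_delta_reciprocal_everywhere(self):
        data = {E: 100.0 / E for E in (0.2, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0)}
        fits = fit_delta(data)
        assert [f.regime for f in fits] == ["weak", "intermediate", "strong"]
        for f in fits:
            assert f.exponent == pytest.approx(1.0, abs=1e-10)

    def test_delta_piecewise_recovery(self):
        # piecewise exponents matching the three-field-regime picture
        exps = {"weak": 1.0, "intermediate": 1.64, "strong": 1.0}
        data = {}
        c = 1000.0
        for E in (0.2, 0.4, 0.7, 1.0):
            data[E] = c * E**-1.0
        c2 = data[1.0]
        for E in (2.0, 4.0, 8.0, 10.0):
            data[E] = c2 * E**-1.64
        c3 = data[10.0] * 10.0
        for E in (16.0, 32.0):
            data[E] = c3 * E**-1.0
        fits = {f.regime: f for f in fit_delta(data)}
        for regime, true in exps.items():
            f = fits[regime]
            assert abs(f.exponent - true) < max(2 * f.stderr, 0.02)

    def test_empty_regime_warns(self):
        with pytest.warns(RuntimeWarning):
            fits = fit_delta({2.0: 10.0, 4.0: 5.0})
        assert len(fits) == 1


class TestRadiusOfGyration:
    def test_point_mass(self):
        assert radius_of_gyration(np.zeros((5, 3))) == 0.0

    def test_two_points(self):
        pts = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 2.0]])
        assert radius_of_gyration(pts) == pytest.approx(1.0)

    def test_rigid_rod_closed_form(self):
        N = 50
        rod = np.column_stack([np.zeros(N), np.zeros(N), np.arange(N, dtype=float)])
        assert radius_of_gyration(rod) == pytest.approx(math.sqrt((N**2 - 1) / 12.0))


class TestRegionCurves:
    def test_region_rg_of_scripted_rod(self, small_geom):
        g = small_geom
        # 10-monomer rod fully in the cis region, static over 5 frames
        z = np.tile(np.arange(10.0, 20.0), (5, 1))
        traj = make_traj(g, z)
        curves = region_rg([traj], g)
        expect = math.sqrt((10**2 - 1) / 12.0)
        assert np.nanmax(np.abs(curves["I"].mean - expect)) < 1e-9
        # region III is empty: missing values, not zeros
        assert np.all(np.isnan(curves["III"].mean))

    def test_chain_end_positions_track_script(self, small_geom):
        g = small_geom
        F = 11
        z1 = np.linspace(g.z_exit, g.z_exit + 10, F)
        zN = np.linspace(g.z_exit - 12, g.z_exit - 2, F)
        z = np.linspace(z1, zN, 8).T  # (F, 8) linear chain between the ends
        traj = make_traj(g, z)
        curves = chain_end_positions([traj], g)
        assert curves["z1"].mean[0] == pytest.approx(0.0, abs=1e-9)
        assert curves["z1"].mean[-1] == pytest.approx(10.0, abs=1e-9)
        assert np.allclose(curves["z1-zN"].mean, curves["z1"].mean - curves["zN"].mean, equal_nan=True)

    def test_monomer_counts_manual_frame(self, small_geom):
        g = small_geom
        z = np.array([[g.z_entrance - 5.0, g.z_entrance - 1.0, g.z_entrance + 1.0, g.z_exit, g.z_exit + 3.0]])
        traj = make_traj(g, np.repeat(z, 3, axis=0))
        counts = monomer_counts([traj], g)
        assert counts["I"].mean[0] == 2
        assert counts["II"].mean[0] == 2  # closed pore interval
        assert counts["III"].mean[0] == 1
        total = counts["I"].mean + counts["II"].mean + counts["III"].mean
        assert np.allclose(total, 5)


class TestTranslocationMSD:
    def test_deterministic_linear_drift_gives_beta_2(self):
        series = [synth_s_trajectory(128, 2.0, 200, seed=0, noise=0.0) for _ in range(12)]
        curves, fit = translocation_msd(series)
        assert fit.exponent == pytest.approx(2.0, abs=1e-6)
        assert curves.mean[-1] == pytest.approx(127.0**2)

    def test_window_validation(self):
        series = [synth_s_trajectory(64, 1.5, 100, seed=i) for i in range(12)]
        with pytest.raises(ValueError):
            translocation_msd(series, fit_window=(0.5, 1.5))
        with pytest.raises(ValueError):
            translocation_msd(series[:5])

    def test_beta_recovery_with_noise(self):
        series = [synth_s_trajectory(256, 1.5, 400, seed=100 + i) for i in range(200)]
        _, fit = translocation_msd(series)
        assert abs(fit.exponent - 1.5) < max(2 * fit.stderr, 0.06)


def brute_force_condensed(positions, q, n_mono, box, lam):
    """Independent O(n^2) reference count of condensed ions."""
    counts = {+1: 0, -1: 0}
    for i in range(n_mono, len(positions)):
        best = np.inf
        for j in range(n_mono):
            d = positions[i] - positions[j]
            d -= box * np.round(d / box)
            best = min(best, float(np.dot(d, d)))
        if best < lam * lam:
            counts[int(np.sign(q[i]))] += 1
    return counts


class TestCondensation:
    def test_no_ions_near_chain(self, small_geom):
        from peltrans.fixtures import synth_condensation_config

        state, box = synth_condensation_config(0, 10, 3.0, seed=1)
        rec = condensation_counts(state.positions, state.charge_valence, 32, box, 3.0)
        assert sum(rec.nc_plus.values()) == 0 and sum(rec.nc_minus.values()) == 0
        assert rec.Qc == 0.0

    def test_single_counterion_at_criterion_edge(self, default_geom):
        g = default_geom
        # one monomer in the trans region, one counterion 2.9 away (< 3)
        pos = np.array([[10.0, 10.0, g.z_exit + 5.0], [10.0, 10.0, g.z_exit + 7.9]])
        rec = condensation_counts(pos, np.array([-1, 1]), 1, g.box, 3.0, geom=g)
        assert rec.nc_plus["III"] == 1
        assert rec.Qc == +1.0

    def test_matches_brute_force_on_random_frames(self, rng, default_geom):
        g = default_geom
        box = np.asarray(g.box)
        for _ in range(10):
            n_mono, n_ion = 20, 50
            pos = np.vstack(
                [
                    np.array([24.0, 24.0, 60.0]) + rng.normal(0, 4, (n_mono, 3)),
                    rng.random((n_ion, 3)) * box,
                ]
            )
            q = np.concatenate([np.full(n_mono, -1), rng.choice([-1, 1], n_ion)])
            rec = condensation_counts(pos, q, n_mono, box, 3.0, geom=g)
            ref = brute_force_condensed(pos, q, n_mono, box, 3.0)
            assert sum(rec.nc_plus.values()) == ref[+1]
            assert sum(rec.nc_minus.values()) == ref[-1]


class TestManningAndLineDensity:
    @pytest.mark.parametrize("lam,expect", [(3.0, 1.0 / 3.0), (1.0, 1.0), (2.0, 0.5)])
    def test_manning_reference(self, lam, expect):
        assert manning_reference(lam) == pytest.approx(expect)

    def test_straight_chain_no_condensation(self):
        N = 128
        box = np.array([300.0, 300.0, 300.0])
        pos = np.column_stack([np.full(N, 150.0), np.full(N, 150.0), 10.0 + np.arange(N, dtype=float)])
        ell, dens = effective_line_density(pos, np.full(N, -1), N, box, 3.0)
        assert ell == pytest.approx(127.0)
        assert dens == pytest.approx(128.0 / 127.0)

    def test_complete_neutralization_gives_zero(self):
        N = 16
        box = np.array([100.0, 100.0, 100.0])
        chain = np.column_stack([np.full(N, 50.0), np.full(N, 50.0), 40.0 + np.arange(N, dtype=float)])
        ions = chain + np.array([1.0, 0.0, 0.0])  # one condensed counterion per monomer
        pos = np.vstack([chain, ions])
        q = np.concatenate([np.full(N, -1), np.full(N, +1)])
        _, dens = effective_line_density(pos, q, N, box, 3.0)
        assert dens == pytest.approx(0.0, abs=1e-12)


class TestSpatialDistributions:
    def test_profiles_normalized(self, small_geom, rng):
        g = small_geom
        z = rng.uniform(5.0, 25.0, size=(6, 20))
        traj = make_traj(g, z, n_extra=10, extra_q=[1] * 5 + [-1] * 5)
        traj.positions[:, 20:, 2] = rng.uniform(30.0, 55.0, size=(6, 10))
        prof = z_probability_profiles([traj], g, windows=(0.0,), window_width=1.0)[0.0]
        for key in ("m", "+1", "-1"):
            assert np.sum(prof[key]) * 0.5 == pytest.approx(1.0)

    def test_point_mass_occupies_single_bin(self, small_geom):
        g = small_geom
        traj = make_traj(g, np.full((3, 8), 12.3))
        prof = z_probability_profiles([traj], g, windows=(0.0,), window_width=1.0)[0.0]
        assert np.count_nonzero(prof["m"]) == 1

    def test_empty_window_warns(self, small_geom):
        traj = make_traj(small_geom, np.full((3, 4), 10.0))
        with pytest.warns(RuntimeWarning):
            out = z_probability_profiles([traj], small_geom, windows=(0.7,), window_width=0.001)
        assert out[0.7] is None

    def test_density_map_marginal_matches_z_profile(self, small_geom, rng):
        g = small_geom
        z = rng.uniform(5.0, 25.0, size=(4, 30))
        traj = make_traj(g, z)
        traj.positions[:, :, 1] = rng.uniform(0, g.box[1], size=(4, 30))
        prof = z_probability_profiles([traj], g, windows=(0.0,), window_width=1.0, bin_width=1.0)[0.0]
        _, _, dmap = density_map_yz([traj], g, window=(0.0, 1.0), cell=1.0)
        marg = dmap.sum(axis=0)
        marg = marg / (marg.sum() * 1.0)
        assert np.allclose(marg[: len(prof["m"])], prof["m"], atol=1e-12)

    def test_peak_to_wall_distance(self, small_geom):
        g = small_geom
        traj = make_traj(g, np.full((3, 16), g.z_entrance - 8.2))
        prof = z_probability_profiles([traj], g, windows=(0.0,), window_width=1.0)[0.0]
        assert peak_to_wall_distance(prof, g) == pytest.approx(8.2, abs=0.5)


class TestEnsembleInvariance:
    def test_reordering_runs_leaves_curves_unchanged(self, small_geom, rng):
        g = small_geom
        trajs = [make_traj(g, rng.uniform(5, 25, size=(8, 12))) for _ in range(6)]
        a = monomer_counts(trajs, g)["I"].mean
        b = monomer_counts(trajs[::-1], g)["I"].mean
        assert np.array_equal(a, b, equal_nan=True)

    def test_split_half_means_agree(self, rng):
        series = [synth_s_trajectory(128, 1.5, 300, seed=i) for i in range(80)]
        c1, _ = translocation_msd(series[:40])
        c2, _ = translocation_msd(series[40:])
        late = T_GRID >= 0.5
        se = np.sqrt(c1.spread[late] ** 2 / 40 + c2.spread[late] ** 2 / 40)
        assert np.all(np.abs(c1.mean[late] - c2.mean[late]) < 4 * se + 1e-9)
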