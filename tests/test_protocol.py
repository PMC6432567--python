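"""System assembly, equilibration and translocation-run contracts.

Interacting-system tests use a reduced geometry (24 × 24.25 × 60 box) and a
short chain with a small amount of salt so the whole file stays fast; the
physics contracts (tethering, thermostat, bond statistics, first passage,
one-way barrier) are scale-free.
"""

import numpy as np
import pytest

from peltrans.forces import BarrierSpec
from peltrans.integrator import LangevinParams, run_rng
from peltrans.model import SPECIES_CODES
from peltrans.protocol import RunConfig, equilibrate, initialize_system, run_translocation
from peltrans.trajio import Trajectory

SMALL = dict(n_salt_cations=16, n_salt_anions=16, equilibration_steps=2500)


@pytest.fixture(scope="module")
def small_system(small_geom, params_module):
    cfg = RunConfig(N=16, seed=2, **SMALL)
    state = initialize_system(cfg, small_geom, params_module, rng=run_rng(2))
    return cfg, state


@pytest.fixture(scope="module")
def params_module():
    from peltrans.model import ModelParams

    return ModelParams()


class TestInitializeSystem:
    def test_head_monomer_at_trans_opening(self, small_system, small_geom):
        _, state = small_system
        head = state.positions[0]
        x0, y0 = small_geom.pore_axis_xy
        assert np.hypot(head[0] - x0, head[1] - y0) < 1e-9
        assert abs(head[2] - small_geom.z_exit) <= 0.5

    def test_charge_audit(self, small_system):
        _, state = small_system
        assert state.net_charge == 0
        assert state.n_monomers == 16

    def test_packing_min_distance(self, small_system, small_geom):
        _, state = small_system
        pos = state.positions
        box = np.asarray(small_geom.box)
        d = pos[:, None, :] - pos[None, :, :]
        d -= box * np.round(d / box)
        r = np.sqrt((d**2).sum(-1))
        np.fill_diagonal(r, np.inf)
        assert r.min() >= 0.8

    def test_chain_is_connected(self, small_system, small_geom):
        _, state = small_system
        box = np.asarray(small_geom.box)
        steps = np.diff(state.positions[:16], axis=0)
        steps -= box * np.round(steps / box)
        assert np.allclose(np.linalg.norm(steps, axis=1), 1.0, atol=1e-6)


class TestEquilibrate:
    @pytest.fixture(scope="class")
    def equilibrated(self, small_geom, params_module):
        cfg = RunConfig(N=16, seed=5, **SMALL)
        state = initialize_system(cfg, small_geom, params_module, rng=run_rng(5))
        tether0 = state.positions[0].copy()
        state, rec = equilibrate(state, cfg, small_geom, params_module, record_every=100)
        return state, rec, tether0

    def test_tether_holds_head_monomer(self, equilibrated):
        state, _, tether0 = equilibrated
        assert np.array_equal(state.positions[0], tether0)

    def test_mean_bond_length_near_harmonic_prediction(self, equilibrated):
        # 1D Boltzmann integral for the k=600 spring at T=1 gives <b> just
        # above r0; anything in [1.00, 1.02] is consistent
        _, rec, _ = equilibrated
        assert 1.00 <= rec.mean_bond_length <= 1.02

    def test_thermostat_on_target(self, equilibrated):
        _, rec, _ = equilibrated
        assert rec.kinetic_T == pytest.approx(1.0, abs=0.1)


class TestFirstPassageDetection:
    def test_scripted_crossing(self, small_geom, params_module):
        """Chain already past the exit except the tail bead: passage on release."""
        cfg = RunConfig(N=4, E=8.0, n_salt_cations=0, n_salt_anions=0, max_steps=40_000, seed=9)
        g = small_geom
        x0, y0 = g.pore_axis_xy
        chain = np.array(
            [
                [x0, y0, g.z_exit + 3.2],
                [x0, y0, g.z_exit + 2.2],
                [x0, y0, g.z_exit + 1.2],
                [x0, y0 + 0.3, g.z_exit + 0.2],
            ]
        )
        ions = np.array([[x0 + 5, y0, g.z_exit + 6.0], [x0 - 5, y0, g.z_exit + 6.0], [x0, y0 + 5, g.z_exit + 6.0], [x0, y0 - 5, g.z_exit + 6.0]])
        pos = np.vstack([chain, ions])
        from peltrans.model import SystemState

        state = SystemState(
            pos,
            np.zeros_like(pos),
            np.array([-1, -1, -1, -1, 1, 1, 1, 1]),
            np.array([0, 0, 0, 0, 1, 1, 1, 1]),
        )
        res = run_translocation(state, cfg, g, params_module, lp=LangevinParams(dt=0.001, seed=9))
        assert res.completed
        assert 0 < res.tau < 40.0

    def test_incomplete_run_reported(self, small_geom, params_module):
        cfg = RunConfig(N=16, E=0.5, max_steps=50, seed=1, **{k: v for k, v in SMALL.items() if k != "equilibration_steps"})
        state = initialize_system(cfg, small_geom, params_module, rng=run_rng(1))
        res = run_translocation(state, cfg, small_geom, params_module)
        assert not res.completed
        assert res.tau is None


@pytest.fixture(scope="module")
def smoke_runs(small_geom, params_module):
    """Three short driven translocations of an N=16 chain at E=4."""
    results = []
    for seed in (11, 12, 13):
        cfg = RunConfig(N=16, E=4.0, seed=seed, max_steps=300_000, save_every=500, **{k: v for k, v in SMALL.items() if k != "equilibration_steps"}, equilibration_steps=1500)
        state = initialize_system(cfg, small_geom, params_module, rng=run_rng(seed))
        state, _ = equilibrate(state, cfg, small_geom, params_module, record_every=500)
        results.append(run_translocation(state, cfg, small_geom, params_module))
    return results


class TestSmokeEnsemble:
    def test_all_runs_complete(self, smoke_runs):
        assert all(r.completed for r in smoke_runs)
        assert all(r.tau > 0 for r in smoke_runs)

    def test_head_monomer_never_rethreads(self, smoke_runs, small_geom):
        # the one-way barrier caps how far the head can dip below the exit
        floor = small_geom.z_exit - 2.0 ** (1.0 / 6.0) * BarrierSpec().sigma
        for r in smoke_runs:
            z1 = r.trajectory.positions[:, 0, 2]
            assert np.all(z1 >= floor - 1e-9)

    def test_region_counts_sum_to_N_every_frame(self, smoke_runs, small_geom):
        from peltrans.geometry import region_codes

        for r in smoke_runs:
            for f in range(r.trajectory.n_frames):
                z = r.trajectory.positions[f, :16, 2]
                codes = region_codes(z, small_geom)
                assert len(codes) == 16

    def test_charge_and_particle_conservation(self, smoke_runs):
        for r in smoke_runs:
            assert int(np.sum(r.trajectory.charge_valence)) == 0
            assert r.trajectory.positions.shape[1] == 16 + 16 + 32

    def test_completed_final_frame_fully_trans(self, smoke_runs, small_geom):
        for r in smoke_runs:
            z = r.trajectory.positions[-1, :16, 2]
            assert np.all(z > small_geom.z_exit)

    def test_mean_translocation_coordinate_nondecreasing(self, smoke_runs, small_geom):
        from peltrans.observables import monomer_counts

        curves = monomer_counts([r.trajectory for r in smoke_runs], small_geom)
        m = curves["III"].mean
        good = np.isfinite(m)
        coarse = m[good][:: max(1, good.sum() // 10)]
        assert np.all(np.diff(coarse) >= -1.5)  # nondecreasing within noise
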