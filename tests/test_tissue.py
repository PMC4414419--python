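"""3D tissue solver: voxelization, conservation, null cases, convergence."""

import numpy as np
import pytest

from cytograd import (ModelParams, SimConfig, build_geometry, run,
                      pulse_experiment, homogenized_lambda)
from cytograd.tissue import VoxelGrid

P = ModelParams()


class TestVoxelGrid:
    def test_cells_are_resolved(self):
        g = build_geometry((3, 3, 3), 0.25, seed=0)
        grid = VoxelGrid(g, 2.5)
        assert grid.dims == (18, 18, 18)
        # excluded volume close to the analytic sphere packing fraction
        frac = 1.0 - grid.n_free / np.prod(grid.dims)
        sphere_frac = (4 / 3) * np.pi * 5 ** 3 / 15 ** 3
        assert frac == pytest.approx(sphere_frac, rel=0.15)

    def test_every_cell_has_enough_surface_voxels(self):
        g = build_geometry((3, 3, 3), 0.25, seed=0)
        grid = VoxelGrid(g, 2.5)
        assert min(len(s) for s in grid.surface_voxels) >= 30

    def test_too_coarse_voxels_rejected(self):
        g = build_geometry((3, 3, 3), 0.25, seed=0)
        with pytest.raises(ValueError):
            VoxelGrid(g, 3.0)

    def test_secretion_voxel_is_extracellular_and_near_the_point(self):
        g = build_geometry((3, 3, 3), 1.0, seed=4)
        grid = VoxelGrid(g, 2.5)
        for k in g.indices("secretor"):
            v = grid.secretion_voxel(int(k))
            assert 0 <= v < grid.n_free

    def test_laplacian_conserves_with_closed_boundary(self):
        g = build_geometry((2, 2, 2), 0.25, seed=0)
        grid = VoxelGrid(g, 2.5)
        K, _ = grid.laplacian(3.6e4, "no_flux")
        x = np.random.default_rng(0).random(grid.n_free)
        assert abs((K @ x).sum()) < 1e-7 * abs(K.diagonal()).sum()


class TestNullDynamics:
    def test_no_secretors_stays_empty(self):
        g = build_geometry((2, 2, 2), 0.0, seed=0)
        traj = run(g, P, SimConfig(voxel_size=2.5, t_end=2.0))
        assert traj.bulk_nM.max() == 0.0
        assert traj.mass_balance_error == 0.0

    def test_pure_source_accumulates_qeff_t(self):
        # one secretor, no consumers, no degradation, closed box
        g = build_geometry((2, 2, 2), single_central_secretor=True, seed=0)
        p = P.replace(k_d=0.0, v0_Th=0.0, v1_Th=0.0)
        traj = run(g, p, SimConfig(voxel_size=2.5, t_end=5.0, q_eff=1000.0,
                                   responder_R0=0.0))
        assert traj.ledger["resident"][-1] == pytest.approx(
            1000.0 * traj.times[-1], rel=1e-6)


class TestMassBalance:
    def test_ledger_closes_on_small_culture(self, small_culture):
        assert small_culture.mass_balance_error < 1e-3

    def test_ledger_closes_with_absorbing_boundary(self):
        g = build_geometry((2, 2, 2), single_central_secretor=True, seed=0)
        traj = run(g, P, SimConfig(voxel_size=2.5, t_end=3.0, q_eff=5e4,
                                   boundary="absorbing"))
        assert traj.mass_balance_error < 1e-3
        assert traj.ledger["outflux"][-1] > 0


class TestDynamics:
    def test_transient_peak_then_decline(self, small_culture):
        # concentration rises, peaks within ~10 h, then is consumed
        bulk = small_culture.bulk_nM
        t_peak = small_culture.times[int(np.argmax(bulk))]
        assert t_peak < 10.0
        assert bulk[-1] < 0.2 * bulk.max()

    def test_some_but_not_all_responders_activate(self, small_culture):
        mask = small_culture.activated_mask()
        resp = small_culture.geometry.indices("responder_th")
        n = mask[resp].sum()
        assert 0 < n < len(resp)

    def test_bimodal_receptor_distribution(self, small_culture):
        rs = small_culture.surface_receptors()
        rs = rs[~np.isnan(rs)]
        lo, hi = rs[rs <= 4000], rs[rs > 4000]
        assert len(lo) and len(hi)
        # the two modes are widely separated relative to their spread
        assert np.median(hi) > 5 * np.median(lo)

    def test_seed_robustness_of_activated_count(self):
        counts = []
        for seed in (0, 1, 2):
            g = build_geometry((3, 3, 3), 0.25, seed=seed)
            traj = run(g, P, SimConfig(voxel_size=2.5, t_end=30.0))
            resp = g.indices("responder_th")
            counts.append(int(traj.activated_mask()[resp].sum()))
        assert max(counts) - min(counts) <= max(3, 0.3 * max(counts))

    def test_grid_and_step_refinement_stable(self):
        # halving voxels and tightening dt barely moves the outcome
        g = build_geometry((2, 2, 2), 0.25, seed=3)
        coarse = run(g, P, SimConfig(voxel_size=2.5, t_end=6.0))
        fine = run(g, P, SimConfig(voxel_size=1.25, t_end=6.0))
        tight = run(g, P, SimConfig(voxel_size=2.5, t_end=6.0, dt_max=0.02))
        assert fine.bulk_nM[-1] == pytest.approx(coarse.bulk_nM[-1], rel=0.05)
        assert tight.bulk_nM[-1] == pytest.approx(coarse.bulk_nM[-1],
                                                  rel=0.05)
        a = coarse.surface_receptors()
        for other in (fine, tight):
            b = other.surface_receptors()
            ok = ~np.isnan(a)
            assert np.nanmax(np.abs(a[ok] - b[ok]) / (a[ok] + 100)) < 0.2


class TestPulse:
    @pytest.fixture(scope="class")
    def pulse(self):
        g = build_geometry((7, 7, 7), single_central_secretor=True, seed=0)
        return pulse_experiment(g, P, voxel_size=2.5)

    def test_release_is_fully_accounted(self, pulse):
        total = pulse.captured + pulse.degraded + pulse.escaped \
            + pulse.resident
        assert total == pytest.approx(1.0, abs=2e-3)

    def test_capture_probabilities_positive_and_decaying_far_out(self, pulse):
        assert (pulse.p_layer >= 0).all()
        assert pulse.p_layer.sum() == pytest.approx(pulse.captured, rel=1e-9)

    def test_no_receptors_everything_degrades_or_escapes(self):
        g = build_geometry((3, 3, 3), single_central_secretor=True, seed=0)
        p = P.replace(k_d=5.0)
        dist = pulse_experiment(g, p, voxel_size=2.5, R_resp=0.0,
                                boundary="no_flux", t_max_h=30.0)
        assert dist.captured == 0.0
        assert dist.degraded == pytest.approx(1.0, abs=2e-3)

    def test_truncation_warns(self):
        g = build_geometry((3, 3, 3), single_central_secretor=True, seed=0)
        with pytest.warns(RuntimeWarning, match="truncated"):
            pulse_experiment(g, P, voxel_size=2.5, t_max_h=0.02,
                             boundary="no_flux")

    def test_homogenized_lambda_value(self):
        # sqrt(D/k_hom) with basal receptors and one cell per (15 um)^3
        lam = homogenized_lambda(P, 100.0, 15.0)
        assert lam == pytest.approx(81.0, rel=0.01)
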