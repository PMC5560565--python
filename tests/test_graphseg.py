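import numpy as np
import pytest

from octlayers import PhantomParams, generate_phantom, make_eval_mask
from octlayers.volume_io import downsample_volume
from octlayers.graphseg import (
    ConstraintSpec, segment_surfaces, brute_force_segment, coarse_localize,
    build_plan, segment_retina, _propagate_bounds,
)
from octlayers import costs as cm

from conftest import noiseless_overrides, random_instance


def loose(n=1):
    return ConstraintSpec(smoothness_x=100, smoothness_b=100, pairs=[])


class TestSegmentSurfaces:
    def test_zero_cost_row_is_found(self):
        c = np.ones((2, 3, 8))
        c[:, :, 5] = 0.0
        pos = segment_surfaces([c], loose())
        np.testing.assert_array_equal(pos, np.full((1, 2, 3), 5))

    def test_zero_smoothness_forces_flat_argmin_of_column_sums(self):
        rng = np.random.default_rng(4)
        c = rng.integers(0, 50, (1, 6, 9))
        spec = ConstraintSpec(smoothness_x=0, smoothness_b=0, pairs=[])
        pos = segment_surfaces([c], spec)
        assert len(np.unique(pos)) == 1
        assert pos[0, 0, 0] == c.sum(axis=(0, 1)).argmin()

    def test_named_output_is_a_surface_set(self):
        c = np.ones((1, 2, 6))
        c[:, :, 2] = 0
        ss = segment_surfaces([c, c], ConstraintSpec(1, 1, [(0, 1, 1, 3)]),
                              names=("A", "B"))
        assert ss.names == ("A", "B")
        ss.check_ordering()

    def test_separation_constraints_hold_exactly(self):
        rng = np.random.default_rng(5)
        costs = [rng.integers(0, 30, (2, 4, 12)) for _ in range(3)]
        spec = ConstraintSpec(2, 3, [(0, 1, 2, 5), (1, 2, 1, 4)])
        pos = segment_surfaces(costs, spec)
        d01 = pos[1] - pos[0]
        d12 = pos[2] - pos[1]
        assert d01.min() >= 2 and d01.max() <= 5
        assert d12.min() >= 1 and d12.max() <= 4
        assert np.abs(np.diff(pos, axis=2)).max() <= 2
        assert np.abs(np.diff(pos, axis=1)).max() <= 3

    def test_infeasible_constraints_rejected_before_solving(self):
        c = np.ones((1, 2, 6))
        with pytest.raises(ValueError, match="infeasible"):
            segment_surfaces([c, c], ConstraintSpec(1, 1, [(0, 1, 7, 9)]))

    def test_adding_constant_to_one_surface_changes_nothing(self):
        rng = np.random.default_rng(6)
        costs = [rng.integers(0, 30, (1, 4, 10)) for _ in range(2)]
        spec = ConstraintSpec(1, 1, [(0, 1, 1, 5)])
        a = segment_surfaces(costs, spec)
        b = segment_surfaces([costs[0] + 17, costs[1]], spec)
        np.testing.assert_array_equal(a, b)

    def test_column_floor_confines_the_solution(self):
        c = np.ones((1, 4, 12))
        c[:, :, 2] = 0.0  # attractive row above the floor
        c[:, :, 8] = 0.1
        floor = np.full((1, 4), 5)
        pos = segment_surfaces([c], loose(), column_floor=floor)
        np.testing.assert_array_equal(pos, np.full((1, 1, 4), 8))


class TestBruteForce:
    def test_single_column_single_surface_is_argmin(self):
        c = np.array([[[4, 1, 7, 0, 9]]])
        pos = brute_force_segment([c], loose())
        assert pos[0, 0, 0] == 3

    def test_infeasible_rejected(self):
        c = np.ones((1, 1, 4))
        with pytest.raises(ValueError, match="infeasible"):
            brute_force_segment([c, c], ConstraintSpec(1, 1, [(0, 1, 5, 9)]))

    def test_too_large_instance_rejected(self):
        c = np.ones((4, 10, 30))
        with pytest.raises(ValueError, match="too large"):
            brute_force_segment([c, c, c], loose(), max_configs=1000)


class TestOracleEquivalence:
    @pytest.mark.parametrize("block", range(4))
    def test_solver_matches_exhaustive_enumeration(self, block):
        """Min-cut solver and exhaustive oracle agree in cost and
        configuration (pointwise-minimal tie-break) on random instances."""
        ran = 0
        for seed in range(block * 60, block * 60 + 60):
            costs, spec = random_instance(seed)
            try:
                bf = brute_force_segment(costs, spec)
            except ValueError:
                continue  # infeasible draw
            gc = segment_surfaces(costs, spec)
            np.testing.assert_array_equal(gc, bf, err_msg=f"seed {seed}")
            ran += 1
        assert ran >= 30


class TestBoundsPropagation:
    def test_chain_of_min_separations(self):
        lo, hi = _propagate_bounds(3, 20, [(0, 1, 3, 19), (1, 2, 4, 19)])
        np.testing.assert_array_equal(lo, [0, 3, 7])
        np.testing.assert_array_equal(hi, [12, 15, 19])

    def test_total_min_separation_exceeding_depth_is_infeasible(self):
        with pytest.raises(ValueError, match="infeasible"):
            _propagate_bounds(2, 6, [(0, 1, 6, 10)])


@pytest.fixture(scope="module")
def noiseless_work(noiseless_phantom):
    vol, truth, params = noiseless_phantom
    work = downsample_volume(vol, 2, 2)
    return vol, truth, params, work, coarse_localize(work)


class TestCoarseLocalize:
    def test_roi_contains_all_truth_surfaces(self, noiseless_work):
        vol, truth, params, work, roi = noiseless_work
        st = truth.surfaces.stack() / 2  # truth on the working grid
        assert st.min() >= roi.z0 and st.max() <= roi.z1

    def test_ilm_estimate_close_to_truth_outside_onh(self, noiseless_work):
        vol, truth, params, work, roi = noiseless_work
        annulus = np.asarray(make_eval_mask(work.shape, work.spacing).mask)
        est = roi.ilm + 20.0 / work.spacing[2]  # undo the margin
        ilm_truth = truth.surfaces["ILM"][:, ::2] / 2
        err = np.abs(est - ilm_truth)[annulus]
        assert (err <= 2).mean() >= 0.99

    def test_zero_margins_give_ilm_to_deep_window(self, noiseless_work):
        vol, truth, params, work, _ = noiseless_work
        roi0 = coarse_localize(work, margin_above_um=0.0, margin_below_um=0.0)
        ilm_truth = truth.surfaces["ILM"][:, ::2] / 2
        bm_truth = truth.surfaces["BM"][:, ::2] / 2
        annulus = np.asarray(make_eval_mask(work.shape, work.spacing).mask)
        # with zero margins the per-column window is the ILM/deep estimate
        assert np.abs(roi0.ilm - ilm_truth)[annulus].max() <= 3
        assert roi0.z0 <= ilm_truth[annulus].min()
        assert roi0.z1 >= bm_truth[annulus].max() - 3


class TestStagePlans:
    def test_healthy_plan_surfaces(self):
        plan = build_plan("healthy", 1.56)
        assert [s.surfaces for s in plan.stages] == [
            ("ILM", "RNFGC-IPL"),
            ("IPL-INL", "INL-OPL", "OPL-ONL"),
            ("ELM", "EZ-Top", "EZ-Bottom", "OS-RPE", "BM")]
        assert len(plan.all_surfaces) == 10

    def test_ld_plan_allows_zero_onl(self):
        plan = build_plan("ld", 1.56)
        assert len(plan.all_surfaces) == 6
        (pair,) = plan.stages[2].constraints.pairs
        assert pair[2] == 0  # min separation ONL-Top -> BM

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            build_plan("sick", 1.56)


class TestPipelineGradientMode:
    def test_stage1_noiseless_recovery_within_one_working_voxel(self, noiseless_work):
        vol, truth, params, work, roi = noiseless_work
        plan = build_plan("healthy", work.spacing[2])
        stage = plan.stages[0]
        cvs = [cm.gradient_cost(work, cm.DEFAULT_POLARITY[n], 1.0)
               .values[:, :, roi.z0:roi.z1 + 1] for n in stage.surfaces]
        pos = segment_surfaces(cvs, stage.constraints)
        annulus = np.asarray(make_eval_mask(work.shape, work.spacing).mask)
        for i, name in enumerate(stage.surfaces):
            t = truth.surfaces[name][:, ::2] / 2
            err = np.abs(pos[i] + roi.z0 - t)[annulus]
            assert err.max() <= 1.0, name

    def test_mode_mismatch_rejected(self, noiseless_work):
        vol, *_ = noiseless_work
        plan = build_plan("ld", 1.56)
        with pytest.raises(ValueError, match="mode"):
            segment_retina(vol, "healthy", plan=plan)
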