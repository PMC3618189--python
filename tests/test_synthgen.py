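"""Generator contracts: targets are hit, ground truth is exact, seeds reproduce."""

import numpy as np
import pandas as pd
import pytest

from trabmri import (CohortSpec, Perturbation, TrabecularParams,
                     generate_cohort, generate_followup, generate_slice,
                     generate_stack)
from trabmri.synthgen import (BONE_LEVEL, MARROW_LEVEL, InfeasibleParameters,
                              VARIABLE_SCALES)


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_bone_fraction_hits_target(seed):
    params = TrabecularParams(target_bvtv=0.477, seed=seed)
    _, truth = generate_slice(params)
    assert abs(truth.bone_fraction - 0.477) < 0.03


def test_noise_free_slice_is_two_level_inside_disc(clean_slice):
    """Without PSF or noise the grey slice encodes the truth map exactly."""
    grey, truth = clean_slice
    inside = truth.endosteal
    assert np.all(grey[inside & truth.bone] == BONE_LEVEL)
    assert np.all(grey[inside & ~truth.bone] == MARROW_LEVEL)


def test_fixed_seed_is_bit_identical():
    params = TrabecularParams(seed=7)
    g1, t1 = generate_slice(params)
    g2, t2 = generate_slice(params)
    assert np.array_equal(g1, g2)
    assert np.array_equal(t1.bone, t2.bone)
    assert np.array_equal(t1.hole_areas_px, t2.hole_areas_px)


def test_hole_areas_partition_marrow_exactly(default_slice):
    """Ground-truth hole areas sum to the marrow pixel count of the disc."""
    _, truth = default_slice
    marrow_px = int((truth.endosteal & ~truth.bone).sum())
    assert int(truth.hole_areas_px.sum()) == marrow_px
    assert np.all(truth.hole_areas_px > 0)


def test_hole_count_near_target(default_slice, default_params):
    _, truth = default_slice
    target = default_params.hole_count_target
    assert abs(truth.hole_areas_px.size - target) <= 0.1 * target


def test_infeasible_hole_count_raises():
    with pytest.raises(InfeasibleParameters):
        generate_slice(TrabecularParams(hole_count_target=5000, seed=0))


def test_invalid_params_rejected():
    with pytest.raises(InfeasibleParameters):
        TrabecularParams(target_bvtv=0.95)
    with pytest.raises(InfeasibleParameters):
        TrabecularParams(endosteal_radius=15.0)
    with pytest.raises(InfeasibleParameters):
        Perturbation(bone_loss_fraction=1.5)


@pytest.fixture(scope="module")
def baseline():
    return generate_stack(TrabecularParams(seed=4), n_slices=10)


class TestFollowup:

    def test_identity_perturbation_preserves_truth(self, baseline):
        _, truth = baseline
        _, ftruth = generate_followup(truth, Perturbation())
        for s, f in zip(truth.slices, ftruth.slices):
            assert np.array_equal(s.bone, f.bone)
            assert np.array_equal(s.endosteal, f.endosteal)

    def test_bone_loss_fraction_is_realized(self, baseline):
        _, truth = baseline
        _, ftruth = generate_followup(truth, Perturbation(bone_loss_fraction=0.05))
        b0 = sum(int(s.trabecular_bone.sum()) for s in truth.slices)
        b1 = sum(int(s.trabecular_bone.sum()) for s in ftruth.slices)
        assert b1 / b0 == pytest.approx(0.95, abs=0.01)

    def test_bone_loss_monotone_in_bvtv(self, baseline):
        _, truth = baseline
        fracs = []
        for loss in (0.0, 0.05, 0.15):
            _, f = generate_followup(truth, Perturbation(bone_loss_fraction=loss))
            fracs.append(np.mean([s.bone_fraction for s in f.slices]))
        assert fracs[0] >= fracs[1] >= fracs[2]

    def test_out_of_fov_shift_fails(self, baseline):
        _, truth = baseline
        with pytest.raises(InfeasibleParameters):
            generate_followup(truth, Perturbation(shift=(60.0, 0.0)))

    def test_slice_offset_moves_reference(self, baseline):
        _, truth = baseline
        _, f = generate_followup(truth, Perturbation(slice_offset=2))
        assert f.distal_reference == truth.distal_reference + 2


class TestCohort:
    def test_fixed_seed_reproduces_table(self):
        a = generate_cohort(CohortSpec(n_diabetes=4, n_control=4, seed=11))
        b = generate_cohort(CohortSpec(n_diabetes=4, n_control=4, seed=11))
        pd.testing.assert_frame_equal(a["table"], b["table"])

    def test_group_sizes_and_visits(self):
        out = generate_cohort(CohortSpec(n_diabetes=5, n_control=7, seed=3))
        table = out["table"]
        assert len(table) == 2 * 12
        counts = table[table.visit == "baseline"].group.value_counts()
        assert counts["diabetes"] == 5 and counts["control"] == 7

    def test_planted_effect_appears_in_truth_means(self):
        spec = CohortSpec(n_diabetes=60, n_control=60, seed=5,
                          effect_pct_change={"hole_count": 17.2},
                          ethnicity_effect_pct={})
        truth = generate_cohort(spec)["truth"]
        diff = (truth[truth.group == "diabetes"].pct_hole_count.mean()
                - truth[truth.group == "control"].pct_hole_count.mean())
        sd = VARIABLE_SCALES["hole_count"]["pct_sd"]
        assert diff == pytest.approx(17.2, abs=4 * sd * np.sqrt(2 / 60))

    def test_degenerate_ethnicity_is_constant(self):
        spec = CohortSpec(n_diabetes=4, n_control=4, seed=2,
                          ethnicity_prob=(1.0, 1.0))
        table = generate_cohort(spec)["table"]
        assert set(table.ethnicity) == {"caucasian"}

    def test_too_small_groups_fail(self):
        with pytest.raises(InfeasibleParameters):
            generate_cohort(CohortSpec(n_diabetes=2, n_control=5, seed=0))
        with pytest.raises(InfeasibleParameters):
            CohortSpec(n_diabetes=1, n_control=5)

    def test_rendered_stacks_follow_table_targets(self):
        out = generate_cohort(CohortSpec(n_diabetes=3, n_control=3, seed=9),
                              render=True, n_slices=8)
        table = out["table"].set_index(["subject_id", "visit"])
        for (sid, visit), (stack, truth) in out["stacks"].items():
            assert stack.n_slices == 8
            if visit == "baseline":
                target = table.loc[(sid, "baseline"), "bvtv"] / 100
                # trabecular slices (beyond the dense band) track the target
                fracs = [s.bone_fraction for s in truth.slices[2:]]
                assert np.mean(fracs) == pytest.approx(target, abs=0.03)
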