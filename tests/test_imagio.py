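"""Stack I/O round-trips and longitudinal slice matching."""

import numpy as np
import pytest

from trabmri import (ImageStack, Perturbation, TrabecularParams,
                     generate_followup, generate_stack, read_stack,
                     register_pair, select_analysis_volume, write_stack)
from trabmri.imagio import (ImageIOError, RegistrationError,
                            detect_distal_reference, match_report)


@pytest.fixture(scope="module")
def stack_and_truth():
    return generate_stack(TrabecularParams(seed=5), n_slices=12)


@pytest.fixture(scope="module")
def stack(stack_and_truth):
    return stack_and_truth[0]


class TestIO:
    @pytest.mark.parametrize("name", ["s.tif", "s.nii", "s.nii.gz"])
    def test_round_trip(self, stack, tmp_path, name):
        path = write_stack(stack, tmp_path / name)
        back = read_stack(path)
        np.testing.assert_allclose(back.data, stack.data, rtol=1e-6)
        assert back.voxel_inplane == pytest.approx(0.195)
        assert back.voxel_thickness == pytest.approx(1.0)

    def test_nifti_pixdim_is_voxel_size(self, stack, tmp_path):
        path = write_stack(stack, tmp_path / "v.nii")
        assert read_stack(path).voxel_inplane == pytest.approx(0.195)

    def test_too_few_slices_rejected(self):
        with pytest.raises(ImageIOError, match="8"):
            ImageStack(data=np.zeros((7, 16, 16)), voxel_inplane=0.195,
                       voxel_thickness=1.0)

    def test_missing_file(self, tmp_path):
        with pytest.raises(ImageIOError):
            read_stack(tmp_path / "nope.tif")

    def test_voxel_override(self, stack, tmp_path):
        import tifffile
        path = tmp_path / "plain.tif"
        tifffile.imwrite(path, stack.data)  # no geometry metadata
        with pytest.raises(ImageIOError, match="voxel_inplane"):
            read_stack(path)
        back = read_stack(path, voxel_inplane=0.2, voxel_thickness=1.0)
        assert back.voxel_inplane == 0.2


class TestRegistration:
    def test_identical_stacks_identity_match(self, stack):
        pair = register_pair(stack, stack)
        assert pair.slice_offset == 0
        assert pair.match_score == pytest.approx(1.0, abs=1e-6)
        assert pair.inplane_transform == pytest.approx((0.0, 0.0, 0.0))

    def test_pure_slice_offset_recovered(self, stack):
        rolled = ImageStack(data=np.roll(stack.data, 2, axis=0),
                            voxel_inplane=stack.voxel_inplane,
                            voxel_thickness=stack.voxel_thickness)
        assert register_pair(stack, rolled).slice_offset == 2

    def test_planted_rigid_shift_recovered(self, stack_and_truth):
        _, truth = stack_and_truth
        _, f = generate_followup(truth, Perturbation(shift=(3.0, 2.0)))
        fstack, _ = f, None
        pair = register_pair(stack_and_truth[0],
                             generate_followup(truth,
                                               Perturbation(shift=(3.0, 2.0)))[0])
        sx, sy, rot = pair.inplane_transform
        assert pair.slice_offset == 0
        # transform maps follow-up onto baseline: inverse of the planted shift
        assert sx == pytest.approx(-2.0, abs=1.0)
        assert sy == pytest.approx(-3.0, abs=1.0)
        assert abs(rot) <= 1.0

    def test_registration_symmetric(self, stack_and_truth):
        stack, truth = stack_and_truth
        fstack, _ = generate_followup(
            truth, Perturbation(shift=(2.0, -1.0), slice_offset=1))
        ab = register_pair(stack, fstack)
        ba = register_pair(fstack, stack)
        assert ab.slice_offset == -ba.slice_offset
        assert ab.inplane_transform[0] == pytest.approx(
            -ba.inplane_transform[0], abs=1.0)
        assert ab.inplane_transform[1] == pytest.approx(
            -ba.inplane_transform[1], abs=1.0)

    def test_offset_robust_to_generator_noise(self, stack_and_truth):
        """Extra i.i.d. noise at the generator level keeps the offset."""
        stack, truth = stack_and_truth
        fstack, _ = generate_followup(truth, Perturbation(slice_offset=-2))
        rng = np.random.default_rng(0)
        noisy = ImageStack(
            data=fstack.data + rng.normal(0, 15.0, fstack.data.shape),
            voxel_inplane=fstack.voxel_inplane,
            voxel_thickness=fstack.voxel_thickness)
        assert register_pair(stack, noisy).slice_offset == -2

    def test_unrelated_stacks_flagged_unmatchable(self, stack):
        rng = np.random.default_rng(1)
        noise = ImageStack(data=rng.normal(size=stack.data.shape),
                           voxel_inplane=stack.voxel_inplane,
                           voxel_thickness=stack.voxel_thickness)
        with pytest.raises(RegistrationError):
            register_pair(stack, noise, min_match_score=0.5)

    def test_match_report_serializable(self, stack):
        import json
        json.dumps(match_report(register_pair(stack, stack)))


class TestAnalysisVolume:
    def test_eight_slices_from_reference(self, stack):
        pair = register_pair(stack, stack)
        vol = select_analysis_volume(pair, 3)
        assert vol.baseline_volume.n_slices == 8
        np.testing.assert_array_equal(vol.baseline_volume.data,
                                      stack.data[3:11])
        np.testing.assert_array_equal(vol.followup_volume.data,
                                      stack.data[3:11])

    def test_insufficient_slices_listed(self, stack):
        pair = register_pair(stack, stack)  # 12 matched slices
        with pytest.raises(ImageIOError, match="6"):
            select_analysis_volume(pair, 6)
        with pytest.raises(ImageIOError):
            select_analysis_volume(pair, 5)

    def test_detected_reference_matches_marked_band(self, stack_and_truth):
        stack, truth = stack_and_truth
        assert detect_distal_reference(stack) == truth.distal_reference
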