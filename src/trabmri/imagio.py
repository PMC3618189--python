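"""Image-stack I/O and longitudinal slice matching.

An :class:`ImageStack` holds the ordered axial grey-level slices of one
subject-visit with its voxel geometry (in-plane size and slice thickness in
mm), read from / written to multi-page TIFF or NIfTI.

Longitudinal matching reproduces the step that makes baseline and follow-up
measurements cover the same anatomical volume: an exhaustive search over
integer through-plane slice offsets (slice thickness, 1 mm, is ~5× the
in-plane resolution, so no through-plane interpolation is done), with an
in-plane rigid transform (translation via phase correlation, plus a small
discrete rotation search) estimated per matched slice pair. The similarity
metric is the normalized cross-correlation (NCC) after alignment, robust to
global intensity rescaling between visits. A pair whose best mean NCC falls
below a configurable floor is flagged unmatchable, mirroring the exclusion of
motion-artifact scans.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import nibabel as nib
import tifffile
from scipy import ndimage
from skimage.registration import phase_cross_correlation

MIN_SLICES = 8


class ImageIOError(RuntimeError):
    pass


class RegistrationError(RuntimeError):
    """Best match score below the floor: pair flagged unmatchable."""


@dataclass(frozen=True)
class ImageStack:
    """Ordered axial grey-level slices with voxel geometry."""

    data: np.ndarray            # (n_slices, H, W) float32
    voxel_inplane: float        # mm
    voxel_thickness: float      # mm
    subject_id: str = ""
    visit: str = ""

    def __post_init__(self):
        data = np.asarray(self.data, dtype=np.float32)
        object.__setattr__(self, "data", data)
        if data.ndim != 3:
            raise ImageIOError("stack data must be (n_slices, H, W)")
        if data.shape[0] < MIN_SLICES:
            raise ImageIOError(
                f"stack has {data.shape[0]} slices; at least {MIN_SLICES} required")
        if self.voxel_inplane <= 0 or self.voxel_thickness <= 0:
            raise ImageIOError("voxel sizes must be positive")

    @property
    def n_slices(self) -> int:
        return int(self.data.shape[0])

    def __iter__(self):
        return iter(self.data)


@dataclass(frozen=True)
class MatchedPair:
    """Slice-matched baseline/follow-up volumes of one subject.

    ``inplane_transform`` is (shift_x, shift_y, rotation_deg) mapping the
    follow-up onto the baseline (apply the rotation about the image centre,
    then the shift, to a follow-up slice to align it with its baseline
    partner). Per-slice estimates are kept in ``per_slice_transforms``.
    """

    baseline_volume: ImageStack
    followup_volume: ImageStack
    slice_offset: int
    inplane_transform: tuple[float, float, float]
    match_score: float
    per_slice_transforms: tuple[tuple[float, float, float], ...] = ()
    baseline_start: int = 0     # index of first matched slice in the baseline stack

    def __post_init__(self):
        if self.baseline_volume.n_slices != self.followup_volume.n_slices:
            raise ImageIOError("matched volumes must have equal slice counts")


# ---------------------------------------------------------------------------
# I/O

def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF (.tif) or NIfTI (.nii/.nii.gz)."""
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(
            path, stack.data, imagej=True,
            resolution=(1.0 / stack.voxel_inplane, 1.0 / stack.voxel_inplane),
            metadata={"spacing": stack.voxel_thickness, "unit": "mm"},
        )
    elif path.name.endswith((".nii", ".nii.gz")):
        affine = np.diag([stack.voxel_inplane, stack.voxel_inplane,
                          stack.voxel_thickness, 1.0])
        img = nib.Nifti1Image(np.transpose(stack.data, (2, 1, 0)), affine)
        img.header.set_zooms((stack.voxel_inplane, stack.voxel_inplane,
                              stack.voxel_thickness))
        nib.save(img, path)
    else:
        raise ImageIOError(f"unsupported format: {path.suffix}")
    return path


def read_stack(path: str | Path, *, voxel_inplane: float | None = None,
               voxel_thickness: float | None = None,
               subject_id: str = "", visit: str = "") -> ImageStack:
    """Read a TIFF or NIfTI stack; voxel geometry from metadata or override.

    Raises :class:`ImageIOError` naming the missing field when the file
    carries no voxel geometry and no override is given.
    """
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"no such file: {path}")
    if path.suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            page = tif.pages[0]
            xres = page.tags.get("XResolution")
            if voxel_inplane is None:
                # a default 1:1 resolution tag carries no real geometry
                if xres is None or xres.value[0] == 0 or \
                        xres.value[1] / xres.value[0] == 1.0:
                    raise ImageIOError("missing voxel metadata: voxel_inplane")
                voxel_inplane = xres.value[1] / xres.value[0]
            if voxel_thickness is None:
                meta = tif.imagej_metadata or {}
                if "spacing" not in meta:
                    raise ImageIOError("missing voxel metadata: voxel_thickness")
                voxel_thickness = float(meta["spacing"])
    elif path.name.endswith((".nii", ".nii.gz")):
        img = nib.load(path)
        data = np.transpose(np.asanyarray(img.dataobj), (2, 1, 0))
        zooms = img.header.get_zooms()
        if voxel_inplane is None:
            voxel_inplane = float(zooms[0])
        if voxel_thickness is None:
            voxel_thickness = float(zooms[2])
    else:
        raise ImageIOError(f"unsupported format: {path.suffix}")
    return ImageStack(data=np.asarray(data, np.float32),
                      voxel_inplane=float(voxel_inplane),
                      voxel_thickness=float(voxel_thickness),
                      subject_id=subject_id, visit=visit)


# ---------------------------------------------------------------------------
# registration

def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def _align_translation(ref: np.ndarray, mov: np.ndarray
                       ) -> tuple[np.ndarray, tuple[float, float]]:
    shift, _, _ = phase_cross_correlation(ref, mov, upsample_factor=10,
                                          normalization=None)
    aligned = ndimage.shift(mov, shift, order=1, mode="nearest")
    # (shift_x, shift_y) with x = column, y = row
    return aligned, (float(shift[1]), float(shift[0]))


def _align_rigid(ref: np.ndarray, mov: np.ndarray, angles_deg
                 ) -> tuple[tuple[float, float, float], float]:
    best = None
    for ang in angles_deg:
        rot = mov if ang == 0 else ndimage.rotate(mov, ang, reshape=False,
                                                  order=1, mode="nearest")
        aligned, (sx, sy) = _align_translation(ref, rot)
        score = _ncc(ref, aligned)
        if best is None or score > best[1]:
            best = ((sx, sy, float(ang)), score)
    return best


def register_pair(
    baseline: ImageStack,
    followup: ImageStack,
    *,
    max_slice_offset: int = 3,
    rotation_search_deg=(-3.0, -2.0, -1.0, 0.0, 1.0, 2.0, 3.0),
    min_match_score: float = 0.5,
) -> MatchedPair:
    """Match follow-up slices to baseline slices and estimate the rigid transform.

    Through-plane: exhaustive search over integer slice offsets ``k`` in
    ``[-max_slice_offset, max_slice_offset]`` maximizing the mean NCC of the
    overlapping slice pairs (baseline[j] vs follow-up[j + k]) after
    translation alignment. In-plane: per matched pair, a discrete rotation
    search with phase-correlation translation at each angle; the pair-level
    transform is the per-slice median. Deterministic for fixed inputs.
    """
    if baseline.data.shape[1:] != followup.data.shape[1:]:
        raise ImageIOError("stacks have different slice dimensions")
    if not np.isclose(baseline.voxel_inplane, followup.voxel_inplane):
        raise ImageIOError("stacks have different voxel geometry")

    n_b, n_f = baseline.n_slices, followup.n_slices
    best_k, best_score = None, -np.inf
    for k in range(-max_slice_offset, max_slice_offset + 1):
        scores = []
        for j in range(n_b):
            jf = j + k
            if jf < 0 or jf >= n_f:
                continue
            aligned, _ = _align_translation(baseline.data[j], followup.data[jf])
            scores.append(_ncc(baseline.data[j], aligned))
        if scores and np.mean(scores) > best_score:
            best_score = float(np.mean(scores))
            best_k = k

    if best_k is None:
        raise RegistrationError("no overlapping slices at any offset")

    # rigid refinement at the selected offset
    per_slice, scores, base_idx = [], [], []
    for j in range(n_b):
        jf = j + best_k
        if jf < 0 or jf >= n_f:
            continue
        (transform, score) = _align_rigid(baseline.data[j], followup.data[jf],
                                          rotation_search_deg)
        per_slice.append(transform)
        scores.append(score)
        base_idx.append(j)

    match_score = float(np.mean(scores))
    if match_score < min_match_score:
        raise RegistrationError(
            f"best match score {match_score:.3f} below floor {min_match_score}")

    med = tuple(float(np.median([t[i] for t in per_slice])) for i in range(3))
    start = base_idx[0]
    stop = base_idx[-1] + 1
    sub_b = replace(baseline, data=baseline.data[start:stop])
    sub_f = replace(followup, data=followup.data[start + best_k:stop + best_k])
    return MatchedPair(
        baseline_volume=sub_b,
        followup_volume=sub_f,
        slice_offset=best_k,
        inplane_transform=med,
        match_score=match_score,
        per_slice_transforms=tuple(per_slice),
        baseline_start=start,
    )


def select_analysis_volume(pair: MatchedPair, distal_reference_slice: int
                           ) -> MatchedPair:
    """Restrict a matched pair to the 8 contiguous slices starting at the
    distal reference (index within the matched baseline volume)."""
    n = pair.baseline_volume.n_slices
    r = distal_reference_slice - pair.baseline_start
    available = n - r
    if r < 0 or available < MIN_SLICES:
        raise ImageIOError(
            f"need {MIN_SLICES} contiguous matched slices from reference "
            f"{distal_reference_slice}; only {max(available, 0)} available")
    sl = slice(r, r + MIN_SLICES)
    return replace(
        pair,
        baseline_volume=replace(pair.baseline_volume,
                                data=pair.baseline_volume.data[sl]),
        followup_volume=replace(pair.followup_volume,
                                data=pair.followup_volume.data[sl]),
        per_slice_transforms=pair.per_slice_transforms[sl],
        baseline_start=distal_reference_slice,
    )


def detect_distal_reference(stack: ImageStack, *, band_drop: float = 0.5) -> int:
    """Detect the first slice proximal to the dense (growth-plate-like) band.

    Uses the per-slice bone fraction inside the segmented endosteal region:
    the distal band is markedly denser, so the reference is the first slice
    whose bone fraction falls below the midpoint between the maximum and
    minimum per-slice fractions (weighted by ``band_drop``).
    """
    from .segment import binarize, segment_endosteal

    fracs = []
    for sl in stack.data:
        m = segment_endosteal(sl, stack.voxel_inplane)
        fracs.append(binarize(sl, m).bone_fraction)
    fracs = np.asarray(fracs)
    cut = fracs.min() + band_drop * (fracs.max() - fracs.min())
    below = np.nonzero(fracs < cut)[0]
    return int(below[0]) if below.size else 0


def match_report(pair: MatchedPair) -> dict:
    """JSON-serializable registration report for one subject."""
    return {
        "slice_offset": pair.slice_offset,
        "inplane_transform": {
            "shift_x": pair.inplane_transform[0],
            "shift_y": pair.inplane_transform[1],
            "rotation_deg": pair.inplane_transform[2],
        },
        "match_score": pair.match_score,
        "n_matched_slices": pair.baseline_volume.n_slices,
    }


def write_match_report(pair: MatchedPair, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(match_report(pair), indent=2))
    return path
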