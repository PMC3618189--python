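"""Synthetic trabecular image stacks, longitudinal pairs and two-group cohorts.

Every downstream stage (segmentation, morphometry, network analysis,
longitudinal change, inference) is testable against known ground truth
without external data. The generator emulates a 1 T peripheral-MRI
acquisition of the distal radius: 20 axial slices of 195 µm × 195 µm × 1 mm
voxels, a dark cortical rim enclosing a trabecular network with bone volume
fraction ≈ 47–48 %, ≈ 65–75 marrow holes per slice of ≈ 2 mm² mean area, and
an endosteal area ≈ 260–270 mm².

Texture model
-------------
Trabecular texture is a thresholded smoothed Gaussian random field: white
noise smoothed at a correlation length calibrated (per slice, by bisection)
so that the number of 4-connected marrow components inside the endosteal
disc hits the requested hole count; the threshold is the field quantile that
realizes the requested bone fraction essentially exactly. Intensities are
two-class — bone dark, marrow bright, as in gradient-echo MRI of bone — with
a Gaussian point-spread blur and additive Gaussian noise so the binarization
stage is exercised under class-contrast degradation.

Slices are generated as independent 2-D textures: the acquisition voxels are
~5× anisotropic and all measurements are per-slice, so through-plane blur is
deliberately not simulated.

Follow-up visits derive from baseline ground truth by surface-first removal
of a stated fraction of trabecular bone (resorption-like thinning), a rigid
in-plane transform, an integer through-plane slice offset, and fresh noise;
all perturbation parameters are recorded as ground truth.

Cohorts are simulated on two levels. The outcome table (per-subject,
per-variable baseline values and percent changes, group and ethnicity
structure) is drawn numerically at the scales observed in the emulated
study; image stacks can additionally be rendered for each subject-visit,
driven by that table's BVTV / hole-count / endosteal-area targets, with
structural change rendered as bone loss plus rigid misalignment. Exact
per-variable percent-change effects are planted in the table — a pixel-level
generator cannot realize nine correlated outcome changes simultaneously —
so statistical recovery tests operate on the table while pipeline tests
operate on rendered stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .imagio import ImageStack
from .segment import CROSS

# grey levels: bone dark, marrow/soft tissue bright (gradient-echo-like)
BONE_LEVEL = 60.0
MARROW_LEVEL = 190.0
BACKGROUND_LEVEL = 170.0

#: Outcome-variable scales emulating the observed two-group study:
#: baseline mean/SD, control-group mean percent change, percent-change SD.
VARIABLE_SCALES: dict[str, dict[str, float]] = {
    "hole_size":       {"mean": 2.07, "sd": 0.44, "ctrl_pct": 5.0,  "pct_sd": 18.0},
    "hole_count":      {"mean": 70.0, "sd": 16.0, "ctrl_pct": -7.1, "pct_sd": 20.0},
    "endosteal_area":  {"mean": 268.0, "sd": 55.0, "ctrl_pct": -4.5, "pct_sd": 16.0},
    "bvtv":            {"mean": 47.7, "sd": 1.1,  "ctrl_pct": 0.1,  "pct_sd": 1.7},
    "tbth":            {"mean": 0.515, "sd": 0.01, "ctrl_pct": -0.3, "pct_sd": 1.9},
    "tbsp":            {"mean": 0.545, "sd": 0.015, "ctrl_pct": -0.2, "pct_sd": 1.5},
    "tbn":             {"mean": 0.925, "sd": 0.03, "ctrl_pct": 0.3,  "pct_sd": 1.9},
    "nodal_density":   {"mean": 0.16, "sd": 0.01, "ctrl_pct": -3.8, "pct_sd": 6.5},
    "branch_density":  {"mean": 0.41, "sd": 0.055, "ctrl_pct": 3.3, "pct_sd": 13.4},
}

#: Default planted group effect (diabetes − control) on mean percent change,
#: emulating the adjusted two-year differences of the emulated study.
DEFAULT_EFFECT_PCT: dict[str, float] = {
    "hole_size": -9.1, "hole_count": 17.2, "endosteal_area": 7.3,
    "bvtv": 0.6, "tbth": -0.3, "tbsp": -0.8, "tbn": 1.0,
    "nodal_density": 3.0, "branch_density": -2.8,
}


class InfeasibleParameters(ValueError):
    """Requested texture targets cannot be realized; never silently clipped."""


@dataclass(frozen=True)
class TrabecularParams:
    """Targets and acquisition parameters for one synthetic slice/stack."""

    target_bvtv: float = 0.477          # bone fraction inside endosteal disc
    target_tbth: float = 0.52           # mm; realized thickness is emergent
    hole_count_target: int = 70         # marrow components per slice
    endosteal_radius: float = 9.2       # mm -> area ~ pi r^2 ~ 266 mm^2
    cortical_thickness: float = 2.0     # mm
    noise_sd: float = 15.0              # grey-level units
    psf_fwhm: float = 0.2               # mm
    seed: int = 0
    voxel_inplane: float = 0.195        # mm
    voxel_thickness: float = 1.0        # mm
    image_size: int = 128               # pixels per side

    def __post_init__(self):
        if not (0.2 < self.target_bvtv < 0.8):
            raise InfeasibleParameters("target_bvtv must lie in (0.2, 0.8)")
        if self.target_tbth <= self.voxel_inplane:
            raise InfeasibleParameters("target_tbth must exceed the voxel size")
        if self.hole_count_target < 1:
            raise InfeasibleParameters("hole_count_target must be positive")
        r_out = (self.endosteal_radius + self.cortical_thickness) / self.voxel_inplane
        if r_out >= self.image_size / 2 - 2:
            raise InfeasibleParameters("endosteal region exceeds the field of view")


@dataclass(frozen=True)
class Perturbation:
    """Controlled structural change plus rigid misalignment for a follow-up."""

    bone_loss_fraction: float = 0.0
    shift: tuple[float, float] = (0.0, 0.0)     # (rows, cols) voxels
    rotation_deg: float = 0.0
    slice_offset: int = 0
    noise_sd: float | None = None               # None -> baseline noise

    def __post_init__(self):
        if not (0.0 <= self.bone_loss_fraction < 1.0):
            raise InfeasibleParameters("bone_loss_fraction must lie in [0, 1)")


@dataclass(frozen=True)
class SliceTruth:
    """Exact ground truth for one slice."""

    bone: np.ndarray            # bool; trabecular bone AND cortical rim
    endosteal: np.ndarray       # bool disc inside the endosteal border
    periosteal: np.ndarray      # bool disc out to the periosteal border
    hole_labels: np.ndarray     # int; 4-connected marrow components in disc
    hole_areas_px: np.ndarray   # per-hole pixel counts, label order

    @property
    def trabecular_bone(self) -> np.ndarray:
        return self.bone & self.endosteal

    @property
    def bone_fraction(self) -> float:
        return float(self.trabecular_bone.sum()) / float(self.endosteal.sum())


@dataclass(frozen=True)
class StackTruth:
    """Per-slice ground truth plus stack-level annotations."""

    slices: tuple[SliceTruth, ...]
    params: TrabecularParams
    distal_reference: int = 0               # first slice proximal to the band
    perturbation: Perturbation | None = None


@dataclass(frozen=True)
class CohortSpec:
    """Statistical structure of a two-group longitudinal cohort."""

    n_diabetes: int = 14
    n_control: int = 21
    effect_pct_change: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_PCT))
    ethnicity_prob: tuple[float, float] = (0.8, 1.0)   # P(Caucasian): (diabetes, control)
    # offset on the primary outcome's percent change for Caucasian subjects,
    # sized so the population ethnicity-outcome correlation is ~ -0.36 at the
    # default group sizes and Caucasian fractions
    ethnicity_effect_pct: Mapping[str, float] = field(
        default_factory=lambda: {"hole_size": -33.0})
    followup_months_mean_sd: tuple[float, float] = (25.4, 1.9)
    seed: int = 0

    def __post_init__(self):
        if self.n_diabetes < 2 or self.n_control < 2:
            raise InfeasibleParameters("group sizes must be at least 2")
        if not all(0.0 <= p <= 1.0 for p in self.ethnicity_prob):
            raise InfeasibleParameters("ethnicity probabilities must lie in [0, 1]")


# ---------------------------------------------------------------------------
# single slices

def _grids(params: TrabecularParams):
    n = params.image_size
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    dist = np.hypot(yy - c, xx - c)
    r_in = params.endosteal_radius / params.voxel_inplane
    r_out = r_in + params.cortical_thickness / params.voxel_inplane
    return dist <= r_in, (dist > r_in) & (dist <= r_out), dist <= r_out


def _threshold_field(field2d: np.ndarray, disc: np.ndarray, bvtv: float
                     ) -> np.ndarray:
    thr = np.quantile(field2d[disc], bvtv)
    return (field2d <= thr) & disc


def _hole_count(bone_in: np.ndarray, disc: np.ndarray) -> int:
    _, n = ndimage.label(disc & ~bone_in, structure=CROSS)
    return n


def _calibrate_sigma(white: np.ndarray, disc: np.ndarray,
                     params: TrabecularParams) -> float:
    """Bisect the smoothing length so the marrow component count hits target."""
    lo, hi = 0.6, 10.0

    def count(sigma: float) -> int:
        sm = ndimage.gaussian_filter(white, sigma)
        return _hole_count(_threshold_field(sm, disc, params.target_bvtv), disc)

    c_lo, c_hi = count(lo), count(hi)
    target = params.hole_count_target
    if not (c_hi <= target <= c_lo):
        raise InfeasibleParameters(
            f"hole_count_target={target} unreachable at target_bvtv="
            f"{params.target_bvtv} (achievable range [{c_hi}, {c_lo}])")
    for _ in range(22):
        mid = 0.5 * (lo + hi)
        if count(mid) >= target:
            lo = mid
        else:
            hi = mid
    sigma = lo if abs(count(lo) - target) <= abs(count(hi) - target) else hi
    if abs(count(sigma) - target) > max(3, 0.15 * target):
        raise InfeasibleParameters(
            f"could not calibrate hole count near {target} (got {count(sigma)})")
    return sigma


def render_grey(truth: SliceTruth, params: TrabecularParams,
                rng: np.random.Generator | None = None) -> np.ndarray:
    """Render a grey-level slice from ground truth: two-class intensities,
    Gaussian PSF blur, additive Gaussian noise."""
    img = np.full(truth.bone.shape, BACKGROUND_LEVEL)
    img[truth.periosteal] = MARROW_LEVEL
    img[truth.bone] = BONE_LEVEL
    if params.psf_fwhm > 0:
        sigma = params.psf_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / params.voxel_inplane
        img = ndimage.gaussian_filter(img, sigma)
    if params.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(params.seed)
        img = img + rng.normal(0.0, params.noise_sd, img.shape)
    return img.astype(np.float32)


def _truth_from_bone(bone_in: np.ndarray, disc: np.ndarray, rim: np.ndarray,
                     peri: np.ndarray) -> SliceTruth:
    labels, n = ndimage.label(disc & ~bone_in, structure=CROSS)
    areas = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, n + 1)).astype(int)
    return SliceTruth(bone=bone_in | rim, endosteal=disc, periosteal=peri,
                      hole_labels=labels, hole_areas_px=areas)


def generate_slice(params: TrabecularParams,
                   rng: np.random.Generator | None = None,
                   bvtv_override: float | None = None,
                   ) -> tuple[np.ndarray, SliceTruth]:
    """Generate one grey-level slice with exact ground truth.

    Returns ``(grey, truth)``; the ground-truth bone fraction inside the
    endosteal disc equals the target up to quantile granularity (well inside
    ±0.03) and the ground-truth holes enumerate every 4-connected marrow
    component with exact pixel areas.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    bvtv = params.target_bvtv if bvtv_override is None else bvtv_override
    disc, rim, peri = _grids(params)
    white = rng.standard_normal((params.image_size, params.image_size))
    p_eff = params if bvtv_override is None else replace(params, target_bvtv=bvtv)
    sigma = _calibrate_sigma(white, disc, p_eff)
    bone_in = _threshold_field(ndimage.gaussian_filter(white, sigma), disc, bvtv)
    truth = _truth_from_bone(bone_in, disc, rim, peri)
    grey = render_grey(truth, params, rng)
    return grey, truth


# ---------------------------------------------------------------------------
# stacks

def generate_stack(params: TrabecularParams, *, n_slices: int = 20,
                   band_slices: int = 2, band_bvtv: float = 0.65,
                   subject_id: str = "", visit: str = "baseline",
                   ) -> tuple[ImageStack, StackTruth]:
    """Generate a baseline stack of independent axial slices.

    The first ``band_slices`` slices emulate the dense metaphyseal band at
    the growth-plate region (elevated bone fraction); the recorded distal
    reference is the first slice proximal to that band.
    """
    greys, truths = [], []
    for i in range(n_slices):
        rng = np.random.default_rng([params.seed, i])
        dense = i < band_slices
        # the dense band keeps the same texture scale but a higher bone
        # fraction; the hole-count calibration applies to trabecular slices
        if dense:
            disc, rim, peri = _grids(params)
            white = rng.standard_normal((params.image_size, params.image_size))
            sigma = _calibrate_sigma(white, disc, params)
            bone_in = _threshold_field(ndimage.gaussian_filter(white, sigma),
                                       disc, band_bvtv)
            truth = _truth_from_bone(bone_in, disc, rim, peri)
            greys.append(render_grey(truth, params, rng))
            truths.append(truth)
        else:
            g, t = generate_slice(params, rng=rng)
            greys.append(g)
            truths.append(t)
    stack = ImageStack(data=np.stack(greys), voxel_inplane=params.voxel_inplane,
                       voxel_thickness=params.voxel_thickness,
                       subject_id=subject_id, visit=visit)
    return stack, StackTruth(slices=tuple(truths), params=params,
                             distal_reference=band_slices)


def _remove_bone(truth: SliceTruth, fraction: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Remove ``fraction`` of trabecular bone pixels, surface first."""
    trab = truth.trabecular_bone
    n_remove = int(round(fraction * trab.sum()))
    if n_remove == 0:
        return truth.bone.copy()
    marrow = truth.endosteal & ~truth.bone
    depth = ndimage.distance_transform_edt(~marrow)
    ii, jj = np.nonzero(trab)
    order = np.lexsort((rng.random(ii.size), depth[ii, jj]))
    keep = truth.bone.copy()
    keep[ii[order[:n_remove]], jj[order[:n_remove]]] = False
    return keep


def _rigid(arr: np.ndarray, shift: tuple[float, float], rotation_deg: float
           ) -> np.ndarray:
    out = arr.astype(np.uint8)
    if rotation_deg != 0:
        out = ndimage.rotate(out, rotation_deg, reshape=False, order=0)
    if shift != (0.0, 0.0):
        out = ndimage.shift(out, shift, order=0, cval=0)
    return out.astype(bool)


def generate_followup(baseline_truth: StackTruth, perturbation: Perturbation,
                      *, seed: int | None = None, subject_id: str = "",
                      ) -> tuple[ImageStack, StackTruth]:
    """Derive a follow-up stack from baseline ground truth.

    Per slice: remove the stated fraction of trabecular bone (surface-first
    thinning), apply the rigid in-plane transform, re-render grey levels with
    fresh noise; then offset the slice order by ``slice_offset`` (follow-up
    slice ``j`` derives from baseline slice ``j − slice_offset``, cyclically).
    Raises when the transform pushes the structure outside the field of view.
    """
    params = baseline_truth.params
    if seed is None:
        seed = params.seed + 1
    p_noise = params if perturbation.noise_sd is None else replace(
        params, noise_sd=perturbation.noise_sd)

    n = len(baseline_truth.slices)
    greys, truths = [], []
    for j in range(n):
        src = baseline_truth.slices[(j - perturbation.slice_offset) % n]
        rng = np.random.default_rng([seed, j])
        bone = _remove_bone(src, perturbation.bone_loss_fraction, rng)
        moved = {}
        for name, arr in (("bone", bone), ("endosteal", src.endosteal),
                          ("periosteal", src.periosteal)):
            moved[name] = _rigid(arr, perturbation.shift,
                                 perturbation.rotation_deg)
        if moved["periosteal"].sum() != src.periosteal.sum():
            raise InfeasibleParameters(
                "rigid transform pushes the bone cross-section outside the "
                "field of view")
        labels, ncomp = ndimage.label(moved["endosteal"] & ~moved["bone"],
                                      structure=CROSS)
        areas = ndimage.sum_labels(np.ones_like(labels), labels,
                                   index=np.arange(1, ncomp + 1)).astype(int)
        truth = SliceTruth(bone=moved["bone"], endosteal=moved["endosteal"],
                           periosteal=moved["periosteal"],
                           hole_labels=labels, hole_areas_px=areas)
        greys.append(render_grey(truth, p_noise, rng))
        truths.append(truth)

    stack = ImageStack(data=np.stack(greys), voxel_inplane=params.voxel_inplane,
                       voxel_thickness=params.voxel_thickness,
                       subject_id=subject_id, visit="followup")
    return stack, StackTruth(
        slices=tuple(truths), params=params,
        distal_reference=baseline_truth.distal_reference + perturbation.slice_offset,
        perturbation=perturbation)


# ---------------------------------------------------------------------------
# cohorts

def generate_cohort(
    spec: CohortSpec,
    *,
    render: bool = False,
    params: TrabecularParams | None = None,
    n_slices: int = 12,
) -> dict:
    """Simulate a two-group longitudinal cohort with known ground truth.

    Returns a dict with:

    ``table``
        One row per subject-visit: ``subject_id, group, ethnicity, visit,
        months_since_baseline`` plus the nine outcome variables.
    ``truth``
        One row per subject: planted per-variable percent changes plus group
        and ethnicity.
    ``stacks``
        When ``render=True``, ``{(subject_id, visit): (ImageStack,
        StackTruth)}`` rendered from the table's BVTV / hole-count /
        endosteal-area targets with bone loss + rigid misalignment.

    The per-group per-variable mean percent changes differ by
    ``spec.effect_pct_change`` in expectation (Caucasian subjects receive the
    additional ``ethnicity_effect_pct`` offsets, emulating the
    ethnicity–outcome association of the emulated study).
    """
    if spec.n_diabetes < 3 or spec.n_control < 3:
        raise InfeasibleParameters(
            "at least 3 subjects per group are required for regression with "
            "one covariate")
    rng = np.random.default_rng(spec.seed)
    variables = list(VARIABLE_SCALES)
    # the ethnicity offset is centred on the expected Caucasian fraction so
    # it induces the covariate-outcome correlation without shifting the
    # marginal group means away from their emulated values
    n_total = spec.n_diabetes + spec.n_control
    p_cauc_bar = (spec.n_diabetes * spec.ethnicity_prob[0]
                  + spec.n_control * spec.ethnicity_prob[1]) / n_total
    rows, truth_rows = [], []
    stacks: dict[tuple[str, str], tuple[ImageStack, StackTruth]] = {}
    base_params = params or TrabecularParams()

    sid = 0
    for group, n_g, p_cauc in (("diabetes", spec.n_diabetes, spec.ethnicity_prob[0]),
                               ("control", spec.n_control, spec.ethnicity_prob[1])):
        for _ in range(n_g):
            sid += 1
            subject = f"S{sid:03d}"
            caucasian = bool(rng.random() < p_cauc)
            months = float(rng.normal(*spec.followup_months_mean_sd))

            baseline, pct = {}, {}
            for v in variables:
                sc = VARIABLE_SCALES[v]
                baseline[v] = float(np.clip(
                    rng.normal(sc["mean"], sc["sd"]),
                    0.05 * sc["mean"], None))
                mu = sc["ctrl_pct"]
                if group == "diabetes":
                    mu += float(spec.effect_pct_change.get(v, 0.0))
                mu += float(spec.ethnicity_effect_pct.get(v, 0.0)) * (
                    float(caucasian) - p_cauc_bar)
                pct[v] = float(rng.normal(mu, sc["pct_sd"]))
            # keep the histomorphometric identity at baseline
            baseline["tbn"] = baseline["bvtv"] / 100.0 / baseline["tbth"]
            followup = {v: baseline[v] * (1.0 + pct[v] / 100.0)
                        for v in variables}

            for visit, vals, m in (("baseline", baseline, 0.0),
                                   ("followup", followup, months)):
                rows.append({"subject_id": subject, "group": group,
                             "ethnicity": "caucasian" if caucasian else "non_caucasian",
                             "visit": visit, "months_since_baseline": round(m, 2),
                             **{v: vals[v] for v in variables}})
            truth_rows.append({"subject_id": subject, "group": group,
                               "caucasian": caucasian,
                               **{f"pct_{v}": pct[v] for v in variables}})

            if render:
                sub_seed = int(rng.integers(0, 2**31 - 1))
                # radius capped so the cortical shell stays inside the FOV
                radius = float(np.clip(
                    np.sqrt(baseline["endosteal_area"] / np.pi), 7.0, 9.8))
                # the realizable hole count scales with the disc area; cap
                # the rendering target at the feasible density (the numeric
                # table stays the statistical ground truth)
                disc_px = np.pi * (radius / base_params.voxel_inplane) ** 2
                max_holes = int(0.0110 * disc_px)
                p_sub = replace(
                    base_params,
                    target_bvtv=float(np.clip(baseline["bvtv"] / 100.0, 0.25, 0.75)),
                    hole_count_target=int(np.clip(round(baseline["hole_count"]),
                                                  30, max_holes)),
                    endosteal_radius=radius,
                    seed=sub_seed,
                )
                b_stack, b_truth = generate_stack(p_sub, n_slices=n_slices,
                                                  subject_id=subject)
                pert = Perturbation(
                    bone_loss_fraction=float(np.clip(-pct["bvtv"] / 100.0, 0.0, 0.3)),
                    shift=(float(rng.integers(-3, 4)), float(rng.integers(-3, 4))),
                    rotation_deg=0.0,
                    slice_offset=int(rng.integers(-2, 3)),
                )
                f_stack, f_truth = generate_followup(b_truth, pert,
                                                     seed=sub_seed + 1,
                                                     subject_id=subject)
                stacks[(subject, "baseline")] = (b_stack, b_truth)
                stacks[(subject, "followup")] = (f_stack, f_truth)

    table = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    return {"table": table, "truth": truth, "stacks": stacks, "spec": spec}
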