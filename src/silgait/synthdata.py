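"""Synthetic test data with known ground truth.

Two generators:

* :func:`render_run` draws a rodent-like silhouette — an elliptical trunk
  with half-disk caps at both ends and a curved, tapering tail — moving
  across a walkway frame sequence, together with a paw-detection log and
  the exact nose-to-tail-base length.  The tail root half-width equals the
  species structuring-element radius, the regime in which the length
  formula's r_d correction is exact (about half the element sits in the
  tail-root area); the tail tapers below the removal threshold everywhere
  else so opening always deletes it.

* :func:`generate_cohort` simulates a longitudinal two-genotype study:
  per-animal body-length growth trajectories, run-level gait parameters
  coupled to length (stride ∝ length, speeds ∝ √length — dynamically
  similar, i.e. Froude-consistent — durations independent of length) with
  multiplicative log-normal noise, optional genotype-driven length and
  gait offsets, and the raw left/right CSV schema of the io module.

All randomness flows from an explicit seed; identical seeds give
bit-identical frames and tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import ellipse as _draw_ellipse

from .errors import ParameterError, RenderError
from .silhouette import (
    PawTrackSet,
    ResolutionSpec,
    RunInput,
    SPECIES_PROFILES,
    SpeciesProfile,
    make_diamond_se,
)

# --------------------------------------------------------------------------
# single-run renderer
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticRodentSpec:
    """Geometry and photometry of one rendered rodent (rat-like defaults).

    ``tail_width_px`` is the width at the tail *tip*; the root half-width
    is pinned to the structuring-element radius of the species profile.
    """

    body_length_mm: float = 220.0     # nose to tail base, ground truth
    body_width_mm: float = 40.0
    tail_length_mm: float = 160.0
    tail_width_px: int = 3
    orientation_deg: float = 0.0      # about the body centre; + bends nose down
    position: tuple[float, float] | None = None  # body centre (row, col) px
    body_rgb: tuple[int, int, int] = (200, 190, 180)
    background_rgb: tuple[int, int, int] = (60, 60, 60)
    noise_amplitude: int = 4          # additive uniform noise, < threshold/2
    resolution: ResolutionSpec = field(default_factory=lambda: ResolutionSpec(1.0, 1.0))
    species_profile: SpeciesProfile = field(
        default_factory=lambda: SPECIES_PROFILES["rat"]
    )
    speed_px_per_frame: float = 5.0
    frame_shape: tuple[int, int] | None = None  # (H, W); default auto-sized
    hole_radius_px: int = 3           # carved interior hole (0 disables)
    distractor: bool = True           # extra blob exercising largest-object

    def __post_init__(self) -> None:
        se = make_diamond_se(self.species_profile.r_d_mm, self.resolution)
        if self.tail_width_px >= 2 * se.r_d_px:
            raise ParameterError(
                "tail tip width must be below the structuring-element "
                f"diameter ({self.tail_width_px} >= {2 * se.r_d_px})"
            )
        if self.body_width_mm < 2 * self.species_profile.r_d_mm:
            raise ParameterError(
                "body width must be at least the structuring-element "
                "diameter so opening preserves the trunk"
            )
        if self.noise_amplitude * 2 > self.species_profile.threshold:
            raise ParameterError("noise amplitude must stay below threshold/2")


def _body_mask(
    shape: tuple[int, int],
    centre_mm: tuple[float, float],
    spec: SyntheticRodentSpec,
) -> np.ndarray:
    """Solid trunk: ellipse plus half-disk caps at nose and rear, drawn in
    physical (mm) coordinates so anisotropic pixels are handled."""
    h, w = shape
    res = spec.resolution
    rows = np.arange(h)[:, None] * res.y_mm
    cols = np.arange(w)[None, :] * res.x_mm
    cx, cy = centre_mm
    th = math.radians(spec.orientation_deg)
    u = (cols - cx) * math.cos(th) + (rows - cy) * math.sin(th)
    v = -(cols - cx) * math.sin(th) + (rows - cy) * math.cos(th)
    a = spec.body_length_mm / 2.0
    b = spec.body_width_mm / 2.0
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    mask |= (u - (a - b)) ** 2 + v**2 <= b**2   # nose cap
    mask |= (u + (a - b)) ** 2 + v**2 <= b**2   # rear cap
    return mask


def _stamp_tail(
    mask: np.ndarray,
    centre_mm: tuple[float, float],
    spec: SyntheticRodentSpec,
    se_footprint: np.ndarray,
) -> None:
    """Quadratic Bezier ribbon from the tail base, tapering from just under
    the structuring-element width at the root to the tip width, with one
    exact structuring-element footprint stamped at the base.

    The footprint is the widest part of the tail, so opening retains
    exactly it and nothing further down the ribbon: the silhouette
    protrudes into the tail by exactly the element radius, the regime the
    length formula's r_d subtraction corrects for.
    """
    res = spec.resolution
    th = math.radians(spec.orientation_deg)
    rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    a = spec.body_length_mm / 2.0
    t_len = spec.tail_length_mm
    r_px = (se_footprint.shape[0] - 1) // 2
    # control points in body coordinates (u along axis, v across); leave the
    # root along the body axis — a diagonal root would present a vertical
    # cross-section wider than the ribbon and survive opening
    p0 = np.array([-a, 0.0])
    p1 = np.array([-a - 0.55 * t_len, 0.0])
    p2 = np.array([-a - 0.95 * t_len, 0.25 * t_len])
    root_halfwidth_mm = (r_px - 0.5) * res.x_mm
    tip_halfwidth_mm = max(spec.tail_width_px * res.x_mm / 2.0, 0.5 * res.x_mm)
    cx, cy = centre_mm
    h, w = mask.shape
    for t in np.linspace(0.0, 1.0, 300):
        q = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2
        r_mm = (1 - t) * root_halfwidth_mm + t * tip_halfwidth_mm
        x, y = rot @ q + np.array([cx, cy])
        rr, cc = _draw_ellipse(
            y / res.y_mm, x / res.x_mm, r_mm / res.y_mm, r_mm / res.x_mm,
            shape=(h, w),
        )
        mask[rr, cc] = True
    # exact structuring-element stamp at the tail base
    bx, by = rot @ p0 + np.array([cx, cy])
    brow = int(round(by / res.y_mm))
    bcol = int(round(bx / res.x_mm))
    r0, c0 = brow - r_px, bcol - r_px
    rr, cc = np.nonzero(se_footprint)
    rr = rr + r0
    cc = cc + c0
    ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
    mask[rr[ok], cc[ok]] = True


def render_run(
    spec: SyntheticRodentSpec, n_frames: int = 4, seed: int = 0
) -> tuple[RunInput, PawTrackSet, dict]:
    """Render one run: ``n_frames`` frames of the rodent translating along
    the walkway, plus a clean-geometry background frame.

    The paw log marks the front paws on frames 1..n−1 and the hind paws on
    frames 2..n, so the analysis window is the interior frames 2..n−1.

    Returns ``(run_input, paw_tracks, ground_truth)`` where the ground
    truth records the exact nose-to-tail-base length and the solid (hole-
    free, tail-free) body pixel count per frame.
    """
    if n_frames < 3:
        raise ParameterError("need at least 3 frames for an interior window")
    res = spec.resolution
    se = make_diamond_se(spec.species_profile.r_d_mm, res)
    root_halfwidth_mm = se.r_d_px * res.x_mm

    travel_mm = spec.speed_px_per_frame * res.x_mm * (n_frames - 1)
    th = math.radians(spec.orientation_deg)
    body_vert = spec.body_width_mm / 2.0 + abs(math.sin(th)) * spec.body_length_mm / 2.0
    body_horz = spec.body_length_mm / 2.0 + spec.body_width_mm / 2.0
    tail_horz = spec.tail_length_mm + root_halfwidth_mm
    tail_vert = 0.25 * spec.tail_length_mm + root_halfwidth_mm
    vert = max(body_vert, tail_vert)
    if spec.frame_shape is not None:
        h, w = spec.frame_shape
    else:
        h = int(math.ceil((2.0 * vert + 20.0) / res.y_mm))
        w = int(math.ceil((tail_horz + 2.0 * body_horz + travel_mm + 30.0) / res.x_mm))
    if spec.position is not None:
        c_row, c_col = spec.position
        cx0, cy0 = c_col * res.x_mm, c_row * res.y_mm
    else:
        cx0 = tail_horz + body_horz + 10.0
        cy0 = (h / 2.0) * res.y_mm

    # fit check at first and last frame positions
    if (
        cx0 - body_horz - tail_horz < 0
        or cx0 + travel_mm + body_horz > w * res.x_mm
        or cy0 - vert < 0
        or cy0 + vert > h * res.y_mm
    ):
        raise RenderError(
            f"geometry does not fit in a {h}x{w} frame at resolution "
            f"{res.x_mm}x{res.y_mm} mm/px"
        )

    rng = np.random.default_rng(seed)
    bg_clean = np.empty((h, w, 3), np.int16)
    bg_clean[:] = np.array(spec.background_rgb, np.int16)
    background = np.clip(
        bg_clean + rng.integers(-spec.noise_amplitude, spec.noise_amplitude + 1,
                                size=bg_clean.shape),
        0, 255,
    ).astype(np.uint8)

    frames: list[np.ndarray] = []
    body_pixels: list[int] = []
    body_col_ranges: list[tuple[int, int]] = []
    centres: list[tuple[float, float]] = []
    for f in range(n_frames):
        cx = cx0 + f * spec.speed_px_per_frame * res.x_mm
        body = _body_mask((h, w), (cx, cy0), spec)
        body_pixels.append(int(body.sum()))
        bcols = np.flatnonzero(body.any(axis=0))
        body_col_ranges.append((int(bcols[0]), int(bcols[-1])))
        full = body.copy()
        _stamp_tail(full, (cx, cy0), spec, se.footprint)
        if spec.distractor:
            r_px = se.r_d_px + 2
            rr, cc = _draw_ellipse(r_px + 4, r_px + 6, r_px, r_px, shape=(h, w))
            full[rr, cc] = True
        img = bg_clean.copy()
        img[full] = np.array(spec.body_rgb, np.int16)
        if spec.hole_radius_px > 0:
            rr, cc = _draw_ellipse(
                cy0 / res.y_mm, cx / res.x_mm,
                spec.hole_radius_px, spec.hole_radius_px, shape=(h, w),
            )
            img[rr, cc] = np.array(spec.background_rgb, np.int16)
        img = np.clip(
            img + rng.integers(-spec.noise_amplitude, spec.noise_amplitude + 1,
                               size=img.shape),
            0, 255,
        ).astype(np.uint8)
        frames.append(img)
        centres.append((cy0 / res.y_mm, cx / res.x_mm))

    run = RunInput(
        frames=frames, background=background, resolution=res,
        species_profile=spec.species_profile,
    )
    tracks = PawTrackSet(
        f_RF=tuple(range(1, n_frames)),
        f_LF=tuple(range(1, n_frames)),
        f_RH=tuple(range(2, n_frames + 1)),
        f_LH=tuple(range(2, n_frames + 1)),
    )
    truth = {
        "length_mm": spec.body_length_mm,
        "length_cm": spec.body_length_mm / 10.0,
        "body_pixels": body_pixels,
        "body_col_ranges": body_col_ranges,
        "body_area_mm2": body_pixels[0] * res.pixel_area_mm2,
        "centres_px": centres,
        "r_d_px": se.r_d_px,
        "seed": seed,
    }
    return run, tracks, truth


# --------------------------------------------------------------------------
# longitudinal cohort generator
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Longitudinal two-genotype study conditions (rat-like defaults).

    The default growth trajectory and noise levels are calibrated so that
    the non-scaled stride-vs-length correlation in a wild-type cohort sits
    near 0.7, the rat-like regime; see docs/methods.md.
    """

    n_per_genotype: int = 16
    genotypes: tuple[str, ...] = ("WT", "TG")
    ages: tuple[float, ...] = (10.0, 18.0, 26.0, 34.0, 42.0)  # weeks
    mean_length_mm_by_age: tuple[float, ...] = (190.0, 215.0, 228.0, 236.0, 240.0)
    genotype_length_factor: dict = field(default_factory=dict)  # e.g. {"TG": 0.9}
    animal_length_sd_mm: float = 8.0     # persistent per-animal size offset
    age_length_sd_mm: float = 3.0        # per-age-point wobble
    beta_stride: float = 0.68            # stride_cm per length_cm
    beta_body_speed: float = 6.5         # cm/s per sqrt(cm)
    beta_swing_speed: float = 15.0       # cm/s per sqrt(cm)
    stride_length_exp: float = 1.0       # stride ~ length^exp (0 = uncoupled)
    speed_length_exp: float = 0.5        # speeds ~ length^exp (Froude-consistent)
    stand_time_s: float = 0.25
    swing_time_s: float = 0.12
    noise_sd: float = 0.08               # multiplicative, animal x age level
    run_noise_sd: float = 0.05           # multiplicative, run level
    lr_jitter_sd: float = 0.02           # left/right asymmetry
    genotype_param_factor: dict = field(default_factory=dict)
    # ^ direct gait offsets: {parameter: {genotype: factor}}
    n_runs: int = 3
    weight_coeff_g_cm3: float = 0.0376   # mass ~ length^3
    weight_noise_sd: float = 0.05
    area_coeff: float = 0.143            # a_sil ~ 0.143 * length_mm^2
    measurement_noise_sd: float = 0.01   # silhouette-length reading noise

    def __post_init__(self) -> None:
        if self.n_per_genotype < 2:
            raise ParameterError("need at least 2 animals per genotype")
        if len(self.ages) != len(self.mean_length_mm_by_age):
            raise ParameterError("one mean length per age point required")
        for sd in (self.animal_length_sd_mm, self.age_length_sd_mm,
                   self.noise_sd, self.run_noise_sd, self.lr_jitter_sd,
                   self.weight_noise_sd, self.measurement_noise_sd):
            if sd < 0:
                raise ParameterError("standard deviations must be >= 0")


def _geno_factor(spec: SyntheticCohortSpec, param: str, geno: str) -> float:
    return float(spec.genotype_param_factor.get(param, {}).get(geno, 1.0))


def generate_cohort(spec: SyntheticCohortSpec, seed: int = 0) -> pd.DataFrame:
    """Simulate the run-level gait table of a longitudinal study.

    Returns a DataFrame in the raw left/right CSV schema of the io module,
    plus per-run ``l_sil_cm`` / ``a_sil_mm2`` silhouette readings, the
    animal weight and the true body length (``true_length_cm``).
    """
    rng = np.random.default_rng(seed)
    means = np.asarray(spec.mean_length_mm_by_age, float)
    rows = []
    for geno in spec.genotypes:
        lf = float(spec.genotype_length_factor.get(geno, 1.0))
        for i in range(spec.n_per_genotype):
            animal = f"{geno}{i:02d}"
            offset = rng.normal(0.0, spec.animal_length_sd_mm)
            for age, mean_l in zip(spec.ages, means):
                length_mm = mean_l * lf + offset + rng.normal(0.0, spec.age_length_sd_mm)
                length_cm = length_mm / 10.0
                eta = {  # animal x age biological noise, shared by that session's runs
                    "stride": rng.normal(0.0, spec.noise_sd),
                    "speed": rng.normal(0.0, spec.noise_sd),
                    "swing_speed": rng.normal(0.0, spec.noise_sd),
                    "stand": rng.normal(0.0, spec.noise_sd),
                    "swing": rng.normal(0.0, spec.noise_sd),
                }
                weight = (
                    spec.weight_coeff_g_cm3 * length_cm**3
                    * math.exp(rng.normal(0.0, spec.weight_noise_sd))
                )
                for k in range(spec.n_runs):
                    row = {
                        "animal_id": animal,
                        "genotype": geno,
                        "age": age,
                        "run_id": f"{animal}_w{age:g}_r{k}",
                        "weight": weight,
                        "true_length_cm": length_cm,
                    }

                    def run_eps() -> float:
                        return float(rng.normal(0.0, spec.run_noise_sd))

                    def split(base: float, p: str, fh: str) -> None:
                        d = rng.normal(0.0, spec.lr_jitter_sd)
                        row[f"{p}_{fh}_left"] = base * math.exp(d)
                        row[f"{p}_{fh}_right"] = base * math.exp(-d)

                    for fh in ("front", "hind"):
                        stride = (
                            spec.beta_stride
                            * length_cm**spec.stride_length_exp
                            * math.exp(eta["stride"] + run_eps())
                            * _geno_factor(spec, "stride", geno)
                        )
                        split(stride, "stride", fh)
                        stand = (
                            spec.stand_time_s * math.exp(eta["stand"] + run_eps())
                            * _geno_factor(spec, "stand_time", geno)
                        )
                        swing = (
                            spec.swing_time_s * math.exp(eta["swing"] + run_eps())
                            * _geno_factor(spec, "swing_time", geno)
                        )
                        split(stand, "stand_time", fh)
                        split(swing, "swing_time", fh)
                        row[f"step_cycle_{fh}_left"] = (
                            row[f"stand_time_{fh}_left"] + row[f"swing_time_{fh}_left"]
                        )
                        row[f"step_cycle_{fh}_right"] = (
                            row[f"stand_time_{fh}_right"] + row[f"swing_time_{fh}_right"]
                        )
                        sw_speed = (
                            spec.beta_swing_speed
                            * length_cm**spec.speed_length_exp
                            * math.exp(eta["swing_speed"] + run_eps())
                            * _geno_factor(spec, "swing_speed", geno)
                        )
                        split(sw_speed, "swing_speed", fh)
                    v = (
                        spec.beta_body_speed
                        * length_cm**spec.speed_length_exp
                        * math.exp(eta["speed"] + run_eps())
                        * _geno_factor(spec, "body_speed", geno)
                    )
                    for paw in ("rf", "lf", "rh", "lh"):
                        row[f"body_speed_{paw}"] = v * math.exp(
                            rng.normal(0.0, spec.lr_jitter_sd)
                        )
                    row["l_sil_cm"] = length_cm * math.exp(
                        rng.normal(0.0, spec.measurement_noise_sd)
                    )
                    row["a_sil_mm2"] = (
                        spec.area_coeff * length_mm**2
                        * math.exp(rng.normal(0.0, 2 * spec.measurement_noise_sd))
                    )
                    rows.append(row)
    return pd.DataFrame(rows)
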