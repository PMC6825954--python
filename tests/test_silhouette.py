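"""Image-pipeline unit and property tests: frame window, background
subtraction, diamond element, opening, hole filling, largest object,
measurement, and run aggregation."""

import numpy as np
import pytest
from scipy import ndimage

from silgait import (
    DiamondSE,
    PawTrackSet,
    ResolutionSpec,
    RunInput,
    SPECIES_PROFILES,
    compute_frame_window,
    extract_frame_silhouette,
    fill_holes,
    make_diamond_se,
    measure_silhouette,
    open_remove_tail,
    process_run,
    retain_largest_object,
    subtract_background,
)
from silgait.errors import (
    EmptyWindowError,
    MissingPawError,
    NoSilhouetteError,
    ParameterError,
    ShapeError,
)

from oracles import diamond_offsets, opening_bf, random_blob_mask

RES1 = ResolutionSpec(1.0, 1.0)


# --------------------------------------------------------------------- window

@pytest.mark.parametrize(
    "rh, lh, rf, lf, expected",
    [
        ([3, 4], [5, 6], list(range(2, 91)), list(range(2, 88)), (5, 87)),
        (list(range(1, 11)),) * 3 + (list(range(1, 11)), (1, 10)),
    ],
)
def test_frame_window_from_paw_appearances(rh, lh, rf, lf, expected):
    tracks = PawTrackSet(f_RF=tuple(rf), f_LF=tuple(lf),
                         f_RH=tuple(rh), f_LH=tuple(lh))
    w = compute_frame_window(tracks)
    assert (w.f_start, w.f_stop) == expected


def test_frame_window_errors():
    with pytest.raises(MissingPawError):
        compute_frame_window(
            PawTrackSet(f_RF=(1,), f_LF=(1,), f_RH=(), f_LH=(1,))
        )
    with pytest.raises(EmptyWindowError):
        compute_frame_window(
            PawTrackSet(f_RF=(1, 4), f_LF=(1, 4), f_RH=(9,), f_LH=(2,))
        )


# --------------------------------------------------- background subtraction

def test_background_subtraction_threshold_is_strict_and_or_over_channels():
    bg = np.full((2, 2, 3), 100, np.uint8)
    frame = bg.copy()
    frame[0, 0] = (110, 110, 110)   # diff exactly 10 -> background
    frame[0, 1] = (100, 100, 111)   # one channel above -> foreground
    mask = subtract_background(frame, bg, 10)
    assert not mask[0, 0]
    assert mask[0, 1]
    assert not subtract_background(bg, bg, 10).any()


def test_background_subtraction_shape_mismatch():
    with pytest.raises(ShapeError):
        subtract_background(np.zeros((3, 3, 3)), np.zeros((3, 4, 3)), 10)


def test_grayscale_frames_are_promoted():
    bg = np.zeros((4, 4), np.uint8)
    frame = bg.copy()
    frame[1, 1] = 50
    assert subtract_background(frame, bg, 10)[1, 1]


# ------------------------------------------------------- structuring element

@pytest.mark.parametrize(
    "r_mm, x_mm, expected_px",
    [(5.0, 0.7, 7), (9.0, 1.0, 9), (0.2, 1.0, 1)],
)
def test_diamond_radius_conversion(r_mm, x_mm, expected_px):
    se = make_diamond_se(r_mm, ResolutionSpec(x_mm, x_mm))
    assert se.r_d_px == expected_px


def test_diamond_pixel_count_matches_lattice_enumeration():
    se = make_diamond_se(9.0, RES1)
    assert se.n_pixels == len(diamond_offsets(9)) == 181


def test_diamond_requires_positive_radius():
    with pytest.raises(ParameterError):
        make_diamond_se(0.0, RES1)


# ------------------------------------------------------------------ opening

def _se(r_px: int) -> DiamondSE:
    from skimage.morphology import diamond

    return DiamondSE(float(r_px), r_px, diamond(r_px).astype(bool))


def test_opening_removes_thin_line_keeps_disk():
    mask = np.zeros((60, 120), bool)
    yy, xx = np.ogrid[:60, :120]
    disk = (yy - 30) ** 2 + (xx - 30) ** 2 <= 20**2
    mask |= disk
    mask[30, 50:91] = True  # 1-px line, 40 px long
    opened = open_remove_tail(mask, _se(2))
    assert not opened[30, 60:91].any()          # line gone
    assert opened[disk].sum() >= 0.9 * disk.sum()  # disk mostly kept
    np.testing.assert_array_equal(opened, opening_bf(mask, diamond_offsets(2)))


def test_opening_with_single_pixel_element_is_identity(rng):
    mask = random_blob_mask(rng)
    se = DiamondSE(0.0, 0, np.ones((1, 1), bool))
    np.testing.assert_array_equal(open_remove_tail(mask, se), mask)


def test_opening_erases_mask_thinner_than_element():
    mask = np.zeros((30, 30), bool)
    mask[10, :] = True  # 1-px line
    assert not open_remove_tail(mask, _se(3)).any()


def test_opening_is_idempotent(rng):
    se = _se(2)
    for _ in range(10):
        mask = random_blob_mask(rng)
        once = open_remove_tail(mask, se)
        np.testing.assert_array_equal(open_remove_tail(once, se), once)


# ------------------------------------------------------ fill holes / largest

def test_fill_holes_annulus_blob_and_border_channel():
    yy, xx = np.ogrid[:40, :40]
    annulus = ((yy - 20) ** 2 + (xx - 20) ** 2 <= 15**2) & (
        (yy - 20) ** 2 + (xx - 20) ** 2 >= 8**2
    )
    filled = fill_holes(annulus)
    assert filled[20, 20]
    assert filled.sum() > annulus.sum()

    blob = (yy - 20) ** 2 + (xx - 20) ** 2 <= 10**2
    np.testing.assert_array_equal(fill_holes(blob), blob)

    open_region = np.ones((10, 10), bool)
    open_region[4:6, 4:] = False  # channel to the border
    np.testing.assert_array_equal(fill_holes(open_region), open_region)


def test_largest_object_selection_and_tie_break():
    mask = np.zeros((20, 40), bool)
    mask[2:12, 2:12] = True     # 100 px
    mask[5:10, 20:30] = True    # 50 px
    out = retain_largest_object(mask)
    assert out[:, :12].sum() == 100 and not out[:, 20:].any()

    single = np.zeros((5, 5), bool)
    single[1:3, 1:3] = True
    np.testing.assert_array_equal(retain_largest_object(single), single)

    tie = np.zeros((20, 40), bool)
    tie[10:15, 1:11] = True     # 50 px, first pixel later in scan order
    tie[2:7, 25:35] = True      # 50 px, first pixel earlier
    out = retain_largest_object(tie)
    assert out[2, 25] and not out[10, 1]

    with pytest.raises(NoSilhouetteError):
        retain_largest_object(np.zeros((4, 4), bool))


# -------------------------------------------------------------- measurement

def _line_mask(row, c0, c1, shape=(40, 300)):
    m = np.zeros(shape, bool)
    m[row, c0:c1 + 1] = True
    return m


@pytest.mark.parametrize(
    "c0, c1, r_px, x_mm, expected_cm",
    [
        (11, 250, 9, 1.0, 23.0),
        (50, 150, 7, 0.7, 6.51),
    ],
)
def test_length_formula_on_horizontal_silhouettes(c0, c1, r_px, x_mm, expected_cm):
    res = ResolutionSpec(x_mm, x_mm)
    mask = _line_mask(20, c0, c1)
    fs = measure_silhouette(mask, mask, _se(r_px), res)
    assert fs.length_cm == pytest.approx(expected_cm, abs=1e-9)


def test_length_clamps_to_zero_for_tiny_silhouette():
    mask = np.zeros((10, 10), bool)
    mask[5, 5] = True
    fs = measure_silhouette(mask, mask, _se(9), RES1)
    assert fs.length_cm == 0.0


def test_area_is_pixel_count_times_pixel_area():
    mask = np.zeros((50, 50), bool)
    mask[:40, :25] = True  # 1000 px
    res = ResolutionSpec(0.7, 0.7)
    fs = measure_silhouette(mask, mask, _se(1), res)
    assert fs.area_without_tail_mm2 == pytest.approx(490.0)


def test_area_with_tail_never_below_area_without(rat_render):
    run, tracks, _ = rat_render
    result = process_run(run, tracks)
    for fs in result.per_frame:
        assert fs.area_with_tail_mm2 >= fs.area_without_tail_mm2


# ---------------------------------------------------------------- run level

def _rect_run(widths, height=25, r_mm=9.0):
    """Frames with a white rectangle of varying width on black background."""
    h, w = 60, 400
    bg = np.zeros((h, w, 3), np.uint8)
    frames = []
    for wid in widths:
        f = bg.copy()
        f[10:10 + height, 50:50 + wid] = 200
        frames.append(f)
    run = RunInput(frames=frames, background=bg, resolution=RES1,
                   species_profile=SPECIES_PROFILES["rat"])
    n = len(frames)
    tracks = PawTrackSet(
        f_RF=tuple(range(1, n + 1)), f_LF=tuple(range(1, n + 1)),
        f_RH=tuple(range(1, n + 1)), f_LH=tuple(range(1, n + 1)),
    )
    return run, tracks


def test_run_values_are_maxima_over_frames():
    run, tracks = _rect_run([60, 80, 70])
    result = process_run(run, tracks)
    # rectangle width w spans w columns -> length (w-1-9) mm
    assert result.silhouette_length_cm == pytest.approx((80 - 1 - 9) / 10.0)
    assert result.n_frames_used == 3
    # opening chamfers each rectangle corner by a diamond quadrant of
    # r(r+1)/2 = 45 px
    assert result.area_without_tail_mm2 == pytest.approx(80 * 25 - 4 * 45)
    assert result.area_with_tail_mm2 == pytest.approx(80 * 25)


def test_single_frame_window_returns_that_frame():
    run, tracks = _rect_run([70])
    result = process_run(run, tracks)
    assert result.n_frames_used == 1
    assert result.silhouette_length_cm == pytest.approx(6.0)


def test_empty_frames_are_skipped_not_fatal(caplog):
    run, tracks = _rect_run([60, 0, 70])  # middle frame has no foreground
    result = process_run(run, tracks)
    assert result.n_frames_used == 2
    assert result.silhouette_length_cm == pytest.approx(6.0)


def test_all_empty_frames_raise():
    run, tracks = _rect_run([0, 0])
    with pytest.raises(NoSilhouetteError):
        process_run(run, tracks)


def test_run_aggregation_monotone_in_window_size():
    run, tracks = _rect_run([60, 80, 70])
    small = PawTrackSet(f_RF=(1,), f_LF=(1,), f_RH=(1,), f_LH=(1,))
    sub = process_run(run, small)
    full = process_run(run, tracks)
    assert full.silhouette_length_cm >= sub.silhouette_length_cm
    assert full.area_without_tail_mm2 >= sub.area_without_tail_mm2


def test_paw_log_beyond_frame_range_rejected():
    run, tracks = _rect_run([60])
    bad = PawTrackSet(f_RF=(1, 5), f_LF=(1,), f_RH=(1,), f_LH=(1,))
    with pytest.raises(ParameterError):
        process_run(run, bad)


# ---------------------------------------------- synthetic ground-truth runs

def test_synthetic_run_recovers_known_length(rat_render):
    run, tracks, truth = rat_render
    result = process_run(run, tracks)
    err_px = abs(result.silhouette_length_cm * 10 - truth["length_mm"])
    assert err_px <= 2 * run.resolution.x_mm


def test_synthetic_mouse_recovers_known_length(mouse_render):
    run, tracks, truth = mouse_render
    result = process_run(run, tracks)
    err = abs(result.silhouette_length_cm * 10 - truth["length_mm"])
    assert err <= 2 * run.resolution.x_mm


def test_pipeline_stage_monotonicity(rat_render):
    run, _, _ = rat_render
    se = make_diamond_se(run.species_profile.r_d_mm, run.resolution)
    fg = subtract_background(run.frames[1], run.background, 10)
    opened = open_remove_tail(fg, se)
    assert opened.sum() <= fg.sum()          # opening is anti-extensive
    assert (opened & ~fg).sum() == 0
    filled = fill_holes(opened)
    assert filled.sum() >= opened.sum()      # filling is extensive
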