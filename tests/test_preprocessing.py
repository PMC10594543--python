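"""Stabilization, min-G compositing, flat-fielding and contrast enhancement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import capiwide as cw
from capiwide.preprocessing import gamma_lut
from conftest import naive_min_green, ssd_match, textured_stack


# ---------------------------------------------------------------------------
# stabilization


def test_static_stack_aligns_to_identity(rng):
    stack, _ = textured_stack(rng, n=4, shifts=[(0, 0)] * 4)
    res = cw.stabilize(stack, template_margin_px=5)
    assert res.offsets == [(5, 5)] * 4
    h, w = stack.frame_shape
    template = stack.frames[0, 5:h - 5, 5:w - 5]
    for frame in res.aligned.frames:
        assert np.array_equal(frame, template)


def test_injected_shifts_recovered_exactly_and_agree_with_ssd_oracle(rng):
    m = 5
    stack, shifts = textured_stack(rng, n=6)
    res = cw.stabilize(stack, template_margin_px=m)
    h, w = stack.frame_shape
    gray = stack.frames.mean(axis=3)
    template = gray[0, m:h - m, m:w - m]
    for k, (dx, dy) in enumerate(shifts):
        assert res.offsets[k] == (m + dx, m + dy)
        assert ssd_match(gray[k], template) == res.offsets[k]


def test_stabilized_geometry_matches_margin(rng):
    stack, _ = textured_stack(rng, n=3, h=60, w=80)
    res = cw.stabilize(stack, template_margin_px=10)
    assert res.template_size == (60, 40)
    assert res.aligned.frame_shape == (40, 60)
    assert res.aligned.n_frames == 3


def test_untextured_template_is_rejected():
    frames = np.full((2, 40, 40, 3), 100, dtype=np.uint8)
    with pytest.raises(ValueError, match="untextured"):
        cw.stabilize(cw.FrameStack(frames), template_margin_px=5)


def test_margin_must_fit_frame(rng):
    stack, _ = textured_stack(rng, n=2, h=20, w=20)
    with pytest.raises(ValueError, match="margin"):
        cw.stabilize(stack, template_margin_px=10)


# ---------------------------------------------------------------------------
# min-G composite


def test_single_frame_composite_is_the_frame(rng):
    frame = rng.integers(0, 256, (10, 12, 3), dtype=np.uint8)
    comp = cw.min_green_composite(cw.FrameStack(frame[None]))
    assert np.array_equal(comp.image, frame)
    assert (comp.source_frame_index == 0).all()


def test_one_pixel_example_selects_lowest_green():
    frames = np.array([[[[200, 120, 90]]], [[[180, 80, 70]]],
                       [[[210, 200, 190]]]], dtype=np.uint8)
    comp = cw.min_green_composite(cw.FrameStack(frames))
    assert tuple(comp.image[0, 0]) == (180, 80, 70)
    assert comp.source_frame_index[0, 0] == 1


def test_green_ties_resolve_to_earliest_frame():
    frames = np.zeros((3, 1, 1, 3), dtype=np.uint8)
    frames[0, 0, 0] = (10, 50, 30)
    frames[1, 0, 0] = (90, 50, 70)  # same G, later frame
    frames[2, 0, 0] = (20, 60, 10)
    comp = cw.min_green_composite(cw.FrameStack(frames))
    assert tuple(comp.image[0, 0]) == (10, 50, 30)
    assert comp.source_frame_index[0, 0] == 0


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2 ** 31 - 1))
def test_composite_matches_naive_loop_and_dominates_green(seed):
    r = np.random.default_rng(seed)
    frames = r.integers(0, 256, (r.integers(1, 6), 7, 9, 3), dtype=np.uint8)
    comp = cw.min_green_composite(cw.FrameStack(frames))
    assert np.array_equal(comp.image, naive_min_green(frames))
    # composite G is a lower bound of every frame's G
    assert (comp.image[..., 1][None] <= frames[..., 1]).all()
    # the recorded source frame supplies the pixel exactly
    picked = np.take_along_axis(
        frames, comp.source_frame_index[None, ..., None], axis=0)[0]
    assert np.array_equal(comp.image, picked)


# ---------------------------------------------------------------------------
# flat-fielding


def test_constant_image_is_a_fixed_point():
    img = np.empty((40, 50, 3), dtype=np.uint8)
    img[..., 0], img[..., 1], img[..., 2] = 100, 150, 200
    out = cw.flatten_illumination(img, cw.FlatFieldConfig(kernel_radius_px=7))
    assert np.array_equal(out, img)


def test_vignette_removed_below_cv_threshold():
    """A uniform scene under radial vignette: channel CV > 0.10 before,
    < 0.01 after flat-fielding (kernel-radius border excluded)."""
    h, w, r = 120, 160, 20
    yy, xx = np.mgrid[0:h, 0:w]
    vig = 1.0 - 0.9 * (((yy - h / 2) / (h / 2)) ** 2
                       + ((xx - w / 2) / (w / 2)) ** 2) / 2.0
    img = np.clip(np.round(vig[..., None] * [180.0, 140.0, 120.0]),
                  0, 255).astype(np.uint8)
    out = cw.flatten_illumination(img, cw.FlatFieldConfig(kernel_radius_px=r))
    for c in range(3):
        before = img[r:-r, r:-r, c].astype(float)
        after = out[r:-r, r:-r, c].astype(float)
        assert before.std() / before.mean() > 0.10
        assert after.std() / after.mean() < 0.01


def test_flat_field_default_kernel_radius_is_300():
    assert cw.FlatFieldConfig().kernel_radius_px == 300


def test_flat_field_rejects_non_rgb():
    with pytest.raises(ValueError):
        cw.flatten_illumination(np.zeros((10, 10), dtype=np.uint8),
                                cw.FlatFieldConfig(kernel_radius_px=2))


# ---------------------------------------------------------------------------
# contrast enhancement


def test_gamma_map_fixes_endpoints_and_hits_closed_form():
    lut = gamma_lut(0.3)
    assert lut[0] == 0 and lut[255] == 255
    assert lut[128] == round(255 * (128 / 255) ** 0.3) == 207


def test_constant_channel_stays_constant():
    img = np.full((16, 16, 3), 77, dtype=np.uint8)
    out = cw.enhance_contrast(img, cw.ContrastConfig(gamma=0.3))
    for c in range(3):
        assert np.unique(out[..., c]).size == 1


def test_equalization_then_gamma_order(rng):
    """Disabling equalization must reduce to the pure gamma map."""
    img = rng.integers(0, 256, (20, 20, 3), dtype=np.uint8)
    out = cw.enhance_contrast(img, cw.ContrastConfig(gamma=0.5,
                                                     apply_equalization=False))
    assert np.array_equal(out, gamma_lut(0.5)[img])


def test_default_contrast_config_matches_protocol():
    cfg = cw.ContrastConfig()
    assert cfg.gamma == 0.3 and cfg.apply_equalization


# ---------------------------------------------------------------------------
# full pipeline


def test_pipeline_geometry_and_vessel_continuity(small_scene):
    """The preprocessed still has template geometry, and the min-G composite
    covers intermittent vessels without the gaps a single frame shows."""
    cfg, stack, gt = small_scene
    m = 4
    still = cw.preprocess_video(
        stack, cw.FlatFieldConfig(kernel_radius_px=30),
        cw.ContrastConfig(), template_margin_px=m)
    assert still.shape == (cfg.height_px - 2 * m, cfg.width_px - 2 * m, 3)

    stab = cw.stabilize(stack, template_margin_px=m)
    comp = cw.min_green_composite(stab.aligned)
    gt_crop = gt.capillary_mask[m:-m, m:-m] > 0
    bg_med = np.median(comp.image[..., 1][~gt_crop])
    # per-vessel green in the composite vs the same pixels in frame 0
    dark_comp = (comp.image[..., 1] < bg_med - 15)[gt_crop].mean()
    dark_single = (stab.aligned.frames[0][..., 1] < bg_med - 15)[gt_crop].mean()
    assert dark_comp > dark_single  # compositing fills RBC-free gaps
    assert dark_comp > 0.5


def test_single_constant_frame_pipeline_is_identity_composition():
    """With stabilization skipped, a constant frame passes through flat-field
    and contrast as a constant."""
    img = np.full((32, 32, 3), 120, dtype=np.uint8)
    still = cw.preprocess_video(
        cw.FrameStack(img[None]), cw.FlatFieldConfig(kernel_radius_px=4),
        cw.ContrastConfig(), template_margin_px=0)
    assert np.unique(still.reshape(-1, 3), axis=0).shape[0] == 1
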