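"""ROI geometry: local frame, square placement, similarity equivariance."""

import numpy as np
import pytest

from veinroi import roi
from veinroi import synthetic as syn

WORKED = np.array([[-1.0, 3.0], [0.0, 0.0], [2.5, 0.1], [6.0, 0.0]])


def test_worked_example_frame():
    fr = roi.build_frame(WORKED)
    assert np.allclose(fr.origin, [3, 0])
    assert np.allclose(fr.x_axis, [1, 0])
    assert np.allclose(fr.y_axis, [0, 1])
    assert fr.unit_length == pytest.approx(6.0)


def test_worked_example_box():
    box = roi.locate_roi(roi.build_frame(WORKED))
    assert np.allclose(box.center, [3, 5])
    assert box.side == pytest.approx(6.0)
    assert np.allclose(box.corners, [[0, 2], [6, 2], [6, 8], [0, 8]])


def test_degenerate_keypoints_rejected():
    bad = WORKED.copy()
    bad[3] = bad[1]
    with pytest.raises(ValueError):
        roi.build_frame(bad)
    collinear = np.array([[3.0, 0.0], [0.0, 0.0], [1.0, 0.0], [6.0, 0.0]])
    with pytest.raises(ValueError):
        roi.build_frame(collinear)


def _transform(kps, deg, scale, shift):
    a = np.deg2rad(deg)
    R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    return scale * kps @ R.T + shift


@pytest.mark.parametrize("deg,scale,shift", [
    (90.0, 1.0, (0.0, 0.0)),
    (37.0, 2.5, (11.0, -4.0)),
    (-120.0, 0.3, (100.0, 50.0)),
])
def test_similarity_equivariance(deg, scale, shift):
    box = roi.locate_roi(roi.build_frame(WORKED))
    tbox = roi.locate_roi(roi.build_frame(_transform(WORKED, deg, scale, shift)))
    expect = _transform(box.corners, deg, scale, shift)
    assert np.abs(expect - tbox.corners).max() < 1e-9 * max(1.0, np.abs(expect).max())
    assert tbox.side == pytest.approx(scale * box.side)


def test_center_offset_ratio_is_5_6(rng):
    for _ in range(50):
        kps = rng.uniform(-50, 50, (4, 2))
        try:
            fr = roi.build_frame(kps)
        except ValueError:
            continue
        box = roi.locate_roi(fr)
        ratio = np.linalg.norm(box.center - fr.origin) / box.side
        assert ratio == pytest.approx(5 / 6, abs=1e-12)
        # center lies strictly on P0's side of the P1P3 line
        assert fr.y_axis @ (box.center - fr.origin) > 0
        assert np.sign(fr.y_axis @ (kps[0] - fr.origin)) > 0


def test_crop_constant_image_full_coverage():
    img = np.full((64, 64), 137.0)
    kps = np.array([[20.0, 40.0], [22.0, 30.0], [30.0, 26.0], [38.0, 28.0]])
    box = roi.extract_roi(kps)
    crop, coverage = roi.crop_roi(img, box, out_size=32)
    assert coverage == 1.0
    assert np.allclose(crop, 137.0)


def test_crop_half_off_image_coverage():
    img = np.zeros((64, 64))
    box = roi.ROIBox(center=np.array([0.0, 32.0]), side=20.0,
                     corners=np.array([[-10, 22], [10, 22], [10, 42], [-10, 42]],
                                      dtype=float),
                     rotation=0.0)
    _, coverage = roi.crop_roi(img, box, out_size=20)
    assert coverage == pytest.approx(0.5, abs=0.05)


def test_crop_center_outside_errors():
    img = np.zeros((32, 32))
    box = roi.ROIBox(center=np.array([100.0, 100.0]), side=10.0,
                     corners=np.zeros((4, 2)), rotation=0.0)
    with pytest.raises(ValueError):
        roi.crop_roi(img, box)


def test_crop_of_rotated_render_matches_rotated_crop():
    """Cropping a rotated hand render with its rotated keypoints gives the
    same ROI content as cropping the unrotated render (up to resampling)."""
    import dataclasses
    rng = np.random.default_rng(8)
    for _ in range(20):
        p0 = dataclasses.replace(
            syn.sample_params(rng, image_size=(160, 160),
                              background_mode="clean"),
            global_rotation=0.0, occlusion_fraction=0.0, noise_sigma=0.0)
        p45 = dataclasses.replace(p0, global_rotation=45.0)
        try:
            s0, s45 = syn.render_hand(p0), syn.render_hand(p45)
        except syn.InvalidHandError:
            continue
        c0, cov0 = roi.crop_roi(s0.image, roi.extract_roi(s0.keypoints), 48)
        c45, cov45 = roi.crop_roi(s45.image, roi.extract_roi(s45.keypoints), 48)
        if min(cov0, cov45) < 1.0:
            continue
        assert np.abs(c0 - c45).mean() < 2.0
        return
    pytest.fail("no valid rotated pair found")


def test_roi_on_dorsum_of_synthetic_hand(small_samples):
    """The located square sits on or next to the hand, wrist-ward of the
    finger webs (on small palms the 5/6 offset can graze the palm edge)."""
    from scipy.ndimage import binary_dilation

    for s in small_samples[:6]:
        box = roi.extract_roi(s.keypoints)
        mask = binary_dilation(s.hand_mask, iterations=4)
        cx, cy = np.round(box.center).astype(int)
        h, w = mask.shape
        if 0 <= cx < w and 0 <= cy < h:
            assert mask[cy, cx]
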