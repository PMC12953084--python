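"""Donut-method ROI construction and polarization scoring.

The key check is oracle equivalence: on small toy images the masks and the
score must agree exactly with brute-force pixel enumeration that shares no
code with the implementation.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glymquant.polarization import donut_rois, polarization_rate
from glymquant.segmentation import AstrocyteSegmentation

from conftest import make_image


def make_seg(gfap_mask, soma_masks=None, pixel_size_um=1.0):
    gfap_mask = np.asarray(gfap_mask, dtype=bool)
    soma_masks = soma_masks or {}
    return AstrocyteSegmentation(
        gfap_mask=gfap_mask,
        labels=gfap_mask.astype(int),
        soma_masks={k: np.asarray(v, dtype=bool) for k, v in soma_masks.items()},
        skeletons={},
        nucleus_centroids={},
        pixel_size_um=pixel_size_um,
    )


def brute_force_annulus(mask, d):
    """Pixel-enumeration oracle: all pixels within Chebyshev distance d of
    the mask, minus the mask (square/8-connectivity dilation)."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            for rr in range(max(0, r - d), min(h, r + d + 1)):
                for cc in range(max(0, c - d), min(w, c + d + 1)):
                    if mask[rr, cc]:
                        out[r, c] = True
    return out & ~mask


def test_single_pixel_annulus_has_120_pixels():
    """Dilating one pixel by 5 gives an 11x11 square; the annulus drops the
    centre: 121 - 1 = 120 pixels."""
    mask = np.zeros((16, 16), dtype=bool)
    mask[8, 8] = True
    roi_pas, _ = donut_rois(make_seg(mask), dilation_px=5)
    assert roi_pas.sum() == 120
    np.testing.assert_array_equal(roi_pas, brute_force_annulus(mask, 5))


def test_annulus_clips_at_border():
    """A mask touching the border gives a clipped annulus, no wraparound."""
    mask = np.zeros((12, 12), dtype=bool)
    mask[0, 0] = True
    roi_pas, _ = donut_rois(make_seg(mask), dilation_px=5)
    np.testing.assert_array_equal(roi_pas, brute_force_annulus(mask, 5))
    assert not roi_pas[-1, :].any()  # far edge untouched


def test_dilation_must_be_positive():
    mask = np.ones((4, 4), dtype=bool)
    with pytest.raises(ValueError):
        donut_rois(make_seg(mask), dilation_px=0)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.data())
def test_oracle_equivalence_on_random_small_images(data):
    """donut_rois + polarization_rate match pixel enumeration on any
    image up to 16x16."""
    h = data.draw(st.integers(4, 16))
    w = data.draw(st.integers(4, 16))
    rng = np.random.default_rng(data.draw(st.integers(0, 2**16)))
    mask = rng.random((h, w)) < 0.15
    if not mask.any():
        mask[h // 2, w // 2] = True
    d = data.draw(st.integers(1, 5))
    soma = mask & (rng.random((h, w)) < 0.5)
    seg = make_seg(mask, {1: soma})
    roi_pas, roi_ass = donut_rois(seg, dilation_px=d)
    expected_pas = brute_force_annulus(mask, d)
    np.testing.assert_array_equal(roi_pas, expected_pas)
    np.testing.assert_array_equal(roi_ass, soma)

    aqp4 = rng.integers(0, 20, (h, w)).astype(float)
    img = make_image({"AQP4": aqp4})
    res = polarization_rate(img, (roi_pas, roi_ass))
    # independent arithmetic with plain Python sums
    i_pas = sum(aqp4[r, c] for r in range(h) for c in range(w) if expected_pas[r, c])
    i_ass = sum(aqp4[r, c] for r in range(h) for c in range(w) if soma[r, c])
    i_glob = aqp4.sum()
    assert res.rate == pytest.approx((i_pas - i_ass) / i_glob * 100, abs=1e-10)


def test_hand_computed_8x8_toy():
    """Frozen hand-worked example on an 8x8 grid."""
    mask = np.zeros((8, 8), dtype=bool)
    mask[3:5, 3:5] = True              # 2x2 cell block
    soma = np.zeros((8, 8), dtype=bool)
    soma[3, 3] = True
    aqp4 = np.zeros((8, 8))
    aqp4[2, 2] = 10.0                  # in the d=1 annulus
    aqp4[3, 3] = 4.0                   # in the soma
    aqp4[7, 7] = 6.0                   # elsewhere
    seg = make_seg(mask, {1: soma})
    res = polarization_rate(make_image({"AQP4": aqp4}), donut_rois(seg, 1))
    # I_PAS=10, I_ASS=4, I_global=20 -> (10-4)/20*100 = 30
    assert res.rate == pytest.approx(30.0)
    assert (res.i_pas, res.i_ass, res.i_global) == (10.0, 4.0, 20.0)


def test_extreme_rates():
    """All AQP4 in the annulus scores 100; balanced ROIs score 0."""
    mask = np.zeros((10, 10), dtype=bool)
    mask[5, 5] = True
    soma = mask.copy()
    seg = make_seg(mask, {1: soma})
    rois = donut_rois(seg, 1)
    all_pas = np.zeros((10, 10))
    all_pas[rois[0]] = 3.0
    assert polarization_rate(make_image({"AQP4": all_pas}), rois).rate == 100.0

    balanced = np.zeros((10, 10))
    balanced[4, 5] = 5.0               # one annulus pixel
    balanced[5, 5] = 5.0               # the soma pixel
    assert polarization_rate(make_image({"AQP4": balanced}), rois).rate == 0.0


def test_zero_global_intensity_raises():
    mask = np.zeros((6, 6), dtype=bool)
    mask[3, 3] = True
    seg = make_seg(mask, {1: mask})
    with pytest.raises(ZeroDivisionError):
        polarization_rate(make_image({"AQP4": np.zeros((6, 6))}), donut_rois(seg, 1))


def test_moving_intensity_into_annulus_never_decreases_rate():
    """Monotonicity: shifting AQP4 from soma to annulus raises the score."""
    rng = np.random.default_rng(0)
    mask = rng.random((12, 12)) < 0.2
    mask[6, 6] = True
    soma = np.zeros_like(mask)
    soma[6, 6] = True
    seg = make_seg(mask, {1: soma})
    rois = donut_rois(seg, 2)
    aqp4 = rng.random((12, 12)) * 10
    prev = polarization_rate(make_image({"AQP4": aqp4}), rois).rate
    pas_px = tuple(np.argwhere(rois[0])[0])
    for _ in range(5):
        moved = min(aqp4[6, 6], 1.0)
        aqp4[6, 6] -= moved
        aqp4[pas_px] += moved
        rate = polarization_rate(make_image({"AQP4": aqp4}), rois).rate
        assert rate >= prev - 1e-12
        prev = rate
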