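import numpy as np
import pytest

from negvol import (
    BoundingBox,
    LocalizationError,
    Mask,
    Volume,
    box_corner_mse,
    coarse_segment,
    crop_voi,
    extract_voi_boxes,
    minimum_threshold,
    postprocess_localization,
    resample,
    minmax_normalize,
)


def _brute_force_valley(values, bins=256):
    """Independent oracle: smooth the histogram exactly as specified and
    scan every bin for the deepest valley between the two largest modes."""
    hist, edges = np.histogram(values, bins=bins)
    h = hist.astype(float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    for _ in range(10000):
        maxima = [i for i in range(len(h))
                  if h[i] > 0
                  and h[i] > (h[i - 1] if i else -1)
                  and h[i] > (h[i + 1] if i + 1 < len(h) else -1)]
        if len(maxima) <= 2:
            break
        h = np.convolve(h, np.ones(3) / 3, mode="same")
    if len(maxima) != 2:
        return float("nan")
    lo, hi = maxima
    seg = h[lo: hi + 1]
    ties = np.flatnonzero(seg == seg.min())
    return centers[lo + int(ties[len(ties) // 2])]  # mid-plateau tie-break


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_minimum_threshold_matches_brute_force_valley(seed):
    rng = np.random.default_rng(seed)
    values = np.concatenate([
        rng.normal(0.1, 0.04, 4000), rng.normal(0.9, 0.04, 5000)
    ]).clip(0, 1)
    tau = minimum_threshold(values)
    oracle = _brute_force_valley(values)
    assert tau == pytest.approx(oracle, abs=1e-9)
    assert 0.3 < tau < 0.7  # valley lies between the modes


def test_minimum_threshold_bimodal_synthetic_valley():
    rng = np.random.default_rng(10)
    values = np.concatenate([
        rng.normal(0.1, 0.05, 6000), rng.normal(0.9, 0.05, 6000)
    ]).clip(0, 1)
    tau = minimum_threshold(values)
    assert 0.35 < tau < 0.65


def test_postprocess_unimodal_falls_back_with_warning():
    p = Volume(np.zeros((8, 8, 8)), [1, 1, 1])
    with pytest.warns(UserWarning):
        mask = postprocess_localization(p)
    assert mask.data.sum() == 0


def test_postprocess_removes_specks_keeps_blobs():
    data = np.zeros((24, 24, 12))
    data[2:10, 4:12, 4:8] = 0.95    # blob 1
    data[14:22, 4:12, 4:8] = 0.95   # blob 2
    data[12, 2, 2] = 0.95           # 1-voxel speck
    data += 0.02
    mask = postprocess_localization(Volume(data.clip(0, 1), [1, 1, 1]))
    assert mask.data[3:9, 5:11, 5:7].all()
    assert mask.data[14:22, 5:11, 5:7].any()
    assert mask.data[12, 2, 2] == 0


def test_postprocess_output_subset_of_threshold():
    rng = np.random.default_rng(2)
    data = np.where(rng.random((20, 20, 10)) > 0.5,
                    rng.normal(0.9, 0.03, (20, 20, 10)),
                    rng.normal(0.1, 0.03, (20, 20, 10))).clip(0, 1)
    tau = minimum_threshold(data)
    mask = postprocess_localization(Volume(data, [1, 1, 1]))
    assert not np.any(mask.data.astype(bool) & ~(data > tau))


def test_extract_voi_boxes_sides_and_containment():
    data = np.zeros((40, 20, 20), np.uint8)
    data[4:12, 6:14, 6:14] = 1   # left blob
    data[28:36, 6:14, 6:14] = 1  # right blob
    left, right = extract_voi_boxes(Mask(data, [1, 1, 1]))
    assert left.side == "left" and right.side == "right"
    assert left.min_index[0] <= 4 and left.max_index[0] >= 12
    assert right.min_index[0] <= 28 and right.max_index[0] >= 36


def test_extract_voi_boxes_single_component_fails():
    data = np.zeros((20, 20, 20), np.uint8)
    data[5:15, 5:15, 5:15] = 1
    with pytest.raises(LocalizationError):
        extract_voi_boxes(Mask(data, [1, 1, 1]))


def test_extract_voi_boxes_rescales_to_full_resolution():
    data = np.zeros((20, 10, 10), np.uint8)
    data[2:6, 3:7, 3:7] = 1
    data[14:18, 3:7, 3:7] = 1
    left, _ = extract_voi_boxes(Mask(data, [1, 1, 1]), full_shape=(80, 40, 40))
    assert left.max_index[0] <= 80 and left.min_index[0] >= 0
    assert left.shape[0] >= 4 * (6 - 2)  # scaled up by ~4


def test_crop_voi_identity_and_round_trip():
    v = Volume(np.random.default_rng(0).random((12, 10, 8)), [1, 1, 1])
    full = BoundingBox([0, 0, 0], [12, 10, 8])
    assert np.array_equal(crop_voi(v, full).data, v.data)
    sub = BoundingBox([2, 3, 1], [7, 8, 5])
    crop = crop_voi(v, sub)
    assert np.array_equal(crop.data, v.data[2:7, 3:8, 1:5])
    assert np.allclose(crop.origin, [2, 3, 1])


def test_crop_voi_fixed_patch_uses_real_data():
    v = Volume(np.arange(12 * 10 * 8, dtype=float).reshape(12, 10, 8), [1, 1, 1])
    box = BoundingBox([4, 4, 2], [8, 8, 6])
    out = crop_voi(v, box, patch_shape=(8, 8, 8))
    assert out.shape == (8, 8, 8)
    # the expanded window must contain surrounding volume data, not padding
    assert np.count_nonzero(out.data) >= 8 * 8 * 8 - 1


def test_crop_voi_out_of_bounds():
    v = Volume(np.zeros((8, 8, 8)), [1, 1, 1])
    with pytest.raises(IndexError):
        crop_voi(v, BoundingBox([2, 2, 2], [9, 4, 4]))


def test_box_corner_mse_zero_for_identical():
    b = BoundingBox([1, 2, 3], [6, 7, 8], side="left")
    assert box_corner_mse(b, b) == 0.0
    b2 = BoundingBox([2, 2, 3], [6, 7, 8], side="left")
    assert box_corner_mse(b2, b) == pytest.approx(1 / 6)


# ------------------------------------------------ learned coarse localization

def test_coarse_segment_probability_field(small_cohort, toy_models):
    from negvol.studies import LOC_SHAPE

    head = small_cohort[0]  # held out from training
    low = resample(minmax_normalize(head.volume), LOC_SHAPE)
    prob = coarse_segment(low, toy_models["loc"])
    assert prob.data.shape == tuple(LOC_SHAPE)
    assert prob.data.min() >= 0 and prob.data.max() <= 1
    # probability mass concentrates in the ground-truth joint boxes
    scale = np.array(LOC_SHAPE) / np.array(head.volume.shape)
    inside = np.zeros(tuple(LOC_SHAPE), bool)
    for lo, hi in head.boxes.values():
        l = np.floor(lo * scale).astype(int)
        h = np.ceil(hi * scale).astype(int)
        inside[l[0]:h[0], l[1]:h[1], l[2]:h[2]] = True
    assert prob.data[inside].sum() / prob.data.sum() >= 0.8


def test_localization_boxes_on_phantom_head(small_cohort, toy_models):
    from negvol.studies import LOC_SHAPE

    head = small_cohort[0]
    low = resample(minmax_normalize(head.volume), LOC_SHAPE)
    prob = coarse_segment(low, toy_models["loc"])
    mask = postprocess_localization(prob)
    left, right = extract_voi_boxes(mask, full_shape=head.volume.shape)
    mse = np.mean([
        box_corner_mse(left, BoundingBox(*head.boxes["left"], side="left")),
        box_corner_mse(right, BoundingBox(*head.boxes["right"], side="right")),
    ])
    assert np.isfinite(mse)
    # boxes land on the correct sides of the midline
    nx = head.volume.shape[0]
    assert (left.min_index[0] + left.max_index[0]) / 2 < nx / 2
    assert (right.min_index[0] + right.max_index[0]) / 2 > nx / 2
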