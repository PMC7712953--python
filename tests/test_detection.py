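"""WMH detection: smoothing, thresholding, labeling, volumetry, classification."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from wmhkit import (
    DetectParams,
    GridMismatchError,
    WmhDetector,
    apply_manual_edits,
    classify_subject,
    compute_threshold,
    default_phantom_spec,
    gen_flair_phantom,
    label_lesions,
    make_wmh_map,
    overlap_map,
    preprocess,
    wmh_load,
)
from wmhkit.detection import WmhMap
from wmhkit.synthetic import Ellipsoid, LesionSpec, PhantomSpec

SHAPE = (12, 12, 12)


def full_mask(make_volume, shape=SHAPE):
    return make_volume(np.ones(shape, dtype=np.uint8))


def empty_mask(make_volume, shape=SHAPE):
    return make_volume(np.zeros(shape, dtype=np.uint8))


# ---------------------------------------------------------------------------
# preprocess
# ---------------------------------------------------------------------------

def test_preprocess_fwhm0_is_masked_identity(make_volume, rng):
    img = make_volume(rng.normal(size=SHAPE))
    brain = make_volume((rng.random(SHAPE) > 0.3).astype(np.uint8))
    excl = empty_mask(make_volume)
    out = preprocess(img, brain, excl, DetectParams(smoothing_fwhm_mm=0.0))
    mask = brain.data.astype(bool)
    np.testing.assert_array_equal(out.data[mask], img.data[mask])
    assert np.all(out.data[~mask] == 0)


def test_preprocess_preserves_constants_inside_mask(make_volume):
    img = make_volume(np.full(SHAPE, 42.0))
    brain = make_volume(np.zeros(SHAPE, dtype=np.uint8))
    brain.data[3:9, 3:9, 3:9] = 1
    excl = empty_mask(make_volume)
    out = preprocess(img, brain, excl, DetectParams(smoothing_fwhm_mm=6.0))
    np.testing.assert_allclose(out.data[brain.data.astype(bool)], 42.0)


def test_preprocess_impulse_matches_direct_convolution(make_volume):
    """Oracle: explicit discrete-Gaussian convolution sum at the impulse."""
    data = np.zeros(SHAPE)
    data[6, 6, 6] = 1.0
    img = make_volume(data)
    params = DetectParams(smoothing_fwhm_mm=2.0)
    out = preprocess(img, full_mask(make_volume), empty_mask(make_volume), params)

    sigma_vox = 2.0 / (2.0 * math.sqrt(2.0 * math.log(2.0))) / 2.0  # fwhm/vox=2mm
    radius = int(4.0 * sigma_vox + 0.5)
    offsets = np.arange(-radius, radius + 1)
    w = np.exp(-(offsets**2) / (2.0 * sigma_vox**2))
    w /= w.sum()
    expected_center = w[radius] ** 3  # separable kernel at distance 0
    assert out.data[6, 6, 6] == pytest.approx(expected_center, rel=1e-10)


def test_preprocess_excludes_exclusion_region(make_volume, rng):
    img = make_volume(rng.normal(100, 5, SHAPE))
    brain = full_mask(make_volume)
    excl = make_volume(np.zeros(SHAPE, dtype=np.uint8))
    excl.data[:, :, :4] = 1
    out = preprocess(img, brain, excl, DetectParams())
    assert np.all(out.data[:, :, :4] == 0)


def test_preprocess_grid_mismatch_names_input(make_volume):
    img = make_volume(np.zeros(SHAPE))
    brain = make_volume(np.ones((8, 8, 8), dtype=np.uint8))
    with pytest.raises(GridMismatchError, match="brain"):
        preprocess(img, brain, brain, DetectParams())


# ---------------------------------------------------------------------------
# compute_threshold
# ---------------------------------------------------------------------------

def test_threshold_constant_image_returns_constant(make_volume):
    img = make_volume(np.full(SHAPE, 7.5))
    assert compute_threshold(img, full_mask(make_volume), DetectParams()) == 7.5


def test_threshold_closed_form_zero_ten(make_volume):
    data = np.zeros(SHAPE)
    data[::2] = 10.0  # half the voxels 0, half 10
    img = make_volume(data)
    thr = compute_threshold(img, full_mask(make_volume), DetectParams())
    vals = data.ravel()
    expected = vals.mean() + 1.5 * np.std(vals, ddof=1)
    assert thr == pytest.approx(expected)
    # n = 1728 voxels half 0 / half 10: sample SD = 5 * sqrt(n/(n-1))
    assert thr == pytest.approx(5.0 + 1.5 * 5.0 * math.sqrt(1728 / 1727), rel=1e-12)


def test_threshold_mean100_sd20_gives_130(make_volume):
    # two-point sample with mean 100 and *sample* SD exactly 20
    x = 20.0 / math.sqrt(2.0)
    data = np.zeros((2, 1, 1))
    data[0], data[1] = 100.0 - x, 100.0 + x
    img = make_volume(data, affine=np.eye(4))
    brain = make_volume(np.ones((2, 1, 1), dtype=np.uint8), affine=np.eye(4))
    assert compute_threshold(img, brain, DetectParams()) == pytest.approx(130.0)


def test_threshold_population_sd_mode(make_volume):
    data = np.zeros(SHAPE)
    data[::2] = 10.0
    img = make_volume(data)
    thr = compute_threshold(img, full_mask(make_volume), DetectParams(sd_mode="population"))
    assert thr == pytest.approx(data.mean() + 1.5 * data.std())


def test_threshold_empty_mask_errors(make_volume):
    img = make_volume(np.zeros(SHAPE))
    with pytest.raises(ValueError, match="empty"):
        compute_threshold(img, empty_mask(make_volume), DetectParams())


# ---------------------------------------------------------------------------
# make_wmh_map / manual edits
# ---------------------------------------------------------------------------

def test_map_extremes(make_volume, rng):
    img = make_volume(rng.normal(size=SHAPE))
    brain, excl = full_mask(make_volume), empty_mask(make_volume)
    assert make_wmh_map(img, img.data.max() + 1, brain, excl).n_voxels == 0
    low = make_wmh_map(img, img.data.min() - 1, brain, excl)
    assert low.n_voxels == np.prod(SHAPE)


def test_map_threshold_below_min_equals_brain_minus_exclusion(make_volume, rng):
    img = make_volume(rng.normal(size=SHAPE))
    brain = make_volume((rng.random(SHAPE) > 0.5).astype(np.uint8))
    excl = make_volume((rng.random(SHAPE) > 0.7).astype(np.uint8))
    m = make_wmh_map(img, -np.inf and img.data.min() - 1, brain, excl)
    expected = brain.data.astype(bool) & ~excl.data.astype(bool)
    np.testing.assert_array_equal(m.volume.data.astype(bool), expected)


@settings(max_examples=20, derandomize=True)
@given(st.integers(0, 10_000))
def test_lowering_threshold_k_never_shrinks_map(seed):
    rng = np.random.default_rng(seed)
    data = rng.normal(100, 10, (10, 10, 10))
    import wmhkit

    img = wmhkit.ImageVolume(data, np.eye(4))
    brain = wmhkit.ImageVolume(np.ones((10, 10, 10), np.uint8), np.eye(4))
    excl = wmhkit.ImageVolume(np.zeros((10, 10, 10), np.uint8), np.eye(4))
    prev = None
    for k in (3.0, 1.5, 0.5):
        thr = compute_threshold(img, brain, DetectParams(threshold_k=k))
        m = make_wmh_map(img, thr, brain, excl).volume.data.astype(bool)
        if prev is not None:
            assert np.all(m >= prev)  # superset
        prev = m


def test_manual_edits(make_volume):
    data = np.zeros(SHAPE, dtype=np.uint8)
    data[2:7, 2:6, 2:7] = 1  # 100 voxels
    assert data.sum() == 100
    m = WmhMap(make_volume(data))
    nothing = apply_manual_edits(m, make_volume(np.zeros(SHAPE, dtype=np.uint8)))
    assert nothing.n_voxels == 100 and nothing.edited is False
    everything = apply_manual_edits(m, make_volume(data.copy()))
    assert everything.n_voxels == 0 and everything.edited is True
    part = np.zeros(SHAPE, dtype=np.uint8)
    part[2:7, 2:6, 2:5] = 1  # hits 60 of the 100
    hit = apply_manual_edits(m, make_volume(part))
    assert hit.n_voxels == 40 and hit.edited is True


# ---------------------------------------------------------------------------
# label_lesions
# ---------------------------------------------------------------------------

def _flood_fill_components(binary, connectivity):
    """Brute-force BFS labeling, independent of scipy.ndimage.label."""
    offsets = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if (di, dj, dk) == (0, 0, 0):
                    continue
                order = abs(di) + abs(dj) + abs(dk)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((di, dj, dk))
    seen = np.zeros_like(binary, dtype=bool)
    comps = []
    for idx in np.argwhere(binary):
        idx = tuple(idx)
        if seen[idx]:
            continue
        stack, comp = [idx], []
        seen[idx] = True
        while stack:
            cur = stack.pop()
            comp.append(cur)
            for off in offsets:
                nb = tuple(c + o for c, o in zip(cur, off))
                if any(n < 0 or n >= s for n, s in zip(nb, binary.shape)):
                    continue
                if binary[nb] and not seen[nb]:
                    seen[nb] = True
                    stack.append(nb)
        comps.append(sorted(comp))
    return sorted(comps)


def test_diagonal_adjacency_depends_on_connectivity(make_volume):
    data = np.zeros(SHAPE, dtype=np.uint8)
    data[5, 5, 5] = 1
    data[6, 6, 5] = 1  # face-diagonal neighbour
    vent = empty_mask(make_volume)
    t26 = label_lesions(WmhMap(make_volume(data)), vent, DetectParams(connectivity=26))
    t6 = label_lesions(WmhMap(make_volume(data)), vent, DetectParams(connectivity=6))
    assert len(t26) == 1 and len(t6) == 2


def test_component_volume_is_count_times_voxel_volume(make_volume):
    data = np.zeros(SHAPE, dtype=np.uint8)
    data[4:6, 4:6, 4:6] = 1  # 8 voxels
    data[9, 9, 9] = 1
    # make a 19-voxel ball
    ball = np.zeros(SHAPE, dtype=np.uint8)
    g = np.ogrid[:12, :12, :12]
    ball[((g[0] - 6) ** 2 + (g[1] - 6) ** 2 + (g[2] - 6) ** 2) <= 2.25] = 1
    table = label_lesions(WmhMap(make_volume(ball)), empty_mask(make_volume), DetectParams())
    assert list(table["n_voxels"]) == [19]
    assert table.loc[0, "volume_mm3"] == pytest.approx(152.0)  # 19 * 8 mm^3


def test_empty_map_gives_empty_table(make_volume):
    table = label_lesions(
        WmhMap(make_volume(np.zeros(SHAPE, dtype=np.uint8))),
        empty_mask(make_volume),
        DetectParams(),
    )
    assert len(table) == 0


def test_periventricular_split_matches_bruteforce_distances(make_volume):
    vent = np.zeros(SHAPE, dtype=np.uint8)
    vent[5:7, 5:7, 5:7] = 1
    lesions = np.zeros(SHAPE, dtype=np.uint8)
    lesions[8, 5, 5] = 1            # 2 voxels from ventricle face = 4 mm
    lesions[0, 0, 0] = 1            # far corner
    table = label_lesions(WmhMap(make_volume(lesions)), make_volume(vent), DetectParams())

    # oracle: all-pairs voxel-center distances in mm
    vvox = np.argwhere(vent) * 2.0
    classes = {}
    for idx in map(tuple, np.argwhere(lesions)):
        d = np.sqrt(((vvox - np.array(idx) * 2.0) ** 2).sum(axis=1)).min()
        classes[idx] = "periventricular" if d <= 10.0 else "subcortical"
    got = dict(
        zip(
            [tuple((table[["centroid_x_mm", "centroid_y_mm", "centroid_z_mm"]].iloc[i] / 2).astype(int)) for i in range(len(table))],
            table["compartment"],
        )
    )
    assert got[(8, 5, 5)] == classes[(8, 5, 5)] == "periventricular"
    assert got[(0, 0, 0)] == classes[(0, 0, 0)] == "subcortical"


@settings(max_examples=10, derandomize=True, deadline=None)
@given(st.integers(0, 10_000), st.sampled_from([6, 18, 26]))
def test_labeling_agrees_with_flood_fill_oracle(seed, connectivity):
    rng = np.random.default_rng(seed)
    binary = (rng.random((10, 10, 10)) < 0.2).astype(np.uint8)
    import wmhkit

    vol = wmhkit.ImageVolume(binary, np.diag([2.0, 2.0, 2.0, 1.0]))
    vent = wmhkit.ImageVolume(np.zeros_like(binary), vol.affine)
    table = label_lesions(
        WmhMap(vol), vent, DetectParams(connectivity=connectivity)
    )
    oracle = _flood_fill_components(binary.astype(bool), connectivity)
    assert len(table) == len(oracle)
    assert sorted(table["n_voxels"]) == sorted(len(c) for c in oracle)


# ---------------------------------------------------------------------------
# loads / classification / overlap
# ---------------------------------------------------------------------------

def _table(volumes_and_classes):
    return pd.DataFrame(
        {
            "lesion_id": range(1, len(volumes_and_classes) + 1),
            "n_voxels": [int(v / 8) for v, _ in volumes_and_classes],
            "volume_mm3": [v for v, _ in volumes_and_classes],
            "compartment": [c for _, c in volumes_and_classes],
        }
    )


def test_wmh_load_cases():
    assert wmh_load(_table([])) == (0.0, 0.0, 0.0)
    pv, sc, tot = wmh_load(
        _table([(3012, "periventricular"), (281, "subcortical")])
    )
    assert (pv, sc, tot) == (3012.0, 281.0, 3293.0)
    pv, sc, tot = wmh_load(_table([(100.0, "subcortical")] * 10))
    assert (pv, sc, tot) == (0.0, 1000.0, 1000.0)


@settings(max_examples=25, derandomize=True)
@given(st.lists(st.tuples(st.floats(1, 5000), st.booleans()), max_size=12))
def test_compartment_sums_always_add_to_total(items):
    table = _table(
        [(v, "periventricular" if b else "subcortical") for v, b in items]
    )
    pv, sc, tot = wmh_load(table)
    assert tot == pytest.approx(pv + sc)
    assert tot == pytest.approx(table["volume_mm3"].sum() if len(table) else 0.0)


def test_classification_rule_is_strict_at_150():
    params = DetectParams()
    assert classify_subject(_table([]), params) == "WMH-"
    assert classify_subject(_table([(150.0, "subcortical")]), params) == "WMH-"
    assert (
        classify_subject(
            _table([(144.0, "subcortical"), (152.0, "periventricular")]), params
        )
        == "WMH+"
    )


def test_overlap_map_counts_fractions(make_volume):
    a = np.zeros(SHAPE, dtype=np.uint8)
    a[2:4] = 1
    b = np.zeros(SHAPE, dtype=np.uint8)
    b[8:10] = 1
    ov = overlap_map([WmhMap(make_volume(a)), WmhMap(make_volume(b))])
    assert set(np.unique(ov.data)) == {0.0, 0.5}
    single = overlap_map([WmhMap(make_volume(a))])
    np.testing.assert_array_equal(single.data, a)
    ten = overlap_map([WmhMap(make_volume(a))] * 10)
    assert np.all(ten.data[2:4] == 1.0)
    with pytest.raises(ValueError):
        overlap_map([])


# ---------------------------------------------------------------------------
# end-to-end detection on a phantom
# ---------------------------------------------------------------------------

def test_detector_recovers_single_lesion_with_good_dice():
    spec = PhantomSpec(
        lesions=(LesionSpec((32.0, 40.0, 34.0), (7.0, 7.0, 7.0), 4.0),), rng_seed=21
    )
    ph = gen_flair_phantom(spec)
    res = WmhDetector(
        ph.flair, ph.brain_mask, ph.ventricle_mask, ph.exclusion_mask
    ).fit()
    truth = Ellipsoid((32.0, 40.0, 34.0), (7.0, 7.0, 7.0)).rasterize(
        spec.grid_shape, spec.voxel_size_mm
    )
    detected = res.wmh_map.volume.data.astype(bool)
    from scipy import ndimage

    core = ndimage.binary_erosion(truth)
    assert detected[core].mean() >= 0.95  # detected map covers the lesion core
    dice = 2 * (detected & truth).sum() / (detected.sum() + truth.sum())
    assert dice >= 0.7
    assert res.classification == "WMH+"


def test_detector_default_phantom_compartments_and_summary():
    spec = default_phantom_spec(rng_seed=5)
    ph = gen_flair_phantom(spec)
    res = WmhDetector(
        ph.flair, ph.brain_mask, ph.ventricle_mask, ph.exclusion_mask,
        subject_id="demo",
    ).fit()
    big = res.lesion_table.nlargest(3, "n_voxels")
    # designed phantom: one deep lesion, two near the ventricles
    assert sorted(big["compartment"]) == [
        "periventricular", "periventricular", "subcortical",
    ]
    pv, sc, tot = res.loads
    assert tot == pytest.approx(pv + sc)
    assert "demo" in res.summary() and "WMH+" in res.summary()
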