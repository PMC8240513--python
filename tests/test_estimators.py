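"""Ground-cover estimators: exact counting semantics, segmentation geometry.

The per-pixel/per-point estimators are checked against independent
brute-force loop oracles, and the strict boundary rules (VI = 0, intensity
= 5, height = 10 cm classify as non-vegetation) are asserted explicitly.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canopygc import (
    EstimatorConfig,
    LidarScan,
    NdviStream,
    SensorBundle,
    assign_to_plot,
    build_gc_table,
    gc_lidar_ht,
    gc_lidar_rr,
    gc_rgb_image,
    gc_rgb_plot,
    ndvi_plot_mean,
    normalize_heights,
    sampling_region,
    simulate_trial,
    vegetation_index,
)
from canopygc.config import TrialConfig
from canopygc.errors import (
    IntegrityError,
    InvalidGeometryError,
    MissingDataError,
)
from canopygc.estimators import SamplingRegion, estimate_bundle


# -- independent brute-force oracles ----------------------------------------

def oracle_gc_rgb(image, thr=0.0):
    count = 0
    H, W = image.shape[:2]
    for i in range(H):
        for j in range(W):
            r, g = int(image[i, j, 0]), int(image[i, j, 1])
            vi = 0.0 if r + g == 0 else (g - r) / (g + r)
            if vi > thr:
                count += 1
    return count / (H * W)


def oracle_gc_rr(scan, thr=5.0):
    return sum(1 for v in scan.intensity if v < thr) / len(scan)


def oracle_gc_ht(scan, thr=0.10):
    return sum(1 for z in scan.z if z > thr) / len(scan)


def oracle_normalize(scan):
    zs = sorted(scan.z)
    # hand-rolled linear-interpolation 5th percentile
    idx = 0.05 * (len(zs) - 1)
    lo = math.floor(idx)
    frac = idx - lo
    ground = zs[lo] if lo + 1 >= len(zs) else zs[lo] + frac * (zs[lo + 1] - zs[lo])
    return [max(z - ground, 0.0) for z in scan.z]


def oracle_ndvi_mean(stream):
    return sum(stream.values) / len(stream)


# -- vegetation index ---------------------------------------------------------

def test_vegetation_index_arithmetic():
    assert vegetation_index(50, 100) == pytest.approx(50 / 150)
    assert vegetation_index(80, 80) == 0.0  # boundary: NOT > 0
    assert vegetation_index(0, 0) == 0.0    # zero-denominator rule
    with pytest.raises(ValueError):
        vegetation_index(-1, 10)


@settings(max_examples=50, derandomize=True)
@given(st.integers(0, 255), st.integers(0, 255))
def test_vegetation_index_bounded(r, g):
    vi = vegetation_index(r, g)
    assert -1.0 <= vi <= 1.0
    assert (vi > 0) == (g > r)


# -- per-image / per-scan estimators -----------------------------------------

def test_gc_rgb_constructed_count():
    img = np.zeros((10, 10, 3), dtype=np.uint8)
    img[..., 0] = 100  # red everywhere: VI < 0
    flat = img.reshape(-1, 3)
    flat[:37, 1] = 200  # exactly 37 green-dominant pixels
    flat[37:, 1] = 50
    assert gc_rgb_image(img) == pytest.approx(0.37)


def test_gc_rgb_grey_image_is_zero():
    img = np.full((6, 8, 3), 120, dtype=np.uint8)
    assert gc_rgb_image(img) == 0.0


def test_gc_rgb_plot_mean_and_errors(rng):
    imgs = [np.zeros((4, 4, 3), np.uint8), np.zeros((4, 4, 3), np.uint8)]
    imgs[0][..., 1] = 10  # all green -> 1.0... red=0,green=10 -> vi=1 > 0
    # first image all-vegetation, second all-zero (VI=0)
    assert gc_rgb_plot(imgs) == pytest.approx(0.5)
    assert gc_rgb_plot([imgs[0]]) == pytest.approx(1.0)
    with pytest.raises(MissingDataError):
        gc_rgb_plot([])


def test_gc_lidar_rr_strict_boundary():
    scan = LidarScan(np.column_stack([
        np.zeros(6), np.zeros(6), np.zeros(6), [0, 3, 4, 5, 6, 255]]))
    assert gc_lidar_rr(scan) == pytest.approx(3 / 6)  # 5 itself is soil
    scan4 = LidarScan(np.column_stack([np.zeros(3), np.zeros(3), np.zeros(3),
                                       [4.0, 4.0, 4.0]]))
    assert gc_lidar_rr(scan4) == 1.0


def test_gc_lidar_ht_strict_boundary():
    z = [0.00, 0.05, 0.11, 0.30]
    scan = LidarScan(np.column_stack([np.zeros(4), np.zeros(4), z, np.zeros(4)]))
    assert gc_lidar_ht(scan) == pytest.approx(0.5)
    z10 = LidarScan(np.column_stack([np.zeros(3), np.zeros(3),
                                     [0.10, 0.10, 0.10], np.zeros(3)]))
    assert gc_lidar_ht(z10) == 0.0  # exactly 10 cm is ground


def test_normalize_heights_flat_and_translation(rng):
    flat = LidarScan(np.column_stack([np.zeros(60), np.zeros(60),
                                      np.full(60, 0.37), np.zeros(60)]))
    assert np.allclose(normalize_heights(flat).z, 0.0)

    pts = np.column_stack([rng.uniform(0, 5, 300), rng.uniform(-0.5, 0.5, 300),
                           rng.uniform(0, 0.4, 300), rng.uniform(0, 50, 300)])
    scan = LidarScan(pts)
    shifted = LidarScan(pts + np.array([0, 0, 0.3, 0]))
    a = gc_lidar_ht(normalize_heights(scan))
    b = gc_lidar_ht(normalize_heights(shifted))
    assert a == pytest.approx(b)


def test_normalize_heights_few_points_warns():
    pts = np.column_stack([np.zeros(10), np.zeros(10),
                           np.linspace(0.2, 0.5, 10), np.zeros(10)])
    with pytest.warns(UserWarning, match="min-z"):
        out = normalize_heights(LidarScan(pts))
    assert out.z.min() == 0.0


def test_ndvi_plot_mean_values():
    s = NdviStream(np.column_stack([[0, 1, 2], [0.4, 0.5, 0.6]]))
    assert ndvi_plot_mean(s) == pytest.approx(0.5)
    single = NdviStream(np.array([[0.0, 0.7]]))
    assert ndvi_plot_mean(single) == pytest.approx(0.7)
    with pytest.raises(MissingDataError):
        ndvi_plot_mean(NdviStream(np.empty((0, 2))))


@pytest.mark.parametrize("case", range(4))
def test_estimators_match_bruteforce_oracles(case, rng):
    """Each estimator equals an independent per-element loop, exactly."""
    for _ in range(25):
        if case == 0:
            img = rng.integers(0, 256, (12, 16, 3), dtype=np.uint8)
            assert gc_rgb_image(img) == pytest.approx(oracle_gc_rgb(img), abs=0)
        elif case == 1:
            pts = np.column_stack([rng.uniform(0, 5, 200), np.zeros(200),
                                   rng.uniform(0, 0.4, 200),
                                   rng.uniform(0, 40, 200)])
            scan = LidarScan(pts)
            assert gc_lidar_rr(scan) == pytest.approx(oracle_gc_rr(scan), abs=0)
        elif case == 2:
            pts = np.column_stack([rng.uniform(0, 5, 200), np.zeros(200),
                                   rng.uniform(0, 0.4, 200), np.zeros(200)])
            scan = LidarScan(pts)
            norm = normalize_heights(scan)
            np.testing.assert_allclose(norm.z, oracle_normalize(scan), atol=1e-12)
            assert gc_lidar_ht(norm) == pytest.approx(oracle_gc_ht(norm), abs=0)
        else:
            s = NdviStream(np.column_stack([np.arange(50) * 0.1,
                                            rng.uniform(0, 0.99, 50)]))
            assert ndvi_plot_mean(s) == pytest.approx(oracle_ndvi_mean(s),
                                                      abs=1e-12)


def test_permutation_invariance(rng):
    img = rng.integers(0, 256, (10, 12, 3), dtype=np.uint8)
    shuf = img.reshape(-1, 3)[rng.permutation(120)].reshape(10, 12, 3)
    assert gc_rgb_image(img) == pytest.approx(gc_rgb_image(shuf))

    pts = np.column_stack([rng.uniform(0, 5, 300), np.zeros(300),
                           rng.uniform(0, 0.4, 300), rng.uniform(0, 40, 300)])
    perm = pts[rng.permutation(300)]
    assert gc_lidar_rr(LidarScan(pts)) == gc_lidar_rr(LidarScan(perm))
    assert gc_lidar_ht(normalize_heights(LidarScan(pts))) == pytest.approx(
        gc_lidar_ht(normalize_heights(LidarScan(perm))))


# -- segmentation geometry -----------------------------------------------------

def test_sampling_region_geometry(default_trial):
    design, _ = default_trial
    region = sampling_region(design, 1)
    assert region.along_length == pytest.approx(5.0)   # 6 m minus 2 x 0.5 m
    assert region.cross_length == pytest.approx(1.25)  # 5 inner rows +- half gap
    # half-open convention: the exact end is excluded
    assert not region.contains([region.along_end]).any()
    assert region.contains([region.along_start]).all()


def test_sampling_region_errors(default_trial):
    design, _ = default_trial
    with pytest.raises(InvalidGeometryError):
        sampling_region(design, 1, EstimatorConfig(end_buffer=3.0))
    with pytest.raises(KeyError):
        sampling_region(design, 9999)


def test_assign_to_plot_counts(default_trial):
    design, _ = default_trial
    region = sampling_region(design, 1)
    # 10 Hz at 1 m/s across the plot -> exactly 50 readings inside 5 m
    pos = 0.1 * np.arange(60)
    assert len(assign_to_plot(pos, region)) == 50
    # inter-plot path position not assigned
    assert len(assign_to_plot([5.9], region)) == 0
    # 1 m image grid with zero phase -> 5 positions inside
    grid = np.arange(0.0, 6.0, 1.0)
    assert len(assign_to_plot(grid + 0.5, region)) == 5


# -- GC table assembly --------------------------------------------------------

def _tiny_bundle(plot, event_id, with_images=True):
    rng = np.random.default_rng(plot * 100 + event_id)
    pts = np.column_stack([rng.uniform(0, 6, 400), rng.uniform(-0.6, 0.6, 400),
                           rng.uniform(0, 0.3, 400), rng.uniform(0, 40, 400)])
    nd = np.column_stack([np.arange(0, 6, 0.1),
                          rng.uniform(0.3, 0.6, 60)])
    imgs, positions = [], []
    if with_images:
        positions = [0.7, 1.7, 2.7, 3.7, 4.7]
        imgs = [rng.integers(0, 256, (6, 8, 3), dtype=np.uint8)
                for _ in positions]
    return SensorBundle(plot=plot, event_id=event_id, image_positions=positions,
                        images=imgs, scan=LidarScan(pts), ndvi=NdviStream(nd))


def test_build_gc_table_shape_and_missing():
    cfg = TrialConfig(n_plots=4, n_genotypes=2, n_field_rows=2, n_field_cols=2)
    design, _ = simulate_trial(cfg, seed=1)
    bundles = [_tiny_bundle(p, e) for p in range(1, 5) for e in (1, 2)]
    table = build_gc_table(bundles, design)
    assert len(table) == 4 * 2 * 4  # plots x events x methods
    assert table["value"].notna().all()
    assert (table["n_samples"] > 0).all()

    # a bundle without images yields a flagged GC_RGB row, not a zero
    b = _tiny_bundle(1, 3, with_images=False)
    t = build_gc_table([b], design)
    rgb = t[t["method"] == "GC_RGB"].iloc[0]
    assert np.isnan(rgb["value"]) and rgb["n_samples"] == 0
    assert t[t["method"] != "GC_RGB"]["value"].notna().all()


def test_build_gc_table_rejects_duplicates():
    cfg = TrialConfig(n_plots=4, n_genotypes=2, n_field_rows=2, n_field_cols=2)
    design, _ = simulate_trial(cfg, seed=1)
    b = _tiny_bundle(1, 1)
    with pytest.raises(IntegrityError):
        build_gc_table([b, b], design)


def test_build_gc_table_deterministic():
    cfg = TrialConfig(n_plots=4, n_genotypes=2, n_field_rows=2, n_field_cols=2)
    design, _ = simulate_trial(cfg, seed=1)
    bundles = [_tiny_bundle(p, 1) for p in range(1, 5)]
    t1 = build_gc_table(bundles, design)
    t2 = build_gc_table(bundles, design)
    assert t1.equals(t2)


def test_estimate_bundle_value_ranges(default_trial, schedule, default_config):
    from canopygc import render_bundle

    design, truth = default_trial
    b = render_bundle(5, schedule[0], design, truth, default_config.sensors,
                      11, schedule)
    rows = estimate_bundle(b, design)
    vals = {r["method"]: r["value"] for r in rows}
    assert 0 <= vals["NDVI"] <= 0.99
    for m in ("GC_RGB", "GC_LIDAR_RR", "GC_LIDAR_HT"):
        assert 0 <= vals[m] <= 1
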