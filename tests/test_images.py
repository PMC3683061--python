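"""Image preprocessing, detection, description and BOW encoding tests."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from pmfusion.errors import CodebookError
from pmfusion.images import (
    BowVector,
    Codebook,
    DetectorConfig,
    FundusImage,
    build_codebook,
    describe_keypoints,
    detect_keypoints,
    encode_bow,
    extract_descriptors,
    preprocess_image,
    read_codebook,
    save_codebook,
)


def rgb(green: np.ndarray) -> FundusImage:
    img = np.zeros(green.shape + (3,), dtype=np.uint8)
    img[:, :, 1] = green
    return FundusImage(img)


def textured_image(seed=5, size=256):
    rng = np.random.default_rng(seed)
    base = gaussian_filter(rng.random((size, size)) * 180, 3) + 30
    return rgb(base.astype(np.uint8))


# ---------------------------------------------------------- preprocess


def test_preprocess_resizes_to_height_256():
    img = rgb(np.zeros((512, 768), np.uint8))
    gray, mask = preprocess_image(img)
    assert gray.shape == (256, 384)
    assert mask.shape == (256, 384)


def test_preprocess_square_mask_radius():
    gray, mask = preprocess_image(rgb(np.zeros((256, 256), np.uint8)))
    assert gray.shape == (256, 256)
    c = (256 - 1) / 2
    r = 0.95 * 128  # 121.6 px
    assert mask[int(round(c)), int(round(c + r - 1))]
    assert not mask[int(round(c)), int(round(c + r + 2))]


def test_preprocess_takes_green_channel_only():
    img = np.zeros((64, 64, 3), np.uint8)
    img[:, :, 0] = 255  # red saturated, green empty
    gray, _ = preprocess_image(FundusImage(img))
    assert np.all(gray == 0)


# ------------------------------------------------------------ detection


def test_detect_uniform_raster_yields_nothing():
    gray, mask = preprocess_image(rgb(np.full((256, 256), 77, np.uint8)))
    assert detect_keypoints(gray, mask) == []


def test_detect_harris_finds_square_corners():
    green = np.full((256, 256), 30, np.uint8)
    green[100:156, 100:156] = 220
    gray, mask = preprocess_image(rgb(green))
    kps = [k for k in detect_keypoints(gray, mask) if k.detector == "HAR"]
    corners = [(100, 100), (100, 155), (155, 100), (155, 155)]

    # independent corner-response oracle: plain structure-tensor Harris
    # computed with numpy only, maximized near the known corners
    g = gray / 255.0
    gy, gx = np.gradient(gaussian_filter(g, 1.0))
    axx = gaussian_filter(gx * gx, 2.0)
    axy = gaussian_filter(gx * gy, 2.0)
    ayy = gaussian_filter(gy * gy, 2.0)
    resp = axx * ayy - axy**2 - 0.04 * (axx + ayy) ** 2
    r_or, c_or = np.unravel_index(np.argmax(resp), resp.shape)
    assert min((r_or - y) ** 2 + (c_or - x) ** 2 for y, x in corners) <= 9

    hits = 0
    for y, x in corners:
        if any((k.x - x) ** 2 + (k.y - y) ** 2 <= 9 for k in kps):
            hits += 1
    assert hits >= 1  # at least one corner found within 3 px


def test_detect_hessian_finds_blob_center():
    yy, xx = np.mgrid[0:256, 0:256]
    blob = 30 + 180 * np.exp(-((yy - 128) ** 2 + (xx - 128) ** 2) / (2 * 6.0**2))
    gray, mask = preprocess_image(rgb(blob.astype(np.uint8)))

    # determinant-of-Hessian oracle at the known center/scale
    g = gaussian_filter(gray / 255.0, 4.8)
    hyy = np.gradient(np.gradient(g, axis=0), axis=0)
    hxx = np.gradient(np.gradient(g, axis=1), axis=1)
    hxy = np.gradient(np.gradient(g, axis=0), axis=1)
    doh = hxx * hyy - hxy**2
    r_or, c_or = np.unravel_index(np.argmax(doh), doh.shape)
    assert (r_or - 128) ** 2 + (c_or - 128) ** 2 <= 9

    hes = [k for k in detect_keypoints(gray, mask) if k.detector == "HES"]
    assert any((k.x - 128) ** 2 + (k.y - 128) ** 2 <= 9 for k in hes)


def test_detect_respects_mask():
    img = textured_image(seed=9)
    gray, mask = preprocess_image(img)
    h, w = gray.shape
    cy, cx = (h - 1) / 2, (w - 1) / 2
    radius = 0.95 * min(h, w) / 2
    for k in detect_keypoints(gray, mask):
        assert (k.y - cy) ** 2 + (k.x - cx) ** 2 <= radius**2
        assert k.scale > 0


# ---------------------------------------------------------- description


def test_descriptors_quantized_and_deterministic():
    gray, mask = preprocess_image(textured_image())
    kps = detect_keypoints(gray, mask)
    d1, kept1 = describe_keypoints(gray, kps)
    d2, kept2 = describe_keypoints(gray, kps)
    assert d1.shape[1] == 128
    assert d1.dtype == np.uint8  # every bin an integer in [0, 255]
    assert np.array_equal(d1, d2) and kept1 == kept2


def test_descriptors_invariant_to_brightness_shift():
    img = textured_image(seed=5)
    shifted = FundusImage(img.pixels.copy())
    shifted.pixels[:, :, 1] += 20  # no saturation in the fixture
    d1 = extract_descriptors(img)
    d2 = extract_descriptors(shifted)
    assert d1.shape == d2.shape
    assert np.array_equal(d1, d2)


def test_descriptors_rotation_invariant_to_90_degrees():
    img = textured_image(seed=5)
    gray, mask = preprocess_image(img)
    d, kept = describe_keypoints(gray, detect_keypoints(gray, mask))
    rot = FundusImage(np.rot90(img.pixels, k=1).copy())
    gray_r, mask_r = preprocess_image(rot)
    d_r, kept_r = describe_keypoints(gray_r, detect_keypoints(gray_r, mask_r))
    index = {
        (round(k.x), round(k.y), k.scale, k.detector): i
        for i, k in enumerate(kept_r)
    }
    n_matched = 0
    for i, k in enumerate(kept):
        # rot90 maps (x, y) -> (y, W-1-x)
        j = index.get((round(k.y), 255 - round(k.x), k.scale, k.detector))
        if j is None:
            continue
        n_matched += 1
        a, b = d[i].astype(float), d_r[j].astype(float)
        assert np.linalg.norm(a - b) <= 0.15 * np.linalg.norm(a)
    assert n_matched >= 10


def test_descriptor_window_outside_raster_dropped():
    gray = np.zeros((64, 64))
    from pmfusion.images import Keypoint

    kps = [Keypoint(2.0, 2.0, 4.8, "HAR")]  # window exits the raster
    d, kept = describe_keypoints(gray, kps)
    assert len(kept) == 0 and d.shape == (0, 128)


# -------------------------------------------------------------- codebook


def descriptor_cluster(center, n, rng):
    return np.clip(
        center + rng.normal(0, 2, size=(n, 128)), 0, 255
    ).astype(np.uint8)


def test_codebook_recovers_synthetic_clusters():
    rng = np.random.default_rng(0)
    c1 = np.full(128, 40.0)
    c2 = np.full(128, 200.0)
    sets = [
        ("img1", descriptor_cluster(c1, 30, rng)),
        ("img2", descriptor_cluster(c2, 30, rng)),
        ("img3", np.vstack([descriptor_cluster(c1, 15, rng),
                            descriptor_cluster(c2, 15, rng)])),
        ("img4", np.vstack([descriptor_cluster(c1, 15, rng),
                            descriptor_cluster(c2, 15, rng)])),
    ]
    cb = build_codebook(sets, k=2, seed=1)
    got = sorted(cb.centroids.mean(axis=1))
    # each centroid within 1.0 of a true cluster mean
    assert abs(got[0] - 40.0) < 1.0 and abs(got[1] - 200.0) < 1.0


def test_codebook_deterministic_and_provenance():
    rng = np.random.default_rng(1)
    sets = [
        (f"img{i}", descriptor_cluster(np.full(128, 30.0 + 20 * i), 40, rng))
        for i in range(6)
    ]
    cb1 = build_codebook(sets, k=3, seed=7)
    cb2 = build_codebook(sets, k=3, seed=7)
    assert np.array_equal(cb1.centroids, cb2.centroids)
    assert cb1.build_seed == 7
    assert len(cb1.image_ids) == 3  # ceil(6/2) images pooled


def test_codebook_too_few_descriptors():
    rng = np.random.default_rng(2)
    sets = [("a", descriptor_cluster(np.full(128, 50.0), 3, rng)),
            ("b", descriptor_cluster(np.full(128, 80.0), 3, rng))]
    with pytest.raises(CodebookError):
        build_codebook(sets, k=100, seed=0)


def test_codebook_text_roundtrip(tmp_path):
    rng = np.random.default_rng(3)
    cb = Codebook(centroids=rng.random((4, 128)) * 255, build_seed=9,
                  image_ids=["a", "b"])
    save_codebook(tmp_path / "cb.txt", cb)
    loaded = read_codebook(tmp_path / "cb.txt")
    assert loaded.build_seed == 9 and loaded.image_ids == ["a", "b"]
    assert np.allclose(loaded.centroids, cb.centroids, atol=1e-6)


# -------------------------------------------------------------- encoding


def test_encode_bow_empty_and_conservation():
    cb = Codebook(
        centroids=np.vstack([np.full(128, v) for v in (10.0, 100.0, 200.0)]),
        build_seed=0,
    )
    empty = encode_bow(np.empty((0, 128)), cb)
    assert empty.raw_count == 0 and np.all(empty.histogram == 0.0)

    rng = np.random.default_rng(4)
    desc = rng.integers(0, 256, size=(7, 128)).astype(np.uint8)
    vec = encode_bow(desc, cb)
    assert vec.counts.sum() == 7  # pre-normalization conservation
    assert np.linalg.norm(vec.histogram) == pytest.approx(1.0)


def test_encode_bow_matches_bruteforce_assignment():
    rng = np.random.default_rng(5)
    cb = Codebook(centroids=rng.random((6, 128)) * 255, build_seed=0)
    desc = rng.integers(0, 256, size=(20, 128)).astype(float)
    vec = encode_bow(desc, cb)
    counts = np.zeros(6, int)
    for d in desc:
        dists = [np.sum((d - c) ** 2) for c in cb.centroids]
        counts[int(np.argmin(dists))] += 1
    assert np.array_equal(vec.counts, counts)


def test_encode_bow_tie_goes_to_lowest_index():
    c = np.full(128, 100.0)
    cb = Codebook(centroids=np.vstack([c + 1, c - 1]), build_seed=0)
    vec = encode_bow(c[None, :], cb)  # equidistant from both centroids
    assert vec.counts[0] == 1 and vec.counts[1] == 0


def test_full_path_count_conservation():
    from pmfusion.simulate import render_fundus

    rng = np.random.default_rng(6)
    img = FundusImage(render_fundus(1, rng, 0.8))
    gray, mask = preprocess_image(img)
    kps = detect_keypoints(gray, mask)
    desc, kept = describe_keypoints(gray, kps)
    assert len(desc) == len(kept) <= len(kps)
    cb = Codebook(centroids=np.random.default_rng(1).random((5, 128)) * 255,
                  build_seed=0)
    vec = encode_bow(desc, cb)
    assert vec.counts.sum() == len(kept)
    assert 50 <= len(kps) <= 2000  # sensible keypoint budget on a fundus
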