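"""Bag-of-visual-words feature extraction from retinal fundus images.

The image arm of the pipeline follows the classical local-feature recipe:
the fundus photograph is resized to a height of 256 pixels (aspect ratio
preserved), the green channel is extracted (retinal structure is best
differentiated there), and interest points are collected only within 0.95
of the field-of-view radius.  Two complementary detectors supply the
points — multiscale Harris (corners) and determinant-of-Hessian (blobs),
each with Laplacian scale selection — and every point is described by a
128-bin SIFT gradient-orientation histogram quantized to [0, 255].
Descriptors pooled from a random half of the training images are k-means
clustered into a k=100 visual-word codebook, and each image becomes the
normalized histogram of its descriptors' nearest visual words.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter, gaussian_laplace
from scipy.spatial.distance import cdist
from skimage.feature import hessian_matrix, peak_local_max, structure_tensor
from sklearn.cluster import KMeans

from .errors import CodebookError
from .types import FeatureView

__all__ = [
    "FundusImage",
    "Keypoint",
    "Codebook",
    "BowVector",
    "DetectorConfig",
    "load_image",
    "preprocess_image",
    "detect_keypoints",
    "describe_keypoints",
    "extract_descriptors",
    "build_codebook",
    "encode_bow",
    "bow_table",
    "save_codebook",
    "read_codebook",
]

log = logging.getLogger(__name__)


@dataclass
class FundusImage:
    """8-bit RGB fundus raster with its subject identifier."""

    pixels: np.ndarray  # H x W x 3, uint8, channel order R, G, B
    subject_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("expected an H x W x 3 raster")
        if self.pixels.shape[0] < 32 or self.pixels.shape[1] < 32:
            raise ValueError("image smaller than 32 x 32")
        if self.pixels.dtype != np.uint8:
            self.pixels = np.clip(self.pixels, 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class Keypoint:
    """Interest point in resized-image coordinates."""

    x: float
    y: float
    scale: float
    detector: str  # "HAR" or "HES"


@dataclass
class Codebook:
    """k-means visual-word centroids plus build provenance."""

    centroids: np.ndarray  # k x 128
    build_seed: int
    image_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.ndim != 2 or self.centroids.shape[1] != 128:
            raise ValueError("centroids must be k x 128")
        if self.centroids.shape[0] < 2:
            raise ValueError("codebook needs k >= 2")
        if len(np.unique(self.centroids, axis=0)) != self.centroids.shape[0]:
            raise ValueError("duplicate centroids")

    @property
    def k(self) -> int:
        return self.centroids.shape[0]


@dataclass
class BowVector:
    """Visual-word occurrence histogram for one image."""

    histogram: np.ndarray  # k floats, normalized unless raw_count == 0
    raw_count: int
    counts: np.ndarray  # k ints, pre-normalization


@dataclass(frozen=True)
class DetectorConfig:
    """Detector and descriptor parameters (all adjustable).

    The scale pyramid has ``n_scales`` levels with sigma doubling from
    ``sigma0``.  Response thresholds are relative to the per-image maximal
    response, with small absolute floors so structureless rasters yield no
    points; the defaults put a typical fundus image in the range of a few
    hundred keypoints.
    """

    n_scales: int = 5
    sigma0: float = 1.2
    harris_k: float = 0.04
    harris_rel_thresh: float = 0.01
    harris_abs_floor: float = 1e-4
    hessian_rel_thresh: float = 0.02
    hessian_abs_floor: float = 1e-4
    mask_radius_fraction: float = 0.95
    norm: str = "l2"  # BOW normalization: "l2" or "l1"

    @property
    def sigmas(self) -> np.ndarray:
        return self.sigma0 * 2.0 ** np.arange(self.n_scales)


def load_image(path, subject_id: str = "") -> FundusImage:
    """Read a PNG/JPEG file as an RGB fundus image."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"))
    return FundusImage(pixels=arr, subject_id=subject_id or str(path))


def preprocess_image(
    img: FundusImage, mask_radius_fraction: float = 0.95
) -> tuple[np.ndarray, np.ndarray]:
    """Green channel resized to height 256, plus the circular analysis mask.

    The raster is bilinearly resized to height 256 with the aspect ratio
    preserved; the mask is the disc of radius
    ``mask_radius_fraction * min(H, W) / 2`` centered on the raster.
    """
    green = img.pixels[:, :, 1].astype(float)
    h0, w0 = green.shape
    h1 = 256
    w1 = max(1, round(w0 * h1 / h0))
    pil = Image.fromarray(green)
    gray = np.asarray(pil.resize((w1, h1), resample=Image.BILINEAR), dtype=float)
    cy, cx = (h1 - 1) / 2.0, (w1 - 1) / 2.0
    radius = mask_radius_fraction * min(h1, w1) / 2.0
    yy, xx = np.mgrid[0:h1, 0:w1]
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    return gray, mask


def _quantize_response(resp: np.ndarray) -> np.ndarray:
    """Round a detector response to 1e-6 relative precision.

    Peak selection sorts candidates by response value, so two nearly equal
    peaks could swap order under round-off-level input perturbations (e.g.
    a uniform brightness shift).  Snapping the response to a coarse grid
    makes every downstream comparison exactly reproducible.
    """
    m = np.abs(resp).max(initial=0.0)
    if m <= 0:
        return resp
    q = m * 1e-6
    return np.round(resp / q) * q


def _scale_normalized_log(gray: np.ndarray, sigmas) -> np.ndarray:
    """|sigma^2 * Laplacian-of-Gaussian| stack for scale selection."""
    return _quantize_response(
        np.stack([np.abs(s**2 * gaussian_laplace(gray, s)) for s in sigmas])
    )


def _laplacian_scale_max(log_stack: np.ndarray, level: int, r: int, c: int) -> bool:
    """True if the normalized LoG at (level, r, c) is maximal over the
    available neighboring pyramid levels."""
    val = log_stack[level, r, c]
    lo = max(0, level - 1)
    hi = min(log_stack.shape[0], level + 2)
    # tiny relative slack so round-off cannot flip the decision
    return val >= log_stack[lo:hi, r, c].max() * (1.0 - 1e-9)


def detect_keypoints(
    gray: np.ndarray, mask: np.ndarray, config: DetectorConfig = DetectorConfig()
) -> list[Keypoint]:
    """Union of Harris-Laplace corners and Hessian-Laplace blobs.

    Per pyramid level, candidate points are local maxima of the Harris
    (resp. determinant-of-Hessian) response above a relative threshold; a
    candidate survives only if its scale-normalized Laplacian response is
    maximal across neighboring levels and it lies inside the mask.
    Deterministic for a fixed raster.
    """
    gray = np.asarray(gray, dtype=float) / 255.0
    # center the raster: the truncated Laplacian/derivative kernels do not
    # sum exactly to zero, so a uniform intensity shift would otherwise
    # leak into the responses
    gray = gray - gray.mean()
    sigmas = config.sigmas
    log_stack = _scale_normalized_log(gray, sigmas)
    kps: list[Keypoint] = []
    for level, s in enumerate(sigmas):
        # corners: Harris on the smoothed image, integration scale s;
        # reflect padding keeps the response invariant to intensity shifts
        smoothed = gaussian_filter(gray, 0.5 * s)
        axx, axy, ayy = structure_tensor(
            smoothed, sigma=s, mode="reflect", order="rc"
        )
        har = _quantize_response(
            axx * ayy - axy**2 - config.harris_k * (axx + ayy) ** 2
        )
        thr = max(
            config.harris_abs_floor,
            config.harris_rel_thresh * har.max() * (1.0 - 1e-9),
        )
        if har.max() > config.harris_abs_floor:
            for r, c in peak_local_max(
                har, min_distance=max(1, int(round(s))), threshold_abs=thr
            ):
                if mask[r, c] and _laplacian_scale_max(log_stack, level, r, c):
                    kps.append(Keypoint(float(c), float(r), float(s), "HAR"))
        # blobs: scale-normalized determinant of the Hessian
        H = hessian_matrix(
            gray, sigma=s, mode="reflect", order="rc",
            use_gaussian_derivatives=True,
        )
        doh = _quantize_response(s**4 * (H[0] * H[2] - H[1] ** 2))
        thr = max(
            config.hessian_abs_floor,
            config.hessian_rel_thresh * doh.max() * (1.0 - 1e-9),
        )
        if doh.max() > config.hessian_abs_floor:
            for r, c in peak_local_max(
                doh, min_distance=max(1, int(round(s))), threshold_abs=thr
            ):
                if mask[r, c] and _laplacian_scale_max(log_stack, level, r, c):
                    kps.append(Keypoint(float(c), float(r), float(s), "HES"))
    return kps


_N_CELLS = 4  # SIFT spatial grid
_N_ORI = 8  # orientation bins per cell
_CELL_WIDTH_SIGMAS = 3.0  # cell width in units of the keypoint scale


def _dominant_orientation(mag, ori, yy, xx, y, x, sigma) -> float:
    """Peak of the 36-bin gradient-orientation histogram around (y, x)."""
    w = np.exp(-((yy - y) ** 2 + (xx - x) ** 2) / (2 * (1.5 * sigma) ** 2))
    hist = np.bincount(
        ((ori + np.pi) / (2 * np.pi) * 36).astype(int).clip(0, 35).ravel(),
        weights=(w * mag).ravel(),
        minlength=36,
    )
    return (np.argmax(hist) + 0.5) / 36 * 2 * np.pi - np.pi


def describe_keypoints(
    gray: np.ndarray,
    kps: list[Keypoint],
    config: DetectorConfig = DetectorConfig(),
) -> tuple[np.ndarray, list[Keypoint]]:
    """128-bin SIFT descriptors (4x4 cells x 8 orientations) per keypoint.

    Gradients are taken on the image smoothed at the keypoint scale, the
    descriptor frame is rotated to the dominant gradient orientation
    (rotation invariance), and contributions are trilinearly interpolated
    over cells and orientation bins with Gaussian spatial weighting.  The
    histogram is L2-normalized, clipped at 0.2, renormalized and quantized
    to integers in [0, 255].  Keypoints whose support window exits the
    raster are dropped and logged.  Returns (descriptors, kept_keypoints).
    """
    gray = np.asarray(gray, dtype=float)
    gray = gray - gray.mean()  # intensity-shift invariance
    h, w = gray.shape
    out, kept = [], []
    cache: dict[float, tuple] = {}
    n_dropped = 0
    for kp in kps:
        s = kp.scale
        if s not in cache:
            sm = gaussian_filter(gray, s)
            gx = np.gradient(sm, axis=1)
            gy = np.gradient(sm, axis=0)
            cache[s] = (np.hypot(gx, gy), np.arctan2(gy, gx))
        mag, ori = cache[s]

        cell = _CELL_WIDTH_SIGMAS * s
        half = int(np.ceil(cell * (_N_CELLS + 1) / 2 * np.sqrt(2)))
        r0, r1 = int(round(kp.y)) - half, int(round(kp.y)) + half + 1
        c0, c1 = int(round(kp.x)) - half, int(round(kp.x)) + half + 1
        if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
            n_dropped += 1
            continue
        yy, xx = np.mgrid[r0:r1, c0:c1]
        m = mag[r0:r1, c0:c1]
        o = ori[r0:r1, c0:c1]
        theta = _dominant_orientation(m, o, yy, xx, kp.y, kp.x, s)

        dy = (yy - kp.y).ravel()
        dx = (xx - kp.x).ravel()
        ct, st = np.cos(theta), np.sin(theta)
        u = (ct * dx + st * dy) / cell + (_N_CELLS - 1) / 2.0
        v = (-st * dx + ct * dy) / cell + (_N_CELLS - 1) / 2.0
        inside = (u > -1) & (u < _N_CELLS) & (v > -1) & (v < _N_CELLS)
        if not inside.any():
            n_dropped += 1
            continue
        u, v = u[inside], v[inside]
        weight = (m.ravel() * np.exp(
            -(dx**2 + dy**2) / (2 * (0.5 * _N_CELLS * cell) ** 2)
        ))[inside]
        ang = ((o.ravel()[inside] - theta + np.pi) % (2 * np.pi)) / (
            2 * np.pi
        ) * _N_ORI  # [0, 8)

        hist = np.zeros((_N_CELLS, _N_CELLS, _N_ORI))
        u0 = np.floor(u).astype(int)
        v0 = np.floor(v).astype(int)
        a0 = np.floor(ang).astype(int)
        for du, wu in ((0, 1 - (u - u0)), (1, u - u0)):
            for dv, wv in ((0, 1 - (v - v0)), (1, v - v0)):
                for da, wa in ((0, 1 - (ang - a0)), (1, ang - a0)):
                    ui, vi = u0 + du, v0 + dv
                    ok = (ui >= 0) & (ui < _N_CELLS) & (vi >= 0) & (vi < _N_CELLS)
                    np.add.at(
                        hist,
                        (vi[ok], ui[ok], (a0[ok] + da) % _N_ORI),
                        weight[ok] * wu[ok] * wv[ok] * wa[ok],
                    )
        d = hist.ravel()
        norm = np.linalg.norm(d)
        if norm > 0:
            d = np.minimum(d / norm, 0.2)
            norm = np.linalg.norm(d)
            d = d / norm if norm > 0 else d
        out.append(np.clip(np.round(d * 512.0), 0, 255).astype(np.uint8))
        kept.append(kp)
    if n_dropped:
        log.info("dropped %d keypoints with out-of-raster windows", n_dropped)
    desc = np.array(out, dtype=np.uint8) if out else np.empty((0, 128), np.uint8)
    return desc, kept


def extract_descriptors(
    img: FundusImage, config: DetectorConfig = DetectorConfig()
) -> np.ndarray:
    """Full image -> descriptor path: preprocess, detect, describe."""
    gray, mask = preprocess_image(img, config.mask_radius_fraction)
    kps = detect_keypoints(gray, mask, config)
    desc, _ = describe_keypoints(gray, kps, config)
    return desc


def build_codebook(
    descriptor_sets: list, k: int = 100, seed: int = 0
) -> Codebook:
    """k-means codebook from a seeded random half of the training images.

    ``descriptor_sets`` is a list of ``(image_id, descriptors)`` pairs.
    ceil(n/2) images are chosen by a seeded permutation, their descriptors
    pooled and clustered; a fixed seed reproduces the codebook exactly.
    """
    if len(descriptor_sets) < 2:
        raise CodebookError("need at least 2 training images")
    rng = np.random.default_rng(seed)
    n_half = (len(descriptor_sets) + 1) // 2
    chosen = sorted(rng.permutation(len(descriptor_sets))[:n_half].tolist())
    ids = [descriptor_sets[i][0] for i in chosen]
    pooled = np.concatenate(
        [np.asarray(descriptor_sets[i][1], dtype=float).reshape(-1, 128)
         for i in chosen]
    )
    if pooled.shape[0] < k:
        raise CodebookError(
            f"{pooled.shape[0]} descriptors pooled but k={k}; lower k"
        )
    km = KMeans(n_clusters=k, random_state=seed % (2**32), n_init=4)
    km.fit(pooled)
    return Codebook(centroids=km.cluster_centers_, build_seed=seed, image_ids=ids)


def encode_bow(
    descriptors: np.ndarray,
    codebook: Codebook,
    norm: str = "l2",
) -> BowVector:
    """Histogram of nearest-visual-word assignments, then normalized.

    Euclidean nearest centroid with ties to the lowest centroid index;
    an image with zero descriptors yields an all-zero vector (flagged in
    the log rather than failing the pipeline).
    """
    desc = np.asarray(descriptors, dtype=float).reshape(-1, 128)
    if desc.shape[0] == 0:
        log.warning("image yielded no descriptors; emitting zero BOW vector")
        z = np.zeros(codebook.k)
        return BowVector(histogram=z, raw_count=0, counts=z.astype(int))
    assign = np.argmin(cdist(desc, codebook.centroids), axis=1)
    counts = np.bincount(assign, minlength=codebook.k)
    if norm == "l2":
        hist = counts / np.linalg.norm(counts)
    elif norm == "l1":
        hist = counts / counts.sum()
    else:
        raise ValueError(f"unknown norm {norm!r}")
    return BowVector(histogram=hist, raw_count=int(counts.sum()), counts=counts)


def bow_table(
    images: list,
    codebook: Codebook,
    config: DetectorConfig = DetectorConfig(),
) -> FeatureView:
    """BOW feature view for a list of FundusImage (or path, id) entries."""
    ids, rows = [], []
    for entry in images:
        img = entry if isinstance(entry, FundusImage) else load_image(*entry)
        vec = encode_bow(extract_descriptors(img, config), codebook, config.norm)
        ids.append(img.subject_id)
        rows.append(vec.histogram)
    return FeatureView(
        source_id="I",
        subject_ids=ids,
        matrix=np.array(rows),
        feature_names=[f"word_{j}" for j in range(codebook.k)],
    )


def save_codebook(path, codebook: Codebook) -> None:
    """Persist centroids as a flat text matrix with a metadata header."""
    with open(path, "w") as fh:
        fh.write(f"# k: {codebook.k}\n")
        fh.write(f"# build_seed: {codebook.build_seed}\n")
        fh.write(f"# images: {','.join(map(str, codebook.image_ids))}\n")
        for row in codebook.centroids:
            fh.write(" ".join(f"{v:.9g}" for v in row) + "\n")


def read_codebook(path) -> Codebook:
    meta = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
            elif line.strip():
                rows.append([float(v) for v in line.split()])
    return Codebook(
        centroids=np.array(rows),
        build_seed=int(meta.get("build_seed", 0)),
        image_ids=[s for s in meta.get("images", "").split(",") if s],
    )
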