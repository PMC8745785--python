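"""Bag-of-visual-features encoding of spectrogram images.

Pipeline: detect keypoints on grayscale spectrogram images, describe each
with a 64-dimensional SURF-style descriptor, quantize descriptors against a
k-means codebook of "visual words", and represent every image by its
L1-normalized word-occurrence histogram.

Descriptors follow the SURF layout: a 20s x 20s window around the keypoint
(s = keypoint scale in pixels) is split into a 4x4 grid of subregions; Haar
wavelet responses dx, dy are sampled on a 5x5 grid per subregion, weighted
by a Gaussian (sigma = 3.3 s), and summed as (sum dx, sum dy, sum |dx|,
sum |dy|) per subregion -> 4 x 4 x 4 = 64 values, L2-normalized.

Detectors:

* ``surf``  — sparse determinant-of-Hessian extrema (the SURF detection
  principle), found per scale with scikit-image's Hessian determinant map.
* ``dense`` — descriptors on a regular grid at a fixed scale; the standard
  choice for texture-like images where dense sampling outperforms sparse
  interest points.
* ``orb``   — scikit-image ORB (256-bit binary descriptors exposed as
  256-d float vectors; descriptor_dim differs from the 64-d default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from .errors import CodebookError, DescriptorError, LeakageError
from .spectrogram import SpectrogramImage, WindowRef

DESCRIPTOR_DIM = 64
DEFAULT_VOCABULARY_SIZE = 500
DEFAULT_FRACTION_STRONGEST = 0.8


@dataclass
class DetectorConfig:
    kind: str = "dense"  # {surf, dense, orb}
    scale: int = 2  # keypoint scale s (px) for dense grids
    step_x: int = 8  # dense grid stride, columns
    step_y: int = 4  # dense grid stride, rows
    doh_sigmas: tuple[float, ...] = (1.5, 3.0, 6.0)  # surf: Hessian scales
    doh_threshold: float = 1e-4  # surf: minimum det-of-Hessian response
    orb_n_keypoints: int = 100

    @property
    def descriptor_dim(self) -> int:
        return 256 if self.kind == "orb" else DESCRIPTOR_DIM


@dataclass
class KeypointSet:
    """Keypoints plus their descriptors for one image."""

    image_ref: WindowRef
    xy: np.ndarray  # (n, 2) float: (x=col, y=row)
    scales: np.ndarray  # (n,) px
    responses: np.ndarray  # (n,) detector strength
    descriptors: np.ndarray  # (n, d), rows L2-normalized

    def __len__(self) -> int:
        return len(self.xy)


@dataclass
class Codebook:
    """K visual words: k-means centroids over descriptor space."""

    centroids: np.ndarray  # (k, d)
    k: int
    trained_on: int  # descriptors clustered
    seed: int
    detector: DetectorConfig = field(default_factory=DetectorConfig)

    @property
    def dim(self) -> int:
        return self.centroids.shape[1]


@dataclass
class BofVector:
    """Visual-word occurrence histogram for one image (the feature vector)."""

    values: np.ndarray  # (k,), L1-normalized when any keypoint exists
    normalized: bool
    image_ref: WindowRef
    label: str
    degenerate: bool = False  # True when no keypoints were found


# ---------------------------------------------------------------------------
# SURF-style descriptors
# ---------------------------------------------------------------------------


def _integral(img: np.ndarray) -> np.ndarray:
    ii = np.zeros((img.shape[0] + 1, img.shape[1] + 1), dtype=np.float64)
    np.cumsum(np.cumsum(img, axis=0), axis=1, out=ii[1:, 1:])
    return ii


def _haar_maps(img: np.ndarray, s: int) -> tuple[np.ndarray, np.ndarray]:
    """Full-image Haar responses dx, dy with half-size ``s``.

    Defined only ``s`` pixels inside the image; callers must pad.  The x
    filter is [-1 | +1] over a 2s x 2s box split left/right; y analogous.
    """
    ii = _integral(img)
    H, W = img.shape

    def box(y0, y1, x0, x1):
        return ii[y1, x1] - ii[y0, x1] - ii[y1, x0] + ii[y0, x0]

    dx = np.full((H, W), 0.0)
    dy = np.full((H, W), 0.0)
    ys = np.arange(s, H - s)
    xs = np.arange(s, W - s)
    if len(ys) == 0 or len(xs) == 0:
        return dx, dy
    Y, X = np.meshgrid(ys, xs, indexing="ij")
    dx[s : H - s, s : W - s] = box(Y - s, Y + s, X, X + s) - box(Y - s, Y + s, X - s, X)
    dy[s : H - s, s : W - s] = box(Y, Y + s, X - s, X + s) - box(Y - s, Y, X - s, X + s)
    return dx, dy


def _surf_descriptors(
    img: np.ndarray, pts_yx: np.ndarray, s: int
) -> tuple[np.ndarray, np.ndarray]:
    """64-d SURF-style descriptors at integer keypoints (y, x), scale s.

    Returns (descriptors, raw_energy) where raw_energy (pre-normalization
    L2 norm) doubles as a contrast/strength measure.
    """
    if len(pts_yx) == 0:
        return np.zeros((0, DESCRIPTOR_DIM)), np.zeros(0)
    pad = int(np.ceil(10.5 * s)) + 2 * s
    imgp = np.pad(img.astype(np.float64), pad, mode="reflect")
    dxm, dym = _haar_maps(imgp, s)
    offs = np.round((np.arange(20) - 9.5) * s).astype(int)
    oy, ox = np.meshgrid(offs, offs, indexing="ij")
    w = np.exp(-(oy**2 + ox**2) / (2 * (3.3 * s) ** 2))
    oy, ox, w = oy.ravel(), ox.ravel(), w.ravel()
    ys = pts_yx[:, 0, None] + pad + oy[None, :]
    xs = pts_yx[:, 1, None] + pad + ox[None, :]
    sdx = dxm[ys, xs] * w[None, :]
    sdy = dym[ys, xs] * w[None, :]

    def pool(v):
        # sample index k = row*20 + col; rows/cols split into 4 blocks of 5
        v = v.reshape(-1, 4, 5, 4, 5)
        return v.sum(axis=(2, 4))  # (n, 4, 4)

    feats = np.stack(
        [pool(sdx), pool(sdy), pool(np.abs(sdx)), pool(np.abs(sdy))], axis=-1
    ).reshape(len(pts_yx), DESCRIPTOR_DIM)
    energy = np.linalg.norm(feats, axis=1)
    safe = np.where(energy > 0, energy, 1.0)
    return feats / safe[:, None], energy


def _detect_dense(img: np.ndarray, cfg: DetectorConfig, ref: WindowRef) -> KeypointSet:
    H, W = img.shape
    ys = np.arange(cfg.step_y // 2, H, cfg.step_y)
    xs = np.arange(cfg.step_x // 2, W, cfg.step_x)
    Y, X = np.meshgrid(ys, xs, indexing="ij")
    pts = np.column_stack([Y.ravel(), X.ravel()])
    desc, energy = _surf_descriptors(img, pts, cfg.scale)
    return KeypointSet(
        image_ref=ref,
        xy=pts[:, ::-1].astype(np.float64),
        scales=np.full(len(pts), float(cfg.scale)),
        responses=energy,
        descriptors=desc,
    )


def _detect_surf(img: np.ndarray, cfg: DetectorConfig, ref: WindowRef) -> KeypointSet:
    from skimage.feature import hessian_matrix_det, peak_local_max

    imgf = img.astype(np.float64) / 255.0
    all_pts, all_scales, all_resp = [], [], []
    for sigma in cfg.doh_sigmas:
        doh = hessian_matrix_det(imgf, sigma=sigma)
        peaks = peak_local_max(
            doh, min_distance=2, threshold_abs=cfg.doh_threshold, exclude_border=False
        )
        if len(peaks):
            all_pts.append(peaks)
            all_scales.append(np.full(len(peaks), max(1.0, round(sigma))))
            all_resp.append(doh[peaks[:, 0], peaks[:, 1]])
    if not all_pts:
        return KeypointSet(
            image_ref=ref,
            xy=np.zeros((0, 2)),
            scales=np.zeros(0),
            responses=np.zeros(0),
            descriptors=np.zeros((0, DESCRIPTOR_DIM)),
        )
    pts = np.concatenate(all_pts)
    scales = np.concatenate(all_scales)
    resp = np.concatenate(all_resp)
    descs = np.zeros((len(pts), DESCRIPTOR_DIM))
    for s in np.unique(scales):
        m = scales == s
        descs[m], _ = _surf_descriptors(img, pts[m], int(s))
    return KeypointSet(
        image_ref=ref,
        xy=pts[:, ::-1].astype(np.float64),
        scales=scales,
        responses=resp,
        descriptors=descs,
    )


def _detect_orb(img: np.ndarray, cfg: DetectorConfig, ref: WindowRef) -> KeypointSet:
    from skimage.feature import ORB

    orb = ORB(n_keypoints=cfg.orb_n_keypoints)
    try:
        orb.detect_and_extract(img.astype(np.float64) / 255.0)
    except RuntimeError:  # skimage raises when no keypoints are found
        return KeypointSet(ref, np.zeros((0, 2)), np.zeros(0), np.zeros(0), np.zeros((0, 256)))
    desc = orb.descriptors.astype(np.float64)
    norms = np.linalg.norm(desc, axis=1)
    desc = desc / np.where(norms > 0, norms, 1.0)[:, None]
    return KeypointSet(
        image_ref=ref,
        xy=orb.keypoints[:, ::-1].astype(np.float64),
        scales=orb.scales.astype(np.float64),
        responses=orb.responses.astype(np.float64),
        descriptors=desc,
    )


def detect_keypoints(
    image: SpectrogramImage, detector: DetectorConfig | str | None = None
) -> KeypointSet:
    """Detect and describe keypoints; deterministic for a fixed image+config."""
    if detector is None:
        detector = DetectorConfig()
    elif isinstance(detector, str):
        detector = DetectorConfig(kind=detector)
    if image.pixels.size == 0:
        raise ValueError("cannot detect keypoints on an empty image")
    dispatch = {"dense": _detect_dense, "surf": _detect_surf, "orb": _detect_orb}
    if detector.kind not in dispatch:
        raise ValueError(f"unknown detector {detector.kind!r}")
    return dispatch[detector.kind](
        image.pixels.astype(np.float64), detector, image.provenance
    )


# ---------------------------------------------------------------------------
# Codebook and encoding
# ---------------------------------------------------------------------------


def _strongest(kp: KeypointSet, fraction: float) -> np.ndarray:
    """Descriptors of the strongest `fraction` of keypoints (at least one)."""
    if len(kp) == 0:
        return kp.descriptors
    n_keep = max(1, int(np.ceil(fraction * len(kp))))
    order = np.argsort(-kp.responses, kind="stable")[:n_keep]
    return kp.descriptors[np.sort(order)]


def cluster_descriptors(descriptors: np.ndarray, k: int, seed: int) -> KMeans:
    """k-means++ clustering of pooled descriptors (the codebook core)."""
    if len(descriptors) < k:
        raise CodebookError(
            f"{len(descriptors)} descriptors < k={k}; use a smaller vocabulary"
        )
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=1, max_iter=300, tol=1e-4,
        random_state=seed,
    )
    km.fit(descriptors)
    return km


def build_codebook(
    training_images: Sequence[SpectrogramImage],
    k: int = DEFAULT_VOCABULARY_SIZE,
    fraction_strongest: float = DEFAULT_FRACTION_STRONGEST,
    seed: int = 0,
    detector: DetectorConfig | str | None = None,
) -> Codebook:
    """Cluster pooled descriptors from *training* images into K visual words.

    Raises :class:`LeakageError` if any image is tagged ``split="test"`` —
    the vocabulary must never see evaluation data.
    """
    if not 0 < fraction_strongest <= 1:
        raise ValueError("fraction_strongest must be in (0, 1]")
    leaked = [im.provenance for im in training_images if im.split == "test"]
    if leaked:
        raise LeakageError(
            f"{len(leaked)} test-split images passed to build_codebook "
            f"(first: {leaked[0]})"
        )
    if detector is None or isinstance(detector, str):
        detector = DetectorConfig(kind=detector) if isinstance(detector, str) else DetectorConfig()
    pools = [
        _strongest(detect_keypoints(im, detector), fraction_strongest)
        for im in training_images
    ]
    descriptors = np.concatenate(pools) if pools else np.zeros((0, detector.descriptor_dim))
    km = cluster_descriptors(descriptors, k, seed)
    return Codebook(
        centroids=km.cluster_centers_.copy(),
        k=k,
        trained_on=len(descriptors),
        seed=seed,
        detector=detector,
    )


def encode(image: SpectrogramImage, codebook: Codebook) -> BofVector:
    """Visual-word occurrence histogram of one image, L1-normalized.

    Hard assignment to the Euclidean-nearest centroid (ties break to the
    lowest centroid index).  An image with no keypoints encodes as the
    uniform histogram 1/K, flagged degenerate.
    """
    kp = detect_keypoints(image, codebook.detector)
    if len(kp) and kp.descriptors.shape[1] != codebook.dim:
        raise DescriptorError(
            f"descriptor dim {kp.descriptors.shape[1]} != codebook dim {codebook.dim}"
        )
    if len(kp) == 0:
        return BofVector(
            values=np.full(codebook.k, 1.0 / codebook.k),
            normalized=True,
            image_ref=image.provenance,
            label=image.label,
            degenerate=True,
        )
    d2 = (
        (kp.descriptors**2).sum(axis=1, keepdims=True)
        - 2 * kp.descriptors @ codebook.centroids.T
        + (codebook.centroids**2).sum(axis=1)[None, :]
    )
    assign = np.argmin(d2, axis=1)
    counts = np.bincount(assign, minlength=codebook.k).astype(np.float64)
    return BofVector(
        values=counts / counts.sum(),
        normalized=True,
        image_ref=image.provenance,
        label=image.label,
        degenerate=False,
    )


def encode_all(
    images: Sequence[SpectrogramImage], codebook: Codebook
) -> list[BofVector]:
    return [encode(im, codebook) for im in images]


def feature_matrix(vectors: Sequence[BofVector]):
    """Stack BofVectors into (X, y, groups, stages) arrays for classifiers."""
    X = np.vstack([v.values for v in vectors])
    y = np.array([v.label for v in vectors])
    groups = np.array([v.image_ref.record_id for v in vectors])
    stages = np.array([v.image_ref.stage for v in vectors])
    return X, y, groups, stages
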