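"""Affine-covariant elliptical salient regions and appearance similarity.

The detector is an affine-adapted determinant-of-Hessian blob detector: blobs
are located as scale-normalized DoH maxima over a small scale stack, refined
to sub-pixel accuracy, and each is assigned an elliptical region whose shape
follows the local second-moment (structure tensor) matrix. The saliency
strength ``c`` is the normalized detector response at the maximum, which is
comparable across the two cameras after intensity normalization.

An elliptical region is the set ``{u : (u - x)^T S^{-1} (u - x) <= 1}`` with
``x`` the (col, row) center and ``S`` a 2x2 SPD shape matrix in px^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates, maximum_filter
from shapely.geometry import Polygon
from skimage.exposure import equalize_hist
from skimage.feature import hessian_matrix, structure_tensor

from .exceptions import InvalidFeatureError

PATCH_SIZE = 21

_g = np.linspace(-1.0, 1.0, PATCH_SIZE)
_GX, _GY = np.meshgrid(_g, _g)
#: pixels of the normalized patch grid that fall inside the unit circle
CIRCLE_MASK = (_GX**2 + _GY**2) <= 1.0 + 1e-9


@dataclass
class DetectorParams:
    """Settings for :func:`detect_regions`.

    sigmas : detection scales in px (region radius is about sqrt(2)*sigma).
    threshold_rel : keep maxima above this fraction of the strongest response.
    min_separation : minimum center-to-center distance between regions, px.
    max_features : cap on the number of returned regions (strongest first).
    border : margin in px inside which maxima are discarded.
    """

    sigmas: tuple[float, ...] = (1.6, 2.4, 3.6, 5.4)
    threshold_rel: float = 0.02
    threshold_abs: float = 1e-7
    min_separation: float = 5.0
    max_features: int = 4000
    border: int = 8


@dataclass
class FeatureRegion:
    """A salient point with saliency strength, elliptical region and patch."""

    x: np.ndarray  # (col, row), sub-pixel
    c: float  # saliency strength, > 0
    shape: np.ndarray  # 2x2 SPD shape matrix, px^2
    patch: np.ndarray | None = field(default=None, repr=False)
    scale: float = 0.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).ravel()
        self.shape = np.asarray(self.shape, dtype=float)
        if self.c <= 0:
            raise InvalidFeatureError("saliency strength must be positive")
        if self.shape.shape != (2, 2) or abs(self.shape[0, 1] - self.shape[1, 0]) > 1e-9:
            raise InvalidFeatureError("shape matrix must be symmetric 2x2")
        if np.linalg.eigvalsh(self.shape)[0] <= 0:
            raise InvalidFeatureError("shape matrix must be positive definite")

    @property
    def ellipse(self) -> tuple[np.ndarray, np.ndarray]:
        """(center, shape matrix) pair describing the region."""
        return self.x, self.shape


def _to_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:  # luma conversion
        img = 0.299 * img[..., 0] + 0.587 * img[..., 1] + 0.114 * img[..., 2]
    return img


def _sqrtm_spd(S: np.ndarray) -> np.ndarray:
    """Unique symmetric positive-definite square root of a 2x2 SPD matrix."""
    vals, vecs = np.linalg.eigh(S)
    return (vecs * np.sqrt(np.maximum(vals, 1e-12))) @ vecs.T


def detect_regions(image: np.ndarray, params: DetectorParams | None = None) -> list[FeatureRegion]:
    """Detect affine-covariant elliptical regions, strongest first.

    Constant or empty images yield an empty list. Returned regions are sorted
    by descending saliency and no two centers are closer than
    ``params.min_separation``.
    """
    params = params or DetectorParams()
    g = _to_gray(image)
    if g.size == 0 or np.ptp(g) < 1e-12:
        return []
    g = (g - g.min()) / np.ptp(g)

    sigmas = tuple(params.sigmas)
    stack = np.empty((len(sigmas),) + g.shape)
    for k, s in enumerate(sigmas):
        Hrr, Hrc, Hcc = hessian_matrix(g, sigma=s, order="rc", use_gaussian_derivatives=False)
        stack[k] = (Hrr * Hcc - Hrc * Hrc) * s**4

    # local maxima over the (scale, row, col) stack
    localmax = stack == maximum_filter(stack, size=3, mode="nearest")
    thr = max(params.threshold_abs, params.threshold_rel * stack.max())
    localmax &= stack > thr
    b = int(params.border)
    if b > 0:
        localmax[:, :b, :] = localmax[:, -b:, :] = False
        localmax[:, :, :b] = localmax[:, :, -b:] = False
    ks, rows, cols = np.nonzero(localmax)
    if ks.size == 0:
        return []
    resp = stack[ks, rows, cols]

    # strongest-first greedy non-maximum suppression on center distance
    order = np.lexsort((cols, rows, -resp))
    ks, rows, cols, resp = ks[order], rows[order], cols[order], resp[order]
    kept: list[int] = []
    kept_xy = np.empty((0, 2))
    min_sep2 = params.min_separation**2
    for i in range(ks.size):
        xy = np.array([cols[i], rows[i]], dtype=float)
        if kept_xy.size:
            d2 = np.sum((kept_xy - xy) ** 2, axis=1)
            if d2.min() < min_sep2:
                continue
        kept.append(i)
        kept_xy = np.vstack([kept_xy, xy])
        if len(kept) >= params.max_features:
            break

    # structure tensors per scale, for affine adaptation
    tensors = {}
    for k in sorted(set(ks[kept])):
        s = sigmas[k]
        Arr, Arc, Acc = structure_tensor(g, sigma=s, order="rc")
        tensors[k] = (Arr, Arc, Acc)

    regions: list[FeatureRegion] = []
    h, w = g.shape
    for i in kept:
        k, r, ci = int(ks[i]), int(rows[i]), int(cols[i])
        s = sigmas[k]
        # sub-pixel quadratic refinement along rows and columns
        dc = dr = 0.0
        if 0 < ci < w - 1:
            den = stack[k, r, ci + 1] - 2 * stack[k, r, ci] + stack[k, r, ci - 1]
            if abs(den) > 1e-18:
                dc = float(np.clip(-0.5 * (stack[k, r, ci + 1] - stack[k, r, ci - 1]) / den, -0.5, 0.5))
        if 0 < r < h - 1:
            den = stack[k, r + 1, ci] - 2 * stack[k, r, ci] + stack[k, r - 1, ci]
            if abs(den) > 1e-18:
                dr = float(np.clip(-0.5 * (stack[k, r + 1, ci] - stack[k, r - 1, ci]) / den, -0.5, 0.5))
        center = np.array([ci + dc, r + dr])

        Arr, Arc, Acc = tensors[k]
        # structure tensor in (col, row) axes
        mu = np.array([[Acc[r, ci], Arc[r, ci]], [Arc[r, ci], Arr[r, ci]]])
        det = float(np.linalg.det(mu))
        radius2 = 2.0 * s * s  # isotropic DoH region radius sqrt(2)*sigma
        if det > 1e-18 and np.trace(mu) > 1e-12:
            mu_n = mu / np.sqrt(det)  # unit-determinant anisotropy
            shape = radius2 * np.linalg.inv(mu_n)
            # cap eccentricity to keep patches well sampled
            vals, vecs = np.linalg.eigh(shape)
            vals = np.clip(vals, radius2 / 4.0, radius2 * 4.0)
            shape = (vecs * vals) @ vecs.T
        else:
            shape = radius2 * np.eye(2)
        regions.append(
            FeatureRegion(x=center, c=float(resp[i]), shape=shape, scale=s)
        )

    for reg in regions:
        reg.patch = extract_patch(g, reg.x, reg.shape)
    regions.sort(key=lambda f: (-f.c, f.x[1], f.x[0]))
    return regions


def extract_patch(image: np.ndarray, center: np.ndarray, shape: np.ndarray) -> np.ndarray:
    """Sample the elliptical region onto the fixed 21x21 normalized grid.

    The unit square grid is mapped through the symmetric square root of the
    shape matrix, so corresponding regions on the two cameras are sampled
    consistently without an arbitrary rotation.
    """
    g = _to_gray(image)
    A = _sqrtm_spd(np.asarray(shape, dtype=float))
    pts = np.stack([_GX.ravel(), _GY.ravel()], axis=0)  # 2 x n, unit square
    xy = A @ pts + np.asarray(center, dtype=float)[:, None]
    vals = map_coordinates(g, [xy[1], xy[0]], order=1, mode="nearest")
    return vals.reshape(PATCH_SIZE, PATCH_SIZE)


def ellipse_polygon(center: np.ndarray, shape: np.ndarray, n: int = 256) -> Polygon:
    """Polygonal approximation of an elliptical region boundary."""
    A = _sqrtm_spd(np.asarray(shape, dtype=float))
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    ring = A @ np.stack([np.cos(t), np.sin(t)]) + np.asarray(center, float)[:, None]
    return Polygon(ring.T)


def ellipse_overlap(E_i, E_j) -> float:
    """Intersection-over-union of two elliptical regions, in [0, 1].

    Arguments may be ``FeatureRegion`` instances or ``(center, shape)`` pairs.
    """
    ci, Si = E_i.ellipse if isinstance(E_i, FeatureRegion) else E_i
    cj, Sj = E_j.ellipse if isinstance(E_j, FeatureRegion) else E_j
    if np.allclose(ci, cj, atol=1e-12) and np.allclose(Si, Sj, atol=1e-12):
        return 1.0
    pi = ellipse_polygon(ci, Si)
    pj = ellipse_polygon(cj, Sj)
    inter = pi.intersection(pj).area
    if inter <= 0.0:
        return 0.0
    union = pi.area + pj.area - inter
    return float(inter / union)


def _equalize(patch: np.ndarray) -> np.ndarray:
    """Histogram-equalize a patch over its own intensity range (256 bins)."""
    p = np.asarray(patch, dtype=float)
    if np.ptp(p) < 1e-12:
        return np.zeros_like(p)
    return equalize_hist(p, nbins=256, mask=CIRCLE_MASK if p.shape == CIRCLE_MASK.shape else None)


def appearance_similarity(patch_a: np.ndarray, patch_b: np.ndarray) -> float:
    """Histogram-equalized NCC of two patches on the common grid, in [-1, 1].

    Equalization makes the score invariant to monotone intensity changes
    between the cameras. Zero-variance patches are unmatchable and score 0.
    """
    pa, pb = np.asarray(patch_a, float), np.asarray(patch_b, float)
    if pa.shape != pb.shape:
        raise ValueError("patches must share a sampling grid")
    if pa.shape == CIRCLE_MASK.shape:
        mask = CIRCLE_MASK
    else:
        mask = np.ones(pa.shape, dtype=bool)
    # equalization is monotone non-decreasing: handle anti-correlation by sign
    ea, eb = _equalize(pa)[mask], _equalize(pb)[mask]
    ea = ea - ea.mean()
    eb = eb - eb.mean()
    na, nb = np.linalg.norm(ea), np.linalg.norm(eb)
    if na < 1e-12 or nb < 1e-12:
        return 0.0
    val = float(np.dot(ea, eb) / (na * nb))
    return max(-1.0, min(1.0, val))


def ncc(patch_a: np.ndarray, patch_b: np.ndarray) -> float:
    """Plain normalized cross-correlation without equalization."""
    pa = np.asarray(patch_a, float).ravel()
    pb = np.asarray(patch_b, float).ravel()
    pa = pa - pa.mean()
    pb = pb - pb.mean()
    na, nb = np.linalg.norm(pa), np.linalg.norm(pb)
    if na < 1e-12 or nb < 1e-12:
        return 0.0
    return float(np.clip(np.dot(pa, pb) / (na * nb), -1.0, 1.0))
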