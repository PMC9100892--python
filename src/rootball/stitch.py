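"""Multi-view registration and compositing against a fiducial background.

The root ball itself is nearly textureless, so registration leans on the
high-texture fiducial curtain behind it: Harris corners thinned by adaptive
non-maximal suppression (ANMS), normalized intensity-patch descriptors,
ratio-test matching with a symmetric cross-check, and RANSAC homography
estimation with a least-squares refit on the inliers.

Coordinate convention: pixels are 0-based (row, col), origin top-left;
homographies act on homogeneous (x=col, y=row, 1) and are normalized so the
bottom-right entry is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from scipy.spatial.distance import cdist
from skimage.feature import corner_harris, corner_peaks
from skimage.measure import ransac
from skimage.transform import ProjectiveTransform, warp

from .frame import Intrinsics, RGBDFrame, luma


class InsufficientOverlapError(RuntimeError):
    """Fewer than four putative matches survive filtering."""


class HomographyError(RuntimeError):
    """RANSAC found no model supported by at least four inliers."""


@dataclass
class MatchSet:
    """Paired corner coordinates, as (x, y) columns, with inlier flags."""

    pts_a: np.ndarray      # (N, 2) x, y in frame A
    pts_b: np.ndarray      # (N, 2) x, y in frame B
    inliers: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.pts_a)


def normalize_homography(H: np.ndarray) -> np.ndarray:
    H = np.asarray(H, dtype=np.float64)
    if H.shape != (3, 3):
        raise ValueError("homography must be 3x3")
    if abs(H[2, 2]) < 1e-15 or not np.isfinite(np.linalg.det(H)) \
            or abs(np.linalg.det(H)) < 1e-12:
        raise ValueError("homography is singular or badly scaled")
    return H / H[2, 2]


def apply_homography(H: np.ndarray, pts_xy: np.ndarray) -> np.ndarray:
    p = np.column_stack([pts_xy, np.ones(len(pts_xy))])
    q = p @ np.asarray(H).T
    return q[:, :2] / q[:, 2:3]


# ----------------------------------------------------------------------------
# corners

def detect_corners(color: np.ndarray, max_corners: int = 1500,
                   quality: float = 0.01, anms_n: int = 500) -> np.ndarray:
    """Harris corners thinned by ANMS; returns (N, 2) float (x, y).

    ANMS keeps the ``anms_n`` corners with the largest suppression radius
    (distance to the nearest sufficiently stronger corner), which spreads the
    kept corners over the whole field of view instead of clustering them on
    the strongest texture.
    """
    gray = luma(color)
    resp = corner_harris(gray, method="k", k=0.04, sigma=1.0)
    if resp.max() <= 0:
        return np.empty((0, 2))
    peaks = corner_peaks(resp, min_distance=3, threshold_rel=quality,
                         num_peaks=max_corners)
    if len(peaks) == 0:
        return np.empty((0, 2))
    strength = resp[peaks[:, 0], peaks[:, 1]]
    radii = _anms_radii(peaks[:, ::-1].astype(float), strength)
    order = np.argsort(-radii)[:anms_n]
    order = order[np.argsort(-radii[order], kind="stable")]
    return peaks[order][:, ::-1].astype(float)


def _anms_radii(pts_xy: np.ndarray, strength: np.ndarray,
                robustness: float = 0.9) -> np.ndarray:
    """Suppression radius per corner: distance to nearest stronger corner."""
    n = len(pts_xy)
    radii = np.full(n, np.inf)
    if n <= 1:
        return radii
    d = cdist(pts_xy, pts_xy)
    stronger = strength[None, :] * robustness > strength[:, None]
    d = np.where(stronger, d, np.inf)
    radii = d.min(axis=1)
    return radii


# ----------------------------------------------------------------------------
# descriptors and matching

_PATCH_N = 8          # descriptor is an 8x8 grid ...
_PATCH_SPACING = 5.0  # ... sampled every 5 px from a blurred 40x40 neighborhood


def compute_descriptors(color: np.ndarray, corners_xy: np.ndarray) -> np.ndarray:
    """Bias/gain-normalized 8x8 intensity patches around each corner."""
    gray = gaussian_filter(luma(color), sigma=2.0)
    offs = (np.arange(_PATCH_N) - (_PATCH_N - 1) / 2.0) * _PATCH_SPACING
    dy, dx = np.meshgrid(offs, offs, indexing="ij")
    desc = np.empty((len(corners_xy), _PATCH_N * _PATCH_N))
    for i, (x, y) in enumerate(corners_xy):
        rows = y + dy
        cols = x + dx
        patch = map_coordinates(gray, [rows.ravel(), cols.ravel()],
                                order=1, mode="nearest")
        patch = patch - patch.mean()
        sd = patch.std()
        desc[i] = patch / sd if sd > 1e-12 else 0.0
    return desc


def match_descriptors(corners_a: np.ndarray, desc_a: np.ndarray,
                      corners_b: np.ndarray, desc_b: np.ndarray,
                      ratio: float = 0.8) -> MatchSet:
    """Nearest-descriptor matching with Lowe ratio test and cross-check."""
    if len(corners_a) == 0 or len(corners_b) == 0:
        raise InsufficientOverlapError("no corners to match")
    d = cdist(desc_a, desc_b)
    nn_b = np.argmin(d, axis=1)
    pairs = []
    for i, j in enumerate(nn_b):
        row = d[i]
        best = row[j]
        row2 = np.delete(row, j)
        second = row2.min() if len(row2) else np.inf
        if best > ratio * second:
            continue
        if np.argmin(d[:, j]) != i:   # symmetric cross-check
            continue
        pairs.append((i, j))
    if len(pairs) < 4:
        raise InsufficientOverlapError(
            f"only {len(pairs)} matches survive the ratio test (need >= 4)")
    ia, ib = np.array(pairs).T
    return MatchSet(pts_a=corners_a[ia], pts_b=corners_b[ib])


def match_frames(frame_a: RGBDFrame, frame_b: RGBDFrame,
                 max_corners: int = 1500, anms_n: int = 500,
                 ratio: float = 0.8) -> MatchSet:
    """Corner detection + description + matching for two frames."""
    ca = detect_corners(frame_a.color, max_corners=max_corners, anms_n=anms_n)
    cb = detect_corners(frame_b.color, max_corners=max_corners, anms_n=anms_n)
    if len(ca) < 4 or len(cb) < 4:
        raise InsufficientOverlapError("too few corners detected")
    da = compute_descriptors(frame_a.color, ca)
    db = compute_descriptors(frame_b.color, cb)
    return match_descriptors(ca, da, cb, db, ratio=ratio)


# ----------------------------------------------------------------------------
# homography estimation

def estimate_homography(matches: MatchSet, reproj_tol_px: float = 2.0,
                        n_iters: int = 2000, seed: int = 0,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """RANSAC (4-point minimal samples) + least-squares refit on the inliers.

    Returns (H, inlier_flags) with H mapping frame-A coordinates into
    frame B, normalized so H[2,2] == 1.  The inlier criterion is a symmetric
    reprojection error <= ``reproj_tol_px``.
    """
    if len(matches) < 4:
        raise HomographyError(f"need >= 4 matches, got {len(matches)}")
    src = np.asarray(matches.pts_a, dtype=np.float64)
    dst = np.asarray(matches.pts_b, dtype=np.float64)
    if len(matches) == 4:
        tf = ProjectiveTransform.from_estimate(src, dst)
        if not tf:
            raise HomographyError("degenerate 4-point configuration")
        inl = np.ones(4, dtype=bool)
    else:
        model, inl = ransac((src, dst), ProjectiveTransform, min_samples=4,
                            residual_threshold=reproj_tol_px,
                            max_trials=n_iters, rng=seed)
        if model is None or inl is None or inl.sum() < 4:
            raise HomographyError("RANSAC found no model with >= 4 inliers")
        tf = ProjectiveTransform.from_estimate(src[inl], dst[inl])
        if not tf:
            raise HomographyError("inlier refit failed")
        # refresh inlier flags against the refit model
        err = np.linalg.norm(tf(src) - dst, axis=1)
        inl = err <= reproj_tol_px
        if inl.sum() >= 4:
            tf2 = ProjectiveTransform.from_estimate(src[inl], dst[inl])
            if tf2:
                tf = tf2
    matches.inliers = inl
    return normalize_homography(tf.params), inl


def chain_to_reference(pairwise: list[np.ndarray], n_frames: int,
                       reference_index: int) -> list[np.ndarray]:
    """Compose consecutive-pair homographies H[i->i+1] into H[i->reference]."""
    if len(pairwise) != n_frames - 1:
        raise ValueError("need one pairwise homography per consecutive pair")
    homs = [np.eye(3) for _ in range(n_frames)]
    for i in range(reference_index - 1, -1, -1):
        homs[i] = homs[i + 1] @ pairwise[i]
    for i in range(reference_index + 1, n_frames):
        homs[i] = homs[i - 1] @ np.linalg.inv(pairwise[i - 1])
    return [normalize_homography(h) for h in homs]


# ----------------------------------------------------------------------------
# compositing

def composite_views(frames: list[RGBDFrame], homographies: list[np.ndarray],
                    reference_index: int = 0) -> RGBDFrame:
    """Warp all frames into the reference plane and blend.

    Color is blended with center-weighted feathering (weight = distance to
    the frame border), which hides seams and exposure steps in the overlap
    bands.  Depth uses first-valid-wins with nearest-neighbor sampling —
    feathering depth would invent geometry that no sensor observed.
    """
    if len(frames) != len(homographies):
        raise ValueError("one homography per frame required")
    homs = [normalize_homography(h) for h in homographies]

    corners_all = []
    for f, H in zip(frames, homs):
        h, w = f.shape
        c = np.array([[0, 0], [w - 1, 0], [w - 1, h - 1], [0, h - 1]], float)
        corners_all.append(apply_homography(H, c))
    allc = np.vstack(corners_all)
    x0, y0 = np.floor(allc.min(axis=0)).astype(int)
    x1, y1 = np.ceil(allc.max(axis=0)).astype(int)
    out_w, out_h = x1 - x0 + 1, y1 - y0 + 1
    T = np.array([[1, 0, -x0], [0, 1, -y0], [0, 0, 1]], float)

    acc = np.zeros((out_h, out_w, 3))
    wacc = np.zeros((out_h, out_w))
    depth_out = np.zeros((out_h, out_w))
    for f, H in zip(frames, homs):
        h, w = f.shape
        full = T @ H
        tf = ProjectiveTransform(matrix=full)
        yy, xx = np.mgrid[0:h, 0:w]
        weight = np.minimum.reduce([xx + 1.0, w - xx + 0.0, yy + 1.0, h - yy + 0.0])
        weight /= weight.max()
        warped_w = warp(weight, tf.inverse, output_shape=(out_h, out_w),
                        order=1, mode="constant", cval=0.0)
        for ch in range(3):
            wc = warp(f.color[..., ch].astype(float), tf.inverse,
                      output_shape=(out_h, out_w), order=1,
                      mode="constant", cval=0.0)
            acc[..., ch] += wc * warped_w
        wacc += warped_w
        wd = warp(f.depth.astype(float), tf.inverse,
                  output_shape=(out_h, out_w), order=0,
                  mode="constant", cval=0.0)
        take = (depth_out == 0) & (wd > 0)
        depth_out[take] = wd[take]

    valid = wacc > 1e-9
    color = np.zeros((out_h, out_w, 3))
    color[valid] = acc[valid] / wacc[valid, None]
    color = np.clip(np.round(color), 0, 255).astype(np.uint8)

    ref_k = frames[reference_index].intrinsics
    k = Intrinsics(fx=ref_k.fx, fy=ref_k.fy, cx=ref_k.cx - x0, cy=ref_k.cy - y0)
    return RGBDFrame(color=color, depth=depth_out, intrinsics=k)


def extract_roi(frame: RGBDFrame, rect: tuple[int, int, int, int]) -> RGBDFrame:
    """Crop (x, y, w, h); the principal point shifts by the crop offset."""
    x, y, w, h = rect
    return frame.crop(x, y, w, h)


def align_depth(frame: RGBDFrame) -> RGBDFrame:
    """Extension hook for sensor-specific depth-to-color alignment.

    Synthetic and pre-aligned frames pass through unchanged; a hardware
    backend would override this with the vendor alignment.
    """
    return frame


def stitch_views(frames: list[RGBDFrame], reference_index: int = 0,
                 reproj_tol_px: float = 2.0, seed: int = 0,
                 ) -> tuple[RGBDFrame, list[np.ndarray]]:
    """Full chain: match consecutive pairs, RANSAC, chain, composite."""
    pairwise = []
    for a, b in zip(frames[:-1], frames[1:]):
        m = match_frames(b, a)      # H maps frame i+1 into frame i's plane
        H, _ = estimate_homography(m, reproj_tol_px=reproj_tol_px, seed=seed)
        pairwise.append(np.linalg.inv(H))   # store as H[i -> i+1]
    homs = chain_to_reference(pairwise, len(frames), reference_index)
    return composite_views(frames, homs, reference_index), homs
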