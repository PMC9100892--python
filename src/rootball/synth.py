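"""Synthetic root-ball scenes with full ground truth.

Real captures photograph a plug seedling's root ball in front of a
high-texture fiducial (2-D-code style) curtain, rotating the plant 90 deg
between shots so that four overlapping color+depth views cover the whole
surface.  This module emulates that situation end to end so every downstream
stage — stitching, preprocessing, vesselness segmentation and phenotyping —
can be tested against known geometry:

* a pseudo-random black/white block pattern stands in for the 2-D code
  (only its corner density matters, decoding is never needed);
* surface roots are smooth random-walk tubes of per-root constant width,
  brighter than the speckled substrate, drawn with anti-aliased edges and
  flat end caps so the analytic projected area is simply sum(length*width);
* the four views are horizontal windows of the panorama (rotating a
  cylindrical plug translates its unrolled surface), related by stored
  invertible homographies, with additive Gaussian sensor noise;
* depth comes from a frontal ray/cylinder intersection, giving a physical
  pixel pitch of (distance - radius)/f at the tangent column.

Physical scale: with the default cylinder (radius 30 mm, camera distance
90 mm, f = 600 px) one pixel spans 0.1 mm = 0.01 cm at the tangent point, so
root widths of 4-9 px correspond to diameters of 400-900 um.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .frame import Intrinsics, RGBDFrame

# scene layout fractions (panorama rows): fiducial bands top+bottom, the
# substrate (root-ball surface) band in the middle, dark curtain between
_FIDUCIAL_BAND = 0.18
_SUBSTRATE_TOP = 0.28
_SUBSTRATE_BOTTOM = 0.72
_SUBSTRATE_XMARGIN = 0.04

_CURTAIN_LEVEL = 18
_SUBSTRATE_LEVEL = 70
_SUBSTRATE_TEXTURE_SD = 6.0
_SPECKLE_LO, _SPECKLE_HI = 140, 190


@dataclass
class SceneSpec:
    """Parameters of one synthetic root-ball scene.

    ``image_size`` is the panorama (stitched) size; the four rendered views
    are horizontal windows of it.  ``width_range`` is in pixels; the physical
    diameter ground truth follows from the depth model's pixel pitch.
    """

    image_size: tuple[int, int] = (320, 832)     # (H, W) of the panorama
    n_roots: int = 12
    width_range: tuple[float, float] = (4.0, 9.0)  # px
    root_intensity: int = 210
    substrate_speckle_density: float = 0.02
    fiducial_cell: int = 8
    cylinder_radius_mm: float = 30.0
    camera_distance_mm: float = 90.0
    focal_px: float = 600.0
    root_length_range: tuple[float, float] = (110.0, 170.0)  # px
    curve_sd: float = 0.05      # rad per 2-px step; 0 = straight roots
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_roots < 0:
            raise ValueError("n_roots must be >= 0")
        if self.width_range[0] < 1:
            raise ValueError("width_range min must be >= 1 px")
        if self.width_range[0] > self.width_range[1]:
            raise ValueError("width_range must be (min, max)")
        if self.camera_distance_mm <= self.cylinder_radius_mm:
            raise ValueError("camera must be outside the cylinder")

    @property
    def pixel_size_cm(self) -> float:
        """Physical pixel pitch (cm/px) at the cylinder's tangent column."""
        return (self.camera_distance_mm - self.cylinder_radius_mm) / self.focal_px / 10.0


@dataclass
class GroundTruth:
    """Analytic ground truth for one generated scene.

    ``total_length`` and ``total_projected_area`` come from the drawn
    centerline geometry (arc length x width), not from pixel counts, so they
    are independent oracles for the measurement chain.  ``mean_diameter`` is
    the length-weighted commanded tube width.
    """

    root_mask: np.ndarray
    skeleton: np.ndarray
    total_length: float            # cm
    total_projected_area: float    # cm^2
    mean_diameter: float           # um
    view_homographies: list[np.ndarray]
    intrinsics: Intrinsics
    pixel_size_cm: float
    per_root: list[dict] = field(default_factory=list)


# ----------------------------------------------------------------------------
# fiducial background

def generate_fiducial_background(spec: SceneSpec) -> np.ndarray:
    """Pseudo-random black/white block pattern used as the stitching curtain.

    Every 2x2 block junction is a high-contrast corner with probability 3/4,
    which comfortably exceeds the one-corner-per-four-cells density the
    stitcher needs.
    """
    H, W = spec.image_size
    c = int(spec.fiducial_cell)
    if c < 4:
        raise ValueError("fiducial_cell must be >= 4 px")
    if c > H or c > W:
        raise ValueError("fiducial cell larger than the image")
    ny, nx = H // c, W // c
    if ny < 2 or nx < 2:
        raise ValueError("degenerate fiducial: fewer than 2 cells per axis")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xF1D]))
    cells = rng.integers(0, 2, size=(math.ceil(H / c), math.ceil(W / c)))
    gray = np.kron(cells, np.ones((c, c), dtype=np.uint8))[:H, :W]
    img = np.where(gray > 0, 230, 25).astype(np.uint8)
    return np.repeat(img[..., None], 3, axis=2)


# ----------------------------------------------------------------------------
# root tubes

def _smooth_walk(rng: np.random.Generator, bounds: tuple[float, float, float, float],
                 length: float, step: float = 2.0, curve_sd: float = 0.05,
                 max_turn: float = 0.08) -> np.ndarray:
    """Centerline polyline (N,2) as (x, y), steered to stay inside ``bounds``.

    The per-step heading change (steering + curvature noise) is capped at
    ``max_turn`` rad, keeping the minimum bend radius (step/max_turn = 25 px)
    well above the tube width so the drawn tube never self-overlaps; walks
    that still reach a boundary slide along it.
    """
    y0, y1, x0, x1 = bounds
    cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
    margin = 10.0
    p = np.array([rng.uniform(x0 + margin, x1 - margin),
                  rng.uniform(y0 + margin, y1 - margin)])
    theta = rng.uniform(0, 2 * np.pi)
    n_steps = max(2, int(round(length / step)))
    pts = np.empty((n_steps + 1, 2))
    pts[0] = p
    for i in range(n_steps):
        turn = rng.normal(0.0, curve_sd)
        d_edge = min(p[0] - x0, x1 - p[0], p[1] - y0, y1 - p[1])
        if d_edge < 3 * margin:
            desired = math.atan2(cy - p[1], cx - p[0])
            diff = (desired - theta + np.pi) % (2 * np.pi) - np.pi
            gain = min(1.0, (3 * margin - d_edge) / (3 * margin))
            turn += gain * np.clip(diff, -max_turn, max_turn)
        theta += float(np.clip(turn, -max_turn, max_turn))
        q = p + step * np.array([math.cos(theta), math.sin(theta)])
        q[0] = np.clip(q[0], x0, x1)
        q[1] = np.clip(q[1], y0, y1)
        if np.hypot(*(q - p)) < 0.5 * step:
            # pinned against a boundary: end the root here rather than coil
            return pts[:i + 1].copy()
        p = q
        pts[i + 1] = p
    return pts


def _densify(pts: np.ndarray, spacing: float = 0.25) -> np.ndarray:
    segs = np.diff(pts, axis=0)
    lens = np.hypot(segs[:, 0], segs[:, 1])
    out = [pts[0]]
    for i, L in enumerate(lens):
        if L == 0:
            continue
        n = max(1, int(math.ceil(L / spacing)))
        t = np.arange(1, n + 1) / n
        out.append(pts[i] + t[:, None] * segs[i])
    return np.vstack(out)


def _tube_coverage(pts: np.ndarray, width: float, shape: tuple[int, int]):
    """Anti-aliased coverage and binary mask of a flat-capped constant-width tube.

    Returns (coverage, binary, skeleton_rr, skeleton_cc, bbox slices).
    Flat end caps keep the drawn area equal to length x width (no rounded-cap
    excess), which keeps the analytic area conservation exact to boundary
    anti-aliasing.
    """
    H, W = shape
    dense = _densify(pts)
    r = width / 2.0
    pad = r + 2.0
    x_lo = max(0, int(math.floor(dense[:, 0].min() - pad)))
    x_hi = min(W, int(math.ceil(dense[:, 0].max() + pad)) + 1)
    y_lo = max(0, int(math.floor(dense[:, 1].min() - pad)))
    y_hi = min(H, int(math.ceil(dense[:, 1].max() + pad)) + 1)
    ys, xs = np.mgrid[y_lo:y_hi, x_lo:x_hi]
    pix = np.column_stack([xs.ravel() + 0.0, ys.ravel() + 0.0])
    d, _ = cKDTree(dense).query(pix, workers=1)
    cov = np.clip(r + 0.5 - d, 0.0, 1.0)
    # flat caps: trim the rounded overshoot beyond each end.  The cut is kept
    # local (within the cap's reach of the endpoint) so the end plane cannot
    # slice through distant, curved parts of the same tube.
    for end, inner in ((pts[0], pts[1]), (pts[-1], pts[-2])):
        u = end - inner
        n = np.hypot(*u)
        if n > 0:
            u = u / n
            s = (pix - end) @ u
            near = np.linalg.norm(pix - end, axis=1) <= r + 1.5
            cut = np.where(near, np.clip(0.5 - s, 0.0, 1.0), 1.0)
            cov = np.minimum(cov, cut)
    cov = cov.reshape(ys.shape)
    binary = cov >= 0.5
    return cov, binary, (slice(y_lo, y_hi), slice(x_lo, x_hi))


def _rasterize_centerline(pts: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """8-connected pixel chain along the polyline (ground-truth skeleton)."""
    from skimage.draw import line

    H, W = shape
    skel = np.zeros(shape, dtype=bool)
    ipts = np.round(pts).astype(int)
    for a, b in zip(ipts[:-1], ipts[1:]):
        rr, cc = line(int(a[1]), int(a[0]), int(b[1]), int(b[0]))
        ok = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
        skel[rr[ok], cc[ok]] = True
    return skel


# ----------------------------------------------------------------------------
# scene assembly

def _view_layout(W: int, n_views: int, overlap_frac: float) -> tuple[int, list[int]]:
    if not (0.0 < overlap_frac < 0.5):
        raise ValueError("overlap_frac must be in (0, 0.5)")
    wv = int(round(W / (1.0 + (n_views - 1) * (1.0 - overlap_frac))))
    stride = (W - wv) / max(1, n_views - 1)
    offsets = [int(round(i * stride)) for i in range(n_views)]
    offsets[-1] = W - wv
    return wv, offsets


def generate_root_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Draw the full panorama (fiducial + substrate + roots) with ground truth.

    Roots are placed with bounded mutual overlap (a redraw is attempted when a
    candidate tube covers more than 2% of an existing one) so that analytic
    area conservation holds to within boundary anti-aliasing.
    """
    H, W = spec.image_size
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5CE]))

    canvas = np.full((H, W), float(_CURTAIN_LEVEL))
    fid = generate_fiducial_background(spec)[..., 0].astype(float)
    band = int(round(_FIDUCIAL_BAND * H))
    canvas[:band] = fid[:band]
    canvas[H - band:] = fid[H - band:]

    sy0, sy1 = int(_SUBSTRATE_TOP * H), int(_SUBSTRATE_BOTTOM * H)
    sx0, sx1 = int(_SUBSTRATE_XMARGIN * W), int(W - _SUBSTRATE_XMARGIN * W)
    sub_h, sub_w = sy1 - sy0, sx1 - sx0
    substrate = _SUBSTRATE_LEVEL + rng.normal(0, _SUBSTRATE_TEXTURE_SD, (sub_h, sub_w))
    n_speckle = int(round(spec.substrate_speckle_density * sub_h * sub_w))
    if n_speckle:
        ry = rng.integers(0, sub_h, n_speckle)
        rx = rng.integers(0, sub_w, n_speckle)
        substrate[ry, rx] = rng.uniform(_SPECKLE_LO, _SPECKLE_HI, n_speckle)
    canvas[sy0:sy1, sx0:sx1] = substrate

    root_mask = np.zeros((H, W), dtype=bool)
    skeleton = np.zeros((H, W), dtype=bool)
    per_root: list[dict] = []
    s_cm = spec.pixel_size_cm

    total_len_px = 0.0
    total_area_px2 = 0.0
    for _ in range(spec.n_roots):
        width = rng.uniform(*spec.width_range)
        length = rng.uniform(*spec.root_length_range)
        inset = width / 2.0 + 2.0
        bounds = (sy0 + inset, sy1 - inset, sx0 + inset, sx1 - inset)
        best = None
        for _try in range(25):
            pts = _smooth_walk(rng, bounds, length, curve_sd=spec.curve_sd)
            cov, binary, sl = _tube_coverage(pts, width, (H, W))
            own = max(1, int(binary.sum()))
            overlap = np.logical_and(binary, root_mask[sl]).sum() / own
            if best is None or overlap < best[0]:
                best = (overlap, pts, cov, binary, sl)
            if overlap <= 0.02:
                break
        _, pts, cov, binary, sl = best
        level = spec.root_intensity + rng.normal(0, 4)
        canvas[sl] = canvas[sl] * (1 - cov) + level * cov
        root_mask[sl] |= binary
        skeleton |= _rasterize_centerline(pts, (H, W))
        seg = np.diff(pts, axis=0)
        arc = float(np.hypot(seg[:, 0], seg[:, 1]).sum())
        total_len_px += arc
        total_area_px2 += arc * width
        per_root.append({"length_cm": arc * s_cm, "width_um": width * s_cm * 1e4})

    wv, offsets = _view_layout(W, 4, 0.25)
    homs = []
    for off in offsets:
        Hm = np.eye(3)
        Hm[0, 2] = float(off)
        homs.append(Hm)
    intr = Intrinsics(fx=spec.focal_px, fy=spec.focal_px,
                      cx=(wv - 1) / 2.0, cy=(H - 1) / 2.0)

    mean_diam_um = 0.0
    if total_len_px > 0:
        mean_diam_um = (total_area_px2 / total_len_px) * s_cm * 1e4

    panorama = np.clip(canvas, 0, 255).astype(np.uint8)
    panorama = np.repeat(panorama[..., None], 3, axis=2)
    gt = GroundTruth(
        root_mask=root_mask,
        skeleton=skeleton,
        total_length=total_len_px * s_cm,
        total_projected_area=total_area_px2 * s_cm ** 2,
        mean_diameter=mean_diam_um,
        view_homographies=homs,
        intrinsics=intr,
        pixel_size_cm=s_cm,
        per_root=per_root,
    )
    return panorama, gt


def substrate_roi(spec: SceneSpec) -> tuple[int, int, int, int]:
    """ROI rectangle (x, y, w, h) of the root-ball band plus a curtain margin."""
    H, W = spec.image_size
    y0 = int(0.22 * H)
    y1 = int(0.78 * H)
    return 0, y0, W, y1 - y0


def cylinder_depth(shape: tuple[int, int], intrinsics: Intrinsics,
                   radius_mm: float, distance_mm: float) -> np.ndarray:
    """Per-pixel depth (mm, uint16-compatible float) of a frontal cylinder.

    The cylinder axis is vertical through (X=0, Z=distance).  Pixels whose ray
    misses the cylinder get depth 0 (invalid), as a real sensor would report.
    """
    H, W = shape
    u = np.arange(W, dtype=np.float64) - intrinsics.cx
    t = u / intrinsics.fx                       # ray slope dx/dz
    a = 1.0 + t ** 2
    disc = distance_mm ** 2 - a * (distance_mm ** 2 - radius_mm ** 2)
    z = np.zeros(W)
    ok = disc >= 0
    z[ok] = (distance_mm - np.sqrt(disc[ok])) / a[ok]
    return np.broadcast_to(z, (H, W)).copy()


def render_views(panorama: np.ndarray, gt: GroundTruth, n_views: int = 4,
                 overlap_frac: float = 0.25, noise_sd: float = 2.0,
                 spec: SceneSpec | None = None, seed: int | None = None,
                 ) -> list[RGBDFrame]:
    """Cut the panorama into overlapping views and attach cylinder depth.

    Views are related to the panorama by the (stored) translational
    homographies; additive Gaussian noise (default sd 2 intensity levels)
    keeps downstream RANSAC non-degenerate.  ``gt.view_homographies`` is
    updated when the layout differs from the one stored at generation time.
    """
    H, W = panorama.shape[:2]
    wv, offsets = _view_layout(W, n_views, overlap_frac)
    homs = []
    for off in offsets:
        Hm = np.eye(3)
        Hm[0, 2] = float(off)
        homs.append(Hm)
    gt.view_homographies = homs
    intr = Intrinsics(fx=gt.intrinsics.fx, fy=gt.intrinsics.fy,
                      cx=(wv - 1) / 2.0, cy=(H - 1) / 2.0)
    gt.intrinsics = intr

    radius = spec.cylinder_radius_mm if spec is not None else 30.0
    distance = spec.camera_distance_mm if spec is not None else 90.0
    base_seed = seed if seed is not None else (spec.seed if spec is not None else 0)
    depth = cylinder_depth((H, wv), intr, radius, distance)

    frames = []
    for i, off in enumerate(offsets):
        crop = panorama[:, off:off + wv].astype(np.float64)
        if noise_sd > 0:
            vr = np.random.default_rng(np.random.SeedSequence([base_seed, 0xB1E, i]))
            crop = crop + vr.normal(0.0, noise_sd, crop.shape)
        color = np.clip(np.round(crop), 0, 255).astype(np.uint8)
        frames.append(RGBDFrame(color=color,
                                depth=np.round(depth).astype(np.uint16).astype(np.float64),
                                intrinsics=intr))
    return frames


# ----------------------------------------------------------------------------
# regression study data

def generate_regression_dataset(n: int, slope: float, intercept: float,
                                noise_sd: float, seed: int,
                                x_range: tuple[float, float] = (5.0, 40.0),
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Paired (x, y) samples for the allometric linear-model recovery study.

    x plays the role of the directly measured quantity (e.g. surface-root
    area, cm^2) and y the destructively measured total (e.g. total-root
    area); y = slope*x + intercept + N(0, noise_sd).
    """
    if n < 3:
        raise ValueError("need n >= 3 samples to fit a line")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x0152]))
    x = rng.uniform(x_range[0], x_range[1], n)
    y = slope * x + intercept + rng.normal(0.0, noise_sd, n)
    return x, y
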