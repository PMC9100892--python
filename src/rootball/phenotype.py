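"""Phenotype measurement and allometric prediction.

The measurement chain on a calibrated, segmented root-ball image:

1.  *Calibration.*  Back-project every valid depth pixel through the pinhole
    model to a 3-D point cloud; the physical ROI area S_ROI is the sum of the
    per-pixel surface-patch areas.  Then

        S_pix = S_ROI / n_pixels,      L_pix = sqrt(S_pix).

2.  *Average diameter.*  Overlapping root crossings bias a naive
    area/length ratio, so the non-overlapping roots are isolated first:
    thin roots vanish under erosion and cannot be restored by the matching
    dilation, while thick overlap blobs are restored — subtracting the
    restored image from the original keeps exactly the non-overlapping part.
    Their skeleton length is

        TLSR_NO = (skeleton pixel count) * 1.2 * L_pix

    (1.2 averages the unit pixel edge and diagonal lengths), and the average
    diameter of total root is estimated by

        ADTR ~= SASR_NO / TLSR_NO.

3.  *Encapsulation.*  DSR = root pixels / root-ball pixels * 100%.

4.  *Allometric predictions.*  Total-root surface area, length and volume
    from univariate linear models fitted against destructive reference
    measurements:

        SATR = 2.16556 * SASR + 7.6522        (cm^2)
        LTR  = SATR_pred / ADTR               (cm; no pi factor by design)
        LTRP = 2.9723 * LTR + 16.83062        (cm)
        VTR  = pi * (ADTR/2)^2 * LTRP         (cm^3)

    The default coefficients are the published ones; ``fit_model`` refits
    them from paired measurements.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt, median_filter
from skimage.morphology import dilation, disk, erosion, skeletonize

from .frame import Intrinsics
from .units import cm_to_um, um_to_cm

#: Skeleton-length correction averaging the pixel edge and diagonal lengths.
SKELETON_LENGTH_FACTOR = 1.2

#: Published total-root surface-area model: SATR = 2.16556 * SASR + 7.6522.
PAPER_SURFACE_AREA_MODEL = ("surface_area", 2.16556, 7.6522)
#: Published total-root length model: LTRP = 2.9723 * LTR + 16.83062.
PAPER_LENGTH_MODEL = ("length", 2.9723, 16.83062)


class UndefinedDiameterError(RuntimeError):
    """Diameter is undefined (empty mask / zero-length skeleton)."""


@dataclass(frozen=True)
class CalibrationResult:
    """Physical scale of the image plane derived from the depth point cloud."""

    s_roi: float        # cm^2, actual ROI surface area
    n_pixels: int       # ROI pixel count
    s_pix: float        # cm^2 per pixel
    l_pix: float        # cm per pixel

    @classmethod
    def from_roi(cls, s_roi: float, n_pixels: int) -> "CalibrationResult":
        if n_pixels < 1:
            raise ValueError("ROI must contain at least one pixel")
        s_pix = s_roi / n_pixels
        return cls(s_roi=s_roi, n_pixels=n_pixels, s_pix=s_pix,
                   l_pix=math.sqrt(s_pix))


@dataclass(frozen=True)
class DiameterEstimate:
    sasr_no: float              # cm^2, area of non-overlapping surface roots
    tlsr_no_skeleton: float     # cm, their skeleton length
    adtr: float                 # um, estimated average diameter of total root


@dataclass(frozen=True)
class EncapsulationResult:
    dsr: float          # %, density of surface root
    sasr: float         # cm^2, surface area of surface root
    ssam: float         # cm^2, surface area of the surface matrix
    pix_root: int
    pix_all: int


@dataclass(frozen=True)
class PredictionModel:
    """Univariate linear model y = slope * x + intercept."""

    slope: float
    intercept: float
    n_fit: int | None = None
    r2: float | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise ValueError("model coefficients must be finite")

    def __call__(self, x: float) -> float:
        return self.slope * x + self.intercept


def paper_surface_area_model() -> PredictionModel:
    """The published SATR-from-SASR model."""
    return PredictionModel(slope=PAPER_SURFACE_AREA_MODEL[1],
                           intercept=PAPER_SURFACE_AREA_MODEL[2])


def paper_length_model() -> PredictionModel:
    """The published LTRP-from-LTR model."""
    return PredictionModel(slope=PAPER_LENGTH_MODEL[1],
                           intercept=PAPER_LENGTH_MODEL[2])


# ----------------------------------------------------------------------------
# calibration

def backproject(depth_mm: np.ndarray, intrinsics: Intrinsics) -> np.ndarray:
    """Pinhole back-projection of a depth grid to an (H, W, 3) point cloud, mm."""
    z = np.asarray(depth_mm, dtype=np.float64)
    h, w = z.shape
    u = np.arange(w) - intrinsics.cx
    v = np.arange(h) - intrinsics.cy
    x = z * (u[None, :] / intrinsics.fx)
    y = z * (v[:, None] / intrinsics.fy)
    return np.stack([x, y, z], axis=-1)


def _infill_nearest(depth: np.ndarray) -> np.ndarray:
    invalid = depth <= 0
    if not invalid.any():
        return depth
    if invalid.all():
        return depth
    _, (ir, ic) = distance_transform_edt(invalid, return_indices=True)
    return depth[ir, ic]


def calibrate(depth_mm: np.ndarray, intrinsics: Intrinsics,
              roi_mask: np.ndarray | None = None) -> CalibrationResult:
    """Physical pixel scale from the depth point cloud.

    Invalid (zero) depth is infilled by nearest neighbor before
    back-projection.  The per-pixel patch area is the magnitude of the cross
    product of the central-difference tangent vectors of the point grid —
    the local quadrilateral patch area, exact for planar surfaces.
    """
    depth = np.asarray(depth_mm, dtype=np.float64)
    roi = np.ones(depth.shape, bool) if roi_mask is None else roi_mask.astype(bool)
    if not (depth[roi] > 0).any():
        raise ValueError("no valid depth inside the ROI")
    pts = backproject(_infill_nearest(depth), intrinsics)
    du = np.gradient(pts, axis=1)   # along columns (x direction)
    dv = np.gradient(pts, axis=0)   # along rows (y direction)
    area_mm2 = np.linalg.norm(np.cross(du, dv), axis=-1)
    s_roi_cm2 = float(area_mm2[roi].sum()) / 100.0
    return CalibrationResult.from_roi(s_roi_cm2, int(roi.sum()))


# ----------------------------------------------------------------------------
# diameter from non-overlapping roots

def extract_nonoverlapping(root_mask: np.ndarray, erosion_r: int = 2,
                           median_k: int = 3, dilation_r: int | None = None,
                           ) -> np.ndarray:
    """Isolate roots that erosion destroys and dilation cannot restore.

    eroded = erode(mask, disk(erosion_r)); cleaned = median(eroded, k);
    restored = dilate(cleaned, disk(dilation_r)); output = mask & ~restored.
    ``dilation_r`` defaults to ``erosion_r`` (symmetric restoration).
    """
    mask = np.asarray(root_mask, dtype=bool)
    if dilation_r is None:
        dilation_r = erosion_r
    if not mask.any():
        return mask.copy()
    eroded = erosion(mask, disk(erosion_r))
    cleaned = median_filter(eroded, size=median_k)
    restored = dilation(cleaned, disk(dilation_r))
    return mask & ~restored


def skeleton_length(mask: np.ndarray, cal: CalibrationResult,
                    ) -> tuple[float, np.ndarray]:
    """Topology-preserving thinning; length = count * 1.2 * L_pix (cm).

    The 1.2 multiplier is the average of the unit pixel edge (1) and
    diagonal (sqrt 2) lengths; it systematically overestimates axis-aligned
    runs and underestimates diagonal ones (documented bias), but is unbiased
    for roughly isotropic root orientations.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return 0.0, np.zeros_like(mask)
    skel = skeletonize(mask)
    length = float(skel.sum()) * SKELETON_LENGTH_FACTOR * cal.l_pix
    return length, skel


def euclidean_skeleton_length(skel: np.ndarray, cal: CalibrationResult) -> float:
    """Independent chain-length oracle: sum of 8-neighbor step lengths.

    Each 4-neighbor link contributes L_pix and each diagonal link
    sqrt(2)*L_pix, each link counted once.
    """
    s = np.asarray(skel, dtype=bool)
    straight = ((s[:, :-1] & s[:, 1:]).sum() + (s[:-1, :] & s[1:, :]).sum())
    diag = ((s[:-1, :-1] & s[1:, 1:]).sum() + (s[:-1, 1:] & s[1:, :-1]).sum())
    return float(straight + math.sqrt(2.0) * diag) * cal.l_pix


def average_diameter(nonoverlap_mask: np.ndarray, skeleton_length_cm: float,
                     cal: CalibrationResult) -> DiameterEstimate:
    """ADTR from the non-overlapping-root area-to-length ratio, in um."""
    n_no = int(np.asarray(nonoverlap_mask, dtype=bool).sum())
    sasr_no = cal.s_pix * n_no
    if skeleton_length_cm <= 0:
        raise UndefinedDiameterError("zero-length skeleton: diameter undefined")
    adtr_cm = sasr_no / skeleton_length_cm
    return DiameterEstimate(sasr_no=sasr_no, tlsr_no_skeleton=skeleton_length_cm,
                            adtr=cm_to_um(adtr_cm))


# ----------------------------------------------------------------------------
# encapsulation

def encapsulation(root_mask: np.ndarray, matrix_mask: np.ndarray,
                  cal: CalibrationResult | None = None) -> EncapsulationResult:
    """DSR = 100 * root pixels / root-ball pixels (root is part of the ball)."""
    root = np.asarray(root_mask, dtype=bool)
    matrix = np.asarray(matrix_mask, dtype=bool)
    all_mask = matrix | root
    pix_all = int(all_mask.sum())
    if pix_all == 0:
        raise ValueError("empty matrix mask: encapsulation undefined")
    pix_root = int(root.sum())
    s_pix = cal.s_pix if cal is not None else float("nan")
    return EncapsulationResult(dsr=100.0 * pix_root / pix_all,
                               sasr=pix_root * s_pix, ssam=pix_all * s_pix,
                               pix_root=pix_root, pix_all=pix_all)


# ----------------------------------------------------------------------------
# allometric predictions

def predict_total_surface_area(sasr_cm2: float,
                               model: PredictionModel | None = None) -> float:
    """SATR (cm^2) from SASR via the linear model (published by default)."""
    if sasr_cm2 < 0:
        raise ValueError("SASR must be >= 0")
    model = model or paper_surface_area_model()
    return model(sasr_cm2)


def predict_total_length(satrp_cm2: float, adtr_um: float,
                         model: PredictionModel | None = None,
                         ) -> tuple[float, float]:
    """(LTR, LTRP) in cm: LTR = SATR_pred / ADTR, then the linear model."""
    if adtr_um <= 0:
        raise ValueError("ADTR must be > 0 to derive a length")
    model = model or paper_length_model()
    ltr = satrp_cm2 / um_to_cm(adtr_um)
    return ltr, model(ltr)


def total_volume(adtr_um: float, ltrp_cm: float) -> float:
    """Cylinder-model total-root volume, cm^3."""
    if adtr_um < 0 or ltrp_cm < 0:
        raise ValueError("inputs must be >= 0")
    r_cm = um_to_cm(adtr_um) / 2.0
    return math.pi * r_cm ** 2 * ltrp_cm


def fit_model(x: np.ndarray, y: np.ndarray) -> PredictionModel:
    """Ordinary-least-squares line fit with r^2."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) <= 0:
        raise ValueError("x is constant: slope undefined")
    A = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return PredictionModel(slope=float(slope), intercept=float(intercept),
                           n_fit=len(x), r2=r2)


# ----------------------------------------------------------------------------
# report

_REPORT_FIELDS = ("adtr_um", "sasr_cm2", "dsr_pct", "sa_cm2",
                  "satrp_cm2", "ltr_cm", "ltrp_cm", "vtr_cm3")


@dataclass(frozen=True)
class PhenotypeReport:
    """All measured and predicted phenotypes for one plant, with units."""

    adtr_um: float      # average diameter of total root
    sasr_cm2: float     # surface area of surface root
    dsr_pct: float      # encapsulation (density of surface root)
    sa_cm2: float       # surface soil area of the root ball
    satrp_cm2: float    # predicted surface area of total root
    ltr_cm: float       # calculated length of total root
    ltrp_cm: float      # predicted length of total root
    vtr_cm3: float      # predicted volume of total root
    plant_id: str = "plant"
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in _REPORT_FIELDS}
        d["plant_id"] = self.plant_id
        if self.meta:
            d["meta"] = self.meta
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "PhenotypeReport":
        kwargs = {k: float(d[k]) for k in _REPORT_FIELDS}
        return cls(plant_id=str(d.get("plant_id", "plant")),
                   meta=d.get("meta", {}), **kwargs)

    def csv_row(self) -> str:
        vals = [format(getattr(self, k), ".12g") for k in _REPORT_FIELDS]
        return ",".join([self.plant_id] + vals)

    @staticmethod
    def csv_header() -> str:
        return "plant_id,ADTR_um,SASR_cm2,DSR_pct,Sa_cm2,SATRP_cm2,LTR_cm,LTRP_cm,VTR_cm3"


def assemble_report(*, diameter: DiameterEstimate | None,
                    encaps: EncapsulationResult | None,
                    cal: CalibrationResult | None,
                    surface_model: PredictionModel | None = None,
                    length_model: PredictionModel | None = None,
                    plant_id: str = "plant", meta: dict | None = None,
                    ) -> PhenotypeReport:
    """Combine all intermediates and re-check the volume consistency.

    Raises ValueError naming the first missing upstream quantity.
    """
    for name, val in (("diameter", diameter), ("encapsulation", encaps),
                      ("calibration", cal)):
        if val is None:
            raise ValueError(f"missing upstream value: {name}")
    sa = encaps.ssam
    sasr = encaps.sasr
    satrp = predict_total_surface_area(sasr, surface_model)
    ltr, ltrp = predict_total_length(satrp, diameter.adtr, length_model)
    vtr = total_volume(diameter.adtr, ltrp)
    report = PhenotypeReport(adtr_um=diameter.adtr, sasr_cm2=sasr,
                             dsr_pct=encaps.dsr, sa_cm2=sa, satrp_cm2=satrp,
                             ltr_cm=ltr, ltrp_cm=ltrp, vtr_cm3=vtr,
                             plant_id=plant_id, meta=meta or {})
    check_report_consistency(report)
    return report


def check_report_consistency(report: PhenotypeReport, rtol: float = 1e-9) -> None:
    """Verify VTR = pi (ADTR/2)^2 LTRP; raises ValueError on mismatch."""
    expect = total_volume(report.adtr_um, report.ltrp_cm)
    if not math.isclose(report.vtr_cm3, expect, rel_tol=rtol, abs_tol=1e-15):
        raise ValueError(
            f"inconsistent report: VTR={report.vtr_cm3} but "
            f"pi(ADTR/2)^2*LTRP={expect}")
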