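"""Image preprocessing: enhancement, edge-based background removal, and
homomorphic illumination correction.

The stitched root-ball image sits on a dark, low-texture curtain.  The
background-removal step exploits that contrast in *texture*: the Sobel edge
map is dense on the substrate (speckle, root boundaries) and nearly empty on
the curtain, so morphological consolidation of the edge map isolates the
root-ball blob.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage.filters import sobel, threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import diamond, dilation, disk, erosion, opening

from .frame import luma

_REFERENCE_WIDTH = 1280  # structuring-element radii are specified at this width


class NoForegroundError(RuntimeError):
    """The morphological pipeline left no foreground component."""


@dataclass
class PreprocessParams:
    """Tunables for the three preprocessing steps.

    Structuring-element radii are given at a 1280-px-wide reference
    resolution and scaled linearly with the actual image width.
    ``component_filter`` selects how the connected-component cut is applied:
    ``"largest-half"`` keeps components at least half as large as the biggest
    one (isolating the root-ball blob), ``"image-fraction"`` keeps components
    covering at least half the image.
    """

    gain: float = 1.4
    gamma: float = 0.8
    sobel_threshold: float | None = None        # None -> Otsu on gradient magnitude
    dilate_disk_r: int = 5
    erode_diamond_r: int = 3
    open_disk_r: int = 3
    component_filter: str = "largest-half"
    homomorphic_gamma_h: float = 1.5
    homomorphic_gamma_l: float = 0.5
    homomorphic_cutoff: float = 0.05            # D0 as a fraction of min(H, W)

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        for r in (self.dilate_disk_r, self.erode_diamond_r, self.open_disk_r):
            if r < 1:
                raise ValueError("structuring-element radii must be >= 1")
        if not (self.homomorphic_gamma_h >= self.homomorphic_gamma_l > 0):
            raise ValueError("need gammaH >= gammaL > 0")
        if self.component_filter not in ("largest-half", "image-fraction"):
            raise ValueError("unknown component_filter mode")


def enhance(color: np.ndarray, gain: float = 1.4, gamma: float = 0.8) -> np.ndarray:
    """Brightness gain followed by gamma contrast: clip(gain*x, 0, 1)**gamma.

    Input and output are normalized to [0, 1]; 8-bit input is divided by 255
    first.  gamma < 1 lifts mid-tones (brightening), gamma > 1 darkens.
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    x = np.asarray(color, dtype=np.float64)
    if x.max() > 1.0:
        x = x / 255.0
    return np.clip(gain * x, 0.0, 1.0) ** gamma


def _scaled(radius: int, width: int) -> int:
    return max(1, int(round(radius * width / _REFERENCE_WIDTH)))


def remove_background(color: np.ndarray, params: PreprocessParams | None = None,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Isolate the root-ball region by consolidating the Sobel edge map.

    Pipeline (fixed order): Sobel magnitude -> threshold -> dilate (disk) ->
    fill holes -> erode (diamond) -> open (disk) -> connected-component
    filter.  Returns (mask, masked color image).
    """
    params = params or PreprocessParams()
    gray = luma(color)
    W = gray.shape[1]
    mag = sobel(gray)
    thr = params.sobel_threshold
    if thr is None:
        if mag.max() <= 1e-12:
            raise NoForegroundError("no edges in the image")
        thr = threshold_otsu(mag)
    edges = mag > thr
    if not edges.any():
        raise NoForegroundError("no edges above threshold")
    m = dilation(edges, disk(_scaled(params.dilate_disk_r, W)))
    m = binary_fill_holes(m)
    m = erosion(m, diamond(_scaled(params.erode_diamond_r, W)))
    m = opening(m, disk(_scaled(params.open_disk_r, W)))
    lab = label(m, connectivity=2)
    if lab.max() == 0:
        raise NoForegroundError("morphology removed all components")
    areas = np.bincount(lab.ravel())[1:]
    if params.component_filter == "largest-half":
        cut = areas.max() / 2.0
    else:
        cut = gray.size / 2.0
    keep = np.flatnonzero(areas >= cut) + 1
    mask = np.isin(lab, keep)
    if not mask.any():
        raise NoForegroundError("component filter removed everything")
    masked = np.asarray(color).copy()
    masked[~mask] = 0
    return mask, masked


def homomorphic_filter(gray: np.ndarray, gamma_h: float = 1.5,
                       gamma_l: float = 0.5, cutoff: float = 0.05) -> np.ndarray:
    """Log-domain Gaussian high-emphasis filtering.

    Models the image as illumination (low frequency) times reflectance (high
    frequency): log(1+x) -> FFT -> gain gammaL + (gammaH-gammaL) *
    (1 - exp(-D^2 / (2 D0^2))) -> inverse FFT -> expm1 -> min/max rescale to
    [0, 1].  D is the centered frequency-index distance and
    D0 = cutoff * min(H, W).  With gammaH > 1 > gammaL the smooth
    illumination field is attenuated and fine structure (thin roots) boosted.
    """
    x = np.asarray(gray, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    if x.max() > 1.0:
        x = x / 255.0
    h, w = x.shape
    logx = np.log1p(x)
    F = np.fft.fft2(logx)
    fy = np.fft.fftfreq(h) * h
    fx = np.fft.fftfreq(w) * w
    D2 = fy[:, None] ** 2 + fx[None, :] ** 2
    d0 = cutoff * min(h, w)
    gain = gamma_l + (gamma_h - gamma_l) * (1.0 - np.exp(-D2 / (2.0 * d0 ** 2)))
    out = np.expm1(np.real(np.fft.ifft2(F * gain)))
    lo, hi = out.min(), out.max()
    if hi - lo < 1e-12:
        return np.zeros_like(out)
    return (out - lo) / (hi - lo)
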