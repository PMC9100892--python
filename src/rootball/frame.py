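"""Core containers: camera intrinsics and co-registered color+depth frames."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


@dataclass(frozen=True)
class Intrinsics:
    """Pinhole camera intrinsics, in pixels."""

    fx: float
    fy: float
    cx: float
    cy: float

    def to_dict(self) -> dict:
        return {"fx": self.fx, "fy": self.fy, "cx": self.cx, "cy": self.cy}

    @classmethod
    def from_dict(cls, d: dict) -> "Intrinsics":
        return cls(fx=float(d["fx"]), fy=float(d["fy"]),
                   cx=float(d["cx"]), cy=float(d["cy"]))


@dataclass
class RGBDFrame:
    """One co-registered view: 8-bit color, 16-bit depth in millimetres.

    ``depth == 0`` marks invalid (no return) pixels.  Color and depth share the
    same pixel grid; pixel coordinates are 0-based (row, col) with the origin at
    the top-left, and homographies act on homogeneous (x=col, y=row, 1).
    """

    color: np.ndarray
    depth: np.ndarray
    intrinsics: Intrinsics

    def __post_init__(self) -> None:
        color = np.asarray(self.color)
        depth = np.asarray(self.depth)
        if color.ndim != 3 or color.shape[2] != 3:
            raise ValueError("color must be an H x W x 3 array")
        if depth.shape != color.shape[:2]:
            raise ValueError(
                f"depth shape {depth.shape} does not match color {color.shape[:2]}"
            )
        if np.any(depth < 0):
            raise ValueError("depth must be non-negative (0 = invalid)")
        self.color = color
        self.depth = depth

    @property
    def shape(self) -> tuple[int, int]:
        return self.color.shape[:2]

    def crop(self, x: int, y: int, w: int, h: int) -> "RGBDFrame":
        """Crop to a rectangle, shifting the principal point by the offset."""
        H, W = self.shape
        if w <= 0 or h <= 0:
            raise ValueError("ROI rectangle must have positive size")
        if x < 0 or y < 0 or x + w > W or y + h > H:
            raise ValueError(f"ROI ({x},{y},{w},{h}) outside canvas {W}x{H}")
        k = replace(self.intrinsics, cx=self.intrinsics.cx - x,
                    cy=self.intrinsics.cy - y)
        return RGBDFrame(color=self.color[y:y + h, x:x + w].copy(),
                         depth=self.depth[y:y + h, x:x + w].copy(),
                         intrinsics=k)


def luma(color: np.ndarray) -> np.ndarray:
    """Standard Rec.601 luma grayscale in [0, 1] from an 8-bit RGB image."""
    c = np.asarray(color, dtype=np.float64)
    if c.ndim == 2:
        g = c
    else:
        g = 0.299 * c[..., 0] + 0.587 * c[..., 1] + 0.114 * c[..., 2]
    if g.max() > 1.0:
        g = g / 255.0
    return g
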