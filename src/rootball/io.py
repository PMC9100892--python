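"""PNG / JSON / CSV input-output helpers."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .frame import Intrinsics, RGBDFrame


def write_color_png(path: str | Path, color: np.ndarray) -> None:
    iio.imwrite(Path(path), np.asarray(color, dtype=np.uint8))


def read_color_png(path: str | Path) -> np.ndarray:
    img = iio.imread(Path(path))
    if img.ndim == 2:
        img = np.repeat(img[..., None], 3, axis=2)
    return img[..., :3].astype(np.uint8)


def write_depth_png(path: str | Path, depth_mm: np.ndarray) -> None:
    """Depth in millimetres as a 16-bit PNG (0 = invalid)."""
    d = np.clip(np.round(np.asarray(depth_mm, dtype=np.float64)), 0, 65535)
    iio.imwrite(Path(path), d.astype(np.uint16))


def read_depth_png(path: str | Path) -> np.ndarray:
    return iio.imread(Path(path)).astype(np.float64)


def write_mask_png(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * 255).astype(np.uint8))


def read_mask_png(path: str | Path) -> np.ndarray:
    return iio.imread(Path(path)) > 127


def write_intrinsics(path: str | Path, k: Intrinsics) -> None:
    Path(path).write_text(json.dumps(k.to_dict(), indent=2))


def read_intrinsics(path: str | Path) -> Intrinsics:
    return Intrinsics.from_dict(json.loads(Path(path).read_text()))


def write_homographies(path: str | Path, homs: list[np.ndarray]) -> None:
    Path(path).write_text(json.dumps([np.asarray(h).tolist() for h in homs],
                                     indent=2))


def read_homographies(path: str | Path) -> list[np.ndarray]:
    return [np.asarray(h, dtype=np.float64)
            for h in json.loads(Path(path).read_text())]


def write_frame(dirpath: str | Path, name: str, frame: RGBDFrame) -> None:
    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    write_color_png(d / f"{name}_color.png", frame.color)
    write_depth_png(d / f"{name}_depth.png", frame.depth)
    write_intrinsics(d / f"{name}_intrinsics.json", frame.intrinsics)


def read_frame(dirpath: str | Path, name: str) -> RGBDFrame:
    d = Path(dirpath)
    color_p = d / f"{name}_color.png"
    depth_p = d / f"{name}_depth.png"
    intr_p = d / f"{name}_intrinsics.json"
    for p in (color_p, depth_p, intr_p):
        if not p.exists():
            raise FileNotFoundError(str(p))
    return RGBDFrame(color=read_color_png(color_p),
                     depth=read_depth_png(depth_p),
                     intrinsics=read_intrinsics(intr_p))


def write_float_png(path: str | Path, values: np.ndarray) -> None:
    """A [0,1] float map scaled to the full 16-bit range."""
    v = np.clip(np.asarray(values, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(Path(path), np.round(v * 65535).astype(np.uint16))
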