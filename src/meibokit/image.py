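"""Image container and raster I/O.

Infrared meibographs from clinical topographers (e.g. the Keratograph 5M)
are exported as 1360 x 1024 px bitmaps, nominally RGB but near-monochrome.
Everything downstream works on an 8-bit grayscale grid with row 0 at the
top, ``x`` = column increasing rightward and ``y`` = row increasing
downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

from .errors import UnsupportedFormatError

#: ITU-R BT.601 luma weights used for RGB -> grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])

#: Approximate physical scale of the acquisition device.  Chosen so that a
#: typical 20 px gland width corresponds to roughly 0.4 mm; documented as
#: approximate because the vendor does not publish the value.
DEFAULT_MM_PER_PX = 0.02


@dataclass
class MeibographyImage:
    """A single-frame grayscale meibography image.

    Attributes
    ----------
    pixels : ndarray of uint8, shape (height_px, width_px)
        Grayscale intensities in [0, 255].
    mm_per_px : float
        Physical pixel pitch used to convert gland axes to millimetres.
    source_id : str
        Free-text label (usually the file stem).
    """

    pixels: np.ndarray
    mm_per_px: float = DEFAULT_MM_PER_PX
    source_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim == 3:
            arr = rgb_to_gray(arr)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("pixels must be a nonempty 2-D grid")
        if arr.dtype != np.uint8:
            if arr.min() < 0 or arr.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            arr = np.round(arr).astype(np.uint8)
        if not arr.flags.writeable:  # rank filters need a writable buffer
            arr = arr.copy()
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")
        self.pixels = arr

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]


def rgb_to_gray(rgb: np.ndarray) -> np.ndarray:
    """Convert an (H, W, 3) array to uint8 grayscale with BT.601 weights."""
    gray = np.tensordot(rgb[..., :3].astype(float), _LUMA, axes=([-1], [0]))
    return np.clip(np.round(gray), 0, 255).astype(np.uint8)


def load_image(path: str | Path, mm_per_px: float = DEFAULT_MM_PER_PX) -> MeibographyImage:
    """Read a BMP or PNG raster into a :class:`MeibographyImage`.

    RGB input is collapsed to grayscale on load; 16-bit input is rescaled
    to 8 bits.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if path.suffix.lower() not in {".bmp", ".png"}:
        raise UnsupportedFormatError(f"unsupported raster format: {path.suffix!r}")
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except UnidentifiedImageError as exc:  # pragma: no cover - corrupt file
        raise UnsupportedFormatError(str(exc)) from exc
    if arr.ndim == 3:
        arr = rgb_to_gray(arr)
    elif arr.dtype != np.uint8:
        lo, hi = float(arr.min()), float(arr.max())
        scale = 255.0 / (hi - lo) if hi > lo else 0.0
        arr = np.round((arr.astype(float) - lo) * scale).astype(np.uint8)
    return MeibographyImage(pixels=arr, mm_per_px=mm_per_px, source_id=path.stem)


def save_image(path: str | Path, pixels: np.ndarray) -> None:
    """Write a uint8 or uint16 grid as PNG/BMP."""
    Image.fromarray(np.asarray(pixels)).save(str(path))


def read_polygon(path: str | Path) -> np.ndarray:
    """Read a manual ROI polygon: plain-text lines of ``x,y`` vertices
    (0-based pixel coordinates).  Returns an (N, 2) float array of
    (x, y) pairs."""
    verts = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        x_s, y_s = line.split(",")[:2]
        verts.append((float(x_s), float(y_s)))
    if len(verts) < 3:
        raise ValueError("polygon needs at least 3 vertices")
    return np.asarray(verts, dtype=float)
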