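"""Meibomian gland segmentation and labeling.

Glands are bright, roughly vertical stripes inside the ROI.  They are
enhanced with a difference-of-Gaussians band-pass (sigma 2 px vs 30 px),
binarized with a locally adaptive threshold biased toward foreground,
cleaned with a 5 x 3 median filter, and filtered by size (>= 800 px) and
orientation (within [40 deg, 140 deg] of the horizontal axis, i.e. near
vertical).  Compound labels — glands fused in fork-like structures — are
split by a gated fragmentation pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.signal import find_peaks
from skimage import measure
from skimage.segmentation import watershed

from .config import FragmentationParams, SegmentationConfig
from .errors import DegenerateObjectError, EmptyROIError
from .roi import ROIResult

_EIGHT = np.ones((3, 3), int)


@dataclass
class GlandLabelMap:
    """Labeled gland segmentation: 0 = background, labels 1..n_glands
    numbered left to right by centroid column."""

    labels: np.ndarray

    @property
    def n_glands(self) -> int:
        return int(self.labels.max())

    def pixel_sets(self) -> list[np.ndarray]:
        """Per-label boolean masks, in label order."""
        return [self.labels == i for i in range(1, self.n_glands + 1)]


def bandpass_dog(gray: np.ndarray, sigma_low: float = 2.0,
                 sigma_high: float = 30.0,
                 mask: np.ndarray | None = None) -> np.ndarray:
    """Difference-of-Gaussians band-pass.

    The narrow Gaussian suppresses pixel noise, the wide one estimates
    the local illumination; their difference enhances gland edges
    without amplifying noise.  A constant image maps to zero.

    With ``mask`` given, both blurs are normalized convolutions
    restricted to the masked region, so the dark surround outside the
    tarsus cannot bleed into the wide blur and produce spurious
    positive responses just inside the boundary.
    """
    if not sigma_low < sigma_high:
        raise ValueError("sigma_low must be smaller than sigma_high")
    x = np.asarray(gray, dtype=float)
    if mask is None:
        return ndi.gaussian_filter(x, sigma_low) - ndi.gaussian_filter(x, sigma_high)
    m = np.asarray(mask, float)
    xm = x * m
    with np.errstate(divide="ignore", invalid="ignore"):
        lo = ndi.gaussian_filter(xm, sigma_low) / ndi.gaussian_filter(m, sigma_low)
        hi = ndi.gaussian_filter(xm, sigma_high) / ndi.gaussian_filter(m, sigma_high)
    out = np.nan_to_num(lo - hi, nan=0.0, posinf=0.0, neginf=0.0)
    return out * (m > 0)


def suppress_reflections(gray: np.ndarray, threshold: int = 200,
                         pad_px: int = 2) -> np.ndarray:
    """Replace saturated specular highlights with the nearest
    non-saturated intensity.

    Specular blobs otherwise sever the glands they sit on into stacked
    fragments during thresholding.  The reflection mask (intensity >
    ``threshold``, dilated by ``pad_px`` to cover rim artifacts) is
    filled by linear interpolation along each column — glands run
    vertically, so a column-wise fill continues the structure the blob
    interrupted instead of bleeding in lateral intergland values.
    """
    img = np.asarray(gray)
    refl = img > threshold
    if not refl.any():
        return img.copy()
    if pad_px > 0:
        refl = ndi.binary_dilation(refl, iterations=pad_px)
    out = img.astype(float).copy()
    rows = np.arange(img.shape[0])
    for col in np.nonzero(refl.any(axis=0))[0]:
        bad = refl[:, col]
        if bad.all():
            continue
        # denoise the rim samples so a single noisy endpoint cannot seed
        # a coherent bright streak through the filled region
        good_vals = ndi.gaussian_filter1d(out[~bad, col], sigma=2.0)
        out[bad, col] = np.interp(rows[bad], rows[~bad], good_vals)
    return np.clip(np.round(out), 0, 255).astype(img.dtype)


def object_orientation(pixel_set: np.ndarray) -> float:
    """Orientation of an object's moment ellipse, degrees in [0, 180).

    Measured from the +x (column) axis; a vertical stripe maps to 90.
    Uses the eigenvector of the second central moment matrix in (x, y) =
    (column, row) coordinates.
    """
    mask = np.asarray(pixel_set, bool)
    ys, xs = np.nonzero(mask)
    if ys.size < 3:
        raise DegenerateObjectError("need at least 3 pixels for an orientation")
    x = xs - xs.mean()
    y = ys - ys.mean()
    mxx = np.mean(x * x) + 1.0 / 12.0   # pixel-patch correction, matches
    myy = np.mean(y * y) + 1.0 / 12.0   # the moment-ellipse convention
    mxy = np.mean(x * y)
    theta = 0.5 * np.degrees(np.arctan2(2.0 * mxy, mxx - myy))
    return float(theta % 180.0)


def _axis_lengths(mask: np.ndarray) -> tuple[float, float]:
    """Major/minor axis lengths of the moment ellipse of a pixel set."""
    ys, xs = np.nonzero(mask)
    x = xs - xs.mean()
    y = ys - ys.mean()
    mxx = np.mean(x * x) + 1.0 / 12.0
    myy = np.mean(y * y) + 1.0 / 12.0
    mxy = np.mean(x * y)
    common = np.sqrt(((mxx - myy) / 2.0) ** 2 + mxy**2)
    lam1 = (mxx + myy) / 2.0 + common
    lam2 = (mxx + myy) / 2.0 - common
    return 4.0 * np.sqrt(max(lam1, 0.0)), 4.0 * np.sqrt(max(lam2, 0.0))


def segment_glands(bandpassed: np.ndarray, roi: ROIResult,
                   sensitivity: float | None = None,
                   min_gland_px: int | None = None,
                   config: SegmentationConfig | None = None) -> np.ndarray:
    """Binary gland mask inside the ROI.

    The band-passed image is thresholded against its local mean in an
    ``adaptive_window_px`` square; ``sensitivity`` > 0.5 lowers the
    threshold (more foreground), mirroring a high-sensitivity adaptive
    threshold.  A 5 x 3 median filter smooths gland outlines, then
    components below ``min_gland_px`` or oriented outside
    [orientation_min, orientation_max] degrees are removed.
    """
    cfg = config or SegmentationConfig()
    if sensitivity is None:
        sensitivity = cfg.sensitivity
    if min_gland_px is None:
        min_gland_px = cfg.min_gland_px
    roi_mask = np.asarray(roi.mask, bool)
    if not roi_mask.any():
        raise EmptyROIError("ROI mask is empty")
    bp = np.asarray(bandpassed, dtype=float)
    if bp.shape != roi_mask.shape:
        raise ValueError("band-passed image and ROI dimensions differ")

    masked = bp * roi_mask
    local_mean = ndi.uniform_filter(masked, size=cfg.adaptive_window_px)
    # the threshold sits a margin above the local mean so texture-free
    # dropout (band-pass response ~ 0) yields no foreground; sensitivity
    # -> 1 shrinks the margin, admitting more pixels as foreground
    spread = float(masked[roi_mask].std()) if roi_mask.any() else 0.0
    offset = (1.0 - sensitivity) * spread
    binary = (masked > local_mean + offset) & roi_mask

    binary = ndi.median_filter(binary.astype(np.uint8),
                               size=cfg.median_shape).astype(bool)
    binary &= roi_mask

    labels, n = ndi.label(binary, structure=_EIGHT)
    if n == 0:
        return binary
    keep = np.zeros(n + 1, bool)
    for region in measure.regionprops(labels):
        if region.num_pixels < min_gland_px:
            continue
        ori = object_orientation(labels == region.label)
        if cfg.orientation_min_deg <= ori <= cfg.orientation_max_deg:
            keep[region.label] = True
    return keep[labels]


def label_glands(mask: np.ndarray) -> GlandLabelMap:
    """Label 8-connected components, renumbered left-to-right by
    centroid column.  An empty mask yields ``n_glands = 0``."""
    labels, n = ndi.label(np.asarray(mask, bool), structure=_EIGHT)
    if n == 0:
        return GlandLabelMap(labels.astype(np.int32))
    centroids = ndi.center_of_mass(np.ones_like(labels), labels, range(1, n + 1))
    order = np.argsort([c[1] for c in centroids], kind="stable")
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[1 + order] = np.arange(1, n + 1, dtype=np.int32)
    return GlandLabelMap(remap[labels])


def _column_profile_extrema(mask: np.ndarray,
                            prominence_frac: float) -> tuple[int, np.ndarray]:
    """Lobes and valleys of an object's column pixel-count profile.

    Returns ``(n_lobes, valley_columns)`` where lobes are significant
    local maxima (each an apparent gland) and valleys the significant
    local minima between them; significance means a prominence of at
    least ``prominence_frac`` of the profile maximum.
    """
    profile = mask.sum(axis=0).astype(float)
    cols = np.nonzero(profile)[0]
    if cols.size == 0:
        return 0, np.array([], dtype=int)
    sub = profile[cols.min():cols.max() + 1]
    if sub.size < 3 or sub.max() <= 0:
        return 1, np.array([], dtype=int)
    prom = prominence_frac * sub.max()
    # pad so lobes at the object's left/right edge are counted; valleys
    # are interior by construction (pad with the maximum)
    maxima, _ = find_peaks(np.r_[0.0, sub, 0.0], prominence=prom)
    minima, _ = find_peaks(np.r_[-sub.max(), -sub, -sub.max()], prominence=prom)
    return max(int(maxima.size), 1), minima - 1 + cols.min()


def _split_object(mask: np.ndarray, cut_cols: np.ndarray) -> list[np.ndarray]:
    """Split one object at the given cut columns with a marker-based
    watershed of its distance transform, so no foreground pixel is lost."""
    marker_mask = mask.copy()
    for c in cut_cols:
        marker_mask[:, max(c - 1, 0):c + 2] = False
    markers, n = ndi.label(marker_mask, structure=_EIGHT)
    if n < 2:
        return [mask]
    dist = ndi.distance_transform_edt(mask)
    ws = watershed(-dist, markers, mask=mask, connectivity=2)
    return [ws == i for i in range(1, n + 1) if np.any(ws == i)]


def _fragment_ok(fragment: np.ndarray, params: FragmentationParams) -> bool:
    ys, xs = np.nonzero(fragment)
    if ys.size < 3:
        return False
    try:
        ori = object_orientation(fragment)
    except DegenerateObjectError:
        return False
    if abs(ori - 90.0) > params.o2_th:
        return False
    length, width = _axis_lengths(fragment)
    return width > 0 and length / width >= params.r_th


def fragment_compound_glands(labelmap: GlandLabelMap,
                             params: FragmentationParams | None = None) -> GlandLabelMap:
    """Split labels that cover several glands fused fork-like.

    For each object the column-wise pixel-count profile is scanned: the
    count ``Nl`` of significant lobes (prominent local maxima, each an
    apparent gland) triggers a split attempt when ``Nl > nl_th``, as
    does an orientation more than ``o_th`` degrees off vertical.  Cuts
    are made at the profile valleys via a watershed of the object's
    distance transform and are accepted only when more than ``no_th``
    fragments result, every fragment is within ``o2_th`` degrees of
    vertical, and every fragment's length/width ratio is at least
    ``r_th``; otherwise the object passes through unchanged.  Accepted
    fragments are re-examined until nothing triggers.  The foreground
    pixel set is always preserved exactly.
    """
    params = params or FragmentationParams()
    queue = [m for m in labelmap.pixel_sets()]
    final: list[np.ndarray] = []
    while queue:
        obj = queue.pop()
        nl, valleys = _column_profile_extrema(obj, params.min_prominence_frac)
        try:
            off_vertical = abs(object_orientation(obj) - 90.0) > params.o_th
        except DegenerateObjectError:
            off_vertical = False
        if nl <= params.nl_th and not off_vertical:
            final.append(obj)
            continue
        fragments = _split_object(obj, valleys)
        if (len(fragments) > params.no_th
                and all(_fragment_ok(f, params) for f in fragments)):
            queue.extend(fragments)
        else:
            final.append(obj)

    out = np.zeros(labelmap.labels.shape, dtype=np.int32)
    for i, obj in enumerate(final, start=1):
        out[obj] = i
    return label_glands(out > 0) if not final else _relabel(out, final)


def _relabel(labels: np.ndarray, objects: list[np.ndarray]) -> GlandLabelMap:
    """Renumber arbitrary per-object masks left-to-right, keeping objects
    distinct even where 8-connectivity would merge touching fragments."""
    cols = [float(np.nonzero(o)[1].mean()) for o in objects]
    order = np.argsort(cols, kind="stable")
    out = np.zeros(labels.shape, dtype=np.int32)
    for new, idx in enumerate(order, start=1):
        out[objects[idx]] = new
    return GlandLabelMap(out)
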