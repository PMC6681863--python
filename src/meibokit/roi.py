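"""Tarsal-conjunctiva region-of-interest detection.

The everted upper eyelid appears as a bright band across the frame.  The
band's upper boundary is a wide convex structure; its lower boundary is a
high-gradient edge against the lid margin.  The two boundaries are
detected independently on the upper/lower halves of the image, fitted
with a quadratic and a constrained fourth-degree Chebyshev series
respectively, and the enclosed region is refined with Chan-Vese active
contouring on a local-standard-deviation transform of the image.

Coordinate convention: 0-based, ``x`` = column rightward, ``y`` = row
downward; boundary curves map column -> row; masks use half-open row
intervals ``upper(x) <= y < lower(x)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import chebyshev as C
from scipy import ndimage as ndi
from scipy.signal import find_peaks
from skimage import measure, morphology
from skimage.draw import polygon2mask
from skimage.filters import rank, threshold_otsu, sobel_h
from skimage.segmentation import morphological_chan_vese

from .config import ROIConfig
from .errors import EmptyMaskError, FlatImageError, MeibokitError, NoBoundaryFound
from .image import MeibographyImage


# ---------------------------------------------------------------------------
# domain types


@dataclass
class EyelidSplit:
    """The image cut into upper/lower halves at the brightest band row."""

    upper_subimage: np.ndarray
    lower_subimage: np.ndarray
    split_row: int

    def recombine(self) -> np.ndarray:
        return np.vstack([self.upper_subimage, self.lower_subimage])


@dataclass
class BoundaryCurve:
    """A fitted eyelid boundary: column -> row.

    ``kind`` is ``"quadratic"`` (power basis, 3 coefficients, positive
    quadratic term: convex upper boundary) or ``"chebyshev4"`` (5
    Chebyshev-series coefficients on x rescaled to [-1, 1], degree-4
    coefficient <= 0: concave lower boundary).
    """

    kind: str
    coefficients: np.ndarray
    domain: tuple[float, float]
    rms_fit_error: float = 0.0

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.kind == "quadratic":
            if self.coefficients.shape != (3,):
                raise ValueError("quadratic curve needs 3 coefficients")
            if self.coefficients[2] <= 0:
                raise ValueError("upper boundary must be convex (quadratic term > 0)")
        elif self.kind == "chebyshev4":
            if self.coefficients.shape != (5,):
                raise ValueError("chebyshev4 curve needs 5 coefficients")
            if self.coefficients[4] > 1e-12:
                raise ValueError("lower boundary must be concave (degree-4 term <= 0)")
        else:
            raise ValueError(f"unknown curve kind {self.kind!r}")

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.kind == "quadratic":
            c0, c1, c2 = self.coefficients
            return c0 + c1 * x + c2 * x * x
        lo, hi = self.domain
        u = np.clip(2.0 * (x - lo) / max(hi - lo, 1e-12) - 1.0, -1.0, 1.0)
        return C.chebval(u, self.coefficients)

    def shifted(self, dy: float) -> "BoundaryCurve":
        """Return the same curve translated by ``dy`` rows."""
        coeffs = self.coefficients.copy()
        coeffs[0] += dy
        return BoundaryCurve(self.kind, coeffs, self.domain, self.rms_fit_error)


@dataclass
class ROIResult:
    """Final region-of-interest mask with provenance."""

    mask: np.ndarray
    upper: BoundaryCurve | None = None
    lower: BoundaryCurve | None = None
    status: str = "auto"              # auto | manual | failed
    error: str | None = None

    @property
    def area_px(self) -> int:
        return int(np.count_nonzero(self.mask))


# ---------------------------------------------------------------------------
# operations


def split_eyelid_image(image: MeibographyImage, config: ROIConfig | None = None) -> EyelidSplit:
    """Cut the frame at the row of maximal mean brightness.

    The tarsal band lies between the two boundaries and is the brightest
    horizontal structure, so the argmax of the smoothed row-mean profile
    falls strictly between them.  Raises :class:`FlatImageError` when no
    row stands out from the profile median by the configured margin.
    """
    cfg = config or ROIConfig()
    gray = image.pixels
    profile = gray.mean(axis=1)
    smooth = ndi.uniform_filter1d(profile, size=cfg.split_smooth_rows, mode="nearest")
    if smooth.max() < np.median(smooth) + cfg.split_peak_margin:
        raise FlatImageError("no bright tarsal band in the row-mean intensity profile")
    split_row = int(np.argmax(smooth))
    split_row = min(max(split_row, 1), gray.shape[0] - 1)
    return EyelidSplit(gray[:split_row], gray[split_row:], split_row)


def _fit_quadratic(cols: np.ndarray, rows: np.ndarray) -> tuple[np.ndarray, float]:
    coeffs = np.polynomial.polynomial.polyfit(cols, rows, 2)
    resid = rows - np.polynomial.polynomial.polyval(cols, coeffs)
    return coeffs, float(np.sqrt(np.mean(resid**2)))


def detect_upper_boundary(upper_subimage: np.ndarray,
                          min_edge_px: int = 500,
                          config: ROIConfig | None = None) -> BoundaryCurve:
    """Detect the convex upper boundary of the everted eyelid.

    Pipeline: disk erosion (r = 10 px, removes lashes and other high
    spatial frequencies) -> unsharp masking built from a sigma = 30 px
    Gaussian low-pass -> 40 x 40 px median filter -> Otsu binarization ->
    horizontal Sobel edges -> drop edge components below ``min_edge_px``
    -> quadratic fit per edge -> return the fit with the smallest
    strictly positive quadratic coefficient.
    """
    cfg = config or ROIConfig()
    img = np.ascontiguousarray(upper_subimage, dtype=np.uint8)
    if img.shape[0] < cfg.median_size_px:
        raise NoBoundaryFound("upper subimage too short for boundary detection")

    eroded = rank.minimum(img, morphology.disk(cfg.erosion_radius_px))
    blurred = ndi.gaussian_filter(eroded.astype(float), cfg.sharpen_sigma_px)
    sharp = eroded + cfg.sharpen_amount * (eroded - blurred)
    sharp_u8 = np.clip(np.round(sharp), 0, 255).astype(np.uint8)
    smoothed = rank.median(sharp_u8, np.ones((cfg.median_size_px, cfg.median_size_px), bool))

    if smoothed.max() == smoothed.min():
        raise NoBoundaryFound("featureless upper subimage")
    binary = smoothed > threshold_otsu(smoothed)

    edges = np.abs(sobel_h(binary.astype(float))) > 1e-6
    labels = measure.label(edges, connectivity=2)
    best: tuple[float, BoundaryCurve] | None = None
    for region in measure.regionprops(labels):
        if region.num_pixels < min_edge_px:
            continue
        rows, cols = region.coords[:, 0].astype(float), region.coords[:, 1].astype(float)
        if np.ptp(cols) < 3:
            continue
        coeffs, rms = _fit_quadratic(cols, rows)
        if coeffs[2] <= 0:
            continue
        if best is None or coeffs[2] < best[0]:
            curve = BoundaryCurve("quadratic", coeffs,
                                  (float(cols.min()), float(cols.max())), rms)
            best = (coeffs[2], curve)
    if best is None:
        raise NoBoundaryFound("no convex edge component survived filtering")
    return best[1]


def _column_peak_map(entropy_img: np.ndarray, prominence_frac: float) -> np.ndarray:
    """Mark, per column, the bottom-most prominent local maximum of the
    entropy response.

    Glandular texture keeps the entropy high throughout the band, so a
    column can hold many maxima; the transition into the darker lid
    margin is always the last prominent one, which is what identifies
    the lower boundary.
    """
    peaks = np.zeros(entropy_img.shape, bool)
    for col in range(entropy_img.shape[1]):
        column = entropy_img[:, col]
        span = float(np.ptp(column))
        if span <= 0:
            continue
        # the height gate rejects low-entropy noise bumps below the lid
        idx, _ = find_peaks(column, prominence=prominence_frac * span,
                            height=float(column.min()) + 0.5 * span)
        if idx.size:
            peaks[idx.max(), col] = True
    return peaks


def detect_lower_boundary(lower_subimage: np.ndarray,
                          min_obj_px: int = 500,
                          config: ROIConfig | None = None) -> BoundaryCurve:
    """Detect the concave lower boundary of the everted eyelid.

    The boundary is a high-gradient edge, located by a 9 x 9 px local
    entropy filter: per column, the entropy response spikes where the
    bright band meets the darker lid margin.  Prominent per-column peaks
    are joined with a 3 x 12 horizontal dilation and a disk-6 closing,
    small objects are dropped, the component with the largest horizontal
    extent is kept, and its pixels are fitted with a degree-4 Chebyshev
    series whose top coefficient is constrained to be <= 0 (concavity).
    """
    cfg = config or ROIConfig()
    img = np.ascontiguousarray(lower_subimage, dtype=np.uint8)
    if img.shape[1] < cfg.dilate_rect[1]:
        raise NoBoundaryFound("lower subimage too narrow for boundary detection")

    # mild denoising first: raw sensor noise alone carries several bits of
    # local entropy and would mask the boundary spike
    if cfg.entropy_presmooth_sigma > 0:
        img = np.clip(np.round(ndi.gaussian_filter(img.astype(float),
                                                   cfg.entropy_presmooth_sigma)),
                      0, 255).astype(np.uint8)
    ent = rank.entropy(img, np.ones((cfg.entropy_size_px, cfg.entropy_size_px), bool))
    peaks = _column_peak_map(ent, cfg.peak_prominence_frac)
    joined = ndi.binary_dilation(peaks, structure=np.ones(cfg.dilate_rect, bool))
    joined = ndi.binary_closing(joined, structure=morphology.disk(cfg.close_radius_px))
    labels = measure.label(joined, connectivity=2)

    best_region = None
    best_extent = 0
    for region in measure.regionprops(labels):
        if region.num_pixels < min_obj_px:
            continue
        extent = region.bbox[3] - region.bbox[1]
        if extent > best_extent:
            best_extent, best_region = extent, region
    if best_region is None:
        raise NoBoundaryFound("no lower-boundary component survived filtering")

    rows = best_region.coords[:, 0].astype(float)
    cols = best_region.coords[:, 1].astype(float)
    return fit_chebyshev_concave(cols, rows)


def fit_chebyshev_concave(cols: np.ndarray, rows: np.ndarray) -> BoundaryCurve:
    """Least-squares degree-4 Chebyshev fit with the degree-4 coefficient
    constrained to be <= 0 (the lower eyelid boundary is concave).

    The Chebyshev basis is orthogonal on the rescaled column interval, so
    the inequality-constrained solution is the unconstrained fit when its
    top coefficient is already nonpositive, and otherwise the fit
    restricted to degrees 0..3 (active constraint, c4 = 0).
    """
    lo, hi = float(cols.min()), float(cols.max())
    if hi - lo < 4:
        raise NoBoundaryFound("lower-boundary component spans too few columns")
    u = 2.0 * (cols - lo) / (hi - lo) - 1.0
    V = C.chebvander(u, 4)
    coeffs, *_ = np.linalg.lstsq(V, rows, rcond=None)
    if coeffs[4] > 0:
        sub, *_ = np.linalg.lstsq(V[:, :4], rows, rcond=None)
        coeffs = np.append(sub, 0.0)
    resid = rows - V @ coeffs
    rms = float(np.sqrt(np.mean(resid**2)))
    return BoundaryCurve("chebyshev4", coeffs, (lo, hi), rms)


def build_initial_mask(upper: BoundaryCurve, lower: BoundaryCurve,
                       shape: tuple[int, int]) -> np.ndarray:
    """Rasterize the region between two boundary curves.

    Pixel (x, y) is foreground iff ``upper(x) <= y < lower(x)`` on the
    overlapping column domain; columns where the curves cross contribute
    nothing.  Raises :class:`EmptyMaskError` when no column encloses any
    rows.
    """
    h, w = shape
    lo = max(upper.domain[0], lower.domain[0], 0)
    hi = min(upper.domain[1], lower.domain[1], w - 1)
    if hi < lo:
        raise EmptyMaskError("boundary curves have no overlapping column domain")
    cols = np.arange(int(np.ceil(lo)), int(np.floor(hi)) + 1)
    top = upper(cols)
    bot = lower(cols)
    rows = np.arange(h)[:, None]
    mask = np.zeros((h, w), bool)
    eps = 1e-6  # subpixel tolerance so float noise cannot flip a row
    mask[:, cols] = (rows >= top[None, :] - eps) & (rows < bot[None, :] - eps)
    if not mask.any():
        raise EmptyMaskError("upper boundary at or below lower boundary everywhere")
    return mask


def local_std(gray: np.ndarray, size: int) -> np.ndarray:
    """Local standard deviation in a ``size`` x ``size`` neighbourhood."""
    x = np.asarray(gray, dtype=float)
    m = ndi.uniform_filter(x, size=size, mode="reflect")
    m2 = ndi.uniform_filter(x * x, size=size, mode="reflect")
    return np.sqrt(np.clip(m2 - m * m, 0.0, None))


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Largest 8-connected component of a binary mask."""
    labels, n = ndi.label(mask, structure=np.ones((3, 3), int))
    if n <= 1:
        return mask.astype(bool)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))


def refine_roi_chan_vese(image: MeibographyImage, initial_mask: np.ndarray,
                         iterations: int | None = None,
                         config: ROIConfig | None = None) -> np.ndarray:
    """Refine an initial ROI mask with Chan-Vese active contouring.

    The contour evolves on the 9 x 9 local-standard-deviation transform
    of the grayscale image (the glandular band is strongly textured, the
    surround is flat), seeded with ``initial_mask``.  Evolution uses the
    morphological Chan-Vese scheme, stopping early once the mask changes
    by less than ``chan_vese_tol`` of its area between checkpoints, and
    runs on a decimated grid for speed.  Returns the largest connected
    component of the converged region.
    """
    cfg = config or ROIConfig()
    if iterations is None:
        iterations = cfg.chan_vese_iterations
    init = np.asarray(initial_mask, bool)
    if not init.any():
        raise EmptyMaskError("empty initial mask")
    if iterations <= 0:
        return init.copy()

    feature = local_std(image.pixels, cfg.std_filter_size_px)
    s = max(1, int(cfg.chan_vese_downscale))
    feat = feature[::s, ::s]
    level = init[::s, ::s].astype(np.int8)
    if not level.any():
        level = np.zeros_like(feat, dtype=np.int8)
        level[feat.shape[0] // 2, feat.shape[1] // 2] = 1

    done = 0
    while done < iterations:
        step = min(cfg.chan_vese_checkpoint, iterations - done)
        new = morphological_chan_vese(feat, num_iter=step, init_level_set=level,
                                      smoothing=cfg.chan_vese_smoothing)
        done += step
        area = max(int(new.sum()), 1)
        changed = int(np.count_nonzero(new != (level > 0)))
        level = new.astype(np.int8)
        if changed < cfg.chan_vese_tol * area:
            break

    refined = level > 0
    if s > 1:
        refined = np.kron(refined, np.ones((s, s), bool))[: init.shape[0], : init.shape[1]]
        if refined.shape != init.shape:  # pad short edges after decimation
            out = np.zeros(init.shape, bool)
            out[: refined.shape[0], : refined.shape[1]] = refined
            refined = out
    if not refined.any():
        return init.copy()
    # the local-std transform smears the texture boundary outward by about
    # half the filter window; shave that halo off the converged region
    halo = cfg.std_filter_size_px // 2
    if halo > 0:
        shaved = ndi.binary_erosion(refined, structure=morphology.disk(halo))
        if shaved.any():
            refined = shaved
    return largest_component(refined)


def rasterize_polygon(vertices_xy: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize an (N, 2) array of (x, y) vertices into a binary mask."""
    verts_rc = np.asarray(vertices_xy, float)[:, ::-1]  # (row, col)
    return polygon2mask(shape, verts_rc)


def select_roi(image: MeibographyImage,
               manual_polygon: np.ndarray | None = None,
               config: ROIConfig | None = None) -> ROIResult:
    """Full ROI selection: automatic boundary detection with Chan-Vese
    refinement, or rasterization of a manually supplied polygon.

    Never raises: any stage failure is recorded in ``status='failed'``
    with the causal error message, so batch processing can continue.
    """
    cfg = config or ROIConfig()
    shape = image.pixels.shape
    if manual_polygon is not None:
        mask = rasterize_polygon(manual_polygon, shape)
        return ROIResult(mask=mask, status="manual")
    try:
        split = split_eyelid_image(image, cfg)
        upper = detect_upper_boundary(split.upper_subimage, cfg.min_edge_px, cfg)
        lower = detect_lower_boundary(split.lower_subimage, cfg.min_obj_px, cfg)
        lower = lower.shifted(split.split_row)
        init = build_initial_mask(upper, lower, shape)
        mask = refine_roi_chan_vese(image, init, cfg.chan_vese_iterations, cfg)
        return ROIResult(mask=mask, upper=upper, lower=lower, status="auto")
    except MeibokitError as exc:
        return ROIResult(mask=np.zeros(shape, bool), status="failed",
                         error=f"{type(exc).__name__}: {exc}")
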