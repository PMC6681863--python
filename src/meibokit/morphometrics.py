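"""Dropout area, gland morphometrics, and the polar irregularity score.

Dropout area (DOA) is the fraction of the tarsal conjunctiva without
glandular tissue::

    DOA = 100 * (N_pxROI - N_pxGL - N_pxR) / N_pxROI

where ``N_pxROI`` counts ROI pixels, ``N_pxGL`` pixels of the blurred
gland region (glands plus narrow intergland tissue, obtained by closing
the gland mask with a 20 px disk), and ``N_pxR`` specular-reflection
pixels (intensity > 200), which are excluded from the computation.

Per-gland length and width are the major/minor axes of the ellipse with
the same normalized second central moments as the gland.  Irregularity
traces the gland boundary, converts it to polar coordinates about the
mass center, normalizes the radii, and integrates (trapezoidal rule, in
degrees) the protrusion of the profile outside a mean +/- 1 SD envelope
built from a population of regular glands.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

from .config import MorphometricsConfig
from .errors import (DegenerateObjectError, InsufficientReferenceError,
                     InvalidCountsError, NonStarShapedWarning, OutsideROIError)
from .image import DEFAULT_MM_PER_PX
from .roi import ROIResult
from .segmentation import GlandLabelMap, _axis_lengths, object_orientation


# ---------------------------------------------------------------------------
# domain types


@dataclass
class DOAResult:
    """Pixel counts and the resulting dropout-area percentage."""

    n_px_roi: int
    n_px_gl: int
    n_px_r: int
    doa_percent: float


@dataclass
class GlandMetrics:
    """Morphometrics of a single gland."""

    length_px: float
    width_px: float
    length_mm: float
    width_mm: float
    orientation_deg: float
    area_px: int
    centroid_xy: tuple[float, float]
    relative_length_percent: float | None = None
    irregularity: float | None = None
    oblique_flag: bool = False          # relative length > 100%


@dataclass
class RadialProfile:
    """Normalized boundary radii at 1-degree steps around the mass center."""

    radii_norm: np.ndarray              # 360 values in (0, 1]
    mass_center: tuple[float, float]    # (x, y) in image coordinates

    angles_deg = np.arange(360)

    def __post_init__(self) -> None:
        r = np.asarray(self.radii_norm, dtype=float)
        if r.shape != (360,):
            raise ValueError("radial profile must have 360 samples")
        if not np.all(np.isfinite(r)) or np.any(r <= 0):
            raise ValueError("radii must be finite and positive")
        self.radii_norm = r


@dataclass
class IrregularityEnvelope:
    """Per-angle mean +/- 1 SD limits from a reference gland population."""

    mean_profile: np.ndarray
    sd_profile: np.ndarray
    n_reference: int

    @property
    def upper(self) -> np.ndarray:
        return self.mean_profile + self.sd_profile

    @property
    def lower(self) -> np.ndarray:
        return self.mean_profile - self.sd_profile

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["angle_deg", "mean", "sd"])
            for a in range(360):
                writer.writerow([a, f"{self.mean_profile[a]:.6f}",
                                 f"{self.sd_profile[a]:.6f}"])

    @classmethod
    def from_csv(cls, path: str | Path, n_reference: int = 0) -> "IrregularityEnvelope":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(mean_profile=data[:, 1], sd_profile=data[:, 2],
                   n_reference=n_reference)


@dataclass
class EyelidReport:
    """Per-eyelid summary: DOA, gland count, and mean morphometrics."""

    doa: DOAResult | None
    n_glands: int
    mean_length_mm: float | None
    mean_width_mm: float | None
    mean_relative_length: float | None
    eyelid_irregularity: float | None
    per_gland: list[GlandMetrics] = field(default_factory=list)
    roi_status: str = "auto"
    source_id: str = ""
    config_digest: str = ""
    error: str | None = None

    def to_dict(self) -> dict:
        d = {
            "source_id": self.source_id,
            "roi_status": self.roi_status,
            "config_digest": self.config_digest,
            "error": self.error,
            "n_glands": self.n_glands,
            "doa_percent": None if self.doa is None else self.doa.doa_percent,
            "n_px_roi": None if self.doa is None else self.doa.n_px_roi,
            "n_px_gl": None if self.doa is None else self.doa.n_px_gl,
            "n_px_r": None if self.doa is None else self.doa.n_px_r,
            "eyelid_irregularity": self.eyelid_irregularity,
            "mean_relative_length_percent": self.mean_relative_length,
            "mean_length_mm": self.mean_length_mm,
            "mean_width_mm": self.mean_width_mm,
            "per_gland": [
                {
                    "length_px": g.length_px, "width_px": g.width_px,
                    "length_mm": g.length_mm, "width_mm": g.width_mm,
                    "orientation_deg": g.orientation_deg,
                    "area_px": g.area_px,
                    "centroid_x": g.centroid_xy[0], "centroid_y": g.centroid_xy[1],
                    "relative_length_percent": g.relative_length_percent,
                    "irregularity": g.irregularity,
                    "oblique_flag": bool(g.oblique_flag),
                }
                for g in self.per_gland
            ],
        }
        return d

    def summary_row(self) -> dict:
        """One-row summary shaped like a clinical results table."""
        return {
            "source_id": self.source_id,
            "roi_status": self.roi_status,
            "doa_percent": None if self.doa is None else round(self.doa.doa_percent, 2),
            "n_glands": self.n_glands,
            "irregularity": self.eyelid_irregularity,
            "relative_length_percent": self.mean_relative_length,
            "length_mm": self.mean_length_mm,
            "width_mm": self.mean_width_mm,
            "error": self.error,
        }


# ---------------------------------------------------------------------------
# dropout area


def _disk_closing(mask: np.ndarray, radius: int) -> np.ndarray:
    """Exact binary closing with a Euclidean disk, via two distance
    transforms on a zero-padded grid (fast for large radii)."""
    r = int(radius)
    padded = np.pad(mask, r + 1)
    dilated = ndi.distance_transform_edt(~padded) <= r
    closed = ndi.distance_transform_edt(dilated) > r
    return closed[r + 1:-(r + 1), r + 1:-(r + 1)]


def estimate_gland_region(gland_mask: np.ndarray, roi: ROIResult,
                          disk_radius: int = 20,
                          method: str = "closing") -> tuple[np.ndarray, int]:
    """Blur the gland mask into the gland-plus-intergland region.

    Closing with a ``disk_radius`` px disk fills background corridors
    narrower than twice the radius — the intergland spaces — while
    leaving wide dropout open.  The result is clipped to the ROI.
    Returns the region mask and its pixel count ``N_pxGL``.

    ``method='meanfilter'`` is an alternative interpretation: a disk
    mean filter of the gland mask thresholded at 0.2 occupancy.
    """
    gm = np.asarray(gland_mask, bool)
    roi_mask = np.asarray(roi.mask, bool)
    if gm.shape != roi_mask.shape:
        raise ValueError("gland mask and ROI dimensions differ")
    if not gm.any():
        return np.zeros_like(gm), 0
    if method == "closing":
        region = _disk_closing(gm, disk_radius)
    elif method == "meanfilter":
        yy, xx = np.mgrid[-disk_radius:disk_radius + 1, -disk_radius:disk_radius + 1]
        disk = (yy**2 + xx**2 <= disk_radius**2).astype(float)
        occupancy = ndi.convolve(gm.astype(float), disk / disk.sum(), mode="constant")
        region = (occupancy > 0.2) | gm
    else:
        raise ValueError(f"unknown gland-region method {method!r}")
    region &= roi_mask
    region |= gm & roi_mask
    return region, int(region.sum())


def detect_reflections(gray: np.ndarray, roi: ROIResult,
                       threshold: int = 200) -> tuple[np.ndarray, int]:
    """Specular reflections: ROI pixels with intensity strictly greater
    than ``threshold``."""
    mask = (np.asarray(gray) > threshold) & np.asarray(roi.mask, bool)
    return mask, int(mask.sum())


def compute_doa(n_px_roi: int, n_px_gl: int, n_px_r: int) -> DOAResult:
    """Dropout-area percentage from the three pixel counts."""
    if n_px_roi <= 0:
        raise InvalidCountsError("ROI pixel count must be positive")
    if n_px_gl < 0 or n_px_r < 0 or n_px_gl + n_px_r > n_px_roi:
        raise InvalidCountsError("gland + reflection pixels exceed the ROI")
    doa = 100.0 * (n_px_roi - n_px_gl - n_px_r) / n_px_roi
    return DOAResult(int(n_px_roi), int(n_px_gl), int(n_px_r), float(doa))


# ---------------------------------------------------------------------------
# per-gland morphometrics


def gland_ellipse_metrics(pixel_set: np.ndarray,
                          mm_per_px: float = DEFAULT_MM_PER_PX) -> GlandMetrics:
    """Length/width/orientation from the moment-matched ellipse.

    Length and width are the major and minor axis lengths of the ellipse
    sharing the object's normalized second central moments; millimetre
    values use ``mm_per_px``.
    """
    mask = np.asarray(pixel_set, bool)
    ys, xs = np.nonzero(mask)
    if ys.size < 3:
        raise DegenerateObjectError("need at least 3 pixels for moment analysis")
    length, width = _axis_lengths(mask)
    if width <= 0:
        raise DegenerateObjectError("collinear pixel set has no moment ellipse")
    return GlandMetrics(
        length_px=length, width_px=width,
        length_mm=length * mm_per_px, width_mm=width * mm_per_px,
        orientation_deg=object_orientation(mask),
        area_px=int(ys.size),
        centroid_xy=(float(xs.mean()), float(ys.mean())),
    )


def eyelid_height_at(roi: ROIResult, column: float) -> float:
    """Local eyelid height at a column: distance between the fitted
    boundary curves when available, else the ROI mask's row extent."""
    x = float(column)
    if roi.upper is not None and roi.lower is not None:
        h = float(roi.lower(x) - roi.upper(x))
        if h > 0:
            return h
        raise OutsideROIError(f"boundary curves cross at column {x:.0f}")
    col = int(round(x))
    if not 0 <= col < roi.mask.shape[1]:
        raise OutsideROIError(f"column {x:.0f} outside the image")
    rows = np.nonzero(roi.mask[:, col])[0]
    if rows.size == 0:
        raise OutsideROIError(f"column {x:.0f} outside the ROI span")
    return float(rows.max() - rows.min() + 1)


def relative_length(gland: GlandMetrics, roi: ROIResult,
                    centroid_column: float | None = None) -> float:
    """Gland length as a percentage of the local eyelid height.

    Can exceed 100% for oblique glands; callers flag those cases.
    """
    x = gland.centroid_xy[0] if centroid_column is None else centroid_column
    return 100.0 * gland.length_px / eyelid_height_at(roi, x)


# ---------------------------------------------------------------------------
# polar boundary profile and irregularity


def _boundary_polygon(mask: np.ndarray) -> np.ndarray:
    """Outer boundary of a binary object as an (N, 2) array of (x, y)
    subpixel vertices (longest 0.5-level contour)."""
    contours = measure.find_contours(np.asarray(mask, float), 0.5)
    if not contours:
        raise DegenerateObjectError("object has no traceable boundary")
    contour = max(contours, key=len)
    return contour[:, ::-1]  # (row, col) -> (x, y)


def _polygon_centroid(poly: np.ndarray) -> tuple[float, float]:
    """Area centroid of a simple closed polygon (shoelace formula)."""
    x, y = poly[:, 0], poly[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = cross.sum() / 2.0
    if abs(area) < 1e-9:
        return (float(x.mean()), float(y.mean()))
    cx = ((x + xn) * cross).sum() / (6.0 * area)
    cy = ((y + yn) * cross).sum() / (6.0 * area)
    return (float(cx), float(cy))


def radial_profile(shape: np.ndarray, normalization: str = "max") -> RadialProfile:
    """Polar boundary profile of a gland at 1-degree steps.

    The boundary is traced, radii are measured from the mass center by
    exact ray/segment intersection for angles 0..359, and normalized by
    the maximum radius (``normalization='mean'`` divides by the mean
    instead).  When a ray crosses the boundary more than once the
    outermost crossing is used and :class:`NonStarShapedWarning` is
    emitted.
    """
    arr = np.asarray(shape)
    is_polygon = arr.ndim == 2 and arr.shape[1] == 2 and arr.dtype.kind == "f"
    if is_polygon:
        poly = arr.astype(float)
        mc = _polygon_centroid(poly)
    else:
        mask = arr.astype(bool)
        ys, xs = np.nonzero(mask)
        if ys.size < 3:
            raise DegenerateObjectError("object too small for a radial profile")
        mc = (float(xs.mean()), float(ys.mean()))
        poly = _boundary_polygon(mask)

    # center, flip y so angles follow the mathematical convention
    px = poly[:, 0] - mc[0]
    py = -(poly[:, 1] - mc[1])
    qx, qy = np.roll(px, -1), np.roll(py, -1)
    ex, ey = qx - px, qy - py

    ang = np.deg2rad(np.arange(360.0))
    dx, dy = np.cos(ang)[:, None], np.sin(ang)[:, None]
    cross_de = dx * ey[None, :] - dy * ex[None, :]
    cross_pe = px[None, :] * ey[None, :] - py[None, :] * ex[None, :]
    cross_pd = px[None, :] * dy - py[None, :] * dx
    with np.errstate(divide="ignore", invalid="ignore"):
        s = cross_pe / cross_de          # distance along the ray
        t = cross_pd / -cross_de         # position along the segment
    valid = np.isfinite(s) & np.isfinite(t) & (t >= 0) & (t < 1) & (s > 1e-9)
    s_masked = np.where(valid, s, -np.inf)
    radii = s_masked.max(axis=1)

    multi = ((valid & (s_masked < radii[:, None] - 0.5)).sum(axis=1) > 0)
    if multi.any():
        warnings.warn("boundary crossed more than once on some rays; "
                      "outermost crossing used", NonStarShapedWarning,
                      stacklevel=2)

    missing = ~np.isfinite(radii)
    if missing.any():  # rays through a vertex exactly: borrow neighbours
        good = np.nonzero(~missing)[0]
        if good.size == 0:
            raise DegenerateObjectError("no boundary crossings found")
        radii[missing] = np.interp(np.nonzero(missing)[0], good, radii[good],
                                   period=360)

    denom = radii.max() if normalization == "max" else radii.mean()
    return RadialProfile(radii_norm=radii / denom, mass_center=mc)


def build_envelope(profiles: list[RadialProfile]) -> IrregularityEnvelope:
    """Per-angle sample mean and SD (ddof = 1) over reference profiles."""
    if len(profiles) < 2:
        raise InsufficientReferenceError("need at least 2 reference profiles")
    stack = np.stack([p.radii_norm for p in profiles])
    return IrregularityEnvelope(mean_profile=stack.mean(axis=0),
                                sd_profile=stack.std(axis=0, ddof=1),
                                n_reference=len(profiles))


def irregularity_score(profile: np.ndarray | RadialProfile,
                       envelope: IrregularityEnvelope) -> float:
    """Area (trapezoidal rule, degree units) by which a normalized
    profile protrudes outside the mean +/- 1 SD envelope."""
    r = profile.radii_norm if isinstance(profile, RadialProfile) else np.asarray(profile, float)
    if r.shape != envelope.mean_profile.shape:
        raise ValueError("profile and envelope sampled on different angles")
    excess = np.clip(r - envelope.upper, 0.0, None)
    deficit = np.clip(envelope.lower - r, 0.0, None)
    return float(np.trapezoid(excess + deficit, dx=1.0))


# ---------------------------------------------------------------------------
# eyelid summary


def eyelid_summary(labelmap: GlandLabelMap, roi: ROIResult, gray: np.ndarray,
                   envelope: IrregularityEnvelope | None = None,
                   mm_per_px: float = DEFAULT_MM_PER_PX,
                   config: MorphometricsConfig | None = None) -> EyelidReport:
    """Assemble the per-eyelid report: DOA, per-gland morphometrics and
    irregularity, and their eyelid-level means.

    The eyelid irregularity scores the per-angle mean profile of all
    glands against the envelope; per-gland scores are also attached.
    With zero glands the DOA is still computed and the metric means are
    null.
    """
    cfg = config or MorphometricsConfig()
    gland_mask = labelmap.labels > 0
    region, n_gl = estimate_gland_region(gland_mask, roi, cfg.disk_radius_px,
                                         cfg.gland_region_method)
    refl, _ = detect_reflections(gray, roi, cfg.reflection_threshold)
    # keep the three pixel classes disjoint: reflections are excluded
    # from the gland-region count before the dropout formula
    n_gl = int((region & ~refl).sum())
    n_r = int(refl.sum())
    doa = compute_doa(roi.area_px, n_gl, n_r) if roi.area_px > 0 else None

    metrics: list[GlandMetrics] = []
    profiles: list[RadialProfile] = []
    for mask in labelmap.pixel_sets():
        try:
            g = gland_ellipse_metrics(mask, mm_per_px)
        except DegenerateObjectError:
            continue
        try:
            g.relative_length_percent = relative_length(g, roi)
            g.oblique_flag = g.relative_length_percent > 100.0
        except OutsideROIError:
            g.relative_length_percent = None
        try:
            prof = radial_profile(mask, cfg.radial_normalization)
            profiles.append(prof)
            if envelope is not None:
                g.irregularity = irregularity_score(prof, envelope)
        except DegenerateObjectError:
            pass
        metrics.append(g)

    eyelid_irr = None
    if envelope is not None and profiles:
        mean_prof = np.stack([p.radii_norm for p in profiles]).mean(axis=0)
        eyelid_irr = irregularity_score(mean_prof, envelope)

    def _mean(vals):
        vals = [v for v in vals if v is not None]
        return float(np.mean(vals)) if vals else None

    return EyelidReport(
        doa=doa,
        n_glands=len(metrics),
        mean_length_mm=_mean([g.length_mm for g in metrics]),
        mean_width_mm=_mean([g.width_mm for g in metrics]),
        mean_relative_length=_mean([g.relative_length_percent for g in metrics]),
        eyelid_irregularity=eyelid_irr,
        per_gland=metrics,
        roi_status=roi.status,
    )
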