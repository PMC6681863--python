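"""Synthetic meibography generator with full ground truth.

Emulates the structures the analysis pipeline is sensitive to: a bright
tarsal band bounded by a convex upper edge and a concave lower edge,
vertically oriented bright glands with configurable count/width/length
and lateral sinuosity, contiguous dropout regions, saturated specular
reflections, a smooth illumination gradient, fine tissue mottling, and
additive Gaussian noise.  Every layer is returned as a ground-truth mask
so each pipeline stage can be scored without clinical data.

The generator is not photorealistic: it has no depth-of-field blur, no
eyelashes, and tissue texture is stationary mottling rather than real
conjunctival microstructure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .errors import InsufficientReferenceError, ParameterError
from .image import MeibographyImage
from .roi import BoundaryCurve, fit_chebyshev_concave


@dataclass
class SyntheticParams:
    """Generation settings.  Defaults emulate a Keratograph-style frame:
    1360 x 1024 px, ~25 glands of ~20 px width spanning most of the
    exposed tarsal height."""

    width_px: int = 1360
    height_px: int = 1024
    n_glands: int = 30
    gland_width_px: float = 20.0
    gland_width_sd: float = 2.0
    gland_length_fraction: float = 0.98   # of the local eyelid height
    dropout_fraction: float = 0.0         # of the ROI area
    boundary_wave_amplitude: float = 0.1  # lateral sinuosity, fraction of width
    n_reflections: int = 2
    noise_sd: float = 5.0
    illumination_gradient: float = 20.0   # intensity span across the frame
    background_intensity: float = 30.0
    base_intensity: float = 95.0          # tarsal tissue between/without glands
    gland_amplitude: float = 75.0         # peak above the tissue base
    mottle_sd: float = 8.0                # fine tissue texture amplitude
    mottle_corr_px: float = 1.2           # texture correlation length
    seed: int = 0

    def validate(self) -> None:
        if self.width_px < 100 or self.height_px < 100:
            raise ParameterError("image must be at least 100 x 100 px")
        if self.n_glands < 0:
            raise ParameterError("n_glands must be nonnegative")
        if self.gland_width_px <= 0:
            raise ParameterError("gland width must be positive")
        for name in ("gland_length_fraction", "dropout_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1]")
        if self.noise_sd < 0 or self.n_reflections < 0:
            raise ParameterError("noise_sd and n_reflections must be nonnegative")


@dataclass
class SyntheticSample:
    """A rendered frame plus every ground-truth layer."""

    image: MeibographyImage
    truth_roi: np.ndarray
    truth_glands: np.ndarray
    truth_dropout: np.ndarray
    truth_reflections: np.ndarray
    truth_doa_percent: float
    truth_upper: BoundaryCurve
    truth_lower: BoundaryCurve
    gland_truth: list[dict]
    params: SyntheticParams


def _band_curves(p: SyntheticParams) -> tuple[np.ndarray, np.ndarray, BoundaryCurve, BoundaryCurve]:
    """Upper/lower band boundary rows per column plus fitted curve objects."""
    w, h = p.width_px, p.height_px
    cx = w / 2.0
    u = (np.arange(w) - cx) / (w / 2.0)
    # geometry scales with the frame; reference values target a ~500 px
    # central band height in a 1024-row frame
    # the exposed tarsus narrows toward the canthi: ~500 px high at the
    # center of a 1024-row frame, ~190 px at the lateral edges
    top_apex = 0.254 * h
    bot_apex = 0.742 * h
    upper_rows = top_apex + 0.15 * h * u**2
    lower_rows = bot_apex - 0.09 * h * u**2 - 0.06 * h * u**4
    cols = np.arange(w, dtype=float)
    c_up = np.polynomial.polynomial.polyfit(cols, upper_rows, 2)
    upper = BoundaryCurve("quadratic", c_up, (0.0, float(w - 1)))
    lower = fit_chebyshev_concave(cols, lower_rows)
    return upper_rows, lower_rows, upper, lower


def _pick_dropout_columns(col_area: np.ndarray, target: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Choose contiguous column spans whose ROI area sums to ``target``.

    Dropout appears clinically as contiguous regions of missing glands,
    so whole-column spans are removed rather than scattered pixels.
    """
    w = col_area.size
    chosen = np.zeros(w, bool)
    remaining = target
    guard = 0
    while remaining > col_area.max() and guard < 20:
        guard += 1
        start = int(rng.integers(0, w))
        x = start
        # grow rightward, then leftward if the right edge is reached
        while remaining > 0 and x < w:
            if not chosen[x]:
                chosen[x] = True
                remaining -= col_area[x]
            x += 1
            if chosen[x - 1] and x < w and chosen[x]:
                break  # merged into an existing span; stop this span
        x = start - 1
        while remaining > 0 and x >= 0 and not chosen[x]:
            chosen[x] = True
            remaining -= col_area[x]
            x -= 1
    return chosen


def generate_meibography(params: SyntheticParams | None = None, **overrides) -> SyntheticSample:
    """Render a synthetic meibography frame with ground truth.

    A fixed seed yields byte-identical output: all random draws come
    from a single ``default_rng(seed)`` stream consumed in a fixed
    order (gland geometry, dropout placement, mottle, noise,
    reflections).
    """
    p = params or SyntheticParams()
    if overrides:
        p = SyntheticParams(**{**p.__dict__, **overrides})
    p.validate()
    rng = np.random.default_rng(p.seed)
    w, h = p.width_px, p.height_px

    upper_rows, lower_rows, upper_curve, lower_curve = _band_curves(p)
    rows = np.arange(h)[:, None].astype(float)
    band = (rows >= upper_rows[None, :]) & (rows < lower_rows[None, :])
    height_per_col = np.maximum(lower_rows - upper_rows, 0.0)

    # --- glands -----------------------------------------------------------
    glands = np.zeros((h, w), bool)
    bump = np.zeros((h, w), float)
    gland_truth: list[dict] = []
    if p.n_glands > 0:
        span = 0.47 * w
        centers = w / 2.0 + np.linspace(-span, span, p.n_glands)
        centers = centers + rng.normal(0.0, 0.06 * (2 * span / max(p.n_glands, 1)),
                                       p.n_glands)
        widths = np.clip(rng.normal(p.gland_width_px, p.gland_width_sd, p.n_glands),
                         0.4 * p.gland_width_px, 2.0 * p.gland_width_px)
        phases = rng.uniform(0, 2 * np.pi, p.n_glands)
        wavelens = rng.uniform(200.0, 400.0, p.n_glands)
        yy = np.arange(h, dtype=float)
        for ci, wi, ph, lam in zip(centers, widths, phases, wavelens):
            margin = 0.5 * (1.0 - p.gland_length_fraction)
            xi = int(round(ci))
            if not 0 <= xi < w:
                continue
            top = upper_rows[xi] + margin * height_per_col[xi]
            bot = lower_rows[xi] - margin * height_per_col[xi]
            amp = p.boundary_wave_amplitude * wi
            cpath = ci + amp * np.sin(2 * np.pi * yy / lam + ph)
            half = wi / 2.0
            lo = max(int(ci - half - amp - 3), 0)
            hi = min(int(ci + half + amp + 4), w)
            dx = np.abs(np.arange(lo, hi)[None, :] - cpath[:, None])
            inside_rows = (yy >= top) & (yy < bot)
            # super-Gaussian cross profile: near-flat top, fast skirts
            prof = np.exp(-np.log(2) * (dx / half) ** 4)
            taper = np.clip(np.minimum(yy - top, bot - yy) / 6.0, 0, 1)
            bump[:, lo:hi] += p.gland_amplitude * prof * (inside_rows * taper)[:, None]
            gmask = (dx <= half) & inside_rows[:, None]
            glands[:, lo:hi] |= gmask
            gland_truth.append({
                "center_col": float(ci), "width_px": float(wi),
                "top_row": float(top), "bottom_row": float(bot),
                "length_px": float(bot - top),
            })
    glands &= band

    # --- dropout ----------------------------------------------------------
    dropout = np.zeros((h, w), bool)
    if p.dropout_fraction > 0:
        col_area = height_per_col.copy()
        target = p.dropout_fraction * col_area.sum()
        cols_sel = _pick_dropout_columns(col_area, target, rng)
        dropout = band & cols_sel[None, :]
        bump[:, cols_sel] = 0.0
        glands[:, cols_sel] = False

    # --- compose intensities ---------------------------------------------
    # vascular-scale micro-texture: visible to a local-std transform but
    # carrying almost no energy in the gland-scale band-pass
    mottle = rng.normal(0.0, 1.0, (h, w))
    mottle = ndi.gaussian_filter(mottle, p.mottle_corr_px)
    sd = mottle.std()
    if sd > 0:
        mottle *= p.mottle_sd / sd
    img = np.full((h, w), p.background_intensity, float)
    img[band] = p.base_intensity + mottle[band]
    img += bump
    img += p.illumination_gradient * (np.arange(w)[None, :] / max(w - 1, 1) - 0.5)
    img += rng.normal(0.0, p.noise_sd, (h, w))

    # --- specular reflections (painted last so they stay saturated) ------
    reflections = np.zeros((h, w), bool)
    healthy = band & ~dropout
    if p.n_reflections > 0 and healthy.any():
        ys, xs = np.nonzero(healthy)
        for _ in range(p.n_reflections):
            k = int(rng.integers(0, ys.size))
            cy, cxr = ys[k], xs[k]
            ry = float(rng.uniform(5, 14))
            rx = float(rng.uniform(8, 20))
            yy2 = np.arange(h)[:, None]
            xx2 = np.arange(w)[None, :]
            blob = (((yy2 - cy) / ry) ** 2 + ((xx2 - cxr) / rx) ** 2) <= 1.0
            reflections |= blob & healthy
        img[reflections] = 235.0 + 20.0 * rng.random(int(reflections.sum()))

    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)

    n_roi = int(band.sum())
    n_drop = int(dropout.sum())
    truth_doa = 100.0 * n_drop / n_roi if n_roi else 0.0
    return SyntheticSample(
        image=MeibographyImage(pixels=pixels, source_id=f"synthetic-{p.seed}"),
        truth_roi=band, truth_glands=glands, truth_dropout=dropout,
        truth_reflections=reflections, truth_doa_percent=truth_doa,
        truth_upper=upper_curve, truth_lower=lower_curve,
        gland_truth=gland_truth, params=p,
    )


def generate_gland_shape(length_px: float, width_px: float,
                         wave_amplitude: float = 0.0, n_lobes: int = 6,
                         seed: int = 0) -> np.ndarray:
    """Binary gland silhouette: a vertical ellipse whose boundary radius
    is modulated by ``wave_amplitude * sin(n_lobes * theta + phase)``.

    ``wave_amplitude = 0`` yields a smooth "regular" gland; positive
    amplitudes produce the lobed, irregular outlines used to exercise
    the irregularity score.
    """
    if not length_px >= width_px > 0:
        raise ParameterError("require length_px >= width_px > 0")
    if wave_amplitude < 0 or wave_amplitude >= 1:
        raise ParameterError("wave_amplitude must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0, 2 * np.pi)
    a = length_px / 2.0   # vertical semi-axis
    b = width_px / 2.0
    pad = 3
    hh = int(np.ceil(2 * a * (1 + wave_amplitude))) + 2 * pad
    ww = int(np.ceil(2 * b * (1 + wave_amplitude))) + 2 * pad
    cy, cx = hh / 2.0, ww / 2.0
    yy = np.arange(hh)[:, None] - cy
    xx = np.arange(ww)[None, :] - cx
    r = np.hypot(xx, yy)
    theta = np.arctan2(yy, xx)
    r_ell = 1.0 / np.sqrt((np.cos(theta) / b) ** 2 + (np.sin(theta) / a) ** 2)
    r_bound = r_ell * (1.0 + wave_amplitude * np.sin(n_lobes * theta + phase))
    return r <= r_bound


def build_reference_envelope(n: int = 200, seed: int = 0):
    """Envelope of normalized polar profiles from ``n`` regular glands.

    The reference population is synthetic: smooth (amplitude-0) gland
    silhouettes with natural length/width variation, standing in for a
    clinically curated set of regular glands.  Returns an
    :class:`~meibokit.morphometrics.IrregularityEnvelope`.
    """
    from .morphometrics import build_envelope, radial_profile

    if n < 2:
        raise InsufficientReferenceError("need at least 2 reference glands")
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(n):
        length = float(np.clip(rng.normal(400.0, 50.0), 200.0, 600.0))
        width = float(np.clip(rng.normal(22.0, 4.0), 10.0, 40.0))
        shape = generate_gland_shape(length, width, 0.0, seed=seed * 100003 + i)
        profiles.append(radial_profile(shape))
    return build_envelope(profiles)
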