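"""Batch-mode orchestration: image -> report, directory -> table.

Mirrors the clinical workflow: every image is processed without user
input; an ROI failure produces a failed report row instead of aborting
the batch, and the batch summary accounts for automatic successes,
manual adjustments, and unrecoverable failures.
"""

from __future__ import annotations

import functools
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .errors import EmptyDirectoryError
from .image import MeibographyImage, load_image, read_polygon, save_image
from .morphometrics import EyelidReport, IrregularityEnvelope, eyelid_summary
from .roi import ROIResult, select_roi
from .segmentation import (GlandLabelMap, bandpass_dog, fragment_compound_glands,
                           label_glands, segment_glands, suppress_reflections)

logger = logging.getLogger("meibokit")

IMAGE_SUFFIXES = {".png", ".bmp"}


@functools.lru_cache(maxsize=1)
def default_envelope() -> IrregularityEnvelope:
    """The bundled irregularity envelope: 200 synthetic regular glands.

    This ships in place of a clinically curated reference population;
    rebuild with :func:`meibokit.synthetic.build_reference_envelope` or
    :func:`meibokit.morphometrics.build_envelope` from your own glands
    for clinical use.
    """
    from .synthetic import build_reference_envelope

    return build_reference_envelope(n=200, seed=20190802)


def analyze(image: MeibographyImage,
            config: AnalysisConfig | None = None,
            manual_polygon: np.ndarray | None = None,
            envelope: IrregularityEnvelope | None = None,
            roi: ROIResult | None = None) -> EyelidReport:
    """Run the full pipeline on an in-memory image.

    ROI selection (automatic, or rasterized from ``manual_polygon``, or
    injected via ``roi``) -> band-pass -> adaptive segmentation ->
    fragmentation -> morphometrics.  An ROI failure yields a report with
    ``roi_status='failed'`` and null metrics rather than an exception.
    """
    cfg = config or AnalysisConfig()
    if envelope is None:
        envelope = default_envelope()
    if roi is None:
        roi = select_roi(image, manual_polygon, cfg.roi)
    if roi.status == "failed" or roi.area_px == 0:
        report = EyelidReport(doa=None, n_glands=0, mean_length_mm=None,
                              mean_width_mm=None, mean_relative_length=None,
                              eyelid_irregularity=None, roi_status="failed",
                              error=roi.error or "empty ROI")
    else:
        # specular highlights would sever the glands they sit on during
        # thresholding; suppress them for segmentation only (reflection
        # pixels are still counted from the original image in the DOA)
        degleamed = suppress_reflections(image.pixels,
                                         cfg.morphometrics.reflection_threshold)
        bp = bandpass_dog(degleamed, cfg.segmentation.sigma_low_px,
                          cfg.segmentation.sigma_high_px, mask=roi.mask)
        gmask = segment_glands(bp, roi, config=cfg.segmentation)
        labels = label_glands(gmask)
        labels = fragment_compound_glands(labels, cfg.fragmentation)
        report = eyelid_summary(labels, roi, image.pixels, envelope,
                                cfg.morphometrics.mm_per_px, cfg.morphometrics)
    report.source_id = image.source_id
    report.config_digest = cfg.digest()
    return report


def analyze_image(path: str | Path,
                  config: AnalysisConfig | None = None,
                  manual_roi: str | Path | None = None,
                  envelope: IrregularityEnvelope | None = None) -> EyelidReport:
    """Load a BMP/PNG meibograph and analyze it.

    ``manual_roi`` names a plain-text polygon file of ``x,y`` vertex
    lines used instead of automatic ROI detection.
    """
    cfg = config or AnalysisConfig()
    image = load_image(path, cfg.morphometrics.mm_per_px)
    polygon = read_polygon(manual_roi) if manual_roi is not None else None
    return analyze(image, cfg, polygon, envelope)


def failure_summary(n_total: int, n_manual: int, n_unrecoverable: int = 0) -> dict:
    """Batch accounting: manual-adjustment rate and implementation
    success rate (images fully analyzed without an unrecoverable
    preprocessing failure), both as percentages of the batch."""
    if n_total <= 0:
        raise ValueError("empty batch")
    return {
        "n_total": int(n_total),
        "n_manual": int(n_manual),
        "n_unrecoverable": int(n_unrecoverable),
        "manual_adjustment_rate_percent": 100.0 * n_manual / n_total,
        "implementation_success_rate_percent":
            100.0 * (n_total - n_unrecoverable) / n_total,
    }


def batch_analyze(directory: str | Path,
                  config: AnalysisConfig | None = None,
                  envelope: IrregularityEnvelope | None = None,
                  ) -> tuple[pd.DataFrame, dict]:
    """Analyze every BMP/PNG in a directory.

    Returns one summary row per image (processing continues past
    failures, which are flagged with their cause) and the batch failure
    accounting.  Rows depend only on their own image and the config, so
    the table is reproducible and order-independent.
    """
    cfg = config or AnalysisConfig()
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(str(directory))
    paths = sorted(p for p in directory.iterdir()
                   if p.suffix.lower() in IMAGE_SUFFIXES)
    if not paths:
        raise EmptyDirectoryError(f"no BMP/PNG images in {directory}")
    if envelope is None:
        envelope = default_envelope()

    rows = []
    n_manual = n_failed = 0
    for path in paths:
        manual = path.with_suffix(".roi.txt")
        report = analyze_image(path, cfg,
                               manual if manual.exists() else None, envelope)
        if report.roi_status == "manual":
            n_manual += 1
        elif report.roi_status == "failed":
            n_failed += 1
            logger.warning("ROI failed for %s: %s", path.name, report.error)
        rows.append(report.summary_row())

    summary = failure_summary(len(paths), n_manual, n_failed)
    logger.info("batch: %d images, %d auto, %d manual, %d failed (%.2f%% "
                "implementation success)", len(paths),
                len(paths) - n_manual - n_failed, n_manual, n_failed,
                summary["implementation_success_rate_percent"])
    return pd.DataFrame(rows), summary


def write_report(report: EyelidReport, path: str | Path) -> None:
    """Serialize a report as JSON (full) or CSV (one summary row)."""
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(report.to_dict(), indent=2))
    elif path.suffix == ".csv":
        pd.DataFrame([report.summary_row()]).to_csv(path, index=False)
    else:
        raise ValueError("report path must end in .json or .csv")


def write_labelmap(labels: GlandLabelMap | np.ndarray, path: str | Path) -> None:
    """Write a gland label map as a 16-bit PNG."""
    arr = labels.labels if isinstance(labels, GlandLabelMap) else labels
    save_image(path, np.asarray(arr).astype(np.uint16))


def render_overlay(image: MeibographyImage, roi: ROIResult,
                   labels: GlandLabelMap, path: str | Path) -> None:
    """Review overlay: ROI outline, numbered glands, dropout shading."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from .config import MorphometricsConfig
    from .morphometrics import estimate_gland_region

    cfg = MorphometricsConfig()
    region, _ = estimate_gland_region(labels.labels > 0, roi, cfg.disk_radius_px)
    dropout = roi.mask & ~region

    fig, ax = plt.subplots(figsize=(10, 7.5))
    ax.imshow(image.pixels, cmap="gray", vmin=0, vmax=255)
    ax.contour(roi.mask, levels=[0.5], colors="deepskyblue", linewidths=1.2)
    shade = np.zeros((*dropout.shape, 4))
    shade[dropout] = (1.0, 0.2, 0.2, 0.35)
    ax.imshow(shade)
    for i, mask in enumerate(labels.pixel_sets(), start=1):
        ys, xs = np.nonzero(mask)
        if ys.size:
            ax.contour(mask, levels=[0.5], colors="yellow", linewidths=0.6)
            ax.text(xs.mean(), ys.mean(), str(i), color="yellow", fontsize=7,
                    ha="center", va="center")
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=130)
    plt.close(fig)
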