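"""Analysis configuration.

All tunable numeric parameters of the pipeline live here with the
device-calibrated defaults (Keratograph 5M, 1360 x 1024 px frames).  The
config round-trips losslessly through YAML so a batch run can be
reproduced from its config file alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .image import DEFAULT_MM_PER_PX


@dataclass
class ROIConfig:
    """Region-of-interest detection parameters."""

    split_smooth_rows: int = 31        # moving-average window for the row-mean profile
    split_peak_margin: float = 5.0     # intensity units above the profile median
    erosion_radius_px: int = 10        # disk erosion before upper-boundary detection
    sharpen_sigma_px: float = 30.0     # Gaussian low-pass used for unsharp masking
    sharpen_amount: float = 1.0
    median_size_px: int = 40           # square median window on the upper subimage
    min_edge_px: int = 500             # smallest edge component kept (pixel count)
    entropy_size_px: int = 9           # local-entropy neighbourhood on the lower subimage
    entropy_presmooth_sigma: float = 1.5  # denoise before the entropy filter
    peak_prominence_frac: float = 0.10  # of the column's entropy dynamic range
    dilate_rect: tuple[int, int] = (3, 12)   # rows x cols, horizontal rectangle
    close_radius_px: int = 6
    min_obj_px: int = 500
    chan_vese_iterations: int = 100
    chan_vese_smoothing: int = 2
    chan_vese_tol: float = 0.001       # fractional mask change declaring convergence
    chan_vese_checkpoint: int = 10     # iterations between convergence checks
    chan_vese_downscale: int = 2       # evolve the contour on a decimated grid
    std_filter_size_px: int = 9        # local-std transform fed to Chan-Vese


@dataclass
class SegmentationConfig:
    """Gland segmentation parameters."""

    sigma_low_px: float = 2.0          # narrow Gaussian of the band-pass pair
    sigma_high_px: float = 30.0        # wide Gaussian of the band-pass pair
    adaptive_window_px: int = 35       # local-mean threshold window
    sensitivity: float = 0.8           # -> 1 thresholds more pixels as foreground
    median_shape: tuple[int, int] = (5, 3)  # rows x cols smoothing window
    min_gland_px: int = 800
    orientation_min_deg: float = 40.0
    orientation_max_deg: float = 140.0


@dataclass
class FragmentationParams:
    """Thresholds gating the fork-splitting of compound gland labels."""

    nl_th: int = 1           # max tolerated significant column-profile minima
    o_th: float = 50.0       # degrees off vertical triggering a split attempt
    no_th: int = 1           # minimum fragment count for an accepted split
    o2_th: float = 50.0      # max degrees off vertical for every fragment
    r_th: float = 3.0        # minimum fragment length/width ratio
    min_prominence_frac: float = 0.20  # of the column profile maximum

    def __post_init__(self) -> None:
        if min(self.nl_th, self.o_th, self.no_th, self.o2_th, self.r_th) <= 0:
            raise ValueError("all fragmentation thresholds must be positive")


@dataclass
class MorphometricsConfig:
    """Dropout-area and gland-shape parameters."""

    disk_radius_px: int = 20           # closing radius separating intergland from dropout
    reflection_threshold: int = 200    # strict lower bound for specular pixels
    gland_region_method: str = "closing"  # or "meanfilter"
    radial_normalization: str = "max"  # or "mean"
    mm_per_px: float = DEFAULT_MM_PER_PX


@dataclass
class AnalysisConfig:
    """Top-level configuration aggregating every stage."""

    roi: ROIConfig = field(default_factory=ROIConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    fragmentation: FragmentationParams = field(default_factory=FragmentationParams)
    morphometrics: MorphometricsConfig = field(default_factory=MorphometricsConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        kwargs = {}
        for f, sub_cls in (("roi", ROIConfig), ("segmentation", SegmentationConfig),
                           ("fragmentation", FragmentationParams),
                           ("morphometrics", MorphometricsConfig)):
            sub = dict(data.get(f, {}))
            for sf in fields(sub_cls):
                if sf.name in sub and isinstance(sub[sf.name], list):
                    sub[sf.name] = tuple(sub[sf.name])
            kwargs[f] = sub_cls(**sub)
        return cls(**kwargs)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(_listify(self.to_dict()), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "AnalysisConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(yaml.safe_load(text))

    def digest(self) -> str:
        """Short provenance hash carried into every report."""
        blob = json.dumps(_listify(self.to_dict()), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    return obj
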