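"""Ground-cover estimators and plot segmentation.

Four per-plot estimates of canopy ground cover:

* ``GC_RGB`` — fraction of image pixels whose greenness index
  VI = (Green - Red) / (Green + Red) exceeds 0, averaged over the plot's
  images;
* ``GC_LIDAR_RR`` — fraction of LiDAR returns with red-reflectance intensity
  strictly below 5 (dark returns are green tissue, bright returns soil);
* ``GC_LIDAR_HT`` — fraction of LiDAR returns strictly higher than 10 cm
  above local ground;
* ``NDVI`` — plot mean of the active sensor's readings (not a cover fraction,
  but an equally usable genotype-discrimination signal).

Segmentation excludes the outermost sown rows and a 0.5 m buffer at each plot
end, so a 6 m plot yields an approximately 1.25 m x 5 m sampling region. All
classification thresholds are strict inequalities; boundary values (VI = 0,
intensity = 5, height = 10 cm) count as non-vegetation / soil / ground.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import EstimatorConfig
from .errors import IntegrityError, InvalidGeometryError, MissingDataError
from .sensors import LidarScan, NdviStream, SensorBundle
from .trial import TrialDesign

METHOD_NDVI = "NDVI"
METHOD_RGB = "GC_RGB"
METHOD_LIDAR_RR = "GC_LIDAR_RR"
METHOD_LIDAR_HT = "GC_LIDAR_HT"
METHODS = (METHOD_NDVI, METHOD_RGB, METHOD_LIDAR_RR, METHOD_LIDAR_HT)


@dataclass(frozen=True)
class SamplingRegion:
    """Half-open along-track x cross-track rectangle, metres."""

    along_start: float
    along_end: float
    cross_start: float
    cross_end: float

    def __post_init__(self):
        if self.along_end <= self.along_start or self.cross_end <= self.cross_start:
            raise InvalidGeometryError("region intervals must have positive length")

    @property
    def along_length(self) -> float:
        return self.along_end - self.along_start

    @property
    def cross_length(self) -> float:
        return self.cross_end - self.cross_start

    def contains(self, along, cross=None):
        """Membership mask; intervals are half-open [start, end)."""
        along = np.asarray(along, dtype=float)
        m = (along >= self.along_start) & (along < self.along_end)
        if cross is not None:
            cross = np.asarray(cross, dtype=float)
            m &= (cross >= self.cross_start) & (cross < self.cross_end)
        return m


def vegetation_index(red, green):
    """Greenness index VI = (green - red) / (green + red).

    Vectorized; zero-denominator pixels (red = green = 0) return 0, which the
    strict VI > 0 rule classifies as non-vegetation (black pixels are not
    green canopy). Negative channel values are a domain error.
    """
    red = np.asarray(red, dtype=float)
    green = np.asarray(green, dtype=float)
    if np.any(red < 0) or np.any(green < 0):
        raise ValueError("channel values must be non-negative")
    denom = green + red
    with np.errstate(invalid="ignore", divide="ignore"):
        vi = np.where(denom > 0, (green - red) / np.where(denom > 0, denom, 1.0), 0.0)
    if np.isscalar(red) or red.ndim == 0:
        return float(vi)
    return vi


def gc_rgb_image(image: np.ndarray, cfg: EstimatorConfig | None = None) -> float:
    """Fraction of pixels with VI strictly above the threshold (default 0)."""
    cfg = cfg or EstimatorConfig()
    img = np.asarray(image)
    if img.size == 0 or img.ndim != 3 or img.shape[2] < 3:
        raise MissingDataError("expected a non-empty H x W x 3 image")
    vi = vegetation_index(img[..., 0], img[..., 1])  # blue channel ignored
    return float(np.mean(vi > cfg.vi_threshold))


def gc_rgb_plot(images, cfg: EstimatorConfig | None = None) -> float:
    """Unweighted mean of per-image green-pixel fractions for one plot."""
    if len(images) == 0:
        raise MissingDataError("no images assigned to plot")
    return float(np.mean([gc_rgb_image(im, cfg) for im in images]))


def gc_lidar_rr(scan: LidarScan, cfg: EstimatorConfig | None = None) -> float:
    """Fraction of returns with intensity strictly below the threshold (5)."""
    cfg = cfg or EstimatorConfig()
    if len(scan) == 0:
        raise MissingDataError("empty LiDAR scan")
    return float(np.mean(scan.intensity < cfg.rr_threshold))


def normalize_heights(scan: LidarScan, min_points: int = 50) -> LidarScan:
    """Re-reference z to local ground level, floored at 0.

    Ground is taken as the 5th percentile of raw z inside the region — robust
    to the vegetated fraction as long as some returns hit soil. Below
    ``min_points`` returns the percentile is unreliable; a warning is issued
    and the minimum z is used instead.
    """
    import warnings

    if len(scan) < min_points:
        warnings.warn(
            f"only {len(scan)} points; using min-z ground reference",
            stacklevel=2,
        )
        ground = float(np.min(scan.z))
    else:
        ground = float(np.percentile(scan.z, 5.0))
    pts = scan.points.copy()
    pts[:, 2] = np.maximum(pts[:, 2] - ground, 0.0)
    return LidarScan(pts)


def gc_lidar_ht(scan: LidarScan, cfg: EstimatorConfig | None = None) -> float:
    """Fraction of returns strictly higher than the height threshold (10 cm).

    ``scan`` is expected to be ground-normalized (see ``normalize_heights``).
    """
    cfg = cfg or EstimatorConfig()
    if len(scan) == 0:
        raise MissingDataError("empty LiDAR scan")
    return float(np.mean(scan.z > cfg.ht_threshold))


def ndvi_plot_mean(stream: NdviStream) -> float:
    """Arithmetic mean of the NDVI readings assigned to a plot."""
    if len(stream) == 0:
        raise MissingDataError("empty NDVI stream")
    return float(np.mean(stream.values))


def sampling_region(
    design: TrialDesign, plot: int, cfg: EstimatorConfig | None = None
) -> SamplingRegion:
    """Sampling region of one plot after edge exclusion.

    Along track: [end_buffer, plot_length - end_buffer). Cross track: the
    inner ``n_rows_per_plot - 2`` sown rows plus half a row spacing on each
    side, centred on the plot axis. With 7 rows at 0.25 m this gives 1.25 m.
    """
    cfg = cfg or EstimatorConfig()
    if (design.plots["plot"] == plot).sum() == 0:
        raise KeyError(f"plot {plot} not in design")
    L = design.plot_length
    if 2 * cfg.end_buffer >= L:
        raise InvalidGeometryError(
            f"end buffers ({cfg.end_buffer} m each) exceed plot length {L} m"
        )
    if cfg.exclude_outer_rows:
        n_inner = design.n_rows_per_plot - 2
        if n_inner < 1:
            raise InvalidGeometryError("too few sown rows to exclude the outer pair")
    else:
        n_inner = design.n_rows_per_plot
    half_width = (n_inner - 1) * design.row_spacing / 2 + design.row_spacing / 2
    return SamplingRegion(
        along_start=cfg.end_buffer,
        along_end=L - cfg.end_buffer,
        cross_start=-half_width,
        cross_end=half_width,
    )


def assign_to_plot(positions, region: SamplingRegion) -> np.ndarray:
    """Indices of along-track positions falling in [start, end)."""
    positions = np.asarray(positions, dtype=float)
    return np.flatnonzero(
        (positions >= region.along_start) & (positions < region.along_end)
    )


def estimate_bundle(
    bundle: SensorBundle,
    design: TrialDesign,
    cfg: EstimatorConfig | None = None,
) -> list[dict]:
    """Per-method GC rows for one plot/event bundle.

    Missing sensors produce flagged rows (value NaN, n_samples 0) rather than
    silently dropping or zeroing the estimate — downstream statistics must be
    able to distinguish absent data from zero cover.
    """
    cfg = cfg or EstimatorConfig()
    region = sampling_region(design, bundle.plot, cfg)
    rows = []

    def row(method, value, n):
        rows.append(
            {
                "plot": bundle.plot,
                "event_id": bundle.event_id,
                "method": method,
                "value": value,
                "n_samples": n,
            }
        )

    # NDVI
    if bundle.ndvi is not None and len(bundle.ndvi) > 0:
        idx = assign_to_plot(bundle.ndvi.positions, region)
        if len(idx):
            row(METHOD_NDVI, ndvi_plot_mean(NdviStream(bundle.ndvi.readings[idx])),
                len(idx))
        else:
            row(METHOD_NDVI, np.nan, 0)
    else:
        row(METHOD_NDVI, np.nan, 0)

    # RGB
    if bundle.images:
        idx = assign_to_plot(np.asarray(bundle.image_positions), region)
        if len(idx):
            imgs = [bundle.images[i] for i in idx]
            row(METHOD_RGB, gc_rgb_plot(imgs, cfg), len(idx))
        else:
            row(METHOD_RGB, np.nan, 0)
    else:
        row(METHOD_RGB, np.nan, 0)

    # LiDAR (both estimators share the segmented scan)
    if bundle.scan is not None and len(bundle.scan) > 0:
        mask = region.contains(bundle.scan.along, bundle.scan.cross)
        if mask.any():
            seg = LidarScan(bundle.scan.points[mask])
            row(METHOD_LIDAR_RR, gc_lidar_rr(seg, cfg), len(seg))
            row(METHOD_LIDAR_HT, gc_lidar_ht(normalize_heights(seg), cfg), len(seg))
        else:
            row(METHOD_LIDAR_RR, np.nan, 0)
            row(METHOD_LIDAR_HT, np.nan, 0)
    else:
        row(METHOD_LIDAR_RR, np.nan, 0)
        row(METHOD_LIDAR_HT, np.nan, 0)

    return rows


def build_gc_table(
    bundles,
    design: TrialDesign,
    cfg: EstimatorConfig | None = None,
) -> pd.DataFrame:
    """Long-format GC table: one row per (plot, event, method).

    Columns: plot, event_id, method, value, n_samples. ``value`` is NaN with
    ``n_samples`` 0 when a sensor stream was missing for that plot/event.
    """
    cfg = cfg or EstimatorConfig()
    rows = []
    for b in bundles:
        rows.extend(estimate_bundle(b, design, cfg))
    table = pd.DataFrame(rows, columns=["plot", "event_id", "method", "value",
                                        "n_samples"])
    dup = table.duplicated(subset=["plot", "event_id", "method"])
    if dup.any():
        first = table.loc[dup, ["plot", "event_id", "method"]].iloc[0].tolist()
        raise IntegrityError(f"duplicate (plot, event, method) row: {first}")
    return table.sort_values(["event_id", "plot", "method"]).reset_index(drop=True)
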