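"""Simulated sensor streams: RGB camera, LiDAR scanner, active NDVI.

Each generator renders one plot at one sampling event from the plot's latent
ground cover. The physical behaviours the package studies are built in here:

* the **camera** is passive — its green/soil pixel contrast scales with a
  saturating exposure function of solar radiation, so at very low light the
  per-pixel greenness classification degrades toward a coin flip (and a
  per-image white-balance jitter makes dim-light images unstable between
  frames, as auto-exposure cameras are);
* the **LiDAR** returns bimodal red-reflectance intensity (dark vegetation vs
  bright soil) plus canopy-height structure; dew on leaves shifts vegetation
  intensity upward across the classification threshold, depressing the
  reflectance-based GC estimate while leaving heights untouched;
* the **active NDVI** carries its own light source and by construction
  ignores both solar radiation and dew.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SensorConfig
from .errors import UnknownEventError
from .schedule import SamplingEvent
from .trial import GroundTruth, TrialDesign

NDVI_MAX = 0.99  # the instrument reports values in [0, 0.99]


@dataclass
class LidarScan:
    """Point cloud: columns along_track (m), cross_track (m), z (m), intensity."""

    points: np.ndarray  # (n, 4) float array

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 4:
            raise ValueError("LidarScan expects an (n, 4) array")
        if len(self.points) < 1:
            raise ValueError("LidarScan needs at least one point")

    @property
    def along(self):
        return self.points[:, 0]

    @property
    def cross(self):
        return self.points[:, 1]

    @property
    def z(self):
        return self.points[:, 2]

    @property
    def intensity(self):
        return self.points[:, 3]

    def __len__(self):
        return len(self.points)


@dataclass
class NdviStream:
    """NDVI readings with along-track positions; values in [0, 0.99]."""

    readings: np.ndarray  # (n, 2): position (m), ndvi

    def __post_init__(self):
        self.readings = np.asarray(self.readings, dtype=float)
        if self.readings.ndim != 2 or self.readings.shape[1] != 2:
            raise ValueError("NdviStream expects an (n, 2) array")

    @property
    def positions(self):
        return self.readings[:, 0]

    @property
    def values(self):
        return self.readings[:, 1]

    def __len__(self):
        return len(self.readings)


@dataclass
class SensorBundle:
    """All three sensor streams for one plot at one sampling event."""

    plot: int
    event_id: int
    image_positions: list[float] = field(default_factory=list)
    images: list[np.ndarray] = field(default_factory=list)  # uint8 (H, W, 3)
    scan: LidarScan | None = None
    ndvi: NdviStream | None = None


def subseed(master_seed: int, plot: int, event_id: int) -> np.random.SeedSequence:
    """Stable per-plot per-event seed derived from the master seed."""
    return np.random.SeedSequence([int(master_seed), int(plot), int(event_id)])


def exposure_factor(solar_radiation: float, halflight: float = 0.2) -> float:
    """Saturating camera exposure in [0, 1): L^2 / (L^2 + h^2)."""
    L = float(solar_radiation)
    return L * L / (L * L + halflight * halflight)


def _check_gc(true_gc: float) -> float:
    gc = float(true_gc)
    if not 0.0 < gc < 1.0:
        raise ValueError(f"true_gc must lie strictly in (0, 1), got {gc}")
    return gc


def simulate_rgb_images(
    true_gc: float,
    event: SamplingEvent,
    n_images: int,
    image_size: tuple[int, int] | None = None,
    seed=0,
    cfg: SensorConfig | None = None,
) -> list[np.ndarray]:
    """Render ``n_images`` independent plot images as uint8 (H, W, 3) arrays.

    Each pixel is vegetation with probability ``true_gc``. The rendered
    channel is ``dark_level + base * exposure(radiation) + noise`` clipped to
    [0, 255]; at adequate light the green-pixel fraction concentrates near
    ``true_gc``, while at zero radiation the green-red contrast vanishes and
    classifying a pixel is close to a coin flip.
    """
    gc = _check_gc(true_gc)
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    cfg = cfg or SensorConfig()
    H, W = image_size if image_size is not None else (cfg.image_height, cfg.image_width)
    rng = np.random.default_rng(seed)
    expo = exposure_factor(event.solar_radiation, cfg.exposure_halflight)
    veg = np.array(cfg.veg_rgb)
    soil = np.array(cfg.soil_rgb)

    images = []
    for _ in range(n_images):
        is_veg = rng.random((H, W)) < gc
        base = np.where(is_veg[..., None], veg, soil)  # (H, W, 3)
        wb = rng.normal(0.0, cfg.wb_noise_sd)  # per-image green-red balance drift
        px = cfg.dark_level + base * expo
        px[..., 1] += wb
        px = px + rng.normal(0.0, cfg.channel_noise_sd, px.shape)
        images.append(np.clip(np.rint(px), 0, 255).astype(np.uint8))
    return images


def simulate_lidar_scan(
    true_gc: float,
    canopy_height: float,
    event: SamplingEvent,
    n_points: int,
    seed=0,
    cfg: SensorConfig | None = None,
    along_extent: tuple[float, float] = (0.0, 6.0),
) -> LidarScan:
    """Render one plot's LiDAR point cloud.

    Vegetation returns: intensity ~ N(veg_mean [+ dew shift], veg_sd), height
    ~ canopy_height * Beta(a, b). Soil returns: intensity ~ N(soil_mean,
    soil_sd), height |N(0, roughness)| (uneven ground). Intensities are
    clipped to [0, 255]. When ``event.dew`` is true the vegetation intensity
    mean shifts upward so the expected reflectance-based GC drops below its
    dry-canopy value.
    """
    gc = _check_gc(true_gc)
    if canopy_height <= 0:
        raise ValueError("canopy_height must be positive")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    cfg = cfg or SensorConfig()
    rng = np.random.default_rng(seed)

    along = rng.uniform(along_extent[0], along_extent[1], n_points)
    cross = rng.uniform(-cfg.scan_cross_extent, cfg.scan_cross_extent, n_points)
    is_veg = rng.random(n_points) < gc

    veg_mean = cfg.veg_intensity_mean + (cfg.dew_intensity_shift if event.dew else 0.0)
    intensity = np.where(
        is_veg,
        rng.normal(veg_mean, cfg.veg_intensity_sd, n_points),
        rng.normal(cfg.soil_intensity_mean, cfg.soil_intensity_sd, n_points),
    )
    intensity = np.clip(intensity, 0.0, 255.0)

    a, b = cfg.veg_height_beta
    z = np.where(
        is_veg,
        canopy_height * rng.beta(a, b, n_points),
        np.abs(rng.normal(0.0, cfg.ground_roughness_sd, n_points)),
    )
    return LidarScan(np.column_stack([along, cross, z, intensity]))


def simulate_ndvi_stream(
    true_gc: float,
    event: SamplingEvent,
    travel_speed: float = 1.0,
    rate: float = 10.0,
    region_length: float = 5.0,
    seed=0,
    cfg: SensorConfig | None = None,
    start: float = 0.0,
) -> NdviStream:
    """Render the 10 Hz active-NDVI stream across a region.

    Readings sit every ``travel_speed / rate`` metres. Each reading is
    ``ndvi_soil + (ndvi_veg - ndvi_soil) * true_gc + noise`` clipped to
    [0, 0.99]. The generator ignores solar radiation and dew by construction:
    the sensor is active and carries its own light source.
    """
    gc = float(true_gc)
    if not 0.0 <= gc <= 1.0:  # band-ratio sensor: bare soil / full cover valid
        raise ValueError(f"true_gc must lie in [0, 1], got {gc}")
    if travel_speed <= 0 or rate <= 0:
        raise ValueError("travel_speed and rate must be positive")
    cfg = cfg or SensorConfig()
    rng = np.random.default_rng(seed)

    spacing = travel_speed / rate
    n = int(np.floor(region_length / spacing + 1e-9))
    pos = start + spacing * np.arange(n)
    level = cfg.ndvi_soil + (cfg.ndvi_veg - cfg.ndvi_soil) * gc
    vals = np.clip(level + rng.normal(0.0, cfg.ndvi_noise_sd, n), 0.0, NDVI_MAX)
    return NdviStream(np.column_stack([pos, vals]))


def render_bundle(
    plot: int,
    event: SamplingEvent,
    design: TrialDesign,
    truth: GroundTruth,
    cfg: SensorConfig,
    master_seed: int,
    schedule: list[SamplingEvent] | None = None,
) -> SensorBundle:
    """Render all three sensor streams for one plot at one event.

    Camera triggers sit every ``cfg.image_spacing`` metres from a seeded
    uniform phase offset; the scan and the NDVI stream cover the plot's full
    along-track extent (segmentation to the sampling region happens in the
    estimators). Sub-seeds derive deterministically from (master seed, plot,
    event), so any plot/event is reproducible in isolation.
    """
    if schedule is not None and all(e.event_id != event.event_id for e in schedule):
        raise UnknownEventError(f"event {event.event_id} not in schedule")
    if (design.plots["plot"] == plot).sum() == 0:
        raise KeyError(f"plot {plot} not in design")

    rng = np.random.default_rng(subseed(master_seed, plot, event.event_id))
    gc = truth.true_gc(plot)
    height = truth.canopy_height(plot)
    L = design.plot_length

    phase = rng.uniform(0.0, cfg.image_spacing)
    positions = list(np.arange(phase, L, cfg.image_spacing))
    images = simulate_rgb_images(
        gc, event, n_images=len(positions), image_size=None,
        seed=rng.integers(0, 2**31), cfg=cfg,
    )
    scan = simulate_lidar_scan(
        gc, height, event, cfg.n_points,
        seed=rng.integers(0, 2**31), cfg=cfg, along_extent=(0.0, L),
    )
    ndvi = simulate_ndvi_stream(
        gc, event, cfg.travel_speed, cfg.ndvi_rate, region_length=L,
        seed=rng.integers(0, 2**31), cfg=cfg, start=0.0,
    )
    return SensorBundle(
        plot=plot,
        event_id=event.event_id,
        image_positions=positions,
        images=images,
        scan=scan,
        ndvi=ndvi,
    )
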