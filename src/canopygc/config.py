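"""Configuration objects for the simulator, estimators and pipeline.

All defaults are desk-scale study conditions: the trial structure matches the
field experiment the package emulates (192 plots, 99 genotypes, 13 hourly
sampling events over an afternoon and the following morning), while per-plot
sensor volumes (pixels, points, readings) are kept small enough that the full
pipeline runs in seconds on one CPU.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

from .errors import InvalidDesignError


@dataclass
class TrialConfig:
    """Layout and genetic structure of the simulated field trial.

    The latent per-plot ground cover is generated on the logit scale as
    ``mu + genotype + row + column + residual`` with independent zero-mean
    Gaussian effects, then mapped through the inverse logit so true GC stays
    strictly inside (0, 1).
    """

    n_plots: int = 192
    n_genotypes: int = 99
    n_field_rows: int = 12          # trial grid rows (plots, not crop rows)
    n_field_cols: int = 16
    plot_length: float = 6.0        # m
    n_rows_per_plot: int = 7        # sown crop rows per plot
    row_spacing: float = 0.25       # m
    path_width: float = 0.4         # m between plots along track
    mu: float = -0.2007             # logit(0.45): early-season mean cover
    sigma2_genotype: float = 0.04   # logit-scale variances
    sigma2_row: float = 0.01
    sigma2_col: float = 0.01
    sigma2_residual: float = 0.033  # gives plot-level repeatability ~0.7
    height_intercept: float = 0.06  # canopy height (m) = a + b * true_gc
    height_slope: float = 0.25
    height_noise_sd: float = 0.015

    def validate(self) -> None:
        if self.n_genotypes > self.n_plots:
            raise InvalidDesignError(
                f"n_genotypes ({self.n_genotypes}) exceeds n_plots ({self.n_plots})"
            )
        if self.n_plots > self.n_field_rows * self.n_field_cols:
            raise InvalidDesignError(
                "field grid too small for the requested number of plots"
            )
        if self.n_genotypes < 1 or self.n_plots < 1:
            raise InvalidDesignError("need at least one plot and one genotype")


@dataclass
class ScheduleConfig:
    """Diurnal sampling schedule: 7 afternoon + 6 next-morning hourly events.

    ``radiation`` is the local light level (MJ m^-2 h^-1) driving the camera
    exposure model; the default curve is an idealized clear-sky diurnal course
    with its minimum just after sunset (18:00) and low but non-zero light just
    after sunrise (07:00).
    """

    afternoon_hours: tuple[int, ...] = (12, 13, 14, 15, 16, 17, 18)
    morning_hours: tuple[int, ...] = (7, 8, 9, 10, 11, 12)
    radiation: tuple[float, ...] = (
        2.0, 2.1, 2.0, 1.7, 1.2, 0.6, 0.05,   # afternoon day 1
        0.15, 0.4, 0.8, 1.3, 1.8, 2.0,        # morning day 2
    )
    dew_hours: tuple[int, ...] = (7, 8)       # morning hours with dew on leaves
    dew_light_bound: float = 0.5              # dew only plausible at low light

    def validate(self) -> None:
        n = len(self.afternoon_hours) + len(self.morning_hours)
        if len(self.radiation) != n:
            raise InvalidDesignError(
                f"radiation curve has {len(self.radiation)} values for {n} events"
            )
        if any(r < 0 for r in self.radiation):
            raise InvalidDesignError("solar radiation must be non-negative")


@dataclass
class SensorConfig:
    """Parameters of the three simulated sensor streams."""

    # RGB camera: vegetation pixels are green-dominant, soil red-dominant.
    image_height: int = 48
    image_width: int = 64
    image_spacing: float = 1.0      # m between camera triggers
    veg_rgb: tuple[float, float, float] = (60.0, 120.0, 55.0)
    soil_rgb: tuple[float, float, float] = (140.0, 110.0, 90.0)
    channel_noise_sd: float = 8.0   # per-pixel per-channel sensor noise (DN)
    wb_noise_sd: float = 4.0        # per-image green-red balance jitter (DN)
    dark_level: float = 15.0        # sensor floor so dark frames are noise, not black
    exposure_halflight: float = 0.2  # radiation at which exposure reaches 1/2

    # LiDAR: bimodal red-reflectance intensity, vegetation dark / soil bright.
    n_points: int = 1800
    veg_intensity_mean: float = 2.0
    veg_intensity_sd: float = 1.5
    soil_intensity_mean: float = 30.0
    soil_intensity_sd: float = 8.0
    dew_intensity_shift: float = 6.0   # added to vegetation mean when dew present
    veg_height_beta: tuple[float, float] = (2.0, 2.0)  # z ~ h * Beta(a, b)
    ground_roughness_sd: float = 0.02  # soil |N(0, sd)| height, uneven ground
    scan_cross_extent: float = 0.7     # scan covers +-0.7 m across track

    # Active NDVI: invariant to light and dew by construction.
    ndvi_soil: float = 0.10
    ndvi_veg: float = 0.90
    ndvi_noise_sd: float = 0.02
    ndvi_rate: float = 10.0         # Hz
    travel_speed: float = 1.0       # m/s


@dataclass
class EstimatorConfig:
    """Thresholds and plot-segmentation geometry for the four GC estimators.

    All thresholds are strict inequalities: a pixel is vegetation when
    VI > vi_threshold, a LiDAR return when intensity < rr_threshold or
    normalized height > ht_threshold. Ties classify as soil/ground.
    """

    vi_threshold: float = 0.0
    rr_threshold: float = 5.0       # intensity DN; < 5 is vegetation
    ht_threshold: float = 0.10      # m above local ground; > 10 cm is vegetation
    end_buffer: float = 0.5         # m excluded at each plot end
    exclude_outer_rows: bool = True

    def validate(self) -> None:
        if self.ht_threshold <= 0:
            raise ValueError("ht_threshold must be positive")
        if not (0 < self.rr_threshold < 255):
            raise ValueError("rr_threshold must lie in (0, 255)")


@dataclass
class ExperimentConfig:
    """Top-level configuration bundling all stages."""

    trial: TrialConfig = field(default_factory=TrialConfig)
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    sensors: SensorConfig = field(default_factory=SensorConfig)
    estimator: EstimatorConfig = field(default_factory=EstimatorConfig)
    master_seed: int | None = None

    def validate(self) -> None:
        self.trial.validate()
        self.schedule.validate()
        self.estimator.validate()

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ExperimentConfig":
        def build(klass, key):
            sub = dict(d.get(key) or {})
            fields = {f.name for f in dataclasses.fields(klass)}
            unknown = set(sub) - fields
            if unknown:
                raise ValueError(f"unknown {key} config keys: {sorted(unknown)}")
            # YAML lists come back as lists; dataclass defaults use tuples
            for k, v in sub.items():
                if isinstance(v, list):
                    sub[k] = tuple(v)
            return klass(**sub)

        return cls(
            trial=build(TrialConfig, "trial"),
            schedule=build(ScheduleConfig, "schedule"),
            sensors=build(SensorConfig, "sensors"),
            estimator=build(EstimatorConfig, "estimator"),
            master_seed=d.get("master_seed"),
        )

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
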