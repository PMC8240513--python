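"""Diurnal sampling schedule: hourly events with light level and dew flag.

A sampling campaign runs hourly from 12:00 to 18:00 on day one and 07:00 to
12:00 the following morning — 13 events. Each event carries the solar
radiation driving the camera exposure model and a dew flag affecting LiDAR
reflectance. A packaged meteorological fixture reproduces the hourly weather
table of the emulated experiment (two campaigns, with dew flagged on the
first morning's 07:00 and 08:00 samplings).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .config import ScheduleConfig
from .errors import InvalidDesignError


@dataclass(frozen=True)
class SamplingEvent:
    event_id: int
    clock_label: str            # e.g. "12:00 d1"
    solar_radiation: float      # MJ m^-2 h^-1
    dew: bool
    air_temp: float | None = None
    dewpoint: float | None = None
    rh: float | None = None

    def __post_init__(self):
        if self.solar_radiation < 0:
            raise InvalidDesignError("solar_radiation must be >= 0")


def make_event_schedule(config: ScheduleConfig | None = None) -> list[SamplingEvent]:
    """Build the 13-event hourly schedule from a schedule configuration.

    Dew may be flagged only at configured dew hours whose light level does not
    exceed ``config.dew_light_bound``; a dew hour at higher light is an error.
    """
    config = config or ScheduleConfig()
    config.validate()
    events: list[SamplingEvent] = []
    hours = [(h, "d1") for h in config.afternoon_hours] + [
        (h, "d2") for h in config.morning_hours
    ]
    for i, ((hour, day), rad) in enumerate(zip(hours, config.radiation), start=1):
        dew = day == "d2" and hour in config.dew_hours
        if dew and rad > config.dew_light_bound:
            raise InvalidDesignError(
                f"dew flagged at {hour:02d}:00 {day} but radiation {rad} exceeds "
                f"the low-light bound {config.dew_light_bound}"
            )
        events.append(
            SamplingEvent(
                event_id=i,
                clock_label=f"{hour:02d}:00 {day}",
                solar_radiation=float(rad),
                dew=dew,
            )
        )
    return events


def load_met_table(path=None) -> pd.DataFrame:
    """Load a meteorological fixture (hourly weather per campaign).

    Columns: event, time, date, t_air, t_dew, rh, radiation, dew_flag.
    With no path, the packaged two-campaign table is returned.
    """
    if path is None:
        ref = resources.files("canopygc.data") / "met_table.csv"
        with resources.as_file(ref) as p:
            return pd.read_csv(p)
    return pd.read_csv(path)


def schedule_from_met_table(met: pd.DataFrame, campaign: int) -> list[SamplingEvent]:
    """Build SamplingEvents from one campaign of a met fixture table."""
    sub = met[met["event"] == campaign]
    if sub.empty:
        raise InvalidDesignError(f"campaign {campaign} not present in met table")
    events = []
    for i, (_, r) in enumerate(sub.iterrows(), start=1):
        day = "d1" if i <= 7 else "d2"
        events.append(
            SamplingEvent(
                event_id=i,
                clock_label=f"{r['time']} {day}",
                solar_radiation=float(r["radiation"]),
                dew=bool(int(r["dew_flag"])),
                air_temp=float(r["t_air"]),
                dewpoint=float(r["t_dew"]),
                rh=float(r["rh"]),
            )
        )
    return events


def schedule_frame(events: list[SamplingEvent]) -> pd.DataFrame:
    """Tabular view of a schedule (one row per event)."""
    return pd.DataFrame(
        {
            "event_id": [e.event_id for e in events],
            "clock_label": [e.clock_label for e in events],
            "solar_radiation": [e.solar_radiation for e in events],
            "dew": [e.dew for e in events],
        }
    )
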