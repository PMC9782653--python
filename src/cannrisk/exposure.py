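"""Exposure assessment: assumption set, additive exposure, usage-log summaries.

The central quantity is the consumer's daily intake of the additive,

    daily exposure (mg/day) = concentration (mg/g) × concentrate consumed (mg/day) / 1000,

driven by a conservative daily-consumption assumption. The default
assumption set (100 mg concentrate/day, 60 kg body weight, 20 / 6.7 / 0.3 m³
inhalation volumes for 24 h / workday / 15 min) is the recommended
first-tier set for cannabis-concentrate vaporization; the 100 mg/day figure
is the mean of the 95th-percentile weekly and monthly daily-average
consumption observed in smart-vaporizer telemetry.

Usage logs (device id, date, mg consumed) are summarized into the standard
habits-and-practices structure: daily statistics over use days only, weekly
and monthly calendar-window totals including non-use days, and use-day
frequency per month. Percentiles are empirical quantiles with linear
interpolation between order statistics.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field


class ExposureAssumptions(BaseModel):
    """First-tier exposure assumption set (all values positive)."""

    model_config = ConfigDict(extra="forbid")

    daily_consumption_mg: float = Field(default=100.0, gt=0)
    bioavailability_fraction: float = Field(default=1.0, gt=0, le=1)
    body_weight_kg: float = Field(default=60.0, gt=0)
    inhalation_volume_24h_m3: float = Field(default=20.0, gt=0)
    inhalation_volume_8h_m3: float = Field(default=6.7, gt=0)
    inhalation_volume_15min_m3: float = Field(default=0.3, gt=0)
    days_per_month: float = Field(default=30.5, gt=0)


def load_assumptions(path: str | Path) -> ExposureAssumptions:
    """Load an assumption config from YAML or JSON; absent keys keep defaults."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return ExposureAssumptions.model_validate(data or {})


class ExposureEstimate(BaseModel):
    additive_mg_per_day: float = Field(ge=0)
    concentration_mg_per_g: float
    consumption_mg_per_day: float


def daily_exposure(
    concentration_mg_per_g: float, consumption_mg_per_day: float
) -> ExposureEstimate:
    """Daily additive intake: concentration (mg/g) × consumption (mg/day) / 1000."""
    if concentration_mg_per_g < 0 or consumption_mg_per_day < 0:
        raise ValueError("concentration and consumption must be non-negative")
    if concentration_mg_per_g > 1000:
        raise ValueError(
            f"concentration {concentration_mg_per_g} mg/g exceeds 1000 mg/g "
            "(an impossible mass fraction)"
        )
    return ExposureEstimate(
        additive_mg_per_day=concentration_mg_per_g * consumption_mg_per_day / 1000.0,
        concentration_mg_per_g=concentration_mg_per_g,
        consumption_mg_per_day=consumption_mg_per_day,
    )


def thc_daily_dose(
    thc_concentration_mg_per_g: float,
    consumption_mg_per_day: float,
    bioavailability_fraction: float = 1.0,
) -> float:
    """Cross-check utility: absorbed THC dose in mg/day.

    Bioavailability enters here only; additive exposure keeps the
    conservative 100% absorption assumption.
    """
    return (
        daily_exposure(thc_concentration_mg_per_g, consumption_mg_per_day).additive_mg_per_day
        * bioavailability_fraction
    )


# --------------------------------------------------------------------------
# usage logs


@dataclass
class UsageLog:
    """Per-device daily consumption records.

    ``frame`` columns: device_id (str), date (datetime64), consumed_mg (float ≥ 0);
    at most one record per device-day.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["device_id", "date", "consumed_mg"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise ValueError(f"usage log missing columns: {missing}")
        frame = self.frame[required].copy()
        frame["date"] = pd.to_datetime(frame["date"])
        frame["consumed_mg"] = frame["consumed_mg"].astype(float)
        if (frame["consumed_mg"] < 0).any():
            raise ValueError("consumed_mg must be >= 0")
        if frame.duplicated(["device_id", "date"]).any():
            raise ValueError("usage log must have at most one record per device-day")
        self.frame = frame.sort_values(["device_id", "date"]).reset_index(drop=True)

    @classmethod
    def from_records(cls, records: list[tuple]) -> "UsageLog":
        return cls(pd.DataFrame(records, columns=["device_id", "date", "consumed_mg"]))

    def __len__(self) -> int:
        return len(self.frame)


def read_usage_csv(path: str | Path) -> UsageLog:
    return UsageLog(pd.read_csv(path, parse_dates=["date"]))


def write_usage_csv(log: UsageLog, path: str | Path) -> None:
    out = log.frame.copy()
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


class Stats(BaseModel):
    """Mean and 50/90/95th empirical percentiles of one pooled observation set."""

    mean: float
    p50: float
    p90: float
    p95: float

    @classmethod
    def from_values(cls, values: np.ndarray) -> "Stats":
        values = np.asarray(values, dtype=float)
        return cls(
            mean=float(values.mean()),
            p50=float(np.percentile(values, 50)),
            p90=float(np.percentile(values, 90)),
            p95=float(np.percentile(values, 95)),
        )

    def scaled(self, divisor: float) -> "Stats":
        return Stats(
            mean=self.mean / divisor,
            p50=self.p50 / divisor,
            p90=self.p90 / divisor,
            p95=self.p95 / divisor,
        )


class ConsumptionSummary(BaseModel):
    """Habits-and-practices summary of a usage log.

    Daily statistics cover use days only; weekly/monthly totals are
    calendar-window sums including non-use days within each device's observed
    span, with daily averages obtained by dividing by 7 and by
    ``days_per_month`` respectively.
    """

    daily_use_days_mg: Stats
    weekly_total_mg: Stats
    weekly_daily_average_mg: Stats
    monthly_total_mg: Stats
    monthly_daily_average_mg: Stats
    use_days_per_month: Stats
    n_devices: int

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "daily (use days only), mg": self.daily_use_days_mg,
            "weekly total, mg": self.weekly_total_mg,
            "weekly (daily average), mg": self.weekly_daily_average_mg,
            "monthly total, mg": self.monthly_total_mg,
            "monthly (daily average), mg": self.monthly_daily_average_mg,
            "days of consumption per month": self.use_days_per_month,
        }
        return pd.DataFrame(
            {name: s.model_dump() for name, s in rows.items()}
        ).T[["mean", "p50", "p90", "p95"]]


def _pooled_window_totals(
    frame: pd.DataFrame, window_start: pd.Series, n_windows: pd.Series
) -> np.ndarray:
    """Pool per-device window totals, zero-filling windows without records.

    ``window_start`` maps each record to its calendar window key;
    ``n_windows`` gives, per device, how many windows its observed span covers.
    """
    totals = frame.groupby(["device_id", window_start], observed=True)["consumed_mg"].sum()
    observed_per_device = totals.groupby(level=0).size()
    missing = (n_windows - observed_per_device.reindex(n_windows.index).fillna(0)).astype(int)
    if (missing < 0).any():
        raise AssertionError("observed windows exceed covered windows")
    zeros = np.zeros(int(missing.sum()))
    return np.concatenate([totals.to_numpy(dtype=float), zeros])


def summarize_usage(
    log: UsageLog, assumptions: Optional[ExposureAssumptions] = None
) -> ConsumptionSummary:
    """Summarize a usage log into the standard consumption-percentile structure."""
    assumptions = assumptions or ExposureAssumptions()
    frame = log.frame
    if frame.empty:
        raise ValueError("usage log is empty")
    positive = frame[frame["consumed_mg"] > 0]
    if positive.empty:
        raise ValueError("usage log contains no use days (all consumption zero)")

    daily = Stats.from_values(positive["consumed_mg"].to_numpy())

    span = frame.groupby("device_id")["date"].agg(["min", "max"])

    # ISO weeks: align each date to its Monday.
    monday = frame["date"] - pd.to_timedelta(frame["date"].dt.weekday, unit="D")
    first_monday = span["min"] - pd.to_timedelta(span["min"].dt.weekday, unit="D")
    last_monday = span["max"] - pd.to_timedelta(span["max"].dt.weekday, unit="D")
    n_weeks = ((last_monday - first_monday).dt.days // 7 + 1).astype(int)
    weekly_vals = _pooled_window_totals(frame, monday, n_weeks)
    weekly = Stats.from_values(weekly_vals)

    # calendar months
    month_key = frame["date"].dt.to_period("M")
    month_index = lambda s: s.dt.year * 12 + s.dt.month  # noqa: E731
    n_months = (month_index(span["max"]) - month_index(span["min"]) + 1).astype(int)
    monthly_vals = _pooled_window_totals(frame, month_key, n_months)
    monthly = Stats.from_values(monthly_vals)

    # use-day counts per device-month, zero-filled for covered months without use
    counts = positive.groupby(["device_id", positive["date"].dt.to_period("M")], observed=True)[
        "consumed_mg"
    ].size()
    observed_months = counts.groupby(level=0).size()
    missing_months = (n_months - observed_months.reindex(n_months.index).fillna(0)).astype(int)
    use_day_vals = np.concatenate(
        [counts.to_numpy(dtype=float), np.zeros(int(missing_months.sum()))]
    )

    return ConsumptionSummary(
        daily_use_days_mg=daily,
        weekly_total_mg=weekly,
        weekly_daily_average_mg=weekly.scaled(7.0),
        monthly_total_mg=monthly,
        monthly_daily_average_mg=monthly.scaled(assumptions.days_per_month),
        use_days_per_month=Stats.from_values(use_day_vals),
        n_devices=int(frame["device_id"].nunique()),
    )


class Timeframe(str, enum.Enum):
    WEEKLY = "weekly"
    MONTHLY = "monthly"


def daily_average_from_period(
    total_mg: float,
    timeframe: Timeframe | str,
    assumptions: Optional[ExposureAssumptions] = None,
) -> float:
    """Convert a weekly or monthly total into a daily average (÷7 or ÷30.5)."""
    if total_mg < 0:
        raise ValueError("total must be >= 0")
    assumptions = assumptions or ExposureAssumptions()
    timeframe = Timeframe(timeframe)
    if timeframe is Timeframe.WEEKLY:
        return total_mg / 7.0
    return total_mg / assumptions.days_per_month


def round_to_one_sf(value: float) -> float:
    """Round to one significant figure (headline display)."""
    if value == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(value)))
    scale = 10.0 ** exponent
    return round(value / scale) * scale


class RecommendedConsumption(BaseModel):
    mean_mg_per_day: float
    headline_mg_per_day: float


def recommended_daily_consumption(
    weekly_p95_daily_mg: float, monthly_p95_daily_mg: float
) -> RecommendedConsumption:
    """Derive the first-tier daily-consumption constant.

    The recommendation is the arithmetic mean of the 95th-percentile weekly
    and monthly daily averages, with a one-significant-figure headline value.
    """
    if weekly_p95_daily_mg <= 0 or monthly_p95_daily_mg <= 0:
        raise ValueError("percentile inputs must be positive")
    mean = (weekly_p95_daily_mg + monthly_p95_daily_mg) / 2.0
    return RecommendedConsumption(
        mean_mg_per_day=mean, headline_mg_per_day=round_to_one_sf(mean)
    )
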