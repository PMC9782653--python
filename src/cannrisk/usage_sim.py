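"""Synthetic device-usage telemetry with realistic consumption structure.

Real closed-loop vaporizer telemetry shows two salient features: most
devices are used intermittently (mean ≈ 7.8 use days per month, median 5,
95th percentile 24) and per-use-day consumption is heavy-tailed (median
44 mg but mean 151 mg). The simulator reproduces both:

* monthly use-day counts are geometric (a negative binomial with shape 1),
  which with mean 7.8 lands the median at 5 and the 95th percentile at 24
  without extra parameters; the first month is zero-truncated so every
  device appears in the log, later months may be silent;
* use days fall uniformly at random within each month;
* per-use-day consumption is i.i.d. log-normal calibrated in closed form to
  a target median m and mean M: location = ln m, scale = sqrt(2 ln(M/m)).

Same parameters + same seed give a byte-identical log.
"""

from __future__ import annotations

import calendar
import math
from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .exposure import UsageLog


def calibrate_lognormal(median_mg: float, mean_mg: float) -> tuple[float, float]:
    """Closed-form (location, scale) of a log-normal with given median and mean.

    median = exp(µ) and mean = exp(µ + σ²/2) invert to µ = ln(median),
    σ = sqrt(2 ln(mean/median)). mean < median is impossible for a log-normal.
    """
    if median_mg <= 0:
        raise ValueError("median must be positive")
    if mean_mg < median_mg:
        raise ValueError(
            f"a log-normal cannot have mean ({mean_mg}) below median ({median_mg})"
        )
    return math.log(median_mg), math.sqrt(2.0 * math.log(mean_mg / median_mg))


@dataclass(frozen=True)
class UsageSimParams:
    """Simulation parameters; defaults emulate the telemetry summary statistics."""

    n_devices: int = 1000
    n_days: int = 90
    start_date: date = date(2021, 1, 1)
    mean_use_days_per_month: float = 7.8
    median_mg: float = 44.0
    mean_mg: float = 151.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_devices < 0 or self.n_days < 0:
            raise ValueError("n_devices and n_days must be >= 0")
        if self.mean_use_days_per_month <= 0:
            raise ValueError("mean_use_days_per_month must be positive")
        calibrate_lognormal(self.median_mg, self.mean_mg)  # validates the pair


def _month_windows(start: date, n_days: int) -> list[tuple[date, int]]:
    """Calendar-month windows (first covered day, window length) spanning the horizon."""
    windows = []
    end = start + timedelta(days=n_days)  # exclusive
    cursor = start
    while cursor < end:
        month_days = calendar.monthrange(cursor.year, cursor.month)[1]
        month_end = date(cursor.year, cursor.month, month_days) + timedelta(days=1)
        window_end = min(month_end, end)
        windows.append((cursor, (window_end - cursor).days))
        cursor = month_end
    return windows


def simulate_usage(params: UsageSimParams) -> UsageLog:
    """Generate a synthetic usage log; deterministic for a given seed."""
    rng = np.random.default_rng(params.seed)
    mu, sigma = calibrate_lognormal(params.median_mg, params.mean_mg)
    # geometric success probability giving mean use days (support 0,1,2,…)
    p = 1.0 / (1.0 + params.mean_use_days_per_month)
    windows = _month_windows(params.start_date, params.n_days)

    device_ids: list[str] = []
    dates: list[date] = []
    amounts: list[float] = []
    for i in range(params.n_devices):
        device = f"dev{i:05d}"
        for month_index, (window_start, window_days) in enumerate(windows):
            k = int(rng.geometric(p)) - 1
            if month_index == 0:
                while k == 0:  # zero-truncated: every device appears in the log
                    k = int(rng.geometric(p)) - 1
            k = min(k, window_days)
            if k == 0:
                continue
            offsets = rng.choice(window_days, size=k, replace=False)
            consumed = rng.lognormal(mu, sigma, size=k)
            for off, mg in zip(sorted(int(o) for o in offsets), consumed):
                device_ids.append(device)
                dates.append(window_start + timedelta(days=off))
                amounts.append(float(mg))

    frame = pd.DataFrame(
        {"device_id": device_ids, "date": pd.to_datetime(dates), "consumed_mg": amounts}
    )
    return UsageLog(frame)
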