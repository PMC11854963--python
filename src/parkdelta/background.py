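"""Overnight-percentile background estimation and removal.

The persistent concentration not attributable to nearby sources is
operationalised as the 10th percentile of overnight hourly values —
overnight because vehicle traffic is minimal and the atmosphere stable,
the 10th percentile rather than the minimum to be robust to single
anomalous hours.  Hours strictly below the background are discarded as
unphysical for a local-source analysis; the background is subtracted
from the rest, leaving the local (traffic) enhancement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from parkdelta.errors import InsufficientDataError
from parkdelta.qaqc import POLLUTANTS

#: clock hours taken as "midnight to 3 a.m." (hour labels 00:00, 01:00, 02:00)
DEFAULT_WINDOW = frozenset({0, 1, 2})


@dataclass(frozen=True)
class BackgroundEstimate:
    sensor_id: str
    pollutant: str
    window_hours: frozenset
    p10: float

    def __post_init__(self) -> None:
        if not self.window_hours:
            raise InsufficientDataError("background window is empty")
        if self.p10 < 0:
            raise ValueError("background concentration cannot be negative")


def select_overnight(
    records: pd.DataFrame,
    window=DEFAULT_WINDOW,
    hour_col: str = "hour_start",
) -> pd.DataFrame:
    """Rows whose clock hour falls in the overnight window."""
    hours = pd.to_datetime(records[hour_col]).dt.hour
    return records.loc[hours.isin(set(window))]


def percentile10(values: np.ndarray) -> float:
    """Linearly interpolated 10th percentile (rank 1 + 0.1·(n−1)).

    The single interpolation convention used throughout the package,
    for backgrounds and for rose percentiles alike.
    """
    return float(np.percentile(np.asarray(values, dtype=float), 10.0))


def estimate_background(
    overnight: pd.DataFrame,
    pollutant: str,
    *,
    sensor_id: str = "",
    value_col: str | None = None,
    window=DEFAULT_WINDOW,
) -> BackgroundEstimate:
    """10th percentile of overnight combined concentrations.

    Raises
    ------
    InsufficientDataError
        If there are no overnight values to estimate from.
    """
    col = value_col or pollutant
    values = overnight[col].dropna().to_numpy()
    if values.size == 0:
        raise InsufficientDataError("no overnight data for background estimation")
    return BackgroundEstimate(
        sensor_id=sensor_id,
        pollutant=pollutant,
        window_hours=frozenset(window),
        p10=percentile10(values),
    )


def subtract_background(
    records: pd.DataFrame, bg: BackgroundEstimate, value_col: str | None = None
) -> pd.DataFrame:
    """Remove hours strictly below background and subtract it from the rest.

    A value exactly equal to the background is retained as 0.  Output
    concentrations are therefore always ≥ 0.
    """
    col = value_col or bg.pollutant
    keep = ~(records[col] < bg.p10)
    out = records.loc[keep].copy()
    out[col] = out[col] - bg.p10
    return out


def remove_background_paired(
    paired: pd.DataFrame,
    window=DEFAULT_WINDOW,
    pollutants=POLLUTANTS,
) -> tuple[pd.DataFrame, list[BackgroundEstimate]]:
    """Apply background removal to every pollutant on both sides of a pair.

    Backgrounds are estimated per sensor per pollutant from that
    sensor's own overnight hours of the whole retained record.  A value
    below its background becomes missing (the hour drops out of that
    pollutant's paired analyses); the rest are shifted down by the
    background.  Meteorological columns are untouched — background
    subtraction is a concentration concept only.
    """
    out = paired.copy()
    estimates: list[BackgroundEstimate] = []
    overnight = select_overnight(out, window)
    for side in ("park", "road"):
        for p in pollutants:
            col = f"{side}_{p}"
            if col not in out.columns:
                continue
            bg = estimate_background(
                overnight, p, sensor_id=side, value_col=col, window=window
            )
            below = out[col] < bg.p10
            out[col] = out[col] - bg.p10
            out.loc[below, col] = np.nan
            estimates.append(bg)
    return out, estimates
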