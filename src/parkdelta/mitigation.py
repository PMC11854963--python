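"""Road-minus-park mitigation statistics.

For every simultaneously measured hour the difference
``delta = road − park`` is computed per variable; a positive PM delta
means lower concentrations inside the vegetated area, i.e. mitigation.
Deltas are aggregated by site-specific period of day (overnight /
daytime / evening — boundaries differ between sites because their
diurnal transitions differ) and by 16-point compass wind sector, and
summarised as diurnal profiles and percentile roses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from parkdelta.errors import ConfigurationError
from parkdelta.qaqc import POLLUTANTS

#: variables the delta is computed for (PM on background-removed values,
#: meteorology on raw values)
DELTA_VARIABLES = POLLUTANTS + ["temperature", "rh", "pressure"]

DEFAULT_ROSE_LEVELS = (10, 25, 50, 75, 90, 99)

SECTOR_NAMES = [
    "N", "NNE", "NE", "ENE", "E", "ESE", "SE", "SSE",
    "S", "SSW", "SW", "WSW", "W", "WNW", "NW", "NNW",
]


@dataclass(frozen=True)
class PeriodConfig:
    """Three labeled clock-hour intervals partitioning the day.

    ``hours`` maps each label (overnight/daytime/evening) to the set of
    clock hours it covers; the three sets must partition {0..23}.
    """

    hours: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = set(self.hours)
        if labels != {"overnight", "daytime", "evening"}:
            raise ConfigurationError(
                "periods must be labeled overnight/daytime/evening"
            )
        all_hours = sorted(h for hs in self.hours.values() for h in hs)
        if all_hours != list(range(24)):
            raise ConfigurationError("period intervals must partition hours 0-23")

    @classmethod
    def from_bounds(cls, overnight: tuple, daytime: tuple, evening: tuple):
        """Build from inclusive (first_hour, last_hour) bounds."""
        return cls({
            "overnight": set(range(overnight[0], overnight[1] + 1)),
            "daytime": set(range(daytime[0], daytime[1] + 1)),
            "evening": set(range(evening[0], evening[1] + 1)),
        })

    @classmethod
    def fsp(cls):
        """Small-park site: overnight 00–09 h, daytime 10–18 h, evening 19–23 h."""
        return cls.from_bounds((0, 9), (10, 18), (19, 23))

    @classmethod
    def cientec(cls):
        """Forest site: overnight 00–07 h, daytime 08–15 h, evening 16–23 h."""
        return cls.from_bounds((0, 7), (8, 15), (16, 23))


def assign_period(hour: int, cfg: PeriodConfig) -> str:
    """Unique period label for a clock hour."""
    for label, hours in cfg.hours.items():
        if hour in hours:
            return label
    raise ConfigurationError(f"hour {hour} not covered by any period")


def compute_deltas(
    paired: pd.DataFrame,
    variables=DELTA_VARIABLES,
    period_cfg: PeriodConfig | None = None,
) -> pd.DataFrame:
    """Per-hour road − park deltas and road-based percent differences.

    ``pct_v = 100·(road_v − park_v)/road_v``, defined only where the
    road value is strictly positive.  If ``period_cfg`` is given, a
    ``period`` column is attached; if wind columns are present a
    ``sector`` column is attached (missing where wind is missing).
    """
    out = pd.DataFrame({"hour_start": paired["hour_start"]})
    for v in variables:
        road = paired[f"road_{v}"]
        park = paired[f"park_{v}"]
        out[f"delta_{v}"] = road - park
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = 100.0 * (road - park) / road
        out[f"pct_{v}"] = pct.where(road > 0)
    if period_cfg is not None:
        hours = pd.to_datetime(out["hour_start"]).dt.hour
        out["period"] = hours.map(lambda h: assign_period(int(h), period_cfg))
    for col in ("wd", "ws"):
        if col in paired.columns:
            out[col] = paired[col]
    if "wd" in out.columns:
        out["sector"] = assign_sector(out["wd"].to_numpy())
    return out


def aggregate_by_period(
    deltas: pd.DataFrame,
    cfg: PeriodConfig | None = None,
    variables=DELTA_VARIABLES,
) -> pd.DataFrame:
    """Mean delta, mean per-hour percent and hour counts per period × variable.

    Percentages are averaged per hour then over hours, which weights
    every hour equally regardless of its absolute concentration.  The
    mean delta is reported alongside so both conventions are available.
    """
    df = deltas
    if "period" not in df.columns:
        if cfg is None:
            raise ConfigurationError("deltas carry no period labels and no config given")
        hours = pd.to_datetime(df["hour_start"]).dt.hour
        df = df.assign(period=hours.map(lambda h: assign_period(int(h), cfg)))
    rows = []
    for label in ("overnight", "daytime", "evening"):
        sub = df.loc[df["period"] == label]
        for v in variables:
            d = sub[f"delta_{v}"].dropna()
            p = sub[f"pct_{v}"].dropna()
            rows.append({
                "period": label,
                "variable": v,
                "mean_delta": d.mean() if len(d) else np.nan,
                "mean_pct": p.mean() if len(p) else np.nan,
                "n_hours": int(len(d)),
            })
    return pd.DataFrame(rows)


def diurnal_profile(
    records: pd.DataFrame,
    value_cols,
    hour_col: str = "hour_start",
) -> pd.DataFrame:
    """Mean of each variable by clock hour (24 rows, absent hours missing)."""
    hours = pd.to_datetime(records[hour_col]).dt.hour
    prof = records[list(value_cols)].groupby(hours).mean()
    return prof.reindex(range(24)).rename_axis("hour")


def assign_sector(wd, n_sectors: int = 16):
    """Compass sector index for a wind direction in degrees.

    Sectors are centred on the compass points (sector 0 = N at 0°) with
    half-width 180/n_sectors; an edge tie goes to the higher sector via
    the floor rule.
    """
    width = 360.0 / n_sectors
    wd = np.asarray(wd, dtype=float)
    sector = np.floor(np.mod(wd + width / 2.0, 360.0) / width)
    out = np.where(np.isnan(wd), -1, sector).astype(int)
    if out.ndim == 0:
        return int(out)
    return out


def percentile_rose(
    deltas: pd.DataFrame,
    levels=DEFAULT_ROSE_LEVELS,
    value_col: str = "delta_pm25",
    pct_col: str = "pct_pm25",
    n_sectors: int = 16,
) -> pd.DataFrame:
    """Per-wind-sector percentiles of the PM2.5 delta plus mean percent.

    Uses the same linear interpolation convention as the background
    percentile.  Sectors without data are present with n_hours = 0 and
    missing statistics.  Rows where the sector is missing (no wind) are
    excluded.
    """
    df = deltas.loc[deltas.get("sector", pd.Series(-1, index=deltas.index)) >= 0]
    rows = []
    for k in range(n_sectors):
        sub = df.loc[df["sector"] == k]
        vals = sub[value_col].dropna().to_numpy()
        row = {
            "sector": k,
            "name": SECTOR_NAMES[k] if n_sectors == 16 else str(k),
            "n_hours": int(vals.size),
            "mean_pct": sub[pct_col].dropna().mean() if len(sub) else np.nan,
        }
        for lev in levels:
            row[f"p{lev}"] = (
                float(np.percentile(vals, lev)) if vals.size else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)
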