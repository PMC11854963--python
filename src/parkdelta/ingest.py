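"""Read and write the pipeline's file formats.

Sensor logs are delimited text with one row per 2-minute reading:
timestamp, the six particulate columns (PM1/PM2.5/PM10 for the A and B
laser channels, atmospheric correction), optional factory-correction
duplicates, and the meteorological columns (temperature, relative
humidity, pressure).  Wind records are hourly direction/speed rows from
a meteorological station.  All timestamps are local clock time; an
optional fixed UTC offset is applied once at ingest because every
downstream rule (overnight window, period-of-day boundaries) is
clock-hour based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from parkdelta.errors import ConfigurationError, EmptyStreamError

#: canonical reading columns, in storage order
PM_COLUMNS = ["pm1_a", "pm25_a", "pm10_a", "pm1_b", "pm25_b", "pm10_b"]
MET_COLUMNS = ["temperature", "rh", "pressure"]
REQUIRED_COLUMNS = ["timestamp"] + PM_COLUMNS + MET_COLUMNS
#: factory-correction (CF = 1) duplicates; parsed when present, never analysed
CF1_COLUMNS = [c + "_cf1" for c in PM_COLUMNS]


@dataclass
class SensorStream:
    """An ordered 2-minute reading series from one dual-channel sensor.

    ``readings`` holds one row per reading with the canonical columns
    above plus a boolean ``valid`` flag (False for readings with
    out-of-range humidity, negative concentrations, or a missing
    channel).  ``n_skipped`` counts malformed rows dropped at parse
    time and ``n_duplicates`` counts exact timestamp duplicates
    collapsed to their first occurrence, so that
    ``rows_in == len(readings) + n_skipped + n_duplicates``.
    """

    sensor_id: str
    site: str
    role: str  # "park" or "roadside"
    readings: pd.DataFrame = field(repr=False)
    n_skipped: int = 0
    n_duplicates: int = 0

    def __post_init__(self) -> None:
        if self.role not in ("park", "roadside"):
            raise ConfigurationError(
                f"role must be 'park' or 'roadside', got {self.role!r}"
            )

    def __len__(self) -> int:
        return len(self.readings)

    def replace_readings(self, readings: pd.DataFrame) -> "SensorStream":
        """Same stream metadata over a new reading table."""
        return SensorStream(
            sensor_id=self.sensor_id,
            site=self.site,
            role=self.role,
            readings=readings.reset_index(drop=True),
            n_skipped=self.n_skipped,
            n_duplicates=self.n_duplicates,
        )


def _flag_validity(df: pd.DataFrame) -> pd.Series:
    rh_ok = df["rh"].between(0.0, 100.0)
    conc = df[PM_COLUMNS]
    conc_ok = (conc >= 0).all(axis=1)
    channels_ok = conc.notna().all(axis=1)
    return rh_ok & conc_ok & channels_ok


def read_sensor_log(
    path,
    dialect: dict[str, str] | None = None,
    *,
    sensor_id: str = "",
    site: str = "",
    role: str = "park",
    sep: str = ",",
    utc_offset_hours: float = 0.0,
) -> SensorStream:
    """Parse a delimited sensor log into a :class:`SensorStream`.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    dialect
        Map from canonical column names (``timestamp``, ``pm25_a`` ...)
        to the names used in the file.  Omitted entries default to the
        canonical name itself.
    utc_offset_hours
        Fixed offset added once to every timestamp, converting the
        logger clock to local time.

    Raises
    ------
    ConfigurationError
        If a required column is absent (the message names it).
    EmptyStreamError
        If the file yields no readings.
    """
    dialect = dict(dialect or {})
    raw = pd.read_csv(path, sep=sep, dtype=str, skip_blank_lines=True)
    rows_in = len(raw)

    colmap = {}
    for canon in REQUIRED_COLUMNS:
        src = dialect.get(canon, canon)
        if src not in raw.columns:
            raise ConfigurationError(f"sensor log is missing required column {canon!r}")
        colmap[canon] = src
    for canon in CF1_COLUMNS:
        src = dialect.get(canon, canon)
        if src in raw.columns:
            colmap[canon] = src

    df = pd.DataFrame({canon: raw[src] for canon, src in colmap.items()})
    df["timestamp"] = pd.to_datetime(df["timestamp"], errors="coerce")
    numeric_cols = [c for c in df.columns if c != "timestamp"]
    df[numeric_cols] = df[numeric_cols].apply(pd.to_numeric, errors="coerce")

    # malformed = unparseable timestamp or any required field non-numeric
    required_numeric = [c for c in numeric_cols if c not in CF1_COLUMNS]
    malformed = df["timestamp"].isna() | df[required_numeric].isna().any(axis=1)
    n_skipped = int(malformed.sum())
    df = df.loc[~malformed]

    if utc_offset_hours:
        df["timestamp"] = df["timestamp"] + pd.Timedelta(hours=utc_offset_hours)

    df = df.sort_values("timestamp", kind="stable")
    dup = df["timestamp"].duplicated(keep="first")
    n_duplicates = int(dup.sum())
    df = df.loc[~dup].reset_index(drop=True)

    if df.empty:
        raise EmptyStreamError(f"no readings parsed from {path}")

    df["valid"] = _flag_validity(df)
    assert rows_in == len(df) + n_skipped + n_duplicates
    return SensorStream(
        sensor_id=sensor_id or str(path),
        site=site,
        role=role,
        readings=df,
        n_skipped=n_skipped,
        n_duplicates=n_duplicates,
    )


def read_wind(path, *, sep: str = ",") -> tuple[pd.DataFrame, int]:
    """Parse hourly wind records.

    Expects columns ``hour_start``, ``wd`` (degrees) and ``ws`` (m/s).
    Directions are normalised to [0, 360) by modulo; rows with
    non-numeric fields or negative speed are skipped and counted.

    Returns
    -------
    (records, n_skipped)
        ``records`` has columns hour_start, wd, ws sorted by hour.
    """
    raw = pd.read_csv(path, sep=sep, dtype=str, skip_blank_lines=True)
    for col in ("hour_start", "wd", "ws"):
        if col not in raw.columns:
            raise ConfigurationError(f"wind file is missing required column {col!r}")
    df = pd.DataFrame(
        {
            "hour_start": pd.to_datetime(raw["hour_start"], errors="coerce"),
            "wd": pd.to_numeric(raw["wd"], errors="coerce"),
            "ws": pd.to_numeric(raw["ws"], errors="coerce"),
        }
    )
    bad = df.isna().any(axis=1) | (df["ws"] < 0)
    n_skipped = int(bad.sum())
    df = df.loc[~bad].copy()
    df["wd"] = np.mod(df["wd"], 360.0)
    df = df.sort_values("hour_start", kind="stable").reset_index(drop=True)
    return df, n_skipped


def join_wind(paired: pd.DataFrame, wind: pd.DataFrame) -> pd.DataFrame:
    """Attach hourly wind to a paired hourly table on ``hour_start``.

    Hours without a wind match are retained with ``wind_missing=True``
    (excluded only from wind-conditional analyses); an empty wind table
    yields an all-flagged output rather than an error.
    """
    if wind.empty:
        out = paired.copy()
        out["wd"] = np.nan
        out["ws"] = np.nan
        out["wind_missing"] = True
        return out
    out = paired.merge(
        wind[["hour_start", "wd", "ws"]], on="hour_start", how="left", validate="m:1"
    )
    out["wind_missing"] = out["wd"].isna()
    return out


def write_hourly(df: pd.DataFrame, path) -> None:
    """Write an hourly table as delimited text (full float precision).

    Floats are written in shortest round-trip representation so a
    subsequent :func:`read_hourly` reproduces them bit-exactly.
    """
    df.to_csv(path, index=False)


def read_hourly(path) -> pd.DataFrame:
    """Read a table written by :func:`write_hourly`."""
    df = pd.read_csv(path)
    for col in df.columns:
        if col == "hour_start" or col.endswith("hour_start"):
            df[col] = pd.to_datetime(df[col])
    return df
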