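"""Synthetic paired sensor streams, wind series and point clouds.

The generator emulates the statistical structure of a paired
park/roadside deployment next to an urban road: a smooth 24-hour
background that peaks overnight (shallow nocturnal mixing layer), a
two-peak traffic increment at the morning and evening rush hours, and a
park sensor that sees only a fraction ``1 − m`` of the road increment —
``m`` is the ground-truth mitigation the pipeline must recover.  Both
laser channels of each sensor observe the same true value with
independent multiplicative channel noise; meteorology follows a diurnal
temperature cycle with inversely coupled humidity.

Data-quality artifacts (below-detection readings, humidity spikes,
under-filled hours, discordant A/B hours, hours present on one side
only) are injected at known, recorded locations so the cleaning cascade
can be audited against exact expected counts:

* clean readings are floored at LOD + 0.5 µg/m³ on the PM2.5 channel
  mean and their humidity capped at 94 %, so only injected artifacts
  can trip the detection-limit and humidity filters;
* whole-hour artifacts occupy mutually disjoint clock hours, and the
  ones that invalidate an hour (short hours, discordant hours) are
  injected on BOTH streams of the pair so they never leak into the
  simultaneity count;
* per-reading artifacts are injected only inside clean hours, at most
  10 per hour, so no hour accidentally falls under the completeness
  threshold.

Everything is drawn from one seeded generator: identical seed and
configuration give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from parkdelta.errors import ConfigurationError
from parkdelta.ingest import SensorStream
from parkdelta.background import percentile10, DEFAULT_WINDOW
from parkdelta.lidar_site import PointCloud

READINGS_PER_HOUR = 30  # one reading every 2 minutes
_MAX_READING_ARTIFACTS_PER_HOUR = 10


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults emulate a small urban park site.

    Concentrations are µg/m³, times are clock hours.  The defaults give
    road daily means around 18 µg/m³ with a morning peak near 25 —
    the magnitude range of low-cost sensor data at trafficked urban
    sites — and artifact rates of the order seen in year-long low-cost
    deployments.
    """

    n_days: int = 10
    # background: 24-h cosine peaking overnight
    b0: float = 9.0               # background mean level
    b1: float = 1.0               # background diurnal amplitude
    bg_peak_hour: float = 2.0
    # traffic increment: two Gaussian rush-hour peaks
    peak_heights: tuple = (16.0, 14.0)
    peak_hours: tuple = (8.0, 18.0)
    peak_width: float = 3.0       # hours
    # mitigation: fraction of the road increment absent at the park sensor
    mitigation: float = 0.25
    # noise
    sigma_ch: float = 0.02        # relative, per channel per reading
    sigma_obs: float = 1.5        # µg/m³, per reading, shared by channels
    # size-fraction ratios relative to PM2.5
    pm1_ratio: float = 0.7
    pm10_ratio: float = 1.2
    # meteorology
    t_mean: float = 27.0
    t_amp: float = 4.0
    t_peak_hour: float = 14.0
    t_sigma: float = 0.3
    h_mean: float = 55.0
    h_coupling: float = -1.5      # % RH per °C of temperature anomaly
    h_sigma: float = 2.0
    p_mean: float = 924.0
    p_sigma: float = 0.5
    # wind
    sector_probs: tuple = tuple([1.0 / 16] * 16)
    ws_shape: float = 2.0         # gamma shape
    ws_scale: float = 0.75        # gamma scale (mean = shape·scale m/s)
    upwind_sectors: tuple | None = None  # if set, mitigation acts only there
    # artifact rates
    lod_rate: float = 0.10             # per clean-hour reading
    rh_spike_rate: float = 0.0002      # per clean-hour reading
    short_hour_rate: float = 0.05      # per hour slot
    discordant_hour_rate: float = 0.02
    discordant_factor: float = 1.5     # channel-B inflation in discordant hours
    unmatched_hour_rate: float = 0.07
    # QA floor: clean readings never fall below lod + this margin
    lod_margin: float = 0.5
    lod: float = 1.5
    start: str = "2023-07-01"

    def validate(self) -> None:
        bad = []
        if not (0.0 <= self.mitigation <= 1.0):
            bad.append("mitigation")
        for name in ("lod_rate", "rh_spike_rate", "short_hour_rate",
                     "discordant_hour_rate", "unmatched_hour_rate"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                bad.append(name)
        for name in ("sigma_ch", "sigma_obs", "t_sigma", "h_sigma", "p_sigma"):
            if getattr(self, name) < 0:
                bad.append(name)
        if abs(sum(self.sector_probs) - 1.0) > 1e-9 or len(self.sector_probs) != 16:
            bad.append("sector_probs")
        if self.n_days < 1:
            bad.append("n_days")
        if bad:
            raise ConfigurationError(f"invalid SimConfig fields: {bad}")


@dataclass
class TruthRecord:
    """Ground truth of one simulation, including exact artifact accounting.

    ``expected_removed`` maps each cleaning-cascade step name to the
    count it must report when run on the generated pair (readings for
    the per-reading steps, hourly records for the per-hour steps,
    summed over both streams).
    """

    seed: int
    mitigation: float
    config: dict = field(repr=False)
    expected_removed: dict = field(default_factory=dict)
    background_hourly: np.ndarray = field(default=None, repr=False)   # (24,)
    road_increment_hourly: np.ndarray = field(default=None, repr=False)
    short_hours: list = field(default_factory=list)
    discordant_hours: list = field(default_factory=list)
    unmatched_hours: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# deterministic diurnal curves (fractional hour of day)

def _circular_dist(t, center):
    d = np.abs(np.asarray(t, dtype=float) - center) % 24.0
    return np.minimum(d, 24.0 - d)


def background_curve(cfg: SimConfig, tod):
    """True background B(t) at fractional hour of day t."""
    return cfg.b0 + cfg.b1 * np.cos(
        2.0 * np.pi * (np.asarray(tod, dtype=float) - cfg.bg_peak_hour) / 24.0
    )


def traffic_curve(cfg: SimConfig, tod):
    """True road traffic increment R(t) at fractional hour of day t."""
    tod = np.asarray(tod, dtype=float)
    r = np.zeros_like(tod)
    for height, center in zip(cfg.peak_heights, cfg.peak_hours):
        r = r + height * np.exp(
            -(_circular_dist(tod, center) ** 2) / (2.0 * cfg.peak_width**2)
        )
    return r


def hourly_true_pm25(cfg: SimConfig, role: str) -> np.ndarray:
    """Noise-free hourly-mean PM2.5 by clock hour (24,) for one role."""
    offsets = np.arange(READINGS_PER_HOUR) * 2.0 / 60.0
    factor = 1.0 if role == "roadside" else 1.0 - cfg.mitigation
    out = np.empty(24)
    for h in range(24):
        tod = h + offsets
        out[h] = float(np.mean(background_curve(cfg, tod)
                               + factor * traffic_curve(cfg, tod)))
    return out


def expected_background_p10(cfg: SimConfig, role: str,
                            window=DEFAULT_WINDOW) -> float:
    """Noise-free pipeline background: p10 of the overnight hourly values."""
    vals = hourly_true_pm25(cfg, role)[sorted(window)]
    return percentile10(np.tile(vals, cfg.n_days))


def expected_period_pct(cfg: SimConfig, period_hours,
                        subtract_background: bool = True,
                        window=DEFAULT_WINDOW) -> float:
    """Noise-free expectation of the pipeline's mean percent delta.

    Matches the pipeline's convention: per-hour percent (road-based
    denominator, on background-subtracted values when the pipeline
    subtracts) averaged over the period's clock hours.
    """
    road = hourly_true_pm25(cfg, "roadside")
    park = hourly_true_pm25(cfg, "park")
    if subtract_background:
        road = road - expected_background_p10(cfg, "roadside", window)
        park = park - expected_background_p10(cfg, "park", window)
    hours = sorted(period_hours)
    pct = 100.0 * (road[hours] - park[hours]) / road[hours]
    return float(np.mean(pct))


# ---------------------------------------------------------------------------

def _simulate_wind(cfg: SimConfig, rng: np.random.Generator,
                   hour_starts: pd.DatetimeIndex) -> pd.DataFrame:
    n = len(hour_starts)
    sectors = rng.choice(16, size=n, p=np.asarray(cfg.sector_probs))
    wd = np.mod(sectors * 22.5 + rng.uniform(-11.25, 11.25, size=n), 360.0)
    ws = rng.gamma(cfg.ws_shape, cfg.ws_scale, size=n)
    return pd.DataFrame({"hour_start": hour_starts, "wd": wd, "ws": ws,
                         "sector": sectors})


def _stream_frame(cfg: SimConfig, rng: np.random.Generator, role: str,
                  timestamps: pd.DatetimeIndex, tod: np.ndarray,
                  mit_by_hour: np.ndarray, hour_index: np.ndarray,
                  hour_category: np.ndarray) -> tuple[pd.DataFrame, int, int]:
    """One stream's readings plus realized (lod, rh) injection counts."""
    n = len(timestamps)
    factor = np.ones(n) if role == "roadside" else 1.0 - mit_by_hour[hour_index]
    true25 = background_curve(cfg, tod) + factor * traffic_curve(cfg, tod)
    value25 = true25 + rng.normal(0.0, cfg.sigma_obs, size=n)
    # floor: clean readings are always detectable
    value25 = np.maximum(value25, cfg.lod + cfg.lod_margin)

    clean_reading = hour_category[hour_index] == 0

    # per-reading artifacts, clean hours only, capped per hour
    u = rng.uniform(size=n)
    lod_mask = clean_reading & (u < cfg.lod_rate)
    rh_mask = clean_reading & ~lod_mask & (u < cfg.lod_rate + cfg.rh_spike_rate)
    artifact = lod_mask | rh_mask
    # enforce the per-hour cap deterministically (first readings win)
    order = np.arange(n)
    cum_in_hour = np.zeros(n, dtype=int)
    counts: dict[int, int] = {}
    for i in order[artifact]:
        h = int(hour_index[i])
        counts[h] = counts.get(h, 0) + 1
        cum_in_hour[i] = counts[h]
    over = artifact & (cum_in_hour > _MAX_READING_ARTIFACTS_PER_HOUR)
    lod_mask &= ~over
    rh_mask &= ~over

    value25[lod_mask] = 0.5  # far below detection on both channels

    # channel noise (shared across size fractions within a channel)
    delta_a = rng.normal(0.0, cfg.sigma_ch, size=n)
    delta_b = rng.normal(0.0, cfg.sigma_ch, size=n)
    b_factor = np.where(hour_category[hour_index] == 2, cfg.discordant_factor, 1.0)

    df = pd.DataFrame({"timestamp": timestamps})
    for name, ratio in (("pm1", cfg.pm1_ratio), ("pm25", 1.0), ("pm10", cfg.pm10_ratio)):
        base = ratio * value25
        df[f"{name}_a"] = base * (1.0 + delta_a)
        df[f"{name}_b"] = base * (1.0 + delta_b) * b_factor

    t_anom = cfg.t_amp * np.cos(2.0 * np.pi * (tod - cfg.t_peak_hour) / 24.0)
    temperature = cfg.t_mean + t_anom + rng.normal(0.0, cfg.t_sigma, size=n)
    rh = cfg.h_mean + cfg.h_coupling * t_anom + rng.normal(0.0, cfg.h_sigma, size=n)
    rh = np.clip(rh, 20.0, 94.0)
    rh[rh_mask] = 96.0 + 3.0 * rng.uniform(size=int(rh_mask.sum()))
    pressure = cfg.p_mean + rng.normal(0.0, cfg.p_sigma, size=n)
    df["temperature"] = temperature
    df["rh"] = rh
    df["pressure"] = pressure
    df["valid"] = True

    # whole-hour thinning/deletion
    reading_in_hour = np.arange(n) % READINGS_PER_HOUR
    keep = np.ones(n, dtype=bool)
    keep[(hour_category[hour_index] == 1) & (reading_in_hour >= 6)] = False  # short
    side = 3 if role == "park" else 4
    keep[hour_category[hour_index] == side] = False  # unmatched: hour absent here
    df = df.loc[keep].reset_index(drop=True)
    n_lod = int((lod_mask & keep).sum())
    n_rh = int((rh_mask & keep).sum())
    return df, n_lod, n_rh


def simulate_pair(
    cfg: SimConfig | None = None, seed: int = 0
) -> tuple[SensorStream, SensorStream, pd.DataFrame, TruthRecord]:
    """Generate a park/roadside stream pair, hourly wind, and ground truth.

    Road PM2.5 at reading time t is B(h) + R(h) + ε and park PM2.5 is
    B(h) + (1 − m)·R(h) + ε; each sensor's A/B channels observe the
    value with independent multiplicative noise.  Artifacts are injected
    per the configured rates and their exact expected cleaning-cascade
    counts recorded in the returned :class:`TruthRecord`.
    """
    cfg = cfg or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)

    n_hours = cfg.n_days * 24
    hour_starts = pd.date_range(cfg.start, periods=n_hours, freq="h")
    timestamps = pd.date_range(cfg.start, periods=n_hours * READINGS_PER_HOUR,
                               freq="2min")
    tod = (timestamps.hour + timestamps.minute / 60.0).to_numpy()
    hour_index = np.arange(len(timestamps)) // READINGS_PER_HOUR

    wind = _simulate_wind(cfg, rng, hour_starts)

    # hour categories: 0 clean, 1 short, 2 discordant, 3 unmatched (park
    # side deleted), 4 unmatched (road side deleted) — mutually exclusive
    u = rng.uniform(size=n_hours)
    category = np.zeros(n_hours, dtype=int)
    p1 = cfg.short_hour_rate
    p2 = p1 + cfg.discordant_hour_rate
    p3 = p2 + cfg.unmatched_hour_rate
    category[(u >= p1) & (u < p2)] = 2
    unmatched = (u >= p2) & (u < p3)
    # alternate which side loses the hour
    unm_idx = np.flatnonzero(unmatched)
    category[unm_idx[::2]] = 3
    category[unm_idx[1::2]] = 4
    category[u < p1] = 1

    if cfg.upwind_sectors is not None:
        mit_by_hour = np.where(
            np.isin(wind["sector"].to_numpy(), list(cfg.upwind_sectors)),
            cfg.mitigation, 0.0,
        )
    else:
        mit_by_hour = np.full(n_hours, cfg.mitigation)

    park_df, lod_p, rh_p = _stream_frame(
        cfg, rng, "park", timestamps, tod, mit_by_hour, hour_index, category
    )
    road_df, lod_r, rh_r = _stream_frame(
        cfg, rng, "roadside", timestamps, tod, mit_by_hour, hour_index, category
    )

    n_short = int((category == 1).sum())
    n_disc = int((category == 2).sum())
    n_unmatched = int(((category == 3) | (category == 4)).sum())
    truth = TruthRecord(
        seed=seed,
        mitigation=cfg.mitigation,
        config=asdict(cfg),
        expected_removed={
            "detection_limit": lod_p + lod_r,
            "humidity_cap": rh_p + rh_r,
            "temperature_range": 0,
            "hourly_completeness": 2 * n_short,
            "ab_agreement": 2 * n_disc,
            "simultaneity": n_unmatched,
        },
        background_hourly=background_curve(cfg, np.arange(24.0)),
        road_increment_hourly=traffic_curve(cfg, np.arange(24.0)),
        short_hours=np.flatnonzero(category == 1).tolist(),
        discordant_hours=np.flatnonzero(category == 2).tolist(),
        unmatched_hours=unm_idx.tolist(),
    )

    park = SensorStream(sensor_id="sim-park", site="synthetic", role="park",
                        readings=park_df)
    road = SensorStream(sensor_id="sim-road", site="synthetic", role="roadside",
                        readings=road_df)
    return park, road, wind[["hour_start", "wd", "ws"]], truth


# ---------------------------------------------------------------------------
# point clouds

def simulate_cloud(kind: str, params: dict | None = None,
                   seed: int = 0) -> PointCloud:
    """Synthetic classified point clouds with known geometry.

    ``lattice``: regular cubic grid (exact neighbour counts known);
    ``barrier``: uniform-random vegetation slab with optional thinning —
    the un-thinned base is reproducible from the seed, so a thinned
    cloud is an exact subset of its base; ``site``: flat ground plane
    plus vegetation/building blocks of known footprint and height.
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if kind == "lattice":
        n = int(params.get("n", 7))
        s = float(params.get("spacing", 1.0))
        ax = np.arange(n) * s
        x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
        xyz = np.column_stack([x.ravel(), y.ravel(), z.ravel()])
        return PointCloud(xyz, np.full(len(xyz), "vegetation", dtype=object))
    if kind == "barrier":
        size = params.get("size", (20.0, 4.0, 8.0))   # length, depth, height
        n_points = int(params.get("n_points", 4000))
        thin = float(params.get("thin", 0.0))
        if not (0.0 <= thin < 1.0):
            raise ConfigurationError("thin must be in [0, 1)")
        xyz = rng.uniform(0.0, 1.0, size=(n_points, 3)) * np.asarray(size)
        if thin > 0:
            keep = rng.uniform(size=n_points) >= thin
            xyz = xyz[keep]
        return PointCloud(xyz, np.full(len(xyz), "vegetation", dtype=object))
    if kind == "site":
        radius = float(params.get("radius", 50.0))
        spacing = float(params.get("ground_spacing", 1.0))
        ax = np.arange(-radius, radius + spacing / 2, spacing)
        gx, gy = np.meshgrid(ax, ax, indexing="ij")
        ground = np.column_stack([gx.ravel(), gy.ravel(),
                                  np.zeros(gx.size)])
        parts = [ground]
        labels = [np.full(len(ground), "ground", dtype=object)]
        for cls_name, key in (("vegetation", "veg"), ("building", "bld")):
            block = params.get(key)
            if block is None:
                continue
            (x0, y0), (sx, sy), height = block
            bx = np.arange(x0 + 0.25, x0 + sx, 0.5)
            by = np.arange(y0 + 0.25, y0 + sy, 0.5)
            px, py = np.meshgrid(bx, by, indexing="ij")
            pts = np.column_stack([px.ravel(), py.ravel(),
                                   np.full(px.size, float(height))])
            parts.append(pts)
            labels.append(np.full(len(pts), cls_name, dtype=object))
        return PointCloud(np.vstack(parts), np.concatenate(labels))
    raise ConfigurationError(f"unknown cloud kind {kind!r}")
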