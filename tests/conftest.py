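import numpy as np
import pandas as pd
import pytest

from parkdelta.background import remove_background_paired
from parkdelta.ingest import join_wind
from parkdelta.qaqc import run_cascade
from parkdelta.synthetic import SimConfig, simulate_pair


@pytest.fixture(scope="session")
def sim_ten_days():
    """A 10-day synthetic pair with default artifact rates, seed 1."""
    cfg = SimConfig(n_days=10)
    park, road, wind, truth = simulate_pair(cfg, seed=1)
    return cfg, park, road, wind, truth


@pytest.fixture(scope="session")
def cleaned_ten_days(sim_ten_days):
    cfg, park, road, wind, truth = sim_ten_days
    paired, ledger = run_cascade(park, road)
    return cfg, paired, ledger, wind, truth


@pytest.fixture(scope="session")
def pipeline_thirty_days():
    """Full pipeline output over 30 simulated days (seed 7): cascade,
    background removal, wind join."""
    cfg = SimConfig(n_days=30)
    park, road, wind, truth = simulate_pair(cfg, seed=7)
    paired, ledger = run_cascade(park, road)
    removed, estimates = remove_background_paired(paired)
    joined = join_wind(removed, wind)
    return cfg, joined, estimates, truth


@pytest.fixture
def tiny_sensor_csv(tmp_path):
    """Three well-formed 2-minute readings as a sensor-log file."""
    rows = []
    for i, ts in enumerate(["2023-07-01 00:00", "2023-07-01 00:02",
                            "2023-07-01 00:04"]):
        rows.append({
            "timestamp": ts,
            "pm1_a": 5.0 + i, "pm25_a": 8.0 + i, "pm10_a": 10.0 + i,
            "pm1_b": 5.1 + i, "pm25_b": 8.1 + i, "pm10_b": 10.1 + i,
            "temperature": 25.0, "rh": 60.0, "pressure": 924.0,
        })
    path = tmp_path / "sensor.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def percentile_oracle(values, p):
    """Brute-force sort-and-interpolate percentile at rank 1 + p·(n−1)."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if n == 1:
        return float(v[0])
    rank = p * (n - 1)
    lo = int(np.floor(rank))
    hi = min(lo + 1, n - 1)
    frac = rank - lo
    return float(v[lo] * (1 - frac) + v[hi] * frac)
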