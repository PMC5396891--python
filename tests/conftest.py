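import datetime as dt

import numpy as np
import pandas as pd
import pytest

YEAR_START = dt.date(2015, 1, 1)


def mk_deployment(site_cameras: dict[str, list[str]], cluster: str | None = None) -> pd.DataFrame:
    """Hand-built deployment table; one cluster per site unless given."""
    rows = []
    for i, (site, cams) in enumerate(sorted(site_cameras.items())):
        for j, cam in enumerate(cams):
            rows.append(
                (site, cluster or f"{site}C1", cam, 100.0 * i + 10.0 * j, 0.0,
                 YEAR_START, YEAR_START + dt.timedelta(days=364))
            )
    return pd.DataFrame(
        rows,
        columns=["site_id", "cluster_id", "camera_id", "x_m", "y_m",
                 "active_start", "active_end"],
    )


def mk_events(rows) -> pd.DataFrame:
    """Event table from (site, camera, species, minutes-from-year-start) tuples."""
    out = pd.DataFrame(rows, columns=["site_id", "camera_id", "species_id", "minutes"])
    out["timestamp"] = pd.Timestamp(YEAR_START) + pd.to_timedelta(out.pop("minutes"), unit="m")
    return out[["site_id", "camera_id", "species_id", "timestamp"]]


def random_events(
    rng: np.random.Generator,
    n: int,
    sites=("S1", "S2"),
    cams_per_site=3,
    species=("sp1", "sp2"),
    horizon_days: int = 30,
    avoid_midnight: bool = False,
) -> pd.DataFrame:
    """Random small event lists for oracle comparisons."""
    rows = []
    for _ in range(n):
        site = sites[rng.integers(0, len(sites))]
        cam = f"{site}-{rng.integers(1, cams_per_site + 1):02d}"
        sp = species[rng.integers(0, len(species))]
        day = int(rng.integers(0, horizon_days))
        minute = int(rng.integers(30, 1410)) if avoid_midnight else int(rng.integers(0, 1440))
        rows.append((site, cam, sp, day * 1440 + minute))
    return mk_events(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def two_site_deployment():
    return mk_deployment(
        {"S1": [f"S1-{i:02d}" for i in range(1, 4)],
         "S2": [f"S2-{i:02d}" for i in range(1, 4)]}
    )
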