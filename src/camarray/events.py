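"""Event independence filtering and daily detection histories.

Raw trigger events of the same species at the same site are merged into
independent detections with a sliding time window: an event joins the
current chain if its gap to the chain's *latest* event is strictly less
than the window (default 30 minutes), regardless of which camera in the
site recorded it. Each chain becomes one independent detection dated by its
first event. Detections are then spread onto a binary per-camera daily
history, the substrate for the survey detectability estimator.
"""

from __future__ import annotations

import datetime as dt
from collections.abc import Iterable

import numpy as np
import pandas as pd

from camarray.synthetic import EVENT_COLUMNS, YEAR_DAYS

__all__ = [
    "DETECTION_COLUMNS",
    "DAILY_HISTORY_COLUMNS",
    "ValidationError",
    "deduplicate",
    "build_daily_history",
]

DETECTION_COLUMNS = [
    "site_id",
    "species_id",
    "timestamp_first",
    "timestamp_last",
    "contributing_cameras",
]

DAILY_HISTORY_COLUMNS = ["site_id", "camera_id", "species_id", "day", "detected"]


class ValidationError(ValueError):
    """Raised when inputs violate the data contracts (unknown cameras, out-of-year records, ...)."""


def _check_cameras(events: pd.DataFrame, deployment: pd.DataFrame) -> None:
    known = set(zip(deployment["site_id"], deployment["camera_id"]))
    seen = set(zip(events["site_id"], events["camera_id"]))
    unknown = seen - known
    if unknown:
        raise ValidationError(f"events reference cameras absent from the deployment: {sorted(unknown)[:5]}")


def deduplicate(
    events: pd.DataFrame,
    window_minutes: float = 30.0,
    camera_subset: Iterable[str] | None = None,
    deployment: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Merge raw events into independent site-level detections.

    Events of the same (site, species) are chained greedily in time order;
    an event joins the open chain iff its gap to the chain's latest event is
    < ``window_minutes``. The rule deliberately spans all cameras within a
    site: the same animal passing two nearby cameras within the window is a
    single detection. If ``camera_subset`` is given, only events from those
    cameras are considered first — the counterfactual record a smaller array
    would have produced.

    Returns a DataFrame with columns :data:`DETECTION_COLUMNS`;
    ``contributing_cameras`` holds a sorted tuple of camera ids.
    """
    if window_minutes <= 0:
        raise ValidationError("window_minutes must be > 0")
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValidationError(f"events table is missing columns {missing}")
    if deployment is not None and len(events):
        _check_cameras(events, deployment)

    ev = events
    if camera_subset is not None:
        ev = ev[ev["camera_id"].isin(set(camera_subset))]
    if len(ev) == 0:
        out = pd.DataFrame(columns=DETECTION_COLUMNS)
        return out.astype({"timestamp_first": "datetime64[ns]", "timestamp_last": "datetime64[ns]"})

    ev = ev.sort_values("timestamp", kind="mergesort")
    rows: list[tuple] = []
    for (site, species), grp in ev.groupby(["site_id", "species_id"], sort=True):
        ts = grp["timestamp"].to_numpy()
        cams = grp["camera_id"].to_numpy()
        gaps_min = np.diff(ts).astype("timedelta64[s]").astype(np.float64) / 60.0
        starts = np.concatenate([[0], np.flatnonzero(gaps_min >= window_minutes) + 1])
        ends = np.concatenate([starts[1:], [len(ts)]])
        for s, e in zip(starts, ends):
            rows.append(
                (site, species, ts[s], ts[e - 1], tuple(sorted(set(cams[s:e]))))
            )
    out = pd.DataFrame(rows, columns=DETECTION_COLUMNS)
    return out.sort_values(
        ["timestamp_first", "site_id", "species_id"], kind="mergesort"
    ).reset_index(drop=True)


def build_daily_history(
    detections: pd.DataFrame,
    deployment: pd.DataFrame,
    year_start: dt.date,
    n_days: int = YEAR_DAYS,
) -> pd.DataFrame:
    """Binary per-camera daily detection history over a simulated year.

    Cell (site, camera c, species, day d) is 1 iff some independent
    detection at that site/species lists c among its contributing cameras
    and starts (``timestamp_first``) on day d, with days indexed 1..n_days
    from ``year_start``. Returns the full long-format grid (columns
    :data:`DAILY_HISTORY_COLUMNS`); all-zero if ``detections`` is empty.
    """
    species = sorted(detections["species_id"].unique()) if len(detections) else []
    dep = deployment.sort_values("camera_id", kind="mergesort")
    grid = pd.MultiIndex.from_product(
        [dep["camera_id"], species if species else ["__none__"], range(1, n_days + 1)],
        names=["camera_id", "species_id", "day"],
    )
    hist = pd.DataFrame(index=grid).reset_index()
    if not species:
        hist = hist.iloc[0:0]
    cam_site = dict(zip(dep["camera_id"], dep["site_id"]))
    hist.insert(0, "site_id", hist["camera_id"].map(cam_site))
    hist["detected"] = 0

    if len(detections):
        day = (
            pd.to_datetime(detections["timestamp_first"]).dt.normalize()
            - pd.Timestamp(year_start)
        ).dt.days + 1
        if (day < 1).any() or (day > n_days).any():
            raise ValidationError("detection outside the indexed year")
        hot: set[tuple] = set()
        for cams, sp, d in zip(detections["contributing_cameras"], detections["species_id"], day):
            for c in cams:
                hot.add((c, sp, int(d)))
        if hot:
            mask = [
                (c, sp, d) in hot
                for c, sp, d in zip(hist["camera_id"], hist["species_id"], hist["day"])
            ]
            hist.loc[mask, "detected"] = 1
    return hist.reset_index(drop=True)[DAILY_HISTORY_COLUMNS]
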