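"""Synthetic camera-trap deployments and raw trigger-event streams.

Emulates a clustered field design: each site holds a small number of 1-ha
camera clusters, each cluster holds several cameras at random coordinates,
and every camera records motion-trigger events for each of several species
over a (nominally yearlong) deployment. Event streams are generated from a
per-camera-day Poisson process with log-normal camera heterogeneity,
sinusoidal seasonal modulation, and optional short-lag "companion" events at
nearby cameras that exercise the downstream 30-minute independence rule.

All randomness flows through a single ``numpy.random.Generator`` seeded by
the caller, so a fixed seed reproduces deployments and event streams exactly.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEPLOYMENT_COLUMNS",
    "EVENT_COLUMNS",
    "ConfigurationError",
    "SpacingConfig",
    "SpeciesModel",
    "DEFAULT_SPECIES_MODELS",
    "generate_deployment",
    "simulate_events",
]

DEPLOYMENT_COLUMNS = [
    "site_id",
    "cluster_id",
    "camera_id",
    "x_m",
    "y_m",
    "active_start",
    "active_end",
]

EVENT_COLUMNS = ["site_id", "camera_id", "species_id", "timestamp"]

#: Mean distance between two independent uniform points in the unit square
#: (Robbins constant for the square); used to size the sampling square so the
#: expected mean pairwise camera distance hits the configured target.
_UNIT_SQUARE_MEAN_DIST = 0.5214054331647207

MINUTES_PER_DAY = 1440
YEAR_DAYS = 365


class ConfigurationError(ValueError):
    """Raised for invalid generator configuration (counts, distances, rates)."""


@dataclass(frozen=True)
class SpacingConfig:
    """Target spacing geometry for a clustered deployment, in metres.

    ``intra_cluster_mean_m`` is the target mean pairwise distance between
    cameras within one cluster; realized deployments are rejection-sampled
    until the brute-force mean lies within ``intra_cluster_band_m`` of the
    target. Cluster centroids within a site are placed exactly
    ``inter_cluster_distance_m`` apart (regular polygon for >2 clusters), and
    sites are laid out on a widely separated grid so cameras from different
    sites can never interact.
    """

    intra_cluster_mean_m: float = 65.2
    intra_cluster_band_m: float = 7.9
    inter_cluster_distance_m: float = 589.3
    site_separation_m: float = 10_000.0
    max_attempts: int = 1000

    def __post_init__(self) -> None:
        for name in (
            "intra_cluster_mean_m",
            "intra_cluster_band_m",
            "inter_cluster_distance_m",
            "site_separation_m",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class SpeciesModel:
    """Per-species encounter model for the event generator.

    Parameters
    ----------
    daily_event_rate
        Expected raw trigger events per camera per day for an average camera
        (the camera-effect distribution has mean 1).
    camera_heterogeneity_sd
        Standard deviation of the per-camera log-rate effect. Effects are
        log-normal with mean 1 and are fixed per (camera, species), so some
        cameras are persistently hot or cold for a species.
    seasonal_amplitude
        Amplitude a in [0, 1) of a sinusoidal day-of-year modulation
        ``1 + a * sin(2*pi*(d-1)/365 + phase)`` of the daily rate.
    within_day_cluster_prob
        Probability that a generated event spawns one companion event 1-29
        minutes later at a camera of the same cluster (possibly itself),
        producing the short cross-camera co-occurrences the deduplication
        window is meant to absorb.
    """

    species_id: str
    daily_event_rate: float
    camera_heterogeneity_sd: float = 0.0
    seasonal_amplitude: float = 0.0
    within_day_cluster_prob: float = 0.0
    seasonal_phase: float = 0.0

    def __post_init__(self) -> None:
        if self.daily_event_rate < 0:
            raise ConfigurationError("daily_event_rate must be >= 0")
        if self.camera_heterogeneity_sd < 0:
            raise ConfigurationError("camera_heterogeneity_sd must be >= 0")
        if not 0.0 <= self.seasonal_amplitude < 1.0:
            raise ConfigurationError("seasonal_amplitude must be in [0, 1)")
        if not 0.0 <= self.within_day_cluster_prob <= 1.0:
            raise ConfigurationError("within_day_cluster_prob must be in [0, 1]")


#: Illustrative four-species community spanning high to low per-camera
#: encounter rates. Rates and heterogeneity are chosen so that frequently
#: detected species saturate season detectability quickly with a single
#: camera while rarely detected, strongly camera-heterogeneous species
#: plateau low with one camera and gain most from added cameras.
DEFAULT_SPECIES_MODELS = (
    SpeciesModel("deer", 1.2, camera_heterogeneity_sd=0.5,
                 seasonal_amplitude=0.3, within_day_cluster_prob=0.10),
    SpeciesModel("raccoon", 0.5, camera_heterogeneity_sd=0.7,
                 seasonal_amplitude=0.3, within_day_cluster_prob=0.10,
                 seasonal_phase=1.5),
    SpeciesModel("opossum", 0.015, camera_heterogeneity_sd=2.0,
                 seasonal_amplitude=0.4, within_day_cluster_prob=0.05,
                 seasonal_phase=3.0),
    SpeciesModel("bobcat", 0.008, camera_heterogeneity_sd=2.2,
                 seasonal_amplitude=0.2, within_day_cluster_prob=0.05,
                 seasonal_phase=4.5),
)


def _cluster_centers(n_clusters: int, distance: float) -> np.ndarray:
    """Cluster centroid offsets within a site, pairwise-adjacent ``distance`` apart."""
    if n_clusters == 1:
        return np.zeros((1, 2))
    if n_clusters == 2:
        return np.array([[0.0, 0.0], [distance, 0.0]])
    # regular polygon with side length = distance
    radius = distance / (2.0 * np.sin(np.pi / n_clusters))
    angles = 2.0 * np.pi * np.arange(n_clusters) / n_clusters
    return radius * np.column_stack([np.cos(angles), np.sin(angles)])


def _sample_cluster(
    n_cameras: int, spacing: SpacingConfig, rng: np.random.Generator
) -> np.ndarray:
    """Camera offsets within one cluster, rejection-sampled to the spacing band."""
    side = spacing.intra_cluster_mean_m / _UNIT_SQUARE_MEAN_DIST
    if n_cameras < 2:
        return rng.uniform(0.0, side, size=(n_cameras, 2))
    for _ in range(spacing.max_attempts):
        xy = rng.uniform(0.0, side, size=(n_cameras, 2))
        diffs = xy[:, None, :] - xy[None, :, :]
        dists = np.sqrt((diffs**2).sum(axis=-1))
        mean_dist = dists[np.triu_indices(n_cameras, k=1)].mean()
        if abs(mean_dist - spacing.intra_cluster_mean_m) <= spacing.intra_cluster_band_m:
            return xy
    raise ConfigurationError(
        "could not place cameras within the configured intra-cluster spacing "
        f"band after {spacing.max_attempts} attempts"
    )


def generate_deployment(
    n_sites: int = 4,
    clusters_per_site: int = 2,
    cameras_per_cluster: int = 5,
    spacing: SpacingConfig | None = None,
    seed: int | np.random.Generator | None = None,
    start_date: dt.date = dt.date(2015, 1, 1),
    n_days: int = YEAR_DAYS,
    failure_prob: float = 0.0,
) -> pd.DataFrame:
    """Generate a clustered camera deployment table.

    Returns a DataFrame with one row per camera (columns
    :data:`DEPLOYMENT_COLUMNS`): planar coordinates in metres and an active
    date interval. By default every camera is active for the whole simulated
    period; with ``failure_prob`` > 0 each camera independently loses a
    random leading or trailing stretch of its deployment, emulating an
    unserviced failure.

    Deterministic under a fixed ``seed``.
    """
    if n_sites < 1 or clusters_per_site < 1 or cameras_per_cluster < 1:
        raise ConfigurationError("site, cluster and camera counts must all be >= 1")
    if n_days < 1:
        raise ConfigurationError("n_days must be >= 1")
    if not 0.0 <= failure_prob <= 1.0:
        raise ConfigurationError("failure_prob must be in [0, 1]")
    spacing = spacing or SpacingConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    end_date = start_date + dt.timedelta(days=n_days - 1)
    rows: list[tuple] = []
    for s in range(n_sites):
        site_id = f"S{s + 1}"
        origin = np.array([s * spacing.site_separation_m, 0.0])
        centers = _cluster_centers(clusters_per_site, spacing.inter_cluster_distance_m)
        for c in range(clusters_per_site):
            cluster_id = f"{site_id}C{c + 1}"
            xy = _sample_cluster(cameras_per_cluster, spacing, rng) + centers[c] + origin
            for k in range(cameras_per_cluster):
                camera_id = f"{cluster_id}-{k + 1:02d}"
                active_start, active_end = start_date, end_date
                if failure_prob > 0 and rng.random() < failure_prob:
                    dark = int(rng.integers(1, max(2, n_days // 2)))
                    if rng.random() < 0.5:
                        active_start = start_date + dt.timedelta(days=dark)
                    else:
                        active_end = end_date - dt.timedelta(days=dark)
                rows.append(
                    (site_id, cluster_id, camera_id,
                     float(xy[k, 0]), float(xy[k, 1]), active_start, active_end)
                )
    return pd.DataFrame(rows, columns=DEPLOYMENT_COLUMNS)


def _seasonal_profile(model: SpeciesModel, n_days: int) -> np.ndarray:
    days = np.arange(n_days)
    return 1.0 + model.seasonal_amplitude * np.sin(
        2.0 * np.pi * days / YEAR_DAYS + model.seasonal_phase
    )


def simulate_events(
    deployment: pd.DataFrame,
    species_models: "list[SpeciesModel] | tuple[SpeciesModel, ...]" = DEFAULT_SPECIES_MODELS,
    start_date: dt.date | None = None,
    n_days: int = YEAR_DAYS,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate raw trigger events for every camera and species.

    Per camera-day event counts are Poisson with rate
    ``daily_event_rate * seasonal(day) * camera_effect``; event times are
    uniform within the day at minute resolution. Each event additionally
    spawns, with probability ``within_day_cluster_prob``, one companion event
    1-29 minutes later at a uniformly chosen camera of the same cluster.
    Events outside a camera's active interval (or past the simulation end)
    are dropped.

    Returns a DataFrame with columns :data:`EVENT_COLUMNS`, sorted by
    timestamp; byte-identical across runs for a fixed seed.
    """
    if deployment is None or len(deployment) == 0:
        raise ValueError("deployment is empty: no cameras to simulate")
    if n_days < 1:
        raise ConfigurationError("n_days must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    dep = deployment.sort_values("camera_id", kind="mergesort").reset_index(drop=True)
    if start_date is None:
        start_date = min(pd.to_datetime(dep["active_start"]).dt.date)
    n_cams = len(dep)
    start_ts = pd.Timestamp(start_date)

    # per-camera active-day window [a0, a1] as day offsets from start_date
    a0 = (pd.to_datetime(dep["active_start"]) - start_ts).dt.days.to_numpy()
    a1 = (pd.to_datetime(dep["active_end"]) - start_ts).dt.days.to_numpy()
    a0 = np.clip(a0, 0, n_days - 1)
    a1 = np.clip(a1, 0, n_days - 1)

    cluster_codes, cluster_index = pd.factorize(dep["cluster_id"], sort=True)
    members_by_cluster = [
        np.flatnonzero(cluster_codes == c) for c in range(len(cluster_index))
    ]

    frames: list[pd.DataFrame] = []
    for model in species_models:
        if model.camera_heterogeneity_sd > 0:
            z = rng.standard_normal(n_cams)
            effects = np.exp(
                model.camera_heterogeneity_sd * z - 0.5 * model.camera_heterogeneity_sd**2
            )
        else:
            effects = np.ones(n_cams)
        lam = model.daily_event_rate * np.outer(effects, _seasonal_profile(model, n_days))
        counts = rng.poisson(lam)  # (n_cams, n_days)

        # mask days outside the camera's active interval
        day_grid = np.arange(n_days)
        active = (day_grid[None, :] >= a0[:, None]) & (day_grid[None, :] <= a1[:, None])
        counts = np.where(active, counts, 0)

        flat = counts.ravel()
        total = int(flat.sum())
        if total == 0:
            continue
        cam_of = np.repeat(np.arange(n_cams), counts.sum(axis=1))
        day_of = np.repeat(np.tile(day_grid, n_cams), flat)
        minute = rng.integers(0, MINUTES_PER_DAY, size=total)
        t_min = day_of * MINUTES_PER_DAY + minute

        cams_all, t_all = [cam_of], [t_min]
        if model.within_day_cluster_prob > 0:
            spawn = rng.random(total) < model.within_day_cluster_prob
            if spawn.any():
                parents = np.flatnonzero(spawn)
                comp_cam = np.empty(parents.size, dtype=np.int64)
                parent_clusters = cluster_codes[cam_of[parents]]
                for c, members in enumerate(members_by_cluster):
                    sel = parent_clusters == c
                    if sel.any():
                        comp_cam[sel] = members[rng.integers(0, members.size, sel.sum())]
                comp_t = t_min[parents] + rng.integers(1, 30, size=parents.size)
                comp_day = comp_t // MINUTES_PER_DAY
                keep = (
                    (comp_t < n_days * MINUTES_PER_DAY)
                    & (comp_day >= a0[comp_cam])
                    & (comp_day <= a1[comp_cam])
                )
                cams_all.append(comp_cam[keep])
                t_all.append(comp_t[keep])

        cam_idx = np.concatenate(cams_all)
        t_cat = np.concatenate(t_all)
        frames.append(
            pd.DataFrame(
                {
                    "site_id": dep["site_id"].to_numpy()[cam_idx],
                    "camera_id": dep["camera_id"].to_numpy()[cam_idx],
                    "species_id": model.species_id,
                    "timestamp": start_ts + pd.to_timedelta(t_cat, unit="m"),
                }
            )
        )

    if not frames:
        return pd.DataFrame(columns=EVENT_COLUMNS).astype({"timestamp": "datetime64[ns]"})
    events = pd.concat(frames, ignore_index=True)
    events = events.sort_values(
        ["timestamp", "site_id", "camera_id", "species_id"], kind="mergesort"
    ).reset_index(drop=True)
    return events[EVENT_COLUMNS]
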