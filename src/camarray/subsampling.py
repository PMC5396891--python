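"""Monte Carlo parsing of a yearlong dataset into hypothetical study designs.

Each draw fixes an array size m (cameras per site), a season window
(start day and length, wrapping across the year boundary), and a replicate
length L; the season is cut into k = floor(S/L) replicates and each
(site, replicate) cell is scored 1 iff the selected cameras produced at
least one independent detection in it. Repeating the draw thousands of
times maps out how survey and season detectability respond to design.

Two extraction paths exist: :func:`extract_replicate_matrix` is the
readable single-draw reference built directly on
:func:`camarray.events.deduplicate`, while :func:`run_monte_carlo` uses a
pre-sorted per-(species, site) event index for speed. The two are held
equivalent by tests.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from camarray.events import ValidationError, deduplicate
from camarray.synthetic import YEAR_DAYS

__all__ = [
    "MC_RESULT_COLUMNS",
    "DesignConfig",
    "SubsampleDraw",
    "ReplicateDetectionMatrix",
    "InvalidDrawError",
    "draw_design",
    "extract_replicate_matrix",
    "run_monte_carlo",
]

logger = logging.getLogger(__name__)

SECONDS_PER_DAY = 86_400

MC_RESULT_COLUMNS = [
    "iteration_id",
    "species_id",
    "array_size",
    "season_start",
    "season_length",
    "replicate_length",
    "n_replicates",
    "p",
    "p_star",
]


class InvalidDrawError(ValueError):
    """Raised when a valid design cannot be drawn from the configured ranges."""


@dataclass(frozen=True)
class DesignConfig:
    """Ranges from which Monte Carlo study designs are drawn.

    ``array_sizes`` lists admissible m values (cameras per site, 1-10);
    season length S is drawn uniformly on ``season_length_range`` in
    ``"random"`` mode or uniformly over ``season_grid`` in ``"grid"`` mode
    (used for season-length sweeps at fixed designs); replicate length L is
    uniform on ``replicate_length_range`` (1-28 days, the range reported
    across camera-trap studies). Draws with L > S are rejected and redrawn.
    """

    array_sizes: tuple[int, ...] = tuple(range(1, 11))
    season_length_range: tuple[int, int] = (1, 365)
    replicate_length_range: tuple[int, int] = (1, 28)
    season_mode: str = "random"
    season_grid: tuple[int, ...] | None = None
    max_redraws: int = 1000

    def __post_init__(self) -> None:
        if not self.array_sizes or any(not 1 <= m <= 10 for m in self.array_sizes):
            raise InvalidDrawError("array_sizes must be non-empty with values in 1..10")
        s_lo, s_hi = self.season_length_range
        if not 1 <= s_lo <= s_hi <= 365:
            raise InvalidDrawError("season_length_range must satisfy 1 <= lo <= hi <= 365")
        l_lo, l_hi = self.replicate_length_range
        if not 1 <= l_lo <= l_hi <= 28:
            raise InvalidDrawError("replicate_length_range must satisfy 1 <= lo <= hi <= 28")
        if self.season_mode not in ("random", "grid"):
            raise InvalidDrawError("season_mode must be 'random' or 'grid'")
        if self.season_mode == "grid":
            if not self.season_grid:
                raise InvalidDrawError("grid mode requires a non-empty season_grid")
            if any(not 1 <= s <= 365 for s in self.season_grid):
                raise InvalidDrawError("season_grid values must lie in 1..365")


@dataclass(frozen=True)
class SubsampleDraw:
    """One Monte Carlo design draw.

    ``selected_cameras`` maps each site to the sorted tuple of m camera ids
    the hypothetical design would have deployed; ``n_replicates`` is
    floor(S / L), trailing remainder days being discarded.
    """

    iteration_id: int
    array_size: int
    season_start: int
    season_length: int
    replicate_length: int
    n_replicates: int
    selected_cameras: dict[str, tuple[str, ...]] = field(compare=True)


@dataclass
class ReplicateDetectionMatrix:
    """Binary site x replicate detection matrix for one species and draw."""

    values: np.ndarray  # shape (N, k), dtype int8, cells 0/1
    sites: tuple[str, ...]
    species_id: str
    draw: SubsampleDraw

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.values.shape[1]


def _site_cameras(deployment) -> dict[str, list[str]]:
    """Site -> sorted camera ids; accepts a deployment table or a ready mapping."""
    if isinstance(deployment, dict):
        return {site: sorted(cams) for site, cams in deployment.items()}
    return {
        site: sorted(grp["camera_id"])
        for site, grp in deployment.groupby("site_id", sort=True)
    }


def draw_design(
    design_config: DesignConfig,
    deployment: "pd.DataFrame | dict[str, list[str]]",
    rng: np.random.Generator,
    iteration_id: int = 0,
) -> SubsampleDraw:
    """Draw one study design uniformly from the configured ranges.

    ``deployment`` is the camera table (or a ready site -> cameras mapping).
    Camera subsets are drawn uniformly without replacement per site; (S, L)
    pairs with L > S are rejected and redrawn (up to ``max_redraws``,
    rejections logged at DEBUG level).
    """
    site_cams = _site_cameras(deployment)
    if not site_cams:
        raise ValidationError("deployment is empty")
    m = int(design_config.array_sizes[rng.integers(0, len(design_config.array_sizes))])
    short = [s for s, cams in site_cams.items() if len(cams) < m]
    if short:
        raise InvalidDrawError(f"array size {m} exceeds camera count at sites {short}")

    s_lo, s_hi = design_config.season_length_range
    l_lo, l_hi = design_config.replicate_length_range
    rejections = 0
    for _ in range(design_config.max_redraws):
        if design_config.season_mode == "grid":
            grid = design_config.season_grid
            season_length = int(grid[rng.integers(0, len(grid))])
        else:
            season_length = int(rng.integers(s_lo, s_hi + 1))
        replicate_length = int(rng.integers(l_lo, l_hi + 1))
        if replicate_length <= season_length:
            break
        rejections += 1
    else:
        raise InvalidDrawError(
            f"no draw with L <= S found in {design_config.max_redraws} attempts"
        )
    if rejections:
        logger.debug("rejected %d draws with L > S", rejections)

    season_start = int(rng.integers(1, YEAR_DAYS + 1))
    selected = {
        site: tuple(sorted(
            np.asarray(cams, dtype=object)[rng.choice(len(cams), size=m, replace=False)]
        ))
        for site, cams in sorted(site_cams.items())
    }
    return SubsampleDraw(
        iteration_id=iteration_id,
        array_size=m,
        season_start=season_start,
        season_length=season_length,
        replicate_length=replicate_length,
        n_replicates=season_length // replicate_length,
        selected_cameras=selected,
    )


def _replicate_day_index(draw: SubsampleDraw, n_days: int = YEAR_DAYS) -> np.ndarray:
    """0-based day-of-year indices of shape (k, L), wrapping modulo the year."""
    k, L = draw.n_replicates, draw.replicate_length
    start0 = draw.season_start - 1
    return ((start0 + np.arange(k * L)) % n_days).reshape(k, L)


def extract_replicate_matrix(
    events: pd.DataFrame,
    draw: SubsampleDraw,
    species_id: str,
    year_start: dt.date,
    window_minutes: float = 30.0,
    attribution: str = "rededuplicate",
) -> ReplicateDetectionMatrix:
    """Score one draw's site x replicate detection matrix for one species.

    With the default ``attribution="rededuplicate"`` the independence rule is
    re-applied to the selected cameras only — the record the smaller array
    would actually have produced. With ``attribution="first_camera"`` the
    full-site record is deduplicated once, each detection is attributed to
    the camera of its earliest event, and the subset merely filters
    detections; results differ only when chains span cameras.
    """
    if attribution not in ("rededuplicate", "first_camera"):
        raise ValidationError(f"unknown attribution mode {attribution!r}")
    if len(events) and species_id not in set(events["species_id"]):
        raise ValidationError(f"species {species_id!r} absent from the event table")

    sites = tuple(sorted(draw.selected_cameras))
    k = draw.n_replicates
    day_idx = _replicate_day_index(draw)
    values = np.zeros((len(sites), k), dtype=np.int8)
    sp_events = events[events["species_id"] == species_id] if len(events) else events

    for i, site in enumerate(sites):
        site_events = sp_events[sp_events["site_id"] == site] if len(sp_events) else sp_events
        if len(site_events) == 0:
            continue
        if attribution == "rededuplicate":
            det = deduplicate(
                site_events, window_minutes, camera_subset=draw.selected_cameras[site]
            )
            first_ts = det["timestamp_first"]
        else:
            det = deduplicate(site_events, window_minutes)
            # attribute each chain to the camera of its earliest event
            srt = site_events.sort_values("timestamp", kind="mergesort")
            first_cam = srt.drop_duplicates("timestamp").set_index("timestamp")["camera_id"]
            cam_of_chain = det["timestamp_first"].map(first_cam)
            keep = cam_of_chain.isin(set(draw.selected_cameras[site]))
            first_ts = det.loc[keep, "timestamp_first"]
        if len(first_ts) == 0:
            continue
        days0 = (
            pd.to_datetime(first_ts).dt.normalize() - pd.Timestamp(year_start)
        ).dt.days.to_numpy()
        if (days0 < 0).any() or (days0 >= YEAR_DAYS).any():
            raise ValidationError("detection outside the indexed year")
        det_days = np.zeros(YEAR_DAYS, dtype=bool)
        det_days[days0] = True
        values[i] = det_days[day_idx].any(axis=1)
    return ReplicateDetectionMatrix(values=values, sites=sites, species_id=species_id, draw=draw)


class _EventIndex:
    """Pre-sorted per-(species, site) event arrays for fast repeated subsetting."""

    def __init__(
        self,
        events: pd.DataFrame,
        deployment: pd.DataFrame,
        species_ids: list[str],
        year_start: dt.date,
        window_minutes: float,
        attribution: str,
    ) -> None:
        self.window_seconds = window_minutes * 60.0
        self.attribution = attribution
        self.site_cams = _site_cameras(deployment)
        self.sites = tuple(sorted(self.site_cams))
        self.cam_code = {
            site: {cam: i for i, cam in enumerate(cams)}
            for site, cams in self.site_cams.items()
        }
        self._data: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        if len(events) == 0:
            return
        t_sec = (
            (pd.to_datetime(events["timestamp"]) - pd.Timestamp(year_start))
            .dt.total_seconds()
            .to_numpy()
        )
        if (t_sec < 0).any() or (t_sec >= YEAR_DAYS * SECONDS_PER_DAY).any():
            raise ValidationError("events outside the indexed year")
        for (species, site), grp_idx in events.groupby(
            ["species_id", "site_id"], sort=True
        ).indices.items():
            if species not in species_ids or site not in self.cam_code:
                continue
            t = t_sec[grp_idx]
            order = np.argsort(t, kind="stable")
            t = t[order]
            codes = (
                events["camera_id"]
                .to_numpy()[grp_idx][order]
            )
            codes = np.array([self.cam_code[site][c] for c in codes], dtype=np.int64)
            if self.attribution == "first_camera":
                starts = np.concatenate(
                    [[0], np.flatnonzero(np.diff(t) >= self.window_seconds) + 1]
                )
                self._data[(species, site)] = (
                    (t[starts] // SECONDS_PER_DAY).astype(np.int64),
                    codes[starts],
                )
            else:
                self._data[(species, site)] = (t, codes)

    def detection_days(
        self, species: str, site: str, mask_table: np.ndarray
    ) -> np.ndarray:
        """Boolean day-of-year vector of independent-detection start days."""
        det = np.zeros(YEAR_DAYS, dtype=bool)
        entry = self._data.get((species, site))
        if entry is None:
            return det
        if self.attribution == "first_camera":
            start_days, first_codes = entry
            det[start_days[mask_table[first_codes]]] = True
            return det
        t, codes = entry
        t = t[mask_table[codes]]
        if t.size == 0:
            return det
        starts = np.concatenate(
            [[0], np.flatnonzero(np.diff(t) >= self.window_seconds) + 1]
        )
        det[(t[starts] // SECONDS_PER_DAY).astype(np.int64)] = True
        return det


def run_monte_carlo(
    events: pd.DataFrame,
    deployment: pd.DataFrame,
    design_config: DesignConfig | None = None,
    species_ids: list[str] | None = None,
    n_iterations: int = 5000,
    master_seed: int = 0,
    year_start: dt.date | None = None,
    window_minutes: float = 30.0,
    attribution: str = "rededuplicate",
) -> pd.DataFrame:
    """Run the Monte Carlo design study and return a tidy results table.

    One design draw per iteration, scored for every species: columns
    :data:`MC_RESULT_COLUMNS` with one row per (iteration, species) holding
    the survey detection probability p = sum(P)/(N k) and the season
    detection probability p* = 1 - (1 - p)^k.

    Per-iteration RNG substreams are spawned from ``master_seed`` by
    counter-based seeding, so the table is exactly reproducible and
    insensitive to iteration order.
    """
    if n_iterations < 1:
        raise ValidationError("n_iterations must be >= 1")
    design_config = design_config or DesignConfig()
    if species_ids is None:
        species_ids = sorted(events["species_id"].unique()) if len(events) else []
    if year_start is None:
        year_start = min(pd.to_datetime(deployment["active_start"]).dt.date)

    index = _EventIndex(
        events, deployment, list(species_ids), year_start, window_minutes, attribution
    )
    n_cams = {site: len(cams) for site, cams in index.site_cams.items()}

    records: list[tuple] = []
    for i in range(n_iterations):
        rng = np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(i,)))
        draw = draw_design(design_config, index.site_cams, rng, iteration_id=i)
        day_idx = _replicate_day_index(draw)
        k = draw.n_replicates
        masks = {}
        for site in index.sites:
            table = np.zeros(n_cams[site], dtype=bool)
            table[[index.cam_code[site][c] for c in draw.selected_cameras[site]]] = True
            masks[site] = table
        for species in species_ids:
            total = 0
            for site in index.sites:
                det = index.detection_days(species, site, masks[site])
                total += int(det[day_idx].any(axis=1).sum())
            p = total / (len(index.sites) * k)
            p_star = 1.0 - (1.0 - p) ** k
            records.append(
                (
                    i,
                    species,
                    draw.array_size,
                    draw.season_start,
                    draw.season_length,
                    draw.replicate_length,
                    k,
                    p,
                    p_star,
                )
            )
    return pd.DataFrame(records, columns=MC_RESULT_COLUMNS)
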