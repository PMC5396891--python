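"""Deployment geometry and event-stream generator behaviour."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from camarray.synthetic import (
    ConfigurationError,
    SpacingConfig,
    SpeciesModel,
    generate_deployment,
    simulate_events,
)


def pairwise_mean(xy: np.ndarray) -> float:
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    iu = np.triu_indices(len(xy), k=1)
    return float(d[iu].mean())


class TestDeployment:
    def test_default_field_design_counts_and_determinism(self):
        dep = generate_deployment(4, 2, 5, seed=1)
        assert len(dep) == 40
        assert (dep.groupby("site_id").size() == 10).all()
        assert (dep.groupby(["site_id", "cluster_id"]).size() == 5).all()
        pd.testing.assert_frame_equal(dep, generate_deployment(4, 2, 5, seed=1))

    def test_single_camera_degenerate(self):
        dep = generate_deployment(1, 1, 1, seed=7)
        assert len(dep) == 1

    def test_intra_cluster_spacing_band_bruteforce(self):
        spacing = SpacingConfig()
        dep = generate_deployment(2, 2, 5, spacing=spacing, seed=3)
        assert len(dep) == 20
        for _, grp in dep.groupby("cluster_id"):
            mean_dist = pairwise_mean(grp[["x_m", "y_m"]].to_numpy())
            assert abs(mean_dist - spacing.intra_cluster_mean_m) <= spacing.intra_cluster_band_m

    def test_inter_cluster_centroid_distance(self):
        spacing = SpacingConfig()
        dep = generate_deployment(3, 2, 5, spacing=spacing, seed=11)
        for _, grp in dep.groupby("site_id"):
            cents = grp.groupby("cluster_id")[["x_m", "y_m"]].mean().to_numpy()
            d = np.linalg.norm(cents[0] - cents[1])
            # centroids of 5 uniform points jitter around the exact cluster centres
            assert abs(d - spacing.inter_cluster_distance_m) < 60.0

    @pytest.mark.parametrize("bad", [dict(n_sites=0), dict(clusters_per_site=0),
                                     dict(cameras_per_cluster=-1)])
    def test_invalid_counts_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            generate_deployment(**{**dict(n_sites=1, clusters_per_site=1,
                                          cameras_per_cluster=1), **bad}, seed=0)

    def test_invalid_spacing_rejected(self):
        with pytest.raises(ConfigurationError):
            SpacingConfig(intra_cluster_mean_m=-5.0)


class TestSimulateEvents:
    def test_zero_rate_gives_no_events(self):
        dep = generate_deployment(1, 1, 2, seed=0)
        events = simulate_events(dep, [SpeciesModel("sp", 0.0)], seed=1)
        assert len(events) == 0

    def test_total_event_count_matches_poisson_moments(self):
        # lambda=2/day, 1 camera, 365 days: total ~ Poisson(730), sd ~ 27
        dep = generate_deployment(1, 1, 1, seed=0)
        events = simulate_events(dep, [SpeciesModel("sp", 2.0)], seed=5)
        assert abs(len(events) - 730) <= 3 * np.sqrt(730)

    def test_companion_events_always_within_window(self):
        dep = generate_deployment(1, 1, 2, seed=2)
        events = simulate_events(
            dep,
            [SpeciesModel("sp", 0.2, within_day_cluster_prob=1.0)],
            n_days=60,
            seed=3,
        )
        start = pd.Timestamp(dt.date(2015, 1, 1))
        t = np.sort((events["timestamp"] - start).dt.total_seconds().to_numpy() / 60.0)
        horizon = 60 * 1440
        checked = 0
        for i, ti in enumerate(t):
            if ti > horizon - 30:
                # a primary whose companion fell past the simulation end may be isolated
                continue
            prev_gap = ti - t[i - 1] if i > 0 else np.inf
            next_gap = t[i + 1] - ti if i + 1 < len(t) else np.inf
            assert min(prev_gap, next_gap) < 30
            checked += 1
        assert checked > 10

    def test_doubling_rate_doubles_event_count(self):
        dep = generate_deployment(1, 1, 1, seed=0)
        totals = {1.0: 0, 2.0: 0}
        for lam in totals:
            for seed in range(10):
                totals[lam] += len(
                    simulate_events(dep, [SpeciesModel("sp", lam)], seed=seed)
                )
        ratio = totals[2.0] / totals[1.0]
        # sums are Poisson(3650) and Poisson(7300); 3 SE on the ratio is ~0.07
        assert abs(ratio - 2.0) < 0.15

    def test_timestamps_within_simulated_window(self):
        dep = generate_deployment(2, 1, 2, seed=4)
        n_days = 45
        events = simulate_events(
            dep, [SpeciesModel("sp", 1.0, within_day_cluster_prob=0.5)],
            n_days=n_days, seed=6,
        )
        start = pd.Timestamp(dt.date(2015, 1, 1))
        assert (events["timestamp"] >= start).all()
        assert (events["timestamp"] < start + pd.Timedelta(days=n_days)).all()

    def test_fixed_seed_is_byte_identical(self):
        dep = generate_deployment(2, 2, 3, seed=9)
        a = simulate_events(dep, seed=10).to_csv(index=False)
        b = simulate_events(dep, seed=10).to_csv(index=False)
        assert a == b

    def test_empty_deployment_rejected(self):
        with pytest.raises(ValueError):
            simulate_events(pd.DataFrame(), seed=0)

    def test_camera_failure_respects_active_interval(self):
        dep = generate_deployment(2, 1, 3, seed=1, failure_prob=1.0)
        events = simulate_events(dep, [SpeciesModel("sp", 1.0)], seed=2)
        active = dep.set_index("camera_id")[["active_start", "active_end"]]
        days = events["timestamp"].dt.date
        starts = events["camera_id"].map(active["active_start"])
        ends = events["camera_id"].map(active["active_end"])
        assert ((days >= starts) & (days <= ends)).all()

    def test_invalid_species_model_rejected(self):
        with pytest.raises(ConfigurationError):
            SpeciesModel("sp", -1.0)
        with pytest.raises(ConfigurationError):
            SpeciesModel("sp", 1.0, seasonal_amplitude=1.0)
        with pytest.raises(ConfigurationError):
            SpeciesModel("sp", 1.0, within_day_cluster_prob=1.5)
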