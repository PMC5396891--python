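"""Design draws, replicate-matrix extraction, and the Monte Carlo engine."""

import numpy as np
import pandas as pd
import pytest

from camarray.subsampling import (
    DesignConfig,
    InvalidDrawError,
    SubsampleDraw,
    _replicate_day_index,
    draw_design,
    extract_replicate_matrix,
    run_monte_carlo,
)
from camarray.events import ValidationError
from conftest import YEAR_START, mk_deployment, mk_events, random_events
from _oracles import replicate_matrix_enumeration


def ten_camera_deployment(n_sites=2):
    return mk_deployment(
        {f"S{i}": [f"S{i}-{j:02d}" for j in range(1, 11)] for i in range(1, n_sites + 1)}
    )


def manual_draw(deployment, m, season_start, season_length, replicate_length, rng=None):
    rng = rng or np.random.default_rng(0)
    selected = {
        site: tuple(sorted(np.random.default_rng(1).choice(sorted(grp["camera_id"]), m, replace=False)))
        for site, grp in deployment.groupby("site_id")
    }
    return SubsampleDraw(
        iteration_id=0, array_size=m, season_start=season_start,
        season_length=season_length, replicate_length=replicate_length,
        n_replicates=season_length // replicate_length, selected_cameras=selected,
    )


class TestDrawDesign:
    def test_collapsed_ranges_force_the_design(self, rng):
        dep = ten_camera_deployment()
        cfg = DesignConfig(array_sizes=(3,), season_length_range=(90, 90),
                           replicate_length_range=(10, 10))
        for _ in range(5):
            draw = draw_design(cfg, dep, rng)
            assert draw.array_size == 3
            assert draw.n_replicates == 9
            assert all(len(v) == 3 for v in draw.selected_cameras.values())

    def test_full_array_selects_whole_site(self, rng):
        dep = ten_camera_deployment()
        cfg = DesignConfig(array_sizes=(10,))
        draw = draw_design(cfg, dep, rng)
        for site, grp in dep.groupby("site_id"):
            assert set(draw.selected_cameras[site]) == set(grp["camera_id"])

    def test_array_size_frequencies_uniform(self):
        dep = ten_camera_deployment(n_sites=1)
        cfg = DesignConfig()
        rng = np.random.default_rng(7)
        counts = np.zeros(10)
        n = 10_000
        for _ in range(n):
            counts[draw_design(cfg, dep, rng).array_size - 1] += 1
        se = np.sqrt(n * 0.1 * 0.9)
        assert (np.abs(counts - n * 0.1) <= 3 * se).all()

    def test_replicate_longer_than_season_always_rejected(self, rng):
        dep = ten_camera_deployment()
        cfg = DesignConfig(season_length_range=(5, 5), replicate_length_range=(7, 7),
                           max_redraws=50)
        with pytest.raises(InvalidDrawError):
            draw_design(cfg, dep, rng)

    def test_redraw_resolves_partial_conflicts(self, rng):
        dep = ten_camera_deployment()
        cfg = DesignConfig(season_length_range=(5, 60), replicate_length_range=(7, 7))
        for _ in range(50):
            draw = draw_design(cfg, dep, rng)
            assert draw.replicate_length <= draw.season_length

    def test_oversized_array_rejected(self, rng, two_site_deployment):
        cfg = DesignConfig(array_sizes=(5,))
        with pytest.raises(InvalidDrawError):
            draw_design(cfg, two_site_deployment, rng)

    def test_invalid_config_ranges_rejected(self):
        with pytest.raises(InvalidDrawError):
            DesignConfig(array_sizes=(0, 3))
        with pytest.raises(InvalidDrawError):
            DesignConfig(replicate_length_range=(1, 29))
        with pytest.raises(InvalidDrawError):
            DesignConfig(season_mode="grid")

    def test_grid_mode_draws_from_grid(self, rng):
        dep = ten_camera_deployment()
        grid = (30, 90, 180)
        cfg = DesignConfig(season_mode="grid", season_grid=grid)
        for _ in range(30):
            assert draw_design(cfg, dep, rng).season_length in grid


class TestExtractReplicateMatrix:
    def test_zero_events_all_zero_matrix(self, two_site_deployment):
        draw = manual_draw(two_site_deployment, 2, 10, 60, 10)
        matrix = extract_replicate_matrix(mk_events([]), draw, "sp", YEAR_START)
        assert matrix.values.shape == (2, 6)
        assert matrix.values.sum() == 0

    def test_year_wrap_window_arithmetic(self, two_site_deployment):
        draw = manual_draw(two_site_deployment, 1, 360, 10, 5)
        days = _replicate_day_index(draw) + 1  # 1-based days
        assert days[0].tolist() == [360, 361, 362, 363, 364]
        assert days[1].tolist() == [365, 1, 2, 3, 4]

    def test_wrapped_replicate_catches_new_year_event(self, two_site_deployment):
        cam = two_site_deployment["camera_id"].iloc[0]
        draw = SubsampleDraw(0, 1, 360, 10, 5, 2, {"S1": (cam,)})
        events = mk_events([("S1", cam, "sp", 2 * 1440 + 100)])  # day 3
        matrix = extract_replicate_matrix(events, draw, "sp", YEAR_START)
        assert matrix.values.tolist() == [[0, 1]]

    def test_matches_enumeration_oracle_on_random_inputs(self):
        dep = mk_deployment(
            {"S1": [f"S1-{j:02d}" for j in range(1, 4)],
             "S2": [f"S2-{j:02d}" for j in range(1, 4)]}
        )
        rng = np.random.default_rng(11)
        cfg = DesignConfig(array_sizes=(1, 2, 3), season_length_range=(5, 80))
        for _ in range(25):
            events = random_events(rng, int(rng.integers(5, 60)), horizon_days=90)
            draw = draw_design(cfg, dep, rng)
            for sp in ("sp1", "sp2"):
                got = extract_replicate_matrix(events, draw, sp, YEAR_START)
                expected = replicate_matrix_enumeration(events, draw, sp, YEAR_START)
                np.testing.assert_array_equal(got.values, expected)

    def test_unknown_species_rejected(self, two_site_deployment):
        draw = manual_draw(two_site_deployment, 1, 1, 30, 10)
        events = mk_events([("S1", "S1-01", "deer", 100)])
        with pytest.raises(ValidationError):
            extract_replicate_matrix(events, draw, "unicorn", YEAR_START)

    def test_adding_a_camera_never_removes_detections(self):
        # midnight-spanning chains excluded: merge dating is by chain start
        dep = ten_camera_deployment(n_sites=1)
        rng = np.random.default_rng(3)
        for _ in range(20):
            events = random_events(
                rng, 60, sites=("S1",), cams_per_site=10, horizon_days=80,
                avoid_midnight=True,
            )
            cams = sorted(dep["camera_id"])
            chosen = list(rng.choice(cams, size=4, replace=False))
            base = SubsampleDraw(0, 3, int(rng.integers(1, 365)), 60, 10, 6,
                                 {"S1": tuple(sorted(chosen[:3]))})
            grown = SubsampleDraw(0, 4, base.season_start, 60, 10, 6,
                                  {"S1": tuple(sorted(chosen))})
            a = extract_replicate_matrix(events, base, "sp1", YEAR_START).values
            b = extract_replicate_matrix(events, grown, "sp1", YEAR_START).values
            assert (b >= a).all()

    def test_attribution_modes_agree_without_cross_camera_chains(self, rng):
        dep = ten_camera_deployment(n_sites=1)
        rows = [("S1", f"S1-{int(rng.integers(1, 11)):02d}", "sp", int(d) * 1440 + 700)
                for d in rng.choice(300, size=40, replace=False)]
        events = mk_events(rows)
        draw = manual_draw(dep, 4, 50, 200, 14)
        a = extract_replicate_matrix(events, draw, "sp", YEAR_START, attribution="rededuplicate")
        b = extract_replicate_matrix(events, draw, "sp", YEAR_START, attribution="first_camera")
        np.testing.assert_array_equal(a.values, b.values)


class TestRunMonteCarlo:
    def test_single_iteration_single_row_per_species(self, rng, two_site_deployment):
        events = random_events(rng, 50)
        cfg = DesignConfig(array_sizes=(1, 2, 3))
        mc = run_monte_carlo(events, two_site_deployment, cfg, n_iterations=1,
                             master_seed=5, year_start=YEAR_START)
        assert len(mc) == 2  # sp1, sp2
        assert set(mc["species_id"]) == {"sp1", "sp2"}

    def test_fixed_master_seed_reproduces_table_exactly(self, rng, two_site_deployment):
        events = random_events(rng, 80)
        cfg = DesignConfig(array_sizes=(1, 2))
        kwargs = dict(design_config=cfg, n_iterations=40, master_seed=9,
                      year_start=YEAR_START)
        a = run_monte_carlo(events, two_site_deployment, **kwargs)
        b = run_monte_carlo(events, two_site_deployment, **kwargs)
        pd.testing.assert_frame_equal(a, b)

    def test_fast_path_matches_reference_extraction(self, rng, two_site_deployment):
        events = random_events(rng, 120, horizon_days=200)
        cfg = DesignConfig(array_sizes=(1, 2, 3), season_length_range=(10, 180))
        master_seed = 21
        mc = run_monte_carlo(events, two_site_deployment, cfg, n_iterations=15,
                             master_seed=master_seed, year_start=YEAR_START)
        for i in range(15):
            it_rng = np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(i,)))
            draw = draw_design(cfg, two_site_deployment, it_rng, iteration_id=i)
            for sp in ("sp1", "sp2"):
                matrix = extract_replicate_matrix(events, draw, sp, YEAR_START)
                p_ref = matrix.values.mean()
                row = mc[(mc["iteration_id"] == i) & (mc["species_id"] == sp)]
                assert row["p"].iloc[0] == pytest.approx(p_ref, abs=1e-12)
                assert row["n_replicates"].iloc[0] == draw.n_replicates

    def test_matrix_dimensions_follow_floor_rule(self, rng, two_site_deployment):
        events = random_events(rng, 30)
        cfg = DesignConfig(array_sizes=(2,), season_length_range=(30, 150))
        mc = run_monte_carlo(events, two_site_deployment, cfg, n_iterations=30,
                             master_seed=2, year_start=YEAR_START)
        assert (mc["n_replicates"] == mc["season_length"] // mc["replicate_length"]).all()
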