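import datetime as dt

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from shapely.geometry import box

from deersurvey import (
    CountMatrix,
    daily_max_count_matrix,
    make_landscape_and_sites,
    mark_resight_estimate,
    pmsp_scenario,
    pmsp_transect_layout,
    read_photo_records,
    simulate_drone_flights,
    simulate_marked_photos,
    simulate_nmix_counts,
    strip_area_km2,
    tallies_from_photos,
)
from deersurvey.synthetic_data import (
    PMSP_AREA_KM2,
    PMSP_N_FLIGHTS,
    PMSP_N_OCCASIONS,
    PMSP_N_SITES,
    PMSP_SPACING_M,
    calibrate_abundance_intercept,
)


class TestLandscape:
    def test_default_layout_matches_study_design(self):
        land = make_landscape_and_sites(seed=1)
        assert len(land.sites) == 22
        xy = land.sites[["x", "y"]].to_numpy()
        d = squareform(pdist(xy))
        np.fill_diagonal(d, np.inf)
        nearest = d.min(axis=1)
        assert np.all(np.abs(nearest - PMSP_SPACING_M) <= 50)

    def test_flat_landscape_when_smoothness_infinite(self):
        land = make_landscape_and_sites(smoothness=np.inf, seed=2)
        assert (land.covariates["slope"] == 0).all()

    def test_same_seed_identical(self):
        a = make_landscape_and_sites(seed=5)
        b = make_landscape_and_sites(seed=5)
        pd.testing.assert_frame_equal(a.covariates, b.covariates)
        np.testing.assert_array_equal(a.grid.data, b.grid.data)

    def test_spacing_too_large_errors(self):
        with pytest.raises(ValueError, match="spacing"):
            make_landscape_and_sites(n_sites=22, spacing_m=2000.0)

    def test_standardized_covariates_are_z_scored(self):
        land = make_landscape_and_sites(seed=3)
        for col in ("elevation", "slope", "aspect_ns", "dist_edge"):
            assert abs(land.covariates_std[col].mean()) < 1e-9
            assert abs(land.covariates_std[col].std(ddof=1) - 1) < 1e-9


class TestSimulateNmixCounts:
    def test_perfect_detection_reproduces_latent_abundance(self):
        land = make_landscape_and_sites(seed=4)
        cm, truth = simulate_nmix_counts(
            land.covariates_std, alpha={"intercept": 0.0}, link="log",
            n_occasions=5, seed=6,
        )
        np.testing.assert_array_equal(cm.counts, np.tile(truth.N_true[:, None], (1, 5)))

    def test_mean_abundance_matches_poisson_rate(self):
        cov = pd.DataFrame({"site_id": [f"S{i}" for i in range(10_000)]})
        _, truth = simulate_nmix_counts(
            cov, beta={"intercept": np.log(5.0)}, alpha={"intercept": 0.0},
            n_occasions=1, seed=7,
        )
        assert truth.N_true.mean() == pytest.approx(5.0, rel=0.02)

    def test_fixed_seed_identical(self):
        land = make_landscape_and_sites(seed=8)
        a, _ = simulate_nmix_counts(land.covariates_std, seed=9)
        b, _ = simulate_nmix_counts(land.covariates_std, seed=9)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_single_occasion_marginal_is_thinned_poisson(self):
        # with one occasion, C ~ Poisson(lambda p); chi-square GOF on 10,000 draws
        n = 10_000
        lam, p = 5.0, 0.4
        cov = pd.DataFrame({"site_id": [f"S{i}" for i in range(n)]})
        cm, _ = simulate_nmix_counts(
            cov, beta={"intercept": np.log(lam)},
            alpha={"intercept": np.log(p)}, link="log", n_occasions=1, seed=10,
        )
        draws = cm.counts[:, 0].astype(int)
        kmax = 9
        observed = np.bincount(np.minimum(draws, kmax), minlength=kmax + 1)
        expected = stats.poisson.pmf(np.arange(kmax), lam * p)
        expected = np.append(expected, 1 - expected.sum()) * n
        chi = stats.chisquare(observed, expected)
        assert chi.pvalue > 0.01

    def test_calibrated_intercept_hits_target_total(self):
        land = make_landscape_and_sites(seed=11)
        slopes = {"aspect_ns": -0.26, "elevation": 0.23}
        b0 = calibrate_abundance_intercept(land.covariates_std, slopes, 409.6)
        _, truth = simulate_nmix_counts(
            land.covariates_std, beta={"intercept": b0, **slopes}, seed=12,
        )
        assert truth.lambda_true.sum() == pytest.approx(409.6, abs=1e-9)


class TestSimulateMarkedPhotos:
    def test_zero_rate_means_no_sightings(self):
        records, tallies, _ = simulate_marked_photos(rate=0.0, seed=1)
        assert records == []
        assert tallies["male_occurrences"].sum() == 0

    def test_fixed_seed_identical(self):
        _, a, _ = simulate_marked_photos(seed=13)
        _, b, _ = simulate_marked_photos(seed=13)
        pd.testing.assert_frame_equal(a, b)

    def test_round_trips_through_io(self, tmp_path):
        records, tallies, _ = simulate_marked_photos(
            n_males=10, n_females=5, n_fawns=2, days=20, seed=14)
        rows = [
            {
                "site_id": r.site_id, "timestamp": r.timestamp.isoformat(),
                "n_males": r.n_males, "n_females": r.n_females,
                "n_fawns": r.n_fawns, "n_unknown": r.n_unknown,
                "male_id": ";".join(sorted(r.male_ids)) if r.male_ids else "",
            }
            for r in records
        ]
        path = tmp_path / "photos.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        back = read_photo_records(path)
        assert len(back) == len(records)
        t2 = tallies_from_photos(back)
        merged = tallies[tallies["male_occurrences"] > 0].reset_index(drop=True)
        pd.testing.assert_frame_equal(
            t2[t2["male_occurrences"] > 0].reset_index(drop=True)[merged.columns],
            merged,
        )

    def test_photo_stream_feeds_count_matrix(self):
        records, _, _ = simulate_marked_photos(
            n_males=8, n_females=4, n_fawns=1, days=10, seed=15)
        sites = sorted({r.site_id for r in records})
        dates = [dt.date(2017, 12, 1) + dt.timedelta(days=j) for j in range(10)]
        cm = daily_max_count_matrix(records, sites, dates)
        assert cm.max_count() >= 1


class TestSimulateDroneFlights:
    def test_full_region_strip_is_a_census(self):
        region = box(0, 0, 2.0, 1.0)
        layout = pd.DataFrame([
            {"transect_id": "T1", "y_km": 0.5, "x_start_km": 0.0,
             "length_km": 2.0, "swath_km": 1.0}
        ])
        rec, truth = simulate_drone_flights(20.0, region, layout, n_flights=3, seed=16)
        assert rec["count"].tolist() == truth.extra["realized_N"]

    def test_fixed_seed_identical(self):
        region = box(0, 0, 2.8, PMSP_AREA_KM2 / 2.8)
        layout = pmsp_transect_layout()
        a, _ = simulate_drone_flights(25.0, region, layout, seed=17)
        b, _ = simulate_drone_flights(25.0, region, layout, seed=17)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_layout_errors(self):
        with pytest.raises(ValueError, match="empty"):
            simulate_drone_flights(10.0, box(0, 0, 1, 1), pd.DataFrame(), seed=0)


class TestPmspPreset:
    def test_design_constants(self):
        layout = pmsp_transect_layout()
        assert len(layout) == 12
        assert strip_area_km2(layout) == pytest.approx(1.375, abs=1e-9)
        # 300 m spacing between adjacent transects
        assert np.diff(layout["y_km"]).tolist() == pytest.approx([0.3] * 11)
        assert (layout["swath_km"] == 0.1).all()
        assert (PMSP_N_SITES, PMSP_AREA_KM2, PMSP_N_OCCASIONS, PMSP_N_FLIGHTS) == (
            22, 10.24, 90, 5)

    def test_scenario_is_coherent_and_deterministic(self):
        a = pmsp_scenario(seed=20)
        b = pmsp_scenario(seed=20)
        assert a.density_true == b.density_true
        np.testing.assert_array_equal(a.counts.counts, b.counts.counts)
        pd.testing.assert_frame_equal(a.tallies, b.tallies)
        pd.testing.assert_frame_equal(a.transects, b.transects)
        assert a.counts.n_sites == 22
        assert a.counts.n_occasions == 90
        assert a.transects["flight_id"].nunique() == 5
        # the three simulated surveys share one true density
        assert a.drone_truth.total_density_true == pytest.approx(a.density_true)
        total = sum(a.mark_resight_truth.demographics.values())
        assert total == pytest.approx(a.density_true * a.area_km2, abs=1.0)

    def test_mark_resight_recovery_single_scenario(self):
        # homogeneous sighting rates and extrapolation 1.0: the ratio
        # estimator should land near the known total
        sc = pmsp_scenario(seed=21)
        res = mark_resight_estimate(sc.tallies, extrapolation=1.0,
                                    area_km2=sc.area_km2)
        total = sum(sc.mark_resight_truth.demographics.values())
        assert res.population == pytest.approx(total, rel=0.15)
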