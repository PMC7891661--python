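"""Forward simulators: determinism, noise models, ground-truth closure."""

import numpy as np
import pandas as pd
import pytest

from taurflux.incubation import analyze_experiment, fit_release_slope
from taurflux.synthetic import (
    CommunityConfig,
    IncubationConfig,
    generate_fish_counts,
    generate_incubation_experiment,
    generate_season_scenario,
    generate_specimen_set,
    generate_tracer_samples,
)
from taurflux.tracer import TracerConfig, estimate_rates


class TestIncubationGenerator:
    def test_noise_free_slope_is_exact(self):
        config = IncubationConfig(
            true_release_per_individual={"taurine": 0.24},
            n_individuals=50,
            jar_volume_l=0.5,
            plateau_time_h={"taurine": 8.0},
            noise_cv=0.0,
            seed=0,
        )
        exp = generate_incubation_experiment(config)
        # 0.24 nmol/ind/d × 50 / (0.5 L × 24 h/d) = 1 nmol/L/h, exact line
        slope, r2, _, _ = fit_release_slope(exp.times_h, exp.concentrations["taurine"][0])
        assert slope == pytest.approx(1.0, rel=1e-12)
        assert r2 == pytest.approx(1.0)

    def test_zero_release_stays_at_baseline(self):
        config = IncubationConfig(
            true_release_per_individual={"taurine": 0.0},
            n_individuals=50, noise_cv=0.0, baseline_nmol_l={"taurine": 3.0},
        )
        exp = generate_incubation_experiment(config)
        assert np.allclose(exp.concentrations["taurine"], 3.0)

    def test_seed_reproducibility(self):
        kw = dict(
            true_release_per_individual={"taurine": 1.0},
            n_individuals=50, noise_cv=0.05,
        )
        a = generate_incubation_experiment(IncubationConfig(seed=5, **kw))
        b = generate_incubation_experiment(IncubationConfig(seed=5, **kw))
        c = generate_incubation_experiment(IncubationConfig(seed=6, **kw))
        assert np.array_equal(a.concentrations["taurine"], b.concentrations["taurine"])
        assert not np.array_equal(a.concentrations["taurine"], c.concentrations["taurine"])

    def test_rejects_bad_times(self):
        with pytest.raises(ValueError):
            IncubationConfig(
                true_release_per_individual={"taurine": 1.0},
                n_individuals=10, sample_times_h=(0, 1, 1),
            )

    def test_concentrations_non_negative(self):
        config = IncubationConfig(
            true_release_per_individual={"taurine": 2.0},
            n_individuals=100, noise_cv=0.5, seed=99,
        )
        exp = generate_incubation_experiment(config)
        assert np.all(exp.concentrations["taurine"] >= 0)


class TestSpecimenGenerator:
    def test_degenerate_distribution(self):
        table = generate_specimen_set(1, (1000.0, 0.0), (300.0, 0.0), seed=0)
        assert table.iloc[0]["length_um"] == 1000.0
        assert table.iloc[0]["diameter_um"] == 300.0

    def test_reproducible(self):
        a = generate_specimen_set(100, seed=4)
        b = generate_specimen_set(100, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_mean_within_three_se(self):
        n, mean, sd = 10_000, 1000.0, 150.0
        table = generate_specimen_set(n, (mean, sd), seed=8)
        se = sd / np.sqrt(n)
        assert abs(table["length_um"].mean() - mean) < 3 * se

    def test_all_positive(self):
        table = generate_specimen_set(500, (50.0, 100.0), seed=1)
        assert (table > 0).all().all()


class TestTracerGenerator:
    def test_worked_dpm_example(self):
        # expected net filter DPM 13320 at V=0.01 L, t=6 h, SA=60 mCi/mmol
        cfg = TracerConfig.taurine_14c(
            sample_volume_l=0.01, incubation_time_h=6.0, blank_dpm_mean=0.0
        )
        sample = generate_tracer_samples(40.0, 0.0, cfg, poisson_noise=False)
        assert sample.filter_dpm[0] == pytest.approx(13320.0)
        est = estimate_rates(sample)
        assert est.assimilation == pytest.approx(40.0, rel=1e-9)

    def test_zero_rates_at_blank(self):
        cfg = TracerConfig.taurine_14c(blank_dpm_mean=20.0)
        sample = generate_tracer_samples(0.0, 0.0, cfg, poisson_noise=False)
        assert np.allclose(sample.filter_dpm, 20.0)
        assert estimate_rates(sample).uptake == 0.0

    def test_dpm_non_negative_and_reproducible(self):
        cfg = TracerConfig.taurine_14c()
        a = generate_tracer_samples(1.0, 1.0, cfg, seed=3)
        b = generate_tracer_samples(1.0, 1.0, cfg, seed=3)
        assert np.array_equal(a.filter_dpm, b.filter_dpm)
        assert np.all(a.filter_dpm >= 0) and np.all(a.wick_dpm >= 0)


class TestFishGenerator:
    def config(self, **kw):
        base = dict(
            total_cells_per_ml=1e5,
            taxon_fractions={"A": 0.6, "B": 0.4},
            fraction_substrate_positive={"A": 1.0, "B": 1.0},
            cell_rate_lognormal_params={"A": (10.0, 0.5), "B": (5.0, 0.5)},
            seed=2,
        )
        base.update(kw)
        return CommunityConfig(**base)

    def test_all_substrate_positive(self):
        counts, _ = generate_fish_counts(self.config())
        assert (counts["probe_substrate_positive"] == counts["probe_positive"]).all()

    def test_single_taxon_matches_dapi(self):
        config = self.config(
            taxon_fractions={"A": 1.0},
            fraction_substrate_positive={"A": 0.5},
            cell_rate_lognormal_params={"A": (10.0, 0.5)},
        )
        counts, _ = generate_fish_counts(config)
        assert counts["probe_positive"].iloc[0] == counts["dapi_count"].iloc[0]

    def test_degenerate_lognormal_recovers_median(self):
        config = self.config(
            taxon_fractions={"A": 1.0},
            fraction_substrate_positive={"A": 1.0},
            cell_rate_lognormal_params={"A": (10.0, 0.0)},
            cells_counted_per_filter=10_000,
        )
        _, areas = generate_fish_counts(config, rate_per_area_amol_um2_d=2.0)
        recovered = (areas["area_um2"] * 2.0).mean()
        assert recovered == pytest.approx(10.0, rel=0.05)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            self.config(taxon_fractions={"A": 0.6, "B": 0.5})


class TestSeasonScenario:
    def test_unknown_season_rejected(self):
        with pytest.raises(ValueError):
            generate_season_scenario("monsoon")

    def test_fall_release_exceeds_spring(self):
        fall = generate_season_scenario("fall", seed=1)
        spring = generate_season_scenario("spring", seed=1)
        assert (
            fall.ground_truth["bulk_release_nmol_l_d"]
            > spring.ground_truth["bulk_release_nmol_l_d"]
        )

    def test_seeded_bundle_identical(self):
        a = generate_season_scenario("winter", seed=9)
        b = generate_season_scenario("winter", seed=9)
        assert np.array_equal(
            a.incubation.concentrations["taurine"],
            b.incubation.concentrations["taurine"],
        )
        assert np.array_equal(a.tracer_sample.filter_dpm, b.tracer_sample.filter_dpm)
        pd.testing.assert_frame_equal(a.fish_counts, b.fish_counts)

    def test_noise_free_end_to_end_closure(self):
        bundle = generate_season_scenario("fall", seed=0, noise=False)
        truth = bundle.ground_truth
        rates = analyze_experiment(bundle.incubation)
        taurine = [r for r in rates if r.analyte == "taurine"]
        for r in taurine:
            assert r.per_individual_nmol_d == pytest.approx(
                truth["per_individual_release_nmol_d"], rel=1e-9
            )
        est = estimate_rates(bundle.tracer_sample)
        assert est.assimilation == pytest.approx(
            truth["true_assimilation_nmol_l_d"], rel=1e-9
        )
        assert est.respiration == pytest.approx(
            truth["true_respiration_nmol_l_d"], rel=1e-9
        )

    def test_write_round_trip(self, tmp_path):
        bundle = generate_season_scenario("summer", seed=2)
        bundle.write(tmp_path)
        for name in ("incubation.csv", "specimens.csv", "tracer.csv",
                     "fish_counts.csv", "grain_areas.csv", "ground_truth.json"):
            assert (tmp_path / name).exists()
        df = pd.read_csv(tmp_path / "incubation.csv")
        assert set(df.columns) == {
            "time_h", "analyte", "replicate", "conc_nmol_L", "is_control"
        }
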