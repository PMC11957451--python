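"""Observable-phase analytics: TVDT, initiation age, cutoff, survival,
mutation burden."""

import numpy as np
import pytest

from tumorfield import (
    CohortConfig,
    PalpationSeries,
    classification_report,
    derive_cutoff,
    gen_palpation,
    initiation_age,
    mutation_summary,
    presets,
    tumor_free_survival,
    tvdt,
)


def exponential_series(doubling_days, n_points=5, start_age=100.0, v0=20.0,
                       step=3.5, noise=None, rng=None):
    ages = start_age + step * np.arange(n_points)
    vols = v0 * 2.0 ** ((ages - start_age) / doubling_days)
    if noise:
        vols = vols * rng.lognormal(-np.log(1 + noise**2) / 2,
                                    np.sqrt(np.log(1 + noise**2)), n_points)
    return PalpationSeries("t0", "d16", ages, vols)


class TestTvdt:
    def test_exact_doubling_recovered(self):
        assert tvdt(exponential_series(12.0)) == pytest.approx(12.0)

    def test_constant_volume_is_undefined(self):
        s = PalpationSeries("t1", "p95", np.array([0.0, 10.0, 20.0]),
                            np.array([50.0, 50.0, 50.0]))
        assert tvdt(s) is None

    def test_too_few_measurements_excluded(self):
        s = PalpationSeries("t2", "d16", np.array([0.0, 10.0]),
                            np.array([10.0, 20.0]))
        assert tvdt(s) is None

    def test_noisy_exponential_within_ten_percent(self):
        rng = np.random.default_rng(6)
        s = exponential_series(12.0, n_points=6, noise=0.05, rng=rng)
        assert tvdt(s) == pytest.approx(12.0, rel=0.10)

    def test_generator_round_trip_population_mean(self):
        cfg = CohortConfig(seed=4, n_palpated_tumors=200)
        estimates = [tvdt(s) for s in gen_palpation(cfg)]
        estimates = [e for e in estimates if e is not None]
        assert np.mean(estimates) == pytest.approx(cfg.tvdt_mean_days, rel=0.05)

    def test_noiseless_generator_returns_mean_exactly(self):
        cfg = CohortConfig(seed=0, n_palpated_tumors=5, tvdt_cv=0.0,
                           caliper_cv=0.0)
        for s in gen_palpation(cfg):
            assert tvdt(s) == pytest.approx(cfg.tvdt_mean_days, rel=1e-9)


class TestInitiationAge:
    def test_first_volume_at_reference_means_no_rewind(self):
        s = exponential_series(12.0, v0=20.0)
        assert initiation_age(s, 12.0, reference_volume=20.0) == pytest.approx(
            s.age_days[0]
        )

    def test_three_doublings_rewind(self):
        s = exponential_series(12.0, v0=8.0, start_age=200.0)
        assert initiation_age(s, 12.0, reference_volume=1.0) == pytest.approx(
            200.0 - 36.0
        )

    def test_generator_round_trip_recovers_onset(self):
        cfg = CohortConfig(seed=9, n_palpated_tumors=30, caliper_cv=0.02)
        # rewind to 90% of the detection volume (caliper noise can push the
        # first reading slightly below the nominal detection volume)
        ref = 0.9 * cfg.detect_volume_mm3
        rewind = 12.0 * np.log2(cfg.detect_volume_mm3 / ref)
        for s in gen_palpation(cfg)[:10]:
            dt = tvdt(s)
            est = initiation_age(s, dt, reference_volume=ref)
            assert est + rewind == pytest.approx(s.age_days[0], abs=5.0)

    def test_invalid_reference_rejected(self):
        s = exponential_series(12.0)
        with pytest.raises(ValueError):
            initiation_age(s, 12.0, reference_volume=0.0)


class TestDeriveCutoff:
    def test_uniform_order_statistics(self):
        # 15th percentile of 100 areas evenly spaced on [9, 100]
        areas = np.linspace(9.0, 100.0, 100)
        expected = 9.0 + 0.15 * 99 * (100.0 - 9.0) / 99.0
        assert derive_cutoff(areas) == pytest.approx(expected, rel=1e-12)

    def test_constant_areas(self):
        assert derive_cutoff([4.2] * 10) == 4.2

    def test_generator_round_trip_hits_nine(self):
        # palpable areas whose 15th percentile sits at 9 mm^2 by construction
        rng = np.random.default_rng(12)
        areas = 9.0 * np.exp(rng.exponential(0.8, 5000) - np.quantile(
            rng.exponential(0.8, 5000), 0.15))
        got = derive_cutoff(areas)
        assert got == pytest.approx(9.0, rel=0.05)

    def test_monotone_in_percentile_and_scale_equivariant(self):
        rng = np.random.default_rng(3)
        areas = rng.lognormal(2.0, 0.5, 500)
        qs = [derive_cutoff(areas, p) for p in (5, 15, 50, 90)]
        assert qs == sorted(qs)
        assert derive_cutoff(3.0 * areas, 15) == pytest.approx(
            3.0 * derive_cutoff(areas, 15)
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            derive_cutoff([])


class TestClassificationReport:
    def test_perfect_separation(self):
        areas = np.array([1.0, 2.0, 20.0, 30.0])
        labels = np.array([False, False, True, True])
        rep = classification_report(areas, labels, cutoff=9.0)
        assert rep == {"palpable": 1.0, "unpalpable": 1.0}

    def test_cutoff_below_everything(self):
        areas = np.array([5.0, 6.0, 7.0, 8.0])
        labels = np.array([True, True, False, False])
        rep = classification_report(areas, labels, cutoff=0.1)
        assert rep["palpable"] == 1.0 and rep["unpalpable"] == 0.0

    def test_absent_class_reported_as_undefined(self):
        rep = classification_report(
            np.array([10.0]), np.array([True]), cutoff=9.0
        )
        assert rep["unpalpable"] is None

    def test_overlap_accuracy_matches_analytic_expectation(self):
        # unpalpable areas uniform on (0, 12): P(area < 9) = 0.75 exactly
        rng = np.random.default_rng(2)
        n = 4000
        areas = rng.uniform(0.0, 12.0, n)
        labels = np.zeros(n, dtype=bool)
        rep = classification_report(areas + 1e-12, labels, cutoff=9.0)
        sigma = np.sqrt(0.75 * 0.25 / n)
        assert abs(rep["unpalpable"] - 0.75) < 3 * sigma


class TestTumorFreeSurvival:
    def test_hand_computable_median(self):
        # S(100)=0.75, S(110)=0.50 -> first time S <= 0.5 is 110
        curve = tumor_free_survival([100.0, 110.0, 120.0, 130.0])
        assert curve.median_time == 110.0
        assert curve.survival_at(105.0) == pytest.approx(0.75)

    def test_all_censored_curve_stays_at_one(self):
        curve = tumor_free_survival([], censor_ages=[50.0, 60.0, 70.0])
        assert np.all(curve.survival == 1.0)
        assert curve.median_time is None

    def test_generator_round_trip_median_near_113_days(self):
        medians = []
        for seed in range(5):
            cfg = CohortConfig(seed=seed, n_palpated_tumors=60)
            onsets = [s.age_days[0] for s in gen_palpation(cfg)]
            medians.append(tumor_free_survival(onsets).median_time)
        assert abs(np.mean(medians) - 113.0) < 7.0

    def test_censoring_slows_decline(self):
        events = [100.0, 120.0, 140.0]
        a = tumor_free_survival(events)
        b = tumor_free_survival(events, censor_ages=[110.0, 115.0])
        assert b.survival_at(125.0) >= a.survival_at(125.0)


class TestMutationSummary:
    def test_published_table_means(self):
        summary = mutation_summary(presets.mutation_table())
        assert summary["by_genotype"] == {"d16": 5111, "p95": 3784}
        assert summary["by_genotype_and_size"]["d16_unpalpable"] == 7430
        assert summary["by_genotype_and_size"]["p95_unpalpable"] == 4348
        assert summary["by_genotype_and_size"]["d16_palpable"] == 2792
        assert summary["by_genotype_and_size"]["p95_palpable"] == 2937
        assert summary["by_size_class"] == {"palpable": 2850, "unpalpable": 5889}

    def test_single_row_is_its_own_mean(self):
        df = presets.mutation_table().iloc[[0]]
        assert mutation_summary(df)["grand_mean"] == int(df["total"].iloc[0])

    def test_inconsistent_row_named_in_error(self):
        df = presets.mutation_table().copy()
        df.loc[3, "total"] += 1
        with pytest.raises(ValueError, match="3"):
            mutation_summary(df)

    def test_group_means_recombine_to_grand_mean(self):
        df = presets.mutation_table()
        by = df.groupby("genotype")["total"]
        grand = (by.mean() * by.size()).sum() / by.size().sum()
        assert grand == pytest.approx(df["total"].mean())
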