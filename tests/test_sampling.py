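import numpy as np
import pandas as pd
import pytest

from bwasdesign import (
    ModelSpec,
    SimConfig,
    TargetShape,
    binary_weights,
    cross_sectional_weights,
    local_frequency,
    longitudinal_combination_weights,
    run_scheme_experiment,
    simulate_longitudinal_study,
    weighted_bootstrap,
)
from bwasdesign.cohort import CROSS_SECTIONAL, LONGITUDINAL
from bwasdesign.sampling import WeightTable, quantile_winsor_bounds


class TestLocalFrequency:
    def test_identical_points_count_everyone(self):
        pts = np.full(17, 3.0)
        assert np.all(local_frequency(pts, 0.5) == 17)

    def test_isolated_points_count_themselves(self):
        pts = np.arange(0.0, 20.0, 2.0)  # spacing 2 > 2 * 0.5
        assert np.all(local_frequency(pts, 0.5) == 1)

    def test_matches_brute_force_in_2d(self, rng):
        pts = rng.uniform(0, 5, size=(150, 2))
        hw = 0.5
        brute = np.array(
            [
                np.sum(np.all(np.abs(pts - pts[i]) <= hw, axis=1))
                for i in range(len(pts))
            ]
        )
        np.testing.assert_array_equal(local_frequency(pts, hw), brute)

    def test_boundary_distance_is_inclusive(self):
        counts = local_frequency(np.array([0.0, 0.5]), 0.5)
        assert np.all(counts == 2)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError, match="empty"):
            local_frequency(np.empty(0), 0.5)


class TestCrossSectionalWeights:
    def test_uniform_on_uniform_grid_near_equal(self):
        ages = np.linspace(50, 78, 300)
        wt = cross_sectional_weights(ages, TargetShape("uniform"), (50, 78))
        inner = wt.weights[10:-10]  # edges see truncated windows
        assert inner.max() / inner.min() < 1.05

    def test_winsorization_affects_weight_not_value(self, rng):
        ages = np.concatenate([[40.0], rng.uniform(50, 78, 500)])
        wt = cross_sectional_weights(ages, TargetShape("bell"), (50, 78))
        at50 = cross_sectional_weights(
            np.concatenate([[50.0], ages[1:]]), TargetShape("bell"), (50, 78)
        )
        assert wt.weights[0] == pytest.approx(at50.weights[0])
        assert ages[0] == 40.0  # stored value untouched

    def test_resample_variance_ordering(self, rng):
        """U-shaped > uniform > bell in resampled age variance."""
        ages = rng.uniform(50, 78, 1500)
        variances = {}
        for fam in ("bell", "uniform", "u_shaped"):
            wt = cross_sectional_weights(ages, TargetShape(fam), (50, 78))
            p = wt.weights / wt.weights.sum()
            mu = p @ ages
            variances[fam] = p @ (ages - mu) ** 2
        assert variances["u_shaped"] > variances["uniform"] > variances["bell"]

    def test_inverted_bounds_rejected(self, rng):
        with pytest.raises(ValueError, match="inverted"):
            cross_sectional_weights(
                rng.uniform(0, 1, 10), TargetShape("bell"), (78, 50)
            )


class TestBinaryWeights:
    def test_matched_target_gives_equal_weights(self):
        v = np.array([0, 1] * 25)
        wt = binary_weights(v, 0.5)
        assert np.allclose(wt.weights, wt.weights[0])

    def test_minority_upweight_ratio(self):
        v = np.array([1] * 80 + [0] * 20)
        wt = binary_weights(v, 0.5)
        ratio = wt.weights[-1] / wt.weights[0]  # class 0 vs class 1
        assert ratio == pytest.approx((0.5 / 0.2) / (0.5 / 0.8))

    def test_expected_resample_prevalence(self, rng):
        v = rng.binomial(1, 0.7, 1000)
        wt = binary_weights(v, 0.10)
        p = wt.weights / wt.weights.sum()
        assert p @ v == pytest.approx(0.10, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            binary_weights(np.ones(10), 0.5)


@pytest.fixture(scope="module")
def adni_like():
    cfg = SimConfig(
        n_subjects=800,
        visits_per_subject=3,
        beta_between=0.0,
        age_effect=(1.0, 0.0, 0.0),
        baseline_age_distribution=("uniform", 65.0, 85.0),
        visit_gap_distribution=("uniform", 0.5, 3.0),
        seed=77,
    )
    return simulate_longitudinal_study(cfg)


class TestCombinationWeights:
    def test_one_followup_one_combination(self):
        cfg = SimConfig(n_subjects=50, visits_per_subject=2, seed=1)
        t = simulate_longitudinal_study(cfg)
        wt = longitudinal_combination_weights(
            t, TargetShape("uniform"), TargetShape("uniform"), (45, 90), (0, 5)
        )
        assert len(wt.keys) == 50
        assert wt.unit == "subject_pair"

    def test_combination_count(self, adni_like):
        # 3 visits -> 2 (baseline, follow-up) pairs per subject
        wt = longitudinal_combination_weights(
            adni_like, TargetShape("uniform"), TargetShape("uniform"),
            (65, 85), (0, 5),
        )
        assert len(wt.keys) == 2 * adni_like.n_subjects

    def test_between_target_independent_of_within_shape(self, adni_like):
        """Changing the within-subject shape must leave the implied baseline-age
        distribution unchanged: the two targets factorize."""
        marginals = {}
        for fam in ("decreasing", "increasing"):
            wt = longitudinal_combination_weights(
                adni_like, TargetShape("uniform"), TargetShape(fam),
                (65, 85), (0, 5),
            )
            base_rows = [k[0] for k in wt.keys]
            ages = adni_like.data.reset_index(drop=True).loc[base_rows, "age"]
            p = wt.weights / wt.weights.sum()
            grid = np.quantile(ages, [0.25, 0.5, 0.75])
            cdf = [np.sum(p[(ages <= g).to_numpy()]) for g in grid]
            marginals[fam] = np.asarray(cdf)
        np.testing.assert_allclose(
            marginals["decreasing"], marginals["increasing"], atol=0.02
        )

    def test_increasing_change_target_widens_age_gaps(self, adni_like):
        gaps = {}
        for fam in ("decreasing", "increasing"):
            wt = longitudinal_combination_weights(
                adni_like, TargetShape("uniform"), TargetShape(fam),
                (65, 85), (0, 5),
            )
            boot = weighted_bootstrap(adni_like, wt, 400, seed=3)
            wide = boot.data.pivot(index="subject_id", columns="visit_index")["age"]
            gaps[fam] = float((wide[1] - wide[0]).mean())
        assert gaps["increasing"] > gaps["decreasing"]

    def test_no_eligible_subject_raises(self, cross_sectional_cohort):
        with pytest.raises(ValueError, match="follow-ups"):
            longitudinal_combination_weights(
                cross_sectional_cohort, TargetShape("uniform"),
                TargetShape("uniform"), (45, 90), (0, 5),
            )

    def test_weighting_never_alters_stored_values(self, adni_like):
        before = adni_like.data.copy()
        longitudinal_combination_weights(
            adni_like, TargetShape("u_shaped"), TargetShape("increasing"),
            (65, 85), (0, 5),
        )
        pd.testing.assert_frame_equal(adni_like.data, before)


class TestWeightedBootstrap:
    def test_zero_weight_units_never_appear(self, rng):
        ages = rng.uniform(50, 78, 100)
        w = np.ones(100)
        w[:50] = 0.0
        cfg = SimConfig(n_subjects=100, seed=5)
        t = simulate_longitudinal_study(cfg)
        wt = WeightTable(unit="record", keys=list(range(100)), weights=w)
        boot = weighted_bootstrap(t, wt, 500, seed=6)
        picked = set(boot.data["age"])
        excluded = set(t.data["age"].iloc[:50])
        assert picked.isdisjoint(excluded)

    def test_equal_weights_uniform_inclusion(self):
        cfg = SimConfig(n_subjects=50, seed=8)
        t = simulate_longitudinal_study(cfg)
        wt = WeightTable(unit="record", keys=list(range(50)), weights=np.ones(50))
        counts = np.zeros(50)
        boot = weighted_bootstrap(t, wt, 5000, seed=9)
        for a in boot.data["age"]:
            counts[t.data.index[t.data["age"] == a][0]] += 1
        assert abs(counts.mean() - 100) < 1e-9  # 5000/50
        assert counts.std() < 3 * np.sqrt(100)

    def test_pair_units_make_two_visit_subjects(self, adni_like):
        wt = longitudinal_combination_weights(
            adni_like, TargetShape("uniform"), TargetShape("uniform"),
            (65, 85), (0, 5),
        )
        boot = weighted_bootstrap(adni_like, wt, 120, seed=10)
        assert boot.design == LONGITUDINAL
        assert (boot.data.groupby("subject_id").size() == 2).all()
        assert boot.data["subject_id"].nunique() == 120

    def test_resampled_histogram_approaches_target(self, rng):
        """KS distance to the uniform target shrinks as n grows."""
        ages = np.sort(rng.normal(64, 6, 3000))
        ages = np.clip(ages, 50, 78)
        wt = cross_sectional_weights(ages, TargetShape("uniform"), (50, 78))
        cfg = SimConfig(n_subjects=3000, baseline_age_distribution=("normal", 64, 6), seed=11)
        t = simulate_longitudinal_study(cfg)
        t.data["age"] = ages  # align the table with the weighted ages
        from scipy.stats import kstest

        d = {}
        for n in (200, 5000):
            boot = weighted_bootstrap(t, wt, n, seed=12)
            d[n] = kstest(boot.data["age"], "uniform", args=(50, 28)).statistic
        assert d[5000] < d[200]
        assert d[5000] < 0.05


class TestSchemeExperiment:
    def test_single_replicate_reproducible(self, cross_sectional_cohort, cs_spec):
        ages = cross_sectional_cohort.data["age"].to_numpy()
        bounds = quantile_winsor_bounds(ages)
        schemes = {
            "uniform": cross_sectional_weights(ages, TargetShape("uniform"), bounds)
        }
        r1 = run_scheme_experiment(
            cross_sectional_cohort, schemes, [60], cs_spec, "x", B=1, seed=13
        )
        r2 = run_scheme_experiment(
            cross_sectional_cohort, schemes, [60], cs_spec, "x", B=1, seed=13
        )
        pd.testing.assert_frame_equal(r1.summary, r2.summary)
        pd.testing.assert_frame_equal(r1.replicates, r2.replicates)

    def test_power_non_decreasing_in_n(self, cross_sectional_cohort, cs_spec):
        ages = cross_sectional_cohort.data["age"].to_numpy()
        bounds = quantile_winsor_bounds(ages)
        schemes = {
            "uniform": cross_sectional_weights(ages, TargetShape("uniform"), bounds)
        }
        res = run_scheme_experiment(
            cross_sectional_cohort, schemes, [40, 120, 360], cs_spec, "x",
            B=120, seed=14,
        )
        p = res.summary.sort_values("n")["power"].to_numpy()
        assert p[0] <= p[1] + 0.05 and p[1] <= p[2] + 0.05
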