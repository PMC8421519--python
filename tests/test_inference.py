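"""Likelihood-ratio tests, shape selection, whole-curve and comparator tests."""

import numpy as np
import pytest

from kinresp.data import Dataset
from kinresp.regression import Formula, fit
from kinresp.inference import (
    lr_test,
    pairwise_curve_tests,
    select_shape,
    single_timepoint_test,
    subsample_experiment,
    timecourse_anova,
)
from kinresp.synthetic import default_scenario, generate

from conftest import manual_dataset, two_group_dataset


class TestLRTest:
    def test_identical_fits_give_unit_p(self, reference_fit):
        res = lr_test(reference_fit, reference_fit)
        assert res.deviance == 0.0
        assert res.p == 1.0

    def test_nested_reduction(self, noisy_dataset, reference_fit):
        res3 = fit(noisy_dataset, Formula.pred(3, s=3))
        test = lr_test(reference_fit, res3)
        assert test.df == reference_fit.n_params - res3.n_params
        assert test.deviance > 0
        assert 0 <= test.p <= 1

    def test_non_nested_rejected(self, noisy_dataset):
        res3 = fit(noisy_dataset, Formula.pred(3, s=3))
        res4 = fit(noisy_dataset, Formula.pred(4, s=3))
        with pytest.raises(ValueError, match="not nested"):
            lr_test(res3, res4)

    def test_mismatched_data_rejected(self, noisy_dataset, reference_fit):
        smaller = noisy_dataset.subset_subjects(noisy_dataset.subjects[:30])
        other = fit(smaller, Formula.pred(3, s=3))
        with pytest.raises(ValueError, match="different data"):
            lr_test(reference_fit, other)

    def test_shape_comparison_uses_ad_hoc_single_df(self, noisy_dataset):
        # same stratification, different s: the ad-hoc 1-df convention
        f2 = fit(noisy_dataset, Formula.pred(2, s=2))
        f3 = fit(noisy_dataset, Formula.pred(2, s=3))
        test = lr_test(f3, f2)
        assert test.df == 1
        assert test.deviance > 0  # data were generated at s=3

    def test_deviance_additivity_on_nested_triple(self, noisy_dataset, reference_fit):
        res0 = fit(noisy_dataset, Formula.pred(0, s=3))
        res3 = fit(noisy_dataset, Formula.pred(3, s=3))
        d_03 = lr_test(res0, res3).deviance
        d_02 = lr_test(res0, reference_fit).deviance
        d_23 = lr_test(reference_fit, res3).deviance
        assert d_03 == pytest.approx(d_02 + d_23, abs=1e-6)


class TestSelectShape:
    def test_recovers_generating_shape(self):
        for s_true in (1, 3):
            ds = generate(default_scenario(n_per_group=10, s=s_true, seed=17))
            assert select_shape(ds, Formula.pred(2, s=1)) == s_true

    def test_invalid_candidates_rejected(self, noisy_dataset):
        with pytest.raises(ValueError):
            select_shape(noisy_dataset, Formula.pred(2), candidates=(0, 1))


class TestPairwiseCurveTests:
    def test_symmetric_in_pair_order(self, noisy_dataset, reference_fit):
        tab = pairwise_curve_tests(
            noisy_dataset, Formula.pred(2, s=3),
            pairs=[("A", "B")], full_fit=reference_fit,
        )
        assert tab.p_value("A", "B") == tab.p_value("B", "A")

    def test_detects_damage_strength_difference(self, noisy_dataset, reference_fit):
        tab = pairwise_curve_tests(
            noisy_dataset, Formula.pred(2, s=3),
            pairs=[("A", "F"), ("C", "D")], full_fit=reference_fit,
        )
        assert tab.p_value("A", "F", adjusted=False) < 1e-6
        assert tab.extra["df"] == 2  # p0 and k stratified under pred2

    def test_collapsing_identical_groups_keeps_deviance_small(self):
        # under the null the collapse loses little likelihood: calibrated test
        rejections = 0
        n_rep = 30
        for rep in range(n_rep):
            ds = two_group_dataset(seed=70_000 + rep)
            tab = pairwise_curve_tests(ds, Formula.pred(0, s=3))
            stat = tab.statistic("X", "Y")
            assert stat >= 0.0
            rejections += tab.p_value("X", "Y", adjusted=False) < 0.05
        assert rejections <= 0.2 * n_rep

    def test_collapse_never_beats_full_likelihood(self):
        ds = two_group_dataset(seed=81)
        full = fit(ds, Formula.pred(0, s=3))
        collapsed = fit(ds.merge_groups("X", "Y"), Formula.pred(0, s=3))
        assert collapsed.loglik <= full.loglik + 1e-9


class TestSingleTimepoint:
    def test_duplicated_group_gives_unit_p(self):
        rows = [(f"x{i}", "X", 24.0, 36.0 + 0.1 * i) for i in range(6)]
        rows += [(f"y{i}", "Y", 24.0, 36.0 + 0.1 * i) for i in range(6)]
        ds = manual_dataset(rows)
        tab = single_timepoint_test(ds, 24.0)
        assert tab.p_value("X", "Y") == pytest.approx(1.0)

    def test_large_offset_detected(self):
        rng = np.random.default_rng(5)
        rows = [(f"x{i}", "X", 24.0, 36.0 + rng.normal(0, 1)) for i in range(20)]
        rows += [(f"y{i}", "Y", 24.0, 34.0 + rng.normal(0, 1)) for i in range(20)]
        tab = single_timepoint_test(manual_dataset(rows), 24.0)
        assert tab.p_value("X", "Y") < 1e-4

    def test_undersized_group_rejected(self):
        rows = [("x1", "X", 24.0, 36.0), ("y1", "Y", 24.0, 35.0), ("y2", "Y", 24.0, 35.5)]
        with pytest.raises(ValueError, match="< 2 subjects"):
            single_timepoint_test(manual_dataset(rows), 24.0)


class TestTimecourseAnova:
    def test_identical_groups_not_significant(self):
        rows = []
        for g in ("X", "Y"):
            for i in range(5):
                for t in (0.0, 6.0, 12.0, 18.0, 24.0):
                    rows.append((f"{g}{i}", g, t, 37.0 - 0.05 * t + 0.01 * i))
        tab = timecourse_anova(manual_dataset(rows))
        assert tab.p_value("X", "Y", adjusted=False) > 0.05

    def test_nominal_level_on_linear_null_data(self):
        # truly linear-in-time data, identical groups: rejection near alpha
        rng = np.random.default_rng(11)
        rejections = 0
        n_rep = 150
        for _ in range(n_rep):
            rows = []
            for g in ("X", "Y"):
                for i in range(10):
                    for t in (0.0, 6.0, 12.0, 18.0, 24.0):
                        rows.append(
                            (f"{g}{i}", g, t, 37.0 - 0.1 * t + rng.normal(0, 0.4))
                        )
            tab = timecourse_anova(manual_dataset(rows))
            rejections += tab.p_value("X", "Y", adjusted=False) < 0.05
        assert 0.01 <= rejections / n_rep <= 0.12

    def test_less_discriminative_than_kinetic_lr(self):
        """The linear comparator yields larger p than the whole-curve LR test."""
        wins = 0
        n_rep = 5
        for rep in range(n_rep):
            ds = two_group_dataset(
                p0_a=0.15, p0_b=0.35, n=6, subject_cv=0.1, seed=50_000 + rep
            )
            lr_p = pairwise_curve_tests(ds, Formula.pred(0, s=3)).p_value(
                "X", "Y", adjusted=False
            )
            an_p = timecourse_anova(ds).p_value("X", "Y", adjusted=False)
            assert an_p < 0.05  # still frequently significant
            wins += lr_p < an_p
        assert wins >= 4


@pytest.fixture(scope="module")
def three_group_dataset():
    full = generate(default_scenario(n_per_group=8, seed=11))
    return Dataset(
        full.df[full.df["group"].isin(["A", "C", "F"])], groups=["A", "C", "F"]
    )


class TestSubsampleExperiment:
    def test_full_size_reproduces_full_result(self, three_group_dataset):
        res = subsample_experiment(
            three_group_dataset, n_per_group=8, n_reps=1, seed=5,
            formula=Formula.pred(2, s=3),
        )
        rep = res.replicates[0]["lr"].table["p_raw"].to_numpy()
        assert np.allclose(rep, res.full_lr.table["p_raw"].to_numpy())

    def test_same_seed_is_deterministic(self, three_group_dataset):
        kwargs = dict(n_per_group=4, n_reps=2, seed=99, formula=Formula.pred(2, s=3))
        a = subsample_experiment(three_group_dataset, **kwargs)
        b = subsample_experiment(three_group_dataset, **kwargs)
        assert a.concordance.equals(b.concordance)

    def test_kinetic_concordance_at_least_matches_anova(self, three_group_dataset):
        res = subsample_experiment(
            three_group_dataset, n_per_group=6, n_reps=3, seed=21,
            formula=Formula.pred(2, s=3),
        )
        assert res.mean_concordance["lr"] >= res.mean_concordance["anova"]

    def test_oversized_request_rejected(self, three_group_dataset):
        with pytest.raises(ValueError, match="fewer than"):
            subsample_experiment(
                three_group_dataset, n_per_group=100, n_reps=1, seed=1,
                formula=Formula.pred(2, s=3),
            )
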