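"""Accuracy deconstruction: ROC/AUC, crossover cutoffs, misdiagnosis cost,
geometric-mean consensus, and effect size."""

import io

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

import chant.measurand as M
from chant.exceptions import ConfigurationError, DegenerateDataError
from chant.items import Orientation
from conftest import pair_counting_auc


def hi(values, name="m"):
    return M.OrientedMeasurand(np.asarray(values, dtype=float),
                               Orientation.HIGHER_ABNORMAL, name)


def lo(values, name="m"):
    return M.OrientedMeasurand(np.asarray(values, dtype=float),
                               Orientation.LOWER_ABNORMAL, name)


class TestConfusion:
    def test_perfect_separation(self):
        t = M.confusion_at_cutoff(hi([1, 2, 9, 10]), [0, 0, 1, 1], 5.0)
        assert (t.tp, t.fp, t.fn, t.tn) == (2, 0, 0, 2)

    def test_lower_abnormal_orientation(self):
        # timed vibration: shorter perception is abnormal, cutoff inclusive
        t = M.confusion_at_cutoff(lo([20.0, 10.0]), [0, 1], 13.2)
        assert (t.tp, t.fp, t.fn, t.tn) == (1, 0, 0, 1)

    def test_inclusive_on_abnormal_side(self):
        t = M.confusion_at_cutoff(hi([5.5, 5.4]), [1, 0], 5.5)
        assert (t.tp, t.fn) == (1, 0) and t.tn == 1

    def test_all_negative_labels(self):
        t = M.confusion_at_cutoff(hi([1, 2, 3]), [0, 0, 0], 2.0)
        assert t.tp == 0 and t.fn == 0 and t.total == 3


class TestRoc:
    def test_perfect_measurand(self):
        roc = M.empirical_roc(hi([1, 2, 9, 10]), [0, 0, 1, 1])
        assert roc.auc == 1.0
        assert roc.fpr[0] == 0.0 and roc.tpr[-1] == 1.0

    def test_tied_values(self):
        roc = M.empirical_roc(hi([1, 2, 2, 3]), [0, 0, 1, 1])
        assert roc.auc == pytest.approx(0.875)

    def test_chance_level(self, rng):
        values = rng.normal(size=2000)
        labels = rng.random(2000) < 0.5
        assert M.empirical_roc(hi(values), labels).auc == pytest.approx(0.5, abs=0.05)

    def test_single_class_errors(self):
        with pytest.raises(DegenerateDataError):
            M.empirical_roc(hi([1, 2, 3]), [1, 1, 1])

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_pair_counting_oracle_and_library(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.integers(0, 10, 150).astype(float)  # heavy ties
        labels = rng.random(150) < 0.4
        auc = M.empirical_roc(hi(values), labels).auc
        assert auc == pytest.approx(pair_counting_auc(values, labels), abs=1e-12)
        assert auc == pytest.approx(roc_auc_score(labels, values), abs=1e-12)

    def test_orientation_flips_auc(self, rng):
        values = rng.normal(size=300)
        labels = values + rng.normal(size=300) > 0
        a_hi = M.empirical_roc(hi(values), labels).auc
        a_lo = M.empirical_roc(lo(values), labels).auc
        assert a_hi + a_lo == pytest.approx(1.0)


class TestCrossover:
    def test_step_gap_midpoint(self):
        c = M.crossover_cutoff(hi([1, 2, 3, 4]), [0, 0, 1, 1], "sens_spec")
        assert c == pytest.approx(2.5)

    def test_symmetric_classes_cross_at_zero(self, rng):
        n = 4000
        values = np.r_[rng.normal(-1, 1, n), rng.normal(1, 1, n)]
        labels = np.r_[np.zeros(n, bool), np.ones(n, bool)]
        c = M.crossover_cutoff(hi(values), labels, "sens_spec")
        assert c == pytest.approx(0.0, abs=0.1)

    def test_ppv_npv_equals_sens_spec_at_even_prevalence(self, rng):
        values = np.r_[rng.normal(0, 1, 100), rng.normal(1.5, 1, 100)]
        labels = np.r_[np.zeros(100, bool), np.ones(100, bool)]
        m = hi(values)
        c_ss = M.crossover_cutoff(m, labels, "sens_spec")
        c_pn = M.crossover_cutoff(m, labels, "ppv_npv")
        assert c_pn == pytest.approx(c_ss, abs=0.1)

    def test_lr_crossover_tracks_sens_spec(self, rng):
        values = np.r_[rng.normal(0, 1, 300), rng.normal(1.5, 1, 300)]
        labels = np.r_[np.zeros(300, bool), np.ones(300, bool)]
        m = hi(values)
        c_lr = M.crossover_cutoff(m, labels, "lr")
        c_ss = M.crossover_cutoff(m, labels, "sens_spec")
        assert c_lr == pytest.approx(c_ss, abs=0.1)

    def test_lower_abnormal_crossover(self):
        # mirror of the gap example: abnormal values are the small ones
        c = M.crossover_cutoff(lo([-1, -2, -3, -4]), [0, 0, 1, 1], "sens_spec")
        assert c == pytest.approx(-2.5)

    def test_unknown_criterion(self):
        with pytest.raises(ConfigurationError):
            M.crossover_cutoff(hi([1, 2]), [0, 1], "nope")

    def test_single_class_errors(self):
        with pytest.raises(DegenerateDataError):
            M.crossover_cutoff(hi([1, 2]), [1, 1], "sens_spec")


class TestMonotoneCurves:
    def test_sens_spec_monotone_in_cutoff(self, rng):
        """Raising the cutoff can only lower sensitivity and raise
        specificity (on the abnormality-score scale)."""
        values = rng.normal(size=400)
        labels = values + rng.normal(size=400) > 0.3
        m = hi(values)
        cuts = np.unique(values)
        sens = []
        spec = []
        for c in cuts:
            se, sp = M.sens_spec_at(m, labels, c)
            sens.append(se)
            spec.append(sp)
        assert np.all(np.diff(sens) <= 1e-12)
        assert np.all(np.diff(spec) >= -1e-12)


class TestCost:
    def test_perfect_separation_zero_cost(self):
        cut, curve = M.min_cost_cutoff(hi([1, 2, 9, 10]), [0, 0, 1, 1])
        assert min(v for _, v in curve) == 0.0

    def test_gap_example(self):
        cut, curve = M.min_cost_cutoff(hi([1, 2, 3, 4]), [0, 0, 1, 1])
        assert 2 < cut <= 3
        assert min(v for _, v in curve) == 0.0

    def test_cost_bounds_and_normalisation(self, rng):
        values = rng.normal(size=200)
        labels = rng.random(200) < 0.4
        _, curve = M.min_cost_cutoff(hi(values), labels)
        costs = [v for _, v in curve]
        assert all(0.0 <= v <= 1.0 for v in costs)

    def test_fn_weight_makes_cutoff_more_lenient(self, rng):
        """Doubling the false-negative cost never pushes the chosen cutoff to
        a stricter (more abnormal-restrictive) position."""
        for seed in range(5):
            r = np.random.default_rng(seed)
            values = np.r_[r.normal(0, 1, 150), r.normal(1.2, 1, 150)]
            labels = np.r_[np.zeros(150, bool), np.ones(150, bool)]
            cut_eq, _ = M.min_cost_cutoff(hi(values), labels,
                                          M.CostWeights(c_fn=1.0))
            cut_fn, _ = M.min_cost_cutoff(hi(values), labels,
                                          M.CostWeights(c_fn=2.0))
            assert cut_fn <= cut_eq + 1e-12

    def test_permutation_invariance(self, rng):
        values = rng.normal(size=100)
        labels = rng.random(100) < 0.5
        perm = rng.permutation(100)
        t1 = M.confusion_at_cutoff(hi(values), labels, 0.2)
        t2 = M.confusion_at_cutoff(hi(values[perm]), labels[perm], 0.2)
        assert M.misdiagnosis_cost(t1, M.CostWeights()) == M.misdiagnosis_cost(
            t2, M.CostWeights()
        )


class TestGeometricMean:
    def test_identical_inputs(self):
        assert M.geometric_mean_cutoff(3.0, 3.0, 3.0, 3.0) == pytest.approx(3.0)

    def test_arithmetic_example(self):
        assert M.geometric_mean_cutoff(2, 8, 4, 4) == pytest.approx(4.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_between_min_and_max(self, seed):
        r = np.random.default_rng(seed)
        cuts = r.uniform(0.5, 20.0, 4)
        gm = M.geometric_mean_cutoff(*cuts)
        assert cuts.min() - 1e-12 <= gm <= cuts.max() + 1e-12

    def test_nonpositive_requires_offset(self):
        with pytest.raises(ConfigurationError, match="offset"):
            M.geometric_mean_cutoff(0.0, 1.0, 2.0, 3.0)
        gm = M.geometric_mean_cutoff(0.0, 1.0, 2.0, 3.0, offset=1.0)
        assert 0.0 <= gm <= 3.0


class TestEffectSize:
    def test_perfect_group_separation(self):
        e = M.partial_eta_squared([0, 0, 0, 5, 5, 5], ["a"] * 3 + ["b"] * 3)
        assert e.partial_eta_squared == pytest.approx(1.0)

    def test_independent_factor(self, rng):
        y = rng.normal(size=2000)
        g = rng.integers(0, 2, 2000)
        e = M.partial_eta_squared(y, g)
        assert e.partial_eta_squared == pytest.approx(0.0, abs=0.01)

    def test_hand_sums_of_squares_oracle(self):
        # groups {0,0,1,1} and {1,1,2,2}: means 0.5 / 1.5, grand mean 1,
        # SS_between = 4*0.25 + 4*0.25 = 2, SS_within = 1 + 1 = 2
        y = [0, 0, 1, 1, 1, 1, 2, 2]
        g = ["a"] * 4 + ["b"] * 4
        e = M.partial_eta_squared(y, g)
        assert e.ss_effect == pytest.approx(2.0)
        assert e.ss_error == pytest.approx(2.0)
        assert e.partial_eta_squared == pytest.approx(0.5)

    def test_matches_explicit_ss_without_covariates(self, rng):
        y = rng.normal(size=90)
        g = rng.integers(0, 3, 90)
        e = M.partial_eta_squared(y, g)
        # independent explicit decomposition
        grand = y.mean()
        ss_b = sum(len(y[g == k]) * (y[g == k].mean() - grand) ** 2 for k in range(3))
        ss_w = sum(((y[g == k] - y[g == k].mean()) ** 2).sum() for k in range(3))
        assert e.partial_eta_squared == pytest.approx(ss_b / (ss_b + ss_w), abs=1e-10)

    def test_covariate_partialling(self, rng):
        # the covariate carries all the signal; the factor adds nothing
        x = rng.normal(size=300)
        g = rng.integers(0, 2, 300)
        y = 2.0 * x + rng.normal(scale=0.1, size=300)
        e = M.partial_eta_squared(y, g, covariates=x)
        assert e.partial_eta_squared == pytest.approx(0.0, abs=0.02)

    def test_single_group_rejected(self):
        with pytest.raises(ConfigurationError):
            M.partial_eta_squared([1, 2, 3], ["a", "a", "a"])


class TestEvaluate:
    def test_perfect_measurand_row(self):
        m = hi(np.r_[np.zeros(20), np.ones(20) * 10.0], name="perfect")
        labels = np.r_[np.zeros(20, bool), np.ones(20, bool)]
        rep = M.evaluate_measurand(m, labels, gm_offset=1.0)
        assert rep.auc == 1.0
        assert rep.min_cost == 0.0
        d = rep.decision
        for cut in (d.cutoff_sens_spec, d.cutoff_ppv_npv, d.cutoff_lr,
                    d.cutoff_min_cost):
            assert 0.0 < cut <= 10.0

    def test_row_csv_roundtrip(self, small_cohort):
        labels = small_cohort["latent_status"].to_numpy(dtype=bool)
        table = M.evaluate_cohort(small_cohort, labels)
        buf = io.StringIO()
        table.to_csv(buf, index=False)
        buf.seek(0)
        back = pd.read_csv(buf)
        pd.testing.assert_frame_equal(back, table)

    def test_geometric_mean_within_component_range(self, small_cohort):
        labels = small_cohort["latent_status"].to_numpy(dtype=bool)
        cols = ["cutoff_sens_spec", "cutoff_ppv_npv", "cutoff_lr",
                "cutoff_min_cost"]
        table = M.evaluate_cohort(small_cohort, labels).dropna(subset=cols)
        assert len(table) >= 3  # the ordinal reflex grid may not resolve
        lo_ = table[cols].min(axis=1)
        hi_ = table[cols].max(axis=1)
        assert ((table["geometric_mean_cutoff"] >= lo_ - 1e-9)
                & (table["geometric_mean_cutoff"] <= hi_ + 1e-9)).all()
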