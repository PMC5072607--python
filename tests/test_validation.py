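"""Validation statistics: 2x2 metrics, likelihood ratios, post-test
probability, reliability, and content validity."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chant.exceptions import ConfigurationError, DegenerateDataError, UndefinedMetricError
from chant.measurand import ConfusionTable
from chant.synthetic import (
    CohortConfig,
    RaterAgreement,
    generate_cohort,
    generate_panel_responses,
    generate_rater_pair,
    panel_from_counts,
    reliability_config,
)
from chant.scorer import score_cohort
from chant.validation import (
    PanelResponse,
    cronbach_alpha,
    cvr,
    diagnostic_metrics,
    fagan_posttest,
    inter_tester,
    item_total_correlation,
    panel_response_from_matrix,
    reliability_report,
)
from conftest import spearman_oracle


class TestDiagnosticMetrics:
    def test_internal_validation_table(self):
        m = diagnostic_metrics(ConfusionTable(tp=10, fp=3, fn=0, tn=17))
        assert m.sensitivity == 1.0
        assert m.specificity == pytest.approx(0.85)
        assert m.ppv == pytest.approx(0.769, abs=5e-4)
        assert m.npv == 1.0
        assert m.lr_pos == pytest.approx(6.67, abs=5e-3)
        assert m.lr_neg == 0.0

    def test_field_test_table(self):
        m = diagnostic_metrics(ConfusionTable(tp=32, fp=1, fn=11, tn=6))
        assert m.sensitivity == pytest.approx(0.7442, abs=5e-5)
        assert m.specificity == pytest.approx(0.8571, abs=5e-5)
        assert m.ppv == pytest.approx(0.9697, abs=5e-5)
        assert m.npv == pytest.approx(0.3529, abs=5e-5)

    def test_perfect_specificity_gives_infinite_lr(self):
        m = diagnostic_metrics(ConfusionTable(tp=5, fp=0, fn=0, tn=5))
        assert math.isinf(m.lr_pos)

    @pytest.mark.parametrize(
        "table, message",
        [
            (ConfusionTable(tp=0, fp=3, fn=0, tn=7), "sensitivity"),
            (ConfusionTable(tp=3, fp=0, fn=7, tn=0), "specificity"),
            (ConfusionTable(tp=0, fp=0, fn=5, tn=5), "PPV"),
            (ConfusionTable(tp=5, fp=5, fn=0, tn=0), "NPV"),
        ],
    )
    def test_undefined_metrics_error_by_name(self, table, message):
        with pytest.raises(UndefinedMetricError, match=message):
            diagnostic_metrics(table)


class TestFagan:
    def test_internal_validation_example(self):
        post = fagan_posttest(0.43, 6.67)
        assert post == pytest.approx(0.834, abs=5e-4)
        assert round(100 * post) == 83

    def test_lr_one_is_identity(self):
        for p in (0.1, 0.43, 0.9):
            assert fagan_posttest(p, 1.0) == pytest.approx(p)

    def test_field_test_example(self):
        # exact odds arithmetic gives 91%, one point below the nomogram read
        assert fagan_posttest(0.66, 5.29) == pytest.approx(0.911, abs=5e-4)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(0.01, 0.99), st.floats(0.01, 100.0))
    def test_round_trip(self, pretest, lr):
        post = fagan_posttest(pretest, lr)
        assert fagan_posttest(post, 1.0 / lr) == pytest.approx(pretest, abs=1e-12)

    def test_invalid_pretest(self):
        with pytest.raises(ConfigurationError):
            fagan_posttest(0.0, 2.0)
        with pytest.raises(ConfigurationError):
            fagan_posttest(1.0, 2.0)

    @settings(max_examples=200, deadline=None)
    @given(st.integers(1, 50), st.integers(1, 50), st.integers(0, 50),
           st.integers(0, 50))
    def test_ppv_equals_posttest_at_prevalence(self, tp, tn, fp, fn):
        """PPV is the post-test probability when the pre-test probability is
        the sample prevalence (ties the 2x2 panel to the nomogram)."""
        table = ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)
        m = diagnostic_metrics(table)
        if not math.isfinite(m.lr_pos) or m.lr_pos == 0.0:
            return
        prevalence = (tp + fn) / table.total
        assert m.ppv == pytest.approx(fagan_posttest(prevalence, m.lr_pos),
                                      abs=1e-12)


class TestCronbach:
    def test_identical_items(self):
        x = np.tile(np.arange(10.0), (4, 1)).T
        assert cronbach_alpha(x) == pytest.approx(1.0)

    def test_two_item_closed_form(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        y = 0.5 * x + rng.normal(size=200) * np.sqrt(1 - 0.25)
        y = (y - y.mean()) / y.std(ddof=1)
        x = (x - x.mean()) / x.std(ddof=1)
        r = np.corrcoef(x, y)[0, 1]
        assert cronbach_alpha(np.c_[x, y]) == pytest.approx(2 * r / (1 + r))

    def test_covariance_identity(self, rng):
        """alpha equals k*cbar / (vbar + (k-1)*cbar) with cbar/vbar the mean
        off-diagonal covariance and mean variance (algebraic identity)."""
        x = rng.normal(size=(60, 5))
        x += rng.normal(size=(60, 1))  # common factor
        cov = np.cov(x, rowvar=False)
        k = 5
        vbar = np.diag(cov).mean()
        cbar = (cov.sum() - np.diag(cov).sum()) / (k * (k - 1))
        expected = k * cbar / (vbar + (k - 1) * cbar)
        assert cronbach_alpha(x) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            cronbach_alpha(np.ones((10, 3)))

    def test_reliability_calibration(self):
        """The reliability-study generator settings reproduce the published
        internal consistency (~0.88) at the pilot sample size."""
        cohort = generate_cohort(reliability_config(n_patients=30, seed=0))
        tallies = score_cohort(cohort)[
            ["pain_tally", "numb_tally", "vib_tally", "reflex_tally"]
        ]
        binary = (tallies == 2).astype(float)
        assert cronbach_alpha(binary) == pytest.approx(0.88, abs=0.08)


class TestItemTotal:
    def test_identical_items(self):
        x = np.tile(np.arange(12.0), (4, 1)).T
        per_item, mean = item_total_correlation(x)
        assert all(v == pytest.approx(1.0) for v in per_item.values())
        assert mean == pytest.approx(1.0)

    def test_independent_item_near_zero(self, rng):
        x = rng.normal(size=(3000, 3))
        x[:, :2] += rng.normal(size=(3000, 1))
        per_item, _ = item_total_correlation(x)
        assert abs(per_item["2"]) < 0.06

    def test_matches_midrank_oracle_exactly(self):
        # hand-checkable 8-patient, 4-item fixture with ties
        x = np.array([
            [0, 1, 1, 0],
            [1, 1, 0, 1],
            [2, 0, 1, 2],
            [0, 0, 0, 0],
            [2, 2, 2, 2],
            [1, 2, 1, 1],
            [0, 1, 2, 1],
            [2, 2, 0, 2],
        ], dtype=float)
        per_item, mean = item_total_correlation(x)
        total = x.sum(axis=1)
        expected = [spearman_oracle(x[:, j], total - x[:, j]) for j in range(4)]
        for j in range(4):
            assert per_item[str(j)] == pytest.approx(expected[j], abs=1e-12)
        assert mean == pytest.approx(np.mean(expected), abs=1e-12)

    def test_constant_item_flagged_nan(self):
        x = np.c_[np.ones(10), np.arange(10.0), np.arange(10.0)[::-1]]
        per_item, _ = item_total_correlation(x)
        assert math.isnan(per_item["0"])


class TestInterTester:
    def test_identical_raters(self, small_cohort):
        cols = ["id", "pain_right", "vib_left"]
        rho = inter_tester(small_cohort[cols], small_cohort[cols])
        assert all(v == pytest.approx(1.0) for v in rho.values())

    def test_independent_raters_near_zero(self, rng):
        a = pd.DataFrame({"x": rng.normal(size=3000)})
        b = pd.DataFrame({"x": rng.normal(size=3000)})
        rho = inter_tester(a, b)
        assert abs(rho["x"]) < 0.06

    def test_matches_midrank_oracle(self, rng):
        a = pd.DataFrame({"x": rng.integers(0, 5, 50).astype(float)})
        b = pd.DataFrame({"x": a["x"] + rng.integers(-1, 2, 50)})
        rho = inter_tester(a, b)
        assert rho["x"] == pytest.approx(
            spearman_oracle(a["x"].to_numpy(), b["x"].to_numpy()), abs=1e-12
        )

    def test_mismatched_ids_rejected(self, small_cohort):
        shifted = small_cohort.copy()
        shifted["id"] = shifted["id"].iloc[::-1].to_numpy()
        with pytest.raises(ConfigurationError):
            inter_tester(small_cohort[["id", "pain_right"]],
                         shifted[["id", "pain_right"]])

    def test_calibrated_concordance(self):
        """A 2% per-item disagreement rate keeps all per-item correlations at
        or above the published minimum of 0.93 (n=1000)."""
        cohort = generate_cohort(reliability_config(n_patients=1000, seed=0))
        r2 = generate_rater_pair(cohort, RaterAgreement(flip_prob=0.02), seed=1)
        rho = inter_tester(cohort[list(r2.columns)], r2)
        assert all(v >= 0.93 for v in rho.values())


class TestCvr:
    def test_panel_of_five_examples(self):
        values, mean = cvr(PanelResponse(5, (4, 5, 5, 5)))
        assert values == pytest.approx((0.6, 1.0, 1.0, 1.0))
        assert mean == pytest.approx(0.9)

    def test_unanimous_upper_bound(self):
        values, _ = cvr(PanelResponse(7, (7,)))
        assert values[0] == 1.0

    def test_arithmetic(self):
        values, _ = cvr(PanelResponse(4, (1,)))
        assert values[0] == pytest.approx(-0.5)

    def test_no_essential_lower_bound(self):
        panel = generate_panel_responses(5, [0.0] * 4, seed=0)
        values, _ = cvr(panel_response_from_matrix(panel))
        assert values == pytest.approx((-1.0,) * 4)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(1, 15), st.data())
    def test_antisymmetric_around_half(self, n, data):
        n_e = data.draw(st.integers(0, n))
        v1, _ = cvr(PanelResponse(n, (n_e,)))
        v2, _ = cvr(PanelResponse(n, (n - n_e,)))
        assert v1[0] == pytest.approx(-v2[0])

    def test_count_exceeding_panel_rejected(self):
        with pytest.raises(ConfigurationError):
            PanelResponse(5, (6,))


def test_reliability_report_bundle(small_cohort):
    tallies = score_cohort(small_cohort)[
        ["pain_tally", "numb_tally", "vib_tally", "reflex_tally"]
    ]
    report = reliability_report(tallies)
    assert -1.0 <= report.cronbach_alpha <= 1.0
    assert report.item_total_mean == pytest.approx(
        np.mean([v for v in report.item_total.values() if not math.isnan(v)])
    )
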