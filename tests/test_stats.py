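"""Cohort statistics: correlation/regression, K-S, Welch, summary table."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cupcov.stats import (
    HipRecord,
    ZeroVarianceError,
    cohort_summary,
    ks_normality,
    pearson_regression,
    welch_two_sample,
)


class TestPearsonRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = pearson_regression(x, 2 * x + 1)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # r = cov/(sx sy) = 0.6 for this classic 4-point set
        res = pearson_regression([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.pearson_r == pytest.approx(0.6)
        assert res.r_squared == pytest.approx(0.36)

    def test_errors(self):
        with pytest.raises(ValueError):
            pearson_regression([1, 2], [3, 4])
        with pytest.raises(ZeroVarianceError):
            pearson_regression([1, 1, 1], [1, 2, 3])

    @given(
        st.lists(
            st.floats(min_value=-100, max_value=100), min_size=4, max_size=30
        ).filter(lambda xs: np.std(xs) > 1e-3)
    )
    @settings(max_examples=50, deadline=None)
    def test_r_squared_identity(self, xs):
        rng = np.random.default_rng(0)
        y = np.asarray(xs) * 0.5 + rng.normal(size=len(xs))
        if np.std(y) <= 1e-9:
            return
        res = pearson_regression(np.asarray(xs), y)
        assert res.r_squared == pytest.approx(res.pearson_r**2, abs=1e-12)

    def test_r_invariant_under_positive_affine_rescaling(self, rng):
        x = rng.normal(size=25)
        y = rng.normal(size=25) + 0.5 * x
        r0 = pearson_regression(x, y).pearson_r
        r1 = pearson_regression(3.2 * x + 7, 0.1 * y - 4).pearson_r
        assert r1 == pytest.approx(r0, abs=1e-12)


class TestKSNormality:
    def test_null_calibration(self):
        # normal data: p should rarely be small even with estimated params
        # (estimating mean/SD inflates p — the Lilliefors caveat)
        ok = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(3.0, 2.0, size=10_000)
            _, p = ks_normality(x)
            ok += p > 0.05
        assert ok >= 95

    def test_gross_alternative_detected(self):
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(-5, 1, 100), rng.normal(5, 1, 100)])
        _, p = ks_normality(x)
        assert p < 0.01

    def test_errors(self):
        with pytest.raises(ValueError):
            ks_normality([1.0, 2.0, 3.0])
        with pytest.raises(ZeroVarianceError):
            ks_normality([2.0] * 50)


class TestWelch:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        t, df, p = welch_two_sample(x, x)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_separated_samples_significant(self, rng):
        x = rng.normal(0, 1, 50)
        y = rng.normal(3, 1, 50)
        _, _, p = welch_two_sample(x, y)
        assert p < 0.001

    def test_matches_hand_computed_t(self):
        x = np.array([19.8, 20.4, 19.6, 17.8, 18.5, 18.9, 18.3, 18.9, 19.5, 22.0])
        y = np.array([28.2, 26.6, 20.1, 23.3, 25.2, 22.1, 17.7, 27.6, 20.6, 13.7])
        t, df, p = welch_two_sample(x, y)
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        se = np.sqrt(vx / 10 + vy / 10)
        assert t == pytest.approx((x.mean() - y.mean()) / se, abs=1e-12)
        num = (vx / 10 + vy / 10) ** 2
        den = (vx / 10) ** 2 / 9 + (vy / 10) ** 2 / 9
        assert df == pytest.approx(num / den, abs=1e-9)

    def test_constant_equal_samples_convention(self):
        t, _, p = welch_two_sample([5.0, 5.0], [5.0, 5.0])
        assert (t, p) == (0.0, 1.0)

    def test_constant_unequal_samples_raise(self):
        with pytest.raises(ZeroVarianceError):
            welch_two_sample([5.0, 5.0], [6.0, 6.0])


def _record(i, asucr, aiucr, psucr, piucr, h=32.0, r=25.0):
    tucr = asucr + aiucr + psucr + piucr
    return HipRecord(f"h{i}", asucr, aiucr, psucr, piucr, tucr, h, r, h * r * r)


class TestCohortSummary:
    def test_identical_hips_report_not_applicable(self):
        records = [_record(i, 0.08, 0.05, 0.10, 0.06) for i in range(6)]
        summary = cohort_summary(records)
        assert np.allclose(summary.descriptives["sd"], 0.0, atol=1e-12)
        assert (summary.correlations["sig"] == "n/a").all()

    def test_group_counts_match_direct_counting(self):
        records = [
            _record(i, 0.05 + 0.02 * i, 0.05, 0.10, 0.05, h=30 + i, r=24 + 0.3 * i)
            for i in range(10)
        ]
        summary = cohort_summary(records, group_split_tucr=0.3)
        tucrs = np.array([r.tucr for r in records])
        assert summary.group_counts["n_low"] == int((tucrs <= 0.3).sum())
        assert summary.group_counts["n_high"] == int((tucrs > 0.3).sum())

    def test_generator_correlation_yields_positive_sample_r(self):
        # cohorts drawn with the positively correlated P-S/P-I deficiencies
        # show a positive sample correlation in >= 95 of 100 seeded cohorts
        from cupcov.synthetic import (
            CohortParams,
            canonical_quadrant_weights,
            draw_cohort_params,
        )

        w = np.array(canonical_quadrant_weights())
        positive = 0
        for s in range(100):
            ps = draw_cohort_params(
                CohortParams.from_reference(n_hips=30, master_seed=3000 + s)
            )
            seg = np.array([[p.f_ps, p.f_pi] for p in ps]) * w[2:]
            if np.corrcoef(seg[:, 0], seg[:, 1])[0, 1] > 0:
                positive += 1
        assert positive >= 95

    def test_record_validation(self):
        with pytest.raises(ValueError):
            HipRecord("x", 0.1, 0.1, 0.1, 0.1, 0.9, 30, 25, 18750.0)
        with pytest.raises(ValueError):
            HipRecord("x", -0.1, 0.2, 0.1, 0.1, 0.3, 30, 25, 18750.0)

    def test_report_renders(self):
        records = [
            _record(i, 0.05 + 0.01 * i, 0.05, 0.10, 0.05, h=30 + i) for i in range(8)
        ]
        text = cohort_summary(records).report()
        assert "No multiple-testing correction" in text
        assert "tucr" in text
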