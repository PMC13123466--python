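"""Sorting statistics: ratio definitions, enrichment algebra, the logistic
decline model, and the summary-statistics t-test against a raw-data oracle."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from taxisort import metrics as M
from taxisort.errors import InvalidInputError, UndefinedMetricError


def counts(**kw):
    base = dict(
        n_competent_in=0,
        n_competent_bottom=0,
        n_competent_top=0,
        n_deficient_in=0,
        n_deficient_top=0,
        n_deficient_bottom=0,
    )
    base.update(kw)
    return M.ConfusionCounts(**base)


class TestEfficiencies:
    def test_competent_example(self):
        c = counts(n_competent_in=100, n_competent_bottom=88, n_competent_top=12)
        assert M.efficiency_competent(c) == pytest.approx(0.88)

    @pytest.mark.parametrize("bottom,expected", [(100, 1.0), (0, 0.0)])
    def test_competent_extremes(self, bottom, expected):
        c = counts(n_competent_in=100, n_competent_bottom=bottom)
        assert M.efficiency_competent(c) == expected

    def test_deficient_example(self):
        c = counts(n_deficient_in=100, n_deficient_top=94, n_deficient_bottom=6)
        assert M.efficiency_deficient(c) == pytest.approx(0.94)

    @pytest.mark.parametrize("top,expected", [(50, 1.0), (0, 0.0)])
    def test_deficient_extremes(self, top, expected):
        c = counts(n_deficient_in=50, n_deficient_top=top)
        assert M.efficiency_deficient(c) == expected

    def test_zero_denominators_rejected(self):
        with pytest.raises(InvalidInputError):
            M.efficiency_competent(counts())
        with pytest.raises(InvalidInputError):
            M.efficiency_deficient(counts())

    def test_outlet_counts_cannot_exceed_input(self):
        with pytest.raises(InvalidInputError):
            counts(n_competent_in=10, n_competent_bottom=8, n_competent_top=4)

    @given(
        n_in=st.integers(1, 1000),
        frac=st.floats(0, 1),
    )
    @settings(max_examples=60, derandomize=True)
    def test_always_within_unit_interval(self, n_in, frac):
        bottom = int(n_in * frac)
        c = counts(n_competent_in=n_in, n_competent_bottom=bottom)
        assert 0.0 <= M.efficiency_competent(c) <= 1.0


class TestSpecificity:
    def test_mixed_population_example(self):
        c = counts(
            n_deficient_in=100, n_deficient_top=85, n_competent_in=100, n_competent_top=15
        )
        assert M.specificity(c) == pytest.approx(0.85)

    def test_no_false_positives_is_perfect(self):
        c = counts(n_deficient_in=10, n_deficient_top=7)
        assert M.specificity(c) == 1.0

    def test_equal_counts(self):
        c = counts(n_deficient_in=10, n_deficient_top=5, n_competent_in=10, n_competent_top=5)
        assert M.specificity(c) == 0.5

    def test_empty_top_outlet_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            M.specificity(counts(n_deficient_in=10, n_competent_in=10))


def enumerate_cumulative(effs):
    """Brute-force oracle: walk the outcome tree of a single worm that is
    re-sorted from the top stream, summing the probability of every leaf
    in which it was recovered at the bottom at least once."""

    def walk(round_idx, prob):
        if round_idx == len(effs):
            return 0.0  # never recovered
        eps = effs[round_idx]
        recovered_here = prob * eps
        return recovered_here + walk(round_idx + 1, prob * (1.0 - eps))

    return walk(0, 1.0)


class TestCumulativeEfficiency:
    @pytest.mark.parametrize(
        "effs",
        [
            (0.9, 0.9, 0.9),
            (0.88, 0.5, 0.7),
            (0.3,),
            (0.5, 0.0, 1.0, 0.2),
            (0.0, 0.0),
        ],
    )
    def test_matches_exhaustive_path_enumeration(self, effs):
        assert M.cumulative_efficiency(effs) == pytest.approx(enumerate_cumulative(effs), abs=1e-12)

    def test_three_rounds_at_ninety_percent(self):
        assert M.cumulative_efficiency([0.9, 0.9, 0.9]) == pytest.approx(0.999)

    def test_single_round_identity(self):
        assert M.cumulative_efficiency([0.37]) == pytest.approx(0.37)

    def test_absorbing_round(self):
        assert M.cumulative_efficiency([0.2, 1.0, 0.1]) == 1.0

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=6))
    @settings(max_examples=60, derandomize=True)
    def test_monotone_in_rounds(self, effs):
        partial = [M.cumulative_efficiency(effs[: k + 1]) for k in range(len(effs))]
        assert all(b >= a - 1e-12 for a, b in zip(partial, partial[1:]))

    def test_series_container(self):
        series = M.RoundSeries(efficiencies=(0.9, 0.8), recovery_interval_min=120.0)
        assert M.cumulative_efficiency(series) == pytest.approx(0.98)

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            M.cumulative_efficiency([])


PRINTED = M.LogisticDecline(a=0.49, b=-3.29, c=0.41, d=3.3)


class TestLogisticModel:
    def test_plateaus_of_printed_coefficients(self):
        early = M.evaluate_logistic(PRINTED, -1e3)
        late = M.evaluate_logistic(PRINTED, 1e3)
        assert sorted([early, late]) == pytest.approx([0.41, 0.90])

    def test_zero_amplitude_is_constant(self):
        flat = M.LogisticDecline(a=0.0, b=-1.0, c=0.37, d=5.0)
        assert M.evaluate_logistic(flat, np.linspace(0, 50, 7)) == pytest.approx([0.37] * 7)

    def test_midpoint_symmetry(self):
        assert M.evaluate_logistic(PRINTED, 3.3) == pytest.approx(0.49 / 2 + 0.41)

    def test_bounded_by_plateaus(self):
        t = np.linspace(-50, 50, 401)
        y = M.evaluate_logistic(PRINTED, t)
        assert np.all(y >= 0.41 - 1e-12) and np.all(y <= 0.90 + 1e-12)


class TestLogisticFit:
    T = np.arange(0.0, 8.01, 0.125)

    def test_noiseless_self_fit_is_exact(self):
        y = M.evaluate_logistic(PRINTED, self.T)
        model, report = M.fit_logistic_decline(self.T, y)
        assert report.r_squared == pytest.approx(1.0, abs=1e-9)
        assert model.d == pytest.approx(3.3, rel=1e-3)

    def test_constant_data_flagged_degenerate(self):
        y = np.full_like(self.T, 0.6)
        model, report = M.fit_logistic_decline(self.T, y)
        assert report.degenerate
        assert model.a == 0.0 and model.c == pytest.approx(0.6)

    def test_parameter_recovery_under_noise(self):
        """Mean recovered parameters within 5% of truth over 20 noise seeds
        at sigma = 0.01."""
        true = np.array([PRINTED.a, PRINTED.b, PRINTED.c, PRINTED.d])
        clean = M.evaluate_logistic(PRINTED, self.T)
        fits = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = np.clip(clean + rng.normal(0, 0.01, clean.size), 0.0, 1.0)
            model, report = M.fit_logistic_decline(self.T, y)
            fits.append([model.a, model.b, model.c, model.d])
        bias = np.mean(fits, axis=0) - true
        assert np.all(np.abs(bias / true) < 0.05)

    def test_too_few_points_rejected(self):
        with pytest.raises(InvalidInputError):
            M.fit_logistic_decline([0, 1, 2, 3], [0.9, 0.8, 0.5, 0.41])


class TestTTestFromSummary:
    G_TOP = M.GaitSummary(mean=3.50, sd=0.46, n=150)
    G_BOT = M.GaitSummary(mean=3.62, sd=0.35, n=150)

    def test_gait_frequency_comparison(self):
        t, df, p = M.two_sample_t_from_summary(self.G_TOP, self.G_BOT)
        assert abs(t) == pytest.approx(2.54, abs=0.01)
        assert 0.005 < p < 0.02  # two-tailed; one-tailed is about half

    def test_identical_groups(self):
        g = M.GaitSummary(3.5, 0.4, 30)
        t, df, p = M.two_sample_t_from_summary(g, g)
        assert t == 0.0 and p == 1.0

    def test_root_n_scaling(self):
        t1, *_ = M.two_sample_t_from_summary(self.G_TOP, self.G_BOT)
        big1 = M.GaitSummary(3.50, 0.46, 600)
        big2 = M.GaitSummary(3.62, 0.35, 600)
        t4, *_ = M.two_sample_t_from_summary(big1, big2)
        assert abs(t4) == pytest.approx(2 * abs(t1), rel=1e-2)

    @pytest.mark.parametrize("pooled", [False, True])
    def test_agrees_with_raw_data_computation(self, pooled):
        """Generate raw samples with exactly the summary moments and compare
        against scipy's from-raw t-test."""
        rng = np.random.default_rng(7)

        def sample(summary):
            x = rng.normal(size=summary.n)
            x = (x - x.mean()) / x.std(ddof=1)
            return summary.mean + summary.sd * x

        a, b = sample(self.G_TOP), sample(self.G_BOT)
        t_ref, p_ref = stats.ttest_ind(a, b, equal_var=pooled)
        t, df, p = M.two_sample_t_from_summary(self.G_TOP, self.G_BOT, pooled=pooled)
        assert t == pytest.approx(t_ref, rel=1e-9)
        assert p == pytest.approx(p_ref, rel=1e-9)

    def test_one_tailed_is_half_of_two_tailed(self):
        _, _, p2 = M.two_sample_t_from_summary(self.G_TOP, self.G_BOT, tails=2)
        _, _, p1 = M.two_sample_t_from_summary(self.G_TOP, self.G_BOT, tails=1)
        assert p1 == pytest.approx(p2 / 2, rel=1e-12)
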