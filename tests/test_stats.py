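import math

import numpy as np
import pytest
from scipy import stats as sps

from mosslif import ChannelCombo, SyntheticConfig, compute_histograms, welch_t
from mosslif.errors import DegenerateVarianceError, InsufficientDataError, ValidationError
from mosslif.stats import (
    all_pairs_differences,
    control_band,
    exceeds_band,
    summarize_session,
    SessionSummary,
)
from mosslif.distance import combo_distance
from mosslif.synthetic import generate_trial

from oracles import welch_closed_form

R = ChannelCombo.parse("R")


def _sets(config, trial_id, n=None):
    sets = [compute_histograms(img) for img in generate_trial(config, trial_id)]
    return sets if n is None else sets[:n]


def _summary(mean, combo=R, metric="density_difference", n=10):
    return SessionSummary(
        trial_id="t", day=1, session="am", combo=combo, metric=metric,
        mean=mean, sd=0.0, se=0.0, n=n,
    )


class TestAllPairs:
    def test_disjoint_lists_full_product(self, tiny_config):
        trial = _sets(tiny_config, "trial", 2)
        control = _sets(tiny_config, "control", 3)
        samples = all_pairs_differences(trial, control, "density_difference", R)
        assert len(samples) == 6
        # values match independent per-pair calls, in the same order
        expected = [
            combo_distance(t, c, "density_difference", R) for t in trial for c in control
        ]
        assert [s.value for s in samples] == expected

    def test_self_comparison_excludes_identical_images(self, tiny_config):
        control = _sets(tiny_config, "control")
        samples = all_pairs_differences(control, control, "density_difference", R)
        n = len(control)
        assert len(samples) == n * n - n
        assert all(s.value > 0 or s.trial_meta != s.control_meta for s in samples)

    def test_single_image_against_itself_is_empty(self, tiny_config):
        one = _sets(tiny_config, "control", 1)
        assert all_pairs_differences(one, one, "density_difference", R) == []

    def test_session_exclusion_drops_same_session_pairs(self, tiny_config):
        control = _sets(tiny_config, "control")
        samples = all_pairs_differences(
            control, control, "density_difference", R, exclude="session"
        )
        per_session = tiny_config.images_per_session
        n = len(control)
        assert len(samples) == n * (n - per_session)
        assert all(
            s.trial_meta.session_key != s.control_meta.session_key for s in samples
        )

    def test_empty_list_rejected(self, tiny_config):
        control = _sets(tiny_config, "control", 2)
        with pytest.raises(InsufficientDataError):
            all_pairs_differences([], control, "density_difference", R)


class TestSummarizeSession:
    def test_constant_samples(self, tiny_config):
        control = _sets(tiny_config, "control", 5)
        trial = _sets(tiny_config, "trial", 1)
        samples = all_pairs_differences(trial, control, "density_difference", R)
        c = samples[0].value
        constant = [s.__class__(**{**s.__dict__, "value": c}) for s in samples]
        summ = summarize_session(constant)
        assert (summ.mean, summ.sd, summ.se) == (c, 0.0, 0.0)

    def test_two_point_closed_form(self, tiny_config):
        control = _sets(tiny_config, "control", 2)
        trial = _sets(tiny_config, "trial", 1)
        samples = all_pairs_differences(trial, control, "density_difference", R)
        fixed = [
            samples[0].__class__(**{**samples[0].__dict__, "value": 0.0}),
            samples[1].__class__(**{**samples[1].__dict__, "value": 1.0}),
        ]
        summ = summarize_session(fixed)
        assert summ.mean == 0.5
        assert summ.sd == pytest.approx(math.sqrt(0.5), abs=1e-12)
        assert summ.se == pytest.approx(0.5, abs=1e-12)
        assert summ.se == pytest.approx(summ.sd / math.sqrt(summ.n), abs=1e-9)

    def test_large_batch_matches_two_pass_oracle(self, tiny_config, rng):
        control = _sets(tiny_config, "control")
        trial = _sets(tiny_config, "trial", tiny_config.images_per_session)
        samples = all_pairs_differences(trial, control, "density_difference", R)
        summ = summarize_session(samples)
        values = [s.value for s in samples]
        mean = sum(values) / len(values)
        var = sum((v - mean) ** 2 for v in values) / (len(values) - 1)
        assert summ.mean == pytest.approx(mean, abs=1e-12)
        assert summ.sd == pytest.approx(math.sqrt(var), abs=1e-12)

    def test_insufficient_samples_rejected(self, tiny_config):
        control = _sets(tiny_config, "control", 2)
        trial = _sets(tiny_config, "trial", 1)
        samples = all_pairs_differences(trial, control, "density_difference", R)
        with pytest.raises(InsufficientDataError):
            summarize_session(samples[:1])


class TestWelchT:
    def test_identical_samples_give_t_zero_p_one(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.p == 1.0

    def test_hand_computed_example(self):
        res = welch_t([0, 0, 1, 1], [10, 10, 11, 11])
        t_ref, dof_ref = welch_closed_form([0, 0, 1, 1], [10, 10, 11, 11])
        assert res.t == pytest.approx(t_ref, abs=1e-9)
        assert res.t == pytest.approx(-10 / math.sqrt(1 / 6), abs=1e-9)
        assert res.dof == pytest.approx(6.0, abs=1e-9)

    def test_agrees_with_scipy_on_random_samples(self, rng):
        for _ in range(20):
            a = rng.normal(size=rng.integers(3, 30))
            b = rng.normal(loc=rng.normal(), size=rng.integers(3, 30))
            res = welch_t(a, b)
            ref = sps.ttest_ind(a, b, equal_var=False)
            assert res.t == pytest.approx(ref.statistic, abs=1e-9)
            assert res.p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_null_p_values_are_calibrated(self, rng):
        """Fraction of p < 0.01 under the null stays within binomial 3 sigma."""
        n_rep, n = 2000, 15
        a = rng.normal(size=(n_rep, n))
        b = rng.normal(size=(n_rep, n))
        hits = sum(welch_t(a[i], b[i]).p < 0.01 for i in range(n_rep))
        tol = 3 * math.sqrt(0.01 * 0.99 / n_rep)
        assert abs(hits / n_rep - 0.01) <= tol

    def test_degenerate_variance_rejected(self):
        with pytest.raises(DegenerateVarianceError):
            welch_t([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])


class TestControlBand:
    def test_equal_means_degenerate_band(self):
        summaries = [_summary(0.3) for _ in range(5)]
        band = control_band(summaries, level=0.99)
        assert band.center == 0.3
        assert band.ci99_lo == band.ci99_hi == 0.3
        assert band.sigma3_lo == band.sigma3_hi == 0.3

    def test_two_point_closed_form(self):
        band = control_band([_summary(0.0), _summary(1.0)], level=0.99)
        s = math.sqrt(0.5)
        half = sps.t.ppf(0.995, 1) * s * math.sqrt(1 + 1 / 2)
        assert band.center == 0.5
        assert band.ci99_hi == pytest.approx(0.5 + half, abs=1e-9)
        assert band.ci99_lo == pytest.approx(0.5 - half, abs=1e-9)
        assert band.sigma3_hi == pytest.approx(0.5 + 3 * s, abs=1e-12)

    def test_heldout_coverage_near_level(self, rng):
        """~99% of held-out control session means fall inside the band."""
        inside = total = 0
        for _ in range(400):
            means = rng.normal(0.2, 0.01, size=14)
            band = control_band([_summary(m) for m in means], level=0.99)
            held = rng.normal(0.2, 0.01, size=200)
            inside += int(((held >= band.ci99_lo) & (held <= band.ci99_hi)).sum())
            total += held.size
        assert inside / total == pytest.approx(0.99, abs=0.005)

    def test_sigma3_contains_ci99_for_large_n(self, rng):
        means = rng.normal(0.2, 0.02, size=200)
        band = control_band([_summary(m) for m in means], level=0.99)
        assert band.sigma3_lo < band.ci99_lo < band.ci99_hi < band.sigma3_hi

    def test_too_few_summaries_rejected(self):
        with pytest.raises(InsufficientDataError):
            control_band([_summary(0.1)])


class TestExceedsBand:
    @pytest.fixture
    def band(self):
        return control_band([_summary(m) for m in (0.1, 0.2, 0.3, 0.2, 0.2)], level=0.99)

    def test_center_is_inside(self, band):
        assert exceeds_band(_summary(band.center), band) is False

    def test_boundary_is_not_exceedance(self, band):
        assert exceeds_band(_summary(band.ci99_hi), band) is False
        assert exceeds_band(_summary(band.ci99_lo), band) is False

    def test_epsilon_above_boundary_is_exceedance(self, band):
        assert exceeds_band(_summary(band.ci99_hi + 1e-12), band) is True
        assert exceeds_band(_summary(band.ci99_lo - 1e-12), band) is True

    def test_combo_mismatch_rejected(self, band):
        other = _summary(0.2, combo=ChannelCombo.parse("G"))
        with pytest.raises(ValidationError, match="match"):
            exceeds_band(other, band)
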