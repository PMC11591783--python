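"""SA labeling: dichotomization boundaries, standardization round-trip,
EM mixture fitting, density intersection and the fusion rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hs

from satrain.errors import DataError, DegenerateDataError, JoinError
from satrain.labeling import (Gmm1D, SaThresholds, dichotomize_fatigue,
                              dichotomize_stress, fit_gmm_1d, label_dataset,
                              label_sa, pdf_intersection, score_threshold,
                              standardize_rt)


class TestDichotomization:
    @pytest.mark.parametrize("kss,expected", [
        (1, "low"), (5, "low"), (6, "high"), (9, "high")])
    def test_fatigue_boundaries(self, kss, expected):
        assert dichotomize_fatigue(kss) == expected

    @pytest.mark.parametrize("sati6,expected", [
        (6, "low"), (14, "low"), (15, "high"), (24, "high")])
    def test_stress_boundaries(self, sati6, expected):
        assert dichotomize_stress(sati6) == expected

    @pytest.mark.parametrize("func,bad", [
        (dichotomize_fatigue, 0), (dichotomize_fatigue, 10),
        (dichotomize_stress, 5), (dichotomize_stress, 25)])
    def test_out_of_range_rejected(self, func, bad):
        with pytest.raises(DataError):
            func(bad)


class TestStandardization:
    def test_simple_example(self):
        z, std = standardize_rt([1.0, 2.0, 3.0])
        np.testing.assert_allclose(z, [-1, 0, 1])
        assert std.shift == 2.0 and std.scale == 1.0

    def test_hand_computed_sample_sd(self):
        # mean 5, sample SD sqrt(32/7) = 2.138
        _, std = standardize_rt([2, 4, 4, 4, 5, 5, 7, 9])
        assert std.shift == 5.0
        np.testing.assert_allclose(std.scale, 2.13809, atol=1e-5)

    def test_output_is_zero_mean_unit_sd(self, rng):
        z, _ = standardize_rt(rng.lognormal(1, 0.4, size=500))
        assert abs(z.mean()) < 1e-9
        assert abs(z.std(ddof=1) - 1) < 1e-9

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(hs.lists(hs.floats(0.5, 30.0), min_size=3, max_size=40, unique=True))
    def test_round_trip_exact(self, rts):
        z, std = standardize_rt(rts)
        np.testing.assert_allclose(std.inverse(z), rts, atol=1e-9)

    def test_constant_input_degenerate(self):
        with pytest.raises(DegenerateDataError):
            standardize_rt([3.0, 3.0, 3.0])

    def test_minmax_mode_maps_to_unit_interval(self):
        z, _ = standardize_rt([2.0, 4.0, 6.0], mode="minmax")
        np.testing.assert_allclose(z, [0.0, 0.5, 1.0])


class TestGmmFit:
    def test_parameter_recovery_on_synthetic_mixture(self):
        rng = np.random.default_rng(42)
        x = np.concatenate([rng.normal(0, 1, 1000), rng.normal(5, 1, 1000)])
        g = fit_gmm_1d(x, seed=0)
        assert abs(g.mu[0] - 0) < 0.1 and abs(g.mu[1] - 5) < 0.1
        assert abs(g.w[0] - 0.5) < 0.05 and abs(g.w[1] - 0.5) < 0.05

    def test_agrees_with_sklearn_reference(self):
        from sklearn.mixture import GaussianMixture
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(-1, 0.7, 600), rng.normal(3, 1.2, 400)])
        ours = fit_gmm_1d(x, seed=0)
        ref = GaussianMixture(2, n_init=5, random_state=0).fit(x[:, None])
        order = np.argsort(ref.means_.ravel())
        np.testing.assert_allclose(ours.mu, ref.means_.ravel()[order], atol=0.05)
        np.testing.assert_allclose(ours.w, ref.weights_[order], atol=0.02)

    def test_separated_clusters_hit_variance_floor(self):
        x = np.array([0.0] * 5 + [10.0] * 5)
        g = fit_gmm_1d(x, seed=0)
        np.testing.assert_allclose(g.mu, [0.0, 10.0], atol=1e-6)
        assert g.sigma2[0] <= 1e-5 and g.sigma2[1] <= 1e-5

    def test_loglik_monotone_over_iterations(self):
        """EM property: running EM from the previous fit's parameters
        can only increase the log-likelihood."""
        rng = np.random.default_rng(11)
        x = np.concatenate([rng.normal(0, 1, 300), rng.normal(4, 2, 300)])
        from satrain.labeling import _em_run
        w, mu, s2 = np.array([.5, .5]), np.array([-1., 5.]), np.array([1., 1.])
        lls = []
        for _ in range(20):
            w, mu, s2, ll, _, _ = _em_run(x, w, mu, s2, tol=0, max_iter=1)
            lls.append(ll)
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_too_few_points_rejected(self):
        with pytest.raises(DataError):
            fit_gmm_1d(np.arange(5))


class TestPdfIntersection:
    def _model(self, w, mu, s2):
        return Gmm1D(w=w, mu=mu, sigma2=s2, loglik=0.0, n_iter=1, converged=True)

    def test_symmetric_case_midpoint(self):
        r = pdf_intersection(self._model((0.5, 0.5), (0.0, 4.0), (1.0, 1.0)))
        assert not r.fallback
        np.testing.assert_allclose(r.threshold, 2.0, atol=1e-9)

    def test_weighted_case_closed_form(self):
        # 0.8 phi(x) = 0.2 phi(x-4)  =>  x = 2 + ln(4)/4
        r = pdf_intersection(self._model((0.8, 0.2), (0.0, 4.0), (1.0, 1.0)))
        np.testing.assert_allclose(r.threshold, 2.0 + np.log(4.0) / 4.0, atol=1e-9)
        np.testing.assert_allclose(r.threshold, 2.3466, atol=1e-3)

    @pytest.mark.parametrize("w,mu,s2", [
        ((0.5, 0.5), (0.0, 4.0), (1.0, 1.0)),
        ((0.7, 0.3), (-2.0, 1.0), (0.5, 2.0)),
        ((0.36, 0.64), (1.0, 6.0), (0.8, 3.0)),
    ])
    def test_defining_equation_holds(self, w, mu, s2):
        m = self._model(w, mu, s2)
        r = pdf_intersection(m)
        assert not r.fallback
        assert abs(m.component_pdf(r.threshold, 0)
                   - m.component_pdf(r.threshold, 1)) < 1e-8
        assert mu[0] < r.threshold < mu[1]

    def test_equal_means_degenerate(self):
        with pytest.raises(DegenerateDataError):
            pdf_intersection(self._model((0.5, 0.5), (1.0, 1.0), (1.0, 2.0)))

    def test_unweighted_flag_moves_threshold(self):
        m = self._model((0.8, 0.2), (0.0, 4.0), (1.0, 1.0))
        assert pdf_intersection(m, weighted=False).threshold == pytest.approx(2.0)


class TestScoreThreshold:
    def test_single_value(self):
        assert score_threshold([16]) == 16

    def test_even_sample_mean_of_central_pair(self):
        assert score_threshold([12, 14, 18, 20]) == 16.0

    def test_appending_median_is_invariant(self):
        scores = [10, 14, 16, 20, 22]
        med = score_threshold(scores)
        assert score_threshold(scores + [med]) == med

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            score_threshold([])


class TestFusionRule:
    THR = SaThresholds(rt_threshold_std=0.99, rt_threshold_s=6.55,
                       score_threshold=16.0)

    @pytest.mark.parametrize("rt,score,expected", [
        (7.0, 10, "low"),    # RT above threshold decides alone
        (5.0, 17, "low"),    # RT below, score above median
        (5.0, 16, "high"),   # boundary: score equal to median is not "exceeded"
        (6.55, 17, "low"),   # boundary RT not exceeded, score decides
        (6.55, 16, "high"),  # neither strictly exceeded
    ])
    def test_rule_truth_table(self, rt, score, expected):
        assert label_sa(rt, self.THR, score) == expected

    def test_rt_above_threshold_ignores_missing_score(self):
        assert label_sa(7.0, self.THR, None) == "low"

    def test_missing_score_below_threshold_rejected(self):
        with pytest.raises(DataError):
            label_sa(5.0, self.THR, None)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(hs.floats(0.5, 12.0), hs.floats(8, 32), hs.floats(0.1, 3.0),
           hs.floats(0.1, 3.0))
    def test_monotone_in_rt_and_score(self, rt, score, drt, dscore):
        """Raising RT or subjective score can never flip low -> high."""
        base = label_sa(rt, self.THR, score)
        if base == "low":
            assert label_sa(rt + drt, self.THR, score) == "low"
            assert label_sa(rt, self.THR, score + dscore) == "low"


class TestLabelDataset:
    def test_cohort_threshold_in_design_window(self, default_config):
        from satrain.synthetic import simulate_cohort
        trials, scores = simulate_cohort(default_config)
        labeled, thr, table = label_dataset(trials, scores, seed=0)
        assert 5.5 <= thr.rt_threshold_s <= 7.5
        # exact round trip between standardized and second-scale thresholds
        np.testing.assert_allclose(
            thr.standardization.inverse(thr.rt_threshold_std),
            thr.rt_threshold_s, atol=1e-9)

    def test_condition_counts_conserve_total(self, small_cohort):
        trials, scores = small_cohort
        labeled, _, table = label_dataset(trials, scores, seed=0)
        assert table.total == len(trials)
        assert set(labeled["sa_label"]) <= {"low", "high"}

    def test_unmatched_trial_raises_join_error(self, small_cohort):
        trials, scores = small_cohort
        with pytest.raises(JoinError):
            label_dataset(trials, scores.iloc[:-1], seed=0)

    def test_labels_append_expected_columns(self, small_cohort):
        trials, scores = small_cohort
        labeled, _, _ = label_dataset(trials, scores, seed=0)
        for col in ("sa_label", "fatigue_label", "stress_label", "rt_threshold_s"):
            assert col in labeled.columns
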