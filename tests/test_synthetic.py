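"""Cohort generator: design cardinality, sampling distributions,
signal-stream structure and determinism."""

import numpy as np
import pandas as pd
import pytest

from satrain.config import CohortConfig, EVENT_TYPES, RtMixtureConfig
from satrain.errors import ConfigurationError
from satrain.synthetic import (build_design, generate_cohort,
                               sample_block_scores, sample_trial,
                               simulate_cohort, synth_ecg, synth_eeg,
                               synth_gaze)


class TestBuildDesign:
    def test_default_design_has_1824_rows(self, default_config):
        design = build_design(default_config)
        assert len(design) == 1824
        assert len(design) == 19 * 4 * 3 * 8

    def test_minimal_design_has_each_event_once(self):
        cfg = CohortConfig(n_subjects=1, conditions=("LL",),
                           low_sa_rate_by_condition={"LL": 0.2},
                           n_blocks_per_condition=1, n_trials_per_block=8)
        design = build_design(cfg)
        assert len(design) == 8
        assert sorted(design["event_type"]) == sorted(EVENT_TYPES)

    def test_each_block_is_a_permutation_of_events(self, small_config):
        design = build_design(small_config)
        for _, block in design.groupby(["subject_id", "condition", "block"]):
            assert sorted(block["event_type"]) == sorted(EVENT_TYPES)

    def test_deterministic_given_seed(self, small_config):
        pd.testing.assert_frame_equal(build_design(small_config),
                                      build_design(small_config))

    def test_cardinality_matches_factor_product(self):
        cfg = CohortConfig(n_subjects=3, n_blocks_per_condition=2,
                           n_trials_per_block=4, seed=1)
        assert len(build_design(cfg)) == 3 * 4 * 2 * 4

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigurationError, match="n_subjects"):
            CohortConfig(n_subjects=0)
        with pytest.raises(ConfigurationError, match="low_sa_rate"):
            CohortConfig(low_sa_rate_by_condition={"LL": 1.5, "LH": .3,
                                                   "HL": .3, "HH": .4})


class TestSampleTrial:
    def test_zero_low_rate_gives_all_high(self, rng):
        cfg = CohortConfig(low_sa_rate_by_condition=dict.fromkeys(
            ("LL", "LH", "HL", "HH"), 0.0))
        states = {sample_trial("LL", cfg, rng)[0] for _ in range(200)}
        assert states == {"high"}

    def test_low_fraction_matches_configured_rate(self, default_config, rng):
        n = 10_000
        p = default_config.low_sa_rate_by_condition["HH"]  # 207/441
        draws = sum(sample_trial("HH", default_config, rng)[0] == "low"
                    for _ in range(n))
        se = np.sqrt(p * (1 - p) / n)
        assert abs(draws / n - p) < 3 * se

    def test_rt_positive_and_duration_in_range(self, default_config, rng):
        lo, hi = default_config.segment_duration_range_s
        for _ in range(100):
            _, rt, dur = sample_trial("LL", default_config, rng)
            assert rt > default_config.rt_mixture.min_rt_s
            assert lo <= dur <= hi

    def test_unknown_condition_rejected(self, default_config, rng):
        with pytest.raises(ConfigurationError):
            sample_trial("XX", default_config, rng)

    def test_mixture_intersection_recovered_near_design_value(self, rng):
        """Labeling the generator's own RTs puts the GMM-intersection
        threshold in the 5.5-7.5 s design window."""
        from satrain.labeling import fit_gmm_1d, pdf_intersection, standardize_rt
        cfg = CohortConfig()
        rts = [sample_trial("HH", cfg, rng)[1] for _ in range(10_000)]
        z, std = standardize_rt(rts)
        thr = std.inverse(pdf_intersection(fit_gmm_1d(z, seed=0)).threshold)
        assert 5.5 <= thr <= 7.5


class TestBlockScores:
    def test_ll_without_noise_is_low_fatigue_low_stress(self, rng):
        cfg = CohortConfig(crossover_noise=0.0)
        s = sample_block_scores("LL", 0.1, cfg, rng)
        assert s["kss"] <= 5 and s["sati6"] < 15

    def test_hh_without_noise_is_high_fatigue_high_stress(self, rng):
        cfg = CohortConfig(crossover_noise=0.0)
        s = sample_block_scores("HH", 0.5, cfg, rng)
        assert s["kss"] >= 6 and s["sati6"] >= 15

    def test_mars_increases_with_low_sa_fraction(self, default_config, rng):
        hi = [sample_block_scores("LL", 1.0, default_config, rng)["mars_sa_score"]
              for _ in range(1000)]
        lo = [sample_block_scores("LL", 0.0, default_config, rng)["mars_sa_score"]
              for _ in range(1000)]
        diff = np.mean(hi) - np.mean(lo)
        se = np.sqrt(np.var(hi) / 1000 + np.var(lo) / 1000)
        assert abs(diff - 8.0) < 3 * se + 0.3  # rounding/clipping bias margin

    def test_scores_within_instrument_ranges(self, default_config, rng):
        for cond in ("LL", "LH", "HL", "HH"):
            s = sample_block_scores(cond, 0.4, default_config, rng)
            assert 1 <= s["kss"] <= 9
            assert 6 <= s["sati6"] <= 24
            lo, hi = default_config.mars_range
            assert lo <= s["mars_sa_score"] <= hi


class TestSignalStreams:
    trial_high = {"segment_duration_s": 30.0, "true_sa_state": "high"}
    trial_low = {"segment_duration_s": 30.0, "true_sa_state": "low"}

    def test_gaze_sample_count(self, default_config, rng):
        g = synth_gaze(self.trial_high, default_config, rng)
        assert len(g) == 450  # 15 Hz x 30 s

    def test_gaze_no_missing_when_fraction_zero(self, default_config, rng):
        g = synth_gaze(self.trial_high, default_config, rng, missing_fraction=0.0)
        assert g["valid"].all()

    def test_gaze_view_scene_dwell_higher_under_high_sa(self, default_config, rng):
        from satrain.pipeline import gaze_features_for_stream
        share = {}
        for name, trial in (("high", self.trial_high), ("low", self.trial_low)):
            vals = [gaze_features_for_stream(
                synth_gaze(trial, default_config, rng))["dwell_view_scene"]
                for _ in range(40)]
            share[name] = np.mean(vals)
        assert share["high"] > share["low"]

    def test_ecg_peak_count_at_constant_60bpm(self, default_config, rng):
        trial = {"segment_duration_s": 60.0, "true_sa_state": "high"}
        _, r = synth_ecg(trial, default_config, rng,
                         params={"hr_bpm": 60.0, "amp_lf_ms": 0.0,
                                 "amp_hf_ms": 0.0, "jitter_ms": 0.0})
        assert abs(r.size - 60) <= 1

    def test_ecg_no_modulation_gives_zero_sdnn(self, default_config, rng):
        _, r = synth_ecg(self.trial_high, default_config, rng,
                         params={"hr_bpm": 72.0, "amp_lf_ms": 0.0,
                                 "amp_hf_ms": 0.0, "jitter_ms": 0.0})
        assert np.std(np.diff(r)) < 1e-9

    def test_ecg_mean_hr_ordering(self, default_config, rng):
        hr = {}
        for name, trial in (("high", self.trial_high), ("low", self.trial_low)):
            rates = []
            for _ in range(20):
                _, r = synth_ecg(trial, default_config, rng)
                rates.append(60.0 / np.mean(np.diff(r)))
            hr[name] = np.mean(rates)
        assert hr["low"] > hr["high"]

    def test_eeg_shape(self, default_config, rng):
        e = synth_eeg(self.trial_high, default_config, rng)
        assert e.shape == (32, 256 * 30)

    def test_eeg_frontal_theta_higher_under_high_sa(self, default_config, rng):
        from satrain.eeg import EegSegment, extract_band_powers, region_average
        theta = {}
        for name, trial in (("high", self.trial_high), ("low", self.trial_low)):
            vals = []
            for _ in range(8):
                bm = extract_band_powers(
                    EegSegment(synth_eeg(trial, default_config, rng)),
                    detect_bads=False)
                vals.append(region_average(bm).loc["frontal", "theta"])
            theta[name] = np.mean(vals)
        assert theta["high"] > theta["low"]

    def test_eeg_zero_amplitudes_equalize_states(self, default_config, rng):
        from satrain.eeg import EegSegment, extract_band_powers
        zero = {b: {"high": 0.0, "low": 0.0} for b in ("theta", "alpha", "beta")}
        p = {}
        for name, trial in (("high", self.trial_high), ("low", self.trial_low)):
            vals = [extract_band_powers(
                EegSegment(synth_eeg(trial, default_config, rng, amplitudes=zero)),
                detect_bads=False).power.to_numpy().mean() for _ in range(5)]
            p[name] = np.mean(vals)
        assert abs(p["high"] - p["low"]) / p["high"] < 0.15  # sampling noise only


class TestGenerateCohort:
    def test_manifest_counts_and_determinism(self, tmp_path, small_config):
        m1 = generate_cohort(small_config, tmp_path / "a")
        m2 = generate_cohort(small_config, tmp_path / "b")
        assert m1["n_trials"] == 2 * 4 * 3 * 8 == 192
        assert ((tmp_path / "a" / "design.csv").read_bytes()
                == (tmp_path / "b" / "design.csv").read_bytes())
        assert ((tmp_path / "a" / "scores.csv").read_bytes()
                == (tmp_path / "b" / "scores.csv").read_bytes())

    def test_default_manifest_count(self, tmp_path):
        cfg = CohortConfig(seed=3)
        m = generate_cohort(cfg, tmp_path / "full")
        assert m["n_trials"] == 1824

    def test_signal_files_written_and_readable(self, tmp_path, small_config):
        from satrain import io as sio
        generate_cohort(small_config, tmp_path / "sig", write_signals=2)
        trial_dirs = sorted((tmp_path / "sig" / "signals").iterdir())
        assert len(trial_dirs) == 2
        wave, meta = sio.read_signal(trial_dirs[0] / "ecg")
        assert meta["rate_hz"] == 512.0
        assert wave.size > 0
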