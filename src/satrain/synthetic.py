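"""Synthetic cohort generator.

Emulates a within-subject simulator study of situation awareness (SA) in
high-speed-train driving: 19 subjects x 4 conditions (LL/LH/HL/HH
crossing fatigue and stress induction) x 3 blocks x 8 fault/abnormal
events = 1824 trial segments.  Each trial carries a ground-truth SA
state drawn at the condition's low-SA rate, a response time from a
two-state lognormal mixture, block-level subjective scores (KSS,
SATI-6, adapted MARS), and — on demand — raw gaze, ECG and EEG streams
whose statistics depend on the SA state:

* gaze: fixation/saccade alternation with an SA-dependent AOI dwell
  mixture (high SA looks mostly at the external View Scene);
* ECG: lower heart rate and larger HRV under high SA (RR modulated at
  0.1 Hz and 0.25 Hz plus white jitter, stereotyped beat template);
* EEG: frontal theta and frontal+parietal beta larger under high SA,
  alpha larger under low SA, over a 1/f background.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .config import (CohortConfig, EVENT_TYPES, FATIGUE_CONDITIONS,
                     STRESS_CONDITIONS)
from .eeg import CHANNELS_32, REGIONS
from .errors import ConfigurationError
from .gaze import DEFAULT_AOI_LAYOUT, make_stream

__all__ = [
    "build_design",
    "sample_trial",
    "simulate_trials",
    "sample_block_scores",
    "simulate_cohort",
    "synth_gaze",
    "synth_ecg",
    "synth_eeg",
    "generate_cohort",
]

#: SA-state-dependent AOI dwell-probability mixtures.
AOI_DWELL = {
    "high": {"View Scene": 0.60, "MMI": 0.20, "DMI": 0.20},
    "low": {"View Scene": 0.30, "MMI": 0.35, "DMI": 0.35},
}

#: ECG generator defaults per SA state: mean HR (bpm), LF/HF modulation
#: amplitudes and white jitter SD (ms) sized to give SDNN ~50 ms (high)
#: and ~25 ms (low).
ECG_PARAMS = {
    "high": {"hr_bpm": 72.0, "amp_lf_ms": 45.0, "amp_hf_ms": 45.0, "jitter_ms": 15.0},
    "low": {"hr_bpm": 84.0, "amp_lf_ms": 20.0, "amp_hf_ms": 20.0, "jitter_ms": 10.0},
}

#: EEG oscillation amplitudes (uV) per band and SA state.  Theta (6 Hz)
#: lives on frontal channels; alpha (10 Hz) and beta (20 Hz) on frontal
#: and parietal channels.
EEG_AMPLITUDES = {
    "theta": {"high": 6.0, "low": 3.0},
    "alpha": {"high": 3.0, "low": 6.0},
    "beta": {"high": 4.0, "low": 2.0},
}
EEG_BAND_FREQ = {"theta": 6.0, "alpha": 10.0, "beta": 20.0}
EEG_BAND_CHANNELS = {
    "theta": set(REGIONS["frontal"]),
    "alpha": set(REGIONS["frontal"]) | set(REGIONS["parietal"]),
    "beta": set(REGIONS["frontal"]) | set(REGIONS["parietal"]),
}
EEG_BACKGROUND_RMS_UV = 4.0


# ---------------------------------------------------------------------------
# design table

def build_design(config: CohortConfig) -> pd.DataFrame:
    """Trial-skeleton table: one row per (subject, condition, block, trial).

    Condition (session) order is counterbalanced across subjects by
    cycling a balanced ordering; within each block the 8 event types are
    either a seeded random permutation or a cyclically shifted
    Latin-square row (``config.event_balancing``).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    conds = list(config.conditions)
    n_ev = config.n_trials_per_block
    if n_ev == len(EVENT_TYPES):
        events = list(EVENT_TYPES)
    elif n_ev < len(EVENT_TYPES):
        events = list(EVENT_TYPES[:n_ev])
    else:
        raise ConfigurationError(
            f"n_trials_per_block may not exceed the {len(EVENT_TYPES)} event types")
    rows = []
    for s in range(config.n_subjects):
        subject = f"S{s + 1:02d}"
        # counterbalance: rotate condition order by subject index
        order = conds[s % len(conds):] + conds[: s % len(conds)]
        for cond in order:
            for b in range(1, config.n_blocks_per_condition + 1):
                if config.event_balancing == "latin":
                    shift = (s * config.n_blocks_per_condition + b - 1) % n_ev
                    perm = events[shift:] + events[:shift]
                else:
                    perm = list(rng.permutation(events))
                for trial, ev in enumerate(perm, start=1):
                    rows.append((subject, cond, b, trial, ev))
    df = pd.DataFrame(rows, columns=["subject_id", "condition", "block",
                                     "trial", "event_type"])
    assert len(df) == config.n_trials_total
    return df


# ---------------------------------------------------------------------------
# per-trial sampling

def _lognormal_rt(median_s: float, sigma_log: float, min_rt_s: float,
                  rng: np.random.Generator) -> float:
    for _ in range(1000):
        rt = float(rng.lognormal(np.log(median_s), sigma_log))
        if rt > min_rt_s:
            return rt
    return min_rt_s + 1e-3  # pathological config; keep positive


def sample_trial(condition: str, config: CohortConfig,
                 rng: np.random.Generator) -> tuple[str, float, float]:
    """Draw (true_sa_state, rt_s, segment_duration_s) for one trial.

    SA state is Bernoulli at the condition's low-SA rate; RT comes from
    the state's lognormal component; segment duration is uniform on the
    configured interval.
    """
    if condition not in config.low_sa_rate_by_condition:
        raise ConfigurationError(f"unknown condition {condition!r}")
    p_low = config.low_sa_rate_by_condition[condition]
    state = "low" if rng.random() < p_low else "high"
    m = config.rt_mixture
    if state == "low":
        rt = _lognormal_rt(m.low_median_s, m.low_sigma_log, m.min_rt_s, rng)
    else:
        rt = _lognormal_rt(m.high_median_s, m.high_sigma_log, m.min_rt_s, rng)
    lo, hi = config.segment_duration_range_s
    duration = float(rng.uniform(lo, hi))
    return state, rt, duration


def simulate_trials(design: pd.DataFrame, config: CohortConfig,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Fill a design skeleton with sampled SA states, RTs and durations."""
    out = design.copy()
    states, rts, durs, t_events = [], [], [], []
    for _, row in out.iterrows():
        state, rt, dur = sample_trial(row["condition"], config, rng)
        states.append(state)
        rts.append(rt)
        durs.append(dur)
        # event onset inside the block timeline; plumbing only
        t_events.append(90.0 * (row["trial"] - 1) + float(rng.uniform(0.0, 10.0)))
    out["true_sa_state"] = states
    out["t_event_s"] = t_events
    out["rt_s"] = rts
    out["t_response_s"] = out["t_event_s"] + out["rt_s"]
    out["segment_duration_s"] = durs
    return out


def sample_block_scores(condition: str, true_low_fraction_in_block: float,
                        config: CohortConfig, rng: np.random.Generator
                        ) -> dict[str, int]:
    """Draw one block's subjective scores.

    KSS is high (>= 6) iff the condition induces fatigue, SATI-6 >= 15
    iff it induces stress, each flipped with probability
    ``config.crossover_noise``.  The adapted-MARS SA score (higher =
    worse SA) rises with the block's true low-SA fraction:
    Normal(12 + 8 * fraction, 2), rounded and clipped to the MARS range.
    """
    if not 0.0 <= true_low_fraction_in_block <= 1.0:
        raise ConfigurationError("true_low_fraction_in_block must lie in [0, 1]")
    fatigued = condition in FATIGUE_CONDITIONS
    stressed = condition in STRESS_CONDITIONS
    if rng.random() < config.crossover_noise:
        fatigued = not fatigued
    if rng.random() < config.crossover_noise:
        stressed = not stressed
    kss = int(rng.integers(6, 10)) if fatigued else int(rng.integers(1, 6))
    sati6 = int(rng.integers(15, 25)) if stressed else int(rng.integers(6, 15))
    lo, hi = config.mars_range
    mars = int(np.clip(round(rng.normal(12.0 + 8.0 * true_low_fraction_in_block, 2.0)),
                       lo, hi))
    return {"kss": kss, "sati6": sati6, "mars_sa_score": mars}


def simulate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full tabular cohort: (trials, block_scores), deterministic by seed."""
    rng = np.random.default_rng(config.seed)
    trials = simulate_trials(build_design(config), config, rng)
    rows = []
    for (subject, cond, block), grp in trials.groupby(
            ["subject_id", "condition", "block"], sort=True):
        frac = float((grp["true_sa_state"] == "low").mean())
        scores = sample_block_scores(cond, frac, config, rng)
        rows.append({"subject_id": subject, "condition": cond, "block": block,
                     **scores})
    return trials, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# raw signal synthesis

def _trial_fields(trial: Mapping) -> tuple[float, str]:
    dur = float(trial["segment_duration_s"])
    state = str(trial["true_sa_state"])
    if dur <= 0:
        raise ConfigurationError("segment_duration_s must be > 0")
    if state not in ("high", "low"):
        raise ConfigurationError("true_sa_state must be 'high' or 'low'")
    return dur, state


def synth_gaze(trial: Mapping, config: CohortConfig, rng: np.random.Generator,
               aoi_layout: Mapping[str, tuple[float, float, float, float]] | None = None,
               missing_fraction: float | None = None) -> pd.DataFrame:
    """15 Hz gaze stream alternating fixations and saccades.

    Fixation targets are drawn inside AOI rectangles with SA-dependent
    probabilities; within-fixation jitter stays below 0.5 deg and
    consecutive fixation centres are >= 4 deg apart so saccade steps
    exceed the 30 deg/s I-VT threshold.  A configurable fraction of
    samples is invalidated to exercise gap interpolation.
    """
    duration, state = _trial_fields(trial)
    layout = dict(DEFAULT_AOI_LAYOUT if aoi_layout is None else aoi_layout)
    if missing_fraction is None:
        missing_fraction = config.gaze_missing_fraction
    rate = config.gaze_hz
    n = int(round(duration * rate))
    probs = AOI_DWELL[state]
    names = list(probs)
    p = np.array([probs[k] for k in names])

    def draw_center(prev):
        for _ in range(50):
            aoi = names[rng.choice(len(names), p=p)]
            x0, x1, y0, y1 = layout[aoi]
            c = np.array([rng.uniform(x0 + 1.0, x1 - 1.0),
                          rng.uniform(y0 + 1.0, y1 - 1.0)])
            if prev is None or np.linalg.norm(c - prev) >= 4.0:
                return c
        return c  # crowded layout; accept last draw

    xs = np.empty(0)
    ys = np.empty(0)
    center = None
    while xs.size < n:
        nxt = draw_center(center)
        if center is not None:
            dist = float(np.linalg.norm(nxt - center))
            n_inter = max(0, int(dist // 7.0))
            for k in range(1, n_inter + 1):
                pt = center + (nxt - center) * k / (n_inter + 1)
                xs = np.append(xs, pt[0])
                ys = np.append(ys, pt[1])
        center = nxt
        n_fix = int(round(rng.uniform(0.25, 0.9) * rate))
        jitter = np.clip(rng.normal(0.0, 0.08, size=(n_fix, 2)), -0.4, 0.4)
        xs = np.append(xs, center[0] + jitter[:, 0])
        ys = np.append(ys, center[1] + jitter[:, 1])
    xs, ys = xs[:n], ys[:n]
    valid = rng.random(n) >= missing_fraction
    xs = np.where(valid, xs, np.nan)
    ys = np.where(valid, ys, np.nan)
    return make_stream(np.arange(n) / rate, xs, ys, valid)


_BEAT_WAVES = (  # (amplitude mV, centre offset s, width s): P, Q, R, S, T
    (0.12, -0.20, 0.025),
    (-0.15, -0.025, 0.010),
    (1.00, 0.0, 0.012),
    (-0.20, 0.025, 0.012),
    (0.30, 0.25, 0.050),
)


def synth_ecg(trial: Mapping, config: CohortConfig, rng: np.random.Generator,
              params: Mapping[str, float] | None = None,
              noise_mv: float = 0.02) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic single-lead ECG with ground-truth R-peak times.

    RR intervals follow ``base + A_lf sin(2 pi 0.1 t) + A_hf sin(2 pi
    0.25 t) + N(0, jitter)``; a stereotyped P-QRS-T template of Gaussians
    is placed at each R time over white noise.  Returns (waveform in mV
    at ``config.ecg_hz``, R-peak times in s).
    """
    duration, state = _trial_fields(trial)
    prm = dict(ECG_PARAMS[state]) if params is None else dict(params)
    fs = config.ecg_hz
    base_ms = 60000.0 / prm["hr_bpm"]
    t = 0.35
    r_times = []
    while t < duration - 0.05:
        r_times.append(t)
        rr = (base_ms
              + prm["amp_lf_ms"] * np.sin(2 * np.pi * 0.10 * t)
              + prm["amp_hf_ms"] * np.sin(2 * np.pi * 0.25 * t)
              + rng.normal(0.0, prm["jitter_ms"]))
        t += float(np.clip(rr, 300.0, 2000.0)) / 1000.0
    n = int(round(duration * fs))
    tt = np.arange(n) / fs
    x = rng.normal(0.0, noise_mv, size=n)
    for r in r_times:
        lo = max(0, int((r - 0.35) * fs))
        hi = min(n, int((r + 0.45) * fs))
        seg = tt[lo:hi] - r
        for amp, mu, w in _BEAT_WAVES:
            x[lo:hi] += amp * np.exp(-0.5 * ((seg - mu) / w) ** 2)
    return x, np.asarray(r_times)


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude noise, unit RMS."""
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    return x / np.std(x)


def synth_eeg(trial: Mapping, config: CohortConfig, rng: np.random.Generator,
              amplitudes: Mapping[str, Mapping[str, float]] | None = None
              ) -> np.ndarray:
    """32-channel EEG (uV, 256 Hz): 1/f background + SA-dependent bands.

    Theta (6 Hz) rides on frontal channels, alpha (10 Hz) and beta
    (20 Hz) on frontal+parietal channels, with amplitudes set by the SA
    state (theta and beta larger under high SA, alpha larger under low).
    """
    duration, state = _trial_fields(trial)
    amps = EEG_AMPLITUDES if amplitudes is None else amplitudes
    fs = config.eeg_hz
    n = int(round(duration * fs))
    tt = np.arange(n) / fs
    chans = CHANNELS_32[: config.eeg_channels]
    data = np.empty((len(chans), n))
    for i, ch in enumerate(chans):
        # per-channel gain spread keeps cross-channel variance realistic
        x = EEG_BACKGROUND_RMS_UV * rng.uniform(0.7, 1.4) * _pink_noise(n, rng)
        for band, freq in EEG_BAND_FREQ.items():
            if ch in EEG_BAND_CHANNELS[band]:
                amp = amps[band][state] * rng.uniform(0.8, 1.2)
                x += amp * np.sin(2 * np.pi * freq * tt + rng.uniform(0, 2 * np.pi))
        data[i] = x
    return data


# ---------------------------------------------------------------------------
# on-disk dataset

def generate_cohort(config: CohortConfig, out_dir, write_signals: int = 0) -> dict:
    """Write a cohort dataset: design.csv, scores.csv, manifest.json.

    ``write_signals`` > 0 additionally synthesises raw gaze/ECG/EEG for
    that many trials (taken evenly across the design) under
    ``signals/trial_<index>/``.  Deterministic given ``config.seed``;
    returns the manifest dict.
    """
    from . import io as sio  # local import to avoid cycle at import time
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trials, scores = simulate_cohort(config)
    sio.write_design(out / "design.csv", trials)
    sio.write_scores(out / "scores.csv", scores)

    signal_index = []
    if write_signals > 0:
        step = max(1, len(trials) // write_signals)
        chosen = trials.iloc[::step].head(write_signals)
        for idx, row in chosen.iterrows():
            rng = np.random.default_rng([config.seed, int(idx)])
            tdir = out / "signals" / f"trial_{idx:05d}"
            tdir.mkdir(parents=True, exist_ok=True)
            gaze = synth_gaze(row, config, rng)
            gaze.to_csv(tdir / "gaze.csv", index=False)
            ecg_wave, r_times = synth_ecg(row, config, rng)
            sio.write_signal(tdir / "ecg", ecg_wave, rate_hz=config.ecg_hz,
                             channels=["ECG"], units="mV")
            np.savetxt(tdir / "r_times_truth.txt", r_times)
            eeg_data = synth_eeg(row, config, rng)
            sio.write_signal(tdir / "eeg", eeg_data, rate_hz=config.eeg_hz,
                             channels=list(CHANNELS_32[: config.eeg_channels]),
                             units="uV")
            signal_index.append({"trial_index": int(idx), "dir": str(tdir.name)})

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "n_trials": int(len(trials)),
        "n_blocks": int(len(scores)),
        "n_low_sa_true": int((trials["true_sa_state"] == "low").sum()),
        "signals": signal_index,
        "ground_truth_labels": trials["true_sa_state"].tolist(),
    }
    sio.write_json(out / "manifest.json", manifest)
    return manifest
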