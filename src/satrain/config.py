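"""Cohort and pipeline configuration.

The defaults encode the experimental design being emulated: 19 subjects,
4 conditions (LL/LH/HL/HH coding fatigue x stress as low/high), 3 blocks
per condition, 8 fault/abnormal-driving events per block, gaze at 15 Hz,
ECG at 512 Hz and 32-channel EEG at 256 Hz.  Per-condition low-SA rates
default to the observed distribution of low/high SA samples in the study
design this generator emulates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import ConfigurationError

CONDITIONS = ("LL", "LH", "HL", "HH")

#: Conditions in which fatigue (first letter) / stress (second letter) is induced.
FATIGUE_CONDITIONS = frozenset({"HL", "HH"})
STRESS_CONDITIONS = frozenset({"LH", "HH"})

#: Default per-condition probability that a trial is a low-SA trial.
DEFAULT_LOW_SA_RATES = {
    "LL": 102 / 412,
    "LH": 151 / 422,
    "HL": 153 / 430,
    "HH": 207 / 441,
}

#: The eight fault / abnormal-driving event types, one of each per block.
EVENT_TYPES = (
    "vcb_not_closing",
    "traction_loss_1",
    "traction_loss_2",
    "aux_converter_failure",
    "rain_onset",
    "rain_end",
    "fog_onset",
    "fog_end",
)


@dataclass(frozen=True)
class RtMixtureConfig:
    """Two-state lognormal response-time model.

    RTs are positive and right-skewed, so each SA state draws from a
    lognormal: ``median_s`` is the state's median RT in seconds and
    ``sigma_log`` the log-scale spread.  Draws below ``min_rt_s`` are
    rejected and redrawn.  The defaults place the two components so that
    the pooled-cohort mixture threshold (density intersection) falls in
    the mid-single-digit seconds.
    """

    high_median_s: float = 3.0
    high_sigma_log: float = 0.32
    low_median_s: float = 10.0
    low_sigma_log: float = 0.10
    min_rt_s: float = 0.5

    def validate(self) -> None:
        for name in ("high_median_s", "high_sigma_log", "low_median_s",
                     "low_sigma_log", "min_rt_s"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"rt_mixture.{name} must be > 0")


@dataclass(frozen=True)
class CohortConfig:
    """Full parameterisation of the synthetic cohort generator."""

    n_subjects: int = 19
    conditions: Sequence[str] = CONDITIONS
    n_blocks_per_condition: int = 3
    n_trials_per_block: int = 8
    low_sa_rate_by_condition: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LOW_SA_RATES))
    rt_mixture: RtMixtureConfig = field(default_factory=RtMixtureConfig)
    segment_duration_range_s: tuple[float, float] = (30.0, 60.0)
    gaze_hz: float = 15.0
    ecg_hz: float = 512.0
    eeg_hz: float = 256.0
    eeg_channels: int = 32
    # subjective-score generator
    mars_range: tuple[int, int] = (8, 32)
    crossover_noise: float = 0.05  # P(block's fatigue/stress state flips)
    # gaze generator
    gaze_missing_fraction: float = 0.02
    # design balancing: "random" permutes events per block, "latin" cycles
    # a Latin-square row so each event visits each serial position
    event_balancing: str = "latin"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("n_subjects", "n_blocks_per_condition", "n_trials_per_block"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if len(set(self.conditions)) != len(self.conditions) or not self.conditions:
            raise ConfigurationError("conditions must be a nonempty set of unique codes")
        for cond in self.conditions:
            if cond not in self.low_sa_rate_by_condition:
                raise ConfigurationError(
                    f"low_sa_rate_by_condition missing condition {cond!r}")
            p = self.low_sa_rate_by_condition[cond]
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(
                    f"low_sa_rate_by_condition[{cond!r}] must lie in [0, 1]")
        self.rt_mixture.validate()
        lo, hi = self.segment_duration_range_s
        if not (0 < lo <= hi):
            raise ConfigurationError(
                "segment_duration_range_s must be a positive interval")
        for name in ("gaze_hz", "ecg_hz", "eeg_hz"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.eeg_channels < 4:
            raise ConfigurationError("eeg_channels must be >= 4")
        if not 0.0 <= self.crossover_noise <= 1.0:
            raise ConfigurationError("crossover_noise must lie in [0, 1]")
        if not 0.0 <= self.gaze_missing_fraction < 1.0:
            raise ConfigurationError("gaze_missing_fraction must lie in [0, 1)")
        if self.mars_range[0] >= self.mars_range[1]:
            raise ConfigurationError("mars_range must be an increasing pair")
        if self.event_balancing not in ("random", "latin"):
            raise ConfigurationError("event_balancing must be 'random' or 'latin'")

    @property
    def n_trials_total(self) -> int:
        return (self.n_subjects * len(self.conditions)
                * self.n_blocks_per_condition * self.n_trials_per_block)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["conditions"] = list(self.conditions)
        d["low_sa_rate_by_condition"] = dict(self.low_sa_rate_by_condition)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        if "rt_mixture" in d and isinstance(d["rt_mixture"], Mapping):
            d["rt_mixture"] = RtMixtureConfig(**d["rt_mixture"])
        for key in ("segment_duration_range_s", "mars_range"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        if "conditions" in d and isinstance(d["conditions"], list):
            d["conditions"] = tuple(d["conditions"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown cohort config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline settings (simulate -> label -> features -> validate).

    ``standardization`` selects how RTs are normalised before the mixture
    fit ('zscore' or 'minmax'); ``weighted_intersection`` chooses whether
    the mixture threshold uses the weighted (Bayes-boundary) or unweighted
    component densities.  ``max_signal_trials`` caps how many trials get
    raw gaze/ECG/EEG synthesised and processed end-to-end, keeping the
    all-in-one run tractable while the tabular design stays full-size.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    standardization: str = "zscore"
    weighted_intersection: bool = True
    bonferroni: bool = True
    max_signal_trials: int = 24
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.standardization not in ("zscore", "minmax"):
            raise ConfigurationError("standardization must be 'zscore' or 'minmax'")
        if self.max_signal_trials < 0:
            raise ConfigurationError("max_signal_trials must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = self.cohort.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], Mapping):
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**d)
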