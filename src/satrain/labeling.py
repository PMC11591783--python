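"""Rule-based situation-awareness labeling.

Each trial gets a binary SA label fused from two sources:

1. **Response time (RT)** — prioritised because it is objective and
   per-trial.  RTs of the whole cohort are standardized, a two-component
   univariate Gaussian mixture is fit by EM, and the RT cutoff is the
   point where the two weighted component densities intersect (the Bayes
   decision boundary of the mixture).
2. **Subjective SA score** — a block-level adapted-MARS rating (higher =
   worse SA), dichotomized at the cohort median.

Fusion rule: a trial is *low SA* if its RT exceeds the RT cutoff, or —
failing that — if its block's subjective score exceeds the median;
otherwise it is *high SA*.  "Exceeds" is strict in both places.

Fatigue (KSS) and stress (SATI-6) labels are simple dichotomizations and
are carried alongside the SA label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, DegenerateDataError, JoinError
from .stats import ContingencyTable

__all__ = [
    "Gmm1D",
    "RtStandardization",
    "SaThresholds",
    "dichotomize_fatigue",
    "dichotomize_stress",
    "standardize_rt",
    "fit_gmm_1d",
    "pdf_intersection",
    "score_threshold",
    "label_sa",
    "label_dataset",
]

_VARIANCE_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# subjective-scale dichotomization

def dichotomize_fatigue(kss: int) -> str:
    """KSS 1-5 -> 'low' fatigue, 6-9 -> 'high'."""
    if not 1 <= kss <= 9:
        raise DataError(f"KSS score must lie in [1, 9], got {kss}")
    return "low" if kss <= 5 else "high"


def dichotomize_stress(sati6: int) -> str:
    """SATI-6 >= 15 -> 'high' stress, < 15 -> 'low'."""
    if not 6 <= sati6 <= 24:
        raise DataError(f"SATI-6 score must lie in [6, 24], got {sati6}")
    return "high" if sati6 >= 15 else "low"


# ---------------------------------------------------------------------------
# RT standardization

@dataclass(frozen=True)
class RtStandardization:
    """Affine transform z = (rt - shift) / scale and its inverse.

    For z-scoring, shift/scale are the sample mean and SD (ddof=1); for
    min-max, the minimum and range.
    """

    shift: float
    scale: float
    mode: str = "zscore"

    def forward(self, rt_s):
        return (np.asarray(rt_s, dtype=float) - self.shift) / self.scale

    def inverse(self, z):
        return np.asarray(z, dtype=float) * self.scale + self.shift


def standardize_rt(rts: Sequence[float], mode: str = "zscore"
                   ) -> tuple[np.ndarray, RtStandardization]:
    """Standardize RTs for mixture fitting.

    'zscore' (default) maps to mean 0 / sample SD 1; 'minmax' maps the
    observed range onto [0, 1].  Constant input has no scale and raises.
    """
    rts = np.asarray(rts, dtype=float)
    if rts.size < 2:
        raise DataError("standardize_rt needs at least 2 values")
    if mode == "zscore":
        shift, scale = float(np.mean(rts)), float(np.std(rts, ddof=1))
    elif mode == "minmax":
        shift, scale = float(np.min(rts)), float(np.ptp(rts))
    else:
        raise DataError(f"unknown standardization mode {mode!r}")
    if scale <= 0:
        raise DegenerateDataError("RT sample is constant; cannot standardize")
    std = RtStandardization(shift, scale, mode)
    return std.forward(rts), std


# ---------------------------------------------------------------------------
# two-component 1-D Gaussian mixture by EM

@dataclass(frozen=True)
class Gmm1D:
    """Two-component univariate Gaussian mixture, components sorted by mean."""

    w: tuple[float, float]
    mu: tuple[float, float]
    sigma2: tuple[float, float]
    loglik: float
    n_iter: int
    converged: bool

    def component_pdf(self, x, j: int):
        return self.w[j] * _normal_pdf(np.asarray(x, float), self.mu[j], self.sigma2[j])

    def pdf(self, x):
        return self.component_pdf(x, 0) + self.component_pdf(x, 1)


def _normal_pdf(x, mu, s2):
    return np.exp(-0.5 * (x - mu) ** 2 / s2) / np.sqrt(2 * np.pi * s2)


def _em_run(x: np.ndarray, w, mu, s2, tol: float, max_iter: int):
    """One EM run from the given start; returns (w, mu, s2, loglik, it, conv)."""
    n = x.size
    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step via log densities for stability
        comp = np.column_stack([
            w[0] * _normal_pdf(x, mu[0], s2[0]),
            w[1] * _normal_pdf(x, mu[1], s2[1]),
        ])
        tot = comp.sum(axis=1)
        tot = np.maximum(tot, 1e-300)
        ll = float(np.log(tot).sum())
        resp = comp / tot[:, None]
        # M-step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        w = nk / n
        mu = (resp * x[:, None]).sum(axis=0) / nk
        s2 = (resp * (x[:, None] - mu) ** 2).sum(axis=0) / nk
        s2 = np.maximum(s2, _VARIANCE_FLOOR)
        if prev_ll > -np.inf and abs(ll - prev_ll) <= tol * max(1.0, abs(prev_ll)):
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
    return w, mu, s2, prev_ll, it, converged


def fit_gmm_1d(data: Sequence[float], k: int = 2, seed: int = 0,
               tol: float = 1e-6, max_iter: int = 500,
               n_restarts: int = 5) -> Gmm1D:
    """Fit a two-component 1-D Gaussian mixture by EM.

    Initialisation is a median split (lower/upper half statistics);
    additional restarts jitter the initial means with a seeded RNG and the
    best final log-likelihood wins.  Variances are floored at 1e-6 and
    the returned components are sorted by mean.
    """
    if k != 2:
        raise DataError("only k = 2 components are supported")
    x = np.asarray(data, dtype=float)
    if x.size < 10:
        raise DataError("fit_gmm_1d needs at least 10 observations")
    rng = np.random.default_rng(seed)
    med = np.median(x)
    lower, upper = x[x <= med], x[x > med]
    if upper.size == 0:  # heavy ties at the median
        lower, upper = x[x < med], x[x >= med]
    if lower.size == 0 or upper.size == 0:
        raise DegenerateDataError("data has no spread around its median")
    base_mu = np.array([lower.mean(), upper.mean()])
    base_s2 = np.maximum(np.array([lower.var(), upper.var()]), _VARIANCE_FLOOR)
    base_w = np.array([lower.size, upper.size], dtype=float) / x.size
    sd = float(x.std())

    best = None
    for r in range(max(1, n_restarts)):
        if r == 0:
            w0, mu0, s20 = base_w.copy(), base_mu.copy(), base_s2.copy()
        else:
            w0 = np.array([0.5, 0.5])
            mu0 = base_mu + rng.normal(0.0, 0.25 * sd + 1e-12, size=2)
            s20 = np.maximum(base_s2 * rng.uniform(0.5, 2.0, size=2), _VARIANCE_FLOOR)
        w, mu, s2, ll, it, conv = _em_run(x, w0, mu0, s20, tol, max_iter)
        if best is None or ll > best[3]:
            best = (w, mu, s2, ll, it, conv)

    w, mu, s2, ll, it, conv = best
    order = np.argsort(mu)
    return Gmm1D(w=tuple(float(w[j]) for j in order),
                 mu=tuple(float(mu[j]) for j in order),
                 sigma2=tuple(float(s2[j]) for j in order),
                 loglik=float(ll), n_iter=int(it), converged=bool(conv))


class IntersectionResult(NamedTuple):
    threshold: float
    fallback: bool


def pdf_intersection(model: Gmm1D, weighted: bool = True) -> IntersectionResult:
    """Decision threshold where the two component densities intersect.

    Solves ``w1 phi(x; mu1, s1) = w2 phi(x; mu2, s2)`` (or the unweighted
    version) through the quadratic obtained by equating log densities and
    returns the root strictly between the component means.  If no such
    root exists (extreme weight imbalance), the argmin of the absolute
    density difference on a 10,001-point grid over [mu1, mu2] is returned
    with ``fallback=True``.
    """
    (w1, w2), (m1, m2), (s1, s2) = model.w, model.mu, model.sigma2
    if math.isclose(m1, m2, rel_tol=0.0, abs_tol=1e-12):
        raise DegenerateDataError("component means coincide; no intersection")
    lw1, lw2 = (math.log(w1), math.log(w2)) if weighted else (0.0, 0.0)
    # log equality: -(x-m1)^2/(2 s1) + lw1 - 0.5 ln s1 = same for component 2
    a = 0.5 / s2 - 0.5 / s1
    b = m1 / s1 - m2 / s2
    c = (m2 ** 2 / (2 * s2) - m1 ** 2 / (2 * s1)
         + lw1 - lw2 + 0.5 * (math.log(s2) - math.log(s1)))
    lo, hi = min(m1, m2), max(m1, m2)
    roots: list[float] = []
    if abs(a) < 1e-300:
        if b != 0:
            roots = [-c / b]
    else:
        disc = b * b - 4 * a * c
        if disc >= 0:
            sq = math.sqrt(disc)
            roots = [(-b - sq) / (2 * a), (-b + sq) / (2 * a)]
    inside = [r for r in roots if lo < r < hi]
    if inside:
        return IntersectionResult(float(inside[0]), False)
    grid = np.linspace(lo, hi, 10_001)
    d1 = w1 * _normal_pdf(grid, m1, s1) if weighted else _normal_pdf(grid, m1, s1)
    d2 = w2 * _normal_pdf(grid, m2, s2) if weighted else _normal_pdf(grid, m2, s2)
    return IntersectionResult(float(grid[np.argmin(np.abs(d1 - d2))]), True)


# ---------------------------------------------------------------------------
# thresholds + fusion rule

def score_threshold(scores: Sequence[float]) -> float:
    """Cohort median of the subjective SA scores (mean of central pair)."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise DataError("score_threshold requires a nonempty sample")
    return float(np.median(scores))


@dataclass(frozen=True)
class SaThresholds:
    """The pair of decision thresholds used by the fusion rule."""

    rt_threshold_std: float
    rt_threshold_s: float
    score_threshold: float
    standardization: RtStandardization | None = None
    intersection_fallback: bool = False


def label_sa(rt_s: float, thresholds: SaThresholds,
             mars_score: float | None) -> str:
    """Apply the RT-prioritised fusion rule to one trial.

    low SA iff rt > rt_threshold (strict), else low iff score > median
    (strict), else high.  The score may be omitted only when the RT alone
    already decides (RT above threshold).
    """
    if not (math.isfinite(thresholds.rt_threshold_s)
            and math.isfinite(thresholds.score_threshold)):
        raise DataError("thresholds must be finite")
    if rt_s > thresholds.rt_threshold_s:
        return "low"
    if mars_score is None or (isinstance(mars_score, float) and math.isnan(mars_score)):
        raise DataError("subjective SA score required when RT does not exceed threshold")
    return "low" if mars_score > thresholds.score_threshold else "high"


def label_dataset(trials: pd.DataFrame, block_scores: pd.DataFrame,
                  standardization: str = "zscore",
                  weighted_intersection: bool = True,
                  seed: int = 0
                  ) -> tuple[pd.DataFrame, SaThresholds, ContingencyTable]:
    """Label a whole cohort.

    Joins each trial to its block's subjective scores on (subject_id,
    condition, block), standardizes all RTs jointly, fits the mixture,
    derives both thresholds, and applies the fusion rule per trial.
    Returns the labeled table (with ``sa_label``, ``fatigue_label``,
    ``stress_label`` and ``rt_threshold_s`` columns appended), the
    thresholds, and the per-condition low/high contingency table.
    """
    keys = ["subject_id", "condition", "block"]
    for col in keys + ["rt_s"]:
        if col not in trials.columns:
            raise DataError(f"trials table missing column {col!r}")
    for col in keys + ["mars_sa_score", "kss", "sati6"]:
        if col not in block_scores.columns:
            raise DataError(f"block_scores table missing column {col!r}")
    if block_scores.duplicated(subset=keys).any():
        raise JoinError("block_scores contains duplicate (subject, condition, block) keys")
    merged = trials.merge(block_scores[keys + ["mars_sa_score", "kss", "sati6"]],
                          on=keys, how="left", validate="many_to_one")
    if merged["mars_sa_score"].isna().any():
        bad = merged.loc[merged["mars_sa_score"].isna(), keys].iloc[0].to_dict()
        raise JoinError(f"trial failed to join to block scores: {bad}")

    z, std = standardize_rt(merged["rt_s"].to_numpy(), mode=standardization)
    gmm = fit_gmm_1d(z, seed=seed)
    inter = pdf_intersection(gmm, weighted=weighted_intersection)
    rt_thr_s = float(std.inverse(inter.threshold))
    thresholds = SaThresholds(
        rt_threshold_std=inter.threshold,
        rt_threshold_s=rt_thr_s,
        score_threshold=score_threshold(block_scores["mars_sa_score"].to_numpy()),
        standardization=std,
        intersection_fallback=inter.fallback,
    )
    out = merged.copy()
    out["sa_label"] = [
        label_sa(rt, thresholds, score)
        for rt, score in zip(out["rt_s"], out["mars_sa_score"])
    ]
    out["fatigue_label"] = [dichotomize_fatigue(int(k)) for k in out["kss"]]
    out["stress_label"] = [dichotomize_stress(int(s)) for s in out["sati6"]]
    out["rt_threshold_s"] = rt_thr_s
    table = ContingencyTable.from_labels(out)
    return out, thresholds, table
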