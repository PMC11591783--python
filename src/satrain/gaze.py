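"""Eye-tracking pipeline: gap interpolation, median filtering, I-VT
fixation/saccade classification, AOI dwell analysis and fixation heatmaps.

Gaze is represented directly as angular position (degrees) on a uniform
15 Hz grid, with a per-sample validity flag.  A stream is a DataFrame
with columns ``t``, ``x_deg``, ``y_deg``, ``valid``.

Classification follows the velocity-threshold (I-VT) rule: point-to-point
angular velocity above 30 deg/s marks a saccade sample, at or below marks
a fixation sample.  Maximal runs of fixation samples are aggregated into
fixation events, assigned to areas of interest (AOIs: the external View
Scene, the MMI driver display, the DMI signalling display), and pooled
into duration-weighted density heatmaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "AOI_NAMES",
    "DEFAULT_AOI_LAYOUT",
    "FixationEvent",
    "make_stream",
    "interpolate_gaps",
    "median_filter",
    "angular_velocity",
    "ivt_classify",
    "aggregate_fixations",
    "assign_aoi",
    "dwell_shares",
    "fixation_heatmap",
]

AOI_NAMES = ("View Scene", "MMI", "DMI")

#: Axis-aligned AOI rectangles (x_min, x_max, y_min, y_max) in degrees of
#: visual angle.  View Scene spans the upper field; the DMI signalling
#: display sits lower-left, the MMI driver display lower-right.  Rectangle
#: membership uses the half-open convention [min, max).
DEFAULT_AOI_LAYOUT: dict[str, tuple[float, float, float, float]] = {
    "View Scene": (-24.0, 24.0, 0.0, 13.5),
    "DMI": (-24.0, 0.0, -13.5, 0.0),
    "MMI": (0.0, 24.0, -13.5, 0.0),
}


def make_stream(t, x_deg, y_deg, valid=None) -> pd.DataFrame:
    t = np.asarray(t, dtype=float)
    if t.size >= 2:
        dt = np.diff(t)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise DataError("gaze timestamps must be strictly increasing on a uniform grid")
    if valid is None:
        valid = np.isfinite(np.asarray(x_deg, float)) & np.isfinite(np.asarray(y_deg, float))
    return pd.DataFrame({
        "t": t,
        "x_deg": np.asarray(x_deg, dtype=float),
        "y_deg": np.asarray(y_deg, dtype=float),
        "valid": np.asarray(valid, dtype=bool),
    })


def _invalid_runs(valid: np.ndarray):
    """Yield (start, stop) index pairs of maximal invalid runs (stop exclusive)."""
    n = valid.size
    i = 0
    while i < n:
        if not valid[i]:
            j = i
            while j < n and not valid[j]:
                j += 1
            yield i, j
            i = j
        else:
            i += 1


def interpolate_gaps(stream: pd.DataFrame, max_gap_ms: float = 75.0) -> pd.DataFrame:
    """Linearly fill invalid runs no longer than ``max_gap_ms``.

    A run is fillable only when bounded by valid samples on both sides
    (leading/trailing gaps stay missing).  Gap duration is measured as
    the time span covered by the missing samples themselves, i.e.
    ``run_length / rate``.  Valid samples are never altered.
    """
    out = stream.copy()
    t = out["t"].to_numpy()
    valid = out["valid"].to_numpy().copy()
    if valid.all() or t.size < 3:
        return out
    dt = t[1] - t[0]
    x = out["x_deg"].to_numpy().copy()
    y = out["y_deg"].to_numpy().copy()
    for start, stop in list(_invalid_runs(valid)):
        if start == 0 or stop == t.size:
            continue
        gap_ms = (stop - start) * dt * 1000.0
        if gap_ms > max_gap_ms:
            continue
        t0, t1 = t[start - 1], t[stop]
        frac = (t[start:stop] - t0) / (t1 - t0)
        x[start:stop] = x[start - 1] + frac * (x[stop] - x[start - 1])
        y[start:stop] = y[start - 1] + frac * (y[stop] - y[start - 1])
        valid[start:stop] = True
    out["x_deg"], out["y_deg"], out["valid"] = x, y, valid
    return out


def median_filter(stream: pd.DataFrame, window: int = 3) -> pd.DataFrame:
    """Sliding median over valid samples, per coordinate.

    The window is centred and clipped at the stream edges (shrunken
    windows; an even count medians as the mean of the central pair).
    Invalid samples pass through untouched and do not enter any window.
    """
    if window % 2 == 0 or window < 1:
        raise DataError("median filter window must be odd and >= 1")
    out = stream.copy()
    valid = out["valid"].to_numpy()
    half = window // 2
    for col in ("x_deg", "y_deg"):
        v = out[col].to_numpy().copy()
        src = out[col].to_numpy()
        idx = np.flatnonzero(valid)
        # filter each maximal run of valid samples independently
        if idx.size:
            splits = np.flatnonzero(np.diff(idx) > 1) + 1
            for run in np.split(idx, splits):
                vals = src[run]
                for k in range(run.size):
                    lo, hi = max(0, k - half), min(run.size, k + half + 1)
                    v[run[k]] = np.median(vals[lo:hi])
        out[col] = v
    return out


def angular_velocity(stream: pd.DataFrame) -> np.ndarray:
    """Point-to-point angular speed in deg/s (two-point backward difference).

    The first sample, invalid samples, and the first valid sample after a
    gap have undefined velocity (NaN) and are excluded from I-VT
    classification.
    """
    t = stream["t"].to_numpy()
    x = stream["x_deg"].to_numpy()
    y = stream["y_deg"].to_numpy()
    valid = stream["valid"].to_numpy()
    v = np.full(t.size, np.nan)
    if t.size < 2:
        return v
    ok = valid[1:] & valid[:-1]
    dt = np.diff(t)
    dist = np.hypot(np.diff(x), np.diff(y))
    v[1:][ok] = dist[ok] / dt[ok]
    return v


def ivt_classify(velocities: np.ndarray, threshold_deg_s: float = 30.0) -> np.ndarray:
    """Label each sample 'saccade' (v > threshold, strict), 'fixation'
    (v <= threshold) or 'undefined' (velocity NaN)."""
    v = np.asarray(velocities, dtype=float)
    labels = np.full(v.size, "undefined", dtype=object)
    defined = np.isfinite(v)
    labels[defined & (v > threshold_deg_s)] = "saccade"
    labels[defined & (v <= threshold_deg_s)] = "fixation"
    return labels


@dataclass(frozen=True)
class FixationEvent:
    t_start_s: float
    t_end_s: float
    duration_s: float
    centroid: tuple[float, float]
    n_samples: int
    aoi: str = "none"


def aggregate_fixations(stream: pd.DataFrame, labels: np.ndarray,
                        min_duration_ms: float = 60.0) -> list[FixationEvent]:
    """Collapse maximal runs of fixation samples into events.

    Event duration is the time span between first and last member sample;
    runs shorter than ``min_duration_ms`` are dropped; the centroid is the
    mean member position.
    """
    labels = np.asarray(labels, dtype=object)
    if labels.size != len(stream):
        raise DataError("labels must align with the stream")
    t = stream["t"].to_numpy()
    x = stream["x_deg"].to_numpy()
    y = stream["y_deg"].to_numpy()
    events: list[FixationEvent] = []
    is_fix = labels == "fixation"
    i = 0
    n = labels.size
    while i < n:
        if is_fix[i]:
            j = i
            while j < n and is_fix[j]:
                j += 1
            dur = t[j - 1] - t[i]
            if dur * 1000.0 >= min_duration_ms and dur > 0:
                events.append(FixationEvent(
                    t_start_s=float(t[i]), t_end_s=float(t[j - 1]),
                    duration_s=float(dur),
                    centroid=(float(x[i:j].mean()), float(y[i:j].mean())),
                    n_samples=int(j - i)))
            i = j
        else:
            i += 1
    return events


def _check_layout(layout: Mapping[str, tuple[float, float, float, float]]) -> None:
    rects = list(layout.items())
    for i in range(len(rects)):
        for j in range(i + 1, len(rects)):
            (_, a), (_, b) = rects[i], rects[j]
            if (a[0] < b[1] and b[0] < a[1]) and (a[2] < b[3] and b[2] < a[3]):
                raise DataError(
                    f"AOI rectangles {rects[i][0]!r} and {rects[j][0]!r} overlap")


def assign_aoi(fixations: Sequence[FixationEvent],
               aoi_layout: Mapping[str, tuple[float, float, float, float]] | None = None
               ) -> list[FixationEvent]:
    """Assign each fixation to the AOI containing its centroid.

    Membership is half-open ([x_min, x_max) x [y_min, y_max)) so shared
    boundaries are unambiguous; centroids outside every rectangle get
    ``aoi='none'``.
    """
    layout = DEFAULT_AOI_LAYOUT if aoi_layout is None else dict(aoi_layout)
    _check_layout(layout)
    out = []
    for f in fixations:
        cx, cy = f.centroid
        name = "none"
        for aoi, (x0, x1, y0, y1) in layout.items():
            if x0 <= cx < x1 and y0 <= cy < y1:
                name = aoi
                break
        out.append(FixationEvent(f.t_start_s, f.t_end_s, f.duration_s,
                                 f.centroid, f.n_samples, name))
    return out


def dwell_shares(fixations: Sequence[FixationEvent],
                 aoi_names: Sequence[str] = AOI_NAMES) -> dict[str, float]:
    """Share of total fixation time per AOI (plus 'none'); shares sum to 1."""
    total = sum(f.duration_s for f in fixations)
    shares = {name: 0.0 for name in list(aoi_names) + ["none"]}
    if total == 0:
        return shares
    for f in fixations:
        shares[f.aoi if f.aoi in shares else "none"] += f.duration_s
    return {k: v / total for k, v in shares.items()}


def fixation_heatmap(fixations: Sequence[FixationEvent],
                     grid_shape: tuple[int, int] = (54, 96),
                     bandwidth_deg: float = 1.5,
                     extent: tuple[float, float, float, float] = (-24.0, 24.0, -13.5, 13.5)
                     ) -> np.ndarray:
    """Duration-weighted Gaussian fixation-density map.

    Each fixation spreads its duration over the grid with an isotropic
    Gaussian kernel centred on its centroid; kernels truncated by the
    grid edge are renormalised so the grid total equals the total
    fixation duration (mass conservation).  ``grid_shape`` is (rows=y,
    cols=x); returns an array in seconds per cell.
    """
    ny, nx = grid_shape
    if ny < 2 or nx < 2:
        raise DataError("heatmap grid must be at least 2x2")
    x0, x1, y0, y1 = extent
    xc = np.linspace(x0, x1, nx + 1)[:-1] + (x1 - x0) / (2 * nx)
    yc = np.linspace(y0, y1, ny + 1)[:-1] + (y1 - y0) / (2 * ny)
    grid = np.zeros((ny, nx))
    for f in fixations:
        cx, cy = f.centroid
        kx = np.exp(-0.5 * ((xc - cx) / bandwidth_deg) ** 2)
        ky = np.exp(-0.5 * ((yc - cy) / bandwidth_deg) ** 2)
        kernel = np.outer(ky, kx)
        s = kernel.sum()
        if s > 0:
            grid += f.duration_s * kernel / s
    return grid
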