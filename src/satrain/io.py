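"""File formats: design/scores CSV dialects, raw-signal binary+sidecar
pairs, JSON reports, and the packaged reference contingency table.

All tabular files are UTF-8 RFC-4180 CSV.  Lines starting with ``#`` are
provenance headers and are skipped on read.  Raw signals are stored as
little-endian float32 arrays (``<name>.bin``) with a JSON sidecar
(``<name>.json``) recording rate, shape, channel names and units.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .stats import ContingencyTable

__all__ = [
    "DESIGN_COLUMNS",
    "SCORE_COLUMNS",
    "read_design",
    "write_design",
    "read_scores",
    "write_scores",
    "write_signal",
    "read_signal",
    "write_json",
    "load_table1",
    "config_hash",
]

DESIGN_COLUMNS = ("subject_id", "condition", "block", "trial", "event_type",
                  "true_sa_state", "t_event_s", "rt_s", "t_response_s",
                  "segment_duration_s")
SCORE_COLUMNS = ("subject_id", "condition", "block", "kss", "sati6",
                 "mars_sa_score")


def config_hash(config_dict: dict) -> str:
    """Short stable hash of a config mapping, for provenance headers."""
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _read_csv(path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"file not found: {path}")
    df = pd.read_csv(path, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required column(s) {missing}")
    return df


def _write_csv(path, df: pd.DataFrame, header_comment: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def read_design(path) -> pd.DataFrame:
    """Read a trial table; validates the required columns and dtypes."""
    df = _read_csv(path, ("subject_id", "condition", "block", "trial", "rt_s"))
    if (df["rt_s"] <= 0).any():
        bad = int(df.index[df["rt_s"] <= 0][0]) + 2  # 1-based + header line
        raise DataError(f"{path}: non-positive rt_s near line {bad}")
    return df


def write_design(path, trials: pd.DataFrame, provenance: str | None = None) -> None:
    cols = [c for c in DESIGN_COLUMNS if c in trials.columns]
    cols += [c for c in trials.columns if c not in cols]
    _write_csv(path, trials[cols], provenance)


def read_scores(path) -> pd.DataFrame:
    df = _read_csv(path, SCORE_COLUMNS)
    if ((df["kss"] < 1) | (df["kss"] > 9)).any():
        raise DataError(f"{path}: KSS out of range [1, 9]")
    if ((df["sati6"] < 6) | (df["sati6"] > 24)).any():
        raise DataError(f"{path}: SATI-6 out of range [6, 24]")
    return df


def write_scores(path, scores: pd.DataFrame, provenance: str | None = None) -> None:
    cols = [c for c in SCORE_COLUMNS if c in scores.columns]
    cols += [c for c in scores.columns if c not in cols]
    _write_csv(path, scores[cols], provenance)


def write_signal(stem, data: np.ndarray, rate_hz: float,
                 channels: list[str], units: str) -> None:
    """Write ``<stem>.bin`` (float32, C order) + ``<stem>.json`` sidecar."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(data, dtype="<f4")
    arr.tofile(stem.with_suffix(".bin"))
    sidecar = {"rate_hz": rate_hz, "shape": list(arr.shape),
               "channels": channels, "units": units, "dtype": "<f4"}
    write_json(stem.with_suffix(".json"), sidecar)


def read_signal(stem) -> tuple[np.ndarray, dict]:
    stem = Path(stem)
    meta_path = stem.with_suffix(".json")
    bin_path = stem.with_suffix(".bin")
    if not meta_path.exists() or not bin_path.exists():
        raise DataError(f"signal files not found for stem {stem}")
    meta = json.loads(meta_path.read_text())
    arr = np.fromfile(bin_path, dtype=meta.get("dtype", "<f4"))
    arr = arr.reshape(meta["shape"]).astype(float)
    return arr, meta


def write_json(path, obj) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, default=str) + "\n")


def load_table1() -> ContingencyTable:
    """The packaged reference SA x condition contingency table.

    Low/high SA sample counts per condition as reported by the study this
    pipeline reproduces; used for replay-mode validation with zero
    generation time.
    """
    with resources.files("satrain").joinpath("data/table1.csv").open() as fh:
        df = pd.read_csv(fh)
    return ContingencyTable(tuple(df["condition"]),
                            tuple(int(v) for v in df["low_sa"]),
                            tuple(int(v) for v in df["high_sa"]))
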