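"""EEG pipeline: bad-channel handling, common-average reference, 1-30 Hz
band-pass, 1-s epoching and band-power features.

A trial segment is 32 channels (standard 10-20 montage) at 256 Hz in
microvolts.  Preprocessing order is fixed: detect/interpolate bad
channels (spherical splines, via mne) -> common average reference ->
zero-phase 1-30 Hz band-pass.  The segment is then cut into
non-overlapping 1-s epochs; per epoch and channel a Hann-windowed
periodogram (1 Hz resolution) is integrated over theta (4-8 Hz), alpha
(8-13 Hz) and beta (13-30 Hz), and epochs are averaged — yielding
32 x 3 = 96 band-power features per segment (integrated power, uV^2).

Band-edge ownership: the lower edge of each band is inclusive and the
upper edge exclusive, except the top of beta (30 Hz) which is inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sig

from .errors import DataError, QualityError

__all__ = [
    "CHANNELS_32",
    "BANDS",
    "REGIONS",
    "EegSegment",
    "BandPowerMap",
    "detect_bad_channels",
    "interpolate_channels",
    "car_reference",
    "bandpass_eeg",
    "epoch_1s",
    "psd_band_power",
    "region_average",
    "preprocess_segment",
    "extract_band_powers",
]

#: Standard 32-electrode 10-20 montage channel names.
CHANNELS_32 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2",
    "AF3", "AF4", "PO3", "PO4",
)

#: Frequency bands in Hz; [lower inclusive, upper exclusive) except beta's
#: upper edge which is inclusive.
BANDS = {"theta": (4.0, 8.0), "alpha": (8.0, 13.0), "beta": (13.0, 30.0)}

#: Electrode groupings for regional summaries.
REGIONS = {
    "frontal": ("Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz"),
    "parietal": ("P3", "P4", "P7", "P8", "Pz"),
    "occipital": ("O1", "O2"),
    "central_temporal": ("FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4",
                         "T8", "CP5", "CP1", "CP2", "CP6", "AF3", "AF4",
                         "PO3", "PO4", "Oz"),
}


@dataclass(frozen=True)
class EegSegment:
    """One trial's EEG: ``data`` is channels x samples in microvolts."""

    data: np.ndarray
    sfreq: float = 256.0
    ch_names: tuple[str, ...] = CHANNELS_32
    bad_channels: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 2 or data.shape[0] != len(self.ch_names):
            raise DataError(
                f"data must be {len(self.ch_names)} channels x samples")
        if len(set(self.ch_names)) != len(self.ch_names):
            raise DataError("channel names must be unique")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class BandPowerMap:
    """Per-channel, per-band integrated power (uV^2) for one segment."""

    power: pd.DataFrame  # index: channels, columns: bands
    n_epochs: int

    def to_vector(self) -> pd.Series:
        """Flatten to 96 named features '<channel>_<band>'."""
        out = {}
        for ch in self.power.index:
            for band in self.power.columns:
                out[f"{ch}_{band}"] = float(self.power.loc[ch, band])
        return pd.Series(out)


def detect_bad_channels(segment: EegSegment, variance_z: float = 4.0,
                        flat_tol_uv: float = 0.1) -> frozenset[str]:
    """Flag channels with outlying log-variance or flat-line signals.

    Log-variance z-scores are robust (median/MAD across channels); a
    channel is bad when |z| exceeds ``variance_z`` upward or its
    peak-to-peak amplitude falls below ``flat_tol_uv``.  More than 25%
    bad channels rejects the whole segment.
    """
    if len(segment.ch_names) < 4:
        raise DataError("bad-channel detection needs at least 4 channels")
    data = segment.data
    ptp = np.ptp(data, axis=1)
    flat = ptp < flat_tol_uv
    logvar = np.log(np.maximum(np.var(data, axis=1), 1e-300))
    med = np.median(logvar[~flat]) if (~flat).any() else 0.0
    mad = np.median(np.abs(logvar[~flat] - med)) if (~flat).any() else 0.0
    scale = mad * 1.4826 if mad > 0 else np.inf
    z = (logvar - med) / scale
    bad = flat | (z > variance_z)
    names = frozenset(np.asarray(segment.ch_names)[bad])
    if len(names) > 0.25 * len(segment.ch_names):
        raise QualityError(
            f"{len(names)} of {len(segment.ch_names)} channels bad; segment rejected")
    return names


def _montage_positions(ch_names) -> dict[str, np.ndarray]:
    import mne
    montage = mne.channels.make_standard_montage("standard_1020")
    pos = montage.get_positions()["ch_pos"]
    return {ch: pos[ch] for ch in ch_names}


def interpolate_channels(segment: EegSegment,
                         bad: frozenset[str] | set[str] | None = None) -> EegSegment:
    """Reconstruct bad channels by spherical-spline interpolation.

    Uses the standard 10-20 montage positions and mne's spherical-spline
    implementation (Perrin-style, order-4 Legendre expansion).  Good
    channels are untouched; the returned segment has an empty bad set.
    """
    bad = segment.bad_channels if bad is None else frozenset(bad)
    if not bad:
        return replace(segment, bad_channels=frozenset())
    unknown = bad - set(segment.ch_names)
    if unknown:
        raise DataError(f"unknown bad channels: {sorted(unknown)}")
    n_good = len(segment.ch_names) - len(bad)
    if n_good < 4:
        raise DataError("need at least 4 good channels to interpolate")
    import mne
    info = mne.create_info(list(segment.ch_names), segment.sfreq, ch_types="eeg")
    raw = mne.io.RawArray(segment.data * 1e-6, info, verbose="error")
    raw.set_montage(mne.channels.make_standard_montage("standard_1020"),
                    verbose="error")
    raw.info["bads"] = sorted(bad)
    raw.interpolate_bads(reset_bads=True, verbose="error")
    return EegSegment(raw.get_data() * 1e6, segment.sfreq, segment.ch_names,
                      frozenset())


def car_reference(segment: EegSegment) -> EegSegment:
    """Common average reference: subtract the per-sample channel mean."""
    data = segment.data - segment.data.mean(axis=0, keepdims=True)
    return replace(segment, data=data)


def bandpass_eeg(segment: EegSegment, low: float = 1.0, high: float = 30.0) -> EegSegment:
    """Zero-phase Butterworth band-pass, per channel."""
    if not 0 < low < high < segment.sfreq / 2:
        raise DataError("band edges must satisfy 0 < low < high < Nyquist")
    sos = sig.butter(4, [low, high], btype="bandpass", fs=segment.sfreq,
                     output="sos")
    padlen = int(min(segment.n_samples - 1,
                     max(3 * (2 * sos.shape[0] + 1), 0.5 * segment.sfreq / low)))
    return replace(segment, data=sig.sosfiltfilt(sos, segment.data, axis=1,
                                                 padlen=padlen))


def epoch_1s(segment: EegSegment) -> np.ndarray:
    """Cut into non-overlapping 1-s epochs; trailing remainder dropped.

    Returns an array of shape (n_epochs, n_channels, samples_per_epoch).
    """
    spe = int(round(segment.sfreq))
    n_epochs = segment.n_samples // spe
    if n_epochs < 1:
        raise DataError("segment shorter than one 1-s epoch")
    trimmed = segment.data[:, : n_epochs * spe]
    return trimmed.reshape(segment.data.shape[0], n_epochs, spe).transpose(1, 0, 2)


def psd_band_power(epochs: np.ndarray, sfreq: float = 256.0,
                   ch_names: tuple[str, ...] = CHANNELS_32) -> BandPowerMap:
    """Average per-epoch Hann periodogram band powers.

    For each epoch and channel a Hann-windowed periodogram at 1 Hz
    resolution is integrated over each band, then averaged across
    epochs.  Output is the channels x bands map (96 features for the
    default montage).
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim != 3 or epochs.shape[0] < 1:
        raise DataError("epochs must be (n_epochs, n_channels, n_samples) with >= 1 epoch")
    freqs, psd = sig.periodogram(epochs, fs=sfreq, window="hann", axis=-1)
    df = freqs[1] - freqs[0]
    cols = {}
    for band, (lo, hi) in BANDS.items():
        mask = (freqs >= lo) & ((freqs < hi) | ((band == "beta") & (freqs == hi)))
        cols[band] = (psd[..., mask].sum(axis=-1) * df).mean(axis=0)
    power = pd.DataFrame(cols, index=list(ch_names))
    return BandPowerMap(power=power, n_epochs=epochs.shape[0])


def region_average(band_map: BandPowerMap,
                   regions: dict[str, tuple[str, ...]] | None = None) -> pd.DataFrame:
    """Mean channel power per region and band (rows: regions)."""
    regions = REGIONS if regions is None else regions
    rows = {}
    for name, chans in regions.items():
        unknown = set(chans) - set(band_map.power.index)
        if unknown:
            raise DataError(f"region {name!r} references unknown channels: "
                            f"{sorted(unknown)}")
        rows[name] = band_map.power.loc[list(chans)].mean(axis=0)
    return pd.DataFrame(rows).T


def preprocess_segment(segment: EegSegment, detect_bads: bool = True) -> EegSegment:
    """Fixed preprocessing chain: bads -> interpolate -> CAR -> 1-30 Hz."""
    if detect_bads:
        bads = detect_bad_channels(segment)
        if bads:
            segment = interpolate_channels(segment, bads)
    segment = car_reference(segment)
    return bandpass_eeg(segment)


def extract_band_powers(segment: EegSegment, detect_bads: bool = True) -> BandPowerMap:
    """Full EEG chain for one trial: preprocess, epoch, band powers."""
    clean = preprocess_segment(segment, detect_bads=detect_bads)
    return psd_band_power(epoch_1s(clean), sfreq=clean.sfreq, ch_names=clean.ch_names)
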