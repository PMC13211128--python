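"""Signal conditioning: linear detrend, per-recording z-score, epoch
segmentation and multirate harmonization.

The pipeline applies, in order: detrend -> z-score -> segment -> harmonize.
No filtering or epoch exclusion is performed anywhere in this module.
"""

from __future__ import annotations

import warnings
from fractions import Fraction

import numpy as np
from scipy.signal import resample_poly

from .containers import EpochDataset, Recording
from .profiles import DatasetProfile, get_profile

__all__ = [
    "detrend_linear",
    "zscore_recording",
    "segment_epochs",
    "harmonize_rates",
    "preprocess_recording",
]


def detrend_linear(channel_signal: np.ndarray) -> np.ndarray:
    """Remove the least-squares first-order (linear) trend from a 1-D signal."""
    x = np.asarray(channel_signal, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("detrend_linear expects a 1-D array")
    if x.size < 2:
        raise ValueError("need at least two samples to fit a line")
    t = np.arange(x.size, dtype=np.float64)
    # centered design keeps the normal equations well conditioned
    tc = t - t.mean()
    slope = (tc @ x) / (tc @ tc)
    intercept = x.mean()
    return x - (slope * tc + intercept)


def zscore_recording(recording: Recording) -> Recording:
    """Standardize each channel over the *whole* recording (mean 0, std 1)."""
    out = recording.copy()
    for mod, sig in out.signals.items():
        mu = sig.mean(axis=1, keepdims=True)
        sd = sig.std(axis=1, keepdims=True)
        zero_var = sd[:, 0] == 0
        if zero_var.any():
            warnings.warn(
                f"{mod}: zero-variance channel(s) {np.where(zero_var)[0].tolist()} "
                "passed through as zeros", RuntimeWarning)
            sd[zero_var] = 1.0
        out.signals[mod] = (sig - mu) / sd
    out.preprocessing_flags = list(recording.preprocessing_flags) + ["zscore"]
    return out


def _detrend_recording(recording: Recording) -> Recording:
    out = recording.copy()
    for mod, sig in out.signals.items():
        out.signals[mod] = np.stack([detrend_linear(ch) for ch in sig])
    out.preprocessing_flags = list(recording.preprocessing_flags) + ["detrend"]
    return out


def segment_epochs(recording: Recording, epoch_s: float = 30.0,
                   profile: DatasetProfile | None = None) -> EpochDataset:
    """Cut a recording into contiguous non-overlapping whole epochs.

    The trailing partial epoch is dropped; both modalities are truncated to
    the same epoch count.
    """
    counts, samples = {}, {}
    for mod, sig in recording.signals.items():
        fs = recording.fs[mod]
        n = epoch_s * fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError(f"epoch_s={epoch_s} at fs={fs} is not an integer sample count")
        samples[mod] = int(round(n))
        counts[mod] = sig.shape[1] // samples[mod]
    n_epochs = min(counts.values())
    if n_epochs == 0:
        warnings.warn("recording shorter than one epoch; empty dataset", RuntimeWarning)

    def cut(mod):
        sig = recording.signals[mod]
        L = samples[mod]
        used = sig[:, :n_epochs * L]
        return used.reshape(sig.shape[0], n_epochs, L).transpose(1, 0, 2)

    if profile is None:
        eeg = recording.signals["eeg"]
        profile = get_profile(
            "custom", eeg_channels=eeg.shape[0],
            eog_channels=recording.signals.get("eog", np.empty((0, 0))).shape[0],
            fs_eeg=recording.fs["eeg"],
            fs_eog=recording.fs.get("eog", recording.fs["eeg"]),
            epoch_s=epoch_s)
    return EpochDataset(
        eeg=cut("eeg") if n_epochs else np.empty((0, recording.signals["eeg"].shape[0], samples["eeg"])),
        eog=(cut("eog") if n_epochs else np.empty((0, recording.signals["eog"].shape[0], samples["eog"])))
        if "eog" in recording.signals else None,
        labels=None,
        subject_ids=np.full(n_epochs, recording.subject_id, dtype=np.int64),
        profile=profile,
        fs_eeg=recording.fs["eeg"],
        fs_eog=recording.fs.get("eog", recording.fs["eeg"]),
        preprocessing_flags=list(recording.preprocessing_flags) + ["segment"],
    )


def _resample_epochs(arr: np.ndarray, fs_from: float, fs_to: float) -> np.ndarray:
    if fs_from == fs_to:
        return arr
    frac = Fraction(fs_to / fs_from).limit_denominator(1000)
    if abs(float(frac) - fs_to / fs_from) > 1e-9:
        raise ValueError(f"non-rational rate ratio {fs_to}/{fs_from}")
    return resample_poly(arr, frac.numerator, frac.denominator, axis=-1)


def harmonize_rates(dataset: EpochDataset, target_fs: float | None = None) -> EpochDataset:
    """Polyphase-resample both modalities to a common rate (default: max)."""
    if target_fs is None:
        target_fs = max(dataset.fs_eeg, dataset.fs_eog)
    eeg = _resample_epochs(dataset.eeg, dataset.fs_eeg, target_fs)
    eog = None if dataset.eog is None else _resample_epochs(dataset.eog, dataset.fs_eog, target_fs)
    flags = list(dataset.preprocessing_flags)
    if dataset.fs_eeg != target_fs or dataset.fs_eog != target_fs:
        flags = flags + ["harmonize"]
    return EpochDataset(
        eeg=eeg, eog=eog, labels=dataset.labels, subject_ids=dataset.subject_ids,
        profile=dataset.profile, fs_eeg=target_fs, fs_eog=target_fs,
        preprocessing_flags=flags,
    )


def preprocess_recording(recording: Recording, epoch_s: float = 30.0,
                         profile: DatasetProfile | None = None,
                         target_fs: float | None = None) -> EpochDataset:
    """Full pipeline: detrend -> z-score -> segment -> harmonize."""
    rec = _detrend_recording(recording)
    rec = zscore_recording(rec)
    ds = segment_epochs(rec, epoch_s=epoch_s, profile=profile)
    return harmonize_rates(ds, target_fs=target_fs)
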