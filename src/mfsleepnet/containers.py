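"""In-memory data containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .profiles import N_STAGES, DatasetProfile


@dataclass
class Recording:
    """A continuous multichannel recording for one subject, in microvolts.

    ``signals`` maps modality name ('eeg', 'eog') to a (channels, samples)
    array; ``fs`` maps modality name to its sampling rate in Hz.
    """

    signals: dict
    fs: dict
    subject_id: int = 0
    units: str = "uV"
    preprocessing_flags: list = field(default_factory=list)

    def __post_init__(self):
        for mod, sig in self.signals.items():
            sig = np.asarray(sig, dtype=np.float64)
            if sig.ndim != 2:
                raise ValueError(f"{mod} signal must be (channels, samples)")
            self.signals[mod] = sig
            if mod not in self.fs or self.fs[mod] <= 0:
                raise ValueError(f"missing or invalid sampling rate for {mod}")

    def copy(self) -> "Recording":
        return Recording(
            signals={m: s.copy() for m, s in self.signals.items()},
            fs=dict(self.fs),
            subject_id=self.subject_id,
            units=self.units,
            preprocessing_flags=list(self.preprocessing_flags),
        )


@dataclass
class EpochDataset:
    """Stacked 30-s epochs: eeg (N, C_eeg, L_eeg), eog (N, C_eog, L_eog)."""

    eeg: np.ndarray
    eog: np.ndarray | None
    labels: np.ndarray | None
    subject_ids: np.ndarray
    profile: DatasetProfile
    fs_eeg: float
    fs_eog: float
    preprocessing_flags: list = field(default_factory=list)

    def __post_init__(self):
        self.eeg = np.asarray(self.eeg, dtype=np.float64)
        n = self.eeg.shape[0]
        if self.eog is not None:
            self.eog = np.asarray(self.eog, dtype=np.float64)
            if self.eog.shape[0] != n:
                raise ValueError("eeg/eog epoch counts differ")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (n,):
                raise ValueError("labels shape mismatch")
            if n and (self.labels.min() < 0 or self.labels.max() >= N_STAGES):
                raise ValueError("labels out of range 0..4")
        self.subject_ids = np.asarray(self.subject_ids, dtype=np.int64)
        if self.subject_ids.shape != (n,):
            raise ValueError("subject_ids shape mismatch")

    def __len__(self):
        return self.eeg.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.eeg.shape[0]

    def select(self, idx) -> "EpochDataset":
        idx = np.asarray(idx)
        return EpochDataset(
            eeg=self.eeg[idx],
            eog=None if self.eog is None else self.eog[idx],
            labels=None if self.labels is None else self.labels[idx],
            subject_ids=self.subject_ids[idx],
            profile=self.profile,
            fs_eeg=self.fs_eeg,
            fs_eog=self.fs_eog,
            preprocessing_flags=list(self.preprocessing_flags),
        )

    def subjects(self):
        return np.unique(self.subject_ids)


def concatenate_datasets(parts) -> EpochDataset:
    parts = list(parts)
    if not parts:
        raise ValueError("no datasets to concatenate")
    first = parts[0]
    has_eog = first.eog is not None
    has_labels = first.labels is not None
    return EpochDataset(
        eeg=np.concatenate([p.eeg for p in parts]),
        eog=np.concatenate([p.eog for p in parts]) if has_eog else None,
        labels=np.concatenate([p.labels for p in parts]) if has_labels else None,
        subject_ids=np.concatenate([p.subject_ids for p in parts]),
        profile=first.profile,
        fs_eeg=first.fs_eeg,
        fs_eog=first.fs_eog,
        preprocessing_flags=list(first.preprocessing_flags),
    )
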