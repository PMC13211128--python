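"""Dataset container (HDF5 first, NPZ fallback) and best-effort EDF ingestion.

Container schema (version 1): groups/arrays ``eeg`` (N, C, L), ``eog``
(N, C, L, optional), ``labels`` (N,), ``subject_ids`` (N,); attributes
carry the profile fields, per-modality sampling rates, preprocessing flags
and ``schema_version``.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .containers import EpochDataset, Recording
from .profiles import DatasetProfile, get_profile

__all__ = [
    "SCHEMA_VERSION",
    "write_container",
    "read_container",
    "ingest_edf",
    "write_edf",
    "map_hypnogram_codes",
]

SCHEMA_VERSION = 1


def _profile_attrs(profile: DatasetProfile) -> dict:
    return {
        "profile_name": profile.name,
        "eeg_channels": profile.eeg_channels,
        "eog_channels": profile.eog_channels,
        "profile_fs_eeg": profile.fs_eeg,
        "profile_fs_eog": profile.fs_eog,
        "epoch_s": profile.epoch_s,
    }


def write_container(dataset: EpochDataset, path) -> None:
    path = Path(path)
    attrs = {
        "schema_version": SCHEMA_VERSION,
        "fs_eeg": dataset.fs_eeg,
        "fs_eog": dataset.fs_eog,
        "preprocessing_flags": list(dataset.preprocessing_flags),
        **_profile_attrs(dataset.profile),
    }
    if path.suffix == ".npz":
        arrays = {"eeg": dataset.eeg, "subject_ids": dataset.subject_ids}
        if dataset.eog is not None:
            arrays["eog"] = dataset.eog
        if dataset.labels is not None:
            arrays["labels"] = dataset.labels
        attrs["preprocessing_flags"] = "|".join(attrs["preprocessing_flags"])
        np.savez(path, **arrays, **{f"attr_{k}": np.array(v) for k, v in attrs.items()})
        return
    with h5py.File(path, "w") as f:
        f.create_dataset("eeg", data=dataset.eeg)
        if dataset.eog is not None:
            f.create_dataset("eog", data=dataset.eog)
        if dataset.labels is not None:
            f.create_dataset("labels", data=dataset.labels)
        f.create_dataset("subject_ids", data=dataset.subject_ids)
        for k, v in attrs.items():
            f.attrs[k] = v


def _rebuild(eeg, eog, labels, subject_ids, attrs) -> EpochDataset:
    if int(attrs["schema_version"]) != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported container schema_version={attrs['schema_version']}; "
            f"this reader supports version {SCHEMA_VERSION}")
    name = str(attrs["profile_name"])
    if name == "custom":
        profile = get_profile(
            "custom",
            eeg_channels=int(attrs["eeg_channels"]),
            eog_channels=int(attrs["eog_channels"]),
            fs_eeg=float(attrs["profile_fs_eeg"]),
            fs_eog=float(attrs["profile_fs_eog"]),
            epoch_s=float(attrs["epoch_s"]))
    else:
        profile = get_profile(name)
    flags = attrs["preprocessing_flags"]
    if isinstance(flags, (str, np.str_)):
        flags = [f for f in str(flags).split("|") if f]
    return EpochDataset(
        eeg=eeg, eog=eog, labels=labels, subject_ids=subject_ids,
        profile=profile, fs_eeg=float(attrs["fs_eeg"]),
        fs_eog=float(attrs["fs_eog"]), preprocessing_flags=list(flags))


def read_container(path) -> EpochDataset:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as data:
            attrs = {k[len("attr_"):]: data[k][()] for k in data.files
                     if k.startswith("attr_")}
            return _rebuild(
                data["eeg"],
                data["eog"] if "eog" in data.files else None,
                data["labels"] if "labels" in data.files else None,
                data["subject_ids"], attrs)
    with h5py.File(path, "r") as f:
        if "schema_version" not in f.attrs:
            raise ValueError("not a recognized container: missing schema_version")
        return _rebuild(
            f["eeg"][()],
            f["eog"][()] if "eog" in f else None,
            f["labels"][()] if "labels" in f else None,
            f["subject_ids"][()], dict(f.attrs))


# ---------------------------------------------------------------------------
# minimal EDF reader/writer (16-bit integer format, best-effort)
# ---------------------------------------------------------------------------

def write_edf(path, signals: dict, fs: dict, record_s: float = 1.0) -> None:
    """Write a minimal uncalibrated-free EDF file from µV signals.

    Channels are stored as 16-bit integers with per-channel physical
    min/max covering the data range. Intended for fixtures and round-trip
    testing, not clinical archiving.
    """
    labels, chans, rates = [], [], []
    for mod, sig in signals.items():
        for c in range(sig.shape[0]):
            labels.append(f"{mod.upper()} ch{c}")
            chans.append(np.asarray(sig[c], dtype=np.float64))
            rates.append(fs[mod])
    n_sig = len(chans)
    samples_per_record = [int(round(r * record_s)) for r in rates]
    n_records = min(len(ch) // spr for ch, spr in zip(chans, samples_per_record))
    phys_min = [min(ch.min(), -1.0) for ch in chans]
    phys_max = [max(ch.max(), 1.0) for ch in chans]
    dig_min, dig_max = -32768, 32767

    def pad(text, width):
        return str(text)[:width].ljust(width).encode("ascii")

    header = b"".join([
        pad("0", 8), pad("X", 80), pad("X", 80),
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(256 * (1 + n_sig), 8), pad("", 44),
        pad(n_records, 8), pad(record_s, 8), pad(n_sig, 4),
    ])
    per_signal = [
        [pad(lbl, 16) for lbl in labels],
        [pad("AgAgCl electrode", 80)] * n_sig,
        [pad("uV", 8)] * n_sig,
        [pad(f"{m:g}", 8) for m in phys_min],
        [pad(f"{m:g}", 8) for m in phys_max],
        [pad(dig_min, 8)] * n_sig,
        [pad(dig_max, 8)] * n_sig,
        [pad("", 80)] * n_sig,
        [pad(spr, 8) for spr in samples_per_record],
        [pad("", 32)] * n_sig,
    ]
    with open(path, "wb") as f:
        f.write(header)
        for block in per_signal:
            f.write(b"".join(block))
        for r in range(n_records):
            for ch, spr, pmin, pmax in zip(chans, samples_per_record,
                                           phys_min, phys_max):
                chunk = ch[r * spr:(r + 1) * spr]
                scale = (dig_max - dig_min) / (pmax - pmin)
                digital = np.round((chunk - pmin) * scale + dig_min)
                digital = np.clip(digital, dig_min, dig_max).astype("<i2")
                f.write(digital.tobytes())


def _read_edf_raw(path):
    with open(path, "rb") as f:
        head = f.read(256)
        header_bytes = int(head[184:192])
        n_records = int(head[236:244])
        record_s = float(head[244:252])
        n_sig = int(head[252:256])
        sig_head = f.read(header_bytes - 256)

        def fields(offset, width):
            start = offset * n_sig
            return [sig_head[start + i * width:start + (i + 1) * width]
                    .decode("ascii").strip() for i in range(n_sig)]

        # per-signal field byte offsets: label 0, transducer 16, dim 96,
        # phys min/max 104/112, dig min/max 120/128, prefilter 136, spr 216
        labels = fields(0, 16)
        phys_min = [float(x) for x in fields(104, 8)]
        phys_max = [float(x) for x in fields(112, 8)]
        dig_min = [float(x) for x in fields(120, 8)]
        dig_max = [float(x) for x in fields(128, 8)]
        spr = [int(x) for x in fields(216, 8)]
        data = [[] for _ in range(n_sig)]
        for _ in range(n_records):
            for i in range(n_sig):
                raw = np.frombuffer(f.read(2 * spr[i]), dtype="<i2").astype(np.float64)
                gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
                data[i].append(phys_min[i] + (raw - dig_min[i]) * gain)
    signals = [np.concatenate(d) for d in data]
    rates = [s / record_s for s in spr]
    return labels, signals, rates, n_records * record_s


#: legacy R&K and AASM hypnogram codes -> stage index (W N1 N2 N3 REM)
_STAGE_CODE_MAP = {
    "W": 0, "WAKE": 0, "0": 0,
    "N1": 1, "S1": 1, "1": 1,
    "N2": 2, "S2": 2, "2": 2,
    "N3": 3, "S3": 3, "S4": 3, "3": 3, "4": 3,  # R&K stages 3/4 merge to N3
    "REM": 4, "R": 4, "5": 4,
}


def map_hypnogram_codes(codes, on_unknown="error"):
    """Map stage codes to the 5-class scheme; unknown codes drop or raise."""
    out = []
    for code in codes:
        key = str(code).strip().upper()
        if key in _STAGE_CODE_MAP:
            out.append(_STAGE_CODE_MAP[key])
        elif on_unknown == "drop":
            out.append(-1)
        else:
            raise ValueError(f"unknown hypnogram stage code {code!r}")
    return np.asarray(out, dtype=np.int64)


def ingest_edf(path, channel_map: dict, subject_id: int = 0) -> Recording:
    """Read an EDF file into a Recording (best-effort).

    ``channel_map`` maps modality name ('eeg'/'eog') to the list of EDF
    channel labels to use, e.g. ``{"eeg": ["EEG Fpz-Cz"], "eog": [...]}``.
    """
    labels, signals, rates, _ = _read_edf_raw(path)
    out_signals, out_fs = {}, {}
    for mod, wanted in channel_map.items():
        rows, fs_values = [], []
        for name in wanted:
            if name not in labels:
                raise KeyError(
                    f"channel {name!r} not in EDF; available: {labels}")
            i = labels.index(name)
            rows.append(signals[i])
            fs_values.append(rates[i])
        if len(set(fs_values)) > 1:
            raise ValueError(f"{mod} channels have mixed sampling rates")
        out_signals[mod] = np.stack(rows)
        out_fs[mod] = fs_values[0]
    return Recording(signals=out_signals, fs=out_fs, subject_id=subject_id)
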