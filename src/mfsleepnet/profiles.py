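"""Dataset profiles and the five-stage label scheme.

Stage order is fixed everywhere as W=0, N1=1, N2=2, N3=3, REM=4.
"""

from __future__ import annotations

from dataclasses import dataclass

STAGES = ("W", "N1", "N2", "N3", "REM")
STAGE_TO_INDEX = {s: i for i, s in enumerate(STAGES)}
N_STAGES = len(STAGES)

W, N1, N2, N3, REM = range(5)


@dataclass(frozen=True)
class DatasetProfile:
    """Channel counts and sampling rates for a supported recording montage."""

    name: str
    eeg_channels: int
    eog_channels: int
    fs_eeg: float
    fs_eog: float
    epoch_s: float = 30.0

    def __post_init__(self):
        for fs in (self.fs_eeg, self.fs_eog):
            if fs <= 0:
                raise ValueError("sampling rate must be positive")
            n = self.epoch_s * fs
            if abs(n - round(n)) > 1e-9:
                raise ValueError(
                    f"epoch_s={self.epoch_s} at fs={fs} Hz does not yield an "
                    f"integer sample count")
        if self.eeg_channels < 1 or self.eog_channels < 0:
            raise ValueError("invalid channel counts")

    @property
    def eeg_samples(self) -> int:
        return int(round(self.epoch_s * self.fs_eeg))

    @property
    def eog_samples(self) -> int:
        return int(round(self.epoch_s * self.fs_eog))


_PRESETS = {
    "sleep_edf": DatasetProfile("sleep_edf", 2, 1, 100.0, 100.0),
    "shhs": DatasetProfile("shhs", 2, 2, 125.0, 50.0),
    "hsp": DatasetProfile("hsp", 6, 2, 200.0, 200.0),
}


def get_profile(name: str, **overrides) -> DatasetProfile:
    """Look up a preset profile, or build a ``custom`` one from overrides."""
    if name in _PRESETS:
        if overrides:
            raise ValueError(f"preset profile {name!r} takes no overrides")
        return _PRESETS[name]
    if name == "custom":
        return DatasetProfile(name="custom", **overrides)
    raise KeyError(f"unknown dataset profile {name!r}; choose from "
                   f"{sorted(_PRESETS)} or 'custom'")
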