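"""Stage-conditioned synthetic EEG/EOG generator.

Epochs are built as 1/f background noise plus stage-specific narrowband
oscillations and transient events (spindles, K-complexes, blinks, saccade
bursts), with per-subject gain, baseline drift and white noise applied on
top. All amplitudes are in microvolts. Every generator is a pure function
of its seed.

The stage recipes plant deliberately complementary structure: W/N1/N2/N3
separate mainly in the EEG spectrum, while REM is EEG-ambiguous with N1 and
carries its signature (opposite-polarity saccade bursts) in the EOG. N3
additionally leaks a shared slow-wave component into the EOG, giving that
stage elevated cross-modal correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .containers import Recording, concatenate_datasets
from .profiles import N_STAGES, STAGES, W, get_profile

__all__ = [
    "StageProfile",
    "SubjectParams",
    "STAGE_BANDS",
    "stage_profiles",
    "generate_epoch",
    "generate_hypnogram",
    "generate_subject_recording",
    "generate_cohort",
    "default_transition_matrix",
    "draw_subject_params",
]

BACKGROUND_RMS = 5.0  # µV, shared 1/f floor for both modalities


@dataclass(frozen=True)
class StageProfile:
    """Spectral and event recipe for one sleep stage and one modality."""

    stage: str
    oscillation_bands: tuple  # of (low_hz, high_hz, rms_uv)
    events: tuple = ()        # event names drawn from the registry below
    background_exponent: float = 1.0

    def validate(self, fs: float):
        nyq = fs / 2.0
        for low, high, amp in self.oscillation_bands:
            if not (0 < low < high):
                raise ValueError(f"invalid band edges ({low}, {high})")
            if high > nyq:
                raise ValueError(f"band ({low}, {high}) exceeds Nyquist {nyq} Hz")
            if amp <= 0:
                raise ValueError("relative band amplitude must be positive")


# Designated discriminative EEG band per stage (used by the periodogram
# fidelity oracle): alpha in W, theta in N1, spindle/sigma in N2,
# high-amplitude delta in N3, sawtooth-range activity in REM.
STAGE_BANDS = {
    "W": (8.0, 12.0),
    "N1": (4.0, 8.0),
    "N2": (12.0, 14.0),
    "N3": (0.5, 2.0),
    "REM": (2.0, 4.0),
}

_EEG_PROFILES = {
    "W": StageProfile("W", ((8.0, 12.0, 10.0),)),
    "N1": StageProfile("N1", ((4.0, 8.0, 10.0),)),
    "N2": StageProfile("N2", ((12.0, 14.0, 8.0),), events=("spindle", "kcomplex")),
    "N3": StageProfile("N3", ((0.5, 2.0, 18.0),)),
    # REM shares N1's theta range; the stronger 2-4 Hz component keeps its
    # designated band dominant while leaving the modalities complementary.
    "REM": StageProfile("REM", ((2.0, 4.0, 8.0), (4.0, 8.0, 5.0))),
}

_EOG_PROFILES = {
    "W": StageProfile("W", (), events=("blink",)),
    "N1": StageProfile("N1", ((0.25, 0.75, 8.0),)),
    "N2": StageProfile("N2", ()),
    "N3": StageProfile("N3", ()),  # receives the shared delta leak instead
    "REM": StageProfile("REM", (), events=("rem_burst",)),
}

N3_EOG_LEAK = 0.6  # fraction of the N3 slow-wave component mixed into EOG


def stage_profiles(stage: str, modality: str) -> StageProfile:
    table = _EEG_PROFILES if modality == "eeg" else _EOG_PROFILES
    return table[stage]


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject heterogeneity: gain, baseline drift and noise level."""

    gain: float = 1.0
    drift_slope: float = 0.0          # µV/s
    drift_wave: tuple = (0.0, 300.0)  # (amplitude µV, period s)
    noise_sd: float = 1.0
    seed: int = 0
    #: per-stage oscillation-amplitude factors, e.g. (("W", 0.4),) — used to
    #: plant class-conditional distribution shifts for adaptation studies
    stage_amp_scale: tuple = ()

    def __post_init__(self):
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def drift(self, t: np.ndarray) -> np.ndarray:
        amp, period = self.drift_wave
        out = self.drift_slope * t
        if amp:
            out = out + amp * np.sin(2 * np.pi * t / period)
        return out


def draw_subject_params(rng: np.random.Generator, seed: int) -> SubjectParams:
    return SubjectParams(
        gain=rng.uniform(0.6, 1.8),
        drift_slope=rng.uniform(-0.02, 0.02),
        drift_wave=(rng.uniform(5.0, 20.0), rng.uniform(200.0, 600.0)),
        noise_sd=rng.uniform(0.5, 2.0),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# signal primitives
# ---------------------------------------------------------------------------

def _colored_noise(rng, n, fs, beta, rms):
    """Gaussian 1/f^beta noise with the requested RMS."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spectrum = rng.normal(size=len(freqs)) + 1j * rng.normal(size=len(freqs))
    with np.errstate(divide="ignore"):
        scale = np.where(freqs > 0, freqs ** (-beta / 2.0), 0.0)
    x = np.fft.irfft(spectrum * scale, n=n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _band_noise(rng, n, fs, low, high, rms):
    """Narrowband Gaussian noise confined to [low, high] Hz."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= low) & (freqs <= high)
    spectrum = np.zeros(len(freqs), dtype=complex)
    spectrum[mask] = rng.normal(size=mask.sum()) + 1j * rng.normal(size=mask.sum())
    x = np.fft.irfft(spectrum, n=n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _spindle(rng, fs):
    dur = rng.uniform(0.5, 1.5)
    n = max(int(dur * fs), 4)
    t = np.arange(n) / fs
    freq = rng.uniform(12.0, 14.0)
    return 8.0 * np.hanning(n) * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))


def _kcomplex(rng, fs):
    # biphasic pulse: derivative-of-Gaussian, ~1 s
    n = max(int(1.0 * fs), 4)
    t = np.linspace(-3, 3, n)
    pulse = -t * np.exp(-t * t / 2.0)
    return 20.0 * pulse / np.abs(pulse).max()


def _blink(rng, fs):
    dur = rng.uniform(0.2, 0.35)
    n = max(int(dur * fs), 4)
    t = np.linspace(-2.5, 2.5, n)
    return 40.0 * np.exp(-t * t / 2.0)


def _rem_burst(rng, fs):
    # 3-6 rapid alternating-sign deflections
    pieces = []
    for i in range(rng.integers(3, 7)):
        dur = rng.uniform(0.15, 0.3)
        n = max(int(dur * fs), 3)
        sign = 1.0 if i % 2 == 0 else -1.0
        pieces.append(sign * 30.0 * np.hanning(n))
    return np.concatenate(pieces)


_EVENTS = {
    "spindle": (_spindle, "eeg", (1, 3)),
    "kcomplex": (_kcomplex, "eeg", (1, 2)),
    "blink": (_blink, "eog", (2, 4)),
    "rem_burst": (_rem_burst, "eog", (1, 3)),
}


def _place_events(rng, sig, fs, names, record):
    n = sig.shape[-1]
    for name in names:
        maker, modality, (lo, hi) = _EVENTS[name]
        for _ in range(rng.integers(lo, hi + 1)):
            shape = maker(rng, fs)
            if len(shape) >= n:
                start = 0
                shape = shape[:n]
            else:
                start = int(rng.integers(0, n - len(shape)))
            sig[start:start + len(shape)] += shape
            record.append({"name": name, "modality": modality,
                           "start": start, "stop": start + len(shape)})


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------

def _validate_stage(stage):
    if isinstance(stage, (int, np.integer)):
        if not 0 <= int(stage) < N_STAGES:
            raise ValueError(f"stage index {stage} out of range")
        return STAGES[int(stage)]
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    return stage


def generate_epoch(stage, profile, subject=None, rng=None, *, t_offset=0.0,
                   include_background=True, include_oscillations=True,
                   include_events=True, return_events=False):
    """Generate one 30-s epoch as ``{'eeg': (C, L), 'eog': (C, L)}``.

    The include_* switches suppress individual signal components; with all
    three off and ``noise_sd == 0`` the output is exactly the subject's
    deterministic drift line (times gain).
    """
    stage = _validate_stage(stage)
    if isinstance(profile, str):
        profile = get_profile(profile)
    subject = subject or SubjectParams()
    if rng is None:
        rng = np.random.default_rng(subject.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)

    events: list = []
    out = {}
    shared_delta = None
    for modality, n_ch, fs, L in (
        ("eeg", profile.eeg_channels, profile.fs_eeg, profile.eeg_samples),
        ("eog", profile.eog_channels, profile.fs_eog, profile.eog_samples),
    ):
        sp = stage_profiles(stage, modality)
        sp.validate(fs)
        sig = np.zeros((n_ch, L))
        for c in range(n_ch):
            if include_background:
                sig[c] += _colored_noise(rng, L, fs, sp.background_exponent,
                                         BACKGROUND_RMS)
            if include_oscillations:
                amp_factor = dict(subject.stage_amp_scale).get(stage, 1.0)
                for low, high, amp in sp.oscillation_bands:
                    comp = _band_noise(rng, L, fs, low, high, amp * amp_factor)
                    sig[c] += comp
                    if modality == "eeg" and stage == "N3" and c == 0:
                        shared_delta = comp
            mirrored_burst = (modality == "eog" and stage == "REM" and n_ch == 2)
            if include_events and not mirrored_burst:
                chan_events: list = []
                _place_events(rng, sig[c], fs, sp.events, chan_events)
                for ev in chan_events:
                    ev["channel"] = c
                events.extend(chan_events)
            if subject.noise_sd:
                sig[c] += rng.normal(0.0, subject.noise_sd, L)
        if modality == "eog" and stage == "REM" and n_ch == 2 and include_events:
            burst = np.zeros(L)
            meta: list = []
            _place_events(rng, burst, fs, ("rem_burst",), meta)
            sig[0] += burst
            sig[1] -= burst  # opposite polarity pair
            for ev in meta:
                ev["channel"] = 0
            events.extend(meta)
        if modality == "eog" and stage == "N3" and shared_delta is not None:
            # shared slow-wave leak (resampled if the rates differ)
            leak = shared_delta
            if L != len(leak):
                leak = np.interp(np.linspace(0, 1, L, endpoint=False),
                                 np.linspace(0, 1, len(leak), endpoint=False), leak)
            sig += N3_EOG_LEAK * leak
        t = t_offset + np.arange(L) / fs
        sig = subject.gain * (sig + subject.drift(t))
        out[modality] = sig
    if return_events:
        return out, events
    return out


def default_transition_matrix(self_prob=0.85):
    """Hypnogram transition preset with sleep-architecture-like structure."""
    off = {
        0: {1: 0.80, 4: 0.20},                 # W -> N1, REM
        1: {0: 0.15, 2: 0.75, 4: 0.10},        # N1 -> W, N2, REM
        2: {1: 0.20, 3: 0.50, 4: 0.30},        # N2 -> N1, N3, REM
        3: {2: 1.00},                          # N3 -> N2
        4: {0: 0.30, 1: 0.30, 2: 0.40},        # REM -> W, N1, N2
    }
    P = np.zeros((N_STAGES, N_STAGES))
    for i, row in off.items():
        P[i, i] = self_prob
        for j, w in row.items():
            P[i, j] = (1 - self_prob) * w
    return P


def generate_hypnogram(n_epochs, transition_matrix=None, rng=None, start=W):
    """Sample a stage sequence from a first-order Markov chain."""
    if n_epochs <= 0:
        raise ValueError("n_epochs must be positive")
    P = default_transition_matrix() if transition_matrix is None \
        else np.asarray(transition_matrix, dtype=float)
    if P.shape != (N_STAGES, N_STAGES) or (P < 0).any():
        raise ValueError("transition matrix must be 5x5 with non-negative entries")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition matrix rows must sum to 1")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    seq = np.empty(n_epochs, dtype=np.int64)
    state = int(start)
    for i in range(n_epochs):
        seq[i] = state
        state = int(rng.choice(N_STAGES, p=P[state]))
    return seq


def _resolve_imbalance(imbalance):
    """Accepts None, a stage-frequency vector, or a transition matrix."""
    if imbalance is None:
        return default_transition_matrix()
    arr = np.asarray(imbalance, dtype=float)
    if arr.shape == (N_STAGES,):
        if (arr < 0).any() or not np.isclose(arr.sum(), 1.0, atol=1e-9):
            raise ValueError("stage-frequency vector must be a probability vector")
        return np.tile(arr, (N_STAGES, 1))  # i.i.d. draws via rank-1 chain
    if arr.shape == (N_STAGES, N_STAGES):
        return arr
    raise ValueError("imbalance must be a length-5 vector or a 5x5 matrix")


def generate_subject_recording(profile, subject, labels, *, rng=None):
    """Concatenate per-epoch signals into a continuous raw Recording.

    Drift and gain are applied over the whole recording so that detrending
    and per-recording normalization have real work to do.
    """
    if isinstance(profile, str):
        profile = get_profile(profile)
    labels = np.asarray(labels, dtype=np.int64)
    if rng is None:
        rng = np.random.default_rng(subject.seed)
    base = SubjectParams(gain=1.0, noise_sd=subject.noise_sd, seed=subject.seed,
                         stage_amp_scale=subject.stage_amp_scale)
    chunks = {"eeg": [], "eog": []}
    for i, lab in enumerate(labels):
        ep = generate_epoch(lab, profile, base, rng, t_offset=0.0)
        for mod in chunks:
            chunks[mod].append(ep[mod])
    signals, fs = {}, {"eeg": profile.fs_eeg, "eog": profile.fs_eog}
    for mod in chunks:
        sig = np.concatenate(chunks[mod], axis=1)
        t = np.arange(sig.shape[1]) / fs[mod]
        signals[mod] = subject.gain * (sig + subject.drift(t))
    return Recording(signals=signals, fs=fs, subject_id=subject.seed)


def generate_cohort(n_subjects, epochs_per_subject, profile, imbalance=None,
                    master_seed=0, *, preprocess=False, target_fs=None,
                    subject_params=None):
    """Build an EpochDataset of ``n_subjects`` heterogeneous subjects.

    With ``preprocess=False`` the epochs are raw (gain/drift intact); with
    ``preprocess=True`` the standard conditioning pipeline is applied per
    subject recording before segmentation.
    """
    if n_subjects <= 0 or epochs_per_subject <= 0:
        raise ValueError("counts must be positive")
    if isinstance(profile, str):
        profile = get_profile(profile)
    P = _resolve_imbalance(imbalance)
    master = np.random.default_rng(master_seed)
    parts = []
    for s in range(n_subjects):
        seed = int(master.integers(0, 2 ** 31))
        rng = np.random.default_rng(seed)
        if subject_params is None:
            subject = draw_subject_params(rng, seed=s)
        else:
            subject = replace(subject_params, seed=s)
        start = int(rng.choice(N_STAGES))
        labels = generate_hypnogram(epochs_per_subject, P, rng, start=start)
        rec = generate_subject_recording(profile, subject, labels, rng=rng)
        if preprocess:
            from .preprocess import preprocess_recording
            ds = preprocess_recording(rec, profile=profile, target_fs=target_fs)
        else:
            from .preprocess import segment_epochs
            ds = segment_epochs(rec, profile=profile)
        ds.labels = labels[:len(ds)]
        ds.subject_ids = np.full(len(ds), s, dtype=np.int64)
        parts.append(ds)
    return concatenate_datasets(parts)
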