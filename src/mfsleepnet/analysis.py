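"""Stage-wise EEG-EOG correlation statistics, branch probes around the
fusion step, and gradient-based class-activation maps."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2, rankdata
from sklearn.linear_model import LogisticRegression

from . import nn
from .containers import EpochDataset
from .metrics import cohens_kappa, confusion, overall_accuracy
from .model import MFSleepNet
from .profiles import N_STAGES, STAGES

__all__ = [
    "spearman_epoch",
    "stagewise_correlation",
    "StageCorrelationResult",
    "kruskal_wallis",
    "branch_probe",
    "ProbeResult",
    "gradcam",
    "GradCAMMap",
]


def spearman_epoch(eeg_epoch, eog_epoch) -> float:
    """Spearman rho: Pearson correlation of average ranks. NaN if constant."""
    x = np.asarray(eeg_epoch, dtype=np.float64).ravel()
    y = np.asarray(eog_epoch, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError("inputs must have equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan
    rx = rankdata(x)
    ry = rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


@dataclass
class StageCorrelationResult:
    rho_by_stage: dict = field(default_factory=dict)   # stage -> array of rho
    median_by_stage: dict = field(default_factory=dict)
    median_abs_by_stage: dict = field(default_factory=dict)
    H: float = np.nan
    p_value: float = np.nan


def stagewise_correlation(dataset: EpochDataset,
                          channel_policy="mean_pairs") -> StageCorrelationResult:
    """Per-epoch EEG-EOG Spearman rho grouped by stage, plus the omnibus
    Kruskal-Wallis test across stage groups.

    channel_policy: 'mean_pairs' averages rho over all EEG x EOG channel
    pairs per epoch; 'first_pair' uses channel 0 of each modality.
    """
    if dataset.labels is None or dataset.eog is None:
        raise ValueError("labeled dataset with both modalities required")
    if dataset.eeg.shape[-1] != dataset.eog.shape[-1]:
        raise ValueError("modalities must be harmonized to equal length")
    result = StageCorrelationResult()
    rho = np.empty(len(dataset))
    for i in range(len(dataset)):
        if channel_policy == "first_pair":
            rho[i] = spearman_epoch(dataset.eeg[i, 0], dataset.eog[i, 0])
        elif channel_policy == "mean_pairs":
            vals = [spearman_epoch(e, o)
                    for e in dataset.eeg[i] for o in dataset.eog[i]]
            rho[i] = np.nanmean(vals)
        else:
            raise ValueError(f"unknown channel policy {channel_policy!r}")
    groups = []
    for s in range(N_STAGES):
        mask = dataset.labels == s
        vals = rho[mask]
        vals = vals[~np.isnan(vals)]
        if len(vals) == 0:
            warnings.warn(f"stage {STAGES[s]} absent; omitted from the test",
                          RuntimeWarning)
            continue
        result.rho_by_stage[STAGES[s]] = vals
        result.median_by_stage[STAGES[s]] = float(np.median(vals))
        result.median_abs_by_stage[STAGES[s]] = float(np.median(np.abs(vals)))
        groups.append(vals)
    if len(groups) >= 2:
        result.H, result.p_value = kruskal_wallis(groups)
    return result


def kruskal_wallis(groups):
    """Rank-based omnibus test with tie correction; chi-square p-value."""
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need at least two non-empty groups")
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = rankdata(pooled)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    start = 0
    H = 0.0
    for g in groups:
        r = ranks[start:start + len(g)]
        H += r.sum() ** 2 / len(g)
        start += len(g)
    H = 12.0 / (n * (n + 1)) * H - 3 * (n + 1)
    # tie correction
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (tie_counts ** 3 - tie_counts).sum() / (n ** 3 - n)
    if correction > 0:
        H /= correction
    df = len(groups) - 1
    return float(H), float(chi2.sf(H, df))


@dataclass
class ProbeResult:
    mode: str                       # 'before' or 'after'
    oa: dict = field(default_factory=dict)     # branch -> OA %
    kappa: dict = field(default_factory=dict)  # branch -> kappa


def _branch_features(model: MFSleepNet, ds: EpochDataset, batch_size=64):
    """Time-pooled modulated branch features from the trained full model."""
    model.eval()
    feats = {"eeg": [], "eog": []}
    for start in range(0, len(ds), batch_size):
        idx = np.arange(start, min(start + batch_size, len(ds)))
        f_eeg = model.embed_eeg(ds.eeg[idx])
        f_eog = model.embed_eog(ds.eog[idx])
        _, w = model.fusion(f_eeg, f_eog)
        feats["eeg"].append(
            nn.mean_time(f_eeg * w["w_eog_to_eeg"], keepdims=False).data)
        feats["eog"].append(
            nn.mean_time(f_eog * w["w_eeg_to_eog"], keepdims=False).data)
    return {k: np.concatenate(v) for k, v in feats.items()}


def branch_probe(model, train_ds: EpochDataset, test_ds: EpochDataset,
                 mode: str, seed=0) -> ProbeResult:
    """Branch performance around the fusion step.

    mode='before': ``model`` is a dict {'eeg': model1, 'eog': model2} of
    trained single-modality networks, evaluated directly.
    mode='after': ``model`` is the trained full network; a linear probe is
    fit on its frozen cross-modulated branch features.
    """
    result = ProbeResult(mode=mode)
    if mode == "before":
        from .training import predict
        for branch, m in model.items():
            preds = predict(m, test_ds)
            cm = confusion(test_ds.labels, preds)
            result.oa[branch] = overall_accuracy(cm)
            result.kappa[branch] = cohens_kappa(cm)
        return result
    if mode != "after":
        raise ValueError("mode must be 'before' or 'after'")
    if not isinstance(model, MFSleepNet) or model.config.modality != "both":
        raise ValueError("'after' mode requires a trained full model")
    train_feats = _branch_features(model, train_ds)
    test_feats = _branch_features(model, test_ds)
    for branch in ("eeg", "eog"):
        mu = train_feats[branch].mean(axis=0)
        sd = train_feats[branch].std(axis=0) + 1e-12
        clf = LogisticRegression(max_iter=1000, random_state=seed)
        clf.fit((train_feats[branch] - mu) / sd, train_ds.labels)
        preds = clf.predict((test_feats[branch] - mu) / sd)
        cm = confusion(test_ds.labels, preds)
        result.oa[branch] = overall_accuracy(cm)
        result.kappa[branch] = cohens_kappa(cm)
    return result


@dataclass
class GradCAMMap:
    values: np.ndarray      # (T,) non-negative, max-normalized when nonzero
    upsampled: np.ndarray   # (L,)
    tap: str
    target_class: int
    zero: bool = False


VALID_TAPS = ("eeg_branch", "eog_branch", "gated_output")


def gradcam(model: MFSleepNet, eeg, eog, tap: str, target_class: int,
            upsample_to: int | None = None) -> GradCAMMap:
    """Gradient-weighted activation map at one of the three tap points.

    Weights are the time-averaged gradients of the target-class logit with
    respect to the tap's feature map; the map is the ReLU of the weighted
    channel sum, max-normalized and linearly upsampled to signal length.
    """
    if tap not in VALID_TAPS:
        raise ValueError(f"tap must be one of {VALID_TAPS}")
    model.eval()

    def to_batch(x):
        if x is None:
            return None
        x = np.asarray(x, dtype=np.float64)
        return x[None] if x.ndim == 2 else x

    eeg, eog = to_batch(eeg), to_batch(eog)
    result = model.forward(eeg, eog)
    if tap not in result.intermediates:
        raise ValueError(f"tap {tap!r} not available for modality "
                         f"{model.config.modality!r}")
    feature = result.intermediates[tap]
    score = result.logits
    onehot = np.zeros_like(score.data)
    onehot[:, target_class] = 1.0
    score.backward(onehot)
    grads = feature.grad            # (1, C, T)
    acts = feature.data
    weights = grads.mean(axis=-1, keepdims=True)
    cam = np.maximum((weights * acts).sum(axis=1), 0.0)[0]  # (T,)
    zero = cam.max() == 0.0
    if not zero:
        cam = cam / cam.max()
    if upsample_to is None:
        L = (eeg if tap != "eog_branch" else eog).shape[-1]
    else:
        L = upsample_to
    xs = np.linspace(0, 1, len(cam))
    up = np.interp(np.linspace(0, 1, L), xs, cam)
    return GradCAMMap(values=cam, upsampled=up, tap=tap,
                      target_class=int(target_class), zero=bool(zero))
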