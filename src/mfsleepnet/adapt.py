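"""Subject-adaptive external validation: stratified 1:9 per-subject split,
head-only fine-tuning with a checksum-verified frozen backbone."""

from __future__ import annotations

import copy
import hashlib
import warnings
from dataclasses import dataclass

import numpy as np

from .containers import EpochDataset
from .metrics import evaluate
from .model import MFSleepNet
from .nn import Adam, cross_entropy
from .training import TrainConfig, predict

__all__ = [
    "subject_split",
    "finetune_head",
    "external_validate",
    "AdaptationResult",
    "backbone_digest",
]


def backbone_digest(model: MFSleepNet) -> str:
    """SHA-256 over all non-head parameters, in name order."""
    h = hashlib.sha256()
    for name, p in sorted(model.backbone_parameters()):
        h.update(name.encode())
        h.update(np.ascontiguousarray(p.data).tobytes())
    return h.hexdigest()


def subject_split(labels, ratio=0.10, seed=0):
    """Stratified adaptation/test split of one subject's epochs.

    Per-class counts use largest-remainder rounding toward the target
    fraction, with at least one adaptation epoch per class when possible.
    Returns (adapt_idx, test_idx), disjoint and exhaustive.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n == 0:
        raise ValueError("no epochs to split")
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(labels, return_counts=True)
    target = ratio * counts
    base = np.floor(target).astype(int)
    remainder = target - base
    total = int(round(ratio * n))
    # largest-remainder: distribute the leftover epochs
    short = total - base.sum()
    order = np.argsort(-remainder)
    for i in range(abs(int(short))):
        base[order[i % len(order)]] += 1 if short > 0 else -1
    take = np.minimum(np.maximum(base, (counts >= 2).astype(int)), counts - 1)
    take = np.maximum(take, 0)
    if (counts < 10).any() and len(classes) == 1:
        warnings.warn("subject has a single class with few epochs; "
                      "best-effort split", RuntimeWarning)
    adapt_idx = []
    for cls, k in zip(classes, take):
        members = np.where(labels == cls)[0]
        adapt_idx.extend(rng.choice(members, size=int(k), replace=False))
    adapt_idx = np.sort(np.array(adapt_idx, dtype=np.int64))
    test_idx = np.setdiff1d(np.arange(n), adapt_idx)
    return adapt_idx, test_idx


def _pooled_features(model: MFSleepNet, ds: EpochDataset, batch_size=64):
    """Time-pooled pre-head features from the frozen extractor (eval mode)."""
    from .nn import mean_time
    model.eval()
    out = []
    for start in range(0, len(ds), batch_size):
        idx = np.arange(start, min(start + batch_size, len(ds)))
        eeg = ds.eeg[idx] if model.config.modality in ("both", "eeg") else None
        eog = ds.eog[idx] if model.config.modality in ("both", "eog") else None
        result = model.forward(eeg, eog)
        out.append(mean_time(result.intermediates["gated_output"],
                             keepdims=False).data)
    return np.concatenate(out)


def finetune_head(model: MFSleepNet, adapt_ds: EpochDataset,
                  config: TrainConfig | None = None) -> MFSleepNet:
    """Fine-tune only the classification head on the adaptation set.

    The feature extractor is frozen (eval-mode batch statistics), so the
    head is trained on cached pooled features — identical gradients to
    backpropagating through the fixed backbone, at a fraction of the cost.
    Returns a new model; every non-head parameter is bit-identical to the
    input model (verified by checksum)."""
    if len(adapt_ds) == 0:
        raise ValueError("empty adaptation set")
    config = config or TrainConfig(epochs=20, lr=1e-4, batch_size=32)
    adapted = copy.deepcopy(model)
    digest_before = backbone_digest(adapted)
    feats = _pooled_features(adapted, adapt_ds)
    head_params = [p for _, p in adapted.head_parameters()]
    opt = Adam(head_params, lr=config.lr, weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed)
    from .nn import as_tensor
    for _ in range(config.epochs):
        order = rng.permutation(len(adapt_ds))
        for start in range(0, len(adapt_ds), config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = adapted.head(as_tensor(feats[idx]))
            loss = cross_entropy(logits, adapt_ds.labels[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
    if backbone_digest(adapted) != digest_before:
        raise RuntimeError("freeze contract violated: backbone changed")
    return adapted


@dataclass
class AdaptationResult:
    subject_id: int
    oa_before: float
    oa_after: float | None
    n_adapt: int
    n_test: int
    head_params_updated: int
    backbone_digest_before: str
    backbone_digest_after: str | None
    adapt_test_overlap: int = 0  # audited; must be 0


def external_validate(model: MFSleepNet, heldout: EpochDataset,
                      with_adaptation=True, ratio=0.10, seed=0,
                      finetune_config: TrainConfig | None = None,
                      train_subjects=None):
    """Per-subject direct-transfer OA, optionally followed by head-only
    adaptation on a stratified 10% of each subject's epochs."""
    if train_subjects is not None:
        overlap = np.intersect1d(heldout.subjects(), np.asarray(train_subjects))
        if len(overlap):
            raise ValueError(f"held-out subjects overlap training set: {overlap}")
    results = []
    digest0 = backbone_digest(model)
    for sid in heldout.subjects():
        sub = heldout.select(np.where(heldout.subject_ids == sid)[0])
        adapt_idx, test_idx = subject_split(sub.labels, ratio=ratio,
                                            seed=seed + int(sid))
        test_ds = sub.select(test_idx)
        preds = predict(model, test_ds)
        oa_before = evaluate(test_ds.labels, preds).oa
        oa_after, digest_after = None, None
        if with_adaptation:
            adapted = finetune_head(model, sub.select(adapt_idx), finetune_config)
            digest_after = backbone_digest(adapted)
            preds = predict(adapted, test_ds)
            oa_after = evaluate(test_ds.labels, preds).oa
        results.append(AdaptationResult(
            subject_id=int(sid),
            oa_before=oa_before,
            oa_after=oa_after,
            n_adapt=len(adapt_idx),
            n_test=len(test_idx),
            head_params_updated=sum(p.data.size for _, p in model.head_parameters()),
            backbone_digest_before=digest0,
            backbone_digest_after=digest_after,
            adapt_test_overlap=len(np.intersect1d(adapt_idx, test_idx)),
        ))
    return results
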