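"""Training protocol: Adam with weight decay, stratified epoch-level 5-fold
cross-validation, best-validation-accuracy checkpointing, ablation presets."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .containers import EpochDataset
from .metrics import evaluate
from .model import MFSleepNet, ModelConfig
from .nn import Adam, cross_entropy

__all__ = [
    "TrainConfig",
    "FoldSplit",
    "HYPERPARAMETER_GRID",
    "stratified_kfold",
    "train_model",
    "predict",
    "cross_validate",
    "CrossValidationReport",
    "ablation_config",
    "ablation_study",
    "save_checkpoint",
    "load_checkpoint",
]

#: learning-rate x weight-decay grid used for hyperparameter selection
HYPERPARAMETER_GRID = {
    "lr": (1e-3, 1e-4, 1e-5),
    "weight_decay": (1e-5, 1e-4, 1e-3),
}


@dataclass
class TrainConfig:
    lr: float = 1e-4
    weight_decay: float = 1e-4
    epochs: int = 100
    batch_size: int = 32
    seed: int = 0
    val_fraction: float = 0.1  # split off the training fold for checkpointing

    def __post_init__(self):
        if self.lr < 0 or self.weight_decay < 0 or self.epochs < 1 \
                or self.batch_size < 1 or not 0 < self.val_fraction < 1:
            raise ValueError("invalid training configuration")


@dataclass
class FoldSplit:
    fold_id: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    stratified: bool = True
    subject_aware: bool = False


def stratified_kfold(labels, k=5, seed=0, subject_ids=None,
                     subject_aware=False):
    """Partition epochs into k folds; stratified by stage, or by subject."""
    labels = np.asarray(labels)
    if subject_aware:
        if subject_ids is None:
            raise ValueError("subject_aware folds require subject_ids")
        subjects = np.unique(subject_ids)
        rng = np.random.default_rng(seed)
        order = rng.permutation(subjects)
        groups = np.array_split(order, k)
        folds = []
        for i, group in enumerate(groups):
            test_mask = np.isin(subject_ids, group)
            folds.append(FoldSplit(i + 1, np.where(~test_mask)[0],
                                   np.where(test_mask)[0], stratified=False,
                                   subject_aware=True))
        return folds
    classes, counts = np.unique(labels, return_counts=True)
    for cls, cnt in zip(classes, counts):
        if cnt < k:
            raise ValueError(f"class {cls} has only {cnt} members; "
                             f"needs at least k={k} for stratified folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [FoldSplit(i + 1, tr, te)
            for i, (tr, te) in enumerate(skf.split(np.zeros(len(labels)), labels))]


def _batches(n, batch_size, rng=None):
    idx = np.arange(n) if rng is None else rng.permutation(n)
    for start in range(0, n, batch_size):
        yield idx[start:start + batch_size]


def _inputs(model, ds: EpochDataset, idx):
    mod = model.config.modality
    eeg = ds.eeg[idx] if mod in ("both", "eeg") else None
    eog = ds.eog[idx] if mod in ("both", "eog") else None
    return eeg, eog


def predict(model: MFSleepNet, ds: EpochDataset, batch_size=64):
    """Class predictions in eval mode."""
    model.eval()
    preds = np.empty(len(ds), dtype=np.int64)
    for idx in _batches(len(ds), batch_size):
        eeg, eog = _inputs(model, ds, idx)
        preds[idx] = model.forward(eeg, eog).probabilities.argmax(axis=1)
    return preds


def train_model(model: MFSleepNet, train_ds: EpochDataset,
                val_ds: EpochDataset, config: TrainConfig,
                parameters=None, verbose=False):
    """Train with shuffled mini-batches and retain the checkpoint with the
    best validation accuracy (earliest epoch on ties)."""
    rng = np.random.default_rng(config.seed)
    params = parameters if parameters is not None else model.parameters()
    opt = Adam(params, lr=config.lr, weight_decay=config.weight_decay)
    history = {"train_loss": [], "val_accuracy": []}
    best = {"val_accuracy": -np.inf, "epoch": -1, "state": None}
    for epoch in range(config.epochs):
        model.train()
        losses = []
        for idx in _batches(len(train_ds), config.batch_size, rng):
            eeg, eog = _inputs(model, train_ds, idx)
            result = model.forward(eeg, eog)
            loss = cross_entropy(result.logits, train_ds.labels[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {loss.data}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_pred = predict(model, val_ds, batch_size=config.batch_size)
        val_acc = float((val_pred == val_ds.labels).mean())
        history["train_loss"].append(float(np.mean(losses)))
        history["val_accuracy"].append(val_acc)
        if val_acc > best["val_accuracy"]:
            best = {"val_accuracy": val_acc, "epoch": epoch,
                    "state": model.state_dict()}
        if verbose:
            print(f"epoch {epoch}: loss={np.mean(losses):.4f} val_acc={val_acc:.4f}")
    if best["state"] is not None:
        model.load_state_dict(best["state"])
    checkpoint = {"state": best["state"], "epoch": best["epoch"],
                  "val_accuracy": best["val_accuracy"],
                  "config": model.config, "seed": model.seed}
    return checkpoint, history


@dataclass
class CrossValidationReport:
    per_fold: list = field(default_factory=list)  # of MetricsReport
    folds: list = field(default_factory=list)     # of FoldSplit

    def summary(self) -> dict:
        out = {}
        for key in ("oa", "kappa", "mf1"):
            vals = np.array([getattr(r, key) for r in self.per_fold])
            out[key] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1))
                        if len(vals) > 1 else 0.0}
        return out


def cross_validate(dataset: EpochDataset, model_config: ModelConfig,
                   train_config: TrainConfig, k=5,
                   model_factory=None, verbose=False) -> CrossValidationReport:
    """Stratified epoch-level k-fold CV; reports per-fold OA / kappa / MF1."""
    folds = stratified_kfold(dataset.labels, k=k, seed=train_config.seed)
    report = CrossValidationReport(folds=folds)
    for fold in folds:
        tr_idx, va_idx = train_test_split(
            fold.train_idx, test_size=train_config.val_fraction,
            stratify=dataset.labels[fold.train_idx],
            random_state=train_config.seed + fold.fold_id)
        if model_factory is not None:
            model = model_factory(fold)
        else:
            model = MFSleepNet(model_config, seed=train_config.seed + fold.fold_id)
        train_model(model, dataset.select(tr_idx), dataset.select(va_idx),
                    train_config, verbose=verbose)
        preds = predict(model, dataset.select(fold.test_idx))
        report.per_fold.append(evaluate(dataset.labels[fold.test_idx], preds))
    return report


def ablation_config(method: int, base: ModelConfig) -> ModelConfig:
    """Ablation presets: 1 EEG-only, 2 EOG-only, 3 plain concatenation,
    4 + cross-channel fusion, 5 full model."""
    if method == 1:
        return base.with_(modality="eeg", use_fusion=False, use_gtca=False)
    if method == 2:
        return base.with_(modality="eog", use_fusion=False, use_gtca=False)
    if method == 3:
        return base.with_(modality="both", use_fusion=False, use_gtca=False)
    if method == 4:
        return base.with_(modality="both", use_fusion=True, use_gtca=False)
    if method == 5:
        return base.with_(modality="both", use_fusion=True, use_gtca=True)
    raise ValueError("method must be in 1..5")


def _active_parameters(model: MFSleepNet):
    """Parameters on the active forward path (bypassed modules excluded)."""
    cfg = model.config
    names = []
    if cfg.modality in ("both", "eeg"):
        names += ["eeg_backbone", "eeg_embed"]
    if cfg.modality in ("both", "eog"):
        names += ["eog_backbone", "eog_embed"]
    if cfg.modality == "both" and cfg.use_fusion:
        names.append("fusion")
    if cfg.modality == "both" and cfg.use_gtca:
        names.append("gtca")
    names.append("head")
    params = []
    for n in names:
        params.extend(getattr(model, n).parameters())
    return params


def ablation_study(dataset: EpochDataset, base_config: ModelConfig,
                   train_config: TrainConfig, methods=(1, 2, 3, 4, 5),
                   seeds=(0,), test_fraction=0.3, verbose=False):
    """Mean test OA per ablation method over seeds (single stratified split
    per seed to stay inside desk-scale budgets)."""
    results = {m: [] for m in methods}
    for seed in seeds:
        idx = np.arange(len(dataset))
        tr, te = train_test_split(idx, test_size=test_fraction,
                                  stratify=dataset.labels, random_state=seed)
        tr, va = train_test_split(tr, test_size=train_config.val_fraction,
                                  stratify=dataset.labels[tr], random_state=seed)
        for method in methods:
            cfg = ablation_config(method, base_config)
            model = MFSleepNet(cfg, seed=seed)
            tc = TrainConfig(**{**vars(train_config), "seed": seed})
            train_model(model, dataset.select(tr), dataset.select(va), tc,
                        parameters=_active_parameters(model), verbose=verbose)
            preds = predict(model, dataset.select(te))
            oa = evaluate(dataset.labels[te], preds).oa
            results[method].append(oa)
            if verbose:
                print(f"seed {seed} method {method}: OA={oa:.2f}%")
    return {m: float(np.mean(v)) for m, v in results.items()}, results


def save_checkpoint(path, model: MFSleepNet, extra=None):
    state = model.state_dict()
    meta = {"config_yaml": model.config.to_yaml(), "seed": model.seed}
    if extra:
        meta.update(extra)
    np.savez(path, __meta__=np.array([repr(meta)], dtype=object),
             **{f"param/{k}": v for k, v in state.items()})


def load_checkpoint(path) -> MFSleepNet:
    import ast
    with np.load(path, allow_pickle=True) as data:
        meta = ast.literal_eval(str(data["__meta__"][0]))
        state = {k[len("param/"):]: data[k] for k in data.files
                 if k.startswith("param/")}
    config = ModelConfig.from_yaml(meta["config_yaml"])
    model = MFSleepNet(config, seed=int(meta["seed"]))
    model.load_state_dict(state)
    return model
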