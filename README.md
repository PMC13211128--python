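# mfsleepnet

Multimodal EEG+EOG sleep staging as a tested library and CLI:

- **Synthetic PSG generator** (`mfsleepnet.synth_psg`) — stage-conditioned
  30-s epochs (alpha in W, theta in N1, spindles/K-complexes in N2,
  high-amplitude delta in N3, saccade bursts in REM EOG) over 1/f
  background, with per-subject gain/drift/noise heterogeneity and
  hypnogram-like Markov stage sequences. Replaces dataset downloads for
  every test.
- **Preprocessing** (`mfsleepnet.preprocess`) — first-order least-squares
  detrend, per-recording z-score, 30-s segmentation, polyphase multirate
  harmonization. No filtering, no epoch exclusion.
- **Model** (`mfsleepnet.model`) — modality-specific 1-D residual backbones
  (bottleneck blocks for EEG, basic blocks for EOG; stem + four stages,
  temporal downsampling ×32), 1×1 projections to a shared embedding,
  bidirectional cross-channel gating fusion, and a gated temporal-channel
  attention block (temporal attention, per-timestep gate, efficient channel
  attention with the adaptive-kernel rule), ending in GAP + linear head.
  Built on a small numpy autodiff backend (`mfsleepnet.nn`) — no GPU or
  external DL framework required.
- **Training** (`mfsleepnet.training`) — Adam + weight decay, stratified
  epoch-level 5-fold CV, best-validation-accuracy checkpointing, the five
  ablation presets (EEG-only / EOG-only / concat / +fusion / full).
- **Metrics** (`mfsleepnet.metrics`) — confusion matrix, overall accuracy,
  Cohen's kappa, macro-F1 with per-class precision/recall/F1.
- **Analysis** (`mfsleepnet.analysis`) — per-epoch EEG–EOG Spearman
  correlation by stage with a Kruskal–Wallis omnibus test, before/after
  fusion branch probes, and Grad-CAM maps at three tap points.
- **Adaptation** (`mfsleepnet.adapt`) — per-subject stratified 1:9 split
  and head-only fine-tuning with a checksum-verified frozen backbone.
- **I/O + CLI** (`mfsleepnet.io`, `mfsleepnet.cli`) — HDF5/NPZ dataset
  container, minimal best-effort EDF ingestion, and the `mfsleepnet`
  command group.

Stage labels are fixed everywhere as W=0, N1=1, N2=2, N3=3, REM=4.

## CLI

```bash
mfsleepnet simulate --profile sleep_edf --subjects 5 --epochs 200 --seed 1 --out cohort.h5
mfsleepnet preprocess --data cohort.h5 --out cohort_125.h5      # multirate harmonization
mfsleepnet train --data cohort.h5 --width-multiplier 0.0625 --folds 5 --seed 1 --out runs/
mfsleepnet evaluate --data cohort.h5 --checkpoint runs/model.npz --out metrics.json
mfsleepnet ablate --data cohort.h5 --seeds 0,1,2 --out ablation.json
mfsleepnet correlate --data cohort.h5 --out correlation.csv
mfsleepnet gradcam --data cohort.h5 --checkpoint model.npz --tap gated_output --stage N2 --out cam.csv
mfsleepnet adapt --checkpoint model.npz --subjects heldout.h5 --ratio 0.1 --seed 1 --out adapt.csv
```

Every command takes a single `--seed` and writes a JSON run manifest next
to its output.

## Library quick start

```python
import numpy as np
from mfsleepnet import ModelConfig, MFSleepNet, get_profile
from mfsleepnet.synth_psg import generate_cohort
from mfsleepnet.training import TrainConfig, train_model, predict

profile = get_profile("sleep_edf")
cohort = generate_cohort(5, 100, profile, master_seed=1, preprocess=True)
config = ModelConfig.from_profile(profile, width_multiplier=1 / 16)
model = MFSleepNet(config, seed=0)
checkpoint, history = train_model(model, cohort, cohort,
                                  TrainConfig(epochs=10, lr=1e-3))
predictions = predict(model, cohort)
```
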