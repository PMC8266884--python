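"""Leave-one-out cross-validation: splitting, training, model selection.

Each participant is held out once; the remaining participants are randomly
split 75/25 into training and validation sets (17/6 for a 24-participant
cohort).  The model trains for up to ``max_epochs`` epochs; after every
epoch the validation intersection-over-union (IoU) is computed on the
(augmented) validation slices and the weights of the maximum-IoU epoch are
retained — ties break toward the earlier epoch.  The retained model then
predicts the held-out participant, so n participants yield n prediction
masks from n distinct models with no data leakage.

Optimizer hyperparameters (Adam, learning rate, batch size) are not part of
the published protocol and are configurable on :class:`ExperimentConfig`.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import nn
from .augment import AugmentationPolicy, balance_and_augment
from .io_types import (
    CLASS_CMB,
    CLASS_IRON,
    DatasetManifest,
    ExperimentConfig,
    LabelVolume,
    MultiModalVolume,
    ValidationError,
    load_volume_set,
)
from .network import NetworkSpec, UNet, build_network
from .preprocess import assemble_channels, unpad_2d


@dataclass
class FoldPlan:
    test_id: str
    train_ids: list
    val_ids: list
    seed: int = 0

    def __post_init__(self) -> None:
        groups = [set(self.train_ids), set(self.val_ids), {self.test_id}]
        total = sum(len(g) for g in groups)
        union = set().union(*groups)
        if total != len(union):
            raise ValidationError("fold partitions overlap")


@dataclass
class TrainingState:
    epoch: int = 0
    val_iou_history: list = field(default_factory=list)
    train_loss_history: list = field(default_factory=list)
    best_epoch: int = 0  # 1-based; argmax of val_iou_history, earliest on ties
    best_iou: float = -np.inf

    def record(self, loss: float, iou: float) -> bool:
        """Append one epoch; return True when this epoch is the new best."""
        self.epoch += 1
        self.train_loss_history.append(loss)
        self.val_iou_history.append(iou)
        if iou > self.best_iou:
            self.best_iou = iou
            self.best_epoch = self.epoch
            return True
        return False


def make_folds(cohort: Sequence[str], val_fraction: float = 0.25,
               seed: int = 0) -> list:
    """One leave-one-out fold per participant, with a seeded 75/25 split.

    The validation count is ``round(val_fraction * (n - 1))`` — 6 of 23 for
    a 24-participant cohort — and the split is re-randomized per fold.
    """
    cohort = list(cohort)
    if len(cohort) < 3:
        raise ValidationError("LOOCV needs a cohort of at least 3 participants")
    if len(set(cohort)) != len(cohort):
        raise ValidationError("participant ids must be unique")
    folds = []
    for k, test_id in enumerate(cohort):
        rest = [p for p in cohort if p != test_id]
        rng = np.random.default_rng([seed, k])
        order = rng.permutation(len(rest))
        n_val = max(1, round(val_fraction * len(rest)))
        val_ids = [rest[i] for i in order[:n_val]]
        train_ids = [rest[i] for i in order[n_val:]]
        folds.append(FoldPlan(test_id=test_id, train_ids=train_ids,
                              val_ids=val_ids, seed=seed))
    return folds


def compute_iou(pred_masks: np.ndarray, ref_masks: np.ndarray,
                task: str = "single_class_cmb") -> float:
    """Pooled intersection-over-union across all pixels.

    Single-class tasks: binary IoU (1.0 when both masks are empty).
    Multiclass: mean of per-class IoU over the lesion classes present in
    the reference (binary any-lesion IoU if the reference has none).
    """
    pred = np.asarray(pred_masks)
    ref = np.asarray(ref_masks)
    if pred.shape != ref.shape:
        raise ValidationError("pred and ref shapes differ")

    def _binary(p, r):
        inter = np.logical_and(p, r).sum()
        union = np.logical_or(p, r).sum()
        return 1.0 if union == 0 else float(inter / union)

    if task != "multiclass":
        return _binary(pred > 0, ref > 0)
    present = [c for c in (CLASS_CMB, CLASS_IRON) if (ref == c).any()]
    if not present:
        return _binary(pred > 0, ref > 0)
    return float(np.mean([_binary(pred == c, ref == c) for c in present]))


# ---------------------------------------------------------------------------
# in-memory cohort handling


def load_cohort(manifest: DatasetManifest) -> list:
    """[(pid, MultiModalVolume, LabelVolume), ...] from a manifest on disk."""
    out = []
    for entry in manifest.entries:
        vol, labels = load_volume_set(manifest, entry)
        if labels is None:
            raise ValidationError(f"{entry.participant_id}: labels required for training")
        out.append((entry.participant_id, vol, labels))
    return out


def _task_target(label_2d: np.ndarray, task: str) -> np.ndarray:
    if task == "single_class_cmb":
        return (label_2d == CLASS_CMB).astype(np.float32)
    if task == "single_class_iron":
        return (label_2d == CLASS_IRON).astype(np.float32)
    return label_2d.astype(np.int64)


def _batches(samples, batch_size, task):
    for i in range(0, len(samples), batch_size):
        chunk = samples[i:i + batch_size]
        x = np.stack([s.image for s in chunk])
        y = np.stack([_task_target(s.label, task) for s in chunk])
        yield x, y


def _copy_weights(net: UNet):
    state = []
    for layer in net.layers():
        entry = {k: v.copy() for k, v in layer.params.items()}
        if isinstance(layer, nn.BatchNorm2d):
            entry["__rm__"] = layer.running_mean.copy()
            entry["__rv__"] = layer.running_var.copy()
        state.append(entry)
    return state


def _restore_weights(net: UNet, state) -> None:
    for layer, entry in zip(net.layers(), state):
        for k in layer.params:
            layer.params[k] = entry[k].copy()
        if isinstance(layer, nn.BatchNorm2d):
            layer.running_mean = entry["__rm__"].copy()
            layer.running_var = entry["__rv__"].copy()


def default_network_spec(config: ExperimentConfig) -> NetworkSpec:
    head = "softmax_multi" if config.task == "multiclass" else "sigmoid_single"
    return NetworkSpec(
        n_resolutions=config.n_resolutions,
        in_channels=len(config.modalities),
        head=head,
        n_classes=3,
        base_width=config.base_width,
    )


def _prepare_slices(cohort, ids, config, policy, task, rng,
                    augment: bool = True):
    samples = []
    by_id = {pid: (vol, lab) for pid, vol, lab in cohort}
    for pid in ids:
        vol, lab = by_id[pid]
        samples.extend(assemble_channels(vol, lab, config))
    if augment and policy is not None:
        samples = balance_and_augment(samples, policy, task, rng)
    return samples


def _predict_binary_stack(net, samples, config, batch_size=8):
    """Per-slice class maps (list of 2D int arrays) for a sample list."""
    out = []
    for i in range(0, len(samples), batch_size):
        chunk = samples[i:i + batch_size]
        x = np.stack([s.image for s in chunk])
        probs = net.predict_proba(x)
        if net.spec.head == "sigmoid_single":
            cls = CLASS_CMB if config.task == "single_class_cmb" else CLASS_IRON
            masks = (probs[:, 0] >= config.threshold).astype(np.int16) * cls
        else:
            masks = probs.argmax(axis=1).astype(np.int16)
        out.extend(masks)
    return out


def train_fold(
    fold: FoldPlan,
    cohort: list,
    config: ExperimentConfig,
    policy: Optional[AugmentationPolicy] = None,
    net_spec: Optional[NetworkSpec] = None,
    augment_validation: bool = True,
) -> tuple:
    """Train one fold; returns ``(state, best_net)``.

    The best network is the deep copy of the weights at the maximum-IoU
    epoch (earliest epoch on ties).
    """
    task = config.task
    net_spec = net_spec or default_network_spec(config)
    rng = np.random.default_rng([config.seed, zlib.crc32(fold.test_id.encode())])
    train_samples = _prepare_slices(cohort, fold.train_ids, config, policy,
                                    task, rng, augment=True)
    val_samples = _prepare_slices(cohort, fold.val_ids, config, policy, task,
                                  rng, augment=augment_validation)
    if config.max_val_samples is not None and len(val_samples) > config.max_val_samples:
        idx = rng.permutation(len(val_samples))[:config.max_val_samples]
        val_samples = [val_samples[i] for i in idx]

    net = build_network(net_spec, seed=config.seed)
    opt = nn.Adam(net.layers(), lr=config.learning_rate)
    state = TrainingState()
    best = _copy_weights(net)
    # reference for IoU is the task target (e.g. CMB-only mask for the
    # single-class CMB task), not the full multi-class label volume
    val_ref = np.stack([_task_target(s.label, task) for s in val_samples])
    for _epoch in range(config.max_epochs):
        order = rng.permutation(len(train_samples))
        if config.max_train_samples_per_epoch is not None:
            order = order[:config.max_train_samples_per_epoch]
        epoch_samples = [train_samples[i] for i in order]
        losses = []
        for x, y in _batches(epoch_samples, config.batch_size, task):
            loss = net.train_loss(x, y)
            opt.step()
            losses.append(loss)
        val_pred = np.stack(_predict_binary_stack(net, val_samples, config))
        iou = compute_iou(val_pred, val_ref, task)
        if state.record(float(np.mean(losses)), iou):
            best = _copy_weights(net)
    _restore_weights(net, best)
    return state, net


def predict_participant(net: UNet, vol: MultiModalVolume,
                        config: ExperimentConfig) -> LabelVolume:
    """Predict a 3D label volume for one participant, slice by slice."""
    samples = assemble_channels(vol, None, config)
    maps = _predict_binary_stack(net, samples, config)
    planes = [unpad_2d(m, s.orig_shape, s.pad_offsets)
              for m, s in zip(maps, samples)]
    stack = np.stack(planes)  # axial axis first
    labels = np.moveaxis(stack, 0, vol.axial_axis)
    return LabelVolume(labels=labels.astype(np.int16), voxel_dims=vol.voxel_dims)


def run_loocv(
    cohort: list,
    config: ExperimentConfig,
    policy: Optional[AugmentationPolicy] = None,
    net_spec: Optional[NetworkSpec] = None,
    callback=None,
    checkpoint_dir=None,
) -> dict:
    """Full leave-one-out run.

    Returns ``{participant_id: (predicted LabelVolume, TrainingState)}``;
    every participant is predicted by the model whose training never saw
    its data.  With *checkpoint_dir*, each fold's best model is saved as
    ``fold_<test_id>.npz``.
    """
    from dataclasses import asdict

    from .network import save_checkpoint

    ids = [pid for pid, _, _ in cohort]
    folds = make_folds(ids, config.val_fraction, config.seed)
    by_id = {pid: vol for pid, vol, _ in cohort}
    results = {}
    for fold in folds:
        state, net = train_fold(fold, cohort, config, policy, net_spec)
        pred = predict_participant(net, by_id[fold.test_id], config)
        results[fold.test_id] = (pred, state)
        if checkpoint_dir is not None:
            meta = {"config": asdict(config), "test_id": fold.test_id,
                    "best_epoch": state.best_epoch, "best_iou": state.best_iou}
            save_checkpoint(net, f"{checkpoint_dir}/fold_{fold.test_id}.npz",
                            meta=meta)
        if callback is not None:
            callback(fold, state, pred)
    return results
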