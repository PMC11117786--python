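"""Training: multi-branch loss, weighted sampling, warm-up cosine schedule.

The total loss sums the fused branch with the per-sequence auxiliary
branches, L = L_ALL + L_T1 + L_T2, each a mean binary cross-entropy on
logits.  Class imbalance is handled by weighted random sampling with
replacement, weight 1/N_c per class, which equalizes the expected
class mix per epoch.  The learning rate ramps linearly over the
warm-up epochs (epoch/warmup) and then follows a half-cosine decay
0.5·[cos(π·(epoch−warmup)/(num_epoch−warmup)) + 1] to zero; AdamW with
decoupled weight decay updates the parameters (decay on conv/linear
weights only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .augmentation import AugmentationConfig, apply_augment
from .imaging_io import CohortManifest, slice_select
from .fusion_net import FUSED, MultiSequenceModel
from .nn import Tensor, AdamW, bce_with_logits
from skimage.transform import resize

__all__ = ["SamplerWeights", "LossBreakdown", "ScheduleConfig", "TrainConfig",
           "SplitPlan", "class_weights", "sample_indices", "branch_loss",
           "total_loss", "lr_multiplier", "split_cohort", "SliceDataset",
           "train", "predict_cohort"]


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

@dataclass
class SamplerWeights:
    n0: int
    n1: int

    def __post_init__(self):
        if self.n0 < 1 or self.n1 < 1:
            raise ValueError(f"both classes must be present, got counts "
                             f"N0={self.n0}, N1={self.n1}")

    @property
    def weight_per_class(self) -> dict[int, float]:
        return {0: 1.0 / self.n0, 1: 1.0 / self.n1}


def class_weights(labels) -> SamplerWeights:
    """Reciprocal-count class weights: weight(c) = 1/N_c."""
    labels = np.asarray(labels)
    return SamplerWeights(n0=int(np.sum(labels == 0)),
                          n1=int(np.sum(labels == 1)))


def sample_indices(labels, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw `n` indices with replacement, proportional to class weight."""
    labels = np.asarray(labels)
    w = class_weights(labels).weight_per_class
    p = np.array([w[int(y)] for y in labels], dtype=float)
    p /= p.sum()
    return rng.choice(len(labels), size=n, replace=True, p=p)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def branch_loss(logits, labels) -> float:
    """Mean binary cross-entropy of raw logits, numerically stable."""
    s = np.asarray(logits, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if s.size == 0:
        raise ValueError("empty batch has no defined loss")
    if s.shape != y.shape:
        raise ValueError(f"logits/labels length mismatch: {s.shape} vs {y.shape}")
    if not np.all(np.isfinite(s)):
        raise ValueError("non-finite logit")
    per = np.maximum(s, 0.0) - s * y + np.log1p(np.exp(-np.abs(s)))
    return float(per.mean())


@dataclass
class LossBreakdown:
    l_all: float
    l_t1: float
    l_t2: float

    def __post_init__(self):
        for name, v in (("l_all", self.l_all), ("l_t1", self.l_t1),
                        ("l_t2", self.l_t2)):
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")

    @property
    def total(self) -> float:
        return self.l_all + self.l_t1 + self.l_t2


def total_loss(l_all: float, l_t1: float, l_t2: float) -> LossBreakdown:
    """L = L_ALL + L_T1 + L_T2; absent branches contribute 0."""
    return LossBreakdown(l_all=l_all, l_t1=l_t1, l_t2=l_t2)


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------

@dataclass
class ScheduleConfig:
    base_lr: float = 0.001
    warmup_epoch: int = 25
    num_epoch: int = 100

    def __post_init__(self):
        if not 0 < self.warmup_epoch < self.num_epoch:
            raise ValueError("need 0 < warmup_epoch < num_epoch")
        if self.base_lr <= 0:
            raise ValueError("base_lr must be positive")


def lr_multiplier(epoch: float, schedule: ScheduleConfig) -> float:
    """Warm-up/cosine multiplier in [0, 1]; epochs are 1-based.

    epoch ≤ warmup: epoch / warmup_epoch (reaches exactly 1 at warmup);
    after: 0.5·[cos(π·(epoch−warmup)/(num_epoch−warmup)) + 1], reaching
    0 at the final epoch.
    """
    if not 1 <= epoch <= schedule.num_epoch:
        raise ValueError(f"epoch {epoch} outside [1, {schedule.num_epoch}]")
    w = schedule.warmup_epoch
    if epoch <= w:
        return float(epoch / w)
    return float(0.5 * (math.cos(math.pi * (epoch - w)
                                 / (schedule.num_epoch - w)) + 1.0))


# ---------------------------------------------------------------------------
# cohort splitting
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]
    folds: list[tuple[list[str], list[str]]] = field(default_factory=list)

    def __post_init__(self):
        all_ids = self.train_ids + self.val_ids + self.test_ids
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("split partitions overlap")


def split_cohort(manifest: CohortManifest, proportions=(198, 50, 63),
                 k: int = 5, seed: int = 0) -> SplitPlan:
    """Stratified train/validation/test split plus k-fold re-partitions.

    Partition sizes follow `proportions` scaled to the cohort size (the
    default 198:50:63 reproduces the reference protocol exactly at
    n=311).  The k folds re-partition train+validation; the test set is
    identical across folds.
    """
    labelled = [(r.patient_id, r.label) for r in manifest.records
                if r.label is not None]
    ids = np.array([i for i, _ in labelled])
    y = np.array([l for _, l in labelled])
    n = len(ids)
    total = sum(proportions)
    n_train = round(n * proportions[0] / total)
    n_val = round(n * proportions[1] / total)
    n_test = n - n_train - n_val
    if min(n_train, n_val, n_test) < 2:
        raise ValueError(f"cohort of {n} too small for proportions {proportions}")
    trval_ids, test_ids, trval_y, test_y = train_test_split(
        ids, y, test_size=n_test, stratify=y, random_state=seed)
    train_ids, val_ids, train_y, val_y = train_test_split(
        trval_ids, trval_y, test_size=n_val, stratify=trval_y, random_state=seed)
    for name, part in (("train", train_y), ("validation", val_y),
                       ("test", test_y)):
        if len(np.unique(part)) < 2:
            raise ValueError(f"class absent from the {name} partition")
    folds = []
    if k and k >= 2:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        for tr, va in skf.split(trval_ids, trval_y):
            folds.append((trval_ids[tr].tolist(), trval_ids[va].tolist()))
    return SplitPlan(train_ids=train_ids.tolist(), val_ids=val_ids.tolist(),
                     test_ids=test_ids.tolist(), folds=folds)


# ---------------------------------------------------------------------------
# slice dataset
# ---------------------------------------------------------------------------

class SliceDataset:
    """2D model inputs from a cohort: slice selection, augmentation, z-scoring.

    Slices are taken axially per the configured policy, z-scored, and
    replicated to 3 channels.  Augmentation applies only when
    ``training=True`` is passed to :meth:`images_for`.
    """

    def __init__(self, manifest: CohortManifest, resolution=(96, 96),
                 slice_policy: str = "top_k_mean", k_slices: int = 3,
                 augment: AugmentationConfig | None = None):
        self.manifest = manifest
        self.resolution = tuple(resolution)
        if augment is None:
            augment = AugmentationConfig(output_size=self.resolution)
        else:
            augment.output_size = self.resolution
        self.augment = augment
        self.by_id = {r.patient_id: r for r in manifest.records}
        self._cache: dict[tuple[str, str], list[np.ndarray]] = {}
        self.slice_policy = slice_policy
        self.k_slices = k_slices

    def sequences_of(self, patient_id: str) -> list[str]:
        return [s for s in ("T1", "T2") if self.by_id[patient_id].has(s)]

    def label_of(self, patient_id: str) -> int | None:
        return self.by_id[patient_id].label

    def n_slices(self, patient_id: str) -> int:
        seqs = self.sequences_of(patient_id)
        return len(self._raw_slices(patient_id, seqs[0]))

    def _raw_slices(self, patient_id: str, seq: str) -> list[np.ndarray]:
        key = (patient_id, seq)
        if key not in self._cache:
            vol = self.by_id[patient_id].volume(seq)
            images, _ = slice_select(vol, self.slice_policy, k=self.k_slices)
            self._cache[key] = images
        return self._cache[key]

    @staticmethod
    def _normalize(img: np.ndarray) -> np.ndarray:
        std = float(img.std())
        img = (img - img.mean()) / (std if std > 0 else 1.0)
        return np.repeat(img[None].astype(np.float32), 3, axis=0)

    def images_for(self, patient_id: str, slice_idx: int, seq: str,
                   training: bool, rng: np.random.Generator | None = None
                   ) -> np.ndarray:
        """(3, H, W) network input for one slice of one sequence."""
        raw = self._raw_slices(patient_id, seq)
        img = raw[min(slice_idx, len(raw) - 1)]
        if training:
            assert rng is not None, "training-mode augmentation needs an rng"
            img = apply_augment(img, self.augment, rng)
        elif img.shape != self.resolution:
            img = resize(img, self.resolution, order=1, mode="edge",
                         anti_aliasing=False, preserve_range=True)
        return self._normalize(np.asarray(img, dtype=np.float32))


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    batch_size: int = 32
    weight_decay: float = 1e-4
    seed: int = 0
    sequences: tuple[str, ...] = ("T1", "T2")

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.weight_decay < 0:
            raise ValueError("weight decay must be >= 0")


def _forward_losses(model: MultiSequenceModel, dataset: SliceDataset,
                    batch: list[tuple[str, int, int]], training: bool,
                    rng: np.random.Generator | None):
    """Tensor losses (l_all, l_t1, l_t2) for one batch of (pid, slice, label)."""
    seq_names = list(model.config.sequence_names)
    complete = [s for s in batch
                if all(dataset.by_id[s[0]].has(q) for q in seq_names)]
    losses: dict[str, Tensor | None] = {FUSED: None}
    for seq in seq_names:
        subset = [s for s in batch if dataset.by_id[s[0]].has(seq)]
        losses[seq] = None
        if not subset:
            continue
        x = np.stack([dataset.images_for(pid, sl, seq, training, rng)
                      for pid, sl, _ in subset])
        y = np.array([lab for _, _, lab in subset], dtype=np.float32)
        if subset == complete:
            # shared forward: branch loss + contribution to fused features
            feats = model.extractors[seq](Tensor(x))
            logit = model.classifiers[seq](feats).reshape(-1)
            losses[seq] = bce_with_logits(logit, y)
            losses.setdefault("_feats", {})[seq] = feats
        else:
            logit = model.classifiers[seq](
                model.extractors[seq](Tensor(x))).reshape(-1)
            losses[seq] = bce_with_logits(logit, y)
    feats = losses.pop("_feats", {})
    if complete and len(feats) == len(seq_names):
        from .nn import concat as t_concat
        if model.config.fusion_method == "concatenate":
            f = t_concat([feats[q] for q in seq_names], axis=1)
        else:
            f = feats[seq_names[0]]
            for q in seq_names[1:]:
                f = f + feats[q]
        y_all = np.array([lab for _, _, lab in complete], dtype=np.float32)
        losses[FUSED] = bce_with_logits(
            model.fused_classifier(f).reshape(-1), y_all)
    elif complete:
        # mixed-availability batch: dedicated forward over complete records
        xs = {q: np.stack([dataset.images_for(pid, sl, q, training, rng)
                           for pid, sl, _ in complete]) for q in seq_names}
        logits = model.forward_branches({q: Tensor(v) for q, v in xs.items()})
        if FUSED in logits:
            y_all = np.array([lab for _, _, lab in complete], dtype=np.float32)
            losses[FUSED] = bce_with_logits(logits[FUSED], y_all)
    return losses


def predict_cohort(model: MultiSequenceModel, dataset: SliceDataset,
                   ids: list[str], branch: str = FUSED
                   ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Patient-level probabilities for one branch (mean over slices).

    Returns (probabilities, labels, patient_ids) over the patients for
    which the branch is computable.  Inference only — augmentation off,
    batch normalization in running-statistics mode.
    """
    model.eval()
    seq_names = list(model.config.sequence_names)
    probs, labels, kept = [], [], []
    for pid in ids:
        have = [q for q in seq_names if dataset.by_id[pid].has(q)]
        if branch == FUSED and len(have) < len(seq_names):
            continue
        if branch != FUSED and branch not in have:
            continue
        needed = seq_names if branch == FUSED else [branch]
        n_sl = dataset.n_slices(pid)
        xs = {q: Tensor(np.stack([dataset.images_for(pid, j, q, False)
                                  for j in range(n_sl)])) for q in needed}
        logits = model.forward_branches(xs)
        s = logits[branch].data
        probs.append(float(np.mean(1.0 / (1.0 + np.exp(-s)))))
        labels.append(dataset.label_of(pid))
        kept.append(pid)
    return np.array(probs), np.array(labels), kept


def train(model: MultiSequenceModel, dataset: SliceDataset, split: SplitPlan,
          config: TrainConfig, schedule: ScheduleConfig,
          val_metric_every: int = 1):
    """Run the full training loop; returns (model, history DataFrame).

    Each epoch draws one weighted-with-replacement pass over the
    training samples (slice level; slices inherit the patient label),
    applies augmentation, and steps AdamW at base_lr × lr_multiplier.
    The history logs L, L_ALL, L_T1, L_T2 and validation AUC per epoch.
    Reproducible for a fixed config seed.
    """
    from .evaluation import roc_auc, ScoredCohort

    rng = np.random.default_rng(config.seed)
    samples = [(pid, j, dataset.label_of(pid))
               for pid in split.train_ids
               for j in range(dataset.n_slices(pid))]
    if not samples:
        raise ValueError("empty training partition")
    labels = [s[2] for s in samples]
    opt = AdamW(model.parameters(), lr=schedule.base_lr,
                weight_decay=config.weight_decay,
                decay_params=model.decay_parameters())
    history = []
    for epoch in range(1, schedule.num_epoch + 1):
        lr = schedule.base_lr * lr_multiplier(epoch, schedule)
        opt.lr = lr
        order = sample_indices(labels, len(samples), rng)
        model.train()
        sums = {FUSED: 0.0, "T1": 0.0, "T2": 0.0}
        counts = {FUSED: 0, "T1": 0, "T2": 0}
        for start in range(0, len(order), config.batch_size):
            batch = [samples[i] for i in order[start:start + config.batch_size]]
            losses = _forward_losses(model, dataset, batch, True, rng)
            terms = [t for t in losses.values() if t is not None]
            if not terms:
                continue
            L = terms[0]
            for t in terms[1:]:
                L = L + t
            if not np.isfinite(L.data):
                raise RuntimeError(f"training diverged at epoch {epoch}: "
                                   f"loss {float(L.data)}")
            model.zero_grad()
            L.backward()
            opt.step()
            for k, t in losses.items():
                if t is not None:
                    sums[k] += float(t.data)
                    counts[k] += 1
        row = {"epoch": epoch, "lr": lr}
        for k, out in ((FUSED, "L_ALL"), ("T1", "L_T1"), ("T2", "L_T2")):
            row[out] = sums[k] / counts[k] if counts[k] else 0.0
        row["L"] = row["L_ALL"] + row["L_T1"] + row["L_T2"]
        if split.val_ids and epoch % val_metric_every == 0:
            p, y, _ = predict_cohort(model, dataset, split.val_ids, FUSED)
            row["val_auc"] = (roc_auc(ScoredCohort(p, y, FUSED))
                              if len(np.unique(y)) == 2 else float("nan"))
        history.append(row)
    return model, pd.DataFrame(history)
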