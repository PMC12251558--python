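"""Training loop, leave-one-individual-out cross-validation, and metrics.

Each fold holds out every clip of one individual — the realistic
deployment scenario is a collar on an animal the model has never heard.
Training uses the competitive fusion objective with the decaying
competition weight; class-balancing weights come from the training fold's
class counts; the learning rate follows cosine annealing. The final-epoch
model is evaluated (no early stopping or model selection).

Reported metrics: fraction-correct accuracy, one-vs-rest per-class
precision/recall from the confusion matrix, and a support-weighted F1
(macro available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .audio_io import DatasetManifest, load_clip
from .denoise import DenoiseConfig, denoise_clip
from .features import FeatureConfig, melspectrogram, standardize
from .losses import class_weights, lambda_schedule, total_loss_grads
from .model import DualBranchModel, build_model, cam_forward
from . import nn

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig", "FoldResult", "CvSummary",
    "features_from_manifest", "train_fold", "loio_split", "evaluate",
    "metrics_from_confusion", "cross_validate",
    "branch_overlap", "branch_agreement",
]


@dataclass
class TrainConfig:
    """Optimisation hyper-parameters (defaults follow the method's recipe)."""

    batch_size: int = 16
    lr: float = 1e-4
    epochs: int = 40
    lr_schedule: str = "cosine"      # "cosine" | "constant"
    gamma: float = 2.0               # focal-loss focusing exponent
    seed: int = 0
    lambda_kind: str = "linear"      # decay shape of the competition weight
    lambda_fixed: float | None = None  # set to hold lambda constant (e.g. 1.0)
    use_oap: bool = True
    use_bsp: bool = True

    def __post_init__(self) -> None:
        if min(self.batch_size, self.epochs) < 1 or self.lr <= 0:
            raise ValueError("batch_size, epochs and lr must be positive")


@dataclass
class FoldResult:
    held_out_individual: str
    accuracy: float
    f1: float
    confusion: np.ndarray            # (C, C) counts, rows = true class
    per_class_precision: np.ndarray
    per_class_recall: np.ndarray
    history: dict | None = None      # per-epoch training curves, if kept


@dataclass
class CvSummary:
    mean_accuracy: float
    std_accuracy: float
    mean_f1: float
    std_f1: float
    folds: list[FoldResult] = field(default_factory=list)


def features_from_manifest(manifest: DatasetManifest,
                           feature_config: FeatureConfig | None = None,
                           denoise_config: DenoiseConfig | None = None,
                           sample_rate: int | None = None):
    """Load, optionally denoise, and featurize every clip in a manifest.

    Returns ``(X, y)`` with X of shape (N, 1, n_mels, T) (per-clip
    standardized) and integer labels indexed into ``manifest.class_names``.
    All clips must share one duration and rate.
    """
    cfg = feature_config or FeatureConfig()
    label_idx = {c: i for i, c in enumerate(manifest.class_names)}
    feats, labels = [], []
    for path, _indiv, behavior in manifest.records:
        clip = load_clip(path, target_rate=sample_rate or _wav_rate(path))
        if denoise_config is not None:
            clip = denoise_clip(clip, denoise_config)
        feats.append(standardize(melspectrogram(clip, cfg)).values)
        labels.append(label_idx[behavior])
    X = np.stack(feats)
    return X, np.asarray(labels, dtype=np.int64)


def _wav_rate(path) -> int:
    from scipy.io import wavfile
    rate, _ = wavfile.read(str(path), mmap=True)
    return int(rate)


def train_fold(model: DualBranchModel, X: np.ndarray, y: np.ndarray,
               config: TrainConfig | None = None):
    """Train a dual-branch model on one fold; returns (model, history).

    ``history`` holds per-epoch means of the loss terms plus the lambda
    and learning-rate schedules actually applied. Deterministic for a
    fixed config seed.
    """
    cfg = config or TrainConfig()
    y = np.asarray(y)
    if X.shape[0] != y.shape[0] or X.shape[0] == 0:
        raise ValueError("X and y must be non-empty and aligned")
    classes_present = np.unique(y)
    if classes_present.size < 2:
        raise ValueError("training fold must contain at least two classes")
    C = model.n_classes
    counts = np.bincount(y, minlength=C).astype(float)
    alpha = class_weights(np.maximum(counts, 1.0))
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.parameters(), lr=cfg.lr)
    onehot = np.eye(C)[y]
    history = {k: [] for k in
               ("l_fl", "l_oap", "l_bsp", "l_total", "lambda", "lr")}
    n = X.shape[0]
    model.train(True)
    for epoch in range(cfg.epochs):
        if cfg.lambda_fixed is not None:
            lam = cfg.lambda_fixed
        elif cfg.epochs >= 2:
            lam = lambda_schedule(epoch, cfg.epochs, cfg.lambda_kind)
        else:
            lam = 1.0
        lam_eff = lam if cfg.use_oap else 0.0
        bsp_w = 1.0 if cfg.use_bsp else 0.0
        if cfg.lr_schedule == "cosine":
            opt.lr = nn.cosine_lr(cfg.lr, epoch, cfg.epochs)
        order = rng.permutation(n)
        sums = np.zeros(4)
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, tb = X[idx], onehot[idx]
            fmap = model.forward_features(xb)
            out1 = cam_forward(fmap, model.head1)
            out2 = cam_forward(fmap, model.head2)
            breakdown, gM1, gM2 = total_loss_grads(
                out1.M, out2.M, tb, alpha, cfg.gamma,
                lambda_t=lam_eff, bsp_weight=bsp_w)
            model.zero_grad()
            gF = model.head1.backward(gM1) + model.head2.backward(gM2)
            model.backbone.backward(gF)
            opt.step()
            sums += (breakdown.l_fl, breakdown.l_oap, breakdown.l_bsp,
                     breakdown.l_total)
            n_batches += 1
        history["l_fl"].append(sums[0] / n_batches)
        history["l_oap"].append(sums[1] / n_batches)
        history["l_bsp"].append(sums[2] / n_batches)
        history["l_total"].append(sums[3] / n_batches)
        history["lambda"].append(lam)
        history["lr"].append(opt.lr)
        logger.debug("epoch %d: total=%.4f fl=%.4f oap=%.4f bsp=%.4f lam=%.3f",
                     epoch, *sums / n_batches, lam)
    model.eval()
    return model, history


def loio_split(manifest: DatasetManifest):
    """Leave-one-individual-out folds: one (train_idx, test_idx) per individual."""
    if len(manifest.individual_names) < 2:
        raise ValueError("leave-one-individual-out needs at least two individuals")
    indivs = np.array([r[1] for r in manifest.records])
    folds = []
    for name in manifest.individual_names:
        test = np.flatnonzero(indivs == name)
        train = np.flatnonzero(indivs != name)
        folds.append((train, test))
    return folds


def _batched_scores(model: DualBranchModel, X: np.ndarray, branch,
                    chunk: int = 32) -> np.ndarray:
    model.eval()
    out = []
    for start in range(0, X.shape[0], chunk):
        xb = X[start:start + chunk]
        o1, o2 = model.forward(xb)
        if str(branch) == "1":
            out.append(o1.S)
        elif str(branch) == "2":
            out.append(o2.S)
        elif str(branch) == "mean":
            out.append(0.5 * (o1.S + o2.S))
        else:
            raise ValueError(f"branch must be 1, 2 or 'mean', got {branch!r}")
    return np.concatenate(out, axis=0)


def metrics_from_confusion(confusion: np.ndarray, average: str = "weighted"):
    """Accuracy, per-class precision/recall and aggregated F1 from counts.

    One-vs-rest per class: precision = TP/(TP+FP) down the predicted
    column, recall = TP/(TP+FN) along the true row; F1 per class is their
    harmonic mean, aggregated support-weighted (or macro).
    """
    cm = np.asarray(confusion, dtype=np.float64)
    total = cm.sum()
    accuracy = float(np.trace(cm) / total) if total else 0.0
    tp = np.diag(cm)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(precision + recall > 0,
                      2 * precision * recall / (precision + recall), 0.0)
    support = cm.sum(axis=1)
    if average == "weighted":
        f1_agg = float((f1 * support).sum() / total) if total else 0.0
    elif average == "macro":
        f1_agg = float(f1.mean())
    else:
        raise ValueError(f"unknown average {average!r}")
    return accuracy, precision, recall, f1_agg


def evaluate(model: DualBranchModel, X: np.ndarray, y: np.ndarray,
             held_out_individual: str = "", branch=1,
             f1_average: str = "weighted") -> FoldResult:
    """Single-branch evaluation of a trained model on a held-out fold."""
    if X.shape[0] == 0:
        raise ValueError("test set is empty")
    scores = _batched_scores(model, X, branch)
    pred = scores.argmax(axis=1)
    C = model.n_classes
    cm = _sk_confusion(y, pred, labels=np.arange(C))
    accuracy, precision, recall, f1 = metrics_from_confusion(cm, f1_average)
    return FoldResult(
        held_out_individual=held_out_individual,
        accuracy=accuracy, f1=f1, confusion=cm,
        per_class_precision=precision, per_class_recall=recall,
    )


def cross_validate(manifest: DatasetManifest,
                   config: TrainConfig | None = None,
                   backbone: str = "tinycnn",
                   feature_config: FeatureConfig | None = None,
                   denoise_config: DenoiseConfig | None = None,
                   branch=1) -> CvSummary:
    """Leave-one-individual-out cross-validation of the full pipeline.

    One master seed fans out to per-fold model/training seeds. The summary
    reports mean +/- population standard deviation over folds.
    """
    cfg = config or TrainConfig()
    X, y = features_from_manifest(manifest, feature_config, denoise_config)
    folds = loio_split(manifest)
    seeds = np.random.SeedSequence(cfg.seed).generate_state(2 * len(folds)) % (2**31)
    results = []
    for k, (train_idx, test_idx) in enumerate(folds):
        name = manifest.individual_names[k]
        model = build_model(backbone, manifest.n_classes,
                           class_names=manifest.class_names,
                           seed=int(seeds[2 * k]))
        fold_cfg = TrainConfig(**{**cfg.__dict__, "seed": int(seeds[2 * k + 1])})
        model, history = train_fold(model, X[train_idx], y[train_idx], fold_cfg)
        fold_res = evaluate(model, X[test_idx], y[test_idx],
                            held_out_individual=name, branch=branch)
        fold_res.history = history
        results.append(fold_res)
        logger.info("fold %s: accuracy=%.3f f1=%.3f", name,
                    results[-1].accuracy, results[-1].f1)
    accs = np.array([r.accuracy for r in results])
    f1s = np.array([r.f1 for r in results])
    return CvSummary(
        mean_accuracy=float(accs.mean()), std_accuracy=float(accs.std()),
        mean_f1=float(f1s.mean()), std_f1=float(f1s.std()), folds=results,
    )


def branch_overlap(model: DualBranchModel, X: np.ndarray, chunk: int = 32) -> float:
    """Mean overlap penalty between the two branches' masks over a dataset."""
    from .losses import mask_from_cam, oap_loss
    model.eval()
    vals = []
    for start in range(0, X.shape[0], chunk):
        o1, o2 = model.forward(X[start:start + chunk])
        vals.append(oap_loss(mask_from_cam(o1.M), mask_from_cam(o2.M))
                    * min(chunk, X.shape[0] - start))
    return float(np.sum(vals) / X.shape[0])


def branch_agreement(model: DualBranchModel, X: np.ndarray) -> float:
    """Fraction of clips where branch-1 and mean-branch predictions agree."""
    p1 = _batched_scores(model, X, 1).argmax(axis=1)
    pm = _batched_scores(model, X, "mean").argmax(axis=1)
    return float(np.mean(p1 == pm))
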