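"""Training, evaluation, hyperparameter tuning and explainability exports.

The training loop minimizes the composite deep-supervision loss (weighted
final cross-entropy plus weighted auxiliary cross-entropies) with Adam and
keeps the checkpoint with the best validation accuracy.  Evaluation uses the
final head only.  ``explain`` exports what the routed architecture exposes:
per-stage expert utilization, per-sample routing-pattern matrices, spatial
attention gates upsampled over the input image, and — when ground-truth
lesion masks exist — the mean attention inside versus outside the mask.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.transform import resize as sk_resize
from sklearn.metrics import confusion_matrix as sk_confusion_matrix

from . import autograd as ag
from . import tpe as tpe_mod
from .model import ModelConfig, MoEClassifier, build_model, total_loss
from .nn import Adam, ConfigurationError
from .routing import InputError, StageTrace, expert_utilization, merge_traces, routing_pattern_matrix
from .synthetic import LabeledImageSet


# -- augmentation ------------------------------------------------------------


@dataclass
class AugmentationConfig:
    """Train-time augmentation: resize -> random horizontal flip -> random
    rotation -> brightness shift -> contrast scale -> per-channel
    normalization.  Evaluation applies resize + normalization only."""

    resize_to: int = 224
    horizontal_flip_prob: float = 0.5
    rotation_max_deg: float = 15.0
    brightness_delta: float = 0.1
    contrast_factor_range: tuple[float, float] = (0.9, 1.1)
    normalization_mean: tuple[float, float, float] | None = None
    normalization_sd: tuple[float, float, float] | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.horizontal_flip_prob <= 1:
            raise ConfigurationError("flip probability must lie in [0, 1]")
        if self.rotation_max_deg < 0:
            raise ConfigurationError("rotation bound must be >= 0")


def _resize(image: np.ndarray, size: int) -> np.ndarray:
    if image.shape[0] == size and image.shape[1] == size:
        return image
    return sk_resize(image, (size, size), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)


def _normalize(image: np.ndarray, cfg: AugmentationConfig) -> np.ndarray:
    if cfg.normalization_mean is None:
        return image
    mean = np.asarray(cfg.normalization_mean)
    sd = np.asarray(cfg.normalization_sd)
    return (image - mean) / sd


def apply_augmentations(image: np.ndarray, cfg: AugmentationConfig,
                        rng: np.random.Generator,
                        train: bool = True) -> np.ndarray:
    """Augment one RGB image with values in [0, 1]."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise InputError(f"expected an (H, W, 3) RGB image, got {image.shape}")
    image = _resize(image, cfg.resize_to)
    if not train:
        return _normalize(image, cfg)
    if rng.random() < cfg.horizontal_flip_prob:
        image = image[:, ::-1]
    angle = rng.uniform(-cfg.rotation_max_deg, cfg.rotation_max_deg)
    if angle != 0.0:
        image = ndimage.rotate(image, angle, axes=(0, 1), reshape=False,
                               order=1, mode="nearest")
    image = image + rng.uniform(-cfg.brightness_delta, cfg.brightness_delta)
    lo, hi = cfg.contrast_factor_range
    factor = rng.uniform(lo, hi)
    image = (image - image.mean()) * factor + image.mean()
    image = np.clip(image, 0.0, 1.0)
    return _normalize(image, cfg)


def fit_normalization(cfg: AugmentationConfig, images: np.ndarray) -> AugmentationConfig:
    """Fill normalization constants from the per-channel statistics of a
    training split."""
    cfg.normalization_mean = tuple(float(m) for m in images.mean(axis=(0, 1, 2)))
    cfg.normalization_sd = tuple(
        float(max(s, 1e-6)) for s in images.std(axis=(0, 1, 2))
    )
    return cfg


# -- training ----------------------------------------------------------------


@dataclass
class OptimizerConfig:
    learning_rate: float = 1e-3
    batch_size: int = 16
    epochs: int = 15
    seed: int = 0
    early_stop_acc: float | None = None  # stop once val accuracy reaches this
    augment: bool = False
    augmentation: AugmentationConfig | None = None


@dataclass
class TrainResult:
    history: list[dict]
    best_state: dict[str, np.ndarray]
    best_val_accuracy: float
    best_epoch: int

    @property
    def final_val_accuracy(self) -> float:
        return self.history[-1]["val_accuracy"]


def _accuracy(model: MoEClassifier, images: np.ndarray,
              labels: np.ndarray, batch_size: int = 32) -> tuple[float, float]:
    """(mean final-head cross-entropy, accuracy) in eval mode."""
    model.eval()
    losses, correct = [], 0
    for i in range(0, len(images), batch_size):
        xb, yb = images[i : i + batch_size], labels[i : i + batch_size]
        out = model(xb)
        losses.append(
            ag.softmax_cross_entropy(out.final_logits, yb).item() * len(xb)
        )
        correct += int((out.final_logits.data.argmax(axis=1) == yb).sum())
    return sum(losses) / len(images), correct / len(images)


def train(model: MoEClassifier, train_set: LabeledImageSet,
          val_set: LabeledImageSet, opt_cfg: OptimizerConfig) -> TrainResult:
    """Mini-batch training of the composite loss; returns per-epoch metrics
    and the best-by-validation-accuracy parameter state.  Fully seeded."""
    n_classes = model.cfg.num_classes
    if int(train_set.labels.max()) >= n_classes:
        raise ConfigurationError(
            f"data has class index {int(train_set.labels.max())} but the "
            f"model expects {n_classes} classes"
        )
    rng = np.random.default_rng(opt_cfg.seed)
    aug_rng = np.random.default_rng(np.random.SeedSequence((opt_cfg.seed, 1)))
    optimizer = Adam(model.parameters(), lr=opt_cfg.learning_rate)
    history: list[dict] = []
    best_state = model.state_dict()
    best_acc, best_epoch = -1.0, -1
    for epoch in range(opt_cfg.epochs):
        model.train()
        order = rng.permutation(len(train_set))
        epoch_loss, seen = 0.0, 0
        for bi, start in enumerate(range(0, len(order), opt_cfg.batch_size)):
            idx = order[start : start + opt_cfg.batch_size]
            xb = train_set.images[idx]
            if opt_cfg.augment and opt_cfg.augmentation is not None:
                xb = np.stack([
                    apply_augmentations(im, opt_cfg.augmentation, aug_rng)
                    for im in xb
                ])
            yb = train_set.labels[idx]
            out = model(xb)
            loss = total_loss(
                ag.softmax_cross_entropy(out.final_logits, yb),
                [ag.softmax_cross_entropy(a, yb) for a in out.aux_logits],
                model.cfg,
                training=True,
            )
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {bi}"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_loss += loss.item() * len(idx)
            seen += len(idx)
        train_loss, train_acc = _accuracy(model, train_set.images, train_set.labels)
        val_loss, val_acc = _accuracy(model, val_set.images, val_set.labels)
        history.append({
            "epoch": epoch,
            "total_loss": epoch_loss / seen,
            "train_loss": train_loss,
            "train_accuracy": train_acc,
            "val_loss": val_loss,
            "val_accuracy": val_acc,
        })
        if val_acc > best_acc:
            best_acc, best_epoch = val_acc, epoch
            best_state = model.state_dict()
        if opt_cfg.early_stop_acc is not None and val_acc >= opt_cfg.early_stop_acc:
            break
    model.load_state_dict(best_state)
    model.eval()
    return TrainResult(history, best_state, best_acc, best_epoch)


# -- checkpoints -------------------------------------------------------------


def save_checkpoint(model: MoEClassifier, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    with open(path, "wb") as fh:  # file handle: keep the exact filename
        np.savez(fh, __config__=np.frombuffer(
            json.dumps(asdict(model.cfg)).encode(), dtype=np.uint8
        ), **state)


def load_checkpoint(path: str | Path) -> MoEClassifier:
    path = Path(path)
    if not path.exists():
        raise InputError(f"checkpoint {path} does not exist")
    data = np.load(path, allow_pickle=False)
    cfg_dict = json.loads(bytes(data["__config__"]).decode())
    cfg_dict["gamma_aux"] = tuple(cfg_dict["gamma_aux"])
    model = build_model(ModelConfig(**cfg_dict))
    model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    model.eval()
    return model


# -- evaluation --------------------------------------------------------------


@dataclass
class ClassificationReport:
    """Per-class precision/recall/F1 (percent, full precision), supports,
    overall accuracy and macro/weighted averages, all derived from the
    confusion matrix (rows = true class, columns = predicted)."""

    classes: tuple[str, ...]
    confusion: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    accuracy: float
    macro_avg: tuple[float, float, float]
    weighted_avg: tuple[float, float, float]

    def to_table(self) -> str:
        lines = [f"{'Class':<16}{'Precision (%)':>14}{'Recall (%)':>12}"
                 f"{'F1-Score (%)':>14}{'Support':>9}"]
        for i, c in enumerate(self.classes):
            lines.append(f"{c:<16}{self.precision[i]:>14.0f}"
                         f"{self.recall[i]:>12.0f}{self.f1[i]:>14.0f}"
                         f"{self.support[i]:>9d}")
        n = int(self.support.sum())
        lines.append(f"{'Accuracy':<16}{'':>14}{'':>12}"
                     f"{self.accuracy:>14.0f}{n:>9d}")
        lines.append(f"{'Macro Avg':<16}{self.macro_avg[0]:>14.0f}"
                     f"{self.macro_avg[1]:>12.0f}{self.macro_avg[2]:>14.0f}{n:>9d}")
        lines.append(f"{'Weighted Avg':<16}{self.weighted_avg[0]:>14.0f}"
                     f"{self.weighted_avg[1]:>12.0f}{self.weighted_avg[2]:>14.0f}{n:>9d}")
        return "\n".join(lines)


def report_from_predictions(y_true: np.ndarray, y_pred: np.ndarray,
                            classes: tuple[str, ...]) -> ClassificationReport:
    labels = np.arange(len(classes))
    cm = sk_confusion_matrix(y_true, y_pred, labels=labels)
    support = cm.sum(axis=1)
    pred_tot = cm.sum(axis=0)
    tp = np.diag(cm).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred_tot > 0, tp / pred_tot, 0.0) * 100
        recall = np.where(support > 0, tp / support, 0.0) * 100
        f1 = np.where(precision + recall > 0,
                      2 * precision * recall / (precision + recall), 0.0)
    accuracy = tp.sum() / cm.sum() * 100
    w = support / support.sum()
    return ClassificationReport(
        classes=classes,
        confusion=cm,
        precision=precision,
        recall=recall,
        f1=f1,
        support=support,
        accuracy=float(accuracy),
        macro_avg=(float(precision.mean()), float(recall.mean()), float(f1.mean())),
        weighted_avg=(float(precision @ w), float(recall @ w), float(f1 @ w)),
    )


def evaluate(model: MoEClassifier, dataset: LabeledImageSet) -> ClassificationReport:
    """Classify with the final head (auxiliary heads are ignored) and build
    the report from the confusion matrix."""
    if len(dataset) == 0:
        raise InputError("cannot evaluate an empty dataset")
    preds = model.predict(dataset.images)
    return report_from_predictions(dataset.labels, preds, dataset.classes)


# -- explainability ----------------------------------------------------------


def collect_diagnostics(model: MoEClassifier, images: np.ndarray,
                        batch_size: int = 32):
    """Eval-mode forward over a dataset, accumulating per-stage routing
    traces and per-stage mean spatial attention gates (over experts)."""
    model.eval()
    n_stages = model.cfg.num_stages
    traces: list[list[StageTrace]] = [[] for _ in range(n_stages)]
    gates: list[list[np.ndarray]] = [[] for _ in range(n_stages)]
    for i in range(0, len(images), batch_size):
        out = model(images[i : i + batch_size])
        for s in range(n_stages):
            traces[s].append(out.stage_traces[s])
            maps = [m.spatial_gate for m in out.attention[s] if m is not None]
            if maps:
                gates[s].append(np.mean(maps, axis=0))  # (B, h, w)
    merged = [merge_traces(ts) for ts in traces]
    gate_arrays = [np.concatenate(g, axis=0) if g else None for g in gates]
    return merged, gate_arrays


def attention_mask_stats(gate_maps: np.ndarray, masks: np.ndarray) -> dict:
    """Compare upsampled attention inside vs outside lesion masks.

    Returns per-image mean attention inside/outside and the fraction of
    lesion-bearing images whose inside mean exceeds the outside mean.
    """
    size = masks.shape[1]
    inside, outside = [], []
    for gate, mask in zip(gate_maps, masks):
        if not mask.any() or mask.all():
            inside.append(np.nan)
            outside.append(np.nan)
            continue
        up = sk_resize(gate, (size, size), order=1, mode="edge",
                       anti_aliasing=False, preserve_range=True)
        inside.append(float(up[mask].mean()))
        outside.append(float(up[~mask].mean()))
    inside = np.array(inside)
    outside = np.array(outside)
    valid = ~np.isnan(inside)
    frac = float((inside[valid] > outside[valid]).mean()) if valid.any() else np.nan
    return {
        "inside_mean": inside,
        "outside_mean": outside,
        "fraction_inside_higher": frac,
        "n_lesion_images": int(valid.sum()),
    }


def explain(model: MoEClassifier, dataset: LabeledImageSet,
            out_dir: str | Path, n_pattern_samples: int = 20,
            n_overlays: int = 8) -> dict:
    """Write utilization CSVs, routing-pattern CSVs, attention overlay PNGs
    and (when masks exist) attention-vs-mask statistics."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    traces, gate_arrays = collect_diagnostics(model, dataset.images)
    results: dict = {"utilization": {}, "attention": {}}
    for trace, gates in zip(traces, gate_arrays):
        s = trace.stage_index
        util = expert_utilization(trace)
        results["utilization"][s] = util
        header = ",".join(f"expert_{j + 1}" for j in range(trace.n_experts))
        np.savetxt(out / f"utilization_stage{s}.csv", util[None, :],
                   delimiter=",", header=f"stage {s}: {header}", comments="")
        k = min(n_pattern_samples, trace.weights.shape[0])
        np.savetxt(out / f"routing_stage{s}.csv",
                   routing_pattern_matrix(trace, k), delimiter=",",
                   header=f"stage {s}: {header}", comments="")
        if gates is not None and dataset.masks.any():
            stats = attention_mask_stats(gates, dataset.masks)
            results["attention"][s] = stats
    _write_overlays(model, dataset, gate_arrays, out, n_overlays)
    if results["attention"]:
        last = max(results["attention"])
        stats = results["attention"][last]
        with open(out / "attention_mask_stats.csv", "w") as fh:
            fh.write("stage,fraction_inside_higher,n_lesion_images\n")
            for s, st in sorted(results["attention"].items()):
                fh.write(f"{s},{st['fraction_inside_higher']:.6f},"
                         f"{st['n_lesion_images']}\n")
    return results


def _write_overlays(model, dataset, gate_arrays, out: Path, n_overlays: int):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = min(n_overlays, len(dataset))
    final = [g for g in gate_arrays if g is not None]
    if not final:
        return
    n_stages = len(final)
    fig, axes = plt.subplots(n, n_stages + 1,
                             figsize=(2.2 * (n_stages + 1), 2.2 * n),
                             squeeze=False)
    size = dataset.images.shape[1]
    for i in range(n):
        axes[i][0].imshow(dataset.images[i])
        axes[i][0].set_title(dataset.classes[dataset.labels[i]], fontsize=8)
        for s, gates in enumerate(final):
            up = sk_resize(gates[i], (size, size), order=1, mode="edge",
                           anti_aliasing=False, preserve_range=True)
            axes[i][s + 1].imshow(dataset.images[i])
            axes[i][s + 1].imshow(up, cmap="jet", alpha=0.45,
                                  vmin=0.0, vmax=1.0)
            axes[i][s + 1].set_title(f"stage {s + 1}", fontsize=8)
    for ax in fig.axes:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(out / "attention_overlays.png", dpi=100)
    plt.close(fig)


# -- tuning ------------------------------------------------------------------


def tune(space: tpe_mod.SearchSpace, budget: int, train_set: LabeledImageSet,
         val_set: LabeledImageSet, base_model_cfg: ModelConfig,
         tpe_cfg: tpe_mod.TPEConfig | None = None, epochs_per_trial: int = 3,
         out_dir: str | Path | None = None) -> tuple[dict, float, list]:
    """Hyperparameter search: each trial trains a fresh model briefly and
    reports the best validation loss; delegates the search to
    :func:`endomoe.tpe.optimize`."""
    tpe_cfg = tpe_cfg or tpe_mod.TPEConfig()

    def objective(config: dict) -> float:
        cfg_kwargs = asdict(base_model_cfg)
        cfg_kwargs["gamma_aux"] = tuple(cfg_kwargs["gamma_aux"])
        if "dropout_rate" in config:
            cfg_kwargs["dropout_rate"] = config["dropout_rate"]
        if "gamma_aux" in config:
            n_aux = base_model_cfg.num_stages - 1
            cfg_kwargs["gamma_aux"] = (config["gamma_aux"],) * n_aux
        model = build_model(ModelConfig(**cfg_kwargs))
        opt = OptimizerConfig(
            learning_rate=config.get("learning_rate", 1e-3),
            batch_size=int(config.get("batch_size", 16)),
            epochs=epochs_per_trial,
            seed=tpe_cfg.seed,
        )
        result = train(model, train_set, val_set, opt)
        return min(h["val_loss"] for h in result.history)

    best_config, best_value, history = tpe_mod.optimize(
        objective, space, tpe_cfg, budget
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "trials.jsonl", "w") as fh:
            for t in history:
                fh.write(json.dumps({
                    "index": t.index, "config": t.config,
                    "value": None if t.failed else t.value,
                    "failed": t.failed,
                }) + "\n")
        import yaml

        (out / "incumbent.yaml").write_text(
            yaml.safe_dump({"best_value": best_value, "config": best_config})
        )
    return best_config, best_value, history
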