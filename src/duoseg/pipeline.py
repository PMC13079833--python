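"""Training loop, checkpoints, inference and evaluation.

Training uses AdamW (lr 3e-4, weight decay 1e-5 by default), batch sizes 8
(train) / 1 (validation), the joint dual-branch BCE+Dice objective, and one
master seed from which every randomness stream (weight init, shuffling,
noise injection, repeat runs) is derived.  Checkpoints are ``.npz`` files
carrying the weights, the configs, the seed and a content hash of the weight
bytes.  No learning-rate schedule is applied (constant lr); the step budget
is part of the config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import load_manifest, load_pair, one_hot, resize_pair
from .errors import ConfigurationError
from .losses import bce_dice_loss, joint_loss
from .metrics import evaluate_case
from .model import DualDecoderNet, ModelConfig, build_model, predict_labels
from .nn import AdamW, derive_seed
from .phantoms import add_gaussian_noise

__all__ = [
    "TrainConfig",
    "TrainResult",
    "train",
    "save_checkpoint",
    "load_checkpoint",
    "evaluate",
    "noise_sweep",
    "samples_from_manifest",
]


@dataclass(frozen=True)
class TrainConfig:
    """Hyper-parameters of a training run (defaults are the standard recipe)."""

    encoder_variant: str = "b2"
    num_classes: int = 7
    image_size: int = 256
    learning_rate: float = 3e-4
    weight_decay: float = 1e-5
    batch_size: int = 8
    val_batch_size: int = 1
    max_steps: int = 300
    seed: int = 0
    use_cafe_branch: bool = True
    use_gglf_branch: bool = True
    use_multiplicative_term: bool = True
    fusion_width: int = 64
    guide_width: int = 64
    attention_reduction: int = 16
    encoder_weights: str | None = None
    checkpoint_dir: str | None = None
    val_interval: int = 100
    repeats: int = 1

    def __post_init__(self):
        if self.learning_rate < 0 or self.weight_decay < 0:
            raise ConfigurationError("learning rate and weight decay must be >= 0")
        if self.num_classes < 2:
            raise ConfigurationError("num_classes must be >= 2")
        if min(self.batch_size, self.val_batch_size) < 1:
            raise ConfigurationError("batch sizes must be >= 1")
        if self.image_size % 32:
            raise ConfigurationError("image_size must be divisible by 32")
        if self.max_steps < 1 or self.repeats < 1:
            raise ConfigurationError("max_steps and repeats must be >= 1")

    def model_config(self) -> ModelConfig:
        return ModelConfig(
            encoder_variant=self.encoder_variant,
            num_classes=self.num_classes,
            use_context_branch=self.use_cafe_branch,
            use_guided_branch=self.use_gglf_branch,
            fusion_width=self.fusion_width,
            guide_width=self.guide_width,
            attention_reduction=self.attention_reduction,
            encoder_weights=self.encoder_weights,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "TrainConfig":
        return TrainConfig(**d)


@dataclass
class TrainResult:
    model: DualDecoderNet
    log: pd.DataFrame  # one row per step with the loss terms
    best_val_dice: float
    checkpoint_path: str | None


def samples_from_manifest(
    manifest: str | Path | pd.DataFrame,
    base_dir: str | Path | None = None,
    split: str | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Load (image, labels) pairs referenced by a manifest."""
    if isinstance(manifest, (str, Path)):
        base_dir = Path(manifest).parent if base_dir is None else Path(base_dir)
        manifest = load_manifest(manifest)
    elif base_dir is None:
        raise ConfigurationError("base_dir is required with an in-memory manifest")
    rows = manifest if split is None else manifest[manifest["split"] == split]
    return [
        load_pair(Path(base_dir) / r["image"], Path(base_dir) / r["label"])
        for _, r in rows.iterrows()
    ]


def _prepare(samples, config: TrainConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resize, stack, one-hot encode: images (N,H,W), labels, targets (N,K,H,W)."""
    imgs, labs, targets = [], [], []
    for image, labels in samples:
        if image.shape != (config.image_size, config.image_size):
            image, labels = resize_pair(image, labels, config.image_size)
        imgs.append(np.asarray(image, dtype=np.float32))
        labs.append(np.asarray(labels))
        targets.append(one_hot(labels, config.num_classes))
    return np.stack(imgs), np.stack(labs), np.stack(targets)


def _step_loss(model: DualDecoderNet, images, targets, config: TrainConfig):
    out = model(images)
    if out.p1 is not None and out.p2 is not None:
        terms = joint_loss(out.p1, out.p2, targets,
                           use_multiplicative=config.use_multiplicative_term)
        return terms.total, terms.as_floats()
    logits = out.p1 if out.p1 is not None else out.p2
    loss = bce_dice_loss(logits.sigmoid(), targets)
    key = "loss_p1" if out.p1 is not None else "loss_p2"
    zeros = {"loss_p1": 0.0, "loss_p2": 0.0, "loss_mul": 0.0}
    zeros[key] = float(loss.data)
    return loss, {**zeros, "total": float(loss.data)}


def _mean_val_dice(model, images, labels, num_classes: int, batch: int) -> float:
    dices = []
    for i in range(0, len(images), batch):
        pred = predict_labels(model, images[i : i + batch])
        for p, g in zip(pred, labels[i : i + batch]):
            dices.append(evaluate_case(p, g, num_classes).mean_dice)
    vals = [d for d in dices if not np.isnan(d)]
    return float(np.mean(vals)) if vals else float("nan")


def train(
    config: TrainConfig,
    train_samples,
    val_samples=None,
) -> TrainResult:
    """Train the network on (image, labels) pairs.

    ``train_samples``/``val_samples`` are lists of pairs or a manifest path
    (in which case the manifest's train/val splits are used).  Returns the
    trained model, the per-step loss log, and the best validation Dice; the
    checkpoint kept is the best-by-validation-Dice state (falling back to
    the final state when no validation set is given).
    """
    if isinstance(train_samples, (str, Path)):
        manifest = train_samples
        train_samples = samples_from_manifest(manifest, split="train")
        if val_samples is None:
            val_samples = samples_from_manifest(manifest, split="val")
    if not train_samples:
        raise ConfigurationError("empty training set")
    if config.repeats > 1:
        results = []
        for r in range(config.repeats):
            sub = dataclasses.replace(
                config, repeats=1, seed=derive_seed(config.seed, "repeat", r)
            )
            results.append(train(sub, train_samples, val_samples))
        dices = [res.best_val_dice for res in results]
        best = results[int(np.nanargmax(dices))]
        return TrainResult(
            model=best.model,
            log=pd.concat([r.log for r in results], keys=range(len(results))),
            best_val_dice=float(np.nanmean(dices)),
            checkpoint_path=best.checkpoint_path,
        )

    images, labels, targets = _prepare(train_samples, config)
    val = _prepare(val_samples, config) if val_samples else None
    model = build_model(config.model_config(), seed=derive_seed(config.seed, "init"))
    optim = AdamW(
        model.parameters(),
        lr=config.learning_rate,
        weight_decay=config.weight_decay,
    )
    shuffle_rng = np.random.default_rng(derive_seed(config.seed, "shuffle"))
    n = len(images)
    order: list[int] = []
    rows = []
    best_dice, best_state = -np.inf, None

    for step in range(1, config.max_steps + 1):
        while len(order) < config.batch_size:
            order.extend(shuffle_rng.permutation(n).tolist())
        idx = [order.pop(0) for _ in range(config.batch_size)]
        model.train()
        loss, terms = _step_loss(model, images[idx], targets[idx], config)
        if not np.isfinite(loss.data):
            raise RuntimeError(
                f"non-finite loss at step {step}: {terms}; aborting training"
            )
        optim.zero_grad()
        loss.backward()
        optim.step()
        rows.append({"step": step, **terms})
        if val is not None and (step % config.val_interval == 0 or step == config.max_steps):
            vd = _mean_val_dice(model, val[0], val[1], config.num_classes,
                                config.val_batch_size)
            rows[-1]["val_dice"] = vd
            if vd > best_dice:
                best_dice, best_state = vd, model.state_dict()

    if best_state is not None:
        model.load_state_dict(best_state)
    else:
        best_dice = float("nan")
    log = pd.DataFrame(rows)
    ckpt_path = None
    if config.checkpoint_dir:
        out = Path(config.checkpoint_dir)
        out.mkdir(parents=True, exist_ok=True)
        ckpt_path = str(out / "checkpoint.npz")
        save_checkpoint(model, config, ckpt_path)
        log.to_csv(out / "train_log.tsv", sep="\t", index=False)
    return TrainResult(model=model, log=log, best_val_dice=float(best_dice),
                       checkpoint_path=ckpt_path)


def _weights_hash(state: dict[str, np.ndarray]) -> str:
    h = hashlib.sha256()
    for key in sorted(state):
        h.update(key.encode())
        h.update(np.ascontiguousarray(state[key]).tobytes())
    return h.hexdigest()[:16]


def save_checkpoint(model: DualDecoderNet, config: TrainConfig, path: str | Path) -> None:
    state = model.state_dict()
    meta = json.dumps(
        {
            "train_config": config.to_dict(),
            "model_config": dataclasses.asdict(model.config),
            "seed": config.seed,
            "weights_hash": _weights_hash(state),
        }
    )
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **state)


def load_checkpoint(path: str | Path) -> tuple[DualDecoderNet, TrainConfig]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    config = TrainConfig.from_dict(meta["train_config"])
    model = build_model(ModelConfig(**meta["model_config"]), seed=meta["seed"])
    model.load_state_dict(state)
    if _weights_hash(model.state_dict()) != meta["weights_hash"]:
        raise ValueError(f"checkpoint {path} failed its content-hash check")
    return model, config


def evaluate(
    model: DualDecoderNet,
    samples,
    config: TrainConfig,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-case metrics and a summary row for a labelled sample list.

    ``noise_sigma > 0`` adds seeded Gaussian noise to every image before
    prediction (robustness protocol).  Means are over foreground classes;
    classes absent from both maps are excluded, not counted as zero.
    """
    images, labels, _ = _prepare(samples, config)
    rows = []
    for i in range(len(images)):
        img = images[i]
        if noise_sigma > 0:
            img = add_gaussian_noise(img, noise_sigma, derive_seed(seed, "noise", i))
        pred = predict_labels(model, img[None])[0]
        cm = evaluate_case(pred, labels[i], config.num_classes)
        row = {"case": i, "noise_sigma": noise_sigma, "mean_dice": cm.mean_dice,
               "mean_hd": cm.mean_hausdorff, "mean_hd95": cm.mean_hausdorff95}
        for k in range(1, config.num_classes):
            row[f"dice_{k}"] = cm.dice[k - 1]
            row[f"hd_{k}"] = cm.hausdorff[k - 1]
            row[f"hd95_{k}"] = cm.hausdorff95[k - 1]
        rows.append(row)
    per_case = pd.DataFrame(rows)
    summary = (
        per_case.drop(columns=["case", "noise_sigma"]).mean(numeric_only=True).to_frame().T
    )
    summary.insert(0, "noise_sigma", noise_sigma)
    return per_case, summary


def noise_sweep(
    model: DualDecoderNet,
    samples,
    config: TrainConfig,
    sigmas: tuple[float, ...] = (0.05, 0.1, 0.2),
    seed: int = 0,
) -> pd.DataFrame:
    """Robustness protocol: evaluate at several Gaussian noise levels.

    Returns one summary row per noise level (plus the clean baseline at
    sigma 0 first).
    """
    summaries = []
    for s in (0.0, *sigmas):
        _, summary = evaluate(model, samples, config, noise_sigma=s, seed=seed)
        summaries.append(summary)
    return pd.concat(summaries, ignore_index=True)
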