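"""The feature-merging CNN, its decision rules, and the training protocol.

The network sends the spectrogram image through a CNN backbone, squashes the
pooled backbone features through an elementwise sigmoid so they live in [0, 1]
like the min–max-scaled handcrafted features, concatenates both vectors
(feature merging), applies dropout, and ends in a single fully connected unit
with a sigmoid output.  A score ``x`` is labeled abnormal iff ``x > 0.5``
(the 0.5 boundary itself is *normal*), while the two-lead fused score
``y = y1 + y2 - 0.5`` is labeled abnormal iff ``y >= 0.5`` — the boundary
conventions of the two rules differ and both are kept exactly as defined.

Training uses plain SGD on binary cross-entropy with step learning-rate decay
(initial rate 0.1 halved every ``decay_every`` epochs), an inner 80/20
train/validation split, and early stopping when validation accuracy drops in
two consecutive epochs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn

__all__ = ["ModelConfig", "Prediction", "FusedPrediction", "MergedModel",
           "build_model", "classify", "fuse_leads", "train",
           "save_checkpoint", "load_checkpoint", "BACKBONES"]

#: VGG channel plans ('M' = 2x2 max pool).
_VGG_PLANS = {
    "vgg16": [64, 64, "M", 128, 128, "M", 256, 256, 256, "M",
              512, 512, 512, "M", 512, 512, 512, "M"],
    "vgg19": [64, 64, "M", 128, 128, "M", 256, 256, 256, 256, "M",
              512, 512, 512, 512, "M", 512, 512, 512, 512, "M"],
}
#: ResNet basic-block counts per stage.
_RESNET_PLANS = {"resnet18": [2, 2, 2, 2], "resnet34": [3, 4, 6, 3]}

BACKBONES = ("tiny-test", "vgg16", "vgg19", "resnet18", "resnet34")


@dataclass
class ModelConfig:
    backbone: str = "tiny-test"
    input_mode: str = "gray"            # "gray" (1 channel) or "rgb" (3)
    n_handcrafted: int = 9              # 9 for rhythm models, 11 for heartbeat
    input_hw: tuple[int, int] = (32, 32)
    dropout_rate: float = 0.5
    lr_init: float = 0.1
    lr_decay: float = 0.5
    decay_every: int = 10
    early_stop_patience: int = 2        # consecutive validation-accuracy drops
    batch_size: int = 32
    max_epochs: int = 30
    val_frac: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backbone not in BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}; choose from {BACKBONES}")
        if self.input_mode not in ("gray", "rgb"):
            raise ValueError("input_mode must be 'gray' or 'rgb'")
        if self.lr_init <= 0 or not 0 < self.lr_decay < 1:
            raise ValueError("need lr_init > 0 and 0 < lr_decay < 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        self.input_hw = tuple(self.input_hw)


@dataclass
class Prediction:
    score: float
    label: int


@dataclass
class FusedPrediction:
    y1: float
    y2: float
    y: float
    label: int


def _tiny_backbone(cin: int, rng) -> tuple[nn.Sequential, int]:
    return nn.Sequential(
        nn.Conv2d(cin, 8, 3, pad=1, rng=rng), nn.ReLU(), nn.MaxPool2d(2),
        nn.Conv2d(8, 16, 3, pad=1, rng=rng), nn.ReLU(), nn.MaxPool2d(2),
        nn.GlobalAvgPool(),
    ), 16


def _vgg_backbone(plan, cin: int, rng) -> tuple[nn.Sequential, int]:
    layers: list[nn.Layer] = []
    c = cin
    for item in plan:
        if item == "M":
            layers.append(nn.MaxPool2d(2))
        else:
            layers += [nn.Conv2d(c, item, 3, pad=1, rng=rng), nn.ReLU()]
            c = item
    layers.append(nn.GlobalAvgPool())
    return nn.Sequential(*layers), 512


def _basic_block(cin: int, cout: int, stride: int, rng) -> nn.ResidualBlock:
    main = nn.Sequential(
        nn.Conv2d(cin, cout, 3, stride=stride, pad=1, rng=rng, bias=False),
        nn.BatchNorm2d(cout), nn.ReLU(),
        nn.Conv2d(cout, cout, 3, pad=1, rng=rng, bias=False),
        nn.BatchNorm2d(cout),
    )
    shortcut = None
    if stride != 1 or cin != cout:
        shortcut = nn.Sequential(
            nn.Conv2d(cin, cout, 1, stride=stride, pad=0, rng=rng, bias=False),
            nn.BatchNorm2d(cout),
        )
    return nn.ResidualBlock(main, shortcut)


def _resnet_backbone(blocks, cin: int, rng) -> tuple[nn.Sequential, int]:
    layers: list[nn.Layer] = [
        nn.Conv2d(cin, 64, 7, stride=2, pad=3, rng=rng, bias=False),
        nn.BatchNorm2d(64), nn.ReLU(), nn.MaxPool2d(3, stride=2, pad=1),
    ]
    c = 64
    for stage, n_blocks in enumerate(blocks):
        cout = 64 * 2**stage
        for b in range(n_blocks):
            stride = 2 if stage > 0 and b == 0 else 1
            layers.append(_basic_block(c, cout, stride, rng))
            c = cout
    layers.append(nn.GlobalAvgPool())
    return nn.Sequential(*layers), 512


class MergedModel:
    """Backbone + sigmoid normalization + feature merging + dense sigmoid head."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        cin = 1 if config.input_mode == "gray" else 3
        if config.backbone == "tiny-test":
            self.backbone, self.backbone_dim = _tiny_backbone(cin, rng)
        elif config.backbone in _VGG_PLANS:
            self.backbone, self.backbone_dim = _vgg_backbone(_VGG_PLANS[config.backbone], cin, rng)
        else:
            self.backbone, self.backbone_dim = _resnet_backbone(
                _RESNET_PLANS[config.backbone], cin, rng)
        self.cnn_sigmoid = nn.Sigmoid()
        self.merged_dim = self.backbone_dim + config.n_handcrafted
        self.dropout = nn.Dropout(config.dropout_rate, rng=np.random.default_rng(config.seed + 1))
        self.head = nn.Dense(self.merged_dim, 1, rng=rng)
        self.out_sigmoid = nn.Sigmoid()

    def forward(self, images: np.ndarray, feats: np.ndarray, train: bool = False) -> np.ndarray:
        """Scores in [0, 1]; ``images`` is (B, C, H, W), ``feats`` (B, n_handcrafted)."""
        images = np.asarray(images, dtype=float)
        feats = np.atleast_2d(np.asarray(feats, dtype=float))
        cnn = self.cnn_sigmoid.forward(self.backbone.forward(images, train), train)
        merged = np.concatenate([cnn, feats], axis=1)
        self._split = cnn.shape[1]
        z = self.head.forward(self.dropout.forward(merged, train), train)
        return self.out_sigmoid.forward(z, train)[:, 0]

    def backward(self, grad_scores: np.ndarray) -> None:
        grad = self.out_sigmoid.backward(grad_scores[:, None])
        grad = self.dropout.backward(self.head.backward(grad))
        grad_cnn = grad[:, : self._split]
        self.backbone.backward(self.cnn_sigmoid.backward(grad_cnn))

    def params(self) -> list[dict]:
        return self.backbone.params() + self.head.params()

    def predict(self, images, feats) -> list[Prediction]:
        scores = self.forward(images, feats, train=False)
        return [Prediction(float(s), classify(float(s))) for s in scores]


def build_model(config: ModelConfig) -> MergedModel:
    """Construct the feature-merging network for the given configuration."""
    return MergedModel(config)


def classify(x: float) -> int:
    """Single-model decision rule: normal (0) iff ``x <= 0.5``."""
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"score {x} outside [0, 1]")
    return 0 if x <= 0.5 else 1


def fuse_leads(y1: float, y2: float) -> FusedPrediction:
    """Two-lead fusion: ``y = y1 + y2 - 0.5``, abnormal iff ``y >= 0.5``.

    A single confident lead can dominate the decision.  Note the boundary is
    *abnormal* here, unlike the single-model rule.
    """
    for v in (y1, y2):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"lead score {v} outside [0, 1]")
    y = y1 + y2 - 0.5
    return FusedPrediction(y1=y1, y2=y2, y=y, label=1 if y >= 0.5 else 0)


def lr_at_epoch(config: ModelConfig, epoch: int) -> float:
    """Step-decay schedule; ``epoch`` is 1-based.  Epochs 1..decay_every run at
    ``lr_init``, the next block at ``lr_init * lr_decay``, and so on."""
    return config.lr_init * config.lr_decay ** ((epoch - 1) // config.decay_every)


def should_stop(val_accuracies: list[float], patience: int = 2) -> bool:
    """Early-stopping rule: stop once validation accuracy has strictly
    decreased in ``patience`` consecutive epochs."""
    drops = 0
    for prev, cur in zip(val_accuracies[:-1], val_accuracies[1:]):
        drops = drops + 1 if cur < prev else 0
    return drops >= patience


def train(model: MergedModel, images: np.ndarray, feats: np.ndarray,
          labels: np.ndarray, config: ModelConfig | None = None) -> dict:
    """Train in place; returns a history dict.

    The training set is split 80/20 into an inner train/validation pair
    (seeded); each epoch shuffles the inner training set, runs SGD on binary
    cross-entropy at the scheduled learning rate, then measures validation
    accuracy for the early-stopping rule.
    """
    config = config or model.config
    images = np.asarray(images, dtype=float)
    feats = np.atleast_2d(np.asarray(feats, dtype=float))
    labels = np.asarray(labels, dtype=float)
    n = len(labels)
    if n == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(n)
    n_val = max(1, int(round(config.val_frac * n))) if n > 1 else 0
    val_idx, tr_idx = order[:n_val], order[n_val:]
    if len(tr_idx) == 0:
        tr_idx, val_idx = order, order[:0]

    history = {"loss": [], "train_acc": [], "val_acc": [], "lr": []}
    for epoch in range(1, config.max_epochs + 1):
        lr = lr_at_epoch(config, epoch)
        perm = rng.permutation(len(tr_idx))
        epoch_loss = 0.0
        for start in range(0, len(tr_idx), config.batch_size):
            idx = tr_idx[perm[start : start + config.batch_size]]
            scores = model.forward(images[idx], feats[idx], train=True)
            loss, grad = nn.bce_loss(scores, labels[idx])
            model.backward(grad)
            nn.sgd_step(model.params(), lr)
            epoch_loss += loss * len(idx)
        history["loss"].append(epoch_loss / len(tr_idx))
        tr_scores = model.forward(images[tr_idx], feats[tr_idx], train=False)
        history["train_acc"].append(
            float(np.mean((tr_scores > 0.5) == (labels[tr_idx] > 0.5))))
        history["lr"].append(lr)
        if len(val_idx):
            val_scores = model.forward(images[val_idx], feats[val_idx], train=False)
            val_acc = float(np.mean((val_scores > 0.5) == (labels[val_idx] > 0.5)))
        else:
            val_acc = history["train_acc"][-1]
        history["val_acc"].append(val_acc)
        if should_stop(history["val_acc"], config.early_stop_patience):
            history["stopped_early"] = True
            break
    history.setdefault("stopped_early", False)
    history["epochs_run"] = len(history["loss"])
    return history


# ---------------------------------------------------------------------------
# checkpoints: single JSON file with a versioned header


def save_checkpoint(model: MergedModel, path: str | Path,
                    scaler_json: str | None = None,
                    feature_names: tuple[str, ...] | None = None) -> Path:
    path = Path(path)
    payload = {
        "format": "ecgfusion-checkpoint-v1",
        "config": asdict(model.config),
        "feature_names": list(feature_names) if feature_names else None,
        "scaler": scaler_json,
        "weights": [p["value"].tolist() for p in _all_state(model)],
    }
    path.write_text(json.dumps(payload))
    return path


def load_checkpoint(path: str | Path) -> tuple[MergedModel, dict]:
    """Rebuild a model from a checkpoint; returns (model, metadata)."""
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "ecgfusion-checkpoint-v1":
        raise ValueError(f"not an ecgfusion checkpoint: {path}")
    cfg = payload["config"]
    cfg["input_hw"] = tuple(cfg["input_hw"])
    model = MergedModel(ModelConfig(**cfg))
    state = _all_state(model)
    if len(state) != len(payload["weights"]):
        raise ValueError("checkpoint weight count mismatch")
    for p, w in zip(state, payload["weights"]):
        arr = np.asarray(w, dtype=float)
        if arr.shape != p["value"].shape:
            raise ValueError("checkpoint weight shape mismatch")
        p["value"][...] = arr
    meta = {"feature_names": payload.get("feature_names"),
            "scaler": payload.get("scaler")}
    return model, meta


def _all_state(model: MergedModel) -> list[dict]:
    """Trainable params plus batch-norm running statistics."""
    state = list(model.params())
    for layer in _walk(model.backbone):
        if isinstance(layer, nn.BatchNorm2d):
            state.append({"value": layer.run_mean, "grad": None})
            state.append({"value": layer.run_var, "grad": None})
    return state


def _walk(layer):
    yield layer
    if isinstance(layer, nn.Sequential):
        for sub in layer.layers:
            yield from _walk(sub)
    elif isinstance(layer, nn.ResidualBlock):
        yield from _walk(layer.main)
        if layer.shortcut:
            yield from _walk(layer.shortcut)
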