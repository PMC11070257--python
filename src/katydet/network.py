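"""Compact quasi-DenseNet classifier and its training recipe.

The classifier maps 204 x 319 log-PSD spectrograms to 32 per-class sigmoid
scores. A 3x3/32-filter pre-convolution feeds five dense-style blocks (two
composite layers per block, growth rate 32). Each composite layer is
BN -> ReLU -> 1x1 conv (bottleneck, 4 x growth = 128 filters) -> BN -> ReLU ->
3x3 conv (growth filters), its output concatenated onto the block's running
feature stack. Transitions between blocks are BN -> ReLU -> 1x1 conv with
channel compression 0.4 -> 3x3/stride-3 ceil-mode average pooling, taking the
spatial dims 204x319 -> 68x107 -> 23x36 -> 8x12 -> 3x4. The head is global
average pooling, dropout (0.05), a 64-node dense layer, batch norm, ReLU and
a 32-node sigmoid output. The bottleneck width, compression factor and
biased convolutions were calibrated so the default configuration has 476k
total and 471k trainable parameters (the difference being batch-norm moving
statistics).

Training follows a fixed recipe: 90/10 train/validation split, inverse-
frequency class weighting of a per-class binary cross-entropy, dropout 0.05,
Adam at initial learning rate 0.01 dropped x0.1 at epochs 20/40/50, 60
epochs, mini-batches of 32, augmentations applied on the fly each epoch.
All randomness (weight init, split, shuffling, dropout, augmentation draws)
derives from a single integer seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.base import BaseEstimator

from katydet import _autodiff as ad
from katydet._autodiff import Var
from katydet.augment import AugmentChain, build_chain
from katydet.frontend import MODEL_INPUT_SHAPE, to_model_input
from katydet.signals import Segment

__all__ = [
    "ArchitectureConfig",
    "TrainingSchedule",
    "QuasiDenseNet",
    "build_model",
    "train",
    "replicate_train",
    "class_weights",
    "SpectrogramClassifier",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ArchitectureConfig:
    """Structural hyperparameters of the quasi-DenseNet.

    The defaults are the deployed configuration (204x319 inputs, 32
    classes). ``bottleneck_factor`` multiplies the growth rate to give the
    1x1 bottleneck width; ``compression`` scales channel counts at
    transitions (floored). ``pre_pool`` optionally inserts an average pool
    on the input ahead of the pre-convolution (``(3, 1)`` pools frequency
    only, preserving the 2.5 ms time resolution that carries inter-pulse
    intervals) — used by reduced desk-scale configurations, never by the
    default. ``input_offset_db``/``input_scale`` apply a fixed affine map to
    the dB-full-scale input (default maps [-100, 0] onto [0, ~1.4]); the
    constants are architecture-level, identical for every input, and carry
    no learnable parameters.
    """

    input_shape: tuple[int, int] = MODEL_INPUT_SHAPE
    pre_conv_filters: int = 32
    num_blocks: int = 5
    layers_per_block: int = 2
    growth_rate: int = 32
    bottleneck_factor: int = 4
    compression: float = 0.4
    transition_pool: int = 3
    head_width: int = 64
    num_classes: int = 32
    dropout_rate: float = 0.05
    pre_pool: tuple[int, int] | None = None
    input_offset_db: float = 100.0
    input_scale: float = 1.0 / 70.0


@dataclass(frozen=True)
class TrainingSchedule:
    """Optimization schedule; defaults follow the deployed recipe."""

    epochs: int = 60
    batch_size: int = 32
    initial_lr: float = 0.01
    lr_drop_epochs: tuple[int, ...] = (20, 40, 50)
    lr_drop_factor: float = 0.1
    validation_fraction: float = 0.10
    clip_norm: float | None = None
    seed: int = 0

    def lr_at(self, epoch: int) -> float:
        """Learning rate in force during a (0-based) epoch."""
        drops = sum(1 for e in self.lr_drop_epochs if epoch >= e)
        return self.initial_lr * self.lr_drop_factor ** drops


def _ceil_div(a: int, b: int) -> int:
    return -(-a // b)


class QuasiDenseNet:
    """Numpy implementation of the quasi-DenseNet (forward, backward, counts)."""

    def __init__(self, config: ArchitectureConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.params: list[Var] = []
        self._bn_state: list[tuple[np.ndarray, np.ndarray]] = []
        self._dropout_rng = np.random.default_rng(rng.integers(2**31))

        c = config.pre_conv_filters
        self.pre_conv = self._conv(rng, 1, c, 3)
        self.blocks = []
        self.transitions = []
        h, w = config.input_shape
        if config.pre_pool:
            h, w = _ceil_div(h, config.pre_pool[0]), _ceil_div(w, config.pre_pool[1])
        bottleneck = config.bottleneck_factor * config.growth_rate
        for b in range(config.num_blocks):
            layers = []
            for _ in range(config.layers_per_block):
                layers.append(
                    dict(
                        bn1=self._bn(c),
                        conv1=self._conv(rng, c, bottleneck, 1),
                        bn2=self._bn(bottleneck),
                        conv2=self._conv(rng, bottleneck, config.growth_rate, 3),
                    )
                )
                c += config.growth_rate
            self.blocks.append(layers)
            if b < config.num_blocks - 1:
                c_out = int(math.floor(config.compression * c))
                if c_out < 1:
                    raise ValueError("transition compression collapsed channels below 1")
                self.transitions.append(dict(bn=self._bn(c), conv=self._conv(rng, c, c_out, 1)))
                c = c_out
                h, w = _ceil_div(h, config.transition_pool), _ceil_div(w, config.transition_pool)
                if h < 1 or w < 1:
                    raise ValueError("pooling collapsed spatial dimensions below 1")
        self.final_bn = self._bn(c)
        self.pre_pool_dims = (h, w)
        self.fc1 = self._dense(rng, c, config.head_width)
        self.head_bn = self._bn(config.head_width)
        self.fc2 = self._dense(rng, config.head_width, config.num_classes)

    # -- parameter constructors -------------------------------------------------
    def _conv(self, rng, c_in: int, c_out: int, k: int) -> dict:
        std = math.sqrt(2.0 / (k * k * c_in))  # He initialization
        w = Var(rng.normal(0.0, std, size=(c_out, c_in, k, k)), trainable=True, name="conv_w")
        b = Var(np.zeros(c_out), trainable=True, name="conv_b")
        self.params += [w, b]
        return dict(w=w, b=b)

    def _dense(self, rng, n_in: int, n_out: int) -> dict:
        std = math.sqrt(2.0 / n_in)
        w = Var(rng.normal(0.0, std, size=(n_in, n_out)), trainable=True, name="dense_w")
        b = Var(np.zeros(n_out), trainable=True, name="dense_b")
        self.params += [w, b]
        return dict(w=w, b=b)

    def _bn(self, c: int) -> dict:
        gamma = Var(np.ones(c), trainable=True, name="bn_gamma")
        beta = Var(np.zeros(c), trainable=True, name="bn_beta")
        mean, var = np.zeros(c, dtype=np.float32), np.ones(c, dtype=np.float32)
        self.params += [gamma, beta]
        self._bn_state.append((mean, var))
        return dict(gamma=gamma, beta=beta, mean=mean, var=var)

    # -- forward ----------------------------------------------------------------
    def _apply_bn(self, x: Var, bn: dict, training: bool) -> Var:
        return ad.batchnorm(x, bn["gamma"], bn["beta"], bn["mean"], bn["var"], training)

    def forward(self, x: np.ndarray, training: bool = False) -> Var:
        """Logits for a batch of spectrograms (N, H, W) or (N, 1, H, W)."""
        if x.ndim == 3:
            x = x[:, None, :, :]
        cfg = self.config
        v = Var((x + cfg.input_offset_db) * cfg.input_scale)
        if cfg.pre_pool:
            v = ad.avg_pool_ceil(v, cfg.pre_pool, cfg.pre_pool)
        v = ad.conv2d(v, self.pre_conv["w"], self.pre_conv["b"], padding="same")
        for b, layers in enumerate(self.blocks):
            features = [v]
            for layer in layers:
                inp = features[0] if len(features) == 1 else ad.concat(features)
                t = self._apply_bn(inp, layer["bn1"], training)
                t = ad.relu(t)
                t = ad.conv2d(t, layer["conv1"]["w"], layer["conv1"]["b"], padding="same")
                t = self._apply_bn(t, layer["bn2"], training)
                t = ad.relu(t)
                t = ad.conv2d(t, layer["conv2"]["w"], layer["conv2"]["b"], padding="same")
                features.append(t)
            v = ad.concat(features)
            if b < len(self.transitions):
                tr = self.transitions[b]
                v = self._apply_bn(v, tr["bn"], training)
                v = ad.relu(v)
                v = ad.conv2d(v, tr["conv"]["w"], tr["conv"]["b"], padding="same")
                v = ad.avg_pool_ceil(v, cfg.transition_pool, cfg.transition_pool)
        v = ad.relu(self._apply_bn(v, self.final_bn, training))
        v = ad.global_avg_pool(v)
        v = ad.dropout(v, cfg.dropout_rate, self._dropout_rng, training)
        v = ad.dense(v, self.fc1["w"], self.fc1["b"])
        v = ad.relu(self._apply_bn(v, self.head_bn, training))
        return ad.dense(v, self.fc2["w"], self.fc2["b"])

    def predict_scores(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Per-class sigmoid scores in (0,1), inference mode."""
        outs = []
        for i in range(0, len(x), batch_size):
            logits = self.forward(np.asarray(x[i : i + batch_size], dtype=np.float32))
            outs.append(1.0 / (1.0 + np.exp(-logits.value)))
        return np.concatenate(outs, axis=0)

    # -- bookkeeping ------------------------------------------------------------
    def parameter_counts(self) -> tuple[int, int]:
        """(total, trainable) parameter counts; non-trainable = BN moving stats."""
        trainable = sum(p.size for p in self.params if p.trainable)
        non_trainable = sum(m.size + v.size for m, v in self._bn_state)
        return trainable + non_trainable, trainable

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights):
            p.value = np.asarray(w, dtype=np.float32).reshape(p.shape)

    def save(self, path) -> None:
        """Persist architecture config, weights and BN statistics (npz)."""
        import json

        arrays = {f"param_{i}": p.value for i, p in enumerate(self.params)}
        for i, (m, v) in enumerate(self._bn_state):
            arrays[f"bn_mean_{i}"] = m
            arrays[f"bn_var_{i}"] = v
        cfg = asdict(self.config)
        cfg["input_shape"] = list(cfg["input_shape"])
        arrays["config_json"] = np.frombuffer(
            json.dumps(cfg).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "QuasiDenseNet":
        import json

        with np.load(path) as data:
            cfg = json.loads(bytes(data["config_json"]).decode())
            cfg["input_shape"] = tuple(cfg["input_shape"])
            if cfg.get("pre_pool"):
                cfg["pre_pool"] = tuple(cfg["pre_pool"])
            cfg["lr_drop_epochs"] = cfg.get("lr_drop_epochs")  # tolerate absent keys
            cfg.pop("lr_drop_epochs", None)
            model = cls(ArchitectureConfig(**cfg))
            for i, p in enumerate(model.params):
                p.value = data[f"param_{i}"].astype(np.float32)
            for i, (m, v) in enumerate(model._bn_state):
                m[:] = data[f"bn_mean_{i}"]
                v[:] = data[f"bn_var_{i}"]
        return model


def build_model(config: ArchitectureConfig | None = None, seed: int = 0) -> QuasiDenseNet:
    """Instantiate the quasi-DenseNet; raises if the config collapses spatially."""
    model = QuasiDenseNet(config or ArchitectureConfig(), seed=seed)
    total, trainable = model.parameter_counts()
    logger.info("built quasi-DenseNet: %d total / %d trainable parameters, "
                "pre-pooling dims %s", total, trainable, model.pre_pool_dims)
    return model


def class_weights(labels: np.ndarray) -> np.ndarray:
    """Inverse-class-frequency weights normalized to unit mean.

    Frequency of a class is the sum of its (soft) ground-truth scores. A
    class absent from the training labels gets weight 0 with a warning.
    """
    freq = labels.sum(axis=0)
    w = np.zeros_like(freq, dtype=np.float64)
    present = freq > 0
    if not present.all():
        absent = np.flatnonzero(~present)
        logger.warning("classes %s have no training examples; weight set to 0", list(absent))
    w[present] = 1.0 / freq[present]
    if present.any():
        w /= w[present].mean()
    return w


def _spectrogram_batch(segments, chains, background_pool, rng, training: bool) -> np.ndarray:
    mats = []
    for seg in segments:
        if training and chains is not None:
            chain = chains["focal"] if seg.provenance == "focal" else chains["non-focal"]
            mats.append(chain.process(seg.samples, seg.rate, background_pool))
        else:
            mats.append(to_model_input(seg))
    return np.asarray(mats, dtype=np.float32)


def train(
    model: QuasiDenseNet,
    dataset: list[tuple[Segment, np.ndarray]],
    chains: dict[str, AugmentChain] | None,
    schedule: TrainingSchedule | None = None,
    background_pool: list[np.ndarray] | None = None,
) -> tuple[QuasiDenseNet, dict]:
    """Train on (segment, label-vector) pairs with on-the-fly augmentation.

    Splits 90/10 into train/validation (uniform random, seeded), weights the
    per-class binary cross-entropy by inverse class frequency, applies the
    provenance-matched augmentation chain to every training input every
    epoch, and follows the stepped Adam learning-rate schedule. Returns the
    model and a history dict with per-epoch train/validation loss and
    element-wise binary accuracy at threshold 0.5.
    """
    schedule = schedule or TrainingSchedule()
    rng = np.random.default_rng(schedule.seed)
    n = len(dataset)
    order = rng.permutation(n)
    n_val = int(round(schedule.validation_fraction * n))
    val_idx, train_idx = order[:n_val], order[n_val:]
    if len(train_idx) == 0:
        raise ValueError("no training examples after validation split")
    labels = np.asarray([lab for _, lab in dataset], dtype=np.float32)
    weights = class_weights(labels[train_idx]).astype(np.float32)

    val_x = _spectrogram_batch([dataset[i][0] for i in val_idx], None, None, rng, training=False)
    val_y = labels[val_idx]

    opt = ad.Adam([p for p in model.params], lr=schedule.initial_lr,
                  clip_norm=schedule.clip_norm)
    history = {k: [] for k in ("loss", "binary_accuracy", "val_loss", "val_binary_accuracy", "lr")}
    for epoch in range(schedule.epochs):
        opt.lr = schedule.lr_at(epoch)
        perm = rng.permutation(train_idx)
        ep_loss, ep_correct, ep_count = 0.0, 0, 0
        for start in range(0, len(perm), schedule.batch_size):
            batch = perm[start : start + schedule.batch_size]
            segs = [dataset[i][0] for i in batch]
            x = _spectrogram_batch(segs, chains, background_pool, rng, training=chains is not None)
            y = labels[batch]
            logits = model.forward(x, training=True)
            loss = ad.sigmoid_bce(logits, y, weights)
            ad.backward(loss)
            opt.step()
            ep_loss += float(loss.value) * len(batch)
            pred = logits.value > 0.0  # sigmoid(z) > 0.5
            ep_correct += int((pred == (y >= 0.5)).sum())
            ep_count += y.size
        history["loss"].append(ep_loss / len(perm))
        history["binary_accuracy"].append(ep_correct / ep_count)
        history["lr"].append(opt.lr)
        if len(val_idx):
            vl = model.forward(val_x, training=False)
            vloss = ad.sigmoid_bce(vl, val_y, weights)
            history["val_loss"].append(float(vloss.value))
            history["val_binary_accuracy"].append(
                float(((vl.value > 0.0) == (val_y >= 0.5)).mean())
            )
        logger.info(
            "epoch %d/%d lr=%g loss=%.4f acc=%.4f",
            epoch + 1, schedule.epochs, opt.lr,
            history["loss"][-1], history["binary_accuracy"][-1],
        )
    return model, history


def replicate_train(
    scenarios: dict[str, dict],
    seeds: list[int],
    config: ArchitectureConfig | None = None,
    train_fn=None,
) -> dict[tuple[str, int], QuasiDenseNet]:
    """Train (or initialize) a scenarios x replicates grid of models.

    Within one replicate every scenario's model starts from identical
    seeded weights; replicate seeds must be pairwise distinct. ``train_fn``,
    when given, is called as ``train_fn(model, scenario_name,
    scenario_settings, seed)`` and must return the trained model; without it
    the grid holds freshly initialized models (useful for seeding-contract
    checks).
    """
    if len(set(seeds)) != len(seeds):
        raise ValueError(f"replicate seeds must be distinct, got {seeds}")
    grid: dict[tuple[str, int], QuasiDenseNet] = {}
    for seed in seeds:
        for name, settings in scenarios.items():
            model = build_model(config, seed=seed)
            if train_fn is not None:
                model = train_fn(model, name, settings, seed)
            grid[(name, seed)] = model
    return grid


class SpectrogramClassifier(BaseEstimator):
    """Sklearn-style estimator facade over the quasi-DenseNet.

    ``fit(X, y)`` accepts a list of conditioned :class:`Segment` objects (or
    a 2-D array of 0.8 s waveforms at 96 kHz) and a (n_samples, n_classes)
    soft label matrix. ``predict_proba`` returns per-class sigmoid scores;
    ``predict`` thresholds them at 0.5. Augmentation is enabled by
    ``augment=True`` (provenance-matched chains seeded from ``seed``).
    """

    def __init__(self, config: ArchitectureConfig | None = None,
                 schedule: TrainingSchedule | None = None,
                 augment: bool = False, seed: int = 0):
        self.config = config
        self.schedule = schedule
        self.augment = augment
        self.seed = seed

    def _as_segments(self, X) -> list[Segment]:
        segs = []
        for item in X:
            if isinstance(item, Segment):
                segs.append(item)
            else:
                segs.append(Segment(samples=np.asarray(item, dtype=np.float64),
                                    start_s=0.0, provenance="field"))
        return segs

    def fit(self, X, y, background_pool: list[np.ndarray] | None = None):
        y = np.asarray(y, dtype=np.float64)
        segs = self._as_segments(X)
        if y.ndim != 2 or len(segs) != len(y):
            raise ValueError("y must be a (n_samples, n_classes) label matrix matching X")
        config = self.config or ArchitectureConfig(num_classes=y.shape[1])
        if config.num_classes != y.shape[1]:
            raise ValueError(
                f"label matrix has {y.shape[1]} classes but config expects {config.num_classes}"
            )
        schedule = self.schedule or TrainingSchedule(seed=self.seed)
        chains = None
        if self.augment:
            chains = {
                "focal": build_chain("focal", seed=self.seed + 1),
                "non-focal": build_chain("non-focal", seed=self.seed + 2),
            }
        model = build_model(config, seed=self.seed)
        self.model_, self.history_ = train(model, list(zip(segs, y)), chains,
                                           schedule, background_pool)
        self.n_classes_ = config.num_classes
        total, trainable = model.parameter_counts()
        self.n_parameters_, self.n_trainable_parameters_ = total, trainable
        return self

    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")
        segs = self._as_segments(X)
        spect = np.asarray([to_model_input(s) for s in segs], dtype=np.float32)
        return self.model_.predict_scores(spect)

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)
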