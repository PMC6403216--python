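"""Two-branch ensemble 1D CNN for 1p/19q co-deletion classification.

Each branch runs a pretraining block of valid convolutions and width-2 max
pools on its chromosome signal (chr1 and chr19 respectively), then a stack
of three bottleneck residual blocks, each repeated ``residual_iterations``
times at its own width.  The residual output is reduced by global average
pooling and bridged by a fully connected ReLU layer to a fixed per-branch
feature vector (1024 by default); the two feature vectors are concatenated
(2048) and classified by a softmax output layer.

Class 1 is 1p/19q co-deletion, class 2 is no co-deletion; the first output
probability is the co-deletion score used downstream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import _nn
from .profile_io import LABEL_CODEL, LABEL_NO_CODEL
from .vectorize import SampleFeatures

__all__ = [
    "EnsembleConfig",
    "TrainConfig",
    "TrainedEnsemble",
    "build_ensemble",
    "forward_proba",
    "train_ensemble",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

# class index 0 = co-deletion (positive), 1 = no co-deletion
CLASS_LABELS = (LABEL_CODEL, LABEL_NO_CODEL)

# (kernel, channels) conv / width-2 pool sequences of the pretraining blocks
_BRANCH1_PRETRAIN = (("conv", 170, 32), ("pool", 2), ("conv", 151, 64),
                     ("pool", 2), ("conv", 51, 64), ("pool", 2))
_BRANCH2_PRETRAIN = (("conv", 150, 32), ("pool", 2), ("conv", 51, 64),
                     ("pool", 2), ("conv", 51, 64), ("pool", 2))
# (mid_channels, out_channels) of the three bottleneck residual blocks
_RESIDUAL_SPECS = ((32, 128), (64, 256), (128, 512))


@dataclass
class EnsembleConfig:
    branch1_pretrain: tuple = _BRANCH1_PRETRAIN
    branch2_pretrain: tuple = _BRANCH2_PRETRAIN
    residual_specs: tuple = _RESIDUAL_SPECS
    residual_iterations: int = 10
    branch_feature_len: int = 1024
    n_classes: int = 2
    input_lens: Tuple[int, int] = (1869, 649)
    tie_branch_weights: bool = False
    seed: int = 0

    @property
    def concat_len(self) -> int:
        return 2 * self.branch_feature_len

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "EnsembleConfig":
        raw = json.loads(text)
        raw["branch1_pretrain"] = tuple(tuple(s) for s in raw["branch1_pretrain"])
        raw["branch2_pretrain"] = tuple(tuple(s) for s in raw["branch2_pretrain"])
        raw["residual_specs"] = tuple(tuple(s) for s in raw["residual_specs"])
        raw["input_lens"] = tuple(raw["input_lens"])
        return cls(**raw)


@dataclass
class TrainConfig:
    """Training hyperparameters (all invented defaults, CPU-sized)."""

    epochs: int = 60
    batch_size: int = 16
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    early_stop_patience: int = 10
    seed: int = 0
    validation_fraction: float = 0.0
    loss_tol: float = 1e-3  # stop once epoch training loss falls below

    def __post_init__(self):
        if min(self.epochs, self.batch_size, self.early_stop_patience) < 1:
            raise ValueError("epochs, batch_size, early_stop_patience must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 <= self.validation_fraction <= 0.5:
            raise ValueError("validation_fraction must be in [0, 0.5]")


def _build_branch(pretrain, residual_specs, residual_iterations,
                  feature_len, input_len, rng, name):
    layers: List[_nn.Layer] = []
    shape = (1, input_len)
    for i, spec in enumerate(pretrain):
        if spec[0] == "conv":
            _, kernel, channels = spec
            conv = _nn.Conv1d(shape[0], channels, int(kernel), "valid", rng,
                              f"{name}.pre{i}")
            shape = conv.out_shape(shape)
            layers += [conv, _nn.ReLU()]
        elif spec[0] == "pool":
            pool = _nn.MaxPool1d()
            shape = pool.out_shape(shape)
            layers.append(pool)
        else:
            raise ValueError(f"{name}: unknown pretrain layer spec {spec!r}")
    for bi, (mid, out) in enumerate(residual_specs):
        for rep in range(residual_iterations):
            block = _nn.ResidualBlock(shape[0], int(mid), int(out), rng,
                                      f"{name}.res{bi}.{rep}")
            shape = block.out_shape(shape)
            layers.append(block)
    layers.append(_nn.GlobalAvgPool())
    bridge = _nn.Dense(shape[0], feature_len, rng, f"{name}.bridge")
    layers += [bridge, _nn.ReLU()]
    return _nn.Sequential(layers), shape


class TrainedEnsemble:
    """A (possibly untrained) fitted-model handle.

    Holds the two branch networks, the softmax head, the builder config and
    per-epoch training history.  Inference is deterministic and batch-order
    invariant.
    """

    def __init__(self, config: EnsembleConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.branch_a, self._shape_a = _build_branch(
            config.branch1_pretrain, config.residual_specs,
            config.residual_iterations, config.branch_feature_len,
            config.input_lens[0], rng, "branch_a")
        if config.tie_branch_weights:
            raise NotImplementedError("weight tying is not implemented")
        self.branch_b, self._shape_b = _build_branch(
            config.branch2_pretrain, config.residual_specs,
            config.residual_iterations, config.branch_feature_len,
            config.input_lens[1], rng, "branch_b")
        self.head = _nn.Dense(config.concat_len, config.n_classes, rng, "head")
        self.training_history: List[Dict[str, float]] = []

    # -- geometry ---------------------------------------------------------
    @property
    def pretrain_shapes(self) -> Tuple[Tuple[int, int], Tuple[int, int]]:
        """(channels, length) entering each branch's residual stack."""
        return (self._pretrain_shape(self.config.branch1_pretrain,
                                     self.config.input_lens[0]),
                self._pretrain_shape(self.config.branch2_pretrain,
                                     self.config.input_lens[1]))

    @staticmethod
    def _pretrain_shape(pretrain, input_len):
        c, length = 1, input_len
        for spec in pretrain:
            if spec[0] == "conv":
                c, length = spec[2], length - spec[1] + 1
            else:
                length //= 2
        return c, length

    @property
    def head_input_dim(self) -> int:
        return self.head.in_dim

    @property
    def branch_feature_len(self) -> int:
        return self.config.branch_feature_len

    def parameter_count(self) -> int:
        return sum(p.size for p, _ in self._params_grads())

    def _params_grads(self):
        return (self.branch_a.params_grads() + self.branch_b.params_grads()
                + self.head.params_grads())

    # -- inference --------------------------------------------------------
    def _check_inputs(self, x1: np.ndarray, x2: np.ndarray):
        l1, l2 = self.config.input_lens
        if x1.shape[1] != l1 or x2.shape[1] != l2:
            raise ValueError(
                f"input lengths {(x1.shape[1], x2.shape[1])} do not match "
                f"configured {(l1, l2)}")

    def forward_logits(self, x1: np.ndarray, x2: np.ndarray,
                       train: bool = False) -> np.ndarray:
        x1 = np.asarray(x1, dtype=_nn.DTYPE)
        x2 = np.asarray(x2, dtype=_nn.DTYPE)
        self._check_inputs(x1, x2)
        f1 = self.branch_a.forward(x1[:, None, :], train)
        f2 = self.branch_b.forward(x2[:, None, :], train)
        self._concat_split = f1.shape[1]
        return self.head.forward(np.concatenate([f1, f2], axis=1), train)

    def branch_features(self, x1: np.ndarray,
                        x2: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Per-branch feature vectors immediately before concatenation."""
        x1 = np.asarray(x1, dtype=_nn.DTYPE)
        x2 = np.asarray(x2, dtype=_nn.DTYPE)
        self._check_inputs(x1, x2)
        return (self.branch_a.forward(x1[:, None, :]),
                self.branch_b.forward(x2[:, None, :]))

    def predict_proba(self, x1: np.ndarray, x2: np.ndarray,
                      batch_size: int = 32) -> np.ndarray:
        """Class probabilities, shape (N, n_classes); column 0 is co-deletion."""
        x1 = np.atleast_2d(np.asarray(x1, dtype=_nn.DTYPE))
        x2 = np.atleast_2d(np.asarray(x2, dtype=_nn.DTYPE))
        out = []
        for lo in range(0, x1.shape[0], batch_size):
            logits = self.forward_logits(x1[lo:lo + batch_size],
                                         x2[lo:lo + batch_size])
            out.append(_nn.softmax(logits.astype(np.float64)))
        return np.concatenate(out, axis=0)

    def backward(self, grad_logits: np.ndarray):
        grad = self.head.backward(grad_logits)
        k = self._concat_split
        self.branch_a.backward(grad[:, :k])
        self.branch_b.backward(grad[:, k:])


def build_ensemble(config: Optional[EnsembleConfig] = None) -> TrainedEnsemble:
    """Construct an untrained ensemble; raises naming the offending layer
    when the configured geometry is impossible."""
    model = TrainedEnsemble(config or EnsembleConfig())
    logger.info("built ensemble: %d parameters, head input %d",
                model.parameter_count(), model.head_input_dim)
    return model


def forward_proba(model: TrainedEnsemble,
                  sample: SampleFeatures) -> Tuple[float, float]:
    """(P(co-deletion), P(no co-deletion)) for one sample."""
    p = model.predict_proba(sample.x1.values[None, :],
                            sample.x2.values[None, :])[0]
    return float(p[0]), float(p[1])


def _encode(train_set: Sequence[SampleFeatures]):
    x1 = np.stack([s.x1.values for s in train_set]).astype(_nn.DTYPE)
    x2 = np.stack([s.x2.values for s in train_set]).astype(_nn.DTYPE)
    labels = []
    for s in train_set:
        if s.label not in CLASS_LABELS:
            raise ValueError(
                f"sample {s.sample_id} has no usable label: {s.label!r}")
        labels.append(CLASS_LABELS.index(s.label))
    return x1, x2, np.asarray(labels, dtype=np.int64)


def train_ensemble(model: TrainedEnsemble,
                   train_set: Sequence[SampleFeatures],
                   tc: Optional[TrainConfig] = None) -> TrainedEnsemble:
    """Fit the ensemble in place with minibatch Adam and return it.

    Monitors validation loss when ``validation_fraction > 0``, otherwise
    training loss; stops early on patience exhaustion or once the loss
    drops below ``loss_tol``.
    """
    tc = tc or TrainConfig()
    if len(train_set) == 0:
        raise ValueError("empty training set")
    x1, x2, y = _encode(train_set)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    if tc.optimizer.lower() != "adam":
        raise ValueError(f"unsupported optimizer {tc.optimizer!r}")

    rng = np.random.default_rng(tc.seed)
    n = len(y)
    n_val = int(round(tc.validation_fraction * n))
    order = rng.permutation(n)
    val_idx, tr_idx = order[:n_val], order[n_val:]
    if len(np.unique(y[tr_idx])) < 2:
        raise ValueError("training split lost a class; lower validation_fraction")

    opt = _nn.Adam(model._params_grads(), lr=tc.learning_rate)
    best = np.inf
    stale = 0
    for epoch in range(tc.epochs):
        perm = rng.permutation(tr_idx)
        losses, hits, seen = [], 0, 0
        for lo in range(0, len(perm), tc.batch_size):
            idx = perm[lo:lo + tc.batch_size]
            opt.zero_grad()
            logits = model.forward_logits(x1[idx], x2[idx], train=True)
            loss, grad = _nn.softmax_xent(logits, y[idx])
            model.backward(grad)
            opt.step()
            losses.append(loss * len(idx))
            hits += int((logits.argmax(axis=1) == y[idx]).sum())
            seen += len(idx)
        record = {"epoch": epoch, "loss": sum(losses) / seen,
                  "accuracy": hits / seen}
        if n_val:
            vl_logits = model.forward_logits(x1[val_idx], x2[val_idx])
            vloss, _ = _nn.softmax_xent(vl_logits, y[val_idx])
            record["val_loss"] = vloss
            record["val_accuracy"] = float(
                (vl_logits.argmax(axis=1) == y[val_idx]).mean())
        model.training_history.append(record)
        monitored = record.get("val_loss", record["loss"])
        logger.info("epoch %d: loss %.4f acc %.3f%s", epoch, record["loss"],
                    record["accuracy"],
                    f" val_loss {record['val_loss']:.4f}" if n_val else "")
        if monitored < best - 1e-6:
            best = monitored
            stale = 0
        else:
            stale += 1
        if record["loss"] < tc.loss_tol:
            logger.info("converged: training loss below %.2g", tc.loss_tol)
            break
        if stale >= tc.early_stop_patience:
            logger.info("early stop after %d stale epochs", stale)
            break
    return model


# -- persistence ----------------------------------------------------------

_FORMAT_VERSION = 1


def save_model(model: TrainedEnsemble, path) -> None:
    """Save config, weights and history to a single ``.npz`` artifact."""
    arrays = {f"p{i:04d}": p for i, (p, _) in enumerate(model._params_grads())}
    np.savez_compressed(
        path,
        __meta__=np.frombuffer(json.dumps({
            "format_version": _FORMAT_VERSION,
            "config": json.loads(model.config.to_json()),
            "history": model.training_history,
        }).encode(), dtype=np.uint8),
        **arrays)


def load_model(path) -> TrainedEnsemble:
    """Load an artifact saved by :func:`save_model`; forward passes of the
    loaded model are bit-identical to the saved one."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("format_version") != _FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format {meta.get('format_version')!r}")
        model = TrainedEnsemble(EnsembleConfig.from_json(
            json.dumps(meta["config"])))
        model.training_history = meta["history"]
        for i, (p, _) in enumerate(model._params_grads()):
            stored = data[f"p{i:04d}"]
            if stored.shape != p.shape:
                raise ValueError("model artifact does not match its config")
            p[...] = stored
    return model
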