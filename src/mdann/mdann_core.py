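"""Multi-attribute domain-adversarial model: assembly, training, prediction.

Architecture: a convolutional encoder (initialized from a pretrained
autoencoder and fine-tuned), whose bottleneck is global-average-pooled into
an embedding vector shared by

* a predictor head (three fully connected layers, sigmoid output) trained
  on the disease label, and
* K adversarial components (ACs; two fully connected layers each, sigmoid
  output), one per sensitive attribute, trained to recover that attribute
  from the embedding.

The heads are joined through an averaged gradient-reversal layer: identity
in the forward pass; in the backward pass the mean of the ACs' embedding
gradients is multiplied by ``-lambda`` before it reaches the encoder, while
the predictor's gradient flows through unmodified.  The encoder therefore
descends the prediction loss and ascends the attribute losses — it is pushed
toward representations from which the attributes are indistinguishable.

Updates are simultaneous (one backward pass through the reversal layer), not
alternating min/max phases.  Each head's loss is either the AUC saddle
objective (with its own auxiliary scalars, robust to imbalance) or weighted
cross-entropy.  With K = 0 the model is exactly a plain classifier.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import auc_minimax as am
from ._nn import (Adam, GlobalAvgPool2d, Linear, Param, ReLU, Sequential,
                  Sigmoid)
from .cae_extractor import CAEConfig, CAEModel, build_cae
from .cohort_io import Cohort
from .fairness_metrics import classification_metrics, prediction_table

logger = logging.getLogger("mdann")

__all__ = [
    "MDANNConfig",
    "MDANNModel",
    "averaged_gradient_reversal",
    "build_mdann",
    "train_step",
    "train_mdann",
    "predict",
    "embed",
    "head_losses",
    "encoder_gradient",
    "save_mdann",
    "load_mdann",
]

_LOSS_MODES = ("minimax", "weighted_ce")


@dataclass
class MDANNConfig:
    """Architecture and training hyperparameters of the adversarial model."""

    encoder: CAEConfig = field(default_factory=CAEConfig)
    n_adversarial: int = 0
    ac_hidden: int = 64
    predictor_hidden: tuple[int, int] = (128, 32)
    reversal_lambda: float = 1.0
    lambda_schedule: str | None = None       # None (constant) or "warmup"
    predictor_loss: str = "minimax"
    ac_loss: str = "minimax"
    minimax_mode: str = "trainable"          # "trainable" or "closed_form"
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    ac_lr_scale: float = 5.0   # two-time-scale rule: ACs adapt faster than the
                               # encoder so reversed gradients reward removal,
                               # not score flipping
    reversal_norm_cap: float | None = None
    # optional stabilizer for training: per batch, rescale the reversed
    # gradient so its norm is at most cap * ||predictor gradient|| before it
    # enters the encoder (an adaptive reversal strength).  None = exact
    # -lambda * mean reversal.
    threshold: float = 0.5

    def __post_init__(self):
        if self.n_adversarial < 0:
            raise ValueError("n_adversarial must be >= 0")
        if self.reversal_lambda < 0:
            raise ValueError("reversal_lambda must be >= 0")
        if self.predictor_loss not in _LOSS_MODES or self.ac_loss not in _LOSS_MODES:
            raise ValueError(f"loss modes must be one of {_LOSS_MODES}")
        if self.minimax_mode not in ("trainable", "closed_form"):
            raise ValueError("minimax_mode must be 'trainable' or 'closed_form'")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")


class _Head:
    """A scoring head with its own loss mode and auxiliary state."""

    def __init__(self, network: Sequential, loss_mode: str):
        self.network = network
        self.loss_mode = loss_mode
        # saddle-objective scalars (used when loss_mode == "minimax")
        self.mu1 = Param(np.asarray(0.5))
        self.mu2 = Param(np.asarray(0.5))
        self.theta = Param(np.asarray(0.0))
        self.p = 0.5
        self.class_weights = (1.0, 1.0)

    @property
    def state(self) -> am.MinimaxState:
        return am.MinimaxState(mu1=float(self.mu1.value), mu2=float(self.mu2.value),
                               theta=float(self.theta.value), p=self.p)

    def set_state(self, state: am.MinimaxState) -> None:
        self.mu1.value[...] = state.mu1
        self.mu2.value[...] = state.mu2
        self.theta.value[...] = state.theta
        self.p = state.p

    def scalar_params(self) -> list[Param]:
        return [self.mu1, self.mu2, self.theta] if self.loss_mode == "minimax" else []

    def loss(self, scores: np.ndarray, targets: np.ndarray) -> float:
        batch = am.ScoredBatch(scores, targets)
        if self.loss_mode == "minimax":
            return am.minimax_objective(batch, self.state)
        return am.weighted_cross_entropy(batch, self.class_weights)

    def loss_and_score_grad(self, scores: np.ndarray, targets: np.ndarray,
                            minimax_mode: str) -> tuple[float, np.ndarray]:
        """Loss value and d(loss)/d(scores); accumulates scalar gradients."""
        batch = am.ScoredBatch(scores, targets)
        if self.loss_mode == "weighted_ce":
            return (am.weighted_cross_entropy(batch, self.class_weights),
                    am.weighted_cross_entropy_gradient(batch, self.class_weights))
        if minimax_mode == "closed_form":
            self.set_state(am.closed_form_inner(batch, self.p))
        value = am.minimax_objective(batch, self.state)
        df, dmu1, dmu2, dtheta = am.minimax_gradients(batch, self.state)
        if minimax_mode == "trainable":
            self.mu1.grad += dmu1
            self.mu2.grad += dmu2
            self.theta.grad += -dtheta  # ascent variable: flip for descent update
        return value, df


class _TwoTimescaleAdam:
    """Adam over two parameter groups with different learning rates."""

    def __init__(self, slow: Adam, fast: Adam | None):
        self.slow, self.fast = slow, fast

    def step(self) -> None:
        self.slow.step()
        if self.fast is not None:
            self.fast.step()


class MDANNModel:
    """Encoder + predictor + K adversarial components."""

    def __init__(self, config: MDANNConfig, encoder: Sequential,
                 predictor: _Head, acs: list[_Head]):
        self.config = config
        self.encoder = encoder
        self.pool = GlobalAvgPool2d()
        self.predictor = predictor
        self.acs = acs
        self.ac_attributes: list[str] = []
        self.skipped_batches = 0
        self.history: dict[str, list] = {}
        self._optimizer: Adam | None = None

    @property
    def embedding_dim(self) -> int:
        return self.config.encoder.bottleneck_shape[2]

    def parameters(self) -> list[Param]:
        params = self.encoder.params() + self.predictor.network.params()
        params += self.predictor.scalar_params()
        for ac in self.acs:
            params += ac.network.params() + ac.scalar_params()
        return params

    @property
    def optimizer(self) -> "_TwoTimescaleAdam":
        if self._optimizer is None:
            slow = (self.encoder.params() + self.predictor.network.params()
                    + self.predictor.scalar_params())
            fast: list[Param] = []
            for ac in self.acs:
                fast += ac.network.params() + ac.scalar_params()
            lr = self.config.learning_rate
            self._optimizer = _TwoTimescaleAdam(
                Adam(slow, lr=lr),
                Adam(fast, lr=lr * self.config.ac_lr_scale) if fast else None)
        return self._optimizer

    def _check_images(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 3:
            images = images[:, None, :, :]
        h, w = self.config.encoder.input_size
        if images.shape[1:] != (1, h, w):
            raise ValueError(f"expected grayscale {h}x{w} images, got {images.shape}")
        return images


def averaged_gradient_reversal(forward: np.ndarray, backward: list[np.ndarray],
                               lam: float) -> tuple[np.ndarray, np.ndarray]:
    """The averaged gradient-reversal layer.

    Forward pass is the identity on the embedding.  Backward pass returns the
    adversarial contribution to the upstream (encoder-side) gradient:
    ``-lam * mean(backward)``.  The predictor's gradient flows alongside,
    unmodified, and is added by the caller.
    """
    if len(backward) < 1:
        raise ValueError("need at least one adversarial gradient")
    shapes = {g.shape for g in backward}
    if len(shapes) != 1:
        raise ValueError(f"adversarial gradients disagree in shape: {shapes}")
    mean_grad = np.mean(backward, axis=0)
    return forward, -lam * mean_grad


def _build_head(widths: list[int], loss_mode: str, rng: np.random.Generator) -> _Head:
    layers: list = []
    for i, (a, b) in enumerate(zip(widths[:-1], widths[1:])):
        layers.append(Linear(a, b, rng=rng))
        layers.append(ReLU() if i < len(widths) - 2 else Sigmoid())
    return _Head(Sequential(layers), loss_mode)


def build_mdann(config: MDANNConfig, pretrained: CAEModel, seed: int) -> MDANNModel:
    """Assemble a model with the encoder initialized from a pretrained CAE.

    Heads are randomly initialized from per-head seeds derived from ``seed``,
    so adding or removing components never perturbs the other components'
    initial weights.
    """
    pc, ec = pretrained.config, config.encoder
    if (pc.depth, pc.base_channels, tuple(pc.input_size)) != \
            (ec.depth, ec.base_channels, tuple(ec.input_size)):
        raise ValueError(
            f"encoder config {ec} does not match pretrained CAE config {pc}")
    encoder = build_cae(ec, seed=0).encoder  # same structure, weights overwritten
    for p_new, p_old in zip(encoder.params(), pretrained.encoder.params()):
        p_new.value[...] = p_old.value
    dim = ec.bottleneck_shape[2]
    h1, h2 = config.predictor_hidden
    predictor = _build_head([dim, h1, h2, 1], config.predictor_loss,
                            np.random.default_rng([int(seed), 1]))
    acs = [_build_head([dim, config.ac_hidden, 1], config.ac_loss,
                       np.random.default_rng([int(seed), 2, i]))
           for i in range(config.n_adversarial)]
    return MDANNModel(config, encoder, predictor, acs)


def _forward_embedding(model: MDANNModel, images: np.ndarray) -> np.ndarray:
    return model.pool.forward(model.encoder.forward(model._check_images(images)))


def embed(model: MDANNModel, images: np.ndarray) -> np.ndarray:
    """Pooled bottleneck embeddings, shape (n, channels)."""
    return _forward_embedding(model, images)


def _ac_targets(model: MDANNModel, attributes: np.ndarray) -> np.ndarray:
    attributes = np.atleast_2d(np.asarray(attributes))
    if attributes.shape[1] < len(model.acs):
        raise ValueError(
            f"model has {len(model.acs)} adversarial components but the batch "
            f"provides only {attributes.shape[1]} attribute columns")
    return attributes


def train_step(model: MDANNModel, images: np.ndarray, labels: np.ndarray,
               attributes: np.ndarray | None = None,
               lam: float | None = None) -> dict[str, float] | None:
    """One simultaneous update on a minibatch.

    The predictor loss descends through its head and the encoder; each AC's
    loss descends into that AC's own weights and, through the reversal layer,
    ascends (sign-flipped, averaged, lambda-scaled) into the encoder.
    Returns per-head losses, or None if the batch was skipped (single-class
    batch under the saddle loss).
    """
    cfg = model.config
    if lam is None:
        lam = cfg.reversal_lambda
    labels = np.asarray(labels).ravel()
    if cfg.predictor_loss == "minimax" and labels.min() == labels.max():
        model.skipped_batches += 1
        logger.info("skipping single-class batch under the saddle loss")
        return None
    if model.acs:
        attributes = _ac_targets(model, attributes)

    e = _forward_embedding(model, images)
    losses: dict[str, float] = {}

    scores = model.predictor.network.forward(e).ravel()
    loss_p, dscore = model.predictor.loss_and_score_grad(scores, labels,
                                                         cfg.minimax_mode)
    losses["predictor"] = loss_p
    g_embed = model.predictor.network.backward(dscore[:, None])

    ac_grads = []
    for i, ac in enumerate(model.acs):
        target = attributes[:, i]
        if ac.loss_mode == "minimax" and target.min() == target.max():
            losses[f"ac{i}"] = float("nan")
            continue
        s = ac.network.forward(e).ravel()
        loss_i, ds = ac.loss_and_score_grad(s, target, cfg.minimax_mode)
        losses[f"ac{i}"] = loss_i
        ac_grads.append(ac.network.backward(ds[:, None]))
    if ac_grads:
        _, reversed_grad = averaged_gradient_reversal(e, ac_grads, lam)
        cap = cfg.reversal_norm_cap
        if cap is not None:
            limit = cap * np.linalg.norm(g_embed)
            norm = np.linalg.norm(reversed_grad)
            if norm > limit > 0:
                reversed_grad = reversed_grad * (limit / norm)
        g_embed = g_embed + reversed_grad

    model.encoder.backward(model.pool.backward(g_embed))
    model.optimizer.step()
    return losses


def _stratified_batches(labels: np.ndarray, batch_size: int,
                        rng: np.random.Generator) -> list[np.ndarray]:
    """Shuffled batches with positives dealt round-robin across batches.

    Keeps the minority class represented in every batch whenever it has at
    least one sample per batch, which minimizes skipped single-class batches
    under the saddle loss.
    """
    n = labels.size
    n_batches = max(1, math.ceil(n / batch_size))
    pos = rng.permutation(np.flatnonzero(labels == 1))
    neg = rng.permutation(np.flatnonzero(labels == 0))
    batches: list[list[int]] = [[] for _ in range(n_batches)]
    for j, idx in enumerate(pos):
        batches[j % n_batches].append(idx)
    for j, idx in enumerate(neg):
        batches[(n_batches - 1 - j % n_batches)].append(idx)
    return [np.asarray(b, dtype=np.int64) for b in batches if b]


def _lambda_at(cfg: MDANNConfig, epoch: int) -> float:
    if cfg.lambda_schedule is None:
        return cfg.reversal_lambda
    if cfg.lambda_schedule == "warmup":
        q = epoch / max(cfg.epochs - 1, 1)
        return cfg.reversal_lambda * (2.0 / (1.0 + math.exp(-10.0 * q)) - 1.0)
    raise ValueError(f"unknown lambda schedule {cfg.lambda_schedule!r}")


def _balanced_weights(targets: np.ndarray) -> tuple[float, float]:
    n = targets.size
    n1 = int(targets.sum())
    n0 = n - n1
    if n0 == 0 or n1 == 0:
        return (1.0, 1.0)
    return (n / (2.0 * n0), n / (2.0 * n1))


def _eval_head(scores: np.ndarray, targets: np.ndarray,
               threshold: float) -> tuple[float, float]:
    table = prediction_table(targets, (scores >= threshold).astype(int), scores,
                             attributes={})
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)
        m = classification_metrics(table)
    return m["ACC"], m["AUC"]


def train_mdann(model: MDANNModel, cohort: Cohort, train_idx, val_idx=None,
                seed: int = 0) -> MDANNModel:
    """Train on a cohort split; logs per-epoch predictor and AC metrics.

    The positive proportion ``p`` of every saddle-loss head and the class
    weights of every cross-entropy head are computed once from the training
    fold and frozen.  AC ``i`` targets ``cohort.attribute_names[i]``.
    """
    cfg = model.config
    train_idx = np.asarray(train_idx)
    if len(model.acs) > cohort.coded_attributes.shape[1]:
        raise ValueError(
            f"model has {len(model.acs)} adversarial components but cohort has "
            f"only {cohort.coded_attributes.shape[1]} coded attributes")
    model.ac_attributes = cohort.attribute_names[:len(model.acs)]

    labels = cohort.labels[train_idx]
    attrs = cohort.coded_attributes[train_idx]
    images = cohort.images[train_idx]
    model.predictor.p = float(labels.mean())
    model.predictor.class_weights = _balanced_weights(labels)
    for i, ac in enumerate(model.acs):
        ac.p = float(attrs[:, i].mean())
        ac.class_weights = _balanced_weights(attrs[:, i])

    shuffle_rng = np.random.default_rng([int(seed), 3])
    history: dict[str, list] = {"epoch": [], "lambda": [], "predictor_loss": [],
                                "train_ACC": [], "train_AUC": []}
    if val_idx is not None:
        val_idx = np.asarray(val_idx)
        history["val_ACC"] = []
        history["val_AUC"] = []
    for i in range(len(model.acs)):
        history[f"ac{i}_ACC"] = []
        history[f"ac{i}_AUC"] = []

    for epoch in range(cfg.epochs):
        lam = _lambda_at(cfg, epoch)
        step_losses = []
        for batch_idx in _stratified_batches(labels, cfg.batch_size, shuffle_rng):
            result = train_step(model, images[batch_idx], labels[batch_idx],
                                attrs[batch_idx], lam=lam)
            if result is not None:
                step_losses.append(result["predictor"])
        history["epoch"].append(epoch)
        history["lambda"].append(lam)
        history["predictor_loss"].append(float(np.mean(step_losses))
                                         if step_losses else float("nan"))
        e_train = _forward_embedding(model, images)
        s_train = model.predictor.network.forward(e_train).ravel()
        acc, auc = _eval_head(s_train, labels, cfg.threshold)
        history["train_ACC"].append(acc)
        history["train_AUC"].append(auc)
        if val_idx is not None:
            e_val = _forward_embedding(model, cohort.images[val_idx])
            s_val = model.predictor.network.forward(e_val).ravel()
            acc, auc = _eval_head(s_val, cohort.labels[val_idx], cfg.threshold)
            history["val_ACC"].append(acc)
            history["val_AUC"].append(auc)
            eval_e, eval_attrs = e_val, cohort.coded_attributes[val_idx]
        else:
            eval_e, eval_attrs = e_train, attrs
        for i, ac in enumerate(model.acs):
            s = ac.network.forward(eval_e).ravel()
            acc, auc = _eval_head(s, eval_attrs[:, i], 0.5)
            history[f"ac{i}_ACC"].append(acc)
            history[f"ac{i}_AUC"].append(auc)
    model.history = history
    return model


def predict(model: MDANNModel, images: np.ndarray,
            threshold: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic scores in [0, 1] and hard labels ``score >= threshold``."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    e = _forward_embedding(model, images)
    scores = model.predictor.network.forward(e).ravel()
    return scores, (scores >= threshold).astype(np.int64)


def head_losses(model: MDANNModel, images: np.ndarray, labels: np.ndarray,
                attributes: np.ndarray | None = None
                ) -> tuple[float, list[float]]:
    """Per-head losses at the current parameters and states (no update)."""
    e = _forward_embedding(model, images)
    scores = model.predictor.network.forward(e).ravel()
    loss_p = model.predictor.loss(scores, np.asarray(labels).ravel())
    ac_losses = []
    if model.acs:
        attributes = _ac_targets(model, attributes)
        for i, ac in enumerate(model.acs):
            s = ac.network.forward(e).ravel()
            ac_losses.append(ac.loss(s, attributes[:, i]))
    return loss_p, ac_losses


def encoder_gradient(model: MDANNModel, images: np.ndarray, labels: np.ndarray,
                     attributes: np.ndarray | None = None,
                     lam: float | None = None) -> np.ndarray:
    """Flat total encoder gradient for one batch (no parameter update).

    Equals ``d(L_pred)/d(enc) - lam * (1/K) * sum_i d(L_AC_i)/d(enc)`` — the
    gradient-reversal contract verified by finite differences in the tests.
    """
    cfg = model.config
    if lam is None:
        lam = cfg.reversal_lambda
    for p in model.parameters():
        p.zero_grad()
    e = _forward_embedding(model, images)
    scores = model.predictor.network.forward(e).ravel()
    batch = am.ScoredBatch(scores, np.asarray(labels).ravel())
    if model.predictor.loss_mode == "minimax":
        df, *_ = am.minimax_gradients(batch, model.predictor.state)
    else:
        df = am.weighted_cross_entropy_gradient(batch, model.predictor.class_weights)
    g_embed = model.predictor.network.backward(df[:, None])
    ac_grads = []
    if model.acs:
        attributes = _ac_targets(model, attributes)
        for i, ac in enumerate(model.acs):
            s = ac.network.forward(e).ravel()
            b = am.ScoredBatch(s, attributes[:, i])
            if ac.loss_mode == "minimax":
                ds, *_ = am.minimax_gradients(b, ac.state)
            else:
                ds = am.weighted_cross_entropy_gradient(b, ac.class_weights)
            ac_grads.append(ac.network.backward(ds[:, None]))
    if ac_grads:
        _, reversed_grad = averaged_gradient_reversal(e, ac_grads, lam)
        g_embed = g_embed + reversed_grad
    model.encoder.backward(model.pool.backward(g_embed))
    flat = np.concatenate([p.grad.ravel() for p in model.encoder.params()])
    for p in model.parameters():
        p.zero_grad()
    return flat


def save_mdann(model: MDANNModel, out_dir: Path | str) -> dict[str, str]:
    """Checkpoint: weight bundle + JSON config (+ history CSV if trained)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    arrays = {f"p_{i}": p.value for i, p in enumerate(model.parameters())}
    np.savez_compressed(out_dir / "mdann_weights.npz", **arrays)
    cfg = asdict(model.config)
    cfg["encoder"]["input_size"] = list(model.config.encoder.input_size)
    cfg["predictor_hidden"] = list(model.config.predictor_hidden)
    cfg["ac_attributes"] = model.ac_attributes
    cfg["head_p"] = [model.predictor.p] + [ac.p for ac in model.acs]
    cfg["head_class_weights"] = ([list(model.predictor.class_weights)]
                                 + [list(ac.class_weights) for ac in model.acs])
    (out_dir / "mdann_config.json").write_text(json.dumps(cfg, indent=2))
    if model.history:
        import pandas as pd

        pd.DataFrame(model.history).to_csv(out_dir / "mdann_history.csv", index=False)
    return {"weights": str(out_dir / "mdann_weights.npz"),
            "config": str(out_dir / "mdann_config.json")}


def load_mdann(in_dir: Path | str) -> MDANNModel:
    in_dir = Path(in_dir)
    cfg = json.loads((in_dir / "mdann_config.json").read_text())
    ac_attributes = cfg.pop("ac_attributes", [])
    head_p = cfg.pop("head_p", None)
    head_w = cfg.pop("head_class_weights", None)
    cfg["encoder"] = CAEConfig(**{**cfg["encoder"],
                                  "input_size": tuple(cfg["encoder"]["input_size"])})
    cfg["predictor_hidden"] = tuple(cfg["predictor_hidden"])
    config = MDANNConfig(**cfg)
    pretrained = build_cae(config.encoder, seed=0)
    model = build_mdann(config, pretrained, seed=0)
    with np.load(in_dir / "mdann_weights.npz") as arrays:
        for i, p in enumerate(model.parameters()):
            p.value[...] = arrays[f"p_{i}"]
    model.ac_attributes = ac_attributes
    heads = [model.predictor] + model.acs
    if head_p is not None:
        for h, p in zip(heads, head_p):
            h.p = float(p)
    if head_w is not None:
        for h, w in zip(heads, head_w):
            h.class_weights = (float(w[0]), float(w[1]))
    return model
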