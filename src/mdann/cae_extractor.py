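"""Convolutional autoencoder pretraining and bottleneck encoding.

The encoder stacks ``depth`` strided convolutions (5x5 kernel, stride 2),
each followed by a ReLU; the decoder mirrors them with transposed
convolutions and ends in a sigmoid so reconstructions live in [0, 1].
Channel width doubles per stage: stage ``i`` has ``base_channels * 2**(i-1)``
feature maps, so the bottleneck of a depth-``d`` model on an (H, W) input has
shape ``(H / 2**d, W / 2**d, base_channels * 2**(d-1))``.  With
``base_channels = 128`` on 128x128 inputs this reproduces the reference
geometry (depth 1: 64x64x128, depth 2: 32x32x256, depth 3: 16x16x512);
the default ``base_channels = 8`` is a scaled version for desk-size runs.

Pretraining minimizes mean squared reconstruction error with Adam.  After
pretraining the decoder is discarded; the encoder initializes the
adversarial model's feature extractor.

Reconstruction quality can be monitored with the Fréchet distance between
Gaussian fits of features of real and reconstructed images.  The feature
function is pluggable and defaults to the identity on flattened pixels:
the standard pretrained-Inception embedding is ill-suited to grayscale
slices and would make scores incomparable anyway; the distance math is
identical for any feature map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable

import numpy as np

from ._nn import Adam, Conv2d, ConvTranspose2d, ReLU, Sequential, Sigmoid

__all__ = [
    "CAEConfig",
    "CAEModel",
    "build_cae",
    "pretrain_cae",
    "encode",
    "frechet_distance",
    "fid_monitor",
    "save_cae",
    "load_cae",
]


@dataclass
class CAEConfig:
    """Geometry and training hyperparameters of the autoencoder."""

    depth: int = 2
    base_channels: int = 8
    input_size: tuple[int, int] = (32, 32)
    kernel: int = 5
    stride: int = 2
    epochs: int = 200
    learning_rate: float = 1e-3
    batch_size: int = 32

    def __post_init__(self):
        if self.depth not in (1, 2, 3):
            raise ValueError("depth must be 1, 2 or 3")
        h, w = self.input_size
        div = 2**self.depth
        if h % div or w % div:
            raise ValueError(
                f"input size {self.input_size} must be divisible by 2**depth={div}")

    @property
    def stage_channels(self) -> list[int]:
        return [self.base_channels * 2**i for i in range(self.depth)]

    @property
    def bottleneck_shape(self) -> tuple[int, int, int]:
        h, w = self.input_size
        div = 2**self.depth
        return h // div, w // div, self.stage_channels[-1]


class CAEModel:
    """Encoder/decoder pair with training history."""

    def __init__(self, config: CAEConfig, encoder: Sequential, decoder: Sequential):
        self.config = config
        self.encoder = encoder
        self.decoder = decoder
        self.history: dict[str, list[float]] = {"loss": [], "fid": []}

    def _check_images(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 3:
            images = images[:, None, :, :]
        h, w = self.config.input_size
        if images.shape[2:] != (h, w) or images.shape[1] != 1:
            raise ValueError(
                f"expected grayscale images of size {h}x{w}, got array of "
                f"shape {images.shape}")
        return images

    def encode(self, images: np.ndarray) -> np.ndarray:
        """Bottleneck activations, channels-last: (n, h, w, c)."""
        z = self.encoder.forward(self._check_images(images))
        return np.ascontiguousarray(z.transpose(0, 2, 3, 1))

    def reconstruct(self, images: np.ndarray) -> np.ndarray:
        z = self.encoder.forward(self._check_images(images))
        return self.decoder.forward(z)[:, 0, :, :]


def build_cae(config: CAEConfig, seed: int) -> CAEModel:
    """Deterministically initialize an autoencoder from a seed."""
    rng = np.random.default_rng([int(seed), 0])
    channels = [1] + config.stage_channels
    enc_layers: list = []
    for cin, cout in zip(channels[:-1], channels[1:]):
        enc_layers += [Conv2d(cin, cout, config.kernel, config.stride,
                              config.kernel // 2, rng=rng), ReLU()]
    dec_layers: list = []
    rev = channels[::-1]
    for i, (cin, cout) in enumerate(zip(rev[:-1], rev[1:])):
        dec_layers.append(ConvTranspose2d(cin, cout, config.kernel, config.stride,
                                          config.kernel // 2, 1, rng=rng))
        dec_layers.append(ReLU() if i < len(rev) - 2 else Sigmoid())
    return CAEModel(config, Sequential(enc_layers), Sequential(dec_layers))


def pretrain_cae(cohort, config: CAEConfig, seed: int,
                 fid_every: int | None = None) -> CAEModel:
    """Train an autoencoder on a cohort's images by reconstruction MSE.

    ``cohort`` may be a Cohort or a raw (n, H, W) array.  Deterministic
    given the seed.  ``fid_every`` optionally records a Fréchet-distance
    trace every that many epochs (on flattened pixels).
    """
    images = cohort.images if hasattr(cohort, "images") else np.asarray(cohort)
    model = build_cae(config, seed)
    x_all = model._check_images(images)
    n = x_all.shape[0]
    optimizer = Adam(model.encoder.params() + model.decoder.params(),
                     lr=config.learning_rate)
    shuffle_rng = np.random.default_rng([int(seed), 1])
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            xb = x_all[order[start:start + config.batch_size]]
            z = model.encoder.forward(xb)
            recon = model.decoder.forward(z)
            diff = recon - xb
            losses.append(float((diff**2).mean()))
            dy = 2.0 * diff / diff.size
            model.encoder.backward(model.decoder.backward(dy))
            optimizer.step()
        model.history["loss"].append(float(np.mean(losses)))
        if fid_every and (epoch % fid_every == 0 or epoch == config.epochs - 1):
            model.history["fid"].append(fid_monitor(model, images))
    return model


def encode(model: CAEModel, images: np.ndarray) -> np.ndarray:
    """Bottleneck activations of ``images``, channels-last (n, h, w, c)."""
    return model.encode(images)


def _sqrtm_psd(matrix: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Symmetric PSD matrix square root via eigendecomposition.

    Eigenvalues below ``tol`` (numerical noise) are clipped to zero.
    """
    vals, vecs = np.linalg.eigh((matrix + matrix.T) / 2.0)
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def frechet_distance(mu1, cov1, mu2, cov2) -> float:
    """Fréchet distance between two Gaussians.

    ``||mu1 - mu2||^2 + tr(cov1 + cov2 - 2 (cov1 cov2)^{1/2})``, computed via
    the symmetric form ``tr((S1 C2 S1)^{1/2})`` with ``S1 = cov1^{1/2}`` so
    the matrix square root acts on a symmetric PSD matrix.  Non-negative and
    symmetric in its arguments; scalars are accepted for the 1-D case.
    """
    mu1 = np.atleast_1d(np.asarray(mu1, dtype=np.float64))
    mu2 = np.atleast_1d(np.asarray(mu2, dtype=np.float64))
    cov1 = np.atleast_2d(np.asarray(cov1, dtype=np.float64))
    cov2 = np.atleast_2d(np.asarray(cov2, dtype=np.float64))
    if mu1.shape != mu2.shape or cov1.shape != cov2.shape \
            or cov1.shape != (mu1.size, mu1.size):
        raise ValueError("dimension mismatch between means and covariances")
    s1 = _sqrtm_psd(cov1)
    cross = _sqrtm_psd(s1 @ cov2 @ s1)
    value = float(((mu1 - mu2) ** 2).sum() + np.trace(cov1) + np.trace(cov2)
                  - 2.0 * np.trace(cross))
    return max(value, 0.0)


def fid_monitor(model: CAEModel, real_images: np.ndarray,
                feature_fn: Callable[[np.ndarray], np.ndarray] | None = None) -> float:
    """Fréchet distance between Gaussian fits of real vs reconstructed features.

    ``feature_fn`` maps an (n, H, W) stack to (n, d) features; the default
    flattens pixels.  Requires at least two samples (covariance estimation).
    """
    real = np.asarray(real_images, dtype=np.float64)
    if real.ndim == 4:
        real = real[:, 0]
    if real.shape[0] < 2:
        raise ValueError("need at least 2 samples to estimate a covariance")
    if feature_fn is None:
        feature_fn = lambda imgs: imgs.reshape(imgs.shape[0], -1)
    recon = model.reconstruct(real)
    f_real = np.asarray(feature_fn(real), dtype=np.float64)
    f_recon = np.asarray(feature_fn(recon), dtype=np.float64)
    mu_r, mu_g = f_real.mean(axis=0), f_recon.mean(axis=0)
    cov_r = np.cov(f_real, rowvar=False)
    cov_g = np.cov(f_recon, rowvar=False)
    return frechet_distance(mu_r, cov_r, mu_g, cov_g)


def save_cae(model: CAEModel, out_dir: Path | str) -> dict[str, str]:
    """Checkpoint a model as an array bundle + JSON config (+ history CSV)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for i, p in enumerate(model.encoder.params()):
        arrays[f"enc_{i}"] = p.value
    for i, p in enumerate(model.decoder.params()):
        arrays[f"dec_{i}"] = p.value
    np.savez_compressed(out_dir / "cae_weights.npz", **arrays)
    cfg = asdict(model.config)
    cfg["input_size"] = list(model.config.input_size)
    (out_dir / "cae_config.json").write_text(json.dumps(cfg, indent=2))
    import pandas as pd

    hist = pd.DataFrame({"epoch": range(len(model.history["loss"])),
                         "loss": model.history["loss"]})
    hist.to_csv(out_dir / "cae_history.csv", index=False)
    return {"weights": str(out_dir / "cae_weights.npz"),
            "config": str(out_dir / "cae_config.json"),
            "history": str(out_dir / "cae_history.csv")}


def load_cae(in_dir: Path | str) -> CAEModel:
    in_dir = Path(in_dir)
    cfg = json.loads((in_dir / "cae_config.json").read_text())
    cfg["input_size"] = tuple(cfg["input_size"])
    model = build_cae(CAEConfig(**cfg), seed=0)
    with np.load(in_dir / "cae_weights.npz") as arrays:
        for i, p in enumerate(model.encoder.params()):
            p.value[...] = arrays[f"enc_{i}"]
        for i, p in enumerate(model.decoder.params()):
            p.value[...] = arrays[f"dec_{i}"]
    return model
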