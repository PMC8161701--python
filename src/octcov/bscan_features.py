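"""Per-B-scan preprocessing, augmentation and embedding extraction.

Mirrors the architectural contract of the clinical pipeline's CNN stage:
center-crop landscape B-scans to a square, resize to the network input side,
train a per-B-scan multi-label classifier (three independent sigmoid outputs,
summed binary cross-entropies, Adam, early stopping on validation loss with
the best checkpoint kept), then freeze it and emit the penultimate-layer
activations as a fixed-length embedding per B-scan.

The backbone is pluggable.  The default, ``small_mlp``, is a compact seeded
numpy multilayer perceptron — hidden ReLU layer, an ``embedding_dim`` dense
ReLU layer (the embedding), dropout 0.2 and a 3-sigmoid head — sized for
desk-scale synthetic images rather than GPU-scale transfer learning.  The
``identity`` backbone passes precomputed per-scan feature vectors straight
through, which is what feature-mode cohorts use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from PIL import Image
from skimage.transform import AffineTransform, warp

from .errors import ConfigurationError, DataError, ShapeError, TrainingDivergenceError


@dataclass(frozen=True)
class ExtractorConfig:
    backbone: str = "small_mlp"  # or "identity"
    embedding_dim: int = 256
    hidden_dim: int = 64
    dropout: float = 0.2
    n_outputs: int = 3
    learning_rate: float = 1e-4
    batch_size: int = 16
    max_epochs: int = 50
    patience: int = 10
    input_side: int = 299
    augment: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embedding_dim < 1:
            raise ConfigurationError("embedding_dim must be >= 1")
        if not (0.0 <= self.dropout < 1.0):
            raise ConfigurationError("dropout must be in [0, 1)")
        if self.patience > self.max_epochs:
            raise ConfigurationError("patience must be <= max_epochs")
        if self.backbone not in ("small_mlp", "identity"):
            raise ConfigurationError(f"unknown backbone {self.backbone!r}")


@dataclass(frozen=True)
class Embedding:
    """Fixed-length per-B-scan feature vector with its provenance."""

    vector: np.ndarray
    source: tuple[str, int, int]  # (patient_id, visit_index, bscan_index)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.vector)):
            raise ShapeError("embedding contains non-finite values")


# ---------------------------------------------------------------------------
# preprocessing and augmentation
# ---------------------------------------------------------------------------


def preprocess(image: np.ndarray, input_side: int = 299) -> np.ndarray:
    """Center-crop a landscape B-scan to a square and resize to the net input.

    A height×width raster with width ≥ height is cropped to height×height
    about the horizontal centre and resized to ``input_side`` square (the
    aspect ratio of the square crop is preserved trivially).  Intensities are
    scaled to [0, 1]; no denoising or contrast enhancement is applied.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ShapeError(f"expected a 2-D grayscale image, got shape {img.shape}")
    h, w = img.shape
    if w < h:
        raise ShapeError(f"expected landscape or square raster, got {h}x{w}")
    left = (w - h) // 2
    square = img[:, left:left + h]
    if square.shape[0] != input_side:
        pil = Image.fromarray(square.astype(np.float32), mode="F")
        square = np.asarray(pil.resize((input_side, input_side), Image.BILINEAR))
    out = np.asarray(square, dtype=np.float64)
    if image.dtype == np.uint8 or out.max() > 1.0:
        out = out / 255.0
    return np.clip(out, 0.0, 1.0)


def augment(image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random rotation ≤15°, shear ≤10%, and width/height shifts ≤10%.

    Draws four independent uniforms from ``rng`` (rotation degrees, shear
    fraction, x shift fraction, y shift fraction); all-zero draws give the
    identity transform.  Output shape equals input shape.
    """
    img = np.asarray(image, dtype=np.float64)
    h, w = img.shape
    theta = np.deg2rad(rng.uniform(-15.0, 15.0))
    shear = rng.uniform(-0.10, 0.10)
    dx = rng.uniform(-0.10, 0.10) * w
    dy = rng.uniform(-0.10, 0.10) * h
    center = np.array([w / 2.0, h / 2.0])
    to_origin = AffineTransform(translation=-center)
    transform = AffineTransform(rotation=theta, shear=np.arctan(shear))
    back = AffineTransform(translation=center + np.array([dx, dy]))
    chain = to_origin + transform + back
    return warp(img, chain.inverse, mode="edge", preserve_range=True)


# ---------------------------------------------------------------------------
# extractors
# ---------------------------------------------------------------------------


class IdentityExtractor:
    """Pass-through for cohorts that already carry per-scan feature vectors."""

    def __init__(self, config: ExtractorConfig):
        self.config = config

    def fit(self, train_x, train_y, val_x, val_y):  # noqa: D102 - no-op
        return self

    def embed(self, vector: np.ndarray) -> np.ndarray:
        v = np.asarray(vector, dtype=np.float64).ravel()
        if v.shape[0] != self.config.embedding_dim:
            raise ShapeError(
                f"expected feature length {self.config.embedding_dim}, got {v.shape[0]}"
            )
        return v


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class MLPExtractor:
    """Seeded numpy MLP honouring the per-B-scan training contract.

    Architecture: flattened image → dense(hidden_dim, ReLU) →
    dense(embedding_dim, ReLU) → dropout → dense(3, sigmoid).  Trained with
    Adam on the sum of the three binary cross-entropies, shuffled minibatches,
    optional augmentation of training images each epoch, and early stopping on
    validation loss with the best checkpoint restored.  ``embed`` returns the
    post-ReLU embedding-layer activations with dropout disabled, so inference
    is deterministic for frozen weights.
    """

    def __init__(self, config: ExtractorConfig):
        self.config = config
        self._params: dict[str, np.ndarray] | None = None
        self.history: list[float] = []
        self.best_epoch: int | None = None

    # -- internals -----------------------------------------------------------

    def _init_params(self, n_in: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
        c = self.config
        def he(n_out, n_inp):
            return rng.standard_normal((n_out, n_inp)) * np.sqrt(2.0 / n_inp)
        return {
            "W1": he(c.hidden_dim, n_in), "b1": np.zeros(c.hidden_dim),
            "W2": he(c.embedding_dim, c.hidden_dim), "b2": np.zeros(c.embedding_dim),
            "W3": he(c.n_outputs, c.embedding_dim), "b3": np.zeros(c.n_outputs),
        }

    def _forward(self, x: np.ndarray, params, drop_mask=None):
        h1 = np.maximum(params["W1"] @ x.T + params["b1"][:, None], 0.0)
        emb = np.maximum(params["W2"] @ h1 + params["b2"][:, None], 0.0)
        emb_d = emb if drop_mask is None else emb * drop_mask
        logits = params["W3"] @ emb_d + params["b3"][:, None]
        return h1, emb, emb_d, _sigmoid(logits)

    @staticmethod
    def _bce_sum(p: np.ndarray, y: np.ndarray) -> float:
        eps = 1e-12
        per_output = -(y.T * np.log(p + eps) + (1 - y.T) * np.log(1 - p + eps))
        return float(per_output.sum(axis=0).mean())

    def _val_loss(self, x: np.ndarray, y: np.ndarray, params) -> float:
        *_, p = self._forward(x, params)
        return self._bce_sum(p, y)

    # -- public API ----------------------------------------------------------

    def fit(self, train_x: np.ndarray, train_y: np.ndarray,
            val_x: np.ndarray, val_y: np.ndarray) -> "MLPExtractor":
        c = self.config
        if len(train_x) == 0 or len(val_x) == 0:
            raise DataError("training and validation sets must be non-empty")
        train_x = np.asarray(train_x, dtype=np.float64).reshape(len(train_x), -1)
        val_x = np.asarray(val_x, dtype=np.float64).reshape(len(val_x), -1)
        train_y = np.asarray(train_y, dtype=np.float64).reshape(len(train_x), c.n_outputs)
        val_y = np.asarray(val_y, dtype=np.float64).reshape(len(val_x), c.n_outputs)

        rng = np.random.default_rng(c.seed)
        params = self._init_params(train_x.shape[1], rng)
        adam_m = {k: np.zeros_like(v) for k, v in params.items()}
        adam_v = {k: np.zeros_like(v) for k, v in params.items()}
        step = 0
        best_loss = np.inf
        best_params = {k: v.copy() for k, v in params.items()}
        best_epoch = 0
        wait = 0
        keep_prob = 1.0 - c.dropout
        side = int(round(np.sqrt(train_x.shape[1])))
        can_augment = c.augment and side * side == train_x.shape[1]

        for epoch in range(1, c.max_epochs + 1):
            order = rng.permutation(len(train_x))
            for start in range(0, len(order), c.batch_size):
                batch = order[start:start + c.batch_size]
                xb = train_x[batch]
                if can_augment:
                    xb = np.stack([
                        augment(row.reshape(side, side), rng).ravel() for row in xb
                    ])
                yb = train_y[batch]
                mask = (rng.random((c.embedding_dim, len(batch))) < keep_prob) / keep_prob
                h1, emb, emb_d, p = self._forward(xb, params, drop_mask=mask)

                n = len(batch)
                dlogits = (p - yb.T) / n  # BCE+sigmoid gradient
                grads = {
                    "W3": dlogits @ emb_d.T, "b3": dlogits.sum(axis=1),
                }
                demb = (params["W3"].T @ dlogits) * mask * (emb > 0)
                grads["W2"] = demb @ h1.T
                grads["b2"] = demb.sum(axis=1)
                dh1 = (params["W2"].T @ demb) * (h1 > 0)
                grads["W1"] = dh1 @ xb
                grads["b1"] = dh1.sum(axis=1)

                step += 1
                for k in params:
                    adam_m[k] = 0.9 * adam_m[k] + 0.1 * grads[k]
                    adam_v[k] = 0.999 * adam_v[k] + 0.001 * grads[k] ** 2
                    m_hat = adam_m[k] / (1 - 0.9 ** step)
                    v_hat = adam_v[k] / (1 - 0.999 ** step)
                    params[k] -= c.learning_rate * m_hat / (np.sqrt(v_hat) + 1e-8)

            val_loss = self._val_loss(val_x, val_y, params)
            if not np.isfinite(val_loss):
                raise TrainingDivergenceError(f"non-finite validation loss at epoch {epoch}")
            self.history.append(val_loss)
            if val_loss < best_loss - 1e-12:
                best_loss, best_epoch, wait = val_loss, epoch, 0
                best_params = {k: v.copy() for k, v in params.items()}
            else:
                wait += 1
                if wait >= c.patience:
                    break

        self._params = best_params
        self.best_epoch = best_epoch
        self.best_val_loss = best_loss
        return self

    def embed(self, image: np.ndarray) -> np.ndarray:
        if self._params is None:
            raise DataError("extractor is not trained")
        x = np.asarray(image, dtype=np.float64).reshape(1, -1)
        if x.shape[1] != self._params["W1"].shape[1]:
            raise ShapeError(
                f"expected flattened input of length {self._params['W1'].shape[1]}, "
                f"got {x.shape[1]}"
            )
        _, emb, _, _ = self._forward(x, self._params)
        return emb[:, 0].copy()

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        if self._params is None:
            raise DataError("extractor is not trained")
        x = np.asarray(image, dtype=np.float64).reshape(1, -1)
        *_, p = self._forward(x, self._params)
        return p[:, 0].copy()


def make_extractor(config: ExtractorConfig):
    if config.backbone == "identity":
        return IdentityExtractor(config)
    return MLPExtractor(config)


def train_extractor(train_scans: Sequence[np.ndarray], train_labels: np.ndarray,
                    val_scans: Sequence[np.ndarray], val_labels: np.ndarray,
                    config: ExtractorConfig):
    """Fit the configured backbone on per-B-scan data with visit-level labels."""
    extractor = make_extractor(config)
    if isinstance(extractor, IdentityExtractor):
        return extractor
    if len(train_scans) == 0 or len(val_scans) == 0:
        raise DataError("training and validation sets must be non-empty")
    return extractor.fit(np.asarray(train_scans), train_labels,
                         np.asarray(val_scans), val_labels)


def embed(extractor, bscan: np.ndarray, source: tuple[str, int, int] | None = None):
    """Embed one B-scan; returns an :class:`Embedding` when a source is given."""
    vector = extractor.embed(bscan)
    if source is None:
        return vector
    return Embedding(vector=vector, source=source)


def save_embeddings(matrix: np.ndarray, sources: Sequence[tuple[str, int, int]],
                    prefix) -> None:
    """Write an (n, d) embedding matrix with its sidecar row index CSV."""
    import pandas as pd
    from pathlib import Path

    prefix = Path(prefix)
    np.save(prefix.with_suffix(".npy"), np.asarray(matrix))
    pd.DataFrame(
        [{"patient_id": p, "visit_index": v, "bscan_index": b, "row": i}
         for i, (p, v, b) in enumerate(sources)]
    ).to_csv(prefix.with_suffix(".csv"), index=False)
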