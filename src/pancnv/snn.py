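"""Self-normalizing neural-network classifier.

A plain feed-forward network whose hidden layers use the scaled
exponential linear unit

    selu(x) = lambda * x            for x > 0
    selu(x) = lambda * (alpha*e^x - alpha)   for x <= 0

with scale lambda = 1.0507 and alpha = 1.6733.  With zero-mean,
unit-variance inputs, weights drawn from N(0, 1/fan_in) and alpha
dropout, activations are attracted to a zero-mean/unit-variance fixed
point layer after layer, which removes the need for explicit batch
normalization.  The default architecture is three hidden layers of 200
units; the output layer is linear with a softmax, trained by mini-batch
Adam on the multiclass cross-entropy.

Everything is implemented on NumPy arrays; a model is a list of weight
matrices plus the per-feature standardization statistics of its
training data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from pancnv._seeds import derive_seed
from pancnv.matrix import CNVMatrix

logger = logging.getLogger(__name__)

SELU_LAMBDA = 1.0507
SELU_ALPHA = 1.6733


@dataclass(frozen=True)
class SNNConfig:
    """Architecture and training settings.

    ``encode_states=True`` expands each discrete CNV feature into one
    indicator column per state value before standardization; copy-number
    states are categories of alteration, and the indicator coding lets
    the network weigh, say, amplification separately from gain instead
    of forcing a linear response over the ordinal code.
    """

    hidden_layers: int = 3
    hidden_width: int = 200
    lambda_: float = SELU_LAMBDA
    alpha_: float = SELU_ALPHA
    dropout_rate: float = 0.05
    epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    encode_states: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_layers < 1 or self.hidden_width < 1:
            raise ValueError("hidden_layers and hidden_width must be >= 1")
        if self.lambda_ <= 0 or self.alpha_ <= 0:
            raise ValueError("lambda_ and alpha_ must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


# ---------------------------------------------------------------------------
# SELU primitives
# ---------------------------------------------------------------------------

def selu(x, lambda_: float = SELU_LAMBDA, alpha_: float = SELU_ALPHA):
    """Scaled ELU activation; continuous, strictly increasing, bounded
    below by -lambda*alpha."""
    x = np.asarray(x, dtype=float)
    out = lambda_ * np.where(x > 0, x, alpha_ * np.expm1(np.minimum(x, 0.0)))
    return out if out.ndim else float(out)


def _selu_grad(x, lambda_: float = SELU_LAMBDA, alpha_: float = SELU_ALPHA):
    return lambda_ * np.where(x > 0, 1.0, alpha_ * np.exp(np.minimum(x, 0.0)))


def init_self_normalizing(shape: tuple[int, int], seed) -> np.ndarray:
    """Weights ~ N(0, 1/fan_in); ``shape`` is (fan_in, fan_out).

    ``seed`` may be an int or a Generator.
    """
    fan_in = shape[0]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.normal(0.0, np.sqrt(1.0 / fan_in), size=shape)


def _alpha_dropout_consts(rate: float, lambda_: float, alpha_: float):
    q = 1.0 - rate
    a_prime = -lambda_ * alpha_  # the SELU saturation value
    scale = 1.0 / np.sqrt(q + a_prime**2 * q * (1.0 - q))
    shift = -scale * (1.0 - q) * a_prime
    return a_prime, scale, shift


def alpha_dropout(
    activations,
    rate: float,
    seed,
    training: bool = True,
    lambda_: float = SELU_LAMBDA,
    alpha_: float = SELU_ALPHA,
):
    """Dropout for SELU networks.

    In training mode, dropped units are set to the SELU saturation value
    ``-lambda*alpha`` (not zero), and an affine correction restores zero
    mean and unit variance in expectation for standard-normal inputs.
    Identity when not training or rate is 0.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    activations = np.asarray(activations, dtype=float)
    if not training or rate == 0.0:
        return activations
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a_prime, scale, shift = _alpha_dropout_consts(rate, lambda_, alpha_)
    keep = rng.random(activations.shape) >= rate
    return scale * np.where(keep, activations, a_prime) + shift


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------

class SNNClassifier:
    """fit/predict interface over raw (unstandardized) feature arrays.

    Standardization statistics are computed on the data passed to
    :meth:`fit` only, so cross-validation folds never leak held-out
    information into the scaler.
    """

    def __init__(self, config: SNNConfig | None = None, n_classes: int | None = None):
        self.config = config or SNNConfig()
        self._n_classes = n_classes
        self.loss_history: list[float] = []

    # -- internals -------------------------------------------------------
    def _forward(self, A0, rng=None, training=False):
        cfg = self.config
        caches = []
        h = A0
        for l in range(cfg.hidden_layers):
            z = h @ self.weights[l] + self.biases[l]
            a = selu(z, cfg.lambda_, cfg.alpha_)
            if training and cfg.dropout_rate > 0:
                a_prime, scale, _shift = _alpha_dropout_consts(
                    cfg.dropout_rate, cfg.lambda_, cfg.alpha_
                )
                keep = rng.random(a.shape) >= cfg.dropout_rate
                a_dropped = scale * np.where(keep, a, a_prime) + _shift
                caches.append((h, z, scale * keep))
                a = a_dropped
            else:
                caches.append((h, z, None))
            h = a
        logits = h @ self.weights[-1] + self.biases[-1]
        return logits, h, caches

    def _encode(self, X: np.ndarray) -> np.ndarray:
        if not self.config.encode_states:
            return np.asarray(X, dtype=float)
        X = np.asarray(X)
        return np.concatenate(
            [(X == v).astype(float) for v in self.categories_], axis=1
        )

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SNNClassifier":
        cfg = self.config
        y = np.asarray(y, dtype=np.int64)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training data contains a single class")
        c = self._n_classes or int(classes.max()) + 1

        self.categories_ = np.unique(np.asarray(X)) if cfg.encode_states else None
        X = self._encode(X)

        self.mu_ = X.mean(axis=0)
        sd = X.std(axis=0)
        constant = sd == 0
        if constant.any():
            logger.warning(
                "%d constant feature(s) excluded from standardization",
                int(constant.sum()),
            )
        self.sigma_ = np.where(constant, 1.0, sd)
        A = (X - self.mu_) / self.sigma_

        rng = np.random.default_rng(cfg.seed)
        dims = [X.shape[1]] + [cfg.hidden_width] * cfg.hidden_layers + [c]
        self.weights = [
            init_self_normalizing((dims[l], dims[l + 1]), rng)
            for l in range(len(dims) - 1)
        ]
        self.biases = [np.zeros(dims[l + 1]) for l in range(len(dims) - 1)]
        self.n_classes_ = c

        params = self.weights + self.biases
        m_t = [np.zeros_like(p) for p in params]
        v_t = [np.zeros_like(p) for p in params]
        step = 0
        b1, b2, eps = 0.9, 0.999, 1e-8

        n = X.shape[0]
        self.loss_history = []
        for _epoch in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                Ab, yb = A[idx], y[idx]
                logits, h, caches = self._forward(Ab, rng, training=True)
                probs = _softmax(logits)
                epoch_loss += -np.log(
                    np.clip(probs[np.arange(idx.size), yb], 1e-12, None)
                ).sum()

                dlogits = probs.copy()
                dlogits[np.arange(idx.size), yb] -= 1.0
                dlogits /= idx.size

                grads_w = [None] * len(self.weights)
                grads_b = [None] * len(self.biases)
                grads_w[-1] = h.T @ dlogits
                grads_b[-1] = dlogits.sum(axis=0)
                da = dlogits @ self.weights[-1].T
                for l in range(cfg.hidden_layers - 1, -1, -1):
                    h_in, z, drop_slope = caches[l]
                    if drop_slope is not None:
                        da = da * drop_slope
                    dz = da * _selu_grad(z, cfg.lambda_, cfg.alpha_)
                    grads_w[l] = h_in.T @ dz
                    grads_b[l] = dz.sum(axis=0)
                    if l > 0:
                        da = dz @ self.weights[l].T

                step += 1
                grads = grads_w + grads_b
                for p, g, m, v in zip(params, grads, m_t, v_t):
                    if cfg.optimizer == "adam":
                        m *= b1
                        m += (1 - b1) * g
                        v *= b2
                        v += (1 - b2) * g * g
                        m_hat = m / (1 - b1**step)
                        v_hat = v / (1 - b2**step)
                        p -= cfg.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
                    else:
                        p -= cfg.learning_rate * g
            self.loss_history.append(epoch_loss / n)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        A = (self._encode(X) - self.mu_) / self.sigma_
        logits, _, _ = self._forward(A, training=False)
        return _softmax(logits)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)


def snn_factory(config: SNNConfig | None = None, n_classes: int | None = None):
    """Classifier factory for :func:`pancnv.evaluation.cross_validate`:
    maps a seed to a fresh :class:`SNNClassifier`."""
    base = config or SNNConfig()

    def make(seed: int) -> SNNClassifier:
        return SNNClassifier(replace(base, seed=seed), n_classes=n_classes)

    return make


# ---------------------------------------------------------------------------
# trained-model container + serialization
# ---------------------------------------------------------------------------

@dataclass
class SNNModel:
    """A trained network bound to its feature subset, class names and
    standardization statistics."""

    classifier: SNNClassifier
    feature_ids: list[str]
    class_names: list[str]
    config: SNNConfig

    def predict(self, matrix: CNVMatrix) -> tuple[np.ndarray, np.ndarray]:
        """Class labels (argmax) and per-sample class probabilities."""
        cols = matrix.columns(self.feature_ids)
        probs = self.classifier.predict_proba(matrix.values[:, cols])
        return np.argmax(probs, axis=1), probs


def train_snn(
    matrix: CNVMatrix, feature_subset: Sequence[str], config: SNNConfig | None = None
) -> SNNModel:
    """Train the self-normalizing classifier on a feature subset of a cohort."""
    config = config or SNNConfig()
    if len(feature_subset) == 0:
        raise ValueError("feature subset is empty")
    cols = matrix.columns(list(feature_subset))
    clf = SNNClassifier(config, n_classes=matrix.n_classes)
    clf.fit(matrix.values[:, cols], matrix.labels)
    return SNNModel(
        classifier=clf,
        feature_ids=list(feature_subset),
        class_names=list(matrix.class_names),
        config=config,
    )


def save_model(model: SNNModel, directory) -> None:
    """Model directory = JSON manifest (architecture, SELU constants,
    feature subset) + NPZ container of weights and scaler statistics."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    clf = model.classifier
    manifest = {
        "format": "pancnv-snn-v1",
        "config": asdict(model.config),
        "feature_ids": model.feature_ids,
        "class_names": model.class_names,
        "n_classes": clf.n_classes_,
        "layer_shapes": [list(w.shape) for w in clf.weights],
    }
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n", encoding="utf-8"
    )
    arrays = {"mu": clf.mu_, "sigma": clf.sigma_}
    if getattr(clf, "categories_", None) is not None:
        arrays["categories"] = clf.categories_
    for l, (w, b) in enumerate(zip(clf.weights, clf.biases)):
        arrays[f"W{l}"] = w
        arrays[f"b{l}"] = b
    np.savez(directory / "weights.npz", **arrays)


def load_model(directory) -> SNNModel:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text(encoding="utf-8"))
    if manifest.get("format") != "pancnv-snn-v1":
        raise ValueError(f"{directory}: not a pancnv SNN model directory")
    config = SNNConfig(**manifest["config"])
    clf = SNNClassifier(config, n_classes=manifest["n_classes"])
    with np.load(directory / "weights.npz") as npz:
        clf.mu_ = npz["mu"]
        clf.sigma_ = npz["sigma"]
        clf.categories_ = npz["categories"] if "categories" in npz else None
        n_layers = len(manifest["layer_shapes"])
        clf.weights = [npz[f"W{l}"] for l in range(n_layers)]
        clf.biases = [npz[f"b{l}"] for l in range(n_layers)]
    clf.n_classes_ = manifest["n_classes"]
    return SNNModel(
        classifier=clf,
        feature_ids=list(manifest["feature_ids"]),
        class_names=list(manifest["class_names"]),
        config=config,
    )
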