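"""The embedding-based genotype-classification neural network.

Each SNP gets a learned embedding vector (a per-SNP ``information-dense``
representation of its cluster layout); the embedding is concatenated with
the two raw intensity features (R, Theta) and passed through two
rectified dense layers and a 3-unit softmax output over (AA, AB, BB).
Training minimizes categorical focal cross-entropy

    L = -alpha * (1 - p_t)**gamma * log(p_t)

with the Adam optimizer, early-stopping on validation loss, and
best-weight restoration.  The network is small enough that plain numpy
forward/backward passes train it in seconds on a CPU.

No-call (NC) is never a predicted class: the network's whole purpose is to
assign one of the three diploid genotypes to observations Gencall declined
to call.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import UnknownSnpError
from .snp_metrics_io import (
    GENOTYPE_CLASSES,
    EncodedDataset,
    SnpMetricsRecord,
    encode_dataset,
)

logger = logging.getLogger(__name__)

_EPS_CLIP = 1e-7  # p_t clipped to [eps, 1-eps] before the log


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    Defaults are the production recipe: a 50-dimensional SNP embedding,
    dense layers of 64 then 160 rectified units, a 3-class softmax output,
    focal loss with gamma=2 / alpha=0.25, Adam at learning rate 1e-4 for at
    most 11 epochs with early-stopping patience 5 on validation loss.
    """

    embedding_dim: int = 50
    hidden_units: tuple[int, ...] = (64, 160)
    n_classes: int = 3
    learning_rate: float = 1e-4
    max_epochs: int = 11
    early_stop_patience: int = 5
    focal_gamma: float = 2.0
    focal_alpha: float = 0.25
    batch_size: int = 512
    seed: int = 0

    def __post_init__(self):
        if self.n_classes != 3:
            raise ValueError("n_classes is fixed at 3 (AA, AB, BB)")
        if self.embedding_dim < 1 or any(h < 1 for h in self.hidden_units):
            raise ValueError("all layer sizes must be positive")
        self.hidden_units = tuple(int(h) for h in self.hidden_units)


@dataclass
class TrainedGenotyper:
    """A trained network: vocabulary, embedding table, dense-layer weights.

    ``weights`` is a list of (W, b) pairs, hidden layers first, output
    layer last.  ``history`` holds per-epoch train/validation loss and
    accuracy.
    """

    vocabulary: dict
    embedding: np.ndarray            # (vocab, embedding_dim)
    weights: list                    # [(W, b), ...]; last pair is the output layer
    config: ModelConfig
    history: dict = field(default_factory=dict)

    @property
    def n_parameters(self) -> int:
        return int(self.embedding.size + sum(W.size + b.size for W, b in self.weights))

    # ---- persistence: single self-describing .npz archive -------------
    FORMAT_VERSION = 1

    def save(self, path) -> None:
        """Write a single self-contained archive (numpy .npz)."""
        meta = {
            "format_version": self.FORMAT_VERSION,
            "vocabulary": self.vocabulary,
            "config": asdict(self.config),
            "history": self.history,
            "n_layers": len(self.weights),
        }
        arrays = {"embedding": self.embedding,
                  "meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
        for i, (W, b) in enumerate(self.weights):
            arrays[f"W{i}"] = W
            arrays[f"b{i}"] = b
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "TrainedGenotyper":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            if meta["format_version"] != cls.FORMAT_VERSION:
                raise ValueError(f"unsupported model archive version {meta['format_version']}")
            cfg = meta["config"]
            cfg["hidden_units"] = tuple(cfg["hidden_units"])
            weights = [(z[f"W{i}"], z[f"b{i}"]) for i in range(meta["n_layers"])]
            return cls(
                vocabulary=meta["vocabulary"],
                embedding=z["embedding"],
                weights=weights,
                config=ModelConfig(**cfg),
                history=meta["history"],
            )


@dataclass
class PredictionResult:
    """Per-record 3-class probabilities and the argmax genotype.

    ``kept_indices`` maps rows back into the input record list when some
    records were excluded for unknown snp_ids (``n_excluded`` counts them).
    """

    probabilities: np.ndarray        # (n, 3)
    predicted_genotype: list         # of "AA"/"AB"/"BB"
    max_probability: np.ndarray      # (n,)
    kept_indices: np.ndarray = None  # (n,) indices into the input records
    n_excluded: int = 0

    def __len__(self) -> int:
        return len(self.predicted_genotype)


# ---------------------------------------------------------------------------
# numerics

def softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise stable softmax (max-subtracted)."""
    z = np.atleast_2d(z)
    e = np.exp(z - z.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def focal_loss(
    probabilities: np.ndarray,
    targets: np.ndarray,
    gamma: float = 2.0,
    alpha: float = 0.25,
) -> float:
    """Mean categorical focal cross-entropy.

    With ``p_t`` the probability assigned to the true class, each term is
    ``-alpha * (1 - p_t)**gamma * log(p_t)``; p_t is clipped to
    [1e-7, 1 - 1e-7] before the log.  gamma=0, alpha=1 recovers plain
    categorical cross-entropy.
    """
    p = np.atleast_2d(probabilities)
    t = np.atleast_2d(targets)
    p_t = np.clip((p * t).sum(axis=1), _EPS_CLIP, 1.0 - _EPS_CLIP)
    return float(np.mean(-alpha * (1.0 - p_t) ** gamma * np.log(p_t)))


def _forward_batch(model: TrainedGenotyper, idx: np.ndarray, feats: np.ndarray,
                   return_hidden: bool = False):
    x = np.concatenate([model.embedding[idx], feats], axis=1)
    activations = [x]
    a = x
    for W, b in model.weights[:-1]:
        a = relu(a @ W + b)
        activations.append(a)
    W, b = model.weights[-1]
    probs = softmax(a @ W + b)
    if return_hidden:
        return probs, activations
    return probs


def forward(model: TrainedGenotyper, snp_index: int, r: float, theta: float) -> np.ndarray:
    """Probability 3-vector for a single (snpID, R, Theta) observation.

    Looks up the SNP's embedding row, concatenates (r, theta), applies each
    dense layer (affine then rectifier) and the softmax output layer.
    """
    vocab_size = model.embedding.shape[0]
    if not (0 <= snp_index < vocab_size):
        raise UnknownSnpError([f"index {snp_index} (vocabulary size {vocab_size})"])
    return _forward_batch(
        model, np.array([snp_index]), np.array([[r, theta]], dtype=float)
    )[0]


# ---------------------------------------------------------------------------
# training

def _init_model(vocabulary: dict, config: ModelConfig) -> TrainedGenotyper:
    rng = np.random.default_rng(config.seed)
    vocab_size = len(vocabulary)
    # Keras-style inits: uniform(-0.05, 0.05) embeddings, Glorot-uniform dense.
    embedding = rng.uniform(-0.05, 0.05, size=(vocab_size, config.embedding_dim))
    sizes = [config.embedding_dim + 2, *config.hidden_units, config.n_classes]
    weights = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        W = rng.uniform(-limit, limit, size=(fan_in, fan_out))
        b = np.zeros(fan_out)
        weights.append((W, b))
    return TrainedGenotyper(vocabulary, embedding, weights, config)


def _evaluate(model: TrainedGenotyper, data: EncodedDataset) -> tuple[float, float]:
    """(mean focal loss, accuracy) over a dataset, in batches."""
    cfg = model.config
    n = len(data)
    losses = np.empty(n)
    correct = 0
    bs = max(cfg.batch_size, 4096)
    for start in range(0, n, bs):
        sl = slice(start, min(start + bs, n))
        probs = _forward_batch(model, data.snp_index[sl], data.features[sl])
        t = data.targets[sl]
        p_t = np.clip((probs * t).sum(axis=1), _EPS_CLIP, 1.0 - _EPS_CLIP)
        losses[sl] = -cfg.focal_alpha * (1.0 - p_t) ** cfg.focal_gamma * np.log(p_t)
        correct += int((probs.argmax(axis=1) == t.argmax(axis=1)).sum())
    return float(losses.mean()), correct / n


def _focal_dlogits(probs: np.ndarray, targets: np.ndarray,
                   gamma: float, alpha: float) -> np.ndarray:
    """d(mean focal loss)/d(logits) for a batch (softmax chained in)."""
    p_t = np.clip((probs * targets).sum(axis=1), _EPS_CLIP, 1.0 - _EPS_CLIP)
    one_m = 1.0 - p_t
    # dL/dp_t; the gamma term vanishes identically at gamma == 0
    dl_dpt = -alpha * (one_m ** gamma / p_t - gamma * one_m ** (gamma - 1.0) * np.log(p_t))
    dz = (dl_dpt * p_t)[:, None] * (targets - probs)
    return dz / probs.shape[0]


class _Adam:
    """Adam with bias correction (beta1=0.9, beta2=0.999, eps=1e-7)."""

    def __init__(self, params: dict, lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def train(
    encoded_train: EncodedDataset,
    encoded_val: EncodedDataset,
    config: Optional[ModelConfig] = None,
) -> TrainedGenotyper:
    """Train the network with mini-batch Adam on focal loss.

    Stops at ``max_epochs`` or when validation loss has failed to improve
    for ``early_stop_patience`` consecutive epochs, whichever comes first,
    and always restores the best-validation-loss weights.  Both datasets
    must be encoded against the same vocabulary.  Fully deterministic for a
    fixed ``config.seed``.
    """
    if config is None:
        config = ModelConfig()
    if len(encoded_train) == 0:
        raise ValueError("training set is empty")
    if encoded_train.vocabulary != encoded_val.vocabulary:
        raise ValueError("train and validation sets use different vocabularies")

    model = _init_model(encoded_train.vocabulary, config)
    params = {"E": model.embedding}
    for i, (W, b) in enumerate(model.weights):
        params[f"W{i}"], params[f"b{i}"] = W, b
    opt = _Adam(params, config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xB10C]))

    history = {"loss": [], "accuracy": [], "val_loss": [], "val_accuracy": []}
    best_val = np.inf
    best_state = None
    wait = 0
    n = len(encoded_train)
    n_layers = len(model.weights)

    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            idx = encoded_train.snp_index[batch]
            feats = encoded_train.features[batch]
            targets = encoded_train.targets[batch]

            probs, acts = _forward_batch(model, idx, feats, return_hidden=True)
            dz = _focal_dlogits(probs, targets, config.focal_gamma, config.focal_alpha)

            grads = {}
            delta = dz
            for li in range(n_layers - 1, -1, -1):
                W, _ = model.weights[li]
                a_prev = acts[li]
                grads[f"W{li}"] = a_prev.T @ delta
                grads[f"b{li}"] = delta.sum(axis=0)
                delta = delta @ W.T
                if li > 0:  # through the rectifier of the previous layer
                    delta = delta * (acts[li] > 0)
            dE = np.zeros_like(model.embedding)
            np.add.at(dE, idx, delta[:, : config.embedding_dim])
            grads["E"] = dE
            opt.step(params, grads)

        tr_loss, tr_acc = _evaluate(model, encoded_train)
        val_loss, val_acc = _evaluate(model, encoded_val)
        history["loss"].append(tr_loss)
        history["accuracy"].append(tr_acc)
        history["val_loss"].append(val_loss)
        history["val_accuracy"].append(val_acc)
        logger.info(
            "epoch %d/%d loss=%.3e acc=%.4f val_loss=%.3e val_acc=%.4f",
            epoch + 1, config.max_epochs, tr_loss, tr_acc, val_loss, val_acc,
        )

        if val_loss < best_val:
            best_val = val_loss
            best_state = {k: v.copy() for k, v in params.items()}
            wait = 0
        else:
            wait += 1
            if wait >= max(config.early_stop_patience, 1):
                logger.info("early stopping at epoch %d", epoch + 1)
                break

    if best_state is not None:
        model.embedding[...] = best_state["E"]
        for i, (W, b) in enumerate(model.weights):
            W[...] = best_state[f"W{i}"]
            b[...] = best_state[f"b{i}"]
    model.history = history
    return model


def grid_search(
    encoded_train: EncodedDataset,
    encoded_val: EncodedDataset,
    layer_size_grid: Sequence[int] = tuple(range(32, 161, 32)),
    base_config: Optional[ModelConfig] = None,
    search_epochs: int = 3,
) -> tuple[tuple[int, int], list]:
    """Pick the (hidden1, hidden2) pair minimizing final validation loss.

    Every pair in ``layer_size_grid`` x ``layer_size_grid`` is trained for
    ``search_epochs`` epochs; ties break toward the smaller parameter
    count.  Returns the winning pair and the full results table of
    ``(pair, val_loss, n_parameters)``.
    """
    grid = [int(s) for s in layer_size_grid]
    if not grid:
        raise ValueError("layer_size_grid is empty")
    base = base_config or ModelConfig()
    results = []
    for s1 in grid:
        for s2 in grid:
            cfg = ModelConfig(
                embedding_dim=base.embedding_dim,
                hidden_units=(s1, s2),
                learning_rate=base.learning_rate,
                max_epochs=search_epochs,
                early_stop_patience=base.early_stop_patience,
                focal_gamma=base.focal_gamma,
                focal_alpha=base.focal_alpha,
                batch_size=base.batch_size,
                seed=base.seed,
            )
            m = train(encoded_train, encoded_val, cfg)
            results.append(((s1, s2), m.history["val_loss"][-1], m.n_parameters))
    best = min(results, key=lambda r: (r[1], r[2]))
    return best[0], results


# ---------------------------------------------------------------------------
# application

def predict(model: TrainedGenotyper, records: Sequence[SnpMetricsRecord]) -> PredictionResult:
    """Apply the trained network to records (typically the no-call set).

    Records whose snp_id is not in the model vocabulary cannot be
    predicted (their embedding row was never trained); they are excluded
    from the output with a logged count, and the surviving rows carry
    their original indices in ``kept_indices``.
    """
    kept = [i for i, r in enumerate(records) if r.snp_id in model.vocabulary]
    n_excluded = len(records) - len(kept)
    if n_excluded:
        logger.warning("%d records have snp_ids outside the model vocabulary; excluded",
                       n_excluded)
    if not kept:
        return PredictionResult(np.zeros((0, 3)), [], np.zeros(0),
                                np.array([], dtype=int), n_excluded)
    enc = encode_dataset([records[i] for i in kept], vocabulary=model.vocabulary,
                         with_targets=False)
    probs = np.concatenate([
        _forward_batch(model, enc.snp_index[s], enc.features[s])
        for s in _chunks(len(enc), 8192)
    ])
    pred_idx = probs.argmax(axis=1)  # ties resolve to the lowest index: AA < AB < BB
    return PredictionResult(
        probabilities=probs,
        predicted_genotype=[GENOTYPE_CLASSES[i] for i in pred_idx],
        max_probability=probs.max(axis=1),
        kept_indices=np.asarray(kept, dtype=int),
        n_excluded=n_excluded,
    )


def _chunks(n: int, size: int):
    for start in range(0, n, size):
        yield slice(start, min(start + size, n))


def evaluate_agreement(
    predictions: PredictionResult, reference_genotypes: Sequence[str]
) -> tuple[float, np.ndarray]:
    """Accuracy and 3x3 confusion matrix against reference genotypes.

    ``confusion[i, j]`` counts records with reference class i and
    predicted class j, classes in (AA, AB, BB) order.
    """
    if len(predictions) != len(reference_genotypes):
        raise ValueError(
            f"length mismatch: {len(predictions)} predictions vs "
            f"{len(reference_genotypes)} references"
        )
    cls = {g: i for i, g in enumerate(GENOTYPE_CLASSES)}
    confusion = np.zeros((3, 3), dtype=np.int64)
    for pred, ref in zip(predictions.predicted_genotype, reference_genotypes):
        if ref not in cls:
            raise ValueError(f"reference genotype {ref!r} is not AA/AB/BB")
        confusion[cls[ref], cls[pred]] += 1
    total = confusion.sum()
    accuracy = float(np.trace(confusion) / total) if total else float("nan")
    return accuracy, confusion
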