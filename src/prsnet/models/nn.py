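"""Layered sigmoid network for polygenic risk, trained with mini-batch
gradient descent under a staircase exponential-decay learning schedule.

Two reference architectures are provided:

* ``european`` -- locus-structured: dropout on the input, dense(3L),
  dropout, dense(L), dense(22), dense(5), dense(1), where L is the number
  of loci; 3L reflects the assumption of at most three disease haplotypes
  per locus, 22 the autosome count, 5 a small number of putative parallel
  pathways, and the final unit is the risk score.
* ``chinese`` -- fixed widths dense(50), dropout, dense(30), dropout,
  dense(10), dense(5), dense(1).

All dense activations are logistic sigmoids; the loss is mean binary
cross-entropy.  The implementation is plain numpy, seed-deterministic, and
exposes the penultimate dense layer ("modules") for interpretation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from ..datamodel import GenotypeMatrix

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "NeuralPRSModel",
    "build_nn",
    "lr_at_step",
    "train_nn",
    "nn_score",
    "penultimate_outputs",
    "SCENARIO_PRESETS",
]


@dataclass
class TrainConfig:
    """Mini-batch SGD settings.

    The learning rate at optimisation step ``t`` is
    ``lr0 * decay_rate ** floor(t / decay_steps)`` (staircase schedule).
    ``patience`` enables early stopping: training stops once the
    validation loss has not improved for that many epochs, and the best
    weights are restored.
    """

    epochs: int = 2000
    batch_size: int = 256
    lr0: float = 0.5
    decay_steps: int = 100_000
    decay_rate: float = 0.96
    staircase: bool = True
    patience: Optional[int] = None
    #: restore the weights of the best validation epoch at the end of
    #: training; defaults to on whenever patience is set.  Restoring
    #: without early stopping keeps the full training budget (useful when
    #: the loss has long plateaus) while still guarding against overfit.
    restore_best: Optional[bool] = None
    validation_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if not (0 < self.decay_rate <= 1):
            raise ValueError("decay_rate must lie in (0,1]")
        if self.patience is not None and self.patience < 1:
            raise ValueError("patience must be >= 1 when enabled")


#: training presets for the three evaluation scenarios: fitting on all
#: data, cross-validation, and training against an independent cohort.
SCENARIO_PRESETS = {
    "all-data": TrainConfig(epochs=2000, batch_size=256),
    "cross-validation": TrainConfig(epochs=1500, batch_size=1024),
    "independent-cohort": TrainConfig(epochs=2000, batch_size=256,
                                      patience=50, validation_fraction=0.2),
}


def lr_at_step(config: TrainConfig, step: int) -> float:
    """Learning rate under the (staircase) exponential-decay schedule."""
    if step < 0:
        raise ValueError("step must be >= 0")
    exponent = step / config.decay_steps
    if config.staircase:
        exponent = np.floor(exponent)
    return config.lr0 * config.decay_rate ** exponent


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_auroc: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -35.0, 35.0)))


class NeuralPRSModel:
    """Feed-forward sigmoid network defined by an ordered layer spec.

    ``layer_spec`` entries are ``("dense", width)`` or ``("dropout",
    rate)``.  Dense weights use seeded symmetric-uniform (fan-scaled)
    initialisation; dropout is inverted (inert at inference).
    """

    def __init__(self, layer_spec: Sequence[tuple], n_features: int,
                 init_seed: int = 0) -> None:
        layer_spec = [tuple(l) for l in layer_spec]
        dense_widths = [w for kind, w in layer_spec if kind == "dense"]
        if not dense_widths or dense_widths[-1] != 1:
            raise ValueError("final dense layer must have width 1")
        if any(int(w) != w or w < 1 for w in dense_widths):
            raise ValueError("dense widths must be positive integers")
        for kind, val in layer_spec:
            if kind == "dropout" and not (0 <= val < 1):
                raise ValueError(f"dropout rate {val} outside [0,1)")
            if kind not in ("dense", "dropout"):
                raise ValueError(f"unknown layer kind {kind!r}")
        self.layer_spec = layer_spec
        self.n_features = int(n_features)
        self.init_seed = int(init_seed)
        self.trained = False
        # optional input scaler (set during training when standardize=True);
        # sigmoid stacks train far more reliably on centered inputs
        self.feature_mean: Optional[np.ndarray] = None
        self.feature_sd: Optional[np.ndarray] = None
        self._init_weights()

    def _init_weights(self) -> None:
        rng = np.random.default_rng(self.init_seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        fan_in = self.n_features
        for kind, val in self.layer_spec:
            if kind != "dense":
                continue
            width = int(val)
            limit = np.sqrt(6.0 / (fan_in + width))
            self.weights.append(rng.uniform(-limit, limit, size=(fan_in, width)))
            self.biases.append(np.zeros(width))
            fan_in = width

    @property
    def dense_widths(self) -> list[int]:
        return [int(w) for kind, w in self.layer_spec if kind == "dense"]

    @property
    def penultimate_width(self) -> int:
        widths = self.dense_widths
        if len(widths) < 2:
            raise ValueError("model has no penultimate dense layer")
        return widths[-2]

    # ---- forward / backward ------------------------------------------

    def _forward(self, X: np.ndarray, *, training: bool = False,
                 rng: Optional[np.random.Generator] = None):
        """Run the network.

        Returns ``(dense_inputs, dense_outputs, masks)``: the (post-
        dropout) input to each dense layer, the raw sigmoid output of each
        dense layer, and the dropout mask applied before each dense layer
        (None when inert).
        """
        a = X
        dense_inputs: list[np.ndarray] = []
        dense_outputs: list[np.ndarray] = []
        masks: list[Optional[np.ndarray]] = []
        pending: Optional[np.ndarray] = None
        for kind, val in self.layer_spec:
            if kind == "dropout":
                if training and val > 0:
                    mask = (rng.random(a.shape) >= val) / (1.0 - val)
                    a = a * mask
                    pending = mask if pending is None else pending * mask
            else:
                k = len(dense_inputs)
                dense_inputs.append(a)
                masks.append(pending)
                pending = None
                a = _sigmoid(a @ self.weights[k] + self.biases[k])
                dense_outputs.append(a)
        return dense_inputs, dense_outputs, masks

    def _backward(self, dense_inputs, dense_outputs, masks, y: np.ndarray):
        """Gradients of mean binary cross-entropy w.r.t. weights/biases."""
        n = len(y)
        grads_w = [None] * len(self.weights)
        grads_b = [None] * len(self.weights)
        out = dense_outputs[-1][:, 0]
        delta = ((out - y) / n)[:, None]  # BCE + output sigmoid simplification
        for k in range(len(self.weights) - 1, -1, -1):
            grads_w[k] = dense_inputs[k].T @ delta
            grads_b[k] = delta.sum(axis=0)
            if k > 0:
                delta = delta @ self.weights[k].T
                if masks[k] is not None:
                    delta = delta * masks[k]
                raw = dense_outputs[k - 1]
                delta = delta * raw * (1.0 - raw)
        return grads_w, grads_b

    # ---- public API ---------------------------------------------------

    def _scale(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"feature width {X.shape[1] if X.ndim == 2 else '?'} does "
                f"not match model ({self.n_features})"
            )
        if self.feature_mean is not None:
            X = (X - self.feature_mean) / self.feature_sd
        return X

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Deterministic forward pass (dropout inert); values in (0,1)."""
        _, dense_outputs, _ = self._forward(self._scale(X))
        return dense_outputs[-1][:, 0]

    def penultimate(self, X: np.ndarray) -> np.ndarray:
        """Activations of the dense layer feeding the output node."""
        if len(self.weights) < 2:
            raise ValueError("model has no penultimate dense layer")
        _, dense_outputs, _ = self._forward(self._scale(X))
        return dense_outputs[-2]

    def clone_weights(self):
        return ([w.copy() for w in self.weights], [b.copy() for b in self.biases])

    def set_weights(self, state) -> None:
        ws, bs = state
        self.weights = [w.copy() for w in ws]
        self.biases = [b.copy() for b in bs]

    # ---- serialization ------------------------------------------------

    def to_json(self, config: Optional[TrainConfig] = None) -> str:
        payload = {
            "layer_spec": [list(l) for l in self.layer_spec],
            "n_features": self.n_features,
            "init_seed": self.init_seed,
            "trained": self.trained,
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "feature_mean": None if self.feature_mean is None
            else self.feature_mean.tolist(),
            "feature_sd": None if self.feature_sd is None
            else self.feature_sd.tolist(),
            "train_config": asdict(config) if config else None,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "NeuralPRSModel":
        payload = json.loads(text)
        model = cls(payload["layer_spec"], payload["n_features"],
                    payload["init_seed"])
        model.weights = [np.asarray(w, dtype=float) for w in payload["weights"]]
        model.biases = [np.asarray(b, dtype=float) for b in payload["biases"]]
        model.trained = payload["trained"]
        if payload.get("feature_mean") is not None:
            model.feature_mean = np.asarray(payload["feature_mean"], dtype=float)
            model.feature_sd = np.asarray(payload["feature_sd"], dtype=float)
        return model

    def save(self, path, config: Optional[TrainConfig] = None) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json(config))

    @classmethod
    def load(cls, path) -> "NeuralPRSModel":
        with open(path) as fh:
            return cls.from_json(fh.read())

    def __repr__(self) -> str:
        spec = ", ".join(
            f"dense({w})" if k == "dense" else f"dropout({w})"
            for k, w in self.layer_spec
        )
        return f"NeuralPRSModel([{spec}], trained={self.trained})"


def build_nn(kind: str, n_features: int, *, n_loci: Optional[int] = None,
             dropout_rate: Optional[float] = None,
             seed: int = 0) -> NeuralPRSModel:
    """Construct one of the two reference architectures.

    ``european`` requires ``n_loci >= 1`` (layer widths scale with the
    locus count); ``chinese`` uses the fixed 50/30/10/5/1 widths.  Default
    dropout rates are 0.2 (european) and 0.3 (chinese).
    """
    if kind == "european":
        if not n_loci or n_loci < 1:
            raise ValueError("european architecture needs n_loci >= 1")
        rate = 0.2 if dropout_rate is None else dropout_rate
        spec = [
            ("dropout", rate),
            ("dense", 3 * n_loci),
            ("dropout", rate),
            ("dense", n_loci),
            ("dense", 22),
            ("dense", 5),
            ("dense", 1),
        ]
    elif kind == "chinese":
        rate = 0.3 if dropout_rate is None else dropout_rate
        spec = [
            ("dense", 50),
            ("dropout", rate),
            ("dense", 30),
            ("dropout", rate),
            ("dense", 10),
            ("dense", 5),
            ("dense", 1),
        ]
    else:
        raise ValueError(f"unknown architecture kind {kind!r}")
    return NeuralPRSModel(spec, n_features, init_seed=seed)


def _bce(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def train_nn(model: NeuralPRSModel, X: np.ndarray, y: np.ndarray,
             config: TrainConfig, *,
             X_val: Optional[np.ndarray] = None,
             y_val: Optional[np.ndarray] = None,
             standardize: bool = True) -> TrainHistory:
    """Mini-batch SGD on mean binary cross-entropy.

    Dropout is active only during training passes.  With ``patience`` set,
    training stops when the validation loss fails to improve for that many
    consecutive epochs and the best weights are restored.  Fully
    reproducible given ``config.seed``.

    With ``standardize`` (default) the training features' mean and sd are
    stored on the model and applied to every forward pass; deep sigmoid
    stacks frequently fail to leave the initial plateau on raw dosage
    input.
    """
    from ..metrics import auroc

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if standardize:
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        model.feature_mean = mean
        model.feature_sd = np.where(sd == 0, 1.0, sd)
    X = model._scale(X)
    if X_val is not None:
        X_val_scaled = model._scale(X_val)
    rng = np.random.default_rng(config.seed)
    if X_val is None and config.validation_fraction > 0:
        n_val = int(round(len(y) * config.validation_fraction))
        perm = rng.permutation(len(y))
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        X_val_scaled, y_val = X[val_idx], y[val_idx]  # X already scaled
        X, y = X[train_idx], y[train_idx]
        X_val = X_val_scaled
    has_val = X_val is not None and len(X_val) > 0

    history = TrainHistory()
    n = len(y)
    step = 0
    best_val = np.inf
    best_state = None
    epochs_since_best = 0
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            dense_in, dense_out, masks = model._forward(
                X[idx], training=True, rng=rng
            )
            batch_loss = _bce(y[idx], dense_out[-1][:, 0])
            if not np.isfinite(batch_loss):
                raise FloatingPointError(
                    f"training diverged (non-finite loss) at epoch {epoch}"
                )
            grads_w, grads_b = model._backward(dense_in, dense_out, masks, y[idx])
            lr = lr_at_step(config, step)
            for k in range(len(model.weights)):
                model.weights[k] -= lr * grads_w[k]
                model.biases[k] -= lr * grads_b[k]
            step += 1
            epoch_loss += batch_loss * len(idx)
        history.train_loss.append(epoch_loss / n)
        if has_val:
            _, val_out, _ = model._forward(X_val_scaled)
            val_scores = val_out[-1][:, 0]
            vloss = _bce(np.asarray(y_val, dtype=float), val_scores)
            history.val_loss.append(vloss)
            try:
                history.val_auroc.append(auroc(val_scores, y_val))
            except ValueError:
                history.val_auroc.append(np.nan)
            if vloss < best_val - 1e-12:
                best_val = vloss
                best_state = model.clone_weights()
                history.best_epoch = epoch
                epochs_since_best = 0
            else:
                epochs_since_best += 1
            if config.patience is not None and epochs_since_best >= config.patience:
                history.stopped_epoch = epoch
                break
    restore = config.restore_best if config.restore_best is not None \
        else config.patience is not None
    if restore and best_state is not None:
        model.set_weights(best_state)
    if history.stopped_epoch < 0:
        history.stopped_epoch = len(history.train_loss) - 1
    model.trained = True
    return history


def _as_features(geno) -> np.ndarray:
    if isinstance(geno, GenotypeMatrix):
        return geno.impute_mean().dosage
    return np.asarray(geno, dtype=float)


def nn_score(model: NeuralPRSModel, geno) -> np.ndarray:
    """Per-sample risk score in (0,1); deterministic forward pass."""
    return model.scores(_as_features(geno))


def penultimate_outputs(model: NeuralPRSModel, geno) -> np.ndarray:
    """Samples x penultimate-width matrix of module activations in (0,1)."""
    return model.penultimate(_as_features(geno))
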