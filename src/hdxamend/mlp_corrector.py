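"""Neural-network prediction of per-peptide exchange controls.

A feedforward multilayer perceptron maps a single per-peptide feature — the
population variance of the peptide's RFU values across exposure times, which
makes the model independent of the number and spacing of time points — to the
two control targets (RFU_back, RFU_fwd).  The default architecture uses 9
hidden ReLU layers with tapering widths and a linear 2-unit output; training
is plain full-batch gradient descent on the mean squared error with
backpropagated analytic gradients, 1000 epochs by default, with train and
validation losses recorded per epoch.  Train/validation sets are split by
protein so validation peptides are genuinely unseen.

The network is implemented directly in numpy; gradient correctness is
established against central finite differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_io import (
    ControlTable,
    HdxError,
    StructuralError,
    UptakeTable,
    get_logger,
    make_rng,
)
from .exchange_artifacts import apply_controls

logger = get_logger(__name__)

DEFAULT_HIDDEN_WIDTHS = (64, 64, 48, 48, 32, 32, 16, 16, 8)

#: minimum separation enforced between predicted back and forward controls
MIN_CONTROL_GAP = 1e-3


class TrainingError(HdxError):
    """Training diverged (non-finite loss)."""


class InsufficientDataError(HdxError):
    """Fewer than two RFU values: the variance feature is undefined."""


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def variance_feature(rfu_values) -> float:
    """Population variance (1/n) sum (x - mu)^2 of a peptide's RFU values."""
    x = np.asarray(rfu_values, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("variance feature needs >= 2 time points")
    return float(np.mean((x - x.mean()) ** 2))


def relu(x):
    """Rectified linear unit: max(0, x), elementwise."""
    return np.maximum(0.0, x)


def mse(predicted, true) -> float:
    """Mean squared error between two equal-length arrays."""
    p = np.asarray(predicted, dtype=float)
    t = np.asarray(true, dtype=float)
    if p.shape != t.shape:
        raise StructuralError(f"mse: shape mismatch {p.shape} vs {t.shape}")
    return float(np.mean((p - t) ** 2))


# ---------------------------------------------------------------------------
# Network spec, parameters, forward and backward passes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NetworkSpec:
    hidden_layer_widths: tuple[int, ...] = DEFAULT_HIDDEN_WIDTHS
    input_dim: int = 1
    output_dim: int = 2
    epochs: int = 1000
    learning_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if any(w < 1 for w in self.hidden_layer_widths):
            raise ValueError("hidden layer widths must be >= 1")
        if self.epochs < 0 or self.learning_rate <= 0:
            raise ValueError("epochs must be >= 0 and learning_rate > 0")

    @property
    def layer_dims(self) -> list[tuple[int, int]]:
        dims = [self.input_dim, *self.hidden_layer_widths, self.output_dim]
        return list(zip(dims[:-1], dims[1:]))


def init_params(spec: NetworkSpec, rng=None) -> list[tuple[np.ndarray, np.ndarray]]:
    """He-initialised (W, b) per layer."""
    rng = make_rng(spec.seed if rng is None else rng)
    params = []
    for fan_in, fan_out in spec.layer_dims:
        W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
        b = np.zeros(fan_out)
        params.append((W, b))
    return params


def forward(params, X, return_cache: bool = False):
    """Forward pass: ReLU on hidden layers, linear output.  ``X`` is (n, d)."""
    a = np.asarray(X, dtype=float)
    cache = [a]
    for layer, (W, b) in enumerate(params):
        z = a @ W + b
        a = z if layer == len(params) - 1 else relu(z)
        cache.append(a)
    return (a, cache) if return_cache else a


def loss_and_grads(params, X, Y):
    """MSE loss and its backpropagated gradients w.r.t. every W and b."""
    Y = np.asarray(Y, dtype=float)
    pred, cache = forward(params, X, return_cache=True)
    n = Y.shape[0]
    loss = mse(pred, Y)
    # d(mean((p-y)^2))/dp over all n*output_dim entries
    delta = 2.0 * (pred - Y) / Y.size
    grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(params)
    for layer in range(len(params) - 1, -1, -1):
        a_prev = cache[layer]
        W, _ = params[layer]
        grads[layer] = (a_prev.T @ delta, delta.sum(axis=0))
        if layer > 0:
            delta = (delta @ W.T) * (cache[layer] > 0)
    return loss, grads


# ---------------------------------------------------------------------------
# Training data and trained model
# ---------------------------------------------------------------------------


@dataclass
class TrainingSet:
    """Per-peptide (variance feature, control targets) samples keyed by protein."""

    features: np.ndarray  # (n,)
    targets: np.ndarray  # (n, 2): rfu_back, rfu_fwd
    protein_ids: np.ndarray  # (n,) str

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.targets = np.asarray(self.targets, dtype=float)
        self.protein_ids = np.asarray(self.protein_ids)
        if self.features.ndim != 1 or self.targets.shape != (self.features.size, 2):
            raise StructuralError("training set shapes are inconsistent")
        if np.any(self.targets < 0) or np.any(self.targets > 1):
            raise StructuralError("control targets must lie in [0, 1]")

    @classmethod
    def from_tables(cls, uptake: UptakeTable, controls: ControlTable) -> "TrainingSet":
        if uptake.map.peptides != controls.map.peptides:
            raise StructuralError("uptake and control tables are not aligned")
        feats = np.array([variance_feature(row) for row in uptake.rfu])
        targets = np.column_stack([controls.rfu_back, controls.rfu_fwd])
        pids = np.array([uptake.map.protein_id] * uptake.map.n_peptides)
        return cls(feats, targets, pids)

    @classmethod
    def concatenate(cls, sets) -> "TrainingSet":
        return cls(
            np.concatenate([s.features for s in sets]),
            np.vstack([s.targets for s in sets]),
            np.concatenate([s.protein_ids for s in sets]),
        )


@dataclass
class TrainedModel:
    spec: NetworkSpec
    params: list
    feature_mean: float
    feature_std: float
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)

    def predict(self, features) -> np.ndarray:
        """(n, 2) raw network outputs for raw (unstandardised) features."""
        x = (np.asarray(features, dtype=float).reshape(-1, 1) - self.feature_mean)
        x = x / self.feature_std
        return forward(self.params, x)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "spec": {
                "hidden_layer_widths": list(self.spec.hidden_layer_widths),
                "input_dim": self.spec.input_dim,
                "output_dim": self.spec.output_dim,
                "epochs": self.spec.epochs,
                "learning_rate": self.spec.learning_rate,
                "seed": self.spec.seed,
            },
            "feature_mean": self.feature_mean,
            "feature_std": self.feature_std,
            "layers": [{"W": W.tolist(), "b": b.tolist()} for W, b in self.params],
            "train_loss": self.train_loss,
            "val_loss": self.val_loss,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrainedModel":
        payload = json.loads(Path(path).read_text())
        spec = NetworkSpec(
            hidden_layer_widths=tuple(payload["spec"]["hidden_layer_widths"]),
            input_dim=payload["spec"]["input_dim"],
            output_dim=payload["spec"]["output_dim"],
            epochs=payload["spec"]["epochs"],
            learning_rate=payload["spec"]["learning_rate"],
            seed=payload["spec"]["seed"],
        )
        params = [
            (np.array(layer["W"]), np.array(layer["b"])) for layer in payload["layers"]
        ]
        return cls(spec, params, payload["feature_mean"], payload["feature_std"],
                   payload["train_loss"], payload["val_loss"])


def train(train_set: TrainingSet, val_set: TrainingSet | None, spec: NetworkSpec) -> TrainedModel:
    """Full-batch gradient descent on the MSE over both control targets.

    Deterministic given ``spec.seed``.  Raises :class:`TrainingError` on
    divergence, reporting the epoch and learning rate.
    """
    if train_set.features.size == 0:
        raise StructuralError("empty training set")
    if val_set is not None and val_set.features.size:
        shared = set(train_set.protein_ids) & set(val_set.protein_ids)
        if shared:
            raise StructuralError(
                f"train/validation sets share proteins: {sorted(shared)}"
            )

    mu = float(train_set.features.mean())
    sigma = float(train_set.features.std()) or 1.0
    Xtr = ((train_set.features - mu) / sigma).reshape(-1, 1)
    Ytr = train_set.targets
    if val_set is not None and val_set.features.size:
        Xval = ((val_set.features - mu) / sigma).reshape(-1, 1)
        Yval = val_set.targets
    else:
        Xval = Yval = None

    params = init_params(spec)
    train_hist: list[float] = []
    val_hist: list[float] = []
    for epoch in range(spec.epochs):
        with np.errstate(over="ignore", invalid="ignore"):
            loss, grads = loss_and_grads(params, Xtr, Ytr)
        if not np.isfinite(loss):
            raise TrainingError(
                f"loss diverged at epoch {epoch} (learning_rate={spec.learning_rate})"
            )
        params = [
            (W - spec.learning_rate * gW, b - spec.learning_rate * gb)
            for (W, b), (gW, gb) in zip(params, grads)
        ]
        train_hist.append(loss)
        if Xval is not None:
            val_hist.append(mse(forward(params, Xval), Yval))
    return TrainedModel(spec, params, mu, sigma, train_hist, val_hist)


# ---------------------------------------------------------------------------
# Application to uptake tables
# ---------------------------------------------------------------------------


def predict_controls(model: TrainedModel, table: UptakeTable) -> ControlTable:
    """Per-peptide control predictions for an (uncorrected) uptake table.

    Outputs are clamped to [0, 1]; pairs with back <= fwd are nudged apart
    by :data:`MIN_CONTROL_GAP` and counted in the table metadata.
    """
    feats = np.array([variance_feature(row) for row in table.rfu])
    pred = np.clip(model.predict(feats), 0.0, 1.0)
    back, fwd = pred[:, 0].copy(), pred[:, 1].copy()
    bad = back <= fwd
    if bad.any():
        logger.warning("predict_controls: %d peptide(s) with back <= fwd nudged apart",
                       int(bad.sum()))
        mid = 0.5 * (back[bad] + fwd[bad])
        back[bad] = np.clip(mid + MIN_CONTROL_GAP / 2, MIN_CONTROL_GAP, 1.0)
        fwd[bad] = np.clip(mid - MIN_CONTROL_GAP / 2, 0.0, 1.0 - MIN_CONTROL_GAP)
        back[bad] = np.maximum(back[bad], fwd[bad] + MIN_CONTROL_GAP)
    out = ControlTable(table.map, back, fwd, provenance="predicted_ai")
    out.metadata = {"n_nudged": int(bad.sum())}
    return out


def correct_with_model(table: UptakeTable, model: TrainedModel, clip: bool = False) -> UptakeTable:
    """Predict controls with the model and reconstitute the true RFU."""
    controls = predict_controls(model, table)
    corrected = apply_controls(table, controls, mode="correct", clip=clip)
    corrected.metadata["model"] = {
        "hidden_layer_widths": list(model.spec.hidden_layer_widths),
        "seed": model.spec.seed,
        "param_hash": hash(tuple(float(W.sum()) for W, _ in model.params)),
    }
    return corrected
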