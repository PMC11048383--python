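"""Variational quantum circuit learner for age regression and sex classification.

Architecture: each of the k principal-component features (rescaled to [0, 1])
is angle-encoded as RY(π·x_q) on its own qubit; then ``n_blocks`` repeated
blocks, each consisting of three trainable rotation layers (RX, RY, RZ — one
rotation per qubit per layer) followed by a CNOT entangler (chain: q → q+1,
optionally closed into a ring).  All qubits are measured in the Z basis, the
expectations are summed at a single node, and a sigmoid squashes the weighted
sum to (0, 1).  At the published defaults (17 qubits, 10 blocks) this is
17 data rotations + 510 trainable rotations + 160 CNOTs.

Training minimises MSE (regression, targets min-max encoded to [0, 1]) or
binary cross-entropy (classification, F=0 / M=1) with ADAM at learning rate
0.01, mini-batches reshuffled every epoch, and early stopping on a held-out
validation fraction.  Gradients come from reverse-mode adjoint
differentiation through the statevector; the parameter-shift rule serves as
an independent check in the test-suite.

Because the output head is sigmoid-bounded, decoded regression predictions
always lie inside the training age range — a structural guarantee the
classical baselines do not have.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

from .quantum import (
    CircuitError,
    CircuitSpec,
    GateOp,
    adjoint_zsum_gradients,
    new_state,
)

__all__ = [
    "VQCConfig",
    "VQCParams",
    "TargetCodec",
    "build_circuit",
    "forward",
    "decode",
    "batch_loss_grads",
    "train",
    "VQCRegressor",
    "VQCClassifier",
]

LAYER_KINDS = ("RX", "RY", "RZ")  # fixed per-block layer order


@dataclass(frozen=True)
class VQCConfig:
    """Hyperparameters of the circuit and its training loop."""

    n_qubits: int = 17
    n_blocks: int = 10
    entangler: str = "chain"          # or "ring"
    task: str = "regression"          # or "classification"
    learning_rate: float = 0.01
    batch_size: int = 32
    epochs: int = 100
    seed: int = 0
    freeze_head: bool = False         # pin (w, b) = (1, 0)
    validation_fraction: float = 0.1  # 0 disables early stopping
    patience: int = 10

    #: three rotation layers per block, by construction
    layers_per_block: int = 3

    def __post_init__(self) -> None:
        if self.n_qubits < 1:
            raise ValueError("n_qubits must be >= 1")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.layers_per_block != 3:
            raise ValueError("the ansatz has exactly 3 rotation layers per block")
        if self.entangler not in ("chain", "ring"):
            raise ValueError(f"unknown entangler {self.entangler!r}")
        if self.task not in ("regression", "classification"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if not (0.0 <= self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must be in [0, 1)")

    @property
    def n_params(self) -> int:
        return self.n_blocks * 3 * self.n_qubits


@dataclass
class VQCParams:
    """Trainable state: rotation angles plus the affine output head."""

    angles: np.ndarray  # (n_blocks, 3, n_qubits), radians
    head_scale: float
    head_offset: float

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if not np.all(np.isfinite(self.angles)) or not np.isfinite(self.head_scale) or not np.isfinite(self.head_offset):
            raise ValueError("VQC parameters must be finite")

    def copy(self) -> "VQCParams":
        return VQCParams(self.angles.copy(), self.head_scale, self.head_offset)


def initial_params(config: VQCConfig, rng: np.random.Generator) -> VQCParams:
    """Near-identity start: angles ~ U(-0.1, 0.1), head (1/n_qubits, 0)."""
    angles = rng.uniform(-0.1, 0.1, size=(config.n_blocks, 3, config.n_qubits))
    w = 1.0 if config.freeze_head else 1.0 / config.n_qubits
    b = 0.0
    return VQCParams(angles=angles, head_scale=w, head_offset=b)


@dataclass(frozen=True)
class TargetCodec:
    """Maps raw model output in (0, 1) to ages or labels and back."""

    task: str
    age_min: float | None = None
    age_max: float | None = None
    labels: tuple = ("F", "M")  # index 0 / index 1

    def __post_init__(self) -> None:
        if self.task == "regression":
            if self.age_min is None or self.age_max is None or not self.age_max > self.age_min:
                raise ValueError("regression codec needs age_max > age_min")

    def encode(self, y) -> np.ndarray:
        y = np.asarray(y)
        if self.task == "regression":
            return (y.astype(float) - self.age_min) / (self.age_max - self.age_min)
        out = np.empty(y.shape, dtype=float)
        matched = np.zeros(y.shape, dtype=bool)
        for code, lab in enumerate(self.labels):
            hit = y == lab
            out[hit] = code
            matched |= hit
        if not matched.all():
            raise ValueError(f"labels outside {self.labels}: {np.unique(y[~matched])}")
        return out


def decode(codec: TargetCodec, y_raw):
    """Inverse of the codec: (0,1) output -> age in years, or a class label.

    Classification ties at 0.5 resolve to the positive class (M).
    """
    y_raw = np.asarray(y_raw)
    if codec.task == "regression":
        out = codec.age_min + y_raw * (codec.age_max - codec.age_min)
        return float(out) if out.ndim == 0 else out
    if y_raw.ndim == 0:
        return codec.labels[int(y_raw >= 0.5)]
    return np.asarray(codec.labels, dtype=object)[(y_raw >= 0.5).astype(int)]


def build_circuit(config: VQCConfig, x=None) -> CircuitSpec:
    """The ansatz as an explicit gate list.

    With ``x`` given (k values in [0, 1]) the embedding rotations carry fixed
    angles RY(π·x_q); without it they occupy non-trainable parameter slots
    0..k-1, and the trainable rotation slots follow in (block, layer, qubit)
    order — the layout :func:`train` optimises.
    """
    k = config.n_qubits
    gates: list[GateOp] = []
    if x is not None:
        x = np.asarray(x, dtype=float)
        if x.shape != (k,):
            raise CircuitError(f"expected {k} features, got shape {x.shape}")
        gates.extend(GateOp("RY", q, angle=float(np.pi * x[q])) for q in range(k))
        offset = 0
    else:
        gates.extend(GateOp("RY", q, slot=q, trainable=False) for q in range(k))
        offset = k
    slot = offset
    for _ in range(config.n_blocks):
        for kind in LAYER_KINDS:
            for q in range(k):
                gates.append(GateOp(kind, q, slot=slot, trainable=True))
                slot += 1
        if k > 1:
            for q in range(k - 1):
                gates.append(GateOp("CNOT", target=q + 1, control=q))
            if config.entangler == "ring":
                gates.append(GateOp("CNOT", target=0, control=k - 1))
    return CircuitSpec(n_qubits=k, gates=gates)


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def _forward_batch(template: CircuitSpec, config: VQCConfig, params: VQCParams, X: np.ndarray, want_grads: bool):
    """Summed-Z expectation (and per-sample adjoint gradients) for a batch."""
    B, k = X.shape
    n_slots = template.n_slots
    angles = np.empty((n_slots, B))
    angles[:k] = np.pi * X.T
    angles[k:] = params.angles.reshape(-1)[:, None]
    state = new_state(config.n_qubits, batch=B)
    if want_grads:
        zsum, grads = adjoint_zsum_gradients(template, angles, state=state)
        return zsum, grads[k:]  # trainable rows only
    from .quantum import run_circuit, zsum_expectation

    psi = run_circuit(template, angles, state=state)
    return zsum_expectation(psi), None


def forward(config: VQCConfig, params: VQCParams, x) -> float | np.ndarray:
    """Model output sigmoid(w · Σ_q <Z_q> + b), strictly in (0, 1)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != config.n_qubits:
        raise CircuitError(f"expected {config.n_qubits} features, got {x.shape[1]}")
    template = build_circuit(config)
    zsum, _ = _forward_batch(template, config, params, x, want_grads=False)
    out = _sigmoid(params.head_scale * zsum + params.head_offset)
    return float(out[0]) if out.shape == (1,) else out


class _Adam:
    """Plain ADAM on a flat parameter vector (β1=0.9, β2=0.999, ε=1e-8)."""

    def __init__(self, dim: int, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = np.zeros(dim)
        self.v = np.zeros(dim)
        self.t = 0

    def step(self, theta: np.ndarray, grad: np.ndarray) -> np.ndarray:
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * grad
        self.v = self.b2 * self.v + (1 - self.b2) * grad ** 2
        mhat = self.m / (1 - self.b1 ** self.t)
        vhat = self.v / (1 - self.b2 ** self.t)
        return theta - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _loss_and_dS(config: VQCConfig, f: np.ndarray, y: np.ndarray):
    """Per-batch loss and dL/d(pre-sigmoid logit) per sample (mean reduction)."""
    B = len(y)
    if config.task == "regression":
        loss = float(np.mean((f - y) ** 2))
        dlogit = 2.0 * (f - y) * f * (1.0 - f) / B
    else:
        eps = 1e-12
        loss = float(-np.mean(y * np.log(f + eps) + (1 - y) * np.log(1 - f + eps)))
        dlogit = (f - y) / B
    return loss, dlogit


def batch_loss_grads(template: CircuitSpec, config: VQCConfig, params: VQCParams,
                     Xb: np.ndarray, yb: np.ndarray):
    """Mean batch loss and its gradient w.r.t. (angles, head_scale, head_offset).

    The angle gradient composes the adjoint circuit derivative with the
    sigmoid/loss chain rule; this is the quantity ADAM steps on.
    """
    zsum, dS = _forward_batch(template, config, params, Xb, want_grads=True)
    w, b = params.head_scale, params.head_offset
    f = _sigmoid(w * zsum + b)
    loss, dlogit = _loss_and_dS(config, f, yb)
    grad_angles = dS @ (dlogit * w)
    grad_w = float(dlogit @ zsum)
    grad_b = float(np.sum(dlogit))
    return loss, grad_angles, grad_w, grad_b


def train(config: VQCConfig, train_X: np.ndarray, train_y: np.ndarray,
          params: VQCParams | None = None) -> tuple[VQCParams, list[float]]:
    """Fit the circuit by mini-batch ADAM; returns (params, per-epoch loss).

    ``train_X`` rows must already be in [0, 1]^k and ``train_y`` encoded to
    [0, 1] (regression) or {0, 1} (classification).  The training order is
    reshuffled every epoch from the run seed.  If ``validation_fraction`` is
    positive, that tail fraction of a seeded shuffle is held out and the
    parameters with the best validation loss are returned (patience epochs
    without improvement stop training early).
    """
    X = np.asarray(train_X, dtype=float)
    y = np.asarray(train_y, dtype=float)
    if X.ndim != 2 or X.shape[1] != config.n_qubits:
        raise ValueError(f"train_X must be (n, {config.n_qubits})")
    if y.shape != (X.shape[0],):
        raise ValueError("train_y length mismatch")
    rng = np.random.default_rng(config.seed)
    if params is None:
        params = initial_params(config, rng)
    template = build_circuit(config)

    n_val = int(np.floor(config.validation_fraction * len(y)))
    use_val = n_val >= 1 and config.epochs > 0
    if use_val:
        order = rng.permutation(len(y))
        val_idx, fit_idx = order[:n_val], order[n_val:]
        X_val, y_val = X[val_idx], y[val_idx]
        X_fit, y_fit = X[fit_idx], y[fit_idx]
    else:
        X_fit, y_fit = X, y

    n_params = config.n_params
    dim = n_params + (0 if config.freeze_head else 2)
    adam = _Adam(dim, config.learning_rate)
    history: list[float] = []
    best = params.copy()
    best_val = np.inf
    stale = 0

    for epoch in range(config.epochs):
        perm = rng.permutation(len(y_fit))
        epoch_losses = []
        for start in range(0, len(perm), config.batch_size):
            idx = perm[start:start + config.batch_size]
            Xb, yb = X_fit[idx], y_fit[idx]
            loss, grad_angles, grad_w, grad_b = batch_loss_grads(template, config, params, Xb, yb)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    f"last finite epoch mean loss: {history[-1] if history else 'n/a'}"
                )
            epoch_losses.append(loss)
            w, b = params.head_scale, params.head_offset
            if config.freeze_head:
                flat = adam.step(params.angles.reshape(-1), grad_angles)
                params = VQCParams(flat.reshape(params.angles.shape), w, b)
            else:
                grad = np.concatenate([grad_angles, [grad_w], [grad_b]])
                theta = np.concatenate([params.angles.reshape(-1), [w], [b]])
                theta = adam.step(theta, grad)
                params = VQCParams(theta[:n_params].reshape(params.angles.shape), theta[n_params], theta[n_params + 1])
        history.append(float(np.mean(epoch_losses)) if epoch_losses else np.nan)

        if use_val:
            zs, _ = _forward_batch(template, config, params, X_val, want_grads=False)
            fv = _sigmoid(params.head_scale * zs + params.head_offset)
            val_loss, _ = _loss_and_dS(config, fv, y_val)
            if val_loss < best_val - 1e-12:
                best_val, best, stale = val_loss, params.copy(), 0
            else:
                stale += 1
                if stale >= config.patience:
                    return best, history
    return (best if use_val and np.isfinite(best_val) else params), history


class _ScoreScaler:
    """Min-max rescale of PCA scores to [0, 1], clipped at transform time."""

    def __init__(self):
        self.lo = None
        self.hi = None

    def fit(self, scores: np.ndarray) -> "_ScoreScaler":
        self.lo = scores.min(axis=0)
        self.hi = scores.max(axis=0)
        span = self.hi - self.lo
        if np.any(span <= 0):
            raise ValueError("degenerate (constant) component score; cannot rescale")
        return self

    def transform(self, scores: np.ndarray) -> np.ndarray:
        if self.lo is None:
            raise RuntimeError("scaler not fitted")
        return np.clip((scores - self.lo) / (self.hi - self.lo), 0.0, 1.0)


class _VQCBase:
    """sklearn-style wrapper: owns score rescaling, codec and training."""

    task: str

    def __init__(self, config: VQCConfig | None = None, **overrides):
        if config is None:
            config = VQCConfig(task=self.task, **overrides)
        elif overrides:
            config = replace(config, **overrides)
        if config.task != self.task:
            config = replace(config, task=self.task)
        self.config = config
        self.params_: VQCParams | None = None
        self.codec_: TargetCodec | None = None
        self.scaler_ = _ScoreScaler()
        self.history_: list[float] = []

    def _encode_targets(self, y) -> np.ndarray:
        raise NotImplementedError

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.config.n_qubits:
            raise ValueError(
                f"model has {self.config.n_qubits} qubits but got {X.shape[1]} features; "
                "set n_qubits = k of the preprocessing model"
            )
        self.scaler_.fit(X)
        y_enc = self._encode_targets(y)
        self.params_, self.history_ = train(self.config, self.scaler_.transform(X), y_enc)
        return self

    def _raw(self, X) -> np.ndarray:
        if self.params_ is None:
            raise RuntimeError("model not fitted")
        X = np.asarray(X, dtype=float)
        out = forward(self.config, self.params_, self.scaler_.transform(X))
        return np.atleast_1d(out)

    def save(self, path) -> None:
        doc = {
            "config": {k: getattr(self.config, k) for k in (
                "n_qubits", "n_blocks", "entangler", "task", "learning_rate",
                "batch_size", "epochs", "seed", "freeze_head",
                "validation_fraction", "patience")},
            "angles": self.params_.angles.tolist(),
            "head_scale": self.params_.head_scale,
            "head_offset": self.params_.head_offset,
            "score_lo": self.scaler_.lo.tolist(),
            "score_hi": self.scaler_.hi.tolist(),
            "codec": {
                "task": self.codec_.task,
                "age_min": self.codec_.age_min,
                "age_max": self.codec_.age_max,
                "labels": list(self.codec_.labels),
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh)

    @classmethod
    def load(cls, path) -> "_VQCBase":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        config = VQCConfig(**doc["config"])
        model = VQCRegressor(config) if config.task == "regression" else VQCClassifier(config)
        model.params_ = VQCParams(np.asarray(doc["angles"]), doc["head_scale"], doc["head_offset"])
        model.scaler_.lo = np.asarray(doc["score_lo"])
        model.scaler_.hi = np.asarray(doc["score_hi"])
        c = doc["codec"]
        model.codec_ = TargetCodec(task=c["task"], age_min=c["age_min"], age_max=c["age_max"],
                                   labels=tuple(c["labels"]))
        return model


class VQCRegressor(_VQCBase):
    """Brain-age regressor; predictions are bounded to the training age range."""

    task = "regression"

    def _encode_targets(self, y) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        self.codec_ = TargetCodec(task="regression", age_min=float(y.min()), age_max=float(y.max()))
        return self.codec_.encode(y)

    def predict(self, X) -> np.ndarray:
        return np.asarray(decode(self.codec_, self._raw(X)), dtype=float)


class VQCClassifier(_VQCBase):
    """Sex classifier; label F encodes to 0 and M to 1, ties go to M."""

    task = "classification"

    def _encode_targets(self, y) -> np.ndarray:
        self.codec_ = TargetCodec(task="classification")
        return self.codec_.encode(np.asarray(y))

    def predict(self, X) -> np.ndarray:
        return np.asarray(decode(self.codec_, self._raw(X)))

    def predict_proba(self, X) -> np.ndarray:
        p1 = self._raw(X)
        return np.column_stack([1.0 - p1, p1])
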