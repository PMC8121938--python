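"""The four-branch classifier, its attention variant, and training routines.

The classifier ("Feature Learner" + "Coordinator") runs each of the four
feature matrices through its own stack of three valid-padding 1-D
convolutions, flattens, and maps each branch to a single sigmoid
confidence. The four confidences are concatenated and a final sigmoid
dense layer coordinates them into the output probability; a sample is
called positive iff that probability is strictly greater than 0.5.

The attention variant keeps the convolutional backbone (whose concatenated
flattened outputs are mapped to a width-H vector C), adds a bidirectional
LSTM over the monomer one-hot time steps producing an output matrix O of
shape (L, H), scores each position by the dot product O·C, normalises the
scores to the attention distribution S with a softmax, and classifies from
the concatenation of the S-weighted context vector with C.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from m6aconvkit.network import autodiff as ad
from m6aconvkit.network.autodiff import Adam, Tensor, binary_cross_entropy
from m6aconvkit.network.layers import BiLSTM, Conv1D, Dense
from m6aconvkit.sequence_features import FEATURE_ORDER


@dataclass(frozen=True)
class ArchitectureConfig:
    """Hyperparameters of both model variants.

    The text of the method fixes only the branch structure (three 1-D
    convolution layers per branch, sigmoid branch/coordinator outputs)
    and the attention output width; filter counts, kernel sizes,
    optimizer settings and the loss are configurable here with
    documented defaults.
    """

    conv_filters: tuple[int, int, int] = (16, 32, 64)
    conv_kernels: tuple[int, int, int] = (5, 5, 3)
    conv_activation: str = "relu"
    #: Width H of the attention dense vector C; the bidirectional LSTM
    #: uses H/2 units per direction so its output matches (L, H).
    attention_hidden: int = 256
    learning_rate: float = 1e-3
    fine_tune_lr_factor: float = 0.1
    batch_size: int = 64
    epochs: int = 10
    loss: str = "bce"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conv_filters) != 3 or len(self.conv_kernels) != 3:
            raise ValueError("each branch must have exactly three convolution layers")
        if min(self.conv_filters) < 1 or min(self.conv_kernels) < 1:
            raise ValueError("filter counts and kernel sizes must be positive")
        if self.attention_hidden < 2 or self.attention_hidden % 2:
            raise ValueError("attention_hidden must be an even integer >= 2")
        if self.loss != "bce":
            raise ValueError(f"unsupported loss {self.loss!r}")
        for name in ("learning_rate", "fine_tune_lr_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("batch_size must be >= 1 and epochs >= 0")


def default_input_shapes(length: int = 41, n_dpp: int = 9) -> dict[str, tuple[int, int]]:
    """Per-branch input shapes for sequences of a given length."""
    return {
        "monomer": (length, 4),
        "dimer": (length - 1, 16),
        "dpp": (length - 1, n_dpp),
        "pse": (length, 4),
    }


class _ConvStack:
    """Three convolutions + flatten; shared by every branch."""

    def __init__(
        self,
        rng: np.random.Generator,
        input_shape: tuple[int, int],
        config: ArchitectureConfig,
        branch: str,
    ) -> None:
        t_len, channels = input_shape
        self.convs: list[Conv1D] = []
        for filters, kernel in zip(config.conv_filters, config.conv_kernels):
            if t_len - kernel + 1 < 1:
                raise ValueError(
                    f"branch {branch!r}: kernel size {kernel} does not fit "
                    f"remaining length {t_len}"
                )
            self.convs.append(Conv1D(rng, channels, filters, kernel, config.conv_activation))
            t_len = t_len - kernel + 1
            channels = filters
        self.out_dim = t_len * channels

    def __call__(self, x: Tensor) -> Tensor:
        for conv in self.convs:
            x = conv(x)
        return ad.reshape(x, (x.shape[0], self.out_dim))

    @property
    def params(self) -> list[Tensor]:
        return [p for conv in self.convs for p in conv.params]


class _BaseModel:
    kind = "base"

    def __init__(self, config: ArchitectureConfig, input_shapes: dict[str, tuple[int, int]]):
        self.config = config
        self.input_shapes = {k: tuple(v) for k, v in input_shapes.items()}
        self.meta: dict = {"trained": False, "epochs_run": 0, "final_loss": None, "seed": None}

    @property
    def trained(self) -> bool:
        return bool(self.meta["trained"])

    @property
    def params(self) -> list[Tensor]:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return int(sum(p.data.size for p in self.params))

    def forward_prob(self, X) -> Tensor:
        raise NotImplementedError

    @property
    def output_bias(self) -> Tensor:
        """Bias of the final sigmoid layer (used for log-odds initialization)."""
        raise NotImplementedError

    def copy(self) -> "_BaseModel":
        return copy.deepcopy(self)

    def _check_inputs(self, X: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
        if not isinstance(X, Mapping):
            raise TypeError("multi-branch models take a mapping of branch name -> array")
        out: dict[str, np.ndarray] = {}
        batch = None
        for name, shape in self.input_shapes.items():
            if name not in X:
                raise ValueError(f"branch {name!r}: input missing")
            arr = np.asarray(X[name], dtype=np.float64)
            if arr.ndim != 3 or arr.shape[1:] != shape:
                raise ValueError(
                    f"branch {name!r}: expected input of shape (batch, {shape[0]}, "
                    f"{shape[1]}), got {arr.shape}"
                )
            if batch is None:
                batch = arr.shape[0]
            elif arr.shape[0] != batch:
                raise ValueError(f"branch {name!r}: inconsistent batch size")
            out[name] = arr
        return out


class FourBranchClassifier(_BaseModel):
    """Feature Learner (4 conv branches → 4 sigmoid confidences) + Coordinator."""

    kind = "four_branch"

    def __init__(self, config: ArchitectureConfig, input_shapes: dict[str, tuple[int, int]]):
        missing = set(FEATURE_ORDER) - set(input_shapes)
        if missing:
            raise ValueError(f"input shapes missing branches: {sorted(missing)}")
        super().__init__(config, {k: input_shapes[k] for k in FEATURE_ORDER})
        rng = np.random.default_rng(config.seed)
        self.stacks = {
            name: _ConvStack(rng, self.input_shapes[name], config, name)
            for name in FEATURE_ORDER
        }
        self.branch_heads = {
            name: Dense(rng, self.stacks[name].out_dim, 1, activation="sigmoid")
            for name in FEATURE_ORDER
        }
        self.coordinator = Dense(rng, 4, 1, activation="sigmoid")

    @property
    def params(self) -> list[Tensor]:
        out: list[Tensor] = []
        for name in FEATURE_ORDER:
            out += self.stacks[name].params + self.branch_heads[name].params
        return out + self.coordinator.params

    def forward(self, X: Mapping[str, np.ndarray]) -> tuple[Tensor, Tensor]:
        """Return (probabilities (B,), confidence vectors (B, 4))."""
        X = self._check_inputs(X)
        confidences = [
            self.branch_heads[name](self.stacks[name](Tensor(X[name])))
            for name in FEATURE_ORDER
        ]
        conf = ad.concat(confidences, axis=1)  # (B, 4) — the Feature Learner output
        prob = self.coordinator(conf)
        batch = conf.shape[0]
        return ad.reshape(prob, (batch,)), conf

    def forward_prob(self, X: Mapping[str, np.ndarray]) -> Tensor:
        return self.forward(X)[0]

    @property
    def output_bias(self) -> Tensor:
        return self.coordinator.b

    def coordinate(self, confidence_vectors: np.ndarray) -> np.ndarray:
        """Coordinator output for externally supplied 4-vectors.

        Exposes the factorization contract: the final probability
        depends on the branches only through the confidence 4-vector.
        """
        conf = np.asarray(confidence_vectors, dtype=np.float64)
        if conf.ndim != 2 or conf.shape[1] != 4:
            raise ValueError("confidence vectors must have shape (batch, 4)")
        return self.coordinator(Tensor(conf)).data[:, 0]


class SingleBranchClassifier(_BaseModel):
    """Sequential 3-conv model over a single feature matrix (ablation baseline)."""

    kind = "single_branch"

    def __init__(
        self,
        feature: str,
        config: ArchitectureConfig,
        input_shape: tuple[int, int],
    ) -> None:
        if feature not in FEATURE_ORDER:
            raise ValueError(f"unknown feature {feature!r}; expected one of {FEATURE_ORDER}")
        super().__init__(config, {feature: input_shape})
        self.feature = feature
        rng = np.random.default_rng(config.seed)
        self.stack = _ConvStack(rng, tuple(input_shape), config, feature)
        self.head = Dense(rng, self.stack.out_dim, 1, activation="sigmoid")

    @property
    def params(self) -> list[Tensor]:
        return self.stack.params + self.head.params

    @property
    def output_bias(self) -> Tensor:
        return self.head.b

    def forward_prob(self, X) -> Tensor:
        if not isinstance(X, Mapping):
            X = {self.feature: X}
        X = self._check_inputs(X)
        prob = self.head(self.stack(Tensor(X[self.feature])))
        return ad.reshape(prob, (prob.shape[0],))


class AttentionClassifier(_BaseModel):
    """Conv backbone + bidirectional LSTM attention over monomer time steps."""

    kind = "attention"

    def __init__(self, config: ArchitectureConfig, input_shapes: dict[str, tuple[int, int]]):
        missing = set(FEATURE_ORDER) - set(input_shapes)
        if missing:
            raise ValueError(f"input shapes missing branches: {sorted(missing)}")
        super().__init__(config, {k: input_shapes[k] for k in FEATURE_ORDER})
        rng = np.random.default_rng(config.seed)
        hidden = config.attention_hidden
        self.stacks = {
            name: _ConvStack(rng, self.input_shapes[name], config, name)
            for name in FEATURE_ORDER
        }
        backbone_dim = sum(self.stacks[name].out_dim for name in FEATURE_ORDER)
        self.dense_c = Dense(rng, backbone_dim, hidden, activation="relu")
        self.bilstm = BiLSTM(rng, self.input_shapes["monomer"][1], hidden // 2)
        self.out_dense = Dense(rng, 2 * hidden, 1, activation="sigmoid")

    @property
    def params(self) -> list[Tensor]:
        out: list[Tensor] = []
        for name in FEATURE_ORDER:
            out += self.stacks[name].params
        return out + self.dense_c.params + self.bilstm.params + self.out_dense.params

    def forward(self, X: Mapping[str, np.ndarray]) -> tuple[Tensor, Tensor]:
        """Return (probabilities (B,), attention distributions S (B, L))."""
        X = self._check_inputs(X)
        flats = [self.stacks[name](Tensor(X[name])) for name in FEATURE_ORDER]
        c_vec = self.dense_c(ad.concat(flats, axis=1))  # (B, H)
        o_mat = self.bilstm(Tensor(X["monomer"]))  # (B, L, H)
        batch, length, hidden = o_mat.shape
        c_expanded = ad.reshape(c_vec, (batch, 1, hidden))
        scores = ad.tsum(o_mat * c_expanded, axis=2)  # (B, L): position impact O·C
        s_vec = ad.softmax(scores, axis=1)
        context = ad.tsum(o_mat * ad.reshape(s_vec, (batch, length, 1)), axis=1)  # (B, H)
        prob = self.out_dense(ad.concat([context, c_vec], axis=1))
        return ad.reshape(prob, (batch,)), s_vec

    @property
    def output_bias(self) -> Tensor:
        return self.out_dense.b

    def forward_prob(self, X: Mapping[str, np.ndarray]) -> Tensor:
        return self.forward(X)[0]


def build_classifier(
    config: ArchitectureConfig, input_shapes: dict[str, tuple[int, int]] | None = None
) -> FourBranchClassifier:
    """Untrained Feature-Learner/Coordinator graph."""
    return FourBranchClassifier(config, input_shapes or default_input_shapes())


def build_attention_model(
    config: ArchitectureConfig, input_shapes: dict[str, tuple[int, int]] | None = None
) -> AttentionClassifier:
    """Untrained attention graph."""
    return AttentionClassifier(config, input_shapes or default_input_shapes())


def build_single_branch(
    feature: str,
    config: ArchitectureConfig,
    input_shape: tuple[int, int] | None = None,
) -> SingleBranchClassifier:
    """Untrained sequential single-feature baseline."""
    if input_shape is None:
        if feature not in FEATURE_ORDER:
            raise ValueError(f"unknown feature {feature!r}; expected one of {FEATURE_ORDER}")
        input_shape = default_input_shapes()[feature]
    return SingleBranchClassifier(feature, config, input_shape)


def _index_inputs(X, idx: np.ndarray):
    if isinstance(X, Mapping):
        return {k: v[idx] for k, v in X.items()}
    return X[idx]


def _run_training(
    model: _BaseModel,
    X,
    y: np.ndarray,
    epochs: int,
    learning_rate: float,
    batch_size: int,
    seed: int,
) -> None:
    y = np.asarray(y, dtype=np.float64)
    classes = np.unique(y)
    if not np.isin(classes, (0.0, 1.0)).all() or len(classes) < 2:
        raise ValueError("training requires binary labels with both classes present")
    if isinstance(X, Mapping):
        X = {k: np.asarray(v, dtype=np.float64) for k, v in X.items()}
        n = next(iter(X.values())).shape[0]
    else:
        X = np.asarray(X, dtype=np.float64)
        n = X.shape[0]
    if n != len(y):
        raise ValueError("inputs and labels disagree on sample count")
    rng = np.random.default_rng(seed)
    optimizer = Adam(model.params, lr=learning_rate)
    history: list[float] = list(model.meta.get("loss_history", []))
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_losses: list[float] = []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            prob = model.forward_prob(_index_inputs(X, idx))
            loss = binary_cross_entropy(prob, y[idx])
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_losses.append(float(loss.data))
        history.append(float(np.mean(epoch_losses)))
    model.meta.update(
        trained=True,
        epochs_run=model.meta["epochs_run"] + epochs,
        final_loss=history[-1] if history else model.meta["final_loss"],
        seed=seed,
        loss_history=history,
    )


def train(
    model: _BaseModel,
    X,
    y: np.ndarray,
    epochs: int | None = None,
    learning_rate: float | None = None,
    batch_size: int | None = None,
    seed: int | None = None,
    init_output_bias: bool = True,
) -> _BaseModel:
    """Train a copy of ``model`` with seeded minibatch Adam on BCE loss.

    The input model is left untouched; the returned copy records epochs
    run, per-epoch mean loss and the training seed in ``meta``. Unless
    disabled, a fresh model's output bias is initialized to the
    training-set log-odds before the first step.
    """
    cfg = model.config
    trained = model.copy()
    if init_output_bias and not trained.trained and not trained.output_bias.data.any():
        # start the final sigmoid at the training-set log-odds so heavily
        # imbalanced data cannot trap the network in the constant-output
        # minimum (engineering default, not part of the published method)
        rate = float(np.clip(np.asarray(y, dtype=np.float64).mean(), 1e-6, 1 - 1e-6))
        trained.output_bias.data[:] = np.log(rate / (1.0 - rate))
    _run_training(
        trained,
        X,
        y,
        epochs=cfg.epochs if epochs is None else epochs,
        learning_rate=cfg.learning_rate if learning_rate is None else learning_rate,
        batch_size=cfg.batch_size if batch_size is None else batch_size,
        seed=cfg.seed if seed is None else seed,
    )
    return trained


def fine_tune(
    model: _BaseModel,
    X,
    y: np.ndarray,
    epochs: int | None = None,
    lr_factor: float | None = None,
    seed: int | None = None,
) -> _BaseModel:
    """Continue training a copy of a trained model at a reduced learning rate."""
    if not model.trained:
        raise ValueError("fine_tune requires a trained model")
    factor = model.config.fine_tune_lr_factor if lr_factor is None else lr_factor
    return train(
        model,
        X,
        y,
        epochs=epochs,
        learning_rate=model.config.learning_rate * factor,
        seed=seed,
    )


def predict(model: _BaseModel, X) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities and hard labels (1 iff probability strictly > 0.5)."""
    prob = model.forward_prob(X).data
    return prob, (prob > 0.5).astype(np.int64)


def feature_confidences(model: FourBranchClassifier, X) -> np.ndarray:
    """Per-branch sigmoid confidences, shape (batch, 4), feature order fixed."""
    if not isinstance(model, FourBranchClassifier):
        raise TypeError("feature_confidences requires the four-branch classifier")
    if not model.trained:
        raise ValueError("feature_confidences requires a trained model")
    return model.forward(X)[1].data


def attention_profile(model: AttentionClassifier, X) -> np.ndarray:
    """Attention distributions S, shape (batch, L); each row sums to 1."""
    if not isinstance(model, AttentionClassifier):
        raise TypeError("attention_profile requires the attention model")
    if not model.trained:
        raise ValueError("attention_profile requires a trained model")
    return model.forward(X)[1].data


# ---------------------------------------------------------------------------
# Persistence: single versioned archive of config + parameters
# ---------------------------------------------------------------------------

_MODEL_FORMAT_VERSION = 1
_KINDS = {
    "four_branch": FourBranchClassifier,
    "attention": AttentionClassifier,
    "single_branch": SingleBranchClassifier,
}


def save_model(model: _BaseModel, path: str | Path) -> None:
    header = {
        "version": _MODEL_FORMAT_VERSION,
        "kind": model.kind,
        "config": asdict(model.config),
        "input_shapes": {k: list(v) for k, v in model.input_shapes.items()},
        "meta": {k: v for k, v in model.meta.items()},
        "feature": getattr(model, "feature", None),
    }
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.params)}
    with open(path, "wb") as handle:
        np.savez(handle, header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8), **arrays)


def load_model(path: str | Path) -> _BaseModel:
    with np.load(path) as data:
        header = json.loads(bytes(data["header"].tobytes()).decode())
        if header["version"] != _MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model archive version {header['version']}")
        cfg_dict = header["config"]
        for key in ("conv_filters", "conv_kernels"):
            cfg_dict[key] = tuple(cfg_dict[key])
        config = ArchitectureConfig(**cfg_dict)
        shapes = {k: tuple(v) for k, v in header["input_shapes"].items()}
        cls = _KINDS[header["kind"]]
        if cls is SingleBranchClassifier:
            feature = header["feature"]
            model = SingleBranchClassifier(feature, config, shapes[feature])
        else:
            model = cls(config, shapes)
        for i, p in enumerate(model.params):
            stored = data[f"param_{i}"]
            if stored.shape != p.data.shape:
                raise ValueError("model archive does not match the reconstructed graph")
            p.data = stored.copy()
        model.meta = header["meta"]
    return model
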