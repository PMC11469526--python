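"""Reference hybrid scattering/CNN classifier.

The depth-7 reference topology for 28x28x3 inputs:

    [scatter-concat 3x3 conv, stride 2] 28 -> 14
    [3x3 conv, stride 2]                14 -> 7
    [3x3 conv, stride 2]                 7 -> 4
    [global average pool] -> [dropout] -> [linear] -> softmax   (CNN head)

plus an auxiliary head that classifies the order-2 windowed scattering
coefficients of the input directly (globally pooled per path -> linear ->
softmax).  Both heads are trained jointly with the balanced loss

    L = ||y - yhat(x)||^2 + gamma * ||y - yhat(S[x])||^2

(batch mean; a cross-entropy variant is selectable).  The whole model stays
under 60k trainable parameters, two to three orders of magnitude smaller
than the standard CNNs it competes with, which is what makes it trainable
on datasets of a thousand images.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import scattering
from .nn import Conv2d, Dropout, GlobalAvgPool, Linear, ReLU, SGDM, one_hot, softmax
from .hybrid_layers import SpectralFilter2d

__all__ = [
    "ESWCNNConfig",
    "DualPrediction",
    "ESWCNN",
    "ParameterBudgetError",
    "build_eswcnn",
    "combined_loss",
    "train",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]


class ParameterBudgetError(ValueError):
    """Raised when a configuration exceeds the trainable-parameter budget."""


@dataclass
class ESWCNNConfig:
    """Hyperparameters of the reference model.

    Defaults follow the training recipe the architecture was designed
    around: SGD with momentum, learning rate 3e-4, batch size 10, 6 epochs,
    dropout 0.2, every-epoch shuffling, and a loss balance gamma = 0.5.
    """

    height: int = 28
    width: int = 28
    in_channels: int = 3
    n_classes: int = 3
    widths: tuple[int, ...] = (32, 48, 64)
    gamma: float = 0.5
    lr: float = 0.0003
    batch_size: int = 10
    epochs: int = 6
    dropout: float = 0.2
    momentum: float = 0.9
    seed: int = 0
    loss: str = "squared_error"  # or "cross_entropy"
    # scattering settings: J=1 order-1 inside the hybrid layer keeps the
    # concatenation at input resolution; J=2 order-2 for the globally
    # invariant auxiliary head
    hybrid_J: int = 1
    hybrid_L: int = 8
    hybrid_order: int = 1
    aux_J: int = 2
    aux_L: int = 8
    aux_order: int = 2
    use_scattering: bool = True  # False: parameter-matched plain CNN
    use_spectral_filter: bool = False
    scatter_every_stage: bool = False  # concatenate scattering at all conv stages
    param_budget: int = 60_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")
        if self.loss not in ("squared_error", "cross_entropy"):
            raise ValueError(f"unknown loss form {self.loss!r}")


@dataclass
class DualPrediction:
    """Class-probability vectors from the CNN head and the scattering head."""

    y_hat_x: np.ndarray
    y_hat_sx: np.ndarray


class ESWCNN:
    def __init__(self, config: ESWCNNConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config

        self.hybrid_bank = scattering.build_filter_bank(c.height, c.width, c.hybrid_J, c.hybrid_L)
        self.aux_bank = scattering.build_filter_bank(c.height, c.width, c.aux_J, c.aux_L)
        n_paths = scattering.path_count(c.hybrid_J, c.hybrid_L, c.hybrid_order)
        self._stage_banks: dict[tuple[int, int], scattering.MorletFilterBank] = {}

        depth0 = c.in_channels * (1 + n_paths)
        self.convs: list[Conv2d] = []
        self.relus: list[ReLU] = []
        in_ch = depth0
        h = c.height
        for i, out_ch in enumerate(c.widths):
            if i > 0 and c.scatter_every_stage:
                in_ch = in_ch * (1 + n_paths)
            self.convs.append(Conv2d(in_ch, out_ch, rng, stride=2, pad=1))
            self.relus.append(ReLU())
            in_ch = out_ch
            h = (h + 2 - 3) // 2 + 1
        self.spectral = (
            SpectralFilter2d(c.widths[0], (c.height + 1) // 2, (c.width + 1) // 2)
            if c.use_spectral_filter
            else None
        )
        self.pool = GlobalAvgPool()
        self.dropout = Dropout(c.dropout, rng)
        self.head = Linear(c.widths[-1], c.n_classes, rng)
        n_aux = c.in_channels * scattering.path_count(c.aux_J, c.aux_L, c.aux_order)
        self.aux_head = Linear(n_aux, c.n_classes, rng)

        # per-feature standardization of the auxiliary scattering features,
        # fitted on the training set (dataset statistics, not trainable)
        self.aux_mu: np.ndarray | None = None
        self.aux_sd: np.ndarray | None = None

        n = self.n_params()
        if n > c.param_budget:
            raise ParameterBudgetError(
                f"model has {n} trainable parameters, exceeding the budget of "
                f"{c.param_budget}; reduce the stage widths"
            )

    # -- parameter bookkeeping -------------------------------------------
    def layers(self):
        out = list(self.convs) + [self.head, self.aux_head]
        if self.spectral is not None:
            out.append(self.spectral)
        return out

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers())

    # -- fixed feature extraction ----------------------------------------
    def prepare_features(self, images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Precompute the fixed scattering inputs for a batch of images.

        Returns the depth-concatenated hybrid input (N, C*(1+paths), H, W)
        and the pooled auxiliary feature matrix (N, C*aux_paths).  With
        ``use_scattering=False`` the scattering parts are zeroed, giving the
        parameter-matched plain-CNN baseline.
        """
        c = self.config
        images = np.asarray(images, dtype=float)
        if images.ndim != 4 or images.shape[1:] != (c.in_channels, c.height, c.width):
            raise ValueError(
                f"expected images of shape (N, {c.in_channels}, {c.height}, "
                f"{c.width}), got {images.shape}"
            )
        if c.use_scattering:
            s = scattering.scatter_features(images, self.hybrid_bank, c.hybrid_order)
            aux = scattering.scatter_pooled(images, self.aux_bank, c.aux_order)
        else:
            n_paths = scattering.path_count(c.hybrid_J, c.hybrid_L, c.hybrid_order)
            s = np.zeros((images.shape[0], c.in_channels * n_paths, c.height, c.width))
            aux = np.zeros(
                (images.shape[0], c.in_channels * scattering.path_count(c.aux_J, c.aux_L, c.aux_order))
            )
        return np.concatenate([images, s], axis=1), aux

    def _stage_scatter(self, x: np.ndarray) -> np.ndarray:
        c = self.config
        h, w = x.shape[2:]
        key = (h, w)
        if key not in self._stage_banks:
            self._stage_banks[key] = scattering.build_filter_bank(h, w, c.hybrid_J, c.hybrid_L)
        s = scattering.scatter_features(x, self._stage_banks[key], c.hybrid_order)
        return np.concatenate([x, s], axis=1)

    # -- forward / backward ----------------------------------------------
    def forward(
        self, hybrid_input: np.ndarray, aux_features: np.ndarray, train: bool = False
    ) -> DualPrediction:
        x = hybrid_input
        for i, (conv, relu) in enumerate(zip(self.convs, self.relus)):
            if i > 0 and self.config.scatter_every_stage:
                x = self._stage_scatter(x)
            x = relu.forward(conv.forward(x, train), train)
            if i == 0 and self.spectral is not None:
                x = self.spectral.forward(x, train)
        pooled = self.pool.forward(x, train)
        z = self.head.forward(self.dropout.forward(pooled, train), train)
        if self.aux_mu is not None:
            aux_features = (aux_features - self.aux_mu) / self.aux_sd
        z_aux = self.aux_head.forward(aux_features, train)
        return DualPrediction(y_hat_x=softmax(z), y_hat_sx=softmax(z_aux))

    def backward(self, dz: np.ndarray, dz_aux: np.ndarray) -> None:
        """Backpropagate pre-softmax gradients of both heads."""
        self.aux_head.backward(dz_aux)
        g = self.dropout.backward(self.head.backward(dz))
        g = self.pool.backward(g)
        for i in reversed(range(len(self.convs))):
            if i == 0 and self.spectral is not None:
                g = self.spectral.backward(g)
            g = self.convs[i].backward(self.relus[i].backward(g))
            if i > 0 and self.config.scatter_every_stage:
                g = g[:, : self.convs[i - 1].out_channels]  # scattering branch is fixed


def build_eswcnn(config: ESWCNNConfig | None = None) -> ESWCNN:
    """Instantiate the reference model, enforcing the parameter budget."""
    return ESWCNN(config or ESWCNNConfig())


def _softmax_vjp(p: np.ndarray, dldp: np.ndarray) -> np.ndarray:
    """Pre-softmax gradient given dL/d(probabilities)."""
    return p * (dldp - (dldp * p).sum(axis=1, keepdims=True))


def combined_loss(
    y: np.ndarray,
    pred: DualPrediction,
    gamma: float,
    form: str = "squared_error",
    return_grads: bool = False,
):
    """Balanced dual-head loss, batch-mean over samples.

    Default form: ||y - yhat(x)||^2 + gamma ||y - yhat(S[x])||^2 with y a
    one-hot row per sample.  The cross-entropy variant substitutes both
    squared terms.  With ``return_grads=True`` also returns the pre-softmax
    gradients of both heads.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must be in [0, 1], got {gamma}")
    y = np.atleast_2d(np.asarray(y, dtype=float))
    px = np.atleast_2d(pred.y_hat_x)
    ps = np.atleast_2d(pred.y_hat_sx)
    n = y.shape[0]
    if form == "squared_error":
        loss = np.mean(np.sum((y - px) ** 2, axis=1)) + gamma * np.mean(
            np.sum((y - ps) ** 2, axis=1)
        )
        if not return_grads:
            return float(loss)
        dz = _softmax_vjp(px, 2.0 * (px - y) / n)
        dz_aux = _softmax_vjp(ps, gamma * 2.0 * (ps - y) / n)
    elif form == "cross_entropy":
        eps = 1e-12
        loss = -np.mean(np.sum(y * np.log(px + eps), axis=1)) - gamma * np.mean(
            np.sum(y * np.log(ps + eps), axis=1)
        )
        if not return_grads:
            return float(loss)
        dz = (px - y) / n
        dz_aux = gamma * (ps - y) / n
    else:
        raise ValueError(f"unknown loss form {form!r}")
    return float(loss), dz, dz_aux


def train(
    model: ESWCNN,
    images: np.ndarray,
    labels: np.ndarray,
    val_images: np.ndarray | None = None,
    val_labels: np.ndarray | None = None,
    features: tuple[np.ndarray, np.ndarray] | None = None,
) -> dict:
    """Train with SGD-momentum; returns per-epoch loss/accuracy history.

    Scattering features of the (fixed) training set are precomputed once.
    Shuffling, dropout and initialization all derive from the config seed,
    so a (seed, dataset, config) triple reproduces bitwise.
    """
    c = model.config
    labels = np.asarray(labels, dtype=int)
    if images.shape[0] == 0:
        raise ValueError("empty training dataset")
    missing = sorted(set(range(c.n_classes)) - set(labels.tolist()))
    if missing:
        raise ValueError(f"classes absent from training labels: {missing}")

    # the scattering features are fixed, so they may be precomputed once and
    # shared across training runs on the same dataset
    hybrid_in, aux = features if features is not None else model.prepare_features(images)
    if model.aux_mu is None:
        model.aux_mu = aux.mean(axis=0)
        sd = aux.std(axis=0)
        model.aux_sd = np.where(sd > 0, sd, 1.0)
    y = one_hot(labels, c.n_classes)
    opt = SGDM(model.layers(), lr=c.lr, momentum=c.momentum)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([c.seed, 0xE5]))
    n = images.shape[0]
    history: dict[str, list[float]] = {"loss": [], "accuracy": []}
    if val_images is not None:
        history["val_accuracy"] = []
        val_hybrid, val_aux = model.prepare_features(val_images)

    for _epoch in range(c.epochs):
        order = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        correct = 0
        for start in range(0, n, c.batch_size):
            idx = order[start : start + c.batch_size]
            pred = model.forward(hybrid_in[idx], aux[idx], train=True)
            loss, dz, dz_aux = combined_loss(
                y[idx], pred, c.gamma, form=c.loss, return_grads=True
            )
            opt.zero_grad()
            model.backward(dz, dz_aux)
            opt.step()
            epoch_loss += loss * len(idx)
            correct += int((pred.y_hat_x.argmax(axis=1) == labels[idx]).sum())
        history["loss"].append(epoch_loss / n)
        history["accuracy"].append(correct / n)
        if val_images is not None:
            vp = model.forward(val_hybrid, val_aux, train=False)
            history["val_accuracy"].append(
                float((vp.y_hat_x.argmax(axis=1) == np.asarray(val_labels)).mean())
            )
    return history


def predict(
    model: ESWCNN,
    images: np.ndarray,
    batch_size: int = 100,
    features: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, DualPrediction]:
    """Predicted labels (argmax of the CNN head; ties -> lowest class index)
    plus both heads' probability vectors."""
    preds_x, preds_s = [], []
    for start in range(0, images.shape[0], batch_size):
        if features is not None:
            hy, aux = features[0][start : start + batch_size], features[1][start : start + batch_size]
        else:
            hy, aux = model.prepare_features(images[start : start + batch_size])
        p = model.forward(hy, aux, train=False)
        preds_x.append(p.y_hat_x)
        preds_s.append(p.y_hat_sx)
    px = np.concatenate(preds_x)
    ps = np.concatenate(preds_s)
    return px.argmax(axis=1), DualPrediction(px, ps)


def save_checkpoint(model: ESWCNN, path: str | Path) -> None:
    """Single-file parameter archive + JSON config sidecar."""
    path = Path(path)
    arrays = {}
    for i, layer in enumerate(model.layers()):
        for k, v in layer.params.items():
            arrays[f"{i}:{k}"] = v
    if model.aux_mu is not None:
        arrays["aux_mu"] = model.aux_mu
        arrays["aux_sd"] = model.aux_sd
    np.savez(path, **arrays)
    cfg = asdict(model.config)
    cfg["widths"] = list(cfg["widths"])
    Path(str(path) + ".json").write_text(json.dumps(cfg, indent=1))


def load_checkpoint(path: str | Path) -> ESWCNN:
    path = Path(path)
    cfg = json.loads(Path(str(path) + ".json").read_text())
    cfg["widths"] = tuple(cfg["widths"])
    model = ESWCNN(ESWCNNConfig(**cfg))
    data = np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz")
    for i, layer in enumerate(model.layers()):
        for k in layer.params:
            layer.params[k] = data[f"{i}:{k}"]
    if "aux_mu" in data:
        model.aux_mu = data["aux_mu"]
        model.aux_sd = data["aux_sd"]
    return model
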