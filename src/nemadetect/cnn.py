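"""Convolutional classifier for 9x9 director patches.

Architecture: two 3x3 valid convolutions with 32 feature maps each (no
pooling; the input is too small for it), a fully connected layer of 100 ReLU
units with 50% dropout during training, and a 3-way softmax over the classes
(+1/2, none, -1/2). Feature maps shrink 9 -> 7 -> 5, giving 32*5*5 = 800
inputs to the fully connected layer.

Each patch is encoded as two channels (cos 2theta, sin 2theta): the double
angle removes the artificial discontinuity of raw director angles at the pi
wrap and makes the nematic head-tail symmetry exact in the input.

Training minimizes the cross-entropy C = -sum_i sum_c y_ic log p_ic with
plain stochastic gradient descent: batch size 64, 30 epochs, learning rate
0.025 for the first 15 epochs then 0.005, Glorot-normal weight
initialization, zero biases, and a 10% validation holdout evaluated with
dropout disabled at the end of each epoch. The implementation is pure numpy
(im2col convolutions with explicit backprop); the network is small enough
that a full training run takes seconds on one CPU.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .detect import ROI
from .fields import ParameterError, reduce_mod_pi
from .records import CLASSES
from .synthetic import LabeledDataset

ENCODING_VERSION = "double-angle-v1"


@dataclass
class TrainConfig:
    """Optimization settings; defaults follow the published training recipe."""

    batch_size: int = 64
    epochs: int = 30
    lr_first: float = 0.025
    lr_second: float = 0.005
    lr_switch_epoch: int = 15
    dropout_fc: float = 0.5
    validation_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ParameterError("batch_size must be >= 1")
        if not (0.0 <= self.dropout_fc < 1.0):
            raise ParameterError("dropout_fc must be in [0, 1)")
        if not (0.0 < self.validation_fraction < 1.0):
            raise ParameterError("validation_fraction must be in (0, 1)")

    def learning_rate(self, epoch: int) -> float:
        """Learning rate for a 1-based epoch index."""
        return self.lr_first if epoch <= self.lr_switch_epoch else self.lr_second


def encode_roi(roi: ROI | np.ndarray) -> np.ndarray:
    """Encode a director patch as (2, side, side) double-angle channels."""
    patch = roi.theta_patch if isinstance(roi, ROI) else np.asarray(roi, dtype=float)
    if patch.ndim != 2:
        raise ParameterError("patch must be 2D")
    return np.stack([np.cos(2.0 * patch), np.sin(2.0 * patch)])


def encode_patches(patches: np.ndarray) -> np.ndarray:
    """Vectorized encoding of an (n, side, side) patch stack to (n, 2, s, s)."""
    patches = np.asarray(patches, dtype=float)
    return np.stack([np.cos(2.0 * patches), np.sin(2.0 * patches)], axis=1)


def rotate_patch(patch: np.ndarray, quarter_turns: int) -> np.ndarray:
    """Rotate a director patch rigidly by quarter_turns * pi/2.

    Rotating the sample grid and incrementing every director by the same
    angle; with rows indexing y upward, a +pi/2 geometric rotation is
    np.rot90 with k=-1 in array (row, col) space. Four applications are the
    identity (the angle increments sum to 2*pi = 0 mod pi).
    """
    k = quarter_turns % 4
    rotated = np.rot90(patch, k=-k)
    return reduce_mod_pi(rotated + k * np.pi / 2.0)


def reflect_patch(patch: np.ndarray) -> np.ndarray:
    """Reflect a director patch about its vertical centerline (x -> -x)."""
    return reduce_mod_pi(np.pi - patch[:, ::-1])


def augment(dataset: LabeledDataset) -> LabeledDataset:
    """Eightfold augmentation: 4 quarter-turn rotations x 2 reflections.

    Defect charge is invariant under both operations, so labels are copied
    unchanged; output size is exactly 8x the input size.
    """
    if dataset.patches.shape[1] != dataset.patches.shape[2]:
        raise ParameterError("augmentation requires square patches")
    patches, labels = [], []
    for p, lab in zip(dataset.patches, dataset.labels):
        for reflected in (p, reflect_patch(p)):
            for k in range(4):
                patches.append(rotate_patch(reflected, k))
                labels.append(lab)
    return LabeledDataset(
        patches=np.asarray(patches),
        labels=np.asarray(labels),
        provenance=dataset.provenance + "+augmented",
        kappas=None if dataset.kappas is None else np.repeat(dataset.kappas, 8),
    )


def _glorot_normal(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    std = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, std, shape)


def _conv_forward(X: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Valid 3x3 convolution. X: (N,C,H,W), W: (F,C,3,3) -> (N,F,H-2,W-2)."""
    N, C, H, Wd = X.shape
    F = W.shape[0]
    oh, ow = H - 2, Wd - 2
    win = sliding_window_view(X, (3, 3), axis=(2, 3))  # (N,C,oh,ow,3,3)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N, oh * ow, C * 9)
    out = cols @ W.reshape(F, -1).T + b
    return out.reshape(N, oh, ow, F).transpose(0, 3, 1, 2), cols


def _conv_backward(dout: np.ndarray, cols: np.ndarray, X_shape, W: np.ndarray):
    """Gradients of the valid convolution wrt W, b and the input."""
    N, C, H, Wd = X_shape
    F = W.shape[0]
    oh, ow = H - 2, Wd - 2
    dflat = dout.transpose(0, 2, 3, 1).reshape(N, oh * ow, F)
    dW = np.einsum("npf,npk->fk", dflat, cols).reshape(W.shape)
    db = dflat.sum(axis=(0, 1))
    dcols = (dflat @ W.reshape(F, -1)).reshape(N, oh, ow, C, 3, 3)
    dX = np.zeros(X_shape)
    for dy in range(3):
        for dx in range(3):
            dX[:, :, dy : dy + oh, dx : dx + ow] += dcols[..., dy, dx].transpose(
                0, 3, 1, 2
            )
    return dW, db, dX


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class ClassifierModel:
    """Trained-parameter container with a fixed class-order convention."""

    ARCH = "conv32(3x3)-relu-conv32(3x3)-relu-fc100-relu-dropout-fc3-softmax"

    def __init__(self, side: int = 9, n_features: int = 32, n_fc: int = 100,
                 seed: int = 0) -> None:
        if side < 5:
            raise ParameterError("input side must be >= 5 for two 3x3 convolutions")
        self.side = side
        self.class_order = CLASSES
        self.encoding = ENCODING_VERSION
        self.train_config: dict | None = None
        rng = np.random.default_rng(seed)
        f = n_features
        flat = f * (side - 4) * (side - 4)
        self.params = {
            "W1": _glorot_normal(rng, (f, 2, 3, 3), 2 * 9, f * 9),
            "b1": np.zeros(f),
            "W2": _glorot_normal(rng, (f, f, 3, 3), f * 9, f * 9),
            "b2": np.zeros(f),
            "W3": _glorot_normal(rng, (n_fc, flat), flat, n_fc),
            "b3": np.zeros(n_fc),
            "W4": _glorot_normal(rng, (3, n_fc), n_fc, 3),
            "b4": np.zeros(3),
        }

    # -- forward / backward ------------------------------------------------

    def forward(self, X: np.ndarray, dropout_rng: np.random.Generator | None = None,
                dropout_p: float = 0.0):
        """Class probabilities for encoded inputs X of shape (N, 2, s, s).

        Inference is deterministic; pass a generator and dropout_p > 0 only
        during training (inverted dropout on the fully connected layer).
        """
        p = self.params
        z1, cols1 = _conv_forward(X, p["W1"], p["b1"])
        a1 = np.maximum(z1, 0.0)
        z2, cols2 = _conv_forward(a1, p["W2"], p["b2"])
        a2 = np.maximum(z2, 0.0)
        flat = a2.reshape(X.shape[0], -1)
        z3 = flat @ p["W3"].T + p["b3"]
        a3 = np.maximum(z3, 0.0)
        if dropout_rng is not None and dropout_p > 0.0:
            mask = (dropout_rng.random(a3.shape) >= dropout_p) / (1.0 - dropout_p)
            a3 = a3 * mask
        else:
            mask = None
        z4 = a3 @ p["W4"].T + p["b4"]
        probs = _softmax(z4)
        cache = (X, cols1, z1, a1, cols2, z2, a2, flat, z3, a3, mask, probs)
        return probs, cache

    def backward(self, cache, y_onehot: np.ndarray) -> dict:
        """Gradients of the summed cross-entropy over the batch."""
        p = self.params
        X, cols1, z1, a1, cols2, z2, a2, flat, z3, a3, mask, probs = cache
        dz4 = probs - y_onehot  # d(sum CE)/dz4
        grads = {"W4": dz4.T @ a3, "b4": dz4.sum(axis=0)}
        da3 = dz4 @ p["W4"]
        if mask is not None:
            da3 = da3 * mask
        dz3 = da3 * (z3 > 0.0)
        grads["W3"] = dz3.T @ flat
        grads["b3"] = dz3.sum(axis=0)
        dflat = dz3 @ p["W3"]
        da2 = dflat.reshape(a2.shape)
        dz2 = da2 * (z2 > 0.0)
        grads["W2"], grads["b2"], da1 = _conv_backward(dz2, cols2, a1.shape, p["W2"])
        dz1 = da1 * (z1 > 0.0)
        grads["W1"], grads["b1"], _ = _conv_backward(dz1, cols1, X.shape, p["W1"])
        return grads

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        meta = {
            "arch": self.ARCH,
            "side": self.side,
            "class_order": list(self.class_order),
            "encoding": self.encoding,
            "train_config": self.train_config,
        }
        np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.params)

    @classmethod
    def load(cls, path) -> "ClassifierModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"].tobytes()).decode())
            if meta["encoding"] != ENCODING_VERSION:
                raise ParameterError(
                    f"model encoding {meta['encoding']!r} does not match "
                    f"{ENCODING_VERSION!r}"
                )
            model = cls(side=meta["side"])
            model.train_config = meta.get("train_config")
            for k in model.params:
                model.params[k] = data[k]
        if tuple(meta["class_order"]) != CLASSES:
            raise ParameterError("model class order does not match convention")
        return model


def cross_entropy(probs: np.ndarray, y_onehot: np.ndarray) -> float:
    """Mean cross-entropy -<sum_c y_c log p_c> over items."""
    eps = 1e-12
    return float(-(y_onehot * np.log(probs + eps)).sum(axis=1).mean())


def train(
    train_set: LabeledDataset,
    cfg: TrainConfig | None = None,
) -> tuple[ClassifierModel, "pd.DataFrame"]:
    """Train the classifier; returns the model and a per-epoch log.

    The validation holdout (cfg.validation_fraction of the input, seeded
    split) never enters a gradient update; its loss/accuracy are evaluated
    with dropout disabled at the end of each epoch. Training is repeatable
    for a fixed cfg.seed.
    """
    import pandas as pd

    cfg = cfg or TrainConfig()
    if len(train_set) == 0:
        raise ParameterError("empty training set")
    present = np.unique(train_set.labels)
    if len(present) < 3:
        import warnings

        warnings.warn(
            "not all three classes present in training data; the model may "
            "degenerate", stacklevel=2,
        )

    rng = np.random.default_rng(cfg.seed)
    X = encode_patches(train_set.patches)
    Y = train_set.one_hot()

    n = len(train_set)
    order = rng.permutation(n)
    n_val = max(1, int(round(cfg.validation_fraction * n)))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    if len(tr_idx) == 0:
        raise ParameterError("training set too small for the validation split")
    Xv, Yv = X[val_idx], Y[val_idx]
    Xt, Yt = X[tr_idx], Y[tr_idx]

    model = ClassifierModel(side=train_set.side, seed=int(rng.integers(2**31)))
    model.train_config = asdict(cfg)

    log = []
    for epoch in range(1, cfg.epochs + 1):
        lr = cfg.learning_rate(epoch)
        perm = rng.permutation(len(Xt))
        losses, correct = [], 0
        for start in range(0, len(Xt), cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            xb, yb = Xt[idx], Yt[idx]
            probs, cache = model.forward(xb, dropout_rng=rng,
                                         dropout_p=cfg.dropout_fc)
            grads = model.backward(cache, yb)
            for k, g in grads.items():
                model.params[k] -= (lr / len(xb)) * g
            losses.append(cross_entropy(probs, yb) * len(xb))
            correct += int((probs.argmax(1) == yb.argmax(1)).sum())
        pv, _ = model.forward(Xv)
        log.append(
            {
                "epoch": epoch,
                "lr": lr,
                "train_loss": float(np.sum(losses) / len(Xt)),
                "train_acc": correct / len(Xt),
                "val_loss": cross_entropy(pv, Yv),
                "val_acc": float((pv.argmax(1) == Yv.argmax(1)).mean()),
            }
        )
    return model, pd.DataFrame(log)


def predict(
    model: ClassifierModel,
    rois: list[ROI] | np.ndarray | LabeledDataset,
    batch_size: int = 256,
) -> tuple[np.ndarray, list[str]]:
    """Class probabilities and argmax labels; deterministic (no dropout).

    Accepts a list of ROIs, an (n, side, side) patch stack, or a dataset.
    """
    if isinstance(rois, LabeledDataset):
        patches = rois.patches
    elif isinstance(rois, np.ndarray):
        patches = rois
    else:
        patches = np.asarray([r.theta_patch for r in rois])
    if patches.ndim != 3 or patches.shape[1:] != (model.side, model.side):
        raise ParameterError(
            f"expected patches of shape (n, {model.side}, {model.side}), "
            f"got {patches.shape}"
        )
    X = encode_patches(patches)
    probs = np.concatenate(
        [model.forward(X[i : i + batch_size])[0] for i in range(0, len(X), batch_size)]
    ) if len(X) else np.zeros((0, 3))
    labels = [CLASSES[i] for i in probs.argmax(axis=1)]
    return probs, labels
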