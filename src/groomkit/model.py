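"""Baseline C3D and the multi-scale-fusion 3D CNN, with the training loop.

The baseline follows the canonical C3D topology: 8 convolutional layers
(3x3x3 kernels, stride 1), 5 max-pooling layers (2x2x2 except the first
at 1x2x2), two 4096-unit fully connected layers and a softmax head, on
16x112x112x3 input stacks. The fusion variant deepens the backbone to
12 convolutional layers (the two deepest blocks gain two layers each)
and adds a shallow branch: one 16-kernel 3x3x3 convolution tapped after
the first pooling stage, 3D *average*-pooled to a fixed 4x7x7 extent
and concatenated with the backbone flatten before the first fully
connected layer. The few branch channels keep the fused fan-in small
while injecting texture-rich shallow features.

A ``width_multiplier`` shrinks every channel width (the branch stays at
exactly 16 kernels) preserving the topology for desk-scale experiments.

Training uses SGD with momentum, batch size 8, initial learning rate
0.003 decayed by 10x every 4 epochs, dropout 0.5 after the fully
connected layers, and cross-entropy loss; everything is seeded.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

from . import nn
from .data import CLASS_NAMES

_BASE_WIDTHS = {
    # per-block channel widths and convs per block
    "baseline": ((64, 1), (128, 1), (256, 2), (512, 2), (512, 2)),
    "fusion": ((64, 1), (128, 1), (256, 2), (512, 4), (512, 4)),
}


@dataclasses.dataclass(frozen=True)
class NetworkSpec:
    variant: str = "fusion"
    n_classes: int = 7
    width_multiplier: float = 1.0
    fc_width: int = 4096
    dropout: float = 0.5
    branch_channels: int = 16
    branch_pool: tuple[int, int, int] = (4, 7, 7)
    dropout_both_fc: bool = True
    #: fixed input scale applied inside the network; mean-subtracted
    #: pixel stacks arrive in roughly [-128, 128], so 1/255 brings them
    #: to unit order, which the weight initialization assumes
    input_scale: float = 1.0 / 255.0
    #: rectifier slope for negative inputs; 0 is the plain rectifier.
    #: Width-reduced variants train with a small leak (e.g. 0.1): with
    #: only a couple of first-layer channels, dead units otherwise
    #: silence the whole network
    activation_slope: float = 0.0

    def __post_init__(self):
        if self.variant not in _BASE_WIDTHS:
            raise ValueError(
                f"variant must be one of {sorted(_BASE_WIDTHS)}, "
                f"got {self.variant!r}")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.width_multiplier <= 0:
            raise ValueError("width_multiplier must be positive")

    def conv_widths(self) -> list[int]:
        widths = []
        for base, count in _BASE_WIDTHS[self.variant]:
            widths += [max(1, round(base * self.width_multiplier))] * count
        return widths

    def fc_units(self) -> int:
        return max(8, round(self.fc_width * self.width_multiplier))


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    epochs: int = 20
    batch_size: int = 8
    learning_rate: float = 0.003
    lr_decay: float = 0.1
    decay_every: int = 4
    momentum: float = 0.9
    #: optional global gradient-norm ceiling; small-batch training of
    #: the normalization-free network needs it to survive the violent
    #: updates near the loss cliff (None disables)
    clip_norm: float | None = None
    seed: int = 0

    def __post_init__(self):
        if min(self.epochs, self.batch_size, self.decay_every) <= 0:
            raise ValueError("epochs, batch_size, decay_every must be > 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def lr_at_epoch(config: TrainConfig, epoch: int) -> float:
    """Staircase schedule: lr * decay^(epoch // decay_every), 0-based."""
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    return config.learning_rate * config.lr_decay ** (
        epoch // config.decay_every)


class GroomingNet:
    """3D CNN over (N, 16, 112, 112, 3) stacks -> class probabilities."""

    POOL_KERNELS = ((1, 2, 2), (2, 2, 2), (2, 2, 2), (2, 2, 2), (2, 2, 2))

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        widths = spec.conv_widths()
        blocks = _BASE_WIDTHS[spec.variant]
        self.conv_blocks: list[list] = []
        c_in = 3
        wi = 0
        for _base, count in blocks:
            block = []
            for _ in range(count):
                block.append(nn.Conv3d(c_in, widths[wi], rng))
                c_in = widths[wi]
                wi += 1
            self.conv_blocks.append(block)
        self.pools = [nn.MaxPool3d(k) for k in self.POOL_KERNELS]
        act = spec.activation_slope
        self._relus = [[nn.ReLU(act) for _ in block]
                       for block in self.conv_blocks]

        if spec.variant == "fusion":
            self.branch_conv = nn.Conv3d(widths[0], spec.branch_channels, rng)
            self.branch_relu = nn.ReLU(act)
            self.branch_pool = nn.AdaptiveAvgPool3d(spec.branch_pool)
            branch_units = spec.branch_channels * int(
                np.prod(spec.branch_pool))
        else:
            self.branch_conv = None
            branch_units = 0

        # backbone flatten extent for 16x112x112 input
        t, h, w = 16, 112, 112
        for kt, kh, kw in self.POOL_KERNELS:
            t, h, w = -(-t // kt), -(-h // kh), -(-w // kw)
        deep_units = widths[-1] * t * h * w
        fc = spec.fc_units()
        self._dropout_rng = np.random.default_rng(
            int(rng.integers(0, 2 ** 31)))
        self.fc1 = nn.Linear(deep_units + branch_units, fc, rng)
        self.fc1_relu = nn.ReLU(act)
        self.drop1 = nn.Dropout(spec.dropout, self._dropout_rng)
        self.fc2 = nn.Linear(fc, fc, rng)
        self.fc2_relu = nn.ReLU(act)
        self.drop2 = nn.Dropout(
            spec.dropout if spec.dropout_both_fc else 0.0, self._dropout_rng)
        self.fc3 = nn.Linear(fc, spec.n_classes, rng)
        self._deep_units = deep_units
        self._branch_units = branch_units

    # -- introspection used by the architecture audit ------------------
    @property
    def conv_layers(self) -> list:
        return [c for block in self.conv_blocks for c in block]

    @property
    def n_backbone_conv(self) -> int:
        return len(self.conv_layers)

    @property
    def n_max_pools(self) -> int:
        return len(self.pools)

    @property
    def fc_layers(self) -> list:
        return [self.fc1, self.fc2]

    def layers(self) -> list:
        out = self.conv_layers[:]
        if self.branch_conv is not None:
            out.append(self.branch_conv)
        out += [self.fc1, self.fc2, self.fc3]
        return out

    # -- forward / backward --------------------------------------------
    def forward(self, stacks: np.ndarray, train: bool = False) -> np.ndarray:
        """stacks: (N, 16, H, W, 3) float32 -> (N, n_classes) logits."""
        x = np.ascontiguousarray(
            np.asarray(stacks, dtype=np.float32).transpose(0, 4, 1, 2, 3))
        x *= self.spec.input_scale
        tap = None
        for bi, block in enumerate(self.conv_blocks):
            for conv, relu in zip(block, self._relus[bi]):
                x = relu.forward(conv.forward(x), train)
            x = self.pools[bi].forward(x)
            if bi == 0:
                tap = x
        n = x.shape[0]
        deep = x.reshape(n, -1)
        self._deep_shape = x.shape
        if self.branch_conv is not None:
            b = self.branch_relu.forward(self.branch_conv.forward(tap), train)
            b = self.branch_pool.forward(b)
            self._branch_shape = b.shape
            feat = np.concatenate([deep, b.reshape(n, -1)], axis=1)
        else:
            feat = deep
        h = self.drop1.forward(self.fc1_relu.forward(
            self.fc1.forward(feat), train), train)
        h = self.drop2.forward(self.fc2_relu.forward(
            self.fc2.forward(h), train), train)
        return self.fc3.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.fc3.backward(dlogits)
        d = self.fc2.backward(self.fc2_relu.backward(self.drop2.backward(d)))
        d = self.fc1.backward(self.fc1_relu.backward(self.drop1.backward(d)))
        n = d.shape[0]
        d_deep = d[:, :self._deep_units].reshape(self._deep_shape)
        if self.branch_conv is not None:
            d_branch = d[:, self._deep_units:].reshape(self._branch_shape)
            db = self.branch_pool.backward(d_branch)
            db = self.branch_conv.backward(self.branch_relu.backward(db))
        else:
            db = None
        dx = d_deep
        first_conv = self.conv_blocks[0][0]
        for bi in range(len(self.conv_blocks) - 1, -1, -1):
            if bi == 0 and db is not None:
                dx = dx + db  # branch taps the pool-1 output
            dx = self.pools[bi].backward(dx)
            for conv, relu in zip(reversed(self.conv_blocks[bi]),
                                  reversed(self._relus[bi])):
                # the input layer needs no dx (nothing below it)
                dx = conv.backward(relu.backward(dx),
                                   need_dx=conv is not first_conv)

    def predict_proba(self, stacks: np.ndarray,
                      batch_size: int = 8) -> np.ndarray:
        probs = []
        for i in range(0, len(stacks), batch_size):
            logits = self.forward(stacks[i:i + batch_size], train=False)
            probs.append(nn.softmax(logits))
        return np.concatenate(probs)

    def state(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers() for p, _ in
                layer.params()]

    def load_state(self, state) -> None:
        i = 0
        for layer in self.layers():
            for p, _ in layer.params():
                p[:] = state[i]
                i += 1


def build_network(spec: NetworkSpec, seed: int = 0) -> GroomingNet:
    return GroomingNet(spec, seed=seed)


def calibrate_init(net: GroomingNet, stacks: np.ndarray,
                   target_std: float = 1.0, tol: float = 0.05,
                   max_sweeps: int = 3) -> GroomingNet:
    """Variance-calibrated initialization on a sample batch.

    Rescales each convolutional and fully connected layer's weights and
    bias so its post-activation output has standard deviation close to
    ``target_std`` when the network is run on ``stacks`` (layer-
    sequential unit-variance init). Without normalization layers, a
    deep narrow network otherwise attenuates real video statistics so
    strongly that gradient descent stalls; calibrating on data restores
    a well-scaled forward signal. The classifier head is zeroed so the
    initial prediction is exactly uniform — early updates then fit the
    data instead of unlearning initialization noise. Deterministic
    given the batch.
    """
    net.fc3.w[:] = 0.0
    net.fc3.b[:] = 0.0
    def rescaled(out, layer):
        """Scale layer weights toward unit output std; rectifiers are
        positively homogeneous, so the cached output scales in place."""
        std = float(out.std())
        if std > 0 and abs(std - target_std) > tol * target_std:
            factor = target_std / std
            layer.w *= factor
            layer.b *= factor
            out *= factor
            return out, True
        return out, False

    for _ in range(max_sweeps):
        x = np.ascontiguousarray(np.asarray(stacks, dtype=np.float32)
                                 .transpose(0, 4, 1, 2, 3))
        x *= net.spec.input_scale
        adjusted = False
        tap = None
        for bi, block in enumerate(net.conv_blocks):
            for conv, relu in zip(block, net._relus[bi]):
                x = relu.forward(conv.forward(x), False)
                x, changed = rescaled(x, conv)
                adjusted |= changed
            x = net.pools[bi].forward(x)
            if bi == 0:
                tap = x
        n = x.shape[0]
        feat = x.reshape(n, -1)
        if net.branch_conv is not None:
            b = net.branch_relu.forward(net.branch_conv.forward(tap), False)
            b, changed = rescaled(b, net.branch_conv)
            adjusted |= changed
            b = net.branch_pool.forward(b)
            feat = np.concatenate([feat, b.reshape(n, -1)], axis=1)
        h = net.fc1_relu.forward(net.fc1.forward(feat), False)
        h, changed = rescaled(h, net.fc1)
        adjusted |= changed
        h = net.fc2_relu.forward(net.fc2.forward(h), False)
        h, changed = rescaled(h, net.fc2)
        adjusted |= changed
        if not adjusted:
            break
    return net


def predict(model: GroomingNet, stack: np.ndarray):
    """Classify one ClipStack. Returns (class index, probability vector);
    argmax ties resolve to the lowest class index."""
    if stack.ndim != 4:
        raise ValueError("expected a single (16, H, W, 3) stack")
    probs = model.predict_proba(stack[None])[0]
    return int(np.argmax(probs)), probs


def evaluate_dataset(model: GroomingNet, dataset,
                     batch_size: int = 8):
    """(accuracy, mean loss, predicted labels) over a StackDataset."""
    losses, preds, labels = [], [], []
    for xb, yb in dataset.batches(batch_size, train_mode=False):
        logits = model.forward(xb, train=False)
        loss, probs, _ = nn.softmax_cross_entropy(logits, yb)
        losses.append(loss * len(yb))
        preds.append(probs.argmax(axis=1))
        labels.append(yb)
    preds = np.concatenate(preds)
    labels = np.concatenate(labels)
    acc = float((preds == labels).mean())
    return acc, float(np.sum(losses) / len(labels)), preds


def _clip_gradients(model: GroomingNet, max_norm: float) -> None:
    """Scale all gradients so their global L2 norm is at most max_norm."""
    total = 0.0
    for layer in model.layers():
        for _p, g in layer.params():
            total += float(np.sum(np.square(g, dtype=np.float64)))
    norm = np.sqrt(total)
    if norm > max_norm:
        scale = np.float32(max_norm / norm)
        for layer in model.layers():
            for _p, g in layer.params():
                g *= scale


def train(model: GroomingNet, train_set, test_set, config: TrainConfig):
    """Train with seeded SGD; returns (model, history DataFrame).

    The model is left holding the parameters of the epoch with the best
    test accuracy. History has one row per epoch with train/test
    accuracy and loss. A non-finite loss aborts with a diagnostic.
    """
    if len(train_set) == 0 or len(test_set) == 0:
        raise ValueError("train and test sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    optimizer = nn.SGD(model.layers(), lr=config.learning_rate,
                       momentum=config.momentum)
    history = []
    best_acc, best_state = -1.0, None
    for epoch in range(config.epochs):
        optimizer.lr = lr_at_epoch(config, epoch)
        ep_loss, ep_correct, ep_n = 0.0, 0, 0
        for xb, yb in train_set.batches(config.batch_size, train_mode=True,
                                        rng=rng, shuffle=True):
            logits = model.forward(xb, train=True)
            loss, probs, dlogits = nn.softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}; try a lower "
                    "learning rate")
            model.backward(dlogits)
            if config.clip_norm is not None:
                _clip_gradients(model, config.clip_norm)
            optimizer.step()
            ep_loss += loss * len(yb)
            ep_correct += int((probs.argmax(axis=1) == yb).sum())
            ep_n += len(yb)
        test_acc, test_loss, _ = evaluate_dataset(model, test_set,
                                                  config.batch_size)
        history.append((epoch, ep_correct / ep_n, test_acc,
                        ep_loss / ep_n, test_loss))
        if test_acc > best_acc:
            best_acc, best_state = test_acc, model.state()
    if best_state is not None:
        model.load_state(best_state)
    return model, pd.DataFrame(
        history, columns=["epoch", "train_acc", "test_acc",
                          "train_loss", "test_loss"])


def save_checkpoint(model: GroomingNet, path, train_config=None,
                    class_names=CLASS_NAMES) -> None:
    meta = {"spec": dataclasses.asdict(model.spec),
            "train_config": (dataclasses.asdict(train_config)
                             if train_config else None),
            "class_names": list(class_names)}
    arrays = {f"param_{i}": p for i, p in enumerate(model.state())}
    np.savez_compressed(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path):
    """Returns (model, metadata dict)."""
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["meta"]))
        spec_dict = dict(meta["spec"])
        spec_dict["branch_pool"] = tuple(spec_dict["branch_pool"])
        spec = NetworkSpec(**spec_dict)
        model = GroomingNet(spec)
        params = [archive[f"param_{i}"]
                  for i in range(len(archive.files) - 1)]
    model.load_state(params)
    return model, meta
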