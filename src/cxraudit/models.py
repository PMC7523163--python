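"""Classifier family and training scheme for the shortcut audit.

Three architectures are provided, mirroring the capacity ladder commonly
used to check whether shortcut learning is a high-capacity artifact:

* ``dense-cnn`` — the highest-capacity member, a five-conv-block network;
* ``simple-cnn`` — a three-conv-block network;
* ``logistic-embedding`` — a logistic regression on a frozen random
  convolutional feature embedding (only the linear head trains).

The head is either ``multi15`` (14 auxiliary pathology nodes + 1 COVID
node, all supervised with per-node binary cross entropy) or ``single1``
(COVID only). Optimization is plain mini-batch SGD: batch 16, momentum 0.9,
weight decay 1e-4, learning rate 0.01 decayed 10x every 5 epochs, up to 30
epochs, selecting the epoch with the highest COVID-node validation AUROC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .assembly import SplitSpec, fold_manifests
from .data import DatasetManifest
from .errors import ConfigError, ModelSelectionError, ParameterError, UndefinedMetricError
from .nn import SGD, Conv2d, Dense, Flatten, ReLU, Sequential, sigmoid

__all__ = ["TrainHyperparams", "TrainedModelHandle", "ImageClassifier",
           "build_classifier", "train_classifier", "compute_auroc"]

ARCHITECTURES = ("dense-cnn", "simple-cnn", "logistic-embedding")
HEAD_SCHEMES = {"multi15": 15, "single1": 1}


@dataclass
class TrainHyperparams:
    batch_size: int = 16
    momentum: float = 0.9
    weight_decay: float = 1e-4
    lr: float = 0.01
    lr_decay_factor: float = 10.0
    lr_decay_every: int = 5
    max_epochs: int = 30

    def __post_init__(self):
        for name in ("batch_size", "momentum", "weight_decay", "lr",
                     "lr_decay_factor", "lr_decay_every", "max_epochs"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")


class ImageClassifier:
    """A differentiable image classifier exposing per-node log-odds.

    ``logits`` returns pre-sigmoid activations; under the BCE head these
    are the predicted log-odds of each node, the space in which all
    perturbation effects are measured.
    """

    def __init__(self, net: Sequential, architecture_id: str, head_scheme: str,
                 image_size: int):
        self.net = net
        self.architecture_id = architecture_id
        self.head_scheme = head_scheme
        self.image_size = image_size
        self.n_nodes = HEAD_SCHEMES[head_scheme]
        self.covid_node = self.n_nodes - 1

    def _node_index(self, node) -> int:
        if node == "covid":
            return self.covid_node
        node = int(node)
        if not 0 <= node < self.n_nodes:
            raise ConfigError(f"node {node} outside head scheme {self.head_scheme}")
        return node

    def _batch(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 2:
            images = images[None, None]
        elif images.ndim == 3:
            images = images[:, None]
        if images.shape[-1] != self.image_size:
            raise ConfigError(
                f"image size {images.shape[-1]} != training size {self.image_size}")
        return images

    def logits(self, images: np.ndarray, chunk: int = 256) -> np.ndarray:
        x = self._batch(images)
        outs = [self.net.forward(x[i:i + chunk]) for i in range(0, len(x), chunk)]
        return np.concatenate(outs, axis=0)

    def predict_log_odds(self, image: np.ndarray, node="covid") -> float:
        j = self._node_index(node)
        return float(self.logits(image)[0, j])

    def input_gradients(self, images: np.ndarray, node="covid",
                        chunk: int = 128) -> np.ndarray:
        """d(log-odds of node)/d(pixel) for each image; (N, H, W)."""
        j = self._node_index(node)
        x = self._batch(images)
        grads = []
        for i in range(0, len(x), chunk):
            xb = x[i:i + chunk]
            out = self.net.forward(xb)
            dout = np.zeros_like(out)
            dout[:, j] = 1.0
            grads.append(self.net.backward(dout)[:, 0])
        self.net.zero_grad()
        return np.concatenate(grads, axis=0)


def multilabel_bce(z: np.ndarray, t: np.ndarray) -> tuple[float, np.ndarray]:
    """Per-node binary cross entropy, summed over nodes, averaged over the
    batch. Returns (loss, dloss/dz). Summing (not averaging) over nodes
    keeps each node's gradient scale independent of head width, so the
    COVID node trains identically under multi15 and single1."""
    zc = np.clip(z, -60.0, 60.0)
    loss = float(np.mean(np.sum(np.logaddexp(0.0, zc) - t * zc, axis=1)))
    grad = (sigmoid(zc) - t) / z.shape[0]
    return loss, grad


def _conv_stack(blocks, rng, frozen=False):
    layers = []
    for cin, cout, stride in blocks:
        layers += [Conv2d(cin, cout, k=3, stride=stride, pad=1, rng=rng,
                          frozen=frozen), ReLU()]
    return layers


def build_classifier(arch: str, head_scheme: str = "multi15", image_size: int = 64,
                     seed: int = 0) -> ImageClassifier:
    """Desk-scale members of the audited model family.

    All three end in a fully connected head over the flattened final
    feature map (spatial layout preserved, as in the full-scale
    architectures' dense classifier stages); ``logistic-embedding``
    freezes its convolutional embedding at random initialization and
    trains only the linear head — a logistic regression on 1024 fixed
    deep features at 64 px input.
    """
    if arch not in ARCHITECTURES:
        raise ConfigError(f"unknown architecture {arch!r}")
    if head_scheme not in HEAD_SCHEMES:
        raise ConfigError(f"unknown head scheme {head_scheme!r}")
    n_out = HEAD_SCHEMES[head_scheme]
    rng = np.random.default_rng(seed)
    feat = image_size // 8
    if arch == "simple-cnn":
        layers = _conv_stack([(1, 8, 2), (8, 16, 2), (16, 32, 2)], rng)
        layers += [Flatten(), Dense(feat * feat * 32, n_out, rng=rng)]
    elif arch == "dense-cnn":
        layers = _conv_stack(
            [(1, 16, 2), (16, 32, 2), (32, 48, 1), (48, 64, 2)], rng)
        layers += [Flatten(), Dense(feat * feat * 64, n_out, rng=rng)]
    else:  # logistic-embedding
        layers = _conv_stack([(1, 8, 2), (8, 16, 2), (16, 16, 2)], rng,
                             frozen=True)
        layers += [Flatten(), Dense(feat * feat * 16, n_out, rng=rng)]
    net = Sequential(layers)
    return ImageClassifier(net, arch, head_scheme, image_size)


@dataclass
class TrainedModelHandle:
    classifier: ImageClassifier
    architecture_id: str
    head_scheme: str
    selected_epoch: int
    val_auroc_history: list[float]
    train_loss_history: list[float] = field(default_factory=list)
    seed: int = 0

    @property
    def model(self) -> ImageClassifier:
        return self.classifier


def compute_auroc(scores, labels) -> float:
    """AUROC as the normalized Mann-Whitney U statistic; ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUROC undefined: labels contain one class")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def train_classifier(manifest: DatasetManifest, split: SplitSpec,
                     arch: str = "dense-cnn", head_scheme: str = "multi15",
                     hp: TrainHyperparams | None = None,
                     seed: int = 0) -> TrainedModelHandle:
    """SGD training with per-epoch validation-AUROC model selection.

    Fully deterministic: weight init, batch order and everything else flow
    from ``seed``. Weights of the best-validation epoch are restored into
    the returned handle.
    """
    hp = hp or TrainHyperparams()
    train_m, val_m, _ = fold_manifests(manifest, split)
    if len(train_m) == 0 or len(val_m) == 0:
        raise ModelSelectionError("train and val folds must be nonempty")
    val_labels = val_m.covid_labels()
    if val_labels.min() == val_labels.max():
        raise ModelSelectionError("validation fold contains a single class")

    image_size = train_m[0].image.shape[0]
    clf = build_classifier(arch, head_scheme, image_size, seed=seed)
    x_train = train_m.images()
    y_train = train_m.labels(head_scheme)
    x_val = val_m.images()

    opt = SGD(clf.net.params(), lr=hp.lr, momentum=hp.momentum,
              weight_decay=hp.weight_decay)
    rng = np.random.default_rng(seed + 1)
    n = len(x_train)

    val_history: list[float] = []
    loss_history: list[float] = []
    best_state, best_auroc, best_epoch = None, -np.inf, -1

    for epoch in range(hp.max_epochs):
        opt.lr = hp.lr / (hp.lr_decay_factor ** (epoch // hp.lr_decay_every))
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, hp.batch_size):
            idx = order[start:start + hp.batch_size]
            opt.zero_grad()
            z = clf.net.forward(x_train[idx])
            loss, dz = multilabel_bce(z, y_train[idx])
            clf.net.backward(dz)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        loss_history.append(epoch_loss / max(n_batches, 1))

        val_scores = clf.logits(x_val[:, 0])[:, clf.covid_node]
        auroc = compute_auroc(val_scores, val_labels)
        val_history.append(auroc)
        # ties broken toward the later epoch: with a saturated validation
        # AUROC the later weights are the more converged ones
        if auroc >= best_auroc:
            best_auroc, best_epoch = auroc, epoch
            best_state = clf.net.state()

    clf.net.load_state(best_state)
    return TrainedModelHandle(
        classifier=clf, architecture_id=arch, head_scheme=head_scheme,
        selected_epoch=best_epoch, val_auroc_history=val_history,
        train_loss_history=loss_history, seed=seed)
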