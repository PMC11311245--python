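"""Binary RF-patch classifier harness.

The exercised architecture, ``small_cnn``, is a compact 4-block
conv-BN-ReLU stack (single-channel input, single output logit, global
average pooling, ~1.6e4 parameters) implemented directly on NumPy, with
Adam, sigmoid + binary cross-entropy on the single logit, 50% lateral
(horizontal) mirror augmentation, and a 4:1 stratified train/validation
split.  Batch-normalization supports three statistic modes:

- ``batch_stats`` (default): batch statistics are used at *both* training
  and evaluation; the layers keep no running domain statistics, only
  learned affine parameters.  Evaluation therefore depends on the
  composition of the (seeded, shuffled, fixed-size) evaluation batches.
- ``running_stats``: conventional exponential running statistics, used at
  evaluation.
- ``frozen``: statistics track the batches for one warm-up epoch and are
  then pinned for the rest of training and for evaluation (the BN-freezing
  domain-adaptation baseline); affine parameters still learn.

Fine-tuning updates only named trailing layers; all other parameters are
bit-identical before and after.  The large ImageNet-style architectures
(``resnet50_adapted``, ``densenet201_adapted``) are accepted in the config
enum but are not implemented in this build and raise ``NotImplementedError``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score

from .patching import split_train_val

__all__ = [
    "ClassifierConfig",
    "EvalResult",
    "SmallCNNClassifier",
    "build_model",
    "train_model",
    "evaluate_model",
    "fine_tune",
    "auc_threshold",
    "ARCHITECTURES",
]

ARCHITECTURES = ("small_cnn", "resnet50_adapted", "densenet201_adapted")
BN_MODES = ("batch_stats", "running_stats", "frozen")

_F32 = np.float32


@dataclass
class ClassifierConfig:
    """Training configuration (desk-scale defaults)."""

    architecture: str = "small_cnn"
    input_channels: int = 1
    bn_mode: str = "batch_stats"
    learning_rate: float = 2e-3
    epochs: int = 6
    batch_size: int = 256
    eval_batch_size: int = 256
    hflip_prob: float = 0.5
    seed: int = 0
    input_shape: Tuple[int, int] = (200, 26)

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.bn_mode not in BN_MODES:
            raise ValueError(f"unknown bn_mode {self.bn_mode!r}")
        if not 0.0 <= self.hflip_prob <= 1.0:
            raise ValueError("hflip_prob must be in [0, 1]")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class EvalResult:
    """Patchwise evaluation summary."""

    accuracy: float  # percent
    auc: float
    n_patches: int
    n_per_class: Tuple[int, int]
    threshold: float = 0.5


# ---------------------------------------------------------------------------
# layers


class _Conv:
    def __init__(self, c_in, c_out, kh, kw, sh, sw, rng):
        fan_in = c_in * kh * kw
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, c_in, kh, kw)).astype(_F32)
        self.b = np.zeros(c_out, dtype=_F32)
        self.k = (kh, kw)
        self.s = (sh, sw)
        self.trainable = True
        self.needs_input_grad = True  # cleared on the first layer

    def params(self):
        return {"w": self.w, "b": self.b}

    def forward(self, x, train):
        kh, kw = self.k
        sh, sw = self.s
        view = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::sh, ::sw]
        n, c, ho, wo = view.shape[:4]
        cols = np.ascontiguousarray(view.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * ho * wo, c * kh * kw
        )
        wmat = self.w.reshape(self.w.shape[0], -1).T
        out = cols @ wmat + self.b
        if train:
            self._cols = cols
            self._xshape = x.shape
        return out.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)

    def backward(self, g):
        n, f, ho, wo = g.shape
        gm = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * ho * wo, f)
        self.dw = (self._cols.T @ gm).T.reshape(self.w.shape)
        self.db = gm.sum(axis=0)
        if not self.needs_input_grad:
            self._cols = None
            return None
        kh, kw = self.k
        sh, sw = self.s
        c = self._xshape[1]
        dcols = (gm @ self.w.reshape(f, -1)).reshape(n, ho, wo, c, kh, kw)
        dx = np.zeros(self._xshape, dtype=_F32)
        for ki in range(kh):
            for kj in range(kw):
                dx[:, :, ki : ki + sh * ho : sh, kj : kj + sw * wo : sw] += dcols[
                    :, :, :, :, ki, kj
                ].transpose(0, 3, 1, 2)
        self._cols = None
        return dx

    def grads(self):
        return {"w": self.dw, "b": self.db}


class _BN:
    eps = 1e-5

    def __init__(self, c, mode):
        self.gamma = np.ones(c, dtype=_F32)
        self.beta = np.zeros(c, dtype=_F32)
        self.mode = mode
        self.running_mean = np.zeros(c, dtype=_F32)
        self.running_var = np.ones(c, dtype=_F32)
        self.momentum = 0.1
        self.trainable = True

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def freeze_stats(self):
        """Pin the accumulated running statistics (no further updates;
        used in both training and evaluation from now on)."""
        self._stats_frozen = True

    def forward(self, x, train):
        # "frozen" behaves like running_stats during the warm-up phase
        # (statistics must track the young weights to train at all), then
        # freeze_stats() pins them for the rest of training and evaluation
        frozen_now = self.mode == "frozen" and getattr(self, "_stats_frozen", False)
        use_batch = (
            self.mode == "batch_stats"
            or (self.mode in ("running_stats", "frozen") and train and not frozen_now)
        )
        if use_batch:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            if train and self.mode in ("running_stats", "frozen"):
                self.running_mean += self.momentum * (mean - self.running_mean)
                self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._xhat = xhat
            self._inv = inv.astype(_F32)
            self._batch_stats = use_batch
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, g):
        self.dgamma = (g * self._xhat).sum(axis=(0, 2, 3))
        self.dbeta = g.sum(axis=(0, 2, 3))
        gs = g * self.gamma[None, :, None, None]
        if not self._batch_stats:
            return gs * self._inv[None, :, None, None]
        m = g.shape[0] * g.shape[2] * g.shape[3]
        sum_gs = gs.sum(axis=(0, 2, 3))
        sum_gs_xhat = (gs * self._xhat).sum(axis=(0, 2, 3))
        dx = (
            gs
            - (sum_gs / m)[None, :, None, None]
            - self._xhat * (sum_gs_xhat / m)[None, :, None, None]
        ) * self._inv[None, :, None, None]
        self._xhat = None
        return dx

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}


class _ReLU:
    trainable = False

    def params(self):
        return {}

    def forward(self, x, train):
        out = np.maximum(x, 0.0)
        if train:
            self._mask = out > 0
        return out

    def backward(self, g):
        g = g * self._mask
        self._mask = None
        return g

    def grads(self):
        return {}


class _GAP:
    trainable = False

    def params(self):
        return {}

    def forward(self, x, train):
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, g):
        n, c, h, w = self._shape
        return np.broadcast_to(g[:, :, None, None] / (h * w), self._shape).astype(_F32)

    def grads(self):
        return {}


class _Linear:
    def __init__(self, c_in, c_out, rng):
        self.w = rng.normal(0.0, np.sqrt(1.0 / c_in), (c_in, c_out)).astype(_F32)
        self.b = np.zeros(c_out, dtype=_F32)
        self.trainable = True

    def params(self):
        return {"w": self.w, "b": self.b}

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, g):
        self.dw = self._x.T @ g
        self.db = g.sum(axis=0)
        dx = g @ self.w.T
        self._x = None
        return dx

    def grads(self):
        return {"w": self.dw, "b": self.db}


class _Adam:
    def __init__(self, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.state = {}

    def step(self, named_layers):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for lname, layer in named_layers:
            if not layer.trainable:
                continue
            grads = layer.grads()
            for pname, p in layer.params().items():
                g = grads[pname].astype(_F32)
                key = (lname, pname)
                if key not in self.state:
                    self.state[key] = (np.zeros_like(p), np.zeros_like(p))
                m, v = self.state[key]
                m += (1.0 - self.b1) * (g - m)
                v += (1.0 - self.b2) * (g * g - v)
                p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# estimator


class SmallCNNClassifier(BaseEstimator, ClassifierMixin):
    """Binary CNN classifier for RF patches (sklearn-style).

    Parameters mirror :class:`ClassifierConfig`.  ``fit`` accepts an
    ``(N, H, W)`` patch stack and labels in {0, 1}; an optional ``zones``
    vector stratifies the internal 4:1 train/validation split by
    (class, depth).  Training is reproducible under ``seed`` (fixed data
    and ordering).

    Attributes
    ----------
    classes_ : ndarray [0, 1]
    history_ : dict with per-epoch "loss" and "val_accuracy"
    n_parameters_ : total trainable parameter count
    """

    _layer_plan = (
        # (name, kind, args) chained on a 1 x 200 x 26 input
        ("conv1", "conv", (1, 8, 15, 3, 4, 2)),
        ("bn1", "bn", 8),
        ("relu1", "relu", None),
        ("conv2", "conv", (8, 16, 5, 3, 2, 2)),
        ("bn2", "bn", 16),
        ("relu2", "relu", None),
        ("conv3", "conv", (16, 32, 3, 3, 2, 1)),
        ("bn3", "bn", 32),
        ("relu3", "relu", None),
        ("conv4", "conv", (32, 32, 3, 3, 2, 1)),
        ("bn4", "bn", 32),
        ("relu4", "relu", None),
        ("gap", "gap", None),
        ("fc", "linear", (32, 1)),
    )

    def __init__(
        self,
        architecture: str = "small_cnn",
        bn_mode: str = "batch_stats",
        learning_rate: float = 2e-3,
        epochs: int = 6,
        batch_size: int = 256,
        eval_batch_size: int = 256,
        hflip_prob: float = 0.5,
        seed: int = 0,
        input_shape: Tuple[int, int] = (200, 26),
        verbose: int = 0,
    ):
        self.architecture = architecture
        self.bn_mode = bn_mode
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.eval_batch_size = eval_batch_size
        self.hflip_prob = hflip_prob
        self.seed = seed
        self.input_shape = input_shape
        self.verbose = verbose

    # -- construction -------------------------------------------------------

    def build(self) -> "SmallCNNClassifier":
        """Initialize parameters (deterministic under ``seed``)."""
        if self.architecture != "small_cnn":
            raise NotImplementedError(
                f"architecture {self.architecture!r} is not available in this "
                "build; use 'small_cnn'"
            )
        ClassifierConfig(
            architecture=self.architecture,
            bn_mode=self.bn_mode,
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            batch_size=self.batch_size,
            hflip_prob=self.hflip_prob,
            seed=self.seed,
            input_shape=tuple(self.input_shape),
        )  # validation only
        rng = np.random.default_rng(self.seed)
        self.layers_ = []
        for name, kind, args in self._layer_plan:
            if kind == "conv":
                layer = _Conv(*args, rng=rng)
            elif kind == "bn":
                layer = _BN(args, self.bn_mode)
            elif kind == "relu":
                layer = _ReLU()
            elif kind == "gap":
                layer = _GAP()
            else:
                layer = _Linear(*args, rng=rng)
            self.layers_.append((name, layer))
        self.layers_[0][1].needs_input_grad = False
        self.classes_ = np.array([0, 1])
        self.n_parameters_ = int(
            sum(p.size for _, l in self.layers_ for p in l.params().values())
        )
        self.history_ = {"loss": [], "val_accuracy": []}
        return self

    def _ensure_built(self):
        if not hasattr(self, "layers_"):
            self.build()

    def layer_names(self) -> List[str]:
        self._ensure_built()
        return [n for n, l in self.layers_ if l.params()]

    def parameter_snapshot(self):
        """Copies of all parameters, keyed by (layer, param) name."""
        self._ensure_built()
        return {
            (n, pn): p.copy() for n, l in self.layers_ for pn, p in l.params().items()
        }

    def set_trainable(self, names: Optional[Sequence[str]]):
        """Restrict learning to the named layers (None = all trainable)."""
        self._ensure_built()
        known = {n for n, l in self.layers_ if l.params()}
        if names is not None:
            unknown = set(names) - known
            if unknown:
                raise ValueError(f"unknown layer names {sorted(unknown)}; known: {sorted(known)}")
        for n, l in self.layers_:
            if not l.params():
                continue
            l.trainable = True if names is None else (n in names)

    # -- forward ------------------------------------------------------------

    def _forward(self, x, train):
        out = x
        for _, layer in self.layers_:
            out = layer.forward(out, train)
        return out[:, 0]

    def _backward(self, g):
        grad = g[:, None]
        for _, layer in reversed(self.layers_):
            grad = layer.backward(grad)

    def forward_logits(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for one batch as given (no internal shuffling)."""
        self._ensure_built()
        x = np.asarray(X, dtype=_F32)[:, None, :, :]
        return self._forward(x, train)

    # -- training -----------------------------------------------------------

    def fit(self, X, y, zones=None):
        X = np.asarray(X, dtype=_F32)
        y = np.asarray(y)
        if X.ndim != 3:
            raise ValueError("X must have shape (n_patches, axial, lateral)")
        if set(np.unique(y)) != {0, 1}:
            raise ValueError("fit requires both classes 0 and 1 to be present")
        self.input_shape = X.shape[1:]
        self.build()
        tr_idx, val_idx = split_train_val(
            X, ratio=(4, 1), seed=self.seed, zones=zones, labels=y
        )
        rng = np.random.default_rng(self.seed + 1)
        opt = _Adam(self.learning_rate)
        named = self.layers_
        for epoch in range(self.epochs):
            order = tr_idx[rng.permutation(tr_idx.size)]
            losses = []
            for b0 in range(0, order.size, self.batch_size):
                bi = order[b0 : b0 + self.batch_size]
                xb = X[bi][:, None, :, :].copy()
                yb = y[bi].astype(_F32)
                flip = rng.random(bi.size) < self.hflip_prob
                xb[flip] = xb[flip, :, :, ::-1]
                z = self._forward(xb, train=True)
                # binary cross-entropy on the single logit
                loss = float(np.mean(np.logaddexp(0.0, z) - yb * z))
                p = 1.0 / (1.0 + np.exp(-z))
                self._backward(((p - yb) / bi.size).astype(_F32))
                opt.step(named)
                losses.append(loss)
            if epoch == 0 and self.bn_mode == "frozen":
                for _, layer in self.layers_:
                    if isinstance(layer, _BN):
                        layer.freeze_stats()
            val_acc = self._accuracy(X[val_idx], y[val_idx]) if val_idx.size else float("nan")
            self.history_["loss"].append(float(np.mean(losses)))
            self.history_["val_accuracy"].append(val_acc)
            if self.verbose:
                print(f"epoch {epoch}: loss={np.mean(losses):.4f} val_acc={val_acc:.2f}")
        return self

    def fit_more(
        self,
        X,
        y,
        zones=None,
        unfreeze: Optional[Sequence[str]] = None,
        epochs: int = 2,
        learning_rate: Optional[float] = None,
    ):
        """Continue training (fine-tuning) with only ``unfreeze`` layers
        learnable.  ``unfreeze=[]`` is a no-op; ``None`` unfreezes all."""
        self._ensure_built()
        X = np.asarray(X, dtype=_F32)
        y = np.asarray(y)
        if unfreeze is not None and len(unfreeze) == 0:
            return self
        self.set_trainable(unfreeze)
        try:
            rng = np.random.default_rng(self.seed + 2)
            opt = _Adam(learning_rate or self.learning_rate)
            idx = np.arange(X.shape[0])
            for _ in range(epochs):
                order = idx[rng.permutation(idx.size)]
                for b0 in range(0, order.size, self.batch_size):
                    bi = order[b0 : b0 + self.batch_size]
                    xb = X[bi][:, None, :, :].copy()
                    yb = y[bi].astype(_F32)
                    flip = rng.random(bi.size) < self.hflip_prob
                    xb[flip] = xb[flip, :, :, ::-1]
                    z = self._forward(xb, train=True)
                    p = 1.0 / (1.0 + np.exp(-z))
                    self._backward(((p - yb) / bi.size).astype(_F32))
                    opt.step(self.layers_)
        finally:
            self.set_trainable(None)
        return self

    # -- inference ----------------------------------------------------------

    def decision_function(self, X) -> np.ndarray:
        """Logits under the pinned evaluation protocol.

        With ``bn_mode='batch_stats'`` evaluation statistics come from the
        evaluation batches themselves; batches are formed from a seeded
        shuffle at the configured ``eval_batch_size`` so results are
        reproducible for fixed model and data.
        """
        self._ensure_built()
        X = np.asarray(X, dtype=_F32)
        n = X.shape[0]
        order = np.random.default_rng(self.seed + 10007).permutation(n)
        logits = np.empty(n, dtype=np.float64)
        for b0 in range(0, n, self.eval_batch_size):
            bi = order[b0 : b0 + self.eval_batch_size]
            logits[bi] = self.forward_logits(X[bi], train=False)
        return logits

    def predict_proba(self, X) -> np.ndarray:
        p = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) >= 0.0).astype(np.int64)

    def _accuracy(self, X, y) -> float:
        return float((self.predict(X) == y).mean() * 100.0)


# ---------------------------------------------------------------------------
# functional surface

#: Trailing layers unfrozen when fine-tuning each architecture.
DEFAULT_UNFREEZE = {"small_cnn": ("conv4", "bn4", "fc")}


def _config_to_estimator(config: ClassifierConfig) -> SmallCNNClassifier:
    return SmallCNNClassifier(
        architecture=config.architecture,
        bn_mode=config.bn_mode,
        learning_rate=config.learning_rate,
        epochs=config.epochs,
        batch_size=config.batch_size,
        eval_batch_size=config.eval_batch_size,
        hflip_prob=config.hflip_prob,
        seed=config.seed,
        input_shape=config.input_shape,
    )


def build_model(config: ClassifierConfig) -> SmallCNNClassifier:
    """Initialized (untrained) model for the configured architecture."""
    return _config_to_estimator(config).build()


def train_model(model: SmallCNNClassifier, patches, labels, zones=None) -> SmallCNNClassifier:
    """Train ``model`` on normalized patches (stats sourcing is the caller's
    responsibility)."""
    X = patches if isinstance(patches, np.ndarray) else np.stack([p.data for p in patches])
    return model.fit(X, labels, zones=zones)


def evaluate_model(model, patches, labels, threshold: float = 0.5) -> EvalResult:
    """Patchwise accuracy (at ``threshold`` on the sigmoid output) and
    rank-statistic AUC."""
    X = patches if isinstance(patches, np.ndarray) else np.stack([p.data for p in patches])
    y = np.asarray(labels)
    if X.shape[0] == 0:
        raise ValueError("cannot evaluate on an empty patch set")
    scores = 1.0 / (1.0 + np.exp(-model.decision_function(X)))
    pred = (scores >= threshold).astype(np.int64)
    acc = float((pred == y).mean() * 100.0)
    auc = float(roc_auc_score(y, scores)) if len(np.unique(y)) == 2 else float("nan")
    return EvalResult(
        accuracy=acc,
        auc=auc,
        n_patches=int(y.size),
        n_per_class=(int((y == 0).sum()), int((y == 1).sum())),
        threshold=threshold,
    )


def fine_tune(
    model: SmallCNNClassifier,
    adapt_patches,
    labels,
    zones=None,
    unfreeze_spec: Optional[Sequence[str]] = None,
    epochs: int = 2,
    learning_rate: Optional[float] = None,
) -> SmallCNNClassifier:
    """Fine-tune only the named trailing layers on adaptation data.

    ``unfreeze_spec`` defaults to the architecture's standard trailing set
    (last conv block + linear head for ``small_cnn``).
    """
    if unfreeze_spec is None:
        unfreeze_spec = DEFAULT_UNFREEZE[model.architecture]
    X = adapt_patches if isinstance(adapt_patches, np.ndarray) else np.stack(
        [p.data for p in adapt_patches]
    )
    return model.fit_more(
        X, labels, zones=zones, unfreeze=unfreeze_spec, epochs=epochs,
        learning_rate=learning_rate,
    )


def auc_threshold(model, adapt_patches, labels) -> float:
    """Score threshold maximizing Youden's J on an adaptation set.

    Candidates are midpoints between adjacent distinct sorted scores (plus
    the outer extremes); with perfectly separated score groups this returns
    the midpoint of the gap.
    """
    X = adapt_patches if isinstance(adapt_patches, np.ndarray) else np.stack(
        [p.data for p in adapt_patches]
    )
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("adaptation set must contain both classes")
    scores = 1.0 / (1.0 + np.exp(-model.decision_function(X)))
    s = np.unique(scores)
    if s.size == 1:
        return float(s[0])
    cand = (s[:-1] + s[1:]) / 2.0
    n_pos = (y == 1).sum()
    n_neg = (y == 0).sum()
    tpr = np.array([(scores[y == 1] >= t).sum() / n_pos for t in cand])
    fpr = np.array([(scores[y == 0] >= t).sum() / n_neg for t in cand])
    return float(cand[int(np.argmax(tpr - fpr))])
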