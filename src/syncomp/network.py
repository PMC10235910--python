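"""Forward models: stochastic toy units, ReLU layers, linear readouts, MLP.

Two kinds of output unit are used in this package.

*Toy stochastic units* drive the 9-input toy experiments.  Unit ``i`` fires
(``y_i = 1``) with probability ``g(beta * (u_i - h))`` where ``u_i = w_i . x``
is its synaptic drive and ``g`` is the logistic function.  The threshold
``h`` relative to the typical post-training drive selects an operating
regime: with a low threshold (``SYMMETRIC_UNIT``) units fire for every
pattern and learning probes the rules' averaging behaviour; with a
threshold comparable to the drive (``SELECTIVE_UNIT``) early firing is
selective and symmetry breaking between patterns can occur.  See
docs/methods.md for why both regimes are needed.

*Rectified linear units* form the hidden layer of the three-layer image
classifier.  The classifier's output weights are obtained by least-squares
regression of one-hot targets on hidden activities; classification is the
argmax of the readout.  A standard backprop MLP (single ReLU hidden layer,
softmax cross-entropy, mini-batch SGD) is provided as the supervised
baseline, backed by scikit-learn.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

logger = logging.getLogger(__name__)

__all__ = [
    "ToyOutputModel",
    "SYMMETRIC_UNIT",
    "SELECTIVE_UNIT",
    "ActivityRecord",
    "ClassifierModel",
    "toy_rates",
    "toy_forward",
    "relu_forward",
    "fit_readout",
    "mlp_train",
    "evaluate",
    "train_competition_hidden",
    "competition_classifier",
    "random_features_classifier",
    "direct_readout_classifier",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ToyOutputModel:
    """Logistic-Bernoulli stochastic output unit.

    ``P(y_i = 1 | x) = g(beta * (w_i . x - h))``.  The baseline firing
    probability at zero drive, ``g(-beta * h)``, must lie strictly between
    0 and 0.5 so learning can bootstrap from all-zero weights.
    """

    beta: float = 8.0
    h: float = 0.1

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        base = expit(-self.beta * self.h)
        if not (0.0 < base < 0.5):
            raise ValueError(
                f"baseline firing probability g(-beta*h)={base:.3g} must be in (0, 0.5); "
                "choose h > 0"
            )


#: Low-threshold regime: units fire at a high baseline and saturate for all
#: trained patterns.  Used for the LTP-only protocol.
SYMMETRIC_UNIT = ToyOutputModel(beta=8.0, h=0.1)

#: High-threshold regime: units fire only when their drive is comparable to a
#: full pattern, so early firing is selective.  Used for the LTP+LTD and
#: competition protocols.
SELECTIVE_UNIT = ToyOutputModel(beta=8.0, h=0.6)


@dataclass
class ActivityRecord:
    """Per-sample layer activities aligned with class labels."""

    activities: np.ndarray  # (M, N)
    labels: np.ndarray | None = None
    layer_tag: str = "hidden"


@dataclass
class ClassifierModel:
    """Three-layer network: input weights, ReLU hidden layer, linear readout.

    ``w_in`` has shape ``(N, D)``; ``w_out`` has shape ``(C, N)`` with
    per-class intercepts in ``b_out``.  ``predict`` returns the argmax of
    the readout over the ReLU hidden activities.  ``kind`` records how the
    input weights were obtained (competition / random / backprop / none).
    """

    w_in: np.ndarray | None
    w_out: np.ndarray
    b_out: np.ndarray
    n_classes: int
    kind: str = "competition"
    activation: str = "relu"
    meta: dict = field(default_factory=dict)

    @property
    def n_hidden(self) -> int:
        return 0 if self.w_in is None else self.w_in.shape[0]

    def hidden(self, X: np.ndarray) -> np.ndarray:
        if self.w_in is None:  # direct readout on raw inputs
            return np.asarray(X, dtype=float)
        return relu_forward(self.w_in, X).activities

    def decision(self, X: np.ndarray) -> np.ndarray:
        return self.hidden(X) @ self.w_out.T + self.b_out

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.decision(X).argmax(axis=1)


def _check_drive_shapes(W: np.ndarray, X: np.ndarray) -> None:
    if W.ndim != 2:
        raise ValueError(f"weight matrix must be 2-D, got shape {W.shape}")
    if X.shape[-1] != W.shape[1]:
        raise ValueError(
            f"input dimension {X.shape[-1]} does not match weight columns {W.shape[1]}"
        )


def toy_rates(W: np.ndarray, X: np.ndarray, model: ToyOutputModel) -> np.ndarray:
    """Firing probabilities of the stochastic units for inputs ``X``.

    ``X`` may be a single D-vector or an ``(M, D)`` batch; the result has a
    matching leading shape with one probability per output unit.
    """
    W = np.asarray(W, dtype=float)
    X = np.asarray(X, dtype=float)
    _check_drive_shapes(W, X)
    return expit(model.beta * (X @ W.T - model.h))


def toy_forward(
    W: np.ndarray,
    X: np.ndarray,
    model: ToyOutputModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample binary activities of the stochastic units (one Bernoulli draw
    per unit and sample)."""
    p = toy_rates(W, X, model)
    return (rng.random(p.shape) < p).astype(float)


def relu_forward(W_in: np.ndarray, X: np.ndarray,
                 labels: np.ndarray | None = None) -> ActivityRecord:
    """Deterministic rectified-linear layer: ``max(0, X W_in^T)``."""
    W_in = np.asarray(W_in, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    _check_drive_shapes(W_in, X)
    return ActivityRecord(np.maximum(X @ W_in.T, 0.0), labels=labels, layer_tag="hidden")


def fit_readout(
    H: np.ndarray | ActivityRecord,
    labels: np.ndarray,
    ridge: float = 1e-6,
    n_classes: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares one-hot readout with optional ridge penalty.

    Solves ``min ||H W^T + b - Y||^2 + ridge ||W||^2`` for one-hot targets
    ``Y`` and returns ``(W_out, b_out)`` with shapes ``(C, N)`` and ``(C,)``.
    A rank-deficient unpenalized system falls back to the minimum-norm
    pseudoinverse solution (logged).
    """
    if isinstance(H, ActivityRecord):
        H = H.activities
    H = np.asarray(H, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if H.ndim != 2 or len(H) != len(labels):
        raise ValueError(f"activity matrix {H.shape} does not align with {len(labels)} labels")
    C = int(n_classes if n_classes is not None else labels.max() + 1)
    if len(H) < C:
        raise ValueError(f"need at least {C} samples to fit a {C}-class readout, got {len(H)}")
    if ridge < 0:
        raise ValueError(f"ridge must be >= 0, got {ridge}")
    Y = np.eye(C)[labels]
    Hb = np.hstack([H, np.ones((len(H), 1))])
    if ridge > 0:
        reg = ridge * np.eye(Hb.shape[1])
        reg[-1, -1] = 0.0  # do not penalize the intercept
        coef = np.linalg.solve(Hb.T @ Hb + reg, Hb.T @ Y)
    else:
        coef, _, rank, _ = np.linalg.lstsq(Hb, Y, rcond=None)
        if rank < Hb.shape[1]:
            logger.info(
                "rank-deficient readout design (rank %d < %d); using minimum-norm solution",
                rank, Hb.shape[1],
            )
    return coef[:-1].T, coef[-1]


def mlp_train(
    X: np.ndarray,
    labels: np.ndarray,
    n_hidden: int = 200,
    epochs: int = 5,
    batch_size: int = 32,
    learning_rate: float = 0.01,
    seed: int = 0,
) -> ClassifierModel:
    """Backprop baseline: one ReLU hidden layer, softmax cross-entropy,
    plain mini-batch SGD for a fixed number of epochs.

    Each training pattern is seen ``epochs`` times in total, matching the
    comparison protocol in which the competition network sees every pattern
    once but the MLP five times.
    """
    if epochs < 1:
        raise ValueError(f"epochs must be >= 1, got {epochs}")
    from sklearn.exceptions import ConvergenceWarning
    from sklearn.neural_network import MLPClassifier

    clf = MLPClassifier(
        hidden_layer_sizes=(n_hidden,),
        activation="relu",
        solver="sgd",
        learning_rate_init=learning_rate,
        momentum=0.9,
        batch_size=batch_size,
        max_iter=epochs,
        shuffle=True,
        random_state=seed,
        alpha=0.0,
        n_iter_no_change=epochs + 1,
        tol=0.0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, labels)
    if not np.isfinite(clf.loss_):
        raise RuntimeError(
            f"MLP training diverged (loss={clf.loss_}); lower the learning rate"
        )
    classes = clf.classes_
    C = len(classes)
    n_out = max(C, int(labels.max()) + 1)
    w_out = np.zeros((n_out, n_hidden))
    b_out = np.full(n_out, -np.inf)
    if C == 2 and clf.coefs_[1].shape[1] == 1:
        # binary problems use a single logistic output: class 1 iff z > 0
        w_out[classes[0]], b_out[classes[0]] = 0.0, 0.0
        w_out[classes[1]] = clf.coefs_[1][:, 0]
        b_out[classes[1]] = clf.intercepts_[1][0]
    else:
        w_out[classes] = clf.coefs_[1].T
        b_out[classes] = clf.intercepts_[1]
    return ClassifierModel(
        w_in=clf.coefs_[0].T,
        w_out=w_out,
        b_out=b_out,
        n_classes=n_out,
        kind="backprop",
        meta={"epochs": epochs, "batch_size": batch_size, "lr": learning_rate,
              "seed": seed, "final_loss": float(clf.loss_)},
    )


def evaluate(model: ClassifierModel, X: np.ndarray, labels: np.ndarray) -> float:
    """Correct rate in percent on an evaluation set."""
    labels = np.asarray(labels, dtype=int)
    if len(labels) == 0:
        raise ValueError("empty evaluation set")
    if labels.min() < 0 or labels.max() >= model.n_classes:
        raise ValueError(
            f"labels must lie in [0, {model.n_classes}), got range "
            f"[{labels.min()}, {labels.max()}]"
        )
    return float((model.predict(X) == labels).mean() * 100.0)


def train_competition_hidden(
    X: np.ndarray,
    n_hidden: int = 200,
    gamma: float = 0.05,
    Theta: float = 10.0,
    init_scale: float = 1e-3,
    seed: int = 0,
) -> np.ndarray:
    """Unsupervised single-pass training of image input weights.

    Hidden activities are deterministic ReLU drives; per presentation the
    raw Hebbian update of each still-immature neuron (excitatory weight mass
    below ``Theta``) is centred across neurons per input pixel (competition
    for presynaptic resources) and the weights of any pixel whose largest
    outgoing weight exceeds 1 are renormalized.

    Input weights start at small uniform positive values: an all-zero ReLU
    layer produces no activity and could never bootstrap.
    """
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    D = X.shape[1]
    W = rng.uniform(0.0, init_scale, size=(n_hidden, D))
    for x in X:
        y = np.maximum(W @ x, 0.0)
        immature = np.maximum(W, 0.0).sum(axis=1) < Theta
        delta = np.outer(y * immature, x)
        delta -= delta.mean(axis=0, keepdims=True)
        W += gamma * delta
        colmax = W.max(axis=0)
        over = colmax > 1.0
        W[:, over] /= colmax[over]
    return W


def competition_classifier(
    X_train: np.ndarray,
    labels: np.ndarray,
    n_hidden: int = 200,
    n_classes: int | None = None,
    gamma: float = 0.05,
    Theta: float = 10.0,
    ridge: float = 1e-6,
    seed: int = 0,
) -> ClassifierModel:
    """Competition-trained hidden layer plus least-squares readout."""
    w_in = train_competition_hidden(
        X_train, n_hidden=n_hidden, gamma=gamma, Theta=Theta, seed=seed
    )
    H = relu_forward(w_in, X_train)
    w_out, b_out = fit_readout(H, labels, ridge=ridge, n_classes=n_classes)
    return ClassifierModel(
        w_in=w_in, w_out=w_out, b_out=b_out,
        n_classes=w_out.shape[0], kind="competition",
        meta={"gamma": gamma, "Theta": Theta, "seed": seed},
    )


def random_features_classifier(
    X_train: np.ndarray,
    labels: np.ndarray,
    n_hidden: int = 200,
    n_classes: int | None = None,
    ridge: float = 1e-6,
    seed: int = 0,
) -> ClassifierModel:
    """Baseline: standard-normal random input weights, least-squares readout."""
    rng = np.random.default_rng(seed)
    w_in = rng.standard_normal((n_hidden, X_train.shape[1]))
    w_out, b_out = fit_readout(relu_forward(w_in, X_train), labels,
                               ridge=ridge, n_classes=n_classes)
    return ClassifierModel(w_in=w_in, w_out=w_out, b_out=b_out,
                           n_classes=w_out.shape[0], kind="random",
                           meta={"seed": seed})


def direct_readout_classifier(
    X_train: np.ndarray,
    labels: np.ndarray,
    n_classes: int | None = None,
    ridge: float = 1e-6,
) -> ClassifierModel:
    """Baseline: no hidden layer; least squares directly on the inputs."""
    w_out, b_out = fit_readout(np.asarray(X_train, dtype=float), labels,
                               ridge=ridge, n_classes=n_classes)
    return ClassifierModel(w_in=None, w_out=w_out, b_out=b_out,
                           n_classes=w_out.shape[0], kind="direct")


def save_model(model: ClassifierModel, path) -> None:
    """Round-trip serialization of a classifier to a single npz archive."""
    np.savez(
        path,
        w_in=np.array([]) if model.w_in is None else model.w_in,
        w_out=model.w_out,
        b_out=model.b_out,
        n_classes=model.n_classes,
        kind=model.kind,
        meta_keys=np.array(list(model.meta.keys()), dtype=object),
        meta_vals=np.array([repr(v) for v in model.meta.values()], dtype=object),
    )


def load_model(path) -> ClassifierModel:
    with np.load(path, allow_pickle=True) as z:
        w_in = z["w_in"]
        meta = {str(k): eval(v, {"__builtins__": {}}, {})  # noqa: S307 - reprs of scalars
                for k, v in zip(z["meta_keys"], z["meta_vals"])}
        return ClassifierModel(
            w_in=None if w_in.size == 0 else w_in,
            w_out=z["w_out"],
            b_out=z["b_out"],
            n_classes=int(z["n_classes"]),
            kind=str(z["kind"]),
            meta=meta,
        )
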