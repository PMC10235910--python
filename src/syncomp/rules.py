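"""Synaptic weight-update rules and the online training loop.

Three unsupervised rules act on the output-by-input weight matrix ``W``
(``N`` output neurons x ``D`` input units), one noisy sample ``x`` and one
binary output vector ``y`` per presentation:

``ltp``
    Pure Hebbian potentiation, ``W <- W + gamma * outer(y, x)``, followed by
    a per-neuron (row) renormalization whenever a neuron's largest input
    weight exceeds 1.  The long-run weight profile of every neuron tends to
    the mean input, so interfering patterns are averaged together.

``ltp_ltd``
    Potentiation with a depression threshold ``theta``:
    ``W <- W + gamma * outer(y, x - theta)``, same row renormalization.
    Inputs weaker than ``theta`` are depressed, so neurons can silence
    non-preferred pattern groups — enough to separate non-overlapping
    patterns, but overlapping ones remain merged.

``ltp_competition``
    Potentiation gated by neuronal maturation and centred across neurons
    per input unit.  The raw update of neuron ``i`` is ``y_i * x`` while its
    accumulated excitatory weight mass is below the maturation cap
    ``Theta`` and zero afterwards (mature granule cells lose ordinary LTP).
    The applied update subtracts, for each input unit, the average raw
    update over all output neurons — neurons compete for the limited
    synaptic resources of each presynaptic axon, so each column of the
    applied update sums to zero.  Normalization is per input unit (column):
    whenever an input unit's largest outgoing weight exceeds 1 the whole
    column is rescaled, bounding the net output of each input unit.

Ablations of the competition rule replace the maturation gate by the raw
Hebbian term, or drop the mean-subtraction, to probe which ingredient does
what.

Because the renormalizations fire once per presentation, the trained
weights hover on a stochastic limit cycle (each peak is pulled back into
``[1/(1+gamma), 1]``); :func:`train` therefore also returns a trailing
time-average of ``W`` over the final part of the stream, which is the
appropriate estimator of the equilibrium profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import (
    SELECTIVE_UNIT,
    SYMMETRIC_UNIT,
    ToyOutputModel,
    toy_forward,
)
from .patterns import SampleStream

__all__ = [
    "RULES",
    "RuleConfig",
    "WeightMatrix",
    "TrainResult",
    "ltp_update",
    "ltp_ltd_update",
    "normalize_rows",
    "normalize_columns",
    "maturation_gate",
    "competition_step",
    "default_unit_for_rule",
    "train",
]

RULES = ("ltp", "ltp_ltd", "ltp_competition")


@dataclass(frozen=True)
class RuleConfig:
    """Learning-rule identity plus hyperparameters.

    Parameters
    ----------
    rule
        One of ``ltp``, ``ltp_ltd``, ``ltp_competition``.
    gamma
        Learning rate (0.1 in the toy experiments).
    theta
        LTD threshold; inputs below it are depressed.  Any ``0 < theta < 0.5``
        preserves the sign structure of the depressed equilibrium profiles.
    Theta
        Maturation cap on a neuron's accumulated excitatory weight mass.
    gate_positive_part
        If True (default) the maturation gate compares
        ``sum_j max(w_ij, 0)`` against ``Theta``; competition drives many
        weights negative, and counting that suppression against the cap
        would keep tuned winners immature forever.  Set False for the
        literal net-sum gate.
    disable_maturation / disable_competition
        Ablation switches for the competition rule.
    normalization
        ``"row"`` or ``"column"``; ``None`` derives it from the rule
        (row for ltp / ltp_ltd, column for ltp_competition).
    """

    rule: str = "ltp_competition"
    gamma: float = 0.1
    theta: float = 0.2
    Theta: float = 1.5
    gate_positive_part: bool = True
    disable_maturation: bool = False
    disable_competition: bool = False
    normalization: str | None = None

    def __post_init__(self):
        if self.rule not in RULES:
            raise ValueError(f"unknown rule {self.rule!r}; valid rules are {', '.join(RULES)}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if self.theta < 0:
            raise ValueError(f"theta must be >= 0, got {self.theta}")
        if self.Theta <= 0:
            raise ValueError(f"Theta must be > 0, got {self.Theta}")
        if self.normalization not in (None, "row", "column"):
            raise ValueError(f"normalization must be 'row' or 'column', got {self.normalization!r}")

    @property
    def effective_normalization(self) -> str:
        if self.normalization is not None:
            return self.normalization
        return "column" if self.rule == "ltp_competition" else "row"


@dataclass
class WeightMatrix:
    """Output-by-input synaptic weights tagged with their provenance."""

    W: np.ndarray
    rule_tag: str = ""
    step: int = 0

    @property
    def n_out(self) -> int:
        return self.W.shape[0]

    @property
    def n_in(self) -> int:
        return self.W.shape[1]


@dataclass
class TrainResult:
    """Final weights, trailing-average equilibrium estimate, and a trace."""

    weights: WeightMatrix
    tail_mean: np.ndarray
    config: RuleConfig
    unit: ToyOutputModel
    trace: dict = field(default_factory=dict)


def _check_update_shapes(W, x, y) -> None:
    W = np.asarray(W)
    if np.shape(x) != (W.shape[1],):
        raise ValueError(
            f"input vector has shape {np.shape(x)}, expected ({W.shape[1]},) to match "
            f"the {W.shape[1]} input units"
        )
    if np.shape(y) != (W.shape[0],):
        raise ValueError(
            f"output vector has shape {np.shape(y)}, expected ({W.shape[0]},) to match "
            f"the {W.shape[0]} output neurons"
        )


def normalize_rows(W: np.ndarray) -> np.ndarray:
    """Divide each row whose maximum exceeds 1 by that maximum.

    Rows with maximum <= 1 (including all-zero rows) are untouched.
    """
    W = np.array(W, dtype=float)
    if W.size == 0:
        return W
    mx = W.max(axis=1)
    over = mx > 1.0
    W[over] /= mx[over][:, None]
    return W


def normalize_columns(W: np.ndarray) -> np.ndarray:
    """Divide each column whose maximum exceeds 1 by that maximum.

    Negative entries in a rescaled column shrink by the same factor, signs
    preserved.  This bounds the net output of each input unit rather than
    the net input of each neuron.
    """
    W = np.array(W, dtype=float)
    if W.size == 0:
        return W
    mx = W.max(axis=0)
    over = mx > 1.0
    W[:, over] /= mx[over]
    return W


def ltp_update(W: np.ndarray, x: np.ndarray, y: np.ndarray, gamma: float) -> np.ndarray:
    """One Hebbian potentiation step followed by row renormalization."""
    if gamma <= 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    _check_update_shapes(W, x, y)
    return normalize_rows(np.asarray(W, dtype=float) + gamma * np.outer(y, x))


def ltp_ltd_update(W: np.ndarray, x: np.ndarray, y: np.ndarray,
                   gamma: float, theta: float) -> np.ndarray:
    """One potentiation/depression step followed by row renormalization.

    With ``theta = 0`` this is exactly :func:`ltp_update`.
    """
    if gamma <= 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    if theta < 0:
        raise ValueError(f"theta must be >= 0, got {theta}")
    _check_update_shapes(W, x, y)
    return normalize_rows(np.asarray(W, dtype=float) + gamma * np.outer(y, np.asarray(x) - theta))


def maturation_gate(W: np.ndarray, x: np.ndarray, y: np.ndarray, Theta: float,
                    positive_part: bool = True) -> np.ndarray:
    """Raw Hebbian update gated by neuronal maturation.

    Row ``i`` of the result is ``y_i * x`` while neuron ``i`` is immature
    (accumulated weight mass strictly below ``Theta``) and zero once it has
    matured.  By default the mass is the excitatory (positive) part of the
    weights; ``positive_part=False`` uses the literal net sum.
    """
    if Theta <= 0:
        raise ValueError(f"Theta must be > 0, got {Theta}")
    _check_update_shapes(W, x, y)
    W = np.asarray(W, dtype=float)
    mass = np.maximum(W, 0.0).sum(axis=1) if positive_part else W.sum(axis=1)
    immature = mass < Theta  # strict: a neuron exactly at Theta is mature
    return np.outer(np.asarray(y) * immature, x)


def competition_step(delta_tilde: np.ndarray) -> np.ndarray:
    """Centre the raw updates across output neurons, per input unit.

    ``delta[i, j] = delta_tilde[i, j] - mean_i' delta_tilde[i', j]``; every
    column of the result sums to zero exactly, so potentiation of one
    neuron's synapse from input ``j`` comes at the expense of the other
    neurons' synapses from the same input.
    """
    delta_tilde = np.asarray(delta_tilde, dtype=float)
    if delta_tilde.ndim != 2 or delta_tilde.shape[0] < 2:
        raise ValueError(
            "competition requires at least 2 output neurons; got shape "
            f"{delta_tilde.shape}"
        )
    return delta_tilde - delta_tilde.mean(axis=0, keepdims=True)


def default_unit_for_rule(rule: str) -> ToyOutputModel:
    """Operating regime of the stochastic unit used by each toy protocol."""
    return SYMMETRIC_UNIT if rule == "ltp" else SELECTIVE_UNIT


def train(
    stream: SampleStream,
    cfg: RuleConfig,
    n_out: int = 100,
    unit: ToyOutputModel | None = None,
    seed: int = 0,
    w0: np.ndarray | None = None,
    tail_frac: float = 0.5,
    record_trace: bool = True,
) -> TrainResult:
    """One online pass of a learning rule over a sample stream.

    Per presentation: sample binary outputs ``y`` from the stochastic unit,
    form the raw update for ``cfg.rule`` (with the maturation gate and the
    competition centring unless ablated), scale by ``gamma``, add, and apply
    the configured renormalization.  Weights start at zero unless ``w0`` is
    given.

    ``tail_frac`` sets the fraction of final presentations over which the
    trailing average ``tail_mean`` is accumulated.
    """
    if len(stream) == 0:
        raise ValueError("empty sample stream")
    if not (0.0 < tail_frac <= 1.0):
        raise ValueError(f"tail_frac must be in (0, 1], got {tail_frac}")
    if unit is None:
        unit = default_unit_for_rule(cfg.rule)
    rng = np.random.default_rng(seed)
    D = stream.samples.shape[1]
    W = np.zeros((n_out, D)) if w0 is None else np.array(w0, dtype=float)
    if W.shape != (n_out, D):
        raise ValueError(f"w0 has shape {W.shape}, expected ({n_out}, {D})")

    n = len(stream)
    t_tail = int(round(n * (1.0 - tail_frac)))
    acc = np.zeros_like(W)
    n_acc = 0
    trace_steps, trace_mass = [], []
    norm = cfg.effective_normalization

    for t, (x, _label) in enumerate(stream):
        y = toy_forward(W, x, unit, rng)
        if cfg.rule == "ltp":
            W = W + cfg.gamma * np.outer(y, x)
        elif cfg.rule == "ltp_ltd":
            W = W + cfg.gamma * np.outer(y, x - cfg.theta)
        else:
            if cfg.disable_maturation:
                delta = np.outer(y, x)
            else:
                delta = maturation_gate(W, x, y, cfg.Theta,
                                        positive_part=cfg.gate_positive_part)
            if not cfg.disable_competition:
                delta = competition_step(delta)
            W = W + cfg.gamma * delta
        W = normalize_rows(W) if norm == "row" else normalize_columns(W)
        if t >= t_tail:
            acc += W
            n_acc += 1
        if record_trace and (t % max(1, n // 50) == 0 or t == n - 1):
            trace_steps.append(t)
            trace_mass.append(W.sum(axis=1).copy())

    tail_mean = acc / max(n_acc, 1)
    trace = {}
    if record_trace:
        trace = {"steps": np.array(trace_steps),
                 "summed_weights": np.array(trace_mass)}
    return TrainResult(
        weights=WeightMatrix(W=W, rule_tag=cfg.rule, step=n),
        tail_mean=tail_mean,
        config=cfg,
        unit=unit,
        trace=trace,
    )
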