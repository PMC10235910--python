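"""Quantitative readouts: weight clustering, PCA, Mahalanobis separation,
mutual information, adjusted cosine similarity, the competition energy
function, and paired statistical tests.

Conventions used throughout:

* Weight rows are categorized either by the input-unit indices of their two
  largest weights (``top2_units``, with a documented tie rule) or by the
  nearest prototype under cosine similarity (``nearest_fundamental``).
* Cluster separation between two groups of activity vectors is the
  Mahalanobis distance between their means under the pooled within-cluster
  covariance, shrunk toward a multiple of the identity for stability.
* Mutual information between discrete labels is computed from the joint
  histogram in nats, so a balanced C-class problem saturates at ln C.
* The adjusted cosine similarity subtracts an element-shuffled baseline
  from the raw cosine, removing the overlap inflation that nonnegative
  activity vectors produce.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist, pdist
from sklearn.metrics import mutual_info_score

from .patterns import PatternSet

__all__ = [
    "ClusterAssignment",
    "SeparationTable",
    "SecondMoments",
    "cluster_weights",
    "major_categories",
    "cosine_to_fundamentals",
    "pca_project",
    "mahalanobis_between",
    "separation_table",
    "mutual_information_labels",
    "adjusted_cosine",
    "energy",
    "paired_rule_comparison",
    "within_group_collapse",
    "response_partition_entropy",
]

ALL_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


# ---------------------------------------------------------------------------
# weight-profile clustering


@dataclass
class ClusterAssignment:
    """One category per output neuron; ``None`` marks unresolved rows."""

    labels: list
    scheme: str

    def counts(self) -> Counter:
        return Counter(l for l in self.labels if l is not None)

    @property
    def n_resolved(self) -> int:
        return sum(l is not None for l in self.labels)


def _top2_label(row: np.ndarray, resolve_tol: float, tie_tol: float):
    """Sorted pair of the two largest-weight unit indices.

    Rows whose peak does not exceed ``resolve_tol`` carry no meaningful
    tuning (the normalizations cap peaks at 1) and are unresolved.  Weights
    within a relative ``tie_tol`` of the second-largest are treated as tied
    and the lowest two indices among the tied set are chosen — with exact
    arithmetic, three equal maxima resolve to the lowest two indices.
    """
    if row.max() <= resolve_tol:
        return None
    order = np.argsort(-row, kind="stable")
    second = row[order[1]]
    tied = np.flatnonzero(row >= (1.0 - tie_tol) * second - 1e-12)
    if len(tied) >= 2:
        return tuple(sorted(tied.tolist())[:2])
    return tuple(sorted(order[:2].tolist()))


def cluster_weights(
    W: np.ndarray,
    scheme: str = "top2_units",
    ps: PatternSet | None = None,
    resolve_tol: float = 0.5,
    tie_tol: float = 0.05,
) -> ClusterAssignment:
    """Categorize weight rows by tuning.

    ``top2_units`` labels a row by the sorted indices of its two largest
    weights; ``nearest_fundamental`` labels it by the prototype with the
    highest cosine similarity (requires ``ps``).  Rows with no meaningful
    tuning (peak below ``resolve_tol``, or non-positive similarity to every
    prototype) are labelled ``None`` and excluded from counts.
    """
    W = np.asarray(W, dtype=float)
    if not np.any(W):
        raise ValueError("cannot cluster an all-zero weight matrix")
    if scheme == "top2_units":
        labels = [_top2_label(row, resolve_tol, tie_tol) for row in W]
    elif scheme == "nearest_fundamental":
        if ps is None:
            raise ValueError("nearest_fundamental clustering requires a PatternSet")
        sims = cosine_to_fundamentals(W, ps)
        labels = [
            int(np.argmax(s)) if s.max() > 0 else None for s in sims
        ]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return ClusterAssignment(labels=labels, scheme=scheme)


def major_categories(assignment: ClusterAssignment, min_frac: float = 0.05,
                     min_count: int = 3) -> set:
    """Categories holding at least ``max(min_frac * resolved, min_count)``
    neurons — the dominant tuning types of the population."""
    counts = assignment.counts()
    thresh = max(min_frac * assignment.n_resolved, min_count)
    return {k for k, v in counts.items() if v >= thresh}


def cosine_to_fundamentals(W: np.ndarray, ps: PatternSet) -> np.ndarray:
    """Cosine similarity of each weight row to each prototype (N x P).

    Zero-norm weight rows map to similarity 0.
    """
    W = np.asarray(W, dtype=float)
    P = ps.patterns
    p_norm = np.linalg.norm(P, axis=1)
    if np.any(p_norm == 0):
        raise ValueError("pattern set contains a zero-norm prototype")
    w_norm = np.linalg.norm(W, axis=1)
    safe = np.where(w_norm == 0, 1.0, w_norm)
    sims = (W @ P.T) / (safe[:, None] * p_norm[None, :])
    sims[w_norm == 0] = 0.0
    return sims


# ---------------------------------------------------------------------------
# PCA


def pca_project(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standard PCA without whitening.

    Returns ``(projections, explained_variance_ratio, components)`` for the
    ``k`` leading eigenvectors of the covariance of the mean-centred data.
    The sign of each component is fixed so its largest-magnitude loading is
    positive, making projections reproducible across runs.
    """
    X = np.asarray(X, dtype=float)
    M = X.shape[0]
    if M <= k:
        raise ValueError(f"need more than k={k} observations, got {M}")
    Xc = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(Xc)
    if k > rank:
        raise ValueError(f"k={k} exceeds the rank {rank} of the centred data")
    cov = Xc.T @ Xc / (M - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:k]
    comps = evecs[:, order].T  # (k, D)
    flip = np.sign(comps[np.arange(k), np.abs(comps).argmax(axis=1)])
    comps *= flip[:, None]
    evr = evals[order] / evals.clip(min=0).sum()
    return Xc @ comps.T, evr, comps


# ---------------------------------------------------------------------------
# cluster separation


def mahalanobis_between(A: np.ndarray, B: np.ndarray, reg: float = 1e-3) -> float:
    """Mahalanobis distance between two sample clusters.

    Distance between the cluster means under the pooled within-cluster
    covariance, regularized by ``reg * trace(S)/K`` times the identity.
    Symmetric in its arguments.  With ``reg = 0`` a singular covariance is
    rejected with instructions to use nonzero regularization.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if len(A) < 2 or len(B) < 2:
        raise ValueError("each cluster needs at least 2 samples")
    K = A.shape[1]
    Xc = np.vstack([A - A.mean(axis=0), B - B.mean(axis=0)])
    S = Xc.T @ Xc / (len(Xc) - 2)
    if reg > 0:
        S = S + reg * (np.trace(S) / K) * np.eye(K)
    d = A.mean(axis=0) - B.mean(axis=0)
    try:
        sol = np.linalg.solve(S, d)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "singular pooled covariance; pass a nonzero regularization reg"
        ) from err
    return float(np.sqrt(max(d @ sol, 0.0)))


@dataclass
class SeparationTable:
    """Per-pair Mahalanobis distances for the six unordered pattern pairs."""

    distances: dict  # {(a, b): float}
    rule_tag: str = ""

    def values(self, pairs=ALL_PAIRS) -> np.ndarray:
        return np.array([self.distances[p] for p in pairs])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"pair": [f"{a}-{b}" for a, b in self.distances],
             "mahalanobis": list(self.distances.values()),
             "rule": self.rule_tag}
        )


def separation_table(
    activities: np.ndarray,
    labels: np.ndarray,
    rule_tag: str = "",
    pairs=ALL_PAIRS,
    reg: float = 1e-3,
) -> SeparationTable:
    """Mahalanobis separation of activity clusters for each pattern pair."""
    activities = np.asarray(activities, dtype=float)
    labels = np.asarray(labels, dtype=int)
    dists = {}
    for a, b in pairs:
        dists[(a, b)] = mahalanobis_between(
            activities[labels == a], activities[labels == b], reg=reg
        )
    return SeparationTable(distances=dists, rule_tag=rule_tag)


def within_group_collapse(
    activities: np.ndarray,
    labels: np.ndarray,
    groups=((0, 1), (2, 3)),
    eps: float = 1e-9,
) -> float:
    """Within/between distance ratio for interfering pattern pairs.

    For each pair of overlapping classes, the mean pairwise Euclidean
    distance among same-class activity vectors is divided by the mean
    distance across the two classes; the ratios are averaged over the
    groups.  A value near 1 means the classes are indistinguishable
    (collapsed); well-separated classes give a ratio well below 1.
    Identical responses throughout (0/0) count as perfect collapse.
    """
    activities = np.asarray(activities, dtype=float)
    labels = np.asarray(labels, dtype=int)
    ratios = []
    for a, b in groups:
        Aa, Ab = activities[labels == a], activities[labels == b]
        if len(Aa) < 2 or len(Ab) < 2:
            raise ValueError(f"need at least 2 samples per class for pair {(a, b)}")
        d_within = (pdist(Aa).mean() * len(Aa) + pdist(Ab).mean() * len(Ab)) / (
            len(Aa) + len(Ab)
        )
        d_between = cdist(Aa, Ab).mean()
        ratios.append(1.0 if d_between < eps else d_within / d_between)
    return float(np.mean(ratios))


# ---------------------------------------------------------------------------
# information measures


def mutual_information_labels(a, b) -> float:
    """Mutual information between two discrete label sequences, in nats.

    Estimated from the joint histogram; bounded by the smaller marginal
    entropy and hence by ln(C) for C balanced classes.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty label sequence")
    if a.shape != b.shape:
        raise ValueError(f"label sequences differ in length: {a.shape} vs {b.shape}")
    return float(mutual_info_score(a, b))


def response_partition_entropy(responses: np.ndarray, tol: float = 0.1) -> float:
    """Entropy (nats) of the partition of stimuli by distinct responses.

    Two stimuli belong to the same cell of the partition when their mean
    response vectors agree within ``tol`` in the sup norm.  If all stimuli
    evoke the same response the partition has a single cell and the entropy
    is zero; fully distinct responses give ln(n_stimuli).
    """
    R = np.atleast_2d(np.asarray(responses, dtype=float))
    n = len(R)
    cell = -np.ones(n, dtype=int)
    next_id = 0
    for i in range(n):
        if cell[i] >= 0:
            continue
        cell[i] = next_id
        for j in range(i + 1, n):
            if cell[j] < 0 and np.max(np.abs(R[i] - R[j])) <= tol:
                cell[j] = next_id
        next_id += 1
    _, counts = np.unique(cell, return_counts=True)
    p = counts / n
    return float(-(p * np.log(p)).sum())


def adjusted_cosine(
    a: np.ndarray,
    b: np.ndarray,
    n_shuffles: int = 100,
    seed: int = 0,
) -> float:
    """Cosine similarity minus its element-shuffled baseline.

    The baseline is the mean cosine over ``n_shuffles`` draws in which the
    elements of each vector are independently permuted.  Nonnegative
    vectors have a positive expected overlap even when unrelated; the
    subtraction removes that artifact, so exchangeable noise scores near 0
    while genuinely aligned structure scores positive.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape or a.size < 2:
        raise ValueError(f"need two equal-length vectors of size >= 2, got {a.shape}, {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("adjusted cosine is undefined for zero-norm input")
    raw = float(a @ b / (na * nb))
    rng = np.random.default_rng(seed)
    base = 0.0
    for _ in range(n_shuffles):
        base += float(rng.permutation(a) @ rng.permutation(b))
    base /= n_shuffles * na * nb
    return raw - base


# ---------------------------------------------------------------------------
# competition energy function


@dataclass
class SecondMoments:
    """Input second moments: ``xsq[j] = <x_j^2>`` and ``cross[l, j] = <x_l x_j>``."""

    xsq: np.ndarray
    cross: np.ndarray

    def __post_init__(self):
        self.xsq = np.asarray(self.xsq, dtype=float)
        self.cross = np.asarray(self.cross, dtype=float)
        if self.cross.shape != (len(self.xsq), len(self.xsq)):
            raise ValueError("cross-moment matrix does not match xsq length")
        if not np.allclose(self.cross, self.cross.T):
            raise ValueError("cross-moment matrix must be symmetric")

    @classmethod
    def from_samples(cls, X: np.ndarray) -> "SecondMoments":
        X = np.asarray(X, dtype=float)
        cross = X.T @ X / len(X)
        return cls(xsq=np.diag(cross).copy(), cross=cross)


def energy(W: np.ndarray, i: int, moments: SecondMoments) -> float:
    """Energy of neuron ``i``'s input weights under competition without
    maturation.

    With deviations ``d_j = w_ij - mean_{k != i} w_kj`` (leave-one-out mean
    over the other neurons),

        E_i = -1/2 sum_j d_j^2 <x_j^2>  -  sum_{l<j} d_l d_j <x_l x_j>.

    Identical rows give ``E_i = 0``; growing one neuron's weights away from
    the population mean lowers the energy without bound, which is why the
    maturation cap is needed to keep the competition fair.
    """
    W = np.asarray(W, dtype=float)
    N, D = W.shape
    if N < 2:
        raise ValueError("energy requires at least 2 output neurons")
    if not 0 <= i < N:
        raise ValueError(f"neuron index {i} out of range [0, {N})")
    others = np.delete(W, i, axis=0)
    d = W[i] - others.mean(axis=0)
    e = -0.5 * float(d**2 @ moments.xsq)
    cross_terms = np.outer(d, d) * moments.cross
    e -= float(np.triu(cross_terms, k=1).sum())
    return e


# ---------------------------------------------------------------------------
# paired statistics


def paired_rule_comparison(table_a: SeparationTable, table_b: SeparationTable) -> dict:
    """Wilcoxon signed-rank test and variance-equality F test on two
    separation tables over the same six pattern pairs.

    Returns a dict with the two statistics and p-values.  When every paired
    difference is zero the signed-rank test is undefined and reported as
    statistic ``nan`` with p-value 1.
    """
    pairs = tuple(table_a.distances.keys())
    if set(pairs) != set(table_b.distances.keys()):
        raise ValueError("separation tables cover different pattern pairs")
    a = table_a.values(pairs)
    b = table_b.values(pairs)
    diffs = a - b
    if np.allclose(diffs, 0.0):
        w_stat, w_p = float("nan"), 1.0
    else:
        res = stats.wilcoxon(a, b, zero_method="wilcox", mode="exact")
        w_stat, w_p = float(res.statistic), float(res.pvalue)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if vb == 0 and va == 0:
        f_stat, f_p = 1.0, 1.0
    else:
        f_stat = float(va / vb) if vb > 0 else float("inf")
        dfa = dfb = len(a) - 1
        if np.isfinite(f_stat):
            cdf = stats.f.cdf(f_stat, dfa, dfb)
            f_p = float(2 * min(cdf, 1 - cdf))
        else:
            f_p = 0.0
    return {
        "wilcoxon_statistic": w_stat,
        "wilcoxon_p": w_p,
        "f_statistic": f_stat,
        "f_p": f_p,
        "n_pairs": len(a),
    }
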