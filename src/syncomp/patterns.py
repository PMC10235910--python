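"""Fundamental patterns and synthetic sample streams.

The toy task is built from four binary prototypes ("fundamental patterns")
over nine input units.  Two built-in sets are provided:

``overlapping``
    Patterns 0/1 share input unit 2 and patterns 2/3 share input unit 6, so
    the four classes form two interfering groups.  This is the hard case for
    purely Hebbian learning, which averages the groups away.

``nonoverlapping``
    The four patterns activate disjoint unit pairs; a depression term is
    enough to separate them.

Training data are noisy realizations ``x = xi(p) + eps`` with label ``p``
drawn uniformly at random, so the presentation order carries no class
information.  The noise is i.i.d. Gaussian per input unit with standard
deviation ``eta`` (the simplest model consistent with a single "noise
magnitude" parameter).

For image-scale experiments without external data, :func:`make_synthetic_digits`
generates labelled blob images that play the role of a small digit set: each
class has a fixed smooth template, and samples are jittered, noisy copies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PatternSet",
    "SampleStream",
    "make_fundamental_patterns",
    "make_sample_stream",
    "make_synthetic_digits",
    "save_stream",
    "load_stream",
]

_OVERLAPPING = np.array(
    [
        [0, 1, 1, 0, 0, 0, 0, 0, 0],
        [0, 0, 1, 1, 0, 0, 0, 0, 0],
        [0, 0, 0, 0, 0, 1, 1, 0, 0],
        [0, 0, 0, 0, 0, 0, 1, 1, 0],
    ],
    dtype=float,
)

_NONOVERLAPPING = np.array(
    [
        [0, 1, 1, 0, 0, 0, 0, 0, 0],
        [0, 0, 0, 1, 1, 0, 0, 0, 0],
        [0, 0, 0, 0, 0, 1, 1, 0, 0],
        [0, 0, 0, 0, 0, 0, 0, 1, 1],
    ],
    dtype=float,
)

VALID_SET_IDS = ("overlapping", "nonoverlapping")


@dataclass(frozen=True)
class PatternSet:
    """A set of binary prototype patterns.

    Attributes
    ----------
    patterns
        ``(P, D)`` binary matrix; row ``p`` is the prototype of class ``p``.
    set_id
        ``"overlapping"``, ``"nonoverlapping"`` or ``"custom"``.
    overlap_pairs
        Unordered index pairs of prototypes with a nonzero dot product.
    """

    patterns: np.ndarray
    set_id: str = "custom"
    overlap_pairs: tuple = field(default_factory=tuple)

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.patterns.shape[1]

    def groups(self) -> list[list[int]]:
        """Connected components of the overlap graph (interference groups)."""
        parent = list(range(self.n_patterns))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for a, b in self.overlap_pairs:
            parent[find(a)] = find(b)
        comps: dict[int, list[int]] = {}
        for p in range(self.n_patterns):
            comps.setdefault(find(p), []).append(p)
        return sorted(comps.values())


@dataclass
class SampleStream:
    """An ordered stream of noisy labelled samples.

    ``samples[t]`` equals the prototype of class ``labels[t]`` plus i.i.d.
    zero-mean Gaussian noise of standard deviation ``eta`` per entry.
    """

    samples: np.ndarray  # (n, D)
    labels: np.ndarray  # (n,) integer classes
    eta: float
    seed: int

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return zip(self.samples, self.labels)


def make_fundamental_patterns(set_id: str) -> PatternSet:
    """Return one of the two built-in 4x9 prototype sets.

    Parameters
    ----------
    set_id
        ``"overlapping"`` (patterns 0/1 share unit 2, patterns 2/3 share
        unit 6) or ``"nonoverlapping"`` (disjoint unit pairs).
    """
    if set_id == "overlapping":
        return PatternSet(_OVERLAPPING.copy(), "overlapping", ((0, 1), (2, 3)))
    if set_id == "nonoverlapping":
        return PatternSet(_NONOVERLAPPING.copy(), "nonoverlapping", ())
    raise ValueError(
        f"unknown pattern set {set_id!r}; valid ids are {', '.join(VALID_SET_IDS)}"
    )


def make_sample_stream(ps: PatternSet, n: int, eta: float, seed: int) -> SampleStream:
    """Draw ``n`` noisy samples from a pattern set.

    Labels are i.i.d. uniform over the prototypes; each sample is its
    prototype plus N(0, eta^2) noise per entry.  The same seed reproduces
    the stream bit for bit.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if eta < 0:
        raise ValueError(f"eta must be >= 0, got {eta}")
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, ps.n_patterns, size=n)
    samples = ps.patterns[labels] + rng.normal(0.0, eta, size=(n, ps.n_inputs))
    return SampleStream(samples=samples, labels=labels, eta=float(eta), seed=int(seed))


def make_synthetic_digits(
    n_classes: int = 10,
    side: int = 28,
    n: int = 1000,
    seed: int = 0,
    jitter: int = 2,
    noise: float = 0.25,
    n_blobs: int = 3,
) -> SampleStream:
    """Generate a download-free, digit-like image classification set.

    Each class template is a sum of ``n_blobs`` random Gaussian bumps on a
    ``side x side`` canvas, normalized to peak 1.  A sample is its class
    template cyclically shifted by up to ``jitter`` pixels in each direction
    plus Gaussian pixel noise (clipped at 0, so images stay nonnegative).
    Class labels are exactly balanced (up to the remainder of ``n`` modulo
    ``n_classes``) and presented in a random order.

    The returned stream carries the flattened class templates in the
    ``templates`` attribute for reference.
    """
    if n_classes < 2:
        raise ValueError(f"n_classes must be >= 2, got {n_classes}")
    if side < 8:
        raise ValueError(f"side must be >= 8, got {side}")
    if n < n_classes:
        raise ValueError(f"need at least one sample per class: n={n} < n_classes={n_classes}")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:side, 0:side]
    templates = []
    for _ in range(n_classes):
        t = np.zeros((side, side))
        for _ in range(n_blobs):
            cy, cx = rng.uniform(side * 0.2, side * 0.8, size=2)
            sig = rng.uniform(side * 0.06, side * 0.12)
            amp = rng.uniform(0.6, 1.0)
            t += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sig**2))
        templates.append(t / t.max())

    labels = rng.permutation(np.arange(n) % n_classes)
    X = np.empty((n, side * side))
    for i, lab in enumerate(labels):
        img = templates[lab]
        if jitter > 0:
            dy, dx = rng.integers(-jitter, jitter + 1, size=2)
            img = np.roll(np.roll(img, dy, axis=0), dx, axis=1)
        if noise > 0:
            img = np.clip(img + rng.normal(0.0, noise, size=img.shape), 0.0, None)
        X[i] = img.ravel()
    stream = SampleStream(samples=X, labels=labels, eta=float(noise), seed=int(seed))
    stream.templates = np.array([t.ravel() for t in templates])  # type: ignore[attr-defined]
    return stream


def save_stream(stream: SampleStream, samples_path: str | Path, labels_path: str | Path) -> None:
    """Serialize a stream as a dense array file plus a plain-text label file."""
    np.save(samples_path, stream.samples)
    Path(labels_path).write_text("\n".join(str(int(l)) for l in stream.labels) + "\n")


def load_stream(samples_path: str | Path, labels_path: str | Path,
                eta: float = float("nan"), seed: int = -1) -> SampleStream:
    samples = np.load(samples_path)
    labels = np.array(
        [int(line) for line in Path(labels_path).read_text().split()], dtype=int
    )
    if len(labels) != len(samples):
        raise ValueError(
            f"sample/label count mismatch: {len(samples)} samples vs {len(labels)} labels"
        )
    return SampleStream(samples=samples, labels=labels, eta=eta, seed=seed)
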