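"""Shared fixtures: pattern sets and session-scoped trained toy networks.

Training runs are the expensive part of the suite, so one representative
run per rule/task is trained once per session and reused by the unit,
property and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from syncomp import analysis, network, patterns, rules

#: Equilibrium profile of the LTP-only rule on the overlapping task
#: (mean input rescaled to unit max).
EQ_LTP_PROFILE = np.array([0, 0.5, 1, 0.5, 0, 0.5, 1, 0.5, 0])

#: The four top-2 weight categories of the competition rule on the
#: overlapping task.
TARGET_CATEGORIES = {(1, 2), (2, 3), (5, 6), (6, 7)}

THETA_LTD = 0.2


def ltd_templates(ps: patterns.PatternSet, theta: float = THETA_LTD) -> np.ndarray:
    """Depressed-equilibrium templates: 1-theta on a prototype's active
    units, -theta elsewhere."""
    return np.where(ps.patterns > 0, 1.0 - theta, -theta)


@pytest.fixture(scope="session")
def overlapping() -> patterns.PatternSet:
    return patterns.make_fundamental_patterns("overlapping")


@pytest.fixture(scope="session")
def nonoverlapping() -> patterns.PatternSet:
    return patterns.make_fundamental_patterns("nonoverlapping")


def train_rule(ps, rule, seed, n=2000, n_out=100, eta=0.1, **cfg_over):
    stream = patterns.make_sample_stream(ps, n, eta, seed)
    cfg = rules.RuleConfig(rule=rule, **cfg_over)
    return rules.train(stream, cfg, n_out=n_out, seed=seed)


@pytest.fixture(scope="session")
def ltp_result(overlapping):
    return train_rule(overlapping, "ltp", seed=0)


@pytest.fixture(scope="session")
def ltd_overlap_result(overlapping):
    return train_rule(overlapping, "ltp_ltd", seed=0)


@pytest.fixture(scope="session")
def ltd_nonoverlap_result(nonoverlapping):
    return train_rule(nonoverlapping, "ltp_ltd", seed=0)


@pytest.fixture(scope="session")
def competition_result(overlapping):
    return train_rule(overlapping, "ltp_competition", seed=0)


@pytest.fixture(scope="session")
def toy_test_stream(overlapping):
    return patterns.make_sample_stream(overlapping, 600, 0.1, 7777)


def binary_activities(result, stream, seed):
    rng = np.random.default_rng(seed)
    return network.toy_forward(result.weights.W, stream.samples, result.unit, rng)


@pytest.fixture(scope="session")
def digits_small():
    """Small synthetic digit set shared by classifier tests."""
    return patterns.make_synthetic_digits(n_classes=10, side=28, n=1000, seed=0)


def within_group_mahalanobis(acts, labels):
    return (
        analysis.mahalanobis_between(acts[labels == 0], acts[labels == 1]),
        analysis.mahalanobis_between(acts[labels == 2], acts[labels == 3]),
    )
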