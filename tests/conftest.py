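"""Shared fixtures and oracle helpers for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dereg import (
    STATES,
    ExpressionMatrix,
    HiddenAssignment,
    ModelParameters,
    RegulatoryNetwork,
    collective_state,
    default_simulation_theta,
    truth_table,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture
def tiny_net() -> RegulatoryNetwork:
    """One target, one activator, one inhibitor."""
    return RegulatoryNetwork.from_edges({"tg1": ["tf1"]}, {"tg1": ["tf2"]})


@pytest.fixture
def toy_net() -> RegulatoryNetwork:
    """Two targets with disjoint regulator sets (tree-structured graph)."""
    return RegulatoryNetwork.from_edges(
        {"tg1": ["tf1", "tf2"], "tg2": ["tf3"]},
        {"tg1": [], "tg2": ["tf4"]},
    )


@pytest.fixture
def loopy_net() -> RegulatoryNetwork:
    """Two targets sharing a regulator (the factor graph has a cycle)."""
    return RegulatoryNetwork.from_edges(
        {"tg1": ["tf1", "tf2"], "tg2": ["tf2", "tf3"]},
        {"tg1": ["tf3"], "tg2": []},
    )


@pytest.fixture
def theta() -> ModelParameters:
    return default_simulation_theta()


def random_theta(rng: np.random.Generator) -> ModelParameters:
    """A random valid parameter vector with ordered means."""
    alpha = rng.dirichlet(np.ones(3))
    mu = np.sort(rng.normal(0.0, 1.5, size=3))
    sigma = rng.uniform(0.2, 1.0, size=3)
    epsilon = float(rng.uniform(0.01, 0.4))
    return ModelParameters(alpha=alpha, epsilon=epsilon, mu=mu, sigma=sigma)


def random_single_target_net(rng: np.random.Generator) -> RegulatoryNetwork:
    """One target with 1-4 activators and 0-3 inhibitors."""
    na = int(rng.integers(1, 5))
    ni = int(rng.integers(0, 4))
    regs = [f"tf{j}" for j in range(na + ni)]
    return RegulatoryNetwork.from_edges(
        {"tg": regs[:na]}, {"tg": regs[na:]}
    )


def iter_consistent_assignments(net: RegulatoryNetwork):
    """Yield every hidden configuration satisfying the hard constraints."""
    for cfg in itertools.product(STATES, repeat=net.n_regulators):
        reg = dict(zip(net.regulators, cfg))
        s_a = {
            g: collective_state(reg[a] for a in net.activators[g])
            for g in net.targets
        }
        s_i = {
            g: collective_state(reg[b] for b in net.inhibitors[g])
            for g in net.targets
        }
        s_r = {g: truth_table(s_a[g], s_i[g]) for g in net.targets}
        per_target = [
            [(0, s_r[g])] + [(1, s) for s in STATES if s != s_r[g]]
            for g in net.targets
        ]
        for combo in itertools.product(*per_target):
            d = {g: ds[0] for g, ds in zip(net.targets, combo)}
            s = {g: ds[1] for g, ds in zip(net.targets, combo)}
            yield HiddenAssignment(reg, s_a, s_i, s_r, d, s)


def marginals_max_abs_diff(a, b) -> float:
    """L-infinity distance between two SampleMarginals over all variables."""
    worst = 0.0
    for attr in (
        "regulator_s", "target_s_a", "target_s_i", "target_s_r",
        "target_s", "target_d",
    ):
        da, db = getattr(a, attr), getattr(b, attr)
        assert set(da) == set(db)
        for k in da:
            worst = max(worst, float(np.max(np.abs(da[k] - db[k]))))
    return worst


def expression_from_rows(rows: np.ndarray, net: RegulatoryNetwork) -> ExpressionMatrix:
    """Wrap raw rows (aligned to net.genes) into an ExpressionMatrix."""
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    ids = tuple(f"s{i}" for i in range(rows.shape[0]))
    return ExpressionMatrix(rows, ids, net.genes)
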