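"""Synthetic networks and expression data drawn from the generative model.

Simulation follows the model exactly: TF statuses are i.i.d. multinomial
with proportions alpha; each target's collective statuses and regulated
status S^R derive deterministically from the TF draw; the deregulation
indicator is Bernoulli(epsilon) and, when set, the realized status is
uniform over the two states other than S^R; every observed expression value
is Gaussian around the mean of its hidden status.  Ground-truth hidden
assignments and deregulation labels are returned for evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .model import (
    STATES,
    STATE_INDEX,
    ExpressionMatrix,
    HiddenAssignment,
    ModelParameters,
    RegulatoryNetwork,
    collective_state,
    truth_table,
)


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth of one simulated dataset.

    ``deregulated[i, j]`` is 1 iff target ``j`` (in network target order)
    escaped its regulated status in sample ``i`` — equivalently, iff the
    hidden realized status differs from the truth-table status.
    """

    hidden: tuple[HiddenAssignment, ...]
    deregulated: np.ndarray
    theta_true: ModelParameters
    seed: int


def default_simulation_theta(
    sigma: float = 0.3, epsilon: float = 0.05
) -> ModelParameters:
    """Default simulation parameters.

    Means are (-1, 0, 1) — one expression unit between adjacent states —
    with a shared sigma small enough that adjacent states remain separable
    (the rule of thumb being sigma below the gap between means), a uniform
    TF status distribution and a rare deregulation event.
    """
    return ModelParameters(
        alpha=np.full(3, 1 / 3),
        epsilon=epsilon,
        mu=np.array([-1.0, 0.0, 1.0]),
        sigma=np.full(3, float(sigma)),
    )


def generate_network(
    r: int,
    t: int,
    max_act: int = 2,
    max_inh: int = 2,
    seed: int = 0,
) -> RegulatoryNetwork:
    """Uniform-random bipartite network.

    Each target draws an activator count in 0..max_act and an inhibitor
    count in 0..max_inh (redrawn until the total is between 1 and r), then
    samples that many distinct TFs without replacement.  Deterministic
    given the seed.
    """
    if r < 1 or t < 1:
        raise DataError("need at least one regulator and one target")
    if max_act + max_inh < 1:
        raise DataError("max_act + max_inh must be >= 1")
    if max_act > r or max_inh > r:
        raise DataError(
            f"degree caps ({max_act}, {max_inh}) exceed the {r} available regulators"
        )
    rng = np.random.default_rng(seed)
    width = len(str(max(r, t)))
    regs = [f"tf{j + 1:0{width}d}" for j in range(r)]
    tgts = [f"tg{j + 1:0{width}d}" for j in range(t)]
    activators: dict[str, list[str]] = {}
    inhibitors: dict[str, list[str]] = {}
    for g in tgts:
        while True:
            na = int(rng.integers(0, max_act + 1))
            ni = int(rng.integers(0, max_inh + 1))
            if 1 <= na + ni <= r:
                break
        chosen = rng.choice(r, size=na + ni, replace=False)
        activators[g] = [regs[j] for j in chosen[:na]]
        inhibitors[g] = [regs[j] for j in chosen[na:]]
    return RegulatoryNetwork.from_edges(activators, inhibitors)


def simulate_dataset(
    net: RegulatoryNetwork,
    theta: ModelParameters,
    n: int,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Draw ``n`` samples of expression (and hidden truth) from the model.

    All randomness comes from one seeded stream, consumed in a fixed order
    (TF statuses, then per-target deregulation draws, then emissions), so
    identical seeds give bit-identical outputs.
    """
    if n < 1:
        raise DataError("n must be >= 1")
    rng = np.random.default_rng(seed)
    r, t = net.n_regulators, net.n_targets
    genes = net.genes
    values = np.empty((n, r + t))
    hidden: list[HiddenAssignment] = []
    dereg = np.zeros((n, t), dtype=int)
    states = np.array(STATES)

    for i in range(n):
        tf_states = {
            g: int(rng.choice(states, p=theta.alpha)) for g in net.regulators
        }
        s_a: dict[str, int] = {}
        s_i: dict[str, int] = {}
        s_r: dict[str, int] = {}
        d: dict[str, int] = {}
        s: dict[str, int] = {}
        for j, g in enumerate(net.targets):
            s_a[g] = collective_state(tf_states[a] for a in net.activators[g])
            s_i[g] = collective_state(tf_states[b] for b in net.inhibitors[g])
            s_r[g] = truth_table(s_a[g], s_i[g])
            flip = bool(rng.random() < theta.epsilon)
            d[g] = int(flip)
            if flip:
                others = [u for u in STATES if u != s_r[g]]
                s[g] = int(rng.choice(others))
                dereg[i, j] = 1
            else:
                s[g] = s_r[g]
        z = HiddenAssignment(tf_states, s_a, s_i, s_r, d, s)
        hidden.append(z)
        all_states = [tf_states[g] for g in net.regulators] + [
            s[g] for g in net.targets
        ]
        for k, (g, state) in enumerate(zip(genes, all_states)):
            values[i, k] = rng.normal(theta.mu_of(state), theta.sigma_of(state))

    width = len(str(n))
    sample_ids = tuple(f"s{i + 1:0{width}d}" for i in range(n))
    X = ExpressionMatrix(values, sample_ids, genes)
    truth = SimulationTruth(tuple(hidden), dereg, theta, seed)
    return X, truth
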