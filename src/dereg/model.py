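"""Core model types and the cooperative-regulation logic.

The model describes a signed bipartite regulatory network in which each
target gene g is controlled by a set of co-activator transcription factors
A(g) and a set of co-inhibitor transcription factors I(g).  Every gene
carries a hidden ternary expression status S in {-1, 0, +1} (under-, normal,
over-expressed).  Regulation is cooperative: a regulator set has collective
status +1 (resp. -1) only when *all* its members share that status, and 0
otherwise.  The expected (regulated) status of a target, S^R, is a fixed
truth-table function of the two collective statuses.  A binary deregulation
indicator D allows the realized status S of a target to escape S^R: with
probability epsilon, D = 1 and S is drawn uniformly from the two states
other than S^R.  Observed expression is Gaussian given the hidden status,
X | S = s ~ N(mu_s, sigma_s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DataError

#: The three admissible hidden expression states, in canonical order.
STATES: tuple[int, int, int] = (-1, 0, 1)

#: Position of each state in arrays ordered like :data:`STATES`.
STATE_INDEX: dict[int, int] = {-1: 0, 0: 1, 1: 2}

# Truth table of cooperative regulation, keyed (activator collective state,
# inhibitor collective state).  Inhibition dominates unless the inhibitors
# are collectively under-expressed; activation wins only then.
_TRUTH_TABLE: dict[tuple[int, int], int] = {
    (-1, -1): 0, (0, -1): 1, (1, -1): 1,
    (-1, 0): -1, (0, 0): 0, (1, 0): 1,
    (-1, 1): -1, (0, 1): -1, (1, 1): -1,
}

_LOG_2PI = math.log(2.0 * math.pi)


def truth_table(activator_state: int, inhibitor_state: int) -> int:
    """Regulated status S^R of a target given the two collective statuses.

    Parameters
    ----------
    activator_state, inhibitor_state
        Collective ternary status of the co-activator and co-inhibitor sets.

    Returns
    -------
    int
        The target's expected status in {-1, 0, +1}.
    """
    try:
        return _TRUTH_TABLE[(activator_state, inhibitor_state)]
    except (KeyError, TypeError) as exc:
        raise DataError(
            f"non-ternary truth-table input ({activator_state!r}, {inhibitor_state!r})"
        ) from exc


def collective_state(states: Iterable[int]) -> int:
    """Collective status of a co-regulator set.

    Returns ``s`` in {-1, +1} iff every member has status ``s``; returns 0
    otherwise.  An empty set has collective status 0 (the neutral element of
    the regulation logic), which lets the model accept networks where one of
    the two regulator sets of a target is empty.
    """
    result: int | None = None
    for s in states:
        if s not in STATE_INDEX:
            raise DataError(f"non-ternary state {s!r} in collective_state")
        if result is None:
            result = s
        elif s != result:
            return 0
    return 0 if result is None else result


@dataclass(frozen=True)
class RegulatoryNetwork:
    """A signed bipartite regulatory network.

    Attributes
    ----------
    regulators
        Transcription-factor gene identifiers (the set R), sorted.
    targets
        Target gene identifiers (the set T), sorted.
    activators, inhibitors
        Per-target subsets of R (A(g) and I(g)), stored as sorted tuples.

    A gene may not appear in both roles; A(g) and I(g) are disjoint and
    their union is non-empty for every target (either one may be empty).
    """

    regulators: tuple[str, ...]
    targets: tuple[str, ...]
    activators: Mapping[str, tuple[str, ...]]
    inhibitors: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        reg_set = set(self.regulators)
        tgt_set = set(self.targets)
        if len(reg_set) != len(self.regulators) or len(tgt_set) != len(self.targets):
            raise DataError("duplicate gene identifiers in regulators or targets")
        dual = reg_set & tgt_set
        if dual:
            raise DataError(
                f"gene(s) appear both as regulator and target: {sorted(dual)}"
            )
        if not self.targets:
            raise DataError("network has no targets")
        for g in self.targets:
            a = set(self.activators.get(g, ()))
            i = set(self.inhibitors.get(g, ()))
            if not a <= reg_set or not i <= reg_set:
                raise DataError(f"target {g!r} has regulators outside R")
            if a & i:
                raise DataError(
                    f"target {g!r}: {sorted(a & i)} both activator and inhibitor"
                )
            if not (a | i):
                raise DataError(f"target {g!r} has no regulators")
        extra = set(self.activators) - tgt_set | set(self.inhibitors) - tgt_set
        if extra:
            raise DataError(f"regulator sets given for unknown targets: {sorted(extra)}")

    @classmethod
    def from_edges(
        cls,
        activators: Mapping[str, Iterable[str]],
        inhibitors: Mapping[str, Iterable[str]] | None = None,
    ) -> "RegulatoryNetwork":
        """Build a network from per-target regulator sets.

        Regulator and target orderings are canonicalized (sorted) so that
        equal edge sets always produce equal objects.
        """
        inhibitors = inhibitors or {}
        targets = sorted(set(activators) | set(inhibitors))
        regs: set[str] = set()
        act = {g: tuple(sorted(set(activators.get(g, ())))) for g in targets}
        inh = {g: tuple(sorted(set(inhibitors.get(g, ())))) for g in targets}
        for g in targets:
            regs.update(act[g])
            regs.update(inh[g])
        return cls(tuple(sorted(regs)), tuple(targets), act, inh)

    @property
    def n_regulators(self) -> int:
        return len(self.regulators)

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    @property
    def genes(self) -> tuple[str, ...]:
        """All gene identifiers, regulators first then targets."""
        return self.regulators + self.targets

    @property
    def n_edges(self) -> int:
        """Number of regulator->target edges."""
        return sum(
            len(self.activators[g]) + len(self.inhibitors[g]) for g in self.targets
        )


@dataclass(frozen=True)
class ModelParameters:
    """The full parameter vector theta.

    Attributes
    ----------
    alpha
        Length-3 probability vector over TF states, ordered (-1, 0, +1).
    epsilon
        Deregulation rate, P(D = 1), in [0, 1].
    mu, sigma
        Gaussian emission means / standard deviations per state, ordered
        (-1, 0, +1); sigma strictly positive.

    The identifiability convention mu_- <= mu_0 <= mu_+ is guaranteed by the
    initializer and the simulation defaults; it is not re-imposed during EM
    (label switching is documented rather than projected away).
    """

    alpha: np.ndarray
    epsilon: float
    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "alpha", np.asarray(self.alpha, dtype=float))
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float))
        object.__setattr__(self, "sigma", np.asarray(self.sigma, dtype=float))
        if self.alpha.shape != (3,) or self.mu.shape != (3,) or self.sigma.shape != (3,):
            raise DataError("alpha, mu, sigma must each have 3 entries (-1, 0, +1)")
        if np.any(self.alpha < 0) or abs(self.alpha.sum() - 1.0) > 1e-8:
            raise DataError(f"alpha must be a probability vector, got {self.alpha}")
        if not 0.0 <= self.epsilon <= 1.0:
            raise DataError(f"epsilon must lie in [0, 1], got {self.epsilon}")
        if np.any(self.sigma <= 0):
            raise DataError(f"sigma must be strictly positive, got {self.sigma}")

    def mu_of(self, state: int) -> float:
        return float(self.mu[STATE_INDEX[state]])

    def sigma_of(self, state: int) -> float:
        return float(self.sigma[STATE_INDEX[state]])

    def alpha_of(self, state: int) -> float:
        return float(self.alpha[STATE_INDEX[state]])

    def as_vector(self) -> np.ndarray:
        """All 10 scalar components (used for convergence monitoring)."""
        return np.concatenate([self.alpha, [self.epsilon], self.mu, self.sigma])

    def log_emission(self, x: np.ndarray) -> np.ndarray:
        """Gaussian log-density of observations under each state.

        Parameters
        ----------
        x : array of shape (...,)

        Returns
        -------
        array of shape (..., 3), log N(x; mu_s, sigma_s) for s in STATES.
        """
        x = np.asarray(x, dtype=float)[..., None]
        return (
            -0.5 * ((x - self.mu) / self.sigma) ** 2
            - np.log(self.sigma)
            - 0.5 * _LOG_2PI
        )


@dataclass(frozen=True)
class ExpressionMatrix:
    """Observed expression, n samples x G genes, no missing values."""

    values: np.ndarray
    sample_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    _gene_index: dict[str, int] = field(repr=False, compare=False, default_factory=dict)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2 or values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise DataError(
                f"expression shape {values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataError("duplicate gene columns in expression matrix")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataError("duplicate sample identifiers in expression matrix")
        bad = np.argwhere(~np.isfinite(values))
        if bad.size:
            i, j = bad[0]
            raise DataError(
                f"non-finite expression value at sample {self.sample_ids[i]!r}, "
                f"gene {self.gene_ids[j]!r}"
            )
        object.__setattr__(
            self, "_gene_index", {g: j for j, g in enumerate(self.gene_ids)}
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            df.to_numpy(dtype=float),
            tuple(str(s) for s in df.index),
            tuple(str(g) for g in df.columns),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(), index=list(self.sample_ids), columns=list(self.gene_ids)
        )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def aligned_values(self, net: RegulatoryNetwork) -> np.ndarray:
        """Columns reordered to ``net.genes`` (regulators then targets).

        Raises :class:`DataError` naming any network gene absent from the
        matrix.  Extra columns are ignored.
        """
        missing = [g for g in net.genes if g not in self._gene_index]
        if missing:
            raise DataError(f"expression matrix is missing network gene(s): {missing}")
        cols = [self._gene_index[g] for g in net.genes]
        return self.values[:, cols]

    def row_map(self, i: int) -> dict[str, float]:
        """One sample as a gene -> value mapping."""
        return dict(zip(self.gene_ids, self.values[i]))


@dataclass(frozen=True)
class HiddenAssignment:
    """A complete configuration of the hidden variables for one sample.

    ``regulator_states`` maps each TF to its ternary status; the five
    ``target_*`` mappings give, per target, the collective activator and
    inhibitor statuses, the truth-table result S^R, the deregulation
    indicator D and the realized status S.
    """

    regulator_states: Mapping[str, int]
    target_s_a: Mapping[str, int]
    target_s_i: Mapping[str, int]
    target_s_r: Mapping[str, int]
    target_d: Mapping[str, int]
    target_s: Mapping[str, int]

    def is_consistent(self, net: RegulatoryNetwork) -> bool:
        """Whether this assignment satisfies all hard constraints."""
        for g in net.targets:
            s_a = collective_state(self.regulator_states[r] for r in net.activators[g])
            s_i = collective_state(self.regulator_states[r] for r in net.inhibitors[g])
            if self.target_s_a[g] != s_a or self.target_s_i[g] != s_i:
                return False
            s_r = truth_table(s_a, s_i)
            if self.target_s_r[g] != s_r:
                return False
            d, s = self.target_d[g], self.target_s[g]
            if d not in (0, 1) or s not in STATE_INDEX:
                return False
            if (d == 0) != (s == s_r):
                return False
        return all(s in STATE_INDEX for s in self.regulator_states.values())


def complete_data_loglik(
    x: Mapping[str, float],
    z: HiddenAssignment,
    net: RegulatoryNetwork,
    theta: ModelParameters,
) -> float:
    """Joint log-density log p(x, z | theta) for one sample.

    Returns ``-inf`` when ``z`` violates any hard constraint (collective
    statuses, the truth table, or the deregulation consistency rule).  The
    deregulation prior contributes log(1 - epsilon) when D = 0 and
    log(epsilon / 2) for each of the two admissible flipped states when
    D = 1, so that P(D = 1) = epsilon and P(S = s | D = 1) = 1/2.
    """
    missing = [g for g in net.genes if g not in x]
    if missing:
        raise DataError(f"expression row is missing network gene(s): {missing}")
    if not z.is_consistent(net):
        return -math.inf

    def _log_norm(value: float, state: int) -> float:
        mu, sd = theta.mu_of(state), theta.sigma_of(state)
        return -0.5 * ((value - mu) / sd) ** 2 - math.log(sd) - 0.5 * _LOG_2PI

    total = 0.0
    for g in net.regulators:
        a = theta.alpha_of(z.regulator_states[g])
        if a == 0.0:
            return -math.inf
        total += math.log(a) + _log_norm(x[g], z.regulator_states[g])
    for g in net.targets:
        if z.target_d[g] == 1:
            if theta.epsilon == 0.0:
                return -math.inf
            total += math.log(theta.epsilon / 2.0)
        else:
            if theta.epsilon == 1.0:
                return -math.inf
            total += math.log1p(-theta.epsilon)
        total += _log_norm(x[g], z.target_s[g])
    return total
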