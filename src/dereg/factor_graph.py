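"""Factor-graph construction and sum-product belief propagation.

Per sample, the posterior over hidden states factorizes into: a multinomial
prior on each TF status, a deregulation prior on each target's D, Gaussian
evidence on each gene's status, and four families of hard (0/1) constraints
— the two collective-status constraints, the truth table, and the
deregulation consistency rule.  Unary factors (priors and evidence) are
folded into per-variable local potentials; only multi-variable factors
become message-passing nodes, so the graph has ~ 2E + G nodes for E edges
and G genes.

Collective-status constraints over k >= 2 regulators are decomposed into a
balanced binary tree of degree-3 factors implementing the pairwise combine
operator (a, b) -> a if a == b else 0, with auxiliary ternary variables at
internal nodes.  This operator is associative and commutative for the
all-equal semantics, so the decomposition is exact and order-free.

Messages are computed in log space with per-message max-normalization; the
schedule is synchronous flooding (all factor->variable updates, then all
variable->factor updates, per pass).  Inference is exact on acyclic graphs
and approximate (loopy BP) otherwise.  All message arrays carry a leading
sample axis so that many samples sharing one network can be processed in a
single sweep.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .errors import DataError, GraphError
from .model import (
    STATES,
    STATE_INDEX,
    ExpressionMatrix,
    ModelParameters,
    RegulatoryNetwork,
    collective_state,
    truth_table,
)

_NEG_INF = -np.inf

# 0/1 constraint tables, shared by every graph (log domain).
_EQUALITY_TABLE = np.where(np.eye(3, dtype=bool), 0.0, _NEG_INF)

_COMBINE_TABLE = np.full((3, 3, 3), _NEG_INF)
for _a, _b in itertools.product(STATES, STATES):
    _out = _a if _a == _b else 0
    _COMBINE_TABLE[STATE_INDEX[_a], STATE_INDEX[_b], STATE_INDEX[_out]] = 0.0

_TRUTH_TABLE_FACTOR = np.full((3, 3, 3), _NEG_INF)
for _a, _b in itertools.product(STATES, STATES):
    _TRUTH_TABLE_FACTOR[
        STATE_INDEX[_a], STATE_INDEX[_b], STATE_INDEX[truth_table(_a, _b)]
    ] = 0.0

# Consistency factor over (S^R, D, S): D=0 forces S=S^R, D=1 forbids it.
_CONSISTENCY_TABLE = np.full((3, 2, 3), _NEG_INF)
for _r, _s in itertools.product(STATES, STATES):
    _CONSISTENCY_TABLE[STATE_INDEX[_r], int(_r != _s), STATE_INDEX[_s]] = 0.0

#: Factor kinds, numbered in docstrings after their role: alpha prior,
#: deregulation prior, Gaussian evidence (unary, folded into variables);
#: collective activator / inhibitor status, truth table, consistency
#: (multi-variable message-passing nodes).
UNARY_KINDS = ("alpha_prior", "dereg_prior", "evidence", "fixed_state")
FACTOR_KINDS = ("collective_act", "collective_inh", "truth_table", "consistency")


@dataclass
class Factor:
    """A multi-variable factor: a log-domain table over adjacent variables."""

    kind: str
    var_idx: tuple[int, ...]
    log_table: np.ndarray

    @property
    def degree(self) -> int:
        return len(self.var_idx)


class FactorGraph:
    """A discrete factor graph with batched unary potentials.

    ``unary[v]`` has shape (batch, domain(v)) and is the sum of the log
    unary factors attached to variable ``v`` (zero for auxiliary variables).
    ``batched`` records whether the graph was built from a matrix of samples
    (it controls whether :func:`sum_product` returns a list or one object).
    """

    def __init__(self, batch: int = 1, batched: bool = False) -> None:
        self.batch = batch
        self.batched = batched
        self.var_names: list[str] = []
        self.domains: list[int] = []
        self.unary: list[np.ndarray] = []
        self.unary_factors: list[tuple[str, int]] = []  # (kind, var index)
        self.factors: list[Factor] = []
        # role registries used to read marginals back out
        self.regulator_var: dict[str, int] = {}
        self.target_vars: dict[str, dict[str, int]] = {}

    # -- construction -----------------------------------------------------
    def add_variable(self, name: str, domain: int) -> int:
        idx = len(self.var_names)
        self.var_names.append(name)
        self.domains.append(domain)
        self.unary.append(np.zeros((self.batch, domain)))
        return idx

    def add_unary(self, kind: str, var: int, log_values: np.ndarray) -> None:
        self.unary[var] = self.unary[var] + np.broadcast_to(
            log_values, self.unary[var].shape
        )
        self.unary_factors.append((kind, var))

    def add_factor(self, kind: str, var_idx: tuple[int, ...], log_table: np.ndarray) -> None:
        if log_table.shape != tuple(self.domains[v] for v in var_idx):
            raise GraphError(f"factor table shape mismatch for {kind}")
        self.factors.append(Factor(kind, var_idx, log_table))

    # -- introspection ----------------------------------------------------
    @property
    def n_variables(self) -> int:
        return len(self.var_names)

    @property
    def n_nodes(self) -> int:
        """Message-passing nodes: variables plus multi-variable factors."""
        return len(self.var_names) + len(self.factors)

    def edge_list(self) -> list[str]:
        """Debug dump, one tab-separated ``factor<TAB>variable`` line per edge."""
        lines = []
        for i, f in enumerate(self.factors):
            for v in f.var_idx:
                lines.append(f"{f.kind}#{i}\t{self.var_names[v]}")
        return lines


@dataclass(frozen=True)
class SampleMarginals:
    """Posterior marginals of every hidden variable for one sample.

    State distributions are length-3 vectors ordered (-1, 0, +1); the
    deregulation marginal is a length-2 vector ordered (D=0, D=1).
    ``log_evidence`` is filled by the exact enumeration oracle only.
    """

    regulator_s: dict[str, np.ndarray]
    target_s_a: dict[str, np.ndarray]
    target_s_i: dict[str, np.ndarray]
    target_s_r: dict[str, np.ndarray]
    target_s: dict[str, np.ndarray]
    target_d: dict[str, np.ndarray]
    sample_id: str | None = None
    log_evidence: float | None = None

    def validate(self, atol: float = 1e-9) -> None:
        for group in (
            self.regulator_s, self.target_s_a, self.target_s_i,
            self.target_s_r, self.target_s, self.target_d,
        ):
            for name, dist in group.items():
                if np.any(dist < -atol) or abs(dist.sum() - 1.0) > atol:
                    raise GraphError(f"invalid marginal for {name}: {dist}")


def _balanced_reduce(
    fg: FactorGraph, members: list[int], out: int, kind: str, tag: str
) -> None:
    """Wire a collective-status constraint from ``members`` onto ``out``.

    Empty set: ``out`` is pinned to state 0.  Singleton: an equality factor.
    Otherwise a balanced binary combine tree with auxiliary ternary
    variables at internal nodes; every factor has degree <= 3.
    """
    if not members:
        pinned = np.array([_NEG_INF, 0.0, _NEG_INF])
        fg.add_unary("fixed_state", out, pinned)
        return
    if len(members) == 1:
        fg.add_factor(kind, (members[0], out), _EQUALITY_TABLE)
        return

    counter = itertools.count()

    def build(idx: list[int]) -> int:
        if len(idx) == 1:
            return idx[0]
        mid = len(idx) // 2
        left, right = build(idx[:mid]), build(idx[mid:])
        aux = fg.add_variable(f"{tag}:aux{next(counter)}", 3)
        fg.add_factor(kind, (left, right, aux), _COMBINE_TABLE)
        return aux

    mid = len(members) // 2
    left, right = build(members[:mid]), build(members[mid:])
    fg.add_factor(kind, (left, right, out), _COMBINE_TABLE)


def build_factor_graph(
    net: RegulatoryNetwork, theta: ModelParameters, x: np.ndarray
) -> FactorGraph:
    """Build the per-sample factor graph.

    Parameters
    ----------
    net, theta
        The network and current parameters.
    x
        Expression values aligned to ``net.genes`` (regulators then
        targets): shape (G,) for one sample, or (n, G) for a batch sharing
        the same graph structure.

    Regulator lists feeding the collective-status trees are sorted by gene
    identifier, so marginals do not depend on input edge order.
    """
    x = np.asarray(x, dtype=float)
    batched = x.ndim == 2
    x2d = np.atleast_2d(x)
    n_genes = len(net.genes)
    if x2d.shape[1] != n_genes:
        raise DataError(
            f"expression row has {x2d.shape[1]} genes, network needs {n_genes}"
        )
    log_ev = theta.log_emission(x2d)  # (batch, G, 3)
    with np.errstate(divide="ignore"):
        log_alpha = np.log(theta.alpha)
        log_dereg = np.array(
            [math.log1p(-theta.epsilon) if theta.epsilon < 1.0 else _NEG_INF,
             math.log(theta.epsilon / 2.0) if theta.epsilon > 0.0 else _NEG_INF]
        )

    fg = FactorGraph(batch=x2d.shape[0], batched=batched)
    col = {g: j for j, g in enumerate(net.genes)}

    for g in net.regulators:
        v = fg.add_variable(f"S[{g}]", 3)
        fg.regulator_var[g] = v
        fg.add_unary("alpha_prior", v, log_alpha)
        fg.add_unary("evidence", v, log_ev[:, col[g], :])

    for g in net.targets:
        v_sa = fg.add_variable(f"SA[{g}]", 3)
        v_si = fg.add_variable(f"SI[{g}]", 3)
        act = [fg.regulator_var[r] for r in sorted(net.activators[g])]
        inh = [fg.regulator_var[r] for r in sorted(net.inhibitors[g])]
        _balanced_reduce(fg, act, v_sa, "collective_act", f"A[{g}]")
        _balanced_reduce(fg, inh, v_si, "collective_inh", f"I[{g}]")
        v_sr = fg.add_variable(f"SR[{g}]", 3)
        fg.add_factor("truth_table", (v_sa, v_si, v_sr), _TRUTH_TABLE_FACTOR)
        v_d = fg.add_variable(f"D[{g}]", 2)
        fg.add_unary("dereg_prior", v_d, log_dereg)
        v_s = fg.add_variable(f"S[{g}]", 3)
        fg.add_unary("evidence", v_s, log_ev[:, col[g], :])
        fg.add_factor("consistency", (v_sr, v_d, v_s), _CONSISTENCY_TABLE)
        fg.target_vars[g] = {
            "s_a": v_sa, "s_i": v_si, "s_r": v_sr, "d": v_d, "s": v_s
        }
    return fg


def _normalize_log(msg: np.ndarray) -> np.ndarray:
    """Subtract the per-row max where finite (leave all -inf rows alone)."""
    mx = msg.max(axis=-1, keepdims=True)
    return msg - np.where(np.isfinite(mx), mx, 0.0)


def _exclusive_sums(terms: list[np.ndarray], base: np.ndarray) -> list[np.ndarray]:
    """For each j, ``base + sum(terms except terms[j])``.

    Computed with prefix/suffix accumulation — additions only, so entries
    at -inf (hard-constraint zeros) propagate correctly and no NaN can
    arise from an inf - inf cancellation.
    """
    k = len(terms)
    prefix = base
    out_prefix = []
    for j in range(k):
        out_prefix.append(prefix)
        prefix = prefix + terms[j]
    suffix = 0.0
    out = [None] * k
    for j in range(k - 1, -1, -1):
        out[j] = out_prefix[j] + suffix
        suffix = terms[j] + suffix
    return out


def _beliefs(fg: FactorGraph, n_passes: int) -> list[np.ndarray]:
    """Run synchronous flooding and return (unnormalized) log-beliefs."""
    if n_passes < 1:
        raise GraphError("n_passes must be >= 1")
    # adjacency: for each variable, list of (factor index, slot)
    var_edges: list[list[tuple[int, int]]] = [[] for _ in range(fg.n_variables)]
    for fi, f in enumerate(fg.factors):
        for slot, v in enumerate(f.var_idx):
            var_edges[v].append((fi, slot))

    # messages keyed (factor, slot); shapes (batch, domain)
    v2f: dict[tuple[int, int], np.ndarray] = {}
    f2v: dict[tuple[int, int], np.ndarray] = {}
    for fi, f in enumerate(fg.factors):
        for slot, v in enumerate(f.var_idx):
            v2f[(fi, slot)] = _normalize_log(fg.unary[v].copy())
            f2v[(fi, slot)] = np.zeros((fg.batch, fg.domains[v]))

    for _ in range(n_passes):
        # factor -> variable: logsumexp over the other slots' axes of
        # (table + incoming messages from the other slots)
        new_f2v = {}
        for fi, f in enumerate(fg.factors):
            deg = f.degree
            table = np.broadcast_to(f.log_table, (fg.batch,) + f.log_table.shape)
            reshaped = []
            for slot in range(deg):
                shape = [fg.batch] + [1] * deg
                shape[1 + slot] = fg.domains[f.var_idx[slot]]
                reshaped.append(v2f[(fi, slot)].reshape(shape))
            partials = _exclusive_sums(reshaped, table)
            for slot in range(deg):
                axes = tuple(1 + j for j in range(deg) if j != slot)
                msg = logsumexp(partials[slot], axis=axes) if axes else partials[slot]
                new_f2v[(fi, slot)] = _normalize_log(msg)
        f2v = new_f2v
        # variable -> factor: unary + incoming from the other factors
        for v, edges in enumerate(var_edges):
            if not edges:
                continue
            incoming = [f2v[key] for key in edges]
            outgoing = _exclusive_sums(incoming, fg.unary[v])
            for key, msg in zip(edges, outgoing):
                v2f[key] = _normalize_log(msg)

    beliefs = []
    for v in range(fg.n_variables):
        b = fg.unary[v].copy()
        for key in var_edges[v]:
            b = b + f2v[key]
        beliefs.append(b)
    return beliefs


def _beliefs_to_marginals(fg: FactorGraph, beliefs: list[np.ndarray]) -> list[SampleMarginals]:
    probs: list[np.ndarray] = []
    for v, b in enumerate(beliefs):
        mx = b.max(axis=-1, keepdims=True)
        dead = ~np.isfinite(mx[:, 0])
        if dead.any():
            i = int(np.argmax(dead))
            raise GraphError(
                f"all-zero belief at variable {fg.var_names[v]!r} (sample index {i}): "
                "contradictory hard constraints or impossible evidence"
            )
        p = np.exp(b - mx)
        probs.append(p / p.sum(axis=-1, keepdims=True))

    out = []
    for i in range(fg.batch):
        out.append(
            SampleMarginals(
                regulator_s={g: probs[v][i] for g, v in fg.regulator_var.items()},
                target_s_a={g: probs[d["s_a"]][i] for g, d in fg.target_vars.items()},
                target_s_i={g: probs[d["s_i"]][i] for g, d in fg.target_vars.items()},
                target_s_r={g: probs[d["s_r"]][i] for g, d in fg.target_vars.items()},
                target_s={g: probs[d["s"]][i] for g, d in fg.target_vars.items()},
                target_d={g: probs[d["d"]][i] for g, d in fg.target_vars.items()},
            )
        )
    return out


def sum_product(fg: FactorGraph, n_passes: int = 10):
    """Approximate posterior marginals by sum-product message passing.

    Runs ``n_passes`` synchronous flooding passes (every factor, then every
    variable, updated from its neighbors) and returns normalized beliefs.
    Exact on acyclic graphs once the pass count reaches the graph diameter;
    deterministic given the graph and pass count.

    Returns one :class:`SampleMarginals` for a graph built from a single
    row, or a list of them for a batched graph.
    """
    marginals = _beliefs_to_marginals(fg, _beliefs(fg, n_passes))
    return marginals if fg.batched else marginals[0]


# -- exact enumeration oracle ---------------------------------------------

def enumerate_marginals(
    net: RegulatoryNetwork,
    theta: ModelParameters,
    x: np.ndarray,
    cap: float = 1e7,
) -> SampleMarginals:
    """Exact posterior marginals by summation over all hidden configurations.

    Enumerates the 3^r TF configurations; given the TF states, the
    collective statuses and S^R are deterministic and the per-target
    (D, S) pairs decouple, so the sum is exact at cost O(3^r * t).  The
    guard rejects instances whose full joint space 3^r * 6^t exceeds
    ``cap`` (use :func:`sum_product` there instead).  Also fills
    ``log_evidence`` with log p(x | theta).
    """
    r, t = net.n_regulators, net.n_targets
    if 3.0 ** r * 6.0 ** t > cap:
        raise GraphError(
            f"hidden state space 3^{r} * 6^{t} exceeds cap {cap:g}; "
            "use the belief-propagation path (sum_product)"
        )
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size != len(net.genes):
        raise DataError("enumerate_marginals expects one aligned expression row")
    log_ev = theta.log_emission(x)  # (G, 3)
    with np.errstate(divide="ignore"):
        log_alpha = np.log(theta.alpha)
        log_eps2 = (
            math.log(theta.epsilon / 2.0) if theta.epsilon > 0 else _NEG_INF
        )
        log_1meps = math.log1p(-theta.epsilon) if theta.epsilon < 1 else _NEG_INF

    reg_cols = {g: j for j, g in enumerate(net.genes)}
    tgt_ev = {g: log_ev[reg_cols[g]] for g in net.targets}

    def target_options(s_r: int, g: str):
        """(d, s, log-weight) triples for one target given S^R."""
        opts = [(0, s_r, log_1meps + tgt_ev[g][STATE_INDEX[s_r]])]
        for s in STATES:
            if s != s_r:
                opts.append((1, s, log_eps2 + tgt_ev[g][STATE_INDEX[s]]))
        return opts

    configs = list(itertools.product(STATES, repeat=r))
    totals = np.empty(len(configs))
    per_cfg_target: list[list[tuple[int, int, int, float]]] = []
    for ci, cfg in enumerate(configs):
        states = dict(zip(net.regulators, cfg))
        base = sum(
            log_alpha[STATE_INDEX[s]] + log_ev[reg_cols[g], STATE_INDEX[s]]
            for g, s in states.items()
        )
        total = base
        rows = []
        for g in net.targets:
            s_a = collective_state(states[a] for a in net.activators[g])
            s_i = collective_state(states[b] for b in net.inhibitors[g])
            s_r = truth_table(s_a, s_i)
            opts = target_options(s_r, g)
            b_g = logsumexp([w for _, _, w in opts])
            total += b_g
            rows.append((s_a, s_i, s_r, b_g))
        totals[ci] = total
        per_cfg_target.append(rows)

    log_z = float(logsumexp(totals))
    if not np.isfinite(log_z):
        raise GraphError("zero total posterior mass: contradictory model/evidence")

    reg_m = {g: np.zeros(3) for g in net.regulators}
    sa_m = {g: np.zeros(3) for g in net.targets}
    si_m = {g: np.zeros(3) for g in net.targets}
    sr_m = {g: np.zeros(3) for g in net.targets}
    s_m = {g: np.zeros(3) for g in net.targets}
    d_m = {g: np.zeros(2) for g in net.targets}

    for ci, cfg in enumerate(configs):
        w = math.exp(totals[ci] - log_z)
        if w == 0.0:
            continue
        for g, s in zip(net.regulators, cfg):
            reg_m[g][STATE_INDEX[s]] += w
        for g, (s_a, s_i, s_r, b_g) in zip(net.targets, per_cfg_target[ci]):
            sa_m[g][STATE_INDEX[s_a]] += w
            si_m[g][STATE_INDEX[s_i]] += w
            sr_m[g][STATE_INDEX[s_r]] += w
            for d, s, lw in target_options(s_r, g):
                pw = w * math.exp(lw - b_g) if np.isfinite(lw) else 0.0
                s_m[g][STATE_INDEX[s]] += pw
                d_m[g][d] += pw

    marg = SampleMarginals(
        regulator_s=reg_m, target_s_a=sa_m, target_s_i=si_m,
        target_s_r=sr_m, target_s=s_m, target_d=d_m, log_evidence=log_z,
    )
    marg.validate(atol=1e-8)
    return marg


def exact_log_evidence(
    net: RegulatoryNetwork, theta: ModelParameters, x: np.ndarray, cap: float = 1e7
) -> float:
    """Exact observed-data log-likelihood log p(x | theta) for one sample."""
    return float(enumerate_marginals(net, theta, x, cap=cap).log_evidence)
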