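"""EM fitting loop, deregulation scoring and posterior-FDR selection.

The E-step computes per-sample posterior marginals of every hidden variable
with sum-product belief propagation (exact on tree-shaped networks).  The
M-step is closed form: alpha pools the TF status marginals, epsilon is the
mean posterior deregulation probability, and the Gaussian means/variances
are posterior-weighted moments pooled over *all* genes (TF statuses and
targets' realized statuses).  The deregulation score of a (sample, target)
pair is the posterior q(D = 1); because it is a posterior probability, the
false discovery rate of any call set of K pairs with score sum S can be
estimated as (K - S)/K, which drives the thresholding rule.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, FitError
from .factor_graph import (
    SampleMarginals,
    build_factor_graph,
    exact_log_evidence,
    sum_product,
)
from .model import ExpressionMatrix, ModelParameters, RegulatoryNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DeregulationScores:
    """Posterior deregulation probabilities q(D = 1), samples x targets."""

    scores: np.ndarray
    sample_ids: tuple[str, ...]
    target_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.shape != (len(self.sample_ids), len(self.target_ids)):
            raise DataError("score matrix shape does not match identifier lists")
        if np.any(scores < -1e-12) or np.any(scores > 1 + 1e-12):
            raise DataError("deregulation scores must lie in [0, 1]")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores.copy(),
            index=list(self.sample_ids),
            columns=list(self.target_ids),
        )

    def to_long(self) -> pd.DataFrame:
        """Long format: one (sample, target, score) row per pair."""
        rows = [
            (s, g, self.scores[i, j])
            for i, s in enumerate(self.sample_ids)
            for j, g in enumerate(self.target_ids)
        ]
        return pd.DataFrame(rows, columns=["sample", "target", "score"])


@dataclass
class EMIteration:
    """One trace record: theta after iteration ``index`` M-steps."""

    index: int
    theta: ModelParameters
    mean_abs_change: float | None = None
    loglik: float | None = None


@dataclass
class EMTrace:
    records: list[EMIteration] = field(default_factory=list)

    @property
    def n_iterations(self) -> int:
        return max((r.index for r in self.records), default=0)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            v = r.theta
            rows.append(
                {
                    "iteration": r.index,
                    "alpha_minus": v.alpha[0], "alpha_zero": v.alpha[1],
                    "alpha_plus": v.alpha[2], "epsilon": v.epsilon,
                    "mu_minus": v.mu[0], "mu_zero": v.mu[1], "mu_plus": v.mu[2],
                    "sigma_minus": v.sigma[0], "sigma_zero": v.sigma[1],
                    "sigma_plus": v.sigma[2],
                    "mean_abs_change": r.mean_abs_change,
                    "loglik": r.loglik,
                }
            )
        return pd.DataFrame(rows)


def e_step(
    net: RegulatoryNetwork,
    theta: ModelParameters,
    X: ExpressionMatrix,
    n_passes: int = 10,
) -> list[SampleMarginals]:
    """Posterior marginals for every sample.

    Samples are independent given theta; they share one graph structure and
    are propagated together (the result is identical to per-sample runs).
    """
    values = X.aligned_values(net)
    fg = build_factor_graph(net, theta, values)
    try:
        marginals = sum_product(fg, n_passes=n_passes)
    except Exception as exc:
        raise type(exc)(f"E-step failed: {exc}") from exc
    return [
        SampleMarginals(
            regulator_s=m.regulator_s, target_s_a=m.target_s_a,
            target_s_i=m.target_s_i, target_s_r=m.target_s_r,
            target_s=m.target_s, target_d=m.target_d,
            sample_id=X.sample_ids[i],
        )
        for i, m in enumerate(marginals)
    ]


def _pooled_status_weights(
    marginals: list[SampleMarginals], X: ExpressionMatrix, net: RegulatoryNetwork
) -> tuple[np.ndarray, np.ndarray]:
    """Stack q(S) over samples x genes -> (Q of shape (n, G, 3), aligned X)."""
    values = X.aligned_values(net)
    n, G = values.shape
    Q = np.empty((n, G, 3))
    for i, m in enumerate(marginals):
        for j, g in enumerate(net.regulators):
            Q[i, j] = m.regulator_s[g]
        off = net.n_regulators
        for j, g in enumerate(net.targets):
            Q[i, off + j] = m.target_s[g]
    return Q, values


def m_step(
    marginals: list[SampleMarginals],
    X: ExpressionMatrix,
    net: RegulatoryNetwork,
    theta_prev: ModelParameters | None = None,
    sigma_floor: float = 1e-3,
) -> ModelParameters:
    """Closed-form maximizer of the expected complete-data log-likelihood.

    alpha_s pools q(S = s) over TF occurrences; epsilon is the mean q(D = 1)
    over all (sample, target) pairs; mu_s and sigma_s are the q-weighted
    mean and standard deviation of expression pooled over all genes.  A
    state with zero pooled weight keeps its previous mu and sigma (a warning
    is logged); sigma is floored at ``sigma_floor``.
    """
    n = len(marginals)
    if n != X.n_samples:
        raise FitError(f"{n} marginal sets for {X.n_samples} samples")
    Q, values = _pooled_status_weights(marginals, X, net)
    r = net.n_regulators

    alpha = Q[:, :r, :].sum(axis=(0, 1))
    alpha = alpha / alpha.sum()

    d1 = sum(m.target_d[g][1] for m in marginals for g in net.targets)
    epsilon = float(min(max(d1 / (n * net.n_targets), 0.0), 1.0))

    w = Q.sum(axis=(0, 1))  # pooled weight per state
    mu = np.empty(3)
    sigma = np.empty(3)
    for s in range(3):
        if w[s] <= 0.0:
            if theta_prev is None:
                raise FitError(
                    f"state index {s} has zero posterior weight and no previous "
                    "parameters to fall back on"
                )
            logger.warning(
                "M-step: state index %d has zero posterior weight; keeping "
                "previous mu and sigma", s,
            )
            mu[s], sigma[s] = theta_prev.mu[s], theta_prev.sigma[s]
            continue
        mu[s] = float((Q[:, :, s] * values).sum() / w[s])
        var = float((Q[:, :, s] * (values - mu[s]) ** 2).sum() / w[s])
        sigma[s] = max(math.sqrt(var), sigma_floor)
    return ModelParameters(alpha=alpha, epsilon=epsilon, mu=mu, sigma=sigma)


def expected_complete_loglik(
    marginals: list[SampleMarginals],
    X: ExpressionMatrix,
    net: RegulatoryNetwork,
    theta: ModelParameters,
) -> float:
    """E_q[log p(X, Z | theta)] up to the constant hard-constraint terms.

    This is the objective the M-step maximizes; the 0/1 constraint factors
    contribute nothing wherever q is supported.
    """
    Q, values = _pooled_status_weights(marginals, X, net)
    with np.errstate(divide="ignore"):
        log_alpha = np.log(theta.alpha)
        log_e1 = math.log(theta.epsilon / 2.0) if theta.epsilon > 0 else -np.inf
        log_e0 = math.log1p(-theta.epsilon) if theta.epsilon < 1 else -np.inf
    r = net.n_regulators
    wa = Q[:, :r, :].sum(axis=(0, 1))
    total = float(np.where(wa > 0, wa * log_alpha, 0.0).sum())
    for m in marginals:
        for g in net.targets:
            q1 = m.target_d[g][1]
            if q1 > 0:
                total += q1 * log_e1
            if 1 - q1 > 0:
                total += (1 - q1) * log_e0
    log_em = theta.log_emission(values)  # (n, G, 3)
    total += float(np.where(Q > 0, Q * log_em, 0.0).sum())
    return total


def initialize_parameters(X: ExpressionMatrix, epsilon: float = 0.05) -> ModelParameters:
    """Moment-free starting point from pooled expression quantiles.

    mu is set to the 1/6, 3/6, 5/6 pooled quantiles (ordered by
    construction), every sigma to half the pooled interquartile range
    (floored at 1e-3), alpha to the uniform distribution and epsilon to a
    small deregulation rate.
    """
    if X.n_samples < 2:
        raise FitError("initialization requires at least 2 samples")
    pooled = X.values.ravel()
    if np.ptp(pooled) == 0.0:
        raise FitError("constant expression matrix: model is unidentifiable")
    mu = np.quantile(pooled, [1 / 6, 3 / 6, 5 / 6])
    q25, q75 = np.quantile(pooled, [0.25, 0.75])
    sd = max((q75 - q25) / 2.0, 1e-3)
    return ModelParameters(
        alpha=np.full(3, 1 / 3), epsilon=epsilon, mu=mu, sigma=np.full(3, sd)
    )


def fit_em(
    net: RegulatoryNetwork,
    X: ExpressionMatrix,
    theta0: ModelParameters,
    max_iter: int = 100,
    tol: float = 1e-4,
    n_passes: int = 10,
    sigma_floor: float = 1e-3,
    track_loglik: bool = False,
) -> tuple[ModelParameters, list[SampleMarginals], EMTrace]:
    """Alternate E and M steps until the parameters stabilize.

    Stops when the mean absolute change over the 10 scalar parameters drops
    below ``tol``, or after ``max_iter`` iterations.  The returned marginals
    come from a final E-step run at the returned theta, so the reported
    deregulation scores are posteriors under the fitted parameters.

    With ``track_loglik=True`` the exact observed-data log-likelihood is
    recorded at every theta snapshot via enumeration — feasible only on
    small (toy/tree) instances.
    """
    if max_iter < 1:
        raise FitError("max_iter must be >= 1")
    if tol <= 0:
        raise FitError("tol must be > 0")
    X.aligned_values(net)  # fail fast (DataError) on missing genes

    def _loglik(theta: ModelParameters) -> float | None:
        if not track_loglik:
            return None
        vals = X.aligned_values(net)
        return sum(exact_log_evidence(net, theta, vals[i]) for i in range(X.n_samples))

    theta = theta0
    trace = EMTrace([EMIteration(0, theta0, None, _loglik(theta0))])
    for it in range(1, max_iter + 1):
        try:
            marginals = e_step(net, theta, X, n_passes=n_passes)
            theta_new = m_step(
                marginals, X, net, theta_prev=theta, sigma_floor=sigma_floor
            )
        except Exception as exc:
            raise FitError(f"EM failed at iteration {it}: {exc}") from exc
        delta = float(np.mean(np.abs(theta_new.as_vector() - theta.as_vector())))
        theta = theta_new
        trace.records.append(EMIteration(it, theta, delta, _loglik(theta)))
        logger.info(
            "EM iteration %d: mean |dtheta| = %.3g, epsilon = %.4f, mu = %s",
            it, delta, theta.epsilon, np.array2string(theta.mu, precision=3),
        )
        if delta < tol:
            break
    final_marginals = e_step(net, theta, X, n_passes=n_passes)
    return theta, final_marginals, trace


def deregulation_scores(marginals: list[SampleMarginals]) -> DeregulationScores:
    """Extract q(D = 1) into the samples x targets score matrix."""
    if not marginals:
        raise DataError("no marginals given")
    targets = tuple(marginals[0].target_d)
    scores = np.array(
        [[m.target_d[g][1] for g in targets] for m in marginals]
    )
    sample_ids = tuple(
        m.sample_id if m.sample_id is not None else str(i)
        for i, m in enumerate(marginals)
    )
    return DeregulationScores(np.clip(scores, 0.0, 1.0), sample_ids, targets)


def fdr_select(
    scores: DeregulationScores, target_fdr: float
) -> tuple[float, set[tuple[str, str]], float]:
    """Threshold the scores to control the estimated FDR.

    Pairs are ranked by score descending (ties broken by sample index then
    target identifier, so the ranking is deterministic).  Lowering the
    threshold from 1, after K pairs with score sum S are selected the FDR
    estimate is (K - S)/K — non-decreasing along the ranking — and the
    selection stops at the largest K whose estimate stays at or below
    ``target_fdr``.  Pairs tied at the threshold are admitted all together
    or not at all (K is only evaluated at tie-group boundaries), so the
    selected set is exactly "every pair with score >= threshold" and the
    realized FDP equals 1 - precision of the PR curve at that threshold.

    Returns ``(threshold, selected_pairs, estimated_fdr)`` where
    ``threshold`` is the score of the last pair admitted (1.0 when nothing
    is selected).
    """
    if not 0.0 < target_fdr < 1.0:
        raise DataError(f"target FDR must lie in (0, 1), got {target_fdr}")
    n, t = scores.scores.shape
    flat = scores.scores.ravel()
    sample_idx, target_idx = np.unravel_index(np.arange(n * t), (n, t))
    tgt_rank = np.argsort(np.argsort(scores.target_ids))  # lexicographic rank
    order = np.lexsort((tgt_rank[target_idx], sample_idx, -flat))
    sorted_scores = flat[order]
    k = np.arange(1, n * t + 1)
    est = (k - np.cumsum(sorted_scores)) / k
    # admissible stopping points: last index of each tie group
    group_end = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    # 1e-10 slack so that exact boundary cases are not lost to binary
    # floating-point round-off
    ok = (est <= target_fdr + 1e-10) & group_end
    if not ok.any():
        return 1.0, set(), 0.0
    K = int(np.max(np.nonzero(ok)[0])) + 1
    selected = {
        (scores.sample_ids[sample_idx[j]], scores.target_ids[target_idx[j]])
        for j in order[:K]
    }
    return float(sorted_scores[K - 1]), selected, float(est[K - 1])
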