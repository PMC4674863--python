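"""Precision-recall evaluation, FDR calibration and parameter sweeps.

Detection of deregulated (sample, target) pairs is a heavily imbalanced
problem — at the default deregulation rate only a few percent of pairs are
positive — so performance is summarized with precision-recall curves and
their area (AUPR) rather than ROC.  The area is computed by right-
continuous step integration over the distinct score thresholds, matching
the average-precision convention.  Calibration compares the intended FDR of
the posterior-score selection rule with the realized false-discovery
proportion against simulation truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DataError
from .em import (
    DeregulationScores,
    deregulation_scores,
    fdr_select,
    fit_em,
    initialize_parameters,
)
from .model import ModelParameters
from .simulate import default_simulation_theta, generate_network, simulate_dataset


@dataclass(frozen=True)
class PRCurve:
    """A precision-recall curve over all distinct score thresholds."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    aupr: float

    @property
    def points(self) -> list[tuple[float, float, float]]:
        return list(zip(self.thresholds, self.precision, self.recall))


def _flatten(scores) -> np.ndarray:
    if isinstance(scores, DeregulationScores):
        return scores.scores.ravel()
    return np.asarray(scores, dtype=float).ravel()


def pr_curve(scores, truth) -> PRCurve:
    """Precision-recall curve of the scores against binary truth.

    At each distinct score value s (descending), every pair with score >= s
    is called positive; tied pairs therefore enter the curve together.  The
    AUPR is sum over thresholds of (recall increment) x precision.
    """
    s = _flatten(scores)
    y = np.asarray(truth).ravel().astype(bool)
    if s.shape != y.shape:
        raise DataError("scores and truth have different sizes")
    P = int(y.sum())
    if P == 0:
        raise DataError("truth contains no positive labels; recall is undefined")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    # last index of each distinct threshold value
    last = np.nonzero(np.r_[s_sorted[1:] != s_sorted[:-1], True])[0]
    tp = np.cumsum(y_sorted)[last]
    total = last + 1
    precision = tp / total
    recall = tp / P
    aupr = float(np.sum(np.diff(np.r_[0.0, recall]) * precision))
    return PRCurve(s_sorted[last], precision, recall, aupr)


def fdr_calibration(
    scores: DeregulationScores, truth, fdr_grid
) -> pd.DataFrame:
    """Intended FDR vs realized false-discovery proportion.

    For each intended level the posterior-score selection rule is applied
    and the realized FDP (fraction of selected pairs that are true
    negatives) is computed from the truth labels.  An empty selection has
    realized FDP 0 by convention.
    """
    truth = np.asarray(truth).astype(bool)
    if truth.shape != scores.scores.shape:
        raise DataError("truth matrix shape does not match scores")
    truth_map = {
        (s, g): truth[i, j]
        for i, s in enumerate(scores.sample_ids)
        for j, g in enumerate(scores.target_ids)
    }
    rows = []
    for level in fdr_grid:
        threshold, selected, est = fdr_select(scores, level)
        K = len(selected)
        fdp = (
            sum(1 for pair in selected if not truth_map[pair]) / K if K else 0.0
        )
        rows.append(
            {
                "intended_fdr": level, "realized_fdp": fdp, "n_selected": K,
                "threshold": threshold, "estimated_fdr": est,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SweepConfig:
    """Base study conditions for a parameter sweep.

    Defaults give n x G in the several hundreds (the regime where
    performance is stable), two-regulator degree caps, and the default
    simulation parameters.
    """

    r: int = 5
    t: int = 10
    n: int = 30
    max_act: int = 2
    max_inh: int = 2
    theta: ModelParameters = field(default_factory=default_simulation_theta)
    n_passes: int = 10
    max_iter: int = 40
    tol: float = 1e-4

    def genes(self) -> int:
        return self.r + self.t


SWEEPABLE = ("sigma", "epsilon", "mu", "alpha", "n_passes", "n_genes", "n_samples")


def _apply(config: SweepConfig, name: str, value) -> SweepConfig:
    theta = config.theta
    if name == "sigma":
        theta = replace(theta, sigma=np.full(3, float(value)))
        return replace(config, theta=theta)
    if name == "epsilon":
        theta = replace(theta, epsilon=float(value))
        return replace(config, theta=theta)
    if name == "mu":
        theta = replace(theta, mu=np.asarray(value, dtype=float))
        return replace(config, theta=theta)
    if name == "alpha":
        theta = replace(theta, alpha=np.asarray(value, dtype=float))
        return replace(config, theta=theta)
    if name == "n_passes":
        return replace(config, n_passes=int(value))
    if name == "n_genes":
        # scale targets and regulators keeping their base ratio
        total = int(value)
        r = max(1, round(total * config.r / config.genes()))
        return replace(config, r=r, t=max(1, total - r))
    if name == "n_samples":
        return replace(config, n=int(value))
    raise DataError(f"unknown sweep parameter {name!r}; valid: {SWEEPABLE}")


def run_setting(config: SweepConfig, seed: int) -> tuple[PRCurve, DeregulationScores, np.ndarray]:
    """One replicate: simulate, fit from the default initializer, score."""
    rng = np.random.default_rng(seed)
    net_seed, data_seed = (int(v) for v in rng.integers(2**31, size=2))
    net = generate_network(
        config.r, config.t, config.max_act, config.max_inh, seed=net_seed
    )
    X, truth = simulate_dataset(net, config.theta, config.n, seed=data_seed)
    theta0 = initialize_parameters(X)
    _, marginals, _ = fit_em(
        net, X, theta0,
        max_iter=config.max_iter, tol=config.tol, n_passes=config.n_passes,
    )
    scores = deregulation_scores(marginals)
    return pr_curve(scores, truth.deregulated), scores, truth.deregulated


def sweep_experiment(
    parameter_name: str,
    values,
    n_replicates: int = 10,
    base_config: SweepConfig | None = None,
    seed: int = 0,
) -> dict:
    """Clouds of PR curves across one varying parameter.

    For each value of ``parameter_name`` (all other settings fixed at the
    base configuration), ``n_replicates`` independent datasets are
    simulated, fitted and scored.  Replicate seeds derive deterministically
    from the master seed.  Returns {value: [PRCurve, ...]}.
    """
    if parameter_name not in SWEEPABLE:
        raise DataError(
            f"unknown sweep parameter {parameter_name!r}; valid: {SWEEPABLE}"
        )
    base = base_config if base_config is not None else SweepConfig()
    master = np.random.default_rng(seed)
    results: dict = {}
    for value in values:
        config = _apply(base, parameter_name, value)
        rep_seeds = master.integers(2**31, size=n_replicates)
        key = tuple(value) if isinstance(value, (list, tuple, np.ndarray)) else value
        results[key] = [
            run_setting(config, int(s))[0] for s in rep_seeds
        ]
    return results


def sweep_tidy(parameter_name: str, results: dict) -> pd.DataFrame:
    """Tidy long-format table of every PR point in a sweep."""
    rows = []
    for value, curves in results.items():
        for rep, curve in enumerate(curves):
            for thr, prec, rec in curve.points:
                rows.append(
                    {
                        "parameter": parameter_name, "value": str(value),
                        "replicate": rep, "threshold": thr,
                        "precision": prec, "recall": rec,
                    }
                )
    return pd.DataFrame(rows)


def sweep_summary(parameter_name: str, results: dict) -> pd.DataFrame:
    """Per-replicate AUPR summary of a sweep."""
    rows = [
        {
            "parameter": parameter_name, "value": str(value),
            "replicate": rep, "aupr": curve.aupr,
        }
        for value, curves in results.items()
        for rep, curve in enumerate(curves)
    ]
    return pd.DataFrame(rows)
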