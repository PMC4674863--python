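"""Readers and writers for the package's tab-separated file formats.

A single TSV dialect is used throughout (tab-separated, header row, UTF-8,
"." decimal): network edge lists (target, regulator, sign), expression
matrices (rows samples, columns genes, first column the sample identifier),
score matrices, long-format score tables, simulation truth tables and
parameter JSON.  No delimiter autodetection and no transpose tolerance —
silent misorientation is worse than an error.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .em import DeregulationScores
from .model import ExpressionMatrix, ModelParameters, RegulatoryNetwork

_ACTIVATOR_TOKENS = {"activator", "+1", "+", "1"}
_INHIBITOR_TOKENS = {"inhibitor", "-1", "-"}


def read_network(path) -> RegulatoryNetwork:
    """Read a signed edge list with columns (target, regulator, sign).

    Sign tokens: activator/+1/+ and inhibitor/-1/-.  Duplicate edges with
    conflicting signs, genes appearing in both roles, or an empty edge list
    are errors.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"target", "regulator", "sign"}
    if not required <= set(df.columns):
        raise DataError(
            f"{path}: network file needs columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    if df.empty:
        raise DataError(f"{path}: network file has no edges")
    activators: dict[str, set[str]] = {}
    inhibitors: dict[str, set[str]] = {}
    seen: dict[tuple[str, str], str] = {}
    for row in df.itertuples(index=False):
        tgt, reg, sign = str(row.target), str(row.regulator), str(row.sign).strip()
        if sign in _ACTIVATOR_TOKENS:
            role = "activator"
        elif sign in _INHIBITOR_TOKENS:
            role = "inhibitor"
        else:
            raise DataError(f"{path}: unknown sign token {sign!r} for edge {reg}->{tgt}")
        prev = seen.get((tgt, reg))
        if prev is not None and prev != role:
            raise DataError(
                f"{path}: edge ({tgt}, {reg}) listed with conflicting signs"
            )
        seen[(tgt, reg)] = role
        bucket = activators if role == "activator" else inhibitors
        bucket.setdefault(tgt, set()).add(reg)
    try:
        return RegulatoryNetwork.from_edges(activators, inhibitors)
    except DataError as exc:
        raise DataError(f"{path}: {exc}") from exc


def write_network(net: RegulatoryNetwork, path) -> None:
    rows = []
    for g in net.targets:
        for r in net.activators[g]:
            rows.append((g, r, "activator"))
        for r in net.inhibitors[g]:
            rows.append((g, r, "inhibitor"))
    pd.DataFrame(rows, columns=["target", "regulator", "sign"]).to_csv(
        path, sep="\t", index=False
    )


def read_expression(path) -> ExpressionMatrix:
    """Read an expression matrix: rows samples, columns genes.

    Rejects missing / non-numeric cells (reported with their coordinates)
    and duplicated gene columns or sample rows.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    genes = header[1:]
    if len(set(genes)) != len(genes):
        dupes = sorted({g for g in genes if genes.count(g) > 1})
        raise DataError(f"{path}: duplicated gene column(s) {dupes}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].tolist()
        raise DataError(f"{path}: duplicated sample id(s) {dupes}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy())
    if bad.size:
        i, j = bad[0]
        raise DataError(
            f"{path}: missing or non-numeric value {df.iat[i, j]!r} at "
            f"(sample {df.index[i]!r}, gene {df.columns[j]!r})"
        )
    return ExpressionMatrix.from_dataframe(numeric)


def write_expression(X: ExpressionMatrix, path) -> None:
    X.to_dataframe().to_csv(path, sep="\t", index_label="sample")


def write_scores(scores: DeregulationScores, path) -> None:
    """Wide TSV: rows samples, columns targets."""
    scores.to_dataframe().to_csv(path, sep="\t", index_label="sample")


def read_scores(path) -> DeregulationScores:
    X = read_expression(path)  # same tabular layout and checks
    return DeregulationScores(X.values, X.sample_ids, X.gene_ids)


def write_scores_long(
    scores: DeregulationScores, path, selected: set | None = None,
    fdr_level: float | None = None,
) -> None:
    """Long TSV: (sample, target, score, selected_at_fdr)."""
    df = scores.to_long()
    if selected is not None:
        df["selected_at_fdr"] = [
            (s, g) in selected for s, g in zip(df["sample"], df["target"])
        ]
        if fdr_level is not None:
            df.attrs["fdr_level"] = fdr_level
    df.to_csv(path, sep="\t", index=False)


def write_truth(truth_matrix: np.ndarray, sample_ids, target_ids, path) -> None:
    """Long TSV of true deregulation labels: (sample, target, deregulated)."""
    rows = [
        (s, g, int(truth_matrix[i, j]))
        for i, s in enumerate(sample_ids)
        for j, g in enumerate(target_ids)
    ]
    pd.DataFrame(rows, columns=["sample", "target", "deregulated"]).to_csv(
        path, sep="\t", index=False
    )


def read_truth(path, sample_ids, target_ids) -> np.ndarray:
    """Read a truth TSV back into a samples x targets 0/1 matrix."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "target": str})
    required = {"sample", "target", "deregulated"}
    if not required <= set(df.columns):
        raise DataError(f"{path}: truth file needs columns {sorted(required)}")
    si = {s: i for i, s in enumerate(sample_ids)}
    ti = {g: j for j, g in enumerate(target_ids)}
    out = np.zeros((len(sample_ids), len(target_ids)), dtype=int)
    for row in df.itertuples(index=False):
        if row.sample not in si or row.target not in ti:
            raise DataError(
                f"{path}: pair ({row.sample}, {row.target}) not in score matrix"
            )
        out[si[row.sample], ti[row.target]] = int(row.deregulated)
    return out


def write_theta(theta: ModelParameters, path) -> None:
    payload = {
        "alpha": theta.alpha.tolist(),
        "epsilon": theta.epsilon,
        "mu": theta.mu.tolist(),
        "sigma": theta.sigma.tolist(),
        "state_order": list((-1, 0, 1)),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_theta(path) -> ModelParameters:
    payload = json.loads(Path(path).read_text())
    try:
        return ModelParameters(
            alpha=np.asarray(payload["alpha"], dtype=float),
            epsilon=float(payload["epsilon"]),
            mu=np.asarray(payload["mu"], dtype=float),
            sigma=np.asarray(payload["sigma"], dtype=float),
        )
    except KeyError as exc:
        raise DataError(f"{path}: parameter file missing field {exc}") from exc
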