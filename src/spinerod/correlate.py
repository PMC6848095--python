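"""Pattern correlation between 3D rod deformation fields.

Two normalized displacement fields are compared by the Pearson correlation
of their concatenated (X, Y, Z) component vectors, with a 95% confidence
interval from the Fisher variance-stabilizing transform and a two-sided
p-value from the t statistic on n - 2 degrees of freedom.  This reproduces
the single-r-per-model-pair structure of the subtype comparison table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputMismatchError, UndefinedCorrelationError

__all__ = ["CorrelationResult", "correlate_deformations", "correlation_matrix",
           "matrix_to_square"]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    p: float
    n: int


def _flatten(field: np.ndarray) -> np.ndarray:
    a = np.asarray(field, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3:
        raise InputMismatchError("displacement field must have shape (n, 3)")
    return a.reshape(-1)


def correlate_deformations(a: np.ndarray, b: np.ndarray) -> CorrelationResult:
    """Pearson pattern correlation of two displacement fields.

    Fields must be sampled at the same nodes; ``n`` equals 3 times the node
    count.  Raises on mismatched sizes or zero-variance fields.
    """
    x, y = _flatten(a), _flatten(b)
    if x.size != y.size:
        raise InputMismatchError("fields differ in node count")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise UndefinedCorrelationError("zero-variance deformation field")
    res = stats.pearsonr(x, y)
    ci = res.confidence_interval(confidence_level=0.95)
    return CorrelationResult(r=float(res.statistic), ci_low=float(ci.low),
                             ci_high=float(ci.high), p=float(res.pvalue),
                             n=x.size)


def correlation_matrix(fields: list[np.ndarray],
                       labels: list[str]) -> pd.DataFrame:
    """All pairwise pattern correlations as a tidy table.

    Returns one row per unordered pair (upper triangle) with columns
    ``model_a, model_b, r, ci_low, ci_high, p, n`` plus per-axis r values
    for transparency.
    """
    if len(fields) != len(labels):
        raise InputMismatchError("fields and labels differ in length")
    if len(fields) < 2:
        raise InputMismatchError("need at least 2 fields")
    rows = []
    for i in range(len(fields)):
        for j in range(i + 1, len(fields)):
            res = correlate_deformations(fields[i], fields[j])
            per_axis = {}
            for k, ax in enumerate("xyz"):
                a = np.asarray(fields[i])[:, k]
                b = np.asarray(fields[j])[:, k]
                if np.std(a) == 0.0 or np.std(b) == 0.0:
                    per_axis[f"r_{ax}"] = np.nan   # axis carries no signal
                else:
                    per_axis[f"r_{ax}"] = float(stats.pearsonr(a, b).statistic)
            rows.append({"model_a": labels[i], "model_b": labels[j],
                         "r": res.r, "ci_low": res.ci_low,
                         "ci_high": res.ci_high, "p": res.p, "n": res.n,
                         **per_axis})
    return pd.DataFrame(rows)


def matrix_to_square(df: pd.DataFrame, labels: list[str]) -> pd.DataFrame:
    """Pivot the tidy pair table into a symmetric square r matrix."""
    m = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    for _, row in df.iterrows():
        m.loc[row["model_a"], row["model_b"]] = row["r"]
        m.loc[row["model_b"], row["model_a"]] = row["r"]
    return m
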