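"""Composite-score computation, covariate residualization and group tests.

Residualization replaces each node by its least-squares residual after
regressing on that node's covariate set (age everywhere; age, total
intracranial volume and acquisition site for gray-matter-volume nodes), so
that the network downstream reflects associations not driven by these
nuisance variables.  Group comparisons use Welch two-sample t-tests with
Benjamini-Hochberg false-discovery-rate correction across the variable
family.
"""

from __future__ import annotations

import numbers

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .layers import CATEGORICAL_COVARIATES, CohortTable, CovariateSpec

__all__ = [
    "compute_gsi",
    "isi_category",
    "ISI_BANDS",
    "residualize",
    "group_compare",
]


def compute_gsi(anx, som, dep):
    """Global Severity Index: the sum of the anxiety, somatization and
    depression subscale scores of the BSI-18.

    Accepts scalars or aligned arrays; all inputs must be non-negative.
    """
    anx = np.asarray(anx, dtype=float)
    som = np.asarray(som, dtype=float)
    dep = np.asarray(dep, dtype=float)
    if (anx < 0).any() or (som < 0).any() or (dep < 0).any():
        raise ValueError("BSI-18 subscale scores cannot be negative")
    total = anx + som + dep
    return float(total) if total.ndim == 0 else total


#: Insomnia Severity Index bands: the instrument's standard published
#: cutpoints (total score 0-28).
ISI_BANDS = (
    (0, 7, "none"),
    (8, 14, "subthreshold"),
    (15, 21, "moderate"),
    (22, 28, "severe"),
)


def isi_category(total_isi) -> str:
    """Band an Insomnia Severity Index total (integer 0-28)."""
    if not isinstance(total_isi, numbers.Integral):
        if isinstance(total_isi, numbers.Real) and float(total_isi).is_integer():
            total_isi = int(total_isi)
        else:
            raise ValueError(f"ISI total must be an integer, got {total_isi!r}")
    total_isi = int(total_isi)
    for lo, hi, label in ISI_BANDS:
        if lo <= total_isi <= hi:
            return label
    raise ValueError(f"ISI total out of range [0, 28]: {total_isi}")


def _design_matrix(
    covariates: pd.DataFrame, names: tuple[str, ...], node: str
) -> np.ndarray:
    """Intercept + named covariates, categorical ones dummy-expanded.

    Reference-cell coding: the first category in sorted order is dropped.
    Categories absent from this (sub)sample simply contribute no column.
    """
    n = len(covariates)
    cols = [np.ones(n)]
    for name in names:
        col = covariates[name]
        if name in CATEGORICAL_COVARIATES:
            levels = sorted(col.astype(str).unique())
            for level in levels[1:]:
                cols.append((col.astype(str) == level).to_numpy(dtype=float))
        else:
            cols.append(col.to_numpy(dtype=float))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"rank-deficient design for node {node!r} with covariates {names}: "
            "check for collinear or constant covariates (e.g. a single-site "
            "cohort with 'site' in the spec)"
        )
    return X


def residualize(table: CohortTable, spec: CovariateSpec) -> CohortTable:
    """Replace each node by its OLS residual on its covariate set.

    Residuals are exactly orthogonal to every design column (including the
    intercept, so they are mean-centred).  Node order, names and the
    covariate frame are unchanged.
    """
    spec.validate(table)
    out = table.values.copy().astype(float)
    for node in table.node_names:
        X = _design_matrix(table.covariates, spec[node], node)
        y = out[node].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        out[node] = y - X @ beta
    return CohortTable(
        values=out,
        covariates=table.covariates,
        layer_spec=table.layer_spec,
        ordinal=frozenset(),  # residuals are no longer integer-valued scores
    )


def group_compare(
    table_a: CohortTable | pd.DataFrame,
    table_b: CohortTable | pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch t-tests per variable with Benjamini-Hochberg FDR correction.

    Returns a DataFrame indexed by variable with columns ``mean_a``,
    ``mean_b``, ``t``, ``p``, ``p_fdr``, ``significant`` and ``degenerate``
    (the latter flags variables with zero variance in both groups, whose p
    is reported as 1).
    """
    a = table_a.values if isinstance(table_a, CohortTable) else pd.DataFrame(table_a)
    b = table_b.values if isinstance(table_b, CohortTable) else pd.DataFrame(table_b)
    if list(a.columns) != list(b.columns):
        raise ValueError("both groups must share the same variable set")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 participants")

    rows = []
    for var in a.columns:
        xa, xb = a[var].to_numpy(float), b[var].to_numpy(float)
        degenerate = xa.var(ddof=1) == 0.0 and xb.var(ddof=1) == 0.0
        if degenerate:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(xa, xb, equal_var=False)
        rows.append(
            {
                "variable": var,
                "mean_a": xa.mean(),
                "mean_b": xb.mean(),
                "t": float(t),
                "p": float(p),
                "degenerate": bool(degenerate),
            }
        )
    result = pd.DataFrame(rows).set_index("variable")
    reject, p_fdr, _, _ = multipletests(result["p"], alpha=alpha, method="fdr_bh")
    result["p_fdr"] = p_fdr
    result["significant"] = reject
    return result[["mean_a", "mean_b", "t", "p", "p_fdr", "significant", "degenerate"]]
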