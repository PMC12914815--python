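"""Mixed-type correlation estimation for network input.

Questionnaire scores are coarse ordinal variables and many cohort measures
violate normality, so a single correlation type is inappropriate.  Mirroring
automatic correlation selection in psychometric network software, each
variable is classified as ordinal or continuous; a pair is correlated by
Spearman's rank coefficient when either member is ordinal or fails a
normality screen (Shapiro-Wilk at 0.05), and by Pearson's coefficient
otherwise.  Because mixing coefficient types can yield an indefinite matrix,
the result is projected to the nearest positive-semidefinite correlation
matrix by eigenvalue clipping before it is handed to the graphical lasso.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .layers import CohortTable

__all__ = [
    "AssociationMatrix",
    "classify_variable",
    "auto_correlate",
    "nearest_psd",
]

#: maximum number of distinct integer levels for a variable to count as ordinal
ORDINAL_MAX_LEVELS = 7

#: Shapiro-Wilk significance level of the normality screen
NORMALITY_ALPHA = 0.05

#: eigenvalue floor used when projecting to positive semidefiniteness
PSD_EIG_FLOOR = 1e-8


@dataclass
class AssociationMatrix:
    """Symmetric correlation matrix plus per-pair method metadata."""

    matrix: pd.DataFrame
    method_of: dict[tuple[str, str], str] = field(default_factory=dict)
    psd_corrected: bool = False

    @property
    def values(self) -> np.ndarray:
        return self.matrix.to_numpy()

    @property
    def node_names(self) -> list[str]:
        return list(self.matrix.columns)


def classify_variable(values) -> str:
    """'ordinal' iff every value is an integer and there are at most
    ``ORDINAL_MAX_LEVELS`` distinct levels; otherwise 'continuous'.

    A constant vector is an error: zero variance cannot be correlated.
    """
    x = np.asarray(values, dtype=float)
    distinct = np.unique(x)
    if distinct.size < 2:
        raise ValueError("constant variable: zero variance cannot be correlated")
    if np.all(x == np.round(x)) and distinct.size <= ORDINAL_MAX_LEVELS:
        return "ordinal"
    return "continuous"


def nearest_psd(matrix: np.ndarray, floor: float = PSD_EIG_FLOOR) -> np.ndarray:
    """Project a symmetric unit-diagonal matrix to positive semidefiniteness.

    Eigenvalues are clipped at ``floor``, the matrix reconstructed and
    rescaled back to unit diagonal.  An already-PSD input is returned
    unchanged (exact fixed point).
    """
    M = np.asarray(matrix, dtype=float)
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError("nearest_psd requires a symmetric matrix")
    eigval, eigvec = np.linalg.eigh((M + M.T) / 2.0)
    if eigval[0] >= 0.0:
        return M
    clipped = np.clip(eigval, floor, None)
    out = (eigvec * clipped) @ eigvec.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    out = (out + out.T) / 2.0
    np.fill_diagonal(out, 1.0)
    return out


def _is_normalish(x: np.ndarray) -> bool:
    """Shapiro-Wilk screen; vectors passing are eligible for Pearson."""
    # Shapiro-Wilk needs >= 3 observations; tiny samples default to Pearson.
    if len(x) < 3 or np.unique(x).size < 3:
        return True
    _, p = stats.shapiro(x)
    return p >= NORMALITY_ALPHA


def auto_correlate(table: CohortTable | pd.DataFrame) -> AssociationMatrix:
    """Correlation matrix with per-pair automatic method choice.

    Spearman for any pair involving an ordinal or non-normal variable,
    Pearson otherwise; symmetrized, unit diagonal, PSD-corrected if the
    mixture of types produced an indefinite matrix.
    """
    df = table.values if isinstance(table, CohortTable) else pd.DataFrame(table)
    if len(df) < 3:
        raise ValueError("need at least 3 participants to correlate")
    nodes = list(df.columns)
    X = df.to_numpy(dtype=float)

    rank_based = np.zeros(len(nodes), dtype=bool)
    for j, node in enumerate(nodes):
        col = X[:, j]
        if np.unique(col).size < 3:
            raise ValueError(
                f"variable {node!r} has fewer than 3 distinct values; "
                "estimation cannot proceed"
            )
        kind = classify_variable(col)
        rank_based[j] = kind == "ordinal" or not _is_normalish(col)

    pearson = np.corrcoef(X, rowvar=False)
    ranks = np.apply_along_axis(stats.rankdata, 0, X)
    spearman = np.corrcoef(ranks, rowvar=False)

    use_spearman = rank_based[:, None] | rank_based[None, :]
    M = np.where(use_spearman, spearman, pearson)
    M = (M + M.T) / 2.0
    np.fill_diagonal(M, 1.0)

    psd_corrected = bool(np.linalg.eigvalsh(M)[0] < -PSD_EIG_FLOOR)
    if psd_corrected:
        M = nearest_psd(M)

    method_of = {}
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            method_of[(nodes[i], nodes[j])] = (
                "spearman" if use_spearman[i, j] else "pearson"
            )
    return AssociationMatrix(
        matrix=pd.DataFrame(M, index=nodes, columns=nodes),
        method_of=method_of,
        psd_corrected=psd_corrected,
    )
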