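"""Sparse partial-correlation network estimation.

The network is a Gaussian graphical model estimated by graphical-lasso
(L1-penalized precision matrix) over a descending log-spaced penalty path,
with the Extended Bayesian Information Criterion (EBIC) selecting the
penalty.  For precision matrix K the edge weights are the partial
correlations

    w_ij = -K_ij / sqrt(K_ii K_jj),

and the EBIC of a model with E nonzero off-diagonal pairs over p nodes fit
to n observations is

    EBIC = -2 L + E log n + 4 E gamma log p,
    L    = (n / 2) (log det K - trace(S K)),

with gamma (default 0.5) tuning the preference for sparsity; gamma = 0
recovers the ordinary BIC.  The inner L1 solver is scikit-learn's
coordinate-descent graphical lasso, which penalizes off-diagonal entries
only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso

from .association import AssociationMatrix, auto_correlate
from .layers import CohortTable, LayerSpec

__all__ = [
    "EstimationConfig",
    "PcorNetwork",
    "lambda_path",
    "graphical_lasso",
    "ebic_score",
    "precision_to_pcor",
    "estimate_network",
    "density_band",
    "DENSITY_BANDS",
]


@dataclass(frozen=True)
class EstimationConfig:
    """Tuning parameters of the regularized network estimator."""

    gamma: float = 0.5
    n_lambdas: int = 100
    lambda_min_ratio: float = 0.01
    convergence_tol: float = 1e-4
    max_iter: int = 200
    edge_zero_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.n_lambdas < 2:
            raise ValueError("n_lambdas must be >= 2")
        if not (0.0 < self.lambda_min_ratio < 1.0):
            raise ValueError("lambda_min_ratio must lie in (0, 1)")


@dataclass
class PcorNetwork:
    """Estimated partial-correlation network with estimation metadata."""

    weights: pd.DataFrame
    layer_spec: LayerSpec
    n: int
    selected_lambda: float
    ebic_path: pd.DataFrame  # columns: lambda, ebic, n_edges
    edge_zero_tol: float = 1e-6
    association: AssociationMatrix | None = None

    def __post_init__(self) -> None:
        W = self.weights.to_numpy(dtype=float)
        if not np.allclose(W, W.T, atol=1e-8):
            raise ValueError("weight matrix must be symmetric")
        if np.abs(np.diag(W)).max(initial=0.0) != 0.0:
            raise ValueError("weight matrix diagonal must be exactly zero")

    @property
    def node_names(self) -> list[str]:
        return list(self.weights.columns)

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    @property
    def n_possible_edges(self) -> int:
        return self.p * (self.p - 1) // 2

    @property
    def n_edges(self) -> int:
        W = self.weights.to_numpy()
        iu = np.triu_indices(self.p, k=1)
        return int((np.abs(W[iu]) > self.edge_zero_tol).sum())

    @property
    def density(self) -> float:
        return self.n_edges / self.n_possible_edges if self.p > 1 else 0.0

    @property
    def band(self) -> str:
        return density_band(self.density)[0]

    def edge_list(self) -> pd.DataFrame:
        """Long-form nonzero edges with layer labels and intra/inter flag."""
        W = self.weights.to_numpy()
        nodes = self.node_names
        rows = []
        for i in range(self.p):
            for j in range(i + 1, self.p):
                if abs(W[i, j]) > self.edge_zero_tol:
                    li, lj = self.layer_spec[nodes[i]], self.layer_spec[nodes[j]]
                    rows.append(
                        {
                            "node_i": nodes[i],
                            "node_j": nodes[j],
                            "weight": W[i, j],
                            "layer_i": li,
                            "layer_j": lj,
                            "kind": "intra" if li == lj else "inter",
                        }
                    )
        return pd.DataFrame(
            rows, columns=["node_i", "node_j", "weight", "layer_i", "layer_j", "kind"]
        )


#: density bands: (label, inclusive lower bound on the fraction)
DENSITY_BANDS = (("high", 0.5), ("medium", 0.3), ("low", 0.0))


def density_band(network_or_fraction) -> tuple[str, float]:
    """Classify network density: >=50% high, 30-50% medium, <30% low.

    Accepts a :class:`PcorNetwork` or a bare fraction in [0, 1]; returns
    ``(band, fraction)``.
    """
    if isinstance(network_or_fraction, PcorNetwork):
        fraction = network_or_fraction.density
    else:
        fraction = float(network_or_fraction)
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"density fraction must lie in [0, 1], got {fraction}")
    for label, lo in DENSITY_BANDS:
        if fraction >= lo:
            return label, fraction
    return "low", fraction  # pragma: no cover - unreachable


def lambda_path(S: np.ndarray, config: EstimationConfig | None = None) -> np.ndarray:
    """Descending log-spaced penalty path.

    Runs from lambda_max = max |off-diagonal of S| down to
    lambda_max * lambda_min_ratio.  If every off-diagonal is (numerically)
    zero the path degenerates to the single unpenalized point lambda = 0.
    """
    cfg = config or EstimationConfig()
    S = np.asarray(S, dtype=float)
    off = S - np.diag(np.diag(S))
    lam_max = float(np.abs(off).max(initial=0.0))
    if lam_max < 1e-12:
        warnings.warn(
            "all off-diagonal correlations are zero; degenerate single-point path",
            stacklevel=2,
        )
        return np.array([0.0])
    return np.geomspace(lam_max, lam_max * cfg.lambda_min_ratio, cfg.n_lambdas)


def config_or(cfg: EstimationConfig | None) -> EstimationConfig:
    return cfg if cfg is not None else EstimationConfig()


def graphical_lasso(
    S: np.ndarray, lam: float, config: EstimationConfig | None = None
) -> np.ndarray:
    """L1-penalized precision estimate for correlation matrix S.

    Maximizes ``log det K - trace(S K) - lam * sum_{i != j} |K_ij|``.  At
    ``lam = 0`` this is the unpenalized maximum likelihood K = S^-1,
    computed directly.
    """
    cfg = config_or(config)
    S = np.asarray(S, dtype=float)
    if lam < 0:
        raise ValueError("penalty must be >= 0")
    if lam == 0.0:
        try:
            K = np.linalg.inv(S)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular correlation matrix at lambda = 0") from exc
        return (K + K.T) / 2.0
    try:
        with warnings.catch_warnings():
            # the cd solver warns when the dual gap is within rounding of the
            # tolerance at tiny penalties; the estimate is still usable there
            warnings.simplefilter("ignore", category=UserWarning)
            _, K = _sk_graphical_lasso(
                S, alpha=float(lam), tol=cfg.convergence_tol, max_iter=cfg.max_iter
            )
    except FloatingPointError as exc:
        raise RuntimeError(
            f"graphical lasso failed to converge at lambda={lam:.6g} "
            f"within {cfg.max_iter} iterations: {exc}"
        ) from exc
    return (K + K.T) / 2.0


def ebic_score(
    K: np.ndarray,
    S: np.ndarray,
    n: int,
    gamma: float = 0.5,
    edge_zero_tol: float = 1e-6,
) -> float:
    """Extended BIC of precision estimate K against correlation matrix S."""
    K = np.asarray(K, dtype=float)
    S = np.asarray(S, dtype=float)
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        raise ValueError("EBIC requires a positive-definite precision matrix")
    p = K.shape[0]
    iu = np.triu_indices(p, k=1)
    E = int((np.abs(K[iu]) > edge_zero_tol).sum())
    L = (n / 2.0) * (logdet - float(np.trace(S @ K)))
    return -2.0 * L + E * np.log(n) + 4.0 * E * gamma * np.log(p)


def precision_to_pcor(K: np.ndarray, edge_zero_tol: float = 0.0) -> np.ndarray:
    """Partial correlations w_ij = -K_ij / sqrt(K_ii K_jj), zero diagonal.

    Entries with |K_ij| <= ``edge_zero_tol`` are set to exactly zero, so the
    sparsity pattern of K is preserved bit-exactly.
    """
    K = np.asarray(K, dtype=float)
    d = np.diag(K)
    if (d <= 0).any():
        raise ValueError("precision matrix has non-positive diagonal entries")
    s = np.sqrt(d)
    W = -K / np.outer(s, s)
    W = (W + W.T) / 2.0
    if edge_zero_tol > 0:
        W[np.abs(K) <= edge_zero_tol] = 0.0
    np.fill_diagonal(W, 0.0)
    return W


def estimate_network(
    table: CohortTable, config: EstimationConfig | None = None
) -> PcorNetwork:
    """Full estimator: correlation -> penalty path -> glasso -> EBIC choice.

    The input table is expected to be residualized and complete-case.  Ties
    in EBIC resolve toward the larger penalty (sparser model).  Penalty
    points where the coordinate-descent solver fails numerically are dropped
    from the path with a warning.
    """
    cfg = config_or(config)
    if table.n <= len(table.node_names):
        warnings.warn(
            f"n = {table.n} does not exceed the node count "
            f"p = {len(table.node_names)}; estimates may be unstable",
            stacklevel=2,
        )
    assoc = auto_correlate(table)
    S = assoc.values
    n = table.n

    path = lambda_path(S, cfg)
    records = []
    solutions = {}
    for lam in path:
        try:
            K = graphical_lasso(S, float(lam), cfg)
            score = ebic_score(K, S, n, cfg.gamma, cfg.edge_zero_tol)
        except (RuntimeError, ValueError) as exc:
            warnings.warn(
                f"dropping path point lambda={lam:.6g}: {exc}", stacklevel=2
            )
            continue
        p = K.shape[0]
        iu = np.triu_indices(p, k=1)
        E = int((np.abs(K[iu]) > cfg.edge_zero_tol).sum())
        records.append({"lambda": float(lam), "ebic": float(score), "n_edges": E})
        solutions[len(records) - 1] = K
    if not records:
        raise RuntimeError("graphical lasso failed at every penalty on the path")

    ebic_path = pd.DataFrame(records)
    # path is descending in lambda, so the first argmin is the sparsest tie
    best = int(np.argmin(ebic_path["ebic"].to_numpy()))
    K_best = solutions[best]
    W = precision_to_pcor(K_best, edge_zero_tol=cfg.edge_zero_tol)
    nodes = table.node_names
    return PcorNetwork(
        weights=pd.DataFrame(W, index=nodes, columns=nodes),
        layer_spec=table.layer_spec,
        n=n,
        selected_lambda=float(ebic_path.loc[best, "lambda"]),
        ebic_path=ebic_path,
        edge_zero_tol=cfg.edge_zero_tol,
        association=assoc,
    )
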