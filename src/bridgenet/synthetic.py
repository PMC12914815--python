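"""Synthetic multilayer cohort generator.

Emulates the statistical structure the network pipeline assumes: a sparse
Gaussian graphical model whose precision matrix has dense within-layer and
sparse, weaker between-layer support; ordinal questionnaire-like nodes
obtained by discretizing the latent normal; and nuisance confounding by age
on every node plus total intracranial volume (TIV) and multi-site offsets on
the gray-matter-volume (GMV) layer.  Defaults mirror a multicentre mild-TBI
cohort: 457 participants, 4 ordinal mental-health nodes, 6 continuous
cognitive nodes and 8 GMV nodes.

Ground truth (the precision matrix, the planted bridge nodes, the confounder
coefficients) is retained on :class:`TrueModel` so that recovery by the full
pipeline can be tested end to end.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .layers import CohortTable, LayerSpec

__all__ = [
    "TrueModel",
    "CovariateConfig",
    "make_multilayer_precision",
    "make_planted_bridge_model",
    "sample_cohort",
    "default_cohort",
]

DEFAULT_LAYER_NAMES = ("mental_health", "cognition", "gmv")
DEFAULT_LAYER_PREFIXES = {"mental_health": "mh", "cognition": "cog", "gmv": "gmv"}

#: latent-normal cumulative probabilities delimiting 5 ordinal levels; the
#: right-skew mimics symptom questionnaires where most respondents score low
DEFAULT_ORDINAL_PROBS = (0.50, 0.75, 0.90, 0.97)

#: minimum acceptable smallest eigenvalue of the generated precision matrix
SPD_MARGIN = 0.05


@dataclass(frozen=True)
class TrueModel:
    """Ground-truth generative model for a multilayer cohort.

    Attributes
    ----------
    precision
        Symmetric positive-definite precision matrix over the nodes; zeros
        off-diagonal encode conditional independence.
    layer_spec
        Node-to-layer partition.
    age_effect, tiv_effect
        Per-node standardized regression coefficients of the latent node on
        standardized age (all nodes may be nonzero) and standardized TIV
        (zero outside the GMV layer).
    site_effect_sd
        Per-node standard deviation of additive site offsets (zero outside
        the GMV layer).
    ordinal_cutpoints
        Map node -> latent cumulative probabilities at which the node is
        discretized into successive integer levels; empty for continuous
        nodes.
    planted_bridges
        Nodes on which between-layer support was concentrated (if any);
        recorded for recovery testing.
    """

    precision: np.ndarray
    layer_spec: LayerSpec
    age_effect: Mapping[str, float] = field(default_factory=dict)
    tiv_effect: Mapping[str, float] = field(default_factory=dict)
    site_effect_sd: Mapping[str, float] = field(default_factory=dict)
    ordinal_cutpoints: Mapping[str, tuple[float, ...]] = field(default_factory=dict)
    planted_bridges: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        K = np.asarray(self.precision, dtype=float)
        object.__setattr__(self, "precision", K)
        if K.shape[0] != K.shape[1] or K.shape[0] != len(self.layer_spec):
            raise ValueError("precision shape does not match the layer spec")
        if not np.allclose(K, K.T, atol=1e-10):
            raise ValueError("precision matrix must be symmetric")
        if np.linalg.eigvalsh(K)[0] <= 0:
            raise ValueError("precision matrix must be positive definite")
        gmv_nodes = set(self.layer_spec.nodes_in(self.layer_spec.layers[-1]))
        for name, coef in {**self.tiv_effect, **self.site_effect_sd}.items():
            if coef != 0.0 and name not in gmv_nodes:
                raise ValueError(
                    f"TIV/site effect declared for non-GMV node {name!r}"
                )

    @property
    def node_names(self) -> list[str]:
        return self.layer_spec.node_names

    @property
    def p(self) -> int:
        return self.precision.shape[0]

    def implied_covariance(self) -> np.ndarray:
        return np.linalg.inv(self.precision)

    def implied_correlation(self) -> np.ndarray:
        cov = self.implied_covariance()
        d = np.sqrt(np.diag(cov))
        return cov / np.outer(d, d)

    def partial_correlations(self) -> np.ndarray:
        """True partial correlations: -K_ij / sqrt(K_ii K_jj), zero diagonal."""
        K = self.precision
        d = np.sqrt(np.diag(K))
        W = -K / np.outer(d, d)
        np.fill_diagonal(W, 0.0)
        return W


def _layer_spec_from_sizes(
    layer_sizes: Sequence[int], layer_names: Sequence[str]
) -> LayerSpec:
    layer_of: dict[str, str] = {}
    for size, name in zip(layer_sizes, layer_names):
        prefix = DEFAULT_LAYER_PREFIXES.get(name, name[:3])
        for k in range(size):
            layer_of[f"{prefix}{k + 1}"] = name
    return LayerSpec(layer_of)


def _inflate_to_spd(K: np.ndarray, margin: float = SPD_MARGIN) -> np.ndarray:
    """Add delta*I, doubling delta, until the smallest eigenvalue >= margin.

    Preserves the off-diagonal sparsity pattern exactly.
    """
    delta = margin
    out = K.copy()
    while np.linalg.eigvalsh(out)[0] < margin:
        out = K + delta * np.eye(K.shape[0])
        delta *= 2.0
    return out


def make_multilayer_precision(
    layer_sizes: Sequence[int],
    within_density: float = 0.6,
    between_density: float = 0.1,
    weight_range: tuple[float, float] = (0.2, 0.4),
    seed: int = 0,
    *,
    layer_names: Sequence[str] | None = None,
    bridge_nodes: Sequence[str] | None = None,
    between_weight_scale: float = 0.7,
    negative_fraction: float = 0.3,  # fraction of *negative* partial correlations
    ordinal_layers: Sequence[str] = ("mental_health",),
    ordinal_probs: Sequence[float] = DEFAULT_ORDINAL_PROBS,
    age_effect: float = 0.25,
    tiv_effect: float = 0.4,
    site_effect_sd: float = 0.3,
) -> TrueModel:
    """Sample a sparse multilayer precision matrix and wrap it as a TrueModel.

    Off-diagonal support is Bernoulli-sampled independently per unordered
    pair: within-layer pairs with probability ``within_density``,
    between-layer pairs with ``between_density``.  Nonzero entries have
    magnitude uniform in ``weight_range`` (between-layer entries scaled by
    ``between_weight_scale``, reflecting that cross-domain conditional
    associations are weaker than within-domain ones) and sign negative with
    probability ``negative_fraction``.  The diagonal starts at 1 and is
    inflated (add delta*I, doubling delta) until the smallest eigenvalue is
    at least 0.05, which preserves the sparsity pattern.

    If ``bridge_nodes`` is given, between-layer support is restricted to
    pairs incident to at least one of those nodes, planting them as the
    bridge set.
    """
    layer_sizes = list(layer_sizes)
    if any(s <= 0 for s in layer_sizes):
        raise ValueError(f"layer sizes must be positive, got {layer_sizes}")
    if len(layer_sizes) < 2:
        raise ValueError("need at least 2 layers")
    if not (0.0 <= within_density <= 1.0 and 0.0 <= between_density <= 1.0):
        raise ValueError("densities must lie in [0, 1]")
    lo, hi = float(weight_range[0]), float(weight_range[1])
    if not (0.0 < lo <= hi):
        raise ValueError(
            f"weight_range must be a positive interval excluding 0, got {weight_range}"
        )
    if layer_names is None:
        layer_names = DEFAULT_LAYER_NAMES[: len(layer_sizes)]
        if len(layer_names) < len(layer_sizes):
            layer_names = [f"layer{i + 1}" for i in range(len(layer_sizes))]
    spec = _layer_spec_from_sizes(layer_sizes, layer_names)
    nodes = spec.node_names
    p = len(nodes)
    membership = spec.membership()

    bridge_set = set(bridge_nodes or ())
    unknown = bridge_set - set(nodes)
    if unknown:
        raise ValueError(f"bridge_nodes not in the layer spec: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    K = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            within = membership[i] == membership[j]
            if within:
                density = within_density
            else:
                density = between_density
                if bridge_set and not ({nodes[i], nodes[j]} & bridge_set):
                    density = 0.0
            if rng.random() < density:
                mag = rng.uniform(lo, hi)
                if not within:
                    mag *= between_weight_scale
                # pcor_ij = -K_ij/...: a negative precision entry yields a
                # positive partial correlation, the majority case in
                # psychometric networks
                negative_pcor = rng.random() < negative_fraction
                K[i, j] = K[j, i] = mag if negative_pcor else -mag
    K = _inflate_to_spd(K)

    ordinal_layer_set = set(ordinal_layers)
    cutpoints = {
        node: tuple(ordinal_probs)
        for node in nodes
        if spec[node] in ordinal_layer_set
    }
    gmv_layer = spec.layers[-1]
    gmv_nodes = set(spec.nodes_in(gmv_layer))
    return TrueModel(
        precision=K,
        layer_spec=spec,
        age_effect={n: age_effect for n in nodes},
        tiv_effect={n: (tiv_effect if n in gmv_nodes else 0.0) for n in nodes},
        site_effect_sd={n: (site_effect_sd if n in gmv_nodes else 0.0) for n in nodes},
        ordinal_cutpoints=cutpoints,
        planted_bridges=tuple(n for n in nodes if n in bridge_set),
    )


def make_planted_bridge_model(
    seed: int = 0,
    layer_sizes: Sequence[int] = (4, 6, 8),
    bridge_nodes: Sequence[str] = ("mh1", "cog1", "cog2", "gmv1"),
    within_density: float = 0.5,
    weight_range: tuple[float, float] = (0.25, 0.45),
    extra_partners: int = 2,
    **kwargs,
) -> TrueModel:
    """A well-separated multilayer model with a designated bridge set.

    Between-layer support is deterministic rather than Bernoulli-sampled, so
    the designated nodes are bridges by construction in every seed: all
    cross-layer pairs of designated nodes are connected (the planted bridge
    cluster), each designated node additionally connects to
    ``extra_partners`` distinct non-designated nodes in other layers, and no
    non-designated node carries more than one between-layer edge.
    Within-layer support and all edge weights remain random.
    """
    base = make_multilayer_precision(
        layer_sizes,
        within_density=within_density,
        between_density=0.0,
        weight_range=weight_range,
        seed=seed,
        bridge_nodes=bridge_nodes,
        **kwargs,
    )
    spec = base.layer_spec
    nodes = spec.node_names
    idx = {n: i for i, n in enumerate(nodes)}
    bridge_set = list(bridge_nodes)
    unknown = set(bridge_set) - set(nodes)
    if unknown:
        raise ValueError(f"bridge_nodes not in the layer spec: {sorted(unknown)}")

    rng = np.random.default_rng(seed + 1)
    lo, hi = weight_range
    negative_fraction = kwargs.get("negative_fraction", 0.3)

    def draw_entry() -> float:
        mag = rng.uniform(lo, hi)
        return mag if rng.random() < negative_fraction else -mag

    # strip the diagonal inflation, edit support, then re-inflate
    K = base.precision.copy()
    np.fill_diagonal(K, 1.0)
    for a_i, a in enumerate(bridge_set):
        for b in bridge_set[a_i + 1 :]:
            if spec[a] != spec[b]:
                K[idx[a], idx[b]] = K[idx[b], idx[a]] = draw_entry()
    available = [n for n in nodes if n not in bridge_set]
    for a in bridge_set:
        partners = [n for n in available if spec[n] != spec[a]]
        chosen = rng.choice(len(partners), size=min(extra_partners, len(partners)),
                            replace=False)
        for k in chosen:
            b = partners[k]
            K[idx[a], idx[b]] = K[idx[b], idx[a]] = draw_entry()
            available.remove(b)
    K = _inflate_to_spd(K)

    return dataclasses.replace(
        base, precision=K, planted_bridges=tuple(bridge_set)
    )


@dataclass(frozen=True)
class CovariateConfig:
    """Marginal distributions of the nuisance covariates.

    Age in years (truncated normal matching a middle-aged trauma cohort),
    TIV in mm^3, and a small number of acquisition sites with additive mean
    shifts on GMV nodes only.
    """

    age_mean: float = 38.3
    age_sd: float = 16.0
    age_range: tuple[float, float] = (17.0, 83.0)
    tiv_mean: float = 1.5e6
    tiv_sd: float = 1.5e5
    n_sites: int = 4
    effect_scale: float = 1.0  # global multiplier on all confounder effects


def sample_cohort(
    model: TrueModel,
    n: int = 457,
    covariate_config: CovariateConfig | None = None,
    seed: int = 0,
) -> CohortTable:
    """Draw a complete-case cohort from a :class:`TrueModel`.

    Latent node values are multivariate normal with covariance equal to the
    inverse of the precision matrix, standardized to unit marginal variance
    (which leaves partial correlations untouched).  Confounder effects are
    then added — age on all nodes, TIV and per-site offsets on GMV nodes —
    and ordinal nodes are discretized into small-integer scores at fixed
    quantile cutpoints of their own empirical distribution.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = covariate_config or CovariateConfig()
    rng = np.random.default_rng(seed)
    nodes = model.node_names
    p = model.p

    try:
        cov = model.implied_covariance()
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by TrueModel
        raise ValueError("precision matrix is singular; cannot sample") from exc
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    latent = rng.multivariate_normal(np.zeros(p), corr, size=n, method="cholesky")

    a, b = cfg.age_range
    age = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, size=n), a, b)
    tiv = rng.normal(cfg.tiv_mean, cfg.tiv_sd, size=n)
    site_idx = rng.integers(0, cfg.n_sites, size=n)
    site = np.array([f"site{k + 1}" for k in site_idx])

    z_age = (age - age.mean()) / (age.std() or 1.0)
    z_tiv = (tiv - tiv.mean()) / (tiv.std() or 1.0)

    X = latent.copy()
    scale = cfg.effect_scale
    for j, node in enumerate(nodes):
        X[:, j] += scale * model.age_effect.get(node, 0.0) * z_age
        X[:, j] += scale * model.tiv_effect.get(node, 0.0) * z_tiv
        sd = scale * model.site_effect_sd.get(node, 0.0)
        if sd > 0.0:
            offsets = rng.normal(0.0, sd, size=cfg.n_sites)
            X[:, j] += offsets[site_idx]

    values = pd.DataFrame(X, columns=nodes)
    for node, probs in model.ordinal_cutpoints.items():
        col = values[node].to_numpy()
        cuts = np.quantile(col, probs)
        values[node] = np.searchsorted(cuts, col, side="left").astype(float)

    covariates = pd.DataFrame({"age": age, "tiv": tiv, "site": site})
    return CohortTable(
        values=values,
        covariates=covariates,
        layer_spec=model.layer_spec,
        ordinal=frozenset(model.ordinal_cutpoints),
    )


def default_cohort(seed: int = 0, n: int = 457) -> tuple[TrueModel, CohortTable]:
    """Convenience: the default 4+6+8 three-layer model and one cohort draw."""
    model = make_multilayer_precision([4, 6, 8], seed=seed)
    return model, sample_cohort(model, n=n, seed=seed + 1)
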