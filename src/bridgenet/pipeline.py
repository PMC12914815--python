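"""Configured end-to-end pipeline, serialization and the analysis report.

Stages: residualize -> estimate network -> density band -> bridge strength
-> bridge designation -> interlayer edge ranking -> (optional) case-dropping
bootstrap + CS coefficient.  Every artifact is a plain-text format (CSV/TSV,
GraphML, JSON); the report carries provenance (config hash, seeds, package
versions) and is byte-reproducible for a fixed config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .bridge import BridgeProfile, bridge_strength, designate_bridges, rank_interlayer_edges
from .glasso import EstimationConfig, PcorNetwork, density_band
from .layers import CohortTable, CovariateSpec, LayerSpec, default_covariate_spec
from .model import MultilayerGGM
from .stability import DEFAULT_DROP_GRID, cs_coefficient

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "run_pipeline",
    "layout_fruchterman_reingold",
    "edge_summary",
    "write_network",
    "read_weight_matrix",
]

log = logging.getLogger("bridgenet")


class PipelineError(RuntimeError):
    """A stage failure; the message is prefixed with the stage name."""

    def __init__(self, stage: str, message: str) -> None:
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs, loadable from YAML or JSON."""

    cohort_path: str
    layer_spec_path: str
    output_dir: str
    estimation: EstimationConfig = field(default_factory=EstimationConfig)
    percentile: float = 80.0
    run_stability: bool = True
    n_boot: int = 2000
    drop_grid: tuple[float, ...] = DEFAULT_DROP_GRID
    r_threshold: float = 0.70
    prob: float = 0.95
    seed: int = 0
    layout_seed: int = 0
    group_compare: bool = False

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw.update({k: v for k, v in overrides.items() if v is not None})
        est = raw.pop("estimation", {})
        if isinstance(est, dict):
            est = EstimationConfig(**est)
        grid = raw.pop("drop_grid", DEFAULT_DROP_GRID)
        return cls(estimation=est, drop_grid=tuple(grid), **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["drop_grid"] = list(self.drop_grid)
        return d

    def content_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def layout_fruchterman_reingold(
    network: PcorNetwork, seed: int = 0, iterations: int = 100
) -> pd.DataFrame:
    """2-D force-directed (Fruchterman-Reingold) coordinates on |weights|.

    Deterministic for a fixed seed; returns a DataFrame (node, x, y).
    """
    G = nx.Graph()
    G.add_nodes_from(network.node_names)
    for _, row in network.edge_list().iterrows():
        G.add_edge(row["node_i"], row["node_j"], weight=abs(float(row["weight"])))
    pos = nx.spring_layout(G, weight="weight", seed=seed, iterations=iterations)
    frame = pd.DataFrame(
        [{"node": n, "x": float(xy[0]), "y": float(xy[1])} for n, xy in pos.items()]
    )
    if not np.isfinite(frame[["x", "y"]].to_numpy()).all():
        raise PipelineError("layout", "non-finite coordinates produced")
    return frame


def edge_summary(network: PcorNetwork) -> dict:
    """Mean/SD/min/max of edge weights, over all pairs and nonzero edges.

    Sparse networks summarized over *all* unordered pairs (structural zeros
    included) show small means with wide ranges; the nonzero-only summary is
    reported alongside so both conventions are available.
    """
    W = network.weights.to_numpy()
    iu = np.triu_indices(network.p, k=1)
    pairs = W[iu]
    nz = pairs[np.abs(pairs) > network.edge_zero_tol]

    def _stats(x: np.ndarray) -> dict:
        if x.size == 0:
            return {"mean": 0.0, "sd": 0.0, "min": 0.0, "max": 0.0, "count": 0}
        return {
            "mean": float(np.mean(x)),
            "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
            "min": float(np.min(x)),
            "max": float(np.max(x)),
            "count": int(x.size),
        }

    return {"all_pairs": _stats(pairs), "nonzero": _stats(nz)}


# -- serialization ---------------------------------------------------------

def write_network(network: PcorNetwork, out_dir: str | Path, prefix: str = "network") -> dict:
    """Write weight matrix CSV, edge-list TSV and GraphML; return the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "weights": out / f"{prefix}_weights.csv",
        "edges": out / f"{prefix}_edges.tsv",
        "graphml": out / f"{prefix}.graphml",
    }
    network.weights.to_csv(paths["weights"])
    network.edge_list().to_csv(paths["edges"], sep="\t", index=False)
    G = nx.Graph()
    for node in network.node_names:
        G.add_node(node, layer=network.layer_spec[node])
    for _, row in network.edge_list().iterrows():
        G.add_edge(row["node_i"], row["node_j"], weight=float(row["weight"]))
    nx.write_graphml(G, paths["graphml"])
    return {k: str(v) for k, v in paths.items()}


def read_weight_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        log.info("stage %s: start", name)
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc

    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write every artifact.

    Returns the analysis report (also written as ``report.json``).  Any
    stage failure raises :class:`PipelineError` before partial outputs are
    written: validation and estimation happen first, serialization last.
    """
    # ---- load + validate (no outputs written yet) ------------------------
    def _load() -> CohortTable:
        table = CohortTable.from_csv(config.cohort_path, config.layer_spec_path)
        if table.n <= len(table.node_names):
            log.warning("n <= p; estimates may be unstable")
        return table

    table = _stage("load")(_load)

    cov_spec = default_covariate_spec(table.layer_spec)
    model = MultilayerGGM(table, covariates=cov_spec, config=config.estimation)
    log.info(
        "estimate: gamma=%.2f n_lambdas=%d percentile=%.0f",
        config.estimation.gamma, config.estimation.n_lambdas, config.percentile,
    )
    results = _stage("estimate")(model.fit, percentile=config.percentile)
    network = results.network
    band, fraction = density_band(network)
    profile: BridgeProfile = results.bridge_profile
    inter_edges = _stage("bridge")(rank_interlayer_edges, network)

    stability_summary = None
    if config.run_stability:
        log.info("stability: n_boot=%d seed=%d", config.n_boot, config.seed)
        stab = _stage("stability")(
            results.stability,
            n_boot=config.n_boot,
            drop_grid=config.drop_grid,
            seed=config.seed,
        )
        csr = cs_coefficient(stab, config.r_threshold, config.prob)
        stability_summary = {
            "cs": csr.cs,
            "band": csr.band,
            "r_threshold": config.r_threshold,
            "prob": config.prob,
            "n_boot": config.n_boot,
            "seed": config.seed,
            "median_correlations": {
                f"{q:.2f}": (float(m) if np.isfinite(m) else None)
                for q, m in stab.median_correlations().items()
            },
            "skipped_proportions": list(stab.skipped),
        }

    layout = _stage("layout")(
        layout_fruchterman_reingold, network, seed=config.layout_seed
    )

    # ---- serialize -------------------------------------------------------
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifact_paths = _stage("write")(write_network, network, out)
    profile.to_frame(network.layer_spec).to_csv(out / "bridge_profile.tsv", sep="\t")
    layout.to_csv(out / "layout.tsv", sep="\t", index=False)
    if config.run_stability:
        stab.to_frame().to_csv(out / "stability_bootstrap.tsv", sep="\t", index=False)

    edges_intra = network.edge_list().query("kind == 'intra'")
    strongest_intra = (
        edges_intra.reindex(edges_intra["weight"].abs().sort_values(ascending=False).index)
        .head(5)
        .to_dict("records")
    )
    report = {
        "provenance": {
            "package": "bridgenet",
            "version": _pkg_version,
            "config_hash": config.content_hash(),
            "config": config.to_dict(),
        },
        "n_participants": int(network.n),
        "n_nodes": int(network.p),
        "layers": {
            layer: network.layer_spec.nodes_in(layer)
            for layer in network.layer_spec.layers
        },
        "selected_lambda": float(network.selected_lambda),
        "density": {
            "n_edges": int(network.n_edges),
            "n_possible": int(network.n_possible_edges),
            "fraction": float(fraction),
            "percent": round(100.0 * fraction, 1),
            "band": band,
        },
        "edge_summary": edge_summary(network),
        "bridge": {
            "percentile": config.percentile,
            "threshold_value": float(profile.threshold_value),
            "bridges": list(profile.bridges),
            "strengths": {n: float(s) for n, s in profile.strengths.items()},
        },
        "strongest_intralayer_edges": strongest_intra,
        "strongest_interlayer_edges": inter_edges.head(10).to_dict("records"),
        "stability": stability_summary,
        "artifacts": artifact_paths,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    log.info("report written to %s", out / "report.json")
    return report
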