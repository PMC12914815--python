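"""Model/Results interface tying the pipeline stages together.

:class:`MultilayerGGM` is constructed from cohort data plus a layer
partition; :meth:`MultilayerGGM.fit` residualizes the nodes on their
covariates, estimates the regularized partial-correlation network and
returns a :class:`MultilayerGGMResults` carrying the selected network, its
density, the bridge-strength profile and (on demand) the case-dropping
bootstrap stability of that profile.

Example
-------
>>> from bridgenet import MultilayerGGM, synthetic
>>> model_truth, cohort = synthetic.default_cohort(seed=7)
>>> res = MultilayerGGM.from_cohort(cohort).fit()
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import bridge as _bridge
from .association import AssociationMatrix
from .glasso import EstimationConfig, PcorNetwork, density_band, estimate_network
from .layers import CohortTable, CovariateSpec, LayerSpec, default_covariate_spec
from .preprocessing import residualize
from .stability import (
    DEFAULT_DROP_GRID,
    CSCoefficient,
    StabilityResult,
    case_drop_bootstrap,
    cs_coefficient,
)

__all__ = ["MultilayerGGM", "MultilayerGGMResults"]


class MultilayerGGM:
    """Regularized multilayer Gaussian graphical model of a cohort.

    Parameters
    ----------
    table
        Complete-case cohort data with covariates.
    covariates
        Covariate spec for residualization; defaults to age on all nodes
        plus TIV and site on the GMV layer.  Pass ``residualize=False`` to
        skip adjustment entirely (e.g. for pre-residualized data).
    config
        Estimation tuning (EBIC gamma, penalty path, tolerances).
    """

    def __init__(
        self,
        table: CohortTable,
        covariates: CovariateSpec | None = None,
        config: EstimationConfig | None = None,
        residualize: bool = True,
    ) -> None:
        self.table = table
        self.config = config or EstimationConfig()
        self.should_residualize = residualize
        if covariates is None and residualize:
            covariates = default_covariate_spec(table.layer_spec)
        self.covariates = covariates

    @classmethod
    def from_cohort(cls, table: CohortTable, **kwargs) -> "MultilayerGGM":
        return cls(table, **kwargs)

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        layers: Mapping[str, str],
        covariate_columns: tuple[str, ...] = ("age", "tiv", "site"),
        **kwargs,
    ) -> "MultilayerGGM":
        """Build from one flat DataFrame holding nodes and covariates."""
        spec = LayerSpec(layers)
        cov_cols = [c for c in covariate_columns if c in data.columns]
        table = CohortTable(
            values=data[spec.node_names],
            covariates=data[cov_cols],
            layer_spec=spec,
        )
        return cls(table, **kwargs)

    def fit(self, percentile: float = 80.0) -> "MultilayerGGMResults":
        """Residualize, estimate the network, and profile bridge strength."""
        if self.should_residualize and self.covariates is not None:
            working = residualize(self.table, self.covariates)
        else:
            working = self.table
        network = estimate_network(working, self.config)
        strengths = _bridge.bridge_strength(network)
        profile = _bridge.designate_bridges(strengths, percentile=percentile)
        return MultilayerGGMResults(
            model=self,
            working_table=working,
            network=network,
            bridge_profile=profile,
        )


@dataclass
class MultilayerGGMResults:
    """Fitted multilayer network with centrality and stability diagnostics."""

    model: MultilayerGGM
    working_table: CohortTable
    network: PcorNetwork
    bridge_profile: _bridge.BridgeProfile
    _stability: StabilityResult | None = field(default=None, repr=False)

    # -- convenience views -------------------------------------------------
    @property
    def weights(self) -> pd.DataFrame:
        return self.network.weights

    @property
    def association(self) -> AssociationMatrix | None:
        return self.network.association

    @property
    def density(self) -> float:
        return self.network.density

    @property
    def density_band(self) -> str:
        return self.network.band

    @property
    def selected_lambda(self) -> float:
        return self.network.selected_lambda

    @property
    def ebic_path(self) -> pd.DataFrame:
        return self.network.ebic_path

    @property
    def bridges(self) -> tuple[str, ...]:
        return self.bridge_profile.bridges

    def interlayer_edges(self) -> pd.DataFrame:
        return _bridge.rank_interlayer_edges(self.network)

    def edge_summary(self) -> dict:
        from .pipeline import edge_summary  # local import avoids a cycle

        return edge_summary(self.network)

    # -- stability ---------------------------------------------------------
    def stability(
        self,
        n_boot: int = 2000,
        drop_grid: tuple[float, ...] = DEFAULT_DROP_GRID,
        seed: int = 0,
        refit: bool = False,
    ) -> StabilityResult:
        """Case-dropping bootstrap of the bridge strengths (cached)."""
        if self._stability is None or refit:
            self._stability = case_drop_bootstrap(
                self.working_table,
                self.model.config,
                drop_grid=drop_grid,
                n_boot=n_boot,
                seed=seed,
            )
        return self._stability

    def cs(self, r_threshold: float = 0.70, prob: float = 0.95, **kwargs) -> CSCoefficient:
        return cs_coefficient(self.stability(**kwargs), r_threshold, prob)

    # -- presentation ------------------------------------------------------
    def layout(self, seed: int = 0, iterations: int = 100) -> pd.DataFrame:
        from .pipeline import layout_fruchterman_reingold

        return layout_fruchterman_reingold(self.network, seed=seed, iterations=iterations)

    def plot(self, ax=None, seed: int = 0):
        """Draw the network with a force-directed layout; bridges outlined."""
        import matplotlib.pyplot as plt
        import networkx as nx

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 7))
        spec = self.network.layer_spec
        G = nx.Graph()
        G.add_nodes_from(self.network.node_names)
        for _, row in self.network.edge_list().iterrows():
            G.add_edge(row["node_i"], row["node_j"], weight=abs(row["weight"]),
                       signed=row["weight"])
        pos = nx.spring_layout(G, weight="weight", seed=seed)
        palette = dict(zip(spec.layers, ["#4c72b0", "#dd8452", "#55a868", "#c44e52"]))
        colors = [palette.get(spec[n], "#888888") for n in G.nodes]
        edge_colors = ["#2166ac" if G.edges[e]["signed"] > 0 else "#b2182b" for e in G.edges]
        widths = [4 * G.edges[e]["weight"] for e in G.edges]
        nx.draw_networkx_edges(G, pos, ax=ax, edge_color=edge_colors, width=widths, alpha=0.7)
        nx.draw_networkx_nodes(
            G, pos, ax=ax, node_color=colors, node_size=700,
            edgecolors=["magenta" if n in self.bridges else "black" for n in G.nodes],
            linewidths=[2.5 if n in self.bridges else 0.8 for n in G.nodes],
        )
        nx.draw_networkx_labels(G, pos, ax=ax, font_size=8)
        ax.set_axis_off()
        return ax

    def summary(self) -> str:
        """Human-readable fit summary in the style of statistical model results."""
        net = self.network
        es = self.edge_summary()
        band, frac = density_band(net)
        lines = []
        rule = "=" * 64
        lines.append(rule)
        lines.append("Multilayer Gaussian Graphical Model Results".center(64))
        lines.append(rule)
        lines.append(f"{'No. participants:':<28}{net.n:>10}")
        lines.append(f"{'No. nodes:':<28}{net.p:>10}")
        lines.append(f"{'Layers:':<28}{', '.join(net.layer_spec.layers):>36}")
        lines.append(f"{'EBIC gamma:':<28}{self.model.config.gamma:>10.2f}")
        lines.append(f"{'Selected lambda:':<28}{net.selected_lambda:>10.4f}")
        lines.append(
            f"{'Edges (nonzero/possible):':<28}"
            f"{net.n_edges}/{net.n_possible_edges} ({100 * frac:.1f}%, {band})".rjust(10)
        )
        lines.append(
            f"{'Edge weights (all pairs):':<28}"
            f"mean {es['all_pairs']['mean']:.3f} (SD {es['all_pairs']['sd']:.3f}), "
            f"range [{es['all_pairs']['min']:.2f}, {es['all_pairs']['max']:.2f}]"
        )
        lines.append("-" * 64)
        lines.append("Bridge strength (80th-percentile rule)".center(64))
        lines.append("-" * 64)
        frame = self.bridge_profile.to_frame(net.layer_spec)
        for node, row in frame.sort_values("bridge_strength", ascending=False).iterrows():
            marker = "  *bridge*" if row["is_bridge"] else ""
            lines.append(
                f"  {node:<12}{row['layer']:<16}{row['bridge_strength']:>8.3f}{marker}"
            )
        lines.append(
            f"  threshold ({self.bridge_profile.percentile:.0f}th pct)"
            f"{self.bridge_profile.threshold_value:>22.3f}"
        )
        if self._stability is not None:
            csr = cs_coefficient(self._stability)
            lines.append("-" * 64)
            lines.append(
                f"  Bridge-strength stability: CS = {csr.cs:.2f} ({csr.band}; "
                f"{self._stability.n_boot} bootstraps)"
            )
        lines.append(rule)
        return "\n".join(lines)
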