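"""Bridge-strength centrality over a fixed layer partition.

Bridge strength of a node is the sum of the absolute weights of its edges
to nodes in *other* layers — its total interlayer connectivity.  Nodes whose
raw bridge strength lies strictly above the 80th percentile (linear
interpolation between closest ranks) are designated bridge nodes.  The
communities are the a-priori layers; no community detection is performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glasso import PcorNetwork
from .layers import LayerSpec

__all__ = [
    "BridgeProfile",
    "bridge_strength",
    "designate_bridges",
    "rank_interlayer_edges",
]


@dataclass
class BridgeProfile:
    """Per-node bridge strengths with the percentile threshold applied.

    ``strengths`` is ordered as the network's nodes; ``ranking`` is the same
    series sorted descending; ``bridges`` are the nodes strictly above
    ``threshold_value``, in descending strength order.
    """

    strengths: pd.Series
    threshold_value: float
    bridges: tuple[str, ...]
    percentile: float = 80.0

    @property
    def ranking(self) -> pd.Series:
        return self.strengths.sort_values(ascending=False, kind="stable")

    def to_frame(self, layer_spec: LayerSpec | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"bridge_strength": self.strengths})
        if layer_spec is not None:
            df.insert(0, "layer", [layer_spec[n] for n in df.index])
        df["rank"] = (
            df["bridge_strength"].rank(ascending=False, method="min").astype(int)
        )
        df["is_bridge"] = df.index.isin(self.bridges)
        return df


def bridge_strength(
    network: PcorNetwork, layer_spec: LayerSpec | None = None
) -> pd.Series:
    """Sum of |weight| over each node's interlayer edges.

    Nodes with no interlayer edges score exactly 0.
    """
    spec = layer_spec if layer_spec is not None else network.layer_spec
    nodes = network.node_names
    missing = [n for n in nodes if n not in spec]
    if missing:
        raise KeyError(f"nodes missing from the layer spec: {missing}")
    membership = np.array([spec[n] for n in nodes], dtype=object)
    W = np.abs(network.weights.to_numpy(dtype=float))
    W = np.where(W > network.edge_zero_tol, W, 0.0)
    inter = membership[:, None] != membership[None, :]
    strengths = (W * inter).sum(axis=1)
    return pd.Series(strengths, index=nodes, name="bridge_strength")


def designate_bridges(
    strengths: pd.Series | dict, percentile: float = 80.0
) -> BridgeProfile:
    """Threshold raw bridge strengths at the given percentile.

    The threshold is the linear-interpolation percentile of the raw scores;
    bridges are the nodes *strictly* above it, so an all-tied profile
    designates no bridges.
    """
    s = pd.Series(strengths, dtype=float)
    if s.empty:
        raise ValueError("cannot designate bridges from an empty strength map")
    if len(s) < 2:
        raise ValueError("bridge designation needs at least 2 nodes")
    threshold = float(np.percentile(s.to_numpy(), percentile))
    above = s[s > threshold].sort_values(ascending=False, kind="stable")
    return BridgeProfile(
        strengths=s,
        threshold_value=threshold,
        bridges=tuple(above.index),
        percentile=percentile,
    )


def rank_interlayer_edges(
    network: PcorNetwork, layer_spec: LayerSpec | None = None
) -> pd.DataFrame:
    """All nonzero interlayer edges sorted by |weight| descending.

    Ties break lexicographically on the (node_i, node_j) name pair.
    """
    spec = layer_spec if layer_spec is not None else network.layer_spec
    edges = network.edge_list()
    if edges.empty:
        return edges
    inter = edges[edges["kind"] == "inter"].copy()
    inter["abs_weight"] = inter["weight"].abs()
    inter = inter.sort_values(
        by=["abs_weight", "node_i", "node_j"],
        ascending=[False, True, True],
        kind="stable",
    ).drop(columns="abs_weight")
    return inter.reset_index(drop=True)
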