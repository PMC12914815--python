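"""Layer partitions, covariate specifications and the cohort table container.

A multilayer network partitions its variables (nodes) into named layers —
here typically mental health questionnaires, cognitive test scores and
regional gray-matter volumes.  The :class:`LayerSpec` holds that partition;
:class:`CohortTable` couples a participants-by-variables data matrix to it,
together with the nuisance covariates (age, total intracranial volume,
acquisition site) that are regressed out before network estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LayerSpec",
    "CovariateSpec",
    "CohortTable",
    "default_covariate_spec",
]


@dataclass(frozen=True)
class LayerSpec:
    """Assignment of every node to exactly one layer.

    Parameters
    ----------
    layer_of
        Ordered mapping ``node name -> layer label``.  Node order here is
        the canonical node order used by every downstream matrix.
    """

    layer_of: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "layer_of", dict(self.layer_of))
        if len(self.layer_of) == 0:
            raise ValueError("LayerSpec requires at least one node")
        if len(self.layers) < 2:
            raise ValueError(
                f"LayerSpec requires at least 2 layers, got {self.layers}"
            )

    @property
    def node_names(self) -> list[str]:
        return list(self.layer_of)

    @property
    def layers(self) -> list[str]:
        """Layer labels in first-appearance order."""
        seen: dict[str, None] = {}
        for layer in self.layer_of.values():
            seen.setdefault(layer, None)
        return list(seen)

    def nodes_in(self, layer: str) -> list[str]:
        return [n for n, l in self.layer_of.items() if l == layer]

    def __len__(self) -> int:
        return len(self.layer_of)

    def __contains__(self, node: str) -> bool:
        return node in self.layer_of

    def __getitem__(self, node: str) -> str:
        try:
            return self.layer_of[node]
        except KeyError:
            raise KeyError(f"node {node!r} has no layer assignment") from None

    def membership(self) -> np.ndarray:
        """Integer layer index per node, in node order."""
        index = {layer: i for i, layer in enumerate(self.layers)}
        return np.array([index[self.layer_of[n]] for n in self.node_names])

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {"layers": dict(self.layer_of)}

    @classmethod
    def from_dict(cls, data: Mapping) -> "LayerSpec":
        return cls(layer_of=data["layers"])

    def to_yaml(self, path: str | Path, ordinal: Iterable[str] = ()) -> None:
        payload = self.to_dict()
        payload["ordinal"] = sorted(ordinal)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LayerSpec":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data)


#: covariate columns treated as categorical and dummy-expanded in designs
CATEGORICAL_COVARIATES = frozenset({"site"})

#: covariate columns a cohort file may carry alongside the nodes
KNOWN_COVARIATE_COLUMNS = frozenset({"age", "tiv", "site"})


@dataclass(frozen=True)
class CovariateSpec:
    """Per-node sets of covariates to residualize on.

    ``covariates_of[node]`` lists covariate column names; names in
    :data:`CATEGORICAL_COVARIATES` are dummy-expanded (reference cell =
    first category in sorted order).
    """

    covariates_of: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "covariates_of",
            {n: tuple(c) for n, c in self.covariates_of.items()},
        )

    def __getitem__(self, node: str) -> tuple[str, ...]:
        return self.covariates_of.get(node, ())

    def validate(self, table: "CohortTable") -> None:
        available = set(table.covariates.columns)
        for node, covs in self.covariates_of.items():
            if node not in table.layer_spec:
                raise ValueError(f"covariate spec names unknown node {node!r}")
            missing = set(covs) - available
            if missing:
                raise ValueError(
                    f"covariates {sorted(missing)} for node {node!r} are not "
                    f"in the cohort table (have {sorted(available)})"
                )

    def to_dict(self) -> dict:
        return {"covariates": {n: list(c) for n, c in self.covariates_of.items()}}

    @classmethod
    def from_dict(cls, data: Mapping) -> "CovariateSpec":
        return cls(covariates_of={n: tuple(c) for n, c in data["covariates"].items()})


def default_covariate_spec(
    layer_spec: LayerSpec, gmv_layer: str = "gmv"
) -> CovariateSpec:
    """Age removed from every node; TIV and site additionally from GMV nodes."""
    covs = {}
    for node in layer_spec.node_names:
        if layer_spec[node] == gmv_layer:
            covs[node] = ("age", "tiv", "site")
        else:
            covs[node] = ("age",)
    return CovariateSpec(covs)


@dataclass
class CohortTable:
    """Complete-case participants-by-variables data with covariates.

    Attributes
    ----------
    values
        DataFrame of shape ``(n, p)`` whose columns are exactly the layer
        spec's nodes, in order.
    covariates
        DataFrame aligned on the same index; typically columns
        ``age`` (years), ``tiv`` (mm^3) and ``site`` (categorical label).
    layer_spec
        The node-to-layer partition.
    ordinal
        Optional set of node names known to be ordinal questionnaire-style
        scores (small-integer levels).
    """

    values: pd.DataFrame
    covariates: pd.DataFrame
    layer_spec: LayerSpec
    ordinal: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values)
        self.covariates = pd.DataFrame(self.covariates, index=self.values.index)
        self.ordinal = frozenset(self.ordinal)
        expected = self.layer_spec.node_names
        if list(self.values.columns) != expected:
            missing = set(expected) - set(self.values.columns)
            if missing:
                raise ValueError(f"cohort table is missing nodes {sorted(missing)}")
            self.values = self.values[expected]
        if self.values.isna().any().any():
            raise ValueError("cohort table contains missing values; complete cases required")
        numeric_covs = self.covariates.drop(
            columns=[c for c in self.covariates.columns if c in CATEGORICAL_COVARIATES],
            errors="ignore",
        )
        if numeric_covs.isna().any().any():
            raise ValueError("covariates contain missing values")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def node_names(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, rows: Sequence[int] | np.ndarray) -> "CohortTable":
        """Row subsample (positional indices), preserving metadata."""
        return CohortTable(
            values=self.values.iloc[list(rows)].reset_index(drop=True),
            covariates=self.covariates.iloc[list(rows)].reset_index(drop=True),
            layer_spec=self.layer_spec,
            ordinal=self.ordinal,
        )

    # -- serialization -----------------------------------------------------
    def to_csv(self, path: str | Path, sidecar: str | Path | None = None, sep: str = "\t") -> None:
        """Write the table as delimited text plus a layer-spec sidecar."""
        df = pd.concat([self.values, self.covariates], axis=1)
        df.to_csv(path, sep=sep, index=False)
        if sidecar is not None:
            self.layer_spec.to_yaml(sidecar, ordinal=self.ordinal)

    @classmethod
    def from_csv(cls, path: str | Path, sidecar: str | Path, sep: str = "\t") -> "CohortTable":
        data = yaml.safe_load(Path(sidecar).read_text())
        spec = LayerSpec.from_dict(data)
        ordinal = frozenset(data.get("ordinal", ()))
        df = pd.read_csv(path, sep=sep)
        missing = set(spec.node_names) - set(df.columns)
        if missing:
            raise ValueError(f"cohort file lacks node columns {sorted(missing)}")
        cov_cols = [c for c in df.columns if c not in spec.layer_of]
        unknown = set(cov_cols) - KNOWN_COVARIATE_COLUMNS
        if unknown:
            raise ValueError(
                f"columns {sorted(unknown)} are neither nodes in the layer spec "
                f"nor recognised covariates {sorted(KNOWN_COVARIATE_COLUMNS)}; "
                "is the layer spec missing a node?"
            )
        return cls(
            values=df[spec.node_names],
            covariates=df[cov_cols],
            layer_spec=spec,
            ordinal=ordinal,
        )
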