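"""Case-dropping bootstrap stability of bridge-strength centrality.

Centrality orderings estimated from a single sample can be fragile.  The
case-dropping bootstrap quantifies this: repeatedly drop a proportion of
participants, re-estimate the network and the bridge strengths on the
subsample, and correlate them with the full-sample strengths.  The
correlation-stability (CS) coefficient is the largest drop proportion at
which, with the required probability (default 95%), that correlation stays
at or above a threshold (default 0.70).  Interpretive bands follow the
convention: CS >= 0.50 stable, 0.25 <= CS < 0.50 interpret with caution,
CS < 0.25 not interpretable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bridge import bridge_strength
from .glasso import EstimationConfig, estimate_network
from .layers import CohortTable

__all__ = [
    "StabilityResult",
    "CSCoefficient",
    "DEFAULT_DROP_GRID",
    "case_drop_bootstrap",
    "cs_coefficient",
    "cs_band",
]

#: default case-dropping proportions, 5% to 75% in 5% steps
DEFAULT_DROP_GRID = tuple(np.round(np.arange(0.05, 0.751, 0.05), 2))

#: CS interpretive cutoffs
CS_STABLE = 0.50
CS_CAUTION = 0.25


@dataclass(frozen=True)
class CSCoefficient:
    """A CS value with its interpretive band and the rule that produced it."""

    cs: float
    band: str
    r_threshold: float = 0.70
    prob: float = 0.95


@dataclass
class StabilityResult:
    """Bootstrap correlation distributions per drop proportion."""

    drop_grid: tuple[float, ...]
    correlations: dict[float, np.ndarray]  # may contain NaN (degenerate reps)
    full_strengths: pd.Series
    n_boot: int
    seed: int
    skipped: tuple[float, ...] = ()

    def valid_correlations(self, proportion: float) -> np.ndarray:
        r = np.asarray(self.correlations[proportion], dtype=float)
        return r[~np.isnan(r)]

    def median_correlations(self) -> pd.Series:
        meds = {
            q: (np.median(v) if (v := self.valid_correlations(q)).size else np.nan)
            for q in self.drop_grid
        }
        return pd.Series(meds, name="median_correlation")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"proportion": q, "replicate": i, "correlation": r}
            for q in self.drop_grid
            for i, r in enumerate(self.correlations[q])
        ]
        return pd.DataFrame(rows, columns=["proportion", "replicate", "correlation"])


def _strength_correlation(full: np.ndarray, sub: np.ndarray) -> float:
    """Pearson correlation; NaN when either vector is constant."""
    if np.std(full) == 0.0 or np.std(sub) == 0.0:
        return float("nan")
    return float(np.corrcoef(full, sub)[0, 1])


def case_drop_bootstrap(
    table: CohortTable,
    config: EstimationConfig | None = None,
    drop_grid: tuple[float, ...] = DEFAULT_DROP_GRID,
    n_boot: int = 2000,
    seed: int = 0,
) -> StabilityResult:
    """Bootstrap bridge-strength correlations under case dropping.

    Each replicate samples one drop proportion from the grid, subsamples
    participants without replacement, reruns network estimation and bridge
    strength, and records the Pearson correlation of the subsample strengths
    with the full-sample ones.  Grid points whose subsample would retain
    fewer than p + 3 participants are skipped with a warning.  Fully
    deterministic for a given seed.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    cfg = config or EstimationConfig()
    p = len(table.node_names)

    full_net = estimate_network(table, cfg)
    full = bridge_strength(full_net)
    full_vec = full.to_numpy()

    valid, skipped = [], []
    for q in drop_grid:
        keep = table.n - int(round(table.n * q))
        (valid if keep > p + 2 else skipped).append(float(q))
    if skipped:
        warnings.warn(
            f"drop proportions {skipped} leave too few participants "
            f"(need > p + 2 = {p + 2}); skipped",
            stacklevel=2,
        )
    if not valid:
        raise ValueError("every drop proportion leaves too few participants")

    rng = np.random.default_rng(seed)
    correlations: dict[float, list[float]] = {q: [] for q in valid}
    for _ in range(n_boot):
        q = valid[int(rng.integers(len(valid)))]
        keep = table.n - int(round(table.n * q))
        rows = rng.choice(table.n, size=keep, replace=False)
        sub = table.subset(rows)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                net = estimate_network(sub, cfg)
                sub_strengths = bridge_strength(net).to_numpy()
                r = _strength_correlation(full_vec, sub_strengths)
            except (RuntimeError, ValueError):
                r = float("nan")  # degenerate subsample; excluded from tallies
        correlations[q].append(r)

    return StabilityResult(
        drop_grid=tuple(valid),
        correlations={q: np.asarray(v, dtype=float) for q, v in correlations.items()},
        full_strengths=full,
        n_boot=n_boot,
        seed=seed,
        skipped=tuple(skipped),
    )


def cs_band(cs: float) -> str:
    if cs >= CS_STABLE:
        return "stable"
    if cs >= CS_CAUTION:
        return "caution"
    return "uninterpretable"


def cs_coefficient(
    result: StabilityResult, r_threshold: float = 0.70, prob: float = 0.95
) -> CSCoefficient:
    """Correlation-stability coefficient of a bootstrap result.

    CS is the largest drop proportion q such that every grid proportion up
    to and including q keeps at least ``prob`` of its (valid) bootstrap
    correlations at or above ``r_threshold``; 0 if the smallest proportion
    already fails.  Requiring all smaller proportions to pass prevents
    non-monotone sampling flukes from inflating CS.
    """
    if not result.drop_grid:
        raise ValueError("empty stability result")
    cs = 0.0
    for q in sorted(result.drop_grid):
        r = result.valid_correlations(q)
        if r.size == 0:
            break
        if np.mean(r >= r_threshold) >= prob:
            cs = float(q)
        else:
            break
    return CSCoefficient(cs=cs, band=cs_band(cs), r_threshold=r_threshold, prob=prob)
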