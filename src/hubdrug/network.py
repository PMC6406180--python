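"""Variance filtering and weighted co-expression network construction.

Genes are ranked by their standard deviation across samples and only those
strictly above a chosen percentile of the SD distribution are kept (a
stringent filter concentrating on the most variable genes). The retained
genes form a complete weighted graph whose raw edge values are pairwise
Pearson correlations; nonnegative edge weights are obtained by taking
either |r| (default) or r^2, and a node's weighted degree is the sum of
its incident edge weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hubdrug.errors import EmptySelectionError

TRANSFORMS = ("abs", "squared")


@dataclass
class CorrelationNetwork:
    """Complete weighted gene-gene correlation network.

    ``raw_corr`` holds signed Pearson correlations (symmetric, unit
    diagonal); ``weights`` is the nonnegative transform of it with a zeroed
    diagonal, so degree sums never count self-loops.
    """

    node_ids: list[str]
    raw_corr: np.ndarray
    transform: str = "abs"
    weights: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ValueError(f"transform must be one of {TRANSFORMS}, got {self.transform!r}")
        r = np.asarray(self.raw_corr, dtype=float)
        n = len(self.node_ids)
        if r.shape != (n, n):
            raise ValueError(f"raw_corr shape {r.shape} does not match {n} nodes")
        if not np.allclose(r, r.T, atol=1e-12):
            raise ValueError("raw_corr must be symmetric (within 1e-12)")
        if np.any(np.abs(r) > 1 + 1e-12):
            raise ValueError("raw_corr entries must lie in [-1, 1]")
        self.raw_corr = r
        w = np.abs(r) if self.transform == "abs" else r * r
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def edge_weights(self) -> np.ndarray:
        """Off-diagonal weight multiset (upper triangle, row-major)."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return self.weights[iu]


def variance_filter(
    expr: pd.DataFrame,
    percentile: float = 99.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep genes whose SD lies strictly above a percentile threshold.

    The threshold is the linear-interpolation percentile of the full
    per-gene SD distribution (n-1 denominator); selection is strict
    (``sd > threshold``), so ties at the threshold are excluded.

    Returns
    -------
    (variability, filtered)
        ``variability``: one row per input gene with columns
        ``gene_id, sd, percentile, threshold, selected``;
        ``filtered``: the selected sub-matrix in original gene order.
    """
    if not (0 <= percentile < 100):
        raise ValueError("percentile must lie in [0, 100)")
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 samples to compute an SD")
    if expr.shape[0] < 2:
        raise ValueError("need at least 2 genes to define an SD distribution")

    sd = expr.to_numpy(dtype=float).std(axis=1, ddof=1)
    threshold = float(np.percentile(sd, percentile, method="linear"))
    selected = sd > threshold
    variability = pd.DataFrame({
        "gene_id": expr.index,
        "sd": sd,
        "percentile": percentile,
        "threshold": threshold,
        "selected": selected,
    })
    if not selected.any():
        raise EmptySelectionError(
            f"no gene has SD strictly above the {percentile} percentile "
            f"threshold ({threshold:.6g})"
        )
    return variability, expr.loc[selected]


def build_network(expr: pd.DataFrame, transform: str = "abs") -> CorrelationNetwork:
    """Pearson-correlate all gene pairs into a complete weighted network."""
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples for meaningful correlations")
    values = expr.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        bad = [expr.index[i] for i in zero]
        raise ValueError(f"zero-variance genes have undefined correlations: {bad}")
    r = np.corrcoef(values)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationNetwork(node_ids=list(expr.index), raw_corr=r, transform=transform)


def weighted_degree(net: CorrelationNetwork) -> pd.Series:
    """Weighted degree per node: sum of incident edge weights (no self-loops)."""
    if net.n_nodes < 2:
        raise ValueError("network must have at least 2 nodes")
    deg = net.weights.sum(axis=1)
    return pd.Series(deg, index=net.node_ids, name="weighted_degree")
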