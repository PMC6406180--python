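"""Agreement metrics between predicted and observed drug sensitivity.

The headline metric is the concordance index (CI): the probability that,
for a random pair of experiments, the predicted ordering of sensitivities
matches the observed ordering. It is computed as rescaled Kendall tau,
``(tau + 1) / 2``, so 0.5 is chance and 1 a perfect ranking. When the
observed scale is inverse to the predicted one (log-IC50 vs. activity
area: lower observed = more sensitive), the adapted orientation
``(1 - tau) / 2`` counts a high prediction paired with a low observation
as concordant. Approximate 95% intervals come from Fisher's
transformation of tau with the Fieller-Hartley-Pearson variance
0.437 / (n - 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

_TAU_VARIANCE_NUM = 0.437  # Fieller-Hartley-Pearson approximation for Kendall tau
_Z95 = 1.959963984540054


@dataclass
class CIResult:
    """Concordance index with its underlying Kendall tau and 95% interval."""

    tau: float
    ci: float
    orientation: str
    n: int
    interval_95: tuple[float, float]


def _check_pair(pred, obs, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    if p.shape != o.shape or p.ndim != 1:
        raise ValueError("pred and obs must be 1-D vectors of equal length")
    if p.size < min_n:
        raise ValueError(f"need at least {min_n} paired values, got {p.size}")
    if np.ptp(p) == 0:
        raise ValueError("predictions are constant; rank correlation is undefined")
    if np.ptp(o) == 0:
        raise ValueError("observations are constant; rank correlation is undefined")
    return p, o


def _rescale(tau: float, orientation: str) -> float:
    if orientation == "direct":
        return (tau + 1.0) / 2.0
    if orientation == "inverse":
        return (1.0 - tau) / 2.0
    raise ValueError(f"orientation must be 'direct' or 'inverse', got {orientation!r}")


def concordance_index(pred, obs, orientation: str = "direct") -> CIResult:
    """Rescaled-Kendall concordance index with Fisher-transform interval.

    Kendall tau is the tie-corrected tau-b (identical to tau-a on
    tie-free data); the interval maps a symmetric interval on
    ``atanh(tau)`` through the orientation rescaling, clipped to [0, 1].
    """
    p, o = _check_pair(pred, obs)
    n = p.size
    tau = float(stats.kendalltau(p, o).statistic)
    ci = _rescale(tau, orientation)

    se = np.sqrt(_TAU_VARIANCE_NUM / (n - 2))
    z = np.arctanh(np.clip(tau, -1 + 1e-15, 1 - 1e-15))
    tau_lo, tau_hi = np.tanh(z - _Z95 * se), np.tanh(z + _Z95 * se)
    bounds = sorted((_rescale(tau_lo, orientation), _rescale(tau_hi, orientation)))
    lo = float(np.clip(min(bounds[0], ci), 0.0, 1.0))
    hi = float(np.clip(max(bounds[1], ci), 0.0, 1.0))
    return CIResult(tau=tau, ci=ci, orientation=orientation, n=n, interval_95=(lo, hi))


def correlation_metrics(pred, obs) -> tuple[float, float, float]:
    """(Pearson r, Spearman rho, Kendall tau-b) between two vectors."""
    p, o = _check_pair(pred, obs)
    pearson = float(stats.pearsonr(p, o).statistic)
    spearman = float(stats.spearmanr(p, o).statistic)
    kendall = float(stats.kendalltau(p, o).statistic)
    return pearson, spearman, kendall


def _metrics_row(pred: np.ndarray, obs: np.ndarray, orientation: str) -> dict:
    pearson, spearman, kendall = correlation_metrics(pred, obs)
    ci = concordance_index(pred, obs, orientation)
    return {
        "pearson": pearson, "spearman": spearman, "kendall": kendall,
        "ci": ci.ci, "ci_lo": ci.interval_95[0], "ci_hi": ci.interval_95[1],
        "n": len(pred),
    }


def evaluate_per_drug(
    pred: pd.DataFrame,
    sens: pd.DataFrame,
    orientation: str = "direct",
    min_records: int = 3,
) -> pd.DataFrame:
    """Pooled and per-drug agreement between a prediction table and records.

    ``pred`` has samples in rows and drugs in columns; ``sens`` is the
    long-format observed table. Drugs with fewer than ``min_records``
    matched records are omitted (with a warning). The returned frame has
    one row per evaluable drug plus an ``overall`` row pooling all matched
    records, with columns ``pearson, spearman, kendall, ci, ci_lo, ci_hi, n``.
    """
    long_pred = pred.rename_axis("cell_line").reset_index().melt(
        id_vars="cell_line", var_name="drug", value_name="predicted"
    )
    merged = sens.merge(long_pred, on=["cell_line", "drug"], how="inner")
    if merged.empty:
        raise ValueError("prediction table and sensitivity records do not overlap")

    rows = {}
    skipped = 0
    for drug, grp in merged.groupby("drug", sort=True):
        if len(grp) < min_records:
            skipped += 1
            continue
        rows[drug] = _metrics_row(grp["predicted"].to_numpy(),
                                  grp["value"].to_numpy(), orientation)
    if skipped:
        warnings.warn(f"{skipped} drug(s) had fewer than {min_records} matched "
                      "records and were omitted", stacklevel=2)
    rows["overall"] = _metrics_row(merged["predicted"].to_numpy(),
                                   merged["value"].to_numpy(), orientation)
    report = pd.DataFrame.from_dict(rows, orient="index")
    report.index.name = "drug"
    return report


def gene_sensitivity_correlations(expr: pd.DataFrame, sens: pd.DataFrame) -> pd.Series:
    """Per-gene Pearson correlation with sensitivity, pooled over records.

    Each gene's expression is replicated across all of a cell line's drug
    records before correlating, so genes are scored against the full pool
    of cell line-drug experiments. Constant genes yield NaN.
    """
    unknown = set(sens["cell_line"]) - set(expr.columns)
    if unknown:
        raise ValueError(f"sensitivity cell lines absent from expression: {sorted(unknown)}")
    X = expr[sens["cell_line"]].to_numpy(dtype=float)   # genes x records
    y = sens["value"].to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    num = Xc @ yc
    den = np.sqrt((Xc * Xc).sum(axis=1) * (yc @ yc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, np.nan)
    return pd.Series(r, index=expr.index, name="r_sensitivity")


def hub_vs_nonhub_test(
    gene_corrs: pd.Series,
    hub_ids,
) -> tuple[float, float, float, float]:
    """Two-sample Student's t-test of expression-sensitivity correlations.

    Compares the per-gene correlation values of hubs against all other
    genes (pooled-variance, two-tailed). Returns
    (mean_hub, mean_nonhub, t, p_two_tailed).
    """
    hub_ids = set(hub_ids)
    corrs = gene_corrs.dropna()
    hub = corrs[corrs.index.isin(hub_ids)]
    nonhub = corrs[~corrs.index.isin(hub_ids)]
    if len(hub) < 2 or len(nonhub) < 2:
        raise ValueError("each group needs at least 2 genes with defined correlations")
    if hub.var(ddof=1) == 0 and nonhub.var(ddof=1) == 0 and hub.mean() == nonhub.mean():
        return float(hub.mean()), float(nonhub.mean()), 0.0, 1.0
    res = stats.ttest_ind(hub, nonhub, equal_var=True)
    return float(hub.mean()), float(nonhub.mean()), float(res.statistic), float(res.pvalue)


def extreme_response_auc(
    pred: pd.DataFrame,
    sens: pd.DataFrame,
    z_threshold: float = 0.8,
) -> pd.Series:
    """Per-drug AUC for separating extreme responders by predicted score.

    Within each drug the observed values are z-scored; samples are labeled
    sensitive (z > threshold) or resistant (z < -threshold), intermediates
    are dropped, and the AUC is the probability that a random sensitive
    sample receives a higher predicted score than a random resistant one
    (rank/Mann-Whitney computation; cross-class ties count 0.5). Drugs
    lacking either class after filtering are skipped with a warning.
    """
    long_pred = pred.rename_axis("cell_line").reset_index().melt(
        id_vars="cell_line", var_name="drug", value_name="predicted"
    )
    merged = sens.merge(long_pred, on=["cell_line", "drug"], how="inner")
    if merged.empty:
        raise ValueError("prediction table and sensitivity records do not overlap")

    aucs = {}
    skipped = []
    for drug, grp in merged.groupby("drug", sort=True):
        v = grp["value"].to_numpy(dtype=float)
        if len(v) < 4 or np.ptp(v) == 0:
            skipped.append(drug)
            continue
        z = (v - v.mean()) / v.std(ddof=1)
        sensitive = z > z_threshold
        resistant = z < -z_threshold
        n1, n0 = int(sensitive.sum()), int(resistant.sum())
        if n1 == 0 or n0 == 0:
            skipped.append(drug)
            continue
        scores = grp["predicted"].to_numpy(dtype=float)[sensitive | resistant]
        labels = sensitive[sensitive | resistant]
        ranks = stats.rankdata(scores)
        u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
        aucs[drug] = u / (n1 * n0)
    if skipped:
        warnings.warn(f"drugs skipped in extreme-response AUC (missing a class "
                      f"or too few records): {skipped}", stacklevel=2)
    return pd.Series(aucs, name="auc", dtype=float)


def cross_platform_concordance(
    exprA: pd.DataFrame,
    exprB: pd.DataFrame,
) -> tuple[pd.Series, float, tuple[float, float]]:
    """Per-gene Spearman correlation between two platforms' profiles.

    Shared genes and samples are intersected (in A's order); returns the
    per-gene correlations, their mean, and an approximate 95% interval of
    the mean obtained on the Fisher-z scale.
    """
    genes = [g for g in exprA.index if g in set(exprB.index)]
    samples = [s for s in exprA.columns if s in set(exprB.columns)]
    if not genes or len(samples) < 3:
        raise ValueError("platforms share no usable genes/samples")
    A = exprA.loc[genes, samples].to_numpy(dtype=float)
    B = exprB.loc[genes, samples].to_numpy(dtype=float)
    rA = stats.rankdata(A, axis=1)
    rB = stats.rankdata(B, axis=1)
    rAc = rA - rA.mean(axis=1, keepdims=True)
    rBc = rB - rB.mean(axis=1, keepdims=True)
    num = (rAc * rBc).sum(axis=1)
    den = np.sqrt((rAc * rAc).sum(axis=1) * (rBc * rBc).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(den > 0, num / den, np.nan)
    per_gene = pd.Series(rho, index=genes, name="spearman")

    vals = per_gene.dropna().to_numpy()
    z = np.arctanh(np.clip(vals, -1 + 1e-15, 1 - 1e-15))
    mean_rho = float(vals.mean())
    if len(vals) > 1:
        se = z.std(ddof=1) / np.sqrt(len(z))
        lo, hi = np.tanh(z.mean() - _Z95 * se), np.tanh(z.mean() + _Z95 * se)
    else:
        lo = hi = float(np.tanh(z.mean()))
    return per_gene, mean_rho, (float(lo), float(hi))
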