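"""Ridge drug-sensitivity model on standardized hub expression.

Each training row is one cell line-drug experiment, represented by the
z-scored expression of the hub genes plus a one-hot drug-identity block,
with the observed activity area (AA) as target. A single pooled linear
model with a tiny ridge penalty (default 1e-8, effectively ordinary least
squares but robust to collinearity among co-expressed hubs) is fitted by
the penalized normal equations with an unpenalized intercept.

Cross-validation (k-fold or leave-one-out) produces out-of-fold
predictions for unbiased evaluation. A drug-stratified nested-CV lasso
comparator is provided for sparse-model baselines.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.linear_model import Lasso

from hubdrug.synthetic import AA_MEASURE

_SCHEMA_VERSION = 1
DEFAULT_RIDGE = 1e-8


@dataclass
class ScalingParams:
    """Per-gene mean/SD used for z-score standardization."""

    mean: pd.Series
    sd: pd.Series

    def __post_init__(self) -> None:
        if (self.sd <= 0).any():
            bad = list(self.sd.index[self.sd <= 0])
            raise ValueError(f"standardization requires positive SDs; offending genes: {bad}")


def standardize_expression(
    expr: pd.DataFrame,
    params: ScalingParams | None = None,
) -> tuple[pd.DataFrame, ScalingParams]:
    """Z-score each gene across samples (n-1 SD).

    With ``params`` supplied, those fitted means/SDs are applied instead
    (scoring new data on the training scale).
    """
    if params is None:
        mean = expr.mean(axis=1)
        sd = expr.std(axis=1, ddof=1)
        zero = sd[sd == 0]
        if len(zero):
            raise ValueError(
                f"cannot standardize zero-variance genes: {list(zero.index)}"
            )
        params = ScalingParams(mean=mean, sd=sd)
    missing = [g for g in expr.index if g not in params.mean.index]
    if missing:
        raise ValueError(f"no scaling parameters for genes: {missing}")
    mu = params.mean.reindex(expr.index)
    sigma = params.sd.reindex(expr.index)
    z = expr.sub(mu, axis=0).div(sigma, axis=0)
    return z, params


@dataclass
class FeatureTable:
    """Design matrix for the pooled sensitivity model.

    Columns are ordered genes-then-drugs: k standardized hub-expression
    features followed by one indicator per drug in ``drugs`` (each row's
    indicators sum to 1). Rows correspond 1:1 to ``keys`` records.
    """

    keys: pd.DataFrame            # columns cell_line, drug
    X: np.ndarray                 # rows x (k + n_drugs)
    y: np.ndarray
    genes: list[str]
    drugs: list[str]
    n_excluded_incomplete: int = 0
    n_rejected_unknown_drug: int = 0

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    def column_names(self) -> list[str]:
        return list(self.genes) + [f"drug:{d}" for d in self.drugs]


def assemble_features(
    expr_std: pd.DataFrame,
    sens: pd.DataFrame,
    hub_genes: list[str],
    drug_vocab: list[str],
    require_measure: str | None = AA_MEASURE,
) -> FeatureTable:
    """Join standardized hub expression with sensitivity records.

    Keeps one row per record whose cell line has complete expression for
    every hub gene; records with drugs outside ``drug_vocab`` are rejected
    (count reported on the returned table).
    """
    missing = [g for g in hub_genes if g not in expr_std.index]
    if missing:
        raise ValueError(f"hub genes absent from expression matrix: {missing}")
    if require_measure is not None and not (sens["measure"] == require_measure).all():
        raise ValueError(f"sensitivity table must carry the {require_measure} measure")

    hub = expr_std.loc[hub_genes]
    complete_cells = set(hub.columns[hub.notna().all(axis=0)])

    in_vocab = sens["drug"].isin(drug_vocab)
    n_rejected = int((~in_vocab).sum())
    records = sens[in_vocab]
    has_expr = records["cell_line"].isin(complete_cells)
    n_excluded = int((~has_expr).sum())
    records = records[has_expr].reset_index(drop=True)
    if records.empty:
        raise ValueError("no sensitivity record overlaps the expression matrix")

    Xg = hub[records["cell_line"]].to_numpy(dtype=float).T  # rows x k
    drug_idx = pd.Categorical(records["drug"], categories=drug_vocab).codes
    Xd = np.zeros((len(records), len(drug_vocab)))
    Xd[np.arange(len(records)), drug_idx] = 1.0

    return FeatureTable(
        keys=records[["cell_line", "drug"]].copy(),
        X=np.hstack([Xg, Xd]),
        y=records["value"].to_numpy(dtype=float),
        genes=list(hub_genes),
        drugs=list(drug_vocab),
        n_excluded_incomplete=n_excluded,
        n_rejected_unknown_drug=n_rejected,
    )


@dataclass
class FittedModel:
    """A trained pooled ridge model, sufficient to score new samples."""

    genes: list[str]
    drugs: list[str]
    scaling: ScalingParams | None
    intercept: float
    gene_coefs: np.ndarray
    drug_coefs: np.ndarray
    ridge_lambda: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.gene_coefs) != len(self.genes):
            raise ValueError("gene coefficient length does not match gene order")
        if len(self.drug_coefs) != len(self.drugs):
            raise ValueError("drug coefficient length does not match drug vocabulary")

    def coef_vector(self) -> np.ndarray:
        return np.concatenate([self.gene_coefs, self.drug_coefs])

    # --- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema_version": _SCHEMA_VERSION,
            "genes": list(self.genes),
            "drugs": list(self.drugs),
            "scaling": None if self.scaling is None else {
                "mean": {g: float(v) for g, v in self.scaling.mean.items()},
                "sd": {g: float(v) for g, v in self.scaling.sd.items()},
            },
            "intercept": float(self.intercept),
            "gene_coefs": [float(v) for v in self.gene_coefs],
            "drug_coefs": [float(v) for v in self.drug_coefs],
            "ridge_lambda": float(self.ridge_lambda),
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        if d.get("schema_version") != _SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema: {d.get('schema_version')}")
        scaling = None
        if d["scaling"] is not None:
            scaling = ScalingParams(
                mean=pd.Series(d["scaling"]["mean"]),
                sd=pd.Series(d["scaling"]["sd"]),
            )
        return cls(
            genes=list(d["genes"]),
            drugs=list(d["drugs"]),
            scaling=scaling,
            intercept=float(d["intercept"]),
            gene_coefs=np.asarray(d["gene_coefs"], dtype=float),
            drug_coefs=np.asarray(d["drug_coefs"], dtype=float),
            ridge_lambda=float(d["ridge_lambda"]),
            meta=dict(d.get("meta", {})),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FittedModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _ridge_solve(X: np.ndarray, y: np.ndarray, lam: float) -> tuple[float, np.ndarray]:
    """Penalized normal equations on centered data; intercept unpenalized."""
    if lam < 0:
        raise ValueError("ridge penalty must be >= 0")
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean
    G = Xc.T @ Xc + lam * np.eye(X.shape[1])
    b = Xc.T @ yc
    try:
        beta = scipy.linalg.solve(G, b, assume_a="sym")
    except scipy.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular normal equations (collinear columns at lambda = 0); "
            "use a positive ridge penalty"
        ) from exc
    resid = np.linalg.norm(G @ beta - b)
    scale = max(1.0, np.linalg.norm(b))
    if not np.isfinite(beta).all() or resid > 1e-8 * scale:
        raise np.linalg.LinAlgError(
            "normal equations could not be solved to tolerance; "
            "the design is likely collinear — use a positive ridge penalty"
        )
    intercept = y_mean - x_mean @ beta
    return float(intercept), beta


def fit_ridge(
    features: FeatureTable,
    ridge_lambda: float = DEFAULT_RIDGE,
    scaling: ScalingParams | None = None,
    meta: dict | None = None,
) -> FittedModel:
    """Fit the pooled ridge model minimizing ||y - b0 - Xb||^2 + lam ||b||^2."""
    intercept, beta = _ridge_solve(features.X, features.y, ridge_lambda)
    k = len(features.genes)
    m = dict(meta or {})
    m.setdefault("n_rows", features.n_rows)
    return FittedModel(
        genes=features.genes,
        drugs=features.drugs,
        scaling=scaling,
        intercept=intercept,
        gene_coefs=beta[:k],
        drug_coefs=beta[k:],
        ridge_lambda=ridge_lambda,
        meta=m,
    )


def fit_sensitivity_model(
    expr: pd.DataFrame,
    sens: pd.DataFrame,
    hub_genes: list[str],
    drug_vocab: list[str] | None = None,
    ridge_lambda: float = DEFAULT_RIDGE,
) -> FittedModel:
    """Standardize, assemble features and fit in one step (training entry point)."""
    if drug_vocab is None:
        drug_vocab = sorted(sens["drug"].unique())
    expr_std, scaling = standardize_expression(expr.loc[hub_genes])
    features = assemble_features(expr_std, sens, hub_genes, drug_vocab)
    return fit_ridge(features, ridge_lambda, scaling=scaling,
                     meta={"n_rows": features.n_rows,
                           "excluded_incomplete": features.n_excluded_incomplete})


def predict_sensitivity(
    model: FittedModel,
    expr: pd.DataFrame,
    drugs: list[str] | None = None,
    rescale: bool = False,
) -> pd.DataFrame:
    """Score every sample against every requested drug.

    ``rescale=True`` z-scores the input from its own per-gene distribution
    (for expression data on a different scale than the training panel);
    otherwise the model's stored scaling parameters are applied.

    Returns the prediction table with samples in rows and drugs in columns.
    """
    if drugs is None:
        drugs = list(model.drugs)
    unknown = [d for d in drugs if d not in model.drugs]
    if unknown:
        raise ValueError(f"drugs outside the model vocabulary: {unknown}")
    missing = [g for g in model.genes if g not in expr.index]
    if missing:
        raise ValueError(f"expression matrix is missing model genes: {missing}")

    hub = expr.loc[model.genes]
    if rescale:
        z, _ = standardize_expression(hub)
    else:
        if model.scaling is None:
            raise ValueError("model carries no scaling parameters; use rescale=True")
        z, _ = standardize_expression(hub, model.scaling)

    base = model.intercept + z.to_numpy(dtype=float).T @ model.gene_coefs
    drug_pos = {d: i for i, d in enumerate(model.drugs)}
    cols = {d: base + model.drug_coefs[drug_pos[d]] for d in drugs}
    return pd.DataFrame(cols, index=list(expr.columns))[list(drugs)]


def _fold_assignment(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random permutation chunked into k near-equal folds."""
    order = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(order, k)):
        folds[chunk] = f
    return folds


def cross_validate(
    expr: pd.DataFrame,
    sens: pd.DataFrame,
    hub_genes: list[str],
    k: int = 10,
    scheme: str = "kfold",
    standardization: str = "global",
    ridge_lambda: float = DEFAULT_RIDGE,
    seed: int = 0,
    drug_vocab: list[str] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Out-of-fold predictions for every sensitivity record.

    ``standardization="global"`` z-scores expression once on the full
    matrix before splitting (the historical convention for this analysis);
    ``"per_fold"`` refits scaling on each training fold's cell lines and
    applies it to the held-out fold (leakage-safe variant).

    Returns (records, folds): ``records`` has columns
    ``cell_line, drug, observed, predicted, fold`` aligned to the retained
    sensitivity records; ``folds`` is the integer fold id per record.
    """
    if scheme not in ("kfold", "loocv"):
        raise ValueError("scheme must be 'kfold' or 'loocv'")
    if standardization not in ("global", "per_fold"):
        raise ValueError("standardization must be 'global' or 'per_fold'")
    if drug_vocab is None:
        drug_vocab = sorted(sens["drug"].unique())

    hub_expr = expr.loc[hub_genes]
    # assemble once on the raw scale to fix the retained record set
    raw_features = assemble_features(hub_expr, sens, hub_genes, drug_vocab)
    records = raw_features.keys.copy()
    n = len(records)
    if scheme == "loocv":
        k = n
    if k < 2 or k > n:
        raise ValueError(f"k must lie in [2, {n}], got {k}")

    rng = np.random.default_rng(seed)
    folds = _fold_assignment(n, k, rng)

    y = raw_features.y
    Xg_raw = raw_features.X[:, :len(hub_genes)]  # raw expression block
    Xd = raw_features.X[:, len(hub_genes):]

    if standardization == "global":
        z, _ = standardize_expression(hub_expr)
        Xg_global = z[records["cell_line"]].to_numpy(dtype=float).T

    predicted = np.empty(n)
    for f in range(k):
        test = folds == f
        train = ~test
        if standardization == "global":
            Xg_train, Xg_test = Xg_global[train], Xg_global[test]
        else:
            mu = Xg_raw[train].mean(axis=0)
            sd = Xg_raw[train].std(axis=0, ddof=1)
            if np.any(sd == 0):
                raise ValueError("a hub gene is constant within a training fold")
            Xg_train = (Xg_raw[train] - mu) / sd
            Xg_test = (Xg_raw[test] - mu) / sd
        X_train = np.hstack([Xg_train, Xd[train]])
        X_test = np.hstack([Xg_test, Xd[test]])
        intercept, beta = _ridge_solve(X_train, y[train], ridge_lambda)
        predicted[test] = intercept + X_test @ beta

    out = records.assign(observed=y, predicted=predicted, fold=folds)
    return out, folds


# --- sparse (lasso) comparator -----------------------------------------

def fit_lasso(X: np.ndarray, y: np.ndarray, lam: float) -> tuple[float, np.ndarray]:
    """L1-penalized linear fit minimizing (1/2n)||y - b0 - Xb||^2 + lam ||b||_1."""
    est = Lasso(alpha=lam, fit_intercept=True, max_iter=50_000, tol=1e-10)
    est.fit(X, y)
    return float(est.intercept_), est.coef_.copy()


def stratified_drug_folds(
    keys: pd.DataFrame,
    values: np.ndarray,
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Folds with equal drug proportions, rank-balanced on sensitivity.

    Within each drug, records are sorted by sensitivity and consecutive
    blocks of k records are dealt one to each fold (random fold order per
    block), so every fold sees the same share and roughly the same
    distribution of values for every drug.
    """
    folds = np.empty(len(keys), dtype=int)
    for drug, grp in keys.groupby("drug", sort=True):
        idx = grp.index.to_numpy()
        if len(idx) < k:
            raise ValueError(
                f"drug {drug!r} has only {len(idx)} records; need at least {k}"
            )
        order = idx[np.argsort(values[idx], kind="stable")]
        for start in range(0, len(order), k):
            block = order[start:start + k]
            labels = rng.permutation(k)[: len(block)]
            folds[block] = labels
    return folds


def fit_sparse_comparator(
    features: FeatureTable,
    outer_k: int = 10,
    inner_k: int = 10,
    seed: int = 0,
    lambda_grid: np.ndarray | None = None,
) -> tuple[list[tuple[float, np.ndarray]], pd.DataFrame, list[float]]:
    """Nested-CV lasso baseline with drug-stratified outer folds.

    The inner CV selects, per outer fold, the penalty minimizing held-out
    RMSE over a log-spaced grid (descending from the data-driven maximum
    at which all coefficients vanish). Returns (per-fold models as
    (intercept, coefs), out-of-fold prediction records, selected penalty
    per fold).
    """
    rng = np.random.default_rng(seed)
    X, y = features.X, features.y
    n = len(y)
    keys = features.keys.reset_index(drop=True)
    outer = stratified_drug_folds(keys, y, outer_k, rng)

    if lambda_grid is None:
        lam_max = np.max(np.abs(X.T @ (y - y.mean()))) / n
        lambda_grid = np.geomspace(lam_max, lam_max * 1e-4, 40)

    models: list[tuple[float, np.ndarray]] = []
    chosen: list[float] = []
    predicted = np.empty(n)
    for f in range(outer_k):
        test = outer == f
        train_idx = np.flatnonzero(~test)
        inner = _fold_assignment(len(train_idx), inner_k, rng)
        sse = np.zeros(len(lambda_grid))
        for g in range(inner_k):
            tr = train_idx[inner != g]
            va = train_idx[inner == g]
            for j, lam in enumerate(lambda_grid):
                b0, beta = fit_lasso(X[tr], y[tr], lam)
                resid = y[va] - (b0 + X[va] @ beta)
                sse[j] += resid @ resid
        lam_best = float(lambda_grid[int(np.argmin(sse))])
        b0, beta = fit_lasso(X[~test], y[~test], lam_best)
        models.append((b0, beta))
        chosen.append(lam_best)
        predicted[test] = b0 + X[test] @ beta

    out = keys.assign(observed=y, predicted=predicted, fold=outer)
    return models, out, chosen
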