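"""Synthetic expression and drug-sensitivity data with planted ground truth.

The generator emulates the structure the pipeline is designed to exploit in
real cell-line panels: a small minority of genes form high-variance,
highly intercorrelated modules (each driven by one latent factor per
sample), embedded in a large pool of weakly correlated background genes.
Per-drug sensitivity ("activity area", AA: higher = more sensitive) is a
linear function of standardized hub expression plus a drug-specific
intercept and Gaussian noise, and a paired inverse-scale measure
(log-IC50-like: lower = more sensitive) is an affine anti-correlated
transform of AA.

Every stage downstream therefore has a parameter-recovery surface: the
planted hub genes are the ground-truth hubs, and the per-drug effect
vectors are the ground-truth regression coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hubdrug.errors import ConfigurationError

# distinct sub-stream tags so the three operations draw independent,
# reproducible variates from the same config seed
_EXPR_STREAM = 11
_SENS_STREAM = 23
_INV_STREAM = 37

AA_MEASURE = "AA"
LNIC50_MEASURE = "LNIC50"


@dataclass(frozen=True)
class ModuleSpec:
    """One planted co-expression module.

    ``size`` genes share a latent factor; the first gene carries
    ``hub_loading`` and the remaining ``size - 1`` genes carry
    ``member_loading`` (both in (0, 1]).
    """

    size: int
    hub_loading: float = 0.95
    member_loading: float = 0.7

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ConfigurationError("module size must be >= 1")
        for name in ("hub_loading", "member_loading"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ConfigurationError(f"{name} must lie in (0, 1], got {v}")


@dataclass
class SyntheticConfig:
    """Full description of one synthetic study.

    Parameters
    ----------
    n_genes, n_samples
        Matrix dimensions (genes x samples / cell lines).
    modules
        Planted modules; their total size must not exceed ``n_genes``.
    noise_sd
        Per-gene residual SD around the factor contribution; background
        genes are pure noise with this SD.
    hub_variance_scale
        Multiplier (>= 1) applied to all planted module genes so their SD
        clears a high-percentile variance filter.
    drugs, drug_intercepts, drug_effects
        Drug vocabulary, per-drug intercept mu_d (AA units), and per-drug
        effect vector beta_d over the planted hub genes (one coefficient
        per module, in module order).
    sensitivity_noise_sd
        SD of the additive noise on AA values.
    inverse_offset, inverse_slope, inverse_noise_sd
        The paired inverse measure is ``alpha - gamma * AA + noise``
        (slope gamma must be > 0 so the two scales are anti-correlated).
    seed
        Root seed; all three generator operations derive deterministic
        sub-streams from it.
    """

    n_genes: int
    n_samples: int
    modules: list[ModuleSpec]
    drugs: list[str]
    drug_intercepts: dict[str, float]
    drug_effects: dict[str, np.ndarray]
    noise_sd: float = 0.3
    hub_variance_scale: float = 4.0
    sensitivity_noise_sd: float = 0.5
    inverse_offset: float = 2.0
    inverse_slope: float = 1.0
    inverse_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_samples < 1:
            raise ConfigurationError("n_genes and n_samples must be positive")
        total = sum(m.size for m in self.modules)
        if total > self.n_genes:
            raise ConfigurationError(
                f"module sizes sum to {total} but only {self.n_genes} genes exist"
            )
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if self.hub_variance_scale < 1:
            raise ConfigurationError("hub_variance_scale must be >= 1")
        if self.sensitivity_noise_sd < 0:
            raise ConfigurationError("sensitivity_noise_sd must be >= 0")
        if self.inverse_slope <= 0:
            raise ConfigurationError("inverse_slope (gamma) must be > 0")
        if self.inverse_noise_sd < 0:
            raise ConfigurationError("inverse_noise_sd must be >= 0")
        n_hubs = len(self.modules)
        for d in self.drugs:
            if d not in self.drug_intercepts:
                raise ConfigurationError(f"drug {d!r} has no intercept")
            if d not in self.drug_effects:
                raise ConfigurationError(f"drug {d!r} has no effect vector")
            beta = np.asarray(self.drug_effects[d], dtype=float)
            if beta.shape != (n_hubs,):
                raise ConfigurationError(
                    f"effect vector for drug {d!r} has length {beta.size}, "
                    f"expected one coefficient per planted hub ({n_hubs})"
                )


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside a generated expression matrix."""

    planted_hub_ids: list[str]
    module_membership: dict[str, int] = field(default_factory=dict)
    # module index per gene; background genes map to -1
    true_effects: dict[str, np.ndarray] = field(default_factory=dict)
    true_intercepts: dict[str, float] = field(default_factory=dict)

    def member_ids(self) -> list[str]:
        """All planted module genes (hubs and ordinary members)."""
        return [g for g, m in self.module_membership.items() if m >= 0]


def default_config(seed: int = 0, n_drugs: int = 24) -> SyntheticConfig:
    """Study-scale default configuration.

    Five modules of 10 genes planted in 300 background genes (350 genes
    total, 500 cell lines), hub loading 0.95, member loading 0.7, residual
    SD 0.3, module genes variance-boosted 4x. Drug intercepts span the
    typical activity-area range (0.5-4) and per-drug hub effects are
    moderate (|beta| <= 0.6); both are drawn once from the root seed and
    stored in the config, so the ground truth is part of the configuration.
    """
    rng = np.random.default_rng([101, seed])
    drugs = [f"drug{i + 1:02d}" for i in range(n_drugs)]
    n_modules = 5
    intercepts = {d: float(v) for d, v in zip(drugs, rng.uniform(0.5, 4.0, n_drugs))}
    effects = {
        d: rng.uniform(-0.6, 0.6, n_modules).round(3) for d in drugs
    }
    return SyntheticConfig(
        n_genes=350,
        n_samples=500,
        modules=[ModuleSpec(size=10, hub_loading=0.95, member_loading=0.7)
                 for _ in range(n_modules)],
        drugs=drugs,
        drug_intercepts=intercepts,
        drug_effects=effects,
        noise_sd=0.3,
        hub_variance_scale=4.0,
        sensitivity_noise_sd=0.5,
        inverse_offset=2.0,
        inverse_slope=1.0,
        inverse_noise_sd=0.3,
        seed=seed,
    )


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def _sample_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"CL{i + 1:0{width}d}" for i in range(n)]


def generate_expression(config: SyntheticConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a genes x samples log-scale expression matrix.

    Module genes follow a one-factor model ``loading * f_m + eps`` with a
    standard-normal latent factor ``f_m`` per module per sample and
    ``eps ~ N(0, noise_sd^2)``; all planted module genes are then scaled
    by ``hub_variance_scale`` so the planted structure survives a stringent
    variance filter. Background genes are pure noise. Deterministic given
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng([_EXPR_STREAM, config.seed])
    n_g, n_s = config.n_genes, config.n_samples
    genes = _gene_ids(n_g)
    samples = _sample_ids(n_s)

    values = np.empty((n_g, n_s))
    membership = dict.fromkeys(genes, -1)
    hub_ids: list[str] = []

    row = 0
    for m_idx, mod in enumerate(config.modules):
        factor = rng.standard_normal(n_s)
        loadings = np.full(mod.size, mod.member_loading)
        loadings[0] = mod.hub_loading
        noise = rng.normal(0.0, config.noise_sd, size=(mod.size, n_s))
        block = loadings[:, None] * factor[None, :] + noise
        values[row:row + mod.size] = config.hub_variance_scale * block
        hub_ids.append(genes[row])
        for j in range(mod.size):
            membership[genes[row + j]] = m_idx
        row += mod.size

    n_bg = n_g - row
    if n_bg:
        values[row:] = rng.normal(0.0, config.noise_sd, size=(n_bg, n_s))

    expr = pd.DataFrame(values, index=genes, columns=samples)
    truth = SyntheticTruth(
        planted_hub_ids=hub_ids,
        module_membership=membership,
        true_effects={d: np.asarray(config.drug_effects[d], dtype=float)
                      for d in config.drugs},
        true_intercepts={d: config.drug_intercepts[d] for d in config.drugs},
    )
    return expr, truth


def generate_sensitivity(
    expr: pd.DataFrame,
    truth: SyntheticTruth,
    config: SyntheticConfig,
) -> pd.DataFrame:
    """Generate a long-format activity-area table from planted hub expression.

    For each (cell line c, drug d):
    ``AA = mu_d + sum_j beta_{d,j} * z_{c,j} + eps`` where z are the
    per-gene standardized (own mean/SD, n-1 denominator) planted-hub
    expressions and ``eps ~ N(0, sensitivity_noise_sd^2)``. Returns one
    record per (cell line, drug) with columns
    ``cell_line, drug, value, measure``.
    """
    config.validate()
    missing = [g for g in truth.planted_hub_ids if g not in expr.index]
    if missing:
        raise ConfigurationError(f"planted hubs absent from expression matrix: {missing}")
    rng = np.random.default_rng([_SENS_STREAM, config.seed])

    hub = expr.loc[truth.planted_hub_ids].to_numpy(dtype=float)
    mu = hub.mean(axis=1, keepdims=True)
    sd = hub.std(axis=1, ddof=1, keepdims=True)
    z = (hub - mu) / sd  # hubs x samples

    frames = []
    for d in config.drugs:
        beta = np.asarray(config.drug_effects[d], dtype=float)
        aa = config.drug_intercepts[d] + beta @ z
        if config.sensitivity_noise_sd > 0:
            aa = aa + rng.normal(0.0, config.sensitivity_noise_sd, size=aa.shape)
        frames.append(pd.DataFrame({
            "cell_line": expr.columns,
            "drug": d,
            "value": aa,
            "measure": AA_MEASURE,
        }))
    return pd.concat(frames, ignore_index=True)


def generate_inverse_sensitivity(
    aa_table: pd.DataFrame,
    config: SyntheticConfig,
) -> pd.DataFrame:
    """Map an AA table onto a paired inverse-scale (log-IC50-like) table.

    ``LNIC50 = alpha - gamma * AA + eps_inv`` per record, so high
    sensitivity (high AA) maps to a low value, as for log-IC50.
    """
    config.validate()
    if not (aa_table["measure"] == AA_MEASURE).all():
        raise ConfigurationError("input table must carry the direct (AA) measure")
    rng = np.random.default_rng([_INV_STREAM, config.seed])
    out = aa_table.copy()
    v = config.inverse_offset - config.inverse_slope * out["value"].to_numpy()
    if config.inverse_noise_sd > 0:
        v = v + rng.normal(0.0, config.inverse_noise_sd, size=v.shape)
    out["value"] = v
    out["measure"] = LNIC50_MEASURE
    return out
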