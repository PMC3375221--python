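"""Additive/epistatic decomposition of chimeric-allele phenotypes.

Twenty-two chimeric constructs swap five regions of a gene between two
species; each construct's sulfite-resistance delay is measured repeatedly
across 96-well plates (batches).  Two linear mixed models with a per-batch
random intercept are fit by maximum likelihood (not REML, since the models
are compared by a fixed-effect LRT):

* additive:   delay ~ region1 + ... + region5 + (1 | batch)
* epistatic:  additive + all 10 pairwise region:region interactions

Parameter counts follow the convention intercept + fixed effects + 2
variance components: 8 (additive) and 18 (epistatic), so the LRT has 10
degrees of freedom.  Variance explained relative to an intercept-only
null uses R^2 = 1 - exp(-LR/n).  Per-region percent contributions are
100·|effect| / |parent difference|.

The random-intercept ML fit profiles the variance ratio: given
lambda = sigma_b^2/sigma_e^2, the GLS estimates and the profiled
log-likelihood are closed-form (Woodbury on the block-diagonal
covariance); lambda is optimized on a log grid followed by a bounded
scalar polish.  With the batch variance estimated at zero the fixed
effects coincide with ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .rate_screen import chi_square_sf

__all__ = [
    "LMMFit",
    "EffectDecomposition",
    "REGION_COLUMNS",
    "PAIR_INDEX",
    "fit_region_model",
    "fit_intercept_model",
    "lrt_compare",
    "variance_explained",
    "percent_contribution",
    "decompose_effects",
    "permutation_pvalues",
]

REGION_COLUMNS = tuple(f"region{i}" for i in range(1, 6))
PAIR_INDEX = tuple((i, j) for i in range(5) for j in range(i + 1, 5))


@dataclass(frozen=True)
class LMMFit:
    """ML fit of a random-intercept linear mixed model."""

    fixed_effects: pd.Series
    standard_errors: pd.Series
    p_values: pd.Series
    batch_variance: float
    residual_variance: float
    lnL: float
    n: int
    k: int
    model: str  # "null" | "additive" | "epistatic"

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return X[self.fixed_effects.index].to_numpy(dtype=float) @ self.fixed_effects.to_numpy()


# ---------------------------------------------------------------------------
# Profiled-ML machinery
# ---------------------------------------------------------------------------


def _group_blocks(batch: np.ndarray):
    labels, inverse = np.unique(batch, return_inverse=True)
    return [np.flatnonzero(inverse == g) for g in range(labels.size)]


def _profiled_fit(X: np.ndarray, y: np.ndarray, blocks, lam: float):
    """GLS fit and profiled ML log-likelihood at variance ratio ``lam``.

    V = sigma_e^2 (I + lam Z Z'); per batch g of size m,
    V_g^{-1} = (I - lam/(1+lam m) J)/sigma_e^2 and
    log|V_g|/sigma_e^2 = log(1 + lam m).
    """
    n, p = X.shape
    XtAX = np.zeros((p, p))
    XtAy = np.zeros(p)
    logdet = 0.0
    for idx in blocks:
        Xg, yg = X[idx], y[idx]
        m = idx.size
        c = lam / (1.0 + lam * m)
        sx = Xg.sum(axis=0)
        sy = yg.sum()
        XtAX += Xg.T @ Xg - c * np.outer(sx, sx)
        XtAy += Xg.T @ yg - c * sx * sy
        logdet += np.log1p(lam * m)
    beta = np.linalg.solve(XtAX, XtAy)
    rss = 0.0
    for idx in blocks:
        r = y[idx] - X[idx] @ beta
        c = lam / (1.0 + lam * idx.size)
        rss += r @ r - c * r.sum() ** 2
    sigma2 = rss / n
    lnL = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return beta, sigma2, lnL, XtAX


def _fit_lmm(X: np.ndarray, y: np.ndarray, batch: np.ndarray):
    blocks = _group_blocks(batch)

    def neg_profile(log_lam):
        return -_profiled_fit(X, y, blocks, np.exp(log_lam))[2]

    # coarse log grid (including effectively-zero lambda), then polish
    grid = np.concatenate([[-30.0], np.linspace(-12, 8, 41)])
    values = [neg_profile(g) for g in grid]
    best = int(np.argmin(values))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, grid.size - 1)]
    res = minimize_scalar(neg_profile, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    log_lam = res.x if res.fun < values[best] else grid[best]
    lam = np.exp(log_lam)
    if lam < 1e-12:
        lam = 0.0
    beta, sigma2, lnL, XtAX = _profiled_fit(X, y, blocks, lam)
    cov = sigma2 * np.linalg.inv(XtAX)
    return beta, np.sqrt(np.diag(cov)), lam * sigma2, sigma2, lnL


def _design(table: pd.DataFrame, model: str) -> pd.DataFrame:
    for col in REGION_COLUMNS:
        if model != "null" and table[col].nunique() < 2:
            raise ValueError(
                f"{col} is constant across all constructs; design is rank-deficient"
            )
    X = pd.DataFrame({"intercept": np.ones(len(table))}, index=table.index)
    if model == "null":
        return X
    for col in REGION_COLUMNS:
        X[col] = table[col].astype(float)
    if model == "epistatic":
        for i, j in PAIR_INDEX:
            a, b = REGION_COLUMNS[i], REGION_COLUMNS[j]
            X[f"{a}:{b}"] = X[a] * X[b]
    return X


def fit_region_model(
    table: pd.DataFrame,
    interactions: bool = False,
    response: str = "delay_hours",
) -> LMMFit:
    """Fit the additive (or pairwise-epistatic) region model by ML.

    ``table`` needs columns region1..region5 (0/1), batch, and the
    response.  Fixed-effect p-values are two-sided Wald tests.
    """
    model = "epistatic" if interactions else "additive"
    X = _design(table, model)
    y = table[response].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    batch = table["batch"].to_numpy()
    beta, se, batch_var, resid_var, lnL = _fit_lmm(X.to_numpy(dtype=float), y, batch)
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    names = list(X.columns)
    return LMMFit(
        fixed_effects=pd.Series(beta, index=names),
        standard_errors=pd.Series(se, index=names),
        p_values=pd.Series(p, index=names),
        batch_variance=float(batch_var),
        residual_variance=float(resid_var),
        lnL=float(lnL),
        n=len(y),
        k=len(names) + 2,
        model=model,
    )


def fit_intercept_model(table: pd.DataFrame, response: str = "delay_hours") -> LMMFit:
    """Intercept-only null model (random batch intercept retained)."""
    X = _design(table, "null")
    y = table[response].to_numpy(dtype=float)
    batch = table["batch"].to_numpy()
    beta, se, batch_var, resid_var, lnL = _fit_lmm(X.to_numpy(dtype=float), y, batch)
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return LMMFit(
        pd.Series(beta, index=["intercept"]),
        pd.Series(se, index=["intercept"]),
        pd.Series(p, index=["intercept"]),
        float(batch_var), float(resid_var), float(lnL), len(y), 3, "null",
    )


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------


def lrt_compare(fit_null: LMMFit, fit_alt: LMMFit) -> tuple[float, int, float]:
    """Likelihood ratio test between two nested ML fits.

    Returns (2Δln(L), df, p) with df the difference in parameter counts;
    for the additive (k=8) vs epistatic (k=18) comparison df = 10.
    """
    if fit_null.n != fit_alt.n:
        raise ValueError("fits are not on the same data (n mismatch)")
    if fit_alt.k <= fit_null.k:
        raise ValueError("alternative model must have more parameters")
    stat = 2.0 * (fit_alt.lnL - fit_null.lnL)
    if stat < -1e-6:
        raise ValueError("nesting violated: alternative lnL below null")
    stat = max(stat, 0.0)
    df = fit_alt.k - fit_null.k
    return stat, df, chi_square_sf(stat, df)


def variance_explained(LR: float, n: int) -> float:
    """R^2 = 1 - exp(-LR/n) for a likelihood-ratio statistic vs the
    intercept-only null."""
    if LR < 0:
        raise ValueError("likelihood-ratio statistic must be non-negative")
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(1.0 - np.exp(-LR / n))


def percent_contribution(effects, total_difference: float) -> np.ndarray:
    """Per-region percent of the parent-allele difference:
    100·|effect_i| / |total|.  Percents need not sum to 100 (epistasis and
    nonsignificant regions absorb the remainder)."""
    if total_difference == 0:
        raise ValueError("total_difference must be nonzero")
    effects = np.asarray(effects, dtype=float)
    return 100.0 * np.abs(effects) / abs(total_difference)


@dataclass(frozen=True)
class EffectDecomposition:
    additive: LMMFit
    epistatic: LMMFit
    null: LMMFit
    lrt_stat: float
    df: int
    p_value: float
    r2_additive: float
    r2_epistatic: float
    percent_contributions: np.ndarray | None

    def effect_table(self) -> pd.DataFrame:
        """Per-term effect sizes and p-values, additive and epistatic
        columns side by side (the shape of the study's effect table)."""
        idx = list(self.epistatic.fixed_effects.index)
        add = self.additive.fixed_effects.reindex(idx)
        add_p = self.additive.p_values.reindex(idx)
        return pd.DataFrame(
            {
                "effect_additive": add,
                "p_additive": add_p,
                "effect_epistatic": self.epistatic.fixed_effects,
                "p_epistatic": self.epistatic.p_values,
            }
        )


def decompose_effects(
    table: pd.DataFrame,
    response: str = "delay_hours",
    total_difference: float | None = None,
) -> EffectDecomposition:
    """Fit null/additive/epistatic models, test for epistasis, and compute
    variance explained; optionally percent contributions against an
    explicit parent-allele difference."""
    null = fit_intercept_model(table, response)
    add = fit_region_model(table, interactions=False, response=response)
    epi = fit_region_model(table, interactions=True, response=response)
    stat, df, p = lrt_compare(add, epi)
    r2_add = variance_explained(max(2.0 * (add.lnL - null.lnL), 0.0), add.n)
    r2_epi = variance_explained(max(2.0 * (epi.lnL - null.lnL), 0.0), epi.n)
    pct = None
    if total_difference is not None:
        pct = percent_contribution(
            add.fixed_effects[list(REGION_COLUMNS)].to_numpy(), total_difference
        )
    return EffectDecomposition(add, epi, null, stat, df, p, r2_add, r2_epi, pct)


# ---------------------------------------------------------------------------
# Permutation check of parametric p-values
# ---------------------------------------------------------------------------


def permutation_pvalues(
    table: pd.DataFrame,
    nperm: int = 200,
    seed: int = 0,
    response: str = "delay_hours",
) -> dict:
    """Null distribution of the additive-model region p-values under
    permutation of construct labels within day.

    Each permutation shuffles which construct (and hence region design)
    each observation belongs to, within day, refits the additive model and
    collects the five region Wald p-values.  Returns the pooled permuted
    p-values plus their Kolmogorov-Smirnov distance from Uniform(0,1).
    Deterministic given ``seed``.
    """
    if nperm < 100:
        raise ValueError("nperm must be >= 100")
    rng = np.random.default_rng(seed)
    design_cols = list(REGION_COLUMNS) + ["construct"]
    pvals = []
    for _ in range(nperm):
        permuted = table.copy()
        for _, idx in table.groupby("day").groups.items():
            order = rng.permutation(len(idx))
            permuted.loc[idx, design_cols] = (
                table.loc[idx, design_cols].to_numpy()[order]
            )
        fit = fit_region_model(permuted, interactions=False, response=response)
        pvals.extend(fit.p_values[list(REGION_COLUMNS)].tolist())
    pvals = np.asarray(pvals)
    ks_stat, ks_p = stats.kstest(pvals, "uniform")
    return {"p_values": pvals, "ks_stat": float(ks_stat), "ks_p": float(ks_p)}
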