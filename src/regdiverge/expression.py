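"""Expression analysis: qPCR correction, per-gene ANOVA, permutation FDR.

Two measurement layers are handled:

* qPCR of individual genes relative to an *ACT1* reference, with a
  plate-specific correction factor for allele-specific primer pairs
  estimated from heterozygous genomic DNA (true allele ratio 1:1), and
* a genome-scale log2 expression matrix analyzed per gene with the ANOVA
  ``expression = allele*time + technical replicate + error``; genes with
  allele-dependent expression are then attributed to the coding region,
  the 5' noncoding region, or their interaction with the second-level
  model ``expression = noncoding*coding + error`` (with time interactions
  for time-dependent genes).

The false-discovery rate of the genome-scale screen is estimated by
permuting sample labels and comparing the mean permuted significant-gene
count to the observed count.  All ANOVA F-tests are computed by nested
least-squares model comparisons vectorized over genes, with the error
term taken from the full model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FdrEstimate",
    "plate_corrected_relative_expression",
    "median_normalize",
    "gene_anova",
    "classify_source",
    "permutation_fdr",
    "fold_change_sets",
]

DESIGN_COLUMNS = ("sample", "allele", "noncoding_origin", "coding_origin",
                  "time", "replicate", "tech_replicate")


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------


def plate_corrected_relative_expression(
    records: pd.DataFrame,
    het_calibration: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Relative expression 2^-(Ct_target - Ct_reference), corrected for
    allele-specific primer efficiency and mean-normalized for day/batch.

    ``records`` columns: sample, gene, ct_target, ct_reference, plate, and
    optionally primer ('C'/'P' for allele-specific assays), day, batch.
    ``het_calibration`` holds, per plate, Ct measurements of heterozygous
    genomic DNA with both primers; the apparent C:P ratio there is the
    plate factor (the true genomic ratio is 1:1), and C-primer
    measurements are divided by it.  Day/batch normalization divides by
    the geometric mean within each day and each batch.
    """
    for col in ("sample", "gene", "ct_target", "ct_reference", "plate"):
        if col not in records.columns:
            raise ValueError(f"records missing column {col!r}")
    if records[["ct_target", "ct_reference"]].isna().any().any():
        raise ValueError("Ct values must be present and finite (missing ACT1?)")
    out = records.copy()
    out["relative_expression"] = 2.0 ** -(
        out["ct_target"].astype(float) - out["ct_reference"].astype(float)
    )

    uses_primers = "primer" in out.columns and out["primer"].notna().any()
    if uses_primers:
        if het_calibration is None:
            raise ValueError(
                "allele-specific primers present but no heterozygote calibration"
            )
        factors = _plate_factors(het_calibration)
        for plate, sub in out.groupby("plate"):
            mask = (out["plate"] == plate) & (out["primer"] == "C")
            if mask.any():
                if plate not in factors:
                    raise ValueError(f"no heterozygote calibration for plate {plate!r}")
                out.loc[mask, "relative_expression"] /= factors[plate]

    log_expr = np.log2(out["relative_expression"])
    for col in ("day", "batch"):
        if col in out.columns:
            log_expr = log_expr - log_expr.groupby(out[col]).transform("mean")
    out["relative_expression"] = 2.0 ** log_expr
    return out


def _plate_factors(het: pd.DataFrame) -> dict:
    """Apparent C:P allele ratio of heterozygous genomic DNA per plate."""
    factors = {}
    for plate, sub in het.groupby("plate"):
        rel = {}
        for primer, rows in sub.groupby("primer"):
            rel[primer] = float(
                np.mean(2.0 ** -(rows["ct_target"] - rows["ct_reference"]))
            )
        if "C" not in rel or "P" not in rel:
            raise ValueError(f"plate {plate!r} calibration needs both primers")
        factors[plate] = rel["C"] / rel["P"]
    return factors


# ---------------------------------------------------------------------------
# Matrix normalization
# ---------------------------------------------------------------------------


def median_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Center each array (column) at median 0; rank order preserved."""
    if matrix.isna().all().any():
        bad = matrix.columns[matrix.isna().all()][0]
        raise ValueError(f"array {bad!r} is entirely missing")
    return matrix - matrix.median(axis=0)


# ---------------------------------------------------------------------------
# Vectorized nested-model ANOVA
# ---------------------------------------------------------------------------


def _factor_dummies(values: pd.Series) -> np.ndarray:
    """Drop-first treatment coding of a categorical factor."""
    levels = sorted(pd.unique(values))
    return np.column_stack(
        [(values == lv).to_numpy(dtype=float) for lv in levels[1:]]
    ) if len(levels) > 1 else np.empty((len(values), 0))


def _model_matrix(design: pd.DataFrame, terms: list[str]) -> np.ndarray:
    cols = [np.ones((len(design), 1))]
    for term in terms:
        parts = term.split(":")
        mats = [_factor_dummies(design[p]) for p in parts]
        block = mats[0]
        for m in mats[1:]:
            block = np.einsum("ni,nj->nij", block, m).reshape(len(design), -1)
        cols.append(block)
    return np.hstack(cols)


def _rss(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, int]:
    """Residual sum of squares per column of Y, and the model rank."""
    coef, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    return np.einsum("ij,ij->j", resid, resid), rank


def _nested_f(rss_red, rank_red, rss_full, rank_full, rss_err, df_err):
    """F-test of the terms dropped between two nested models, with the
    error taken from the fullest model.  Degenerate genes (zero error and
    zero effect) get F = 0, p = 1."""
    ddf = rank_full - rank_red
    num = np.maximum(rss_red - rss_full, 0.0) / ddf
    den = rss_err / df_err
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.where(num > 0, np.inf, 0.0))
    p = stats.f.sf(F, ddf, df_err)
    p = np.where(F == 0, 1.0, p)
    return F, p


def _aligned_values(matrix: pd.DataFrame, design: pd.DataFrame) -> np.ndarray:
    missing = set(design["sample"]) - set(matrix.columns)
    if missing:
        raise ValueError(f"matrix lacks samples: {sorted(missing)[:5]}")
    return matrix[design["sample"].tolist()].to_numpy(dtype=float).T  # samples x genes


def _check_cells(design: pd.DataFrame) -> None:
    cells = design.groupby(["allele", "time"]).size()
    full = pd.MultiIndex.from_product(
        [sorted(design["allele"].unique()), sorted(design["time"].unique())]
    )
    cells = cells.reindex(full, fill_value=0)
    if (cells < 2).any():
        bad = cells[cells < 2].index.tolist()
        raise ValueError(f"design cells with <2 replicates: {bad}")


def gene_anova(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    second_level_alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-gene ANOVA ``expression = allele*time + tech_replicate + error``.

    Returns one row per gene with p_allele (main effect across
    time-points), p_time (response to sulfite treatment), p_allele_time
    (allele-by-time interaction), log2fc_sulfite, and — for genes
    significant at ``second_level_alpha`` — the second-level attribution
    p-values p_coding / p_noncoding / p_interaction and a ``source``
    label.
    """
    _check_cells(design)
    Y = _aligned_values(matrix, design)

    full_terms = ["allele", "time", "allele:time", "tech_replicate"]
    rss_full, rank_full = _rss(_model_matrix(design, full_terms), Y)
    df_err = len(design) - rank_full
    rss_add, rank_add = _rss(
        _model_matrix(design, ["allele", "time", "tech_replicate"]), Y
    )
    rss_no_allele, rank_no_allele = _rss(
        _model_matrix(design, ["time", "tech_replicate"]), Y
    )
    rss_no_time, rank_no_time = _rss(
        _model_matrix(design, ["allele", "tech_replicate"]), Y
    )

    _, p_allele = _nested_f(rss_no_allele, rank_no_allele, rss_add, rank_add,
                            rss_full, df_err)
    _, p_time = _nested_f(rss_no_time, rank_no_time, rss_add, rank_add,
                          rss_full, df_err)
    _, p_int = _nested_f(rss_add, rank_add, rss_full, rank_full, rss_full, df_err)

    late = design["time"].to_numpy(dtype=float) > 0
    log2fc = Y[late].mean(axis=0) - Y[~late].mean(axis=0)

    results = pd.DataFrame(
        {
            "p_allele": p_allele,
            "p_time": p_time,
            "p_allele_time": p_int,
            "log2fc_sulfite": log2fc,
        },
        index=matrix.index.copy(),
    )

    for col in ("p_coding", "p_noncoding", "p_interaction"):
        results[col] = np.nan
    results["source"] = pd.Series(pd.NA, index=results.index, dtype=object)

    allele_sig = results["p_allele"] < second_level_alpha
    time_dep = (results["p_allele_time"] < second_level_alpha) & ~allele_sig
    if allele_sig.any():
        attribution = classify_source(matrix.loc[allele_sig], design,
                                      time_dependent=False,
                                      alpha=second_level_alpha)
        results.loc[allele_sig, attribution.columns] = attribution.values
    if time_dep.any():
        attribution = classify_source(matrix.loc[time_dep], design,
                                      time_dependent=True,
                                      alpha=second_level_alpha)
        results.loc[time_dep, attribution.columns] = attribution.values
    return results


def classify_source(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    time_dependent: bool = False,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Attribute allele-dependent expression to coding, noncoding, or
    their interaction via ``expression = noncoding*coding + error``
    (``noncoding*coding*time`` for time-dependent genes).

    The label is the significant term with the smallest p-value; the
    classification is invariant to which species is called reference,
    since relabeling flips dummy codings without changing the F-tests.
    """
    Y = _aligned_values(matrix, design)
    if time_dependent:
        base = ["noncoding_origin", "coding_origin", "time",
                "noncoding_origin:time", "coding_origin:time"]
        full = base + ["noncoding_origin:coding_origin",
                       "noncoding_origin:coding_origin:time"]
        tests = {
            "p_noncoding": "noncoding_origin:time",
            "p_coding": "coding_origin:time",
            "p_interaction": "noncoding_origin:coding_origin:time",
        }
    else:
        full = ["noncoding_origin", "coding_origin",
                "noncoding_origin:coding_origin"]
        tests = {
            "p_noncoding": "noncoding_origin",
            "p_coding": "coding_origin",
            "p_interaction": "noncoding_origin:coding_origin",
        }
    rss_full, rank_full = _rss(_model_matrix(design, full), Y)
    df_err = len(design) - rank_full
    out = {}
    for name, term in tests.items():
        reduced = [t for t in full if t != term]
        rss_red, rank_red = _rss(_model_matrix(design, reduced), Y)
        _, p = _nested_f(rss_red, rank_red, rss_full, rank_full, rss_full, df_err)
        out[name] = p
    frame = pd.DataFrame(out, index=matrix.index.copy())
    labels = []
    names = np.array(["noncoding", "coding", "interaction"])
    P = frame[["p_noncoding", "p_coding", "p_interaction"]].to_numpy()
    for row in P:
        sig = row < alpha
        labels.append(names[np.argmin(row)] if sig.any() else "unattributed")
    frame["source"] = labels
    return frame


# ---------------------------------------------------------------------------
# Permutation FDR
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FdrEstimate:
    alpha: float
    n_observed: int
    mean_null: float
    fdr: float | None  # None when nothing observed

    @property
    def fdr_capped(self) -> float | None:
        return None if self.fdr is None else min(self.fdr, 1.0)


def _permute_design(design: pd.DataFrame, rng: np.random.Generator,
                    within_time: bool) -> pd.DataFrame:
    """Reassign allele labels across biological samples, keeping each
    biological sample's technical replicates together."""
    permuted = design.copy()
    bio_cols = ["allele", "noncoding_origin", "coding_origin", "time", "replicate"]
    bio = design[bio_cols].drop_duplicates().reset_index(drop=True)
    groups = bio.groupby("time").groups if within_time else {None: bio.index}
    new_allele = bio[["allele", "noncoding_origin", "coding_origin"]].copy()
    for _, idx in groups.items():
        order = rng.permutation(len(idx))
        new_allele.iloc[np.asarray(idx)] = (
            new_allele.iloc[np.asarray(idx)].to_numpy()[order]
        )
    # map each original biological sample to its permuted allele labels
    merged = design.merge(
        bio.join(new_allele, rsuffix="_new"),
        on=bio_cols, how="left",
    )
    permuted[["allele", "noncoding_origin", "coding_origin"]] = merged[
        ["allele_new", "noncoding_origin_new", "coding_origin_new"]
    ].to_numpy()
    return permuted


def permutation_fdr(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    alpha: float = 0.01,
    nperm: int = 100,
    seed: int = 0,
    test: str = "allele",
) -> FdrEstimate:
    """Permutation estimate of the false-discovery rate at level ``alpha``.

    ``test`` selects the first-level hypothesis: "allele" (main effect;
    labels permuted within time-point) or "allele_time" (interaction;
    labels permuted across all biological samples).  FDR = mean permuted
    significant count / observed significant count; undefined (None) when
    nothing is observed.
    """
    if nperm < 20:
        raise ValueError("nperm must be >= 20")
    if test not in ("allele", "allele_time"):
        raise ValueError("test must be 'allele' or 'allele_time'")
    col = "p_allele" if test == "allele" else "p_allele_time"
    rng = np.random.default_rng(seed)
    observed = int((gene_anova(matrix, design)[col] < alpha).sum())
    null_counts = []
    for _ in range(nperm):
        permuted = _permute_design(design, rng, within_time=(test == "allele"))
        null_counts.append(int((gene_anova(matrix, permuted)[col] < alpha).sum()))
    mean_null = float(np.mean(null_counts))
    fdr = mean_null / observed if observed > 0 else None
    return FdrEstimate(alpha, observed, mean_null, fdr)


# ---------------------------------------------------------------------------
# Fold-change gene sets
# ---------------------------------------------------------------------------


def fold_change_sets(
    results: pd.DataFrame,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.01,
) -> dict[str, list[str]]:
    """Genes with a significant, greater-than-``fc_threshold``-fold change
    after sulfite treatment, split by direction.

    Strict inequalities: |log2 FC| > log2(threshold) and p_time <
    ``p_threshold``; exactly 2-fold is excluded.  The up/down sets are
    disjoint by construction.
    """
    cut = np.log2(fc_threshold)
    sig = results["p_time"] < p_threshold
    up = results.index[sig & (results["log2fc_sulfite"] > cut)].tolist()
    down = results.index[sig & (results["log2fc_sulfite"] < -cut)].tolist()
    return {"up": up, "down": down}
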