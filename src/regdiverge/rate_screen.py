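"""Per-locus dNC/dS rate-heterogeneity screen.

For each noncoding locus the ratio of its substitution rate to the
genome-wide rate at fourfold-degenerate sites (dNC/dS) is fit two ways on
a tree whose branch lengths are the fourfold-degenerate rates:

* constrained — one shared dNC/dS multiplier across all branches,
* unconstrained — one multiplier per branch.

Twice the log-likelihood difference is referred to a chi-square with
(branches - 1) degrees of freedom; the genome-wide screen applies a
Bonferroni correction over the loci actually tested.  Loci whose gapped
columns exceed a fraction of the alignment length (default 15%, strict
inequality) are removed first; an explicit allowlist can retain named
loci despite the filter.

kappa is ML-estimated once per locus under the constrained model and held
fixed in the unconstrained fit, so the test isolates rate heterogeneity.
Base frequencies are empirical counts over the locus (gaps excluded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

from .phylo_core import (
    BranchRates,
    HKY85EigenSystem,
    HKY85Params,
    NucAlignment,
    ScaledTree,
    _site_patterns,
    _tip_partials,
    _TreeNode,
    empirical_base_frequencies,
)

__all__ = [
    "RateHetResult",
    "ScreenReport",
    "IndelDecision",
    "indel_fraction_filter",
    "fit_rate_models",
    "chi_square_sf",
    "screen_loci",
]

logger = logging.getLogger(__name__)

RATIO_BOUNDS = (1e-6, 100.0)
RATIO_STARTS = (0.1, 1.0, 10.0)
KAPPA_BOUNDS = (0.05, 100.0)


# ---------------------------------------------------------------------------
# Indel filter
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IndelDecision:
    keep: bool
    fraction: float
    gap_columns: int
    length: int


def indel_fraction_filter(aln: NucAlignment, threshold: float = 0.15) -> IndelDecision:
    """Drop a locus when its gapped-column fraction strictly exceeds
    ``threshold``.

    The insertion/deletion length is counted as the number of alignment
    columns in which at least one taxon carries a gap, so the fraction is
    commensurate with the alignment length.  The boundary is strict:
    exactly 15% is kept.
    """
    gap_cols = int(np.any(aln.matrix == -1, axis=0).sum())
    fraction = gap_cols / aln.length
    return IndelDecision(
        keep=fraction <= threshold,
        fraction=fraction,
        gap_columns=gap_cols,
        length=aln.length,
    )


# ---------------------------------------------------------------------------
# Likelihood machinery (fast path shared by both fits)
# ---------------------------------------------------------------------------


class _LocusLikelihood:
    """Pruning log-likelihood of one locus as a function of (kappa, ratios).

    Site patterns, tip partials and the traversal order are precomputed
    once; each evaluation costs one 4x4 eigendecomposition plus a few
    pattern-sized matrix products.
    """

    def __init__(self, aln: NucAlignment, tree: ScaledTree):
        if set(aln.taxa) != set(tree.tip_labels):
            raise ValueError("alignment taxa do not match tree tips")
        self.tree = tree
        self.branch_lengths = tree.branch_lengths
        self.patterns, self.counts = _site_patterns(aln)
        self.pi = empirical_base_frequencies(aln)
        taxon_row = {t: i for i, t in enumerate(aln.taxa)}
        self._tips = {
            label: _tip_partials(self.patterns[:, taxon_row[label]])
            for label in aln.taxa
        }
        self.n_branches = tree.n_branches

    def __call__(self, kappa: float, ratios: np.ndarray) -> float:
        eff = self.branch_lengths * ratios
        eig = HKY85EigenSystem(HKY85Params(kappa, self.pi))
        P = eig.transition_probs(eff)

        def partial(node: _TreeNode) -> np.ndarray:
            if not node.children:
                return self._tips[node.label]
            out = np.ones((self.patterns.shape[0], 4))
            for child in node.children:
                out *= partial(child) @ P[child.edge_index].T
            return out

        site_like = partial(self.tree.root) @ self.pi
        if np.any(site_like <= 0):
            return -np.inf
        return float(self.counts @ np.log(site_like))


# ---------------------------------------------------------------------------
# Model fits and LRT
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RateHetResult:
    locus_id: str
    lnL_constrained: float
    lnL_unconstrained: float
    shared_ratio: float
    branch_ratios: np.ndarray
    kappa: float
    lrt_stat: float
    df: int
    p_value: float
    converged: bool = True
    bonferroni_significant: bool | None = None

    def __post_init__(self):
        if self.lrt_stat < -1e-6:
            raise ValueError("LRT statistic below -1e-6 violates nesting")


def chi_square_sf(x: float, df: int) -> float:
    """Upper-tail probability P(X >= x) for X ~ chi-square(df)."""
    if df < 1:
        raise ValueError("df must be a positive integer")
    if x < 0:
        raise ValueError("statistic must be non-negative")
    return float(stats.chi2.sf(x, df))


def fit_rate_models(
    aln: NucAlignment,
    tree: ScaledTree,
    locus_id: str = "locus",
    estimate_kappa: bool = True,
    kappa: float = 2.0,
) -> RateHetResult:
    """Constrained vs unconstrained dNC/dS fits and their LRT.

    Both fits bound ratios to [1e-6, 100] and multi-start at 0.1, 1, 10
    (ratio likelihoods can be flat near 0).  The unconstrained optimization
    also starts from the constrained optimum, which guarantees the nesting
    inequality lnL_u >= lnL_c up to optimizer tolerance.
    """
    ll = _LocusLikelihood(aln, tree)
    nb = ll.n_branches
    log_rb = (np.log(RATIO_BOUNDS[0]), np.log(RATIO_BOUNDS[1]))
    log_kb = (np.log(KAPPA_BOUNDS[0]), np.log(KAPPA_BOUNDS[1]))

    # constrained: optimize (kappa, shared ratio)
    def neg_c(x):
        if estimate_kappa:
            k, r = np.exp(x)
        else:
            k, r = kappa, np.exp(x[0])
        return -ll(k, np.full(nb, r))

    best_c = None
    for r0 in RATIO_STARTS:
        if estimate_kappa:
            x0 = np.array([np.log(2.0), np.log(r0)])
            bounds = [log_kb, log_rb]
        else:
            x0 = np.array([np.log(r0)])
            bounds = [log_rb]
        res = minimize(neg_c, x0, method="L-BFGS-B", bounds=bounds,
                       options={"ftol": 1e-10, "gtol": 1e-8})
        if best_c is None or res.fun < best_c.fun:
            best_c = res
    if estimate_kappa:
        kappa_hat, shared = np.exp(best_c.x)
    else:
        kappa_hat, shared = kappa, float(np.exp(best_c.x[0]))
    lnL_c = -float(best_c.fun)

    # unconstrained: kappa fixed at the per-locus estimate
    def neg_u(x):
        return -ll(kappa_hat, np.exp(x))

    starts = [np.full(nb, np.log(max(shared, RATIO_BOUNDS[0])))]
    starts += [np.full(nb, np.log(r0)) for r0 in RATIO_STARTS]
    best_u = None
    converged = True
    for x0 in starts:
        res = minimize(neg_u, x0, method="L-BFGS-B", bounds=[log_rb] * nb,
                       options={"ftol": 1e-10, "gtol": 1e-8})
        if not res.success:
            res2 = minimize(neg_u, x0 * 0.9 + 0.1, method="L-BFGS-B",
                            bounds=[log_rb] * nb,
                            options={"ftol": 1e-10, "gtol": 1e-8})
            if res2.fun < res.fun:
                res = res2
        if best_u is None or res.fun < best_u.fun:
            best_u = res
    if not best_u.success and not best_c.success:
        converged = False
    lnL_u = -float(best_u.fun)
    if lnL_u < lnL_c:  # numerical slack: constrained start guarantees near-nesting
        lnL_u = max(lnL_u, lnL_c)
    stat = max(2.0 * (lnL_u - lnL_c), 0.0)
    df = nb - 1
    return RateHetResult(
        locus_id=locus_id,
        lnL_constrained=lnL_c,
        lnL_unconstrained=lnL_u,
        shared_ratio=float(shared),
        branch_ratios=np.exp(best_u.x),
        kappa=float(kappa_hat),
        lrt_stat=stat,
        df=df,
        p_value=chi_square_sf(stat, df),
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Genome-wide screen
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreenReport:
    n_tested: int
    n_significant: int
    alpha: float
    per_locus: tuple[RateHetResult, ...]
    filtered_out: tuple[str, ...] = ()
    indel_fractions: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_significant > self.n_tested:
            raise ValueError("n_significant cannot exceed n_tested")

    @property
    def per_test_threshold(self) -> float:
        return self.alpha / self.n_tested if self.n_tested else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.per_locus:
            rows.append(
                {
                    "locus": r.locus_id,
                    "fraction_indel": self.indel_fractions.get(r.locus_id, np.nan),
                    "lnL_constrained": r.lnL_constrained,
                    "lnL_unconstrained": r.lnL_unconstrained,
                    "shared_ratio": r.shared_ratio,
                    **{
                        f"ratio_{i+1}": v for i, v in enumerate(r.branch_ratios)
                    },
                    "kappa": r.kappa,
                    "lrt_stat": r.lrt_stat,
                    "df": r.df,
                    "p_value": r.p_value,
                    "significant": r.bonferroni_significant,
                }
            )
        return pd.DataFrame(rows)


def screen_loci(
    loci: dict[str, NucAlignment],
    tree: ScaledTree,
    alpha: float = 0.05,
    indel_max: float = 0.15,
    allowlist: set[str] | None = None,
) -> ScreenReport:
    """Filter, fit and Bonferroni-flag a collection of noncoding loci.

    The family-wise level ``alpha`` is divided by the number of loci
    actually tested (post-filter).  Loci named in ``allowlist`` are tested
    even if they fail the indel filter (and count toward the correction).
    """
    if not loci:
        raise ValueError("at least one locus required")
    allowlist = allowlist or set()
    fractions: dict[str, float] = {}
    kept: dict[str, NucAlignment] = {}
    dropped: list[str] = []
    for name, aln in loci.items():
        decision = indel_fraction_filter(aln, indel_max)
        fractions[name] = decision.fraction
        if decision.keep or name in allowlist:
            kept[name] = aln
        else:
            dropped.append(name)
    if not kept:
        logger.warning("all loci removed by the indel filter; empty report")
        return ScreenReport(0, 0, alpha, (), tuple(dropped), fractions)

    results = []
    n_tested = len(kept)
    cutoff = alpha / n_tested
    for name, aln in kept.items():
        r = fit_rate_models(aln, tree, locus_id=name)
        results.append(
            RateHetResult(
                **{**r.__dict__, "bonferroni_significant": r.p_value < cutoff}
            )
        )
    n_sig = sum(r.bonferroni_significant for r in results)
    return ScreenReport(n_tested, n_sig, alpha, tuple(results), tuple(dropped), fractions)
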