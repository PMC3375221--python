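"""Pairwise dN/dS estimation, sliding-window scan, Monte-Carlo intervals.

Nonsynonymous and synonymous rates are estimated with Nei-Gojobori (1986)
counting: expected synonymous/nonsynonymous sites per codon from the
fraction of single-base changes that preserve the amino acid, observed
differences averaged with equal weights over all orderings of single-base
steps between differing codons, and a Jukes-Cantor multiple-hit
correction d = -(3/4)·ln(1 - (4/3)p).

A change to or from a stop codon is counted as nonsynonymous (a stop is
not an amino acid), which keeps the site-count identity S + N = 3 per
compared codon.  Codons containing gaps or ambiguity, and pairs where
either codon is a stop, are skipped pairwise; internal stops trigger a
warning.

Confidence intervals follow the K-estimator idea: a parametric bootstrap
resimulates difference counts at the estimated rates and takes empirical
percentiles of the re-estimates.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "PairwiseRates",
    "WindowScan",
    "WindowResult",
    "ng86_pairwise",
    "sliding_window_dnds",
    "mc_confidence_interval",
    "jukes_cantor",
]

logger = logging.getLogger(__name__)

BASES = "ACGT"
_AA = standard_dna_table.forward_table
_STOPS = frozenset(standard_dna_table.stop_codons)


def _is_codon(c: str) -> bool:
    return len(c) == 3 and all(b in BASES for b in c)


@lru_cache(maxsize=None)
def _syn_site_fraction(codon: str) -> float:
    """Expected synonymous sites of one codon (0..3): at each position, the
    fraction of the 3 possible changes that are synonymous."""
    s = 0.0
    aa = _AA[codon]
    for pos in range(3):
        syn = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if mutant not in _STOPS and _AA[mutant] == aa:
                syn += 1
        s += syn / 3.0
    return s


def _step_class(a: str, b: str) -> int:
    """1 if the single-base step a->b is synonymous, else 0; steps touching
    a stop codon count as nonsynonymous."""
    if a in _STOPS or b in _STOPS:
        return 0
    return int(_AA[a] == _AA[b])


@lru_cache(maxsize=None)
def _pair_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons, averaged
    with equal weights over all orderings of the single-base steps."""
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    syn_total = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_pos):
        current = codon_a
        syn = 0
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            syn += _step_class(current, nxt)
            current = nxt
        syn_total += syn
        n_paths += 1
    syn_mean = syn_total / n_paths
    return syn_mean, len(diff_pos) - syn_mean


def jukes_cantor(p: float) -> float:
    """Multiple-hit correction; NaN when the proportion is saturated
    (p >= 3/4)."""
    if p < 0:
        raise ValueError("difference proportion must be non-negative")
    if p >= 0.75:
        return float("nan")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


@dataclass(frozen=True)
class PairwiseRates:
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    codons_compared: int
    dS: float
    dN: float

    @property
    def omega(self) -> float:
        """dN/dS; NaN when dS is zero or either rate is saturated."""
        if not np.isfinite(self.dS) or not np.isfinite(self.dN) or self.dS == 0:
            return float("nan")
        return self.dN / self.dS

    @property
    def saturated(self) -> bool:
        return (self.syn_sites > 0 and self.syn_diffs / self.syn_sites >= 0.75) or (
            self.nonsyn_sites > 0 and self.nonsyn_diffs / self.nonsyn_sites >= 0.75
        )


def _codon_list(seq: str) -> list[str]:
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} is not divisible by 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def _rates_from_counts(S: float, N: float, sd: float, nd: float, n_codons: int) -> PairwiseRates:
    dS = jukes_cantor(sd / S) if S > 0 else 0.0
    dN = jukes_cantor(nd / N) if N > 0 else 0.0
    return PairwiseRates(S, N, sd, nd, n_codons, dS, dN)


def ng86_pairwise(codon_a: str, codon_b: str) -> PairwiseRates:
    """NG86 rates between two in-frame sequences of equal length.

    Site counts are averaged across the two sequences.  Codon pairs are
    skipped when either codon has a gap/ambiguity or is a stop codon.
    """
    ca, cb = _codon_list(codon_a), _codon_list(codon_b)
    if len(ca) != len(cb):
        raise ValueError("sequences must have equal length")
    S = N = sd = nd = 0.0
    used = 0
    stops_seen = 0
    for x, y in zip(ca, cb):
        if not (_is_codon(x) and _is_codon(y)):
            continue
        if x in _STOPS or y in _STOPS:
            stops_seen += 1
            continue
        s_sites = 0.5 * (_syn_site_fraction(x) + _syn_site_fraction(y))
        S += s_sites
        N += 3.0 - s_sites
        s, n = _pair_diffs(x, y)
        sd += s
        nd += n
        used += 1
    if stops_seen:
        warnings.warn(
            f"{stops_seen} internal stop codon pair(s) skipped", stacklevel=2
        )
    return _rates_from_counts(S, N, sd, nd, used)


@dataclass(frozen=True)
class WindowResult:
    start_codon: int
    rates: PairwiseRates
    ci_dN: tuple[float, float] | None = None
    ci_dS: tuple[float, float] | None = None
    ci_omega: tuple[float, float] | None = None


@dataclass(frozen=True)
class WindowScan:
    window_size: int
    step: int
    per_window: tuple[WindowResult, ...]
    whole_gene: PairwiseRates


def sliding_window_dnds(
    codon_a: str,
    codon_b: str,
    window_size: int = 150,
    step: int = 25,
    nsim: int | None = None,
    seed: int = 0,
) -> WindowScan:
    """Sliding-window NG86 scan plus the whole-gene estimate.

    Windows are ``window_size`` codons advanced by ``step``; the final
    window is anchored at the 3' end so the scan tiles the full coding
    region.  If ``nsim`` is given, each window carries Monte-Carlo
    confidence intervals.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    ca, cb = _codon_list(codon_a), _codon_list(codon_b)
    if len(ca) != len(cb):
        raise ValueError("sequences must have equal length")
    n = len(ca)
    if window_size > n:
        raise ValueError("window_size exceeds coding length in codons")
    starts = list(range(0, n - window_size + 1, step))
    if starts[-1] != n - window_size:
        starts.append(n - window_size)
    windows = []
    for w, start in enumerate(starts):
        a = "".join(ca[start : start + window_size])
        b = "".join(cb[start : start + window_size])
        rates = ng86_pairwise(a, b)
        ci_dn = ci_ds = ci_w = None
        if nsim:
            ci = mc_confidence_interval(rates, window_size, nsim, seed=seed + w)
            ci_dn, ci_ds, ci_w = ci["dN"], ci["dS"], ci["omega"]
        windows.append(WindowResult(start, rates, ci_dn, ci_ds, ci_w))
    return WindowScan(window_size, step, tuple(windows), ng86_pairwise(codon_a, codon_b))


def mc_confidence_interval(
    rates: PairwiseRates,
    codons: int,
    nsim: int,
    seed: int,
    level: float = 0.95,
) -> dict[str, tuple[float, float]]:
    """Parametric-bootstrap 95% intervals for dN, dS and omega.

    Synonymous and nonsynonymous difference counts are resimulated as
    binomials over the estimated site counts at the Jukes-Cantor-inverted
    per-site difference probabilities, re-estimated, and the empirical
    2.5/97.5 percentiles taken.  Deterministic given ``seed``.  When the
    input rates are saturated the interval is reported as saturated (NaN).
    """
    if nsim < 100:
        raise ValueError("nsim must be >= 100")
    nan = (float("nan"), float("nan"))
    if rates.saturated:
        return {"dN": nan, "dS": nan, "omega": nan}
    if rates.dS == 0 and rates.dN == 0:
        return {"dN": (0.0, 0.0), "dS": (0.0, 0.0), "omega": nan}
    rng = np.random.default_rng(seed)
    n_s = max(int(round(rates.syn_sites)), 1)
    n_n = max(int(round(rates.nonsyn_sites)), 1)
    p_s = 0.75 * (1.0 - np.exp(-4.0 * rates.dS / 3.0)) if rates.dS > 0 else 0.0
    p_n = 0.75 * (1.0 - np.exp(-4.0 * rates.dN / 3.0)) if rates.dN > 0 else 0.0
    sd = rng.binomial(n_s, p_s, size=nsim)
    nd = rng.binomial(n_n, p_n, size=nsim)
    with np.errstate(invalid="ignore", divide="ignore"):
        ds = np.where(sd / n_s < 0.75, -0.75 * np.log1p(-4.0 * sd / n_s / 3.0), np.nan)
        dn = np.where(nd / n_n < 0.75, -0.75 * np.log1p(-4.0 * nd / n_n / 3.0), np.nan)
        om = np.where(ds > 0, dn / ds, np.nan)
    q = [(1 - level) / 2 * 100, (1 + level) / 2 * 100]

    def pct(v):
        v = v[np.isfinite(v)]
        if v.size == 0:
            return nan
        lo, hi = np.percentile(v, q)
        return (float(lo), float(hi))

    return {"dN": pct(dn), "dS": pct(ds), "omega": pct(om)}
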