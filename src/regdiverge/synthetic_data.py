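"""Seeded generators for every input the pipeline consumes.

The pipeline's statistical machinery (rate-heterogeneity LRT, sliding-window
dN/dS, growth-delay phenotyping, chimera effect decomposition, expression
ANOVA) is exercised on synthetic data with the structure each stage assumes:

* HKY85 sequence evolution on the fixed ((cer,par),mik,bay) topology with
  branch-specific rate multipliers and optional gap runs,
* chimeric-allele phenotype tables with 5-region additive effects, pairwise
  interactions, per-plate (batch) random intercepts and residual noise,
* shifted-logistic growth-curve pairs, and
* expression matrices with coding / noncoding / interaction / time spikes.

Every generator is a pure function of its arguments including ``seed``.
These generators deliberately do not call the analysis code they feed:
the sequence simulator assembles its own HKY85 generator matrix and
exponentiates it with :func:`scipy.linalg.expm`, so simulation and the
pruning likelihood engine share no numerical path.  Only the plain data
containers (alignment, tree, growth curve) are reused.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from scipy.linalg import expm

from .phylo_core import (
    BranchRates,
    HKY85Params,
    NucAlignment,
    ScaledTree,
    _TreeNode,
)

__all__ = [
    "substreams",
    "simulate_alignment",
    "simulate_chimera_table",
    "default_chimera_designs",
    "simulate_growth_pair",
    "simulate_expression_matrix",
    "standard_expression_design",
    "simulate_codon_pair",
]

BASES = "ACGT"


def substreams(seed: int, n: int) -> list[np.random.Generator]:
    """Fan one integer seed out to ``n`` independent generators.

    Uses NumPy's ``SeedSequence.spawn`` so multi-stage runs are reproducible
    from a single seed without stream collisions.
    """
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------


def _hky85_generator(kappa: float, pi: np.ndarray) -> np.ndarray:
    # deliberately re-derived here rather than imported (oracle independence)
    Q = np.tile(np.asarray(pi, dtype=float), (4, 1))
    for i, j in ((0, 2), (1, 3)):  # A<->G, C<->T transitions
        Q[i, j] *= kappa
        Q[j, i] *= kappa
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q / (-float(pi @ np.diag(Q)))


def simulate_alignment(
    tree: ScaledTree,
    params: HKY85Params,
    rates: BranchRates,
    length: int,
    seed: int,
    indel_fraction: float | None = None,
    indel_mean_run: float = 5.0,
) -> NucAlignment:
    """Simulate an alignment under HKY85 along ``tree``.

    Each branch b evolves for an effective length ``L_b * r_b``; root states
    are drawn from the stationary frequencies.  If ``indel_fraction`` is
    given, contiguous gap runs with geometric lengths (mean
    ``indel_mean_run`` columns) are written into random taxa until at least
    that fraction of columns contains a gap.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if indel_fraction is not None and indel_fraction >= 1:
        raise ValueError("indel_fraction must be < 1")
    rng = np.random.default_rng(seed)
    Q = _hky85_generator(params.kappa, params.pi)
    eff = tree.branch_lengths * rates.per_branch(tree.n_branches)
    P = np.array([expm(Q * t) for t in eff])

    tip_states: dict[str, np.ndarray] = {}

    def evolve(node: _TreeNode, states: np.ndarray):
        for child in node.children:
            probs = P[child.edge_index][states]  # (length, 4)
            child_states = _sample_rows(rng, probs)
            if child.children:
                evolve(child, child_states)
            else:
                tip_states[child.label] = child_states

    root_states = rng.choice(4, size=length, p=params.pi)
    evolve(tree.root, root_states)

    matrix = np.vstack([tip_states[t] for t in tree.tip_labels]).astype(np.int8)
    if indel_fraction:
        target = int(np.ceil(indel_fraction * length))
        gapped = np.zeros(length, dtype=bool)
        while gapped.sum() < target:
            run = min(1 + rng.geometric(1.0 / indel_mean_run), length)
            start = rng.integers(0, length - run + 1)
            taxon = rng.integers(0, matrix.shape[0])
            matrix[taxon, start : start + run] = -1
            gapped[start : start + run] = True
    return NucAlignment(tree.tip_labels, matrix)


def _sample_rows(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """Draw one categorical sample per row of a (n, k) probability matrix."""
    cum = probs.cumsum(axis=1)
    cum /= cum[:, -1:]
    u = rng.random((probs.shape[0], 1))
    return (u > cum).sum(axis=1)


# ---------------------------------------------------------------------------
# Chimeric-allele phenotype tables
# ---------------------------------------------------------------------------

# 22 constructs mirroring the study: both full-length parents, the 5
# single-region reciprocal swaps, and 5 pairwise (adjacent + outermost)
# reciprocal swaps.
_PAIR_SWAPS = [(0, 1), (1, 2), (2, 3), (3, 4), (0, 4)]


def default_chimera_designs() -> pd.DataFrame:
    """Region-origin indicators (0 = reference species, 1 = alternate) for
    the default 22-construct panel."""
    rows = []

    def add(bits):
        rows.append({"construct": "".join("CP"[b] for b in bits), **{f"region{i+1}": bits[i] for i in range(5)}})

    add([0] * 5)
    add([1] * 5)
    for i in range(5):
        for base in (0, 1):
            bits = [base] * 5
            bits[i] = 1 - base
            add(bits)
    for i, j in _PAIR_SWAPS:
        for base in (0, 1):
            bits = [base] * 5
            bits[i] = 1 - base
            bits[j] = 1 - base
            add(bits)
    return pd.DataFrame(rows)


def simulate_chimera_table(
    effects,
    interactions=None,
    batch_sd: float = 0.5,
    residual_sd: float = 0.5,
    constructs: pd.DataFrame | None = None,
    reps: int = 3,
    intercept: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate growth-delay phenotypes for a chimeric-allele panel.

    value = intercept + x·effects + sum_{i<j} interactions_ij x_i x_j
            + batch intercept ~ N(0, batch_sd^2) + N(0, residual_sd^2)

    Each replicate is one batch (96-well plate) containing every construct;
    one day per batch.  ``interactions`` is a length-10 vector ordered
    (1,2),(1,3),(1,4),(1,5),(2,3),(2,4),(2,5),(3,4),(3,5),(4,5).
    """
    if batch_sd < 0 or residual_sd < 0:
        raise ValueError("standard deviations must be non-negative")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    effects = np.asarray(effects, dtype=float)
    if effects.shape != (5,):
        raise ValueError("exactly 5 additive region effects required")
    if interactions is None:
        interactions = np.zeros(10)
    interactions = np.asarray(interactions, dtype=float)
    if interactions.shape != (10,):
        raise ValueError("exactly 10 pairwise interactions required")
    if constructs is None:
        constructs = default_chimera_designs()
    rng = np.random.default_rng(seed)

    X = constructs[[f"region{i+1}" for i in range(5)]].to_numpy(dtype=float)
    pair_idx = [(i, j) for i in range(5) for j in range(i + 1, 5)]
    XX = np.column_stack([X[:, i] * X[:, j] for i, j in pair_idx])
    mean = intercept + X @ effects + XX @ interactions

    rows = []
    for rep in range(reps):
        b = rng.normal(0.0, batch_sd)
        noise = rng.normal(0.0, residual_sd, size=len(constructs))
        for k in range(len(constructs)):
            rows.append(
                {
                    "construct": constructs["construct"].iloc[k],
                    **{f"region{i+1}": int(X[k, i]) for i in range(5)},
                    "day": f"day{rep + 1}",
                    "batch": f"plate{rep + 1}",
                    "delay_hours": mean[k] + b + noise[k],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Growth curves
# ---------------------------------------------------------------------------


def simulate_growth_pair(
    t_inflection: float,
    shift_hours: float,
    noise_sd: float = 0.0,
    sampling_min: float = 10.0,
    seed: int = 0,
    duration_h: float = 20.0,
    od_floor: float = 0.1,
    od_ceiling: float = 1.5,
    growth_rate: float = 1.0,
    label: str = "strain",
):
    """A (control, sulfite) pair of shifted-logistic growth curves.

    log-OD follows a logistic rise from log(od_floor) to log(od_ceiling)
    with inflection at ``t_inflection`` (so the maximum specific growth
    rate — the peak of d log OD/dt — sits exactly at the inflection, the
    landmark the delay statistic uses).  The sulfite curve is the control
    curve translated ``shift_hours`` later in time; i.i.d. Gaussian noise
    of sd ``noise_sd`` is added to the OD readings (floored at a small
    positive value so log-OD stays defined).
    """
    from .phenotype import GrowthCurve

    if sampling_min <= 0:
        raise ValueError("sampling interval must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration_h + 1e-9, sampling_min / 60.0)
    lo, hi = np.log(od_floor), np.log(od_ceiling)

    def logistic(t0):
        od = np.exp(lo + (hi - lo) / (1.0 + np.exp(-growth_rate * (times - t0))))
        if noise_sd > 0:
            od = od + rng.normal(0.0, noise_sd, size=times.size)
            od = np.maximum(od, 1e-4)
        return od

    control = GrowthCurve(times, logistic(t_inflection), label=f"{label}:control")
    sulfite = GrowthCurve(times, logistic(t_inflection + shift_hours), label=f"{label}:sulfite")
    return control, sulfite


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


def standard_expression_design(
    n_bio_reps: int = 3,
    times=(0, 15),
    n_tech_reps: int = 2,
) -> pd.DataFrame:
    """Sample sheet for the four-allele chimera expression experiment.

    Alleles are noncoding.coding origin pairs: C.C and P.P full-length
    parents plus the two reciprocal promoter/coding chimeras.  Columns:
    sample, allele, noncoding_origin, coding_origin, time, replicate,
    tech_replicate.
    """
    alleles = [("C.C", 0, 0), ("C.P", 0, 1), ("P.C", 1, 0), ("P.P", 1, 1)]
    rows = []
    for allele, nc, cd in alleles:
        for t in times:
            for rep in range(1, n_bio_reps + 1):
                for tech in range(1, n_tech_reps + 1):
                    rows.append(
                        {
                            "sample": f"{allele}_t{t}_r{rep}_f{tech}",
                            "allele": allele,
                            "noncoding_origin": nc,
                            "coding_origin": cd,
                            "time": t,
                            "replicate": rep,
                            "tech_replicate": tech,
                        }
                    )
    return pd.DataFrame(rows)


def simulate_expression_matrix(
    n_genes: int,
    design: pd.DataFrame,
    spike_spec: dict[str, tuple[int, float]] | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Log-scale expression matrix (genes x samples) with spiked effects.

    ``spike_spec`` maps effect source -> (count, effect size in noise-sd
    units); sources: ``coding``, ``noncoding``, ``interaction`` (coding x
    noncoding), ``time``, ``allele_time`` (coding x time).  Background
    genes are pure N(0, noise_sd) noise.  Returns the matrix and a Series
    of ground-truth spike labels ("null" for background genes).
    """
    spike_spec = dict(spike_spec or {})
    total = sum(n for n, _ in spike_spec.values())
    if total > n_genes:
        raise ValueError("spike counts exceed n_genes")
    required = {"noncoding_origin", "coding_origin", "time"}
    if not required.issubset(design.columns):
        raise ValueError(f"design must have columns {sorted(required)}")
    rng = np.random.default_rng(seed)

    nc = design["noncoding_origin"].to_numpy(dtype=float) - 0.5
    cd = design["coding_origin"].to_numpy(dtype=float) - 0.5
    late = (design["time"].to_numpy(dtype=float) > 0).astype(float)
    patterns = {
        "coding": cd,
        "noncoding": nc,
        "interaction": 2.0 * nc * cd,  # +-0.5 pattern, XOR of origins
        "time": late - late.mean(),
        "allele_time": cd * (late - late.mean()) * 2.0,
    }

    n_samples = len(design)
    values = rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    labels = np.array(["null"] * n_genes, dtype=object)
    g = 0
    for source, (count, size) in spike_spec.items():
        if source not in patterns:
            raise ValueError(f"unknown spike source {source!r}")
        for _ in range(count):
            values[g] += size * noise_sd * patterns[source]
            labels[g] = source
            g += 1

    genes = [f"gene{i+1:05d}" for i in range(n_genes)]
    matrix = pd.DataFrame(values, index=genes, columns=design["sample"].tolist())
    return matrix, pd.Series(labels, index=genes, name="spike")


# ---------------------------------------------------------------------------
# Codon pairs for dN/dS
# ---------------------------------------------------------------------------

_STOPS = set(standard_dna_table.stop_codons)
_AA = standard_dna_table.forward_table


def simulate_codon_pair(n_codons: int, ds: float, dn: float, seed: int) -> tuple[str, str]:
    """A pair of in-frame sequences with target synonymous rate ``ds`` and
    nonsynonymous rate ``dn`` per site.

    Starting from a random stop-free codon sequence, each position of the
    second copy is substituted to a specific alternative base with
    probability p_s/3 (synonymous change) or p_n/3 (nonsynonymous change),
    where p = (3/4)(1 - exp(-4d/3)) is the Jukes-Cantor-inverted difference
    proportion.  At most one substitution per position per draw; multi-hit
    codons arise naturally when neighbouring positions are hit.
    """
    if ds < 0 or dn < 0:
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    p_s = 0.75 * (1.0 - np.exp(-4.0 * ds / 3.0))
    p_n = 0.75 * (1.0 - np.exp(-4.0 * dn / 3.0))
    sense = sorted(set(_AA) - _STOPS)
    seq_a = [sense[i] for i in rng.integers(0, len(sense), size=n_codons)]
    seq_b = []
    for codon in seq_a:
        new = list(codon)
        for pos in range(3):
            current = "".join(new)
            alts = [b for b in BASES if b != current[pos]]
            probs = []
            for b in alts:
                mutant = current[:pos] + b + current[pos + 1 :]
                if mutant in _STOPS:  # never create a stop codon
                    probs.append(0.0)
                elif _AA[mutant] == _AA[current]:
                    probs.append(p_s / 3.0)
                else:
                    probs.append(p_n / 3.0)
            probs.append(1.0 - sum(probs))
            choice = rng.choice(4, p=probs)
            if choice < 3:
                new[pos] = alts[choice]
        seq_b.append("".join(new))
    return "".join(seq_a), "".join(seq_b)
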