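"""Nucleotide substitution model, tree handling, and pruning likelihood.

The rate-heterogeneity screen compares the substitution rate of a noncoding
region against the genome-wide rate at fourfold-degenerate coding sites.
This module supplies the pieces that comparison is built from:

* the HKY85 substitution model (unequal base frequencies, a
  transition/transversion ratio kappa) and its transition probabilities,
* Felsenstein pruning over a fixed 4-taxon topology, with per-branch rate
  multipliers so that the effective length of branch b is ``L_b * r_b``,
* extraction of fourfold-degenerate third codon positions, the neutral
  proxy used to scale the tree, and
* maximum-likelihood branch-length estimation on those sites.

Gap and ambiguous characters are treated as missing data (a partial
likelihood vector of ones at the tip), the standard pruning convention,
so the per-locus alignment length is preserved for the indel filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "NucAlignment",
    "ScaledTree",
    "HKY85Params",
    "BranchRates",
    "BranchLengthFit",
    "hky85_rate_matrix",
    "hky85_transition_probs",
    "HKY85EigenSystem",
    "pruning_log_likelihood",
    "extract_fourfold_sites",
    "estimate_branch_lengths",
    "empirical_base_frequencies",
    "fourfold_degenerate_codons",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
GAP_CODE = -1  # gaps and ambiguity codes share the missing-data code


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX.get(c, GAP_CODE) for c in seq.upper()], dtype=np.int8)


def _decode(row: np.ndarray) -> str:
    return "".join(BASES[c] if c >= 0 else "-" for c in row)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NucAlignment:
    """A gapped nucleotide alignment with one row per taxon.

    ``matrix`` holds integer codes (A,C,G,T -> 0..3; gap or ambiguous -> -1)
    with shape ``(n_taxa, length)``.
    """

    taxa: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.int8)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "taxa", tuple(self.taxa))
        if m.ndim != 2 or m.shape[0] != len(self.taxa):
            raise ValueError("matrix must be (n_taxa, length)")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxon labels must be unique")
        if m.shape[1] < 1:
            raise ValueError("alignment must have at least one column")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @classmethod
    def from_sequences(cls, items) -> "NucAlignment":
        """Build from ``{name: sequence}`` or an iterable of ``(name, seq)``."""
        pairs = list(items.items()) if hasattr(items, "items") else list(items)
        names = [p[0] for p in pairs]
        rows = [_encode(p[1]) for p in pairs]
        lengths = {r.size for r in rows}
        if len(lengths) != 1:
            raise ValueError("all sequences must have equal length")
        return cls(tuple(names), np.vstack(rows))

    @classmethod
    def from_fasta(cls, path) -> "NucAlignment":
        records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
        if not records:
            raise ValueError(f"no sequences in {path}")
        return cls.from_sequences(records)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, row in zip(self.taxa, self.matrix):
                fh.write(f">{name}\n{_decode(row)}\n")

    def sequence(self, taxon: str) -> str:
        return _decode(self.matrix[self.taxa.index(taxon)])

    def take_columns(self, idx) -> "NucAlignment":
        return NucAlignment(self.taxa, self.matrix[:, idx])

    def concat(self, other: "NucAlignment") -> "NucAlignment":
        if self.taxa != other.taxa:
            raise ValueError("taxa must match to concatenate")
        return NucAlignment(self.taxa, np.hstack([self.matrix, other.matrix]))


@dataclass(frozen=True)
class _TreeNode:
    label: str | None
    children: tuple["_TreeNode", ...]
    # index into the branch-length vector of the edge above this node;
    # -1 for the (unrooted) seed node which has no edge above it
    edge_index: int


@dataclass(frozen=True)
class ScaledTree:
    """A fixed topology whose branch lengths are substitutions/site.

    For the screen the lengths are the genome-wide rates at
    fourfold-degenerate sites, the neutral yardstick that dNC/dS is
    measured against.  A 4-taxon unrooted tree is represented rooted at
    its internal trifurcation and has 5 branches.  Branch order is the
    postorder of nodes below the seed node.
    """

    root: _TreeNode
    branch_lengths: np.ndarray
    branch_names: tuple[str, ...]

    def __post_init__(self):
        bl = np.asarray(self.branch_lengths, dtype=float)
        object.__setattr__(self, "branch_lengths", bl)
        if not np.all(np.isfinite(bl)) or np.any(bl < 0):
            raise ValueError("branch lengths must be finite and non-negative")

    @property
    def n_branches(self) -> int:
        return self.branch_lengths.size

    @property
    def tip_labels(self) -> tuple[str, ...]:
        labels: list[str] = []

        def walk(node: _TreeNode):
            if not node.children:
                labels.append(node.label)
            for c in node.children:
                walk(c)

        walk(self.root)
        return tuple(labels)

    @classmethod
    def from_newick(cls, newick: str) -> "ScaledTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        counter = [0]
        names: list[str] = []
        lengths: list[float] = []

        def convert(node) -> _TreeNode:
            children = tuple(convert(c) for c in node.child_nodes())
            if node.parent_node is None:
                return _TreeNode(None, children, -1)
            idx = counter[0]
            counter[0] += 1
            if children:
                tips = sorted(
                    leaf.taxon.label for leaf in node.leaf_iter()
                )
                name = "internal:" + "|".join(tips)
            else:
                name = node.taxon.label
            length = node.edge.length
            if length is None:
                raise ValueError(f"branch above {name} has no length")
            names.append(name)
            lengths.append(float(length))
            return _TreeNode(name if not children else None, children, idx)

        root = convert(tree.seed_node)
        return cls(root, np.array(lengths), tuple(names))

    @classmethod
    def from_newick_file(cls, path) -> "ScaledTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def with_branch_lengths(self, lengths) -> "ScaledTree":
        lengths = np.asarray(lengths, dtype=float)
        if lengths.shape != self.branch_lengths.shape:
            raise ValueError("branch length vector has wrong size")
        return replace(self, branch_lengths=lengths)

    def to_newick(self) -> str:
        def fmt(node: _TreeNode) -> str:
            if node.children:
                inner = ",".join(fmt(c) for c in node.children)
                body = f"({inner})"
            else:
                body = node.label
            if node.edge_index < 0:
                return body
            return f"{body}:{self.branch_lengths[node.edge_index]:.10g}"

        return fmt(self.root) + ";"


# the study's fixed topology: ((cerevisiae,paradoxus),mikatae,bayanus) unrooted
YEAST_TOPOLOGY = "((cer:0.1,par:0.1):0.1,mik:0.1,bay:0.1);"


def yeast_tree(branch_lengths=None) -> ScaledTree:
    """The fixed 4-species *Saccharomyces* topology, optionally re-scaled."""
    tree = ScaledTree.from_newick(YEAST_TOPOLOGY)
    if branch_lengths is not None:
        tree = tree.with_branch_lengths(branch_lengths)
    return tree


@dataclass(frozen=True)
class HKY85Params:
    """HKY85 parameters: transition/transversion ratio and base frequencies."""

    kappa: float
    pi: np.ndarray

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float)
        object.__setattr__(self, "pi", pi)
        if self.kappa <= 0 or not np.isfinite(self.kappa):
            raise ValueError("kappa must be positive and finite")
        if pi.shape != (4,) or np.any(pi < 0):
            raise ValueError("pi must be 4 non-negative frequencies")
        if abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError("pi must sum to 1 within 1e-12")


@dataclass(frozen=True)
class BranchRates:
    """dNC/dS multipliers: one shared (constrained) or one per branch."""

    mode: str  # "constrained" | "unconstrained"
    ratios: np.ndarray

    def __post_init__(self):
        r = np.atleast_1d(np.asarray(self.ratios, dtype=float))
        object.__setattr__(self, "ratios", r)
        if self.mode not in ("constrained", "unconstrained"):
            raise ValueError("mode must be 'constrained' or 'unconstrained'")
        if self.mode == "constrained" and r.size != 1:
            raise ValueError("constrained mode takes exactly one ratio")
        if np.any(r < 0) or not np.all(np.isfinite(r)):
            raise ValueError("ratios must be finite and non-negative")

    def per_branch(self, n_branches: int) -> np.ndarray:
        if self.mode == "constrained":
            return np.full(n_branches, self.ratios[0])
        if self.ratios.size != n_branches:
            raise ValueError(
                f"unconstrained mode needs {n_branches} ratios, got {self.ratios.size}"
            )
        return self.ratios

    @classmethod
    def shared(cls, ratio: float = 1.0) -> "BranchRates":
        return cls("constrained", np.array([ratio]))

    @classmethod
    def free(cls, ratios) -> "BranchRates":
        return cls("unconstrained", np.asarray(ratios, dtype=float))


# ---------------------------------------------------------------------------
# HKY85 transition probabilities
# ---------------------------------------------------------------------------

_TRANSITION_PAIRS = ((0, 2), (1, 3))  # A<->G, C<->T


def hky85_rate_matrix(params: HKY85Params) -> np.ndarray:
    """Instantaneous HKY85 generator, normalized to one expected
    substitution per unit branch length at stationarity."""
    pi = params.pi
    if np.any(pi <= 0):
        raise ValueError(
            "HKY85 with a zero base frequency is unsupported; "
            "all four frequencies must be positive"
        )
    Q = np.tile(pi, (4, 1)).astype(float)
    for i, j in _TRANSITION_PAIRS:
        Q[i, j] *= params.kappa
        Q[j, i] *= params.kappa
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -float(pi @ np.diag(Q))
    return Q / mean_rate


class HKY85EigenSystem:
    """Spectral decomposition of the HKY85 generator.

    Reversibility makes ``diag(sqrt(pi)) Q diag(1/sqrt(pi))`` symmetric, so a
    single `eigh` call yields a numerically stable decomposition from which
    P(t) for any set of branch lengths is a broadcast multiply.  Detailed
    balance holds to round-off by construction.
    """

    def __init__(self, params: HKY85Params):
        self.params = params
        Q = hky85_rate_matrix(params)
        sqrt_pi = np.sqrt(params.pi)
        B = (Q / sqrt_pi[None, :]) * sqrt_pi[:, None]
        B = 0.5 * (B + B.T)  # symmetrize round-off
        w, U = np.linalg.eigh(B)
        self._w = w
        self._left = U / sqrt_pi[:, None]  # D^{-1/2} U
        self._right = (U * sqrt_pi[:, None]).T  # U' D^{1/2}

    def transition_probs(self, t) -> np.ndarray:
        """P(t); ``t`` may be a scalar or a vector of branch lengths."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("branch length must be non-negative")
        expwt = np.exp(np.multiply.outer(t, self._w))  # (..., 4)
        P = np.einsum("ik,...k,kj->...ij", self._left, expwt, self._right)
        return P


def hky85_transition_probs(params: HKY85Params, t: float) -> np.ndarray:
    """HKY85 transition probability matrix P(t) for a single branch length."""
    return HKY85EigenSystem(params).transition_probs(float(t))


# ---------------------------------------------------------------------------
# Pruning likelihood
# ---------------------------------------------------------------------------


def _site_patterns(aln: NucAlignment) -> tuple[np.ndarray, np.ndarray]:
    """Unique alignment columns and their multiplicities."""
    cols = np.ascontiguousarray(aln.matrix.T)
    patterns, counts = np.unique(cols, axis=0, return_counts=True)
    return patterns, counts


def _tip_partials(codes: np.ndarray) -> np.ndarray:
    """(n_patterns, 4) partial likelihoods for one taxon; missing -> ones."""
    n = codes.size
    out = np.zeros((n, 4))
    miss = codes < 0
    out[np.arange(n)[~miss], codes[~miss]] = 1.0
    out[miss] = 1.0
    return out


def pruning_log_likelihood(
    aln: NucAlignment,
    tree: ScaledTree,
    params: HKY85Params,
    rates: BranchRates | None = None,
) -> float:
    """Phylogenetic log-likelihood by Felsenstein pruning.

    Effective branch lengths are ``tree.branch_lengths * rates`` so the
    constrained/unconstrained rate models reuse one engine.  Sites are
    independent; the log-likelihood of concatenated alignments adds.
    """
    if set(aln.taxa) != set(tree.tip_labels):
        raise ValueError(
            f"alignment taxa {sorted(aln.taxa)} do not match "
            f"tree tips {sorted(tree.tip_labels)}"
        )
    if rates is None:
        rates = BranchRates.shared(1.0)
    eff = tree.branch_lengths * rates.per_branch(tree.n_branches)
    eig = HKY85EigenSystem(params)
    P = eig.transition_probs(eff)  # (n_branches, 4, 4)
    patterns, counts = _site_patterns(aln)
    taxon_row = {t: i for i, t in enumerate(aln.taxa)}

    def partial(node: _TreeNode) -> np.ndarray:
        if not node.children:
            return _tip_partials(patterns[:, taxon_row[node.label]])
        out = np.ones((patterns.shape[0], 4))
        for child in node.children:
            down = partial(child)
            out *= down @ P[child.edge_index].T
        return out

    root_partial = partial(tree.root)
    site_like = root_partial @ params.pi
    if np.any(site_like <= 0):
        return -np.inf
    return float(counts @ np.log(site_like))


def empirical_base_frequencies(aln: NucAlignment, pseudocount: float = 0.0) -> np.ndarray:
    """Observed A,C,G,T frequencies over the alignment, gaps excluded."""
    counts = np.array([(aln.matrix == i).sum() for i in range(4)], dtype=float)
    counts += pseudocount
    total = counts.sum()
    if total == 0:
        raise ValueError("alignment contains no unambiguous bases")
    return counts / total


# ---------------------------------------------------------------------------
# Fourfold-degenerate site extraction
# ---------------------------------------------------------------------------


def fourfold_degenerate_codons() -> frozenset[str]:
    """Codons whose third position is fourfold degenerate under the
    standard genetic code (any third base keeps the amino acid)."""
    table = standard_dna_table.forward_table
    out = set()
    for b1 in BASES:
        for b2 in BASES:
            aas = {table.get(b1 + b2 + b3) for b3 in BASES}
            if len(aas) == 1 and None not in aas:
                out.update(b1 + b2 + b3 for b3 in BASES)
    return frozenset(out)


_FOURFOLD = None


def extract_fourfold_sites(codon_aln: NucAlignment) -> NucAlignment:
    """Third positions of codons fourfold degenerate in every taxon.

    A column is retained only when, in each taxon, the codon is gap-free
    and its third position is fourfold degenerate.  The alignment length
    must be a multiple of 3 (in-frame).
    """
    global _FOURFOLD
    if _FOURFOLD is None:
        _FOURFOLD = fourfold_degenerate_codons()
    if codon_aln.length % 3 != 0:
        raise ValueError(
            f"alignment length {codon_aln.length} is not divisible by 3; "
            "an in-frame codon alignment is required"
        )
    keep = []
    m = codon_aln.matrix
    for c in range(codon_aln.length // 3):
        codons = m[:, 3 * c : 3 * c + 3]
        if np.any(codons < 0):
            continue
        ok = all(
            "".join(BASES[b] for b in row) in _FOURFOLD for row in codons
        )
        if ok:
            keep.append(3 * c + 2)
    if not keep:
        raise ValueError("no fourfold-degenerate sites found")
    return codon_aln.take_columns(np.array(keep))


# ---------------------------------------------------------------------------
# Branch-length estimation on fourfold sites
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BranchLengthFit:
    """Result of ML branch-length estimation on fourfold-degenerate sites."""

    tree: ScaledTree
    kappa: float
    pi: np.ndarray
    log_likelihood: float
    converged: bool
    message: str = ""


def estimate_branch_lengths(
    ff_sites: NucAlignment,
    topology: ScaledTree,
    estimate_kappa: bool = True,
    kappa: float = 2.0,
) -> BranchLengthFit:
    """ML branch lengths under HKY85 with empirical base frequencies.

    Branch lengths and (optionally) kappa are optimized jointly on log
    scale with L-BFGS-B.  Identical sequences give lengths at the lower
    bound, effectively zero.
    """
    from scipy.optimize import minimize

    pi = empirical_base_frequencies(ff_sites)
    nb = topology.n_branches
    lb, ub = 1e-8, 20.0

    def unpack(x):
        bl = np.exp(x[:nb])
        k = np.exp(x[nb]) if estimate_kappa else kappa
        return bl, k

    def neg_ll(x):
        bl, k = unpack(x)
        params = HKY85Params(k, pi)
        tree = topology.with_branch_lengths(bl)
        return -pruning_log_likelihood(ff_sites, tree, params)

    x0 = np.concatenate([np.log(np.full(nb, 0.05)), [np.log(2.0)] if estimate_kappa else []])
    bounds = [(np.log(lb), np.log(ub))] * nb + (
        [(np.log(0.05), np.log(100.0))] if estimate_kappa else []
    )
    res = minimize(neg_ll, x0, method="L-BFGS-B", bounds=bounds)
    bl, k = unpack(res.x)
    return BranchLengthFit(
        tree=topology.with_branch_lengths(bl),
        kappa=float(k),
        pi=pi,
        log_likelihood=-float(res.fun),
        converged=bool(res.success),
        message=str(res.message),
    )
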