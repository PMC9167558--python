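"""Hill-number alpha diversity and pairwise beta dissimilarity.

Taxonomic and phylogenetic facets share one framework: the phylogenetic
quantities are computed over tree branches, each branch ``b`` weighted by its
length ``L_b`` and carrying the summed relative abundance ``a_b`` of the
leaves below it, normalised by the mean depth ``T = sum_b L_b * a_b``.  On a
star tree with unit branches this collapses exactly onto the taxonomic case.

Pairwise beta is the two-community diversity ratio ``beta = gamma / alpha``
in ``[1, 2]`` (equal pooling weights), converted to a dissimilarity in
``[0, 1]`` with the Sorensen-type local overlap ``1 - C_qN`` (N = 2), which
reduces to classic Sorensen at q = 0 and to ``ln(beta)/ln(2)`` at q = 1.
The Jaccard-type regional overlap ``1 - U_qN`` is available as a variant.
q = 1 is always evaluated through its closed-form limit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables_io import PhyloTree, RelativeAbundanceTable, TaxonomyTable, aggregate_rank, CountTable
from .ordination_beta import DistanceMatrix

__all__ = [
    "HillConfig",
    "BranchDecomposition",
    "hill_alpha",
    "hill_phylo_alpha",
    "hill_beta_pair",
    "dissimilarity_matrix",
    "pairwise_dissimilarities",
]

_EPS = 1e-12


@dataclass(frozen=True)
class HillConfig:
    """One diversity configuration: order q, facet and taxonomic rank."""

    q: float = 1.0
    facet: str = "taxonomic"
    rank: str = "ASV"

    def __post_init__(self) -> None:
        if not np.isfinite(self.q) or self.q < 0:
            raise ValueError("q must be finite and >= 0")
        if self.facet not in ("taxonomic", "phylogenetic"):
            raise ValueError(f"unknown facet {self.facet!r}")

    @property
    def label(self) -> str:
        return f"q{self.q:g}_{self.facet}_{self.rank}"


def _check_simplex(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < -_EPS):
        raise ValueError("abundances must be non-negative")
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError(f"abundance vector sums to {p.sum():.6g}, not 1")
    return np.clip(p, 0.0, None)


def hill_alpha(p: np.ndarray, q: float) -> float:
    """Effective number of taxa of order *q* for one community.

    q = 0 is richness, q = 1 is exp(Shannon entropy), general q is
    ``(sum_i p_i^q)^(1/(1-q))`` over the support of ``p``.
    """
    p = _check_simplex(p)
    nz = p[p > 0]
    if q == 0:
        return float(nz.size)
    if q == 1:
        return float(np.exp(-np.sum(nz * np.log(nz))))
    return float(np.sum(nz**q) ** (1.0 / (1.0 - q)))


# ---------------------------------------------------------------------------
# branch decomposition
# ---------------------------------------------------------------------------


@dataclass
class BranchDecomposition:
    """Branch lengths and leaf-incidence of a rooted tree.

    ``incidence[b, i]`` is 1 when leaf ``i`` descends from branch ``b``;
    branch abundances for a community ``p`` are ``incidence @ p``.
    """

    lengths: np.ndarray
    incidence: np.ndarray
    leaf_names: list[str]

    @classmethod
    def from_tree(cls, tree: PhyloTree, feature_ids: list[str] | None = None) -> "BranchDecomposition":
        leaves = tree.leaf_names
        if feature_ids is None:
            feature_ids = leaves
        missing = set(feature_ids) - set(leaves)
        if missing:
            raise KeyError(f"features missing from tree: {sorted(missing)}")
        pos = {name: i for i, name in enumerate(feature_ids)}
        lengths = []
        rows = []
        for node in tree.tree.postorder(include_self=False):
            lengths.append(node.length or 0.0)
            row = np.zeros(len(feature_ids))
            for tip in node.tips(include_self=True):
                if tip.name in pos:
                    row[pos[tip.name]] = 1.0
            rows.append(row)
        return cls(np.asarray(lengths), np.asarray(rows), list(feature_ids))

    def abundances(self, p: np.ndarray) -> np.ndarray:
        return self.incidence @ p

    def mean_depth(self, p: np.ndarray) -> float:
        return float(self.lengths @ self.abundances(p))


def hill_phylo_alpha(p: np.ndarray, tree: PhyloTree, q: float) -> float:
    """Effective number of equally-divergent lineages of order *q*.

    ``(sum_b (L_b / T) a_b^q)^(1/(1-q))`` with ``T = sum_b L_b a_b``; the
    q = 1 limit is ``exp(-sum_b (L_b / T) a_b ln a_b)``.
    """
    p = _check_simplex(p)
    decomp = BranchDecomposition.from_tree(tree)
    if len(decomp.leaf_names) != p.size:
        raise ValueError(
            f"abundance vector length {p.size} does not match {len(decomp.leaf_names)} tree leaves"
        )
    a = decomp.abundances(p)
    t = float(decomp.lengths @ a)
    if t <= 0:
        raise ValueError("tree has zero mean depth under this abundance vector")
    w = decomp.lengths / t
    nz = a > 0
    if q == 1:
        return float(np.exp(-np.sum(w[nz] * a[nz] * np.log(a[nz]))))
    return float(np.sum(w[nz] * a[nz] ** q) ** (1.0 / (1.0 - q)))


# ---------------------------------------------------------------------------
# pairwise beta
# ---------------------------------------------------------------------------


def _beta_ratio(weights: np.ndarray, a1: np.ndarray, a2: np.ndarray, q: float) -> float:
    """gamma/alpha for two equally-weighted assemblages over weighted units."""
    abar = (a1 + a2) / 2.0
    nz = abar > 0
    w, abar = weights[nz], abar[nz]
    a1, a2 = a1[nz], a2[nz]
    if q == 1:
        ln_gamma = -np.sum(w * abar * np.log(abar))
        terms = np.zeros_like(w)
        for a in (a1, a2):
            half = a / 2.0
            pos = half > 0
            terms[pos] += half[pos] * np.log(half[pos])
        ln_alpha = -np.sum(w * terms) - np.log(2.0)
        beta = np.exp(ln_gamma - ln_alpha)
    elif q == 0:
        gamma = np.sum(w)
        alpha = 0.5 * (np.sum(w[a1 > 0]) + np.sum(w[a2 > 0]))
        beta = gamma / alpha
    else:
        gamma = np.sum(w * abar**q) ** (1.0 / (1.0 - q))
        pooled = np.sum(w * (a1 / 2.0) ** q) + np.sum(w * (a2 / 2.0) ** q)
        alpha = 0.5 * pooled ** (1.0 / (1.0 - q))
        beta = gamma / alpha
    return float(np.clip(beta, 1.0, 2.0))


def _beta_to_dissimilarity(beta: float, q: float, variant: str) -> float:
    if variant not in ("sorensen", "jaccard"):
        raise ValueError(f"unknown variant {variant!r}")
    if q == 1:
        d = np.log(beta) / np.log(2.0)
    elif variant == "sorensen":
        # 1 - C_qN with N = 2
        e = q - 1.0
        d = 1.0 - ((1.0 / beta) ** e - 0.5**e) / (1.0 - 0.5**e)
    else:
        # 1 - U_qN with N = 2
        e = 1.0 - q
        d = 1.0 - ((1.0 / beta) ** e - 0.5**e) / (1.0 - 0.5**e)
    return float(np.clip(d, 0.0, 1.0))


def _phylo_pair_beta(
    decomp: BranchDecomposition,
    a1: np.ndarray,
    a2: np.ndarray,
    q: float,
    prune: bool,
) -> float:
    """beta ratio for one pair from full-tree branch abundances.

    ``prune=True`` restricts to branches whose pooled abundance lies strictly
    inside (0, 1): branches outside the pair's union support carry 0 and
    branches on the root path above the support's MRCA carry the full mass 1,
    and dropping both is exactly equivalent to shearing the tree to the union
    support and recomputing the mean depth (collapsing unary chains leaves
    every length-weighted sum unchanged).
    """
    abar = (a1 + a2) / 2.0
    if prune:
        mask = (abar > 0) & (abar < 1.0 - 1e-9)
        if not mask.any():
            return 1.0  # identical single-leaf supports
    else:
        mask = abar > 0
    lengths = decomp.lengths[mask]
    a1, a2, abar = a1[mask], a2[mask], abar[mask]
    tbar = float(lengths @ abar)
    if tbar <= 0:
        raise ValueError("zero mean depth for this pair")
    return _beta_ratio(lengths / tbar, a1, a2, q)


def hill_beta_pair(
    p1: np.ndarray,
    p2: np.ndarray,
    q: float,
    facet: str = "taxonomic",
    tree: PhyloTree | None = None,
    variant: str = "sorensen",
    prune: bool = True,
) -> float:
    """Pairwise dissimilarity in [0, 1] between two communities.

    For the phylogenetic facet the tree is by default pruned to the union
    support of the pair and the mean depth recomputed (framework-consistent);
    ``prune=False`` keeps the full tree for a fixed-depth variant.
    """
    p1 = _check_simplex(p1)
    p2 = _check_simplex(p2)
    if p1.shape != p2.shape:
        raise ValueError("mismatched feature spaces")
    if facet == "taxonomic":
        weights = np.ones_like(p1)
        beta = _beta_ratio(weights, p1, p2, q)
    elif facet == "phylogenetic":
        if tree is None:
            raise ValueError("phylogenetic facet requires a tree")
        leaf_names = tree.leaf_names
        if len(leaf_names) != p1.size:
            raise ValueError("abundance vectors do not match tree leaves")
        decomp = BranchDecomposition.from_tree(tree)
        beta = _phylo_pair_beta(
            decomp, decomp.abundances(p1), decomp.abundances(p2), q, prune
        )
    else:
        raise ValueError(f"unknown facet {facet!r}")
    return _beta_to_dissimilarity(beta, q, variant)


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------


def pairwise_dissimilarities(P: np.ndarray, q: float, variant: str = "sorensen") -> np.ndarray:
    """Square matrix of taxonomic pairwise dissimilarities (vectorised paths).

    For q = 1 the Sorensen/Jaccard transforms coincide and the quantity is
    the Jensen-Shannon divergence of the pair divided by ln 2.
    """
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    out = np.zeros((n, n))
    if q == 0:
        pres = (P > 0).astype(float)
        inter = pres @ pres.T
        sizes = pres.sum(axis=1)
        union_terms = sizes[:, None] + sizes[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            if variant == "sorensen":
                out = (union_terms - 2 * inter) / union_terms
            else:
                out = (union_terms - 2 * inter) / (union_terms - inter)
        np.fill_diagonal(out, 0.0)
        return out
    if q == 1:
        logp = np.where(P > 0, np.log(np.clip(P, _EPS, None)), 0.0)
        h = -np.sum(P * logp, axis=1)
        for i in range(n - 1):
            m = (P[i] + P[i + 1 :]) / 2.0
            logm = np.where(m > 0, np.log(np.clip(m, _EPS, None)), 0.0)
            hm = -np.sum(m * logm, axis=1)
            jsd = hm - (h[i] + h[i + 1 :]) / 2.0
            out[i, i + 1 :] = np.clip(jsd / np.log(2.0), 0.0, 1.0)
        return out + out.T
    for i, j in itertools.combinations(range(n), 2):
        out[i, j] = out[j, i] = hill_beta_pair(P[i], P[j], q, "taxonomic", variant=variant)
    return out


def _aggregate_relative(
    table: RelativeAbundanceTable, taxonomy: TaxonomyTable | None, rank: str
) -> RelativeAbundanceTable:
    if rank == "ASV":
        return table
    # reuse the count-table pooling logic on scaled proportions
    scaled = (table.data * 1e9).round().astype(np.int64)
    agg = aggregate_rank(CountTable(scaled, table.feature_kind), taxonomy, rank)
    props = agg.data.to_numpy(dtype=float)
    props = props / props.sum(axis=1, keepdims=True)
    return RelativeAbundanceTable(
        pd.DataFrame(props, index=agg.data.index, columns=agg.data.columns), table.feature_kind
    )


def dissimilarity_matrix(
    table: RelativeAbundanceTable,
    config: HillConfig,
    tree: PhyloTree | None = None,
    taxonomy: TaxonomyTable | None = None,
    variant: str = "sorensen",
    prune: bool = True,
) -> DistanceMatrix:
    """All pairwise Hill dissimilarities under one configuration.

    Aggregation to the configured rank happens first; the phylogenetic facet
    requires rank = ASV (branch abundances are leaf-level) unless a
    rank-collapsed tree is supplied by the caller.
    """
    if len(table.sample_ids) < 2:
        raise ValueError("need at least two samples")
    if config.facet == "phylogenetic" and config.rank != "ASV":
        raise ValueError("phylogenetic facet requires rank='ASV' (or a collapsed tree)")
    work = _aggregate_relative(table, taxonomy, config.rank)
    P = work.proportions
    if config.facet == "taxonomic":
        mat = pairwise_dissimilarities(P, config.q, variant)
    else:
        if tree is None:
            raise ValueError("phylogenetic facet requires a tree")
        order = tree.leaf_names
        aligned = work.data.reindex(columns=order)
        if aligned.isna().any().any():
            missing = sorted(set(work.feature_ids) - set(order))
            raise KeyError(f"features missing from tree: {missing}")
        P = aligned.to_numpy(dtype=float)
        n = P.shape[0]
        mat = np.zeros((n, n))
        decomp = BranchDecomposition.from_tree(tree)
        A = P @ decomp.incidence.T  # (samples, branches)
        for i, j in itertools.combinations(range(n), 2):
            beta = _phylo_pair_beta(decomp, A[i], A[j], config.q, prune)
            mat[i, j] = mat[j, i] = _beta_to_dissimilarity(beta, config.q, variant)
    return DistanceMatrix(list(work.sample_ids), mat)
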