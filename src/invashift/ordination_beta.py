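"""Distance-matrix statistics: PCoA, PERMANOVA (sequential SS), PERMDISP.

PERMANOVA follows the McArdle & Anderson trace formulation: the Gower-centered
matrix ``G`` of ``-d^2/2`` is projected through hat matrices of the cumulative
(Type-I, sequential) design, pseudo-F is the ratio of mean squares, and the
p-value comes from free permutation of sample labels.  PERMDISP embeds the
matrix by PCoA keeping negative-eigenvalue axes and measures each sample's
distance to its group center with the imaginary-axis correction
``sqrt(max(0, d_pos^2 - d_neg^2))``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

from .tables_io import SampleMetadata

__all__ = [
    "DistanceMatrix",
    "PcoaResult",
    "PermanovaResult",
    "DispersionResult",
    "pcoa",
    "permanova",
    "pairwise_permanova",
    "permdisp",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarity matrix with explicit sample ids."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match id list")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(self.values < -1e-12):
            raise ValueError("negative dissimilarity")
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    def __len__(self) -> int:
        return len(self.sample_ids)

    def submatrix(self, sample_ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DistanceMatrix(list(sample_ids), self.values[np.ix_(idx, idx)])

    def between(self, ids_a: Sequence[str], ids_b: Sequence[str]) -> np.ndarray:
        ia = [self.sample_ids.index(s) for s in ids_a]
        ib = [self.sample_ids.index(s) for s in ids_b]
        return self.values[np.ix_(ia, ib)]

    def to_skbio(self):
        import skbio

        return skbio.DistanceMatrix(self.values, ids=self.sample_ids)

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids).to_csv(
            path, sep="\t", index_label="sample_id"
        )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


@dataclass
class PcoaResult:
    """Principal-coordinates embedding of a distance matrix.

    ``coordinates`` holds the real axes (positive eigenvalues); axes for
    negative eigenvalues are kept in ``neg_coordinates`` because dispersion
    analysis needs them for the imaginary correction.
    """

    sample_ids: list[str]
    eigenvalues: np.ndarray
    coordinates: pd.DataFrame
    neg_coordinates: np.ndarray
    proportion_explained: np.ndarray


def pcoa(dm: DistanceMatrix, eig_tol: float = 1e-9) -> PcoaResult:
    """Classical metric multidimensional scaling (Gower 1966).

    Negative eigenvalues (non-Euclidean input) are reported, not discarded:
    their axes are stored separately so downstream corrections can use them.
    """
    g = _gower_center(dm.values)
    eigvals, eigvecs = scipy.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    scale = max(np.abs(eigvals).max(), 1.0)
    pos = eigvals > eig_tol * scale
    neg = eigvals < -eig_tol * scale
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    neg_coords = eigvecs[:, neg] * np.sqrt(-eigvals[neg])
    pos_sum = eigvals[pos].sum()
    prop = eigvals[pos] / pos_sum if pos_sum > 0 else np.zeros(pos.sum())
    df = pd.DataFrame(
        coords,
        index=dm.sample_ids,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return PcoaResult(list(dm.sample_ids), eigvals, df, neg_coords, prop)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


@dataclass
class PermanovaResult:
    """Sequential-SS PERMANOVA table (one row per term plus residual/total)."""

    table: pd.DataFrame
    n_permutations: int
    terms: list[str]

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="term")


def _design_columns(labels: pd.Series) -> np.ndarray:
    return pd.get_dummies(labels, dtype=float).to_numpy()


def _hat(x: np.ndarray) -> np.ndarray:
    q = scipy.linalg.orth(x)
    return q @ q.T


def _permutation_indices(n: int, n_perm: int | str, rng: np.random.Generator):
    """Index rows for the permutation distribution.

    ``n_perm="exhaustive"`` enumerates all n! relabellings (n <= 9 enforced);
    otherwise ``n_perm`` Monte-Carlo permutations are drawn.
    """
    if n_perm == "exhaustive":
        if n > 9:
            raise ValueError("exhaustive enumeration limited to n <= 9 samples")
        perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
        return perms, math.factorial(n)
    if not isinstance(n_perm, (int, np.integer)) or n_perm < 1:
        raise ValueError("n_perm must be >= 1 or 'exhaustive'")
    return np.array([rng.permutation(n) for _ in range(n_perm)], dtype=np.intp), int(n_perm)


def permanova(
    dm: DistanceMatrix,
    meta: SampleMetadata,
    terms: Sequence[str],
    n_perm: int | str = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Permutational multivariate ANOVA with sequential (Type-I) terms.

    *terms* are metadata factors in model order, e.g.
    ``["region", "season", "region:season"]``; interactions are written with
    ``:``.  Pseudo-F for each term uses the residual mean square of the full
    model.  Permutation of sample labels is free (no strata).
    """
    ids = dm.sample_ids
    n = len(ids)
    g = _gower_center(dm.values)
    ss_total = float(np.trace(g))
    if ss_total <= 1e-12:
        raise ValueError(
            "zero total sum of squares: all pairwise distances are equal "
            "(degenerate distance matrix)"
        )

    design = np.ones((n, 1))
    rank_prev = 1
    hat_prev = np.full((n, n), 1.0 / n)
    projectors: list[np.ndarray] = []
    dfs: list[int] = []
    for term in terms:
        labels = meta.group_labels(term, ids)
        design = np.hstack([design, _design_columns(labels)])
        rank = np.linalg.matrix_rank(design)
        df_term = rank - rank_prev
        if df_term == 0:
            raise ValueError(f"term {term!r} is aliased with earlier terms")
        hat = _hat(design)
        projectors.append(hat - hat_prev)
        dfs.append(df_term)
        hat_prev, rank_prev = hat, rank
    resid_proj = np.eye(n) - hat_prev
    df_resid = n - rank_prev
    if df_resid <= 0:
        raise ValueError("model is saturated: no residual degrees of freedom")

    ss_terms = np.array([float(np.sum(p * g)) for p in projectors])
    ss_resid = float(np.sum(resid_proj * g))
    ms_terms = ss_terms / np.array(dfs)
    f_obs = ms_terms / (ss_resid / df_resid)

    rng = np.random.default_rng(seed)
    perms, m = _permutation_indices(n, n_perm, rng)
    exceed = np.zeros(len(terms))
    batch = 512
    for start in range(0, m, batch):
        idx = perms[start : start + batch]
        gp = g[idx[:, :, None], idx[:, None, :]]  # (b, n, n)
        ss_r = np.einsum("ij,pij->p", resid_proj, gp)
        denom = ss_r / df_resid
        for k, proj in enumerate(projectors):
            ss_k = np.einsum("ij,pij->p", proj, gp)
            f_perm = (ss_k / dfs[k]) / denom
            exceed[k] += np.sum(f_perm >= f_obs[k] - 1e-12)
    pvals = (1.0 + exceed) / (1.0 + m)

    rows = []
    for k, term in enumerate(terms):
        rows.append((term, dfs[k], ss_terms[k], ss_terms[k] / ss_total, f_obs[k], pvals[k]))
    rows.append(("Residual", df_resid, ss_resid, ss_resid / ss_total, np.nan, np.nan))
    rows.append(("Total", n - 1, ss_total, 1.0, np.nan, np.nan))
    table = pd.DataFrame(rows, columns=["term", "df", "SS", "R2", "F", "p"]).set_index("term")
    return PermanovaResult(table, m, list(terms))


def pairwise_permanova(
    dm: DistanceMatrix,
    meta: SampleMetadata,
    factor: str,
    n_perm: int | str = 999,
    seed: int = 0,
    p_adjust: str = "fdr",
) -> pd.DataFrame:
    """One-way PERMANOVA restricted to every pair of factor levels."""
    labels = meta.group_labels(factor, dm.sample_ids)
    levels = sorted(labels.unique())
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} needs >= 2 levels")
    counts = labels.value_counts()
    small = [lv for lv in levels if counts[lv] < 2]
    if small:
        raise ValueError(f"levels with < 2 samples: {small}")
    rows = []
    rng = np.random.default_rng(seed)
    for a, b in itertools.combinations(levels, 2):
        keep = [s for s, lab in zip(dm.sample_ids, labels) if lab in (a, b)]
        sub = dm.submatrix(keep)
        res = permanova(sub, meta, [factor], n_perm=n_perm, seed=int(rng.integers(2**31)))
        row = res.table.loc[factor]
        rows.append((a, b, int(row["df"]), row["SS"], row["R2"], row["F"], row["p"]))
    out = pd.DataFrame(rows, columns=["level_a", "level_b", "df", "SS", "R2", "F", "p"])
    if p_adjust == "fdr":
        from statsmodels.stats.multitest import multipletests

        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    elif p_adjust == "none":
        out["q"] = out["p"]
    else:
        raise ValueError(f"unknown p_adjust {p_adjust!r}")
    return out


# ---------------------------------------------------------------------------
# PERMDISP
# ---------------------------------------------------------------------------


@dataclass
class DispersionResult:
    """Homogeneity-of-dispersions test (distance to group center)."""

    distances: pd.Series
    group_means: pd.Series
    f_statistic: float
    p_value: float
    n_permutations: int
    center: str = "centroid"
    degenerate: bool = False


def _group_center(
    pos: np.ndarray, neg: np.ndarray, center: str
) -> tuple[np.ndarray, np.ndarray]:
    if center == "centroid":
        return pos.mean(axis=0), neg.mean(axis=0)
    if center == "spatial_median":
        # Weiszfeld iteration on the corrected distance geometry.
        cp, cn = pos.mean(axis=0), neg.mean(axis=0)
        for _ in range(200):
            d2 = ((pos - cp) ** 2).sum(axis=1) - ((neg - cn) ** 2).sum(axis=1)
            d = np.sqrt(np.clip(d2, 1e-12, None))
            w = 1.0 / d
            w /= w.sum()
            new_cp = w @ pos
            new_cn = w @ neg
            if np.allclose(new_cp, cp, atol=1e-10) and np.allclose(new_cn, cn, atol=1e-10):
                cp, cn = new_cp, new_cn
                break
            cp, cn = new_cp, new_cn
        return cp, cn
    raise ValueError(f"unknown center {center!r}")


def permdisp(
    dm: DistanceMatrix,
    meta: SampleMetadata,
    factor: str,
    n_perm: int = 999,
    seed: int = 0,
    center: str = "centroid",
) -> DispersionResult:
    """Test homogeneity of multivariate dispersions across factor levels.

    Distances to the group center are computed in full PCoA space with
    Anderson's imaginary-axis correction; the F statistic is a one-way ANOVA
    on those distances and its p-value comes from permuting the distances
    across groups.
    """
    labels = meta.group_labels(factor, dm.sample_ids).to_numpy()
    levels, inv = np.unique(labels, return_inverse=True)
    sizes = np.bincount(inv)
    if np.any(sizes < 2):
        bad = levels[sizes < 2]
        raise ValueError(f"groups with < 2 samples: {list(bad)}")
    emb = pcoa(dm)
    pos = emb.coordinates.to_numpy()
    neg = emb.neg_coordinates
    z = np.empty(len(dm))
    for k, level in enumerate(levels):
        rows = inv == k
        cp, cn = _group_center(pos[rows], neg[rows], center)
        d2 = ((pos[rows] - cp) ** 2).sum(axis=1) - ((neg[rows] - cn) ** 2).sum(axis=1)
        z[rows] = np.sqrt(np.clip(d2, 0.0, None))

    def anova_f(values: np.ndarray) -> float:
        grand = values.mean()
        means = np.array([values[inv == k].mean() for k in range(len(levels))])
        ss_between = float(np.sum(sizes * (means - grand) ** 2))
        ss_within = float(sum(((values[inv == k] - means[k]) ** 2).sum() for k in range(len(levels))))
        df_b = len(levels) - 1
        df_w = len(values) - len(levels)
        if ss_within <= 1e-300:
            return np.nan if ss_between <= 1e-300 else np.inf
        return (ss_between / df_b) / (ss_within / df_w)

    f_obs = anova_f(z)
    degenerate = not np.isfinite(f_obs)
    rng = np.random.default_rng(seed)
    if np.isnan(f_obs):  # all distances identical: nothing to test
        p = 1.0
    else:
        exceed = 0
        for _ in range(n_perm):
            f_perm = anova_f(rng.permutation(z))
            if f_perm >= f_obs - 1e-12:
                exceed += 1
        p = (1.0 + exceed) / (1.0 + n_perm)
    distances = pd.Series(z, index=dm.sample_ids, name="distance_to_center")
    group_means = pd.Series(
        [z[inv == k].mean() for k in range(len(levels))], index=levels, name="mean_dispersion"
    )
    return DispersionResult(distances, group_means, f_obs, p, n_perm, center, degenerate)
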