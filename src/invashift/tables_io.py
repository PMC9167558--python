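"""Tabular and tree inputs: containers, readers, cleaning, rarefaction, aggregation.

Containers wrap :class:`pandas.DataFrame` objects indexed by explicit
sample/feature identifiers so that filtering and reordering never rely on
positional indexing.  Trees are :class:`skbio.TreeNode` objects wrapped with
light validation (unique leaf labels, finite non-negative branch lengths,
ultrametricity check).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import skbio

__all__ = [
    "RANKS",
    "CountTable",
    "SampleMetadata",
    "TaxonomyTable",
    "PhyloTree",
    "RelativeAbundanceTable",
    "RarefactionReport",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "read_taxonomy",
    "read_tree",
    "filter_features",
    "rarefy",
    "to_relative",
    "aggregate_rank",
]

#: Taxonomic ranks, highest to lowest, as used throughout the package.
RANKS = ("Domain", "Phylum", "Class", "Order", "Family", "Genus", "Species")

COMPARTMENTS = {"fish", "water", "sediment", "algae", "seagrass", "turf"}
SEASONS = {"spring", "autumn"}


class ValidationError(ValueError):
    """Raised when an input table violates a container invariant."""


@dataclass
class CountTable:
    """Samples x features matrix of non-negative integer counts.

    Parameters
    ----------
    data
        DataFrame with sample ids as index and feature ids as columns.
    feature_kind
        ``"ASV"`` for taxa tables, ``"KO"`` for gene-family tables.
    """

    data: pd.DataFrame
    feature_kind: str = "ASV"

    def __post_init__(self) -> None:
        if self.feature_kind not in ("ASV", "KO"):
            raise ValidationError(f"feature_kind must be ASV or KO, got {self.feature_kind!r}")
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValidationError("count table must have at least one sample and one feature")
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate sample ids")
        if self.data.columns.has_duplicates:
            raise ValidationError("duplicate feature ids")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if np.any(values < 0):
            bad = self.data.index[np.any(values < 0, axis=1)][0]
            raise ValidationError(f"negative count in sample {bad!r}")
        if not np.allclose(values, np.round(values)):
            raise ValidationError("counts must be integers")
        self.data = self.data.astype(np.int64)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        self.data.index.name = None
        self.data.columns.name = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    def select_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        missing = set(sample_ids) - set(self.data.index)
        if missing:
            raise KeyError(f"samples not in table: {sorted(missing)}")
        return CountTable(self.data.loc[list(sample_ids)].copy(), self.feature_kind)

    def select_features(self, feature_ids: Sequence[str]) -> "CountTable":
        missing = set(feature_ids) - set(self.data.columns)
        if missing:
            raise KeyError(f"features not in table: {sorted(missing)}")
        return CountTable(self.data[list(feature_ids)].copy(), self.feature_kind)

    def drop_empty_features(self) -> "CountTable":
        keep = self.data.columns[self.data.sum(axis=0) > 0]
        return CountTable(self.data[keep].copy(), self.feature_kind)


@dataclass
class RelativeAbundanceTable:
    """Samples x features matrix of proportions; every row sums to 1."""

    data: pd.DataFrame
    feature_kind: str = "ASV"

    def __post_init__(self) -> None:
        values = self.data.to_numpy(dtype=float)
        if np.any(values < 0) or np.any(values > 1 + 1e-12):
            raise ValidationError("relative abundances must lie in [0, 1]")
        sums = values.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            bad = self.data.index[np.argmax(np.abs(sums - 1.0))]
            raise ValidationError(f"row {bad!r} does not sum to 1 (sum={sums.max():.6g})")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def proportions(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class SampleMetadata:
    """Per-sample metadata: compartment, host species, region, season, site.

    Region vocabulary is open (the study design uses RedSea / Levantine /
    Crete); compartment and season vocabularies are fixed.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"compartment", "region", "season"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"metadata missing columns: {sorted(missing)}")
        if "host_species" not in self.data.columns:
            self.data = self.data.assign(host_species=pd.NA)
        if "site" not in self.data.columns:
            self.data = self.data.assign(site=pd.NA)
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate sample ids in metadata")
        self.data.index = self.data.index.astype(str)
        bad_comp = set(self.data["compartment"].dropna()) - COMPARTMENTS
        if bad_comp:
            raise ValidationError(f"unknown compartments: {sorted(bad_comp)}")
        bad_season = set(self.data["season"].dropna()) - SEASONS
        if bad_season:
            raise ValidationError(f"unknown seasons: {sorted(bad_season)}")
        fish = self.data[self.data["compartment"] == "fish"]
        if fish["host_species"].isna().any():
            bad = fish.index[fish["host_species"].isna()][0]
            raise ValidationError(f"fish sample {bad!r} lacks host_species")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def validate_against(self, table: CountTable) -> None:
        """Every sample in *table* must have exactly one metadata row."""
        missing = set(table.sample_ids) - set(self.data.index)
        if missing:
            raise ValidationError(f"samples without metadata: {sorted(missing)}")

    def subset(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        return SampleMetadata(self.data.loc[list(sample_ids)].copy())

    def group_labels(self, factor: str, sample_ids: Sequence[str]) -> pd.Series:
        """Factor labels aligned to *sample_ids*; supports ``a:b`` interactions."""
        sub = self.data.loc[list(sample_ids)]
        if ":" in factor:
            parts = factor.split(":")
            lab = sub[parts[0]].astype(str)
            for p in parts[1:]:
                lab = lab + ":" + sub[p].astype(str)
            return lab
        if factor not in sub.columns:
            raise KeyError(f"unknown metadata factor {factor!r}")
        return sub[factor].astype(str)

    def select(self, **criteria: str) -> list[str]:
        """Sample ids matching equality criteria, e.g. ``region='RedSea'``."""
        mask = pd.Series(True, index=self.data.index)
        for key, value in criteria.items():
            if value is not None:
                mask &= self.data[key] == value
        return list(self.data.index[mask])


@dataclass
class TaxonomyTable:
    """Feature -> rank labels for the seven canonical ranks.

    Unknown assignments are stored as the literal label ``"unassigned"``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(RANKS) - set(self.data.columns)
        if missing:
            raise ValidationError(f"taxonomy missing ranks: {sorted(missing)}")
        self.data = self.data[list(RANKS)].fillna("unassigned").astype(str)
        self.data.index = self.data.index.astype(str)
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate feature ids in taxonomy")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    def validate_against(self, table: CountTable) -> None:
        missing = set(table.feature_ids) - set(self.data.index)
        if missing:
            raise ValidationError(f"features without taxonomy: {sorted(missing)}")

    def labels(self, rank: str) -> pd.Series:
        if rank not in RANKS:
            raise KeyError(f"unknown rank {rank!r}")
        return self.data[rank]


@dataclass
class PhyloTree:
    """Rooted tree over ASV leaves with finite non-negative branch lengths.

    Branch lengths are in arbitrary time units (the input tree is expected to
    have been made ultrametric upstream); non-ultrametric input triggers a
    warning, not an error, so that slightly imprecise trees remain usable.
    """

    tree: skbio.TreeNode
    ultrametric_tol: float = 1e-6

    def __post_init__(self) -> None:
        tips = list(self.tree.tips())
        names = [t.name for t in tips]
        if len(names) != len(set(names)):
            raise ValidationError("duplicate leaf labels in tree")
        if any(n is None for n in names):
            raise ValidationError("unnamed leaf in tree")
        for node in self.tree.traverse(include_self=False):
            if node.length is None:
                node.length = 0.0
            if not np.isfinite(node.length) or node.length < 0:
                raise ValidationError(f"invalid branch length on {node.name!r}")
        depths = self._tip_depths()
        if depths and max(depths) - min(depths) > self.ultrametric_tol * max(max(depths), 1.0):
            warnings.warn(
                "tree is not ultrametric within tolerance; phylogenetic Hill "
                "numbers assume equal root-to-tip depths",
                UserWarning,
                stacklevel=2,
            )

    def _tip_depths(self) -> list[float]:
        depths = []

        def walk(node, acc):
            acc += node.length or 0.0
            if node.is_tip():
                depths.append(acc)
            else:
                for child in node.children:
                    walk(child, acc)

        for child in self.tree.children:
            walk(child, 0.0)
        return depths

    @property
    def leaf_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def shear(self, leaf_names: Iterable[str]) -> "PhyloTree":
        """Tree pruned to *leaf_names* (internal unary nodes collapsed)."""
        sub = self.tree.shear(set(leaf_names))
        sub.prune()
        return PhyloTree(sub, self.ultrametric_tol)


@dataclass
class RarefactionReport:
    """Samples dropped during rarefaction, with their original totals."""

    depth: int
    dropped: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_count_table(path: str | Path, format: str = "tsv", feature_kind: str = "ASV") -> CountTable:
    """Read a samples x features count table.

    ``tsv``: first column sample_id, header row of feature ids.
    ``biom``: BIOM 1.0 JSON (dense or sparse); the matrix is transposed into
    sample-major orientation.  BIOM rows are observations (features) and
    columns are samples, per the format definition.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise ValidationError(f"cannot parse {path}: {exc}") from exc
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ValidationError(f"{path} contains no data")
        for col in df.columns:
            if not np.issubdtype(df[col].dtype, np.number):
                raise ValidationError(f"non-numeric counts in column {col!r} of {path}")
        return CountTable(df, feature_kind)
    if format == "biom":
        payload = json.loads(Path(path).read_text())
        feature_ids = [row["id"] for row in payload["rows"]]
        sample_ids = [col["id"] for col in payload["columns"]]
        shape = tuple(payload["shape"])
        mat = np.zeros(shape, dtype=float)
        if payload.get("matrix_type") == "sparse":
            for i, j, v in payload["data"]:
                mat[i, j] = v
        else:
            mat[:] = np.asarray(payload["data"], dtype=float)
        df = pd.DataFrame(mat.T, index=sample_ids, columns=feature_ids)
        return CountTable(df, feature_kind)
    raise ValueError(f"unknown format {format!r}")


def write_count_table(table: CountTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return SampleMetadata(df)


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return TaxonomyTable(df)


def read_tree(path: str | Path) -> PhyloTree:
    tree = skbio.TreeNode.read(str(path), format="newick")
    return PhyloTree(tree)


# ---------------------------------------------------------------------------
# table-level cleaning
# ---------------------------------------------------------------------------


def filter_features(
    table: CountTable,
    taxonomy: TaxonomyTable | None = None,
    min_samples: int = 3,
    exclude_labels: Iterable[str] = (),
) -> CountTable:
    """Prevalence and taxonomy filtering.

    Features observed in ``min_samples`` samples *or fewer* are removed
    (default 3, i.e. a feature must occur in at least 4 samples to be kept).
    Features whose label at any rank matches ``exclude_labels`` (typically
    chloroplast / mitochondria assignments) are removed.  Column order of the
    surviving features is preserved.
    """
    if min_samples < 0:
        raise ValueError("min_samples must be >= 0")
    exclude = set(exclude_labels)
    if exclude and taxonomy is None:
        raise ValueError("exclude_labels requires a taxonomy table")
    if taxonomy is not None:
        taxonomy.validate_against(table)
    occupancy = (table.counts > 0).sum(axis=0)
    keep_mask = occupancy > min_samples
    if exclude:
        tax = taxonomy.data.loc[table.feature_ids]
        excluded = tax.isin(exclude).any(axis=1).to_numpy()
        keep_mask &= ~excluded
    keep = [fid for fid, ok in zip(table.feature_ids, keep_mask) if ok]
    if not keep:
        raise ValidationError("filtering removed every feature")
    return table.select_features(keep)


def rarefy(
    table: CountTable, depth: int, seed: int
) -> tuple[CountTable, RarefactionReport]:
    """Subsample every sample to exactly *depth* reads without replacement.

    One multivariate-hypergeometric draw per sample.  Samples whose total is
    below *depth* are dropped and listed in the report.  Deterministic for a
    fixed seed.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    report = RarefactionReport(depth=depth)
    rows = []
    kept_ids = []
    for sid, row in zip(table.sample_ids, table.counts):
        total = int(row.sum())
        if total < depth:
            report.dropped[sid] = total
            continue
        rows.append(rng.multivariate_hypergeometric(row, depth))
        kept_ids.append(sid)
    if not rows:
        raise ValidationError(f"no sample reaches rarefaction depth {depth}")
    df = pd.DataFrame(np.asarray(rows), index=kept_ids, columns=table.feature_ids)
    return CountTable(df, table.feature_kind), report


def to_relative(table: CountTable) -> RelativeAbundanceTable:
    """Close each sample to relative abundances (rows sum to 1)."""
    totals = table.counts.sum(axis=1)
    if np.any(totals == 0):
        bad = table.data.index[totals == 0][0]
        raise ValidationError(f"sample {bad!r} has zero total count")
    props = table.counts / totals[:, None]
    df = pd.DataFrame(props, index=table.sample_ids, columns=table.feature_ids)
    return RelativeAbundanceTable(df, table.feature_kind)


def aggregate_rank(
    table: CountTable, taxonomy: TaxonomyTable | None, rank: str
) -> CountTable:
    """Sum ASV counts into taxa at *rank* (``Phylum``, ``Family`` or ``ASV``).

    ``rank="ASV"`` returns the input unchanged.  Features labelled
    ``"unassigned"`` at the target rank are pooled per distinct upstream
    label path (so unassigned Families under different Phyla stay separate).
    """
    if rank == "ASV":
        return table
    if rank not in RANKS:
        raise KeyError(f"unknown rank {rank!r}")
    if taxonomy is None:
        raise ValueError("aggregation above ASV requires a taxonomy table")
    taxonomy.validate_against(table)
    upstream = list(RANKS[: RANKS.index(rank)])
    tax = taxonomy.data.loc[table.feature_ids]
    labels = []
    for fid in table.feature_ids:
        row = tax.loc[fid]
        lab = row[rank]
        if lab == "unassigned":
            path = ";".join(row[r] for r in upstream)
            lab = f"unassigned[{path}]"
        labels.append(lab)
    grouped = table.data.T.groupby(pd.Index(labels, name=rank), sort=False).sum().T
    return CountTable(grouped, table.feature_kind)
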