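"""Functional (SCFA) beta-diversity analysis of KO tables.

KO (KEGG Orthology) abundances are treated exactly like taxa: each
short-chain fatty-acid group (formate, acetate, propionate, butyrate,
valerate, or their union "all") selects a KO subset, the subset is re-closed
to relative abundance, and the Hill dissimilarity / PERMANOVA / PERMDISP /
homogenization machinery runs on it unchanged.

The KO identifiers per SCFA group are not public; the shipped defaults are
synthetic placeholder ids matching the published group sizes (formate 25,
acetate 17, propionate 13, butyrate 17, valerate 14) and can be replaced by
an editable TSV mapping (columns: group, ko_id).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hill_diversity import HillConfig, dissimilarity_matrix
from .ordination_beta import DispersionResult, PermanovaResult, permanova, permdisp
from .tables_io import CountTable, SampleMetadata, to_relative

__all__ = ["ScfaGroups", "ScfaGroupResult", "default_scfa_groups", "subset_kos", "scfa_beta_analysis"]

#: Published number of KOs per SCFA group (1-5 carbon atoms).
DEFAULT_GROUP_SIZES = {
    "formate": 25,
    "acetate": 17,
    "propionate": 13,
    "butyrate": 17,
    "valerate": 14,
}


@dataclass
class ScfaGroups:
    """Mapping SCFA group name -> KO id set; "all" is the union."""

    groups: dict[str, set[str]]

    def __post_init__(self) -> None:
        named = {g: ids for g, ids in self.groups.items() if g != "all"}
        if any(len(ids) == 0 for ids in named.values()):
            raise ValueError("every SCFA group needs at least one KO id")
        self.groups = dict(named)
        self.groups["all"] = set().union(*named.values())

    def ids(self, group: str) -> set[str]:
        if group not in self.groups:
            raise KeyError(f"unknown SCFA group {group!r}")
        return self.groups[group]

    @property
    def names(self) -> list[str]:
        return [g for g in self.groups if g != "all"] + ["all"]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ScfaGroups":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"group", "ko_id"} <= set(df.columns):
            raise ValueError("SCFA mapping TSV needs columns 'group' and 'ko_id'")
        groups: dict[str, set[str]] = {}
        for g, sub in df.groupby("group"):
            groups[g] = set(sub["ko_id"])
        return cls(groups)

    def to_tsv(self, path: str | Path) -> None:
        rows = [(g, ko) for g, ids in self.groups.items() if g != "all" for ko in sorted(ids)]
        pd.DataFrame(rows, columns=["group", "ko_id"]).to_csv(path, sep="\t", index=False)


def default_scfa_groups() -> ScfaGroups:
    """Synthetic placeholder KO ids with the published per-group cardinalities."""
    groups = {}
    for c, (name, size) in enumerate(DEFAULT_GROUP_SIZES.items(), start=1):
        groups[name] = {f"K{c}C{i + 1:03d}" for i in range(size)}
    return ScfaGroups(groups)


def subset_kos(
    ko_table: CountTable, groups: ScfaGroups, group: str
) -> tuple[CountTable, list[str]]:
    """Restrict a KO table to one SCFA group's identifiers.

    Returns the projected table (counts unchanged) and the list of group KO
    ids that were absent from the table.
    """
    wanted = groups.ids(group)
    present = [k for k in ko_table.feature_ids if k in wanted]
    missing = sorted(wanted - set(present))
    if not present:
        raise ValueError(f"no KO of group {group!r} present in the table")
    return ko_table.select_features(present), missing


@dataclass
class ScfaGroupResult:
    """Beta analysis of one SCFA group at one order q."""

    group: str
    q: float
    permanova: PermanovaResult | None
    permdisp: DispersionResult | None
    homogenization: pd.DataFrame
    missing_kos: list[str] = field(default_factory=list)
    degenerate: bool = False


def scfa_beta_analysis(
    ko_table: CountTable,
    meta: SampleMetadata,
    groups: ScfaGroups | None = None,
    qs: tuple[float, ...] = (0.0, 1.0),
    n_perm: int = 999,
    seed: int = 0,
    native_region: str = "RedSea",
    terms: tuple[str, ...] = ("region", "season", "region:season"),
) -> dict[tuple[str, float], ScfaGroupResult]:
    """Run the full beta machinery per SCFA group and order q.

    For each group: subset and re-close the KO table, build the taxonomic
    style Hill dissimilarity matrix (KOs as units), then PERMANOVA with the
    region/season/interaction terms, PERMDISP by region, and percent
    homogenization from the native region to every other region.
    A group whose samples are all identical yields a flagged degenerate
    result instead of test statistics.
    """
    groups = groups or default_scfa_groups()
    meta.validate_against(ko_table)
    sub_meta = meta.data.loc[ko_table.sample_ids]
    usable = [t for t in terms if ":" not in t and sub_meta[t].nunique() > 1]
    if len(usable) == len([t for t in terms if ":" not in t]):
        usable += [t for t in terms if ":" in t]
    terms = tuple(usable)
    regions = sorted(set(meta.data.loc[ko_table.sample_ids, "region"]))
    others = [r for r in regions if r != native_region]
    rng = np.random.default_rng(seed)
    out: dict[tuple[str, float], ScfaGroupResult] = {}
    for group in groups.names:
        sub, missing = subset_kos(ko_table, groups, group)
        nonzero = sub.counts.sum(axis=1) > 0
        sub = sub.select_samples([s for s, ok in zip(sub.sample_ids, nonzero) if ok])
        rel = to_relative(sub)
        for q in qs:
            sub_seed = int(rng.integers(2**31))
            dm = dissimilarity_matrix(rel, HillConfig(q=q, facet="taxonomic", rank="ASV"))
            if np.allclose(dm.values, 0.0):
                out[(group, q)] = ScfaGroupResult(
                    group, q, None, None, pd.DataFrame(), missing, degenerate=True
                )
                continue
            perm = permanova(dm, meta, list(terms), n_perm=n_perm, seed=sub_seed)
            disp = permdisp(dm, meta, "region", n_perm=n_perm, seed=sub_seed)
            rows = []
            for other in others:
                # region-wide (all hosts pooled) homogenization per group
                ref_ids = [s for s in meta.select(region=native_region) if s in set(dm.sample_ids)]
                cmp_ids = [s for s in meta.select(region=other) if s in set(dm.sample_ids)]
                if len(ref_ids) < 2 or len(cmp_ids) < 2:
                    continue
                ref_vals = dm.submatrix(ref_ids).values[np.triu_indices(len(ref_ids), k=1)]
                cmp_vals = dm.submatrix(cmp_ids).values[np.triu_indices(len(cmp_ids), k=1)]
                mean_ref, mean_cmp = ref_vals.mean(), cmp_vals.mean()
                pct = 100.0 * (mean_ref - mean_cmp) / mean_ref if mean_ref > 0 else np.nan
                rows.append((native_region, other, mean_ref, mean_cmp, pct))
            homog = pd.DataFrame(
                rows,
                columns=["native_region", "comparison_region", "mean_native",
                         "mean_comparison", "percent_change"],
            )
            out[(group, q)] = ScfaGroupResult(group, q, perm, disp, homog, missing)
    return out
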