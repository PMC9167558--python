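"""Quantify microbiome homogenization between native and invaded ranges.

Working unit: collections of pairwise dissimilarities drawn from a distance
matrix under one of three contexts — pairs of conspecific individuals within
one region, conspecific pairs across two regions, or heterospecific pairs
within one region.  Percent homogenization between a reference (native)
region and a comparison region is ``100 * (mean_ref - mean_cmp) / mean_ref``,
summarised as mean +/- SD across diversity-index configurations.  Rank tests
on these collections ignore the non-independence of shared individuals; the
caveat is recorded in every test result rather than corrected for.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .ordination_beta import DistanceMatrix
from .tables_io import SampleMetadata

__all__ = [
    "PairwiseDissimSet",
    "DissimTestResult",
    "HomogenizationReport",
    "TrajectoryLabels",
    "pairwise_sets",
    "percent_homogenization",
    "dissimilarity_tests",
    "classify_trajectory",
]

CONTEXTS = (
    "intraspecific_within_region",
    "intraspecific_between_regions",
    "interspecific_within_region",
)

PSEUDOREPLICATION_CAVEAT = (
    "pairwise dissimilarities share individuals and are not independent; "
    "p-values are descriptive"
)


@dataclass
class PairwiseDissimSet:
    """Pairwise dissimilarities for one context, group and index config."""

    context: str
    labels: dict[str, str]
    values: np.ndarray
    config: str = ""

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("empty dissimilarity set")

    @property
    def mean(self) -> float:
        return float(self.values.mean())


def pairwise_sets(
    dm: DistanceMatrix,
    meta: SampleMetadata,
    context: str,
    species: str | None = None,
    region: str | None = None,
    regions: tuple[str, str] | None = None,
    species_pair: tuple[str, str] | None = None,
    config: str = "",
) -> PairwiseDissimSet:
    """Extract the pairwise dissimilarities for one context.

    ``intraspecific_within_region``: all C(n, 2) pairs within one
    species x region.  ``intraspecific_between_regions``: all cross pairs of
    one species between two regions.  ``interspecific_within_region``: all
    cross pairs of two species within one region.
    """
    in_dm = set(dm.sample_ids)

    def ids_for(**crit):
        sel = [s for s in meta.select(**crit) if s in in_dm]
        if len(sel) < 2:
            raise ValueError(f"fewer than 2 samples for {crit}")
        return sel

    if context == "intraspecific_within_region":
        if species is None or region is None:
            raise ValueError("species and region required")
        ids = ids_for(host_species=species, region=region)
        sub = dm.submatrix(ids)
        iu = np.triu_indices(len(ids), k=1)
        values = sub.values[iu]
        labels = {"species": species, "region": region}
    elif context == "intraspecific_between_regions":
        if species is None or regions is None:
            raise ValueError("species and a region pair required")
        ids_a = ids_for(host_species=species, region=regions[0])
        ids_b = ids_for(host_species=species, region=regions[1])
        values = dm.between(ids_a, ids_b).ravel()
        labels = {"species": species, "region_a": regions[0], "region_b": regions[1]}
    elif context == "interspecific_within_region":
        if species_pair is None or region is None:
            raise ValueError("species_pair and region required")
        ids_a = ids_for(host_species=species_pair[0], region=region)
        ids_b = ids_for(host_species=species_pair[1], region=region)
        values = dm.between(ids_a, ids_b).ravel()
        labels = {"species_a": species_pair[0], "species_b": species_pair[1], "region": region}
    else:
        raise ValueError(f"unknown context {context!r}")
    return PairwiseDissimSet(context, labels, values, config)


def percent_homogenization(
    pairs: list[tuple[str, PairwiseDissimSet, PairwiseDissimSet]],
) -> tuple[float, float, pd.DataFrame]:
    """Percent dissimilarity decrease from reference to comparison sets.

    *pairs* holds ``(config_label, reference_set, comparison_set)`` triples,
    one per diversity-index configuration.  Positive percentages mean the
    comparison group is more homogeneous than the reference.  Returns the
    unweighted mean and SD across configurations plus the per-config table.
    """
    if not pairs:
        raise ValueError("need at least one configuration")
    rows = []
    for label, ref, cmp_ in pairs:
        if ref.context != cmp_.context:
            raise ValueError("reference and comparison sets have different contexts")
        mean_ref, mean_cmp = ref.mean, cmp_.mean
        if mean_ref <= 0:
            rows.append((label, mean_ref, mean_cmp, np.nan, True))
            continue
        pct = 100.0 * (mean_ref - mean_cmp) / mean_ref
        rows.append((label, mean_ref, mean_cmp, pct, False))
    table = pd.DataFrame(
        rows, columns=["config", "mean_reference", "mean_comparison", "percent_change", "undefined"]
    )
    valid = table.loc[~table["undefined"], "percent_change"]
    mean = float(valid.mean()) if len(valid) else np.nan
    sd = float(valid.std(ddof=1)) if len(valid) > 1 else 0.0
    return mean, sd, table


@dataclass
class DissimTestResult:
    statistic: float
    p_value: float
    test: str
    degenerate: bool = False
    caveat: str = PSEUDOREPLICATION_CAVEAT


def dissimilarity_tests(
    set_a: PairwiseDissimSet | np.ndarray,
    set_b: PairwiseDissimSet | np.ndarray,
    test: str = "kruskal",
) -> DissimTestResult:
    """Rank test between two collections of pairwise dissimilarities.

    ``kruskal`` is the two-group Kruskal-Wallis; ``wilcoxon`` is the
    two-sample rank-sum (Mann-Whitney U, as used for two independent
    collections).
    """
    a = set_a.values if isinstance(set_a, PairwiseDissimSet) else np.asarray(set_a, float)
    b = set_b.values if isinstance(set_b, PairwiseDissimSet) else np.asarray(set_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both sets must be non-empty")
    pooled = np.concatenate([a, b])
    if np.allclose(pooled, pooled[0]):
        return DissimTestResult(np.nan, 1.0, test, degenerate=True)
    if test == "kruskal":
        stat, p = scipy.stats.kruskal(a, b)
    elif test == "wilcoxon":
        stat, p = scipy.stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return DissimTestResult(float(stat), float(p), test)


@dataclass
class TrajectoryLabels:
    """Invasion-trajectory classification for each species and between them."""

    per_species: dict[str, str]
    shifted: dict[str, bool]
    interspecific: str
    overall: str


@dataclass
class HomogenizationReport:
    """Full within/between-species homogenization summary."""

    intraspecific: pd.DataFrame  # species, region pair, mean pct, sd, test stat, p
    interspecific: pd.DataFrame
    per_config: pd.DataFrame
    labels: TrajectoryLabels | None = None
    caveat: str = PSEUDOREPLICATION_CAVEAT


def _verdict(
    native: PairwiseDissimSet, invaded: PairwiseDissimSet, alpha: float, test: str
) -> str:
    res = dissimilarity_tests(native, invaded, test)
    if res.degenerate or res.p_value >= alpha:
        return "no_change"
    return "homogenization" if invaded.mean < native.mean else "differentiation"


def classify_trajectory(
    within_native: dict[str, PairwiseDissimSet],
    within_invaded: dict[str, PairwiseDissimSet],
    between_regions: dict[str, PairwiseDissimSet],
    inter_native: PairwiseDissimSet | None = None,
    inter_invaded: PairwiseDissimSet | None = None,
    alpha: float = 0.05,
    test: str = "kruskal",
) -> TrajectoryLabels:
    """Assign invasion-trajectory labels from dissimilarity comparisons.

    Per species the variability verdict compares within-region dissimilarity
    between native and invaded ranges (sign of the change plus a rank test at
    *alpha*); the shift verdict flags species whose between-region pairs are
    on average more dissimilar than their pooled within-region pairs.  The
    interspecific verdict compares heterospecific dissimilarity across the
    two co-occurrence regions with a rank-sum test.
    """
    if set(within_native) != set(within_invaded):
        raise ValueError("species sets of native and invaded contexts differ")
    per_species: dict[str, str] = {}
    shifted: dict[str, bool] = {}
    for sp in within_native:
        per_species[sp] = _verdict(within_native[sp], within_invaded[sp], alpha, test)
        if sp in between_regions:
            within_pool = np.concatenate(
                [within_native[sp].values, within_invaded[sp].values]
            )
            shifted[sp] = float(between_regions[sp].values.mean()) > float(within_pool.mean())
        else:
            shifted[sp] = False
    if inter_native is not None and inter_invaded is not None:
        inter = _verdict(inter_native, inter_invaded, alpha, "wilcoxon")
    else:
        inter = "not_assessed"
    verdicts = set(per_species.values())
    if verdicts == {"homogenization"} and inter == "homogenization":
        overall = "homogenization within and between species"
    elif verdicts == {"differentiation"} and inter in ("differentiation", "not_assessed"):
        overall = "differentiation within and between species"
    elif verdicts == {"no_change"} and inter in ("no_change", "not_assessed"):
        overall = "no_change"
    else:
        overall = "mixed"
    return TrajectoryLabels(per_species, shifted, inter, overall)


def homogenization_report(
    dms: dict[str, DistanceMatrix],
    meta: SampleMetadata,
    species: list[str],
    native_region: str,
    comparison_regions: list[str],
    alpha: float = 0.05,
    label_config: str | None = None,
) -> HomogenizationReport:
    """Build the full report across index configurations.

    *dms* maps a configuration label (e.g. ``q1_phylogenetic_ASV``) to its
    distance matrix.  Percent changes are averaged (unweighted) across all
    supplied configurations; the trajectory labels are computed on
    *label_config* (default: the first configuration).
    """
    if not dms:
        raise ValueError("no distance matrices supplied")
    label_config = label_config or next(iter(dms))
    intra_rows, inter_rows, config_rows = [], [], []

    def sets_for(cfg, dm, context, **kw):
        return pairwise_sets(dm, meta, context, config=cfg, **kw)

    for sp in species:
        for other in comparison_regions:
            pairs = []
            for cfg, dm in dms.items():
                try:
                    ref = sets_for(cfg, dm, "intraspecific_within_region", species=sp, region=native_region)
                    cmp_ = sets_for(cfg, dm, "intraspecific_within_region", species=sp, region=other)
                except ValueError:
                    continue
                pairs.append((cfg, ref, cmp_))
            if not pairs:
                continue
            mean_pct, sd_pct, table = percent_homogenization(pairs)
            table.insert(0, "comparison", f"{sp}:{native_region}->{other}")
            config_rows.append(table)
            ref0 = next(p[1] for p in pairs if p[0] == label_config)
            cmp0 = next(p[2] for p in pairs if p[0] == label_config)
            res = dissimilarity_tests(ref0, cmp0, "kruskal")
            intra_rows.append(
                (sp, native_region, other, mean_pct, sd_pct, res.statistic, res.p_value)
            )

    if len(species) == 2:
        for other in comparison_regions:
            pairs = []
            for cfg, dm in dms.items():
                try:
                    ref = sets_for(
                        cfg, dm, "interspecific_within_region",
                        species_pair=tuple(species), region=native_region,
                    )
                    cmp_ = sets_for(
                        cfg, dm, "interspecific_within_region",
                        species_pair=tuple(species), region=other,
                    )
                except ValueError:
                    continue
                pairs.append((cfg, ref, cmp_))
            if not pairs:
                continue
            mean_pct, sd_pct, table = percent_homogenization(pairs)
            table.insert(0, "comparison", f"interspecific:{native_region}->{other}")
            config_rows.append(table)
            ref0 = next(p[1] for p in pairs if p[0] == label_config)
            cmp0 = next(p[2] for p in pairs if p[0] == label_config)
            res = dissimilarity_tests(ref0, cmp0, "wilcoxon")
            inter_rows.append((native_region, other, mean_pct, sd_pct, res.statistic, res.p_value))

    intra = pd.DataFrame(
        intra_rows,
        columns=["species", "native_region", "comparison_region", "mean_percent_change",
                 "sd_percent_change", "statistic", "p"],
    )
    inter = pd.DataFrame(
        inter_rows,
        columns=["native_region", "comparison_region", "mean_percent_change",
                 "sd_percent_change", "statistic", "p"],
    )
    per_config = pd.concat(config_rows, ignore_index=True) if config_rows else pd.DataFrame()

    labels = None
    dm0 = dms[label_config]
    try:
        wn, wi, br = {}, {}, {}
        invaded0 = comparison_regions[0]
        for sp in species:
            wn[sp] = pairwise_sets(dm0, meta, "intraspecific_within_region", species=sp,
                                   region=native_region, config=label_config)
            wi[sp] = pairwise_sets(dm0, meta, "intraspecific_within_region", species=sp,
                                   region=invaded0, config=label_config)
            br[sp] = pairwise_sets(dm0, meta, "intraspecific_between_regions", species=sp,
                                   regions=(native_region, invaded0), config=label_config)
        inter_n = inter_i = None
        if len(species) == 2:
            inter_n = pairwise_sets(dm0, meta, "interspecific_within_region",
                                    species_pair=tuple(species), region=native_region,
                                    config=label_config)
            inter_i = pairwise_sets(dm0, meta, "interspecific_within_region",
                                    species_pair=tuple(species), region=invaded0,
                                    config=label_config)
        labels = classify_trajectory(wn, wi, br, inter_n, inter_i, alpha=alpha)
    except ValueError:
        labels = None

    return HomogenizationReport(intra, inter, per_config, labels)
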