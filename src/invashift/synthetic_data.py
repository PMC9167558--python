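"""Synthetic multi-region, multi-species gut-microbiome datasets.

The generator is a Dirichlet-multinomial community model: each (species,
region) group has a mean relative-abundance profile ``pi_g`` and a Dirichlet
concentration ``theta_g``; an individual's composition is drawn as
``Dirichlet(theta_g * pi_g)`` and its counts as ``Multinomial(depth, x)``
with log-normally distributed depths.  ``theta`` is the homogenization dial:
larger values concentrate individuals around the group mean, so planting a
larger ``theta`` in the invaded regions reproduces the within-group
dissimilarity drop the analysis is meant to detect.

Planted structure, all recorded in :class:`GroundTruth`:

* **core taxa** — a fraction of features receives a fixed, even share of the
  mean profile in every group and is carried by every individual, giving
  them uniform high occupancy.  All other taxa are patchy: each non-core
  feature has a per-feature carriage probability (drawn once per scenario)
  and is present in a random subset of individuals, reproducing the
  occupancy-abundance relationship of real ASV tables in which only core
  taxa reach full occupancy;
* **regional shifts** — selected non-core features are multiplied by a
  log-fold factor in invaded regions (a larger factor in the far region
  creates a gradient) and part of the core block *decreases* in the invaded
  range (dominant lineages fading while keeping full occupancy); the
  profile is then re-closed;
* **seasonal effect** — a small log-fold bump on a feature subset in autumn,
  so region x season interaction tests have signal to find;
* **KO table** — a fixed linear map from taxa counts to gene-family (KO)
  counts.  This emulates the *output shape* of reference-based functional
  inference; no attempt is made to mimic real KEGG content.

The baseline profile is log-normal, giving realistic steep rank-abundance
curves.  Defaults mirror the field study design: two species, three regions
(one native), two seasons, group sizes of 8-20 individuals.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from io import StringIO

import dendropy
import numpy as np
import pandas as pd
import skbio

from .hill_diversity import pairwise_dissimilarities
from .tables_io import CountTable, PhyloTree, SampleMetadata, TaxonomyTable, RANKS

__all__ = [
    "SyntheticScenario",
    "GroundTruth",
    "SimulatedDataset",
    "simulate_dataset",
    "expected_dispersion",
    "theta_for_reduction",
    "default_ko_map",
]

SPECIES = ("S_rivulatus", "S_luridus")
REGIONS = ("RedSea", "Levantine", "Crete")


def _default_group_sizes() -> dict[tuple[str, str, str], int]:
    sizes: dict[tuple[str, str, str], int] = {}
    for region in REGIONS:
        for season in ("spring", "autumn"):
            sizes[("S_rivulatus", region, season)] = 20
    for region in ("RedSea", "Crete"):
        for season in ("spring", "autumn"):
            sizes[("S_luridus", region, season)] = 8
    return sizes


def _default_theta() -> dict[tuple[str, str], float]:
    # Calibrated with theta_for_reduction so the dispersion oracle reproduces
    # the observed intraspecific dissimilarity decreases along the invasion
    # gradient: ~46% (Levantine) and ~61% (Crete) for S. rivulatus, ~29%
    # (Crete) for S. luridus, relative to the native Red Sea groups.
    return {
        ("S_rivulatus", "RedSea"): 40.0,
        ("S_rivulatus", "Levantine"): 349.0,
        ("S_rivulatus", "Crete"): 7240.0,
        ("S_luridus", "RedSea"): 40.0,
        ("S_luridus", "Levantine"): 190.0,
        ("S_luridus", "Crete"): 190.0,
    }


@dataclass
class SyntheticScenario:
    """Parameters of one simulated invasion study.

    ``dispersion_theta`` maps (species, region) to the Dirichlet
    concentration; ``shift_logfold`` maps region to the log-fold change
    applied to ``shift_features`` in that region.
    """

    n_features: int = 150
    n_samples_per_group: dict[tuple[str, str, str], int] = field(default_factory=_default_group_sizes)
    baseline_logmean: float = 0.0
    baseline_logsd: float = 0.8
    dispersion_theta: dict[tuple[str, str], float] = field(default_factory=_default_theta)
    core_fraction: float = 0.10
    core_mass: float = 0.6
    noncore_occupancy: tuple[float, float] = (0.5, 0.95)
    shift_features: dict[str, list[int]] | None = None
    shift_logfold: dict[str, float] = field(default_factory=lambda: {"Levantine": 1.0, "Crete": 1.5})
    core_shift_features: list[int] | None = None
    core_shift_logfold: dict[str, float] = field(
        default_factory=lambda: {"Levantine": -1.0, "Crete": -1.5}
    )
    season_features: list[int] | None = None
    season_logfold: float = 0.3
    depth_mean: float = 5000.0
    depth_sd: float = 0.3
    ko_map: pd.DataFrame | None = None
    scfa_groups: dict[str, set[str]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.core_fraction <= 1:
            raise ValueError("core_fraction must be in [0, 1]")
        if any(th <= 0 for th in self.dispersion_theta.values()):
            raise ValueError("dispersion_theta values must be > 0")
        if any(n < 2 for n in self.n_samples_per_group.values()):
            raise ValueError("every group needs >= 2 samples")
        groups = {(sp, reg) for sp, reg, _ in self.n_samples_per_group}
        missing = groups - set(self.dispersion_theta)
        if missing:
            raise ValueError(f"dispersion_theta missing for groups: {sorted(missing)}")
        n_core = int(round(self.core_fraction * self.n_features))
        if self.shift_features is None:
            regions = sorted({reg for _, reg, _ in self.n_samples_per_group} - {"RedSea"})
            n_shift = max(1, self.n_features // 5)
            idx = list(range(n_core, min(n_core + n_shift, self.n_features)))
            self.shift_features = {reg: idx for reg in regions}
        for reg, idx in self.shift_features.items():
            if any(i < 0 or i >= self.n_features for i in idx):
                raise ValueError(f"shift feature index out of range for region {reg!r}")
        if self.core_shift_features is None:
            # part of the core changes relative abundance between ranges
            # (dominant lineages fading in the invaded range) while keeping
            # full occupancy, so core calls are unaffected
            self.core_shift_features = self.core_indices[-max(1, n_core // 3):] if n_core else []
        if any(i not in set(self.core_indices) for i in self.core_shift_features):
            raise ValueError("core_shift_features must be core indices")
        if self.season_features is None:
            start = n_core + max(1, self.n_features // 5)
            self.season_features = list(range(start, min(start + self.n_features // 10, self.n_features)))
        if any(i < 0 or i >= self.n_features for i in self.season_features):
            raise ValueError("season feature index out of range")

    @property
    def feature_ids(self) -> list[str]:
        width = len(str(self.n_features))
        return [f"ASV{i + 1:0{width}d}" for i in range(self.n_features)]

    @property
    def core_indices(self) -> list[int]:
        return list(range(int(round(self.core_fraction * self.n_features))))

    def group_profile(self, region: str, season: str, baseline: np.ndarray) -> np.ndarray:
        """Mean relative-abundance profile for one region x season cell."""
        pi = baseline.copy()
        for i in self.shift_features.get(region, []):
            pi[i] *= np.exp(self.shift_logfold.get(region, 0.0))
        if region in self.core_shift_logfold:
            for i in self.core_shift_features:
                pi[i] *= np.exp(self.core_shift_logfold[region])
        if season == "autumn":
            for i in self.season_features:
                pi[i] *= np.exp(self.season_logfold)
        return pi / pi.sum()

    def baseline_profile(self, rng: np.random.Generator) -> np.ndarray:
        """Baseline profile: log-normal tail plus the evenly-spread core block."""
        pi = np.empty(self.n_features)
        core = self.core_indices
        non_core = [i for i in range(self.n_features) if i not in set(core)]
        raw = rng.lognormal(self.baseline_logmean, self.baseline_logsd, size=len(non_core))
        core_mass = self.core_mass if core else 0.0
        pi[non_core] = raw / raw.sum() * (1.0 - core_mass)
        if core:
            pi[core] = core_mass / len(core)
        return pi

    def feature_occupancy(self, rng: np.random.Generator) -> np.ndarray:
        """Per-feature carriage probability: 1 for core, patchy otherwise."""
        lo, hi = self.noncore_occupancy
        if not 0 < lo <= hi <= 1:
            raise ValueError("noncore_occupancy bounds must satisfy 0 < lo <= hi <= 1")
        occ = rng.uniform(lo, hi, size=self.n_features)
        occ[self.core_indices] = 1.0
        return occ


@dataclass
class GroundTruth:
    """What was planted: core taxa, shifted taxa, true dispersion changes."""

    core_feature_ids: list[str]
    shifted_features: dict[str, dict[str, int]]  # region -> {feature_id: sign}
    percent_dispersion_change: dict[str, float]  # "species:native->region" -> %
    theta: dict[tuple[str, str], float]


@dataclass
class SimulatedDataset:
    table: CountTable
    metadata: SampleMetadata
    taxonomy: TaxonomyTable
    tree: PhyloTree
    ko_table: CountTable
    truth: GroundTruth


def default_ko_map(
    feature_ids: list[str], scfa_groups: dict[str, set[str]], rng: np.random.Generator
) -> pd.DataFrame:
    """Random sparse linear map features -> KOs with per-link weights.

    Every KO receives 5-20 contributing taxa with weights in (0.2, 1]; the
    map is fixed at generation time so KO abundance is a deterministic linear
    function of the taxa counts.
    """
    ko_ids = sorted(set().union(*(scfa_groups[g] for g in scfa_groups if g != "all")))
    n_feat = len(feature_ids)
    mat = np.zeros((n_feat, len(ko_ids)))
    for j in range(len(ko_ids)):
        k = int(rng.integers(5, 21))
        contributors = rng.choice(n_feat, size=min(k, n_feat), replace=False)
        mat[contributors, j] = rng.uniform(0.2, 1.0, size=len(contributors))
    return pd.DataFrame(mat, index=feature_ids, columns=ko_ids)


def _random_taxonomy(feature_ids: list[str], rng: np.random.Generator) -> TaxonomyTable:
    n_phyla = 6
    phyla = [f"Phylum_{i + 1}" for i in range(n_phyla)]
    rows = {}
    for fid in feature_ids:
        p = phyla[int(rng.integers(n_phyla))]
        c = f"{p}_Class{int(rng.integers(2)) + 1}"
        o = f"{c}_Order1"
        fam = f"{p}_Family{int(rng.integers(3)) + 1}"
        genus = f"{fam}_Genus{int(rng.integers(4)) + 1}" if rng.random() > 0.3 else "unassigned"
        rows[fid] = ["Bacteria", p, c, o, fam, genus, "unassigned"]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))
    df.index.name = "feature_id"
    return TaxonomyTable(df)


def _random_tree(feature_ids: list[str], seed: int) -> PhyloTree:
    """Pure-birth (Yule) ultrametric tree over the features."""
    taxa = dendropy.TaxonNamespace(feature_ids)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=len(feature_ids),
        taxon_namespace=taxa,
        rng=random.Random(seed),
    )
    newick = tree.as_string(schema="newick", suppress_rooting=True)
    sk = skbio.TreeNode.read(StringIO(newick), format="newick")
    # dendropy may quote labels; normalise to the raw feature ids
    for tip in sk.tips():
        tip.name = tip.name.replace("'", "").replace(" ", "_")
    return PhyloTree(sk, ultrametric_tol=1e-4)


def _simulate_group_counts(
    scenario: SyntheticScenario,
    pi: np.ndarray,
    occ: np.ndarray,
    theta: float,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    depths = np.maximum(
        rng.lognormal(np.log(scenario.depth_mean), scenario.depth_sd, size=n), 200
    ).astype(int)
    counts = np.empty((n, scenario.n_features), dtype=np.int64)
    for i in range(n):
        carried = rng.random(scenario.n_features) < occ
        pi_i = pi * carried
        pi_i = pi_i / pi_i.sum()
        comp = rng.dirichlet(np.clip(theta * pi_i, 1e-9, None))
        counts[i] = rng.multinomial(depths[i], comp)
    return counts


def simulate_dataset(scenario: SyntheticScenario, oracle_samples: int = 30) -> SimulatedDataset:
    """Draw one full dataset (counts, metadata, taxonomy, tree, KO table).

    ``oracle_samples`` controls the Monte-Carlo size used to record the true
    percent-dispersion changes in the ground truth (0 skips that step).
    Deterministic for a fixed ``scenario.seed``.
    """
    ss = np.random.SeedSequence(scenario.seed)
    keys = ["baseline", "samples", "taxonomy", "tree", "ko", "oracle"]
    streams = {k: np.random.default_rng(s) for k, s in zip(keys, ss.spawn(len(keys)))}

    feature_ids = scenario.feature_ids
    baseline = scenario.baseline_profile(streams["baseline"])
    occupancy = scenario.feature_occupancy(streams["baseline"])

    rows, sids, meta_rows = [], [], []
    rng = streams["samples"]
    for (sp, region, season), n in sorted(scenario.n_samples_per_group.items()):
        pi = scenario.group_profile(region, season, baseline)
        theta = scenario.dispersion_theta[(sp, region)]
        counts = _simulate_group_counts(scenario, pi, occupancy, theta, n, rng)
        for i in range(n):
            sid = f"{sp}_{region}_{season}_{i + 1:03d}"
            sids.append(sid)
            meta_rows.append((sid, "fish", sp, region, season, f"{region}_site1"))
        rows.append(counts)
    table = CountTable(
        pd.DataFrame(np.vstack(rows), index=sids, columns=feature_ids), "ASV"
    )
    meta = SampleMetadata(
        pd.DataFrame(
            [r[1:] for r in meta_rows],
            index=[r[0] for r in meta_rows],
            columns=["compartment", "host_species", "region", "season", "site"],
        )
    )

    taxonomy = _random_taxonomy(feature_ids, streams["taxonomy"])
    tree = _random_tree(feature_ids, int(streams["tree"].integers(2**31)))

    if scenario.scfa_groups is None:
        from .scfa_functional import default_scfa_groups

        scenario.scfa_groups = default_scfa_groups().groups
    ko_map = scenario.ko_map
    if ko_map is None:
        ko_map = default_ko_map(feature_ids, scenario.scfa_groups, streams["ko"])
        scenario.ko_map = ko_map
    ko_counts = np.rint(table.counts.astype(float) @ ko_map.to_numpy()).astype(int)
    ko_table = CountTable(
        pd.DataFrame(ko_counts, index=sids, columns=list(ko_map.columns)), "KO"
    )

    shifted = {
        reg: {feature_ids[i]: int(np.sign(scenario.shift_logfold.get(reg, 0.0)) or 1) for i in idx}
        for reg, idx in scenario.shift_features.items()
    }
    for reg, lf in scenario.core_shift_logfold.items():
        if scenario.core_shift_features and lf != 0.0:
            shifted.setdefault(reg, {}).update(
                {feature_ids[i]: int(np.sign(lf)) for i in scenario.core_shift_features}
            )
    pct_change: dict[str, float] = {}
    if oracle_samples:
        orng = streams["oracle"]
        groups = sorted({(sp, reg) for sp, reg, _ in scenario.n_samples_per_group})
        disp = {
            g: _expected_dispersion_impl(scenario, g, baseline, occupancy, oracle_samples, orng)[0]
            for g in groups
        }
        for sp, reg in groups:
            if reg == "RedSea" or (sp, "RedSea") not in disp:
                continue
            ref = disp[(sp, "RedSea")]
            pct_change[f"{sp}:RedSea->{reg}"] = 100.0 * (ref - disp[(sp, reg)]) / ref
    truth = GroundTruth(
        [feature_ids[i] for i in scenario.core_indices],
        shifted,
        pct_change,
        dict(scenario.dispersion_theta),
    )
    return SimulatedDataset(table, meta, taxonomy, tree, ko_table, truth)


def _expected_dispersion_impl(
    scenario: SyntheticScenario,
    group: tuple[str, str],
    baseline: np.ndarray,
    occupancy: np.ndarray,
    n_samples: int,
    rng: np.random.Generator,
    n_blocks: int = 4,
) -> tuple[float, float]:
    sp, region = group
    theta = scenario.dispersion_theta[(sp, region)]
    pi = scenario.group_profile(region, "spring", baseline)
    block_means = []
    for _ in range(n_blocks):
        counts = _simulate_group_counts(scenario, pi, occupancy, theta, n_samples, rng)
        props = counts / counts.sum(axis=1, keepdims=True)
        d = pairwise_dissimilarities(props, q=1.0)
        block_means.append(d[np.triu_indices(n_samples, k=1)].mean())
    block_means = np.asarray(block_means)
    se = block_means.std(ddof=1) / np.sqrt(n_blocks) if n_blocks > 1 else 0.0
    return float(block_means.mean()), float(se)


def expected_dispersion(
    scenario: SyntheticScenario,
    group: tuple[str, str],
    n_samples: int = 30,
    n_blocks: int = 4,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo mean within-group pairwise dissimilarity (q=1 taxonomic).

    Simulates ``n_blocks`` independent groups of ``n_samples`` individuals
    and returns (mean, Monte-Carlo standard error) of the mean pairwise
    dissimilarity — the oracle for percent-homogenization recovery.
    """
    if (group[0], group[1]) not in scenario.dispersion_theta:
        raise KeyError(f"unknown group {group!r}")
    ss = np.random.SeedSequence(scenario.seed)
    stream = np.random.default_rng(ss.spawn(1)[0])
    baseline = scenario.baseline_profile(stream)
    occupancy = scenario.feature_occupancy(stream)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    return _expected_dispersion_impl(scenario, group, baseline, occupancy, n_samples, rng, n_blocks)


def theta_for_reduction(
    scenario: SyntheticScenario,
    species: str,
    region: str,
    target_percent: float,
    native_region: str = "RedSea",
    seed: int = 0,
    n_samples: int = 30,
    n_blocks: int = 4,
    tol: float = 1.0,
) -> float:
    """Concentration achieving a target percent drop in within-group dissimilarity.

    Finds the Dirichlet concentration for (species, *region*) such that the
    Monte-Carlo dispersion oracle for that group (with its own shifted mean
    profile) sits ``target_percent`` percent below the native group's
    dispersion.  Bisection on the log of a concentration multiplier; used to
    construct scenarios with planted homogenization of a stated size.
    """
    base = expected_dispersion(scenario, (species, native_region), n_samples, n_blocks, seed)[0]
    theta0 = scenario.dispersion_theta[(species, native_region)]
    target = base * (1.0 - target_percent / 100.0)

    def disp(mult: float) -> float:
        probe = SyntheticScenario(
            n_features=scenario.n_features,
            n_samples_per_group=scenario.n_samples_per_group,
            baseline_logmean=scenario.baseline_logmean,
            baseline_logsd=scenario.baseline_logsd,
            dispersion_theta={**scenario.dispersion_theta,
                              (species, region): theta0 * mult},
            core_fraction=scenario.core_fraction,
            core_mass=scenario.core_mass,
            shift_features=scenario.shift_features,
            shift_logfold=scenario.shift_logfold,
            core_shift_features=scenario.core_shift_features,
            core_shift_logfold=scenario.core_shift_logfold,
            noncore_occupancy=scenario.noncore_occupancy,
            depth_mean=scenario.depth_mean,
            depth_sd=scenario.depth_sd,
            seed=scenario.seed,
        )
        return expected_dispersion(probe, (species, region), n_samples, n_blocks, seed)[0]

    lo, hi = 1.0, 2.0
    while disp(hi) > target and hi < 65536:
        hi *= 2.0
    if disp(hi) > target:
        raise ValueError(
            f"target reduction {target_percent}% unreachable: residual dissimilarity "
            "from patchy occupancy and sampling noise exceeds the target floor"
        )
    for _ in range(30):
        mid = np.sqrt(lo * hi)
        d = disp(mid)
        pct = 100.0 * (base - d) / base
        if abs(pct - target_percent) < tol:
            return theta0 * mid
        if d > target:
            lo = mid
        else:
            hi = mid
    return theta0 * np.sqrt(lo * hi)
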