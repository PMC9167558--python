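"""End-to-end pipeline: data -> cleaning -> diversity -> tests -> reports.

One YAML config drives every stage; every stochastic stage draws its seed
from a dedicated substream of the top-level seed, so re-running a config
reproduces identical artifacts (verified by checksums in the manifest) and
single stages can be re-run in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import core_microbiome as core_mod
from . import differential_abundance as da
from . import tables_io as tio
from .hill_diversity import HillConfig, dissimilarity_matrix
from .homogenization import homogenization_report
from .ordination_beta import pcoa, permanova, permdisp
from .scfa_functional import ScfaGroups, default_scfa_groups, scfa_beta_analysis
from .synthetic_data import SyntheticScenario, simulate_dataset

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "default_hill_configs"]

log = logging.getLogger("invashift")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


def default_hill_configs() -> list[HillConfig]:
    """q in {0, 1} x taxonomic ranks {Phylum, Family, ASV} + phylogenetic ASV.

    The phylogenetic facet is leaf-level, so it is computed at the ASV rank
    only: eight configurations in total.
    """
    configs = [
        HillConfig(q=q, facet="taxonomic", rank=rank)
        for q in (0.0, 1.0)
        for rank in ("Phylum", "Family", "ASV")
    ]
    configs += [HillConfig(q=q, facet="phylogenetic", rank="ASV") for q in (0.0, 1.0)]
    return configs


@dataclass
class PipelineConfig:
    """Settings for one run; defaults mirror the study constants.

    Rarefaction depth defaults to 2000 reads but is applied only when
    ``rarefy`` is true (the host-only dataset is analysed unrarefied by
    default to keep all information, as in the study design).
    Core settings: 1000 bootstrap iterations, consensus threshold 0.8,
    per-species subsample size defaulting to the smallest region group.
    """

    outdir: Path
    seed: int = 0
    scenario: dict | None = None
    table_path: str | None = None
    metadata_path: str | None = None
    taxonomy_path: str | None = None
    tree_path: str | None = None
    ko_table_path: str | None = None
    scfa_groups_path: str | None = None
    min_prevalence: int = 3
    exclude_labels: list[str] = field(default_factory=lambda: ["Chloroplast", "Mitochondria"])
    rarefy: bool = False
    rarefaction_depth: int = 2000
    hill: list[dict] | None = None
    n_perm: int = 999
    core_iterations: int = 1000
    core_threshold: float = 0.8
    core_n_boot: dict[str, int] | None = None
    core_mode: str = "at_expectation"
    native_region: str = "RedSea"
    alpha: float = 0.05
    run_scfa: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["outdir"] = Path(raw["outdir"])
        return cls(**raw)

    def hill_configs(self) -> list[HillConfig]:
        if self.hill is None:
            return default_hill_configs()
        return [HillConfig(**h) for h in self.hill]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the artifact manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    stage_names = ["data", "rarefy", "ordination", "core", "scfa"]
    stage_seeds = {
        name: int(s.generate_state(1)[0] % 2**31)
        for name, s in zip(stage_names, ss.spawn(len(stage_names)))
    }
    manifest: dict = {"seed": config.seed, "stages": {}, "files": {}}

    def emit(name: str, path: Path) -> None:
        manifest["files"][name] = {"path": str(path), "sha256": _sha256(path)}

    # -- stage: data ---------------------------------------------------------
    try:
        if config.scenario is not None:
            scenario = SyntheticScenario(**config.scenario, seed=stage_seeds["data"])
            sim = simulate_dataset(scenario)
            table, meta, taxonomy, tree, ko_table = (
                sim.table, sim.metadata, sim.taxonomy, sim.tree, sim.ko_table,
            )
            truth_path = out / "ground_truth.json"
            truth_path.write_text(json.dumps({
                "core_feature_ids": sim.truth.core_feature_ids,
                "shifted_features": sim.truth.shifted_features,
                "percent_dispersion_change": sim.truth.percent_dispersion_change,
            }, indent=1))
            emit("ground_truth", truth_path)
        else:
            if not (config.table_path and config.metadata_path and config.taxonomy_path):
                raise PipelineError("stage data: need either a scenario or input paths")
            table = tio.read_count_table(config.table_path)
            meta = tio.read_metadata(config.metadata_path)
            taxonomy = tio.read_taxonomy(config.taxonomy_path)
            tree = tio.read_tree(config.tree_path) if config.tree_path else None
            ko_table = (
                tio.read_count_table(config.ko_table_path, feature_kind="KO")
                if config.ko_table_path else None
            )
        meta.validate_against(table)
        tio.write_count_table(table, out / "asv_table.tsv")
        emit("asv_table", out / "asv_table.tsv")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage data: {exc}") from exc
    log.info("data stage: %d samples x %d features", *table.counts.shape)

    # -- stage: filtering / rarefaction -------------------------------------
    try:
        table = tio.filter_features(
            table, taxonomy, min_samples=config.min_prevalence,
            exclude_labels=config.exclude_labels,
        )
        if config.rarefy:
            table, report = tio.rarefy(table, config.rarefaction_depth, stage_seeds["rarefy"])
            (out / "rarefaction_dropped.json").write_text(json.dumps(report.dropped))
            emit("rarefaction_dropped", out / "rarefaction_dropped.json")
            meta = meta.subset(table.sample_ids)
    except Exception as exc:
        raise PipelineError(f"stage filter/rarefy: {exc}") from exc

    rel = tio.to_relative(table)

    # -- stage: diversity matrices -------------------------------------------
    dms = {}
    for hc in config.hill_configs():
        if hc.facet == "phylogenetic" and tree is None:
            raise PipelineError(
                f"stage diversity: config {hc.label} requires a phylogenetic tree"
            )
        try:
            dms[hc.label] = dissimilarity_matrix(rel, hc, tree=tree, taxonomy=taxonomy)
        except Exception as exc:
            raise PipelineError(f"stage diversity ({hc.label}): {exc}") from exc
        path = out / f"dissim_{hc.label}.tsv"
        dms[hc.label].write_tsv(path)
        emit(f"dissim_{hc.label}", path)
    manifest["stages"]["diversity"] = sorted(dms)

    # -- stage: ordination + multivariate tests ------------------------------
    try:
        rng = np.random.default_rng(stage_seeds["ordination"])
        ref_label = "q1_taxonomic_ASV" if "q1_taxonomic_ASV" in dms else sorted(dms)[0]
        emb = pcoa(dms[ref_label])
        emb.coordinates.to_csv(out / "pcoa_coordinates.tsv", sep="\t", index_label="sample_id")
        emit("pcoa_coordinates", out / "pcoa_coordinates.tsv")

        species_list = sorted(
            set(meta.data.loc[table.sample_ids, "host_species"].dropna())
        )
        perm_rows, disp_rows = [], []
        for sp in species_list:
            ids = [s for s in meta.select(host_species=sp) if s in set(table.sample_ids)]
            sub_meta = meta.subset(ids)
            # single-level factors carry no information for this species subset
            terms = [t for t in ("region", "season")
                     if sub_meta.data[t].nunique() > 1]
            if len(terms) == 2:
                terms.append("region:season")
            if not terms:
                continue
            for label, dm in dms.items():
                sub = dm.submatrix(ids)
                try:
                    res = permanova(sub, sub_meta, terms,
                                    n_perm=config.n_perm, seed=int(rng.integers(2**31)))
                except ValueError as exc:
                    if "zero total sum of squares" not in str(exc):
                        raise
                    # degenerate configuration (e.g. identical presence at a
                    # coarse rank): record and move on
                    perm_rows.append((sp, label, "degenerate", np.nan, np.nan,
                                      np.nan, np.nan, np.nan))
                    continue
                for term, row in res.table.iterrows():
                    perm_rows.append((sp, label, term, row["df"], row["SS"], row["R2"],
                                      row["F"], row["p"]))
                disp = permdisp(sub, sub_meta, "region", n_perm=config.n_perm,
                                seed=int(rng.integers(2**31)))
                for grp, m in disp.group_means.items():
                    disp_rows.append((sp, label, grp, m, disp.f_statistic, disp.p_value))
        perm_df = pd.DataFrame(perm_rows, columns=[
            "species", "config", "term", "df", "SS", "R2", "F", "p"])
        perm_df.to_csv(out / "permanova.tsv", sep="\t", index=False)
        emit("permanova", out / "permanova.tsv")
        disp_df = pd.DataFrame(disp_rows, columns=[
            "species", "config", "region", "mean_dispersion", "F", "p"])
        disp_df.to_csv(out / "permdisp.tsv", sep="\t", index=False)
        emit("permdisp", out / "permdisp.tsv")

        # Table-1-style summary: per species, average R2 / F across configs
        summ = []
        for sp in species_list:
            sub = perm_df[(perm_df["species"] == sp) & (perm_df["term"] != "degenerate")]
            if sub.empty:
                continue
            piv = sub.pivot_table(index="term", values=["R2", "F"], aggfunc="mean")
            if {"region", "season"} <= set(piv.index):
                ratio = piv.loc["region", "F"] / piv.loc["season", "F"]
            else:
                ratio = np.nan
            for term in piv.index:
                if term in ("Residual", "Total"):
                    continue
                n_sig = int((sub[(sub["term"] == term)]["p"] < config.alpha).sum())
                summ.append((sp, term, n_sig, piv.loc[term, "R2"], piv.loc[term, "F"], ratio))
        summary_df = pd.DataFrame(summ, columns=[
            "species", "term", "n_significant", "mean_R2", "mean_F", "F_region_over_F_season"])
        summary_df.to_csv(out / "permanova_summary.tsv", sep="\t", index=False)
        emit("permanova_summary", out / "permanova_summary.tsv")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage ordination: {exc}") from exc

    # -- stage: core microbiome ----------------------------------------------
    try:
        rng = np.random.default_rng(stage_seeds["core"])
        entries, n_boot_used = {}, {}
        for sp in species_list:
            group_sizes = {
                reg: len(meta.select(host_species=sp, region=reg))
                for reg in sorted(set(meta.data["region"].dropna()))
            }
            group_sizes = {r: n for r, n in group_sizes.items() if n >= 2}
            if not group_sizes:
                continue
            n_boot = (config.core_n_boot or {}).get(sp, min(group_sizes.values()))
            n_boot_used[sp] = n_boot
            for reg in group_sizes:
                entries[(sp, reg)] = core_mod.bootstrap_core(
                    table, meta, sp, reg, n_boot=n_boot, B=config.core_iterations,
                    threshold=config.core_threshold, seed=int(rng.integers(2**31)),
                    mode=config.core_mode,
                )
        consensus = core_mod.consensus_union(
            entries, threshold=config.core_threshold,
            B=config.core_iterations, n_boot=n_boot_used,
        )
        consensus.write_tsv(out / "core_consensus.tsv")
        emit("core_consensus", out / "core_consensus.tsv")
        prop = core_mod.core_proportion(table, consensus)
        prop.to_frame().to_csv(out / "core_proportion.tsv", sep="\t", index_label="sample_id")
        emit("core_proportion", out / "core_proportion.tsv")
        manifest["stages"]["core"] = {"n_consensus": len(consensus.consensus)}
    except Exception as exc:
        raise PipelineError(f"stage core: {exc}") from exc

    # -- stage: differential abundance ---------------------------------------
    try:
        summaries = []
        for sp in species_list:
            ids = [s for s in meta.select(host_species=sp) if s in set(table.sample_ids)]
            if len(set(meta.data.loc[ids, "region"])) < 2:
                continue
            sub_meta = meta.subset(ids)
            per_rank = {}
            for rank in ("Phylum", "Family", "ASV"):
                agg = tio.aggregate_rank(table.select_samples(ids), taxonomy, rank)
                res = da.kruskal_per_feature(
                    tio.to_relative(agg), sub_meta, "region", alpha=config.alpha
                )
                res.insert(0, "rank", rank)
                res.insert(0, "species", sp)
                per_rank[rank] = res
                clr = da.clr_transform(agg)
                da.anova_per_feature(clr, sub_meta, "region", alpha=config.alpha).to_csv(
                    out / f"anova_clr_{sp}_{rank}.tsv", sep="\t", index=False
                )
            pd.concat(per_rank.values()).to_csv(
                out / f"kruskal_{sp}.tsv", sep="\t", index=False
            )
            emit(f"kruskal_{sp}", out / f"kruskal_{sp}.tsv")
            s = da.significance_summary(per_rank)
            s.insert(0, "species", sp)
            summaries.append(s)
        if summaries:
            pd.concat(summaries).to_csv(out / "diffabund_summary.tsv", sep="\t", index=False)
            emit("diffabund_summary", out / "diffabund_summary.tsv")
    except Exception as exc:
        raise PipelineError(f"stage differential_abundance: {exc}") from exc

    # -- stage: homogenization ------------------------------------------------
    try:
        regions = sorted(set(meta.data.loc[table.sample_ids, "region"]))
        others = [r for r in regions if r != config.native_region]
        label = "q1_phylogenetic_ASV" if "q1_phylogenetic_ASV" in dms else sorted(dms)[0]
        report = homogenization_report(
            dms, meta, species_list, config.native_region, others,
            alpha=config.alpha, label_config=label,
        )
        report.intraspecific.to_csv(out / "homogenization_intraspecific.tsv", sep="\t", index=False)
        report.interspecific.to_csv(out / "homogenization_interspecific.tsv", sep="\t", index=False)
        report.per_config.to_csv(out / "homogenization_per_config.tsv", sep="\t", index=False)
        emit("homogenization_intraspecific", out / "homogenization_intraspecific.tsv")
        emit("homogenization_interspecific", out / "homogenization_interspecific.tsv")
        emit("homogenization_per_config", out / "homogenization_per_config.tsv")
        labels = report.labels
        (out / "trajectory_labels.json").write_text(json.dumps({
            "per_species": labels.per_species if labels else None,
            "shifted": labels.shifted if labels else None,
            "interspecific": labels.interspecific if labels else None,
            "overall": labels.overall if labels else None,
            "caveat": report.caveat,
        }, indent=1))
        emit("trajectory_labels", out / "trajectory_labels.json")
    except Exception as exc:
        raise PipelineError(f"stage homogenization: {exc}") from exc

    # -- stage: SCFA functional ------------------------------------------------
    if config.run_scfa and ko_table is not None:
        try:
            groups = (
                ScfaGroups.from_tsv(config.scfa_groups_path)
                if config.scfa_groups_path else default_scfa_groups()
            )
            results = scfa_beta_analysis(
                ko_table, meta, groups, n_perm=config.n_perm,
                seed=stage_seeds["scfa"], native_region=config.native_region,
            )
            rows = []
            for (group, q), res in results.items():
                if res.degenerate or res.permanova is None:
                    rows.append((group, q, np.nan, np.nan, np.nan, np.nan, True))
                    continue
                t = res.permanova.table
                ratio = (
                    t.loc["region", "F"] / t.loc["season", "F"]
                    if "season" in t.index else np.nan
                )
                rows.append((group, q, t.loc["region", "R2"], t.loc["region", "F"],
                             ratio, t.loc["region", "p"], False))
            pd.DataFrame(rows, columns=[
                "group", "q", "region_R2", "region_F", "F_region_over_F_season",
                "region_p", "degenerate",
            ]).to_csv(out / "scfa_permanova.tsv", sep="\t", index=False)
            emit("scfa_permanova", out / "scfa_permanova.tsv")
        except Exception as exc:
            raise PipelineError(f"stage scfa: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
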