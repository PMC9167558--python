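# invashift

Analysis pipeline for **gut-microbiome shift and homogenization during
biological invasion**, built around the case of two Lessepsian rabbitfishes
(*Siganus rivulatus*, *S. luridus*) that moved from their native Red Sea
into the Mediterranean (Levantine Sea, Northern Crete).  The package is for
microbial ecologists who want to ask, from an ASV table, a phylogeny and
sample metadata: did the microbiome *change* between ranges, and did it
become more *homogeneous* within and between host species?

## What it computes

- **Hill-number diversity**, taxonomic and phylogenetic, for order
  `q ∈ {0, 1}` (and any `q ≥ 0`): alpha diversity
  `ᵠD = (Σᵢ pᵢᵠ)^{1/(1−q)}` (with `¹D = exp(−Σ pᵢ ln pᵢ)`), and its
  branch-weighted phylogenetic analogue over an ultrametric tree,
  `ᵠD̄(T) = (Σ_b (L_b/T) a_bᵠ)^{1/(1−q)}`.  Pairwise beta diversity
  `β = γ/ᾱ ∈ [1, 2]` is converted to a Sørensen-type dissimilarity
  `1 − C_qN ∈ [0, 1]` (Jaccard-type available), at Phylum / Family / ASV
  resolution.
- **Core microbiome** by a Poisson abundance–occupancy null: a taxon with
  rate `λ = N/n` is core when its observed occupancy reaches
  `n(1 − e^{−λ})`, stabilised by a bootstrap consensus (1000 subsamples of
  equal size, consensus at > 80% of iterations in at least one
  species × region group).
- **PERMANOVA** (sequential sums of squares with Region × Season
  interaction, exhaustive enumeration for tiny n), **pairwise PERMANOVA**
  with FDR, **PERMDISP** (negative-eigenvalue-corrected distances to group
  centers) and **PCoA** — all from any distance matrix.
- **Differential abundance** per feature: ANOVA on centered log-ratio
  transformed counts and Kruskal–Wallis with Benjamini–Hochberg FDR.
- **SCFA functional analysis**: the same beta machinery applied to KEGG
  Orthology tables restricted to short-chain fatty-acid groups (formate,
  acetate, propionate, butyrate, valerate), each re-closed as its own
  composition.
- **Homogenization**: within-species, between-region and between-species
  pairwise-dissimilarity summaries, percent change from the native region
  averaged across index configurations, and classification of the invasion
  trajectory (homogenization / differentiation / no change, within and
  between species).
- **Synthetic data** with planted ground truth (Dirichlet-multinomial
  communities with planted core taxa, regional shifts and invaded-range
  homogenization) so every stage can be validated end to end; see
  `docs/methods.md`.

## Worked example

Simulate an invasion-structured dataset and run the full pipeline:

```python
from invashift import PipelineConfig, run_pipeline

config = PipelineConfig(outdir="demo_run", seed=1, scenario={}, n_perm=999)
manifest = run_pipeline(config)
print(manifest["stages"]["core"])
```

which prints

```
{'n_consensus': 17}
```

— the bootstrap consensus recovered 17 core ASVs (the scenario plants 15;
the two extras are abundant taxa that genuinely reach full occupancy).  The
homogenization report written to `demo_run/homogenization_intraspecific.tsv`
contains (mean ± SD percent dissimilarity decrease across the eight index
configurations, Kruskal–Wallis on the q = 1 phylogenetic pairwise values):

```
species      native  comparison  mean_pct  sd_pct   p
S_rivulatus  RedSea  Levantine   63.6      23.0     4.3e-256
S_rivulatus  RedSea  Crete       74.2      20.7     2.9e-256
S_luridus    RedSea  Crete       51.3      15.4     3.8e-40
```

meaning the gut microbiome of both species is far more homogeneous among
individuals in the invaded range than in the native Red Sea, with the
strongest drop furthest from the native range, and
`demo_run/trajectory_labels.json` classifies the overall pattern as

```
"overall": "homogenization within and between species"
```

The same analyses are scriptable from the shell:

```bash
invashift simulate --seed 1 --out data/
invashift filter --table data/asv_table.tsv --taxonomy data/taxonomy.tsv --out data/filtered.tsv
invashift rarefy --table data/filtered.tsv --depth 2000 --seed 1 --out data/rarefied.tsv
invashift run --config config.yaml
```

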