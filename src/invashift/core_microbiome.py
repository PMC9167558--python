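"""Core-microbiome identification by a Poisson abundance-occupancy null.

A taxon whose reads were scattered at random across ``n`` equally-sampled
communities would have Poisson-distributed per-sample counts with rate
``lambda = N_total / n`` and expected occupancy ``n * (1 - exp(-lambda))``.
Taxa observed at or above that expectation are evenly spread relative to the
random benchmark and are called core.  Because group sizes differ between
host species and regions, core calls are stabilised by bootstrap: subsamples
of equal size are drawn repeatedly and a taxon joins the consensus core when
it is called in more than a threshold fraction of iterations in at least one
(species, region) group.

Counts should be comparable across samples (equal-depth or rarefied input);
the Poisson null assumes uniform sampling effort.  This is documented, not
enforced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tables_io import CountTable, SampleMetadata

__all__ = [
    "OccupancyRecord",
    "CoreConsensus",
    "occupancy_stats",
    "call_core",
    "bootstrap_core",
    "consensus_union",
    "core_proportion",
]


@dataclass
class OccupancyRecord:
    """Observed vs Poisson-expected occupancy for one feature."""

    feature_id: str
    o_obs: int
    n_total: int
    n: int
    lam: float
    o_exp: float


@dataclass
class CoreConsensus:
    """Bootstrap core-call frequencies per (species, region) and the union core."""

    frequencies: pd.DataFrame  # index feature_id, columns "species|region"
    threshold: float
    b_iterations: int
    n_boot: dict[str, int] = field(default_factory=dict)

    @property
    def consensus(self) -> list[str]:
        mask = (self.frequencies > self.threshold).any(axis=1)
        return list(self.frequencies.index[mask])

    def per_group_core(self, group: str) -> list[str]:
        freq = self.frequencies[group]
        return list(freq.index[freq > self.threshold])

    def write_tsv(self, path: str | Path) -> None:
        long = self.frequencies.reset_index().melt(
            id_vars="feature_id", var_name="group", value_name="frequency"
        )
        parts = long["group"].str.split("|", expand=True)
        long["species"], long["region"] = parts[0], parts[1]
        long["is_core"] = long["frequency"] > self.threshold
        long[["feature_id", "species", "region", "frequency", "is_core"]].to_csv(
            path, sep="\t", index=False
        )


def occupancy_stats(table: CountTable) -> list[OccupancyRecord]:
    """Per-feature occupancy, total count, Poisson rate and expected occupancy."""
    n = len(table.sample_ids)
    if n < 2:
        raise ValueError("occupancy statistics need at least 2 samples")
    counts = table.counts
    o_obs = (counts > 0).sum(axis=0)
    totals = counts.sum(axis=0)
    lam = totals / n
    o_exp = n * (1.0 - np.exp(-lam))
    return [
        OccupancyRecord(fid, int(o), int(t), n, float(l), float(e))
        for fid, o, t, l, e in zip(table.feature_ids, o_obs, totals, lam, o_exp)
    ]


def call_core(
    records: list[OccupancyRecord],
    mode: str = "at_expectation",
    alpha: float = 0.05,
    min_occupancy: int = 1,
    seed: int = 0,
    n_null: int = 1000,
) -> set[str]:
    """Features whose occupancy meets the Poisson benchmark.

    ``at_expectation`` (default): core iff ``O_obs >= O_exp``.
    ``envelope``: core iff ``O_obs`` is at or above the lower alpha-quantile
    of the occupancy of ``n`` independent Poisson(lambda) draws, simulated
    ``n_null`` times — a forgiving variant for sensitivity analysis.
    A feature must additionally be observed in at least ``min_occupancy``
    samples.
    """
    if mode not in ("at_expectation", "envelope"):
        raise ValueError(f"unknown mode {mode!r}")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    core: set[str] = set()
    rng = np.random.default_rng(seed)
    for rec in records:
        if rec.o_obs < max(min_occupancy, 1):
            continue
        if mode == "at_expectation":
            if rec.o_obs >= rec.o_exp:
                core.add(rec.feature_id)
        else:
            null_occ = (rng.poisson(rec.lam, size=(n_null, rec.n)) > 0).sum(axis=1)
            lower = np.quantile(null_occ, alpha)
            if rec.o_obs >= lower:
                core.add(rec.feature_id)
    return core


def bootstrap_core(
    table: CountTable,
    meta: SampleMetadata,
    species: str,
    region: str,
    n_boot: int,
    B: int = 1000,
    threshold: float = 0.8,
    seed: int = 0,
    mode: str = "at_expectation",
    min_occupancy: int = 1,
) -> pd.Series:
    """Bootstrap core-call frequency per feature for one (species, region).

    Each of the ``B`` iterations draws ``n_boot`` samples without replacement
    from the group and runs the Poisson occupancy call; the returned series
    is the fraction of iterations in which each feature was called core.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    group_ids = sorted(meta.select(host_species=species, region=region))
    if n_boot > len(group_ids):
        raise ValueError(
            f"n_boot={n_boot} exceeds group size {len(group_ids)} for {species}/{region}"
        )
    sub = table.select_samples(group_ids)
    counts = sub.counts
    n_features = counts.shape[1]
    rng = np.random.default_rng(seed)
    hits = np.zeros(n_features)
    for _ in range(B):
        pick = rng.choice(len(group_ids), size=n_boot, replace=False)
        c = counts[pick]
        o_obs = (c > 0).sum(axis=0)
        lam = c.sum(axis=0) / n_boot
        o_exp = n_boot * (1.0 - np.exp(-lam))
        if mode == "at_expectation":
            called = (o_obs >= o_exp) & (o_obs >= max(min_occupancy, 1))
        else:
            recs = [
                OccupancyRecord(fid, int(o), int(t), n_boot, float(l), float(e))
                for fid, o, t, l, e in zip(sub.feature_ids, o_obs, c.sum(axis=0), lam, o_exp)
            ]
            core = call_core(
                recs, mode="envelope", min_occupancy=min_occupancy, seed=int(rng.integers(2**31))
            )
            called = np.array([fid in core for fid in sub.feature_ids])
        hits += called
    return pd.Series(hits / B, index=sub.feature_ids, name=f"{species}|{region}")


def consensus_union(
    entries: dict[tuple[str, str], pd.Series],
    threshold: float = 0.8,
    B: int = 1000,
    n_boot: dict[str, int] | None = None,
) -> CoreConsensus:
    """Combine per-group bootstrap frequencies into the consensus core.

    The consensus is the union over groups of features whose frequency
    exceeds the threshold — core "in at least one region and one species".
    """
    if not entries:
        raise ValueError("no bootstrap entries provided")
    freq = pd.DataFrame(
        {f"{sp}|{reg}": series for (sp, reg), series in entries.items()}
    ).fillna(0.0)
    freq.index.name = "feature_id"
    return CoreConsensus(freq, threshold, B, n_boot or {})


def core_proportion(table: CountTable, consensus: CoreConsensus | list[str]) -> pd.Series:
    """Per-sample fraction of reads belonging to consensus-core features."""
    core_ids = consensus.consensus if isinstance(consensus, CoreConsensus) else list(consensus)
    unknown = set(core_ids) - set(table.feature_ids)
    if unknown:
        raise KeyError(f"consensus features not in table: {sorted(unknown)}")
    totals = table.counts.sum(axis=1)
    if np.any(totals == 0):
        bad = table.data.index[totals == 0][0]
        raise ValueError(f"sample {bad!r} has zero total count")
    core_sum = table.data[core_ids].sum(axis=1) if core_ids else pd.Series(0, index=table.data.index)
    return (core_sum / totals).rename("core_proportion")
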