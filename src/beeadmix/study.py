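"""Study-scale benchmark runs: ancestry and mitotype recovery.

These functions reproduce the full analysis at the sampled-population
scale: four reference panels plus 15 admixed individuals with preset
ancestry, K=4 genotype-likelihood admixture with reference labeling, and
the K2P/NJ mitotype classifier on preset clade compositions.  They are
used both as parameter-recovery benchmarks and as worked examples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .admixture import fit_admixture, label_clusters, summarize_population_ancestry
from .mito import (
    assign_clades,
    bootstrap_support,
    clade_bipartition_supports,
    midpoint_root,
)
from .simulate import (
    LINEAGES,
    MITOTYPE_PRESETS,
    SimulationConfig,
    ancestry_preset,
    simulate_admixture_study,
    simulate_mito_alignment,
)

__all__ = ["AncestryBenchmark", "MitotypeBenchmark",
           "run_ancestry_benchmark", "run_mitotype_benchmark"]


@dataclass
class AncestryBenchmark:
    population: str
    mean_pct: dict[str, float]  # lineage -> mean inferred ancestry (%)
    se_pct: dict[str, float]
    truth_pct: dict[str, float]
    loglik: float
    n_admixed: int


@dataclass
class MitotypeBenchmark:
    population: str
    counts: dict[str, int]  # clade -> queries assigned
    true_counts: dict[str, int]
    clade_supports: dict[str, float | None]
    n_queries: int


def run_ancestry_benchmark(
    population: str,
    seed: int,
    n_sites: int = 5000,
    n_references: int = 20,
    n_admixed: int = 15,
    mean_depth: float = 29.0,
    error_rate: float = 0.01,
    fst: float = 0.15,
    k: int = 4,
    n_restarts: int = 10,
) -> AncestryBenchmark:
    """Simulate one admixed population with its reference panels and
    recover mean ancestry percentages via K=4 admixture EM."""
    cfg = SimulationConfig(
        seed=seed, n_sites=n_sites, mean_depth=mean_depth, error_rate=error_rate
    )
    study = simulate_admixture_study(
        cfg, preset=population, n_references=n_references,
        n_admixed=n_admixed, fst=fst,
    )
    model = fit_admixture(study.ds, k=k, n_restarts=n_restarts, seed=seed)
    ref_map = {
        i: row.population
        for i, row in study.sample_info.iterrows()
        if row.role == "reference"
    }
    model = label_clusters(model, ref_map)
    admixed_idx = np.flatnonzero(study.sample_info["role"].values == "admixed")
    summary = summarize_population_ancestry(model, {population: admixed_idx})
    row = summary.iloc[0]
    truth = ancestry_preset(population) * 100.0
    return AncestryBenchmark(
        population=population,
        mean_pct={lab: float(row[f"mean_{lab}"]) for lab in LINEAGES},
        se_pct={lab: float(row[f"se_{lab}"]) for lab in LINEAGES},
        truth_pct=dict(zip(LINEAGES, truth)),
        loglik=model.loglik,
        n_admixed=n_admixed,
    )


def run_mitotype_benchmark(
    population: str,
    seed: int,
    refs_per_clade: int = 3,
    seq_length: int = 15000,
    divergence_between: float = 0.05,
    divergence_within: float = 0.005,
    n_boot: int = 200,
) -> MitotypeBenchmark:
    """Simulate a population's mitotype composition and classify queries
    with the K2P/NJ/midpoint-root pipeline."""
    composition = MITOTYPE_PRESETS[population]
    aln = simulate_mito_alignment(
        composition,
        refs_per_clade=refs_per_clade,
        divergence_between=divergence_between,
        divergence_within=divergence_within,
        seq_length=seq_length,
        seed=seed,
    )
    tree, _ = bootstrap_support(aln, n_reps=n_boot, seed=seed)
    rooted = midpoint_root(tree)
    assignments = assign_clades(rooted, aln)
    counts = {c: int((assignments["clade"] == c).sum()) for c in LINEAGES}
    return MitotypeBenchmark(
        population=population,
        counts=counts,
        true_counts=dict(composition),
        clade_supports=clade_bipartition_supports(tree, aln),
        n_queries=int(sum(composition.values())),
    )
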