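"""End-to-end orchestration: simulate -> filter -> admix/pca/theta/mito.

A single TOML config drives a deterministic run; every stage derives its
seed from the top-level seed and the stage name, so reruns with the same
config reproduce identical tables.  Outputs land in a run directory with a
machine-readable manifest (file hashes, seeds, versions, filter reports).
"""

from __future__ import annotations

import hashlib
import json
import time
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, plots
from .admixture import fit_admixture, label_clusters, summarize_population_ancestry
from .diversity import diversity_table
from .filters import FilterSpec, apply_site_filters, thin_sites
from .gl_io import write_beagle
from .mito import assign_clades, bootstrap_support, midpoint_root, mitotype_table, write_newick
from .pca import gl_pca
from .simulate import (
    LINEAGES,
    MITOTYPE_PRESETS,
    SimulationConfig,
    TrueAncestry,
    ancestry_preset,
    simulate_admixed_genotypes,
    simulate_genotype_likelihoods,
    simulate_mito_alignment,
    simulate_diversity_study,
    simulate_source_frequencies,
    stage_seed,
)

__all__ = ["RunConfig", "PipelineError", "load_config", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


class RunConfig(dict):
    """Validated pipeline configuration (thin dict wrapper)."""

    @property
    def seed(self) -> int:
        return int(self.get("seed", 0))


def load_config(path: str | Path) -> RunConfig:
    with open(path, "rb") as fh:
        return validate_config(tomllib.load(fh))


def validate_config(raw: dict) -> RunConfig:
    cfg = RunConfig(raw)
    pops = cfg.get("populations", {})
    if not pops.get("presets"):
        raise ValueError("config must define populations.presets before any compute")
    unknown = [p for p in pops["presets"] if p not in MITOTYPE_PRESETS]
    if unknown:
        raise ValueError(f"unknown population presets: {unknown}")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: RunConfig | dict, out_dir: str | Path) -> Path:
    """Run every stage; returns the run directory.

    Artifacts of completed stages are preserved if a later stage fails.
    """
    cfg = validate_config(dict(config))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg,
        "stages": {},
    }
    files: list[Path] = []
    stage = "simulate"
    try:
        t0 = time.perf_counter()
        sim_cfg = SimulationConfig(
            seed=stage_seed(cfg.seed, "simulate"),
            **cfg.get("simulation", {}),
        )
        pops = cfg.get("populations", {})
        presets = pops["presets"]
        n_ref = int(pops.get("n_references", 20))
        n_adm = int(pops.get("n_admixed", 15))
        panel = simulate_source_frequencies(sim_cfg, k=4)
        rows, info = [], []
        for k, lin in enumerate(LINEAGES):
            unit = np.zeros(4)
            unit[k] = 1.0
            for i in range(n_ref):
                rows.append(unit)
                info.append((f"ref_{lin}{i}", "reference", lin))
        for preset in presets:
            q = ancestry_preset(preset)
            for i in range(n_adm):
                rows.append(q)
                info.append((f"{preset}_{i}", "admixed", preset))
        ancestry = TrueAncestry(Q_true=np.array(rows))
        genotypes = simulate_admixed_genotypes(
            panel, ancestry, sim_cfg.rng("admixed_genotypes")
        )
        ds = simulate_genotype_likelihoods(
            genotypes, sim_cfg, individual_ids=[t[0] for t in info]
        )
        sample_info = pd.DataFrame(info, columns=["individual", "role", "population"])
        beagle_path = out / "simulated.beagle.gz"
        write_beagle(ds, beagle_path)
        truth_q = pd.DataFrame(ancestry.Q_true, columns=list(LINEAGES))
        truth_q.insert(0, "individual", sample_info["individual"])
        _write_tsv(truth_q, out / "truth_Q.tsv")
        _write_tsv(sample_info, out / "samples.tsv")
        files += [beagle_path, out / "truth_Q.tsv", out / "samples.tsv"]
        manifest["stages"][stage] = {"seconds": time.perf_counter() - t0,
                                     "n_sites": ds.n_sites, "n_individuals": ds.n_individuals}

        stage = "filter"
        t0 = time.perf_counter()
        fcfg = cfg.get("filters", {})
        spec = FilterSpec(
            min_frac_covered=float(fcfg.get("min_frac_covered", 0.63)),
            min_depth=int(fcfg.get("min_depth", 3)),
            snp_lrt_alpha=float(fcfg.get("snp_pval", 1e-6)),
        )
        ds_f, report = apply_site_filters(ds, spec)
        ds_t = thin_sites(ds_f, int(fcfg.get("thin", 100)))
        _write_tsv(report.to_frame(), out / "filter_report.tsv")
        write_beagle(ds_t, out / "filtered.beagle.gz")
        files += [out / "filter_report.tsv", out / "filtered.beagle.gz"]
        manifest["stages"][stage] = {"seconds": time.perf_counter() - t0,
                                     "n_sites": ds_t.n_sites}

        stage = "admixture"
        t0 = time.perf_counter()
        acfg = cfg.get("admixture", {})
        presence = float(acfg.get("presence", 0.94))
        adm_spec = FilterSpec(
            min_frac_covered=presence, min_depth=1, snp_lrt_alpha=None,
            maf_min=float(acfg.get("maf", 0.05)),
        )
        ds_adm, _ = apply_site_filters(ds_t, adm_spec)
        ref_map = {
            i: row.population
            for i, row in sample_info.iterrows()
            if row.role == "reference"
        }
        pop_series = pd.Series(sample_info["population"].values)
        adm_mask = sample_info["role"].values == "admixed"
        populations = {
            p: np.flatnonzero((pop_series.values == p) & adm_mask) for p in presets
        }
        k_list = acfg.get("k", [4])
        for k in k_list:
            model = fit_admixture(
                ds_adm, k=int(k),
                n_restarts=int(acfg.get("n_restarts", 10)),
                seed=stage_seed(cfg.seed, f"admixture_k{k}"),
            )
            if k >= 4:
                model = label_clusters(model, ref_map)
                summary = summarize_population_ancestry(model, populations)
                _write_tsv(summary, out / f"ancestry_summary_K{k}.tsv")
                files.append(out / f"ancestry_summary_K{k}.tsv")
                labels = model.cluster_labels
            else:
                labels = [f"cluster{i}" for i in range(int(k))]
            qdf = pd.DataFrame(model.Q, columns=labels)
            qdf.insert(0, "individual", sample_info["individual"])
            _write_tsv(qdf, out / f"Q_K{k}.tsv")
            fdf = pd.DataFrame(model.F.T, columns=labels)
            fdf.insert(0, "site_id", ds_adm.site_ids)
            _write_tsv(fdf, out / f"F_K{k}.tsv")
            plots.admixture_barplot(
                model.Q, labels, sample_info["population"], out / f"admixture_K{k}.png"
            )
            files += [out / f"Q_K{k}.tsv", out / f"F_K{k}.tsv", out / f"admixture_K{k}.png"]
        manifest["stages"][stage] = {"seconds": time.perf_counter() - t0, "k": list(k_list)}

        stage = "pca"
        t0 = time.perf_counter()
        res = gl_pca(ds_t, n_pcs=int(cfg.get("pca", {}).get("n_pcs", 10)))
        coords = pd.DataFrame(
            res.coords, columns=[f"PC{i+1}" for i in range(res.coords.shape[1])]
        )
        coords.insert(0, "individual", sample_info["individual"])
        _write_tsv(coords, out / "pca_coords.tsv")
        plots.pca_scatter(
            res.coords, sample_info["population"], res.explained_fraction,
            out / "pca.png",
        )
        files += [out / "pca_coords.tsv", out / "pca.png"]
        manifest["stages"][stage] = {"seconds": time.perf_counter() - t0}

        stage = "diversity"
        t0 = time.perf_counter()
        dcfg = cfg.get("diversity", {})
        div_cfg = SimulationConfig(
            seed=stage_seed(cfg.seed, "diversity"),
            n_sites=int(dcfg.get("n_sites", 20000)),
            mean_depth=sim_cfg.mean_depth,
            error_rate=sim_cfg.error_rate,
            n_blocks=int(dcfg.get("n_blocks", 16)),
        )
        study = simulate_diversity_study(div_cfg, presets=tuple(presets))
        table = diversity_table(study.ds, study.populations,
                                jackknife=bool(dcfg.get("jackknife", True)))
        _write_tsv(table, out / "diversity.tsv")
        files.append(out / "diversity.tsv")
        manifest["stages"][stage] = {"seconds": time.perf_counter() - t0}

        stage = "mito"
        t0 = time.perf_counter()
        mcfg = cfg.get("mito", {})
        comps = {p: MITOTYPE_PRESETS[p] for p in presets}
        totals = {c: sum(comp.get(c, 0) for comp in comps.values()) for c in LINEAGES}
        aln = simulate_mito_alignment(
            totals,
            refs_per_clade=int(mcfg.get("refs_per_clade", 3)),
            seq_length=int(mcfg.get("seq_length", 15000)),
            seed=stage_seed(cfg.seed, "mito"),
        )
        # queries are emitted clade by clade; map them back to populations
        pop_of_query = {}
        queries = list(aln.query_names)
        qi = 0
        for clade in LINEAGES:
            for p in presets:
                for _ in range(comps[p].get(clade, 0)):
                    pop_of_query[queries[qi]] = p
                    qi += 1
        aln.to_fasta(out / "mito.fasta")
        tree, boot_info = bootstrap_support(
            aln, n_reps=int(mcfg.get("bootstrap", 2000)),
            seed=stage_seed(cfg.seed, "mito_bootstrap"),
        )
        rooted = midpoint_root(tree)
        write_newick(rooted, out / "mito.nwk")
        assignments = assign_clades(rooted, aln)
        assignments["population"] = assignments["query"].map(pop_of_query)
        assignments["true_clade"] = assignments["query"].map(aln.true_query_clades)
        _write_tsv(assignments, out / "mito_assignments.tsv")
        table4 = mitotype_table(assignments, pop_of_query)
        table4.reset_index().to_csv(out / "mitotype_counts.tsv", sep="\t", index=False)
        files += [out / "mito.fasta", out / "mito.nwk", out / "mito_assignments.tsv",
                  out / "mitotype_counts.tsv"]
        manifest["stages"][stage] = {
            "seconds": time.perf_counter() - t0, **boot_info,
        }
    except Exception as exc:
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc

    manifest["files"] = {str(p.relative_to(out)): _sha256(p) for p in files}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out
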