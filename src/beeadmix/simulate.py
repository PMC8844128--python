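"""Synthetic data with the statistical structure of an admixed hybrid zone.

Emulates the inputs of a genotype-likelihood ancestry study of Africanized
honey bees: four divergent source lineages (A African, M Western European,
C Eastern European, O Middle Eastern), reference individuals drawn from each
lineage, admixed diploids with prescribed per-lineage ancestry proportions,
read-depth/error genotype likelihoods in BEAGLE form, and pre-aligned
mitochondrial sequences evolved under a Kimura 2-parameter process along a
four-clade tree.

Lineage divergence follows the Balding-Nichols model: given an ancestral
frequency p and a drift parameter F, each lineage's frequency is drawn from
Beta(p(1-F)/F, (1-p)(1-F)/F), whose pairwise expected Hudson FST between two
lineages with the same F is F/(... ) ~ F for moderate F.  Admixed genotypes
are generated copy-wise: each of an individual's two allele copies picks an
ancestral lineage k with probability q_ik and is then the minor allele with
probability f_kj, the exact generative counterpart of the admixture model
fitted downstream.

Preset ancestry vectors and mitotype compositions for the four sampled
populations (Panama, Costa Rica, Mexico, San Diego) are the study's reported
population means and are used as simulation ground truth.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gl_io import GenotypeLikelihoodDataset
from .mito import MitoAlignment, _TRANSITION, _TRANSVERSIONS

__all__ = [
    "SimulationConfig",
    "SourcePanel",
    "TrueAncestry",
    "GenotypeMatrix",
    "LINEAGES",
    "ANCESTRY_PRESETS",
    "MITOTYPE_PRESETS",
    "LINEAGE_DRIFT",
    "ancestry_preset",
    "simulate_source_frequencies",
    "simulate_admixed_genotypes",
    "simulate_genotype_likelihoods",
    "simulate_admixture_study",
    "simulate_mito_alignment",
    "neutral_sfs_weights",
    "simulate_sfs_genotypes",
    "simulate_diversity_study",
    "stage_seed",
]

LINEAGES = ("A", "M", "C", "O")

# Population mean ancestry percentages (A, M, C, O); renormalized to sum 1
# when used as per-individual truth.
ANCESTRY_PRESETS: dict[str, dict[str, float]] = {
    "panama": {"A": 89.6, "M": 10.3, "C": 0.09, "O": 0.0},
    "costa_rica": {"A": 85.4, "M": 10.5, "C": 4.05, "O": 0.0},
    "mexico": {"A": 76.7, "M": 14.9, "C": 8.07, "O": 0.45},
    "san_diego": {"A": 37.5, "M": 19.1, "C": 34.8, "O": 8.51},
}

# Observed mitotype counts per population (15 bees each).
MITOTYPE_PRESETS: dict[str, dict[str, int]] = {
    "panama": {"A": 15, "M": 0, "C": 0, "O": 0},
    "costa_rica": {"A": 15, "M": 0, "C": 0, "O": 0},
    "mexico": {"A": 11, "M": 0, "C": 4, "O": 0},
    "san_diego": {"A": 9, "M": 2, "C": 0, "O": 4},
}

# Drift parameters reproducing the observed diversity rank A > O > M > C
# (less drift = more retained ancestral heterozygosity).
LINEAGE_DRIFT: dict[str, float] = {"A": 0.05, "O": 0.10, "M": 0.16, "C": 0.22}


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from a top-level seed."""
    return int(np.random.SeedSequence([seed, zlib.crc32(stage.encode())]).generate_state(1)[0] % (2**31))


def ancestry_preset(name: str) -> np.ndarray:
    """Renormalized (A, M, C, O) ancestry proportions for a population preset."""
    vec = np.array([ANCESTRY_PRESETS[name][lin] for lin in LINEAGES], dtype=float)
    return vec / vec.sum()


@dataclass
class SimulationConfig:
    """Knobs of the genotype-likelihood generator.

    ``mean_depth`` defaults to 29 reads/site, the study-scale sequencing
    depth; ``error_rate`` is a single symmetric per-base error.
    """

    seed: int = 0
    n_sites: int = 5000
    mean_depth: float = 29.0
    error_rate: float = 0.01
    missing_rate: float = 0.0
    n_blocks: int = 16
    genome_length: int | None = None

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not (0.0 < self.error_rate < 0.5):
            raise ValueError("error_rate must be in (0, 0.5)")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")

    def rng(self, stage: str = "simulate") -> np.random.Generator:
        return np.random.default_rng(stage_seed(self.seed, stage))


@dataclass
class SourcePanel:
    """Per-lineage minor-allele frequencies at shared biallelic sites."""

    freqs: np.ndarray  # (K, M)
    lineage_labels: tuple[str, ...] = LINEAGES
    fst: np.ndarray = field(default_factory=lambda: np.full(4, 0.15))

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.fst = np.asarray(self.fst, dtype=float)
        if self.freqs.ndim != 2 or self.freqs.shape[0] < 2:
            raise ValueError("freqs must be (K >= 2, M)")
        if self.freqs.shape[0] != len(self.lineage_labels):
            raise ValueError("lineage_labels must match freqs rows")
        if ((self.freqs < 0) | (self.freqs > 1)).any():
            raise ValueError("frequencies must lie in [0, 1]")

    @property
    def n_lineages(self) -> int:
        return self.freqs.shape[0]

    @property
    def n_sites(self) -> int:
        return self.freqs.shape[1]


@dataclass
class TrueAncestry:
    """Ground-truth ancestry proportions, one row per individual."""

    Q_true: np.ndarray  # (N, K)

    def __post_init__(self) -> None:
        self.Q_true = np.asarray(self.Q_true, dtype=float)
        if (self.Q_true < 0).any():
            raise ValueError("ancestry proportions must be non-negative")
        if not np.allclose(self.Q_true.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each ancestry row must sum to 1")


@dataclass
class GenotypeMatrix:
    """Latent minor-allele dosage genotypes with per-copy ancestry labels."""

    G: np.ndarray  # (N, M) in {0, 1, 2}
    per_site_ancestry: np.ndarray | None = None  # (N, M, 2) lineage of each copy

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G)
        if not np.isin(self.G, (0, 1, 2)).all():
            raise ValueError("genotypes must be 0, 1 or 2")


def simulate_source_frequencies(
    config: SimulationConfig,
    k: int = 4,
    fst: np.ndarray | float | None = None,
    labels: tuple[str, ...] | None = None,
    rng: np.random.Generator | None = None,
) -> SourcePanel:
    """Draw divergent lineage allele frequencies (Balding-Nichols).

    Per site, an ancestral frequency p ~ Uniform(0.05, 0.95) is drifted
    independently into each lineage via Beta(p(1-F)/F, (1-p)(1-F)/F).
    """
    if k < 2:
        raise ValueError("need at least 2 lineages")
    if labels is None:
        labels = LINEAGES if k == 4 else tuple(f"L{i}" for i in range(k))
    if fst is None:
        fst = 0.15
    fst = np.broadcast_to(np.asarray(fst, dtype=float), (k,)).copy()
    if ((fst <= 0) | (fst >= 1)).any():
        raise ValueError("drift parameters must lie in (0, 1)")
    if rng is None:
        rng = config.rng("source_frequencies")
    m = config.n_sites
    p_anc = rng.uniform(0.05, 0.95, size=m)
    freqs = np.empty((k, m))
    for i in range(k):
        scale = (1.0 - fst[i]) / fst[i]
        freqs[i] = rng.beta(p_anc * scale, (1.0 - p_anc) * scale)
    return SourcePanel(freqs=freqs, lineage_labels=tuple(labels), fst=fst)


def simulate_admixed_genotypes(
    panel: SourcePanel,
    ancestry: TrueAncestry,
    seed: int | np.random.Generator = 0,
) -> GenotypeMatrix:
    """Copy-wise generative admixture: each allele copy picks a lineage
    k ~ Categorical(q_i) and is the minor allele with probability f_kj."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q = ancestry.Q_true
    if q.shape[1] != panel.n_lineages:
        raise ValueError("ancestry columns must match panel lineages")
    n, k = q.shape
    m = panel.n_sites
    g = np.empty((n, m), dtype=np.int8)
    copies = np.empty((n, m, 2), dtype=np.int8)
    cum = np.cumsum(q, axis=1)
    for i in range(n):
        u = rng.random((m, 2))
        k_copy = np.searchsorted(cum[i], u.ravel(), side="right").reshape(m, 2)
        k_copy = np.minimum(k_copy, k - 1)
        f = panel.freqs[k_copy, np.arange(m)[:, None]]
        minor = (rng.random((m, 2)) < f).astype(np.int8)
        g[i] = minor.sum(axis=1)
        copies[i] = k_copy
    return GenotypeMatrix(G=g, per_site_ancestry=copies)


def simulate_genotype_likelihoods(
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    individual_ids: list[str] | None = None,
) -> GenotypeLikelihoodDataset:
    """Read-sampling genotype likelihoods from latent genotypes.

    Depth d ~ Poisson(mean_depth), zeroed with probability missing_rate;
    minor-allele read count ~ Binomial(d, g/2 (1-e) + (1-g/2) e); GL(g) is
    the binomial likelihood of the observed counts, normalized per
    individual-site so max GL = 1 (zero depth gives the flat triplet).
    """
    if rng is None:
        rng = config.rng("genotype_likelihoods")
    g_t = genotypes.G.T  # (M, N)
    m, n = g_t.shape
    depth = rng.poisson(config.mean_depth, size=(m, n))
    if config.missing_rate > 0:
        depth[rng.random((m, n)) < config.missing_rate] = 0
    eps = config.error_rate
    emit = g_t / 2.0 * (1.0 - eps) + (1.0 - g_t / 2.0) * eps
    minor_reads = rng.binomial(depth, emit)
    major_reads = depth - minor_reads
    gl = np.empty((m, n, 3))
    for g in range(3):
        e_g = g / 2.0 * (1.0 - eps) + (1.0 - g / 2.0) * eps
        log_l = minor_reads * np.log(e_g) + major_reads * np.log(1.0 - e_g)
        gl[:, :, g] = log_l
    gl -= gl.max(axis=2, keepdims=True)
    gl = np.exp(gl)

    # random biallelic site labels (major != minor)
    major = rng.integers(0, 4, size=m).astype(np.int8)
    minor_allele = ((major + rng.integers(1, 4, size=m)) % 4).astype(np.int8)
    genome_length = config.genome_length or m
    pos = np.linspace(1, genome_length, m).astype(int)
    block_id = np.repeat(
        np.arange(config.n_blocks), np.diff(np.linspace(0, m, config.n_blocks + 1).astype(int))
    )
    site_ids = np.array(
        [f"chr{b + 1}_{p}" for b, p in zip(block_id, pos)], dtype=object
    )
    base_counts = np.stack([major_reads, minor_reads], axis=2)
    return GenotypeLikelihoodDataset(
        site_ids=site_ids,
        major=major,
        minor=minor_allele,
        gl=gl,
        depth=depth,
        base_counts=base_counts,
        block_id=block_id,
        pos=pos,
        individual_ids=individual_ids or [f"ind{i}" for i in range(n)],
    )


@dataclass
class AdmixtureStudy:
    """A simulated reference-panel + admixed-population cohort."""

    ds: GenotypeLikelihoodDataset
    panel: SourcePanel
    ancestry: TrueAncestry
    sample_info: pd.DataFrame  # columns: individual, role, population/lineage
    genotypes: GenotypeMatrix


def simulate_admixture_study(
    config: SimulationConfig,
    preset: str | np.ndarray = "panama",
    n_references: int = 20,
    n_admixed: int = 15,
    fst: float | np.ndarray = 0.15,
    population: str | None = None,
) -> AdmixtureStudy:
    """Reference individuals from each lineage plus one admixed population.

    References carry unit ancestry vectors; admixed individuals all carry
    the preset (or explicit) ancestry proportions.
    """
    panel = simulate_source_frequencies(config, k=4, fst=fst)
    if isinstance(preset, str):
        pop_name = population or preset
        q_admixed = ancestry_preset(preset)
    else:
        pop_name = population or "admixed"
        q_admixed = np.asarray(preset, dtype=float)
        q_admixed = q_admixed / q_admixed.sum()
    rows, info = [], []
    for k, lin in enumerate(LINEAGES):
        unit = np.zeros(4)
        unit[k] = 1.0
        for i in range(n_references):
            rows.append(unit)
            info.append((f"ref_{lin}{i}", "reference", lin))
    for i in range(n_admixed):
        rows.append(q_admixed)
        info.append((f"{pop_name}_{i}", "admixed", pop_name))
    ancestry = TrueAncestry(Q_true=np.array(rows))
    rng = config.rng("admixed_genotypes")
    genotypes = simulate_admixed_genotypes(panel, ancestry, rng)
    ds = simulate_genotype_likelihoods(
        genotypes, config, individual_ids=[t[0] for t in info]
    )
    sample_info = pd.DataFrame(info, columns=["individual", "role", "population"])
    return AdmixtureStudy(
        ds=ds, panel=panel, ancestry=ancestry, sample_info=sample_info, genotypes=genotypes
    )


# ---------------------------------------------------------------------------
# mitochondrial alignments
# ---------------------------------------------------------------------------

def _evolve_k2p(
    seq: np.ndarray, distance: float, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    """One K2P branch: per-site substitution with the closed-form kernel."""
    if distance <= 0:
        return seq.copy()
    beta_t = distance / (kappa + 2.0)
    alpha_t = kappa * beta_t
    e4b = np.exp(-4.0 * beta_t)
    e2ab = np.exp(-2.0 * (alpha_t + beta_t))
    p_ts = 0.25 + 0.25 * e4b - 0.5 * e2ab
    p_tv = 0.25 - 0.25 * e4b  # each of the two transversion targets
    u = rng.random(seq.size)
    out = seq.copy()
    ts_mask = u < p_ts
    tv1_mask = (u >= p_ts) & (u < p_ts + p_tv)
    tv2_mask = (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
    out[ts_mask] = _TRANSITION[seq[ts_mask]]
    out[tv1_mask] = _TRANSVERSIONS[seq[tv1_mask], 0]
    out[tv2_mask] = _TRANSVERSIONS[seq[tv2_mask], 1]
    return out


def simulate_mito_alignment(
    clade_counts: dict[str, int],
    refs_per_clade: int = 3,
    divergence_between: float = 0.05,
    divergence_within: float = 0.005,
    seq_length: int = 15000,
    kappa: float = 4.0,
    seed: int = 0,
    merge_co: bool = False,
) -> MitoAlignment:
    """Pre-aligned mitochondrial sequences along a four-clade star-of-stars.

    A root sequence is evolved to each clade ancestor (half the between-clade
    divergence) and every reference/query sequence evolves independently from
    its clade ancestor (half the within-clade divergence); no indels, so the
    sequences are aligned by construction.  ``merge_co`` makes the O clade
    share the C ancestor, mimicking C-type mtDNA carried by O-clade bees;
    off by default.  Query true clades are recorded as ground truth.
    """
    if seq_length < 100:
        raise ValueError("seq_length must be >= 100 (distances unstable)")
    if divergence_within < 0 or divergence_between <= divergence_within:
        raise ValueError("require divergence_between > divergence_within >= 0")
    if kappa <= 0:
        raise ValueError("transition/transversion ratio must be positive")
    rng = np.random.default_rng(seed)
    root = rng.integers(0, 4, size=seq_length).astype(np.uint8)
    clades = tuple(LINEAGES)
    ancestors = {}
    for clade in clades:
        if merge_co and clade == "O":
            continue
        ancestors[clade] = _evolve_k2p(root, divergence_between / 2.0, kappa, rng)
    if merge_co:
        ancestors["O"] = ancestors["C"]

    bases = np.array(list("ACGT"))
    names, seqs = [], []
    reference_clades: dict[str, str] = {}
    true_query_clades: dict[str, str] = {}
    for clade in clades:
        for i in range(refs_per_clade):
            name = f"ref_{clade}{i}"
            s = _evolve_k2p(ancestors[clade], divergence_within / 2.0, kappa, rng)
            names.append(name)
            seqs.append("".join(bases[s]))
            reference_clades[name] = clade
    q = 0
    for clade in clades:
        for _ in range(int(clade_counts.get(clade, 0))):
            name = f"query{q}"
            s = _evolve_k2p(ancestors[clade], divergence_within / 2.0, kappa, rng)
            names.append(name)
            seqs.append("".join(bases[s]))
            true_query_clades[name] = clade
            q += 1
    return MitoAlignment(
        names=names,
        sequences=seqs,
        reference_clades=reference_clades,
        true_query_clades=true_query_clades,
    )


# ---------------------------------------------------------------------------
# genome-like data for diversity estimation
# ---------------------------------------------------------------------------

def neutral_sfs_weights(n_chrom: int, theta: float) -> np.ndarray:
    """Folded neutral site-category distribution at mutation rate theta/site.

    P(unfolded derived count c) = theta/c for c = 1..n_chrom-1, the rest
    monomorphic; returned folded over minor-allele counts 0..n_chrom//2.
    """
    probs = np.zeros(n_chrom + 1)
    c = np.arange(1, n_chrom)
    probs[1:n_chrom] = theta / c
    if probs.sum() > 1:
        raise ValueError("theta too large for a per-site category distribution")
    probs[0] = 1.0 - probs[1:].sum()
    half = n_chrom // 2
    folded = np.zeros(half + 1)
    for cat in range(n_chrom + 1):
        folded[min(cat, n_chrom - cat)] += probs[cat]
    return folded


def simulate_sfs_genotypes(
    n_individuals: int,
    config: SimulationConfig,
    theta: float = 0.01,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Genotypes drawn from a neutral SFS: each site gets a derived-allele
    count c with P(c) = theta/c, assigned to chromosomes at random.

    Returns the genotype matrix and the per-site true minor-allele counts
    (folded), the ground truth for SFS recovery checks.
    """
    if rng is None:
        rng = config.rng("sfs_genotypes")
    n_chrom = 2 * n_individuals
    probs = np.zeros(n_chrom)
    c = np.arange(1, n_chrom)
    probs[1:] = theta / c
    probs[0] = 1.0 - probs[1:].sum()
    if probs[0] < 0:
        raise ValueError("theta too large")
    counts = rng.choice(n_chrom, size=config.n_sites, p=probs)
    g = np.zeros((n_individuals, config.n_sites), dtype=np.int8)
    seg = np.flatnonzero(counts > 0)
    for j in seg:
        carriers = rng.choice(n_chrom, size=counts[j], replace=False)
        np.add.at(g[:, j], carriers // 2, 1)
    folded_truth = np.minimum(counts, n_chrom - counts)
    return GenotypeMatrix(G=g), folded_truth


@dataclass
class DiversityStudy:
    """Genome-like multi-population cohort for diversity estimation."""

    ds: GenotypeLikelihoodDataset
    populations: dict[str, np.ndarray]  # name -> individual indices
    pop_freqs: dict[str, np.ndarray]  # name -> per-site population frequency
    true_pi: dict[str, float]  # expected per-site heterozygosity


def simulate_diversity_study(
    config: SimulationConfig,
    n_per_population: int = 15,
    seg_fraction: float = 0.04,
    presets: tuple[str, ...] = ("panama", "costa_rica", "mexico", "san_diego"),
    drift: dict[str, float] | None = None,
    min_freq: float = 0.005,
    private_rate: float = 0.03,
    private_max: float = 0.05,
) -> DiversityStudy:
    """Four source lineages plus admixed populations over a genome-like
    site set.

    Most sites are monomorphic; ancestrally segregating sites follow the
    neutral 1/p frequency shape (log-uniform minor-allele frequency on
    [min_freq, 0.5], random orientation) and drift into the lineages.  On
    top of that, each lineage carries private rare variants (rate
    ``private_rate`` per site, frequencies log-uniform on
    [min_freq, private_max]): rare variation is mostly population-private
    in real data and is what a total-sample MAF cutoff ascertains away.
    Lineage drift is ranked so A is the most internally diverse source
    (A > O > M > C), as observed in honey bees.
    """
    rng = config.rng("diversity_study")
    drift = dict(LINEAGE_DRIFT if drift is None else drift)
    m = config.n_sites
    seg = rng.random(m) < seg_fraction
    n_seg = int(seg.sum())
    p_anc = np.zeros(m)
    minor = min_freq * (0.5 / min_freq) ** rng.random(n_seg)  # density ~ 1/p
    flip = rng.random(n_seg) < 0.5
    p_anc[seg] = np.where(flip, 1.0 - minor, minor)
    freqs = np.zeros((4, m))
    for k, lin in enumerate(LINEAGES):
        f_lin = drift[lin]
        scale = (1.0 - f_lin) / f_lin
        s = np.flatnonzero(seg)
        freqs[k, s] = rng.beta(
            np.clip(p_anc[s] * scale, 1e-9, None), np.clip((1 - p_anc[s]) * scale, 1e-9, None)
        )
        # lineage-private rare variants at ancestrally monomorphic sites
        private = (~seg) & (rng.random(m) < private_rate)
        n_priv = int(private.sum())
        freqs[k, private] = min_freq * (private_max / min_freq) ** rng.random(n_priv)
    panel = SourcePanel(freqs=freqs, fst=np.array([drift[lin] for lin in LINEAGES]))

    rows, info = [], []
    for k, lin in enumerate(LINEAGES):
        unit = np.zeros(4)
        unit[k] = 1.0
        for i in range(n_per_population):
            rows.append(unit)
            info.append((f"ref_{lin}{i}", lin))
    for preset in presets:
        q = ancestry_preset(preset)
        for i in range(n_per_population):
            rows.append(q)
            info.append((f"{preset}_{i}", preset))
    ancestry = TrueAncestry(Q_true=np.array(rows))
    genotypes = simulate_admixed_genotypes(panel, ancestry, rng)
    ds = simulate_genotype_likelihoods(
        genotypes, config, rng=rng, individual_ids=[t[0] for t in info]
    )
    pops = [t[1] for t in info]
    populations = {
        name: np.flatnonzero(np.array(pops) == name) for name in dict.fromkeys(pops)
    }
    pop_freqs, true_pi = {}, {}
    for name, idx in populations.items():
        qbar = ancestry.Q_true[idx].mean(axis=0)
        pf = qbar @ freqs
        pop_freqs[name] = pf
        true_pi[name] = float(np.mean(2.0 * pf * (1.0 - pf)))
    return DiversityStudy(ds=ds, populations=populations, pop_freqs=pop_freqs, true_pi=true_pi)
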