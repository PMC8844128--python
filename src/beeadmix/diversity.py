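"""Genome-wide diversity from genotype likelihoods.

Two routes to per-site nucleotide diversity are implemented, mirroring how
low- and mixed-coverage resequencing studies report theta:

* **Folded-SFS route** — per site, the likelihood of each minor-allele
  count c in 0..2N is computed by exact dynamic programming over genotype
  likelihoods (the ANGSD/realSFS "SAF" construction); an EM over folded
  spectrum weights then yields the population SFS, from which pairwise
  theta (theta_pi) and Watterson's theta are read off with their standard
  combinatorial weights.  All sites, including invariant ones, enter the
  denominator.

* **SNP-density-weighted route** — per-SNP heterozygosity 2p(1-p) with an
  n/(n-1) small-sample correction, computed from pooled read counts at a
  fixed list of confident SNPs (total-sample MAF above a cutoff), then
  rescaled by SNP density (SNPs / genome positions) to account for
  invariant sites.

Standard errors come from a delete-one block jackknife over chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .gl_io import GenotypeLikelihoodDataset, count_based_frequencies

__all__ = [
    "FoldedSFS",
    "DiversityEstimate",
    "site_allele_count_likelihood",
    "saf_likelihood_matrix",
    "estimate_folded_sfs",
    "thetas_from_sfs",
    "snp_weighted_pi",
    "block_jackknife",
    "diversity_table",
]

_C2 = np.array([1.0, 2.0, 1.0])  # C(2, g)


@dataclass
class FoldedSFS:
    """Probability weights over folded minor-allele-count categories."""

    n_chrom: int
    weights: np.ndarray  # (n_chrom//2 + 1,), sums to 1
    n_sites_used: int

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if (self.weights < 0).any() or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("SFS weights must be non-negative and sum to 1")


@dataclass
class DiversityEstimate:
    estimator_name: str
    value: float
    se: float = float("nan")
    n_blocks: int = 0


def site_allele_count_likelihood(gl_site: np.ndarray) -> np.ndarray:
    """Likelihood of each total minor-allele count c = 0..2N at one site.

    Exact marginalization over genotype configurations with sum g = c:
    T_i(c) = sum_g T_{i-1}(c - g) GL_i(g) C(2, g), then L(c) = T_N(c) /
    C(2N, c).  Individuals without reads carry flat triplets and contribute
    the binomial allocation weights only.
    """
    gl_site = np.asarray(gl_site, dtype=float)
    n = gl_site.shape[0]
    t = np.zeros(2 * n + 1)
    t[0] = 1.0
    for i in range(n):
        new = np.zeros_like(t)
        for g in range(3):
            new[g:] += t[: len(t) - g or None] * gl_site[i, g] * _C2[g]
        t = new
    c = np.arange(2 * n + 1)
    from scipy.special import comb

    return t / comb(2 * n, c)


def saf_likelihood_matrix(gl: np.ndarray) -> np.ndarray:
    """(M, 2N+1) allele-count likelihoods for all sites, max-normalized.

    Same DP as :func:`site_allele_count_likelihood`, vectorized across
    sites; rows are rescaled (scale drops out of the SFS EM) to avoid
    underflow for large N.
    """
    m, n, _ = gl.shape
    t = np.zeros((m, 2 * n + 1))
    t[:, 0] = 1.0
    for i in range(n):
        new = np.zeros_like(t)
        for g in range(3):
            if g == 0:
                new += t * (gl[:, i, 0] * _C2[0])[:, None]
            else:
                new[:, g:] += t[:, : t.shape[1] - g] * (gl[:, i, g] * _C2[g])[:, None]
        t = new
        if (i + 1) % 8 == 0:
            t /= np.clip(t.max(axis=1, keepdims=True), 1e-300, None)
    from scipy.special import comb

    t = t / comb(2 * n, np.arange(2 * n + 1))[None, :]
    return t / np.clip(t.max(axis=1, keepdims=True), 1e-300, None)


def _fold(l_mat: np.ndarray) -> np.ndarray:
    """Average the two orientations of each folded category."""
    n_cat = l_mat.shape[1]
    n_chrom = n_cat - 1
    half = n_chrom // 2
    out = np.empty((l_mat.shape[0], half + 1))
    for c in range(half + 1):
        if c == n_chrom - c:
            out[:, c] = l_mat[:, c]
        else:
            out[:, c] = 0.5 * (l_mat[:, c] + l_mat[:, n_chrom - c])
    return out


def estimate_folded_sfs(
    ds: GenotypeLikelihoodDataset,
    individuals: Sequence[int] | np.ndarray | None = None,
    min_frac: float = 0.5,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> FoldedSFS:
    """EM estimate of the folded SFS from per-site count likelihoods.

    Only sites where at least ``min_frac`` of the population's individuals
    have reads are used.  The EM over spectrum weights is monotone in the
    likelihood; convergence is declared when the total log-likelihood moves
    by less than ``tol``.
    """
    sub = ds if individuals is None else ds.take_individuals(np.asarray(individuals))
    inf = sub.informative()
    n = sub.n_individuals
    use = inf.sum(axis=1) >= min_frac * n
    if not use.any():
        raise ValueError("no sites pass the coverage fraction rule")
    lf = _fold(saf_likelihood_matrix(sub.gl[use]))
    m, n_cat = lf.shape
    phi = np.full(n_cat, 1.0 / n_cat)
    ll_prev = -np.inf
    for _ in range(max_iter):
        w = lf * phi[None, :]
        rowsum = np.clip(w.sum(axis=1), 1e-300, None)
        ll = float(np.log(rowsum).sum())
        phi = (w / rowsum[:, None]).mean(axis=0)
        if abs(ll - ll_prev) < tol:
            break
        ll_prev = ll
    phi = np.clip(phi, 0.0, None)
    phi /= phi.sum()
    return FoldedSFS(n_chrom=2 * n, weights=phi, n_sites_used=int(m))


def thetas_from_sfs(
    sfs: FoldedSFS, total_sites: int
) -> tuple[DiversityEstimate, DiversityEstimate]:
    """Pairwise and Watterson's theta per site from a folded SFS.

    With eta_c = phi_c * n_sites_used expected site counts per folded
    category: theta_pi = sum_c eta_c c(2N-c)/C(2N,2) / total_sites and
    theta_W = sum_{c>=1} eta_c / (a_{2N-1} total_sites), where
    a_m = sum_{i<=m} 1/i.  ``total_sites`` must include invariant sites.
    """
    if total_sites < sfs.n_sites_used:
        raise ValueError("total_sites cannot be smaller than n_sites_used")
    n2 = sfs.n_chrom
    half = n2 // 2
    c = np.arange(half + 1)
    eta = sfs.weights * sfs.n_sites_used
    pair_w = c * (n2 - c) / (n2 * (n2 - 1) / 2.0)
    pi = float((eta[1:] * pair_w[1:]).sum() / total_sites)
    a_n = (1.0 / np.arange(1, n2)).sum()
    watterson = float(eta[1:].sum() / (a_n * total_sites))
    return (
        DiversityEstimate("pi_sfs", pi),
        DiversityEstimate("watterson_sfs", watterson),
    )


def snp_weighted_pi(
    ds_total: GenotypeLikelihoodDataset,
    population: Sequence[int] | np.ndarray,
    maf_min: float = 0.05,
    genome_length: int | None = None,
    max_missing_frac: float = 0.5,
) -> tuple[DiversityEstimate, dict]:
    """SNP-density-weighted pairwise diversity from pooled read counts.

    The SNP list is defined on the TOTAL sample: count-based minor-allele
    frequency above ``maf_min`` and coverage in at least half the
    individuals.  Within the population, per-SNP pi is
    2 p (1-p) n/(n-1) with n = chromosomes with coverage; the mean over
    SNPs is rescaled by SNP density S_total / genome_length.
    """
    if ds_total.base_counts is None:
        raise ValueError("SNP-weighted pi needs base counts")
    genome_length = genome_length or ds_total.n_sites
    f_tot, _ = count_based_frequencies(ds_total)
    n_total = ds_total.n_individuals
    covered_tot = (ds_total.base_counts.sum(axis=2) > 0).sum(axis=1)
    maf_tot = np.minimum(np.nan_to_num(f_tot), 1.0 - np.nan_to_num(f_tot))
    snp = (maf_tot > maf_min) & (covered_tot >= 0.5 * n_total)
    s_total = int(snp.sum())
    if s_total == 0:
        return DiversityEstimate("pi_snp_weighted", 0.0), {"n_snps": 0, "n_skipped": 0}
    idx = np.asarray(population)
    f_pop, n_chrom = count_based_frequencies(ds_total, idx)
    f_pop, n_chrom = f_pop[snp], n_chrom[snp]
    usable = (n_chrom >= 2) & np.isfinite(f_pop)
    n_skipped = int((~usable).sum())
    pi_snp = 2.0 * f_pop[usable] * (1.0 - f_pop[usable]) * n_chrom[usable] / (
        n_chrom[usable] - 1.0
    )
    value = float(pi_snp.mean() * s_total / genome_length) if pi_snp.size else 0.0
    return (
        DiversityEstimate("pi_snp_weighted", value),
        {"n_snps": s_total, "n_skipped": n_skipped},
    )


def block_jackknife(
    ds: GenotypeLikelihoodDataset,
    estimator: Callable[[GenotypeLikelihoodDataset], float | np.ndarray],
    blocks: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Delete-one-block jackknife over chromosomes.

    ``estimator`` maps a dataset (subset of sites) to a scalar or vector
    statistic.  Returns (full-data value, jackknife SE, number of blocks):
    se = sqrt((B-1)/B * sum_b (theta_(b) - mean)^2).
    """
    if blocks is None:
        blocks = np.unique(ds.block_id)
    blocks = np.asarray(blocks)
    if blocks.size < 2:
        raise ValueError("block jackknife needs at least 2 blocks")
    value = np.atleast_1d(np.asarray(estimator(ds), dtype=float))
    loo = []
    for b in blocks:
        sub = ds.take_sites(np.flatnonzero(ds.block_id != b))
        try:
            loo.append(np.atleast_1d(np.asarray(estimator(sub), dtype=float)))
        except Exception as exc:  # noqa: BLE001 - annotate failing block
            raise RuntimeError(f"estimator failed on leave-out of block {b}") from exc
    loo = np.stack(loo)
    b_count = blocks.size
    mean = loo.mean(axis=0)
    se = np.sqrt((b_count - 1) / b_count * ((loo - mean) ** 2).sum(axis=0))
    return value, se, b_count


def diversity_table(
    ds: GenotypeLikelihoodDataset,
    populations: dict[str, np.ndarray],
    genome_length: int | None = None,
    maf_min: float = 0.05,
    min_frac: float = 0.5,
    jackknife: bool = True,
) -> pd.DataFrame:
    """Per-population theta_pi, SNP-weighted pi and Watterson's theta.

    One row per population with block-jackknife standard errors (each
    chromosome-block deleted in turn) when ``jackknife`` is set.
    """
    genome_total = genome_length or ds.n_sites
    rows = []
    for name, idx in populations.items():
        idx = np.asarray(idx)

        def stat(sub: GenotypeLikelihoodDataset) -> np.ndarray:
            scale = genome_total * sub.n_sites / ds.n_sites
            sfs = estimate_folded_sfs(sub, idx, min_frac=min_frac)
            pi, watt = thetas_from_sfs(sfs, total_sites=int(round(scale)))
            pi_snp, _ = snp_weighted_pi(
                sub, idx, maf_min=maf_min, genome_length=int(round(scale))
            )
            return np.array([pi.value, pi_snp.value, watt.value])

        if jackknife:
            value, se, n_blocks = block_jackknife(ds, stat)
        else:
            value, se, n_blocks = stat(ds), np.full(3, np.nan), 0
        rows.append(
            {
                "population": name,
                "pi_sfs": value[0],
                "pi_sfs_se": se[0],
                "pi_snp_weighted": value[1],
                "pi_snp_weighted_se": se[1],
                "watterson_sfs": value[2],
                "watterson_sfs_se": se[2],
                "n_blocks": n_blocks,
            }
        )
    return pd.DataFrame(rows)
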