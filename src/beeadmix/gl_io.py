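"""Genotype-likelihood datasets and BEAGLE text I/O.

The central container is :class:`GenotypeLikelihoodDataset`: biallelic sites
by individuals by the three diploid genotype likelihoods (0, 1 or 2 copies of
the minor allele).  Likelihoods are stored normalized so that the maximum per
individual-site is 1; an individual with no reads at a site carries the flat
triplet ``(1, 1, 1)`` and is treated as uninformative everywhere downstream.

Per-site operations implemented here mirror the usual ANGSD conventions:
maximum-likelihood minor-allele frequency via EM over genotype posteriors,
a likelihood-ratio SNP statistic against the monomorphic null, major/minor
polarization, and pooled read-count ("base count") allele frequencies.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

BASES = "ACGT"

__all__ = [
    "GenotypeLikelihoodDataset",
    "SiteFrequency",
    "read_beagle",
    "write_beagle",
    "estimate_maf_em",
    "site_frequencies",
    "infer_major_minor",
    "count_based_frequency",
    "BeagleFormatError",
]


class BeagleFormatError(ValueError):
    """Malformed BEAGLE genotype-likelihood file."""


@dataclass
class GenotypeLikelihoodDataset:
    """Biallelic genotype likelihoods for M sites x N individuals.

    Attributes
    ----------
    site_ids : (M,) array of marker names (``chr<block>_<pos>`` convention).
    major, minor : (M,) integer base codes (0=A, 1=C, 2=G, 3=T).
    gl : (M, N, 3) float array, normalized so max per (site, individual) is 1.
    depth : (M, N) integer read counts, or None when unknown (e.g. a BEAGLE
        file read from disk); then flat triplets mark missing data.
    base_counts : (M, N, 2) observed (major, minor) read counts, or None.
    block_id : (M,) integer chromosome/block index per site.
    pos : (M,) integer positions within block.
    individual_ids : N names.
    """

    site_ids: np.ndarray
    major: np.ndarray
    minor: np.ndarray
    gl: np.ndarray
    depth: np.ndarray | None
    base_counts: np.ndarray | None
    block_id: np.ndarray
    pos: np.ndarray
    individual_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gl = np.asarray(self.gl, dtype=float)
        if self.gl.ndim != 3 or self.gl.shape[2] != 3:
            raise ValueError(f"gl must be (M, N, 3), got {self.gl.shape}")
        if not self.individual_ids:
            self.individual_ids = [f"ind{i}" for i in range(self.gl.shape[1])]

    @property
    def n_sites(self) -> int:
        return self.gl.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.gl.shape[1]

    def informative(self) -> np.ndarray:
        """(M, N) boolean mask of individual-sites carrying read information."""
        if self.depth is not None:
            return self.depth > 0
        # flat triplets encode missingness when depths were not preserved
        g = self.gl
        return ~((g[:, :, 0] == g[:, :, 1]) & (g[:, :, 1] == g[:, :, 2]))

    def take_sites(self, index: np.ndarray) -> "GenotypeLikelihoodDataset":
        index = np.asarray(index)
        return replace(
            self,
            site_ids=self.site_ids[index],
            major=self.major[index],
            minor=self.minor[index],
            gl=self.gl[index],
            depth=None if self.depth is None else self.depth[index],
            base_counts=None if self.base_counts is None else self.base_counts[index],
            block_id=self.block_id[index],
            pos=self.pos[index],
            individual_ids=list(self.individual_ids),
        )

    def take_individuals(self, index: np.ndarray) -> "GenotypeLikelihoodDataset":
        index = np.asarray(index)
        return replace(
            self,
            gl=self.gl[:, index],
            depth=None if self.depth is None else self.depth[:, index],
            base_counts=None if self.base_counts is None else self.base_counts[:, index],
            individual_ids=[self.individual_ids[i] for i in index],
        )


@dataclass
class SiteFrequency:
    """Minor-allele frequency estimate at one site.

    ``maf`` is the frequency of the current minor allele and may exceed 0.5
    before :func:`infer_major_minor` repolarizes the site.  ``lrt_stat`` is
    2*(loglik(p_hat) - loglik(0)), the SNP likelihood-ratio statistic.
    """

    maf: float
    n_informative: int
    lrt_stat: float


# ---------------------------------------------------------------------------
# BEAGLE I/O
# ---------------------------------------------------------------------------

def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def write_beagle(ds: GenotypeLikelihoodDataset, path: str | Path) -> None:
    """Write a dataset as BEAGLE genotype-likelihood text (gzip if ``.gz``)."""
    with _open_text(path, "wt") as fh:
        header = ["marker", "allele1", "allele2"]
        for name in ds.individual_ids:
            header.extend([name] * 3)
        fh.write("\t".join(header) + "\n")
        for j in range(ds.n_sites):
            row = [str(ds.site_ids[j]), str(int(ds.major[j])), str(int(ds.minor[j]))]
            row.extend(f"{v:.6g}" for v in ds.gl[j].ravel())
            fh.write("\t".join(row) + "\n")


def _parse_marker(marker: str, fallback_index: int) -> tuple[str, int]:
    chrom, _, pos = marker.rpartition("_")
    if chrom and pos.isdigit():
        return chrom, int(pos)
    return marker, fallback_index


def read_beagle(path: str | Path) -> GenotypeLikelihoodDataset:
    """Read BEAGLE genotype-likelihood text (ANGSD ``--doGlf 2`` dialect).

    Depths and base counts are not representable in BEAGLE and come back as
    None; flat likelihood triplets then mark missing individual-sites.
    Block ids are assigned by order of first appearance of the chromosome
    prefix in ``chr_pos`` marker names.
    """
    rows: list[list[str]] = []
    with _open_text(path) as fh:
        header = fh.readline()
        for line in fh:
            line = line.strip()
            if line:
                rows.append(line.split())
    if not rows:
        n_ind = 0
        if header:
            n_cols = len(header.split())
            if n_cols > 3:
                n_ind = (n_cols - 3) // 3
        return GenotypeLikelihoodDataset(
            site_ids=np.array([], dtype=object),
            major=np.array([], dtype=np.int8),
            minor=np.array([], dtype=np.int8),
            gl=np.zeros((0, n_ind, 3)),
            depth=None,
            base_counts=None,
            block_id=np.array([], dtype=int),
            pos=np.array([], dtype=int),
            individual_ids=[f"ind{i}" for i in range(n_ind)],
        )
    n_cols = len(rows[0])
    if n_cols < 3 or (n_cols - 3) % 3 != 0:
        raise BeagleFormatError(
            f"expected 3 leading columns plus 3 likelihoods per individual, got {n_cols} columns"
        )
    n_ind = (n_cols - 3) // 3
    for i, r in enumerate(rows):
        if len(r) != n_cols:
            raise BeagleFormatError(f"row {i} has {len(r)} columns, expected {n_cols}")
    markers = [r[0] for r in rows]
    major = np.array([int(r[1]) for r in rows], dtype=np.int8)
    minor = np.array([int(r[2]) for r in rows], dtype=np.int8)
    gl = np.array([[float(v) for v in r[3:]] for r in rows]).reshape(len(rows), n_ind, 3)
    # renormalize (round-tripping 6-sig-digit text) so max per entry is 1
    mx = gl.max(axis=2, keepdims=True)
    mx[mx == 0] = 1.0
    gl = gl / mx

    chroms, pos = [], []
    for i, m in enumerate(markers):
        c, p = _parse_marker(m, i)
        chroms.append(c)
        pos.append(p)
    order: dict[str, int] = {}
    for c in chroms:
        order.setdefault(c, len(order))
    block_id = np.array([order[c] for c in chroms], dtype=int)

    names: list[str] = []
    if header:
        cols = header.split()
        if len(cols) == n_cols:
            names = cols[3::3]
    if len(names) != n_ind:
        names = [f"ind{i}" for i in range(n_ind)]
    return GenotypeLikelihoodDataset(
        site_ids=np.array(markers, dtype=object),
        major=major,
        minor=minor,
        gl=gl,
        depth=None,
        base_counts=None,
        block_id=block_id,
        pos=np.array(pos, dtype=int),
        individual_ids=names,
    )


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

_LOG_FLOOR = 1e-300


def _genotype_prior(p: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hardy-Weinberg genotype probabilities for minor-allele frequency p."""
    q = 1.0 - p
    return q * q, 2.0 * p * q, p * p


def _site_loglik(gl: np.ndarray, informative: np.ndarray, p: np.ndarray) -> np.ndarray:
    """(M,) log-likelihood of per-site frequency p; gl is (M, N, 3)."""
    b0, b1, b2 = _genotype_prior(p[:, None])
    s = gl[:, :, 0] * b0 + gl[:, :, 1] * b1 + gl[:, :, 2] * b2
    return np.where(informative, np.log(np.clip(s, _LOG_FLOOR, None)), 0.0).sum(axis=1)


def _maf_em_all(
    gl: np.ndarray,
    informative: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-site EM for the minor-allele frequency.

    Returns (p_hat, lrt_stat).  Update: p' = mean posterior dose / 2 over
    informative individuals, with genotype posteriors proportional to
    GL(g) * Binom(g; 2, p).  Sites without informative individuals get NaN.
    """
    m, n, _ = gl.shape
    n_inf = informative.sum(axis=1)
    ok = n_inf > 0
    p = np.full(m, np.nan)
    if not ok.any():
        return p, np.full(m, np.nan)
    # initialize at the flat-prior posterior mean dose
    tot = gl.sum(axis=2)
    dose = (gl[:, :, 1] + 2.0 * gl[:, :, 2]) / np.clip(tot, _LOG_FLOOR, None)
    with np.errstate(invalid="ignore"):
        p0 = np.where(informative, dose, 0.0).sum(axis=1) / np.maximum(n_inf, 1) / 2.0
    p[ok] = np.clip(p0[ok], 1e-6, 1 - 1e-6)
    active = ok.copy()
    for _ in range(max_iter):
        if not active.any():
            break
        pa = p[active]
        b0, b1, b2 = _genotype_prior(pa[:, None])
        g = gl[active]
        w0 = g[:, :, 0] * b0
        w1 = g[:, :, 1] * b1
        w2 = g[:, :, 2] * b2
        s = np.clip(w0 + w1 + w2, _LOG_FLOOR, None)
        e = (w1 + 2.0 * w2) / s
        p_new = np.where(informative[active], e, 0.0).sum(axis=1) / (2.0 * n_inf[active])
        moved = np.abs(p_new - pa) >= tol
        p[active] = p_new
        idx = np.flatnonzero(active)
        active[idx[~moved]] = False
    ll_hat = _site_loglik(gl, informative, np.nan_to_num(p))
    ll_null = _site_loglik(gl, informative, np.zeros(m))
    lrt = np.where(ok, 2.0 * (ll_hat - ll_null), np.nan)
    return p, np.maximum(lrt, 0.0)


def site_frequencies(ds: GenotypeLikelihoodDataset) -> "pd.DataFrame":
    """Per-site EM minor-allele frequencies, SNP LRT and informative counts."""
    import pandas as pd

    informative = ds.informative()
    p, lrt = _maf_em_all(ds.gl, informative)
    return pd.DataFrame(
        {
            "site_id": ds.site_ids,
            "major": [BASES[a] for a in ds.major],
            "minor": [BASES[a] for a in ds.minor],
            "maf": p,
            "lrt_stat": lrt,
            "n_informative": informative.sum(axis=1),
        }
    )


def estimate_maf_em(ds: GenotypeLikelihoodDataset, site: int) -> SiteFrequency:
    """Maximum-likelihood allele frequency at one site (EM, HW genotype prior)."""
    informative = ds.informative()[site : site + 1]
    if informative.sum() == 0:
        raise ValueError(f"site {site}: no informative individuals, frequency undefined")
    p, lrt = _maf_em_all(ds.gl[site : site + 1], informative)
    return SiteFrequency(maf=float(p[0]), n_informative=int(informative.sum()), lrt_stat=float(lrt[0]))


def infer_major_minor(
    ds: GenotypeLikelihoodDataset, freqs: np.ndarray | None = None
) -> tuple[GenotypeLikelihoodDataset, np.ndarray]:
    """Repolarize sites so the minor allele is the less frequent one.

    Sites whose estimated minor-allele frequency exceeds 0.5 have major/minor
    swapped, the GL triplet reversed, and base-count columns exchanged.  An
    exact tie (p = 0.5) keeps the input polarization.  Returns the polarized
    dataset and the (M,) minor-allele frequencies (all <= 0.5 afterwards).
    """
    if freqs is None:
        freqs, _ = _maf_em_all(ds.gl, ds.informative())
    freqs = np.asarray(freqs, dtype=float)
    swap = freqs > 0.5
    major = np.where(swap, ds.minor, ds.major)
    minor = np.where(swap, ds.major, ds.minor)
    gl = ds.gl.copy()
    gl[swap] = gl[swap][:, :, ::-1]
    base_counts = None
    if ds.base_counts is not None:
        base_counts = ds.base_counts.copy()
        base_counts[swap] = base_counts[swap][:, :, ::-1]
    maf = np.where(swap, 1.0 - freqs, freqs)
    out = replace(ds, major=major.astype(np.int8), minor=minor.astype(np.int8),
                  gl=gl, base_counts=base_counts)
    return out, maf


def count_based_frequency(
    ds: GenotypeLikelihoodDataset,
    individuals: Sequence[int] | np.ndarray | None,
    site: int,
) -> float:
    """Pooled read-count minor-allele frequency at one site.

    Frequency = (sum of minor-allele reads) / (sum of all reads) across the
    chosen individuals, mirroring count-based frequency estimation
    (ANGSD ``-doCounts 1 -doMaf 8``).
    """
    if ds.base_counts is None:
        raise ValueError("dataset carries no base counts")
    counts = ds.base_counts[site]
    if individuals is not None:
        counts = counts[np.asarray(individuals)]
    total = counts.sum()
    if total == 0:
        raise ValueError(f"site {site}: zero pooled reads, frequency undefined")
    return float(counts[:, 1].sum() / total)


def count_based_frequencies(
    ds: GenotypeLikelihoodDataset, individuals: Sequence[int] | np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pooled count frequencies for all sites.

    Returns (freq, n_chromosomes) where n_chromosomes = 2 x individuals with
    at least one read; freq is NaN where no reads were observed.
    """
    if ds.base_counts is None:
        raise ValueError("dataset carries no base counts")
    counts = ds.base_counts
    if individuals is not None:
        counts = counts[:, np.asarray(individuals)]
    total = counts.sum(axis=(1, 2)).astype(float)
    minor = counts[:, :, 1].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(total > 0, minor / total, np.nan)
    covered = (counts.sum(axis=2) > 0).sum(axis=1)
    return freq, 2 * covered
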