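"""PCA of genotype likelihoods via posterior-mean genotypes.

Hard genotype calls are unreliable at modest depth, so each entry of the
genotype matrix is replaced by its posterior expectation under a
Hardy-Weinberg prior at the site's allele frequency; entries without reads
fall back to the prior mean 2p.  The individual-by-individual covariance is
the usual frequency-standardized form

    C = (1/M) sum_j (E_.j - 2 p_j)(E_.j - 2 p_j)^T / (2 p_j (1 - p_j))

and coordinates are leading eigenvectors scaled by sqrt(eigenvalue).  An
optional iterative refinement re-estimates individual-specific allele
frequencies from the leading PCs (the PCAngsd idea); it is off by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .gl_io import GenotypeLikelihoodDataset, _maf_em_all, infer_major_minor

__all__ = ["PCAResult", "posterior_mean_genotypes", "gl_pca"]


@dataclass
class PCAResult:
    covariance: np.ndarray  # (N, N)
    coords: np.ndarray  # (N, n_pcs)
    explained_fraction: np.ndarray  # (n_pcs,)
    site_index: np.ndarray  # sites used


def posterior_mean_genotypes(
    ds: GenotypeLikelihoodDataset, mafs: np.ndarray
) -> np.ndarray:
    """(N, M) posterior expected minor-allele dose.

    E_ij = sum_g g GL_ij(g) Binom(g; 2, p_j) / sum_g GL_ij(g) Binom(g; 2, p_j),
    with the no-data convention E = 2 p_j.
    """
    p = np.asarray(mafs, dtype=float)[:, None]
    gl = ds.gl
    b0 = (1 - p) ** 2
    b1 = 2 * p * (1 - p)
    b2 = p * p
    w0 = gl[:, :, 0] * b0
    w1 = gl[:, :, 1] * b1
    w2 = gl[:, :, 2] * b2
    s = w0 + w1 + w2
    with np.errstate(invalid="ignore", divide="ignore"):
        e = (w1 + 2 * w2) / s
    e = np.where(ds.informative(), e, 2 * p)
    return e.T


def _posterior_mean_individual(gl: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Posterior dose with individual-specific frequencies pi (N, M)."""
    p = pi.T[:, :, None]  # (M, N, 1)
    b = np.concatenate([(1 - p) ** 2, 2 * p * (1 - p), p * p], axis=2)
    w = gl * b
    e = (w[:, :, 1] + 2 * w[:, :, 2]) / np.clip(w.sum(axis=2), 1e-300, None)
    return e.T


def gl_pca(
    ds: GenotypeLikelihoodDataset,
    n_pcs: int = 10,
    maf_min: float = 0.05,
    iterative: bool = False,
    n_refine: int = 2,
) -> PCAResult:
    """Standardized-genotype PCA from genotype likelihoods.

    Sites with estimated MAF below ``maf_min`` (or 0/1, where
    standardization is undefined) are skipped with a warning.  The sign of
    each PC is fixed so its largest-magnitude loading is positive.
    """
    if ds.n_individuals < 2 or ds.n_sites < 2:
        raise ValueError("PCA needs at least 2 individuals and 2 sites")
    freqs, _ = _maf_em_all(ds.gl, ds.informative())
    polarized, maf = infer_major_minor(ds, freqs)
    usable = np.nan_to_num(maf) >= max(maf_min, 1e-6)
    usable &= np.nan_to_num(maf) <= 1 - 1e-6
    n_skipped = int((~usable).sum())
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} sites with MAF < {maf_min} or fixed")
    idx = np.flatnonzero(usable)
    if idx.size < 2:
        raise ValueError("fewer than 2 usable sites for PCA")
    sub = polarized.take_sites(idx)
    p = maf[idx]
    e = posterior_mean_genotypes(sub, p)  # (N, M)

    def standardize(e_mat):
        z = (e_mat - 2 * p[None, :]) / np.sqrt(2 * p * (1 - p))[None, :]
        return z

    z = standardize(e)
    if iterative:
        for _ in range(n_refine):
            cov = z @ z.T / idx.size
            vals, vecs = np.linalg.eigh(cov)
            top = vecs[:, ::-1][:, : min(n_pcs, len(vals))]
            z_hat = top @ (top.T @ z)
            pi = np.clip(
                p[None, :] + 0.5 * z_hat * np.sqrt(2 * p * (1 - p))[None, :],
                1e-4,
                1 - 1e-4,
            )
            e = _posterior_mean_individual(sub.gl, pi)
            e = np.where(sub.informative().T, e, 2 * pi)
            z = standardize(e)

    cov = z @ z.T / idx.size
    if not np.isfinite(cov).all():
        i, j = np.argwhere(~np.isfinite(cov))[0]
        raise ValueError(f"non-finite covariance entry for individuals ({i}, {j})")
    cov = (cov + cov.T) / 2.0
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    n_pcs = min(n_pcs, len(vals))
    lead_vals = np.clip(vals[:n_pcs], 0.0, None)
    coords = vecs[:, :n_pcs] * np.sqrt(lead_vals)[None, :]
    # deterministic sign: largest-magnitude loading positive
    for c in range(n_pcs):
        jmax = np.argmax(np.abs(coords[:, c]))
        if coords[jmax, c] < 0:
            coords[:, c] = -coords[:, c]
    total = np.clip(vals, 0.0, None).sum()
    explained = lead_vals / total if total > 0 else np.zeros(n_pcs)
    return PCAResult(
        covariance=cov, coords=coords, explained_fraction=explained, site_index=idx
    )
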