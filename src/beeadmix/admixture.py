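"""Maximum-likelihood admixture from genotype likelihoods.

Fits the classic admixture model directly on genotype likelihoods (the
NGSadmix approach): individual i's expected minor-allele frequency at site j
is h_ij = sum_k q_ik f_kj, where Q (N x K) are ancestry proportions and
F (K x M) per-cluster allele frequencies.  The observed-data log-likelihood
marginalizes the unknown genotype against its likelihood triplet:

    loglik = sum_ij log sum_g GL_ij(g) C(2,g) h_ij^g (1-h_ij)^(2-g)

EM treats each allele copy's ancestral origin and the genotype as missing
data.  Each iteration is guaranteed not to decrease the log-likelihood;
individual-sites without reads (flat GL) are excluded from the updates since
their likelihood term is constant.

Cluster labels are arbitrary under the likelihood (label switching), so
clusters are matched to lineages afterwards with a Hungarian assignment on
mean reference-panel ancestry.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .gl_io import GenotypeLikelihoodDataset

__all__ = [
    "AncestryModel",
    "admixture_loglik",
    "em_step",
    "fit_admixture",
    "label_clusters",
    "summarize_population_ancestry",
    "LabelingError",
]

_F_CLAMP = 1e-6
_LOG_FLOOR = 1e-300


class LabelingError(RuntimeError):
    """Cluster-to-lineage matching is ambiguous or unsupported by references."""


@dataclass
class AncestryModel:
    """Fitted admixture model: Q rows sum to 1, F clamped inside (0, 1)."""

    Q: np.ndarray  # (N, K)
    F: np.ndarray  # (K, M)
    loglik: float
    K: int
    converged: bool
    n_iter: int
    seed: int
    cluster_labels: list[str] | None = None

    def __post_init__(self) -> None:
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("Q rows must sum to 1")


def _prep(ds: GenotypeLikelihoodDataset):
    """Transpose GLs to (N, M) planes and build the informative mask."""
    gl = ds.gl
    g0 = np.ascontiguousarray(gl[:, :, 0].T)
    g1 = np.ascontiguousarray(gl[:, :, 1].T)
    g2 = np.ascontiguousarray(gl[:, :, 2].T)
    mask = np.ascontiguousarray(ds.informative().T)
    return g0, g1, g2, mask


def _loglik_core(g0, g1, g2, mask, q, f) -> float:
    h = np.clip(q @ f, _F_CLAMP, 1.0 - _F_CLAMP)
    s = g0 * (1 - h) ** 2 + g1 * 2 * h * (1 - h) + g2 * h * h
    return float(np.where(mask, np.log(np.clip(s, _LOG_FLOOR, None)), 0.0).sum())


def admixture_loglik(
    ds: GenotypeLikelihoodDataset, q: np.ndarray, f: np.ndarray
) -> float:
    """Observed-data log-likelihood of (Q, F) given the GL dataset.

    Individual-sites without reads have a constant (zero, for normalized
    flat triplets) contribution.
    """
    q = np.asarray(q, dtype=float)
    f = np.asarray(f, dtype=float)
    if q.shape[1] != f.shape[0]:
        raise ValueError("Q columns must match F rows")
    if f.shape[1] != ds.n_sites or q.shape[0] != ds.n_individuals:
        raise ValueError("model shapes do not match dataset")
    g0, g1, g2, mask = _prep(ds)
    return _loglik_core(g0, g1, g2, mask, q, f)


def _em_step_core(g0, g1, g2, mask, m_i, q, f):
    """One EM sweep; returns (Q', F', loglik of the INPUT parameters)."""
    n, k = q.shape
    h = np.clip(q @ f, _F_CLAMP, 1.0 - _F_CLAMP)
    b0 = (1 - h) ** 2
    b1 = 2 * h * (1 - h)
    b2 = h * h
    w1 = g1 * b1
    w2 = g2 * b2
    s = np.clip(g0 * b0 + w1 + w2, _LOG_FLOOR, None)
    ll = float(np.where(mask, np.log(s), 0.0).sum())
    # expected minor-allele dose and its complement, zeroed where no reads
    e = np.where(mask, (w1 + 2.0 * w2) / s, 0.0)
    e_major = np.where(mask, 2.0 - e, 0.0)
    u = e / h
    v = e_major / (1.0 - h)
    f_new = np.empty_like(f)
    q_new = np.empty_like(q)
    for kk in range(k):
        a_k = (q[:, kk : kk + 1] * f[kk][None, :]) * u  # minor copies from kk
        b_k = (q[:, kk : kk + 1] * (1.0 - f[kk])[None, :]) * v  # major copies
        num = a_k.sum(axis=0)
        den = num + b_k.sum(axis=0)
        f_new[kk] = num / np.clip(den, _LOG_FLOOR, None)
        q_new[:, kk] = a_k.sum(axis=1) + b_k.sum(axis=1)
    if not (np.isfinite(f_new).all() and np.isfinite(q_new).all()):
        bad = np.argwhere(~np.isfinite(f_new))
        raise FloatingPointError(f"non-finite EM responsibility at site {bad[:1]}")
    f_new = np.clip(f_new, _F_CLAMP, 1.0 - _F_CLAMP)
    q_new = q_new / np.clip(2.0 * m_i[:, None], 1.0, None)
    q_new = np.clip(q_new, 0.0, None)
    q_new /= q_new.sum(axis=1, keepdims=True)
    return q_new, f_new, ll


def em_step(
    ds: GenotypeLikelihoodDataset, q: np.ndarray, f: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """One EM update (Q, F) -> (Q', F'); never decreases the log-likelihood."""
    g0, g1, g2, mask = _prep(ds)
    m_i = mask.sum(axis=1).astype(float)
    q_new, f_new, _ = _em_step_core(g0, g1, g2, mask, m_i, np.asarray(q, float), np.asarray(f, float))
    return q_new, f_new


def fit_admixture(
    ds: GenotypeLikelihoodDataset,
    k: int,
    n_restarts: int = 10,
    tol: float = 1e-6,
    max_iter: int = 2000,
    seed: int = 0,
    search_iters: int | None = 100,
    fixed_q: dict[int, np.ndarray] | None = None,
    assert_monotone: bool = False,
) -> AncestryModel:
    """Best-of-restarts EM fit of the K-cluster admixture model.

    Each restart initializes Q ~ Dirichlet(1,..,1) and F ~ Uniform(0.05,
    0.95) from a seed derived deterministically from ``seed``.  With
    ``search_iters`` set (default 100), every restart runs that many burn-in
    sweeps, the best by log-likelihood continues to convergence
    (delta loglik < tol); ``search_iters=None`` runs every restart to
    convergence.  ``fixed_q`` freezes given individuals' ancestry rows
    (supervised mode).  ``assert_monotone`` raises if any sweep decreases
    the log-likelihood (debugging aid for the exact, unaccelerated EM).
    """
    n, m = ds.n_individuals, ds.n_sites
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} individuals")
    if m == 0:
        raise ValueError("no sites in dataset")
    g0, g1, g2, mask = _prep(ds)
    m_i = mask.sum(axis=1).astype(float)

    def apply_fixed(q):
        if fixed_q:
            for idx, row in fixed_q.items():
                q[idx] = row
        return q

    def run(q, f, iters, ll_prev=-np.inf, total_done=0):
        converged = False
        done = total_done
        for _ in range(iters):
            q_new, f_new, ll = _em_step_core(g0, g1, g2, mask, m_i, q, f)
            if assert_monotone and ll < ll_prev - 1e-8:
                raise AssertionError(f"EM decreased loglik: {ll_prev} -> {ll}")
            q, f = apply_fixed(q_new), f_new
            done += 1
            if abs(ll - ll_prev) < tol:
                converged = True
                ll_prev = ll
                break
            ll_prev = ll
        return q, f, ll_prev, converged, done

    states = []
    for r in range(n_restarts):
        rng = np.random.default_rng([seed, r])
        q0 = apply_fixed(rng.dirichlet(np.ones(k), size=n))
        f0 = rng.uniform(0.05, 0.95, size=(k, m))
        burn = max_iter if search_iters is None else min(search_iters, max_iter)
        states.append(run(q0, f0, burn))
    best = max(range(n_restarts), key=lambda r: states[r][2])
    q, f, ll, converged, done = states[best]
    if not converged and done < max_iter:
        q, f, ll, converged, done = run(q, f, max_iter - done, ll, done)
    # final loglik at the returned parameters
    ll_final = _loglik_core(g0, g1, g2, mask, q, f)
    return AncestryModel(
        Q=q, F=f, loglik=ll_final, K=k, converged=converged, n_iter=done, seed=seed
    )


def label_clusters(
    model: AncestryModel,
    reference_lineages: pd.Series | dict[int, str],
) -> AncestryModel:
    """Match clusters to lineages via reference individuals (Hungarian).

    ``reference_lineages`` maps individual indices (rows of Q) to lineage
    names.  Clusters are permuted so column order follows the sorted lineage
    names (extra clusters keep generic names).  Raises
    :class:`LabelingError` if any lineage's matched cluster has mean
    reference ancestry below 0.5.
    """
    ref = dict(reference_lineages)
    if not ref:
        raise LabelingError("no reference individuals given")
    lineages = sorted(set(ref.values()))
    if len(lineages) > model.K:
        raise LabelingError(f"{len(lineages)} lineages but only K={model.K} clusters")
    mean_anc = np.zeros((len(lineages), model.K))
    for li, lin in enumerate(lineages):
        idx = [i for i, l in ref.items() if l == lin]
        mean_anc[li] = model.Q[idx].mean(axis=0)
    rows, cols = linear_sum_assignment(-mean_anc)
    matched = {}
    for li, kk in zip(rows, cols):
        if mean_anc[li, kk] < 0.5:
            raise LabelingError(
                f"lineage {lineages[li]} matches cluster {kk} with mean reference "
                f"ancestry {mean_anc[li, kk]:.3f} < 0.5"
            )
        matched[lineages[li]] = kk
    order = [matched[lin] for lin in lineages]
    extras = [kk for kk in range(model.K) if kk not in order]
    perm = order + extras
    labels = lineages + [f"cluster{kk}" for kk in extras]
    return replace(
        model, Q=model.Q[:, perm], F=model.F[perm], cluster_labels=labels
    )


def summarize_population_ancestry(
    model: AncestryModel,
    populations: dict[str, np.ndarray] | pd.Series,
) -> pd.DataFrame:
    """Per-population mean and SE (sample SD / sqrt(n)) of each lineage's
    ancestry, as percentages; means per population sum to 100."""
    if model.cluster_labels is None:
        raise ValueError("label clusters before summarizing")
    if isinstance(populations, pd.Series):
        populations = {
            name: np.flatnonzero(populations.values == name)
            for name in populations.unique()
        }
    rows = []
    for name, idx in populations.items():
        idx = np.asarray(idx)
        if idx.size == 0:
            raise ValueError(f"population {name!r} has no individuals")
        q = model.Q[idx] * 100.0
        mean = q.mean(axis=0)
        se = q.std(axis=0, ddof=1) / np.sqrt(idx.size) if idx.size > 1 else np.zeros(model.K)
        row = {"population": name, "n": idx.size}
        for kk, lab in enumerate(model.cluster_labels):
            row[f"mean_{lab}"] = mean[kk]
            row[f"se_{lab}"] = se[kk]
        rows.append(row)
    return pd.DataFrame(rows)
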