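"""Site-selection rules for each downstream analysis stage.

Two filter profiles recur in genotype-likelihood pipelines and both are
expressible with :class:`FilterSpec`:

* the variant-calling stage: coverage in >= 63% of individuals at >= 3x
  depth, SNP likelihood-ratio p < 1e-6, no tri-allelic sites, then LD
  thinning by keeping every 100th SNP;
* the admixture stage: presence in >= 94% of individuals and minor-allele
  frequency >= 5%.

Filters are applied in a fixed order (coverage, SNP LRT, tri-allelic, MAF)
and the report records how many sites each rule removed, so that the
removed counts plus survivors always equal the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .gl_io import GenotypeLikelihoodDataset, _maf_em_all, infer_major_minor

__all__ = ["FilterSpec", "FilterReport", "apply_site_filters", "thin_sites"]


@dataclass
class FilterSpec:
    """Thresholds for site selection.

    ``coverage_rule`` chooses how "X% of individuals reporting information
    with depth >= d" is read: ``"joint"`` (default) counts an individual as
    covered only when its depth reaches ``min_depth``; ``"two-rule"``
    requires the fraction with any data >= ``min_frac_covered`` and mean
    depth over covered individuals >= ``min_depth``.
    """

    min_frac_covered: float = 0.63
    min_depth: int = 3
    snp_lrt_alpha: float | None = 1e-6
    maf_min: float = 0.0
    thin_keep_every: int = 1
    drop_triallelic: bool = True
    coverage_rule: str = "joint"

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_frac_covered <= 1.0):
            raise ValueError("min_frac_covered must be in [0, 1]")
        if not (0.0 <= self.maf_min <= 0.5):
            raise ValueError("maf_min must be in [0, 0.5]")
        if self.thin_keep_every < 1:
            raise ValueError("thin_keep_every must be >= 1")
        if self.coverage_rule not in ("joint", "two-rule"):
            raise ValueError("coverage_rule must be 'joint' or 'two-rule'")


@dataclass
class FilterReport:
    """Per-rule removal counts, in application order."""

    n_input: int
    removed: dict[str, int] = field(default_factory=dict)

    @property
    def n_survivors(self) -> int:
        return self.n_input - sum(self.removed.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [{"rule": r, "removed": c} for r, c in self.removed.items()]
        rows.append({"rule": "survivors", "removed": self.n_survivors})
        return pd.DataFrame(rows)


def apply_site_filters(
    ds: GenotypeLikelihoodDataset,
    spec: FilterSpec,
    triallelic: np.ndarray | None = None,
) -> tuple[GenotypeLikelihoodDataset, FilterReport]:
    """Apply coverage, SNP-LRT, tri-allelic and MAF rules, in that order.

    Returns the surviving sites (polarized so MAF <= 0.5) and a report.
    ``triallelic`` optionally flags sites with a third allele (synthetic
    data are biallelic by construction, so the default removes none).
    """
    report = FilterReport(n_input=ds.n_sites)
    keep = np.ones(ds.n_sites, dtype=bool)

    informative = ds.informative()
    if ds.depth is not None:
        covered = ds.depth >= spec.min_depth
    else:
        covered = informative  # BEAGLE input: depth unknown, any data counts
    if spec.coverage_rule == "joint":
        frac = covered.sum(axis=1) / ds.n_individuals
        cov_ok = frac >= spec.min_frac_covered
    else:
        frac_any = informative.sum(axis=1) / ds.n_individuals
        with np.errstate(invalid="ignore"):
            mean_depth = np.where(
                informative.sum(axis=1) > 0,
                (ds.depth if ds.depth is not None else informative).sum(axis=1)
                / np.maximum(informative.sum(axis=1), 1),
                0.0,
            )
        cov_ok = (frac_any >= spec.min_frac_covered) & (mean_depth >= spec.min_depth)
    report.removed["coverage"] = int((keep & ~cov_ok).sum())
    keep &= cov_ok

    freqs, lrt = _maf_em_all(ds.gl, informative)
    if spec.snp_lrt_alpha is not None:
        thresh = chi2.isf(spec.snp_lrt_alpha, df=1)
        snp_ok = np.nan_to_num(lrt) >= thresh
        report.removed["snp_lrt"] = int((keep & ~snp_ok).sum())
        keep &= snp_ok
    else:
        report.removed["snp_lrt"] = 0

    if spec.drop_triallelic and triallelic is not None:
        tri_ok = ~np.asarray(triallelic, dtype=bool)
        report.removed["triallelic"] = int((keep & ~tri_ok).sum())
        keep &= tri_ok
    else:
        report.removed["triallelic"] = 0

    polarized, maf = infer_major_minor(ds, freqs)
    maf_ok = np.nan_to_num(maf) >= spec.maf_min
    report.removed["maf"] = int((keep & ~maf_ok).sum())
    keep &= maf_ok

    return polarized.take_sites(np.flatnonzero(keep)), report


def thin_sites(
    ds: GenotypeLikelihoodDataset, keep_every: int = 100
) -> GenotypeLikelihoodDataset:
    """LD thinning: keep every ``keep_every``-th SNP within each block.

    Sites must be ordered by position within block; the first site of each
    block is always kept, so a block of s sites yields ceil(s/keep_every).
    """
    if keep_every < 1:
        raise ValueError("keep_every must be >= 1")
    if keep_every == 1 or ds.n_sites == 0:
        return ds
    keep = np.zeros(ds.n_sites, dtype=bool)
    for block in pd.unique(ds.block_id):
        idx = np.flatnonzero(ds.block_id == block)
        keep[idx[::keep_every]] = True
    return ds.take_sites(np.flatnonzero(keep))
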