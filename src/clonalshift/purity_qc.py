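"""Tumour purity estimation from VAFs and post-treatment sample exclusion.

Purity is estimated from the clonal (upper) mode of the VAF distribution of
retained somatic variants.  Each VAF is first mapped to the purity it would
imply if the mutation were clonal at multiplicity one given the local total
copy number (for a diploid locus this is simply 2 x VAF); a kernel density
estimate over the implied purities is then scanned for local maxima, and the
largest-purity mode of non-negligible height is returned.  Sub-clonal
mutations imply lower purities and form lower modes, which is why the upper
mode - not the global one - identifies the clonal cluster.

Post-treatment samples are excluded when at least K of three features fire:
a large purity drop relative to the pre-treatment sample, low histological
tumour cell content (< 20%), and a collapsed post-treatment mutation burden.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["QCDecision", "ExclusionThresholds", "estimate_purity", "refine_purity",
           "assess_exclusion"]


def implied_clonal_purity(vaf, total_cn=2.0):
    """Purity implied by a clonal multiplicity-1 mutation with the given VAF.

    Solves vaf = p / (p * cn + 2 (1 - p)) for p, i.e. p = 2 vaf / (1 + 2 vaf - vaf cn).
    """
    vaf = np.asarray(vaf, dtype=float)
    cn = np.asarray(total_cn, dtype=float)
    denom = 1.0 + 2.0 * vaf - vaf * cn
    return np.where(denom > 1e-9, 2.0 * vaf / np.maximum(denom, 1e-9), np.inf)


def estimate_purity(
    vafs,
    total_cn=None,
    min_variants: int = 20,
    mode_rel_height: float = 0.25,
    grid_step: float = 0.002,
):
    """Estimate tumour purity from retained-variant VAFs.

    Returns a float in (0, 1], or ``None`` (with no exception) when fewer
    than ``min_variants`` VAFs are supplied - too few for a stable density
    mode.  ``total_cn`` may be a scalar or per-variant array; default diploid.
    ``mode_rel_height`` sets the minimum height of a candidate mode relative
    to the density maximum.
    """
    v = np.asarray(vafs, dtype=float)
    v = v[np.isfinite(v) & (v > 0)]
    if v.size < min_variants:
        return None
    cn = 2.0 if total_cn is None else total_cn
    p = implied_clonal_purity(v, cn)
    p = p[np.isfinite(p) & (p > 0)]
    p = np.clip(p, 0.0, 1.5)
    if p.size < min_variants:
        return None
    if np.ptp(p) < 1e-9:  # all identical: degenerate KDE
        return float(min(1.0, p[0]))
    kde = stats.gaussian_kde(p)
    grid = np.arange(grid_step, 1.2 + grid_step, grid_step)
    dens = kde(grid)
    # local maxima (plateau-tolerant at boundaries)
    interior = (dens[1:-1] >= dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = np.where(interior)[0] + 1
    if dens[-1] > dens[-2]:
        peaks = np.append(peaks, dens.size - 1)
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(dens))])
    big = peaks[dens[peaks] >= mode_rel_height * dens.max()]
    mode = grid[big.max()] if big.size else grid[int(np.argmax(dens))]
    return float(min(1.0, mode))


def refine_purity(vaf_centers, sizes, total_cn=2.0, min_size: int = 5,
                  min_frac: float = 0.05):
    """Clustering-based purity estimate: the clonal cluster's implied purity.

    Given per-cluster VAF centres and sizes (from the clone clustering), the
    highest-VAF cluster that is not negligibly small (at least ``min_size``
    members and ``min_frac`` of all clustered mutations) is taken as the
    clonal cluster, and its implied multiplicity-1 purity is returned.  More
    robust than the KDE mode at moderate depth, where binomial noise merges
    clonal and sub-clonal density modes.  Returns ``None`` if no cluster
    qualifies.
    """
    v = np.asarray(vaf_centers, dtype=float)
    s = np.asarray(sizes, dtype=float)
    if v.size == 0:
        return None
    floor = max(min_size, min_frac * s.sum())
    ok = s >= floor
    if not ok.any():
        return None
    mode = float(v[ok].max())
    if mode <= 0:
        return None
    p = float(implied_clonal_purity(mode, total_cn))
    return min(1.0, p) if np.isfinite(p) and p > 0 else None


@dataclass
class ExclusionThresholds:
    purity_drop_fraction: float = 0.5    # post purity < fraction * pre purity
    min_histology_content: float = 0.20  # strict: exactly 20% does not fire
    burden_floor_fraction: float = 0.2   # post burden < fraction * pre burden
    min_features: int = 2                # K-of-3 rule
    use_purity: bool = True
    use_histology: bool = True
    use_burden: bool = True


@dataclass
class QCDecision:
    patient_id: str
    purity_pre: float | None
    purity_post: float | None
    histology_content_post: float | None
    pre_burden: int
    post_burden: int
    excluded: bool
    reasons: list = field(default_factory=list)


def assess_exclusion(
    patient_id: str,
    purity_pre: float | None,
    purity_post: float | None,
    histology_content_post: float | None,
    pre_burden: int,
    post_burden: int,
    thresholds: ExclusionThresholds | None = None,
) -> QCDecision:
    """Three-feature post-treatment exclusion rule (default 2-of-3).

    Features that cannot be evaluated (missing purity or histology) do not
    fire.  Worsening any feature can only add reasons, never remove them.
    """
    th = thresholds or ExclusionThresholds()
    reasons = []
    if (
        th.use_purity
        and purity_pre is not None
        and purity_post is not None
        and purity_post < th.purity_drop_fraction * purity_pre
    ):
        reasons.append("purity_drop")
    if (
        th.use_histology
        and histology_content_post is not None
        and histology_content_post < th.min_histology_content
    ):
        reasons.append("low_histology")
    if th.use_burden and post_burden < th.burden_floor_fraction * pre_burden:
        reasons.append("low_burden")
    return QCDecision(
        patient_id=patient_id,
        purity_pre=purity_pre,
        purity_post=purity_post,
        histology_content_post=histology_content_post,
        pre_burden=pre_burden,
        post_burden=post_burden,
        excluded=len(reasons) >= th.min_features,
        reasons=reasons,
    )
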