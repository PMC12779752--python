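"""Region-of-interest analysis: regional activation and effect sizes.

Level 1 of the survey.  Each subject's map is averaged within atlas
regions; regional group activation is a one-sample t-test with Holm
familywise correction across regions; regional effect sizes are Cohen's
d (Hedges-corrected for pseudo-studies, uncorrected for the gold
standard).  Validity compares pseudo-studies to the gold standard on the
ten regions with the largest gold-standard effects; reliability is the
agreement among pseudo-studies over the complete region set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .metrics import (
    ICCResult,
    hedges_factor,
    holm_adjust,
    icc_binary_oneway,
    icc_c1,
    one_sample_t,
)

__all__ = [
    "RegionalResult",
    "regional_means",
    "activation_analysis",
    "select_target_regions",
    "roi_validity",
    "roi_reliability",
]


@dataclass
class RegionalResult:
    """Per-region activation test and effect size for one cohort."""

    region_ids: np.ndarray
    t: np.ndarray
    p: np.ndarray
    p_holm: np.ndarray
    significant: np.ndarray
    d: np.ndarray
    n_subjects: int
    hedges_corrected: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "region_id": self.region_ids, "t": self.t, "p": self.p,
            "p_holm": self.p_holm, "significant": self.significant, "d": self.d,
        })


def regional_means(maps, atlas) -> np.ndarray:
    """Unweighted mean of each subject's map over every atlas region.

    Returns a (n_subjects, n_regions) matrix ordered by region id.
    """
    labels = atlas.labels
    if labels.shape != maps.grid_shape:
        raise ValueError("atlas grid does not match the maps")
    flat_labels = labels.ravel()
    counts = np.bincount(flat_labels, minlength=atlas.n_regions + 1)[1:]
    if np.any(counts == 0):
        raise ValueError("atlas contains empty regions")
    flat = maps.data.reshape(maps.n_subjects, -1)
    sums = np.vstack([
        np.bincount(flat_labels, weights=row, minlength=atlas.n_regions + 1)[1:]
        for row in flat
    ])
    return sums / counts


def activation_analysis(
    regional: np.ndarray, alpha: float = 0.05, hedges: bool = False
) -> RegionalResult:
    """Test every region against zero with Holm correction across regions.

    ``hedges=True`` multiplies the regional Cohen's d by the small-sample
    bias factor (used for pseudo-studies; the gold standard is left
    uncorrected).
    """
    regional = np.asarray(regional, dtype=float)
    n, n_regions = regional.shape
    t, _, p = one_sample_t(regional)
    p_holm, reject = holm_adjust(p, alpha=alpha)
    sd = regional.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = regional.mean(axis=0) / sd
    if hedges:
        d = d * hedges_factor(n)
    return RegionalResult(
        region_ids=np.arange(1, n_regions + 1), t=np.atleast_1d(t),
        p=np.atleast_1d(p), p_holm=np.atleast_1d(p_holm),
        significant=np.atleast_1d(reject), d=np.atleast_1d(d),
        n_subjects=n, hedges_corrected=hedges,
    )


def select_target_regions(gold: RegionalResult, k: int = 10) -> np.ndarray:
    """The k regions with the largest gold-standard effect size.

    Sorted by descending d with ties broken by ascending region id, so
    the selection is deterministic.
    """
    if k > len(gold.region_ids):
        raise ValueError("k exceeds the number of regions")
    order = np.lexsort((gold.region_ids, -gold.d))
    return gold.region_ids[order[:k]]


def _jeffreys_hdi(successes: int, n: int, cred: float = 0.95):
    """Highest-density interval of the Jeffreys Beta posterior."""
    a, b = successes + 0.5, n - successes + 0.5
    dist = stats.beta(a, b)

    def width(p_lo):
        return dist.ppf(p_lo + cred) - dist.ppf(p_lo)

    res = optimize.minimize_scalar(width, bounds=(0.0, 1.0 - cred),
                                   method="bounded")
    lo = dist.ppf(res.x)
    hi = dist.ppf(res.x + cred)
    return float(lo), float(hi)


def roi_validity(
    studies: list,
    gold: RegionalResult,
    targets: np.ndarray,
    all_regions_rank_corr: bool = False,
):
    """Validity of pseudo-studies against the gold standard.

    Returns ``(proportions, rank_corrs)``: the proportion of studies with
    significant activation in each target region (with a 95% highest-
    density interval from a Jeffreys Beta posterior) and each study's
    Spearman correlation between its regional effect sizes and the gold
    standard's, over the target regions by default or over all regions
    with ``all_regions_rank_corr=True``.
    """
    targets = np.asarray(targets)
    tidx = np.searchsorted(gold.region_ids, targets)
    n_studies = len(studies)
    rows = []
    for region, ti in zip(targets, tidx):
        hits = sum(int(s.significant[ti]) for s in studies)
        lo, hi = _jeffreys_hdi(hits, n_studies)
        rows.append({
            "region_id": int(region), "gold_d": float(gold.d[ti]),
            "proportion_significant": hits / n_studies,
            "hdi_low": lo, "hdi_high": hi, "n_studies": n_studies,
        })
    proportions = pd.DataFrame(rows)

    corr_idx = np.arange(len(gold.region_ids)) if all_regions_rank_corr else tidx
    gold_d = gold.d[corr_idx]
    rank_corrs = np.array([
        stats.spearmanr(s.d[corr_idx], gold_d).statistic for s in studies
    ])
    return proportions, rank_corrs


def roi_reliability(studies: list, seed: int | None = None):
    """Agreement among pseudo-studies over the complete region set.

    Returns ``(binary_icc, d_icc)``: the one-way binary ICC of the
    significant/not-significant pattern (regions as units, studies as
    raters) and ICC(C,1) of the regional effect sizes.
    """
    if len(studies) < 2:
        raise ValueError("need at least 2 studies")
    binary = np.column_stack([s.significant.astype(float) for s in studies])
    dmat = np.column_stack([s.d for s in studies])
    binary_icc = icc_binary_oneway(binary, seed=seed)
    d_icc = icc_c1(dmat)
    return binary_icc, d_icc
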