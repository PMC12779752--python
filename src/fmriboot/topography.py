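"""Effect-size topography: voxelwise Cohen's d maps and their agreement.

Level 3 of the survey.  The per-voxel effect size is the across-subject
mean over the across-subject standard deviation (n-1 denominator, so the
Hedges factor applies exactly as stated for pseudo-studies).  Voxels are
binned into the conventional negligible / small / medium / large classes
on |d|.  Validity is the Spearman correlation between a study's masked d
map and the gold standard's; reliability is ICC(C,1) with voxels as
units and studies as raters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import ICCResult, hedges_factor, icc_c1

__all__ = [
    "EffectSizeMap",
    "BIN_NAMES",
    "BIN_EDGES",
    "effect_size_map",
    "bin_effect_sizes",
    "topography_validity",
    "topography_reliability",
]

BIN_NAMES = ("negligible", "small", "medium", "large")
BIN_EDGES = (0.2, 0.5, 0.8)  # half-open on the left: 0.2 <= |d| < 0.5 is small


@dataclass
class EffectSizeMap:
    """Per-voxel standardized effect sizes with Cohen-class bins."""

    d: np.ndarray
    corrected: bool
    bins: np.ndarray  # int codes into BIN_NAMES; -1 outside the mask
    mask: np.ndarray
    n_zero_sd: int = 0

    def bin_proportions(self) -> pd.Series:
        codes = self.bins[self.mask]
        counts = np.bincount(codes[codes >= 0], minlength=len(BIN_NAMES))
        return pd.Series(counts / counts.sum(), index=list(BIN_NAMES))


def bin_effect_sizes(d_map: np.ndarray) -> np.ndarray:
    """Cohen-class codes for |d|: 0 negligible, 1 small, 2 medium, 3 large."""
    return np.digitize(np.abs(np.asarray(d_map, dtype=float)), BIN_EDGES)


def effect_size_map(maps, correct: bool = False, mask: np.ndarray | None = None
                    ) -> EffectSizeMap:
    """Voxelwise Cohen's d, optionally with Hedges bias correction.

    The gold standard uses ``correct=False``; pseudo-studies use
    ``correct=True``.  Voxels whose across-subject standard deviation is
    zero carry no standardized effect; they are removed from the mask and
    counted.
    """
    data = maps.data
    n = data.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if mask is None:
        mask = maps.mask.copy()
    else:
        mask = mask.copy()
    sd = data.std(axis=0, ddof=1)
    zero_sd = (sd == 0) & mask
    mask &= ~zero_sd
    with np.errstate(divide="ignore", invalid="ignore"):
        d = data.mean(axis=0) / sd
    d = np.where(mask, d, np.nan)
    if correct:
        d = d * hedges_factor(n)
    bins = np.where(mask, bin_effect_sizes(np.nan_to_num(d)), -1)
    return EffectSizeMap(d=d, corrected=correct, bins=bins, mask=mask,
                         n_zero_sd=int(zero_sd.sum()))


def _common_mask(study_maps, gold_map=None, mask=None) -> np.ndarray:
    if mask is None:
        mask = study_maps[0].mask.copy()
    else:
        mask = mask.copy()
    for m in study_maps:
        mask &= m.mask
    if gold_map is not None:
        mask &= gold_map.mask
    return mask


def topography_validity(
    study_maps: list,
    gold_map: EffectSizeMap,
    mask: np.ndarray | None = None,
    atlas=None,
):
    """Per-study Spearman correlation with the gold-standard d map.

    Computed over the voxels of the shared mask; ties get average ranks.
    With an atlas, a per-network breakdown is also returned as a tidy
    frame (study, network, rank_corr).
    """
    common = _common_mask(study_maps, gold_map, mask)
    if common.sum() < 3:
        raise ValueError("mask must retain at least 3 voxels")
    gold_vals = gold_map.d[common]
    corrs = np.array([
        stats.spearmanr(m.d[common], gold_vals).statistic for m in study_maps
    ])
    if atlas is None:
        return corrs, None
    rows = []
    networks = sorted(set(atlas.network_of.values()))
    region_net = np.array([""] + [atlas.network_of[r]
                                  for r in range(1, atlas.n_regions + 1)])
    voxel_net = region_net[atlas.labels]
    for net in networks:
        net_mask = common & (voxel_net == net)
        if net_mask.sum() < 3:
            continue
        gv = gold_map.d[net_mask]
        for si, m in enumerate(study_maps):
            rows.append({
                "study": si, "network": net,
                "rank_corr": stats.spearmanr(m.d[net_mask], gv).statistic,
            })
    return corrs, pd.DataFrame(rows)


def topography_reliability(
    study_maps: list, mask: np.ndarray | None = None
) -> ICCResult:
    """ICC(C,1) of d maps with voxels as units, studies as raters."""
    if len(study_maps) < 2:
        raise ValueError("need at least 2 study maps")
    common = _common_mask(study_maps, mask=mask)
    ratings = np.column_stack([m.d[common] for m in study_maps])
    return icc_c1(ratings)
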