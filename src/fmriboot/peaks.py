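"""Peak localization: TFCE enhancement, permutation FWE, peak matching.

Study-level peaks are extracted from threshold-free cluster-enhanced
z-maps after familywise-error thresholding by the max-statistic sign-flip
permutation test (one-sample design).  Gold-standard peaks come from the
raw group t-map.  Validity is the proportion of studies with a peak
inside spheres of fixed radii around each gold peak; reliability is the
distribution of pairwise distances between the study peaks matched to
each gold peak.

Conventions (positive-contrast): negative statistic values receive a
TFCE score of 0, and the permutation threshold removes voxels with
negative activation.  Peaks use strict inequality over the in-bounds
26-neighbourhood, so plateaus and constant maps yield no peaks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "FweResult",
    "tfce_transform",
    "t_to_z",
    "permutation_fwe",
    "local_maxima_mask",
    "find_local_maxima",
    "select_top_gold_peaks",
    "peak_validity",
    "peak_reliability",
]

RADII_MM = (2.0, 4.0, 8.0, 10.0, 20.0)

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)
_FOOTPRINT26 = _STRUCT26.copy()
_FOOTPRINT26[1, 1, 1] = False


@dataclass
class FweResult:
    """Permutation-thresholded enhanced map plus its null distribution."""

    z_map: np.ndarray  # TFCE-enhanced observed map, thresholded
    enhanced: np.ndarray  # TFCE-enhanced observed map, unthresholded
    threshold: float
    null_max_distribution: np.ndarray  # sorted null maxima
    n_perms: int
    exhaustive: bool


def tfce_transform(
    stat_map: np.ndarray,
    E: float = 0.5,
    H: float = 2.0,
    dh: float | None = None,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a 3-D statistic map.

    For each voxel the enhanced value is the threshold integral
    sum_h extent(h)^E * h^H * dh over thresholds ``h`` from ``dh`` to the
    map maximum, where extent(h) is the size of the 26-connected
    supra-threshold component containing the voxel.  ``dh`` defaults to
    1/100 of the positive map range.  Voxels with non-positive values get
    an enhanced value of 0 (positive-contrast convention).
    """
    stat_map = np.asarray(stat_map, dtype=float)
    if not np.all(np.isfinite(stat_map)):
        raise ValueError("stat_map must be finite")
    hmax = stat_map.max()
    out = np.zeros_like(stat_map)
    if hmax <= 0:
        return out
    if dh is None:
        dh = hmax / 100.0
    if dh <= 0:
        raise ValueError("dh must be positive")
    if dh > hmax:
        raise ValueError("dh exceeds the positive range of the map")
    flat = out.ravel()
    h = dh
    while h <= hmax + 1e-12:
        supra = stat_map >= h
        lab, n_comp = ndimage.label(supra, structure=_STRUCT26)
        if n_comp == 0:
            break
        lab_flat = lab.ravel()
        sizes = np.bincount(lab_flat)
        incr = (sizes**E) * (h**H) * dh
        incr[0] = 0.0  # background contributes nothing
        flat += incr[lab_flat]
        h += dh
    return out


def t_to_z(t: np.ndarray, df: int) -> np.ndarray:
    """Quantile-match t(df) values onto the standard normal scale.

    Uses upper-tail survival functions for positive values and lower-tail
    CDFs for negative ones so extreme statistics convert stably.
    """
    t = np.asarray(t, dtype=float)
    z = np.empty_like(t)
    pos = t >= 0
    z[pos] = stats.norm.isf(stats.t.sf(t[pos], df))
    z[~pos] = stats.norm.ppf(stats.t.cdf(t[~pos], df))
    return z


def _sign_flip_matrix(n_subjects: int, n_perms: int, rng) -> tuple[np.ndarray, bool]:
    """Sign-flip designs: exhaustive when 2^n fits inside n_perms.

    Row 0 is always the identity (all-ones) relabelling, so the observed
    statistic is part of the null distribution.
    """
    if 2**n_subjects <= n_perms:
        combos = np.array(list(itertools.product((1.0, -1.0), repeat=n_subjects)))
        return combos, True
    signs = rng.choice([1.0, -1.0], size=(n_perms, n_subjects))
    signs[0] = 1.0
    return signs, False


def permutation_fwe(
    maps,
    alpha: float = 0.05,
    n_perms: int = 1000,
    seed: int | None = None,
    E: float = 0.5,
    H: float = 2.0,
    dh_steps: int = 100,
) -> FweResult:
    """Max-statistic sign-flip FWE threshold for TFCE-enhanced z-maps.

    Each permutation flips the sign of every subject's map independently,
    recomputes the group one-sample t-map, converts it to z, applies TFCE,
    and records the map maximum.  The threshold is the (1 - alpha)
    quantile of the null maxima; observed voxels at or below it (which
    includes all voxels with negative activation, whose TFCE score is 0)
    are removed.  When the full 2^n enumeration is no larger than
    ``n_perms`` it is used instead of Monte-Carlo draws.
    """
    data = np.asarray(maps.data if hasattr(maps, "data") else maps, dtype=float)
    n = data.shape[0]
    shape = data.shape[1:]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if n_perms < 100:
        raise ValueError("n_perms must be >= 100")
    rng = np.random.default_rng(seed)
    X = data.reshape(n, -1)
    df = n - 1
    ssq = np.sum(X**2, axis=0)

    signs, exhaustive = _sign_flip_matrix(n, n_perms, rng)
    means = signs @ X / n
    # sign flips leave per-subject squares unchanged, so the sample
    # variance for every flip comes from the shared sum of squares
    var = np.maximum(ssq - n * means**2, 0.0) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tmats = means / np.sqrt(var / n)
    tmats = np.nan_to_num(tmats, nan=0.0, posinf=0.0, neginf=0.0)

    obs_z = t_to_z(tmats[0], df).reshape(shape)
    # fix the TFCE step height from the observed map so all permutations
    # are enhanced on the same scale; maps whose range falls below one
    # step fall back to their own (finer) step
    obs_max = obs_z.max()
    dh = obs_max / dh_steps if obs_max > 0 else None

    null_max = np.empty(len(signs))
    enhanced = None
    for i in range(len(signs)):
        z = t_to_z(tmats[i], df).reshape(shape)
        zmax = z.max()
        if zmax <= 0:
            enh = np.zeros(shape)
        else:
            step = dh if (dh is not None and dh <= zmax) else zmax / dh_steps
            enh = tfce_transform(z, E=E, H=H, dh=step)
        null_max[i] = enh.max()
        if i == 0:
            enhanced = enh
    null_max.sort()
    threshold = float(np.quantile(null_max, 1.0 - alpha, method="higher"))
    z_map = np.where(enhanced > threshold, enhanced, 0.0)
    return FweResult(z_map=z_map, enhanced=enhanced, threshold=threshold,
                     null_max_distribution=null_max, n_perms=len(signs),
                     exhaustive=exhaustive)


# ---------------------------------------------------------------------------
# peaks


def local_maxima_mask(arr: np.ndarray) -> np.ndarray:
    """Voxels strictly greater than all in-bounds 26-neighbours."""
    arr = np.asarray(arr, dtype=float)
    neigh_max = ndimage.maximum_filter(
        arr, footprint=_FOOTPRINT26, mode="constant", cval=-np.inf)
    return arr > neigh_max


def find_local_maxima(
    stat_map: np.ndarray,
    min_height: float = 0.0,
    voxel_size_mm: float = 1.0,
    atlas=None,
    gold_d_map: np.ndarray | None = None,
) -> pd.DataFrame:
    """Table of strict 26-neighbour local maxima at or above ``min_height``.

    Columns: i, j, k (grid), x_mm, y_mm, z_mm (grid * voxel size under the
    identity affine), height, region_id (0 when no atlas given) and gold_d
    (NaN when no gold effect map given).  Sorted by descending height.
    """
    stat_map = np.asarray(stat_map, dtype=float)
    if not np.all(np.isfinite(stat_map)):
        raise ValueError("stat_map must be finite")
    mask = local_maxima_mask(stat_map) & (stat_map >= min_height)
    ijk = np.argwhere(mask)
    heights = stat_map[mask]
    order = np.argsort(-heights, kind="stable")
    ijk = ijk[order]
    heights = heights[order]
    table = pd.DataFrame({
        "i": ijk[:, 0] if len(ijk) else np.array([], dtype=int),
        "j": ijk[:, 1] if len(ijk) else np.array([], dtype=int),
        "k": ijk[:, 2] if len(ijk) else np.array([], dtype=int),
    })
    for ax, col in enumerate(("x_mm", "y_mm", "z_mm")):
        table[col] = (ijk[:, ax] * voxel_size_mm) if len(ijk) else np.array([])
    table["height"] = heights
    if atlas is not None:
        table["region_id"] = (atlas.labels[tuple(ijk.T)] if len(ijk)
                              else np.array([], dtype=int))
    else:
        table["region_id"] = np.zeros(len(table), dtype=int)
    if gold_d_map is not None and len(ijk):
        table["gold_d"] = np.asarray(gold_d_map)[tuple(ijk.T)]
    else:
        table["gold_d"] = np.full(len(table), np.nan)
    return table


def select_top_gold_peaks(
    gold_t_map: np.ndarray,
    atlas,
    k: int = 10,
    voxel_size_mm: float | None = None,
    gold_d_map: np.ndarray | None = None,
):
    """Top-k positive gold peaks, at most one (the tallest) per region.

    Operates on the raw, unthresholded group t-map.  Returns
    ``(peak_table, short)`` where ``short`` flags that fewer than ``k``
    qualifying peaks exist (all of them are then returned).
    """
    if voxel_size_mm is None:
        voxel_size_mm = atlas.voxel_size_mm
    peaks = find_local_maxima(gold_t_map, min_height=np.finfo(float).tiny,
                              voxel_size_mm=voxel_size_mm, atlas=atlas,
                              gold_d_map=gold_d_map)
    peaks = peaks[peaks["height"] > 0]
    # tallest peak per region; table is height-sorted so first wins
    peaks = peaks.drop_duplicates(subset="region_id", keep="first")
    short = len(peaks) < k
    return peaks.head(k).reset_index(drop=True), short


def _peak_coords_mm(table: pd.DataFrame) -> np.ndarray:
    return table[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)


def peak_validity(
    study_peaks: list,
    gold_peaks: pd.DataFrame,
    radii_mm=RADII_MM,
) -> pd.DataFrame:
    """Proportion of studies with any peak inside each gold-peak sphere.

    Studies with no supra-threshold peaks stay in the denominator (they
    cannot contribute a hit at any radius) and their count is reported in
    the ``n_empty_studies`` column.  Proportions are nondecreasing in the
    radius by construction.
    """
    gold_xyz = _peak_coords_mm(gold_peaks)
    n_studies = len(study_peaks)
    n_empty = sum(1 for t in study_peaks if len(t) == 0)
    rows = []
    for g, gxyz in enumerate(gold_xyz):
        for radius in radii_mm:
            hits = 0
            for t in study_peaks:
                if len(t) == 0:
                    continue
                dist = np.linalg.norm(_peak_coords_mm(t) - gxyz, axis=1)
                if np.any(dist <= radius):
                    hits += 1
            rows.append({
                "gold_peak": g,
                "region_id": int(gold_peaks["region_id"].iloc[g]),
                "gold_height": float(gold_peaks["height"].iloc[g]),
                "gold_d": float(gold_peaks["gold_d"].iloc[g]),
                "radius_mm": radius,
                "proportion": hits / n_studies if n_studies else np.nan,
                "n_studies": n_studies,
                "n_empty_studies": n_empty,
            })
    return pd.DataFrame(rows)


def match_peaks(study_peaks: pd.DataFrame, gold_peaks: pd.DataFrame) -> np.ndarray:
    """mm coordinates of the study peak nearest each gold peak (NaN if none)."""
    gold_xyz = _peak_coords_mm(gold_peaks)
    out = np.full((len(gold_xyz), 3), np.nan)
    if len(study_peaks) == 0:
        return out
    sxyz = _peak_coords_mm(study_peaks)
    for g, gxyz in enumerate(gold_xyz):
        d = np.linalg.norm(sxyz - gxyz, axis=1)
        out[g] = sxyz[np.argmin(d)]
    return out


def peak_reliability(
    study_peaks: list,
    gold_peaks: pd.DataFrame,
    percentiles=(50.0, 75.0, 90.0),
) -> pd.DataFrame:
    """Pairwise distances between the study peaks matched to each gold peak.

    For every gold peak, each study contributes its nearest peak; all
    pairwise inter-study distances of these matched peaks are summarised
    by percentiles.  Studies without any peak are excluded and counted.
    """
    matched = np.stack([match_peaks(t, gold_peaks) for t in study_peaks])
    rows = []
    for g in range(len(gold_peaks)):
        pts = matched[:, g, :]
        ok = np.all(np.isfinite(pts), axis=1)
        pts = pts[ok]
        n_excluded = int((~ok).sum())
        if len(pts) >= 2:
            diffs = pts[:, None, :] - pts[None, :, :]
            dists = np.linalg.norm(diffs, axis=-1)
            iu = np.triu_indices(len(pts), k=1)
            pair = dists[iu]
        else:
            pair = np.array([])
        row = {
            "gold_peak": g,
            "region_id": int(gold_peaks["region_id"].iloc[g]),
            "gold_d": float(gold_peaks["gold_d"].iloc[g]),
            "n_matched_studies": int(len(pts)),
            "n_excluded_studies": n_excluded,
            "mean_distance_mm": float(pair.mean()) if pair.size else np.nan,
        }
        for q in percentiles:
            row[f"p{int(q)}_distance_mm"] = (
                float(np.percentile(pair, q)) if pair.size else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
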