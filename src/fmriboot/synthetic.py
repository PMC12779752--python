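"""Seeded synthetic cohorts with known ground truth.

Every downstream analysis level is exercised against data generated here:
subject-level contrast maps built from a smooth true-effect field plus
i.i.d. Gaussian subject noise, a cuboid parcellation with network labels,
and a connectome cohort in which a scalar trait is linearly predictable
from a sparse set of connectivity edges at a configurable population R².

The noise model is deliberately the simplest one for which the per-voxel
population Cohen's d exactly equals the configured true-effect field:
subject map = d_true * noise_sd + N(0, noise_sd) i.i.d. across subjects
and voxels.  Real contrast maps have spatially correlated noise; that is
out of scope here and documented as such.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

__all__ = [
    "GridAtlas",
    "TrueEffectField",
    "SubjectMapSet",
    "ConnectomeCohort",
    "make_grid_atlas",
    "make_effect_field",
    "make_mixture_field",
    "simulate_contrast_maps",
    "simulate_connectome_cohort",
    "ground_truth_summary",
    "save_maps_nifti",
    "save_atlas_nifti",
    "save_trait_tsv",
]

#: Peak Cohen's d used for the four conventional effect-size classes when
#: building mixture fields.
CLASS_PEAK_D = {"negligible": 0.1, "small": 0.35, "medium": 0.65, "large": 1.0}

N_CONFOUNDS = 24  # synthetic stand-in for 24 motion parameters


@dataclass
class GridAtlas:
    """Integer parcellation of a 3-D grid; label 0 is background."""

    labels: np.ndarray
    n_regions: int
    network_of: dict
    voxel_size_mm: float

    @property
    def shape(self):
        return self.labels.shape

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    def region_voxels(self, region_id: int) -> np.ndarray:
        return np.argwhere(self.labels == region_id)


@dataclass
class TrueEffectField:
    """Per-voxel true Cohen's d plus the blob parameters that produced it."""

    d_true: np.ndarray
    blob_centers: np.ndarray  # (n_blobs, 3) grid coordinates
    blob_peak_d: np.ndarray
    blob_sigma_mm: np.ndarray
    voxel_size_mm: float


@dataclass
class SubjectMapSet:
    """Per-subject 3-D contrast maps on a common grid."""

    data: np.ndarray  # (n_subjects, nx, ny, nz)
    mask: np.ndarray
    voxel_size_mm: float
    subject_ids: np.ndarray

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self):
        return self.data.shape[1:]

    def subset(self, indices) -> "SubjectMapSet":
        """Select subjects by positional index (repeats allowed)."""
        indices = np.asarray(indices)
        return SubjectMapSet(
            data=self.data[indices],
            mask=self.mask,
            voxel_size_mm=self.voxel_size_mm,
            subject_ids=self.subject_ids[indices],
        )


@dataclass
class ConnectomeCohort:
    """Per-subject multivariate time series with a partly predictable trait."""

    timeseries: np.ndarray  # (n_subjects, T, p)
    confounds: np.ndarray  # (n_subjects, T, 24)
    trait: np.ndarray
    true_weights: np.ndarray  # length p(p-1)/2, nonzero on causal edges
    target_r2: float
    edge_index: np.ndarray  # (n_edges, 2) with i > j
    latent: np.ndarray = dc_field(default=None, repr=False)
    subject_ids: np.ndarray = dc_field(default=None)

    @property
    def n_subjects(self) -> int:
        return self.timeseries.shape[0]


# ---------------------------------------------------------------------------
# parcellation


def _bisect_boxes(box, k):
    """Recursively split an index box into k contiguous cuboid blocks."""
    if k == 1:
        return [box]
    k1 = k // 2
    k2 = k - k1
    lengths = [hi - lo for lo, hi in box]
    axis = int(np.argmax(lengths))
    lo, hi = box[axis]
    cut = lo + max(1, min(hi - lo - 1, round((hi - lo) * k1 / k)))
    left = list(box)
    right = list(box)
    left[axis] = (lo, cut)
    right[axis] = (cut, hi)
    return _bisect_boxes(tuple(left), k1) + _bisect_boxes(tuple(right), k2)


def make_grid_atlas(
    shape,
    n_regions: int,
    voxel_size_mm: float = 2.0,
    seed: int | None = None,
    n_networks: int = 7,
) -> GridAtlas:
    """Partition a full-grid mask into contiguous cuboid regions.

    Regions are produced by recursive bisection of the grid along its
    longest axis, so e.g. a 6x6x6 grid with 8 regions yields the eight
    3x3x3 octants.  Networks (a stand-in for the seven canonical
    resting-state networks) are assigned round-robin by region id.  The
    construction is deterministic; ``seed`` is accepted for interface
    symmetry with the other generators.
    """
    shape = tuple(int(s) for s in shape)
    if any(s <= 0 for s in shape):
        raise ValueError("grid shape must have positive dimensions")
    n_voxels = int(np.prod(shape))
    if not (1 <= n_regions <= n_voxels):
        raise ValueError("n_regions must be between 1 and the number of voxels")
    labels = np.zeros(shape, dtype=np.int32)
    boxes = _bisect_boxes(tuple((0, s) for s in shape), n_regions)
    for rid, ((x0, x1), (y0, y1), (z0, z1)) in enumerate(boxes, start=1):
        labels[x0:x1, y0:y1, z0:z1] = rid
    if np.any(labels == 0):  # every voxel must belong to a region
        raise RuntimeError("bisection failed to cover the grid")
    network_of = {r: f"net{(r - 1) % n_networks + 1}" for r in range(1, n_regions + 1)}
    return GridAtlas(labels=labels, n_regions=n_regions,
                     network_of=network_of, voxel_size_mm=float(voxel_size_mm))


# ---------------------------------------------------------------------------
# true-effect fields and contrast maps


def _gaussian_blob(shape, center, peak, sigma_mm, voxel_size_mm):
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center)) * voxel_size_mm**2
    return peak * np.exp(-d2 / (2.0 * sigma_mm**2))


def make_effect_field(
    shape,
    blob_centers,
    blob_peak_d,
    blob_sigma_mm,
    voxel_size_mm: float = 2.0,
) -> TrueEffectField:
    """Sum of isotropic Gaussian blobs as a true Cohen's d field.

    Coordinates are grid indices; the blob width ``blob_sigma_mm`` is in
    millimetres under an identity affine scaled by ``voxel_size_mm``.
    """
    shape = tuple(int(s) for s in shape)
    centers = np.atleast_2d(np.asarray(blob_centers, dtype=float))
    peaks = np.broadcast_to(np.asarray(blob_peak_d, dtype=float), (centers.shape[0],))
    sigmas = np.broadcast_to(np.asarray(blob_sigma_mm, dtype=float), (centers.shape[0],))
    d_true = np.zeros(shape)
    for c, pk, sg in zip(centers, peaks, sigmas):
        d_true += _gaussian_blob(shape, c, pk, sg, voxel_size_mm)
    return TrueEffectField(d_true=d_true, blob_centers=centers,
                           blob_peak_d=np.array(peaks), blob_sigma_mm=np.array(sigmas),
                           voxel_size_mm=float(voxel_size_mm))


def make_mixture_field(
    shape,
    n_per_class=(1, 1, 1, 1),
    blob_sigma_mm: float = 6.0,
    voxel_size_mm: float = 2.0,
    seed: int | None = None,
    min_separation_mm: float = 20.0,
) -> TrueEffectField:
    """Effect field mixing blobs of the four conventional effect classes.

    ``n_per_class`` gives the number of blobs with negligible / small /
    medium / large peak d (0.1, 0.35, 0.65, 1.0).  Centers are drawn
    uniformly on interior grid points subject to a minimum pairwise
    separation so blob peaks stay distinct.
    """
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in shape)
    peaks = []
    for cls, n_cls in zip(CLASS_PEAK_D.values(), n_per_class):
        peaks.extend([cls] * n_cls)
    margin = max(2, int(np.ceil(2 * blob_sigma_mm / voxel_size_mm / 2)))
    centers = []
    attempts = 0
    while len(centers) < len(peaks):
        cand = np.array([rng.integers(margin, s - margin) for s in shape], dtype=float)
        if all(np.linalg.norm((cand - c) * voxel_size_mm) >= min_separation_mm
               for c in centers):
            centers.append(cand)
        attempts += 1
        if attempts > 10000:
            raise RuntimeError("could not place blobs with the requested separation")
    return make_effect_field(shape, np.array(centers), peaks,
                             blob_sigma_mm, voxel_size_mm)


def simulate_contrast_maps(
    atlas: GridAtlas,
    field: TrueEffectField,
    n_subjects: int,
    noise_sd: float = 1.0,
    seed: int | None = None,
    jitter_sd_mm: float = 0.0,
) -> SubjectMapSet:
    """Simulate per-subject contrast maps with exact population Cohen's d.

    Each subject's map is ``field.d_true * noise_sd`` plus i.i.d.
    ``N(0, noise_sd)`` noise per voxel, so the across-subject mean over sd
    equals ``d_true`` exactly in the population.  ``jitter_sd_mm`` > 0
    displaces each subject's blob centers by isotropic Gaussian jitter to
    emulate across-participant variation in peak location (default off).
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if atlas.shape != field.d_true.shape:
        raise ValueError("atlas and effect field grids differ")
    rng = np.random.default_rng(seed)
    shape = field.d_true.shape
    data = np.empty((n_subjects,) + shape)
    if jitter_sd_mm > 0:
        jit_vox = jitter_sd_mm / field.voxel_size_mm
        for s in range(n_subjects):
            centers = field.blob_centers + rng.normal(
                0, jit_vox, size=field.blob_centers.shape)
            subj_field = make_effect_field(
                shape, centers, field.blob_peak_d, field.blob_sigma_mm,
                field.voxel_size_mm)
            data[s] = subj_field.d_true * noise_sd
    else:
        data[:] = field.d_true * noise_sd
    data += rng.normal(0.0, noise_sd, size=data.shape)
    return SubjectMapSet(data=data, mask=atlas.mask,
                         voxel_size_mm=field.voxel_size_mm,
                         subject_ids=np.arange(n_subjects))


# ---------------------------------------------------------------------------
# connectome cohort


def _nearest_correlation(c: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues and renormalise to unit diagonal."""
    w, v = np.linalg.eigh(c)
    if w.min() > 1e-8:
        return c
    w = np.clip(w, 1e-6, None)
    c = (v * w) @ v.T
    d = np.sqrt(np.diag(c))
    return c / np.outer(d, d)


def simulate_connectome_cohort(
    n_subjects: int,
    p_regions: int = 100,
    T: int = 300,
    n_causal: int = 10,
    target_r2: float = 0.25,
    seed: int | None = None,
    edge_slope: float = 0.25,
    base_r: float = 0.1,
) -> ConnectomeCohort:
    """Cohort whose trait is linearly predictable from sparse edges.

    A latent score z ~ N(0,1) per subject shifts the population correlation
    of ``n_causal`` randomly chosen edges by ``edge_slope * z`` (sign drawn
    at random per edge) around ``base_r``; the remaining edges are zero.
    Time series of length ``T`` are drawn from the subject-specific
    correlation matrix.  The trait is
    ``sqrt(target_r2) * z + sqrt(1 - target_r2) * noise`` so the population
    variance explained by the true edge values is exactly ``target_r2``.
    24 smooth random-walk confound columns are returned per subject.
    """
    n_edges = p_regions * (p_regions - 1) // 2
    if not (0 <= target_r2 < 1):
        raise ValueError("target_r2 must lie in [0, 1)")
    if n_causal > n_edges:
        raise ValueError("n_causal exceeds the number of edges")
    if T < 4:
        raise ValueError("T must be at least 4")
    rng = np.random.default_rng(seed)
    rows, cols = np.tril_indices(p_regions, -1)
    causal_pos = rng.choice(n_edges, size=n_causal, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_causal)
    true_weights = np.zeros(n_edges)
    true_weights[causal_pos] = signs * edge_slope

    z = rng.standard_normal(n_subjects)
    noise = rng.standard_normal(n_subjects)
    trait = np.sqrt(target_r2) * z + np.sqrt(1.0 - target_r2) * noise

    ts = np.empty((n_subjects, T, p_regions))
    conf = np.empty((n_subjects, T, N_CONFOUNDS))
    from scipy.ndimage import gaussian_filter1d  # local: only used here

    for s in range(n_subjects):
        corr = np.eye(p_regions)
        r = np.clip(base_r + true_weights[causal_pos] * z[s], -0.95, 0.95)
        corr[rows[causal_pos], cols[causal_pos]] = r
        corr[cols[causal_pos], rows[causal_pos]] = r
        corr = _nearest_correlation(corr)
        chol = np.linalg.cholesky(corr)
        ts[s] = rng.standard_normal((T, p_regions)) @ chol.T
        walks = np.cumsum(rng.standard_normal((T, N_CONFOUNDS)), axis=0)
        walks = gaussian_filter1d(walks, sigma=3.0, axis=0)
        conf[s] = (walks - walks.mean(axis=0)) / (walks.std(axis=0) + 1e-12)

    return ConnectomeCohort(
        timeseries=ts, confounds=conf, trait=trait, true_weights=true_weights,
        target_r2=float(target_r2),
        edge_index=np.column_stack([rows, cols]),
        latent=z, subject_ids=np.arange(n_subjects),
    )


# ---------------------------------------------------------------------------
# ground truth


def ground_truth_summary(field: TrueEffectField, atlas: GridAtlas):
    """True regional effect sizes and true peak list of an effect field.

    Returns ``(regional_d, peak_table)`` where ``regional_d[r-1]`` is the
    mean of ``d_true`` over region r and ``peak_table`` lists the strict
    26-neighbour local maxima of the field (a constant field has none).
    """
    if field.d_true.shape != atlas.shape:
        raise ValueError("field and atlas grids differ")
    from .peaks import find_local_maxima  # deferred: peaks has no dep on us

    labels = atlas.labels.ravel()
    vals = field.d_true.ravel()
    sums = np.bincount(labels, weights=vals, minlength=atlas.n_regions + 1)
    counts = np.bincount(labels, minlength=atlas.n_regions + 1)
    regional_d = sums[1:] / counts[1:]
    peak_table = find_local_maxima(
        field.d_true, min_height=1e-12,
        voxel_size_mm=field.voxel_size_mm, atlas=atlas)
    return regional_d, peak_table


# ---------------------------------------------------------------------------
# on-disk representations


def _affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_mm
    return aff


def save_maps_nifti(mapset: SubjectMapSet, path) -> None:
    """Write subject maps as a 4-D NIfTI (subjects along the 4th axis)."""
    import nibabel as nib

    img = nib.Nifti1Image(np.moveaxis(mapset.data, 0, -1).astype(np.float32),
                          _affine(mapset.voxel_size_mm))
    nib.save(img, str(path))


def save_volume_nifti(volume: np.ndarray, voxel_size_mm: float, path) -> None:
    """Write a single 3-D volume (e.g. an enhanced statistic map)."""
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32),
                          _affine(voxel_size_mm))
    nib.save(img, str(path))


def save_atlas_nifti(atlas: GridAtlas, path) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(atlas.labels.astype(np.int16), _affine(atlas.voxel_size_mm))
    nib.save(img, str(path))


def save_trait_tsv(cohort: ConnectomeCohort, path) -> None:
    ids = cohort.subject_ids
    if ids is None:
        ids = np.arange(cohort.n_subjects)
    pd.DataFrame({"subject_id": ids, "trait": cohort.trait}).to_csv(
        path, sep="\t", index=False)


def save_field_config(field: TrueEffectField, path) -> None:
    """Persist the blob configuration as JSON for provenance."""
    cfg = {
        "blob_centers": field.blob_centers.tolist(),
        "blob_peak_d": field.blob_peak_d.tolist(),
        "blob_sigma_mm": field.blob_sigma_mm.tolist(),
        "voxel_size_mm": field.voxel_size_mm,
        "shape": list(field.d_true.shape),
    }
    with open(path, "w") as fh:
        json.dump(cfg, fh, indent=2)
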