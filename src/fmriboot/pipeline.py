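"""Config-driven orchestration of the full validity/reliability survey.

``run_survey`` wires the stages together: synthetic cohort generation,
gold standards on the full cohort, bootstrap pseudo-studies at each
sample size, the four analysis levels, and a tidy long-format report
(level, metric, unit, size, replicate, value, ci_low, ci_high, flag).
Every row is reproducible from the config and master seed alone.

Permutation-based peak analyses default to study sizes of 40 and below
(the permutation test dominates the cost); the cap is configurable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import peaks as peaks_mod
from . import prediction as pred_mod
from . import roi as roi_mod
from . import topography as topo_mod
from .resampling import StudyDesign, draw_bootstrap_studies, split_holdout
from .synthetic import (
    make_grid_atlas,
    make_mixture_field,
    simulate_connectome_cohort,
    simulate_contrast_maps,
)

__all__ = ["SurveyConfig", "ReliabilityReport", "run_survey",
           "write_report", "read_report", "config_hash"]

LEVELS = ("roi", "peaks", "topography", "prediction")

REPORT_COLUMNS = ("level", "metric", "unit", "size", "replicate",
                  "value", "ci_low", "ci_high", "flag")


@dataclass
class SurveyConfig:
    """All knobs of one survey run; every seed derives from ``seed``."""

    # cohort
    grid_shape: tuple = (16, 16, 16)
    n_regions: int = 32
    voxel_size_mm: float = 2.0
    n_population: int = 400
    noise_sd: float = 1.0
    blobs_per_class: tuple = (1, 1, 1, 1)
    blob_sigma_mm: float = 6.0
    blob_min_separation_mm: float = 20.0
    jitter_sd_mm: float = 0.0
    # connectome cohort
    p_regions: int = 20
    n_timepoints: int = 120
    n_causal: int = 5
    target_r2: float = 0.25
    tr_s: float = 1.0
    # survey design
    sizes: tuple = (20, 40, 60, 80, 100)
    n_boot: int = 100
    alpha: float = 0.05
    holdout_fraction: float = 0.2
    n_targets: int = 10
    radii_mm: tuple = (2.0, 4.0, 8.0, 10.0, 20.0)
    tfce_E: float = 0.5
    tfce_H: float = 2.0
    n_perms_fwe: int = 250
    n_perms_score: int = 1000
    peak_max_size: int = 40
    levels: tuple = LEVELS
    seed: int = 0

    def __post_init__(self):
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        self.sizes = tuple(int(s) for s in self.sizes)
        self.levels = tuple(self.levels)
        self.blobs_per_class = tuple(int(b) for b in self.blobs_per_class)
        self.radii_mm = tuple(float(r) for r in self.radii_mm)
        unknown = set(self.levels) - set(LEVELS)
        if unknown:
            raise ValueError(f"unknown level name(s): {sorted(unknown)}")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if any(s < 2 for s in self.sizes):
            raise ValueError("study sizes must be >= 2")
        if self.n_population < max(self.sizes):
            raise ValueError("population smaller than the largest study size")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SurveyConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SurveyConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def smoke(cls, seed: int = 0) -> "SurveyConfig":
        """A small configuration that exercises every level quickly."""
        return cls(grid_shape=(12, 12, 12), n_regions=8, n_population=60,
                   sizes=(10, 20), n_boot=10, n_perms_fwe=128,
                   n_perms_score=200, p_regions=10, n_timepoints=100,
                   n_causal=3, peak_max_size=20, blob_sigma_mm=4.0,
                   blob_min_separation_mm=8.0, seed=seed)


def config_hash(config: SurveyConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ReliabilityReport:
    """Tidy long-format survey results with full provenance."""

    table: pd.DataFrame
    config: dict
    config_hash: str

    def rows(self, level=None, metric=None) -> pd.DataFrame:
        t = self.table
        if level is not None:
            t = t[t["level"] == level]
        if metric is not None:
            t = t[t["metric"] == metric]
        return t


def _row(level, metric, unit, size, replicate, value,
         ci_low=np.nan, ci_high=np.nan, flag=""):
    return {"level": level, "metric": metric, "unit": str(unit),
            "size": int(size), "replicate": str(replicate),
            "value": float(value) if value is not None else np.nan,
            "ci_low": float(ci_low), "ci_high": float(ci_high), "flag": flag}


def _sub_seed(master: int, *key) -> int:
    ss = np.random.SeedSequence((int(master),) + tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] % (2**31))


def _icc_rows(icc, level, metric, size):
    flag = "degenerate" if icc.degenerate else ""
    val = icc.estimate if np.isfinite(icc.estimate) else np.nan
    return [_row(level, metric, "all", size, "aggregate", val,
                 icc.ci_low, icc.ci_high, flag)]


# ---------------------------------------------------------------------------
# per-level runners


def _run_roi(cfg, maps, atlas, samples, rows):
    regional = roi_mod.regional_means(maps, atlas)
    gold = roi_mod.activation_analysis(regional, alpha=cfg.alpha, hedges=False)
    targets = roi_mod.select_target_regions(gold, k=min(cfg.n_targets,
                                                        atlas.n_regions))
    by_size = {}
    for s in samples:
        idx = s.member_ids.astype(int)
        res = roi_mod.activation_analysis(regional[idx], alpha=cfg.alpha,
                                          hedges=True)
        by_size.setdefault(s.size, []).append(res)
    for size, studies in by_size.items():
        props, corrs = roi_mod.roi_validity(studies, gold, targets)
        for _, r in props.iterrows():
            rows.append(_row("roi", "proportion_significant",
                             f"region{int(r.region_id)}", size, "aggregate",
                             r.proportion_significant, r.hdi_low, r.hdi_high))
        for rep, c in enumerate(corrs):
            rows.append(_row("roi", "rank_corr_validity", "targets", size,
                             rep, c))
        bicc, dicc = roi_mod.roi_reliability(
            studies, seed=_sub_seed(cfg.seed, 1, size))
        rows.extend(_icc_rows(bicc, "roi", "icc_binary", size))
        rows.extend(_icc_rows(dicc, "roi", "icc_d", size))


def _run_peaks(cfg, maps, atlas, samples, rows):
    from .metrics import one_sample_t
    from .topography import effect_size_map

    t_map, _, _ = one_sample_t(maps.data.reshape(maps.n_subjects, -1))
    t_map = t_map.reshape(maps.grid_shape)
    gold_d = effect_size_map(maps, correct=False).d
    gold_peaks, short = peaks_mod.select_top_gold_peaks(
        t_map, atlas, k=cfg.n_targets, gold_d_map=gold_d)
    if short:
        rows.append(_row("peaks", "n_gold_peaks", "all", 0, "aggregate",
                         len(gold_peaks), flag="fewer_than_requested"))
    sizes = [s for s in cfg.sizes if s <= cfg.peak_max_size]
    by_size = {}
    for s in samples:
        if s.size not in sizes:
            continue
        sub = maps.subset(s.member_ids.astype(int))
        fwe = peaks_mod.permutation_fwe(
            sub, alpha=cfg.alpha, n_perms=cfg.n_perms_fwe,
            seed=_sub_seed(cfg.seed, 2, s.size, s.replicate_index),
            E=cfg.tfce_E, H=cfg.tfce_H)
        table = peaks_mod.find_local_maxima(
            fwe.z_map, min_height=np.finfo(float).tiny,
            voxel_size_mm=maps.voxel_size_mm, atlas=atlas)
        by_size.setdefault(s.size, []).append(table)
    for size, tables in by_size.items():
        validity = peaks_mod.peak_validity(tables, gold_peaks,
                                           radii_mm=cfg.radii_mm)
        for _, r in validity.iterrows():
            rows.append(_row("peaks", "proportion_within_radius",
                             f"peak{int(r.gold_peak)}_r{r.radius_mm:g}mm",
                             size, "aggregate", r.proportion))
        rel = peaks_mod.peak_reliability(tables, gold_peaks)
        for _, r in rel.iterrows():
            rows.append(_row("peaks", "pairwise_distance_p90",
                             f"peak{int(r.gold_peak)}", size, "aggregate",
                             r.p90_distance_mm))
            rows.append(_row("peaks", "pairwise_distance_mean",
                             f"peak{int(r.gold_peak)}", size, "aggregate",
                             r.mean_distance_mm))


def _run_topography(cfg, maps, atlas, samples, rows):
    gold_map = topo_mod.effect_size_map(maps, correct=False)
    by_size = {}
    for s in samples:
        sub = maps.subset(s.member_ids.astype(int))
        by_size.setdefault(s.size, []).append(
            topo_mod.effect_size_map(sub, correct=True))
    for size, studies in by_size.items():
        corrs, _ = topo_mod.topography_validity(studies, gold_map)
        for rep, c in enumerate(corrs):
            rows.append(_row("topography", "map_rank_corr", "mask", size,
                             rep, c))
        icc = topo_mod.topography_reliability(studies)
        rows.extend(_icc_rows(icc, "topography", "icc_map", size))


def _run_prediction(cfg, rows):
    cohort = simulate_connectome_cohort(
        n_subjects=cfg.n_population, p_regions=cfg.p_regions,
        T=cfg.n_timepoints, n_causal=cfg.n_causal,
        target_r2=cfg.target_r2, seed=_sub_seed(cfg.seed, 3))
    cleaned = [
        pred_mod.clean_timeseries(cohort.timeseries[s], cohort.confounds[s],
                                  tr_s=cfg.tr_s)
        for s in range(cohort.n_subjects)
    ]
    feats = pred_mod.connectivity_features(cleaned)
    ids = np.arange(cohort.n_subjects)
    train_ids, test_ids = split_holdout(ids, cfg.holdout_fraction,
                                        seed=_sub_seed(cfg.seed, 4))
    X_test = feats.matrix[test_ids]
    y_test = cohort.trait[test_ids]

    gold_model = pred_mod.fit_ridge_pipeline(feats.matrix[train_ids],
                                             cohort.trait[train_ids])
    gold_score = pred_mod.evaluate_model(
        gold_model, X_test, y_test, n_perms=cfg.n_perms_score,
        seed=_sub_seed(cfg.seed, 5))
    rows.append(_row("prediction", "gold_rank_corr", "test", len(train_ids),
                     "gold", gold_score.rank_corr))
    rows.append(_row("prediction", "gold_r2", "test", len(train_ids),
                     "gold", gold_score.r2_reported))

    # bootstrap studies never touch the holdout: drawn from train ids only
    design = StudyDesign(population_ids=train_ids, sizes=cfg.sizes,
                         n_boot=cfg.n_boot, seed=_sub_seed(cfg.seed, 6),
                         holdout_fraction=cfg.holdout_fraction)
    by_size = {}
    for s in draw_bootstrap_studies(design):
        idx = s.member_ids.astype(int)
        model = pred_mod.fit_ridge_pipeline(feats.matrix[idx],
                                            cohort.trait[idx])
        score = pred_mod.evaluate_model(
            model, X_test, y_test, n_perms=cfg.n_perms_score,
            seed=_sub_seed(cfg.seed, 7, s.size, s.replicate_index))
        by_size.setdefault(s.size, []).append((model, score))
        rep = s.replicate_index
        flag = "degenerate" if score.degenerate else ""
        rows.append(_row("prediction", "rank_corr_test", "test", s.size, rep,
                         score.rank_corr, flag=flag))
        rows.append(_row("prediction", "r2_test", "test", s.size, rep,
                         score.r2_reported, flag=flag))
        rows.append(_row("prediction", "significant", "test", s.size, rep,
                         float(score.p_perm <= cfg.alpha)
                         if np.isfinite(score.p_perm) else np.nan, flag=flag))
    for size, pairs in by_size.items():
        models = [m for m, _ in pairs]
        coef_corr = pred_mod.model_validity(models, gold_model)
        for rep, c in enumerate(coef_corr):
            rows.append(_row("prediction", "coef_corr", "features", size,
                             rep, c))
        pred_icc, coef_icc = pred_mod.model_reliability(models, X_test)
        rows.extend(_icc_rows(pred_icc, "prediction", "icc_predictions", size))
        rows.extend(_icc_rows(coef_icc, "prediction", "icc_coefficients", size))


# ---------------------------------------------------------------------------
# orchestration


def build_cohort(cfg: SurveyConfig):
    """Atlas, true-effect field and population contrast maps for a config."""
    atlas = make_grid_atlas(cfg.grid_shape, cfg.n_regions,
                            voxel_size_mm=cfg.voxel_size_mm,
                            seed=_sub_seed(cfg.seed, 0, 0))
    field = make_mixture_field(cfg.grid_shape, n_per_class=cfg.blobs_per_class,
                               blob_sigma_mm=cfg.blob_sigma_mm,
                               voxel_size_mm=cfg.voxel_size_mm,
                               min_separation_mm=cfg.blob_min_separation_mm,
                               seed=_sub_seed(cfg.seed, 0, 1))
    maps = simulate_contrast_maps(atlas, field, cfg.n_population,
                                  noise_sd=cfg.noise_sd,
                                  seed=_sub_seed(cfg.seed, 0, 2),
                                  jitter_sd_mm=cfg.jitter_sd_mm)
    return atlas, field, maps


def run_survey(config: SurveyConfig) -> ReliabilityReport:
    """Execute the requested levels end to end for one configuration."""
    cfg = config
    rows: list[dict] = []
    need_maps = any(lv in cfg.levels for lv in ("roi", "peaks", "topography"))
    if need_maps:
        atlas, _, maps = build_cohort(cfg)
        design = StudyDesign(population_ids=np.arange(cfg.n_population),
                             sizes=cfg.sizes, n_boot=cfg.n_boot,
                             seed=cfg.seed,
                             holdout_fraction=cfg.holdout_fraction)
        samples = draw_bootstrap_studies(design)
    if "roi" in cfg.levels:
        _run_roi(cfg, maps, atlas, samples, rows)
    if "peaks" in cfg.levels:
        _run_peaks(cfg, maps, atlas, samples, rows)
    if "topography" in cfg.levels:
        _run_topography(cfg, maps, atlas, samples, rows)
    if "prediction" in cfg.levels:
        _run_prediction(cfg, rows)
    table = pd.DataFrame(rows, columns=list(REPORT_COLUMNS))
    return ReliabilityReport(table=table, config=cfg.to_dict(),
                             config_hash=config_hash(cfg))


def write_report(report: ReliabilityReport, path) -> None:
    """CSV table plus a JSON sidecar with config hash and seed provenance."""
    path = str(path)
    report.table.to_csv(path, index=False, float_format="%.10g")
    sidecar = {"config": report.config, "config_hash": report.config_hash,
               "seed": report.config.get("seed")}
    with open(path + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True, default=str)


def read_report(path) -> ReliabilityReport:
    path = str(path)
    table = pd.read_csv(path, dtype={"unit": str, "replicate": str,
                                     "flag": str}, keep_default_na=False,
                        na_values=[""])
    table["flag"] = table["flag"].fillna("")
    with open(path + ".json") as fh:
        sidecar = json.load(fh)
    return ReliabilityReport(table=table, config=sidecar["config"],
                             config_hash=sidecar["config_hash"])
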