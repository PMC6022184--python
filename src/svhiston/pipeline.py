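"""End-to-end pipeline: synthesize/load -> features -> train -> report.

A run directory caches each stage's outputs (cohort volumes + manifest,
feature CSVs, JSON report) so later stages can be recomputed from cached
features with identical results.  The resolved configuration and all seeds
are stored in the report for audit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classification import (
    make_splits,
    mcnemar_compare,
    mean_metrics,
    run_split_protocol,
    voxel_baseline,
)
from .histon_features import EXPANSE_MODES, HistonConfig, extract_feature_vector
from .io_volumes import read_manifest
from .slic3d import SlicParams
from .synthetic_phantoms import PhantomParams, SyntheticCohort, generate_cohort, materialize_cohort

logger = logging.getLogger(__name__)


def _strict_fields(cls, data: dict, section: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown config keys in '{section}': {sorted(unknown)}")
    return cls(**data)


@dataclasses.dataclass
class CohortConfig:
    n_ad: int = 20
    n_cn: int = 20
    grid_size: int = 48
    wm_radius: float = 10.0
    gm_radius: float = 16.0
    csf_radius: float = 20.0
    delta_gm: float = 0.2
    omega_ad: float = 3.0
    omega_cn: float = 1.0
    sigma: float = 0.02
    jitter: float = 0.05
    seed: int = 7

    def phantom_params(self) -> PhantomParams:
        return PhantomParams(
            grid_size=self.grid_size,
            wm_radius=self.wm_radius,
            gm_radius=self.gm_radius,
            csf_radius=self.csf_radius,
            delta_gm=self.delta_gm,
            omega_ad=self.omega_ad,
            omega_cn=self.omega_cn,
            sigma=self.sigma,
            jitter=self.jitter,
        )


@dataclasses.dataclass
class FeaturesConfig:
    levels: int = 256
    expanse_mode: str = "mean_of_sds"
    n_supervoxels: int = 300
    compactness: float = 10.0
    max_iterations: int = 10
    min_region_frac: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.expanse_mode not in EXPANSE_MODES:
            raise ValueError(f"expanse_mode must be one of {EXPANSE_MODES}")

    def slic_params(self) -> SlicParams:
        return SlicParams(
            n_supervoxels=self.n_supervoxels,
            compactness=self.compactness,
            max_iterations=self.max_iterations,
            min_region_frac=self.min_region_frac,
            seed=self.seed,
        )

    def histon_config(self) -> HistonConfig:
        return HistonConfig(levels=self.levels, expanse_mode=self.expanse_mode)


@dataclasses.dataclass
class ClassifyConfig:
    n_components: object = 5  # integer or "scree"
    kernel: str = "linear"
    cost: float = 1.0
    n_splits: int = 10
    test_frac: float = 0.2
    seed: int = 0
    compare_kernels: bool = False
    mcnemar_baseline: bool = False


@dataclasses.dataclass
class RunConfig:
    """Validated whole-pipeline configuration; unknown keys are rejected."""

    cohort: CohortConfig = dataclasses.field(default_factory=CohortConfig)
    features: FeaturesConfig = dataclasses.field(default_factory=FeaturesConfig)
    classify: ClassifyConfig = dataclasses.field(default_factory=ClassifyConfig)
    manifest: Optional[str] = None  # use an existing cohort instead of synthesis

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        unknown = set(data) - {"cohort", "features", "classify", "manifest"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(
            cohort=_strict_fields(CohortConfig, data.get("cohort", {}), "cohort"),
            features=_strict_fields(FeaturesConfig, data.get("features", {}), "features"),
            classify=_strict_fields(ClassifyConfig, data.get("classify", {}), "classify"),
            manifest=data.get("manifest"),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def as_dict(self) -> dict:
        return {
            "cohort": dataclasses.asdict(self.cohort),
            "features": dataclasses.asdict(self.features),
            "classify": dataclasses.asdict(self.classify),
            "manifest": self.manifest,
        }


def compute_features(subjects, features_cfg: FeaturesConfig):
    """Extract histon (and plain-histogram) vectors for every subject.

    Returns (histon matrix, histogram matrix, labels) with rows in subject
    order and 768 columns each.
    """
    slic_params = features_cfg.slic_params()
    histon_cfg = features_cfg.histon_config()
    histons, histograms, labels = [], [], []
    for s in subjects:
        t0 = time.perf_counter()
        feat = extract_feature_vector(s, slic_params, histon_cfg)
        logger.info("features %s (%s): %.2fs", s.subject_id, s.label,
                    time.perf_counter() - t0)
        histons.append(feat.vector)
        histograms.append(feat.histogram_vector)
        labels.append(s.label)
    return np.array(histons), np.array(histograms), np.array(labels)


def _features_frame(subjects, matrix) -> pd.DataFrame:
    cols = [f"f{i}" for i in range(matrix.shape[1])]
    df = pd.DataFrame(matrix, columns=cols)
    df.insert(0, "subject_id", [s.subject_id for s in subjects])
    df.insert(1, "label", [s.label for s in subjects])
    return df


def _flatten_gm(subjects) -> np.ndarray:
    """Flattened GM probability vectors (all voxels) for the voxel baseline."""
    rows = []
    for s in subjects:
        gm = s.load_volumes()["GM"]
        data = gm.data
        if gm.is_quantized:
            data = data / (gm.levels - 1)
        rows.append(np.asarray(data, dtype=np.float64).ravel())
    return np.array(rows)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute synth -> features -> train -> evaluate, caching per stage.

    Writes cohort volumes (unless a manifest is given), ``features.csv`` and
    ``histograms.csv``, and ``report.json`` with per-split metrics, means,
    the resolved config and, when requested, the kernel-comparison table and
    the McNemar comparison against the voxel baseline.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # stage 1: cohort
    if config.manifest is not None:
        manifest = Path(config.manifest)
        subjects = read_manifest(manifest)
    else:
        manifest = out_dir / "cohort" / "manifest.csv"
        if manifest.exists():
            logger.info("stage synth: cached cohort at %s", manifest)
            subjects = read_manifest(manifest)
        else:
            cohort = generate_cohort(
                config.cohort.n_ad, config.cohort.n_cn,
                config.cohort.phantom_params(), seed=config.cohort.seed,
            )
            manifest = materialize_cohort(cohort, out_dir / "cohort")
            subjects = read_manifest(manifest)

    # stage 2: features (cached)
    feat_path = out_dir / "features.csv"
    hist_path = out_dir / "histograms.csv"
    if feat_path.exists() and hist_path.exists():
        logger.info("stage features: cached at %s", feat_path)
        fdf = pd.read_csv(feat_path, dtype={"subject_id": str})
        hdf = pd.read_csv(hist_path, dtype={"subject_id": str})
        X = fdf.filter(regex=r"^f\d+$").to_numpy(dtype=np.float64)
        X_hist = hdf.filter(regex=r"^f\d+$").to_numpy(dtype=np.float64)
        labels = fdf["label"].to_numpy()
    else:
        X, X_hist, labels = compute_features(subjects, config.features)
        _features_frame(subjects, X).to_csv(feat_path, index=False)
        _features_frame(subjects, X_hist).to_csv(hist_path, index=False)

    # stage 3: splits + classification
    plan = make_splits(
        subjects, n_splits=config.classify.n_splits,
        test_frac=config.classify.test_frac, seed=config.classify.seed,
    )
    result = run_split_protocol(
        X, labels, plan,
        n_components=config.classify.n_components,
        kernel=config.classify.kernel, cost=config.classify.cost,
    )

    report = {
        "version": __version__,
        "config": config.as_dict(),
        "n_subjects": len(subjects),
        "per_split": [r.as_dict() for r in result["per_split"]],
        "mean": result["mean"],
    }

    if config.classify.compare_kernels:
        table = {}
        for kernel in ("linear", "polynomial", "radial"):
            res_k = run_split_protocol(
                X, labels, plan, n_components=config.classify.n_components,
                kernel=kernel, cost=config.classify.cost,
            )
            table[kernel] = res_k["mean"]
        report["kernel_comparison"] = table

    if config.classify.mcnemar_baseline:
        gm_X = _flatten_gm(subjects)
        per_split_mcnemar = []
        pooled = {"pred_a": [], "pred_b": [], "truth": []}
        baseline_reports = []
        for (train_idx, test_idx), preds in zip(plan.splits, result["predictions"]):
            base = voxel_baseline(
                gm_X[train_idx], labels[train_idx],
                gm_X[test_idx], labels[test_idx],
                seed=config.classify.seed,
            )
            baseline_reports.append(base["report"])
            mc = mcnemar_compare(preds["pred"], base["pred"], labels[test_idx])
            per_split_mcnemar.append(mc)
            pooled["pred_a"].extend(preds["pred"])
            pooled["pred_b"].extend(base["pred"])
            pooled["truth"].extend(labels[test_idx])
        report["voxel_baseline_mean"] = mean_metrics(baseline_reports)
        report["mcnemar_per_split"] = per_split_mcnemar
        report["mcnemar_pooled"] = mcnemar_compare(
            pooled["pred_a"], pooled["pred_b"], pooled["truth"]
        )

    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
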