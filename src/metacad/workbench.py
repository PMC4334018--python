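"""End-to-end experiment orchestration: simulate → extract → evaluate → classify.

Produces the study's report analogues: a per-feature binormal ROC table
with an AUC screening flag, a pairwise significance matrix over the
retained features, the feature correlation matrix, the fused-classifier
ROC, and on-line / off-line feature-set recommendations. Everything is
deterministic given the configuration (stage seeds are derived from the
master seed by fixed offsets).
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classifier as clf
from . import roc, synth
from .features import ANN_FEATURES, FEATURE_NAMES, FeatureConfig, extract_feature_vector

__all__ = [
    "DatasetConfig",
    "SegmentationConfig",
    "RocConfig",
    "ClassifierConfig",
    "ExperimentConfig",
    "ExperimentReport",
    "run_experiment",
    "build_feature_table",
    "recommend_feature_sets",
]

# Fixed per-stage seed offsets (kept small so derived seeds stay < 2^31).
_SEED_DATA = 11
_SEED_CLASSIFIER = 29


@dataclasses.dataclass(frozen=True)
class DatasetConfig:
    n_positive: int = 67
    n_negative: int = 133
    interphase_fraction: float = 0.8
    image_shape: tuple[int, int] = synth.DEFAULT_SHAPE
    scene_overrides: dict = dataclasses.field(default_factory=dict)


@dataclasses.dataclass(frozen=True)
class SegmentationConfig:
    method: str = "otsu"
    fixed_threshold: float | None = None
    connectivity: int = 8
    min_area: int = 20
    center_mode: str = "area_weighted"

    def feature_config(self) -> FeatureConfig:
        return FeatureConfig(
            method=self.method,
            fixed_threshold=self.fixed_threshold,
            connectivity=self.connectivity,
            min_area=self.min_area,
            center_mode=self.center_mode,
        )


@dataclasses.dataclass(frozen=True)
class RocConfig:
    n_categories: int = 10
    floor: float = 0.55
    comparison: str = "delong"
    corr_threshold: float = 0.5


@dataclasses.dataclass(frozen=True)
class ClassifierConfig:
    folds: int = 5
    hidden_units: int = 5


@dataclasses.dataclass(frozen=True)
class ExperimentConfig:
    dataset: DatasetConfig = DatasetConfig()
    segmentation: SegmentationConfig = SegmentationConfig()
    roc: RocConfig = RocConfig()
    classifier: ClassifierConfig = ClassifierConfig()
    seed: int = 0

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(_asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "ExperimentConfig":
        p = Path(source)
        raw = yaml.safe_load(p.read_text() if p.exists() else str(source)) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        ds = dict(raw.get("dataset", {}))
        if "image_shape" in ds:
            ds["image_shape"] = tuple(ds["image_shape"])
        if "scene_overrides" in ds:  # YAML reads tuples back as lists
            ds["scene_overrides"] = {
                k: tuple(v) if isinstance(v, list) else v
                for k, v in ds["scene_overrides"].items()
            }
        return cls(
            dataset=DatasetConfig(**ds),
            segmentation=SegmentationConfig(**raw.get("segmentation", {})),
            roc=RocConfig(**raw.get("roc", {})),
            classifier=ClassifierConfig(**raw.get("classifier", {})),
            seed=int(raw.get("seed", 0)),
        )


def _asdict(cfg: ExperimentConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["dataset"]["image_shape"] = list(d["dataset"]["image_shape"])
    return d


@dataclasses.dataclass
class ExperimentReport:
    config: ExperimentConfig
    feature_table: pd.DataFrame
    feature_rocs: pd.DataFrame  # feature, direction, a, b, auc, se, emp auc, retained
    retained: list[str]
    pvalues: pd.DataFrame
    correlations: pd.DataFrame
    fusion: clf.FusionEvaluation
    online_set: list[str]
    offline_set: list[str]
    config_hash: str


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def build_feature_table(config: ExperimentConfig) -> pd.DataFrame:
    """Simulate the dataset and extract the nine features per scene."""
    ds = config.dataset
    fc = config.segmentation.feature_config()
    rows = []
    for i, (spec, img, gt) in enumerate(
        synth.iter_dataset(
            ds.n_positive,
            ds.n_negative,
            ds.interphase_fraction,
            seed=config.seed + _SEED_DATA,
            image_shape=ds.image_shape,
            **ds.scene_overrides,
        )
    ):
        row = {
            "image_id": i,
            "scene_class": spec.scene_class,
            "label": gt.label,
        }
        row.update(extract_feature_vector(img, fc).as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def run_experiment(
    config: ExperimentConfig | None = None, out_dir: str | Path | None = None
) -> ExperimentReport:
    """Run every stage and (optionally) write the report tables as CSV."""
    config = config or ExperimentConfig()

    try:
        table = build_feature_table(config)
    except Exception as e:  # noqa: BLE001 - re-raise with stage context
        raise StageError("simulate/extract", e) from e

    labels = table["label"].to_numpy(int)
    try:
        fits, emp, directions = {}, {}, {}
        for name in FEATURE_NAMES:
            scores = table[name].to_numpy(float)
            direction = roc.choose_direction(scores, labels)
            data = roc.RatingData(scores[labels == 1], scores[labels == 0], direction)
            fits[name] = roc.fit_binormal(data, n_categories=config.roc.n_categories)
            emp[name] = roc.empirical_auc(data)
            directions[name] = direction
        retained = roc.screen_features(fits, floor=config.roc.floor)
    except roc.InsufficientDataError as e:
        raise StageError("evaluate", e) from e

    feature_rocs = pd.DataFrame(
        {
            "feature": list(FEATURE_NAMES),
            "direction": [directions[f] for f in FEATURE_NAMES],
            "a": [fits[f].a for f in FEATURE_NAMES],
            "b": [fits[f].b for f in FEATURE_NAMES],
            "auc": [fits[f].auc for f in FEATURE_NAMES],
            "se_auc": [fits[f].se_auc for f in FEATURE_NAMES],
            "empirical_auc": [emp[f] for f in FEATURE_NAMES],
            "converged": [fits[f].converged for f in FEATURE_NAMES],
            "retained": [f in retained for f in FEATURE_NAMES],
        }
    )

    pvalues = pd.DataFrame(np.ones((len(retained), len(retained))),
                           index=retained, columns=retained)
    for i, fi in enumerate(retained):
        for fj in retained[i + 1 :]:
            di = _rating(table, fi, directions[fi])
            dj = _rating(table, fj, directions[fj])
            res = roc.compare_auc_paired(di, dj, method=config.roc.comparison)
            pvalues.loc[fi, fj] = pvalues.loc[fj, fi] = res.p_value

    correlations = roc.feature_correlation(table, columns=list(FEATURE_NAMES))

    try:
        fusion = clf.evaluate_fusion(
            table,
            labels,
            cv_folds=config.classifier.folds,
            seed=config.seed + _SEED_CLASSIFIER,
            hidden_units=config.classifier.hidden_units,
            n_categories=config.roc.n_categories,
        )
    except (ValueError, roc.InsufficientDataError) as e:
        raise StageError("classify", e) from e

    aucs = {f: fits[f].auc for f in retained}
    online, offline = _recommend(aucs, correlations, config.roc.corr_threshold)

    report = ExperimentReport(
        config=config,
        feature_table=table,
        feature_rocs=feature_rocs,
        retained=retained,
        pvalues=pvalues,
        correlations=correlations,
        fusion=fusion,
        online_set=online,
        offline_set=offline,
        config_hash=hashlib.sha256(config.to_yaml().encode()).hexdigest()[:16],
    )
    if out_dir is not None:
        _write_report(report, Path(out_dir), fits)
    return report


def _rating(table: pd.DataFrame, feature: str, direction: str) -> roc.RatingData:
    labels = table["label"].to_numpy(int)
    scores = table[feature].to_numpy(float)
    return roc.RatingData(scores[labels == 1], scores[labels == 0], direction)


def recommend_feature_sets(report: ExperimentReport) -> tuple[list[str], list[str]]:
    """On-line set: the single best retained feature. Off-line set: the best
    feature plus the remaining retained features after dropping, from each
    correlated pair, the one with the lower AUC."""
    aucs = {f: float(report.feature_rocs.set_index("feature").loc[f, "auc"])
            for f in report.retained}
    return _recommend(aucs, report.correlations, report.config.roc.corr_threshold)


def _recommend(
    aucs: dict[str, float], corr: pd.DataFrame, threshold: float
) -> tuple[list[str], list[str]]:
    if not aucs:
        return [], []
    ordered = sorted(aucs, key=lambda f: -aucs[f])
    offline: list[str] = []
    for f in ordered:
        redundant = any(
            f in corr.index and g in corr.columns and abs(corr.loc[f, g]) >= threshold
            for g in offline
        )
        if not redundant:
            offline.append(f)
    return [ordered[0]], offline


def _write_report(report: ExperimentReport, out: Path, fits: dict) -> None:
    out.mkdir(parents=True, exist_ok=True)
    fmt = "%.6g"
    report.feature_table.to_csv(out / "feature_table.csv", index=False, float_format=fmt)
    report.feature_rocs.to_csv(out / "feature_rocs.csv", index=False, float_format=fmt)
    report.pvalues.to_csv(out / "pvalues.csv", float_format=fmt)
    report.correlations.to_csv(out / "correlations.csv", float_format=fmt)

    curves = []
    for name, fit in fits.items():
        c = roc.binormal_curve(fit)
        c.insert(0, "feature", name)
        curves.append(c)
    fused_curve = roc.binormal_curve(report.fusion.cv_fit)
    fused_curve.insert(0, "feature", "fused_cv")
    curves.append(fused_curve)
    pd.concat(curves, ignore_index=True).to_csv(
        out / "roc_curves.csv", index=False, float_format=fmt
    )

    cls_rows = pd.DataFrame(
        {
            "protocol": ["cross_validation", "resubstitution"],
            "auc": [report.fusion.cv_fit.auc, report.fusion.resub_fit.auc],
            "se_auc": [report.fusion.cv_fit.se_auc, report.fusion.resub_fit.se_auc],
            "empirical_auc": [
                report.fusion.cv_auc_empirical,
                report.fusion.resub_auc_empirical,
            ],
        }
    )
    cls_rows.to_csv(out / "classifier_roc.csv", index=False, float_format=fmt)

    rec = (
        "on-line feature set: " + ", ".join(report.online_set) + "\n"
        "off-line feature set: " + ", ".join(report.offline_set) + "\n"
    )
    (out / "recommendations.txt").write_text(rec)
    (out / "run_log.txt").write_text(
        "config_hash: " + report.config_hash + "\n---\n" + report.config.to_yaml()
    )
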