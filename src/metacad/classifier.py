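"""Two-level fused classifier for the off-line detection scheme.

Level one is a small feed-forward neural network that combines the average
region area, average region pixel intensity and the STD of the region
distance into a score in [0, 1] (0 = definitely unanalyzable, 1 =
definitely analyzable). Level two fuses that score with the min-max
normalized number of labeled regions by the minimum rule, so an image must
look analyzable to *both* the shape/intensity network and the region count
to receive a high final score.

Fixed combination rules assume their inputs share a scale: the region count
is min-max normalized against the training data, and the network output is
likewise rank-calibrated against its training-score distribution (empirical
CDF) before fusion.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from . import roc
from .features import ANN_FEATURES

__all__ = [
    "FusionModel",
    "FusedScore",
    "FusionEvaluation",
    "normalize_region_count",
    "train_ann",
    "min_rule_fuse",
    "evaluate_fusion",
]

SCHEMA_VERSION = 1


def normalize_region_count(count, bounds: tuple[float, float]):
    """Min-max normalize a region count to [0, 1], clipping outside the bounds.

    Degenerate bounds (min == max) carry no information: every count maps to
    a constant 0.5 (callers flag this via :attr:`FusionModel.count_degenerate`).
    """
    lo, hi = float(bounds[0]), float(bounds[1])
    count = np.asarray(count, float)
    if hi <= lo:
        out = np.full_like(count, 0.5)
    else:
        out = np.clip((count - lo) / (hi - lo), 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def train_ann(
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    hidden_units: int = 5,
    n_members: int = 5,
    alpha: float = 1e-2,
):
    """Train the level-one network: one hidden layer, sigmoid units.

    Features are standardized internally; cross-entropy is minimized with
    full-batch L-BFGS (the reliable choice at a few hundred rows and a
    handful of inputs). Because a tiny network on a small sample is
    sensitive to its random initialization, ``n_members`` independently
    initialized networks are trained and their output probabilities
    averaged; the whole procedure is deterministic given the seed.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    if len(X) < 20:
        raise ValueError("need >= 20 training rows")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    scaler = StandardScaler().fit(X)
    # The minimum rule can lower but never raise a score, so an under-scored
    # true positive is unrecoverable downstream: train on a class-balanced
    # sample (minority class oversampled to parity) to avoid the sensitivity
    # loss an imbalanced cross-entropy fit produces.
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    minority, majority = (pos, neg) if len(pos) < len(neg) else (neg, pos)
    if len(minority) < len(majority):
        reps = int(np.ceil(len(majority) / len(minority)))
        idx = np.concatenate([majority, np.tile(minority, reps)[: len(majority)]])
        idx.sort()
    else:
        idx = np.arange(len(y))
    Xb, yb = X[idx], y[idx]
    members = []
    for k in range(n_members):
        net = MLPClassifier(
            hidden_layer_sizes=(hidden_units,),
            activation="logistic",
            solver="lbfgs",
            max_iter=2000,
            alpha=alpha,
            random_state=seed * n_members + k,
        )
        net.fit(scaler.transform(Xb), yb)
        members.append(net)
    return scaler, members


@dataclasses.dataclass
class FusedScore:
    ann_score: float | np.ndarray
    norm_count: float | np.ndarray
    fused: float | np.ndarray


def min_rule_fuse(ann_score, norm_count) -> FusedScore:
    """Fuse the two level scores by the minimum rule."""
    ann_score = np.asarray(ann_score, float)
    norm_count = np.asarray(norm_count, float)
    for name, v in (("ann_score", ann_score), ("norm_count", norm_count)):
        if np.any((v < 0) | (v > 1)):
            raise ValueError(f"{name} must lie in [0, 1]")
    fused = np.minimum(ann_score, norm_count)
    if fused.ndim == 0:
        return FusedScore(float(ann_score), float(norm_count), float(fused))
    return FusedScore(ann_score, norm_count, fused)


@dataclasses.dataclass
class FusionModel:
    """Trained two-level model: network weights + count normalizer.

    The network forward pass is carried out directly from the stored weight
    matrices, so a serialized model predicts identically after a round trip.
    """

    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    weights: list[list[np.ndarray]]  # per ensemble member, per layer
    biases: list[list[np.ndarray]]
    count_bounds: tuple[float, float]
    count_degenerate: bool
    feature_names: tuple[str, ...]
    training_seed: int
    #: sorted raw network scores of the training images; the empirical CDF
    #: used to put the network output on the same [0, 1] scale as the count
    ann_calibration: np.ndarray | None = None

    @classmethod
    def fit(
        cls,
        table: pd.DataFrame,
        labels: np.ndarray,
        seed: int = 0,
        hidden_units: int = 5,
        feature_names: tuple[str, ...] = ANN_FEATURES,
    ) -> "FusionModel":
        X = table[list(feature_names)].to_numpy(float)
        scaler, members = train_ann(X, labels, seed=seed, hidden_units=hidden_units)
        counts = table["n_regions"].to_numpy(float)
        lo, hi = float(counts.min()), float(counts.max())
        model = cls(
            scaler_mean=scaler.mean_.copy(),
            scaler_scale=scaler.scale_.copy(),
            weights=[[w.copy() for w in m.coefs_] for m in members],
            biases=[[b.copy() for b in m.intercepts_] for m in members],
            count_bounds=(lo, hi),
            count_degenerate=bool(hi <= lo),
            feature_names=tuple(feature_names),
            training_seed=int(seed),
        )
        model.ann_calibration = np.sort(model._raw_ann_score(table))
        return model

    def _raw_ann_score(self, table: pd.DataFrame) -> np.ndarray:
        x0 = (table[list(self.feature_names)].to_numpy(float) - self.scaler_mean) / self.scaler_scale
        out = np.zeros(len(x0))
        for member_w, member_b in zip(self.weights, self.biases):
            x = x0
            for w, b in zip(member_w, member_b):
                x = _sigmoid(x @ w + b)
            out += x[:, 0]
        return out / len(self.weights)

    def ann_score(self, table: pd.DataFrame) -> np.ndarray:
        raw = self._raw_ann_score(table)
        if self.ann_calibration is None:
            return raw
        return np.searchsorted(self.ann_calibration, raw, side="right") / len(
            self.ann_calibration
        )

    def score(self, table: pd.DataFrame) -> pd.DataFrame:
        ann = self.ann_score(table)
        norm = normalize_region_count(table["n_regions"].to_numpy(float), self.count_bounds)
        fused = min_rule_fuse(ann, norm)
        return pd.DataFrame(
            {"ann_score": fused.ann_score, "norm_count": fused.norm_count, "fused": fused.fused}
        )

    # -- serialization ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        payload = {
            "schema_version": SCHEMA_VERSION,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "weights": [[w.tolist() for w in m] for m in self.weights],
            "biases": [[b.tolist() for b in m] for m in self.biases],
            "count_bounds": list(self.count_bounds),
            "count_degenerate": self.count_degenerate,
            "feature_names": list(self.feature_names),
            "training_seed": self.training_seed,
            "ann_calibration": (
                None if self.ann_calibration is None else self.ann_calibration.tolist()
            ),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "FusionModel":
        payload = json.loads(Path(path).read_text())
        if payload["schema_version"] != SCHEMA_VERSION:
            raise ValueError("unsupported model schema version")
        return cls(
            scaler_mean=np.array(payload["scaler_mean"]),
            scaler_scale=np.array(payload["scaler_scale"]),
            weights=[[np.array(w) for w in m] for m in payload["weights"]],
            biases=[[np.array(b) for b in m] for m in payload["biases"]],
            count_bounds=tuple(payload["count_bounds"]),
            count_degenerate=payload["count_degenerate"],
            feature_names=tuple(payload["feature_names"]),
            training_seed=payload["training_seed"],
            ann_calibration=(
                None
                if payload["ann_calibration"] is None
                else np.array(payload["ann_calibration"])
            ),
        )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclasses.dataclass
class FusionEvaluation:
    """Out-of-fold (cross-validated) and resubstitution fusion performance."""

    cv_scores: pd.DataFrame  # per-image ann/norm/fused scores, out of fold
    resub_scores: pd.DataFrame
    labels: np.ndarray
    cv_fit: roc.ROCFit
    resub_fit: roc.ROCFit
    cv_auc_empirical: float
    resub_auc_empirical: float


def evaluate_fusion(
    table: pd.DataFrame,
    labels: np.ndarray,
    cv_folds: int = 5,
    seed: int = 0,
    hidden_units: int = 5,
    n_categories: int = 10,
    cv_repeats: int = 3,
) -> FusionEvaluation:
    """Cross-validate the fused classifier and fit ROCs on its scores.

    Fold assignment is stratified and seeded; the network and the count
    normalization bounds are refit on each training fold, so the out-of-fold
    scores are leakage-free. The whole procedure is repeated ``cv_repeats``
    times with different fold partitions and the per-image scores averaged,
    which damps the fold-assignment noise of a 200-image sample (the
    averaged fused score still never exceeds either averaged component,
    since the mean of minima is bounded by the minimum of means). A
    resubstitution fit (train = test) is reported separately, since the
    original study appears to evaluate on its own training images.
    """
    labels = np.asarray(labels, int)
    n = len(table)
    oof = np.zeros((n, 3))
    for rep in range(cv_repeats):
        rep_oof = np.full((n, 3), np.nan)
        skf = StratifiedKFold(
            n_splits=cv_folds, shuffle=True, random_state=seed + 97 * rep
        )
        for fold, (tr, te) in enumerate(skf.split(np.zeros(n), labels)):
            model = FusionModel.fit(
                table.iloc[tr],
                labels[tr],
                seed=seed + 97 * rep + fold,
                hidden_units=hidden_units,
            )
            rep_oof[te] = model.score(table.iloc[te]).to_numpy()
        oof += rep_oof
    oof /= cv_repeats
    cv_scores = pd.DataFrame(oof, columns=["ann_score", "norm_count", "fused"])

    full_model = FusionModel.fit(table, labels, seed=seed, hidden_units=hidden_units)
    resub_scores = full_model.score(table)

    def _fit(scores):
        data = roc.RatingData(scores[labels == 1], scores[labels == 0])
        return roc.fit_binormal(data, n_categories=n_categories), roc.empirical_auc(data)

    cv_fit, cv_emp = _fit(cv_scores["fused"].to_numpy())
    resub_fit, resub_emp = _fit(resub_scores["fused"].to_numpy())
    return FusionEvaluation(
        cv_scores=cv_scores,
        resub_scores=resub_scores,
        labels=labels,
        cv_fit=cv_fit,
        resub_fit=resub_fit,
        cv_auc_empirical=cv_emp,
        resub_auc_empirical=resub_emp,
    )
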