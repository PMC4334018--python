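"""Binormal ROC estimation and feature comparison.

The binormal model assumes the decision variable of each class is Gaussian
on some latent scale; the ROC curve is then ``TPF = Phi(a + b * Phi^-1(FPF))``
with intercept ``a`` (standardized mean separation) and slope ``b`` (ratio of
negative to positive standard deviations), and the area under the curve is
``AUC = Phi(a / sqrt(1 + b^2))``.

Continuous scores are reduced to ordinal categories at pooled-quantile
boundaries and ``(a, b)`` plus the category cutpoints are estimated by
maximizing the multinomial likelihood (the Dorfman–Alf procedure). Paired
AUC differences are tested with DeLong's structural-component covariance;
the nonparametric Mann–Whitney AUC serves as a model-free reference
throughout.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm, rankdata

__all__ = [
    "RatingData",
    "CategoryTable",
    "ROCFit",
    "ComparisonResult",
    "empirical_auc",
    "categorize_scores",
    "fit_binormal",
    "auc_closed_form",
    "binormal_curve",
    "screen_features",
    "compare_auc_paired",
    "feature_correlation",
    "choose_direction",
]

DIRECTIONS = ("higher_is_positive", "lower_is_positive")


class InsufficientDataError(ValueError):
    """Too few observations in one of the classes to estimate an ROC."""


@dataclasses.dataclass
class RatingData:
    """Scores of the positive (analyzable) and negative (unanalyzable) class.

    ``direction`` states which tail of the score indicates the positive
    class; it is applied (by negation) before any AUC computation. NaN
    scores are dropped with a warning when the data are oriented.
    """

    pos_scores: np.ndarray
    neg_scores: np.ndarray
    direction: str = "higher_is_positive"

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        self.pos_scores = np.asarray(self.pos_scores, float)
        self.neg_scores = np.asarray(self.neg_scores, float)

    def oriented(self) -> tuple[np.ndarray, np.ndarray]:
        pos, neg = self.pos_scores, self.neg_scores
        n_missing = np.isnan(pos).sum() + np.isnan(neg).sum()
        if n_missing:
            warnings.warn(f"dropping {n_missing} missing scores", stacklevel=2)
            pos = pos[~np.isnan(pos)]
            neg = neg[~np.isnan(neg)]
        if self.direction == "lower_is_positive":
            pos, neg = -pos, -neg
        return pos, neg


@dataclasses.dataclass
class CategoryTable:
    """Ordinal frequency table: per-class counts in score categories."""

    edges: np.ndarray  # inner boundaries, ascending
    neg_counts: np.ndarray
    pos_counts: np.ndarray


@dataclasses.dataclass
class ROCFit:
    a: float
    b: float
    auc: float
    se_auc: float
    n_categories: int
    converged: bool
    log_likelihood: float
    cutpoints: np.ndarray | None = None
    degenerate: bool = False


@dataclasses.dataclass
class ComparisonResult:
    delta_auc: float
    z: float
    p_value: float
    covariance: float
    auc_i: float
    auc_j: float


# ---------------------------------------------------------------------------
# Nonparametric AUC


def empirical_auc(data: RatingData) -> float:
    """Mann–Whitney AUC: P(pos > neg) with ties counted one half."""
    pos, neg = data.oriented()
    if len(pos) == 0 or len(neg) == 0:
        raise InsufficientDataError("both classes must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def choose_direction(scores: np.ndarray, labels: np.ndarray) -> str:
    """Orient a feature so its AUC is >= 0.5, using the even-indexed half.

    Using only half the images to pick the direction avoids letting the
    orientation choice inflate the AUC that is later estimated on the full
    sample for genuinely uninformative features.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    keep = ~np.isnan(scores)
    pos_idx = np.flatnonzero(keep & (labels == 1))
    neg_idx = np.flatnonzero(keep & (labels == 0))
    # first half of each class, so both classes are always represented
    pos = scores[pos_idx[: max(len(pos_idx) // 2, 1)]]
    neg = scores[neg_idx[: max(len(neg_idx) // 2, 1)]]
    if len(pos) == 0 or len(neg) == 0:
        return "higher_is_positive"
    auc = empirical_auc(RatingData(pos, neg))
    return "higher_is_positive" if auc >= 0.5 else "lower_is_positive"


# ---------------------------------------------------------------------------
# Dorfman–Alf binormal maximum likelihood


def categorize_scores(data: RatingData, n_categories: int = 10) -> CategoryTable:
    """Bin scores into ordinal categories at pooled-quantile boundaries.

    Duplicate quantile boundaries (heavily tied scores) collapse categories,
    with a warning; the counts always sum to the class sizes.
    """
    if n_categories < 3:
        raise ValueError("need at least 3 categories")
    pos, neg = data.oriented()
    pooled = np.concatenate([pos, neg])
    qs = np.linspace(0, 1, n_categories + 1)[1:-1]
    edges = np.unique(np.quantile(pooled, qs))
    # Drop edges that leave an empty outer bin (all mass at the extremes).
    edges = edges[(edges > pooled.min()) & (edges <= pooled.max())]
    if len(edges) < n_categories - 1:
        warnings.warn(
            f"collapsed to {len(edges) + 1} effective categories (tied scores)",
            stacklevel=2,
        )
    neg_counts = np.bincount(
        np.searchsorted(edges, neg, side="left"), minlength=len(edges) + 1
    )
    pos_counts = np.bincount(
        np.searchsorted(edges, pos, side="left"), minlength=len(edges) + 1
    )
    return CategoryTable(edges=edges, neg_counts=neg_counts, pos_counts=pos_counts)


def _nll_factory(neg_counts: np.ndarray, pos_counts: np.ndarray):
    """Negative log-likelihood over theta = (a, log b, t1, log-increments)."""
    total = neg_counts.sum() + pos_counts.sum()

    def unpack(theta):
        a, logb = theta[0], theta[1]
        b = np.exp(logb)
        t = np.concatenate([[theta[2]], theta[2] + np.cumsum(np.exp(theta[3:]))])
        return a, b, t

    def nll(theta):
        a, b, t = unpack(theta)
        # Negative latent scores ~ N(0, 1); positives ~ N(a/b, 1/b).
        cn = np.concatenate([[0.0], norm.cdf(t), [1.0]])
        cp = np.concatenate([[0.0], norm.cdf(b * t - a), [1.0]])
        pn = np.clip(np.diff(cn), 1e-12, None)
        pp = np.clip(np.diff(cp), 1e-12, None)
        return -(neg_counts @ np.log(pn) + pos_counts @ np.log(pp)) / total

    return nll, unpack, total


def _num_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    for i in range(len(x)):
        e = np.zeros_like(x)
        e[i] = eps * (1 + abs(x[i]))
        g[i] = (f(x + e) - f(x - e)) / (2 * e[i])
    return g


def _num_hess(f, x, eps=1e-4):
    n = len(x)
    h = np.zeros((n, n))
    steps = eps * (1 + np.abs(x))
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = steps[i]
        for j in range(i, n):
            ej = np.zeros(n)
            ej[j] = steps[j]
            h[i, j] = h[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * steps[i] * steps[j])
    return h


def fit_binormal(
    data: RatingData,
    n_categories: int = 10,
    fix_b: bool = False,
    grad_tol: float = 1e-4,
) -> ROCFit:
    """Maximum-likelihood binormal ROC fit on quantile-categorized scores.

    Optimizes ``(a, log b, ordered cutpoints)`` with L-BFGS-B from three
    slope initializations. Empty category cells receive a 0.25 continuity
    correction and ``a`` is capped at ±5, which keeps perfectly separated
    data finite; such fits are flagged ``degenerate``. ``fix_b=True``
    constrains the slope to 1 (equal latent variances). The standard error
    of the AUC comes from the observed information via the delta method.
    """
    pos, neg = data.oriented()
    if len(pos) < 5 or len(neg) < 5:
        raise InsufficientDataError("need >= 5 observations per class")
    table = categorize_scores(data, n_categories)
    neg_counts = table.neg_counts.astype(float)
    pos_counts = table.pos_counts.astype(float)
    k = len(neg_counts)
    if k < 2:
        raise InsufficientDataError(
            "scores collapse to a single category; binormal fit unidentifiable"
        )
    degenerate = bool((neg_counts == 0).any() or (pos_counts == 0).any())
    neg_counts[neg_counts == 0] = 0.25
    pos_counts[pos_counts == 0] = 0.25

    nll, unpack, total = _nll_factory(neg_counts, pos_counts)

    # Empirical cutpoint initialization: normal scores of pooled cumulative
    # fractions; intercept from the empirical AUC.
    pooled_cum = np.cumsum(neg_counts + pos_counts)[:-1] / (neg_counts + pos_counts).sum()
    t0 = norm.ppf(np.clip(pooled_cum, 1e-3, 1 - 1e-3))
    t0 = np.maximum.accumulate(t0 + 1e-6 * np.arange(k - 1))
    auc0 = float(np.clip(empirical_auc(data), 0.02, 0.98))

    if fix_b:
        b_starts = [1.0]
    else:
        b_starts = [0.7, 1.0, 1.4]
    best = None
    for b0 in b_starts:
        a0 = norm.ppf(auc0) * np.sqrt(1 + b0**2)
        incr = np.log(np.clip(np.diff(t0), 1e-3, None)) if k > 2 else np.empty(0)
        theta0 = np.concatenate([[a0, np.log(b0)], [t0[0] if k > 1 else 0.0], incr])
        if fix_b:
            obj = lambda th: nll(np.concatenate([[th[0], 0.0], th[1:]]))
            x0 = np.delete(theta0, 1)
            bounds = [(-5, 5)] + [(-10, 10)] + [(-10, 3)] * (k - 2)
        else:
            obj = nll
            x0 = theta0
            bounds = [(-5, 5), (-2.5, 2.5)] + [(-10, 10)] + [(-10, 3)] * (k - 2)
        res = minimize(obj, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res

    x = best.x
    theta = np.concatenate([[x[0], 0.0], x[1:]]) if fix_b else x
    a, b, t = unpack(theta)
    grad = _num_grad(nll, theta)
    converged = bool(np.linalg.norm(grad) < grad_tol)
    auc = auc_closed_form(a, b)

    # Delta-method SE: invert the observed information (of the un-normalized
    # log-likelihood) and propagate through AUC(a, log b).
    se = float("nan")
    try:
        hess = _num_hess(nll, theta) * total
        cov = np.linalg.pinv(hess)
        q = a / np.sqrt(1 + b**2)
        phi_q = norm.pdf(q)
        g = np.zeros(len(theta))
        g[0] = phi_q / np.sqrt(1 + b**2)
        g[1] = -phi_q * a * b**2 * (1 + b**2) ** -1.5
        se = float(np.sqrt(max(g @ cov @ g, 0.0)))
    except np.linalg.LinAlgError:  # pragma: no cover - pinv rarely fails
        pass

    return ROCFit(
        a=float(a),
        b=float(b),
        auc=float(auc),
        se_auc=se,
        n_categories=k,
        converged=converged,
        log_likelihood=float(-best.fun * total),
        cutpoints=t,
        degenerate=degenerate,
    )


def auc_closed_form(a: float, b: float) -> float:
    """Binormal AUC identity ``Phi(a / sqrt(1 + b^2))``."""
    if b <= 0:
        raise ValueError("slope b must be > 0")
    return float(norm.cdf(a / np.sqrt(1.0 + b * b)))


def binormal_curve(fit: ROCFit, fpf: np.ndarray | None = None) -> pd.DataFrame:
    """ROC curve points ``TPF = Phi(a + b Phi^-1(FPF))`` on an FPF grid."""
    if fpf is None:
        fpf = np.linspace(0.01, 0.99, 99)
    fpf = np.asarray(fpf, float)
    tpf = norm.cdf(fit.a + fit.b * norm.ppf(fpf))
    return pd.DataFrame({"fpf": fpf, "tpf": tpf})


# ---------------------------------------------------------------------------
# Screening and paired comparison


def screen_features(
    fits: dict[str, ROCFit], floor: float = 0.55
) -> list[str]:
    """Keep features whose AUC clears the floor, ordered by descending AUC.

    Features with AUC under or close to one half perform no better than a
    random decision and are discarded.
    """
    if not fits:
        raise ValueError("no fits to screen")
    kept = [name for name, f in fits.items() if f.auc >= floor]
    kept.sort(key=lambda name: -fits[name].auc)
    if not kept:
        warnings.warn("no feature cleared the AUC floor", stacklevel=2)
    return kept


def _structural_components(pos: np.ndarray, neg: np.ndarray):
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    return psi.mean(axis=1), psi.mean(axis=0), psi.mean()


def compare_auc_paired(
    data_i: RatingData,
    data_j: RatingData,
    method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
) -> ComparisonResult:
    """Test the AUC difference of two features scored on the same images.

    DeLong's method estimates the covariance of the two Mann–Whitney AUCs
    from per-case structural components; the z statistic is the AUC
    difference over the SD of the difference, with a two-sided normal
    p-value. ``method="bootstrap"`` instead resamples cases (seeded).
    """
    if len(data_i.pos_scores) != len(data_j.pos_scores) or len(
        data_i.neg_scores
    ) != len(data_j.neg_scores):
        raise ValueError("paired comparison requires image-aligned scores")
    pos_i, neg_i = data_i.oriented()
    pos_j, neg_j = data_j.oriented()
    m, n = len(pos_i), len(neg_i)
    v10_i, v01_i, auc_i = _structural_components(pos_i, neg_i)
    v10_j, v01_j, auc_j = _structural_components(pos_j, neg_j)
    s10 = np.cov(np.stack([v10_i, v10_j]), ddof=1)
    s01 = np.cov(np.stack([v01_i, v01_j]), ddof=1)
    cov_mat = s10 / m + s01 / n
    delta = auc_i - auc_j
    var = cov_mat[0, 0] + cov_mat[1, 1] - 2 * cov_mat[0, 1]

    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        deltas = np.empty(n_boot)
        for t in range(n_boot):
            ip = rng.integers(0, m, m)
            im = rng.integers(0, n, n)
            deltas[t] = _structural_components(pos_i[ip], neg_i[im])[2] - \
                _structural_components(pos_j[ip], neg_j[im])[2]
        var = float(np.var(deltas, ddof=1))
    elif method != "delong":
        raise ValueError(f"unknown comparison method {method!r}")

    if var <= 1e-16:
        z = 0.0
        p = 1.0 if abs(delta) < 1e-12 else 0.0
    else:
        z = float(delta / np.sqrt(var))
        p = float(2.0 * norm.sf(abs(z)))
    return ComparisonResult(
        delta_auc=float(delta),
        z=z,
        p_value=p,
        covariance=float(cov_mat[0, 1]),
        auc_i=float(auc_i),
        auc_j=float(auc_j),
    )


def feature_correlation(table: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation matrix of the feature columns.

    Zero-variance features yield NaN (undefined) correlations; the diagonal
    is 1 for every feature with positive variance.
    """
    cols = list(columns) if columns is not None else list(table.columns)
    sub = table[cols].astype(float)
    if len(sub.dropna()) < 3:
        raise InsufficientDataError("need >= 3 complete rows")
    corr = sub.corr(method="pearson", min_periods=3)
    for c in cols:
        if sub[c].std(skipna=True) > 0:
            corr.loc[c, c] = 1.0
    return corr
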