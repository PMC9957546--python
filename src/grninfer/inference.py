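"""Data-driven link scoring: every candidate TF -> TG edge gets a score.

Three scorer families, all returning a :class:`~grninfer.containers.ScoreMatrix`
(TFs x targets, higher = stronger evidence, NaN on self-links):

* **Co-expression** — absolute Pearson (``pr``), Spearman (``sr``) or Kendall
  tau (``kt``) between TF and target profiles, and context likelihood of
  relatedness (``clr``), which background-corrects a mutual-information
  matrix with per-TF and per-target z-scores and combines them as
  ``sqrt(max(0, z_tf)^2 + max(0, z_tg)^2)``.
* **Feature importance** — one supervised model per target gene predicts its
  expression (regressors) or its discretized expression level (classifiers)
  from all TF profiles; the per-TF importance of the fitted model is the
  link score.  Tree ensembles use impurity importances (summing to 1 per
  target), linear SVMs and Bayesian ridge use absolute coefficients,
  complement naive Bayes uses the spread of per-class feature log-weights.
* **Stability selection** — TIGRESS (least-angle regression, selection
  within the first L steps) and stability randomized lasso (SRL): over R
  resamples of half the conditions with TF columns reweighted by
  uniform(alpha, 1) factors, the score is the frequency with which a TF is
  selected for a target.

Targets default to every gene of the matrix; a gene acting as both TF and
target is removed from its own predictor set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import (
    AdaBoostClassifier,
    AdaBoostRegressor,
    ExtraTreesClassifier,
    ExtraTreesRegressor,
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import BayesianRidge, Lasso, lars_path
from sklearn.naive_bayes import ComplementNB
from sklearn.svm import LinearSVC, LinearSVR

from ._seeds import derive_seed
from .containers import ScoreMatrix, make_edge_frame, validate_expression
from .preprocessing import _efd_row, kmeans_1d

COEXPRESSION_METHODS = ("pr", "sr", "kt")
REGRESSION_METHODS = ("abr", "gbr", "rfr", "xrtr", "svmr", "brsr")
CLASSIFICATION_METHODS = ("abc", "gbc", "rfc", "xrtc", "svmc", "cnbc")
STABILITY_METHODS = ("tigress", "srl")
ALL_METHODS = COEXPRESSION_METHODS + ("clr",) + REGRESSION_METHODS + CLASSIFICATION_METHODS + STABILITY_METHODS


@dataclass
class MethodConfig:
    """Hyperparameters shared by the model-based scorers.

    Parameters
    ----------
    seed : base seed; per-target sub-seeds are derived deterministically.
    n_estimators : trees per ensemble for AB/GB/RF/XRT.
    n_resamples : R, stability-selection resamples.
    n_lars_steps : L, LARS steps within which a TF counts as selected (TIGRESS).
    reweight_low : alpha, lower bound of the uniform(alpha, 1) column reweighting.
    lasso_penalty_factor : SRL penalty as a fraction of the per-target
        lambda_max (the smallest penalty that zeroes every coefficient).
    n_levels : discretization levels for classification targets.
    """

    seed: int = 0
    n_estimators: int = 100
    n_resamples: int = 256
    n_lars_steps: int = 2
    reweight_low: float = 0.3
    lasso_penalty_factor: float = 0.1
    n_levels: int = 5

    def __post_init__(self) -> None:
        if self.n_resamples < 2:
            raise ValueError("n_resamples (R) must be >= 2")
        if not 0 < self.reweight_low <= 1:
            raise ValueError("reweight_low (alpha) must lie in (0, 1]")
        if self.n_lars_steps < 1:
            raise ValueError("n_lars_steps (L) must be >= 1")
        if self.lasso_penalty_factor <= 0:
            raise ValueError("lasso_penalty_factor must be > 0")
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")


def _resolve_axes(expr: pd.DataFrame, tfs, targets):
    validate_expression(expr)
    tf_ids = [str(t) for t in tfs]
    if not tf_ids:
        raise ValueError("regulator list is empty")
    if len(set(tf_ids)) != len(tf_ids):
        raise ValueError("regulator list holds duplicates")
    missing = [t for t in tf_ids if t not in expr.index]
    if missing:
        raise ValueError(f"regulators absent from the expression matrix: {missing}")
    if targets is None:
        tg_ids = [str(g) for g in expr.index]
    else:
        tg_ids = [str(g) for g in targets]
        missing = [g for g in tg_ids if g not in expr.index]
        if missing:
            raise ValueError(f"targets absent from the expression matrix: {missing}")
    return tf_ids, tg_ids


def _finalize(scores: np.ndarray, tf_ids, tg_ids, method: str) -> ScoreMatrix:
    frame = pd.DataFrame(scores, index=pd.Index(tf_ids, name="tf"), columns=tg_ids)
    for i, tf in enumerate(tf_ids):
        for j, tg in enumerate(tg_ids):
            if tf == tg:
                frame.iat[i, j] = np.nan
    return ScoreMatrix(frame, method_name=method)


# ---------------------------------------------------------------------------
# co-expression
# ---------------------------------------------------------------------------

def score_coexpression(
    expr: pd.DataFrame, tfs, statistic: str = "pr", targets=None
) -> ScoreMatrix:
    """Absolute correlation between TF and target expression profiles.

    ``pr`` Pearson, ``sr`` Spearman, ``kt`` Kendall tau; scores lie in
    [0, 1] and are symmetric in the gene pair.  Constant genes score 0
    against everything (with a warning) since no correlation is defined.
    """
    statistic = statistic.lower()
    if statistic not in COEXPRESSION_METHODS:
        raise ValueError(f"unknown co-expression statistic {statistic!r}")
    tf_ids, tg_ids = _resolve_axes(expr, tfs, targets)
    n_conditions = expr.shape[1]
    if n_conditions < 3:
        raise ValueError("co-expression scoring needs at least 3 conditions")

    values = expr.to_numpy(dtype=float)
    gene_pos = {g: i for i, g in enumerate(expr.index.astype(str))}
    constant = values.std(axis=1, ddof=0) == 0
    if constant[[gene_pos[g] for g in set(tf_ids) | set(tg_ids)]].any():
        flat = [g for g in set(tf_ids) | set(tg_ids) if constant[gene_pos[g]]]
        warnings.warn(
            f"constant gene(s) scored 0 in co-expression: {sorted(flat)}",
            RuntimeWarning,
            stacklevel=2,
        )

    if statistic == "kt":
        scores = np.zeros((len(tf_ids), len(tg_ids)))
        for i, tf in enumerate(tf_ids):
            x = values[gene_pos[tf]]
            for j, tg in enumerate(tg_ids):
                y = values[gene_pos[tg]]
                if constant[gene_pos[tf]] or constant[gene_pos[tg]]:
                    continue
                tau = stats.kendalltau(x, y).statistic
                scores[i, j] = abs(tau) if np.isfinite(tau) else 0.0
    else:
        if statistic == "sr":
            data = stats.rankdata(values, axis=1)
        else:
            data = values
        mean = data.mean(axis=1, keepdims=True)
        sd = data.std(axis=1, ddof=0)
        z = np.where(sd[:, None] > 0, (data - mean) / np.where(sd == 0, 1, sd)[:, None], 0.0)
        rows = [gene_pos[t] for t in tf_ids]
        cols = [gene_pos[g] for g in tg_ids]
        scores = np.abs(z[rows] @ z[cols].T) / n_conditions
    scores = np.clip(scores, 0.0, 1.0)
    return _finalize(scores, tf_ids, tg_ids, statistic)


# ---------------------------------------------------------------------------
# CLR
# ---------------------------------------------------------------------------

def _plugin_mi(x: np.ndarray, y: np.ndarray, n_bins: int) -> float:
    joint = np.bincount(x * n_bins + y, minlength=n_bins * n_bins).astype(float)
    joint = joint.reshape(n_bins, n_bins) / x.size
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    mask = joint > 0
    outer = px[:, None] * py[None, :]
    return float(np.sum(joint[mask] * np.log(joint[mask] / outer[mask])))


def mutual_information_matrix(
    expr: pd.DataFrame, tf_ids, tg_ids, n_bins: int | None = None
) -> pd.DataFrame:
    """Plug-in MI between TF and target profiles on an equal-frequency grid.

    Profiles are discretized per gene into ``ceil(log2(c) + 1)`` equal-frequency
    bins by default (Sturges-like rule on c conditions); the MI of each pair
    is the plug-in estimate on the joint histogram.  Self pairs are NaN.
    """
    n_conditions = expr.shape[1]
    if n_bins is None:
        n_bins = math.ceil(math.log2(n_conditions) + 1)
    n_bins = max(2, min(n_bins, n_conditions))
    values = expr.to_numpy(dtype=float)
    labels = np.empty(values.shape, dtype=np.int64)
    for i in range(values.shape[0]):
        labels[i] = _efd_row(values[i], n_bins)
    gene_pos = {g: i for i, g in enumerate(expr.index.astype(str))}
    mi = np.empty((len(tf_ids), len(tg_ids)))
    for i, tf in enumerate(tf_ids):
        for j, tg in enumerate(tg_ids):
            if tf == tg:
                mi[i, j] = np.nan
            else:
                mi[i, j] = _plugin_mi(labels[gene_pos[tf]], labels[gene_pos[tg]], n_bins)
    return pd.DataFrame(mi, index=tf_ids, columns=tg_ids)


def clr_from_mi(mi: pd.DataFrame) -> pd.DataFrame:
    """Apply the CLR background correction to a TF x TG MI matrix.

    For a pair (t, g), ``z_t`` standardizes MI(t, g) against TF t's MI
    distribution over all targets and ``z_g`` against target g's distribution
    over all TFs; negative z-scores are truncated at 0 and the score is the
    Euclidean combination ``sqrt(z_t^2 + z_g^2)``.  A degenerate (zero-sd)
    background contributes 0.  NaN cells (self pairs) are excluded from the
    background statistics and stay NaN.
    """
    values = mi.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row_mean = np.nanmean(values, axis=1, keepdims=True)
        row_sd = np.nanstd(values, axis=1, ddof=0, keepdims=True)
        col_mean = np.nanmean(values, axis=0, keepdims=True)
        col_sd = np.nanstd(values, axis=0, ddof=0, keepdims=True)
    z_tf = np.where(row_sd > 0, (values - row_mean) / np.where(row_sd == 0, 1, row_sd), 0.0)
    z_tg = np.where(col_sd > 0, (values - col_mean) / np.where(col_sd == 0, 1, col_sd), 0.0)
    z_tf = np.maximum(z_tf, 0.0)
    z_tg = np.maximum(z_tg, 0.0)
    scores = np.sqrt(z_tf**2 + z_tg**2)
    scores[np.isnan(values)] = np.nan
    return pd.DataFrame(scores, index=mi.index, columns=mi.columns)


def score_clr(
    expr: pd.DataFrame, tfs, targets=None, n_bins: int | None = None
) -> ScoreMatrix:
    """Context likelihood of relatedness: background-corrected mutual information."""
    tf_ids, tg_ids = _resolve_axes(expr, tfs, targets)
    mi = mutual_information_matrix(expr, tf_ids, tg_ids, n_bins=n_bins)
    scores = clr_from_mi(mi)
    return ScoreMatrix(scores.rename_axis("tf"), method_name="clr")


# ---------------------------------------------------------------------------
# feature importance
# ---------------------------------------------------------------------------

_TREE_REGRESSORS = {
    "abr": AdaBoostRegressor,
    "gbr": GradientBoostingRegressor,
    "rfr": RandomForestRegressor,
    "xrtr": ExtraTreesRegressor,
}


def _importance_from_regressor(model: str, X, y, seed: int, config: MethodConfig):
    if model in _TREE_REGRESSORS:
        est = _TREE_REGRESSORS[model](n_estimators=config.n_estimators, random_state=seed)
        est.fit(X, y)
        return est.feature_importances_
    if model == "svmr":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est = LinearSVR(random_state=seed, max_iter=10000)
            est.fit(X, y)
        return np.abs(np.ravel(est.coef_))
    if model == "brsr":
        est = BayesianRidge()
        est.fit(X, y)
        return np.abs(est.coef_)
    raise ValueError(f"unknown regression model {model!r}")


def _importance_from_classifier(model: str, X, labels, seed: int, config: MethodConfig):
    if model == "abc":
        est = AdaBoostClassifier(n_estimators=config.n_estimators, random_state=seed)
    elif model == "gbc":
        est = GradientBoostingClassifier(n_estimators=config.n_estimators, random_state=seed)
    elif model == "rfc":
        est = RandomForestClassifier(n_estimators=config.n_estimators, random_state=seed)
    elif model == "xrtc":
        est = ExtraTreesClassifier(n_estimators=config.n_estimators, random_state=seed)
    elif model == "svmc":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est = LinearSVC(random_state=seed, max_iter=10000)
            est.fit(X, labels)
        return np.abs(est.coef_).mean(axis=0)
    elif model == "cnbc":
        est = ComplementNB()
        est.fit(X - X.min(), labels)  # CNB needs nonnegative features
        logw = est.feature_log_prob_
        return logw.max(axis=0) - logw.min(axis=0)
    else:
        raise ValueError(f"unknown classification model {model!r}")
    est.fit(X, labels)
    return est.feature_importances_


def score_feature_importance(
    expr: pd.DataFrame,
    tfs,
    model: str,
    config: MethodConfig | None = None,
    targets=None,
) -> ScoreMatrix:
    """Per-target supervised models scored by TF feature importance.

    Regressors (``abr``, ``gbr``, ``rfr``, ``xrtr``, ``svmr``, ``brsr``)
    predict the raw target expression; classifiers (``abc``, ``gbc``,
    ``rfc``, ``xrtc``, ``svmc``, ``cnbc``) predict the target's discretized
    level (K-means, ``config.n_levels`` clusters).  A target whose
    discretized labels collapse to a single class gets an all-zero row and
    a warning.
    """
    model = model.lower()
    if model not in REGRESSION_METHODS + CLASSIFICATION_METHODS:
        raise ValueError(f"unknown feature-importance model {model!r}")
    config = config or MethodConfig()
    tf_ids, tg_ids = _resolve_axes(expr, tfs, targets)
    if len(tf_ids) < 2:
        raise ValueError("feature-importance scoring needs at least 2 TFs")
    if expr.shape[1] < 2:
        raise ValueError("feature-importance scoring needs at least 2 conditions")

    values = expr.to_numpy(dtype=float)
    gene_pos = {g: i for i, g in enumerate(expr.index.astype(str))}
    tf_expr = values[[gene_pos[t] for t in tf_ids]]  # (n_tf, c)
    is_classifier = model in CLASSIFICATION_METHODS

    scores = np.zeros((len(tf_ids), len(tg_ids)))
    degenerate = []
    for j, tg in enumerate(tg_ids):
        predictor_idx = [i for i, tf in enumerate(tf_ids) if tf != tg]
        if not predictor_idx:
            continue
        X = tf_expr[predictor_idx].T  # conditions x predictors
        y = values[gene_pos[tg]]
        seed = derive_seed(config.seed, model, tg)
        if is_classifier:
            labels = kmeans_1d(y, min(config.n_levels, np.unique(y).size))
            if np.unique(labels).size < 2:
                degenerate.append(tg)
                continue
            importance = _importance_from_classifier(model, X, labels, seed, config)
        else:
            importance = _importance_from_regressor(model, X, y, seed, config)
        scores[predictor_idx, j] = importance
    if degenerate:
        warnings.warn(
            f"single-class discretized target(s) scored 0: {degenerate}",
            RuntimeWarning,
            stacklevel=2,
        )
    return _finalize(scores, tf_ids, tg_ids, model)


# ---------------------------------------------------------------------------
# stability selection
# ---------------------------------------------------------------------------

def score_stability_selection(
    expr: pd.DataFrame,
    tfs,
    variant: str = "tigress",
    config: MethodConfig | None = None,
    targets=None,
) -> ScoreMatrix:
    """TIGRESS / stability-randomized-lasso selection frequencies.

    For each target, R resamples each draw floor(c/2) conditions without
    replacement and reweight every TF column by an independent
    uniform(alpha, 1) factor; TIGRESS records the TFs entering within the
    first L least-angle-regression steps, SRL the TFs with a nonzero lasso
    coefficient at penalty ``lasso_penalty_factor * lambda_max``.  Scores are
    selection counts divided by R, hence exact multiples of 1/R in [0, 1].
    """
    variant = variant.lower()
    if variant not in STABILITY_METHODS:
        raise ValueError(f"unknown stability-selection variant {variant!r}")
    config = config or MethodConfig()
    tf_ids, tg_ids = _resolve_axes(expr, tfs, targets)
    n_conditions = expr.shape[1]
    if n_conditions < 4:
        raise ValueError("stability selection needs at least 4 conditions")

    values = expr.to_numpy(dtype=float)
    gene_pos = {g: i for i, g in enumerate(expr.index.astype(str))}
    tf_expr = values[[gene_pos[t] for t in tf_ids]]
    half = n_conditions // 2
    R = config.n_resamples

    scores = np.zeros((len(tf_ids), len(tg_ids)))
    clamped = False
    for j, tg in enumerate(tg_ids):
        predictor_idx = np.array([i for i, tf in enumerate(tf_ids) if tf != tg])
        if predictor_idx.size == 0:
            continue
        L = config.n_lars_steps
        if L > predictor_idx.size:
            L = predictor_idx.size
            clamped = True
        X_full = tf_expr[predictor_idx].T
        y_full = values[gene_pos[tg]]
        rng = np.random.default_rng(derive_seed(config.seed, variant, tg))
        counts = np.zeros(predictor_idx.size)
        if variant == "srl":
            Xc = X_full - X_full.mean(axis=0)
            sd = Xc.std(axis=0, ddof=0)
            Xs = Xc / np.where(sd == 0, 1, sd)
            yc = y_full - y_full.mean()
            lam_max = np.abs(Xs.T @ yc).max() / n_conditions
            lam = max(config.lasso_penalty_factor * lam_max, 1e-12)
        for _ in range(R):
            subset = rng.choice(n_conditions, size=half, replace=False)
            weights = rng.uniform(config.reweight_low, 1.0, size=predictor_idx.size)
            X = X_full[subset]
            y = y_full[subset]
            X = X - X.mean(axis=0)
            sd = X.std(axis=0, ddof=0)
            X = X / np.where(sd == 0, 1, sd) * weights
            y = y - y.mean()
            if variant == "tigress":
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    _, active, _ = lars_path(X, y, method="lar", max_iter=L)
                counts[list(active[:L])] += 1
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    est = Lasso(alpha=lam, fit_intercept=False, max_iter=2000)
                    est.fit(X, y)
                counts[est.coef_ != 0] += 1
        scores[predictor_idx, j] = counts / R
    if clamped:
        warnings.warn(
            "n_lars_steps exceeded the predictor count and was clamped",
            RuntimeWarning,
            stacklevel=2,
        )
    return _finalize(scores, tf_ids, tg_ids, variant)


# ---------------------------------------------------------------------------
# unified dispatch and ranking
# ---------------------------------------------------------------------------

def score_links(
    expr: pd.DataFrame,
    tfs,
    method: str,
    config: MethodConfig | None = None,
    targets=None,
) -> ScoreMatrix:
    """Score all TF -> target links with any named method (see ``ALL_METHODS``)."""
    method = method.lower()
    if method in COEXPRESSION_METHODS:
        return score_coexpression(expr, tfs, method, targets=targets)
    if method == "clr":
        return score_clr(expr, tfs, targets=targets)
    if method in REGRESSION_METHODS + CLASSIFICATION_METHODS:
        return score_feature_importance(expr, tfs, method, config=config, targets=targets)
    if method in STABILITY_METHODS:
        return score_stability_selection(expr, tfs, method, config=config, targets=targets)
    raise ValueError(f"unknown inference method {method!r}")


def scores_to_edges(scores: ScoreMatrix) -> pd.DataFrame:
    """Flatten a score matrix into a ranked edge list.

    Self-links are dropped; edges are sorted by descending score with ties
    broken by (tf, tg) lexical order.
    """
    frame = scores.scores
    long = frame.stack().rename("score").reset_index()
    long.columns = ["tf", "tg", "score"]
    return make_edge_frame(long.to_dict("records"))
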