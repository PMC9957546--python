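"""Link selection, method comparison, and gold-standard evaluation.

Predicted networks are judged as a binary classifier over the *evaluable
universe*: every ordered pair (TF, TG) with both genes experimentally
studied and TF != TG.  Gold-standard edges are the positives; universe
pairs absent from the gold standard count as negatives; predicted links
touching an unstudied gene are excluded and can never change a metric.
AUROC and AUPR are computed over a complete ranking of the universe —
universe pairs missing from the prediction are appended with score -inf in
deterministic (tf, tg) order — while precision/recall/F1 treat the passed
edge list (typically a top-k selection) as the predicted positive set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import average_precision_score, roc_auc_score

from .containers import EvaluationReport, GoldStandard, ScoreMatrix


def select_top_k(edges: pd.DataFrame, k: int, tf: str | None = None, tg: str | None = None) -> pd.DataFrame:
    """Keep the k best links — globally, or entering/leaving one gene.

    ``tf``/``tg`` restrict the scope to links leaving a given TF or entering
    a given target.  Ties inherit the deterministic order of the ranked list.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if tf is not None and tg is not None:
        raise ValueError("restrict by tf or by tg, not both")
    scoped = edges
    if tf is not None:
        if tf not in set(edges["tf"]):
            raise KeyError(f"unknown TF {tf!r}")
        scoped = edges[edges["tf"] == tf]
    if tg is not None:
        if tg not in set(edges["tg"]):
            raise KeyError(f"unknown TG {tg!r}")
        scoped = edges[edges["tg"] == tg]
    return scoped.head(k).reset_index(drop=True)


def _universe(gold: GoldStandard) -> list:
    return [
        (t, g)
        for t in sorted(gold.studied_tfs)
        for g in sorted(gold.studied_tgs)
        if t != g
    ]


def evaluate(edges: pd.DataFrame, gold: GoldStandard) -> EvaluationReport:
    """Score a ranked prediction against a gold standard.

    Returns ranking metrics (AUROC, step-wise AUPR) over the completed
    universe ranking and set metrics (precision, recall, F1) for the passed
    edge list treated as the predicted positives.  Raises if the universe is
    empty, holds no positives, or no negatives (either degenerate case makes
    the ranking metrics undefined).
    """
    if edges.duplicated(subset=["tf", "tg"]).any():
        raise ValueError("ranked edge list holds duplicate (tf, tg) pairs")
    universe = _universe(gold)
    if not universe:
        raise ValueError("empty evaluable universe")
    positives = gold.positives
    if not positives:
        raise ValueError("gold standard holds no positive links")
    if len(positives) == len(universe):
        raise ValueError("gold standard holds no negative links")

    pred_scores = {}
    n_excluded = 0
    for tf, tg, score in edges[["tf", "tg", "score"]].itertuples(index=False):
        if (tf, tg) in pred_scores:
            continue
        if tf in gold.studied_tfs and tg in gold.studied_tgs and tf != tg:
            pred_scores[(tf, tg)] = float(score)
        else:
            n_excluded += 1
    if not pred_scores:
        raise ValueError("no evaluable links remain after the exclusion rule")

    finite = [s for s in pred_scores.values() if np.isfinite(s)]
    floor = (min(finite) if finite else 0.0) - 1.0
    y_true = np.array([pair in positives for pair in universe], dtype=int)
    y_score = np.array(
        [pred_scores.get(pair, -np.inf) for pair in universe], dtype=float
    )
    y_score[~np.isfinite(y_score)] = floor

    auroc = float(roc_auc_score(y_true, y_score))
    aupr = float(average_precision_score(y_true, y_score))

    tp = sum(1 for pair in pred_scores if pair in positives)
    precision = tp / len(pred_scores)
    recall = tp / len(positives)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return EvaluationReport(
        auroc=auroc,
        aupr=aupr,
        f1=f1,
        precision=precision,
        recall=recall,
        n_evaluable_links=len(universe),
        n_excluded_links=n_excluded,
        n_positives=len(positives),
    )


def compare_jaccard(edge_lists: list, k: int, names: list | None = None) -> pd.DataFrame:
    """Pairwise Jaccard index of the top-k edge sets of several methods."""
    if k < 1:
        raise ValueError("k must be >= 1")
    sets = [
        set(map(tuple, edges.head(k)[["tf", "tg"]].itertuples(index=False)))
        for edges in edge_lists
    ]
    n = len(sets)
    names = names or [f"method_{i}" for i in range(n)]
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            union = sets[i] | sets[j]
            out[i, j] = out[j, i] = (
                len(sets[i] & sets[j]) / len(union) if union else 1.0
            )
    return pd.DataFrame(out, index=names, columns=names)


def compare_pca(score_matrices: list, n_components: int | None = None):
    """Project methods into principal-component space for comparison.

    Each method's score matrix is flattened over the shared non-excluded
    cells, standardized to mean 0 / sd 1 (so scale differences between
    methods do not dominate), and treated as one observation.  Returns the
    projection table (methods x components) and the explained-variance
    ratios.
    """
    if len(score_matrices) < 2:
        raise ValueError("PCA comparison needs at least 2 methods")
    reference = score_matrices[0].scores
    rows = []
    for sm in score_matrices:
        if list(sm.scores.index) != list(reference.index) or list(
            sm.scores.columns
        ) != list(reference.columns):
            raise ValueError(f"score-matrix axes of {sm.method_name!r} do not match")
        flat = sm.scores.to_numpy(dtype=float).ravel()
        flat = flat[np.isfinite(reference.to_numpy(dtype=float).ravel())]
        sd = flat.std(ddof=0)
        rows.append((flat - flat.mean()) / sd if sd > 0 else flat - flat.mean())
    data = np.vstack(rows)
    max_components = min(data.shape[0], data.shape[1])
    n_components = min(n_components or max_components, max_components)
    pca = PCA(n_components=n_components, svd_solver="full")
    projection = pca.fit_transform(data)
    names = [sm.method_name for sm in score_matrices]
    table = pd.DataFrame(
        projection,
        index=names,
        columns=[f"PC{i + 1}" for i in range(projection.shape[1])],
    )
    return table, pca.explained_variance_ratio_


def evaluate_scores(scores: ScoreMatrix, gold: GoldStandard) -> EvaluationReport:
    """Convenience: rank a score matrix and evaluate the full ranking."""
    from .inference import scores_to_edges

    return evaluate(scores_to_edges(scores), gold)
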