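"""Independent brute-force oracles used to check the package's fast paths.

These deliberately avoid the library code they verify: the ROC/PR oracle
builds the step curves by an explicit threshold sweep, and the CLR oracle
evaluates the z-score combination cell by cell with plain loops.
"""

import math

import numpy as np


def roc_pr_oracle(y_true, scores):
    """AUROC and AUPR via an exhaustive sweep over distinct score thresholds.

    ROC area is the trapezoid over the tie-grouped (FPR, TPR) step curve;
    PR area is the step-wise sum (R_i - R_{i-1}) * P_i with no interpolation.
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(y_true.sum())
    n_neg = int(y_true.size - n_pos)
    thresholds = np.unique(scores)[::-1]
    tpr = [0.0]
    fpr = [0.0]
    precision_points = []
    recall_points = [0.0]
    for threshold in thresholds:
        called = scores >= threshold
        tp = int((y_true[called] == 1).sum())
        fp = int((y_true[called] == 0).sum())
        tpr.append(tp / n_pos)
        fpr.append(fp / n_neg)
        precision_points.append(tp / (tp + fp))
        recall_points.append(tp / n_pos)
    auroc = 0.0
    for i in range(1, len(tpr)):
        auroc += (fpr[i] - fpr[i - 1]) * (tpr[i] + tpr[i - 1]) / 2.0
    aupr = 0.0
    for i, precision in enumerate(precision_points):
        aupr += (recall_points[i + 1] - recall_points[i]) * precision
    return auroc, aupr


def clr_oracle(mi):
    """Cell-by-cell CLR combination: sqrt(max(0,z_row)^2 + max(0,z_col)^2)."""
    mi = np.asarray(mi, dtype=float)
    n_rows, n_cols = mi.shape
    out = np.empty_like(mi)
    for i in range(n_rows):
        for j in range(n_cols):
            if math.isnan(mi[i, j]):
                out[i, j] = math.nan
                continue
            row = mi[i][~np.isnan(mi[i])]
            col = mi[:, j][~np.isnan(mi[:, j])]
            z_row = 0.0 if row.std() == 0 else (mi[i, j] - row.mean()) / row.std()
            z_col = 0.0 if col.std() == 0 else (mi[i, j] - col.mean()) / col.std()
            out[i, j] = math.sqrt(max(0.0, z_row) ** 2 + max(0.0, z_col) ** 2)
    return out
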