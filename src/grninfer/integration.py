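"""Ensemble integration: standardize member score matrices and average them.

Scores produced by different inference methods live on incomparable scales,
so before averaging each member matrix is standardized by one of six
schemes: a z-score or a rank transform, computed over the full matrix
(``z-full`` / ``rank-full``), per target column (``z-tg`` / ``rank-tg``) or
per TF row (``z-tf`` / ``rank-tf``).  Ranks assign 1 to the highest score
(mid-rank on ties) and are negated afterwards so that "higher = better"
holds for every scheme; the ensemble is the plain arithmetic mean of the
standardized members.  Excluded self-links stay excluded and never enter
any stratum statistic.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import EnsembleResult, ScoreMatrix

SCHEMES = ("z-full", "z-tg", "z-tf", "rank-full", "rank-tg", "rank-tf")


def _z_standardize(frame: pd.DataFrame, axis: str) -> pd.DataFrame:
    values = frame.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if axis == "full":
            mean = np.nanmean(values)
            sd = np.nanstd(values, ddof=0)
            mean = np.full_like(values, mean)
            sd = np.full_like(values, sd)
        elif axis == "tg":  # per column
            mean = np.broadcast_to(np.nanmean(values, axis=0, keepdims=True), values.shape)
            sd = np.broadcast_to(np.nanstd(values, axis=0, ddof=0, keepdims=True), values.shape)
        else:  # per row
            mean = np.broadcast_to(np.nanmean(values, axis=1, keepdims=True), values.shape)
            sd = np.broadcast_to(np.nanstd(values, axis=1, ddof=0, keepdims=True), values.shape)
    if np.any((sd == 0) & np.isfinite(values)):
        warnings.warn(
            "zero-variance stratum standardized to all zeros", RuntimeWarning, stacklevel=3
        )
    out = np.where(sd > 0, (values - mean) / np.where(sd == 0, 1, sd), 0.0)
    out[np.isnan(values)] = np.nan
    return pd.DataFrame(out, index=frame.index, columns=frame.columns)


def _rank_standardize(frame: pd.DataFrame, axis: str) -> pd.DataFrame:
    # rank 1 = highest score, mid-rank on ties; negated so higher stays better
    if axis == "full":
        flat = frame.stack(future_stack=True)
        ranks = flat.rank(ascending=False, method="average")
        out = ranks.unstack()
        out = out.reindex(index=frame.index, columns=frame.columns)
    elif axis == "tg":
        out = frame.rank(axis=0, ascending=False, method="average")
    else:
        out = frame.rank(axis=1, ascending=False, method="average")
    return -out


def standardize_scores(scores: ScoreMatrix, scheme: str) -> ScoreMatrix:
    """Standardize one score matrix under an integration scheme.

    Z-schemes leave every stratum with mean 0 and population sd 1
    (zero-variance strata become all-zero with a warning); rank schemes
    replace scores by negated mid-ranks so ordering within each stratum is
    preserved and higher remains better.
    """
    scheme = scheme.lower()
    if scheme not in SCHEMES:
        raise ValueError(f"unknown integration scheme {scheme!r}")
    kind, axis = scheme.split("-")
    if kind == "z":
        frame = _z_standardize(scores.scores, axis)
    else:
        frame = _rank_standardize(scores.scores, axis)
    return ScoreMatrix(frame, method_name=f"{scores.method_name}|{scheme}")


def integrate(members: list, scheme: str) -> EnsembleResult:
    """Average standardized member score matrices into an ensemble.

    All members must share identical TF and target axes; the ensemble score
    of a link is the arithmetic mean of its standardized member scores, so
    the operation is invariant to member order.
    """
    if len(members) < 2:
        raise ValueError("an ensemble needs at least 2 member score matrices")
    reference = members[0]
    for member in members[1:]:
        if list(member.scores.index) != list(reference.scores.index) or list(
            member.scores.columns
        ) != list(reference.scores.columns):
            raise ValueError(
                f"score-matrix axes of {member.method_name!r} do not match "
                f"{reference.method_name!r}"
            )
    standardized = [standardize_scores(m, scheme).scores for m in members]
    mean = sum(standardized) / len(standardized)
    names = [m.method_name for m in members]
    ensemble = ScoreMatrix(mean, method_name="ensemble(" + "+".join(names) + ")")
    return EnsembleResult(scores=ensemble, members=names, scheme=scheme.lower())
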