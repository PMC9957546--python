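"""Core in-memory containers shared across modules.

Conventions
-----------
* Expression / count matrices are :class:`pandas.DataFrame` objects with
  **genes in rows** and **conditions in columns**.  Gene and condition
  identifiers must be unique and the matrix must hold no missing values.
* Link-score matrices are wrapped in :class:`ScoreMatrix`: a TFs x TGs
  DataFrame where higher means stronger predicted regulation and NaN is the
  sentinel for an excluded self-link (a gene never regulates itself here).
* Ranked edge lists are DataFrames with columns ``tf``, ``tg``, ``score``
  sorted by descending score, ties broken by ``(tf, tg)`` lexical order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EDGE_COLUMNS = ["tf", "tg", "score"]


def validate_expression(expr: pd.DataFrame, *, context: str = "expression matrix") -> None:
    """Check the genes x conditions invariants, raising ``ValueError`` on failure."""
    if expr.index.has_duplicates:
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValueError(f"{context}: duplicated gene ids {dups}")
    if expr.columns.has_duplicates:
        dups = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise ValueError(f"{context}: duplicated condition ids {dups}")
    values = expr.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"{context}: non-numeric values present")
    if np.isnan(values).any():
        raise ValueError(f"{context}: missing values present")


def validate_counts(counts: pd.DataFrame) -> None:
    validate_expression(counts, context="count matrix")
    if (counts.to_numpy() < 0).any():
        raise ValueError("count matrix: negative counts present")


@dataclass
class ScoreMatrix:
    """Regulator x target link scores produced by one inference method.

    ``scores`` is indexed by TF ids with TG ids as columns.  Self-links
    (``tf == tg``) carry NaN and are excluded from every downstream
    statistic; all other entries are finite.
    """

    scores: pd.DataFrame
    method_name: str = ""

    def __post_init__(self) -> None:
        if self.scores.index.has_duplicates or self.scores.columns.has_duplicates:
            raise ValueError("ScoreMatrix: duplicated tf or tg ids")
        self_mask = self._self_link_mask()
        finite = np.isfinite(self.scores.to_numpy())
        if (~finite & ~self_mask).any():
            raise ValueError("ScoreMatrix: non-finite score outside self-links")
        if (finite & self_mask).any():
            raise ValueError("ScoreMatrix: self-links must be excluded (NaN)")

    def _self_link_mask(self) -> np.ndarray:
        tf_ids = self.scores.index.to_numpy()
        tg_ids = self.scores.columns.to_numpy()
        return tf_ids[:, None] == tg_ids[None, :]

    @property
    def tf_ids(self) -> list:
        return self.scores.index.tolist()

    @property
    def tg_ids(self) -> list:
        return self.scores.columns.tolist()


@dataclass(frozen=True)
class GoldStandard:
    """Experimentally verified edges plus the studied-gene universe.

    Only pairs between a studied TF and a studied TG are evaluable; every
    positive edge must lie inside that universe.  Genes absent from the
    studied sets were never assayed and are excluded from evaluation rather
    than counted as negatives.
    """

    positives: frozenset
    studied_tfs: frozenset
    studied_tgs: frozenset

    def __post_init__(self) -> None:
        for tf, tg in self.positives:
            if tf not in self.studied_tfs or tg not in self.studied_tgs:
                raise ValueError(f"gold edge ({tf}, {tg}) outside the studied universe")

    @staticmethod
    def from_edges(positives, studied_tfs=None, studied_tgs=None) -> "GoldStandard":
        positives = frozenset((str(t), str(g)) for t, g in positives)
        if studied_tfs is None:
            studied_tfs = {t for t, _ in positives}
        if studied_tgs is None:
            studied_tgs = {g for _, g in positives}
        return GoldStandard(positives, frozenset(studied_tfs), frozenset(studied_tgs))


@dataclass
class EvaluationReport:
    """Binary-classification metrics of a predicted network vs a gold standard."""

    auroc: float
    aupr: float
    f1: float
    precision: float
    recall: float
    n_evaluable_links: int
    n_excluded_links: int
    n_positives: int

    def to_dict(self) -> dict:
        return {
            "auroc": self.auroc,
            "aupr": self.aupr,
            "f1": self.f1,
            "precision": self.precision,
            "recall": self.recall,
            "n_evaluable_links": self.n_evaluable_links,
            "n_excluded_links": self.n_excluded_links,
            "n_positives": self.n_positives,
        }


@dataclass
class EnsembleResult:
    """Ensemble score matrix plus provenance (members and integration scheme)."""

    scores: ScoreMatrix
    members: list = field(default_factory=list)
    scheme: str = ""


def make_edge_frame(records) -> pd.DataFrame:
    """Build a ranked edge list: descending score, ties by (tf, tg)."""
    edges = pd.DataFrame(records, columns=EDGE_COLUMNS)
    edges = edges.sort_values(
        by=["score", "tf", "tg"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    return edges
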