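"""Readers and writers for all on-disk formats.

Formats
-------
* Expression / count matrix: TSV or CSV, first column gene id, header row
  condition ids (``--transpose`` for conditions-in-rows files).
* Gene lengths: two-column TSV ``gene<TAB>length_bp`` (header optional).
* Regulator list: one gene id per line.
* Gold standard: DREAM5 dialect — ``TF<TAB>TG<TAB>{0,1}``; rows labelled 0
  are known non-interactions and only widen the studied universe.  A
  two-column file means every listed edge is a positive.
* Adjacency list: ``TF<TAB>target<TAB>importance`` in ranked order, the
  dialect consumed by SCENIC-style refinement tools.

All writers render floats with ``repr`` so write/read round-trips are
bit-exact and repeated runs are byte-identical.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EvaluationReport, GoldStandard, ScoreMatrix, make_edge_frame


def _sep_for(path, sep: str | None) -> str:
    if sep:
        return sep
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_expression(path, transpose: bool = False, sep: str | None = None) -> pd.DataFrame:
    """Read a genes x conditions matrix, validating ids and numeric cells."""
    sep = _sep_for(path, sep)
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as err:
        raise ValueError(f"{path}: malformed table ({err})") from err
    if transpose:
        frame = frame.T
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    frame.index.name = None
    frame.columns.name = None
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicated gene id(s) {dups}")
    if frame.columns.has_duplicates:
        dups = frame.columns[frame.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicated condition id(s) {dups}")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~frame.isna()
    if bad.to_numpy().any():
        rows = frame.index[bad.any(axis=1)].tolist()
        raise ValueError(f"{path}: non-numeric cell(s) in gene row(s) {rows}")
    if numeric.isna().to_numpy().any():
        rows = numeric.index[numeric.isna().any(axis=1)].tolist()
        raise ValueError(f"{path}: missing value(s) in gene row(s) {rows}")
    return numeric


def write_expression(expr: pd.DataFrame, path, sep: str | None = None) -> None:
    sep = _sep_for(path, sep)
    with open(path, "w") as handle:
        handle.write("gene" + sep + sep.join(map(str, expr.columns)) + "\n")
        for gene, row in zip(expr.index, expr.to_numpy()):
            handle.write(str(gene) + sep + sep.join(repr(float(v)) for v in row) + "\n")


def read_gene_lengths(path) -> pd.Series:
    """Read a two-column ``gene<TAB>length_bp`` table (header optional)."""
    table = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if table.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (gene, length)")
    if table.iloc[0, 1].strip().lower() in ("length", "length_bp"):
        table = table.iloc[1:]
    lengths = pd.to_numeric(table.iloc[:, 1], errors="raise").astype(int)
    lengths.index = table.iloc[:, 0].astype(str)
    if (lengths <= 0).any():
        raise ValueError(f"{path}: non-positive gene length present")
    return lengths


def read_regulators(path) -> list:
    """Read one regulator id per line; duplicates dropped with a warning."""
    seen = {}
    duplicated = []
    with open(path) as handle:
        for line in handle:
            name = line.strip()
            if not name:
                continue
            if name in seen:
                duplicated.append(name)
            else:
                seen[name] = None
    if duplicated:
        warnings.warn(
            f"duplicated regulator id(s) dropped: {sorted(set(duplicated))}",
            RuntimeWarning,
            stacklevel=2,
        )
    if not seen:
        raise ValueError(f"{path}: empty regulator list")
    return list(seen)


def read_gold_standard(path) -> GoldStandard:
    """Read a DREAM5-style gold standard (2 or 3 tab-separated columns)."""
    positives = set()
    tfs, tgs = set(), set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].strip().upper() == "TF":
                continue
            if len(fields) not in (2, 3):
                raise ValueError(f"{path}:{lineno}: expected 2 or 3 columns")
            tf, tg = fields[0].strip(), fields[1].strip()
            label = fields[2].strip() if len(fields) == 3 else "1"
            if label not in ("0", "1"):
                raise ValueError(f"{path}:{lineno}: label {label!r} not in {{0,1}}")
            tfs.add(tf)
            tgs.add(tg)
            if label == "1":
                positives.add((tf, tg))
    if not tfs:
        raise ValueError(f"{path}: empty gold standard")
    return GoldStandard(frozenset(positives), frozenset(tfs), frozenset(tgs))


def write_gold_standard(gold: GoldStandard, path) -> None:
    universe = [
        (t, g)
        for t in sorted(gold.studied_tfs)
        for g in sorted(gold.studied_tgs)
        if t != g
    ]
    with open(path, "w") as handle:
        for tf, tg in universe:
            label = 1 if (tf, tg) in gold.positives else 0
            handle.write(f"{tf}\t{tg}\t{label}\n")


def read_scores(path, method_name: str | None = None) -> ScoreMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return ScoreMatrix(frame, method_name=method_name or Path(path).stem)


def write_scores(scores: ScoreMatrix, path) -> None:
    frame = scores.scores
    with open(path, "w") as handle:
        handle.write("tf\t" + "\t".join(map(str, frame.columns)) + "\n")
        for tf, row in zip(frame.index, frame.to_numpy()):
            cells = ["" if not np.isfinite(v) else repr(float(v)) for v in row]
            handle.write(str(tf) + "\t" + "\t".join(cells) + "\n")


def write_adjacency(edges: pd.DataFrame, path) -> None:
    """Write a ranked edge list as ``TF<TAB>target<TAB>importance``."""
    with open(path, "w") as handle:
        handle.write("TF\ttarget\timportance\n")
        for tf, tg, score in edges[["tf", "tg", "score"]].itertuples(index=False):
            handle.write(f"{tf}\t{tg}\t{repr(float(score))}\n")


def read_adjacency(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"TF": str, "target": str})
    if list(frame.columns) != ["TF", "target", "importance"]:
        raise ValueError(f"{path}: expected header TF<TAB>target<TAB>importance")
    frame.columns = ["tf", "tg", "score"]
    return make_edge_frame(frame.to_dict("records"))


def write_report(report: EvaluationReport, path, as_json: bool = True) -> None:
    data = report.to_dict()
    with open(path, "w") as handle:
        if as_json:
            json.dump(data, handle, indent=2, sort_keys=True)
            handle.write("\n")
        else:
            for key, value in data.items():
                handle.write(f"{key}\t{value!r}\n")
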