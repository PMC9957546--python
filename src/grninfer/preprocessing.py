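"""Expression-matrix preprocessing: normalization, discretization, standardization.

Three families of transforms, all operating on genes x conditions DataFrames:

* **RNA-seq normalization** — reads-per-million (RPM) for library-size bias,
  reads-per-kilobase (RPK) for gene-length bias, RPKM and TPM for both, and
  median-of-ratios size factors for between-sample depth correction.
* **Discretization** — equal-frequency (EFD), equal-width (EWD), 1-D K-means
  by rows (KMr) or columns (KMc), and an alternating bidirectional K-means
  (BKM); used both as a preprocessing step and to label target genes for
  classification-based scorers.
* **Standardization** — row-wise z-score (Zr), column-wise z-score (Zc) and
  iterative mean polishing (P).

Z-scores use the population convention (divide by n); discretizers are fully
deterministic for a fixed seed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import validate_counts, validate_expression

NORMALIZE_METHODS = ("rpm", "rpk", "rpkm", "tpm", "mor")
DISCRETIZE_METHODS = ("efd", "ewd", "kmr", "kmc", "bkm")
STANDARDIZE_METHODS = ("zr", "zc", "polish")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def _library_sizes(counts: pd.DataFrame) -> np.ndarray:
    sizes = counts.to_numpy(dtype=float).sum(axis=0)
    zero = np.flatnonzero(sizes == 0)
    if zero.size:
        bad = counts.columns[zero].tolist()
        raise ValueError(f"zero library size in condition(s): {bad}")
    return sizes


def normalize_library(counts: pd.DataFrame) -> pd.DataFrame:
    """Reads per million: scale each condition so its column sums to 1e6."""
    validate_counts(counts)
    sizes = _library_sizes(counts)
    return counts / sizes * 1e6


def _lengths_kb(counts: pd.DataFrame, lengths: pd.Series) -> np.ndarray:
    lengths = lengths.astype(float)
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"missing gene length for: {missing.tolist()}")
    kb = lengths.reindex(counts.index).to_numpy() / 1000.0
    if (kb <= 0).any():
        bad = counts.index[kb <= 0].tolist()
        raise ValueError(f"non-positive gene length for: {bad}")
    return kb


def normalize_length(counts: pd.DataFrame, lengths: pd.Series, method: str = "tpm") -> pd.DataFrame:
    """Length-aware normalization: RPK, RPKM or TPM.

    RPK divides counts by gene length in kilobases; RPKM applies RPM first and
    then the per-kilobase division; TPM rescales RPK columns to sum to 1e6 so
    values are comparable across libraries.
    """
    validate_counts(counts)
    method = method.lower()
    kb = _lengths_kb(counts, lengths)
    if method == "rpk":
        return counts.div(kb, axis=0)
    if method == "rpkm":
        return normalize_library(counts).div(kb, axis=0)
    if method == "tpm":
        rpk = counts.div(kb, axis=0)
        sizes = _library_sizes(rpk)
        return rpk / sizes * 1e6
    raise ValueError(f"unknown length normalization {method!r}")


def size_factor_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Median-of-ratios depth normalization.

    Size factors are the per-condition median of count-to-geometric-mean
    ratios, taken over genes expressed in every condition; columns are then
    divided by their factor. This removes a pure sequencing-depth effect
    exactly while being robust to a minority of differentially expressed
    genes.
    """
    validate_counts(counts)
    values = counts.to_numpy(dtype=float)
    all_positive = (values > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError("median-of-ratios: no gene with positive counts in every condition")
    ref = values[all_positive]
    geomean = np.exp(np.log(ref).mean(axis=1))
    factors = np.median(ref / geomean[:, None], axis=0)
    return counts / factors


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Expose the median-of-ratios size factors themselves."""
    normalized = size_factor_normalize(counts)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = counts.to_numpy(dtype=float) / normalized.to_numpy()
    return pd.Series(np.nanmedian(ratio, axis=0), index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, method: str, lengths: pd.Series | None = None) -> pd.DataFrame:
    """Dispatch on method name (``rpm``, ``rpk``, ``rpkm``, ``tpm``, ``mor``)."""
    method = method.lower()
    if method == "rpm":
        return normalize_library(counts)
    if method == "mor":
        return size_factor_normalize(counts)
    if method in ("rpk", "rpkm", "tpm"):
        if lengths is None:
            raise ValueError(f"method {method!r} requires a gene-length table")
        return normalize_length(counts, lengths, method)
    raise ValueError(f"unknown normalization {method!r}")


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

def _efd_row(values: np.ndarray, n_levels: int) -> np.ndarray:
    # rank-based equal-frequency bins; ties broken stably by position
    order = np.argsort(values, kind="stable")
    levels = np.empty(values.shape[0], dtype=np.int64)
    levels[order] = np.arange(values.shape[0]) * n_levels // values.shape[0]
    return levels


def _ewd_row(values: np.ndarray, n_levels: int) -> np.ndarray:
    vmin, vmax = values.min(), values.max()
    if vmax == vmin:
        return np.zeros(values.shape[0], dtype=np.int64)
    scaled = (values - vmin) / (vmax - vmin) * n_levels
    return np.minimum(scaled.astype(np.int64), n_levels - 1)


def kmeans_1d(values: np.ndarray, n_levels: int, max_iter: int = 300) -> np.ndarray:
    """1-D Lloyd K-means with evenly spaced quantile-centre initialization.

    Deterministic by construction.  Labels are relabelled so that a higher
    level always corresponds to a higher cluster centre.  When the data hold
    fewer distinct values than levels, ties collapse: each distinct value
    becomes its own level.
    """
    values = np.asarray(values, dtype=float)
    uniq = np.unique(values)
    if uniq.size <= n_levels:
        return np.searchsorted(uniq, values)
    centers = np.quantile(values, (np.arange(n_levels) + 0.5) / n_levels)
    if np.unique(centers).size < n_levels:
        idx = np.round(np.linspace(0, uniq.size - 1, n_levels)).astype(int)
        centers = uniq[idx]
    labels = np.zeros(values.shape[0], dtype=np.int64)
    for _ in range(max_iter):
        centers = np.sort(centers)
        mid = (centers[1:] + centers[:-1]) / 2.0
        new_labels = np.searchsorted(mid, values)
        new_centers = centers.copy()
        for k in range(n_levels):
            mask = new_labels == k
            if mask.any():
                new_centers[k] = values[mask].mean()
        if np.array_equal(new_labels, labels) and np.allclose(new_centers, centers):
            labels = new_labels
            break
        labels, centers = new_labels, new_centers
    return labels


def _discretize_rows(values: np.ndarray, n_levels: int, row_fn) -> np.ndarray:
    out = np.empty(values.shape, dtype=np.int64)
    for i in range(values.shape[0]):
        out[i] = row_fn(values[i], n_levels)
    return out


def discretize(
    expr: pd.DataFrame, method: str, n_levels: int, seed: int = 0, max_alternations: int = 50
) -> pd.DataFrame:
    """Discretize an expression matrix into integer levels ``0..n_levels-1``.

    ``seed`` is accepted for interface stability; every discretizer here is
    deterministic regardless (quantile-seeded K-means, rank-based EFD).
    BKM alternates row-wise and column-wise K-means re-assignment on the
    current label matrix until the joint labels are stable or
    ``max_alternations`` passes elapse.
    """
    validate_expression(expr)
    method = method.lower()
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    values = expr.to_numpy(dtype=float)
    n_genes, n_conditions = values.shape
    if method in ("efd", "ewd", "kmr", "bkm") and n_levels > n_conditions:
        raise ValueError(
            f"n_levels={n_levels} exceeds the number of conditions ({n_conditions})"
        )
    if method in ("kmc",) and n_levels > n_genes:
        raise ValueError(f"n_levels={n_levels} exceeds the number of genes ({n_genes})")

    if method == "efd":
        out = _discretize_rows(values, n_levels, _efd_row)
    elif method == "ewd":
        out = _discretize_rows(values, n_levels, _ewd_row)
    elif method == "kmr":
        out = _discretize_rows(values, n_levels, lambda v, L: kmeans_1d(v, L))
    elif method == "kmc":
        out = _discretize_rows(values.T, n_levels, lambda v, L: kmeans_1d(v, L)).T
    elif method == "bkm":
        out = _bkm(values, n_levels, max_alternations)
    else:
        raise ValueError(f"unknown discretization {method!r}")
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def _bkm(values: np.ndarray, n_levels: int, max_alternations: int) -> np.ndarray:
    current = values.astype(float)
    previous = None
    labels = None
    for _ in range(max_alternations):
        by_rows = _discretize_rows(current, n_levels, lambda v, L: kmeans_1d(v, L))
        labels = _discretize_rows(
            by_rows.T.astype(float), n_levels, lambda v, L: kmeans_1d(v, L)
        ).T
        if previous is not None and np.array_equal(labels, previous):
            break
        previous = labels
        current = labels.astype(float)
    return labels


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def standardize(
    expr: pd.DataFrame, method: str, tol: float = 1e-8, max_sweeps: int = 100
) -> pd.DataFrame:
    """Standardize expression: ``zr`` (rows), ``zc`` (columns) or ``polish``.

    Z-scores use the population standard deviation (ddof=0). Polishing
    alternately removes row then column means until every absolute mean
    falls below ``tol``; variances are left untouched.  Constant rows
    (for ``zr``) or columns (for ``zc``) are an error — filter flat genes
    before z-scoring.
    """
    validate_expression(expr)
    method = method.lower()
    values = expr.to_numpy(dtype=float)
    if method == "zr":
        sd = values.std(axis=1, ddof=0)
        if (sd == 0).any():
            bad = expr.index[sd == 0].tolist()
            raise ValueError(f"constant gene row(s), cannot z-score: {bad}")
        out = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]
    elif method == "zc":
        sd = values.std(axis=0, ddof=0)
        if (sd == 0).any():
            bad = expr.columns[sd == 0].tolist()
            raise ValueError(f"constant condition column(s), cannot z-score: {bad}")
        out = (values - values.mean(axis=0, keepdims=True)) / sd[None, :]
    elif method == "polish":
        out = values.copy()
        for _ in range(max_sweeps):
            out = out - out.mean(axis=1, keepdims=True)
            out = out - out.mean(axis=0, keepdims=True)
            if (
                np.abs(out.mean(axis=1)).max() < tol
                and np.abs(out.mean(axis=0)).max() < tol
            ):
                break
        else:
            warnings.warn("mean polishing did not converge", RuntimeWarning, stacklevel=2)
    else:
        raise ValueError(f"unknown standardization {method!r}")
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)
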