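"""Cross-species cell-type correspondence from median expression profiles.

For each species, cells are collapsed to a genes x cell-groups matrix of
median expression.  Profiles are normalized as ``ln(1 + x) - rowMeans(ln(1 +
x))`` — a per-gene centering that removes baseline expression so only the
across-group pattern remains — and cell-group pairs are compared by the
Pearson correlation of their centered profiles over the shared homologous
HVG pairs.  A simple correlation-to-centroid scorer assigns reference labels
to query cells the same way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError
from .io_formats import ExpressionMatrix
from .orthology import OrthologTable


@dataclass
class GroupProfileMatrix:
    """Genes x cell-group medians for one species."""

    species: str
    values: pd.DataFrame  # index = gene ids, columns = group labels
    centered: bool = False


@dataclass
class CorrespondenceMatrix:
    """Groups_A x groups_B Pearson correlations over shared gene pairs."""

    values: pd.DataFrame
    n_genes: int

    def row_argmax(self) -> pd.Series:
        return self.values.idxmax(axis=1)


@dataclass
class LabelScoreMatrix:
    """Query cells x reference labels scores (rows sum to 1) + predictions."""

    scores: pd.DataFrame
    predicted: pd.Series


def group_profiles(m: ExpressionMatrix, ann: pd.DataFrame,
                   stat: str = "median",
                   undo_log: bool = False) -> GroupProfileMatrix:
    """Per-group expression profiles (median or mean aggregation).

    Every cell of the matrix must be labeled.  ``undo_log=True`` converts a
    lognorm layer back to the linear normalized scale (expm1) before
    aggregating, so median profiles feed directly into the log1p-centering
    step (the median commutes with the monotone transform either way).
    Median profiles match the display convention of cross-species
    correspondence; mean profiles are the natural centroids for per-cell
    label scoring, where low-count medians quantize to zero.
    """
    if stat not in ("median", "mean"):
        raise ContractError(f"stat must be 'median' or 'mean', got {stat!r}")
    labels = dict(zip(ann["cell_id"], ann["label"]))
    missing = [c for c in m.cell_ids if c not in labels]
    if missing:
        raise ContractError(f"unlabeled cells: {missing[:5]}")
    if undo_log and m.layer != "lognorm":
        raise ContractError("undo_log only applies to the lognorm layer")
    vals = np.expm1(m.values) if undo_log else m.values
    cell_labels = np.array([labels[c] for c in m.cell_ids])
    groups = list(dict.fromkeys(cell_labels))  # first-appearance order
    agg = np.median if stat == "median" else np.mean
    cols = {}
    for g in groups:
        mask = cell_labels == g
        if mask.sum() == 1:
            warnings.warn(f"group {g!r} has a single cell; profile is that cell")
        cols[g] = agg(vals[:, mask], axis=1)
    prof = pd.DataFrame(cols, index=m.gene_ids)
    return GroupProfileMatrix(m.species, prof, centered=False)


def group_median_profiles(m: ExpressionMatrix, ann: pd.DataFrame,
                          undo_log: bool = False) -> GroupProfileMatrix:
    """Median expression of every gene within every annotated cell group."""
    return group_profiles(m, ann, stat="median", undo_log=undo_log)


def center_log_profiles(p: GroupProfileMatrix) -> GroupProfileMatrix:
    """Apply ``ln(1 + x) - rowMeans(ln(1 + x))`` to a profile matrix."""
    if p.centered:
        raise ContractError("profiles are already centered")
    if (p.values.to_numpy() < 0).any():
        raise ContractError("centering expects non-negative profile values")
    logged = np.log1p(p.values.to_numpy(dtype=float))
    centered = logged - logged.mean(axis=1, keepdims=True)
    return GroupProfileMatrix(p.species,
                              pd.DataFrame(centered, index=p.values.index,
                                           columns=p.values.columns),
                              centered=True)


def center_profiles(p: GroupProfileMatrix) -> GroupProfileMatrix:
    """Row-center a profile matrix on its existing scale (no log transform).

    The centroid analogue of :func:`center_log_profiles` for profiles already
    on a log scale (e.g. mean lognorm centroids for label scoring).
    """
    if p.centered:
        raise ContractError("profiles are already centered")
    vals = p.values.to_numpy(dtype=float)
    centered = vals - vals.mean(axis=1, keepdims=True)
    return GroupProfileMatrix(p.species,
                              pd.DataFrame(centered, index=p.values.index,
                                           columns=p.values.columns),
                              centered=True)


def _pearson_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between every column of ``a`` and every column of ``b``.

    Constant columns yield NaN in their rows/columns.
    """
    ac = a - a.mean(axis=0, keepdims=True)
    bc = b - b.mean(axis=0, keepdims=True)
    an = np.linalg.norm(ac, axis=0)
    bn = np.linalg.norm(bc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (ac.T @ bc) / np.outer(an, bn)
    r[an == 0, :] = np.nan
    r[:, bn == 0] = np.nan
    return np.clip(r, -1.0, 1.0)  # guard rounding; NaN propagates


def cross_species_correlation(p_a: GroupProfileMatrix, p_b: GroupProfileMatrix,
                              pairs: pd.DataFrame) -> CorrespondenceMatrix:
    """Pearson correlation of centered group profiles across species.

    Genes are aligned through the ortholog pairs (columns gene_a, gene_b);
    requires at least 3 pairs.  Constant profile columns give NaN entries
    (reported, never imputed as zero).
    """
    if not p_a.centered or not p_b.centered:
        raise ContractError("both profile matrices must be centered first")
    if len(pairs) < 3:
        raise ContractError(f"need >= 3 shared gene pairs, got {len(pairs)}")
    a = p_a.values.loc[pairs["gene_a"]].to_numpy(dtype=float)
    b = p_b.values.loc[pairs["gene_b"]].to_numpy(dtype=float)
    r = _pearson_columns(a, b)
    if np.isnan(r).any():
        warnings.warn("constant profile column(s) produced NaN correlations")
    df = pd.DataFrame(r, index=p_a.values.columns, columns=p_b.values.columns)
    return CorrespondenceMatrix(df, n_genes=len(pairs))


def score_labels(query: ExpressionMatrix, ref_profiles: GroupProfileMatrix,
                 pairs: pd.DataFrame) -> LabelScoreMatrix:
    """Score query cells against reference group centroids.

    Per cell: Pearson r to every centered reference centroid over the paired
    genes (query genes from the pairs column matching the query species side).
    Query expression is first centered per gene by its mean across the query
    cells, mirroring the row-centering of the reference profiles — both sides
    are compared as deviations from their dataset baseline.  Negative
    correlations are rectified to 0 and rows renormalized to sum 1 (uniform
    if every r <= 0 or the cell is constant).  Predicted label is the row
    argmax, earliest label on exact ties.
    """
    if not ref_profiles.centered:
        raise ContractError("reference profiles must be centered")
    if len(pairs) < 3:
        raise ContractError(f"need >= 3 shared gene pairs, got {len(pairs)}")
    gidx = query.gene_index()
    ref_genes = set(ref_profiles.values.index)
    if pairs["gene_a"].isin(gidx).all() and pairs["gene_b"].isin(ref_genes).all():
        qcol, rcol = "gene_a", "gene_b"
    elif pairs["gene_b"].isin(gidx).all() and pairs["gene_a"].isin(ref_genes).all():
        qcol, rcol = "gene_b", "gene_a"
    else:
        raise ContractError("gene pairs do not align query and reference genes")
    q = query.values[[gidx[g] for g in pairs[qcol]], :]
    q = q - q.mean(axis=1, keepdims=True)  # per-gene query baseline removed
    ref = ref_profiles.values.loc[pairs[rcol]].to_numpy(dtype=float)
    r = _pearson_columns(q, ref)
    const = ~np.isfinite(r).any(axis=1)
    if const.any():
        warnings.warn(f"{int(const.sum())} constant query cell(s); "
                      "uniform scores assigned")
    r = np.nan_to_num(r, nan=0.0)
    pos = np.maximum(r, 0.0)
    rowsum = pos.sum(axis=1)
    flat = rowsum == 0
    n_labels = ref.shape[1]
    scores = np.where(flat[:, None], 1.0 / n_labels,
                      pos / np.where(flat, 1.0, rowsum)[:, None])
    sdf = pd.DataFrame(scores, index=query.cell_ids,
                       columns=ref_profiles.values.columns)
    predicted = sdf.columns[np.argmax(sdf.to_numpy(), axis=1)]
    return LabelScoreMatrix(sdf, pd.Series(predicted, index=query.cell_ids,
                                           name="predicted"))
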