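"""Gene-set scores, pseudotime trends, and Wilcoxon differential expression.

Module scores follow the binned-control convention: genes are binned by
dataset-average expression, each set gene draws expression-matched control
genes from its bin, and the score is the per-cell mean of the set minus the
mean of the pooled controls.  Differential expression is a per-gene two-sided
Wilcoxon rank-sum test (exact for small tie-free groups, otherwise the
tie-corrected normal approximation with continuity correction),
Benjamini-Hochberg adjusted, with markers taken as the top upregulated genes
ranked by fold change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError
from .io_formats import ExpressionMatrix

#: adjusted-p threshold below which a gene is called significant
SIGNIFICANCE_THRESHOLD = 1e-4


@dataclass
class ModuleScoreVector:
    scores: pd.Series  # indexed by cell id
    params: dict = field(default_factory=dict)


def module_score(m: ExpressionMatrix, gene_set: list[str], seed: int,
                 n_bins: int = 24, n_ctrl: int = 100) -> ModuleScoreVector:
    """Per-cell gene-set score against expression-matched controls.

    All genes are ranked by their dataset-average expression into ``n_bins``
    equal-frequency bins; every set gene draws ``n_ctrl`` control genes from
    its own bin (with replacement when the bin is smaller) using the seeded
    RNG.  The score is mean(set) - mean(pooled controls) per cell, so a
    random set scores ~0 and the score is invariant to global additive
    shifts of the expression layer.
    """
    if not gene_set:
        raise ContractError("gene_set is empty")
    gidx = m.gene_index()
    missing = [g for g in gene_set if g not in gidx]
    if missing:
        raise ContractError(f"gene(s) absent from matrix: {missing[:5]}")
    rng = np.random.default_rng(seed)
    avg = m.values.mean(axis=1)
    order = np.argsort(avg, kind="stable")
    ranks = np.empty(m.n_genes, dtype=int)
    ranks[order] = np.arange(m.n_genes)
    bins = ranks * n_bins // m.n_genes  # equal-frequency bins
    bin_members = {b: np.flatnonzero(bins == b) for b in range(n_bins)}
    ctrl_rows: list[np.ndarray] = []
    for g in gene_set:
        b = bins[gidx[g]]
        members = bin_members[int(b)]
        replace = len(members) < n_ctrl
        ctrl_rows.append(rng.choice(members, size=n_ctrl, replace=replace))
    ctrl = np.concatenate(ctrl_rows)
    set_rows = np.array([gidx[g] for g in gene_set])
    scores = m.values[set_rows].mean(axis=0) - m.values[ctrl].mean(axis=0)
    return ModuleScoreVector(pd.Series(scores, index=m.cell_ids, name="score"),
                             params={"n_bins": n_bins, "n_ctrl": n_ctrl,
                                     "seed": seed, "n_set": len(gene_set)})


def trend_along_pseudotime(values: np.ndarray | pd.Series,
                           pseudotime: np.ndarray | pd.Series,
                           window_frac: float = 0.2) -> pd.DataFrame:
    """Sliding-window mean of per-cell values along pseudotime order.

    Cells are sorted by pseudotime (stable) and smoothed with a centered
    window of ``ceil(window_frac * N)`` neighbours, truncated at the edges;
    monotone input yields a monotone curve.  Returns a DataFrame with columns
    (pseudotime, value, trend) in pseudotime order.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(pseudotime, dtype=float)
    if len(v) != len(t):
        raise ContractError("values and pseudotime must align")
    if len(v) < 5:
        raise ContractError("need >= 5 cells for a trend")
    if not np.isfinite(t).all():
        raise ContractError("pseudotime must be finite")
    order = np.argsort(t, kind="stable")
    vs, ts = v[order], t[order]
    n = len(vs)
    w = max(int(np.ceil(window_frac * n)), 1)
    half = w // 2
    cs = np.concatenate([[0.0], np.cumsum(vs)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + (w - half), n)
    trend = (cs[hi] - cs[lo]) / (hi - lo)
    return pd.DataFrame({"pseudotime": ts, "value": vs, "trend": trend})


def _wilcoxon_asymptotic(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Vectorized two-sided rank-sum p (tie + continuity corrected) per gene.

    ``xa``/``xb``: genes x cells blocks for the two groups.
    """
    na, nb = xa.shape[1], xb.shape[1]
    x = np.concatenate([xa, xb], axis=1)
    ranks = stats.rankdata(x, axis=1)
    U = ranks[:, :na].sum(axis=1) - na * (na + 1) / 2.0
    mu = na * nb / 2.0
    n = na + nb
    # tie correction: sum over tied groups of (t^3 - t) per gene
    xs = np.sort(x, axis=1)
    same = np.concatenate([np.zeros((x.shape[0], 1), bool),
                           xs[:, 1:] == xs[:, :-1]], axis=1)
    tie_term = np.zeros(x.shape[0])
    for g in range(x.shape[0]):
        runs = np.diff(np.flatnonzero(np.concatenate(
            [[True], ~same[g, 1:], [True]])))
        tie_term[g] = float((runs.astype(float) ** 3 - runs).sum())
    sigma2 = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = np.sqrt(sigma2)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (np.abs(U - mu) - 0.5) / sigma
    p = 2.0 * stats.norm.sf(np.maximum(z, 0.0))
    p = np.where(sigma == 0, 1.0, p)  # all values tied -> no evidence
    return np.minimum(p, 1.0)


def _wilcoxon_exact(xa: np.ndarray, xb: np.ndarray) -> float:
    res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method="exact")
    return float(res.pvalue)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return stats.false_discovery_control(np.asarray(p, float), method="bh")


def wilcoxon_de(m: ExpressionMatrix, cells_a: list[str], cells_b: list[str],
                exact_max_n: int = 10) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum DE between two disjoint cell groups.

    The exact null distribution is used when both groups have at most
    ``exact_max_n`` cells and the gene has no ties across the pooled groups;
    otherwise the normal approximation with tie and continuity corrections.
    Fold change is ``ln((mean_a(expm1 v) + 1) / (mean_b(expm1 v) + 1))``
    (pseudocount 1 on the linear normalized scale).  Returns a DataFrame with
    columns (gene, log_fc, p, p_adj, significant, direction); significance is
    ``p_adj < 1e-4``.
    """
    if m.layer != "lognorm":
        raise ContractError(f"wilcoxon_de expects lognorm layer, got {m.layer}")
    sa, sb = set(cells_a), set(cells_b)
    if sa & sb:
        raise ContractError(f"groups overlap: {sorted(sa & sb)[:5]}")
    if len(cells_a) < 3 or len(cells_b) < 3:
        raise ContractError("each group needs >= 3 cells")
    cidx = {c: i for i, c in enumerate(m.cell_ids)}
    missing = [c for c in list(cells_a) + list(cells_b) if c not in cidx]
    if missing:
        raise ContractError(f"cells absent from matrix: {missing[:5]}")
    xa = m.values[:, [cidx[c] for c in cells_a]]
    xb = m.values[:, [cidx[c] for c in cells_b]]
    na, nb = xa.shape[1], xb.shape[1]
    p = _wilcoxon_asymptotic(xa, xb)
    if na <= exact_max_n and nb <= exact_max_n:
        for g in range(m.n_genes):
            pooled = np.concatenate([xa[g], xb[g]])
            if len(np.unique(pooled)) == len(pooled):  # tie-free
                p[g] = _wilcoxon_exact(xa[g], xb[g])
    mean_a = np.expm1(xa).mean(axis=1)
    mean_b = np.expm1(xb).mean(axis=1)
    log_fc = np.log((mean_a + 1.0) / (mean_b + 1.0))
    p_adj = benjamini_hochberg(p)
    direction = np.where(log_fc > 0, "up", np.where(log_fc < 0, "down", "none"))
    return pd.DataFrame({
        "gene": m.gene_ids,
        "log_fc": log_fc,
        "p": p,
        "p_adj": p_adj,
        "significant": p_adj < SIGNIFICANCE_THRESHOLD,
        "direction": direction,
    })


def marker_signature(deg: pd.DataFrame, k: int = 20) -> list[str]:
    """Top-k significant upregulated genes ranked by fold change (descending).

    Fold-change ties break by smaller adjusted p, then symbol order.  Fewer
    than ``k`` available returns all of them with a warning.
    """
    if k < 1:
        raise ContractError("k must be >= 1")
    up = deg.loc[deg["significant"] & (deg["direction"] == "up")]
    ordered = up.sort_values(["log_fc", "p_adj", "gene"],
                             ascending=[False, True, True])
    genes = ordered["gene"].tolist()
    if len(genes) < k:
        warnings.warn(f"only {len(genes)} significant upregulated genes "
                      f"available (k={k})")
    return genes[:k]
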