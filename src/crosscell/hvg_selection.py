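"""Highly-variable-gene selection restricted to one-to-one orthologs.

The per-gene variance statistic is the vst-style *standardized variance*:
raw counts are standardized by the gene mean and by the standard deviation
expected from a local-regression fit of log10(variance) on log10(mean),
clipped at sqrt(N), and the variance of the clipped values is reported.
Genes sitting on the global mean-variance trend score ~1; genuinely variable
genes score above it.  Selection uses the mean of the standardized variances
over the orthologous candidate set as the cutoff (strictly greater than).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError
from .io_formats import ExpressionMatrix
from .orthology import OrthologTable


def local_poly_fit(x: np.ndarray, y: np.ndarray, span: float = 0.3,
                   degree: int = 2) -> np.ndarray:
    """Local polynomial regression (tricube weights, nearest-span windows).

    Returns fitted values of ``y`` at each ``x``.  Windows are the
    ``ceil(span * n)`` nearest neighbours in ``x``; ties and zero-width
    windows degrade gracefully to weighted means.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n == 0:
        return np.empty(0)
    k = min(n, max(int(np.ceil(span * n)), degree + 2))
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    # left edge of each nearest-k window via two-pointer sweep
    starts = np.empty(n, dtype=int)
    left = 0
    for i in range(n):
        while left + k < n and xs[i] - xs[left] > xs[left + k] - xs[i]:
            left += 1
        starts[i] = left
    idx = starts[:, None] + np.arange(k)[None, :]
    t = xs[idx] - xs[:, None]
    d = np.abs(t)
    dmax = d.max(axis=1)
    flat = dmax <= 0
    dmax_safe = np.where(flat, 1.0, dmax)
    w = (1.0 - np.clip(d / dmax_safe[:, None], 0, 1) ** 3) ** 3
    w[flat] = 1.0
    # powers of t: (n, k, degree+1), column 0 is the intercept
    P = t[:, :, None] ** np.arange(degree + 1)[None, None, :]
    M = np.einsum("nk,nki,nkj->nij", w, P, P)
    b = np.einsum("nk,nki,nk->ni", w, P, ys[idx])
    # tiny ridge keeps windows with duplicated x invertible
    M += 1e-10 * np.eye(degree + 1)[None, :, :]
    beta = np.linalg.solve(M, b[:, :, None])[:, :, 0]
    fitted_sorted = beta[:, 0]
    wm = (w * ys[idx]).sum(axis=1) / w.sum(axis=1)
    fitted_sorted = np.where(flat, wm, fitted_sorted)
    fitted = np.empty(n)
    fitted[order] = fitted_sorted
    return fitted


@dataclass
class HVGTable:
    """Per-gene mean / variance / standardized variance and selection flags.

    ``cutoff`` is None until :func:`select_hvgs_mean_cutoff` has been applied;
    afterwards ``selected`` is exactly ``var_std > cutoff`` and ``cutoff`` is
    the arithmetic mean of ``var_std`` over the candidate genes.
    """

    table: pd.DataFrame  # columns: gene, mean, var, var_std, selected
    cutoff: float | None = None

    def __post_init__(self) -> None:
        required = ["gene", "mean", "var", "var_std", "selected"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ContractError(f"HVGTable missing column(s) {missing}")
        self.table = self.table.reset_index(drop=True)

    @property
    def selected_genes(self) -> list[str]:
        return self.table.loc[self.table["selected"], "gene"].tolist()

    def __len__(self) -> int:
        return len(self.table)


def compute_gene_dispersion(m: ExpressionMatrix, span: float = 0.3,
                            degree: int = 2,
                            clip: float | None = None) -> HVGTable:
    """Per-gene (mean, var, standardized variance) from raw counts.

    For each gene with positive mean and variance, counts are standardized by
    the gene mean and the trend-expected standard deviation, clipped above at
    ``clip`` (default sqrt(n_cells)), and the standardized variance is
    ``sum(z^2) / (N - 1)``.  Zero-variance genes get 0.
    """
    if m.layer != "counts":
        raise ContractError(f"dispersion expects counts layer, got {m.layer}")
    n = m.n_cells
    if n < 2:
        raise ContractError("need at least 2 cells to compute dispersion")
    if clip is None:
        clip = float(np.sqrt(n))
    x = m.values
    mu = x.mean(axis=1)
    var = x.var(axis=1, ddof=1)
    var_std = np.zeros(m.n_genes)
    ok = (var > 0) & (mu > 0)
    if ok.any():
        fit = local_poly_fit(np.log10(mu[ok]), np.log10(var[ok]), span, degree)
        sd_exp = np.sqrt(10.0 ** fit)
        z = (x[ok] - mu[ok][:, None]) / sd_exp[:, None]
        np.minimum(z, clip, out=z)
        var_std[ok] = (z ** 2).sum(axis=1) / (n - 1)
    tbl = pd.DataFrame({"gene": m.gene_ids, "mean": mu, "var": var,
                        "var_std": var_std, "selected": False})
    return HVGTable(tbl, cutoff=None)


def select_hvgs_mean_cutoff(stats: HVGTable,
                            candidates: list[str]) -> HVGTable:
    """Flag HVGs by the mean-of-standardized-variances cutoff.

    The table is restricted to ``candidates`` (typically the one-to-one
    ortholog set present in the matrix); the cutoff is their mean standardized
    variance and selection is strictly greater than the cutoff, so an
    all-equal or single-gene candidate set selects nothing.
    """
    cand = [g for g in candidates if g in set(stats.table["gene"])]
    if not cand:
        raise ContractError("empty candidate set for HVG selection")
    sub = stats.table.set_index("gene").loc[cand].reset_index()
    cutoff = float(sub["var_std"].mean())
    sub["selected"] = sub["var_std"] > cutoff
    return HVGTable(sub[["gene", "mean", "var", "var_std", "selected"]],
                    cutoff=cutoff)


def intersect_homologous_hvgs(hvg_a: HVGTable, hvg_b: HVGTable,
                              t: OrthologTable) -> pd.DataFrame:
    """Orthologous pairs selected as highly variable in *both* species.

    Returns a DataFrame with columns (gene_a, gene_b), ordered as in the
    ortholog table; symmetric in species order by construction.
    """
    if not t.is_bijection():
        raise ContractError("intersect_homologous_hvgs requires a bijective "
                            "ortholog table")
    sel_a = set(hvg_a.selected_genes)
    sel_b = set(hvg_b.selected_genes)
    r = t.rows
    keep = r["gene_a"].isin(sel_a) & r["gene_b"].isin(sel_b)
    out = r.loc[keep, ["gene_a", "gene_b"]].reset_index(drop=True)
    if out.empty:
        warnings.warn("no shared homologous HVGs between the two species")
    return out
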