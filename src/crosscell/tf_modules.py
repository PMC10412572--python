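"""Transcription-factor co-expression modules.

TFs drawn from the homologous-HVG set are compared by the Pearson
correlation distance d = sqrt((1 - r) / 2), clustered by UPGMA (size-weighted
average linkage, deterministic lexicographic tie-breaks) and partitioned by a
static tree cut with a minimum module size; ``height="auto"`` places the cut inside the largest gap
between consecutive merge heights.

When a pseudotime is supplied, each TF's expression is first smoothed along
it with a sliding-window mean, so the correlation captures the shared shape
of the expression trend along the trajectory rather than per-cell sampling
noise; without pseudotime the raw per-cell expression is correlated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError
from .hvg_selection import HVGTable
from .io_formats import ExpressionMatrix


@dataclass
class TFDistanceMatrix:
    """Symmetric TF x TF Pearson-distance grid, d in [0, 1], zero diagonal."""

    values: pd.DataFrame

    @property
    def tfs(self) -> list[str]:
        return list(self.values.index)


@dataclass
class MergeTree:
    """Agglomeration record over n leaves: (left, right, height, size) rows.

    Node ids follow the usual convention: leaves are 0..n-1; the merge on row
    i creates node n+i.  UPGMA guarantees non-decreasing heights.
    """

    leaves: list[str]
    merges: np.ndarray  # (n-1, 4): left id, right id, height, new size

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


@dataclass
class ModuleAssignment:
    """TF -> module id; 0 means unassigned, ids 1..M by decreasing size."""

    labels: pd.Series
    min_size: int
    height: float

    def modules(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for tf, mid in self.labels.items():
            out.setdefault(int(mid), []).append(tf)
        return out


def select_tfs(hvg: HVGTable, tf_list: list[str]) -> list[str]:
    """Selected HVGs that are TFs, in the HVG table's row order."""
    if not tf_list:
        raise ContractError("tf_list is empty")
    tfset = set(tf_list)
    out = [g for g in hvg.selected_genes if g in tfset]
    if not out:
        warnings.warn("no selected HVG is in the TF list")
    return out


def _smooth_by_pseudotime(values: np.ndarray, pseudotime: np.ndarray,
                          window_frac: float) -> np.ndarray:
    order = np.argsort(pseudotime, kind="stable")
    n = len(order)
    w = max(int(np.ceil(window_frac * n)), 1)
    half = w // 2
    cs = np.cumsum(values[:, order], axis=1)
    cs = np.concatenate([np.zeros((values.shape[0], 1)), cs], axis=1)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + (w - half), n)
    return (cs[:, hi] - cs[:, lo]) / (hi - lo)


def tf_distance_matrix(m: ExpressionMatrix, tfs: list[str],
                       pseudotime: pd.Series | np.ndarray | None = None,
                       window_frac: float = 0.2) -> TFDistanceMatrix:
    """Pairwise TF distance d = sqrt((1 - r) / 2).

    ``r`` is the Pearson correlation of TF expression across cells; with a
    pseudotime, expression is ordered and window-smoothed along it first.
    Constant TFs get r := 0 against everything (d = sqrt(1/2)) with a
    warning, keeping the matrix clusterable.
    """
    if m.n_cells < 3:
        raise ContractError("need >= 3 cells for TF correlations")
    gidx = m.gene_index()
    missing = [t for t in tfs if t not in gidx]
    if missing:
        raise ContractError(f"TF(s) absent from matrix: {missing}")
    x = m.values[[gidx[t] for t in tfs], :]
    if pseudotime is not None:
        if isinstance(pseudotime, pd.Series):
            pt = pseudotime.reindex(m.cell_ids).to_numpy(dtype=float)
        else:
            pt = np.asarray(pseudotime, dtype=float)
        if len(pt) != m.n_cells or not np.isfinite(pt).all():
            raise ContractError("pseudotime must be finite and cover all cells")
        x = _smooth_by_pseudotime(x, pt, window_frac)
    sd = x.std(axis=1)
    const = sd == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant TF(s); correlation set to 0")
    xc = x - x.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(xc, axis=1)
    norm_safe = np.where(const, 1.0, norm)
    u = xc / norm_safe[:, None]
    r = u @ u.T
    r[const, :] = 0.0
    r[:, const] = 0.0
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    # sqrt amplifies rounding near r = +/-1 (eps in r becomes ~1e-8 in d);
    # snap correlations within 1e-12 of the boundary to exact values
    r[r > 1.0 - 1e-12] = 1.0
    r[r < -1.0 + 1e-12] = -1.0
    d = np.sqrt((1.0 - r) / 2.0)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return TFDistanceMatrix(pd.DataFrame(d, index=tfs, columns=tfs))


def upgma_cluster(d: TFDistanceMatrix) -> MergeTree:
    """UPGMA agglomeration of a distance matrix.

    Repeatedly merges the closest active pair; the distance from the merged
    cluster to any other is the size-weighted average of the members'
    distances, and the merge height is the merging distance.  Ties are broken
    by the lowest (row, col) pair of cluster ids, making the tree
    deterministic across platforms.
    """
    D = d.values.to_numpy(dtype=float).copy()
    n = D.shape[0]
    if n < 2:
        raise ContractError("need >= 2 leaves to cluster")
    if np.isnan(D).any():
        raise ContractError("distance matrix contains NaN")
    ids = list(range(n))          # active cluster ids, ascending
    rows = {i: D[i].copy() for i in range(n)}   # id -> distances keyed by id order
    sizes = {i: 1 for i in range(n)}
    # maintain a dense working matrix indexed by position in `ids`
    work = D
    merges = np.empty((n - 1, 4))
    for step in range(n - 1):
        k = len(ids)
        iu = np.triu_indices(k, 1)
        flat = work[iu]
        best = np.argmin(flat)   # first minimum = lexicographically lowest pair
        i_pos, j_pos = iu[0][best], iu[1][best]
        hi, hj = ids[i_pos], ids[j_pos]
        height = work[i_pos, j_pos]
        si, sj = sizes[hi], sizes[hj]
        new_id = n + step
        new_size = si + sj
        merges[step] = (hi, hj, height, new_size)
        # size-weighted average distances to every other active cluster
        dnew = (si * work[i_pos] + sj * work[j_pos]) / new_size
        keep = [p for p in range(k) if p not in (i_pos, j_pos)]
        new_work = np.empty((k - 1, k - 1))
        new_work[:-1, :-1] = work[np.ix_(keep, keep)]
        new_work[-1, :-1] = dnew[keep]
        new_work[:-1, -1] = dnew[keep]
        new_work[-1, -1] = 0.0
        work = new_work
        ids = [ids[p] for p in keep] + [new_id]
        sizes[new_id] = new_size
    return MergeTree(leaves=list(d.values.index), merges=merges)


def cut_tree_min_size(tree: MergeTree, height: float | str,
                      min_size: int = 5) -> ModuleAssignment:
    """Static tree cut with a minimum module size.

    Cutting at ``height`` applies every merge with height <= the cut;
    resulting branches of size >= ``min_size`` become modules (ids 1..M by
    decreasing size, ties by smallest leaf index), smaller branches are left
    unassigned (id 0).  ``height="auto"`` scans the merge heights and cuts
    inside the largest gap between consecutive heights — the classic
    separation between within-cluster agglomeration and the late merges that
    join genuinely distinct clusters; ties prefer the lower height.  With a
    single merge height the whole tree is one branch.
    """
    if min_size < 1:
        raise ContractError("min_size must be >= 1")
    n = tree.n_leaves
    if min_size > n:
        warnings.warn(f"min_size {min_size} exceeds {n} leaves; "
                      "all TFs unassigned")
        labels = pd.Series(0, index=tree.leaves, name="module")
        return ModuleAssignment(labels, min_size, height=0.0)
    if height == "auto":
        candidates = sorted(set(float(h) for h in tree.heights))
        if len(candidates) == 1:
            height = candidates[0]
        else:
            gaps = np.diff(candidates)
            height = candidates[int(np.argmax(gaps))]  # first largest gap
    else:
        height = float(height)
        if height < 0 or height > float(tree.heights.max()) + 1e-12:
            raise ContractError("cut height outside [0, max merge height]")
    comp = _cut_components(tree, height)
    return ModuleAssignment(_label_components(tree, comp, min_size),
                            min_size, height=float(height))


def _cut_components(tree: MergeTree, height: float) -> np.ndarray:
    """Leaf -> component id after applying merges with height <= cut."""
    n = tree.n_leaves
    parent = list(range(2 * n - 1))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, (left, right, h, _) in enumerate(tree.merges):
        if h <= height + 1e-12:
            new = n + i
            parent[find(int(left))] = new
            parent[find(int(right))] = new
    roots = np.array([find(i) for i in range(n)])
    _, comp = np.unique(roots, return_inverse=True)
    return comp


def _label_components(tree: MergeTree, comp: np.ndarray,
                      min_size: int) -> pd.Series:
    sizes: dict[int, int] = {}
    first_leaf: dict[int, int] = {}
    for leaf, c in enumerate(comp):
        sizes[c] = sizes.get(c, 0) + 1
        first_leaf.setdefault(int(c), leaf)
    big = [c for c, s in sizes.items() if s >= min_size]
    big.sort(key=lambda c: (-sizes[c], first_leaf[c]))
    remap = {c: i + 1 for i, c in enumerate(big)}
    labels = pd.Series([remap.get(int(c), 0) for c in comp],
                       index=tree.leaves, name="module")
    return labels
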