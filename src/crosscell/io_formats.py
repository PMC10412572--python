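"""On-disk formats and the in-memory expression container.

Supported inputs are the 10x-style Matrix-Market triplet (``matrix.mtx`` +
``features.tsv`` + ``barcodes.tsv``, optionally gzipped feature/barcode
files), dense gene-by-cell TSV matrices, and headered annotation tables.
Every other module consumes only the types produced here.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .errors import ContractError, FormatError, ParameterError, SchemaError

LAYERS = ("counts", "lognorm", "standardized")

#: default per-cell scaling for log-normalization (counts per 10k)
DEFAULT_SCALE = 1e4


@dataclass
class ExpressionMatrix:
    """Genes x cells expression values for one species.

    ``values`` is a dense float array with genes on rows.  ``layer`` declares
    the scale of the values: raw ``counts``, ``lognorm`` (ln(1 + scaled
    counts)) or ``standardized``.  Gene and cell identifiers are unique and
    all indexing in the toolkit is by symbol/id, never positional.
    """

    species: str
    gene_ids: list[str]
    cell_ids: list[str]
    layer: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.layer not in LAYERS:
            raise ParameterError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene_ids in ExpressionMatrix")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise FormatError("duplicate cell_ids in ExpressionMatrix")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if not np.isfinite(self.values).all():
            raise FormatError(f"non-finite values in {self.layer} layer")
        if self.layer == "counts" and (self.values < 0).any():
            raise FormatError("counts layer contains negative entries")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        idx = self.gene_index()
        missing = [g for g in genes if g not in idx]
        if missing:
            raise ContractError(f"genes absent from matrix: {missing[:5]}")
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(self.species, list(genes), list(self.cell_ids),
                                self.layer, self.values[rows])

    def subset_cells(self, cells: list[str]) -> "ExpressionMatrix":
        idx = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in cells if c not in idx]
        if missing:
            raise ContractError(f"cells absent from matrix: {missing[:5]}")
        cols = [idx[c] for c in cells]
        return ExpressionMatrix(self.species, list(self.gene_ids), list(cells),
                                self.layer, self.values[:, cols])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


def make_unique(symbols: list[str]) -> list[str]:
    """Uniquify duplicate symbols with ``.k`` suffixes (ACTB, ACTB.1, ...)."""
    seen: dict[str, int] = {}
    taken = set()
    out = []
    for s in symbols:
        if s not in taken:
            out.append(s)
            taken.add(s)
            seen.setdefault(s, 0)
            continue
        k = seen.get(s, 0) + 1
        cand = f"{s}.{k}"
        while cand in taken:
            k += 1
            cand = f"{s}.{k}"
        seen[s] = k
        out.append(cand)
        taken.add(cand)
    return out


def _read_lines(path: str | Path) -> list[str]:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def read_counts_10x(matrix_path: str | Path, features_path: str | Path,
                    barcodes_path: str | Path, species: str) -> ExpressionMatrix:
    """Read a Matrix-Market triplet with features/barcodes files (10x layout).

    The features file may have one column (symbol) or the 10x three-column
    layout (id, symbol, type); the symbol column is used.  Duplicate symbols
    are uniquified with ``.k`` suffixes.
    """
    try:
        mat = spio.mmread(str(matrix_path))
    except Exception as exc:  # noqa: BLE001 - scipy raises bare ValueError
        raise FormatError(f"cannot parse Matrix-Market file {matrix_path}: {exc}") from exc
    mat = sparse.csr_matrix(mat)
    feat_rows = [line.split("\t") for line in _read_lines(features_path)]
    barcodes = _read_lines(barcodes_path)
    if len(feat_rows) != mat.shape[0]:
        raise FormatError(
            f"features file has {len(feat_rows)} rows but matrix has {mat.shape[0]}")
    if len(barcodes) != mat.shape[1]:
        raise FormatError(
            f"barcodes file has {len(barcodes)} rows but matrix has {mat.shape[1]}")
    symbols = [row[1] if len(row) > 1 else row[0] for row in feat_rows]
    dense = np.asarray(mat.todense(), dtype=float)
    if (dense < 0).any():
        raise FormatError("negative entries in count matrix")
    return ExpressionMatrix(species, make_unique(symbols), make_unique(barcodes),
                            "counts", dense)


def write_counts_10x(m: ExpressionMatrix, out_dir: str | Path) -> dict[str, Path]:
    """Write ``matrix.mtx`` / ``features.tsv`` / ``barcodes.tsv`` into out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.mtx",
        "features": out / "features.tsv",
        "barcodes": out / "barcodes.tsv",
    }
    spio.mmwrite(str(paths["matrix"]), sparse.coo_matrix(m.values))
    paths["features"].write_text(
        "".join(f"{g}\t{g}\tGene Expression\n" for g in m.gene_ids))
    paths["barcodes"].write_text("".join(f"{c}\n" for c in m.cell_ids))
    return paths


def read_dense_tsv(path: str | Path, species: str, layer: str = "counts") -> ExpressionMatrix:
    """Read a dense genes-as-rows TSV matrix (header row = cell ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(species, make_unique([str(g) for g in df.index]),
                            make_unique([str(c) for c in df.columns]),
                            layer, df.to_numpy(dtype=float))


def write_dense_tsv(m: ExpressionMatrix, path: str | Path) -> None:
    m.to_frame().to_csv(path, sep="\t", index_label="gene")


def read_table(path: str | Path, required: list[str],
               dtypes: dict | None = None) -> pd.DataFrame:
    """Read a headered TSV, enforcing required columns; extras are preserved."""
    df = pd.read_csv(path, sep="\t", dtype=dtypes)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read cell annotations (cell_id, label, optional pseudotime)."""
    df = read_table(path, required=["cell_id", "label"],
                    dtypes={"cell_id": str, "label": str})
    return validate_annotations(df)


def validate_annotations(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("cell_id", "label") if c not in df.columns]
    if missing:
        raise SchemaError(f"annotation table missing column(s) {missing}")
    if df["cell_id"].duplicated().any():
        dups = df.loc[df["cell_id"].duplicated(), "cell_id"].tolist()
        raise SchemaError(f"duplicate cell_id in annotations: {dups[:5]}")
    if "pseudotime" in df.columns:
        pt = pd.to_numeric(df["pseudotime"], errors="coerce")
        present = df["pseudotime"].notna()
        if present.any() and not np.isfinite(pt[present]).all():
            raise SchemaError("pseudotime contains non-finite values")
    return df


def log_normalize(m: ExpressionMatrix, scale: float = DEFAULT_SCALE) -> ExpressionMatrix:
    """Per-cell total scaling followed by ln(1 + x).

    Each entry becomes ``ln(1 + scale * x_gc / total_c)``; cells with zero
    total yield all-zero columns (with a warning).  Conserves per-cell scaled
    mass: sum_g(exp(v_gc) - 1) == scale for every non-empty cell.
    """
    if scale <= 0:
        raise ParameterError(f"scale must be positive, got {scale}")
    if m.layer != "counts":
        raise ContractError(f"log_normalize expects counts layer, got {m.layer}")
    totals = m.values.sum(axis=0)
    empty = totals == 0
    if empty.any():
        warnings.warn(f"{int(empty.sum())} cell(s) have zero total counts; "
                      "their columns are all-zero after normalization")
    safe = np.where(empty, 1.0, totals)
    vals = np.log1p(scale * m.values / safe)
    return ExpressionMatrix(m.species, list(m.gene_ids), list(m.cell_ids),
                            "lognorm", vals)
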