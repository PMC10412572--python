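"""Cross-species homologous-gene mappings and symbol unification.

An ortholog table (Ensembl-style) pairs gene symbols of two species with a
homology type (one2one / one2many / many2many) and a binary orthology
confidence.  Downstream comparison assumes a bijection, so filtering keeps
only confident one-to-one pairs and drops any residual ambiguity outright.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ContractError, SchemaError
from .io_formats import read_table

log = logging.getLogger(__name__)

HOMOLOGY_TYPES = ("one2one", "one2many", "many2many")
ORTHOLOG_COLUMNS = ("gene_a", "gene_b", "homology_type", "confidence")


@dataclass
class OrthologTable:
    """Pairs of gene symbols across species A and B with homology metadata."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ORTHOLOG_COLUMNS if c not in self.rows.columns]
        if missing:
            raise SchemaError(f"ortholog table missing column(s) {missing}")
        self.rows = self.rows.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.rows)

    def is_bijection(self) -> bool:
        r = self.rows
        return (not r["gene_a"].duplicated().any()
                and not r["gene_b"].duplicated().any()
                and (r["homology_type"] == "one2one").all()
                and (r["confidence"] == 1).all())

    def mapping(self, direction: str = "a_to_b") -> dict[str, str]:
        src, dst = _direction_cols(direction)
        return dict(zip(self.rows[src], self.rows[dst]))


def _direction_cols(direction: str) -> tuple[str, str]:
    if direction == "a_to_b":
        return "gene_a", "gene_b"
    if direction == "b_to_a":
        return "gene_b", "gene_a"
    raise ValueError(f"direction must be 'a_to_b' or 'b_to_a', got {direction!r}")


def read_ortholog_table(path: str | Path,
                        columns: dict[str, str] | None = None) -> OrthologTable:
    """Read an ortholog TSV; ``columns`` remaps file column names if needed."""
    df = pd.read_csv(path, sep="\t")
    if columns:
        df = df.rename(columns={v: k for k, v in columns.items()})
    missing = [c for c in ORTHOLOG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing ortholog column(s) {missing}")
    df["confidence"] = pd.to_numeric(df["confidence"], errors="raise")
    return OrthologTable(df[list(ORTHOLOG_COLUMNS)
                            + [c for c in df.columns if c not in ORTHOLOG_COLUMNS]])


def filter_one_to_one(t: OrthologTable) -> OrthologTable:
    """Keep confident one-to-one pairs and enforce a strict bijection.

    Rows with ``homology_type != one2one`` or ``confidence != 1`` are removed.
    Any gene still appearing in more than one retained row (a data error) is
    dropped entirely — both conflicting rows go, never an arbitrary keeper.
    Idempotent; an empty result only emits a warning.
    """
    r = t.rows
    keep = (r["homology_type"] == "one2one") & (r["confidence"] == 1)
    sub = r.loc[keep]
    dup_a = sub["gene_a"].duplicated(keep=False)
    dup_b = sub["gene_b"].duplicated(keep=False)
    ambiguous = dup_a | dup_b
    if ambiguous.any():
        log.info("dropped %d residual ambiguous one2one row(s)", int(ambiguous.sum()))
    out = sub.loc[~ambiguous].reset_index(drop=True)
    if out.empty:
        warnings.warn("ortholog table is empty after one-to-one filtering")
    return OrthologTable(out)


def read_alias_table(path: str | Path) -> pd.DataFrame:
    """Read an alias TSV with columns (alias, official)."""
    df = read_table(path, required=["alias", "official"],
                    dtypes={"alias": str, "official": str})
    dup = df["alias"].duplicated()
    if dup.any():
        raise SchemaError(f"alias table maps alias(es) to multiple officials: "
                          f"{df.loc[dup, 'alias'].tolist()[:5]}")
    return df


def normalize_symbols(genes: list[str], aliases: pd.DataFrame) -> list[str]:
    """Replace aliases by official symbols; unknown symbols pass through.

    If two inputs collapse onto one official symbol, the first occurrence is
    kept and the collision is logged.
    """
    lookup = dict(zip(aliases["alias"], aliases["official"]))
    out: list[str] = []
    seen: set[str] = set()
    for g in genes:
        official = lookup.get(g, g)
        if official in seen:
            log.warning("symbol collision: %r collapses onto %r (kept first)",
                        g, official)
            continue
        seen.add(official)
        out.append(official)
    return out


@dataclass
class Translation:
    """Result of mapping symbols across the ortholog bijection."""

    pairs: list[tuple[str, str]]
    unmapped: list[str]

    @property
    def mapped(self) -> list[str]:
        return [b for _, b in self.pairs]


def translate(genes: list[str], t: OrthologTable,
              direction: str = "a_to_b") -> Translation:
    """Map symbols through a bijective ortholog table, preserving order.

    Genes absent from the table are reported in ``unmapped``, never silently
    dropped.  Requires ``t`` to satisfy the bijection invariant.
    """
    if not t.is_bijection():
        raise ContractError("translate requires a bijective ortholog table; "
                            "apply filter_one_to_one first")
    lookup = t.mapping(direction)
    pairs = [(g, lookup[g]) for g in genes if g in lookup]
    unmapped = [g for g in genes if g not in lookup]
    return Translation(pairs=pairs, unmapped=unmapped)
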