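"""End-to-end cross-species comparison pipeline.

Runs: per-species normalization -> ortholog one-to-one filtering ->
standardized-variance computation -> mean-cutoff HVG selection -> shared
homologous-HVG intersection -> median-profile correspondence, with optional
TF-module and differential-expression stages.  Every stage writes a TSV and
the run closes with a manifest recording config, seed, digests and row
counts; reruns on identical inputs reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .correspondence import (center_log_profiles, cross_species_correlation,
                             group_median_profiles)
from .errors import CrosscellError
from .hvg_selection import (compute_gene_dispersion, intersect_homologous_hvgs,
                            select_hvgs_mean_cutoff)
from .io_formats import (ExpressionMatrix, log_normalize, read_annotations,
                         read_counts_10x, read_dense_tsv, write_table)
from .orthology import filter_one_to_one, read_ortholog_table
from .signatures import marker_signature, wilcoxon_de
from .tf_modules import (cut_tree_min_size, select_tfs, tf_distance_matrix,
                         upgma_cluster)

log = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    outputs: dict[str, dict]  # name -> {path, sha256, rows}

    def to_json(self) -> str:
        return json.dumps({"config": self.config, "seed": self.seed,
                           "version": self.version, "outputs": self.outputs},
                          indent=2, sort_keys=True)


class StageError(CrosscellError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_counts(spec: dict, species: str) -> ExpressionMatrix:
    """Load a counts matrix from a config entry (10x triplet dir or TSV)."""
    path = Path(spec["matrix"])
    if path.is_dir():
        def pick(stem: str) -> Path:
            for suffix in (".tsv", ".tsv.gz", ".txt", ""):
                cand = path / f"{stem}{suffix}"
                if cand.exists():
                    return cand
            raise FileNotFoundError(f"{stem} file not found in {path}")
        return read_counts_10x(path / "matrix.mtx", pick("features"),
                               pick("barcodes"), species)
    if path.suffix == ".mtx":
        base = path.parent
        return read_counts_10x(path, base / "features.tsv",
                               base / "barcodes.tsv", species)
    return read_dense_tsv(path, species)


def run_full_comparison(config: dict | str | Path,
                        out_dir: str | Path) -> RunManifest:
    """Execute the full workflow described by a config mapping or YAML path."""
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    scale = float(config.get("scale", 1e4))
    outputs: dict[str, dict] = {}

    def emit(name: str, df: pd.DataFrame, index: bool = False) -> None:
        path = out / f"{name}.tsv"
        partial = path.with_suffix(".tsv.partial")
        if index:
            df.to_csv(partial, sep="\t")
        else:
            write_table(df, partial)
        partial.rename(path)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        outputs[name] = {"path": str(path), "sha256": digest, "rows": len(df)}
        log.info("stage output %s: %d rows (seed=%d)", name, len(df), seed)

    def stage(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(name, exc) from exc

    m_a = stage("load_a", load_counts, config["species_a"],
                config["species_a"].get("name", "A"))
    m_b = stage("load_b", load_counts, config["species_b"],
                config["species_b"].get("name", "B"))
    ann_a = stage("annotations_a", read_annotations,
                  config["species_a"]["annotation"])
    ann_b = stage("annotations_b", read_annotations,
                  config["species_b"]["annotation"])
    orth = stage("orthology", read_ortholog_table, config["orthologs"],
                 config.get("ortholog_columns"))
    bij = stage("orthology", filter_one_to_one, orth)
    emit("orthologs_one2one", bij.rows)

    ln_a = stage("normalize_a", log_normalize, m_a, scale)
    ln_b = stage("normalize_b", log_normalize, m_b, scale)

    disp_a = stage("dispersion_a", compute_gene_dispersion, m_a)
    disp_b = stage("dispersion_b", compute_gene_dispersion, m_b)
    cand_a = [g for g in bij.rows["gene_a"] if g in set(m_a.gene_ids)]
    cand_b = [g for g in bij.rows["gene_b"] if g in set(m_b.gene_ids)]
    hvg_a = stage("hvg_a", select_hvgs_mean_cutoff, disp_a, cand_a)
    hvg_b = stage("hvg_b", select_hvgs_mean_cutoff, disp_b, cand_b)
    for name, hvg in (("hvg_a", hvg_a), ("hvg_b", hvg_b)):
        tbl = hvg.table.copy()
        tbl["cutoff"] = hvg.cutoff
        emit(name, tbl)

    pairs = stage("intersect", intersect_homologous_hvgs, hvg_a, hvg_b, bij)
    emit("shared_hvg_pairs", pairs)

    prof_a = stage("profiles_a", group_median_profiles, ln_a, ann_a, True)
    prof_b = stage("profiles_b", group_median_profiles, ln_b, ann_b, True)
    cen_a = stage("profiles_a", center_log_profiles, prof_a)
    cen_b = stage("profiles_b", center_log_profiles, prof_b)
    corr = stage("correspondence", cross_species_correlation,
                 cen_a, cen_b, pairs)
    emit("correspondence", corr.values, index=True)

    tf_cfg = config.get("tf_lists")
    if tf_cfg:
        min_size = int(config.get("min_module_size", 5))
        for side, (mat, ann, hvg) in {"a": (ln_a, ann_a, hvg_a),
                                      "b": (ln_b, ann_b, hvg_b)}.items():
            tf_path = tf_cfg.get(side)
            if not tf_path:
                continue
            tf_list = [line.strip() for line in
                       Path(tf_path).read_text().splitlines() if line.strip()]
            tfs = stage(f"tf_select_{side}", select_tfs, hvg, tf_list)
            if len(tfs) < 2:
                log.warning("fewer than 2 selected TFs for species %s; "
                            "skipping module stage", side)
                continue
            pt = None
            if "pseudotime" in ann.columns:
                pt = pd.Series(ann["pseudotime"].to_numpy(),
                               index=ann["cell_id"])
            dist = stage(f"tf_distance_{side}", tf_distance_matrix,
                         mat, tfs, pt)
            tree = stage(f"tf_cluster_{side}", upgma_cluster, dist)
            modules = stage(f"tf_cut_{side}", cut_tree_min_size, tree,
                            config.get("cut_height", "auto"), min_size)
            emit(f"tf_modules_{side}",
                 modules.labels.rename_axis("tf").reset_index())

    de_cfg = config.get("de")
    if de_cfg:
        side = de_cfg.get("species", "a")
        mat, ann = (ln_a, ann_a) if side == "a" else (ln_b, ann_b)
        ga = ann.loc[ann["label"] == de_cfg["group_a"], "cell_id"].tolist()
        gb = ann.loc[ann["label"] == de_cfg["group_b"], "cell_id"].tolist()
        deg = stage("deg", wilcoxon_de, mat, ga, gb)
        emit("deg", deg)
        markers = stage("markers", marker_signature, deg,
                        int(de_cfg.get("top_k", 20)))
        emit("marker_signature", pd.DataFrame({"gene": markers}))

    manifest = RunManifest(config=config, seed=seed, version=__version__,
                           outputs=outputs)
    (out / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest
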