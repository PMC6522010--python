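"""File formats: evidence TSV, gene lists, Newick + profile matrices, YAML
configuration, and score-table output.

All tabular formats are UTF-8 TSV with a header row; lines starting with
'#' are comments. Gene sets are plain text, one gene per line. Trees are
rooted Newick. The run configuration and the dataset schemas live in one
YAML file.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from .bayes import ScoreTable
from .containers import DatasetSchema, GeneEvidenceTable, RunConfig, TrainingSets
from .dollo import SpeciesTree

__all__ = [
    "read_evidence_table",
    "read_gene_set",
    "read_training_sets",
    "read_tree_and_profiles",
    "write_score_table",
    "read_score_table",
    "load_config",
    "read_published_scores",
    "setup_logging",
]

log = logging.getLogger("ciliabayes")


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment="#", dtype=str, keep_default_na=False, na_values=[]
    )


def read_evidence_table(path, schemas: list[DatasetSchema]) -> GeneEvidenceTable:
    """Read a gene-by-dataset evidence TSV.

    First column holds gene IDs; every other column header must name a
    dataset with a schema. Blank cells become the dataset's default
    category; labels in a schema's merge map are collapsed.
    """
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a gene column plus >= 1 dataset column")
    gene_col = df.columns[0]
    by_id = {s.dataset_id: s for s in schemas}
    unknown = [c for c in df.columns[1:] if c not in by_id]
    if unknown:
        raise ValueError(f"{path}: datasets without schema in header: {unknown}")
    df = df.set_index(gene_col)
    df.index.name = "gene"
    return GeneEvidenceTable(df, schemas)


def read_gene_set(path) -> frozenset[str]:
    """Plain-text gene list, one ID per line, '#' comments allowed."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    return frozenset(genes)


def read_training_sets(
    positives_path, negatives_path, bait_paths: dict | None = None
) -> TrainingSets:
    """Assemble training sets from gene-list files.

    ``bait_paths`` maps dataset ids to gene-list files of assay baits to
    exclude from the positive set for that dataset.
    """
    baits = {
        d: read_gene_set(p) for d, p in (bait_paths or {}).items()
    }
    return TrainingSets(
        positives=read_gene_set(positives_path),
        negatives=read_gene_set(negatives_path),
        bait_exclusions=baits,
    )


def read_tree_and_profiles(
    tree_path, matrix_path, reference_column: str
) -> tuple[SpeciesTree, dict, dict]:
    """Read a rooted Newick tree plus a species x genes 0/1 profile matrix.

    The matrix's first column holds species names that must match the
    tree's leaves exactly; ``reference_column`` names the organelle
    presence column. Returns (tree, gene -> profile dict, reference
    profile).
    """
    tree = SpeciesTree.from_newick(Path(tree_path).read_text())
    df = _read_tsv(matrix_path)
    df = df.set_index(df.columns[0])
    extra = sorted(set(df.index) - set(tree.leaves))
    missing = sorted(set(tree.leaves) - set(df.index))
    if extra or missing:
        raise ValueError(
            f"{matrix_path}: species/leaf mismatch — matrix-only {extra}, "
            f"tree-only {missing}"
        )
    bad = df.stack()[~df.stack().isin(["0", "1"])]
    if len(bad):
        where = bad.index[0]
        raise ValueError(
            f"{matrix_path}: non-binary entry {bad.iloc[0]!r} at "
            f"species {where[0]!r}, gene {where[1]!r}"
        )
    mat = df.astype(int).loc[tree.leaves]
    if reference_column not in mat.columns:
        raise ValueError(
            f"{matrix_path}: reference column {reference_column!r} not found"
        )
    reference = mat[reference_column].to_dict()
    profiles = {
        g: mat[g].to_dict() for g in mat.columns if g != reference_column
    }
    return tree, profiles, reference


def write_score_table(
    table: ScoreTable, path, evidence: GeneEvidenceTable | None = None
) -> None:
    """Write a ranked score table as TSV.

    Columns: gene, rank, score, posterior, fdr, training_flag, plus one
    column per evidence dataset when ``evidence`` is given. Rows are in
    rank order (descending score, ties by ascending gene ID), which is a
    deterministic function of the table alone.
    """
    df = table.records.copy()
    df.index.name = "gene"
    out = df[["rank", "score", "posterior", "fdr", "training_flag"]].copy()
    for col in ("score", "posterior", "fdr"):
        out[col] = out[col].map(lambda v: f"{v:.12g}")
    if evidence is not None:
        for d in evidence.dataset_ids:
            out[d] = evidence.cells[d].reindex(out.index)
    out.to_csv(path, sep="\t")


def read_score_table(path, config: RunConfig | None = None) -> ScoreTable:
    """Read back a score-table TSV written by :func:`write_score_table`."""
    df = _read_tsv(path).set_index("gene")
    for col in ("score", "posterior", "fdr"):
        df[col] = df[col].astype(float)
    df["rank"] = df["rank"].astype(int)
    df = df.sort_values("rank")
    cols = ["score", "posterior", "training_flag", "rank", "fdr"]
    return ScoreTable(records=df[cols], config=config or RunConfig())


def load_config(path) -> tuple[RunConfig, list[DatasetSchema]]:
    """Load run configuration and dataset schemas from one YAML file.

    Layout::

        prior: 0.05
        smoothing: 0.5
        fdr_threshold: 0.25
        cv_folds: 10
        rng_seed: 0
        ddp_threshold: 9
        datasets:
          - id: tap_ms
            categories: [found, not_found]
            default: not_found
            merge: {Found: found}
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    datasets = raw.pop("datasets", [])
    allowed = {
        "prior",
        "smoothing",
        "fdr_threshold",
        "cv_folds",
        "rng_seed",
        "ddp_threshold",
    }
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    config = RunConfig(**raw)
    schemas = [
        DatasetSchema(
            dataset_id=d["id"],
            categories=tuple(d["categories"]),
            default_category=d.get("default", d["categories"][-1]),
            merge_map=d.get("merge", {}),
        )
        for d in datasets
    ]
    return config, schemas


def read_published_scores(path, column_map: dict) -> pd.DataFrame:
    """Load an externally published genome-wide score table.

    ``column_map`` renames the file's columns onto the standard names
    (at least ``gene`` and ``score``; optionally ``rank``, ``fdr`` and
    ``training_flag``), absorbing export variants of deposited
    supplementary tables. Reads TSV/CSV by extension, or xlsx when
    openpyxl is available.
    """
    p = Path(path)
    if p.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(p)
    else:
        df = pd.read_csv(p, sep="\t" if p.suffix.lower() != ".csv" else ",")
    missing = [c for c in column_map if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: mapped columns absent from file: {missing}")
    df = df.rename(columns=column_map)[list(column_map.values())]
    if "gene" not in df.columns or "score" not in df.columns:
        raise ValueError("column_map must provide 'gene' and 'score'")
    df["score"] = df["score"].astype(float)
    return df.set_index("gene")


def write_json_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=float) + "\n")
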