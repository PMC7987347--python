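"""Readers and writers for the plain-text formats the pipeline consumes.

All tables are tab-delimited UTF-8. Count tables are written samples-as-rows
with an explicit ``#SampleID`` first header cell; the classic transposed
OTU-table layout (``#OTU ID`` first cell, taxa as rows, optional trailing
``taxonomy`` column) is also accepted and detected from that header cell.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .datasets import CountTable, RunConfig, ValidationError, validate_dyads, validate_metadata

TAXONOMY_COLUMN_NAMES = {"taxonomy", "consensus lineage", "consensuslineage"}


def read_count_table(path: str | Path) -> CountTable:
    """Read a TSV count table, either samples-as-rows or OTU-table layout.

    Raises :class:`ValidationError` for negative or non-integer counts and
    duplicated ids. Zero-sum samples are retained here (they are flagged and
    dropped at validation).
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0, comment=None, dtype=str)
    frame.index = frame.index.astype(str)
    first_cell = frame.index.name or ""
    taxonomy = None
    tax_cols = [c for c in frame.columns if c.strip().lower() in TAXONOMY_COLUMN_NAMES]
    if tax_cols:
        taxonomy = frame[tax_cols[0]]
        frame = frame.drop(columns=tax_cols)
    try:
        numeric = frame.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric counts in {path}: {exc}") from exc
    if not np.allclose(numeric.to_numpy(), np.round(numeric.to_numpy())):
        raise ValidationError(f"non-integer counts in {path}")
    if (numeric.to_numpy() < 0).any():
        raise ValidationError(f"negative counts in {path}")
    numeric = numeric.astype(np.int64)
    if first_cell.strip().lower() in {"#otu id", "#otuid", "otu id"}:
        # classic layout: taxa as rows, samples as columns
        numeric = numeric.T
    else:
        taxonomy = None
    numeric.index.name = None
    numeric.columns.name = None
    return CountTable(numeric, taxonomy)


def write_count_table(table: CountTable, path: str | Path, layout: str = "samples") -> None:
    """Write a count table; ``layout`` is ``samples`` (rows) or ``otu`` (transposed)."""
    path = Path(path)
    if layout == "samples":
        out = table.counts.copy()
        out.index.name = "#SampleID"
        out.to_csv(path, sep="\t")
    elif layout == "otu":
        out = table.counts.T.copy()
        out.index.name = "#OTU ID"
        if table.taxonomy is not None:
            out["taxonomy"] = table.taxonomy
        out.to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown layout {layout!r}")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate a sample-metadata TSV (see ``REQUIRED_METADATA_COLUMNS``)."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    frame = frame.replace("", "NA")
    if "timepoint" in frame.columns:
        frame["timepoint"] = pd.to_numeric(frame["timepoint"], errors="coerce").fillna(-1).astype(int)
    if "microbial_density" in frame.columns:
        frame["microbial_density"] = pd.to_numeric(frame["microbial_density"], errors="coerce")
    return validate_metadata(frame)


def write_metadata(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_dyad_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"dyad_id": str})
    return validate_dyads(frame)


def write_dyad_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_tree(path: str | Path) -> TreeNode:
    """Read a rooted newick tree; every tip must be labelled, every edge lengthed."""
    tree = TreeNode.read(str(path), format="newick")
    for tip in tree.tips():
        if tip.name is None or str(tip.name).strip() == "":
            raise ValidationError("tree contains an unlabeled tip")
    names = [t.name for t in tree.tips()]
    if len(names) != len(set(names)):
        raise ValidationError("tree tip labels are not unique")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            label = node.name or "internal node"
            raise ValidationError(f"missing branch length on edge above {label}")
    return tree


def write_tree(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_pathogen_list(path: str | Path) -> list[str]:
    """One genus or 'genus species' name per line; lowercased for matching."""
    entries = [line.strip().lower() for line in Path(path).read_text().splitlines()]
    entries = [e for e in entries if e and not e.startswith("#")]
    if not entries:
        raise ValidationError(f"pathogen list {path} is empty")
    return entries


def write_pathogen_list(entries: list[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(entries) + "\n")


def read_config(path: str | Path) -> RunConfig:
    return RunConfig(**json.loads(Path(path).read_text()))


def write_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(config), indent=2) + "\n")


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    frame = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
    frame.index.name = "#SampleID"
    frame.to_csv(path, sep="\t")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(frame.to_numpy(), ids=[str(i) for i in frame.index])


def read_dataset_dir(data_dir: str | Path):
    """Load and validate a dataset directory (``counts.tsv``, ``metadata.tsv``,
    and optionally ``dyads.tsv``, ``tree.nwk``, ``pathogens.txt``,
    ``host_divergence.tsv``)."""
    from .datasets import validate_dataset

    data = Path(data_dir)
    counts = read_count_table(data / "counts.tsv")
    metadata = read_metadata(data / "metadata.tsv")
    dyads = read_dyad_table(data / "dyads.tsv") if (data / "dyads.tsv").exists() else None
    tree = read_tree(data / "tree.nwk") if (data / "tree.nwk").exists() else None
    pathogens = (
        read_pathogen_list(data / "pathogens.txt") if (data / "pathogens.txt").exists() else None
    )
    host_div = (
        read_distance_matrix(data / "host_divergence.tsv")
        if (data / "host_divergence.tsv").exists()
        else None
    )
    return validate_dataset(counts, metadata, dyads, tree, pathogens, host_divergence=host_div)
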