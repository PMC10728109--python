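"""Readers and writers: delimited expression matrices with sample metadata,
and Cytoscape-compatible network export (GraphML / SIF)."""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .dataset import DatasetError, OmicsDataset

logger = logging.getLogger(__name__)

__all__ = ["read_dataset", "write_dataset", "export_network", "read_graphml_network"]

MISSING_TOKENS = ("", "NA", "NaN", "nan")


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)


def read_dataset(
    matrix_path: str | Path,
    metadata_path: str | Path,
    class_order: list[str],
    missing_tokens: tuple[str, ...] = MISSING_TOKENS,
    transpose: bool = False,
) -> OmicsDataset:
    """Load an expression matrix (features as rows, header of sample IDs)
    plus a metadata table (columns: sample_id, class and optionally
    subject_id, arm, survival_time, event).

    ``transpose`` handles the samples-as-rows dialect.  Cells matching
    ``missing_tokens`` become NaN; any other non-numeric cell is an error.
    """
    mat = _read_table(matrix_path)
    if transpose:
        mat = mat.T
    if mat.index.duplicated().any():
        raise DatasetError(f"duplicate feature IDs in {matrix_path}")
    if mat.columns.duplicated().any():
        raise DatasetError(f"duplicate sample IDs in {matrix_path}")

    meta = _read_table(metadata_path)
    if meta.index.duplicated().any():
        raise DatasetError(f"duplicate sample IDs in {metadata_path}")
    if "class" not in meta.columns:
        raise DatasetError("metadata must contain a 'class' column")

    mat_samples, meta_samples = set(mat.columns), set(meta.index)
    if mat_samples != meta_samples:
        only_mat = sorted(mat_samples - meta_samples)
        only_meta = sorted(meta_samples - mat_samples)
        raise DatasetError(
            f"matrix/metadata sample mismatch: only in matrix {only_mat[:5]}, "
            f"only in metadata {only_meta[:5]}"
        )
    # sample order follows the metadata file
    sample_ids = list(meta.index)
    mat = mat[sample_ids]

    values = np.empty(mat.shape, dtype=float)
    raw = mat.to_numpy()
    for (i, j), cell in np.ndenumerate(raw):
        cell = cell.strip()
        if cell in missing_tokens:
            values[i, j] = np.nan
            continue
        try:
            values[i, j] = float(cell)
        except ValueError:
            raise DatasetError(
                f"non-numeric cell {cell!r} at feature {mat.index[i]!r}, "
                f"sample {mat.columns[j]!r}"
            ) from None

    class_of = {s: str(meta.at[s, "class"]) for s in sample_ids}
    unknown = sorted(set(class_of.values()) - set(class_order))
    if unknown:
        raise DatasetError(f"metadata contains classes outside class_order: {unknown}")

    def _opt(col: str) -> dict[str, str] | None:
        if col not in meta.columns:
            return None
        vals = {s: str(meta.at[s, col]).strip() for s in sample_ids}
        return vals if any(vals.values()) else None

    subject_of = _opt("subject_id")
    arm_of = _opt("arm")
    survival = None
    if "survival_time" in meta.columns and "event" in meta.columns:
        survival = {}
        for s in sample_ids:
            t, e = str(meta.at[s, "survival_time"]).strip(), str(meta.at[s, "event"]).strip()
            if t and e and t not in missing_tokens:
                survival[s] = (float(t), int(float(e)))
        survival = survival or None

    ds = OmicsDataset(
        feature_ids=list(mat.index),
        sample_ids=sample_ids,
        values=values,
        class_of=class_of,
        class_order=list(class_order),
        subject_of=subject_of,
        arm_of=arm_of,
        survival=survival,
    )
    logger.info(
        "read dataset: %d features x %d samples, classes %s",
        ds.n_features, ds.n_samples, ds.class_sizes(),
    )
    return ds


def write_dataset(ds: OmicsDataset, matrix_path: str | Path, metadata_path: str | Path) -> None:
    """Write matrix + metadata TSV/CSV files readable by :func:`read_dataset`."""
    matrix_path, metadata_path = Path(matrix_path), Path(metadata_path)
    sep = "," if matrix_path.suffix.lower() == ".csv" else "\t"
    frame = ds.to_frame()
    frame.index.name = "feature_id"
    # repr-precision floats so a read/write round trip is exact
    frame.to_csv(matrix_path, sep=sep, float_format="%.17g", na_rep="NA")
    msep = "," if metadata_path.suffix.lower() == ".csv" else "\t"
    ds.metadata_frame().to_csv(metadata_path, sep=msep)


# ----------------------------------------------------------------------
def export_network(net: nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Write one stage network as GraphML (node/edge attributes preserved)
    or SIF (lines ``source <sign> target``, Cytoscape-readable)."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(net, path)
    elif format == "sif":
        with open(path, "w") as fh:
            for u, v, attrs in net.edges(data=True):
                fh.write(f"{u}\t{attrs.get('sign', 'link')}\t{v}\n")
            for node in nx.isolates(net):
                fh.write(f"{node}\n")
    else:
        raise ValueError(f"unknown network format {format!r} (expected 'graphml' or 'sif')")
    logger.info("wrote %s network (%d nodes, %d edges) to %s",
                format, net.number_of_nodes(), net.number_of_edges(), path)


def read_graphml_network(path: str | Path) -> nx.Graph:
    return nx.read_graphml(Path(path))
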