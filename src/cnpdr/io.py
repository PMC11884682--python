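"""Readers and writers for the on-disk formats.

Inputs are either per-subject square correlation-matrix CSVs (ROI names as
header and index) plus a phenotype TSV, or a single wide TSV with columns
``sample_id, phenotype, ROI1--ROI2, ...``.  Outputs are TSV importance and
centrality tables, edge lists, GraphML networks, ground-truth node/edge
lists, YAML simulation configs, and a JSON provenance sidecar per run.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .datasets import PAIR_SEP, CorrelationDataset, pair_names, vectorize_upper_triangle
from .simulate import GroundTruth, SimulationConfig

__all__ = [
    "read_subject_matrix",
    "write_subject_matrix",
    "load_dataset",
    "write_dataset",
    "read_phenotype",
    "write_ground_truth",
    "read_ground_truth",
    "write_table",
    "write_network",
    "read_sim_config",
    "write_sim_config",
    "write_provenance",
]


def read_subject_matrix(path: str | Path, *, atol: float = 1e-8) -> tuple[np.ndarray, list[str]]:
    """One subject's square symmetric correlation matrix with named ROIs."""
    frame = pd.read_csv(path, index_col=0)
    roi_names = [str(c) for c in frame.columns]
    if [str(i) for i in frame.index] != roi_names:
        raise ValueError(f"{path}: row and column ROI names differ")
    if len(set(roi_names)) != len(roi_names):
        raise ValueError(f"{path}: duplicate ROI names")
    m = frame.to_numpy(dtype=float)
    if np.abs(np.diag(m) - 1.0).max() > atol:
        raise ValueError(f"{path}: diagonal deviates from 1 beyond tolerance {atol}")
    vectorize_upper_triangle(m, roi_names, atol=atol)  # symmetry check
    return m, roi_names


def write_subject_matrix(path: str | Path, matrix: np.ndarray, roi_names: list[str]) -> None:
    pd.DataFrame(matrix, index=roi_names, columns=roi_names).to_csv(path)


def read_phenotype(path: str | Path) -> pd.Series:
    """Phenotype TSV (sample_id, label) as a binary Series indexed by id."""
    frame = pd.read_csv(path, sep="\t", dtype={0: str})
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected columns sample_id, label")
    ids = frame.iloc[:, 0].astype(str)
    labels = frame.iloc[:, 1]
    if not set(labels.unique()) <= {0, 1}:
        raise ValueError(
            f"{path}: phenotype must be binary 0/1; found {sorted(labels.unique())}"
        )
    return pd.Series(labels.to_numpy(dtype=int), index=list(ids))


def load_dataset(path: str | Path, phenotype_path: str | Path | None = None) -> CorrelationDataset:
    """Assemble a :class:`CorrelationDataset` from disk.

    ``path`` is either a directory of per-subject matrix CSVs (``<id>.csv``)
    with a phenotype TSV, or a wide TSV (``sample_id, phenotype, A--B, ...``;
    the phenotype column may instead come from ``phenotype_path``).
    """
    path = Path(path)
    if path.is_dir():
        if phenotype_path is None:
            raise ValueError("a matrix directory requires a phenotype TSV")
        phenotype = read_phenotype(phenotype_path)
        files = {p.stem: p for p in sorted(path.glob("*.csv"))}
        missing = sorted(set(phenotype.index) - set(files))
        extra = sorted(set(files) - set(phenotype.index))
        if missing or extra:
            raise ValueError(
                f"sample ids disagree between phenotype and matrices; "
                f"missing matrices: {missing or 'none'}; unlabeled matrices: {extra or 'none'}"
            )
        roi_names: list[str] | None = None
        rows = []
        for sid in phenotype.index:
            m, names = read_subject_matrix(files[sid])
            if roi_names is None:
                roi_names = names
            elif names != roi_names:
                diff = sorted(set(names) ^ set(roi_names))
                raise ValueError(f"{files[sid]}: inconsistent ROI set; differing: {diff}")
            rows.append(vectorize_upper_triangle(m, names)[0])
        return CorrelationDataset(
            np.vstack(rows), roi_names, phenotype.to_numpy(), list(phenotype.index)
        )

    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in frame.columns:
        raise ValueError(f"{path}: wide TSV must have a sample_id column")
    sample_ids = list(frame["sample_id"].astype(str))
    if "phenotype" in frame.columns:
        phen = frame["phenotype"].to_numpy(dtype=int)
        feat_cols = [c for c in frame.columns if c not in ("sample_id", "phenotype")]
    else:
        if phenotype_path is None:
            raise ValueError(f"{path}: no phenotype column and no phenotype TSV given")
        series = read_phenotype(phenotype_path)
        missing = sorted(set(sample_ids) - set(series.index))
        if missing:
            raise ValueError(f"phenotype missing for samples: {missing}")
        phen = series.loc[sample_ids].to_numpy()
        feat_cols = [c for c in frame.columns if c != "sample_id"]

    roi_names: list[str] = []
    for col in feat_cols:
        parts = col.split(PAIR_SEP)
        if len(parts) != 2:
            raise ValueError(f"{path}: column {col!r} is not an 'A{PAIR_SEP}B' pair label")
        for name in parts:
            if name not in roi_names:
                roi_names.append(name)
    expected = pair_names(roi_names)
    if feat_cols != expected:
        raise ValueError(
            f"{path}: pair columns are not in row-major upper-triangle order "
            f"over ROIs {roi_names}"
        )
    return CorrelationDataset(
        frame[feat_cols].to_numpy(dtype=float), roi_names, phen, sample_ids
    )


def write_dataset(
    dataset: CorrelationDataset,
    wide_tsv: str | Path,
    matrix_dir: str | Path | None = None,
) -> None:
    """Write the wide TSV and, optionally, per-subject square matrix CSVs."""
    frame = pd.DataFrame(dataset.feature_matrix, columns=dataset.pair_labels)
    frame.insert(0, "phenotype", dataset.phenotype)
    frame.insert(0, "sample_id", dataset.sample_ids)
    frame.to_csv(wide_tsv, sep="\t", index=False)
    if matrix_dir is not None:
        matrix_dir = Path(matrix_dir)
        matrix_dir.mkdir(parents=True, exist_ok=True)
        for i, sid in enumerate(dataset.sample_ids):
            write_subject_matrix(
                matrix_dir / f"{sid}.csv", dataset.subject_matrix(i), dataset.roi_names
            )


def write_ground_truth(truth: GroundTruth, edges_tsv: str | Path, nodes_tsv: str | Path) -> None:
    pd.DataFrame(sorted(truth.differential_edges), columns=["roi_a", "roi_b"]).to_csv(
        edges_tsv, sep="\t", index=False
    )
    pd.DataFrame({"roi": sorted(truth.functional_nodes)}).to_csv(nodes_tsv, sep="\t", index=False)


def read_ground_truth(edges_tsv: str | Path, nodes_tsv: str | Path) -> GroundTruth:
    edges = pd.read_csv(edges_tsv, sep="\t")
    nodes = pd.read_csv(nodes_tsv, sep="\t")
    return GroundTruth(
        functional_nodes=set(nodes["roi"].astype(str)),
        differential_edges={(str(a), str(b)) for a, b in edges.itertuples(index=False)},
    )


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Importance / centrality / benchmark table as TSV with stable columns."""
    table.to_csv(path, sep="\t", index=False)


def write_network(graph: nx.Graph, edge_tsv: str | Path, graphml: str | Path | None = None) -> None:
    rows = [
        {"roi_a": a, "roi_b": b, "weight": d.get("weight")}
        for a, b, d in graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["roi_a", "roi_b", "weight"]).to_csv(
        edge_tsv, sep="\t", index=False
    )
    if graphml is not None:
        nx.write_graphml(graph, graphml)


def read_sim_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown simulation key(s): {sorted(unknown)}")
    if "edges" in raw and raw["edges"] is not None:
        raw["edges"] = [tuple(e) for e in raw["edges"]]
    return SimulationConfig(**raw)


def write_sim_config(config: SimulationConfig, path: str | Path) -> None:
    raw = dataclasses.asdict(config)
    if raw.get("edges"):
        raw["edges"] = [list(e) for e in raw["edges"]]
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def write_provenance(path: str | Path, **entries) -> None:
    """JSON sidecar recording how a run was produced (config, seeds, versions)."""
    import cnpdr

    def default(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return dataclasses.asdict(obj)
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        if isinstance(obj, (set, tuple, np.ndarray)):
            return list(obj)
        raise TypeError(f"not JSON serializable: {type(obj)}")

    payload = {
        "cnpdr_version": cnpdr.__version__,
        "python": platform.python_version(),
        **entries,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=default, sort_keys=False)
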