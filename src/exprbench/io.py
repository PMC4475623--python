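"""Readers and writers for the pipeline's plain-text formats.

A study on disk is three files:

* ``<id>_matrix.tsv``  — header ``probeset_id`` + sample ids; one row per
  probeset with log2 expression values;
* ``<id>_labels.tsv``  — two columns ``sample_id``, ``class``;
* ``<id>_metadata.json`` — study id plus annotations.

Suites add a ``manifest.csv`` with one row per study.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .study import ExpressionStudy

__all__ = ["write_study", "read_study", "write_suite", "read_suite"]


def write_study(study: ExpressionStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write matrix/labels/metadata files; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / f"{study.study_id}_matrix.tsv",
        "labels": out_dir / f"{study.study_id}_labels.tsv",
        "metadata": out_dir / f"{study.study_id}_metadata.json",
    }
    mat = pd.DataFrame(
        study.matrix, index=pd.Index(study.probeset_ids, name="probeset_id"),
        columns=study.sample_ids,
    )
    mat.to_csv(paths["matrix"], sep="\t", float_format="%.6f")
    pd.DataFrame({"sample_id": study.sample_ids, "class": study.labels}).to_csv(
        paths["labels"], sep="\t", index=False
    )
    meta = {"study_id": study.study_id, **_jsonable(study.metadata)}
    paths["metadata"].write_text(json.dumps(meta, indent=1))
    return paths


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def read_study(
    matrix_path: str | Path,
    labels_path: str | Path,
    metadata_path: str | Path | None = None,
) -> ExpressionStudy:
    """Load and validate a study from its on-disk representation."""
    matrix_path, labels_path = Path(matrix_path), Path(labels_path)
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    non_numeric = mat.columns[
        [not pd.api.types.is_numeric_dtype(mat[c]) for c in mat.columns]
    ]
    if len(non_numeric):
        col = non_numeric[0]
        bad = mat[col][pd.to_numeric(mat[col], errors="coerce").isna()]
        raise ValueError(
            f"non-numeric expression value for sample {col!r} at probeset "
            f"{bad.index[0]!r}"
        )
    if mat.isna().any().any():
        loc = np.argwhere(mat.isna().to_numpy())[0]
        raise ValueError(
            f"missing expression value at probeset {mat.index[loc[0]]!r}, "
            f"sample {mat.columns[loc[1]]!r}"
        )
    labels = pd.read_csv(labels_path, sep="\t", dtype=str)
    if list(labels.columns) != ["sample_id", "class"]:
        raise ValueError(
            f"labels file must have columns sample_id, class; got {list(labels.columns)}"
        )
    if list(labels["sample_id"]) != list(mat.columns):
        raise ValueError(
            "sample ids in labels file do not match the matrix header "
            f"({list(labels['sample_id'])[:3]}... vs {list(mat.columns)[:3]}...)"
        )
    n_classes = labels["class"].nunique()
    if n_classes != 2:
        raise ValueError(f"exactly two classes required, found {n_classes}")
    metadata = {}
    study_id = matrix_path.stem.replace("_matrix", "")
    if metadata_path is not None:
        metadata = json.loads(Path(metadata_path).read_text())
        study_id = metadata.pop("study_id", study_id)
    return ExpressionStudy(
        study_id=study_id,
        matrix=mat.to_numpy(float),
        labels=labels["class"].to_numpy(),
        probeset_ids=list(mat.index.astype(str)),
        sample_ids=list(mat.columns.astype(str)),
        metadata=metadata,
    )


def write_suite(studies: Sequence[ExpressionStudy], out_dir: str | Path) -> Path:
    """Write every study plus a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    rows = []
    for st in studies:
        paths = write_study(st, out_dir)
        n1, n2 = st.class_sizes()
        rows.append(
            {
                "study_id": st.study_id,
                "n_probesets": st.n_probesets,
                "n_samples": st.n_samples,
                "n1": n1,
                "n2": n2,
                "matrix": paths["matrix"].name,
                "labels": paths["labels"].name,
                "metadata": paths["metadata"].name,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_suite(manifest_path: str | Path) -> list[ExpressionStudy]:
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    rows = pd.read_csv(manifest_path)
    return [
        read_study(base / r["matrix"], base / r["labels"], base / r["metadata"])
        for _, r in rows.iterrows()
    ]
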