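"""Container for a two-class expression study.

The unit of data flowing through the pipeline is a log2-scale expression
matrix (probesets x samples) together with a binary class label per sample
and light study-level metadata (medical question, cell type).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["ExpressionStudy"]


@dataclass
class ExpressionStudy:
    """A log2 expression matrix with binary labels and metadata.

    Parameters
    ----------
    matrix
        Array of shape ``(n_probesets, n_samples)`` of log2 expression
        values; no missing values allowed.
    labels
        One class label per sample (exactly two distinct values).
    probeset_ids, sample_ids
        Unique identifiers for rows and columns of ``matrix``.
    metadata
        Free-form study-level annotations.  ``medical_question`` and
        ``cell_type`` are the two used downstream as categorical factors.
    """

    study_id: str
    matrix: np.ndarray
    labels: np.ndarray
    probeset_ids: list[str]
    sample_ids: list[str]
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels)
        self.probeset_ids = [str(p) for p in self.probeset_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        p, n = self.matrix.shape
        if len(self.probeset_ids) != p:
            raise ValueError(
                f"{len(self.probeset_ids)} probeset ids for {p} matrix rows"
            )
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n} matrix columns"
            )
        if len(self.labels) != n:
            raise ValueError(f"{len(self.labels)} labels for {n} samples")
        if not np.all(np.isfinite(self.matrix)):
            bad = np.argwhere(~np.isfinite(self.matrix))
            i, j = bad[0]
            raise ValueError(
                "non-finite expression value at probeset "
                f"{self.probeset_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )
        if len(set(self.probeset_ids)) != p:
            raise ValueError("probeset ids are not unique")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids are not unique")
        classes = np.unique(self.labels)
        if len(classes) != 2:
            raise ValueError(
                f"exactly two classes required, found {len(classes)}: "
                f"{classes.tolist()}"
            )

    # ------------------------------------------------------------------
    @property
    def n_probesets(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    @property
    def classes(self) -> np.ndarray:
        """The two class labels, in sorted order."""
        return np.unique(self.labels)

    def class_masks(self) -> tuple[np.ndarray, np.ndarray]:
        """Boolean sample masks for the two (sorted) classes."""
        c1, c2 = self.classes
        return self.labels == c1, self.labels == c2

    def class_sizes(self) -> tuple[int, int]:
        m1, m2 = self.class_masks()
        return int(m1.sum()), int(m2.sum())

    def subset_samples(self, idx: np.ndarray | list[int]) -> "ExpressionStudy":
        """A new study restricted to the given sample indices."""
        idx = np.asarray(idx)
        return ExpressionStudy(
            study_id=self.study_id,
            matrix=self.matrix[:, idx],
            labels=self.labels[idx],
            probeset_ids=list(self.probeset_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            metadata=dict(self.metadata),
        )

    def subset_probesets(self, ids: list[str]) -> "ExpressionStudy":
        """A new study restricted to the given probesets (in given order)."""
        pos = {p: i for i, p in enumerate(self.probeset_ids)}
        missing = [p for p in ids if p not in pos]
        if missing:
            raise KeyError(f"probesets not in study: {missing}")
        rows = [pos[p] for p in ids]
        return ExpressionStudy(
            study_id=self.study_id,
            matrix=self.matrix[rows, :],
            labels=self.labels,
            probeset_ids=list(ids),
            sample_ids=list(self.sample_ids),
            metadata=dict(self.metadata),
        )
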