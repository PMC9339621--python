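"""Core data containers shared across the pipeline."""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["RoiTimeSeries", "LabeledDataset", "ConnectivityMatrix",
           "NormalizedAdjacency", "ConfusionCounts", "MetricReport"]


@dataclasses.dataclass
class RoiTimeSeries:
    """One subject's region-level signal matrix.

    ``values`` has shape (T timepoints, n ROIs); ``label`` is 0 for
    normal control, 1 for MCI, or None when unknown.
    """

    values: np.ndarray
    subject_id: str = "sub-0"
    label: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (T x n) matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.subject_id}: non-finite entries")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError("label must be 0, 1 or None")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]


@dataclasses.dataclass
class LabeledDataset:
    """A cohort of subjects with 0/1 labels and identical (T, n)."""

    subjects: list[RoiTimeSeries]

    def __post_init__(self):
        if not self.subjects:
            raise ValueError("dataset is empty")
        shapes = {s.values.shape for s in self.subjects}
        if len(shapes) != 1:
            raise ValueError(f"subjects have mixed shapes: {sorted(shapes)}")
        if any(s.label is None for s in self.subjects):
            raise ValueError("all subjects must carry a label")

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.subjects], dtype=np.int64)

    @property
    def n_timepoints(self) -> int:
        return self.subjects[0].n_timepoints

    @property
    def n_nodes(self) -> int:
        return self.subjects[0].n_nodes

    def as_array(self) -> np.ndarray:
        """Stack to (n_subjects, T, n)."""
        return np.stack([s.values for s in self.subjects])

    def subset(self, indices) -> "LabeledDataset":
        return LabeledDataset([self.subjects[i] for i in indices])

    def __len__(self) -> int:
        return len(self.subjects)


@dataclasses.dataclass
class ConnectivityMatrix:
    """An n x n functional connectivity matrix.

    ``sparsity`` is the fraction of weakest undirected connections
    removed: 0 for the dense Pearson matrix (unit diagonal), positive
    after sparsification (zero diagonal).
    """

    values: np.ndarray
    sparsity: float = 0.0
    node_names: list[str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape[1] != n:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if np.abs(self.values).max() > 1.0 + 1e-12:
            raise ValueError("correlation entries must lie in [-1, 1]")
        diag = np.diag(self.values)
        if not (np.allclose(diag, 1.0) or np.allclose(diag, 0.0)):
            raise ValueError("diagonal must be all ones (dense) or all "
                             "zeros (sparsified)")
        if self.sparsity > 0.0 and not np.allclose(diag, 0.0):
            raise ValueError("sparsified connectivity must have zero "
                             "diagonal")
        if self.node_names is not None and len(self.node_names) != n:
            raise ValueError("node_names length mismatch")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def is_dense(self) -> bool:
        """True for the unit-diagonal Pearson matrix (not yet
        thresholded)."""
        return bool(np.allclose(np.diag(self.values), 1.0))


@dataclasses.dataclass
class NormalizedAdjacency:
    """The symmetric propagation operator D^{-1/2} (I + |V|) D^{-1/2}."""

    values: np.ndarray
    edge_count: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape[1] != n:
            raise ValueError("adjacency must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("adjacency must be symmetric")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts with MCI (label 1) as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclasses.dataclass(frozen=True)
class MetricReport:
    """Accuracy / sensitivity / specificity as percentages (NaN when a
    denominator is zero)."""

    accuracy: float
    sensitivity: float
    specificity: float
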