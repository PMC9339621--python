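"""Readers and writers for the on-disk interchange formats.

A dataset directory holds one ``sub-<k>.tsv`` per subject (T rows x n
tab-separated columns, no header), a ``participants.tsv`` with columns
``subject_id`` and ``label``, and optionally a ``dataset.yaml`` echoing
the generating configuration.  Matrices (connectivity, adjacency) are
n x n TSV with an optional header row of ROI names.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import LabeledDataset, RoiTimeSeries

logger = logging.getLogger(__name__)

__all__ = ["read_timeseries_dir", "write_dataset", "read_matrix",
           "write_matrix"]


def _read_subject_tsv(path: Path) -> np.ndarray:
    rows: list[list[float]] = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if width is None:
                width = len(cells)
            elif len(cells) != width:
                raise ValueError(f"{path}:{lineno}: ragged row ("
                                 f"{len(cells)} cells, expected {width})")
            try:
                rows.append([float(c) for c in cells])
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: non-numeric cell "
                                 f"({err})") from None
    if not rows:
        raise ValueError(f"{path}: empty time-series file")
    return np.asarray(rows)


def read_timeseries_dir(path) -> LabeledDataset:
    """Load a dataset directory; validates uniform (T, n) and flags
    zero-variance ROI columns."""
    path = Path(path)
    ptsv = path / "participants.tsv"
    if not ptsv.exists():
        raise FileNotFoundError(f"missing {ptsv}")
    table = pd.read_csv(ptsv, sep="\t", dtype={"subject_id": str})
    if not {"subject_id", "label"} <= set(table.columns):
        raise ValueError(f"{ptsv}: needs columns subject_id, label")
    subjects = []
    for rec in table.itertuples(index=False):
        fpath = path / f"{rec.subject_id}.tsv"
        if not fpath.exists():
            raise FileNotFoundError(f"missing subject file {fpath}")
        values = _read_subject_tsv(fpath)
        flat = np.flatnonzero(values.std(axis=0) == 0)
        if flat.size:
            logger.warning("%s: zero-variance ROI column(s) %s", fpath,
                           flat.tolist())
        subjects.append(RoiTimeSeries(values=values,
                                      subject_id=str(rec.subject_id),
                                      label=int(rec.label)))
    return LabeledDataset(subjects=subjects)


def write_dataset(data: LabeledDataset, path, config=None) -> None:
    """Write a dataset directory (one TSV per subject + participants
    table); ``config`` (a dataclass or mapping) is echoed to
    ``dataset.yaml``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in data.subjects:
        np.savetxt(path / f"{s.subject_id}.tsv", s.values, delimiter="\t",
                   fmt="%.17g")
        rows.append({"subject_id": s.subject_id, "label": s.label})
    pd.DataFrame(rows).to_csv(path / "participants.tsv", sep="\t",
                              index=False)
    if config is not None:
        if dataclasses.is_dataclass(config):
            config = dataclasses.asdict(config)
        with open(path / "dataset.yaml", "w") as fh:
            yaml.safe_dump(config, fh, sort_keys=False)


def write_matrix(m: np.ndarray, path, node_names=None) -> None:
    """n x n matrix as TSV, optional ROI-name header row."""
    m = np.asarray(m)
    with open(path, "w") as fh:
        if node_names is not None:
            fh.write("\t".join(node_names) + "\n")
        for row in m:
            fh.write("\t".join(f"{v:.17g}" for v in row) + "\n")


def read_matrix(path, require_square: bool = True,
                require_symmetric: bool = False
                ) -> tuple[np.ndarray, list[str] | None]:
    """Read a TSV matrix; returns (values, node_names or None)."""
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty matrix file")
    names = None
    first = lines[0].split("\t")
    try:
        float(first[0])
    except ValueError:
        names = first
        lines = lines[1:]
    m = np.asarray([[float(c) for c in ln.split("\t")] for ln in lines])
    if require_square and (m.ndim != 2 or m.shape[0] != m.shape[1]):
        raise ValueError(f"{path}: expected a square matrix, got shape "
                         f"{m.shape}")
    if require_symmetric and not np.allclose(m, m.T, atol=1e-10):
        raise ValueError(f"{path}: matrix is not symmetric")
    if names is not None and len(names) != m.shape[1]:
        raise ValueError(f"{path}: header length does not match matrix")
    return m, names
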