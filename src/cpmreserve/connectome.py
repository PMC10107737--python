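"""Functional-connectivity matrix construction and motion-based quality control.

Connectivity is quantified per node pair as the Fisher z-transformed Pearson
correlation of the two nodes' mean time series, giving one symmetric,
zero-diagonal ``n_nodes x n_nodes`` matrix per subject. Head motion is
summarised per frame as framewise displacement (FWD) and drives
sample-level subject exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "NodeTimeSeries",
    "ConnectivityMatrix",
    "MotionRecord",
    "fisher_z",
    "build_connectivity",
    "remove_nodes",
    "compute_fwd",
    "flag_high_motion",
    "n_unique_edges",
]

#: |r| is clipped to this bound before arctanh so duplicated (perfectly
#: correlated) nodes give a large finite z instead of infinity.
R_CLIP = 1.0 - 1e-7

#: Head radius (mm) used to convert rotational displacement to arc length
#: in the framewise-displacement formula (Power convention).
DEFAULT_HEAD_RADIUS_MM = 50.0


def n_unique_edges(n_nodes: int) -> int:
    """Number of unique (upper-triangle) edges of an ``n_nodes`` matrix."""
    return n_nodes * (n_nodes - 1) // 2


@dataclass
class NodeTimeSeries:
    """Per-subject node-by-time matrix of mean regional time series.

    Parameters
    ----------
    values : ndarray, shape (n_nodes, n_timepoints)
        Real-valued mean time series per node.
    node_ids : ndarray of int
        Ordered 1-based atlas labels, one per row of ``values``.
    """

    values: np.ndarray
    node_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D node x time matrix")
        if self.values.shape[1] < 3:
            raise ValueError("need at least 3 time points per node")
        if not np.isfinite(self.values).all():
            raise ValueError("time series contain missing or non-finite values")
        if self.node_ids is None:
            self.node_ids = np.arange(1, self.values.shape[0] + 1)
        self.node_ids = np.asarray(self.node_ids, dtype=int)
        if self.node_ids.shape[0] != self.values.shape[0]:
            raise ValueError("node_ids length must match number of rows")
        if np.unique(self.node_ids).size != self.node_ids.size:
            raise ValueError("node_ids must be unique")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class ConnectivityMatrix:
    """Symmetric zero-diagonal Fisher-z connectivity matrix with node labels."""

    values: np.ndarray
    node_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape[1] != n:
            raise ValueError("connectivity matrix must be square")
        if not np.isfinite(self.values).all():
            raise ValueError("connectivity matrix has non-finite entries")
        if not np.array_equal(self.values, self.values.T):
            raise ValueError("connectivity matrix must be exactly symmetric")
        if np.any(np.diagonal(self.values) != 0.0):
            raise ValueError("connectivity matrix diagonal must be exactly 0")
        if self.node_ids is None:
            self.node_ids = np.arange(1, n + 1)
        self.node_ids = np.asarray(self.node_ids, dtype=int)
        if self.node_ids.shape[0] != n:
            raise ValueError("node_ids length must match matrix order")
        if np.unique(self.node_ids).size != n:
            raise ValueError("node_ids must be unique")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_edges(self) -> int:
        return n_unique_edges(self.n_nodes)

    def edge_vector(self) -> np.ndarray:
        """Unique edges in row-major upper-triangle order (i < j)."""
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        return self.values[iu, ju]


@dataclass
class MotionRecord:
    """Per-frame framewise displacement (mm) for one subject."""

    fwd: np.ndarray
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.fwd = np.asarray(self.fwd, dtype=float)
        if self.fwd.ndim != 1 or self.fwd.size < 1:
            raise ValueError("fwd must be a non-empty 1-D series")
        if np.any(self.fwd < 0):
            raise ValueError("framewise displacement cannot be negative")

    @property
    def mean_fwd(self) -> float:
        return float(self.fwd.mean())

    @property
    def max_frame_to_frame(self) -> float:
        return float(self.fwd.max())


def fisher_z(r):
    """Fisher z-transform of a Pearson correlation, ``z = arctanh(r)``.

    ``|r|`` is first clipped to ``1 - 1e-7`` so perfectly correlated node
    pairs map to a large finite value rather than infinity.

    Parameters
    ----------
    r : float or array_like
        Correlation coefficient(s) with ``|r| <= 1``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1.0):
        raise ValueError("correlation magnitude exceeds 1")
    z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    return float(z) if z.ndim == 0 else z


def build_connectivity(ts: NodeTimeSeries) -> ConnectivityMatrix:
    """Pairwise Fisher-z connectivity matrix from node time series.

    Entry ``(i, j)`` for ``i != j`` is ``fisher_z(pearson_r(series_i,
    series_j))``; the diagonal is exactly zero.

    Raises
    ------
    ValueError
        If any node has zero temporal variance (the node label is named).
    """
    sd = ts.values.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        labels = ", ".join(str(ts.node_ids[i]) for i in dead)
        raise ValueError(f"zero-variance node(s): {labels}")
    r = np.corrcoef(ts.values)
    np.fill_diagonal(r, 0.0)
    z = fisher_z(np.clip(r, -1.0, 1.0))
    z = (z + z.T) / 2.0  # exact symmetry despite float round-off
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(values=z, node_ids=ts.node_ids.copy())


def remove_nodes(m: ConnectivityMatrix, drop_ids: Iterable[int]) -> ConnectivityMatrix:
    """Drop the listed node labels, keeping retained rows/columns in order.

    Raises
    ------
    ValueError
        If any label in ``drop_ids`` is not in the matrix roster.
    """
    drop = np.asarray(sorted(set(int(d) for d in drop_ids)), dtype=int)
    unknown = np.setdiff1d(drop, m.node_ids)
    if unknown.size:
        raise ValueError(f"unknown node label(s): {', '.join(map(str, unknown))}")
    keep = ~np.isin(m.node_ids, drop)
    return ConnectivityMatrix(
        values=m.values[np.ix_(keep, keep)].copy(),
        node_ids=m.node_ids[keep].copy(),
    )


def compute_fwd(
    motion_params: np.ndarray,
    head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM,
    subject_id: str | None = None,
) -> MotionRecord:
    """Framewise displacement from 6-parameter rigid-body realignment estimates.

    Per frame, FWD is the sum of absolute frame-to-frame differences of the
    six parameters, with the three rotations (radians) converted to arc
    length on a sphere of ``head_radius_mm`` (Power convention). The first
    frame has FWD 0.

    Parameters
    ----------
    motion_params : ndarray, shape (n_frames, 6)
        Columns 0-2 translations (mm), columns 3-5 rotations (radians).
    """
    p = np.asarray(motion_params, dtype=float)
    if p.ndim != 2 or p.shape[1] != 6:
        raise ValueError("motion parameters must have 6 columns "
                         "(3 translations mm, 3 rotations rad)")
    if p.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    d = np.abs(np.diff(p, axis=0))
    d[:, 3:] *= head_radius_mm
    fwd = np.concatenate([[0.0], d.sum(axis=1)])
    return MotionRecord(fwd=fwd, subject_id=subject_id)


def flag_high_motion(
    records: Sequence[MotionRecord],
    mean_fwd_threshold: float = 0.4,
    frame_percentile: float = 97.5,
) -> np.ndarray:
    """Sample-level high-motion exclusion flags.

    A subject is excluded if mean FWD exceeds ``mean_fwd_threshold`` (mm) OR
    their largest frame-to-frame movement exceeds the ``frame_percentile``-th
    percentile of frame-to-frame movements pooled across the whole sample.

    Returns
    -------
    ndarray of bool
        True where the subject should be excluded.
    """
    if len(records) < 2:
        raise ValueError("motion exclusion needs at least 2 subjects")
    pooled = np.concatenate([rec.fwd for rec in records])
    cutoff = np.percentile(pooled, frame_percentile)
    flags = np.array(
        [rec.mean_fwd > mean_fwd_threshold or rec.max_frame_to_frame > cutoff
         for rec in records],
        dtype=bool,
    )
    return flags
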