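"""Anatomy of the selected edges: consensus networks, degree, canonical networks.

Summarises which edges a cross-validated CPM relied on: the consensus
edges selected in every fold, per-node degree within each signed mask,
and edge counts within and between ten canonical functional networks
(medial frontal, frontoparietal, default mode, motor, visual I/II,
visual association, salience, subcortical, cerebellar).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cpm import CPMFoldModels, EdgeMaskPair

__all__ = [
    "CANONICAL_NETWORKS",
    "NetworkAssignment",
    "ConsensusMasks",
    "consensus_edges",
    "node_degree",
    "canonical_matrix",
    "random_assignment",
]

CANONICAL_NETWORKS = ["MF", "FP", "DMN", "Mot", "VisI", "VisII", "VAs",
                      "SAL", "SC", "CBL"]


@dataclass
class NetworkAssignment:
    """Node label -> canonical network label mapping."""

    mapping: pd.Series  # index: node label (int), value: network label

    def __post_init__(self) -> None:
        self.mapping = pd.Series(self.mapping)
        self.mapping.index = self.mapping.index.astype(int)
        if self.mapping.index.duplicated().any():
            dup = self.mapping.index[self.mapping.index.duplicated()].tolist()
            raise ValueError(f"node(s) mapped more than once: {dup}")
        bad = sorted(set(self.mapping) - set(CANONICAL_NETWORKS))
        if bad:
            raise ValueError(f"unknown network label(s): {bad}")

    def __getitem__(self, node_id: int) -> str:
        try:
            return self.mapping.loc[int(node_id)]
        except KeyError:
            raise ValueError(f"node {node_id} has no network assignment") from None

    @classmethod
    def from_csv(cls, path: str | Path) -> "NetworkAssignment":
        df = pd.read_csv(path)
        return cls(mapping=pd.Series(df["network_label"].to_numpy(),
                                     index=df["node_id"].to_numpy()))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"node_id": self.mapping.index,
                      "network_label": self.mapping.to_numpy()}
                     ).to_csv(path, index=False)


def random_assignment(node_ids, seed: int = 0) -> NetworkAssignment:
    """Synthetic uniform-random node -> network assignment (test fixture)."""
    rng = np.random.default_rng(seed)
    labels = rng.choice(CANONICAL_NETWORKS, size=len(node_ids))
    return NetworkAssignment(mapping=pd.Series(labels, index=np.asarray(node_ids)))


@dataclass
class ConsensusMasks:
    """Edges selected in every fold, with per-edge selection frequency."""

    pos: np.ndarray
    neg: np.ndarray
    freq_pos: np.ndarray
    freq_neg: np.ndarray
    node_ids: np.ndarray

    @property
    def n_pos(self) -> int:
        return int(self.pos.sum())

    @property
    def n_neg(self) -> int:
        return int(self.neg.sum())


def consensus_edges(fold_models: CPMFoldModels) -> ConsensusMasks:
    """Edges present in every fold's mask of the same sign."""
    if not fold_models.folds:
        raise ValueError("no folds given")
    freq_pos = np.mean([f.masks.pos for f in fold_models.folds], axis=0)
    freq_neg = np.mean([f.masks.neg for f in fold_models.folds], axis=0)
    return ConsensusMasks(
        pos=freq_pos >= 1.0, neg=freq_neg >= 1.0,
        freq_pos=freq_pos, freq_neg=freq_neg,
        node_ids=fold_models.node_ids,
    )


def _mask_matrix(mask, node_ids=None) -> tuple[np.ndarray, np.ndarray]:
    """Accept an n x n symmetric binary matrix or a unique-edge vector."""
    m = np.asarray(mask)
    if m.ndim == 1:
        n = int(round((1 + np.sqrt(1 + 8 * m.size)) / 2))
        if n * (n - 1) // 2 != m.size:
            raise ValueError("edge vector length is not a valid unique-edge count")
        full = np.zeros((n, n))
        iu, ju = np.triu_indices(n, k=1)
        full[iu, ju] = m
        full[ju, iu] = m
        m = full
    else:
        if m.shape[0] != m.shape[1]:
            raise ValueError("mask must be square")
        if not np.array_equal(m, m.T):
            raise ValueError("mask must be symmetric")
    ids = (np.asarray(node_ids, dtype=int) if node_ids is not None
           else np.arange(1, m.shape[0] + 1))
    return m.astype(bool), ids


def node_degree(mask, node_ids=None) -> pd.DataFrame:
    """Per-node count of selected unique edges, sorted by degree.

    Ties are broken by ascending node label. Accepts a symmetric binary
    matrix or a unique-edge vector.
    """
    m, ids = _mask_matrix(mask, node_ids)
    deg = m.sum(axis=1).astype(int)
    df = pd.DataFrame({"node_id": ids, "degree": deg})
    return (df.sort_values(["degree", "node_id"], ascending=[False, True])
            .reset_index(drop=True))


def canonical_matrix(mask, assignment: NetworkAssignment,
                     node_ids=None) -> pd.DataFrame:
    """10x10 unique-edge counts within and between canonical networks.

    Entry (A, B) counts unique selected edges with one end in network A
    and the other in B; the diagonal counts within-network edges; the
    matrix is symmetric and its unique entries sum to the mask's
    unique-edge count.
    """
    m, ids = _mask_matrix(mask, node_ids)
    out = pd.DataFrame(0, index=CANONICAL_NETWORKS, columns=CANONICAL_NETWORKS)
    iu, ju = np.triu_indices(m.shape[0], k=1)
    for i, j in zip(iu[m[iu, ju]], ju[m[iu, ju]]):
        # lookup raises a ValueError naming any unmapped masked node
        a, b = assignment[ids[i]], assignment[ids[j]]
        out.loc[a, b] += 1
        if a != b:
            out.loc[b, a] += 1
    return out
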