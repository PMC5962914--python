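"""Weighted structural connectomes and the network measures analyzed downstream.

Edges connect parcellation regions linked by streamlines: the weight of edge
(A, B) is half the sum of inverse streamline lengths (1/mm) over all
streamlines with one endpoint in A and the other in B, and edges with weight
below 1 are removed as likely false positives.  Efficiency metrics follow the
standard weighted-connectome convention of mapping each edge weight w to a
length 1/w before computing shortest paths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from svdnet.phantom import Parcellation
from svdnet.tracking import Streamline, StreamlineSet

__all__ = [
    "Connectome",
    "NetworkSummary",
    "assign_endpoints",
    "build_connectome",
    "global_efficiency",
    "local_efficiency_mean",
    "network_summaries",
]

logger = logging.getLogger(__name__)


@dataclass
class Connectome:
    """Symmetric non-negative weight matrix over parcellation regions.

    ``raw=True`` marks a pre-threshold matrix (weights < 1 may be present).
    """

    weights: np.ndarray
    node_ids: list[int]
    raw: bool = False

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if len(self.node_ids) != w.shape[0]:
            raise ValueError("node_ids length must match matrix size")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    # ---- I/O -----------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.node_ids, columns=self.node_ids)

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    @classmethod
    def load_csv(cls, path, raw: bool = False) -> "Connectome":
        df = pd.read_csv(path, index_col=0)
        return cls(df.values, [int(c) for c in df.columns], raw=raw)

    def to_edge_list(self) -> pd.DataFrame:
        iu = np.triu_indices(self.n_nodes, k=1)
        mask = self.weights[iu] > 0
        ids = np.asarray(self.node_ids)
        return pd.DataFrame({
            "node_a": ids[iu[0][mask]],
            "node_b": ids[iu[1][mask]],
            "weight": self.weights[iu][mask],
        })


@dataclass
class NetworkSummary:
    """The network properties reported for each connectome."""

    global_efficiency: float
    local_efficiency_mean: float
    n_edges: int
    mean_edge_weight: float | None  # None when the network has no edges
    total_strength: float


# ---------------------------------------------------------------------------
# endpoint assignment and matrix construction
# ---------------------------------------------------------------------------

def assign_endpoints(streamline: Streamline, parcellation: Parcellation,
                     dilation_voxels: int = 0):
    """Region pair (min, max) for a streamline's two terminal points.

    Returns ``None`` (unassigned) when either endpoint falls in background or
    outside the volume, or when both endpoints share one region
    (self-connections are excluded).  ``dilation_voxels`` optionally rescues
    endpoints landing just outside a label (robustness studies only).
    """
    ends = streamline.points[[0, -1]]
    labels = parcellation.label_at_world(ends, dilation_voxels=dilation_voxels)
    a, b = int(labels[0]), int(labels[1])
    if a <= 0 or b <= 0 or a == b:
        return None
    return (min(a, b), max(a, b))


def build_connectome(streamlines: StreamlineSet, parcellation: Parcellation,
                     weight_threshold: float = 1.0,
                     dilation_voxels: int = 0) -> Connectome:
    """Inverse-length edge weights with the low-weight threshold applied.

    w(A, B) = 0.5 * sum over connecting streamlines of 1 / length_mm, the
    factor 1/2 correcting for the number of seeds per millimeter of
    streamline; entries below ``weight_threshold`` are zeroed.
    """
    node_ids = sorted(parcellation.region_ids)
    index = {r: i for i, r in enumerate(node_ids)}
    n = len(node_ids)
    w = np.zeros((n, n))
    n_unassigned = 0
    n_zero_length = 0
    for s in streamlines:
        if s.length_mm <= 0:
            n_zero_length += 1
            continue
        pair = assign_endpoints(s, parcellation, dilation_voxels=dilation_voxels)
        if pair is None:
            n_unassigned += 1
            continue
        i, j = index[pair[0]], index[pair[1]]
        w[i, j] += 1.0 / s.length_mm
    w = 0.5 * (w + w.T)  # accumulate once per edge, then mirror; division by 2 included
    # small additive tolerance so float accumulation cannot drop an edge
    # sitting exactly on the threshold
    w[w < weight_threshold - 1e-9] = 0.0
    if n_unassigned or n_zero_length:
        logger.info("connectome: %d unassigned, %d zero-length streamlines excluded",
                    n_unassigned, n_zero_length)
    return Connectome(w, node_ids, raw=False)


# ---------------------------------------------------------------------------
# network measures
# ---------------------------------------------------------------------------

def _length_matrix(weights: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        lengths = np.where(weights > 0, 1.0 / np.where(weights > 0, weights, 1.0), np.inf)
    np.fill_diagonal(lengths, 0.0)
    return lengths


def _global_efficiency_matrix(weights: np.ndarray) -> float:
    n = weights.shape[0]
    if n < 2:
        return 0.0
    d = shortest_path(_length_matrix(weights), method="D", directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[np.isinf(d)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


def global_efficiency(connectome: Connectome | np.ndarray,
                      weighted: bool = True) -> float:
    """E_glob = mean over ordered node pairs of 1 / weighted shortest-path length.

    Edge lengths are 1/weight; disconnected pairs contribute 0.  The
    ``weighted=False`` sanity-check variant binarizes the weights first.
    """
    w = connectome.weights if isinstance(connectome, Connectome) else np.asarray(connectome, float)
    if w.shape[0] < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    if not weighted:
        w = (w > 0).astype(float)
    return _global_efficiency_matrix(w)


def local_efficiency_mean(connectome: Connectome | np.ndarray,
                          weighted: bool = True) -> float:
    """Mean over nodes of the global efficiency of each node's neighborhood.

    The neighborhood subgraph of node i contains the neighbors of i (not i
    itself) and the edges among them; nodes with fewer than 2 neighbors
    contribute 0.  ``weighted=False`` binarizes the weights first.
    """
    w = connectome.weights if isinstance(connectome, Connectome) else np.asarray(connectome, float)
    if not weighted:
        w = (w > 0).astype(float)
    n = w.shape[0]
    if n < 2:
        raise ValueError("local efficiency needs at least 2 nodes")
    eff = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(w[i] > 0)
        if len(nb) >= 2:
            eff[i] = _global_efficiency_matrix(w[np.ix_(nb, nb)])
    return float(eff.mean())


def network_summaries(connectome: Connectome) -> NetworkSummary:
    """Edge count, mean edge weight, total strength and both efficiencies."""
    w = connectome.weights
    iu = np.triu_indices(connectome.n_nodes, k=1)
    present = w[iu][w[iu] > 0]
    n_edges = int(len(present))
    return NetworkSummary(
        global_efficiency=_global_efficiency_matrix(w) if connectome.n_nodes >= 2 else 0.0,
        local_efficiency_mean=local_efficiency_mean(connectome) if connectome.n_nodes >= 2 else 0.0,
        n_edges=n_edges,
        mean_edge_weight=float(present.mean()) if n_edges else None,
        total_strength=float(w.sum()),
    )
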