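"""Structural connectivity matrices and the operations that build them.

A subject's white-matter network is a symmetric nonnegative weight matrix
over a fixed node set (by default the 90 non-cerebellar AAL regions).
Edge weights follow the connection-density convention: streamline count
per unit end-node surface with a streamline-length correction.  A density
threshold keeps only the strongest edges before any statistics are run.
"""

from __future__ import annotations

import warnings
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .aal import default_labels

__all__ = [
    "Connectome",
    "compute_edge_weight",
    "weights_from_summary",
    "apply_density_threshold",
    "connectivity_vector",
    "vectorize_upper_triangle",
    "nodal_strength",
]


class Connectome:
    """One subject's weighted structural network.

    Parameters
    ----------
    weights : (n, n) array_like
        Symmetric nonnegative weight matrix with a zero diagonal.
    node_labels : sequence of str, optional
        Region labels in matrix order; defaults to the AAL-90 vocabulary
        when ``n == 90`` and to generic labels otherwise.
    """

    def __init__(self, weights, node_labels: Sequence[str] | None = None,
                 validate: bool = True):
        W = np.asarray(weights, dtype=float)
        if node_labels is None:
            node_labels = default_labels(W.shape[0] if W.ndim == 2 else 0)
        self.node_labels = tuple(node_labels)
        self.weights = W
        if validate:
            self._validate()

    def _validate(self) -> None:
        W = self.weights
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError(f"weight matrix must be square, got shape {W.shape}")
        if len(self.node_labels) != W.shape[0]:
            raise ValueError(
                f"{len(self.node_labels)} labels for {W.shape[0]} nodes")
        if not np.all(np.isfinite(W)):
            raise ValueError("weight matrix contains non-finite entries")
        if np.any(W < 0):
            i, j = np.argwhere(W < 0)[0]
            raise ValueError(f"negative weight at ({i}, {j})")
        if np.any(np.diag(W) != 0):
            raise ValueError("diagonal must be zero (no self-connections)")
        if not np.array_equal(W, W.T):
            raise ValueError("weight matrix must be symmetric")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def density_threshold(self, density: float = 0.05) -> "Connectome":
        return apply_density_threshold(self, density)

    def connectivity_vector(self, seed_region: int) -> np.ndarray:
        return connectivity_vector(self, seed_region)

    def upper_triangle(self) -> np.ndarray:
        return vectorize_upper_triangle(self)

    def strength(self, node: int | None = None):
        return nodal_strength(self, node)

    def density(self) -> float:
        """Fraction of node pairs connected by a nonzero edge."""
        n = self.n_nodes
        iu = np.triu_indices(n, k=1)
        return float(np.count_nonzero(self.weights[iu]) / len(iu[0]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.node_labels,
                            columns=self.node_labels)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"Connectome(n_nodes={self.n_nodes}, "
                f"density={self.density():.3f})")


def compute_edge_weight(streamline_lengths, surface_i: float,
                        surface_j: float) -> float:
    """Connection density between two regions.

    weight = (2 / (S_i + S_j)) * sum_f 1/len_f over streamlines f linking
    the pair: connections per unit surface, each streamline corrected by
    its length.  No streamlines gives weight 0.
    """
    if surface_i <= 0 or surface_j <= 0:
        raise ValueError("node surfaces must be strictly positive")
    lengths = np.asarray(streamline_lengths, dtype=float)
    if lengths.size == 0:
        return 0.0
    if np.any(lengths <= 0):
        raise ValueError("streamline lengths must be strictly positive")
    return float(2.0 / (surface_i + surface_j) * np.sum(1.0 / lengths))


def weights_from_summary(summary: pd.DataFrame, surfaces,
                         n_nodes: int) -> "Connectome":
    """Rebuild a weight matrix from a per-pair streamline summary.

    ``summary`` has columns node_i, node_j, count, mean_length where
    mean_length is the harmonic mean of the pair's streamline lengths, so
    sum_f 1/len_f = count / mean_length.
    """
    surfaces = np.asarray(surfaces, dtype=float)
    if np.any(surfaces <= 0):
        raise ValueError("node surfaces must be strictly positive")
    W = np.zeros((n_nodes, n_nodes))
    for row in summary.itertuples(index=False):
        i, j = int(row.node_i), int(row.node_j)
        if row.count == 0:
            continue
        w = (2.0 / (surfaces[i] + surfaces[j])) * row.count / row.mean_length
        W[i, j] = W[j, i] = w
    return Connectome(W)


def apply_density_threshold(connectome: Connectome,
                            density: float = 0.05) -> Connectome:
    """Keep only the strongest edges of a network.

    Retains the ``floor(density * P)`` largest upper-triangle weights
    (``P = n(n-1)/2`` possible edges, zeros included in the ranking base)
    and zeroes the rest.  Ties at the cut are all kept, so the achieved
    density can slightly exceed the target; a warning is emitted.
    """
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    n = connectome.n_nodes
    if n == 0:
        raise ValueError("empty connectome")
    if density == 1.0:
        return Connectome(connectome.weights.copy(), connectome.node_labels,
                          validate=False)
    iu = np.triu_indices(n, k=1)
    vals = connectome.weights[iu]
    n_pairs = vals.size
    m = int(np.floor(density * n_pairs))
    W = np.zeros_like(connectome.weights)
    if m > 0:
        cutoff = np.partition(vals, n_pairs - m)[n_pairs - m]
        keep = (vals >= cutoff) & (vals > 0)
        if keep.sum() > m:
            warnings.warn(
                f"{keep.sum() - m} tied weights at the density cut were kept",
                stacklevel=2)
        W[iu[0][keep], iu[1][keep]] = vals[keep]
        W += W.T
    return Connectome(W, connectome.node_labels, validate=False)


def connectivity_vector(connectome: Connectome,
                        seed_region: int) -> np.ndarray:
    """A region's connections to every other node, in fixed label order.

    Length ``n_nodes - 1``: the self-connection is excluded.
    """
    n = connectome.n_nodes
    if not 0 <= seed_region < n:
        raise IndexError(f"seed region {seed_region} out of range [0, {n})")
    row = connectome.weights[seed_region]
    return np.delete(row, seed_region)


def vectorize_upper_triangle(connectome: Connectome) -> np.ndarray:
    """Upper-triangle weights in (i<j) lexicographic order; length n(n-1)/2."""
    iu = np.triu_indices(connectome.n_nodes, k=1)
    return connectome.weights[iu].copy()


def upper_triangle_pairs(n_nodes: int) -> list[tuple[int, int]]:
    """Node pairs in the order used by :func:`vectorize_upper_triangle`."""
    iu = np.triu_indices(n_nodes, k=1)
    return list(zip(iu[0].tolist(), iu[1].tolist()))


def nodal_strength(connectome: Connectome, node: int | None = None):
    """Overall connectivity strength: sum of absolute incident edge weights."""
    strengths = np.abs(connectome.weights).sum(axis=1)
    if node is None:
        return strengths
    if not 0 <= node < connectome.n_nodes:
        raise IndexError(f"node {node} out of range")
    return float(strengths[node])
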