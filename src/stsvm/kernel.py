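"""Graph Laplacian machinery and the p-step random walk kernel.

The kernel K = (a*I - L)^p, with L the normalized graph Laplacian, is a
symmetric positive semi-definite node-similarity matrix: entry (i, j) sums
down-weighted walks of length <= p between nodes i and j, so nodes joined by
many short alternative paths score as more related than nodes joined by a
single path.  Because the spectrum of L lies in [0, 2], positive
semi-definiteness requires a >= 2.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from .netio import Network


@dataclass(frozen=True)
class SmoothKernel:
    """A p-step random walk kernel aligned to a fixed node order.

    The matrix depends only on the graph topology and (a, p), never on
    expression data, so it can be computed once and reused across
    cross-validation folds and label permutations.
    """

    nodes: tuple[str, ...]
    matrix: np.ndarray
    a: float
    p: int

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.nodes)}

    def save(self, path: str) -> None:
        """Cache the kernel (matrix + node-order manifest + parameters)."""
        np.save(path + ".npy", self.matrix)
        with open(path + ".json", "w") as fh:
            json.dump({"nodes": list(self.nodes), "a": self.a, "p": self.p}, fh)

    @classmethod
    def load(cls, path: str) -> "SmoothKernel":
        with open(path + ".json") as fh:
            meta = json.load(fh)
        matrix = np.load(path + ".npy")
        return cls(tuple(meta["nodes"]), matrix, float(meta["a"]), int(meta["p"]))


def degree_matrix(net: Network) -> np.ndarray:
    """Diagonal matrix of node degrees in the network's node order."""
    return np.diag(net.degrees())


def normalized_laplacian(net: Network) -> np.ndarray:
    """Normalized graph Laplacian D^(-1/2) (D - A) D^(-1/2).

    Rows and columns of isolated nodes are zero (their degree normalization
    is undefined; the zero convention keeps them in the matrix with kernel
    diagonal a^p, so unmapped features stay in the ranking).  Eigenvalues
    lie in [0, 2].
    """
    a = net.adjacency()
    d = net.degrees()
    with np.errstate(divide="ignore"):
        dinv = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
    lap = -a * np.outer(dinv, dinv)
    np.fill_diagonal(lap, np.where(d > 0, 1.0, 0.0))
    return lap


def pstep_rwk(net: Network, a: float = 2.0, p: int = 2) -> SmoothKernel:
    """p-step random walk kernel K = (a*I - L)^p.

    Parameters
    ----------
    net
        The analysis network.
    a
        Restart/decay constant; must be >= 2 so that a*I - L (spectrum of L
        in [0, 2]) is positive semi-definite, and hence K is.
    p
        Number of walk steps (>= 1); K is computed by repeated
        multiplication.
    """
    if a < 2:
        raise ValueError(
            f"a={a} < 2: the normalized Laplacian has eigenvalues up to 2, "
            "so a >= 2 is required for a positive semi-definite kernel"
        )
    if p < 1 or int(p) != p:
        raise ValueError("p must be a positive integer")
    base = a * np.eye(net.n_nodes) - normalized_laplacian(net)
    k = np.linalg.matrix_power(base, int(p))
    k = (k + k.T) / 2.0  # symmetrize away float round-off
    return SmoothKernel(net.nodes, k, float(a), int(p))
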