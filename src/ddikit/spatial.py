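"""Chemical-distance matrices and the learned per-head attention bias.

The chemical distance between two atoms is the minimum summed bond weight
over all connecting paths.  Two weight schemes are supported:

* ``unit`` (default): every bond weighs 1, so the distance is the
  topological shortest path and buckets are exact integers.
* ``bond_order_inverse``: a bond of order k weighs 1/k (aromatic order 1.5),
  making multiply-bonded atoms "closer".

Distances are clipped into ``D_max + 2`` buckets: 0..D_max for reachable
pairs, and a dedicated bucket D_max + 1 for unreachable pairs (molecules can
become disconnected under augmentation).  The bias module holds a learned
(D_max + 2) x H table; realized bias S[h][i][j] = table[bucket(i, j)][h] is
added to the attention logits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .autodiff import Tensor
from .mol_io import MolecularGraph
from .nn import Module, Parameter

WEIGHT_SCHEMES = ("unit", "bond_order_inverse")


@dataclass
class SpatialMatrix:
    dist: np.ndarray            # (n, n) float, np.inf for unreachable
    clipped_bucket: np.ndarray  # (n, n) int in [0, D_max + 1]
    weight_scheme: str
    d_max: int


def chemical_distance(graph: MolecularGraph, scheme: str = "unit",
                      d_max: int = 8) -> SpatialMatrix:
    """All-pairs minimum path cost under the chosen bond-weight scheme."""
    if scheme not in WEIGHT_SCHEMES:
        raise ValueError(f"unknown weight scheme {scheme!r}")
    n = graph.n_atoms
    rows, cols, weights = [], [], []
    for b in graph.bonds:
        w = 1.0 if scheme == "unit" else 1.0 / b.order
        rows += [b.i, b.j]
        cols += [b.j, b.i]
        weights += [w, w]
    mat = csr_matrix((weights, (rows, cols)), shape=(n, n))
    dist = shortest_path(mat, method="D", directed=False,
                         unweighted=(scheme == "unit"))
    dist = np.minimum(dist, dist.T)  # exact symmetry despite float rounding
    np.fill_diagonal(dist, 0.0)
    return SpatialMatrix(dist=dist, clipped_bucket=bucketize(dist, d_max),
                         weight_scheme=scheme, d_max=d_max)


def bucketize(dist: np.ndarray, d_max: int) -> np.ndarray:
    """Round distances to integer buckets, clip to D_max, route unreachable
    pairs to the reserved bucket D_max + 1."""
    finite = np.isfinite(dist)
    bucket = np.full(dist.shape, d_max + 1, dtype=np.intp)
    bucket[finite] = np.minimum(np.floor(dist[finite] + 0.5).astype(np.intp),
                                d_max)
    return bucket


class SpatialBias(Module):
    """Learned per-head scalar bias keyed on the bucketed chemical distance."""

    def __init__(self, n_heads: int, d_max: int, rng: np.random.Generator,
                 scale: float = 0.02):
        self.table = Parameter(rng.normal(0.0, scale,
                                          size=(d_max + 2, n_heads)))
        self._d_max = d_max
        self._n_heads = n_heads

    def __call__(self, buckets: np.ndarray) -> Tensor:
        """buckets (..., n, n) int -> bias (..., H, n, n).

        Gradient flows into the embedding table.
        """
        buckets = np.asarray(buckets, dtype=np.intp)
        if buckets.max(initial=0) > self._d_max + 1 or buckets.min(initial=0) < 0:
            raise RuntimeError("distance bucket out of table range")
        bias = self.table[buckets]          # (..., n, n, H)
        ndim = bias.data.ndim
        axes = tuple(range(ndim - 3)) + (ndim - 1, ndim - 3, ndim - 2)
        return bias.transpose(*axes)        # (..., H, n, n)
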