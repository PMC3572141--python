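"""Graph-Laplacian diffusion priors for local spatial smoothness.

Nearby dipoles on the cortical mantle tend to activate coherently, so a
smoothness prior is encoded by a diffusion kernel on the mesh edge graph:

    L = A - diag(degree)           (negative semidefinite Laplacian)
    W = sum_{i=0}^{order} (rho L)^i / i!   (truncated exp(rho L), order 8)

``rho`` in [0, 1) tunes the smoothness strength; W generalizes the discrete
Laplacian to a large neighborhood order and its entries vanish beyond graph
distance ``order``.  Because L annihilates constants, every row of W sums
to exactly 1.  The truncation can leave tiny negative eigenvalues, so a
PSD-repaired copy (eigenvalue clip at zero) is exposed separately for use
as a covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .surface import Adjacency

__all__ = [
    "SmoothnessKernel",
    "graph_laplacian",
    "smoothness_kernel",
    "parcel_block",
]

DEFAULT_RHO = 0.6  # value of the reference implementation this prior follows
DEFAULT_ORDER = 8


def graph_laplacian(adjacency: Adjacency) -> sp.csr_matrix:
    """Discrete Laplacian ``L = A - diag(degree)`` (rows sum to 0)."""
    A = adjacency.matrix
    return (A - sp.diags(adjacency.degree)).tocsr()


@dataclass
class SmoothnessKernel:
    """Truncated-diffusion smoothness kernel.

    Attributes
    ----------
    matrix : (p, p) ndarray
        The truncated series with exact unit row sums.
    rho : float
        Smoothness strength in [0, 1).
    order : int
        Truncation order of the series (default 8).
    """

    matrix: np.ndarray
    rho: float
    order: int = DEFAULT_ORDER
    _psd: np.ndarray | None = field(default=None, repr=False)

    @property
    def psd_matrix(self) -> np.ndarray:
        """Symmetrized, eigenvalue-clipped copy for covariance use."""
        if self._psd is None:
            Wsym = 0.5 * (self.matrix + self.matrix.T)
            vals, vecs = np.linalg.eigh(Wsym)
            if vals.min() >= 0:
                self._psd = Wsym
            else:
                vals = np.clip(vals, 0.0, None)
                self._psd = (vecs * vals) @ vecs.T
        return self._psd


def smoothness_kernel(
    L, rho: float = DEFAULT_RHO, order: int = DEFAULT_ORDER
) -> SmoothnessKernel:
    """Truncated exponential series ``W = sum (rho L)^i / i!``.

    rho = 0 gives the identity.  The diagonal is adjusted (by O(eps)) so
    each row sums to exactly 1.0 in floating point, preserving symmetry.
    """
    if not (0.0 <= rho < 1.0):
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    Ld = np.asarray(L.todense() if sp.issparse(L) else L, float)
    p = Ld.shape[0]
    W = np.eye(p)
    term = np.eye(p)
    for i in range(1, order + 1):
        term = term @ (rho * Ld) / i
        W += term
    W = 0.5 * (W + W.T)
    # Exact unit row sums: quantize entries to the 2^-40 grid (error
    # <= 2^-41, far below the truncation error) so that partial sums of a
    # row are exact in double precision in any order, then set the
    # diagonal to 1 minus the exact off-diagonal sum.
    W = np.ldexp(np.rint(np.ldexp(W, 40)), -40)
    diag = np.diag_indices(p)
    W[diag] = 0.0
    W[diag] = 1.0 - W.sum(axis=1)
    return SmoothnessKernel(matrix=W, rho=rho, order=order)


def parcel_block(
    W: SmoothnessKernel, parcellation, k: int
) -> np.ndarray:
    """Principal submatrix ``W_k`` of the PSD-repaired kernel on parcel k."""
    idx = parcellation.parcel_vertices(k)
    return W.psd_matrix[np.ix_(idx, idx)]
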