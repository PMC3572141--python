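"""Data-driven parcellization of the cortical surface.

Before inversion, the cortex is partitioned into K non-overlapping,
connected parcels P(s) at a spatial neighborhood scale s.  Seeds are picked
greedily at the dipoles with the highest multivariate source
pre-localization (MSP) score — a per-dipole coefficient in [0, 1]
quantifying how much the dipole's (normalized) forward field projects onto
the signal subspace of the data — and each seed is grown to order s through
still-unassigned vertices, so dipoles likely to contribute to the same
generator end up in the same parcel.

The spatio-temporal activation probability map (stAPM) aggregates the MSP
scores within each parcel into a per-parcel, per-time activation
probability ``alpha_k(t)``, used to initialize the MEM reference measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .surface import TriSurface, Adjacency

__all__ = [
    "MSPScores",
    "Parcellation",
    "ActivationMap",
    "msp_scores",
    "ddp",
    "stapm",
    "EPS_ALPHA",
]

#: Clipping for activation probabilities — keeps the MEM log-partition
#: finite at alpha in {0, 1}.
EPS_ALPHA = 1e-6


@dataclass
class MSPScores:
    """p x tau matrix of per-dipole contribution coefficients in [0, 1]."""

    scores: np.ndarray

    @property
    def static(self) -> np.ndarray:
        """Max-over-time score per dipole (the DDP seed criterion)."""
        return self.scores.max(axis=1)


@dataclass
class Parcellation:
    """Full non-overlapping partition of the cortex at scale s.

    ``labels`` maps each vertex to a parcel id in ``1..K`` (0 is never
    used); parcels are connected on the edge graph and never span
    hemispheres.
    """

    labels: np.ndarray
    scale: int
    seeds: np.ndarray
    _members: list = field(default=None, repr=False)

    @property
    def n_parcels(self) -> int:
        return int(self.labels.max())

    @property
    def parcel_sizes(self) -> np.ndarray:
        return np.bincount(self.labels)[1:]

    def parcel_vertices(self, k: int) -> np.ndarray:
        """0-based vertex indices of parcel ``k`` (k in 1..K)."""
        if not (1 <= k <= self.n_parcels):
            raise IndexError(f"parcel id {k} out of range 1..{self.n_parcels}")
        if self._members is None:
            order = np.argsort(self.labels, kind="stable")
            bounds = np.searchsorted(self.labels[order], np.arange(1, self.n_parcels + 2))
            self._members = [
                order[bounds[i] : bounds[i + 1]] for i in range(self.n_parcels)
            ]
        return self._members[k - 1]

    def to_tsv(self, path: str) -> None:
        seed_flag = np.zeros(len(self.labels), int)
        seed_flag[self.seeds] = 1
        with open(path, "w") as fh:
            fh.write("vertex_index\tlabel\tseed_flag\n")
            for i, (lab, sf_) in enumerate(zip(self.labels, seed_flag)):
                fh.write(f"{i}\t{lab}\t{sf_}\n")

    @classmethod
    def from_tsv(cls, path: str, scale: int = -1) -> "Parcellation":
        data = np.loadtxt(path, skiprows=1, dtype=np.int64)
        labels = data[:, 1]
        seeds = data[data[:, 2] == 1, 0]
        return cls(labels=labels, scale=scale, seeds=seeds)


@dataclass
class ActivationMap:
    """K x tau matrix of parcel activation probabilities alpha_k(t)."""

    alpha: np.ndarray  # clipped to [EPS_ALPHA, 1 - EPS_ALPHA]

    def to_tsv(self, path: str) -> None:
        K, tau = self.alpha.shape
        with open(path, "w") as fh:
            fh.write("parcel\t" + "\t".join(f"t{t}" for t in range(tau)) + "\n")
            for k in range(K):
                fh.write(
                    f"{k + 1}\t" + "\t".join(repr(float(v)) for v in self.alpha[k]) + "\n"
                )


def msp_scores(
    M: np.ndarray, G, subspace_energy: float = 0.95
) -> MSPScores:
    """Multivariate source pre-localization coefficients.

    The data columns and lead-field columns are normalized to unit norm;
    the left singular subspace ``U_r`` of the normalized data capturing
    ``subspace_energy`` of the variance defines a signal subspace, and the
    static score of dipole i is ``||U_r' g_i||^2`` — the squared projection
    of its normalized forward field onto that subspace.  The temporal
    modulation multiplies the static score by the normalized instantaneous
    data energy, so the score of every dipole peaks when the data do.
    """
    from .forward import LeadField

    Gm = G.matrix if isinstance(G, LeadField) else np.asarray(G, float)
    M = np.atleast_2d(np.asarray(M, float))
    if M.ndim == 1:
        M = M[:, None]
    if not (0.0 < subspace_energy <= 1.0):
        raise ValueError("subspace_energy must be in (0, 1]")
    gnorm = np.linalg.norm(Gm, axis=0)
    if np.any(gnorm == 0):
        raise ValueError("zero-norm lead-field column(s)")
    Gn = Gm / gnorm

    col_norms = np.linalg.norm(M, axis=0)
    if np.all(col_norms == 0):
        warnings.warn("all-zero data: MSP scores are all zero")
        return MSPScores(scores=np.zeros((Gm.shape[1], M.shape[1])))
    Mn = np.where(col_norms > 0, M / np.where(col_norms == 0, 1.0, col_norms), 0.0)

    U, sv, _ = np.linalg.svd(Mn, full_matrices=False)
    energy = np.cumsum(sv**2) / np.sum(sv**2)
    r = int(np.searchsorted(energy, subspace_energy - 1e-12) + 1)
    Ur = U[:, :r]

    static = np.einsum("ij,ij->j", Ur.T @ Gn, Ur.T @ Gn)  # ||Ur' g_i||^2
    static = np.clip(static, 0.0, 1.0)

    inst = col_norms**2
    peak = inst.max()
    modulation = inst / peak if peak > 0 else inst
    scores = np.clip(static[:, None] * modulation[None, :], 0.0, 1.0)
    return MSPScores(scores=scores)


def ddp(
    surface: TriSurface,
    adjacency: Adjacency,
    scores: MSPScores,
    s: int,
) -> Parcellation:
    """Data-driven parcellization P(s): greedy seeds + region growing.

    Repeat until every vertex is assigned: pick the unassigned vertex with
    the highest max-over-time MSP score (ties broken by lowest index) as a
    seed, grow a ball of graph order ``s`` around it through unassigned
    vertices only, and label it as a new parcel.  Parcels created late may
    be fragments smaller than order-s balls; the result is always a full
    non-overlapping partition with connected parcels.
    """
    if s < 1:
        raise ValueError("scale s must be >= 1")
    p = adjacency.n_vertices
    crit = scores.static
    if len(crit) != p:
        raise ValueError("scores do not cover all vertices")
    labels = np.zeros(p, dtype=np.int64)
    # stable order: descending score, ascending index on ties
    order = np.lexsort((np.arange(p), -crit))
    A = adjacency.matrix
    seeds = []
    k = 0
    ptr = 0
    while True:
        while ptr < p and labels[order[ptr]] != 0:
            ptr += 1
        if ptr >= p:
            break
        seed = order[ptr]
        k += 1
        seeds.append(seed)
        # BFS through unassigned vertices only
        labels[seed] = k
        frontier = np.array([seed], dtype=np.int64)
        for _ in range(s):
            nxt = np.unique(A[frontier].nonzero()[1])
            nxt = nxt[labels[nxt] == 0]
            if nxt.size == 0:
                break
            labels[nxt] = k
            frontier = nxt
    return Parcellation(labels=labels, scale=s, seeds=np.asarray(seeds))


def stapm(
    scores: MSPScores, parcellation: Parcellation, aggregate: str = "median"
) -> ActivationMap:
    """Spatio-temporal activation probability map alpha_k(t).

    Aggregates the MSP scores of each parcel's dipoles at each time point
    (``median`` by default — robust to parcel-boundary leakage; ``mean``
    and ``max`` available), clipped to [eps, 1 - eps].
    """
    aggfun = {"median": np.median, "mean": np.mean, "max": np.max}.get(aggregate)
    if aggfun is None:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    K = parcellation.n_parcels
    tau = scores.scores.shape[1]
    alpha = np.empty((K, tau))
    for k in range(1, K + 1):
        idx = parcellation.parcel_vertices(k)
        alpha[k - 1] = aggfun(scores.scores[idx], axis=0)
    return ActivationMap(alpha=np.clip(alpha, EPS_ALPHA, 1.0 - EPS_ALPHA))
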