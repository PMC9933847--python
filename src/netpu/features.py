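"""Seed-aware network features.

Four per-gene scores summarize how close a gene sits to a scored seed set
on the interaction graph:

* **heat diffusion** — ``z(t) = expm(-L t) z(0)`` with the combinatorial
  Laplacian ``L = K - A``; total score is conserved (the same amount of
  score flows along every edge).
* **balanced diffusion** — the same equation with the random-walk Laplacian
  ``L_b = I - K^{-1} A``; the degree-weighted total is conserved (every
  node sheds the same amount of score regardless of its degree).
* **NetShort** — a score-weighted harmonic centrality: edges incident to
  high-score seeds are cheap, so genes reachable through many strong seeds
  accumulate a large sum of inverse shortest-path distances.
* **NetRing** — a ring decomposition by minimal hop distance to any seed,
  with a rank recursion whose integer part is the ring level and whose
  fractional part blends the initial score-derived ranks of a node's
  neighbors.

All four are assembled into a per-gene feature matrix normalized to
[0, 1] per column, with larger meaning "closer to the disease".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra
from scipy.sparse.linalg import expm_multiply

from .network import Network, SeedSet

logger = logging.getLogger(__name__)

__all__ = [
    "DiffusionResult", "RingPartition", "FeatureMatrix",
    "heat_diffusion", "balanced_diffusion", "netshort",
    "ring_partition", "netring", "assemble_features",
]


@dataclass(frozen=True)
class DiffusionResult:
    """Diffused scores ``z(t)`` in network node order."""

    z: np.ndarray
    t: float
    mode: Literal["heat", "balanced"]

    def as_dict(self, net: Network) -> dict[str, float]:
        return {g: float(self.z[i]) for i, g in enumerate(net.nodes)}


@dataclass(frozen=True)
class RingPartition:
    """Hop-distance levels from the seed set.

    ``level[i]`` is the minimal unweighted shortest-path distance of node i
    (network order) to any seed; ring ``R(l)`` collects the nodes at level
    l, so ``R(0)`` is exactly the seed set.
    """

    level: np.ndarray

    @property
    def max_level(self) -> int:
        return int(self.level.max())

    def ring(self, l: int) -> np.ndarray:
        return np.flatnonzero(self.level == l)


@dataclass(frozen=True)
class FeatureMatrix:
    """n x d matrix of per-gene features in [0, 1], rows in network order."""

    order: tuple[str, ...]
    columns: tuple[str, ...]
    X: np.ndarray

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.order), len(self.columns)):
            raise ValueError("feature matrix shape does not match order/columns")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.X, index=list(self.order), columns=list(self.columns))


def _initial_scores(net: Network, seeds: SeedSet) -> np.ndarray:
    return seeds.score_vector(net)


def heat_diffusion(net: Network, seeds: SeedSet, t: float) -> DiffusionResult:
    """Diffuse seed scores with the combinatorial Laplacian ``L = K - A``.

    ``z(0)`` is the association score on seeds and 0 elsewhere;
    ``z(t) = expm(-L t) z(0)`` is evaluated by the sparse
    action-of-the-exponential routine, never by densifying L.
    """
    if t <= 0:
        raise ValueError("diffusion time t must be positive")
    A = net.adjacency()
    L = sp.diags(net.degrees()) - A
    z0 = _initial_scores(net, seeds)
    z = expm_multiply(-t * L.tocsc(), z0)
    return DiffusionResult(z=np.asarray(z), t=t, mode="heat")


def balanced_diffusion(net: Network, seeds: SeedSet, t: float) -> DiffusionResult:
    """Diffuse seed scores with the random-walk Laplacian ``L_b = I - K^{-1}A``."""
    if t <= 0:
        raise ValueError("diffusion time t must be positive")
    A = net.adjacency()
    k = net.degrees()
    Lb = sp.identity(net.n, format="csr") - sp.diags(1.0 / k) @ A
    z0 = _initial_scores(net, seeds)
    z = expm_multiply(-t * Lb.tocsc(), z0)
    return DiffusionResult(z=np.asarray(z), t=t, mode="balanced")


def _normalized_scores(net: Network, seeds: SeedSet, penalization: float) -> np.ndarray:
    """Per-node normalized score s~: s_i/maxS on seeds, penalization*minS/maxS off."""
    max_s = seeds.max_score
    min_s = seeds.min_score
    s = np.full(net.n, penalization * min_s / max_s)
    for g in seeds.members:
        s[net.index[g]] = seeds.scores[g] / max_s
    return s


def netshort(net: Network, seeds: SeedSet, penalization: float = 0.5) -> Mapping[str, float]:
    """Score-weighted harmonic centrality.

    Edge (i, j) costs ``2 / (s~_i + s~_j)`` where s~ is the normalized
    association score (seeds: s_i/maxS; non-seeds: penalization * minS/maxS,
    default penalization 0.5).  The measure of node i is the sum over all
    other nodes of the inverse weighted shortest-path distance, so paths
    running through strong seeds are cheap and inflate the score.
    """
    if penalization <= 0:
        raise ValueError("penalization must be positive (zero edge weights break paths)")
    s = _normalized_scores(net, seeds, penalization)
    A = net.adjacency().tocoo()
    w = 2.0 / (s[A.row] + s[A.col])
    W = sp.csr_matrix((w, (A.row, A.col)), shape=A.shape)
    D = dijkstra(W, directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    np.fill_diagonal(inv, 0.0)
    ns = inv.sum(axis=1)
    return {g: float(ns[i]) for i, g in enumerate(net.nodes)}


def ring_partition(net: Network, seeds: SeedSet) -> RingPartition:
    """Multi-source BFS levels from the seed set (ring R(0) = seeds)."""
    A = net.adjacency()
    sources = np.flatnonzero(seeds.mask_vector(net))
    dist = dijkstra(A, directed=False, unweighted=True, indices=sources, min_only=True)
    if not np.isfinite(dist).all():
        raise ValueError("network is not connected")
    return RingPartition(level=dist.astype(int))


def netring(
    net: Network,
    seeds: SeedSet,
    rings: RingPartition | None = None,
    mixing: float = 0.5,
) -> Mapping[str, float]:
    """Ring-level rank of each gene.

    The initial rank is ``1 - s_i/maxS`` for seeds and 1 for non-seeds.  A
    seed's rank is a convex combination (``mixing``) of its own initial rank
    and the mean initial rank of its neighbors, so seeds surrounded by
    strong seeds rank near 0.  A non-seed at ring level l gets rank
    ``l + mean(initial ranks of same/higher-ring neighbors, and lower-ring
    neighbor ranks corrected by l - 1)`` — the integer part encodes the ring
    and the fractional part the local seed environment, so the raw value
    GROWS with distance from the disease.
    """
    if not (0.0 <= mixing <= 1.0):
        raise ValueError("mixing must be in [0, 1]")
    if rings is None:
        rings = ring_partition(net, seeds)
    level = rings.level
    n = net.n
    if len(level) != n:
        raise ValueError("ring partition does not match the network")
    A = net.adjacency()
    k = net.degrees()
    max_s = seeds.max_score
    r_hat = np.ones(n)
    seed_mask = seeds.mask_vector(net)
    for g in seeds.members:
        i = net.index[g]
        r_hat[i] = 1.0 - seeds.scores[g] / max_s
    if (level[seed_mask] != 0).any() or (level[~seed_mask] == 0).any():
        raise ValueError("ring partition inconsistent with the seed set")

    r = np.empty(n)
    indptr, indices = A.indptr, A.indices
    neigh = lambda i: indices[indptr[i]:indptr[i + 1]]
    # seeds: convex combination with the neighborhood mean of initial ranks
    for i in np.flatnonzero(seed_mask):
        r[i] = mixing * r_hat[i] + (1.0 - mixing) * r_hat[neigh(i)].mean()
    # non-seeds ring by ring: lower-ring ranks are already final
    for l in range(1, rings.max_level + 1):
        for i in rings.ring(l):
            nb = neigh(i)
            lower = nb[level[nb] == l - 1]
            other = nb[level[nb] != l - 1]
            r[i] = l + (r_hat[other].sum() + (r[lower] - (l - 1)).sum()) / k[i]
    return {g: float(r[i]) for i, g in enumerate(net.nodes)}


def _minmax(col: np.ndarray, name: str) -> np.ndarray:
    lo, hi = col.min(), col.max()
    if hi == lo:
        logger.warning("feature column %r is constant; normalized to all zeros", name)
        return np.zeros_like(col)
    return (col - lo) / (hi - lo)


def assemble_features(
    net: Network,
    seeds: SeedSet,
    *,
    t_heat: float = 0.005,
    t_balanced: float = 0.005,
    penalization: float = 0.5,
    mixing: float = 0.5,
    invert_netring: bool = True,
) -> FeatureMatrix:
    """Compute all four features and min-max normalize each to [0, 1].

    With ``invert_netring`` (default) the ring rank is flipped to
    ``max - r`` before normalization so that, like the other three columns,
    larger means closer to the seed set.  A constant column normalizes to
    all zeros with a warning.
    """
    heat = heat_diffusion(net, seeds, t_heat).z
    bal = balanced_diffusion(net, seeds, t_balanced).z
    ns_map = netshort(net, seeds, penalization)
    ns = np.array([ns_map[g] for g in net.nodes])
    nr_map = netring(net, seeds, mixing=mixing)
    nr = np.array([nr_map[g] for g in net.nodes])
    if invert_netring:
        nr = nr.max() - nr
    cols = {"heat": heat, "balanced": bal, "netshort": ns, "netring": nr}
    X = np.column_stack([_minmax(v, k) for k, v in cols.items()])
    return FeatureMatrix(order=net.nodes, columns=tuple(cols), X=X)
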