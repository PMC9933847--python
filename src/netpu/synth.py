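"""Synthetic networks with a planted disease module.

The generator emulates the inputs the method consumes: a connected
interaction network, a densely interconnected disease module inside it, and
association scores on a visible subset of the module.  Edges are drawn as a
planted-partition graph — probability ``p_in`` inside the module, ``p_out``
for every other pair — so diffusion from the visible seeds concentrates on
the module, which is the smoothness structure the labeling assumes.  The
module genes not given scores (``hidden_fraction``) play the role of
to-be-discovered positives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .network import Network, SeedSet

logger = logging.getLogger(__name__)

__all__ = ["SyntheticInstance", "generate"]


@dataclass(frozen=True)
class SyntheticInstance:
    net: Network
    module: frozenset[str]
    visible_seeds: SeedSet
    hidden_positives: frozenset[str]
    rng_seed: int


def _gene_names(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"g{str(i).zfill(width)}" for i in range(n)]


def generate(
    n: int = 300,
    module_size: int = 30,
    p_in: float = 0.3,
    p_out: float = 0.01,
    hidden_fraction: float = 0.3,
    score_dist: tuple[float, float] = (0.3, 1.0),
    rng_seed: int = 0,
) -> SyntheticInstance:
    """Draw a planted-partition instance with scored visible seeds.

    Parameters
    ----------
    n, module_size:
        Total genes and planted-module size (module_size < n).
    p_in, p_out:
        Within-module and background edge probabilities, ``0 < p_out < p_in <= 1``.
    hidden_fraction:
        Fraction of module genes withheld from the seed set (unscored
        "extended-only" positives available as a gold standard).
    score_dist:
        (low, high): visible seeds draw association scores uniformly from
        (low, high], echoing the range of curated association scores.
    rng_seed:
        Single seed for edges, module membership, visibility split and scores.

    If the raw draw is disconnected, minimal random inter-component edges
    are added (logged) rather than resampling the whole graph.
    """
    if not (0.0 < p_out < p_in <= 1.0):
        raise ValueError("need 0 < p_out < p_in <= 1")
    if not (0 < module_size < n):
        raise ValueError("need 0 < module_size < n")
    low, high = score_dist
    if not (0.0 <= low < high <= 1.0):
        raise ValueError("score_dist must satisfy 0 <= low < high <= 1")
    rng = np.random.default_rng(rng_seed)
    names = _gene_names(n)
    module_idx = rng.choice(n, size=module_size, replace=False)
    in_module = np.zeros(n, dtype=bool)
    in_module[module_idx] = True

    iu, ju = np.triu_indices(n, k=1)
    p = np.where(in_module[iu] & in_module[ju], p_in, p_out)
    keep = rng.random(len(p)) < p
    edges = [(names[i], names[j]) for i, j in zip(iu[keep], ju[keep])]

    # connectivity repair: wire each extra component to the main one
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(names)
    g.add_edges_from(edges)
    comps = sorted(nx.connected_components(g), key=len, reverse=True)
    if len(comps) > 1:
        logger.info("repairing connectivity: %d extra components", len(comps) - 1)
        main = sorted(comps[0])
        for comp in comps[1:]:
            u = rng.choice(sorted(comp))
            v = rng.choice(main)
            g.add_edge(u, v)
            edges.append((u, v))
    net = Network.from_edges(edges)
    assert net.n == n

    module_names = sorted(names[i] for i in module_idx)
    n_hidden = int(round(hidden_fraction * module_size))
    perm = rng.permutation(module_size)
    hidden = frozenset(module_names[i] for i in perm[:n_hidden])
    visible = sorted(set(module_names) - hidden)
    if not visible:
        raise ValueError("hidden_fraction leaves no visible seeds")
    # uniform on (low, high]
    draws = high - rng.random(len(visible)) * (high - low)
    scores = {g_: float(s) for g_, s in zip(visible, draws)}
    seeds = SeedSet(members=tuple(visible), scores=scores)
    return SyntheticInstance(net=net, module=frozenset(module_names),
                             visible_seeds=seeds, hidden_positives=hidden,
                             rng_seed=rng_seed)
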