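import numpy as np
import pytest

from netpu.network import Network, SeedSet


@pytest.fixture
def path_net() -> Network:
    """The 4-node path 1-2-3-4 used in the worked feature examples."""
    return Network.from_edges([("1", "2"), ("2", "3"), ("3", "4")])


@pytest.fixture
def path_seed_one() -> SeedSet:
    """Single seed at one end of the path, maximal score."""
    return SeedSet(members=("1",), scores={"1": 1.0})


def random_connected(n: int, p: float, seed: int) -> Network:
    """Erdos-Renyi draw repaired to a single component, deterministic per seed."""
    rng = np.random.default_rng(seed)
    names = [f"n{i:03d}" for i in range(n)]
    iu, ju = np.triu_indices(n, k=1)
    keep = rng.random(len(iu)) < p
    edges = [(names[i], names[j]) for i, j in zip(iu[keep], ju[keep])]
    # chain backbone guarantees connectivity without changing distribution much
    edges += [(names[i], names[i + 1]) for i in range(n - 1)]
    return Network.from_edges(edges)


def random_seedset(net: Network, n_seeds: int, seed: int) -> SeedSet:
    rng = np.random.default_rng(seed)
    members = sorted(rng.choice(net.nodes, size=n_seeds, replace=False))
    scores = {g: float(0.3 + 0.7 * rng.random()) for g in members}
    return SeedSet(members=tuple(members), scores=scores)
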