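"""Interaction networks and scored seed sets.

A working network is an undirected, simple, connected graph over gene
identifiers.  Input edge lists are cleaned on load: self-loops are dropped,
undirected duplicates collapsed, and only the largest connected component is
retained.  Node order is lexicographic so that every downstream matrix is
reproducible.

Seed genes carry a gene--disease association score in (0, 1]; seeds absent
from the network are dropped (with a logged count) because all features are
defined on the working graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = ["Network", "SeedSet", "load_network", "load_seeds", "write_network", "write_seeds"]

# BioGRID TAB3 column names used when biogrid=True
_BIOGRID_A = "Official Symbol Interactor A"
_BIOGRID_B = "Official Symbol Interactor B"
_BIOGRID_ORG_A = "Organism ID Interactor A"
_BIOGRID_ORG_B = "Organism ID Interactor B"


@dataclass(frozen=True)
class Network:
    """An undirected, simple, connected gene network.

    Nodes are kept in lexicographic order; ``index`` maps identifier to row
    position so adjacency/Laplacian matrices line up with feature rows.
    """

    nodes: tuple[str, ...]
    edges: frozenset[frozenset[str]]
    index: Mapping[str, int] = field(repr=False)

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "Network":
        """Build a cleaned network from raw (u, v) pairs.

        Applies the full cleaning contract: self-loop removal, undirected
        deduplication, largest-connected-component extraction.
        """
        g = nx.Graph()
        for u, v in edges:
            if u == v:
                continue
            g.add_edge(str(u), str(v))
        if g.number_of_edges() == 0:
            raise ValueError("no edges remain after cleaning")
        components = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
        if len(components) > 1:
            dropped = sum(len(c) for c in components[1:])
            logger.warning(
                "input graph has %d components; keeping the largest, dropping %d nodes",
                len(components), dropped,
            )
        g = g.subgraph(components[0])
        nodes = tuple(sorted(g.nodes))
        index = {v: i for i, v in enumerate(nodes)}
        edge_set = frozenset(frozenset((u, v)) for u, v in g.edges)
        return cls(nodes=nodes, edges=edge_set, index=index)

    @property
    def n(self) -> int:
        return len(self.nodes)

    def adjacency(self) -> sp.csr_matrix:
        """Symmetric 0/1 adjacency in lexicographic node order."""
        rows, cols = [], []
        for e in self.edges:
            u, v = tuple(e)
            i, j = self.index[u], self.index[v]
            rows += [i, j]
            cols += [j, i]
        data = np.ones(len(rows))
        return sp.csr_matrix((data, (rows, cols)), shape=(self.n, self.n))

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency().sum(axis=1)).ravel()

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(tuple(e) for e in self.edges)
        return g


@dataclass(frozen=True)
class SeedSet:
    """Seed genes with association scores in (0, 1].

    ``members`` is the seed subset of the network, in lexicographic order;
    ``scores`` maps every member to its score.
    """

    members: tuple[str, ...]
    scores: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("seed set is empty")
        for g in self.members:
            s = self.scores[g]
            if not (0.0 < s <= 1.0):
                raise ValueError(f"seed {g!r} has score {s} outside (0, 1]")

    @property
    def min_score(self) -> float:
        return min(self.scores[g] for g in self.members)

    @property
    def max_score(self) -> float:
        return max(self.scores[g] for g in self.members)

    def score_vector(self, net: Network) -> np.ndarray:
        """Scores aligned to the network node order; 0 for non-seeds."""
        s = np.zeros(net.n)
        for g in self.members:
            s[net.index[g]] = self.scores[g]
        return s

    def mask_vector(self, net: Network) -> np.ndarray:
        """Boolean seed-membership vector in network node order."""
        m = np.zeros(net.n, dtype=bool)
        for g in self.members:
            m[net.index[g]] = True
        return m

    def restrict(self, keep: Iterable[str]) -> "SeedSet":
        """Seed set restricted to ``keep`` (used by the masking protocol)."""
        keep = set(keep)
        members = tuple(g for g in self.members if g in keep)
        if not members:
            raise ValueError("restriction leaves no seeds")
        return SeedSet(members=members, scores={g: self.scores[g] for g in members})


def _looks_like_header(fields: list[str]) -> bool:
    lowered = [f.strip().lower() for f in fields[:2]]
    return lowered[:2] in (["gene", "score"],) or {"source", "target", "gene_a", "gene_b",
                                                   "node1", "node2", "interactor_a",
                                                   "interactor_b"} & set(lowered) != set() \
        or lowered[0] in ("gene1", "genea")


def load_network(
    path: str | Path,
    *,
    header: bool | None = None,
    biogrid: bool = False,
    organism_filter: str | None = None,
) -> Network:
    """Read an edge list and build the cleaned working network.

    Parameters
    ----------
    path:
        Tab-separated file.  Default dialect: two columns of gene
        identifiers, no header (``header=None`` auto-detects common header
        words; pass True/False to force).
    biogrid:
        Parse a BioGRID TAB3 export instead: interactor official symbols are
        taken from the named columns, and ``organism_filter`` (e.g. "9606")
        restricts both interactors to one organism.
    """
    path = Path(path)
    if biogrid:
        df = pd.read_csv(path, sep="\t", dtype=str, low_memory=False)
        if organism_filter is not None:
            keep = (df[_BIOGRID_ORG_A] == str(organism_filter)) & (
                df[_BIOGRID_ORG_B] == str(organism_filter))
            df = df[keep]
        pairs = list(zip(df[_BIOGRID_A], df[_BIOGRID_B]))
    else:
        rows: list[list[str]] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"line with fewer than 2 columns in {path}: {line!r}")
                rows.append(parts[:2])
        if not rows:
            raise ValueError(f"empty edge-list file: {path}")
        skip = header if header is not None else _looks_like_header(rows[0])
        if skip:
            rows = rows[1:]
        pairs = [(a, b) for a, b in rows]
    if not pairs:
        raise ValueError(f"no edges in {path}")
    return Network.from_edges(pairs)


def load_seeds(path: str | Path, net: Network, *, header: bool | None = None) -> SeedSet:
    """Read a ``gene<TAB>score`` table and intersect it with the network.

    Genes absent from the network are dropped (count logged).  Duplicate
    genes keep their maximum score.  Scores outside (0, 1] abort with the
    offending row.
    """
    path = Path(path)
    scores: dict[str, float] = {}
    dropped = 0
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if header is None:
        header = bool(lines) and _looks_like_header(lines[0].split("\t"))
    if header:
        lines = lines[1:]
    for lineno, line in enumerate(lines, start=1):
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected gene<TAB>score, got {line!r}")
        gene, raw = parts[0], parts[1]
        score = float(raw)
        if not (0.0 < score <= 1.0):
            raise ValueError(f"{path}:{lineno}: score {score} for gene {gene!r} outside (0, 1]")
        if gene not in net.index:
            dropped += 1
            continue
        scores[gene] = max(score, scores.get(gene, 0.0))
    if dropped:
        logger.info("dropped %d seed genes absent from the network", dropped)
    if not scores:
        raise ValueError(f"no seed genes from {path} are present in the network")
    return SeedSet(members=tuple(sorted(scores)), scores=scores)


def write_network(net: Network, path: str | Path) -> None:
    """Write the edge list as TSV with a header row, deterministically sorted."""
    edges = sorted(tuple(sorted(e)) for e in net.edges)
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for u, v in edges:
            fh.write(f"{u}\t{v}\n")


def write_seeds(seeds: SeedSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tscore\n")
        for g in seeds.members:
            fh.write(f"{g}\t{seeds.scores[g]:.17g}\n")
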