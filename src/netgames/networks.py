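"""Ring lattices and Watts-Strogatz small-world networks.

A group of N individuals sits on an undirected graph whose edges define
who interacts with whom.  The baseline structure is a regular ring
lattice in which individual i is connected to its K/2 nearest neighbours
on each side of a circle; small-world variants are derived from it by
rewiring each lattice edge with probability ``p_rew`` to a random,
previously unconnected group member (Watts & Strogatz).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class SocialNetwork:
    """Undirected interaction graph over ``n_individuals`` 0-based nodes.

    ``edges`` holds each undirected edge once as an ``(i, j)`` tuple with
    ``i < j``.  ``adjacency`` is derived and gives, for each individual,
    its sorted neighbour list; the ordering is therefore stable within a
    network instance.  ``lattice_k`` records the degree K of the ring
    lattice the network was built from (kept through rewiring so the
    canonical rewiring traversal order is well defined).
    """

    n_individuals: int
    edges: frozenset[tuple[int, int]]
    lattice_k: int | None = None
    adjacency: tuple[tuple[int, ...], ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        adj: list[list[int]] = [[] for _ in range(self.n_individuals)]
        for i, j in self.edges:
            if not (0 <= i < self.n_individuals and 0 <= j < self.n_individuals):
                raise ValueError(f"edge ({i}, {j}) out of range for n={self.n_individuals}")
            if i == j:
                raise ValueError(f"self-loop at node {i}")
            if i > j:
                raise ValueError(f"edge ({i}, {j}) not normalized (need i < j)")
            adj[i].append(j)
            adj[j].append(i)
        object.__setattr__(self, "adjacency", tuple(tuple(sorted(a)) for a in adj))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self, i: int) -> int:
        return len(self.adjacency[i])

    def degrees(self) -> np.ndarray:
        return np.array([len(a) for a in self.adjacency], dtype=np.int64)

    def has_edge(self, i: int, j: int) -> bool:
        return (min(i, j), max(i, j)) in self.edges

    def to_networkx(self):
        """Export as a :class:`networkx.Graph` (isolated nodes included)."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_individuals))
        g.add_edges_from(self.edges)
        return g

    # -- edge-list text format: "# n_individuals=<N>" header, then "i\tj" --

    def to_edgelist(self, path) -> None:
        """Write a 0-based tab-separated edge list with an ``n_individuals`` header."""
        with open(path, "w") as fh:
            fh.write(f"# n_individuals={self.n_individuals}\n")
            for i, j in sorted(self.edges):
                fh.write(f"{i}\t{j}\n")

    @classmethod
    def from_edgelist(cls, path) -> "SocialNetwork":
        """Read a network written by :meth:`to_edgelist`."""
        n = None
        edges = set()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    key, _, val = line.lstrip("# ").partition("=")
                    if key.strip() == "n_individuals":
                        n = int(val)
                    continue
                a, b = line.split()
                i, j = int(a), int(b)
                edges.add((min(i, j), max(i, j)))
        if n is None:
            raise ValueError("edge list missing '# n_individuals=<N>' header")
        return cls(n_individuals=n, edges=frozenset(edges))


def _lattice_edges(n: int, k: int) -> list[tuple[int, int]]:
    """Lattice edges in canonical traversal order.

    Iterates individuals 0..n-1 and, for each, its k/2 "clockwise" edges
    (i, i+1), ..., (i, i+k/2) modulo n.  For the complete graph
    (k = n - 1) the remaining antipodal edges are appended once.
    """
    edges: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    half = k // 2
    for offset in range(1, half + 1):
        for i in range(n):
            j = (i + offset) % n
            e = (min(i, j), max(i, j))
            if e not in seen:
                seen.add(e)
                edges.append(e)
    if k == n - 1 and k % 2 == 1:
        # even n complete graph: the diameters i -- i + n/2
        for i in range(n // 2):
            e = (i, i + n // 2)
            if e not in seen:
                seen.add(e)
                edges.append(e)
    return edges


def make_ring_lattice(n: int, k: int) -> SocialNetwork:
    """Build the regular ring lattice with ``n`` individuals of degree ``k``.

    Individual i is connected to i±1, ..., i±k/2 (indices modulo n), so
    each of the n individuals has exactly k neighbours and the lattice
    has n*k/2 edges.  ``k`` must be even, except that ``k = n - 1`` is
    always allowed and yields the complete graph (needed for the
    all-connected case, e.g. N = 99, K = 98).

    Parameters
    ----------
    n : int
        Group size N (at least 3).
    k : int
        Neighbour count K with ``2 <= k <= n - 1``; even unless ``k == n - 1``.
    """
    if n < 3:
        raise ValueError(f"need n >= 3, got n={n}")
    if not (2 <= k <= n - 1):
        raise ValueError(f"need 2 <= k <= n-1, got k={k} with n={n}")
    if k % 2 == 1 and k != n - 1:
        raise ValueError(f"odd k={k} only allowed for the complete graph k=n-1={n - 1}")
    edges = _lattice_edges(n, k)
    net = SocialNetwork(n_individuals=n, edges=frozenset(edges), lattice_k=k)
    assert net.n_edges == n * k // 2
    return net


def rewire_small_world(
    net: SocialNetwork, p_rew: float, rng: np.random.Generator
) -> SocialNetwork:
    """Watts-Strogatz rewiring of a ring lattice.

    Each lattice edge, visited in the canonical order (individuals
    0..N-1, each one's K/2 clockwise edges by increasing offset), is
    independently rewired with probability ``p_rew``: the end at the
    visited individual is kept and the far end is moved to a uniformly
    chosen group member that is neither the individual itself nor already
    a neighbour.  If no legal target exists the edge is left in place.
    The total edge count N*K/2 is conserved; the result may be
    disconnected (disconnected realizations are kept, and isolated
    individuals simply have no interactions).

    Parameters
    ----------
    net : SocialNetwork
        A freshly built ring lattice (``lattice_k`` set).
    p_rew : float
        Rewiring probability in [0, 1].
    rng : numpy.random.Generator
        Source of randomness; a fixed seed gives a reproducible network.
    """
    if net.lattice_k is None:
        raise ValueError("rewire_small_world requires a ring lattice (lattice_k set)")
    if not (0.0 <= p_rew <= 1.0):
        raise ValueError(f"p_rew must be in [0, 1], got {p_rew}")
    n, k = net.n_individuals, net.lattice_k
    edge_set = set(net.edges)
    adj: list[set[int]] = [set(a) for a in net.adjacency]
    for i in range(n):
        for offset in range(1, k // 2 + 1):
            if rng.random() >= p_rew:
                continue
            j = (i + offset) % n
            e = (min(i, j), max(i, j))
            if e not in edge_set:
                continue  # already moved by an earlier rewiring of the same pair
            candidates = [m for m in range(n) if m != i and m not in adj[i]]
            if not candidates:
                continue  # node adjacent to all others: keep the edge
            target = candidates[rng.integers(len(candidates))]
            edge_set.remove(e)
            adj[i].discard(j)
            adj[j].discard(i)
            edge_set.add((min(i, target), max(i, target)))
            adj[i].add(target)
            adj[target].add(i)
    out = SocialNetwork(n_individuals=n, edges=frozenset(edge_set), lattice_k=k)
    assert out.n_edges == net.n_edges
    return out


def neighbors(net: SocialNetwork, i: int) -> list[int]:
    """Sorted neighbour list of individual ``i`` (stable within an instance)."""
    if not (0 <= i < net.n_individuals):
        raise IndexError(f"individual index {i} out of range [0, {net.n_individuals})")
    return list(net.adjacency[i])
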