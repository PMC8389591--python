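"""Overlapping community ("module") detection in the weighted network.

A seed-expansion scheme driven by edge weight and neighborhood proximity:

1. sort edges by descending weight D (ties lexicographic);
2. the heaviest edge not yet inside a found community seeds a new one;
3. greedily add the boundary node with the largest positive gain of the
   community fitness f(C) = W_in(C) / (W_in(C) + W_out(C))**alpha, where
   W_in sums internal edge weights and W_out the boundary edge weights;
   ties are broken by neighborhood proximity to the community, then by
   gene name;
4. prune members whose removal increases f, alternating with expansion
   until f(C) is a local maximum under single-node moves;
5. mark the community's internal edges visited and repeat.

Nodes (not edges) may belong to several communities, so overlap emerges
naturally; duplicate communities are collapsed.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx


@dataclass(frozen=True)
class Module:
    """A detected (possibly overlapping) node set with its induced edges."""

    id: int
    genes: frozenset[str]
    edges: tuple[tuple[str, str, float], ...]

    @property
    def n_nodes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def node_proximity(net: nx.Graph, u: str, v: str) -> float:
    """Neighborhood proximity of an adjacent node pair.

    P(u, v) = (w(u,v) + sum over common neighbors c of min(w(u,c), w(v,c)))
              / min(s(u), s(v)),

    with s the weighted degree.  Symmetric and non-negative; high when
    the pair shares much of its weighted neighborhood.
    """
    if not net.has_edge(u, v):
        raise ValueError(f"nodes {u!r} and {v!r} are not adjacent")
    w = lambda a, b: net[a][b].get("weight", 1.0)
    common = set(net[u]) & set(net[v])
    shared = w(u, v) + sum(min(w(u, c), w(v, c)) for c in common)
    s_u = sum(w(u, x) for x in net[u])
    s_v = sum(w(v, x) for x in net[v])
    denom = min(s_u, s_v)
    if denom <= 0:
        return 0.0
    return shared / denom


def _fitness(w_in: float, w_out: float, alpha: float) -> float:
    total = w_in + w_out
    if total <= 0:
        return 0.0
    return w_in / total**alpha


class _Community:
    """Incrementally maintained community with W_in / W_out bookkeeping."""

    def __init__(self, net: nx.Graph, alpha: float):
        self.net = net
        self.alpha = alpha
        self.members: set[str] = set()
        self.w_in = 0.0
        self.w_out = 0.0

    def fitness(self) -> float:
        return _fitness(self.w_in, self.w_out, self.alpha)

    def _deltas(self, node: str) -> tuple[float, float]:
        """(weight to members, weight to non-members) of ``node``."""
        to_in = to_out = 0.0
        for nbr, d in self.net[node].items():
            w = d.get("weight", 1.0)
            if nbr in self.members:
                to_in += w
            else:
                to_out += w
        return to_in, to_out

    def gain_add(self, node: str) -> float:
        to_in, to_out = self._deltas(node)
        return _fitness(self.w_in + to_in, self.w_out - to_in + to_out, self.alpha) - self.fitness()

    def gain_remove(self, node: str) -> float:
        to_in, to_out = self._deltas(node)
        return _fitness(self.w_in - to_in, self.w_out + to_in - to_out, self.alpha) - self.fitness()

    def add(self, node: str) -> None:
        to_in, to_out = self._deltas(node)
        self.w_in += to_in
        self.w_out += to_out - to_in
        self.members.add(node)

    def remove(self, node: str) -> None:
        self.members.discard(node)
        to_in, to_out = self._deltas(node)
        self.w_in -= to_in
        self.w_out -= to_out - to_in

    def boundary(self) -> set[str]:
        out: set[str] = set()
        for m in self.members:
            out.update(n for n in self.net[m] if n not in self.members)
        return out


def _proximity_to_community(net: nx.Graph, node: str, members: set[str]) -> float:
    vals = [node_proximity(net, node, m) for m in members if net.has_edge(node, m)]
    return max(vals) if vals else 0.0


def _expand(net: nx.Graph, seed: tuple[str, str], alpha: float, max_iter: int = 10_000) -> set[str]:
    com = _Community(net, alpha)
    com.add(seed[0])
    com.add(seed[1])
    for _ in range(max_iter):
        changed = False
        # expansion: best positive fitness gain; ties by proximity then name.
        # Past the seed pair, a candidate needs >= 2 neighbors inside the
        # community (neighborhood support), which blocks single-edge
        # pendant attachments from inflating the ratio fitness.
        while True:
            best = None
            for cand in sorted(com.boundary()):
                if len(com.members) > 2:
                    support = sum(1 for n in net[cand] if n in com.members)
                    if support < 2:
                        continue
                g = com.gain_add(cand)
                if g <= 1e-12:
                    continue
                key = (g, _proximity_to_community(net, cand, com.members), _NameOrder(cand))
                if best is None or key > best[0]:
                    best = (key, cand)
            if best is None:
                break
            com.add(best[1])
            changed = True
        # pruning: remove any member whose removal strictly increases fitness
        while len(com.members) > 2:
            best = None
            for cand in sorted(com.members):
                g = com.gain_remove(cand)
                if g <= 1e-12:
                    continue
                if best is None or g > best[0]:
                    best = (g, cand)
            if best is None:
                break
            com.remove(best[1])
            changed = True
        if not changed:
            break
    return set(com.members)


class _NameOrder(str):
    """Reverses string comparison so lexicographically-first names win max()."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def detect_modules(net: nx.Graph, alpha: float = 1.0, min_nodes: int = 2) -> list[Module]:
    """Detect overlapping modules in a weighted network.

    Deterministic for a given graph regardless of edge insertion order.
    Communities smaller than ``min_nodes`` are not reported.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    edges = sorted(
        ((min(u, v), max(u, v), d.get("weight", 1.0)) for u, v, d in net.edges(data=True)),
        key=lambda e: (-e[2], e[0], e[1]),
    )
    visited: set[tuple[str, str]] = set()
    communities: list[set[str]] = []
    seen: set[frozenset[str]] = set()
    for u, v, _w in edges:
        if (u, v) in visited:
            continue
        members = _expand(net, (u, v), alpha)
        for a in members:
            for b in members:
                if a < b and net.has_edge(a, b):
                    visited.add((a, b))
        key = frozenset(members)
        if key not in seen:
            seen.add(key)
            communities.append(members)

    out: list[Module] = []
    mid = 0
    for members in communities:
        if len(members) < min_nodes:
            continue
        mid += 1
        induced = tuple(
            (a, b, float(net[a][b].get("weight", 1.0)))
            for a, b in sorted(
                (min(x, y), max(x, y))
                for x, y in net.subgraph(members).edges
            )
        )
        out.append(Module(id=mid, genes=frozenset(members), edges=induced))
    return out


def filter_modules(
    modules: list[Module],
    min_nodes: int = 6,
    criterion: str = "nodes",
) -> list[Module]:
    """Retain modules with more than ``min_nodes - 1`` nodes (or edges).

    The default keeps modules with at least 6 nodes (strictly more than
    five); ``criterion='edges'`` applies the same cut to edge counts.
    """
    if criterion == "nodes":
        return [m for m in modules if m.n_nodes >= min_nodes]
    if criterion == "edges":
        return [m for m in modules if m.n_edges >= min_nodes]
    raise ValueError(f"unknown filter criterion: {criterion!r}")


def best_match_jaccard(detected: list[Module], reference: set[str]) -> float:
    """Best Jaccard overlap between a reference gene set and detected modules."""
    best = 0.0
    ref = set(reference)
    for m in detected:
        inter = len(ref & m.genes)
        union = len(ref | m.genes)
        if union:
            best = max(best, inter / union)
    return best
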