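"""Topological path analysis on signed interaction networks.

Two search modes connect a source ``u`` to a target ``v``:

* ``shortest`` — every path of minimal length, reconstructed from a
  breadth-first parent-set sweep;
* ``extended`` — every path in which no *interaction* occurs twice
  (elements may repeat, so feedback loops are traversable once), up to a
  length cap.

Each path carries its length L and type T (product of edge signs).
Filtering a path set by a through-element ``e`` splits each surviving path
into an incoming subpath P(u,e) and an outgoing subpath P(e,v); the split
preserves T(P) = T_in * T_out and L(P) = L_in + L_out.  Elements occurring
anywhere in a path set can be ranked by their percentage of appearance in
positive-type and negative-type paths separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .network_core import MolecularNetwork, NetworkError, Path, SignedInteraction

__all__ = [
    "PathSet",
    "ThroughPair",
    "ThroughDecomposition",
    "ElementRanking",
    "shortest_paths",
    "extended_paths",
    "filter_through",
    "rank_elements",
    "DEFAULT_MAX_LENGTH",
    "DEFAULT_PATH_CEILING",
]

DEFAULT_MAX_LENGTH = 8
DEFAULT_PATH_CEILING = 10_000


@dataclass(frozen=True)
class PathSet:
    source: str
    target: str
    paths: tuple[Path, ...]
    search_mode: str  # "shortest" | "extended"
    max_length: int | None = None
    truncated: bool = False  # path-count ceiling hit; result is partial

    def __len__(self) -> int:
        return len(self.paths)

    def __iter__(self):
        return iter(self.paths)

    @property
    def positive(self) -> tuple[Path, ...]:
        return tuple(p for p in self.paths if p.ptype == 1)

    @property
    def negative(self) -> tuple[Path, ...]:
        return tuple(p for p in self.paths if p.ptype == -1)

    def to_tsv(self) -> str:
        lines = ["length\ttype\tsteps\tprovenance"]
        for p in sorted(self.paths, key=lambda p: (p.length, p.nodes)):
            arrows = p.steps[0].source
            for s in p.steps:
                arrows += ("-|" if s.sign < 0 else "->") + s.target
            prov = ";".join(s.provenance for s in p.steps if s.provenance)
            lines.append(f"{p.length}\t{p.ptype:+d}\t{arrows}\t{prov}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class ThroughPair:
    incoming: Path
    outgoing: Path

    @property
    def full(self) -> Path:
        return Path(self.incoming.steps + self.outgoing.steps)


@dataclass(frozen=True)
class ThroughDecomposition:
    through: str
    pairs: tuple[ThroughPair, ...]

    @property
    def positive_fraction(self) -> float | None:
        if not self.pairs:
            return None
        pos = sum(1 for p in self.pairs if p.full.ptype == 1)
        return pos / len(self.pairs)

    @property
    def negative_fraction(self) -> float | None:
        if not self.pairs:
            return None
        return 1.0 - self.positive_fraction

    def table(self) -> list[tuple[int, int, int, int]]:
        """(L_in, T_in, L_out, T_out) per surviving path."""
        return [
            (p.incoming.length, p.incoming.ptype, p.outgoing.length, p.outgoing.ptype)
            for p in self.pairs
        ]


@dataclass(frozen=True)
class ElementRanking:
    """Per element: fraction of positive / negative paths containing it.

    A fraction is ``None`` when the path set has no paths of that type
    (not applicable rather than zero).
    """

    entries: tuple[tuple[str, float | None, float | None], ...]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def as_dict(self) -> dict[str, tuple[float | None, float | None]]:
        return {eid: (pos, neg) for eid, pos, neg in self.entries}

    def to_tsv(self) -> str:
        lines = ["element\tpositive_fraction\tnegative_fraction"]
        for eid, pos, neg in self.entries:
            fmt = lambda x: "NA" if x is None else f"{x:.6g}"
            lines.append(f"{eid}\t{fmt(pos)}\t{fmt(neg)}")
        return "\n".join(lines) + "\n"


def _adjacency(network: MolecularNetwork) -> dict[str, list[SignedInteraction]]:
    adj: dict[str, list[SignedInteraction]] = {eid: [] for eid in network.elements}
    for ia in network.interactions:
        adj[ia.source].append(ia)
    return adj


def _check_nodes(network: MolecularNetwork, *nodes: str) -> None:
    for n in nodes:
        if n not in network:
            raise NetworkError(f"unknown element id: {n!r}")


def shortest_paths(network: MolecularNetwork, u: str, v: str) -> PathSet:
    """All minimal-length paths from u to v (empty set if unreachable).

    BFS records, for every node, the set of incoming interactions used at
    its discovery depth; paths are reconstructed backwards from v.  For
    u == v the search looks for the shortest cycles through u, never the
    empty path.
    """
    _check_nodes(network, u, v)
    adj = _adjacency(network)

    # BFS depths; when u == v we must leave and come back, so v's depth is
    # tracked separately from u's starting depth 0.
    depth: dict[str, int] = {u: 0}
    parents: dict[str, list[SignedInteraction]] = {}
    target_depth: int | None = None
    frontier = [u]
    d = 0
    while frontier and target_depth is None:
        d += 1
        nxt: list[str] = []
        for node in frontier:
            for ia in adj[node]:
                t = ia.target
                known = depth.get(t)
                if t == v:
                    if target_depth is None:
                        target_depth = d
                    if d == target_depth:
                        parents.setdefault(t, []).append(ia)
                    continue
                if known is None:
                    depth[t] = d
                    parents[t] = [ia]
                    nxt.append(t)
                elif known == d:
                    parents[t].append(ia)
        frontier = nxt
    if target_depth is None:
        return PathSet(u, v, (), "shortest")

    # backward reconstruction over the parent sets
    paths: list[Path] = []

    def back(node: str, d: int, acc: list[SignedInteraction]) -> None:
        if d == 0:
            paths.append(Path(tuple(reversed(acc))))
            return
        for ia in parents.get(node, ()):  # parents recorded at depth d
            src_depth = 0 if ia.source == u else depth.get(ia.source)
            if src_depth == d - 1:
                acc.append(ia)
                back(ia.source, d - 1, acc)
                acc.pop()

    back(v, target_depth, [])
    paths.sort(key=lambda p: p.nodes)
    return PathSet(u, v, tuple(paths), "shortest")


def extended_paths(
    network: MolecularNetwork,
    u: str,
    v: str,
    max_length: int = DEFAULT_MAX_LENGTH,
    path_ceiling: int = DEFAULT_PATH_CEILING,
) -> PathSet:
    """All edge-distinct paths from u to v up to ``max_length``.

    Within one path no interaction may be reused, but an element may be
    visited twice when distinct interactions lead through it.  The
    enumeration is exhaustive and order-independent; if more than
    ``path_ceiling`` paths exist the result is flagged as truncated.
    """
    _check_nodes(network, u, v)
    if max_length < 1:
        raise NetworkError("max_length must be >= 1")
    adj = _adjacency(network)
    paths: list[Path] = []
    truncated = False
    used: set[tuple[str, int, str]] = set()
    acc: list[SignedInteraction] = []

    def dfs(node: str) -> None:
        nonlocal truncated
        if truncated:
            return
        if acc and node == v:
            paths.append(Path(tuple(acc)))
            if len(paths) >= path_ceiling:
                truncated = True
            # a longer path may still revisit v through other edges
        if len(acc) == max_length:
            return
        for ia in adj[node]:
            if ia.triple in used:
                continue
            used.add(ia.triple)
            acc.append(ia)
            dfs(ia.target)
            acc.pop()
            used.remove(ia.triple)

    dfs(u)
    paths.sort(key=lambda p: (p.length, p.nodes, tuple(s.sign for s in p.steps)))
    return PathSet(u, v, tuple(paths), "extended", max_length, truncated)


def filter_through(pathset: PathSet, e: str) -> ThroughDecomposition:
    """Keep paths passing through intermediate element e; split each there.

    The split happens at the *first* occurrence of e, so a path looping
    back through e keeps a well-defined incoming/outgoing decomposition
    with L_in + L_out = L and T_in * T_out = T.
    """
    if e == pathset.source or e == pathset.target:
        raise NetworkError(
            f"through-element {e!r} must be an intermediate, not an endpoint"
        )
    pairs: list[ThroughPair] = []
    for p in pathset.paths:
        for i, step in enumerate(p.steps):
            if step.target == e and i < len(p.steps) - 1:
                pairs.append(
                    ThroughPair(Path(p.steps[: i + 1]), Path(p.steps[i + 1 :]))
                )
                break
    return ThroughDecomposition(e, tuple(pairs))


def rank_elements(pathset: PathSet) -> ElementRanking:
    """Percentage of appearance in positive vs negative paths per element.

    Fractions use per-type denominators; a type with no paths yields None.
    Sorted by total appearance count descending, ties lexicographically.
    """
    pos_paths = pathset.positive
    neg_paths = pathset.negative
    counts: dict[str, list[int]] = {}
    for paths, slot in ((pos_paths, 0), (neg_paths, 1)):
        for p in paths:
            for node in set(p.nodes):
                counts.setdefault(node, [0, 0])[slot] += 1
    entries = []
    for eid, (np_, nn) in counts.items():
        pos = np_ / len(pos_paths) if pos_paths else None
        neg = nn / len(neg_paths) if neg_paths else None
        entries.append((eid, pos, neg, np_ + nn))
    entries.sort(key=lambda t: (-t[3], t[0]))
    return ElementRanking(tuple((eid, pos, neg) for eid, pos, neg, _ in entries))
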