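"""Aggregation of similar probe sets into groups via triangles.

Within one similarity class, all triangles of pairwise-similar probe sets
are found and triangles sharing an edge (two probe sets) are aggregated into
groups.  Aggregation can pull in a non-similar member pair (a "bad link"):
triangles (ABC) and (ABD) aggregate to (ABCD) even when (C, D) is not
similar.  Two triangles sharing only one probe set stay in different groups
and the shared probe set is recorded as a pivot, kept apart in its own list.
Similar pairs that belong to no triangle form two-member groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

Pair = tuple[str, str]
Triangle = tuple[str, str, str]


@dataclass
class ProbeSetGroup:
    members: frozenset[str]
    bad_links: frozenset[Pair]
    source_triangles: tuple[Triangle, ...]


@dataclass
class PivotRecord:
    probe_set: str
    groups: list[int]  # indices into the returned group list


def _norm_pair(a: str, b: str) -> Pair:
    return (a, b) if a <= b else (b, a)


def normalize_pairs(pairs: Iterable[Sequence[str]]) -> set[Pair]:
    out = set()
    for a, b in pairs:
        if a == b:
            raise ValueError(f"self-pair {a!r}")
        out.add(_norm_pair(a, b))
    return out


def find_triangles(similar_pairs: Iterable[Sequence[str]]) -> set[Triangle]:
    """All unordered triples whose three pairs are all similar."""
    pairs = normalize_pairs(similar_pairs)
    adj: dict[str, set[str]] = {}
    for a, b in pairs:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    triangles = set()
    for a, b in pairs:
        for c in adj[a] & adj[b]:
            triangles.add(tuple(sorted((a, b, c))))
    return triangles


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def aggregate_groups(
    triangles: Iterable[Triangle], similar_pairs: Iterable[Sequence[str]]
) -> tuple[list[ProbeSetGroup], list[PivotRecord]]:
    """Groups = components of the shared-edge triangle graph, plus lone pairs.

    Group members are the union of a component's triangle vertices; member
    pairs absent from ``similar_pairs`` are the group's bad links.  Probe
    sets appearing in triangle-derived groups of different components are
    pivots.  Similar pairs covered by no triangle become two-member groups.
    """
    pairs = normalize_pairs(similar_pairs)
    tris = sorted(set(tuple(sorted(t)) for t in triangles))
    for t in tris:
        for e in combinations(t, 2):
            if _norm_pair(*e) not in pairs:
                raise ValueError(f"triangle {t} inconsistent with similar pairs: {e}")

    uf = _UnionFind(len(tris))
    edge_to_tris: dict[Pair, list[int]] = {}
    for idx, t in enumerate(tris):
        for e in combinations(t, 2):
            edge_to_tris.setdefault(e, []).append(idx)
    for idxs in edge_to_tris.values():
        for other in idxs[1:]:
            uf.union(idxs[0], other)

    comp_tris: dict[int, list[int]] = {}
    for idx in range(len(tris)):
        comp_tris.setdefault(uf.find(idx), []).append(idx)

    groups: list[ProbeSetGroup] = []
    for idxs in comp_tris.values():
        members = set()
        for idx in idxs:
            members.update(tris[idx])
        bad = frozenset(
            _norm_pair(a, b)
            for a, b in combinations(sorted(members), 2)
            if _norm_pair(a, b) not in pairs
        )
        groups.append(ProbeSetGroup(
            members=frozenset(members),
            bad_links=bad,
            source_triangles=tuple(tris[idx] for idx in sorted(idxs)),
        ))

    # similar pairs inside no triangle become two-member groups
    covered = set()
    for t in tris:
        covered.update(_norm_pair(*e) for e in combinations(t, 2))
    for pair in sorted(pairs - covered):
        groups.append(ProbeSetGroup(frozenset(pair), frozenset(), ()))

    groups.sort(key=lambda g: sorted(g.members))

    membership: dict[str, list[int]] = {}
    for gi, g in enumerate(groups):
        if not g.source_triangles:
            continue  # lone pairs do not create pivots
        for ps in g.members:
            membership.setdefault(ps, []).append(gi)
    pivots = [
        PivotRecord(ps, gis) for ps, gis in sorted(membership.items()) if len(gis) >= 2
    ]
    return groups, pivots
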