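"""Haplotype collapsing and parsimony-style haplotype networks.

Mirrors the usual population-genetic workflow: alignment columns carrying
any gap, unknown or ambiguity symbol in any sequence are removed globally;
identical sequences over the retained columns collapse into haplotypes
annotated with per-group frequencies; haplotypes are joined by a
minimum-spanning network whose edge weights are mutational steps (Hamming
distances). With ``epsilon=0`` the network is the union of all minimum
spanning trees, so ties produce reticulations. A configurable ``max_steps``
stands in for the statistical-parsimony connection limit; edges longer
than it are never drawn and the network may then be disconnected.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .seqio import Alignment, GroupMap

__all__ = [
    "Haplotype",
    "HaplotypeNetwork",
    "mask_uninformative_columns",
    "collapse_haplotypes",
    "build_parsimony_network",
]

_KEEP = frozenset("ACGT")


@dataclass(frozen=True)
class Haplotype:
    """A unique sequence over the retained columns with its carriers."""

    sequence: str
    member_ids: tuple[str, ...]
    group_counts: dict[str, int] = field(hash=False)

    def __post_init__(self) -> None:
        if self.total_count != sum(self.group_counts.values()):
            raise ValueError("group counts do not sum to member count")
        if self.total_count < 1:
            raise ValueError("haplotype with no members")

    @property
    def total_count(self) -> int:
        return len(self.member_ids)


@dataclass
class HaplotypeNetwork:
    nodes: list[Haplotype]
    edges: list[tuple[int, int, int]]  # (node index, node index, steps)
    retained_columns: list[int]  # 0-based indices into the source alignment

    def __post_init__(self) -> None:
        seqs = [h.sequence for h in self.nodes]
        if len(set(seqs)) != len(seqs):
            raise ValueError("duplicate node sequences")
        for i, j, steps in self.edges:
            if i == j:
                raise ValueError("self-edge")
            if steps < 1:
                raise ValueError("edge with < 1 step")
            if steps != hamming(seqs[i], seqs[j]):
                raise ValueError("edge steps do not equal Hamming distance")

    def n_components(self) -> int:
        dsu = _DSU(len(self.nodes))
        for i, j, _ in self.edges:
            dsu.union(i, j)
        return len({dsu.find(i) for i in range(len(self.nodes))})

    def write_csv(self, edge_path: str | Path, node_path: str | Path) -> None:
        groups = sorted({g for h in self.nodes for g in h.group_counts})
        node_rows = []
        for k, h in enumerate(self.nodes):
            row = {"hap_id": k, "count": h.total_count,
                   "member_ids": ";".join(h.member_ids)}
            for g in groups:
                row[f"n_{g}"] = h.group_counts.get(g, 0)
            node_rows.append(row)
        pd.DataFrame(node_rows).to_csv(node_path, index=False)
        pd.DataFrame(
            [{"hap_id_a": i, "hap_id_b": j, "steps": s} for i, j, s in self.edges]
        ).to_csv(edge_path, index=False)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("unequal lengths")
    return sum(x != y for x, y in zip(a, b))


def mask_uninformative_columns(alignment: Alignment) -> tuple[Alignment, list[int]]:
    """Drop every column where any sequence is not a plain A/C/G/T.

    Gaps, '?', N and all ambiguity codes trigger removal of the whole
    column (global masking). Returns the masked alignment and the 0-based
    retained column indices.
    """
    retained = [
        c
        for c in range(alignment.length)
        if all(seq[c] in _KEEP for seq in alignment.sequences)
    ]
    if not retained:
        raise ValueError(f"{alignment.locus_name}: all columns masked")
    records = tuple(
        (rid, "".join(seq[c] for c in retained)) for rid, seq in alignment.records
    )
    return Alignment(alignment.locus_name, records), retained


def collapse_haplotypes(alignment: Alignment, groups: GroupMap) -> list[Haplotype]:
    """Merge identical sequences into haplotypes with group tallies.

    Order is deterministic: decreasing total count, then sequence.
    """
    by_seq: dict[str, list[str]] = {}
    for rid, seq in alignment.records:
        by_seq.setdefault(seq, []).append(rid)
    haps = []
    for seq, ids in by_seq.items():
        gc: dict[str, int] = {}
        for rid in ids:
            g = groups.group_of(rid)
            gc[g] = gc.get(g, 0) + 1
        haps.append(Haplotype(seq, tuple(ids), gc))
    haps.sort(key=lambda h: (-h.total_count, h.sequence))
    return haps


class _DSU:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def build_parsimony_network(
    haps: list[Haplotype],
    epsilon: int = 0,
    max_steps: int | None = None,
    retained_columns: list[int] | None = None,
) -> HaplotypeNetwork:
    """Minimum-spanning network over haplotypes.

    An edge (u, v) with weight w is drawn when w <= w*(u, v) + epsilon,
    where w*(u, v) is the smallest weight at which u and v first fall in
    the same connected component when candidate edges are added in
    nondecreasing weight order (the minimax connection weight). Edges with
    w > max_steps are never candidates, so the network may be disconnected.
    """
    n = len(haps)
    if n < 1:
        raise ValueError("need at least one haplotype")
    cand = []
    for i, j in itertools.combinations(range(n), 2):
        w = hamming(haps[i].sequence, haps[j].sequence)
        if max_steps is None or w <= max_steps:
            cand.append((w, i, j))
    cand.sort()
    # connection weight per candidate pair: sweep weight classes upward,
    # unioning each full class, and record the first class at which the
    # pair's endpoints share a component
    conn: dict[tuple[int, int], int] = {}
    dsu = _DSU(n)
    pending = {(i, j) for _, i, j in cand}
    for w, grp in itertools.groupby(cand, key=lambda t: t[0]):
        for _, i, j in list(grp):
            dsu.union(i, j)
        done = {
            (i, j) for (i, j) in pending if dsu.find(i) == dsu.find(j)
        }
        for p in done:
            conn[p] = w
        pending -= done
    edges = [
        (i, j, w)
        for w, i, j in cand
        if (i, j) in conn and w <= conn[(i, j)] + epsilon
    ]
    return HaplotypeNetwork(list(haps), edges, retained_columns or [])
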