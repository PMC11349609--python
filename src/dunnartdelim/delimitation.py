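"""Tree- and distance-based species delimitation statistics.

For each pair of putative species (clades) the report gives:

* **Mono** — whether each group, and both reciprocally, form exclusive
  clades on the supplied rooted tree.
* **Intra/Inter** — mean within-group distance over mean between-group
  distance; values well below 1 indicate cohesive, separated groups.
* **Prob correct** — leave-one-out nearest-neighbor probability of placing
  an individual in its own group, with a normal-approximation 95% CI.
* **Rosenberg's P_AB** — probability of the observed monophyly arising
  under a null of random coalescence of exchangeable lineages; small
  values reject the single-species null. Only reported when the relevant
  monophyly actually holds (NA otherwise).

Two P_AB variants are computed by the same recursion over random
sequential pairwise coalescence: ``reciprocal`` (both groups monophyletic;
the default) and ``clade_A`` (group A alone).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache

import dendropy
import numpy as np
import pandas as pd

from .distances import DistanceMatrix
from .seqio import GroupMap

__all__ = [
    "CladePair",
    "is_monophyletic",
    "rosenberg_pab",
    "intra_inter_ratio",
    "prob_correct_id",
    "delimit_report",
]


@dataclass(frozen=True)
class CladePair:
    """Two disjoint, named tip sets to be tested as putative species."""

    name_a: str
    tips_a: frozenset[str]
    name_b: str
    tips_b: frozenset[str]

    def __post_init__(self) -> None:
        if not self.tips_a or not self.tips_b:
            raise ValueError("both groups must be non-empty")
        if self.tips_a & self.tips_b:
            raise ValueError("groups must be disjoint")

    @classmethod
    def from_groups(
        cls, groups: GroupMap, labels_a: list[str], labels_b: list[str],
        restrict_to: set[str] | None = None,
    ) -> "CladePair":
        def collect(labels: list[str]) -> frozenset[str]:
            ids = [i for lab in labels for i in groups.members(lab)]
            if restrict_to is not None:
                ids = [i for i in ids if i in restrict_to]
            return frozenset(ids)

        return cls("+".join(labels_a), collect(labels_a),
                   "+".join(labels_b), collect(labels_b))


def is_monophyletic(tree: dendropy.Tree, tips: set[str]) -> bool:
    """True iff some node's descendant tip set equals *tips* exactly."""
    tips = frozenset(tips)
    all_tips = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
    unknown = tips - all_tips
    if unknown:
        raise KeyError(f"unknown tip ids: {sorted(unknown)}")
    if len(tips) == 1 or tips == all_tips:
        return True
    sets: dict[dendropy.Node, frozenset[str]] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            sets[nd] = frozenset([nd.taxon.label])
        else:
            sets[nd] = frozenset().union(*(sets[c] for c in nd.child_nodes()))
        if sets[nd] == tips:
            return True
    return False


@lru_cache(maxsize=None)
def _recip(i: int, j: int) -> Fraction:
    # R(1,1)=1; R(i,j) = [C(i,2) R(i-1,j) + C(j,2) R(i,j-1)] / C(i+j,2)
    if i == 1 and j == 1:
        return Fraction(1)
    total = Fraction(math.comb(i + j, 2))
    acc = Fraction(0)
    if i >= 2:
        acc += math.comb(i, 2) * _recip(i - 1, j)
    if j >= 2:
        acc += math.comb(j, 2) * _recip(i, j - 1)
    return acc / total


@lru_cache(maxsize=None)
def _clade_a(i: int, j: int) -> Fraction:
    # M(1,j)=1; M(i,j) = [C(i,2) M(i-1,j) + C(j,2) M(i,j-1)] / C(i+j,2)
    if i == 1:
        return Fraction(1)
    if j == 0:
        # only A lineages remain: A-clade forms with certainty
        return Fraction(1)
    total = Fraction(math.comb(i + j, 2))
    acc = Fraction(0)
    if i >= 2:
        acc += math.comb(i, 2) * _clade_a(i - 1, j)
    if j >= 2:
        acc += math.comb(j, 2) * _clade_a(i, j - 1)
    return acc / total


def rosenberg_pab(
    a: int, b: int, variant: str = "reciprocal", exact: bool = False
) -> float | Fraction:
    """Probability of monophyly under random sequential pairwise coalescence
    of a + b exchangeable lineages.

    ``variant="reciprocal"``: both the a-group and the b-group monophyletic
    (symmetric in a, b). ``variant="clade_A"``: the a-group alone. Returns
    an exact :class:`~fractions.Fraction` when *exact*.
    """
    if a < 1 or b < 1:
        raise ValueError("group sizes must be >= 1")
    if variant == "reciprocal":
        p = _recip(a, b)
    elif variant == "clade_A":
        p = _clade_a(a, b)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return p if exact else float(p)


def intra_inter_ratio(dist: DistanceMatrix, pair: CladePair) -> float:
    """Mean within-group distance over mean between-group distance.

    Pools within-A and within-B distinct pairs for the numerator. An
    all-zero inter mean yields NaN (flagged undefined). Undefined matrix
    cells are excluded from both means.
    """
    labels = set(dist.labels)
    missing = (pair.tips_a | pair.tips_b) - labels
    if missing:
        raise KeyError(f"ids not in distance matrix: {sorted(missing)}")
    intra = [
        dist.get(x, y)
        for tips in (pair.tips_a, pair.tips_b)
        for x, y in itertools.combinations(sorted(tips), 2)
    ]
    inter = [dist.get(x, y) for x in sorted(pair.tips_a) for y in sorted(pair.tips_b)]
    intra = [d for d in intra if not math.isnan(d)]
    inter = [d for d in inter if not math.isnan(d)]
    if not intra or not inter:
        return math.nan
    inter_mean = float(np.mean(inter))
    if inter_mean == 0:
        return math.nan
    return float(np.mean(intra)) / inter_mean


def prob_correct_id(
    dist: DistanceMatrix, groups: GroupMap, focal: str
) -> tuple[float, tuple[float, float]]:
    """Leave-one-out nearest-neighbor identification success for a group.

    Each focal member is correctly identified when its nearest non-self
    neighbor (over all matrix labels) is also focal; distance ties that
    include a non-focal neighbor count as incorrect (conservative).
    Returns the proportion and a normal-approximation 95% CI truncated
    to [0, 1].
    """
    members = [m for m in groups.members(focal) if m in dist.labels]
    if len(members) < 2:
        raise ValueError(f"focal group {focal!r} needs >= 2 members in the matrix")
    n_correct = 0
    for m in members:
        i = dist.index(m)
        row = dist.values[i].copy()
        row[i] = math.inf
        row[np.isnan(row)] = math.inf
        dmin = row.min()
        if math.isinf(dmin):
            continue
        nearest = [dist.labels[j] for j in np.flatnonzero(row == dmin)]
        if all(groups.group_of(x) == focal for x in nearest):
            n_correct += 1
    n = len(members)
    p = n_correct / n
    half = 1.96 * math.sqrt(p * (1 - p) / n)
    return p, (max(0.0, p - half), min(1.0, p + half))


def _pooled_prob_correct(
    dist: DistanceMatrix, pair: CladePair
) -> tuple[float, tuple[float, float]]:
    """Prob-correct pooled over both groups of a pair, evaluated on the
    submatrix containing only the pair's members."""
    ids = sorted(pair.tips_a | pair.tips_b)
    sub = dist.submatrix(ids)
    gm = GroupMap({i: ("A" if i in pair.tips_a else "B") for i in ids})
    n_correct = 0
    n = 0
    for focal in ("A", "B"):
        members = gm.members(focal)
        if len(members) < 2:
            continue
        p, _ = prob_correct_id(sub, gm, focal)
        n_correct += round(p * len(members))
        n += len(members)
    if n == 0:
        return math.nan, (math.nan, math.nan)
    p = n_correct / n
    half = 1.96 * math.sqrt(p * (1 - p) / n)
    return p, (max(0.0, p - half), min(1.0, p + half))


def delimit_report(
    tree: dendropy.Tree,
    dist: DistanceMatrix,
    pairs: list[CladePair],
    variant: str = "reciprocal",
) -> pd.DataFrame:
    """One report row per clade pair, with the delimitation statistics.

    ``dist`` supplies the distances for intra/inter and prob-correct
    (patristic from the same tree by default in the pipeline; a sequence
    distance matrix is equally valid). P_AB is NA unless the monophyly the
    chosen variant tests actually holds on the tree.
    """
    rows = []
    for pair in pairs:
        mono_a = is_monophyletic(tree, pair.tips_a)
        mono_b = is_monophyletic(tree, pair.tips_b)
        mono_recip = mono_a and mono_b
        relevant = mono_recip if variant == "reciprocal" else mono_a
        pab = (
            rosenberg_pab(len(pair.tips_a), len(pair.tips_b), variant)
            if relevant
            else math.nan
        )
        p, (lo, hi) = _pooled_prob_correct(dist, pair)
        rows.append(
            {
                "species_1": pair.name_a,
                "species_2": pair.name_b,
                "n_1": len(pair.tips_a),
                "n_2": len(pair.tips_b),
                "mono_1": mono_a,
                "mono_2": mono_b,
                "mono_reciprocal": mono_recip,
                "intra_inter": intra_inter_ratio(dist, pair),
                "prob_correct": p,
                "prob_correct_low": lo,
                "prob_correct_high": hi,
                "rosenberg_pab": pab,
                "pab_variant": variant,
                "distance_mode": dist.mode,
            }
        )
    return pd.DataFrame(rows)
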