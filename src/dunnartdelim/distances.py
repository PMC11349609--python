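"""Kimura two-parameter pairwise distances and group-level summaries.

The K2P model corrects observed substitution proportions for multiple hits,
distinguishing transitions (A<->G, C<->T) from transversions. Distances are
computed per pair with pairwise deletion: any alignment column where either
sequence carries a non-ACGT symbol (gap, ?, N or an ambiguity code) is
excluded for that pair only.

Two modes follow the study design: ``k2p_all`` uses all substitutions
(d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q)); ``k2p_tv`` is the transversion
component only (d = -1/2 ln(1-2Q)), as used for slowly evolving loci such
as 12S rRNA.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .seqio import Alignment, GroupMap

__all__ = [
    "SiteCounts",
    "DistanceMatrix",
    "GroupDistanceSummary",
    "SaturationError",
    "count_site_patterns",
    "k2p_distance",
    "pairwise_matrix",
    "group_summary",
]

log = logging.getLogger(__name__)

# state codes: A=0, G=1 (purines), C=2, T=3 (pyrimidines); 255 = missing
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate("AGCT"):
    _CODE[ord(_c)] = _i

DISTANCE_MODES = ("k2p_all", "k2p_tv", "hamming", "patristic", "euclidean")


class SaturationError(ValueError):
    """The K2P logarithm argument is <= 0: the distance is undefined."""


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (non-ACGT -> 255 = missing)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class SiteCounts:
    """Per-pair site classification under pairwise deletion.

    ``P`` and ``Q`` are the transition and transversion proportions over
    the ``n_valid`` compared sites; both are NaN when no site is comparable.
    """

    n_valid: int
    n_transitions: int
    n_transversions: int

    def __post_init__(self) -> None:
        if min(self.n_valid, self.n_transitions, self.n_transversions) < 0:
            raise ValueError("negative site counts")
        if self.n_transitions + self.n_transversions > self.n_valid:
            raise ValueError("more substitutions than valid sites")

    @property
    def P(self) -> float:
        return self.n_transitions / self.n_valid if self.n_valid else math.nan

    @property
    def Q(self) -> float:
        return self.n_transversions / self.n_valid if self.n_valid else math.nan

    @property
    def p_distance(self) -> float:
        """Raw mismatch proportion (uncorrected)."""
        if not self.n_valid:
            return math.nan
        return (self.n_transitions + self.n_transversions) / self.n_valid


def count_site_patterns(seq_a: str, seq_b: str) -> SiteCounts:
    """Classify aligned sites of a sequence pair into transitions and
    transversions, excluding columns where either sequence is non-ACGT."""
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"unequal sequence lengths: {len(seq_a)} vs {len(seq_b)}"
        )
    a = encode(seq_a)
    b = encode(seq_b)
    valid = (a != 255) & (b != 255)
    av, bv = a[valid], b[valid]
    diff = av != bv
    # same purine/pyrimidine class (codes 0,1 vs 2,3) -> transition
    transition = diff & ((av >> 1) == (bv >> 1))
    n_ts = int(transition.sum())
    n_tv = int(diff.sum()) - n_ts
    return SiteCounts(int(valid.sum()), n_ts, n_tv)


def k2p_distance(counts: SiteCounts, mode: str = "k2p_all") -> float:
    """K2P distance (substitutions/site) from site counts.

    Raises :class:`SaturationError` when a logarithm argument is <= 0
    (saturated pair) and ``ValueError`` when no sites are comparable.
    """
    if counts.n_valid == 0:
        raise ValueError("no comparable sites (n_valid = 0)")
    P, Q = counts.P, counts.Q
    w2 = 1.0 - 2.0 * Q
    if mode == "k2p_tv":
        if w2 <= 0:
            raise SaturationError(f"saturated pair: 1-2Q = {w2:.4g} <= 0")
        return -0.5 * math.log(w2)
    if mode == "k2p_all":
        w1 = 1.0 - 2.0 * P - Q
        if w1 <= 0 or w2 <= 0:
            raise SaturationError(
                f"saturated pair: 1-2P-Q = {w1:.4g}, 1-2Q = {w2:.4g}"
            )
        return -0.5 * math.log(w1) - 0.25 * math.log(w2)
    if mode == "hamming":
        return counts.p_distance
    raise ValueError(f"unknown distance mode {mode!r}")


@dataclass
class DistanceMatrix:
    """Symmetric labeled distance matrix; NaN marks undefined cells."""

    labels: tuple[str, ...]
    values: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")
        if self.mode not in DISTANCE_MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        with np.errstate(invalid="ignore"):
            if not np.allclose(
                np.nan_to_num(self.values), np.nan_to_num(self.values.T)
            ):
                raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("nonzero diagonal")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    @property
    def n_undefined(self) -> int:
        """Number of undefined (NaN) unordered off-diagonal pairs."""
        iu = np.triu_indices(self.n, k=1)
        return int(np.isnan(self.values[iu]).sum())

    def submatrix(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.index(x) for x in labels]
        return DistanceMatrix(tuple(labels), self.values[np.ix_(idx, idx)], self.mode)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_square_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="id")

    def write_long_csv(self, path: str | Path) -> None:
        rows = [
            {
                "id_a": self.labels[i],
                "id_b": self.labels[j],
                "distance": self.values[i, j],
                "mode": self.mode,
            }
            for i, j in itertools.combinations(range(self.n), 2)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def pairwise_matrix(alignment: Alignment, mode: str = "k2p_all") -> DistanceMatrix:
    """Pairwise distance matrix over all records of an alignment.

    Saturated or zero-overlap pairs are flagged undefined (NaN) with a
    logged warning count, never silently zeroed.
    """
    if alignment.n < 2:
        raise ValueError("need at least 2 records")
    enc = np.stack([encode(s) for s in alignment.sequences])
    n = alignment.n
    vals = np.zeros((n, n))
    undefined = 0
    for i, j in itertools.combinations(range(n), 2):
        a, b = enc[i], enc[j]
        valid = (a != 255) & (b != 255)
        av, bv = a[valid], b[valid]
        diff = av != bv
        ts = int((diff & ((av >> 1) == (bv >> 1))).sum())
        counts = SiteCounts(int(valid.sum()), ts, int(diff.sum()) - ts)
        try:
            d = k2p_distance(counts, mode)
        except (SaturationError, ValueError):
            d = math.nan
            undefined += 1
        vals[i, j] = vals[j, i] = d
    if undefined:
        log.warning(
            "%s: %d of %d pairs undefined (saturation or no overlap)",
            alignment.locus_name,
            undefined,
            n * (n - 1) // 2,
        )
    return DistanceMatrix(alignment.ids, vals, mode)


@dataclass
class GroupDistanceSummary:
    """Between- and within-group mean/min/max of pairwise distances.

    ``between`` has one row per unordered group pair; ``within`` one row
    per group with >= 2 members (NaN row otherwise). Values are percentages
    (100 x distance) when ``as_percent``.
    """

    between: pd.DataFrame
    within: pd.DataFrame
    as_percent: bool
    mode: str

    def pair_row(self, a: str, b: str) -> pd.Series:
        m = self.between
        row = m[((m.group_a == a) & (m.group_b == b)) | ((m.group_a == b) & (m.group_b == a))]
        if row.empty:
            raise KeyError(f"no group pair ({a}, {b})")
        return row.iloc[0]

    def write_csv(self, path: str | Path) -> None:
        self.between.assign(kind="between").pipe(
            lambda d: pd.concat(
                [d, self.within.assign(kind="within")], ignore_index=True
            )
        ).to_csv(path, index=False)

    def format_matrix(self) -> pd.DataFrame:
        """Square presentation: means above the diagonal, ranges in
        parentheses below it (mirrors the conventional distance table)."""
        labels = list(self.within.group)
        out = pd.DataFrame("", index=labels, columns=labels)
        for lab in labels:
            out.loc[lab, lab] = "-"
        for _, r in self.between.iterrows():
            i, j = labels.index(r.group_a), labels.index(r.group_b)
            hi, lo = (r.group_a, r.group_b) if i < j else (r.group_b, r.group_a)
            out.loc[hi, lo] = f"{r['mean']:.2f}"
            out.loc[lo, hi] = f"({r['min']:.2f}-{r['max']:.2f})"
        return out


def _summarize(ds: list[float]) -> dict[str, float]:
    arr = np.array([d for d in ds if not math.isnan(d)])
    n_undef = len(ds) - len(arr)
    if len(arr) == 0:
        return {"mean": math.nan, "min": math.nan, "max": math.nan,
                "n_pairs": 0, "n_undefined": n_undef}
    return {
        "mean": float(arr.mean()),
        "min": float(arr.min()),
        "max": float(arr.max()),
        "n_pairs": len(arr),
        "n_undefined": n_undef,
    }


def group_summary(
    matrix: DistanceMatrix,
    groups: GroupMap,
    as_percent: bool = False,
    group_order: list[str] | None = None,
) -> GroupDistanceSummary:
    """Summarize a distance matrix by group pairs.

    Every matrix label must be mapped; undefined pairs are excluded from
    summaries and counted in ``n_undefined``.
    """
    unmapped = [x for x in matrix.labels if x not in groups.assignments]
    if unmapped:
        raise KeyError(f"matrix labels missing from group map: {unmapped}")
    if group_order is None:
        group_order = [
            g for g in groups.labels() if any(x in matrix.labels for x in groups.members(g))
        ]
    members = {
        g: [x for x in groups.members(g) if x in matrix.labels] for g in group_order
    }
    scale = 100.0 if as_percent else 1.0
    rows_b = []
    for a, b in itertools.combinations(group_order, 2):
        ds = [matrix.get(x, y) * scale for x in members[a] for y in members[b]]
        rows_b.append({"group_a": a, "group_b": b, **_summarize(ds)})
    rows_w = []
    for g in group_order:
        mem = members[g]
        if len(mem) < 2:
            rows_w.append(
                {"group": g, "mean": math.nan, "min": math.nan, "max": math.nan,
                 "n_pairs": 0, "n_undefined": 0}
            )
            continue
        ds = [matrix.get(x, y) * scale for x, y in itertools.combinations(mem, 2)]
        rows_w.append({"group": g, **_summarize(ds)})
    return GroupDistanceSummary(
        pd.DataFrame(rows_b), pd.DataFrame(rows_w), as_percent, matrix.mode
    )
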