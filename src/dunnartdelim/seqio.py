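"""Input/output and the shared data model.

Reads and validates the three kinds of files the pipeline consumes:
multi-record FASTA alignments (pre-aligned, IUPAC DNA), Newick trees, and
delimited specimen metadata tables mapping sequence/specimen ids to group
labels (subspecies or genetic clade), optional population and sex.

Trees are represented throughout the package as :class:`dendropy.Tree`
objects; alignments and group maps use the lightweight containers defined
here.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import pandas as pd
from Bio import SeqIO

__all__ = [
    "Alignment",
    "GroupMap",
    "AlignmentError",
    "ParseError",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "read_group_map",
    "write_group_map",
    "read_newick",
    "write_newick",
    "tip_labels",
]

#: IUPAC nucleotide one-letter codes (unambiguous + ambiguity codes).
IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")
#: Symbols treated as missing/indel for distance and network computations;
#: preserved verbatim on I/O.
MISSING_SYMBOLS = frozenset("-?")
ALPHABET = IUPAC_CODES | MISSING_SYMBOLS


class AlignmentError(ValueError):
    """An alignment invariant is violated (ragged rows, duplicate ids...)."""


class ParseError(ValueError):
    """A file could not be parsed as the expected format."""


@dataclass(frozen=True)
class Alignment:
    """An equal-length DNA multiple-sequence alignment for one locus.

    Parameters
    ----------
    locus_name:
        Name of the locus (e.g. ``"cytb"``).
    records:
        Ordered ``(id, sequence)`` pairs. Sequences are upper-case IUPAC
        DNA; ``-`` (gap) and ``?`` (unknown) are allowed.
    """

    locus_name: str
    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError(f"{self.locus_name}: alignment has no records")
        length = len(self.records[0][1])
        if length < 1:
            raise AlignmentError(f"{self.locus_name}: zero-length alignment")
        seen: set[str] = set()
        for rid, seq in self.records:
            if not rid:
                raise AlignmentError(f"{self.locus_name}: empty record id")
            if rid in seen:
                raise AlignmentError(f"{self.locus_name}: duplicate id {rid!r}")
            seen.add(rid)
            if len(seq) != length:
                raise AlignmentError(
                    f"{self.locus_name}: record {rid!r} has length "
                    f"{len(seq)}, expected {length}"
                )
            for pos, ch in enumerate(seq):
                if ch not in ALPHABET:
                    raise ParseError(
                        f"{self.locus_name}: illegal character {ch!r} in "
                        f"record {rid!r} at position {pos + 1}"
                    )

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.records[0][1])

    @property
    def n(self) -> int:
        """Number of records."""
        return len(self.records)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(rid for rid, _ in self.records)

    @property
    def sequences(self) -> tuple[str, ...]:
        return tuple(seq for _, seq in self.records)

    def sequence(self, rid: str) -> str:
        for r, s in self.records:
            if r == rid:
                return s
        raise KeyError(rid)

    def subset(self, ids: Iterable[str]) -> "Alignment":
        """Return a new alignment restricted to *ids*, preserving order."""
        keep = set(ids)
        recs = tuple((r, s) for r, s in self.records if r in keep)
        missing = keep - {r for r, _ in recs}
        if missing:
            raise KeyError(f"ids not in alignment: {sorted(missing)}")
        return Alignment(self.locus_name, recs)


@dataclass
class GroupMap:
    """Specimen/sequence id -> group label, with optional population and sex.

    Unrecognized metadata columns from the source table are preserved in
    :attr:`metadata` and retrievable by column name.
    """

    assignments: dict[str, str]
    population: dict[str, str] = field(default_factory=dict)
    sex: dict[str, str] = field(default_factory=dict)
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for rid, label in self.assignments.items():
            if not rid or not str(label):
                raise ValueError(f"empty id or group label: {rid!r} -> {label!r}")

    @property
    def ids(self) -> list[str]:
        return list(self.assignments)

    def labels(self) -> list[str]:
        """Distinct group labels in first-appearance order."""
        out: list[str] = []
        for v in self.assignments.values():
            if v not in out:
                out.append(v)
        return out

    def members(self, label: str) -> list[str]:
        return [i for i, g in self.assignments.items() if g == label]

    def group_of(self, rid: str) -> str:
        return self.assignments[rid]

    def subset(self, ids: Iterable[str]) -> "GroupMap":
        keep = [i for i in ids]
        missing = [i for i in keep if i not in self.assignments]
        if missing:
            raise KeyError(f"ids not in group map: {missing}")
        return GroupMap(
            {i: self.assignments[i] for i in keep},
            {i: self.population[i] for i in keep if i in self.population},
            {i: self.sex[i] for i in keep if i in self.sex},
            None if self.metadata is None else self.metadata.loc[keep],
        )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta_alignment(path: str | Path, locus_name: str | None = None) -> Alignment:
    """Read a FASTA file as a validated :class:`Alignment`.

    Sequence case is normalized to upper; ids are whitespace-trimmed.
    ``locus_name`` defaults to the file stem.
    """
    path = Path(path)
    if locus_name is None:
        locus_name = path.stem
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id.strip(), str(rec.seq).upper()))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return Alignment(locus_name, tuple(records))


def write_fasta_alignment(alignment: Alignment, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in alignment.records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Group map tables


def _detect_sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_group_map(path: str | Path) -> GroupMap:
    """Read a delimited table with header columns ``id`` and ``group``.

    ``population`` and ``sex`` columns are recognized if present
    (case-insensitive); any other columns are preserved as metadata.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), dtype=str)
    cols = {c.lower().strip(): c for c in df.columns}
    if "id" not in cols or "group" not in cols:
        raise ParseError(f"{path}: header must contain 'id' and 'group' columns")
    ids = df[cols["id"]].astype(str).str.strip()
    if ids.duplicated().any():
        dups = sorted(ids[ids.duplicated()].unique())
        raise ValueError(f"{path}: duplicate ids {dups}")
    groups = df[cols["group"]]
    missing = ids[groups.isna() | (groups.astype(str).str.strip() == "")]
    if len(missing):
        raise ValueError(f"{path}: missing group label for ids {sorted(missing)}")
    assignments = dict(zip(ids, groups.astype(str).str.strip()))

    def _optional(key: str) -> dict[str, str]:
        if key not in cols:
            return {}
        col = df[cols[key]]
        return {
            i: str(v).strip()
            for i, v in zip(ids, col)
            if pd.notna(v) and str(v).strip() != ""
        }

    extra_cols = [
        c for k, c in cols.items() if k not in {"id", "group", "population", "sex"}
    ]
    meta = None
    if extra_cols:
        meta = df[extra_cols].copy()
        meta.index = list(ids)
    return GroupMap(assignments, _optional("population"), _optional("sex"), meta)


def write_group_map(groups: GroupMap, path: str | Path) -> None:
    path = Path(path)
    rows = []
    for rid, g in groups.assignments.items():
        rows.append(
            {
                "id": rid,
                "group": g,
                "population": groups.population.get(rid, ""),
                "sex": groups.sex.get(rid, ""),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=_detect_sep(path), index=False)


# ---------------------------------------------------------------------------
# Newick trees


def read_newick(source: str | Path, is_string: bool = False) -> dendropy.Tree:
    """Parse a Newick tree (file path, or literal string with *is_string*).

    Underscores in labels are preserved; single-quoted labels are accepted.
    """
    try:
        if is_string:
            tree = dendropy.Tree.get(
                data=source, schema="newick", preserve_underscores=True
            )
        else:
            tree = dendropy.Tree.get(
                path=str(source), schema="newick", preserve_underscores=True
            )
    except Exception as exc:  # dendropy raises assorted error classes
        raise ParseError(f"newick parse error: {exc}") from exc
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=False,
    )


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]
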