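"""Alignment, sequence, and family-database I/O.

A protein family is a curated seed multiple sequence alignment plus an
optional per-family bit-score threshold (a Pfam-style gathering cutoff) and
an optional guide-tree file. A database is a flat TSV manifest pointing at
one alignment file per family.

Gap dialect: ``-`` and ``.`` are treated identically; both are normalized
to ``-`` on read, and residues are uppercased (Stockholm mixes case).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence as TypingSequence

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"
GAP_CHARS = frozenset("-.")
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUITY_CODES = "BZXUO"

_FORMATS = {"fasta": "fasta", "aligned-fasta": "fasta", "stockholm": "stockholm"}


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


class LookupError_(KeyError):
    """Raised when a requested id is absent from a container."""


def degap(residues: str) -> str:
    """Remove gap characters from an aligned row."""
    return "".join(c for c in residues if c not in GAP_CHARS)


@dataclass(frozen=True)
class Sequence:
    """A named amino-acid sequence (possibly aligned, i.e. with gaps)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be nonempty")

    @property
    def ungapped(self) -> str:
        return degap(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


class Alignment:
    """An ordered collection of equal-length aligned rows.

    Rows keep their input order; ids must be unique within the alignment.
    """

    def __init__(self, rows: TypingSequence[Sequence]):
        rows = list(rows)
        if not rows:
            raise FormatError("alignment must contain at least one row")
        length = len(rows[0].residues)
        ids = set()
        for row in rows:
            if len(row.residues) != length:
                raise FormatError(
                    f"ragged alignment: row {row.id!r} has length "
                    f"{len(row.residues)}, expected {length}"
                )
            if row.id in ids:
                raise FormatError(f"duplicate row id {row.id!r}")
            ids.add(row.id)
        self.rows: list[Sequence] = rows
        self.length: int = length
        self._index = {row.id: i for i, row in enumerate(rows)}

    @property
    def ids(self) -> list[str]:
        return [row.id for row in self.rows]

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def row(self, seq_id: str) -> Sequence:
        try:
            return self.rows[self._index[seq_id]]
        except KeyError:
            raise LookupError_(f"no row with id {seq_id!r}") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return [(r.id, r.residues) for r in self.rows] == [
            (r.id, r.residues) for r in other.rows
        ]

    def __repr__(self) -> str:
        return f"Alignment(n_rows={self.n_rows}, length={self.length})"


def _normalize(residues: str) -> str:
    return residues.upper().replace(".", GAP)


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read an aligned FASTA or Stockholm file.

    Row order is preserved; Stockholm annotation lines (``#=GF``, ``#=GC``,
    ...) are ignored; gaps are normalized to ``-`` and residues uppercased.
    """
    fmt = _FORMATS.get(format.lower())
    if fmt is None:
        raise ValueError(f"unknown alignment format {format!r}")
    path = Path(path)
    try:
        bio_aln = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise FormatError(f"cannot parse {path} as {format}: {exc}") from exc
    rows = [Sequence(rec.id, _normalize(str(rec.seq))) for rec in bio_aln]
    return Alignment(rows)


def write_alignment(aln: Alignment, path: str | Path, format: str = "fasta") -> None:
    """Write an alignment as aligned FASTA or Stockholm."""
    fmt = _FORMATS.get(format.lower())
    if fmt is None:
        raise ValueError(f"unknown alignment format {format!r}")
    records = [
        SeqRecord(Seq(row.residues), id=row.id, description="") for row in aln.rows
    ]
    AlignIO.write(MultipleSeqAlignment(records), str(path), fmt)


def read_sequences(path: str | Path) -> list[Sequence]:
    """Read (possibly unaligned) query sequences from FASTA."""
    from Bio import SeqIO

    seqs = [
        Sequence(rec.id, _normalize(str(rec.seq)))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not seqs:
        raise FormatError(f"no sequences found in {path}")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise FormatError(f"duplicate sequence ids in {path}")
    return seqs


def write_sequences(seqs: Iterable[Sequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq in seqs:
            fh.write(f">{seq.id}\n{seq.residues}\n")


def induced_alignment(aln: Alignment, subset: Iterable[str]) -> Alignment:
    """Restrict an alignment to a subset of its rows.

    Rows keep their original order; columns that are gaps in every retained
    row are removed; all other columns are untouched, so de-gapping a
    retained row yields exactly the original de-gapped row.
    """
    subset = set(subset)
    if not subset:
        raise ValueError("subset must be nonempty")
    unknown = subset - set(aln.ids)
    if unknown:
        raise LookupError_(f"unknown ids in subset: {sorted(unknown)}")
    kept = [row for row in aln.rows if row.id in subset]
    keep_col = [
        any(row.residues[c] not in GAP_CHARS for row in kept)
        for c in range(aln.length)
    ]
    rows = [
        Sequence(row.id, "".join(row.residues[c] for c in range(aln.length) if keep_col[c]))
        for row in kept
    ]
    return Alignment(rows)


@dataclass
class FamilyRecord:
    """One protein family: id, seed alignment, gathering cutoff, optional tree."""

    family_id: str
    seed: Alignment
    threshold: float = 0.0
    guide_tree_path: str | None = None

    def __post_init__(self) -> None:
        if not self.family_id:
            raise ValueError("family_id must be nonempty")
        t = float(self.threshold)
        if not (t == t and abs(t) != float("inf")):
            raise ValueError("threshold must be finite")
        if t < 0:
            raise ValueError("threshold must be >= 0")


@dataclass
class FamilyDatabase:
    """A collection of protein families with unique ids."""

    families: list[FamilyRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.families:
            raise ValueError("database must contain at least one family")
        ids = [f.family_id for f in self.families]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate family ids: {dupes}")

    @property
    def k(self) -> int:
        return len(self.families)

    def family(self, family_id: str) -> FamilyRecord:
        for fam in self.families:
            if fam.family_id == family_id:
                return fam
        raise LookupError_(f"no family {family_id!r}")

    def __iter__(self):
        return iter(self.families)


def load_family_database(manifest_path: str | Path) -> FamilyDatabase:
    """Load a family database from a TSV manifest.

    One row per family: ``family_id<TAB>alignment_path[<TAB>tree_path[<TAB>threshold]]``.
    Relative paths are resolved against the manifest's directory. An empty
    tree field means no tree; a missing/empty threshold defaults to 0.
    Lines starting with ``#`` are comments. Alignment format is inferred
    from the extension (``.sto``/``.stk``/``.stockholm`` → Stockholm,
    otherwise aligned FASTA).
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    families: list[FamilyRecord] = []
    seen: set[str] = set()
    with open(manifest_path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(
                    f"{manifest_path}:{lineno}: expected at least 2 tab-separated fields"
                )
            fid = parts[0].strip()
            if fid in seen:
                raise FormatError(f"{manifest_path}:{lineno}: duplicate family_id {fid!r}")
            seen.add(fid)
            aln_path = base / parts[1].strip()
            fmt = (
                "stockholm"
                if aln_path.suffix.lower() in {".sto", ".stk", ".stockholm"}
                else "fasta"
            )
            try:
                seed = read_alignment(aln_path, fmt)
            except (OSError, FormatError) as exc:
                raise FormatError(f"family {fid!r}: cannot read alignment: {exc}") from exc
            tree_path = None
            if len(parts) >= 3 and parts[2].strip():
                tree_path = str(base / parts[2].strip())
            threshold = 0.0
            if len(parts) >= 4 and parts[3].strip():
                threshold = float(parts[3])
            families.append(
                FamilyRecord(fid, seed, threshold=threshold, guide_tree_path=tree_path)
            )
    return FamilyDatabase(families)


def write_manifest(
    entries: list[tuple[str, str, str | None, float | None]], path: str | Path
) -> None:
    """Write a family-database manifest (paths as given, typically relative)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for fid, aln_path, tree_path, threshold in entries:
            writer.writerow(
                [fid, aln_path, tree_path or "", "" if threshold is None else threshold]
            )
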