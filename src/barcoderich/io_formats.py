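"""File formats and the core sample/alignment data model.

The pipeline exchanges four plain-text formats: aligned FASTA (one file per
locus), a delimited sample metadata table (comma or tab, sniffed), newick
trees, and delimited report tables.  This module owns the first three plus the
two central record types, :class:`SampleRecord` and :class:`LocusAlignment`.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, FormatError

STATUS_OK = "ok"
STATUS_FAIL = "fail"
STATUS_ERROR = "error"
VALID_STATUSES = frozenset({STATUS_OK, STATUS_FAIL, STATUS_ERROR})

#: IUPAC nucleotide codes plus alignment gap.
ALPHABET = frozenset("ACGTRYSWKMBDHVN-")

_CODE_TABLE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE_TABLE[ord(_b)] = _i
_DECODE = np.array(list("ACGT"), dtype="U1")


@dataclass(frozen=True)
class SampleRecord:
    """One stem from a plot survey.

    ``species_label`` is the ground-truth identification; it is ``None`` in
    unknown-flora mode.  ``locus_status`` maps each locus id to one of
    ``ok`` (usable sequence), ``fail`` (no sequence recovered) or ``error``
    (a sequence exists but is flagged as contamination).
    """

    sample_id: str
    plot_id: str
    species_label: Optional[str]
    locus_status: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise FormatError("sample_id must be non-empty")
        for locus, status in self.locus_status.items():
            if status not in VALID_STATUSES:
                raise FormatError(
                    f"unknown status {status!r} for sample {self.sample_id!r} "
                    f"at locus {locus!r}; expected one of {sorted(VALID_STATUSES)}"
                )


@dataclass(frozen=True)
class LocusAlignment:
    """An aligned nucleotide matrix for one locus (or a concatenation).

    ``binary_chars`` optionally carries appended presence/absence indel
    characters (strings over ``0``/``1``/``?``, one per sample).
    ``column_indices`` records, for filtered alignments, the original column
    index of each retained column.  ``boundaries`` records, for concatenated
    alignments, half-open ``(locus_id, start, end)`` spans.
    """

    locus_id: str
    sample_ids: tuple[str, ...]
    rows: tuple[str, ...]
    binary_chars: Optional[tuple[str, ...]] = None
    column_indices: Optional[tuple[int, ...]] = None
    boundaries: Optional[tuple[tuple[str, int, int], ...]] = None
    warnings: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.rows):
            raise AlignmentError("sample_ids and rows differ in count")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError(f"duplicate sample ids in locus {self.locus_id!r}")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise AlignmentError(
                f"unequal row lengths in locus {self.locus_id!r}: {sorted(lengths)}"
            )
        bad = set("".join(self.rows)) - ALPHABET
        if bad:
            raise AlignmentError(
                f"invalid characters in locus {self.locus_id!r}: {sorted(bad)}"
            )
        if self.binary_chars is not None:
            if len(self.binary_chars) != len(self.rows):
                raise AlignmentError("binary_chars count does not match rows")
            blens = {len(b) for b in self.binary_chars}
            if len(blens) > 1:
                raise AlignmentError("binary_chars columns differ across rows")
            if set("".join(self.binary_chars)) - set("01?"):
                raise AlignmentError("binary_chars must be over 0/1/?")
        if self.column_indices is not None and self.rows:
            if len(self.column_indices) != len(self.rows[0]):
                raise AlignmentError("column_indices length mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, sample_id: str) -> str:
        try:
            return self.rows[self.sample_ids.index(sample_id)]
        except ValueError:
            raise KeyError(sample_id) from None

    def binary_row(self, sample_id: str) -> Optional[str]:
        if self.binary_chars is None:
            return None
        return self.binary_chars[self.sample_ids.index(sample_id)]

    def encode(self) -> np.ndarray:
        """Integer-code the matrix: A/C/G/T -> 0..3, anything else -> -1."""
        if not self.rows:
            return np.empty((0, 0), dtype=np.int8)
        buf = np.frombuffer("".join(self.rows).encode("ascii"), dtype=np.uint8)
        return _CODE_TABLE[buf].reshape(self.n_samples, self.n_columns)

    def subset(self, sample_ids: Sequence[str]) -> "LocusAlignment":
        """Restrict to the given samples, preserving the requested order."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"samples not in alignment: {missing}")
        rows = tuple(self.rows[index[s]] for s in sample_ids)
        binary = (
            tuple(self.binary_chars[index[s]] for s in sample_ids)
            if self.binary_chars is not None
            else None
        )
        return replace(
            self, sample_ids=tuple(sample_ids), rows=rows, binary_chars=binary
        )

    def with_rows(self, rows: Iterable[str]) -> "LocusAlignment":
        return replace(self, rows=tuple(rows))


def decode(codes: np.ndarray) -> tuple[str, ...]:
    """Inverse of :meth:`LocusAlignment.encode` for clean (0..3) matrices."""
    if np.any(codes < 0):
        raise AlignmentError("cannot decode codes containing missing states")
    return tuple("".join(r) for r in _DECODE[codes])


def read_fasta(path: str | Path, locus_id: str, allow_empty: bool = False) -> LocusAlignment:
    """Read one locus alignment from an aligned FASTA file.

    Lowercase bases are normalized to uppercase; rows must already be equal
    length (inputs are pre-aligned).  ``allow_empty`` admits record-less files
    (a locus that failed for every sample) as empty alignments.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        if allow_empty:
            return LocusAlignment(locus_id=locus_id, sample_ids=(), rows=())
        raise FormatError(f"no FASTA records in {path}")
    ids = []
    rows = []
    for rec in records:
        if rec.id in ids:
            raise FormatError(f"duplicate id {rec.id!r} in {path}")
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    return LocusAlignment(locus_id=locus_id, sample_ids=tuple(ids), rows=tuple(rows))


def write_fasta(alignment: LocusAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(alignment.sample_ids, alignment.rows)
    ]
    SeqIO.write(records, str(path), "fasta")


_RESERVED_COLUMNS = ("sample_id", "plot_id", "species_label")


def read_metadata(path: str | Path) -> list[SampleRecord]:
    """Read the sample metadata table (CSV or TSV, sniffed).

    Expected header: ``sample_id``, ``plot_id``, optional ``species_label``,
    then one status column per locus.  A missing ``species_label`` column
    puts the survey in unknown-flora mode (labels ``None``).
    """
    text = Path(path).read_text()
    if not text.strip():
        raise FormatError(f"empty metadata file {path}")
    delimiter = "\t" if "\t" in text.splitlines()[0] else ","
    reader = csv.DictReader(io.StringIO(text), delimiter=delimiter)
    if reader.fieldnames is None or "sample_id" not in reader.fieldnames:
        raise FormatError(f"metadata {path} lacks a sample_id column")
    has_labels = "species_label" in reader.fieldnames
    locus_cols = [c for c in reader.fieldnames if c not in _RESERVED_COLUMNS]
    records = []
    seen: set[str] = set()
    for row in reader:
        sid = (row.get("sample_id") or "").strip()
        if not sid:
            raise FormatError(f"metadata {path}: row with missing sample_id")
        if sid in seen:
            raise FormatError(f"metadata {path}: duplicate sample_id {sid!r}")
        seen.add(sid)
        label = row.get("species_label") if has_labels else None
        records.append(
            SampleRecord(
                sample_id=sid,
                plot_id=(row.get("plot_id") or "").strip(),
                species_label=label.strip() if label else None,
                locus_status={c: (row[c] or "").strip() for c in locus_cols},
            )
        )
    return records


def write_metadata(records: Sequence[SampleRecord], path: str | Path) -> None:
    loci: list[str] = []
    for rec in records:
        for locus in rec.locus_status:
            if locus not in loci:
                loci.append(locus)
    has_labels = any(r.species_label is not None for r in records)
    header = ["sample_id", "plot_id"] + (["species_label"] if has_labels else [])
    header += loci
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for rec in records:
            row = [rec.sample_id, rec.plot_id]
            if has_labels:
                row.append(rec.species_label or "")
            row += [rec.locus_status.get(locus, STATUS_FAIL) for locus in loci]
            writer.writerow(row)


def _format_length(value: float) -> str:
    return f"{value:.10g}"


def _format_support(value: float) -> str:
    return f"{value:g}"


def tree_to_newick(tree) -> str:
    """Serialize a :class:`~barcoderich.njtree.BarcodeTree` to newick.

    Bootstrap supports, when present, are written as internal node labels.
    """

    def render(node) -> str:
        if not node.children:
            return f"{node.name}:{_format_length(node.length or 0.0)}"
        inner = ",".join(render(c) for c in node.children)
        label = _format_support(node.support) if node.support is not None else ""
        if node is tree.root:
            return f"({inner}){label}"
        return f"({inner}){label}:{_format_length(node.length or 0.0)}"

    return render(tree.root) + ";"


def write_newick(tree, path: str | Path) -> None:
    """Write a tree (with branch lengths, and supports if set) as newick."""
    try:
        Path(path).write_text(tree_to_newick(tree) + "\n")
    except OSError as exc:  # pragma: no cover - environment dependent
        raise FormatError(f"cannot write newick to {path}: {exc}") from exc


def read_newick(path: str | Path):
    """Read a newick tree back into a :class:`BarcodeTree` (via dendropy)."""
    import dendropy

    from .njtree import BarcodeTree, Node

    dtree = dendropy.Tree.get(path=str(path), schema="newick")

    def convert(dnode) -> Node:
        children = [convert(c) for c in dnode.child_nodes()]
        name = dnode.taxon.label.replace(" ", "_") if dnode.taxon else None
        support = None
        if children and dnode.label:
            try:
                support = float(dnode.label)
            except ValueError:
                name = dnode.label
        length = dnode.edge.length if dnode.edge.length is not None else 0.0
        node = Node(name=name, length=length, support=support)
        for child in children:
            node.add_child(child)
        return node

    root = convert(dtree.seed_node)
    root.length = None
    return BarcodeTree(root)
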