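"""Multi-locus concatenation, simple indel coding, inversion normalization.

Concatenation keeps only samples that yielded a sequence at every locus
(single-locus samples skew monophyly when conspecific sampling is dense).
Indel coding follows the simple presence/absence scheme: one binary character
per distinct gap extent, with gaps subsumed by a longer gap scored missing.
Inversion normalization undoes short reverse-complement segments carried by a
minority of rows; it is opt-in, never a silent default.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .errors import InputError
from .io_formats import LocusAlignment

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(segment: str) -> str:
    return segment.translate(_COMPLEMENT)[::-1]


def concatenate(alignments: Sequence[LocusAlignment]) -> LocusAlignment:
    """Join loci over the intersection of their sample sets.

    Sample order follows the first alignment.  An empty intersection yields a
    zero-sample alignment carrying a degenerate warning rather than an error,
    so the caller can record the outcome per analysis.
    """
    if len(alignments) < 2:
        raise InputError("concatenation needs at least 2 locus alignments")
    shared = set(alignments[0].sample_ids)
    for aln in alignments[1:]:
        shared &= set(aln.sample_ids)
    ordered = tuple(s for s in alignments[0].sample_ids if s in shared)
    locus_id = "+".join(a.locus_id for a in alignments)
    boundaries = []
    offset = 0
    for aln in alignments:
        boundaries.append((aln.locus_id, offset, offset + aln.n_columns))
        offset += aln.n_columns
    warnings: tuple[str, ...] = ()
    if not ordered:
        warnings = ("degenerate-alignment: empty sample intersection",)
        rows: tuple[str, ...] = ()
    else:
        parts = [a.subset(ordered) for a in alignments]
        rows = tuple("".join(p.rows[i] for p in parts) for i in range(len(ordered)))
    return LocusAlignment(
        locus_id=locus_id,
        sample_ids=ordered,
        rows=rows,
        boundaries=tuple(boundaries),
        warnings=warnings,
    )


@dataclass(frozen=True)
class IndelCharacterSet:
    """Presence/absence characters for the distinct gap extents of a locus.

    ``descriptors`` are half-open ``(start, end)`` column spans on the aligned
    locus; ``states[sample]`` is a string over ``0``/``1``/``?`` with one
    position per descriptor.
    """

    descriptors: tuple[tuple[int, int], ...]
    states: Mapping[str, str]

    @property
    def n_characters(self) -> int:
        return len(self.descriptors)


def _gap_runs(row: str) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, ch in enumerate(row):
        if ch == "-":
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(row)))
    return runs


def simple_indel_coding(alignment: LocusAlignment) -> IndelCharacterSet:
    """Code each distinct gap extent as one binary character.

    A sample scores ``1`` when its row has a gap exactly over the descriptor
    span (non-gap flanks), ``?`` when one of its gaps strictly subsumes the
    span, and ``0`` otherwise.  Gap-free alignments yield an empty set.
    """
    runs_per_sample = {
        sid: _gap_runs(row) for sid, row in zip(alignment.sample_ids, alignment.rows)
    }
    descriptors = sorted({run for runs in runs_per_sample.values() for run in runs})
    states = {}
    for sid in alignment.sample_ids:
        runs = runs_per_sample[sid]
        chars = []
        for start, end in descriptors:
            state = "0"
            for s, e in runs:
                if (s, e) == (start, end):
                    state = "1"
                    break
                if s <= start and end <= e:
                    state = "?"
                    break
            chars.append(state)
        states[sid] = "".join(chars)
    return IndelCharacterSet(descriptors=tuple(descriptors), states=states)


def append_indel_characters(
    alignment: LocusAlignment, characters: IndelCharacterSet
) -> LocusAlignment:
    """Attach the coded characters to the alignment as ``binary_chars``."""
    binary = tuple(characters.states[sid] for sid in alignment.sample_ids)
    return replace(alignment, binary_chars=binary)


@dataclass(frozen=True)
class InversionEvent:
    start: int
    end: int
    samples: tuple[str, ...]
    consensus: str
    inverted: str


def detect_and_normalize_inversions(
    alignment: LocusAlignment,
    min_len: int = 4,
    max_len: int = 30,
    flank: int = 4,
) -> tuple[LocusAlignment, tuple[InversionEvent, ...]]:
    """Find and undo short reverse-complement segments in a minority of rows.

    A window is an inversion when a minority of rows carry exactly the
    reverse complement of the majority's window while both groups agree on
    the flanking columns.  Detected minority rows are reverse-complemented in
    place over the window.  Palindromic windows (their own reverse
    complement) are indistinguishable and left alone.  Zero detections is a
    valid outcome.
    """
    if not (4 <= min_len <= max_len <= 30):
        raise InputError("require 4 <= min_len <= max_len <= 30")
    rows = list(alignment.rows)
    n, L = len(rows), alignment.n_columns
    events: list[InversionEvent] = []
    if n < 2:
        return alignment, ()
    for width in range(max_len, min_len - 1, -1):
        for start in range(0, L - width + 1):
            end = start + width
            slices = [row[start:end] for row in rows]
            counter = Counter(slices)
            consensus, n_major = counter.most_common(1)[0]
            if set(consensus) - set("ACGT"):
                continue
            flipped = reverse_complement(consensus)
            if flipped == consensus:
                continue
            n_minor = counter.get(flipped, 0)
            if n_minor == 0 or n_minor >= n_major:
                continue
            lo, hi = max(0, start - flank), min(L, end + flank)
            major_rows = [i for i, s in enumerate(slices) if s == consensus]
            minor_rows = [i for i, s in enumerate(slices) if s == flipped]
            left = Counter(rows[i][lo:start] for i in major_rows).most_common(1)[0][0]
            right = Counter(rows[i][end:hi] for i in major_rows).most_common(1)[0][0]
            if any(rows[i][lo:start] != left or rows[i][end:hi] != right
                   for i in minor_rows):
                continue
            for i in minor_rows:
                rows[i] = rows[i][:start] + consensus + rows[i][end:]
            events.append(
                InversionEvent(
                    start=start,
                    end=end,
                    samples=tuple(alignment.sample_ids[i] for i in minor_rows),
                    consensus=consensus,
                    inverted=flipped,
                )
            )
    return alignment.with_rows(rows), tuple(events)
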