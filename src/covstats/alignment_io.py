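"""Streaming access to coordinate-sorted SAM/BAM alignment files.

Records are normalized into :class:`AlignmentRecord` objects and yielded in
file order, grouped by reference contig. Coordinates are converted to
0-based, half-open at parse time. Secondary (0x100) and supplementary
(0x800) records are skipped so that each sequenced read contributes at most
one primary record to coverage and read counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import pysam

#: CIGAR operation characters indexed by the numeric codes used in BAM.
CIGAR_OPS = "MIDNSHP=X"

#: Operations that consume reference positions.
REF_CONSUMING = frozenset("MDN=X")

#: Operations that consume query (read) bases.
QUERY_CONSUMING = frozenset("MIS=X")


class UnsortedInputError(RuntimeError):
    """Input alignments are not sorted by reference position."""


class InvalidHeaderError(RuntimeError):
    """SAM/BAM header is missing or malformed."""


@dataclass(frozen=True)
class AlignmentRecord:
    """One primary alignment line, normalized.

    ``reference_start`` is 0-based. ``cigar`` is a tuple of
    ``(op_char, length)`` pairs. ``read_length`` is the query length
    including soft clips but excluding hard clips. ``edit_distance`` is the
    NM tag value, or ``None`` when the tag is absent.
    """

    query_name: str
    is_paired: bool
    is_proper_pair: bool
    is_unmapped: bool
    is_secondary: bool
    is_supplementary: bool
    is_first_in_pair: bool
    mate_is_unmapped: bool
    reference_name: Optional[str]
    reference_start: int
    cigar: tuple[tuple[str, int], ...]
    edit_distance: Optional[int]
    read_length: int

    def reference_span(self) -> int:
        """Number of reference bases consumed by the alignment."""
        return sum(n for op, n in self.cigar if op in REF_CONSUMING)


@dataclass
class SampleReadCounts:
    """Running read-count bookkeeping for one alignment file.

    ``total_reads`` counts primary records only (mapped or not) — the
    library-size denominator for relative abundance. ``passing_filters`` is
    updated downstream by the filtering stage.
    """

    total_records: int = 0
    total_reads: int = 0
    mapped_primary: int = 0
    passing_filters: int = 0

    def check(self) -> None:
        if not (
            self.passing_filters
            <= self.mapped_primary
            <= self.total_reads
            <= self.total_records
        ):
            raise AssertionError(f"inconsistent read counts: {self}")


def _convert(rec: pysam.AlignedSegment) -> AlignmentRecord:
    cigar: tuple[tuple[str, int], ...] = ()
    if rec.cigartuples:
        cigar = tuple((CIGAR_OPS[op], n) for op, n in rec.cigartuples)
    read_length = rec.infer_query_length()
    if read_length is None:
        seq = rec.query_sequence
        read_length = len(seq) if seq else 0
    nm: Optional[int] = None
    if rec.has_tag("NM"):
        nm = int(rec.get_tag("NM"))
    return AlignmentRecord(
        query_name=rec.query_name or "",
        is_paired=rec.is_paired,
        is_proper_pair=rec.is_proper_pair,
        is_unmapped=rec.is_unmapped,
        is_secondary=rec.is_secondary,
        is_supplementary=rec.is_supplementary,
        is_first_in_pair=rec.is_read1,
        mate_is_unmapped=rec.mate_is_unmapped if rec.is_paired else False,
        reference_name=rec.reference_name,
        reference_start=rec.reference_start if not rec.is_unmapped else -1,
        cigar=cigar,
        edit_distance=nm,
        read_length=read_length,
    )


def reference_dictionary(path: str | Path) -> dict[str, int]:
    """Ordered map of reference name -> length from the @SQ header lines.

    Raises :class:`InvalidHeaderError` when no @SQ lines are present or a
    length is non-positive.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        names = list(fh.references)
        lengths = list(fh.lengths)
    if not names:
        raise InvalidHeaderError(f"{path}: no @SQ lines in header")
    refs: dict[str, int] = {}
    for name, length in zip(names, lengths):
        if length <= 0:
            raise InvalidHeaderError(
                f"{path}: reference {name!r} has non-positive length {length}"
            )
        refs[name] = length
    return refs


def stream_alignments(
    path: str | Path,
    counts: Optional[SampleReadCounts] = None,
) -> Iterator[AlignmentRecord]:
    """Yield primary records from a coordinate-sorted SAM/BAM in file order.

    Unmapped primary records are yielded too (callers skip them for
    coverage); secondary and supplementary records are counted in
    ``total_records`` only. Coordinate sort order is validated: a record
    for a contig that was already finalized, or a backwards position within
    a contig, raises :class:`UnsortedInputError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if counts is None:
        counts = SampleReadCounts()

    seen_tids: set[int] = set()
    current_tid: Optional[int] = None
    last_pos = -1

    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for raw in fh:
            counts.total_records += 1
            if raw.is_secondary or raw.is_supplementary:
                continue
            counts.total_reads += 1
            if raw.is_unmapped:
                yield _convert(raw)
                continue
            counts.mapped_primary += 1
            tid = raw.reference_id
            if tid != current_tid:
                if tid in seen_tids:
                    raise UnsortedInputError(
                        f"{path}: record {raw.query_name!r} returns to contig "
                        f"{raw.reference_name!r} after it was finalized; "
                        "input must be coordinate-sorted"
                    )
                if current_tid is not None:
                    seen_tids.add(current_tid)
                current_tid = tid
                last_pos = -1
            if raw.reference_start < last_pos:
                raise UnsortedInputError(
                    f"{path}: record {raw.query_name!r} at "
                    f"{raw.reference_name}:{raw.reference_start + 1} is "
                    f"before the previous record (position {last_pos + 1}); "
                    "input must be coordinate-sorted"
                )
            last_pos = raw.reference_start
            yield _convert(raw)
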