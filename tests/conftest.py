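from __future__ import annotations

from pathlib import Path

import pytest

from covstats.alignment_io import AlignmentRecord


def parse_cigar(cigar: str) -> tuple[tuple[str, int], ...]:
    import re

    return tuple(
        (m.group(2), int(m.group(1)))
        for m in re.finditer(r"(\d+)([MIDNSHP=X])", cigar)
    )


def make_record(
    cigar: str = "100M",
    start: int = 0,
    nm: int | None = 0,
    name: str = "r1",
    contig: str = "c1",
    paired: bool = False,
    proper_pair: bool = False,
    first: bool = True,
    unmapped: bool = False,
    mate_unmapped: bool = False,
    read_length: int | None = None,
) -> AlignmentRecord:
    ops = parse_cigar(cigar)
    if read_length is None:
        read_length = sum(n for op, n in ops if op in "MIS=X")
    return AlignmentRecord(
        query_name=name,
        is_paired=paired,
        is_proper_pair=proper_pair,
        is_unmapped=unmapped,
        is_secondary=False,
        is_supplementary=False,
        is_first_in_pair=first,
        mate_is_unmapped=mate_unmapped,
        reference_name=None if unmapped else contig,
        reference_start=-1 if unmapped else start,
        cigar=() if unmapped else ops,
        edit_distance=nm,
        read_length=read_length,
    )


@pytest.fixture
def record_factory():
    return make_record


def write_sam(
    path: Path,
    references: list[tuple[str, int]],
    records: list[str],
    sort_order: str = "coordinate",
) -> Path:
    """Write a SAM file from raw record lines (tab-joined strings)."""
    with open(path, "w") as fh:
        fh.write(f"@HD\tVN:1.6\tSO:{sort_order}\n")
        for name, length in references:
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for line in records:
            fh.write(line + "\n")
    return path


def sam_line(
    name: str,
    flag: int,
    contig: str,
    pos1: int,
    cigar: str,
    nm: int | None = 0,
    mapq: int = 60,
    seq: str | None = None,
) -> str:
    if seq is None:
        qlen = sum(n for op, n in parse_cigar(cigar) if op in "MIS=X")
        seq = "A" * qlen if qlen else "*"
    fields = [name, str(flag), contig, str(pos1), str(mapq), cigar, "*", "0", "0", seq, "*"]
    if nm is not None:
        fields.append(f"NM:i:{nm}")
    return "\t".join(fields)


@pytest.fixture
def sam_writer(tmp_path):
    def _write(references, records, name="test.sam", sort_order="coordinate"):
        return write_sam(tmp_path / name, references, records, sort_order)

    return _write
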