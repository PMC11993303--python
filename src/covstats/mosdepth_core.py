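"""Delta-array depth computation.

The delta array for a contig of length L has L+1 integer slots. Each
covered segment [s, e) adds +1 at index s and -1 at index e; the prefix sum
of the array is the per-base depth. The extra slot means a segment ending
exactly at the contig end needs no special casing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .alignment_io import AlignmentRecord


class MalformedAlignmentError(RuntimeError):
    """An alignment extends past the end of its contig."""


@dataclass
class MosdepthArray:
    contig_name: str
    length: int
    deltas: np.ndarray  # int64, size length + 1

    def add(self, spans: Iterable[tuple[int, int]]) -> None:
        for s, e in spans:
            if s < 0 or e > self.length:
                raise MalformedAlignmentError(
                    f"span ({s}, {e}) outside contig {self.contig_name!r} "
                    f"of length {self.length}"
                )
            self.deltas[s] += 1
            self.deltas[e] -= 1


@dataclass
class DepthVector:
    contig_name: str
    depths: np.ndarray  # int64, size length


def covered_spans(
    record: AlignmentRecord, contig_length: Optional[int] = None
) -> list[tuple[int, int]]:
    """Half-open reference intervals covered by a mapped record.

    M/=/X and D consume and cover reference positions; N consumes but does
    not cover, splitting the alignment into separate spans; clips and
    insertions consume no reference.
    """
    spans: list[tuple[int, int]] = []
    pos = record.reference_start
    start: Optional[int] = None
    for op, n in record.cigar:
        if op in "M=XD":
            if start is None:
                start = pos
            pos += n
        elif op == "N":
            if start is not None:
                spans.append((start, pos))
                start = None
            pos += n
        # I, S, H, P consume no reference
    if start is not None:
        spans.append((start, pos))
    if contig_length is not None:
        for s, e in spans:
            if e > contig_length:
                raise MalformedAlignmentError(
                    f"record {record.query_name!r} covers ({s}, {e}) past the "
                    f"end of {record.reference_name!r} "
                    f"(length {contig_length})"
                )
    return spans


def build_mosdepth_array(
    spans: Iterable[tuple[int, int]], length: int, contig_name: str = ""
) -> MosdepthArray:
    """Build the delta array for one contig from covered spans."""
    arr = MosdepthArray(
        contig_name=contig_name,
        length=length,
        deltas=np.zeros(length + 1, dtype=np.int64),
    )
    arr.add(spans)
    return arr


def depth_vector(array: MosdepthArray) -> DepthVector:
    """Prefix-sum the delta array into per-base depth.

    A negative running depth indicates corrupted input and is fatal.
    """
    depths = np.cumsum(array.deltas[: array.length])
    if depths.size and depths.min() < 0:
        raise MalformedAlignmentError(
            f"negative running depth on contig {array.contig_name!r}"
        )
    return DepthVector(contig_name=array.contig_name, depths=depths)
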