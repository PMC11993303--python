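"""Alignment filtering: which records contribute to coverage.

Thresholds can be applied per record or jointly per read pair
(``pair_mode="together"``), in which case a pair contributes only when both
mates pass. All comparisons are inclusive (>=).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from .alignment_io import AlignmentRecord


class MissingEditDistanceError(RuntimeError):
    """An identity filter is active but a record lacks the NM tag."""


@dataclass
class FilterConfig:
    """Thresholds governing which alignments contribute to coverage.

    Fractional thresholds live in [0, 1]; ``None`` disables a threshold.
    """

    min_percent_identity: Optional[float] = None
    min_aligned_length: Optional[int] = None
    min_aligned_percent: Optional[float] = None
    proper_pairs_only: bool = False
    pair_mode: str = "independent"  # or "together"

    def __post_init__(self) -> None:
        for name in ("min_percent_identity", "min_aligned_percent"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be within [0, 1], got {v}")
        if self.pair_mode not in ("independent", "together"):
            raise ValueError(f"unknown pair_mode {self.pair_mode!r}")

    @property
    def any_active(self) -> bool:
        return (
            self.min_percent_identity is not None
            or self.min_aligned_length is not None
            or self.min_aligned_percent is not None
            or self.proper_pairs_only
        )


@dataclass
class FilterStats:
    """Counters maintained while filtering a stream."""

    kept: int = 0
    discarded: int = 0
    orphans: int = 0  # paired records whose mate never appeared


def aligned_length(record: AlignmentRecord) -> int:
    """Aligned bases: sum of M/=/X plus insertions; clips, D and N excluded."""
    return sum(n for op, n in record.cigar if op in "M=XI")


def percent_identity(record: AlignmentRecord) -> float:
    """Gap-inclusive identity ``1 - NM / aligned_length``."""
    if record.edit_distance is None:
        raise MissingEditDistanceError(
            f"record {record.query_name!r} on {record.reference_name} has no "
            "NM tag; cannot apply an identity filter"
        )
    alen = aligned_length(record)
    if alen == 0:
        return 0.0
    return 1.0 - record.edit_distance / alen


def passes(record: AlignmentRecord, cfg: FilterConfig) -> bool:
    """True iff every active threshold is met for this single record."""
    if cfg.proper_pairs_only and not record.is_proper_pair:
        return False
    if cfg.min_percent_identity is not None:
        if percent_identity(record) < cfg.min_percent_identity:
            return False
    alen = None
    if cfg.min_aligned_length is not None:
        alen = aligned_length(record)
        if alen < cfg.min_aligned_length:
            return False
    if cfg.min_aligned_percent is not None:
        if alen is None:
            alen = aligned_length(record)
        if record.read_length <= 0:
            return False
        if alen / record.read_length < cfg.min_aligned_percent:
            return False
    return True


def pair_filter(
    stream: Iterable[AlignmentRecord],
    cfg: FilterConfig,
    stats: Optional[FilterStats] = None,
) -> Iterator[AlignmentRecord]:
    """Filter a record stream per ``cfg``, yielding kept records.

    In "independent" mode each record is judged alone. In "together" mode
    mapped mates are matched by query name across the coordinate-sorted
    stream using a name-keyed buffer; a pair is kept only if both mates
    pass. Records whose mate is unmapped, and orphans whose mate never
    appears, fall back to independent judgment (orphans tick a warning
    counter). Unmapped records are never yielded.
    """
    if stats is None:
        stats = FilterStats()

    def judge(rec: AlignmentRecord) -> bool:
        ok = passes(rec, cfg)
        if ok:
            stats.kept += 1
        else:
            stats.discarded += 1
        return ok

    if cfg.pair_mode == "independent":
        for rec in stream:
            if rec.is_unmapped:
                continue
            if judge(rec):
                yield rec
        return

    pending: dict[str, AlignmentRecord] = {}
    for rec in stream:
        if rec.is_unmapped:
            continue
        if not rec.is_paired or rec.mate_is_unmapped:
            if judge(rec):
                yield rec
            continue
        mate = pending.get(rec.query_name)
        if mate is None or mate.is_first_in_pair == rec.is_first_in_pair:
            pending[rec.query_name] = rec
            continue
        del pending[rec.query_name]
        if passes(mate, cfg) and passes(rec, cfg):
            stats.kept += 2
            yield mate
            yield rec
        else:
            stats.discarded += 2
    for rec in pending.values():
        stats.orphans += 1
        if judge(rec):
            yield rec
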