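"""Per-reference coverage statistics from a depth vector and read counts.

All depth-based metrics operate on the "effective region" of a contig: the
interval remaining after excluding ``end_exclusion`` bases (default 75)
from each end. Contigs no longer than twice the exclusion have an empty
effective region and report 0 for depth-based metrics; count-based metrics
(count, reads_per_base, rpkm, tpm) always use the full length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

DEFAULT_END_EXCLUSION = 75
DEFAULT_TRIM = 0.05
METABAT_MIN_IDENTITY = 0.97


@dataclass
class ContigMetricInputs:
    depths: np.ndarray  # per-base depth over the full contig
    read_count: int
    contig_length: int
    end_exclusion: int = DEFAULT_END_EXCLUSION
    trim_lower: float = DEFAULT_TRIM
    trim_upper: float = DEFAULT_TRIM

    def __post_init__(self) -> None:
        if self.end_exclusion < 0:
            raise ValueError("end_exclusion must be >= 0")
        if self.trim_lower < 0 or self.trim_upper < 0:
            raise ValueError("trim fractions must be >= 0")
        if self.trim_lower + self.trim_upper >= 1:
            raise ValueError("trim_lower + trim_upper must be < 1")

    def effective_depths(self) -> np.ndarray:
        s, e = effective_region(self.contig_length, self.end_exclusion)
        return self.depths[s:e]


def effective_region(length: int, end_exclusion: int) -> tuple[int, int]:
    """Half-open interval left after excluding both contig ends."""
    if length > 2 * end_exclusion:
        return end_exclusion, length - end_exclusion
    return 0, 0


def mean_coverage(inputs: ContigMetricInputs) -> float:
    d = inputs.effective_depths()
    if d.size == 0:
        return 0.0
    return float(d.sum()) / d.size


def trimmed_mean_of(depths: np.ndarray, trim_lower: float, trim_upper: float) -> float:
    """Mean after discarding floor(trim*n) lowest and highest values."""
    n = depths.size
    if n == 0:
        return 0.0
    lo = int(np.floor(trim_lower * n))
    hi = int(np.floor(trim_upper * n))
    kept = np.sort(depths, kind="stable")[lo : n - hi]
    if kept.size == 0:
        return 0.0
    return float(kept.sum()) / kept.size


def trimmed_mean(inputs: ContigMetricInputs) -> float:
    return trimmed_mean_of(
        inputs.effective_depths(), inputs.trim_lower, inputs.trim_upper
    )


def variance_of(depths: np.ndarray) -> float:
    """Sample variance (n-1 denominator); 0 for fewer than two values."""
    if depths.size < 2:
        return 0.0
    return float(np.var(depths, ddof=1))


def coverage_variance(inputs: ContigMetricInputs) -> float:
    return variance_of(inputs.effective_depths())


def covered_stats(inputs: ContigMetricInputs) -> tuple[int, float]:
    """(covered_bases, covered_fraction) over the effective region."""
    d = inputs.effective_depths()
    if d.size == 0:
        return 0, 0.0
    covered = int((d >= 1).sum())
    return covered, covered / d.size


def reads_per_base(count: int, length: int) -> float:
    if length <= 0:
        raise ValueError("length must be positive")
    return count / length


def rpkm(count: int, length: int, total_mapped: int) -> float:
    """Reads per kilobase of reference per million aligned reads."""
    if length <= 0:
        raise ValueError("length must be positive")
    if total_mapped == 0:
        return 0.0
    return count * 1e9 / (length * total_mapped)


def tpm(counts: Sequence[int], lengths: Sequence[int]) -> np.ndarray:
    """Length-normalized read rates rescaled to sum to 1e6.

    ``rate_i = count_i / length_i``; ``tpm_i = rate_i * 1e6 / sum(rates)``.
    All-zero counts give all-zero output.
    """
    counts_a = np.asarray(counts, dtype=float)
    lengths_a = np.asarray(lengths, dtype=float)
    if np.any(lengths_a <= 0):
        raise ValueError("lengths must be positive")
    rates = counts_a / lengths_a
    total = rates.sum()
    if total == 0:
        return np.zeros_like(rates)
    return rates * 1e6 / total


def metabat_adjusted(inputs: ContigMetricInputs) -> tuple[float, float]:
    """(depth, variance) over the end-excluded region, MetaBAT style.

    ``inputs.depths`` must already come from reads filtered at >= 0.97
    identity; this function only reduces the depth vector.
    """
    d = inputs.effective_depths()
    if d.size == 0:
        return 0.0, 0.0
    return float(d.sum()) / d.size, variance_of(d)
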