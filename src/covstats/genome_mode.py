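"""Genome-level aggregation, presence gating, and relative abundance.

Contig-level depth vectors are pooled per genome: the genome mean is the
effective-length-weighted contig mean (identical to the pooled per-base
mean), and trimmed mean, variance and covered fraction are computed over
the concatenation of all member contigs' effective-region depths.

A genome is only deemed present when at least ``min_covered_fraction``
(default 10%) of its effective length is covered by at least one read;
otherwise its coverage-type metrics are zeroed and its reads are treated
as unaligned for relative abundance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio import SeqIO

from . import metrics
from .metrics import ContigMetricInputs

logger = logging.getLogger(__name__)

DEFAULT_MIN_COVERED_FRACTION = 0.10


class GenomeDefinitionError(RuntimeError):
    """Contradictory or unusable contig-to-genome mapping."""


@dataclass
class GenomeDefinition:
    """Mapping from contig name to genome name, genome order preserved."""

    contig_to_genome: dict[str, str]
    genomes: list[str]

    def __post_init__(self) -> None:
        known = set(self.genomes)
        for contig, genome in self.contig_to_genome.items():
            if genome not in known:
                raise GenomeDefinitionError(
                    f"contig {contig!r} maps to unknown genome {genome!r}"
                )


@dataclass
class GenomeAbundanceInputs:
    mean_coverage_per_genome: dict[str, float]
    aligned_reads: int
    total_reads: int


@dataclass
class GenomePooled:
    """Pooled per-genome evidence feeding every genome-level metric."""

    genome: str
    pooled_depths: np.ndarray  # concatenated effective-region depths
    total_length: int  # sum of full contig lengths
    effective_length: int
    read_count: int


def load_genome_definition(
    fasta_files: Optional[Sequence[str | Path]] = None,
    separator: Optional[str] = None,
    definition_file: Optional[str | Path] = None,
    contig_names: Optional[Iterable[str]] = None,
) -> GenomeDefinition:
    """Build a :class:`GenomeDefinition` from exactly one convention.

    - ``fasta_files``: each FASTA's record names map to the file stem.
    - ``separator``: genome name is the contig name up to the first
      separator character (requires ``contig_names``).
    - ``definition_file``: two-column TSV of (genome, contig).
    """
    supplied = [x is not None for x in (fasta_files, separator, definition_file)]
    if sum(supplied) != 1:
        raise GenomeDefinitionError(
            "exactly one of fasta_files, separator, definition_file required"
        )

    contig_to_genome: dict[str, str] = {}
    genomes: list[str] = []

    def assign(contig: str, genome: str) -> None:
        prev = contig_to_genome.get(contig)
        if prev is not None and prev != genome:
            raise GenomeDefinitionError(
                f"contig {contig!r} claimed by both {prev!r} and {genome!r}"
            )
        contig_to_genome[contig] = genome
        if genome not in genomes:
            genomes.append(genome)

    if fasta_files is not None:
        seen_files: set[str] = set()
        for path in fasta_files:
            path = Path(path)
            stem = path.name
            for ext in (".fna", ".fa", ".fasta"):
                if stem.endswith(ext):
                    stem = stem[: -len(ext)]
                    break
            if stem in seen_files:
                raise GenomeDefinitionError(f"duplicate genome name {stem!r}")
            seen_files.add(stem)
            n = 0
            for rec in SeqIO.parse(str(path), "fasta"):
                if rec.id in contig_to_genome:
                    raise GenomeDefinitionError(
                        f"contig {rec.id!r} appears in more than one FASTA"
                    )
                assign(rec.id, stem)
                n += 1
            if n == 0:
                raise GenomeDefinitionError(f"{path}: no FASTA records")
    elif separator is not None:
        if contig_names is None:
            raise GenomeDefinitionError(
                "separator mode requires the contig names from the BAM header"
            )
        for contig in contig_names:
            genome, sep, _rest = contig.partition(separator)
            if not sep:
                raise GenomeDefinitionError(
                    f"contig {contig!r} lacks separator {separator!r}"
                )
            assign(contig, genome)
    else:
        assert definition_file is not None
        with open(definition_file) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise GenomeDefinitionError(
                        f"{definition_file}:{lineno}: expected 2 tab-separated "
                        f"columns, got {len(parts)}"
                    )
                genome, contig = parts
                if contig in contig_to_genome:
                    raise GenomeDefinitionError(
                        f"{definition_file}:{lineno}: contig {contig!r} "
                        "claimed twice"
                    )
                assign(contig, genome)

    if not contig_to_genome:
        raise GenomeDefinitionError("genome definition resolved no contigs")
    return GenomeDefinition(contig_to_genome=contig_to_genome, genomes=genomes)


def aggregate_genome(
    contig_depths: Mapping[str, np.ndarray],
    contig_counts: Mapping[str, int],
    contig_lengths: Mapping[str, int],
    definition: GenomeDefinition,
    end_exclusion: int = metrics.DEFAULT_END_EXCLUSION,
) -> dict[str, GenomePooled]:
    """Pool contig evidence into per-genome inputs.

    Contigs present in the inputs but absent from the definition are
    excluded with a warning.
    """
    pools: dict[str, GenomePooled] = {
        g: GenomePooled(g, np.zeros(0, dtype=np.int64), 0, 0, 0)
        for g in definition.genomes
    }
    chunks: dict[str, list[np.ndarray]] = {g: [] for g in definition.genomes}
    for contig, length in contig_lengths.items():
        genome = definition.contig_to_genome.get(contig)
        if genome is None:
            logger.warning(
                "contig %r is not assigned to any genome; excluded", contig
            )
            continue
        pool = pools[genome]
        pool.total_length += length
        pool.read_count += int(contig_counts.get(contig, 0))
        s, e = metrics.effective_region(length, end_exclusion)
        pool.effective_length += e - s
        depths = contig_depths.get(contig)
        if depths is not None and e > s:
            chunks[genome].append(np.asarray(depths)[s:e])
        elif e > s:
            chunks[genome].append(np.zeros(e - s, dtype=np.int64))
    for genome, pieces in chunks.items():
        if pieces:
            pools[genome].pooled_depths = np.concatenate(pieces)
    return pools


def genome_metrics(
    pool: GenomePooled,
    trim_lower: float = metrics.DEFAULT_TRIM,
    trim_upper: float = metrics.DEFAULT_TRIM,
    total_mapped: int = 0,
) -> dict[str, float]:
    """Table-level statistics for one genome from pooled evidence."""
    d = pool.pooled_depths
    eff = pool.effective_length
    covered = int((d >= 1).sum()) if d.size else 0
    mean = float(d.sum()) / eff if eff else 0.0
    return {
        "mean": mean,
        "trimmed_mean": metrics.trimmed_mean_of(d, trim_lower, trim_upper),
        "variance": metrics.variance_of(d),
        "covered_fraction": covered / eff if eff else 0.0,
        "covered_bases": covered,
        "length": pool.total_length,
        "count": pool.read_count,
        "reads_per_base": metrics.reads_per_base(pool.read_count, pool.total_length)
        if pool.total_length
        else 0.0,
        "rpkm": metrics.rpkm(pool.read_count, pool.total_length, total_mapped)
        if pool.total_length
        else 0.0,
    }


#: Metrics zeroed when a genome fails the covered-fraction gate.
GATED_METRICS = (
    "mean",
    "trimmed_mean",
    "variance",
    "rpkm",
    "tpm",
    "reads_per_base",
    "count",
)


def apply_min_covered_fraction(
    per_genome: dict[str, dict[str, float]],
    threshold: float = DEFAULT_MIN_COVERED_FRACTION,
) -> dict[str, dict[str, float]]:
    """Zero coverage-type metrics for genomes below the presence gate.

    The comparison is inclusive: ``covered_fraction >= threshold`` is
    retained. Returns a new mapping; ``covered_fraction``,
    ``covered_bases`` and ``length`` are reported as observed either way.
    """
    out: dict[str, dict[str, float]] = {}
    for genome, m in per_genome.items():
        m = dict(m)
        if m.get("covered_fraction", 0.0) < threshold:
            for key in GATED_METRICS:
                if key in m:
                    m[key] = 0 if key == "count" else 0.0
            m["_gated"] = True
        else:
            m["_gated"] = False
        out[genome] = m
    return out


def relative_abundance(
    inputs: GenomeAbundanceInputs,
) -> tuple[dict[str, float], float]:
    """Per-genome relative abundance (percent) plus the unmapped percent.

    ``RA_i = mean_i / sum_j(mean_j) * aligned/total * 100``. When no genome
    has coverage, all abundances are 0 and unmapped is 100.
    """
    if inputs.total_reads <= 0:
        raise ValueError("total_reads must be positive (empty library)")
    if inputs.aligned_reads > inputs.total_reads:
        raise ValueError("aligned_reads exceeds total_reads")
    means = inputs.mean_coverage_per_genome
    total_mean = sum(means.values())
    if total_mean == 0:
        return {g: 0.0 for g in means}, 100.0
    scale = inputs.aligned_reads / inputs.total_reads * 100.0
    ra = {g: m / total_mean * scale for g, m in means.items()}
    return ra, 100.0 - sum(ra.values())
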