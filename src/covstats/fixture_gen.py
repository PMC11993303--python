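"""Synthetic references and alignments with known per-base depth truth.

Fixtures are written as plain-text FASTA and coordinate-sorted SAM plus a
JSON truth sidecar, so every module is testable offline. The truth depth
arrays are produced by a direct per-base increment loop at generation time
— never by the delta-array engine under test.

:func:`pileup_oracle` re-reads a SAM file with its own minimal parser and
filter logic, providing the fully independent reference implementation the
engine is checked against.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

FLAG_PAIRED = 0x1
FLAG_PROPER_PAIR = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_FIRST = 0x40
FLAG_SECOND = 0x80
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


@dataclass
class ReadSpec:
    """One explicit mapped read to place in a fixture."""

    contig: str
    start: int  # 0-based
    cigar: str
    nm: int = 0
    name: Optional[str] = None
    flag_extra: int = 0  # OR-ed into the SAM flag
    mate_start: Optional[int] = None  # set on both mates for pairs


@dataclass
class SimSpec:
    """Recipe for a synthetic fixture.

    Either ``reads`` (explicit placements) or ``target_depths`` (uniform
    random placement of fixed-length perfect reads per contig) drives
    generation. ``n_unmapped`` primary unmapped records are appended.
    """

    seed: int
    contigs: list[tuple[str, int]]
    genome_map: Optional[dict[str, str]] = None
    reads: Optional[list[ReadSpec]] = None
    target_depths: Optional[dict[str, float]] = None
    read_length: int = 100
    n_unmapped: int = 0


@dataclass
class Fixture:
    """Paths plus exact truth for one generated fixture."""

    fasta_path: Path
    sam_path: Path
    truth_path: Path
    depths: dict[str, np.ndarray]  # unfiltered per-base pileup truth
    read_counts: dict[str, int]  # mapped primary reads per contig
    mapped_reads: int
    total_reads: int


def _cigar_ops(cigar: str) -> list[tuple[str, int]]:
    ops = [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(cigar)]
    if "".join(f"{n}{op}" for op, n in ops) != cigar:
        raise ValueError(f"bad CIGAR {cigar!r}")
    return ops


def _query_length(cigar: str) -> int:
    return sum(n for op, n in _cigar_ops(cigar) if op in "MIS=X")


def _reference_span(cigar: str) -> int:
    return sum(n for op, n in _cigar_ops(cigar) if op in "MDN=X")


def _pileup_add(depth: np.ndarray, start: int, cigar: str) -> None:
    # Direct per-base increments: M/=/X and D cover; N skips.
    pos = start
    for op, n in _cigar_ops(cigar):
        if op in "M=XD":
            for p in range(pos, pos + n):
                depth[p] += 1
            pos += n
        elif op == "N":
            pos += n


def generate_fixture(
    spec: SimSpec, outdir: str | Path, name: str = "fixture"
) -> Fixture:
    """Write FASTA + coordinate-sorted SAM + truth JSON for ``spec``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    lengths = dict(spec.contigs)

    reads: list[ReadSpec] = list(spec.reads or [])
    if spec.target_depths:
        for contig, depth in spec.target_depths.items():
            length = lengths[contig]
            rl = min(spec.read_length, length)
            n_reads = int(round(depth * length / rl))
            starts = rng.integers(0, length - rl + 1, size=n_reads)
            for s in starts:
                reads.append(ReadSpec(contig=contig, start=int(s), cigar=f"{rl}M"))

    for i, r in enumerate(reads):
        if r.name is None:
            r.name = f"r{i:06d}"
        span = _reference_span(r.cigar)
        if r.start < 0 or r.start + span > lengths[r.contig]:
            raise ValueError(
                f"read {r.name} ({r.cigar} at {r.contig}:{r.start}) exceeds "
                f"contig bounds (length {lengths[r.contig]})"
            )

    # truth by direct pileup, independent of the delta-array engine
    depths = {c: np.zeros(l, dtype=np.int64) for c, l in spec.contigs}
    read_counts = {c: 0 for c, _ in spec.contigs}
    for r in reads:
        _pileup_add(depths[r.contig], r.start, r.cigar)
        read_counts[r.contig] += 1

    fasta_path = outdir / f"{name}.fna"
    with open(fasta_path, "w") as fh:
        bases = np.array(list("ACGT"))
        for contig, length in spec.contigs:
            seq = "".join(rng.choice(bases, size=length))
            fh.write(f">{contig}\n{seq}\n")

    order = {c: i for i, (c, _) in enumerate(spec.contigs)}
    reads.sort(key=lambda r: (order[r.contig], r.start))

    sam_path = outdir / f"{name}.sam"
    with open(sam_path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for contig, length in spec.contigs:
            fh.write(f"@SQ\tSN:{contig}\tLN:{length}\n")
        for r in reads:
            qlen = _query_length(r.cigar)
            flag = r.flag_extra
            seq = "A" * qlen if qlen else "*"
            if flag & FLAG_PAIRED and r.mate_start is not None:
                rnext, pnext = "=", r.mate_start + 1
            else:
                rnext, pnext = "*", 0
            fh.write(
                f"{r.name}\t{flag}\t{r.contig}\t{r.start + 1}\t60\t{r.cigar}"
                f"\t{rnext}\t{pnext}\t0\t{seq}\t*\tNM:i:{r.nm}\n"
            )
        for i in range(spec.n_unmapped):
            fh.write(
                f"u{i:06d}\t{FLAG_UNMAPPED}\t*\t0\t0\t*\t*\t0\t0\t"
                f"{'A' * spec.read_length}\t*\n"
            )

    mapped = len(reads)
    total = mapped + spec.n_unmapped
    truth_path = outdir / f"{name}.truth.json"
    truth = {
        "depths": {c: depths[c].tolist() for c, _ in spec.contigs},
        "read_counts": read_counts,
        "mapped_reads": mapped,
        "total_reads": total,
        "genome_map": spec.genome_map,
    }
    truth_path.write_text(json.dumps(truth))

    return Fixture(
        fasta_path=fasta_path,
        sam_path=sam_path,
        truth_path=truth_path,
        depths=depths,
        read_counts=read_counts,
        mapped_reads=mapped,
        total_reads=total,
    )


def random_cigar(rng: np.random.Generator, max_ref_span: int) -> str:
    """Random CIGAR exercising S/I/D/N edge cases, ref span <= max_ref_span."""
    parts: list[str] = []
    if rng.random() < 0.3:
        parts.append(f"{rng.integers(1, 15)}S")
    ref_left = max_ref_span
    n_blocks = int(rng.integers(1, 4))
    for b in range(n_blocks):
        m = int(rng.integers(1, max(2, min(60, ref_left // 2 + 1))))
        m = min(m, ref_left)
        if m <= 0:
            break
        parts.append(f"{m}M")
        ref_left -= m
        if b < n_blocks - 1 and ref_left > 2:
            op = rng.choice(["I", "D", "N", ""])
            if op == "I":
                parts.append(f"{rng.integers(1, 6)}I")
            elif op in ("D", "N"):
                n = int(rng.integers(1, min(20, ref_left)))
                parts.append(f"{n}{op}")
                ref_left -= n
    while parts and parts[-1][-1] in "DNI":  # alignments must end on M
        parts.pop()
    if not any(p.endswith("M") for p in parts):
        parts = [f"{max(1, min(10, ref_left))}M"]
    if rng.random() < 0.3:
        parts.append(f"{rng.integers(1, 15)}S")
    return "".join(parts)


def random_sim_spec(
    rng: np.random.Generator,
    max_contigs: int = 3,
    max_contig_length: int = 10_000,
    max_reads: int = 500,
    pair_fraction: float = 0.3,
    max_nm: int = 5,
) -> SimSpec:
    """Randomized fixture recipe for fuzzing the engine against the oracle."""
    n_contigs = int(rng.integers(1, max_contigs + 1))
    contigs = [
        (f"c{i}", int(rng.integers(200, max_contig_length + 1)))
        for i in range(n_contigs)
    ]
    lengths = dict(contigs)
    n_reads = int(rng.integers(0, max_reads + 1))
    reads: list[ReadSpec] = []
    i = 0
    while len(reads) < n_reads:
        contig = contigs[int(rng.integers(0, n_contigs))][0]
        length = lengths[contig]
        cigar = random_cigar(rng, max_ref_span=min(150, length))
        span = _reference_span(cigar)
        start = int(rng.integers(0, length - span + 1))
        nm = int(rng.integers(0, max_nm + 1))
        if rng.random() < pair_fraction and len(reads) + 2 <= n_reads:
            cigar2 = random_cigar(rng, max_ref_span=min(150, length))
            span2 = _reference_span(cigar2)
            start2 = int(rng.integers(0, length - span2 + 1))
            name = f"p{i:06d}"
            base = FLAG_PAIRED | FLAG_PROPER_PAIR
            reads.append(
                ReadSpec(contig, start, cigar, nm, name, base | FLAG_FIRST, start2)
            )
            reads.append(
                ReadSpec(
                    contig,
                    start2,
                    cigar2,
                    int(rng.integers(0, max_nm + 1)),
                    name,
                    base | FLAG_SECOND,
                    start,
                )
            )
        else:
            reads.append(ReadSpec(contig, start, cigar, nm, f"s{i:06d}"))
        i += 1
    return SimSpec(
        seed=int(rng.integers(0, 2**31)),
        contigs=contigs,
        reads=reads,
        n_unmapped=int(rng.integers(0, 10)),
    )


# ---------------------------------------------------------------------------
# Independent oracle


def _oracle_aligned_length(ops: list[tuple[str, int]]) -> int:
    return sum(n for op, n in ops if op in "M=XI")


def _oracle_passes(rec: dict, cfg) -> bool:
    ops = rec["ops"]
    if cfg.proper_pairs_only and not rec["flag"] & FLAG_PROPER_PAIR:
        return False
    alen = _oracle_aligned_length(ops)
    if cfg.min_percent_identity is not None:
        nm = rec["nm"]
        if nm is None:
            raise RuntimeError(f"record {rec['name']} lacks NM tag")
        identity = 1.0 - nm / alen if alen else 0.0
        if identity < cfg.min_percent_identity:
            return False
    if cfg.min_aligned_length is not None and alen < cfg.min_aligned_length:
        return False
    if cfg.min_aligned_percent is not None:
        qlen = sum(n for op, n in ops if op in "MIS=X")
        if qlen == 0 or alen / qlen < cfg.min_aligned_percent:
            return False
    return True


def pileup_oracle(sam_path: str | Path, cfg=None) -> dict[str, np.ndarray]:
    """Per-contig depth arrays by brute-force per-base counting.

    Parses the SAM text directly and walks every kept alignment with a
    plain increment loop — no delta arrays, no shared code with the main
    pipeline. ``cfg`` is a ``FilterConfig`` (or ``None`` for no filtering).
    """
    from .filters import FilterConfig

    if cfg is None:
        cfg = FilterConfig()
    lengths: dict[str, int] = {}
    records: list[dict] = []
    with open(sam_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("@"):
                if line.startswith("@SQ"):
                    fields = dict(
                        f.split(":", 1) for f in line.split("\t")[1:] if ":" in f
                    )
                    lengths[fields["SN"]] = int(fields["LN"])
                continue
            f = line.split("\t")
            flag = int(f[1])
            if flag & (FLAG_SECONDARY | FLAG_SUPPLEMENTARY | FLAG_UNMAPPED):
                continue
            nm = None
            for tag in f[11:]:
                if tag.startswith("NM:i:"):
                    nm = int(tag[5:])
            records.append(
                {
                    "name": f[0],
                    "flag": flag,
                    "contig": f[2],
                    "start": int(f[3]) - 1,
                    "ops": _cigar_ops(f[5]),
                    "nm": nm,
                }
            )

    if cfg.pair_mode == "together":
        by_name: dict[str, list[dict]] = {}
        kept = []
        singles = []
        for rec in records:
            if rec["flag"] & FLAG_PAIRED and not rec["flag"] & FLAG_MATE_UNMAPPED:
                by_name.setdefault(rec["name"], []).append(rec)
            else:
                singles.append(rec)
        for name, group in by_name.items():
            firsts = [r for r in group if r["flag"] & FLAG_FIRST]
            seconds = [r for r in group if r["flag"] & FLAG_SECOND]
            if len(firsts) == 1 and len(seconds) == 1:
                if _oracle_passes(firsts[0], cfg) and _oracle_passes(
                    seconds[0], cfg
                ):
                    kept.extend(group)
            else:  # orphans judged alone
                singles.extend(group)
        kept.extend(r for r in singles if _oracle_passes(r, cfg))
    else:
        kept = [r for r in records if _oracle_passes(r, cfg)]

    depths = {c: np.zeros(l, dtype=np.int64) for c, l in lengths.items()}
    for rec in kept:
        pos = rec["start"]
        arr = depths[rec["contig"]]
        for op, n in rec["ops"]:
            if op in "M=XD":
                for p in range(pos, pos + n):
                    arr[p] += 1
                pos += n
            elif op == "N":
                pos += n
    return depths
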