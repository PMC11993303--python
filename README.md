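# covstats

Per-contig and per-genome read-coverage statistics from coordinate-sorted
SAM/BAM alignments.

`covstats` builds an integer delta array per contig (+1 where a mapped
segment starts, −1 where it ends; prefix sums give per-base depth), applies
optional per-read or per-pair alignment filters, and reduces the depth
vectors into a suite of coverage metrics. In genome mode, contigs are pooled
into genomes, a minimum-covered-fraction presence gate is applied (default:
at least 10% of the genome covered), and relative abundance is estimated as

```
RA_i = mean_i / Σ_j mean_j × aligned_reads / total_reads × 100
```

with the unaligned read fraction reported as an `unmapped` row.

## Metrics

`mean`, `trimmed_mean` (default 5% per tail), `variance` (sample variance),
`metabat` (depth/variance pair with a 97% identity pre-filter, contig mode
only), `covered_fraction`, `covered_bases`, `length`, `count`,
`reads_per_base`, `rpkm`, `tpm`, and `relative_abundance` (genome mode
only). Depth-based metrics exclude the first and last 75 bp of each contig
by default (`--contig-end-exclusion`).

## CLI

```sh
# per-contig mean coverage for two samples
covstats contig -b sample1.bam -b sample2.bam -m mean,variance -o contigs.tsv

# per-genome relative abundance, genomes named by contig prefix
covstats genome -b sample1.bam --separator '~' -o genomes.tsv

# genome membership from per-genome FASTA files, with alignment filtering
covstats genome -b sample1.bam \
    --genome-fasta-files g1.fna --genome-fasta-files g2.fna \
    --min-read-percent-identity 0.95 --pair-mode together \
    -m relative_abundance,mean,covered_fraction
```

Genome membership can be given three ways: per-genome FASTA files
(`--genome-fasta-files` / `--genome-fasta-directory`), a contig-name
separator (`--separator`), or a two-column TSV of genome and contig
(`--genome-definition`).

Inputs must be coordinate-sorted and should retain unmapped reads so the
relative-abundance denominator reflects the whole library; if they do not,
pass `--total-read-count-override`.

Filter flags: `--min-read-percent-identity`, `--min-read-aligned-length`,
`--min-read-aligned-percent`, `--proper-pairs-only`, and
`--pair-mode independent|together` (in `together` mode a pair contributes
only when both mates pass).

## Synthetic fixtures

`covstats.fixture_gen` generates seeded FASTA + coordinate-sorted SAM
fixtures with exact per-base depth truth (computed by direct pileup, not by
the engine), plus `pileup_oracle`, an independent brute-force depth
implementation used to validate the delta-array engine throughout the test
suite.

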