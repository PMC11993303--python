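import numpy as np
import pytest

from covstats import metrics
from covstats.genome_mode import (
    GenomeAbundanceInputs,
    GenomeDefinition,
    GenomeDefinitionError,
    aggregate_genome,
    apply_min_covered_fraction,
    genome_metrics,
    load_genome_definition,
    relative_abundance,
)


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
    return path


class TestLoadGenomeDefinition:
    def test_fasta_mode(self, tmp_path):
        g1 = write_fasta(tmp_path / "g1.fna", [("a", "ACGT"), ("b", "ACGT")])
        g2 = write_fasta(tmp_path / "g2.fna", [("c", "ACGT")])
        d = load_genome_definition(fasta_files=[g1, g2])
        assert d.contig_to_genome == {"a": "g1", "b": "g1", "c": "g2"}
        assert d.genomes == ["g1", "g2"]

    def test_duplicate_contig_across_fastas(self, tmp_path):
        g1 = write_fasta(tmp_path / "g1.fna", [("a", "ACGT")])
        g2 = write_fasta(tmp_path / "g2.fna", [("a", "ACGT")])
        with pytest.raises(GenomeDefinitionError, match="'a'"):
            load_genome_definition(fasta_files=[g1, g2])

    def test_separator_mode(self):
        d = load_genome_definition(separator="~", contig_names=["g1~c7", "g2~c1"])
        assert d.contig_to_genome["g1~c7"] == "g1"
        assert d.genomes == ["g1", "g2"]

    def test_separator_missing(self):
        with pytest.raises(GenomeDefinitionError, match="separator"):
            load_genome_definition(separator="~", contig_names=["plain"])

    def test_definition_file(self, tmp_path):
        f = tmp_path / "def.tsv"
        f.write_text("g1\ta\ng1\tb\ng2\tc\n")
        d = load_genome_definition(definition_file=f)
        assert d.contig_to_genome == {"a": "g1", "b": "g1", "c": "g2"}

    def test_definition_file_duplicate_contig(self, tmp_path):
        f = tmp_path / "def.tsv"
        f.write_text("g1\ta\ng2\ta\n")
        with pytest.raises(GenomeDefinitionError):
            load_genome_definition(definition_file=f)

    def test_exactly_one_convention(self, tmp_path):
        with pytest.raises(GenomeDefinitionError):
            load_genome_definition()
        with pytest.raises(GenomeDefinitionError):
            load_genome_definition(separator="~", definition_file=tmp_path / "x")


def two_contig_setup(depth_a, depth_b, length=1000, end_exclusion=75):
    definition = GenomeDefinition({"a": "g", "b": "g"}, ["g"])
    depths = {
        "a": np.full(length, depth_a, dtype=np.int64),
        "b": np.full(length, depth_b, dtype=np.int64),
    }
    counts = {"a": 10, "b": 20}
    lengths = {"a": length, "b": length}
    return aggregate_genome(depths, counts, lengths, definition, end_exclusion)


class TestAggregateGenome:
    def test_singleton_genome_equals_contig(self):
        definition = GenomeDefinition({"a": "g"}, ["g"])
        rng = np.random.default_rng(0)
        depths = {"a": rng.integers(0, 10, size=1000)}
        pools = aggregate_genome(depths, {"a": 5}, {"a": 1000}, definition, 75)
        pool = pools["g"]
        gmet = genome_metrics(pool)
        inputs = metrics.ContigMetricInputs(depths["a"], 5, 1000)
        assert gmet["mean"] == pytest.approx(metrics.mean_coverage(inputs))
        assert gmet["trimmed_mean"] == pytest.approx(metrics.trimmed_mean(inputs))
        assert gmet["variance"] == pytest.approx(metrics.coverage_variance(inputs))
        cb, cf = metrics.covered_stats(inputs)
        assert gmet["covered_bases"] == cb
        assert gmet["covered_fraction"] == pytest.approx(cf)

    def test_weighted_mean(self):
        pools = two_contig_setup(1, 3)
        assert genome_metrics(pools["g"])["mean"] == pytest.approx(2.0)

    def test_pooled_variance_positive_for_constant_contigs(self):
        pools = two_contig_setup(0, 2)
        m = genome_metrics(pools["g"])
        assert m["variance"] > 0
        # pooled oracle: 850 zeros and 850 twos
        pooled = np.array([0] * 850 + [2] * 850, dtype=float)
        assert m["variance"] == pytest.approx(np.var(pooled, ddof=1))

    def test_length_and_count_summed(self):
        pools = two_contig_setup(1, 1)
        m = genome_metrics(pools["g"])
        assert m["length"] == 2000
        assert m["count"] == 30

    def test_unassigned_contig_excluded(self, caplog):
        definition = GenomeDefinition({"a": "g"}, ["g"])
        depths = {"a": np.ones(500, dtype=np.int64), "x": np.ones(500, dtype=np.int64)}
        pools = aggregate_genome(
            depths, {"a": 1, "x": 9}, {"a": 500, "x": 500}, definition, 0
        )
        assert pools["g"].read_count == 1
        assert pools["g"].total_length == 500

    def test_zero_effective_length_genome(self):
        definition = GenomeDefinition({"a": "g"}, ["g"])
        pools = aggregate_genome(
            {"a": np.ones(100, dtype=np.int64)}, {"a": 3}, {"a": 100}, definition, 75
        )
        m = genome_metrics(pools["g"])
        assert m["mean"] == 0.0
        assert m["covered_fraction"] == 0.0

    def test_split_invariance_without_end_exclusion(self):
        # splitting a contig at an interior point leaves pooled stats unchanged
        rng = np.random.default_rng(9)
        depths = rng.integers(0, 12, size=1000)
        whole = aggregate_genome(
            {"a": depths},
            {"a": 40},
            {"a": 1000},
            GenomeDefinition({"a": "g"}, ["g"]),
            0,
        )
        for cut in (1, 137, 500, 999):
            split = aggregate_genome(
                {"a1": depths[:cut], "a2": depths[cut:]},
                {"a1": 15, "a2": 25},
                {"a1": cut, "a2": 1000 - cut},
                GenomeDefinition({"a1": "g", "a2": "g"}, ["g"]),
                0,
            )
            mw = genome_metrics(whole["g"])
            ms = genome_metrics(split["g"])
            for key in ("mean", "variance", "covered_fraction", "trimmed_mean"):
                assert ms[key] == pytest.approx(mw[key]), key


class TestMinCoveredFractionGate:
    def _metrics(self, covered_fraction):
        return {
            "g": {
                "mean": 2.0,
                "trimmed_mean": 2.0,
                "variance": 1.0,
                "covered_fraction": covered_fraction,
                "covered_bases": 10,
                "length": 100,
                "count": 5,
                "reads_per_base": 0.05,
                "rpkm": 1.0,
                "tpm": 1.0,
            }
        }

    def test_below_threshold_zeroed(self):
        out = apply_min_covered_fraction(self._metrics(0.09), 0.10)
        assert out["g"]["mean"] == 0.0
        assert out["g"]["count"] == 0
        assert out["g"]["_gated"] is True
        assert out["g"]["covered_fraction"] == 0.09  # reported as observed

    def test_boundary_inclusive(self):
        out = apply_min_covered_fraction(self._metrics(0.10), 0.10)
        assert out["g"]["mean"] == 2.0
        assert out["g"]["_gated"] is False

    def test_zero_threshold_no_change(self):
        out = apply_min_covered_fraction(self._metrics(0.001), 0.0)
        assert out["g"]["mean"] == 2.0


class TestRelativeAbundance:
    def test_worked_example(self):
        ra, unmapped = relative_abundance(
            GenomeAbundanceInputs({"A": 2.0, "B": 6.0}, 800, 1000)
        )
        assert ra["A"] == pytest.approx(20.0)
        assert ra["B"] == pytest.approx(60.0)
        assert unmapped == pytest.approx(20.0)

    def test_single_genome_all_aligned(self):
        ra, unmapped = relative_abundance(
            GenomeAbundanceInputs({"A": 3.3}, 500, 500)
        )
        assert ra["A"] == pytest.approx(100.0)
        assert unmapped == pytest.approx(0.0)

    def test_no_coverage(self):
        ra, unmapped = relative_abundance(
            GenomeAbundanceInputs({"A": 0.0, "B": 0.0}, 0, 100)
        )
        assert ra == {"A": 0.0, "B": 0.0}
        assert unmapped == 100.0

    def test_empty_library_fatal(self):
        with pytest.raises(ValueError):
            relative_abundance(GenomeAbundanceInputs({"A": 1.0}, 0, 0))

    def test_conservation(self):
        ra, unmapped = relative_abundance(
            GenomeAbundanceInputs({"A": 1.7, "B": 0.3, "C": 4.4}, 731, 1003)
        )
        assert sum(ra.values()) + unmapped == pytest.approx(100.0, abs=1e-9)

    def test_scale_invariance(self):
        base, _ = relative_abundance(
            GenomeAbundanceInputs({"A": 1.0, "B": 2.0}, 50, 100)
        )
        scaled, _ = relative_abundance(
            GenomeAbundanceInputs({"A": 17.0, "B": 34.0}, 50, 100)
        )
        for g in base:
            assert scaled[g] == pytest.approx(base[g])
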