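"""Synthetic-data generator: embedding, conservation, determinism, spikes."""

from __future__ import annotations

import filecmp
import math

import numpy as np
import pandas as pd
import pytest

from mircaste.simulate import (
    JUNK,
    SIM_ADAPTER,
    MiRNACatalog,
    MiRNAEntry,
    SimDesign,
    Spike,
    default_design,
    generate_reference,
    make_experiment,
    simulate_library,
    write_fasta,
)


class TestGenerateReference:
    def test_catalog_sequences_found_by_independent_substring_scan(self):
        genome, catalog = generate_reference(seed=2, n_mirnas=10,
                                             genome_length=10_000)
        assert len(catalog) == 10
        for entry in catalog:
            contig = genome[entry.contig]
            # independent check: exact string search, not the recorded slice
            assert contig.find(entry.sequence) >= 0
            assert (
                contig[entry.start : entry.start + len(entry.sequence)]
                == entry.sequence
            )

    def test_empty_catalog(self):
        genome, catalog = generate_reference(seed=1, n_mirnas=0,
                                             genome_length=1000)
        assert len(catalog) == 0
        assert len(genome["contig1"]) == 1000

    def test_deterministic_fasta_output(self, tmp_path):
        paths = []
        for i in (1, 2):
            genome, catalog = generate_reference(seed=1, n_mirnas=50,
                                                 genome_length=100_000)
            write_fasta(genome, tmp_path / f"g{i}.fasta")
            catalog.to_fasta(tmp_path / f"c{i}.fasta")
            paths.append(i)
        assert filecmp.cmp(tmp_path / "g1.fasta", tmp_path / "g2.fasta",
                           shallow=False)
        assert filecmp.cmp(tmp_path / "c1.fasta", tmp_path / "c2.fasta",
                           shallow=False)

    def test_impossible_packing_raises(self):
        with pytest.raises(ValueError, match="pack"):
            generate_reference(seed=1, n_mirnas=100, genome_length=1000)

    def test_unique_names_enforced(self):
        with pytest.raises(ValueError, match="unique"):
            MiRNACatalog(
                [MiRNAEntry("a", "A" * 20, "c", 0),
                 MiRNAEntry("a", "C" * 20, "c", 50)]
            )


def _two_phenotype_design(catalog, **kw):
    defaults = dict(
        phenotypes=("LW", "LQ"), replicates_per_phenotype=1,
        depth=1000, error_rate=0.0, junk_fraction=0.0, dispersion=0.0,
        seed=9,
    )
    defaults.update(kw)
    n = len(catalog)
    base = {e.name: 1.0 / n for e in catalog}
    return SimDesign(base_abundance=base, **defaults)


class TestSimulateLibrary:
    def test_noiseless_reads_round_trip_to_catalog(self, small_reference, tmp_path):
        _, catalog = small_reference
        design = _two_phenotype_design(catalog)
        path = tmp_path / "lib.fastq"
        counts = simulate_library(catalog, design, "LW", 0, path)
        sequences = set(c.sequence for c in catalog)
        lines = path.read_text().splitlines()
        reads = lines[1::4]
        assert len(reads) == 1000
        for read in reads:
            # independent structural check: insert + 4 HD bases + adapter fill
            matches = [
                s for s in sequences
                if read.startswith(s)
                and read[len(s) + 4 :]
                == SIM_ADAPTER[: len(read) - len(s) - 4]
            ]
            assert matches, f"read does not decompose: {read}"
        assert counts[JUNK] == 0

    def test_count_conservation(self, small_reference, tmp_path):
        _, catalog = small_reference
        design = _two_phenotype_design(catalog, junk_fraction=0.3,
                                       error_rate=0.01)
        counts = simulate_library(catalog, design, "LW", 0,
                                  tmp_path / "lib.fastq")
        assert sum(counts.values()) == 1000
        assert counts[JUNK] > 0

    def test_byte_identical_for_same_seed(self, small_reference, tmp_path):
        _, catalog = small_reference
        design = _two_phenotype_design(catalog, error_rate=0.01,
                                       junk_fraction=0.2)
        for i in (1, 2):
            simulate_library(catalog, design, "LQ", 0, tmp_path / f"l{i}.fastq")
        assert filecmp.cmp(tmp_path / "l1.fastq", tmp_path / "l2.fastq",
                           shallow=False)

    def test_spiked_ratio_within_binomial_sampling_error(self, tmp_path):
        # one spiked miRNA, 16-fold between LW and LQ, no dispersion/noise:
        # the true-count ratio must sit within 3 SD of 16 under the
        # multinomial sampling model (delta-method SD on the count ratio)
        genome, catalog = generate_reference(seed=21, n_mirnas=5,
                                             genome_length=2_000)
        name = catalog.names[0]
        base = {n: 0.01 for n in catalog.names}
        design = SimDesign(
            base_abundance=base, phenotypes=("LW", "LQ"),
            replicates_per_phenotype=1,
            spikes=(Spike(name, "LW", "LQ", 16.0, up="LW"),),
            depth=4_000_000, error_rate=0.0, junk_fraction=0.95,
            dispersion=0.0, seed=5,
        )
        c_up = simulate_library(catalog, design, "LW", 0,
                                tmp_path / "up.fastq")[name]
        c_dn = simulate_library(catalog, design, "LQ", 0,
                                tmp_path / "dn.fastq")[name]
        ratio = c_up / c_dn
        sd = ratio * math.sqrt(1 / c_up + 1 / c_dn)
        assert abs(ratio - 16.0) <= 3 * sd

    def test_invalid_phenotype_and_replicate(self, small_reference, tmp_path):
        _, catalog = small_reference
        design = _two_phenotype_design(catalog)
        with pytest.raises(ValueError, match="phenotype"):
            simulate_library(catalog, design, "XX", 0, tmp_path / "x.fastq")
        with pytest.raises(ValueError, match="replicate"):
            simulate_library(catalog, design, "LW", 5, tmp_path / "x.fastq")

    def test_adapter_too_short_raises(self, small_reference, tmp_path):
        _, catalog = small_reference
        design = _two_phenotype_design(catalog, adapter="TGGAATTC")
        with pytest.raises(ValueError, match="adapter"):
            simulate_library(catalog, design, "LW", 0, tmp_path / "x.fastq")


class TestMakeExperiment:
    def test_default_design_yields_16_libraries(self, tiny_run):
        exp, _, _ = tiny_run
        assert len(exp.sample_sheet) == 16
        assert len(set(exp.sample_sheet["library_id"])) == 16
        fastqs = sorted(exp.directory.glob("*.fastq"))
        assert len(fastqs) == 16

    def test_single_library_no_spikes_empty_truth(self, small_reference, tmp_path):
        _, catalog = small_reference
        design = _two_phenotype_design(catalog, phenotypes=("EW",))
        exp = make_experiment(catalog, design, tmp_path / "exp")
        assert len(exp.sample_sheet) == 1
        assert exp.truth_table.empty

    def test_same_seed_reproduces_sheet_and_truth(self, small_reference, tmp_path):
        _, catalog = small_reference
        design = default_design(catalog, seed=13, n_spiked=3, depth=2_000)
        e1 = make_experiment(catalog, design, tmp_path / "a")
        e2 = make_experiment(catalog, design, tmp_path / "b")
        pd.testing.assert_frame_equal(
            e1.sample_sheet.drop(columns="path"),
            e2.sample_sheet.drop(columns="path"),
        )
        pd.testing.assert_frame_equal(e1.truth_table, e2.truth_table)
        pd.testing.assert_frame_equal(e1.truth_counts, e2.truth_counts)

    def test_spiked_mirnas_appear_once_per_comparison(self, small_reference,
                                                      tmp_path):
        _, catalog = small_reference
        design = default_design(catalog, seed=13, n_spiked=4, depth=1_000)
        exp = make_experiment(catalog, design, tmp_path / "exp")
        assert not exp.truth_table.duplicated(["miRNA", "comparison"]).any()
        assert len(exp.truth_table) == 4

    def test_base_abundance_normalizes_with_junk(self, small_reference):
        _, catalog = small_reference
        design = _two_phenotype_design(catalog, junk_fraction=0.25)
        total = sum(design.base_abundance.values())
        assert total + design.junk_fraction == pytest.approx(1.0)

    def test_negative_abundance_rejected(self, small_reference):
        _, catalog = small_reference
        with pytest.raises(ValueError, match="nonnegative"):
            SimDesign(base_abundance={"mir-001": -0.1})
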