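"""Shared fixtures: small references and session-scoped synthetic runs."""

from __future__ import annotations

from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from mircaste import PipelineConfig, generate_reference, make_experiment, run_pipeline
from mircaste.simulate import default_design, write_fasta

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_reference():
    """20 miRNAs embedded in a 20 kb genome."""
    genome, catalog = generate_reference(seed=7, n_mirnas=20, genome_length=20_000)
    return genome, catalog


def _run_experiment(genome, catalog, design, root: Path):
    root.mkdir(parents=True, exist_ok=True)
    exp = make_experiment(catalog, design, root / "fastq")
    write_fasta(genome, root / "genome.fasta")
    catalog.to_fasta(root / "mirnas.fasta")
    cfg = PipelineConfig(
        genome_fasta=str(root / "genome.fasta"),
        mirna_fasta=str(root / "mirnas.fasta"),
        sample_sheet=str(root / "fastq" / "samples.tsv"),
        output_dir=str(root / "runs"),
        run_name="run",
    )
    return exp, cfg, run_pipeline(cfg)


@pytest.fixture(scope="session")
def noiseless_run(tmp_path_factory):
    """Error-free, junk-free 16-library experiment plus its pipeline run.

    With no sequencing errors and no junk the pipeline must recover the
    simulator's true counts read-for-read.
    """
    genome, catalog = generate_reference(seed=11, n_mirnas=30,
                                         genome_length=40_000)
    design = default_design(
        catalog, seed=11, n_spiked=0, depth=100_000,
        error_rate=0.0, junk_fraction=0.0,
    )
    root = tmp_path_factory.mktemp("noiseless")
    exp, cfg, result = _run_experiment(genome, catalog, design, root)
    return exp, result


@pytest.fixture(scope="session")
def spiked_run(tmp_path_factory):
    """The default study conditions: 60 miRNAs, 4 phenotypes x 4 replicates
    at 500k reads per library, 6 miRNAs spiked 16-fold between late-instar
    workers and queens, dispersion 0.2, junk 0.25, error rate 0.005."""
    genome, catalog = generate_reference(seed=1, n_mirnas=60,
                                         genome_length=120_000)
    design = default_design(catalog, seed=1)
    root = tmp_path_factory.mktemp("spiked")
    exp, cfg, result = _run_experiment(genome, catalog, design, root)
    return exp, result


@pytest.fixture(scope="session")
def tiny_run(tmp_path_factory):
    """A fast 16-library run for pipeline/CLI plumbing tests."""
    genome, catalog = generate_reference(seed=3, n_mirnas=12,
                                         genome_length=12_000)
    design = default_design(catalog, seed=3, n_spiked=2, depth=5_000)
    root = tmp_path_factory.mktemp("tiny")
    exp, cfg, result = _run_experiment(genome, catalog, design, root)
    return exp, cfg, result
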