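import random

import numpy as np
import pytest

import divescan as dv


@pytest.fixture
def rng():
    return random.Random(0)


@pytest.fixture
def nprng():
    return np.random.default_rng(0)


def write_fastq(path, seqs):
    """Write plain FASTQ with dummy qualities."""
    with open(path, "w") as fh:
        for i, seq in enumerate(seqs):
            fh.write(f"@r{i}\n{seq}\n+\n{'I' * len(seq)}\n")
    return path


@pytest.fixture
def fastq_writer(tmp_path):
    def _write(seqs, name="reads.fastq"):
        return write_fastq(tmp_path / name, seqs)

    return _write


def random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture(scope="session")
def active_sim_run(tmp_path_factory):
    """Full-scale active-element simulation plus pipeline run (shared).

    One 100 kb genome with a 1.5 kb element; 10 genomes each with 20 fresh
    insertions (MIR 0.001); 150 bp reads at 30X with 0.1% error.
    """
    cfg = dv.SimConfig(
        genome_len=100_000, element_len=1_500, activity=20, n_genomes=10,
        mir=0.001, coverage=30.0, read_len=150, error_rate=0.001, seed=1,
    )
    sim = dv.simulate_active(cfg)
    fastq = tmp_path_factory.mktemp("sim") / "active.fastq"
    dv.write_fastq(sim.reads, fastq)
    result = dv.run_dive([fastq], dv.RunConfig(seed=1))
    return sim, result
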