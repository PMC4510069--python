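import pytest

from stallkit.intervals import GenomicInterval
from stallkit.annotation import Transcript
from stallkit.simulate import SimulationConfig, simulate_cohort


def gi(chrom, start, end, strand="."):
    return GenomicInterval(chrom, start, end, strand)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest simulated cohort shared across tests (read-only)."""
    config = SimulationConfig(
        n_transcripts=40, reads_per_transcript=1000, pause_fraction=0.8,
        peak_fraction=0.8, n_replicates=3, seed=11,
    )
    transcripts, chrom_length, reads, replicate_peaks, truth = simulate_cohort(config)
    return {
        "config": config,
        "transcripts": transcripts,
        "chrom_length": chrom_length,
        "reads": reads,
        "replicate_peaks": replicate_peaks,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory):
    """Simulated cohort written to disk (GTF + indexed BAM + peaks + truth)."""
    out = tmp_path_factory.mktemp("cohort")
    config = SimulationConfig(
        n_transcripts=15, reads_per_transcript=400, pause_fraction=0.7,
        peak_fraction=1.0, n_replicates=2, seed=7,
    )
    simulate_cohort(config, out)
    return out, config


@pytest.fixture
def plus_transcript():
    return Transcript("txP", "geneP", gi("chr1", 10000, 12000, "+"))


@pytest.fixture
def minus_transcript():
    return Transcript("txM", "geneM", gi("chr1", 5000, 8000, "-"))
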