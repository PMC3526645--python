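import pytest

from bitematch.qc import (
    FilteredSample,
    PipelineConfig,
    UniqueRead,
    packaged_primer_sets,
)
from bitematch.pipeline import run_full
from bitematch.simulate import SimulationConfig, generate_study

# fixed seed for the default end-to-end study used across the suite
DEFAULT_STUDY_SEED = 7


def make_sample(
    sample_id: str,
    sample_type: str,
    locus: str,
    sequences,
    participant_id: int | None = None,
    min_unique_reads: int = 10,
) -> FilteredSample:
    """FilteredSample from {sequence: frequency} or an iterable of sequences."""
    if not isinstance(sequences, dict):
        sequences = {s: 2 for s in sequences}
    uniques = tuple(
        UniqueRead(seq, freq)
        for seq, freq in sorted(sequences.items(), key=lambda kv: (-kv[1], kv[0]))
    )
    if participant_id is None:
        participant_id = int("".join(c for c in sample_id if c.isdigit()) or 1)
    return FilteredSample(
        sample_id, participant_id, sample_type, locus, uniques,
        audit={}, min_unique_reads=min_unique_reads,
    )


@pytest.fixture(scope="session")
def primer_sets():
    return packaged_primer_sets()


@pytest.fixture(scope="session")
def noise_free_study():
    """Three-participant study with the error process switched off."""
    config = SimulationConfig(
        n_participants=3,
        reads_per_sample=400,
        pooling_mode="single_locus",
        substitution_rate=0.0,
        indel_rate=0.0,
        homopolymer_extra_indel_rate=0.0,
        singleton_contaminant_rate=0.0,
        seed=101,
    )
    return generate_study(config)


@pytest.fixture(scope="session")
def default_study():
    """Default-condition study: 8 participants, pooled libraries, noise on."""
    return generate_study(SimulationConfig(seed=DEFAULT_STUDY_SEED))


@pytest.fixture(scope="session")
def default_run(default_study):
    return run_full(default_study.manifest, default_study.reads_by_sample)


@pytest.fixture()
def loose_config():
    """Relaxed thresholds for property tests on short constructed reads."""
    return PipelineConfig(
        min_raw_length=20, min_trimmed_length=5, min_quality=20,
        min_frequency=2, min_unique_reads=2,
    )
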